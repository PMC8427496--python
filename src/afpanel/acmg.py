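"""Deterministic ACMG/AMP evidence assignment, combining, and review modelling.

The engine assigns only the evidence codes that are computable from the
ingested annotation fields:

* **PVS1** — loss-of-function consequence in a gene where loss of function is
  an established disease mechanism;
* **PM2** — absent from population references, or present below an
  "extreme rarity" frequency (stricter than the reporting-rarity cutoff);
* **PP5 / BP6** — reputable-source assertion (clinical-database pathogenic /
  benign call);
* **PP3 / BP4** — in-silico predictor consensus;
* **BA1 / BS1** — population frequency too high for a rare Mendelian allele.

Codes that require segregation, functional, de-novo or allelic data
(PS1–PS4, PM1, PM3–PM6, PP1, PP2, PP4, BS2–BS4, BP1–BP3, BP5, BP7) exist in
the type system and can be asserted through a manual-override table, but
never auto-trigger.  Triggered codes are combined with the published
ACMG/AMP combining rules into the five-tier scale B < LB < VUS < LP < P,
with conflicting pathogenic and benign evidence resolved to VUS.  VUS calls
are sub-tiered into possibly-benign / uncertain / possibly-pathogenic by
in-silico consensus.  Dual-reviewer adjudication is summarised by raw
agreement and Cohen's κ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import VariantTable
from .panel import GeneRecord, PanelConfig

PATHOGENIC_CODES = (
    "PVS1", "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
)
BENIGN_CODES = (
    "BA1", "BS1", "BS2", "BS3", "BS4",
    "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)
ALL_CODES = PATHOGENIC_CODES + BENIGN_CODES

#: default evidence strength by ACMG code family
DEFAULT_STRENGTH = {
    "PVS": "very_strong", "PS": "strong", "PM": "moderate", "PP": "supporting",
    "BA": "stand_alone", "BS": "strong", "BP": "supporting",
}

TIERS = ("B", "LB", "VUS_PB", "VUS_U", "VUS_PP", "LP", "P")
#: coarse five-tier scale used by the combining rules; VUS_* collapse to VUS
TIER_ORDER = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}


def default_strength(code: str) -> str:
    family = code[:3] if code[:3] in ("PVS",) else code[:2]
    return DEFAULT_STRENGTH[family]


@dataclass(frozen=True)
class EvidenceCode:
    """One (possibly strength-modified) ACMG evidence code."""

    code: str
    strength: str = ""
    triggered: bool = True
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown ACMG code: {self.code!r}")
        if not self.strength:
            object.__setattr__(self, "strength", default_strength(self.code))

    @property
    def is_pathogenic_side(self) -> bool:
        return self.code in PATHOGENIC_CODES


@dataclass(frozen=True)
class Classification:
    tier: str
    evidence: tuple[EvidenceCode, ...] = ()

    @property
    def coarse_tier(self) -> str:
        """VUS sub-tiers collapsed onto VUS (the scale used for grouping)."""
        return "VUS" if self.tier.startswith("VUS") else self.tier


@dataclass
class EngineConfig:
    """Thresholds and toggles for automatic evidence assignment.

    ``pm2_af`` (extreme rarity for PM2) is intentionally stricter than the
    reporting-rarity cutoff used at ingest: a loss-of-function allele seen at
    modest population frequency remains reportable but does not earn PM2, and
    so lands in VUS rather than LP.
    """

    pm2_af: float = 1e-4
    ba1_af: float = 0.05
    bs1_af: float = 0.01
    pp3_frac: float = 0.75
    bp4_frac: float = 0.75
    vus_pp_frac: float = 0.75
    vus_pb_frac: float = 0.75
    min_predictors: int = 3
    pp5_enabled: bool = True


def assign_evidence(
    variant: Mapping, gene: GeneRecord, cfg: EngineConfig | None = None
) -> list[EvidenceCode]:
    """Automatic evidence codes for one annotated variant record.

    ``variant`` is any mapping with the canonical annotation fields (a
    ``VariantTable`` row works).  Codes with insufficient inputs simply do
    not trigger.
    """
    cfg = cfg or EngineConfig()
    out: list[EvidenceCode] = []
    af = variant.get("popmax_af")
    af = None if af is None or (isinstance(af, float) and np.isnan(af)) else float(af)

    if variant.get("consequence") == "lof" and gene.lof_mechanism:
        out.append(EvidenceCode("PVS1", rationale="LoF in LoF-mechanism gene"))
    if af is None or af < cfg.pm2_af:
        out.append(EvidenceCode("PM2", rationale=f"popmax {'absent' if af is None else af} < {cfg.pm2_af}"))
    if af is not None and af >= cfg.ba1_af:
        out.append(EvidenceCode("BA1", rationale=f"popmax {af} >= {cfg.ba1_af}"))
    if af is not None and af >= cfg.bs1_af:
        out.append(EvidenceCode("BS1", rationale=f"popmax {af} >= {cfg.bs1_af}"))

    assertion = variant.get("clinvar_assertion", "absent")
    if cfg.pp5_enabled:
        if assertion in ("pathogenic", "likely_pathogenic"):
            out.append(EvidenceCode("PP5", rationale=f"reputable source: {assertion}"))
        elif assertion in ("benign", "likely_benign"):
            out.append(EvidenceCode("BP6", rationale=f"reputable source: {assertion}"))

    n_del = int(variant.get("insilico_deleterious", 0) or 0)
    n_tol = int(variant.get("insilico_tolerated", 0) or 0)
    n_avail = n_del + n_tol
    if n_avail >= cfg.min_predictors:
        if n_del / n_avail >= cfg.pp3_frac:
            out.append(EvidenceCode("PP3", rationale=f"{n_del}/{n_avail} predictors deleterious"))
        elif n_tol / n_avail >= cfg.bp4_frac:
            out.append(EvidenceCode("BP4", rationale=f"{n_tol}/{n_avail} predictors tolerated"))
    return out


def _strength_counts(evidence: Iterable[EvidenceCode]):
    vs = st = mo = su = 0
    ba = bs = bp = 0
    for ev in evidence:
        if not ev.triggered:
            continue
        if ev.is_pathogenic_side:
            if ev.strength == "very_strong":
                vs += 1
            elif ev.strength == "strong":
                st += 1
            elif ev.strength == "moderate":
                mo += 1
            else:
                su += 1
        else:
            if ev.strength == "stand_alone":
                ba += 1
            elif ev.strength == "strong":
                bs += 1
            else:
                bp += 1
    return vs, st, mo, su, ba, bs, bp


def combine(evidence: Iterable[EvidenceCode]) -> str:
    """Five-tier call from triggered evidence via the ACMG/AMP combining rules.

    Conflicting pathogenic-side and benign-side rule hits resolve to VUS;
    criteria not met default to VUS.
    """
    vs, st, mo, su, ba, bs, bp = _strength_counts(evidence)

    pathogenic = (
        vs >= 2
        or (vs == 1 and (st >= 1 or mo >= 2 or (mo == 1 and su >= 1) or su >= 2))
        or st >= 2
        or (st == 1 and (mo >= 3 or (mo == 2 and su >= 2) or (mo == 1 and su >= 4)))
    )
    likely_pathogenic = (
        (vs >= 1 and mo >= 1)
        or (st >= 1 and mo >= 1)
        or (st >= 1 and su >= 2)
        or mo >= 3
        or (mo >= 2 and su >= 2)
        or (mo >= 1 and su >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_met = pathogenic or likely_pathogenic
    benign_met = benign or likely_benign
    if path_met and benign_met:
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"


def subdivide_vus(variant: Mapping, cfg: EngineConfig | None = None) -> str:
    """Sub-tier a VUS by in-silico consensus over available predictors."""
    cfg = cfg or EngineConfig()
    n_del = int(variant.get("insilico_deleterious", 0) or 0)
    n_tol = int(variant.get("insilico_tolerated", 0) or 0)
    n_avail = n_del + n_tol
    if n_avail < cfg.min_predictors:
        return "VUS_U"
    if n_del / n_avail >= cfg.vus_pp_frac:
        return "VUS_PP"
    if n_tol / n_avail >= cfg.vus_pb_frac:
        return "VUS_PB"
    return "VUS_U"


def classify_variant(
    variant: Mapping,
    gene: GeneRecord,
    cfg: EngineConfig | None = None,
    overrides: Sequence[EvidenceCode] = (),
) -> Classification:
    """assign → combine → (if VUS) sub-tier, with optional manual overrides."""
    cfg = cfg or EngineConfig()
    evidence = list(assign_evidence(variant, gene, cfg))
    for ov in overrides:
        evidence = [e for e in evidence if e.code != ov.code]
        if ov.triggered:
            evidence.append(ov)
    tier = combine(evidence)
    if tier == "VUS":
        tier = subdivide_vus(variant, cfg)
    return Classification(tier=tier, evidence=tuple(e for e in evidence if e.triggered))


def classify_table(
    table: VariantTable,
    panel: PanelConfig,
    cfg: EngineConfig | None = None,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify every record of a filtered variant table.

    Returns the records frame with ``tier`` (fine, VUS sub-tiered),
    ``coarse_tier`` and ``codes`` columns appended.  ``overrides`` is the
    manual-override table (variant_id, code, triggered, strength, rationale).
    """
    cfg = cfg or EngineConfig()
    ov_by_variant: dict[str, list[EvidenceCode]] = {}
    if overrides is not None and len(overrides):
        for row in overrides.itertuples(index=False):
            ov_by_variant.setdefault(row.variant_id, []).append(
                EvidenceCode(
                    code=row.code,
                    strength=getattr(row, "strength", "") or "",
                    triggered=bool(getattr(row, "triggered", True)),
                    rationale=str(getattr(row, "rationale", "")) or "manual override",
                )
            )
    tiers, coarse, codes = [], [], []
    for row in table.records.to_dict("records"):
        cls = classify_variant(
            row, panel.gene(row["gene"]), cfg, ov_by_variant.get(row["variant_id"], ())
        )
        tiers.append(cls.tier)
        coarse.append(cls.coarse_tier)
        codes.append(",".join(e.code for e in cls.evidence))
    out = table.records.copy()
    out["tier"] = tiers
    out["coarse_tier"] = coarse
    out["codes"] = codes
    return out


# ---------------------------------------------------------------------------
# dual-reviewer adjudication


@dataclass(frozen=True)
class ReviewDecision:
    variant_id: str
    reviewer_a_tier: str
    reviewer_b_tier: str

    @property
    def final_tier(self) -> str:
        """Consensus when reviewers agree; placeholder pending third review otherwise."""
        return self.reviewer_a_tier if not self.adjudicated_by_third else self.reviewer_b_tier

    @property
    def adjudicated_by_third(self) -> bool:
        return self.reviewer_a_tier != self.reviewer_b_tier


def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Chance-corrected agreement κ = (pₒ − pₑ)/(1 − pₑ) over two label vectors.

    pₑ uses the reviewers' marginal tier frequencies.  When both raters are
    constant and identical (pₑ = 1), κ is defined as 1.0 with a warning.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = len(a)
    po = float(np.mean(a == b))
    labels = np.union1d(a, b)
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    pe = float(pa @ pb)
    if pe >= 1.0:
        warnings.warn("both reviewers constant and identical; kappa defined as 1.0")
        return 1.0
    return (po - pe) / (1.0 - pe)


def adjudicate(decisions: Sequence[ReviewDecision]) -> tuple[float, float]:
    """(agreement %, Cohen's κ) over a set of dual-review decisions."""
    if len(decisions) < 2:
        raise ValueError("adjudication needs at least 2 review decisions")
    a = [d.reviewer_a_tier for d in decisions]
    b = [d.reviewer_b_tier for d in decisions]
    agreement_pct = 100.0 * float(np.mean(np.asarray(a) == np.asarray(b)))
    return agreement_pct, cohen_kappa(a, b)


def read_reviews(path) -> list[ReviewDecision]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ReviewDecision(r.variant_id, r.reviewer_a_tier, r.reviewer_b_tier)
        for r in df.itertuples(index=False)
    ]
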