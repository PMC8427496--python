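"""Seeded synthetic cohorts for the panel-triage pipeline.

Real early-onset-AF sequencing cohorts are access-controlled, so this module
generates stand-in cohorts with the statistical structure the analysis
assumes.  Two modes:

* :func:`generate` — a stochastic sampler.  Ages follow configurable
  age-at-diagnosis bin weights, the probability of carrying a dominant P/LP
  variant is tied to age through a logistic link with a configurable odds
  ratio per decade of earlier diagnosis, per-gene VUS counts scale linearly
  with coding-transcript length at a configurable slope, recessive carrier
  variants are drawn per gene, and a heart-failure covariate is enriched in
  dominant-variant carriers.  Used for parameter-recovery and calibration
  studies.

* :func:`paper_fixture` — a fully deterministic, constructed cohort of 1293
  participants whose pipeline outputs reproduce the published study's
  printed counts exactly (group sizes 131/812/92/258; per-age-bin group-1
  numerators 20/15/36/52/8; 141 dominant P/LP variants with TTN 38, MYH7 18,
  MYH6 10, LMNA 9, KCNQ1 8 across 34 genes; nine multi-variant carriers;
  82 HFE carriers of whom 24 carry two HFE variants; 494 TTN missense
  records removed by the reporting rule; participant-level syndrome overlap
  counts).  All annotation fields are set so the default rule engine
  reproduces each variant's intended tier.

Positions and alleles are schematic; no sequence-level realism (LD,
population structure, real coordinates) is attempted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .grouping import Participant
from .ingest import COLUMNS, VariantTable, from_frame
from .panel import PanelConfig, load_panel

#: the study's age-at-diagnosis bin counts (n = 1293)
PAPER_AGE_BIN_COUNTS = {"<30": 119, "30-39": 143, "40-49": 364, "50-59": 555, "60-65": 112}
_BIN_RANGES = {"<30": (18, 30), "30-39": (30, 40), "40-49": (40, 50), "50-59": (50, 60), "60-65": (60, 66)}

#: group-1 qualifying genes with their constructed-fixture carrier counts
FIXTURE_DOMINANT_GENES: tuple[tuple[str, int], ...] = (
    ("FHL1", 2), ("TTN", 28), ("MYH7", 18), ("MYH6", 10), ("LMNA", 9),
    ("KCNQ1", 8), ("DSP", 3), ("PKP2", 2), ("FLNC", 4), ("BAG3", 3),
    ("RBM20", 3), ("DES", 2), ("PLN", 2), ("VCL", 2), ("NEXN", 2),
    ("TCAP", 2), ("LDB3", 1), ("TNNT2", 3), ("TNNI3", 2), ("TNNC1", 1),
    ("MYBPC3", 2), ("MYL3", 1), ("ACTN2", 2), ("CSRP3", 2), ("MYPN", 1),
    ("CACNA1C", 3), ("ANK2", 1), ("SCN5A", 2), ("JPH2", 3), ("PRKAG2", 2),
    ("MYOZ2", 2), ("TRIM63", 1), ("CALR3", 1), ("RYR2", 1),
)
FIXTURE_AR_OTHER_GENES = (
    "GAA", "CASQ2", "TRDN", "SGCA", "SGCB", "SGCD", "SGCG", "FKTN", "FKRP", "DOLK",
)


@dataclass
class CohortSpec:
    """Study conditions for the stochastic sampler (defaults mirror the cohort)."""

    n: int = 1293
    age_bin_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(PAPER_AGE_BIN_COUNTS)
    )
    male_frac: float = 0.722
    dominant_prevalence: float = 0.101
    or_per_decade_true: float = 1.25
    vus_slope_true: float = 3.36
    vus_intercept_true: float = 9.0
    vus_noise_sd: float = 6.0
    recessive_rates: Mapping[str, float] = field(
        default_factory=lambda: {"HFE": 0.35, **{g: 0.005 for g in FIXTURE_AR_OTHER_GENES}}
    )
    hf_base_rate: float = 0.155
    hf_enrichment_group1: float = 2.1
    review_disagreement: float = 0.082
    seed: int = 0

    def spec_hash(self) -> str:
        blob = json.dumps(
            {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Cohort:
    """In-memory synthetic cohort: participants, raw variant records, reviews."""

    participants: list[Participant]
    variants: pd.DataFrame  # raw records in the canonical TSV dialect
    reviews: pd.DataFrame
    expected_counts: dict = field(default_factory=dict)
    spec_hash: str = ""

    def participant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.participants],
                "sex": [p.sex for p in self.participants],
                "age_dx": [p.age_dx for p in self.participants],
                "age_enroll": [p.age_enroll for p in self.participants],
                "race": [p.race for p in self.participants],
                "ethnicity": [p.ethnicity for p in self.participants],
                "hf": [p.hf for p in self.participants],
                "hf_type": [p.hf_type for p in self.participants],
                "lvef_pct": [p.lvef_pct if p.lvef_pct is not None else "." for p in self.participants],
            }
        )

    def variant_table(self, panel: PanelConfig) -> VariantTable:
        return from_frame(self.variants, panel, source="<synthetic>")


@dataclass
class FixtureManifest:
    files: dict[str, Path]
    spec_hash: str
    expected_counts: dict


def write_cohort(cohort: Cohort, out_dir: str | Path) -> FixtureManifest:
    """Write participant/variant/review TSVs; regeneration is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "participants": out / "participants.tsv",
        "variants": out / "variants.tsv",
        "reviews": out / "reviews.tsv",
        "expected_counts": out / "expected_counts.json",
    }
    cohort.participant_frame().to_csv(files["participants"], sep="\t", index=False)
    cohort.variants.to_csv(files["variants"], sep="\t", index=False)
    cohort.reviews.to_csv(files["reviews"], sep="\t", index=False)
    files["expected_counts"].write_text(json.dumps(cohort.expected_counts, indent=1))
    return FixtureManifest(files=files, spec_hash=cohort.spec_hash,
                           expected_counts=cohort.expected_counts)


def read_participants(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            Participant(
                id=r.id, sex=r.sex, age_dx=int(r.age_dx), age_enroll=int(r.age_enroll),
                race=r.race, ethnicity=r.ethnicity,
                hf=str(r.hf) in ("True", "true", "1"),
                hf_type=r.hf_type,
                lvef_pct=None if r.lvef_pct in (".", "") else float(r.lvef_pct),
            )
        )
    return out


# ---------------------------------------------------------------------------
# variant record helpers

def _record(pid: str, gene: str, vid: str, consequence: str, zygosity: str = "het",
            popmax: str = ".", clinvar: str = "absent",
            n_del: int = 0, n_tol: int = 0, n_na: int = 0) -> dict:
    return {
        "participant_id": pid, "gene": gene, "variant_id": vid,
        "consequence": consequence, "zygosity": zygosity, "popmax_af": popmax,
        "clinvar_assertion": clinvar, "insilico_deleterious": n_del,
        "insilico_tolerated": n_tol, "insilico_unavailable": n_na,
    }


def _plp(pid: str, gene: str, vid: str, zygosity: str = "het") -> dict:
    # LoF + absent from references + reputable-source pathogenic call
    # → PVS1 + PM2 + PP5 (+PP3) → P under the default engine.
    return _record(pid, gene, vid, "lof", zygosity, ".", "pathogenic", n_del=4)


def _vus(pid: str, gene: str, vid: str, pp: bool = False) -> dict:
    if gene == "TTN":
        # reportable LoF (reporting rule keeps it) at modest population
        # frequency: rare enough to retain, too common for PM2 → VUS.
        return _record(pid, gene, vid, "lof", "het", "0.0005", "absent", n_na=4)
    if pp:
        return _record(pid, gene, vid, "missense", "het", ".", "uncertain", n_del=4)
    return _record(pid, gene, vid, "missense", "het", ".", "uncertain", n_del=2, n_tol=2)


# ---------------------------------------------------------------------------
# the constructed, exact cohort


def paper_fixture(panel: PanelConfig | None = None) -> Cohort:
    """Deterministic 1293-participant cohort reproducing the printed counts."""
    panel = panel or load_panel()

    # per-group, per-bin participant counts (columns: <30, 30-39, 40-49, 50-59, 60-65)
    bins = list(PAPER_AGE_BIN_COUNTS)
    per_group_bins = {
        1: [20, 15, 36, 52, 8],
        2: [76, 90, 218, 346, 82],
        3: [10, 14, 23, 38, 7],
        4: [13, 24, 87, 119, 15],
    }
    male_per_group = {1: 89, 2: 594, 3: 66, 4: 185}
    black_per_group = {1: 3, 2: 39, 3: 0, 4: 6}
    other_race_per_group = {1: 1, 2: 5, 3: 0, 4: 1}
    hispanic_per_group = {1: 1, 2: 3, 3: 0, 4: 3}
    hf_reduced_per_group = {1: 20, 2: 59, 3: 10, 4: 17}
    hf_preserved_per_group = {1: 16, 2: 67, 3: 9, 4: 23}

    participants: list[Participant] = []
    group_members: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    pid_counter = 0
    for group in (1, 2, 3, 4):
        idx_in_group = 0
        n_group = sum(per_group_bins[group])
        n_male = male_per_group[group]
        n_black = black_per_group[group]
        n_other = other_race_per_group[group]
        n_hisp = hispanic_per_group[group]
        n_red = hf_reduced_per_group[group]
        n_pres = hf_preserved_per_group[group]
        for bin_label, count in zip(bins, per_group_bins[group]):
            lo, hi = _BIN_RANGES[bin_label]
            for j in range(count):
                pid_counter += 1
                pid = f"P{pid_counter:04d}"
                age = lo + (j % (hi - lo))
                male = idx_in_group < n_male
                # race/ethnicity assigned from the tail so they do not
                # correlate perfectly with sex
                k = n_group - 1 - idx_in_group
                race = "Black" if k < n_black else ("Other" if k < n_black + n_other else "White")
                ethnicity = "hispanic" if idx_in_group < n_hisp else "non_hispanic"
                if idx_in_group < n_red:
                    hf, hf_type, lvef = True, "reduced_ef", 35.0
                elif idx_in_group < n_red + n_pres:
                    hf, hf_type, lvef = True, "preserved_ef", 55.0
                else:
                    hf, hf_type, lvef = False, "none", 58.0
                participants.append(
                    Participant(
                        id=pid, sex="male" if male else "female", age_dx=age,
                        age_enroll=min(age + 6, 65), race=race, ethnicity=ethnicity,
                        hf=hf, hf_type=hf_type, lvef_pct=lvef,
                    )
                )
                group_members[group].append(pid)
                idx_in_group += 1

    records: list[dict] = []
    vid_counter = 0

    def next_vid() -> str:
        nonlocal vid_counter
        vid_counter += 1
        return f"chr1-{vid_counter * 100}-A-T"

    # --- group 1: 141 dominant P/LP variants in 131 carriers, 34 genes ----
    g1 = group_members[1]
    gene_seq: list[str] = []
    for gene, count in FIXTURE_DOMINANT_GENES:
        gene_seq.extend([gene] * count)
    assert len(gene_seq) == 131
    ttn_members: list[str] = []
    for pid, gene in zip(g1, gene_seq):
        zyg = "hemi" if gene == "FHL1" else "het"
        records.append(_plp(pid, gene, next_vid(), zyg))
        if gene == "TTN":
            ttn_members.append(pid)
    # nine multi-variant carriers: eight with a second TTN variant, one with two more
    for pid in ttn_members[:8]:
        records.append(_plp(pid, "TTN", next_vid()))
    records.append(_plp(ttn_members[8], "TTN", next_vid()))
    records.append(_plp(ttn_members[8], "TTN", next_vid()))

    # --- VUS: 1979 across 104 genes -------------------------------------
    vus_gene_counts: dict[str, int] = {"TTN": 98, "SCN10A": 86, "FLNC": 81, "RYR2": 66}
    other_genes = sorted(panel.symbols() - set(vus_gene_counts))[:100]
    remaining = 1979 - sum(vus_gene_counts.values())
    base, extra = divmod(remaining, len(other_genes))
    for i, gene in enumerate(other_genes):
        vus_gene_counts[gene] = base + (1 if i < extra else 0)
    assert sum(vus_gene_counts.values()) == 1979

    vus_queue: list[str] = []
    for gene in vus_gene_counts:
        vus_queue.extend([gene] * vus_gene_counts[gene])
    g2 = group_members[2]
    carriers = list(g2) + list(g1)  # every group-2 member first, then group 1
    vus_assignees: list[str] = []
    i = 0
    while len(vus_assignees) < len(vus_queue):
        vus_assignees.append(carriers[i % len(carriers)])
        i += 1
    for n, (gene, pid) in enumerate(zip(vus_queue, vus_assignees)):
        records.append(_vus(pid, gene, next_vid(), pp=(gene != "TTN" and n % 5 == 0)))

    # --- recessive P/LP: 520 in 11 genes, HFE = 452 ----------------------
    g3 = group_members[3]
    hfe_carriers = g3[:82]
    for pid in hfe_carriers:
        records.append(_plp(pid, "HFE", next_vid()))
    for pid in hfe_carriers[-24:]:  # double HFE carriers (phase unknown)
        records.append(_plp(pid, "HFE", next_vid()))
    for pid, gene in zip(g3[82:], FIXTURE_AR_OTHER_GENES):
        records.append(_plp(pid, gene, next_vid()))
    # carrier variants on group-2 members (VUS priority keeps them group 2)
    for pid in g2[:346]:
        records.append(_plp(pid, "HFE", next_vid()))
    extra_ar: list[str] = []
    for i, gene in enumerate(FIXTURE_AR_OTHER_GENES):
        extra_ar.extend([gene] * (6 if i < 8 else 5))
    assert len(extra_ar) == 58
    for pid, gene in zip(g2[346:404], extra_ar):
        records.append(_plp(pid, gene, next_vid()))

    # --- 494 TTN missense records removed by the reporting rule ----------
    all_pids = [p.id for p in participants]
    for i in range(494):
        records.append(
            _record(all_pids[i % len(all_pids)], "TTN", next_vid(), "missense",
                    clinvar="uncertain", n_del=1, n_tol=3)
        )

    variants = pd.DataFrame(records, columns=COLUMNS)

    # --- dual reviews of every P/LP and VUS-PP record --------------------
    # reviewer A holds the intended tier; reviewer B departs on every 12th
    # review, mimicking the manual re-review disagreement rate
    reviewed = [
        (r["variant_id"], "P" if r["clinvar_assertion"] == "pathogenic" else "VUS_PP")
        for r in records
        if r["clinvar_assertion"] == "pathogenic"
        or (r["insilico_deleterious"] >= 4 and r["consequence"] == "missense")
    ]
    reviews = pd.DataFrame(
        {
            "variant_id": [v for v, _ in reviewed],
            "reviewer_a_tier": [t for _, t in reviewed],
            "reviewer_b_tier": [
                ("VUS_PP" if t == "P" else "P") if i % 12 == 11 else t
                for i, (_, t) in enumerate(reviewed)
            ],
        }
    )

    expected = {
        "n": 1293,
        "group_counts": {"1": 131, "2": 812, "3": 92, "4": 258},
        "age_bin_numerators": [20, 15, 36, 52, 8],
        "age_bin_denominators": [119, 143, 364, 555, 112],
        "dominant_plp_variants": 141,
        "dominant_gene_counts": {"TTN": 38, "MYH7": 18, "MYH6": 10, "LMNA": 9, "KCNQ1": 8},
        "dominant_genes": 34,
        "multi_dominant_carriers": 9,
        "vus_total": 1979,
        "vus_genes": 104,
        "recessive_plp_variants": 520,
        "recessive_genes": 11,
        "hfe_group3_carriers": 82,
        "hfe_double_carriers": 24,
        "ttn_missense_dropped": 494,
        "syndrome_all": {"DCM": 93, "HCM": 43, "AC_ARVC": 37, "Brugada": 2, "LQTS": 12, "CPVT": 1},
        "syndrome_major": {"DCM": 69, "HCM": 27, "AC_ARVC": 5, "Brugada": 2, "LQTS": 11, "CPVT": 1},
    }
    return Cohort(
        participants=participants,
        variants=variants,
        reviews=reviews,
        expected_counts=expected,
        spec_hash="constructed-fixture",
    )


# ---------------------------------------------------------------------------
# the stochastic sampler


def generate(spec: CohortSpec, panel: PanelConfig | None = None) -> Cohort:
    """Sample a cohort from the study conditions in ``spec`` (seeded)."""
    panel = panel or load_panel()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    labels = list(spec.age_bin_weights)
    w = np.array([spec.age_bin_weights[b] for b in labels], dtype=float)
    if np.allclose(w, np.round(w)) and w.sum() == n:
        bin_counts = w.astype(int)
    else:
        bin_counts = rng.multinomial(n, w / w.sum())
    ages = []
    for label, count in zip(labels, bin_counts):
        lo, hi = _BIN_RANGES[label]
        ages.extend(rng.integers(lo, hi, size=count).tolist())
    ages = np.array(ages)
    rng.shuffle(ages)

    male = rng.random(n) < spec.male_frac

    # dominant-carrier probability through the logistic link
    beta = np.log(spec.or_per_decade_true)
    x = -ages / 10.0

    def mean_prev(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + beta * x))))) - spec.dominant_prevalence

    if spec.dominant_prevalence <= 0.0:
        p_dom = np.zeros(n)
    else:
        alpha = scipy.optimize.brentq(mean_prev, -20, 20)
        p_dom = 1.0 / (1.0 + np.exp(-(alpha + beta * x)))
    carrier = rng.random(n) < p_dom

    # heart failure enriched in carriers on the odds scale
    base_odds = spec.hf_base_rate / (1 - spec.hf_base_rate)
    odds = np.where(carrier, base_odds * spec.hf_enrichment_group1, base_odds)
    p_hf = odds / (1 + odds)
    hf = rng.random(n) < p_hf

    participants = []
    for i in range(n):
        age = int(ages[i])
        hf_type = "none"
        if hf[i]:
            hf_type = "reduced_ef" if rng.random() < 0.5 else "preserved_ef"
        participants.append(
            Participant(
                id=f"S{i + 1:05d}",
                sex="male" if male[i] else "female",
                age_dx=age,
                age_enroll=min(age + int(rng.integers(0, 8)), 65),
                race="White" if rng.random() < 0.957 else "Black",
                ethnicity="hispanic" if rng.random() < 0.005 else "non_hispanic",
                hf=bool(hf[i]),
                hf_type=hf_type,
                lvef_pct=35.0 if hf_type == "reduced_ef" else 55.0,
            )
        )

    records: list[dict] = []
    vid_counter = 0

    def next_vid() -> str:
        nonlocal vid_counter
        vid_counter += 1
        return f"chr1-{vid_counter * 100}-A-T"

    dom_genes = [g for g, _ in FIXTURE_DOMINANT_GENES if g != "FHL1"]
    dom_weights = np.array(
        [c for g, c in FIXTURE_DOMINANT_GENES if g != "FHL1"], dtype=float
    )
    dom_weights /= dom_weights.sum()
    for i in np.flatnonzero(carrier):
        gene = str(rng.choice(dom_genes, p=dom_weights))
        records.append(_plp(participants[i].id, gene, next_vid()))

    # per-gene VUS totals linear in transcript length, Gaussian noise
    for gene_rec in panel.genes:
        mu = spec.vus_intercept_true + spec.vus_slope_true * gene_rec.transcript_length_kbp
        count = int(max(0, round(mu + rng.normal(0.0, spec.vus_noise_sd))))
        owners = rng.integers(0, n, size=count)
        for i in owners:
            records.append(_vus(participants[int(i)].id, gene_rec.symbol, next_vid()))

    for gene, rate in spec.recessive_rates.items():
        hits = np.flatnonzero(rng.random(n) < rate)
        for i in hits:
            records.append(_plp(participants[int(i)].id, gene, next_vid()))

    variants = pd.DataFrame(records, columns=COLUMNS)
    if variants.empty:
        variants = pd.DataFrame(columns=COLUMNS)

    plp_ids = [r["variant_id"] for r in records if r["clinvar_assertion"] == "pathogenic"]
    disagree = rng.random(len(plp_ids)) < spec.review_disagreement
    reviews = pd.DataFrame(
        {
            "variant_id": plp_ids,
            "reviewer_a_tier": ["P"] * len(plp_ids),
            "reviewer_b_tier": ["VUS_PP" if d else "P" for d in disagree],
        }
    )
    return Cohort(
        participants=participants,
        variants=variants,
        reviews=reviews,
        expected_counts={"n": n},
        spec_hash=spec.spec_hash(),
    )
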