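"""Inheritance-aware assignment of participants to mutually exclusive groups.

Each participant lands in exactly one of four priority groups based on their
highest-priority classified variant:

1. ≥1 P/LP variant in a gene with dominant inheritance (autosomal dominant,
   or X-linked per the sex rules below) — "disease-associated variant";
2. ≥1 VUS (any sub-tier) and not group 1;
3. heterozygous P/LP in a gene with recessive inheritance — carrier state;
4. no P/LP variants and no VUS.

X-linked handling is mode-dependent.  In the default mode a P/LP variant in
an X-linked dominant gene qualifies for group 1 in either sex, and a
hemizygous male with a P/LP in an X-linked recessive gene is also group 1
(he is expected to be affected).  ``strict`` mode narrows X-linked-dominant
group-1 eligibility to men and treats X-linked recessive variants as
carrier findings (group 3) regardless of sex.  Two heterozygous P/LP
variants in one recessive gene cannot be phased from these data, so they
remain a flagged carrier finding (possible compound heterozygote); a
homozygous P/LP is flagged with known phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import pandas as pd

from .panel import GeneRecord, PanelConfig

Sex = Literal["male", "female"]


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class Participant:
    """Demographics and covariates for one cohort member (ages in years)."""

    id: str
    sex: Sex
    age_dx: int
    age_enroll: int
    race: str = "White"
    ethnicity: str = "non_hispanic"
    hf: bool = False
    hf_type: str = "none"
    lvef_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.age_dx < 66):
            raise ValueError(f"{self.id}: age at diagnosis {self.age_dx} outside [0, 66)")
        if self.age_dx > self.age_enroll:
            raise ValueError(f"{self.id}: age_dx {self.age_dx} > age_enroll {self.age_enroll}")


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    group: int
    qualifying_variants: tuple[tuple[str, str, str], ...] = ()  # (variant_id, gene, tier)
    biallelic_flag: bool = False
    phase_known: bool = False


def _dominant_qualifies(gene: GeneRecord, sex: str, mode: str) -> bool:
    """Does a P/LP in this gene put a participant of this sex into group 1?"""
    if "AD" in gene.inheritance_modes:
        return True
    if "XLD" in gene.inheritance_modes:
        return sex == "male" or mode == "default"
    if "XLR" in gene.inheritance_modes:
        return sex == "male" and mode == "default"
    return False


def _recessive_qualifies(gene: GeneRecord, sex: str, mode: str) -> bool:
    if "AR" in gene.inheritance_modes:
        return True
    if "XLR" in gene.inheritance_modes:
        return sex == "female" or mode == "strict"
    return False


def assign_group(
    participant: Participant,
    variants: pd.DataFrame,
    panel: PanelConfig,
    mode: str = "default",
) -> GroupAssignment:
    """Assign one participant to their priority group from classified variants.

    ``variants`` must carry ``gene``, ``variant_id``, ``zygosity`` and
    ``coarse_tier`` columns (this participant's records only); row order is
    irrelevant.  A variant in a gene with no inheritance modes is a config
    defect and raises :class:`GroupingError`.
    """
    if mode not in ("default", "strict"):
        raise GroupingError(f"unknown X-linked handling mode: {mode!r}")
    dominant: list[tuple[str, str, str]] = []
    vus: list[tuple[str, str, str]] = []
    recessive: list[tuple[str, str, str]] = []
    hom_recessive_genes: set[str] = set()

    rows = sorted(
        variants.itertuples(index=False), key=lambda r: (r.variant_id, r.gene)
    )
    for row in rows:
        gene = panel.gene(row.gene)
        if not gene.inheritance_modes:
            raise GroupingError(f"gene {gene.symbol} has no inheritance modes (config defect)")
        tier = row.coarse_tier
        entry = (row.variant_id, row.gene, tier)
        if tier in ("P", "LP"):
            if _dominant_qualifies(gene, participant.sex, mode):
                dominant.append(entry)
            elif _recessive_qualifies(gene, participant.sex, mode):
                recessive.append(entry)
                if row.zygosity == "hom":
                    hom_recessive_genes.add(gene.symbol)
        elif tier == "VUS":
            vus.append(entry)

    pid = participant.id
    if dominant:
        return GroupAssignment(pid, 1, tuple(dominant))
    if vus:
        return GroupAssignment(pid, 2, tuple(vus))
    if recessive:
        per_gene = pd.Series([g for _, g, _ in recessive]).value_counts()
        biallelic = bool((per_gene >= 2).any()) or bool(hom_recessive_genes)
        phase_known = bool(hom_recessive_genes) and not bool((per_gene >= 2).any())
        return GroupAssignment(pid, 3, tuple(recessive), biallelic_flag=biallelic,
                               phase_known=phase_known)
    return GroupAssignment(pid, 4)


def assign_groups(
    participants: Iterable[Participant],
    classified: pd.DataFrame,
    panel: PanelConfig,
    mode: str = "default",
) -> list[GroupAssignment]:
    """Vectorised convenience wrapper: one assignment per participant."""
    by_pid = dict(tuple(classified.groupby("participant_id", sort=False)))
    empty = classified.iloc[0:0]
    out = []
    for p in participants:
        out.append(assign_group(p, by_pid.get(p.id, empty), panel, mode))
    return out


def count_multi_dominant(assignments: Iterable[GroupAssignment]) -> int:
    """Group-1 participants carrying ≥2 qualifying dominant P/LP variants."""
    return sum(1 for a in assignments if a.group == 1 and len(a.qualifying_variants) >= 2)


def group_counts(assignments: Iterable[GroupAssignment]) -> dict[int, int]:
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for a in assignments:
        counts[a.group] += 1
    return counts


def assignments_frame(assignments: Iterable[GroupAssignment]) -> pd.DataFrame:
    """Assignments as a TSV-ready frame (qualifying variants semicolon-joined)."""
    return pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in assignments],
            "group": [a.group for a in assignments],
            "qualifying_variants": [
                ";".join(f"{v}|{g}|{t}" for v, g, t in a.qualifying_variants)
                for a in assignments
            ],
            "biallelic_flag": [a.biallelic_flag for a in assignments],
            "phase_known": [a.phase_known for a in assignments],
        }
    )
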