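"""Gene-panel registry: the comprehensive arrhythmia/cardiomyopathy panel.

A panel is a set of :class:`GeneRecord` entries carrying, per gene, the
commercial panels it appears on, the inherited syndromes it is assigned to
(dilated/hypertrophic/arrhythmogenic cardiomyopathy, long-QT, CPVT,
Brugada), a frozen ClinGen gene-disease validity level per syndrome,
inheritance modes, whether loss of function is an established disease
mechanism, coding-transcript length, and the reporting rule applied to its
variants.  Genes whose ClinGen level is strong or definitive for a syndrome
are that syndrome's *major disease genes*.

ClinGen levels are snapshotted in the config file (date-stamped), never
fetched live: curation changes over time and reproducibility requires a
frozen assignment.
"""

from __future__ import annotations

import json
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

Panel = Literal["arrhythmia", "cardiomyopathy"]
Syndrome = Literal["AC_ARVC", "Brugada", "CPVT", "DCM", "HCM", "LQTS", "other"]
ClinGenLevel = Literal["definitive", "strong", "moderate", "limited", "disputed", "none"]
InheritanceMode = Literal["AD", "AR", "XLD", "XLR"]
ReportingRule = Literal["all_rare", "lof_only"]

SYNDROMES: tuple[str, ...] = ("AC_ARVC", "Brugada", "CPVT", "DCM", "HCM", "LQTS")

#: ClinGen levels that make a gene a *major disease gene* for a syndrome.
MAJOR_LEVELS = frozenset({"strong", "definitive"})


class PanelError(ValueError):
    """A panel config failed validation; message names gene and field."""


class GeneRecord(BaseModel):
    """One panel gene with syndrome, inheritance and reporting metadata."""

    symbol: str
    panels: list[Panel]
    syndromes: list[Syndrome] = Field(default_factory=list)
    clingen_level: dict[str, ClinGenLevel] = Field(default_factory=dict)
    inheritance_modes: list[InheritanceMode]
    lof_mechanism: bool = True
    transcript_length_kbp: float = Field(gt=0)
    reporting_rule: ReportingRule = "all_rare"
    provenance: Literal["stated", "inferred", "provisional"] = "inferred"

    @field_validator("panels")
    @classmethod
    def _panels_nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("panels must be non-empty")
        return sorted(set(v))

    @model_validator(mode="after")
    def _levels_match_syndromes(self) -> "GeneRecord":
        unknown = set(self.clingen_level) - set(self.syndromes)
        if unknown:
            raise ValueError(
                f"clingen_level keys {sorted(unknown)} not among syndromes for {self.symbol}"
            )
        return self

    def level_for(self, syndrome: str) -> str:
        """ClinGen validity level of this gene for ``syndrome`` ('none' if unassigned)."""
        return self.clingen_level.get(syndrome, "none")

    @property
    def is_dominant(self) -> bool:
        return "AD" in self.inheritance_modes or "XLD" in self.inheritance_modes

    @property
    def is_recessive(self) -> bool:
        return "AR" in self.inheritance_modes or "XLR" in self.inheritance_modes

    @property
    def is_x_linked(self) -> bool:
        return "XLD" in self.inheritance_modes or "XLR" in self.inheritance_modes


class PanelConfig(BaseModel):
    """A validated gene panel."""

    name: str
    version_date: date
    genes: list[GeneRecord]

    @model_validator(mode="after")
    def _validate(self) -> "PanelConfig":
        if not self.genes:
            raise ValueError("panel contains no genes")
        seen: set[str] = set()
        for g in self.genes:
            if g.symbol in seen:
                raise ValueError(f"duplicate gene symbol: {g.symbol}")
            seen.add(g.symbol)
        return self

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index()

    def _index(self) -> dict[str, GeneRecord]:
        idx = self.__dict__.get("_gene_index")
        if idx is None or len(idx) != len(self.genes):
            idx = {g.symbol: g for g in self.genes}
            self.__dict__["_gene_index"] = idx
        return idx

    def gene(self, symbol: str) -> GeneRecord:
        try:
            return self._index()[symbol]
        except KeyError:
            raise PanelError(f"gene {symbol!r} is not on panel {self.name!r}") from None

    def symbols(self) -> set[str]:
        return set(self._index())


def load_panel(path: str | Path | None = None) -> PanelConfig:
    """Load and validate a panel config (JSON); ``None`` loads the shipped default.

    Raises :class:`PanelError` naming the offending gene/field on any schema
    violation, duplicate symbol, or unknown inheritance mode.
    """
    if path is None:
        text = (
            resources.files("afpanel").joinpath("data/default_panel.json").read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PanelError(f"panel config is not valid JSON: {exc}") from exc
    try:
        cfg = PanelConfig.model_validate(raw)
    except ValidationError as exc:
        raise PanelError(_format_validation_error(raw, exc)) from exc
    # The shipped default must reproduce the published partition.
    if path is None:
        counts = panel_partition_counts(cfg)
        assert counts == (87, 36, 22), counts
        assert len(cfg) == 145
    return cfg


def _format_validation_error(raw: object, exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = err["loc"]
        symbol = ""
        if isinstance(raw, dict) and len(loc) >= 2 and loc[0] == "genes" and isinstance(loc[1], int):
            genes = raw.get("genes", [])
            if isinstance(genes, list) and loc[1] < len(genes) and isinstance(genes[loc[1]], dict):
                symbol = genes[loc[1]].get("symbol", "")
        field = ".".join(str(p) for p in loc[2:]) or ".".join(str(p) for p in loc)
        prefix = f"gene {symbol}: " if symbol else ""
        parts.append(f"{prefix}{field}: {err['msg']}")
    return "invalid panel config: " + "; ".join(parts)


def is_major_disease_gene(gene: GeneRecord, syndrome: str) -> bool:
    """True iff the gene's frozen ClinGen level for ``syndrome`` is strong/definitive."""
    if syndrome not in SYNDROMES:
        raise PanelError(f"unknown syndrome label: {syndrome!r}")
    return gene.level_for(syndrome) in MAJOR_LEVELS


def panel_partition_counts(panel: PanelConfig) -> tuple[int, int, int]:
    """(cardiomyopathy-only, arrhythmia-only, both) gene counts; sums to len(panel)."""
    cardio_only = arr_only = both = 0
    for g in panel.genes:
        on_c = "cardiomyopathy" in g.panels
        on_a = "arrhythmia" in g.panels
        if on_c and on_a:
            both += 1
        elif on_c:
            cardio_only += 1
        else:
            arr_only += 1
    assert cardio_only + arr_only + both == len(panel.genes)
    return cardio_only, arr_only, both


def major_genes(panel: PanelConfig, syndrome: str) -> set[str]:
    """Symbols of the panel's major disease genes for ``syndrome``."""
    return {g.symbol for g in panel.genes if is_major_disease_gene(g, syndrome)}


def write_panel(panel: PanelConfig, path: str | Path) -> None:
    Path(path).write_text(panel.model_dump_json(indent=1))


def panel_json_schema() -> dict:
    """JSON-schema document for the panel config file format."""
    return PanelConfig.model_json_schema()
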