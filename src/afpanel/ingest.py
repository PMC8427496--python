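"""Read, validate and filter per-participant annotated variants.

The canonical interchange format is a flat TSV (one header line, UTF-8,
``.`` for absent values, 1-based VCF-style ``chrom-pos-ref-alt`` variant
ids).  A VCF (v4.2) reader is provided as an optional front end; its INFO
keys are mapped onto the same columns.  Ingest restricts records to panel
genes, applies per-gene reporting rules (e.g. loss-of-function-only
reporting for *TTN*), and removes variants that are too common in
population references.  Every dropped record is counted, so that
``records_in == records_out + dropped_off_panel + dropped_reporting_rule +
dropped_rare`` holds for any input.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .panel import PanelConfig

CONSEQUENCES = ("lof", "missense", "inframe_indel", "synonymous", "splice_region", "other")
#: VCF consequence terms collapsed onto the PVS1-eligible ``lof`` class.
LOF_TERMS = frozenset({"stop_gained", "frameshift", "splice_donor", "splice_acceptor", "lof"})
ZYGOSITIES = ("het", "hom", "hemi")
CLINVAR_ASSERTIONS = (
    "pathogenic", "likely_pathogenic", "uncertain", "likely_benign", "benign",
    "conflicting", "absent",
)

#: canonical TSV column order
COLUMNS = [
    "participant_id", "gene", "variant_id", "consequence", "zygosity",
    "popmax_af", "clinvar_assertion", "insilico_deleterious",
    "insilico_tolerated", "insilico_unavailable",
]

_VARIANT_ID_RE = re.compile(r"^[\w.]+-\d+-[ACGTN]+-[ACGTN]+$")


class IngestError(ValueError):
    """Malformed variant input (missing column, bad coordinate, out-of-range field)."""


@dataclass
class VariantTable:
    """Panel-filtered annotated variants plus drop accounting."""

    records: pd.DataFrame
    source: str = "<memory>"
    n_dropped_off_panel: int = 0
    n_dropped_reporting_rule: int = 0
    n_dropped_rare: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    @property
    def n_input(self) -> int:
        return (
            len(self.records)
            + self.n_dropped_off_panel
            + self.n_dropped_reporting_rule
            + self.n_dropped_rare
        )


def _validate_records(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{source}: missing required column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()
    df["popmax_af"] = pd.to_numeric(df["popmax_af"].replace({".": None, "": None}), errors="coerce")
    bad_af = df["popmax_af"].notna() & ~df["popmax_af"].between(0.0, 1.0)
    if bad_af.any():
        i = int(df.index[bad_af][0])
        raise IngestError(
            f"{source}: popmax_af out of [0,1] at record {i} "
            f"({df.loc[i, 'variant_id']}: {df.loc[i, 'popmax_af']})"
        )
    df["consequence"] = df["consequence"].map(
        lambda c: "lof" if c in LOF_TERMS else c
    )
    bad_csq = ~df["consequence"].isin(CONSEQUENCES)
    if bad_csq.any():
        i = int(df.index[bad_csq][0])
        raise IngestError(f"{source}: unknown consequence {df.loc[i, 'consequence']!r} at record {i}")
    bad_zyg = ~df["zygosity"].isin(ZYGOSITIES)
    if bad_zyg.any():
        i = int(df.index[bad_zyg][0])
        raise IngestError(f"{source}: unknown zygosity {df.loc[i, 'zygosity']!r} at record {i}")
    df["clinvar_assertion"] = df["clinvar_assertion"].replace({".": "absent", "": "absent"})
    bad_cv = ~df["clinvar_assertion"].isin(CLINVAR_ASSERTIONS)
    if bad_cv.any():
        i = int(df.index[bad_cv][0])
        raise IngestError(
            f"{source}: unknown clinvar_assertion {df.loc[i, 'clinvar_assertion']!r} at record {i}"
        )
    bad_vid = ~df["variant_id"].astype(str).map(lambda v: bool(_VARIANT_ID_RE.match(v)))
    if bad_vid.any():
        i = int(df.index[bad_vid][0])
        raise IngestError(
            f"{source}: unparseable variant id {df.loc[i, 'variant_id']!r} at record {i} "
            "(expected chrom-pos-ref-alt)"
        )
    for col in ("insilico_deleterious", "insilico_tolerated", "insilico_unavailable"):
        df[col] = pd.to_numeric(df[col].replace({".": 0, "": 0}), errors="raise").astype(int)
    return df


def _sort(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["participant_id", "variant_id"], kind="mergesort").reset_index(drop=True)


def from_frame(df: pd.DataFrame, panel: PanelConfig, source: str = "<memory>") -> VariantTable:
    """Validate a raw record frame and restrict it to panel genes."""
    df = _validate_records(df, source)
    on_panel = df["gene"].isin(panel.symbols())
    dropped = int((~on_panel).sum())
    return VariantTable(
        records=_sort(df[on_panel]),
        source=source,
        n_dropped_off_panel=dropped,
    )


def read_variants(path: str | Path, panel: PanelConfig, *, fmt: str | None = None,
                  info_map: dict[str, str] | None = None) -> VariantTable:
    """Read annotated variants from TSV (canonical) or VCF and panel-filter them.

    ``fmt`` is inferred from the file suffix when not given.  For VCF input,
    ``info_map`` maps INFO keys onto annotation columns (defaults in
    :data:`DEFAULT_INFO_MAP`).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.empty and not set(COLUMNS) <= set(df.columns):
            raise IngestError(f"{path}: missing required column(s)")
    elif fmt == "vcf":
        df = _read_vcf(path, info_map or DEFAULT_INFO_MAP)
    else:
        raise IngestError(f"unknown variant input format: {fmt!r}")
    return from_frame(df, panel, source=str(path))


#: default INFO-key → column mapping for the VCF front end
DEFAULT_INFO_MAP = {
    "GENE": "gene",
    "CSQ_CLASS": "consequence",
    "POPMAX_AF": "popmax_af",
    "CLNSIG": "clinvar_assertion",
    "INSILICO_DEL": "insilico_deleterious",
    "INSILICO_TOL": "insilico_tolerated",
    "INSILICO_NA": "insilico_unavailable",
}


def _read_vcf(path: Path, info_map: dict[str, str]) -> pd.DataFrame:
    """Per-sample records from a VCF; multi-allelic sites are decomposed per alt."""
    import pysam

    rows: list[dict] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            info = {info_map[k]: v for k, v in rec.info.items() if k in info_map}
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None:
                        continue
                    calls = [a for a in gt if a is not None]
                    n_alt = sum(1 for a in calls if a == ai + 1)
                    if n_alt == 0:
                        continue
                    if len(calls) == 1:
                        zyg = "hemi"
                    else:
                        zyg = "hom" if n_alt == 2 else "het"
                    row = {
                        "participant_id": sample,
                        "variant_id": f"{rec.chrom}-{rec.pos}-{rec.ref}-{alt}",
                        "zygosity": zyg,
                        "popmax_af": ".",
                        "clinvar_assertion": "absent",
                        "insilico_deleterious": 0,
                        "insilico_tolerated": 0,
                        "insilico_unavailable": 0,
                        "gene": None,
                        "consequence": "other",
                    }
                    for col, val in info.items():
                        if isinstance(val, tuple):
                            val = val[ai] if ai < len(val) else val[0]
                        row[col] = val
                    rows.append(row)
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=COLUMNS)
    return df


def apply_reporting_rules(table: VariantTable, panel: PanelConfig) -> VariantTable:
    """Drop records disallowed by gene reporting rules (``lof_only`` genes keep LoF only).

    Idempotent; dropped records accumulate in ``n_dropped_reporting_rule``.
    """
    lof_only = {g.symbol for g in panel.genes if g.reporting_rule == "lof_only"}
    df = table.records
    drop = df["gene"].isin(lof_only) & (df["consequence"] != "lof")
    return replace(
        table,
        records=_sort(df[~drop]),
        n_dropped_reporting_rule=table.n_dropped_reporting_rule + int(drop.sum()),
    )


def rare_filter(table: VariantTable, af_threshold: float = 0.001) -> VariantTable:
    """Remove records with popmax_af ≥ ``af_threshold``; absent popmax is kept (rare)."""
    if not (0.0 < af_threshold < 1.0):
        raise IngestError(f"af_threshold must be in (0, 1), got {af_threshold}")
    df = table.records
    drop = df["popmax_af"].notna() & (df["popmax_af"] >= af_threshold)
    return replace(
        table,
        records=_sort(df[~drop]),
        n_dropped_rare=table.n_dropped_rare + int(drop.sum()),
    )


def write_tsv(table: VariantTable, path: str | Path) -> None:
    """Write the canonical TSV dialect ('.' for absent popmax_af)."""
    df = table.records.copy()
    df["popmax_af"] = df["popmax_af"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)
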