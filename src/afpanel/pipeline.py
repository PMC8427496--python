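"""End-to-end orchestration: panel → filter → classify → review → group → stats."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .acmg import EngineConfig, adjudicate, classify_table, read_reviews
from .grouping import (
    GroupAssignment, Participant, assign_groups, assignments_frame,
    count_multi_dominant, group_counts,
)
from .ingest import VariantTable, apply_reporting_rules, rare_filter, read_variants, write_tsv
from .panel import PanelConfig, load_panel
from .stats import (
    DEFAULT_AGE_BINS, fit_age_trend, gene_breakdown, group_covariate_table,
    prevalence_by_age, syndrome_overlap, vus_burden_regression,
)
from ._util import round_half_up


@dataclass
class RunConfig:
    panel_path: Optional[str] = None  # None → shipped default panel
    variants_path: str = ""
    participants_path: str = ""
    reviews_path: Optional[str] = None
    overrides_path: Optional[str] = None
    af_threshold: float = 0.001
    engine: EngineConfig = field(default_factory=EngineConfig)
    n_boot: int = 10_000
    seed: int = 0
    strict_paper_mode: bool = False
    out_dir: Optional[str] = None


@dataclass
class ReportBundle:
    group_counts: dict[int, int]
    group_pcts: dict[int, float]
    prevalence: list
    trend_uni: object
    trend_multi: object
    syndromes: list
    gene_tables: dict[str, pd.DataFrame]
    vus_regression: dict
    covariates: pd.DataFrame
    adjudication: Optional[tuple[float, float]]
    multi_dominant: int
    assignments: list[GroupAssignment]
    classified: pd.DataFrame
    stage_log: dict


def run_pipeline(
    config: RunConfig,
    *,
    panel: PanelConfig | None = None,
    variants: VariantTable | None = None,
    participants: Sequence[Participant] | None = None,
    reviews=None,
) -> ReportBundle:
    """Execute the full triage-and-statistics pipeline.

    Inputs may be passed in memory (``panel``/``variants``/``participants``)
    or read from the paths in ``config``.  Per-stage record counts are kept
    in ``stage_log`` so the conservation invariants can be audited from the
    report alone.
    """
    stage = "load_panel"
    log: dict = {}
    try:
        if panel is None:
            panel = load_panel(config.panel_path)
        log["panel_genes"] = len(panel)

        stage = "ingest"
        if variants is None:
            variants = read_variants(config.variants_path, panel)
        if participants is None:
            from .synthetic import read_participants

            participants = read_participants(config.participants_path)
        log["records_in"] = variants.n_input
        log["dropped_off_panel"] = variants.n_dropped_off_panel

        stage = "reporting_rules"
        variants = apply_reporting_rules(variants, panel)
        log["dropped_reporting_rule"] = variants.n_dropped_reporting_rule

        stage = "rare_filter"
        variants = rare_filter(variants, config.af_threshold)
        log["dropped_rare"] = variants.n_dropped_rare
        log["records_retained"] = len(variants)
        assert variants.n_input == log["records_in"]

        stage = "classify"
        overrides = None
        if config.overrides_path:
            overrides = pd.read_csv(config.overrides_path, sep="\t", dtype={"variant_id": str})
        classified = classify_table(variants, panel, config.engine, overrides)
        log["tier_counts"] = classified["tier"].value_counts().to_dict()

        stage = "adjudicate"
        adjudication = None
        if reviews is None and config.reviews_path:
            reviews = read_reviews(config.reviews_path)
        if reviews is not None and len(reviews) >= 2:
            adjudication = adjudicate(reviews)
            log["review_agreement_pct"] = round_half_up(adjudication[0], 1)
            log["review_kappa"] = round(adjudication[1], 3)

        stage = "group"
        mode = "strict" if config.strict_paper_mode else "default"
        assignments = assign_groups(participants, classified, panel, mode)
        counts = group_counts(assignments)
        n = len(assignments)
        pcts = {g: round_half_up(100.0 * c / n, 1) for g, c in counts.items()}
        log["group_counts"] = counts

        stage = "statistics"
        prevalence = prevalence_by_age(
            assignments, participants, DEFAULT_AGE_BINS, config.n_boot, config.seed
        )
        trend_uni = fit_age_trend(assignments, participants, "univariable")
        trend_multi = fit_age_trend(assignments, participants, "multivariable")
        syndromes = syndrome_overlap(assignments, panel)
        gene_tables = {
            cat: gene_breakdown(classified, assignments, participants, panel, cat)
            for cat in ("dominant_plp", "vus", "recessive_plp")
        }
        vus_counts = gene_tables["vus"].set_index("gene")["n_variants"]
        if len(vus_counts) >= 3:
            vus_reg = vus_burden_regression(vus_counts, panel)
        else:
            vus_reg = {}
        covariates = group_covariate_table(participants, assignments)
        multi_dom = count_multi_dominant(assignments)

        bundle = ReportBundle(
            group_counts=counts, group_pcts=pcts, prevalence=prevalence,
            trend_uni=trend_uni, trend_multi=trend_multi, syndromes=syndromes,
            gene_tables=gene_tables, vus_regression=vus_reg, covariates=covariates,
            adjudication=adjudication, multi_dominant=multi_dom,
            assignments=assignments, classified=classified, stage_log=log,
        )
        if config.out_dir:
            _write_bundle(bundle, config, panel)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_bundle(bundle: ReportBundle, config: RunConfig, panel: PanelConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assignments_frame(bundle.assignments).to_csv(out / "assignments.tsv", sep="\t", index=False)
    bundle.classified.to_csv(out / "classified.tsv", sep="\t", index=False)
    bundle.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    for cat, df in bundle.gene_tables.items():
        df.to_csv(out / f"genes_{cat}.tsv", sep="\t", index=False)
    summary = summary_dict(bundle)
    summary["manifest"] = {
        "software_version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "strict_paper_mode": config.strict_paper_mode,
        "engine": asdict(config.engine),
        "inputs": {
            k: _digest(v)
            for k, v in {
                "variants": config.variants_path,
                "participants": config.participants_path,
            }.items()
            if v and Path(v).exists()
        },
    }
    (out / "report.json").write_text(json.dumps(summary, indent=1, default=str))
    (out / "report.txt").write_text(render_text(bundle))


def summary_dict(bundle: ReportBundle) -> dict:
    return {
        "groups": {
            str(g): {"n": bundle.group_counts[g], "pct": bundle.group_pcts[g]}
            for g in (1, 2, 3, 4)
        },
        "multi_dominant_carriers": bundle.multi_dominant,
        "prevalence_by_age": [
            {
                "bin": e.label, "numerator": e.numerator, "denominator": e.denominator,
                "pct": e.pct, "ci": [e.ci_low, e.ci_high],
            }
            for e in bundle.prevalence
        ],
        "age_trend": {
            m.model: {
                "or_per_decade": round(m.or_per_decade, 2),
                "ci": [round(m.ci_low, 2), round(m.ci_high, 2)],
                "p": round(m.p_value, 4),
                "spline_f_p_overall": round(m.spline_f_p_overall, 4),
                "spline_f_p_nonlinear": round(m.spline_f_p_nonlinear, 4),
                "separation_flag": m.separation_flag,
            }
            for m in (bundle.trend_uni, bundle.trend_multi)
        },
        "syndrome_overlap": [
            {
                "syndrome": s.syndrome, "n_all": s.n_all_genes, "pct_all": s.pct_all,
                "n_major": s.n_major_genes, "pct_major": s.pct_major,
            }
            for s in bundle.syndromes
        ],
        "vus_regression": {
            k: (round(v, 3) if isinstance(v, float) else None)
            for k, v in bundle.vus_regression.items()
            if k != "excess_table"
        },
        "adjudication": (
            {
                "agreement_pct": round_half_up(bundle.adjudication[0], 1),
                "kappa": round(bundle.adjudication[1], 3),
            }
            if bundle.adjudication
            else None
        ),
        "stage_log": bundle.stage_log,
    }


def render_text(bundle: ReportBundle) -> str:
    """Fig-2-style pretty summary block."""
    lines = ["Panel triage summary", "===================", ""]
    n = sum(bundle.group_counts.values())
    names = {
        1: "dominant P/LP (disease-associated variant)",
        2: "VUS only",
        3: "recessive carrier",
        4: "no suspicious variant",
    }
    for g in (1, 2, 3, 4):
        lines.append(
            f"group {g} ({names[g]}): {bundle.group_counts[g]} ({bundle.group_pcts[g]}%)"
        )
    lines.append(f"total participants: {n}")
    lines.append("")
    lines.append("prevalence of disease-associated variants by age at diagnosis:")
    for e in bundle.prevalence:
        lines.append(
            f"  {e.label:>6}: {e.numerator}/{e.denominator} = {e.pct}% "
            f"(95% CI {e.ci_low}-{e.ci_high})"
        )
    t = bundle.trend_uni
    lines.append("")
    lines.append(
        f"odds of a finding per decade of earlier diagnosis: "
        f"{t.or_per_decade:.2f} (95% CI {t.ci_low:.2f}-{t.ci_high:.2f}; P={t.p_value:.3f})"
    )
    if bundle.adjudication:
        lines.append(
            f"reviewer agreement: {round_half_up(bundle.adjudication[0], 1)}% "
            f"(kappa={bundle.adjudication[1]:.3f})"
        )
    return "\n".join(lines) + "\n"
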