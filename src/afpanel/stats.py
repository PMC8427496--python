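"""Cohort-level statistics for gene-panel diagnostic yield.

Implements the study-level summaries: age-binned prevalence of
disease-associated variants with percentile-bootstrap confidence intervals
(10 000 resamples with replacement by default), logistic models of variant
detection versus age at AF diagnosis (odds ratio per decade of *earlier*
diagnosis, plus a 3-knot restricted cubic spline with overall and
nonlinearity F tests), participant-level syndrome overlap (all genes and
major disease genes), per-gene variant breakdowns, the VUS-burden versus
transcript-length regression, and a Table-1-style covariate comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .grouping import GroupAssignment, Participant
from .panel import PanelConfig, is_major_disease_gene, SYNDROMES
from ._util import round_half_up

#: age-at-diagnosis bins (left-closed, right-open) partitioning [0, 66)
DEFAULT_AGE_BINS: tuple[tuple[str, int, int], ...] = (
    ("<30", 0, 30),
    ("30-39", 30, 40),
    ("40-49", 40, 50),
    ("50-59", 50, 60),
    ("60-65", 60, 66),
)


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bootstrap prevalence


@dataclass(frozen=True)
class PrevalenceEstimate:
    label: str
    numerator: int
    denominator: int
    pct: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_proportion_ci(
    numerator: int,
    denominator: int,
    n_boot: int = 10_000,
    seed: int = 0,
    label: str = "",
) -> PrevalenceEstimate:
    """Percentile-bootstrap 95% CI for a binomial proportion, in percent.

    Resamples a binary vector of length ``denominator`` containing
    ``numerator`` ones, with replacement, ``n_boot`` times (realised as
    Binomial(denominator, p) draws, which is the exact distribution of the
    resampled success count), and takes the 2.5th/97.5th percentiles of the
    resampled proportion.  Deterministic given ``seed``.
    """
    if denominator < 1:
        raise StatsError("denominator must be >= 1")
    if not (0 <= numerator <= denominator):
        raise StatsError(f"numerator {numerator} outside [0, {denominator}]")
    rng = np.random.default_rng(seed)
    p = numerator / denominator
    draws = rng.binomial(denominator, p, size=n_boot) / denominator
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PrevalenceEstimate(
        label=label,
        numerator=numerator,
        denominator=denominator,
        pct=round_half_up(100.0 * p, 1),
        ci_low=round_half_up(100.0 * float(lo), 1),
        ci_high=round_half_up(100.0 * float(hi), 1),
        n_boot=n_boot,
        seed=seed,
    )


def prevalence_by_age(
    assignments: Sequence[GroupAssignment],
    participants: Sequence[Participant],
    bins: Sequence[tuple[str, int, int]] = DEFAULT_AGE_BINS,
    n_boot: int = 10_000,
    seed: int = 0,
    group: int = 1,
) -> list[PrevalenceEstimate]:
    """Per-age-bin prevalence of group-``group`` membership with bootstrap CIs."""
    group_by_pid = {a.participant_id: a.group for a in assignments}
    out = []
    assigned = 0
    for i, (label, lo, hi) in enumerate(bins):
        members = [p for p in participants if lo <= p.age_dx < hi]
        assigned += len(members)
        num = sum(1 for p in members if group_by_pid.get(p.id) == group)
        if not members:
            raise StatsError(f"age bin {label} is empty")
        out.append(
            bootstrap_proportion_ci(num, len(members), n_boot, seed + i, label=label)
        )
    if assigned != len(participants):
        raise StatsError("age bins do not partition the cohort (participant outside all bins)")
    return out


# ---------------------------------------------------------------------------
# logistic age-trend models


@dataclass(frozen=True)
class AgeTrendFit:
    or_per_decade: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    spline_f_p_overall: float
    spline_f_p_nonlinear: float
    knots: tuple[float, ...]
    separation_flag: bool = False


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (Harrell), linear in the tails.

    For k knots returns k−1 columns: the linear term plus k−2 nonlinear
    terms, each normalised by (t_k − t_1)².
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(sorted(knots), dtype=float)
    k = len(t)
    if k < 3:
        raise StatsError("restricted cubic spline needs >= 3 knots")
    cols = [x]
    denom = (t[-1] - t[0]) ** 2

    def cube(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / denom)
    return np.column_stack(cols)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        return model.fit(disp=0, maxiter=200)


def fit_age_trend(
    assignments: Sequence[GroupAssignment],
    participants: Sequence[Participant],
    model: str = "univariable",
    knots_quantiles: tuple[float, float, float] = (0.10, 0.50, 0.90),
    group: int = 1,
) -> AgeTrendFit:
    """Logistic regression of group membership on age at AF diagnosis.

    Age enters as decades of *earlier* diagnosis (−age/10), so an odds ratio
    above 1 means younger diagnosis → more findings.  The multivariable
    model adjusts for sex, race (White vs other) and ethnicity (Hispanic vs
    not); near-empty cells make finer encodings unstable.  A separate fit on
    a 3-knot restricted cubic spline in age tests, by nested model
    comparison, that all age terms are zero (overall) and that the nonlinear
    term is zero.
    """
    group_by_pid = {a.participant_id: a.group for a in assignments}
    y = np.array([1.0 if group_by_pid.get(p.id) == group else 0.0 for p in participants])
    if len(np.unique(y)) < 2:
        raise StatsError("need both outcome classes present")
    age = np.array([float(p.age_dx) for p in participants])
    dec_earlier = -age / 10.0

    covs = [dec_earlier]
    names = ["dec_earlier"]
    if model == "multivariable":
        extra = {
            "male": np.array([1.0 if p.sex == "male" else 0.0 for p in participants]),
            "white": np.array([1.0 if p.race == "White" else 0.0 for p in participants]),
            "hispanic": np.array([1.0 if p.ethnicity == "hispanic" else 0.0 for p in participants]),
        }
        for name, col in extra.items():
            if len(np.unique(col)) < 2:
                warnings.warn(f"adjustment covariate {name!r} is constant; dropped from model")
                continue
            covs.append(col)
            names.append(name)
    elif model != "univariable":
        raise StatsError(f"unknown model: {model!r}")

    X = sm.add_constant(np.column_stack(covs))
    separation = False
    try:
        res = _fit_logit(y, X)
        if not res.mle_retvals.get("converged", True) or np.any(
            np.abs(res.params) > 15
        ):
            separation = True
        beta = res.params[1]
        se = res.bse[1]
        p_value = float(res.pvalues[1])
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        separation = True
        beta, se, p_value = np.nan, np.nan, np.nan

    z = scipy.stats.norm.ppf(0.975)
    or_pd = float(np.exp(beta))
    ci_low = float(np.exp(beta - z * se))
    ci_high = float(np.exp(beta + z * se))

    # spline fit on age itself; overall and nonlinearity tests by nested
    # model comparison (likelihood ratio against chi-square)
    knots = tuple(float(np.quantile(age, q)) for q in knots_quantiles)
    p_overall = p_nonlin = np.nan
    if len(set(knots)) == 3:
        S = sm.add_constant(rcs_basis(age, knots))
        try:
            res_full = _fit_logit(y, S)
            res_null = _fit_logit(y, np.ones((len(y), 1)))
            res_lin = _fit_logit(y, sm.add_constant(age))
            k_age = S.shape[1] - 1
            lr_overall = 2.0 * (res_full.llf - res_null.llf)
            p_overall = float(scipy.stats.chi2.sf(max(lr_overall, 0.0), df=k_age))
            lr_nonlin = 2.0 * (res_full.llf - res_lin.llf)
            p_nonlin = float(scipy.stats.chi2.sf(max(lr_nonlin, 0.0), df=k_age - 1))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            separation = True

    return AgeTrendFit(
        or_per_decade=or_pd,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        model=model,
        spline_f_p_overall=p_overall,
        spline_f_p_nonlinear=p_nonlin,
        knots=knots,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# syndrome overlap


@dataclass(frozen=True)
class SyndromeOverlap:
    syndrome: str
    n_all_genes: int
    pct_all: float
    n_major_genes: int
    pct_major: float


def syndrome_overlap(
    assignments: Sequence[GroupAssignment],
    panel: PanelConfig,
) -> list[SyndromeOverlap]:
    """Participant counts per syndrome among group-1 members.

    A participant counts once per syndrome however many qualifying genes
    they carry; a multi-syndrome gene contributes to each of its syndromes.
    The major-gene restriction keeps only genes whose frozen ClinGen level
    for that syndrome is strong or definitive.
    """
    n_total = len(assignments)
    all_sets: dict[str, set[str]] = {s: set() for s in SYNDROMES}
    major_sets: dict[str, set[str]] = {s: set() for s in SYNDROMES}
    for a in assignments:
        if a.group != 1:
            continue
        for _, gene_symbol, _ in a.qualifying_variants:
            gene = panel.gene(gene_symbol)
            for syn in gene.syndromes:
                if syn == "other":
                    continue
                all_sets[syn].add(a.participant_id)
                if is_major_disease_gene(gene, syn):
                    major_sets[syn].add(a.participant_id)
    out = []
    for syn in SYNDROMES:
        n_all = len(all_sets[syn])
        n_major = len(major_sets[syn])
        out.append(
            SyndromeOverlap(
                syndrome=syn,
                n_all_genes=n_all,
                pct_all=round_half_up(100.0 * n_all / n_total, 1),
                n_major_genes=n_major,
                pct_major=round_half_up(100.0 * n_major / n_total, 1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-gene breakdowns


def _qualifying_variant_ids(assignments: Sequence[GroupAssignment], group: int) -> set[str]:
    out: set[str] = set()
    for a in assignments:
        if a.group == group:
            out.update(v for v, _, _ in a.qualifying_variants)
    return out


def gene_breakdown(
    classified: pd.DataFrame,
    assignments: Sequence[GroupAssignment],
    participants: Sequence[Participant],
    panel: PanelConfig,
    category: str,
) -> pd.DataFrame:
    """Per-gene variant counts for one reporting category.

    Categories: ``dominant_plp`` (group-1 qualifying P/LP variants), ``vus``
    (every VUS after reporting rules, all participants) and
    ``recessive_plp`` (het/hemi P/LP in recessive-mode genes, all
    participants).  Percentages are of the category total, integer-rounded;
    median (IQR) age at diagnosis is over carriers of each gene's variants.
    """
    age_by_pid = {p.id: p.age_dx for p in participants}
    if category == "dominant_plp":
        qual = _qualifying_variant_ids(assignments, 1)
        sub = classified[
            classified["coarse_tier"].isin(["P", "LP"])
            & classified["variant_id"].isin(qual)
        ]
        # qualifying ids are per participant-variant pairs; restrict to group-1 members
        g1 = {a.participant_id for a in assignments if a.group == 1}
        sub = sub[sub["participant_id"].isin(g1)]
    elif category == "vus":
        sub = classified[classified["coarse_tier"] == "VUS"]
    elif category == "recessive_plp":
        rec_genes = {
            g.symbol for g in panel.genes if g.is_recessive and not g.is_dominant
        }
        sub = classified[
            classified["coarse_tier"].isin(["P", "LP"])
            & classified["gene"].isin(rec_genes)
            & classified["zygosity"].isin(["het", "hemi"])
        ]
    else:
        raise StatsError(f"unknown category: {category!r}")

    total = len(sub)
    rows = []
    for gene, grp in sub.groupby("gene"):
        ages = np.array([age_by_pid[pid] for pid in grp["participant_id"].unique()
                         if pid in age_by_pid], dtype=float)
        q1, med, q3 = (
            np.percentile(ages, [25, 50, 75]) if len(ages) else (np.nan,) * 3
        )
        rows.append(
            {
                "gene": gene,
                "n_variants": len(grp),
                "pct_of_category": round_half_up(100.0 * len(grp) / total, 0) if total else 0.0,
                "age_dx_median": med,
                "age_dx_iqr_low": q1,
                "age_dx_iqr_high": q3,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_variants", "pct_of_category",
            "age_dx_median", "age_dx_iqr_low", "age_dx_iqr_high",
        ],
    )
    return out.sort_values(["n_variants", "gene"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# VUS burden vs transcript length


def vus_burden_regression(
    vus_counts_per_gene: Mapping[str, int] | pd.Series,
    panel: PanelConfig,
) -> dict:
    """OLS of per-gene VUS count on coding-transcript length (kbp).

    Returns slope (VUS per kbp) with 95% CI and p, plus a per-gene
    observed-minus-predicted excess table.
    """
    counts = pd.Series(dict(vus_counts_per_gene), dtype=float)
    lengths = pd.Series({g: panel.gene(g).transcript_length_kbp for g in counts.index})
    if len(counts) < 3:
        raise StatsError("VUS-burden regression needs >= 3 genes")
    X = sm.add_constant(lengths.to_numpy())
    res = sm.OLS(counts.to_numpy(), X).fit()
    ci = res.conf_int()[1]
    predicted = res.predict(X)
    excess = pd.DataFrame(
        {
            "gene": counts.index,
            "observed": counts.to_numpy(),
            "predicted": predicted,
            "excess": counts.to_numpy() - predicted,
        }
    ).sort_values("excess", ascending=False).reset_index(drop=True)
    return {
        "beta_per_kbp": float(res.params[1]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "p_value": float(res.pvalues[1]),
        "intercept": float(res.params[0]),
        "excess_table": excess,
    }


# ---------------------------------------------------------------------------
# covariate comparison table


def group_covariate_table(
    participants: Sequence[Participant],
    assignments: Sequence[GroupAssignment],
) -> pd.DataFrame:
    """Table-1-style per-group covariate summary with simple tests.

    Binary covariates: per-group n (%) and a 2×2 chi-square of group 1 vs
    the rest.  Continuous covariates: per-group median (IQR) and a
    Kruskal-Wallis rank test across groups.  Degenerate covariates (a single
    observed level) are skipped with a warning.
    """
    group_by_pid = {a.participant_id: a.group for a in assignments}
    df = pd.DataFrame(
        {
            "group": [group_by_pid[p.id] for p in participants],
            "male": [p.sex == "male" for p in participants],
            "hf": [p.hf for p in participants],
            "hf_reduced_ef": [p.hf_type == "reduced_ef" for p in participants],
            "hf_preserved_ef": [p.hf_type == "preserved_ef" for p in participants],
            "white": [p.race == "White" for p in participants],
            "hispanic": [p.ethnicity == "hispanic" for p in participants],
            "age_dx": [p.age_dx for p in participants],
            "age_enroll": [p.age_enroll for p in participants],
        }
    )
    rows = []
    binary = ["male", "hf", "hf_reduced_ef", "hf_preserved_ef", "white", "hispanic"]
    for cov in binary:
        if df[cov].nunique() < 2:
            warnings.warn(f"covariate {cov!r} is constant; comparison skipped")
            continue
        cells = []
        for g in (1, 2, 3, 4):
            sub = df[df["group"] == g]
            n = int(sub[cov].sum())
            cells.append(f"{n} ({round_half_up(100.0 * n / max(len(sub), 1), 1)})")
        table = pd.crosstab(df["group"] == 1, df[cov])
        chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        rows.append([cov, "n (%)", *cells, float(p)])
    for cov in ("age_dx", "age_enroll"):
        cells = []
        samples = []
        for g in (1, 2, 3, 4):
            vals = df.loc[df["group"] == g, cov].to_numpy(dtype=float)
            samples.append(vals)
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                cells.append(f"{med:g} ({q1:g}-{q3:g})")
            else:
                cells.append("-")
        samples = [s for s in samples if len(s)]
        p = float(scipy.stats.kruskal(*samples).pvalue) if len(samples) > 1 else np.nan
        rows.append([cov, "median (IQR)", *cells, p])
    return pd.DataFrame(
        rows,
        columns=["covariate", "summary", "group1", "group2", "group3", "group4", "p_value"],
    )
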