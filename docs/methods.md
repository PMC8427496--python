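# Methods

This note documents the models, parameters, and numerical choices behind
`afpanel`, and the scope of the synthetic-cohort generator.  It describes
what the software computes; it makes no empirical claims beyond what the
code and its test suite compute.

## Panel registry

The shipped panel config (`src/afpanel/data/default_panel.json`) freezes 145
genes partitioned into 87 cardiomyopathy-only, 36 arrhythmia-only, and 22
shared genes.  Each gene carries: syndrome assignments (DCM, HCM, AC/ARVC,
LQTS, CPVT, Brugada, or "other"), a ClinGen gene-disease validity level per
syndrome, inheritance modes (AD/AR/XLD/XLR), a loss-of-function-mechanism
flag, a coding-transcript length in kbp, and a reporting rule.  A gene is a
*major disease gene* for a syndrome when its frozen level is strong or
definitive.  Levels are snapshotted (date-stamped), never fetched live:
curation drifts over time and reproducibility requires a frozen assignment.
Gene records are marked `provenance: stated` when their membership and
metadata come from the study design this package models, and
`provenance: inferred` where the config is schematic.  The
`lof_mechanism` flag is set uniformly true in the shipped config; this is a
simplification, and analyses of real data should curate it per gene.

## Variant ingest

The canonical interchange format is a flat TSV (one record per
participant-variant pair) with `chrom-pos-ref-alt` identifiers; a VCF v4.2
front end (via pysam) maps INFO keys onto the same columns and decomposes
multi-allelic sites.  Processing order is: panel restriction → per-gene
reporting rules (`lof_only` genes keep loss-of-function consequences only)
→ rarity filter (drop records with popmax allele frequency ≥ 0.001; absent
frequency is treated as rare).  Dropped records are counted per cause so
that `records_in = records_out + dropped_off_panel + dropped_reporting_rule
+ dropped_rare` holds for every input; the pipeline logs these counts per
stage.

## ACMG engine

Only codes computable from the ingested annotations auto-trigger:

| code | trigger (defaults) |
|---|---|
| PVS1 | loss-of-function consequence in a `lof_mechanism` gene |
| PM2 | popmax AF absent or < 1e-4 |
| PP5 / BP6 | reputable-source pathogenic / benign assertion |
| PP3 / BP4 | ≥ 75% of ≥ 3 available in-silico predictors deleterious / tolerated |
| BA1 | popmax AF ≥ 0.05 |
| BS1 | popmax AF ≥ 0.01 |

All other ACMG/AMP codes exist in the type system and can be asserted via a
manual-override table but never auto-trigger.  The PM2 "extreme rarity"
threshold (1e-4) is deliberately stricter than the reporting-rarity cutoff
(1e-3): a loss-of-function allele observed at modest population frequency
remains reportable but earns PVS1 alone, which combines to VUS rather than
LP.  Without this separation, every retained LoF variant in a LoF-mechanism
gene would classify ≥ LP and a LoF VUS could never occur — inconsistent
with how clinical labs handle recurrent *TTN* truncating alleles.

Triggered codes are combined with the published ACMG/AMP combining-rule
table (pathogenic rules i-iii, likely-pathogenic i-vi, benign/likely-benign)
exactly; strength modifiers on overrides are respected; simultaneous
pathogenic-side and benign-side rule hits resolve to VUS, and "criteria not
met" defaults to VUS.  VUS calls are sub-tiered into possibly benign /
uncertain / possibly pathogenic by the same predictor-consensus rule.  The
test suite checks the combiner against an independently written brute-force
oracle on every subset of evidence codes up to size 5, plus directional
monotonicity on every enumerated pair.

Dual-review adjudication reports raw percent agreement and Cohen's κ
(`(pₒ − pₑ)/(1 − pₑ)` with marginal-frequency pₑ).  The degenerate case of
two constant, identical raters has pₑ = 1; κ is defined as 1.0 there, with
a warning.  The in-package κ matches `sklearn.metrics.cohen_kappa_score`
(used in tests as an independent oracle only).

## Priority grouping

Each participant receives exactly one group from their classified variants:

1. ≥ 1 P/LP in a dominant-inheritance gene;
2. otherwise ≥ 1 VUS (any sub-tier);
3. otherwise P/LP carrier state in a recessive gene;
4. otherwise nothing suspicious.

X-linked handling is mode-dependent.  Default mode: XLD P/LP qualifies for
group 1 in either sex; a hemizygous male with an XLR P/LP is also group 1.
Strict mode narrows XLD group-1 eligibility to males and treats XLR
variants as carrier findings for everyone.  Two heterozygous P/LP variants
in one recessive gene are flagged biallelic with unknown phase (possible
compound heterozygote — trans configuration is unconfirmable from unphased
data); a homozygous P/LP is flagged biallelic with known phase.

## Statistics

**Bootstrap prevalence.** The 95% CI for a k-of-n proportion is the
2.5th-97.5th percentile band of the resampled proportion over 10,000
resamples with replacement.  Resampling a fixed binary vector with
replacement makes the resampled success count exactly Binomial(n, k/n), so
the implementation draws from that distribution directly — a numerical
shortcut, not an approximation.  Draws use `numpy.random.default_rng(seed)`;
per-age-bin estimates use `seed + bin_index`.  Tests verify convergence of
the percentile endpoints to exact binomial quantiles within one lattice
step (1/n).

**Age trend.** Logistic regression of group-1 membership on age at AF
diagnosis entered as decades of *earlier* diagnosis (−age/10), so an odds
ratio > 1 means younger diagnosis → more findings.  The multivariable
variant adjusts for sex, race (White vs other) and ethnicity (Hispanic vs
not) as binary indicators (near-empty cells make finer encodings unstable);
a constant covariate is dropped with a warning.  Nonlinearity is assessed
with a 3-knot restricted cubic spline (Harrell basis, linear in the tails,
knots at the 10th/50th/90th percentiles of age).  The overall test (all age
terms zero) and the nonlinearity test (nonlinear term zero) are
likelihood-ratio nested-model comparisons referred to chi-square; at this
event count LR tests calibrate better than Wald statistics, and the test
suite checks approximate uniformity of the overall-test p-value under the
null (KS test over 500 seeded replicates).  Perfect separation or
non-convergence raises a flag on the result instead of failing silently.

**Other summaries.** Syndrome overlap counts each group-1 participant once
per syndrome (however many qualifying genes they carry; a multi-syndrome
gene contributes to each of its syndromes), both over all genes and
restricted to major disease genes.  Per-gene breakdowns cover three
categories (group-1 qualifying P/LP; all VUS after reporting rules;
het/hemi P/LP in recessive-only genes) with integer-rounded category
percentages and median (IQR) carrier age.  VUS burden per gene is regressed
on transcript length by OLS, with a per-gene observed-minus-predicted
excess table.  The covariate table compares group 1 vs the rest by 2×2
chi-square for binary covariates and all groups by Kruskal-Wallis for
continuous ones.  Percentages round half-up to one decimal except the
per-gene category shares, which are integer-rounded.

## Synthetic cohorts

Real early-onset-AF sequencing cohorts are access-controlled, so the
package generates stand-in cohorts in two modes.

**Stochastic sampler** (`generate`).  The defaults are the generator's
documented study conditions: n = 1293; age-bin weights 119/143/364/555/112
over <30 / 30-39 / 40-49 / 50-59 / 60-65; male fraction 0.722; dominant-
carrier prevalence 0.101 tied to age through a logistic link with true odds
ratio 1.25 per decade of earlier diagnosis (the intercept is solved
numerically so the mean carrier probability equals the prevalence);
per-gene VUS counts with mean `9.0 + 3.36 × transcript_length_kbp` plus
Gaussian noise (sd 6.0), truncated at zero — the intercept and noise scale
are chosen so truncation is negligible and the generator actually satisfies
its stated linear model; per-gene recessive carrier rates (HFE 0.35, other
recessive genes 0.005); heart-failure base rate 0.155 with a 2.1 odds
multiplier in dominant carriers; reviewer-B disagreement probability 0.082.
Every generated variant's annotation fields are set so the default engine
deterministically reproduces the intended tier (checked exhaustively in
tests).  Identical specs and seeds give byte-identical output files.

**Constructed fixture** (`paper_fixture`).  A fully deterministic cohort
(no randomness at all) whose pipeline outputs hit an exact, internally
consistent set of published counts: groups 131/812/92/258; per-bin group-1
numerators 20/15/36/52/8; 141 dominant P/LP variants across 34 genes (TTN
38, MYH7 18, MYH6 10, LMNA 9, KCNQ1 8) in 131 carriers including nine
multi-variant carriers; 1,979 VUS in 104 genes; 520 recessive P/LP in 11
genes with 82 group-3 HFE carriers (24 with two HFE variants); 494 TTN
missense records removed by the reporting rule; and the participant-level
syndrome overlap table.  Gene identities beyond the named genes, and the
allocation of multi-syndrome carriers, are engineered to satisfy the
printed marginals and are otherwise arbitrary.

**Scope and limitations.** Positions and alleles are schematic
(`chr1-<k>-A-T`); no sequence-level realism (linkage disequilibrium,
population structure, real coordinates, mutational spectra) is attempted.
The generator's covariates (race, ethnicity) are near-degenerate by design,
mirroring a predominantly White cohort; the multivariable model drops
degenerate covariates rather than estimating them.  The constructed
fixture's reviewer table is built to exercise the adjudication statistics,
not to reproduce any particular review process.  None of the synthetic
outputs should be interpreted as clinical evidence; they exist to verify
the pipeline's arithmetic and statistical calibration.

## Numerical choices

- Percentile bootstrap (not BCa); simplest method consistent with a
  percentile-band definition; seeded via `numpy.random.default_rng`.
- Logistic fits via `statsmodels.Logit` (Newton, max 200 iterations);
  Wald CIs for the odds ratio; LR tests for the spline terms.
- Restricted cubic spline basis authored in-package (Harrell
  parameterization, k−1 columns for k knots, nonlinear terms normalized by
  (t_k − t_1)²); no installed library exposes this basis directly.
- Half-up decimal rounding (`decimal.Decimal`) for reported percentages, to
  match the convention of printed clinical tables rather than banker's
  rounding.
- All thresholds (PM2/BA1/BS1 frequencies, predictor-consensus fractions,
  rarity cutoff, knot quantiles, bootstrap size) are configuration with the
  defaults above; seeds are required inputs for any stochastic operation
  and are echoed in every report manifest.
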