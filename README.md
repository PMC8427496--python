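# afpanel

Variant triage and cohort-yield analysis for gene-panel sequencing of
early-onset atrial fibrillation (AF) cohorts.

## The scientific problem

When people diagnosed with AF before age 66 are sequenced on a comprehensive
arrhythmia/cardiomyopathy gene panel, what fraction carry a clinically
significant ("disease-associated") variant, and how does that fraction depend
on how young they were at diagnosis?  Answering this requires a chain of
steps, each with enough rules to deserve its own tested implementation:

1. **Panel registry** — a frozen 145-gene panel (87 cardiomyopathy-only,
   36 arrhythmia-only, 22 on both) with per-gene syndrome assignments,
   ClinGen gene-disease validity levels, inheritance modes, and reporting
   rules (e.g. *TTN* reports loss-of-function variants only).
2. **Variant ingest** — per-participant annotated variants from TSV or VCF,
   restricted to panel genes, with per-gene reporting rules and a population
   rarity filter; every dropped record is accounted for.
3. **ACMG engine** — deterministic assignment of the computable ACMG/AMP
   evidence codes (PVS1, PM2, PP5/BP6, PP3/BP4, BA1/BS1), the published
   combining rules down to pathogenic (P) / likely pathogenic (LP) / VUS /
   likely benign / benign, VUS sub-tiers by in-silico consensus, manual
   overrides, and dual-reviewer adjudication (raw agreement + Cohen's κ).
4. **Priority grouping** — each participant lands in exactly one group:
   1 = P/LP in a dominant-inheritance gene, 2 = VUS, 3 = recessive carrier
   (with biallelic/phase flags), 4 = nothing suspicious; X-linked genes are
   handled sex- and mode-aware.
5. **Cohort statistics** — age-binned prevalence with seeded percentile
   bootstrap CIs (10,000 resamples), logistic models of detection vs age at
   diagnosis (odds ratio per decade of earlier diagnosis, plus a 3-knot
   restricted cubic spline with likelihood-ratio overall/nonlinearity
   tests), participant-level syndrome overlap, per-gene breakdowns, VUS
   burden vs transcript length, and a Table-1-style covariate comparison.
6. **Synthetic cohorts** — real AF sequencing cohorts are access-controlled,
   so a seeded generator produces stand-in cohorts with the statistical
   structure the analysis assumes, and a constructed fixture reproduces a
   published study's printed counts exactly for end-to-end verification.

See `docs/methods.md` for the statistical model and its limitations.

## Worked example

Generate the constructed demonstration cohort (1,293 participants) and run
the full pipeline:

```sh
afpanel synth paper-fixture --out cohort/
afpanel run --variants cohort/variants.tsv \
            --participants cohort/participants.tsv \
            --reviews cohort/reviews.tsv \
            --boot 10000 --seed 0 --out report/
```

This prints:

```
Panel triage summary
===================

group 1 (dominant P/LP (disease-associated variant)): 131 (10.1%)
group 2 (VUS only): 812 (62.8%)
group 3 (recessive carrier): 92 (7.1%)
group 4 (no suspicious variant): 258 (20.0%)
total participants: 1293

prevalence of disease-associated variants by age at diagnosis:
     <30: 20/119 = 16.8% (95% CI 10.1-23.5)
   30-39: 15/143 = 10.5% (95% CI 5.6-15.4)
   40-49: 36/364 = 9.9% (95% CI 6.9-13.2)
   50-59: 52/555 = 9.4% (95% CI 7.0-11.9)
   60-65: 8/112 = 7.1% (95% CI 2.7-12.5)

odds of a finding per decade of earlier diagnosis: 1.22 (95% CI 1.05-1.42; P=0.011)
reviewer agreement: 91.7% (kappa=0.823)
```

`report/` then contains `report.json` (machine-readable summary with a
manifest of seeds, input digests, and engine thresholds), `report.txt`,
per-participant `assignments.tsv`, the fully classified variant table, the
per-gene breakdown tables, and the covariate comparison.

The same pipeline is available as a library:

```python
import afpanel as ap

panel = ap.load_panel()                      # shipped 145-gene panel
cohort = ap.paper_fixture(panel)             # deterministic demo cohort
table = ap.rare_filter(ap.apply_reporting_rules(cohort.variant_table(panel), panel), 0.001)
classified = ap.classify_table(table, panel)
assignments = ap.assign_groups(cohort.participants, classified, panel)
ap.group_counts(assignments)                 # {1: 131, 2: 812, 3: 92, 4: 258}
```

Other CLI verbs: `afpanel panel validate|summary`, `afpanel ingest`,
`afpanel classify`, `afpanel group`, `afpanel stats`,
`afpanel synth generate --spec spec.json --seed N`.

## Reproduction

Everything stochastic is seeded, and all fixtures are generated
programmatically (no binary data ships with the package).

```sh
pip install --no-build-isolation -e .[test]
python -m pytest -q tests/           # full suite, ~2 minutes on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite verifies the constructed fixture end to end, checks the
bootstrap CI machinery against an exact binomial-quantile oracle, compares
the ACMG combining rules against an independently written brute-force oracle
over an exhaustive enumeration of evidence-code subsets, and runs seeded
parameter-recovery and null-calibration simulations for the regression
surface.  `scripts/acceptance.py` recomputes the bootstrap-CI summary
quantity from scratch and writes it as JSON.

## Layout

```
src/afpanel/
  panel.py       panel registry and validation (shipped config in data/)
  ingest.py      TSV/VCF ingest, reporting rules, rarity filter
  acmg.py        evidence codes, combining rules, VUS sub-tiers, kappa
  grouping.py    priority groups 1-4, X-linked handling, biallelic flags
  stats.py       bootstrap CIs, logistic/spline trends, overlaps, regressions
  synthetic.py   seeded cohort generator + constructed demo fixture
  pipeline.py    end-to-end orchestration and report bundles
  cli.py         click CLI (console script `afpanel`)
```
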