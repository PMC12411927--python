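# prpecon

Analysis toolkit for evaluating a **low-cost platelet-rich plasma (LC-PRP)**
preparation as a knee-osteoarthritis injection therapy, from the injectate's
cellular composition through to a payer-perspective cost-effectiveness
verdict against corticosteroid injection.

The package is aimed at musculoskeletal / sports-medicine researchers and
health economists who want to analyse (or prototype analyses of) single-arm
PRP cohorts: paired whole-blood/PRP cell counts, longitudinal WOMAC and
EQ-5D patient-reported outcomes, bottom-up micro-costing, and a Markov
cohort cost-effectiveness model with probabilistic sensitivity analysis
(PSA). A synthetic-cohort generator with the same statistical structure
makes every stage runnable and testable without patient data.

## What it computes

**Composition** — for each injection with paired complete blood counts,
platelet dose *D = C·V*/1000 (×10⁹), platelet extraction/yield
*E = D_PRP / D_WB* (a dose ratio — the fraction of drawn platelets
recovered), and concentration factor *F = C_PRP / C_WB*. Cohort summaries
report the mean per-injection extraction with a t-based 95% CI and the
ratio-of-mean-doses "cohort extraction", and compare against published
commercial-kit extraction (mean 0.45, range 0.30–0.60) by CI disjointness.
Observed *E* > 1 (cell-counter noise) is flagged, never clamped.

**Outcomes** — two-sided Wilcoxon signed-rank tests of each follow-up visit
(1/3/6/12 months) against baseline, with an exact 2ⁿ-enumeration null for
small tie-free samples, a seeded permutation test under ties, and a tie- and
continuity-corrected normal approximation otherwise; median (IQR) visit
summaries; MCID responder analysis (default threshold 6.6 WOMAC points);
and exact binomial / Fisher power calculations for superiority designs.

**Costing** — per-injection micro-cost in exact integer cents: itemized
supplies + medical-assistant time × wage + medication.

**CEA** — a Markov cohort model (default: single alive state on a 3-month
cycle grid, 12-month horizon) evaluating expected payer cost per strategy
and QALYs as the trapezoid area under the EQ-5D utility curve; ICER /
dominance classification against a $100,000/QALY willingness-to-pay;
PSA with method-of-moments gamma (costs) and beta (utilities) draws,
CE-plane output, probability of dominance, and the acceptability curve
(CEAC) from net monetary benefit NMB = λ·ΔE − ΔC.

## Worked example

```python
from prpecon import CBCPanel, compute_metrics, run_base_case, run_psa
from prpecon.cea import reference_case

# one injection: 45 mL whole blood at 183 ×10^3/uL, 14.9 mL PRP at 485.4
wb  = CBCPanel("inj1", "whole_blood", 45.0, 183.0)
prp = CBCPanel("inj1", "prp", 14.9, 485.4)
m = compute_metrics(wb, prp)
print(round(m.extraction_rate, 3), m.concentration_factor_reported)
# 0.878 2.7   -> 87.8% of drawn platelets recovered, 2.7x concentrated

# payer model: two LC-PRP injections vs two corticosteroid injections
lc, cortico, config = reference_case(seed=1)
base = run_base_case(lc, cortico, config)
print(base.costs, base.qalys, base.verdict)
# (654.0, 1308.0) (0.846, 0.708) dominant

psa = run_psa(lc, cortico, config)
print(psa.prob_dominant)
# 1.0   -> LC-PRP saves cost AND gains QALYs in all 10,000 draws
```

LC-PRP costs $654 for two injections and yields 0.846 QALYs over the year
versus $1308 and 0.708 QALYs for corticosteroid — lower cost *and* higher
effectiveness, i.e. a dominant strategy (no ICER is reported for dominance);
the incremental net monetary benefit at $100,000/QALY is $14,454.

The same stages are available as a CLI:

```bash
prpecon simulate --seed 1 --outdir out      # synthetic cohort CSVs
prpecon composition --panels out/cbc_panels.csv
prpecon outcomes --data out/outcomes.csv --mcid 6.6 --cluster knee
prpecon cost --wage 21 --minutes 20
prpecon cea --seed 1 --n-psa 10000
prpecon run --outdir results --seed 1       # full pipeline + report.json
```

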