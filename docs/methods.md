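# Methods

This note documents the models, calibration choices and numerical
conventions behind `prpecon`, and what the synthetic cohort does and does
not establish.

## Composition metrics

Platelet dose is the exact unit conversion D = C × V / 1000 (concentration
in ×10³/µL times volume in mL gives ×10⁹ platelets). Extraction
E = D_PRP / D_WB is a **dose** ratio: it measures what fraction of the drawn
platelet mass reaches the injectate, and is the right efficiency metric for
a large-volume preparation whose concentration factor is modest. Two cohort
summaries are exposed deliberately:

* `mean_extraction` — the mean of per-injection extraction rates (matches
  per-subject trajectory plots);
* `cohort_extraction_ratio_of_means` — mean PRP dose over mean whole-blood
  dose (the arithmetic behind a headline figure like 7.12/8.38 = 85.0%).

These differ on skewed data (Jensen); the tests assert they do. The 95% CI
on mean extraction uses the t distribution (mean ± t₀.₉₇₅,ₙ₋₁·SD/√n) —
appropriate at n ≈ 30–60 injections; the comparison against published
techniques is a CI-disjointness verdict, which is conservative relative to
a formal two-sample test. Extraction above 1 is physically impossible but
observable under multiplicative counter noise; such values are flagged
(`EXTRACTION_GT_ONE`) and retained in all averages, never truncated, since
truncation would bias the mean downward. Leukocyte-rich is defined as PRP
WBC concentration strictly above whole blood; equality counts as poor.
Concentration factor is reported at one decimal; full precision is kept
internally. Whole-blood panels flagged invalid are excluded from extraction
pairs but their PRP mates remain in PRP-only summaries.

## Wilcoxon signed-rank testing

Differences are follow-up minus baseline; zero differences are dropped
before ranking (the classic convention rather than Pratt's — the most
common default, declared explicitly) and counted. Midranks break ties.
Method selection:

* **exact** — tie-free and n ≤ 20: the null distribution of W⁺ is built by
  convolving the rank generating function (equivalent to enumerating all 2ⁿ
  sign assignments); the two-sided p is the null probability of a statistic
  at least as far from n(n+1)/4 as observed (the distribution is symmetric).
* **permutation** — ties and n ≤ 25: 10⁵ seeded random sign flips with the
  add-one estimator (B+1 denominator), same two-sided deviation criterion.
* **normal_approx** — otherwise: tie-corrected variance
  n(n+1)(2n+1)/24 − Σ(t³−t)/48 with a 0.5 continuity correction.

All-zero differences give p = 1 with a degenerate-data flag. The default
unit of analysis is the knee; `cluster="patient"` collapses bilateral knees
to patient means before pairing, since ~30 knees from ~20 patients leaves
the clustering question open and both analyses should be one switch apart.

IQRs use linear-interpolation (type-7) quantiles throughout — a convention
that must be pinned for reproducibility because integer WOMAC data make the
quantile definition visible. MCID responder status is boundary-inclusive
(improvement ≥ threshold) so the boundary case is deterministic.

## Exact power / sample size

For a superiority design on a proportion (reference p₀ = 0.45 vs
alternative p₁ = 0.90, α = 0.05 two-sided, power 0.80), two exact designs
are computed by full enumeration, never simulation: a one-sample exact
binomial test (rejection region from minimum-likelihood two-sided
p-values) and a two-sample Fisher exact test at equal allocation. Exact
binomial power is not monotone in n (discreteness), so the search scans
upward. Both n's are reported side by side because a design statement like
"Fisher's exact test of superiority over 0.45" does not pin down the
one- vs two-sample structure.

## Micro-costing

Currency lives in integer cents; line totals and labor (wage × minutes/60)
round half-up at the cent, and the reported per-injection figure rounds
half-up to whole dollars — whole-dollar prices assembled from sub-dollar
components. The supply list ($4.00), 20 minutes of medical-assistant time
at $21/h ($7.00) and no medication give the LC-PRP injectate at $11; the
comparator is a $10 triamcinolone vial with neither supplies nor dedicated
labor. Facility and physician fees are deliberately not part of the
injectate micro-cost; they enter the payer model below. Labor time defaults
to the measured 20-minute mean but `LaborInput.from_timing_log` recomputes
it from per-injection timing records.

## Cost-effectiveness model

The cohort engine is a generic Markov state-occupancy model (row-stochastic
transition matrix, occupancy propagated per cycle). The default structure
is a **single alive state**, which collapses the evaluation to an
area-under-the-curve model on the cycle grid: this reproduces every target
output without inventing health states the data cannot identify, while
richer structures remain configurable through the engine. The base case is
invariant to cycle subdivision (tested to 1e-9).

* Horizon 12 months, cycle 3 months, discount rate 0 (standard at ≤ 1-year
  horizons).
* Costs: scheduled injections × (per-injection payer cost + medication),
  discounted per cycle when a rate is set.
* Effectiveness: QALYs as trapezoid AUC of EQ-5D utilities at the observed
  timepoints (months 0, 1, 3, 6, 12), converted to years. No half-cycle
  correction — utility timepoints, not cycles, carry the effectiveness
  information.
* Dominance/ICER: ΔC < 0 ∧ ΔE > 0 → dominant (no ICER printed);
  ΔC > 0 ∧ ΔE < 0 → dominated; otherwise ICER = ΔC/ΔE with a quadrant
  label. Incremental NMB = λΔE − ΔC is always reported (λ default
  $100,000/QALY).

### PSA

Each (mean, SE) parameter is moment-matched: gamma for costs
(k = (mean/se)², θ = se²/mean), beta for utilities
(ν = mean(1−mean)/se² − 1, α = mean·ν, β = (1−mean)·ν); SE = 0 is a point
mass. A parameter supplied without an SE defaults to SE = 20% of its mean
and is so documented. Draw order is fixed — for each strategy in order:
payer cost, medication cost, utilities by timepoint — from a single numpy
`default_rng(seed)` stream (PCG64), so a seed fully determines the PSA.
Outputs: CE-plane draws, probability of dominance (strict quadrant count),
probability of positive incremental NMB at λ, and the CEAC over a
$0–200k grid.

### Reference case calibration

The original model-input table is not publicly deposited, so the package
ships a **synthetic calibration fixture** (`cea.reference_case`) that
reproduces the published totals under the documented schedule assumptions:

* Two injections per strategy ("payer comparability"); LC-PRP both in cycle
  0 (three weeks apart), corticosteroid at months 0 and 3. The
  every-3-months standard-of-care reading (4 injections) is available via
  `cortico_injections=4`.
* Per-injection payer cost $327 (LC-PRP: physician + facility + $11
  injectate) and $644 + $10 medication (corticosteroid), giving $654 vs
  $1308 totals.
* Utility timepoints solved exactly against the trapezoid formula:
  LC-PRP (0.70, 0.81, 0.85, 0.87, 0.849) → 0.846 QALYs; corticosteroid
  (0.70, 0.7300, 0.7204, 0.70, 0.70) → 0.708 QALYs. Both arms share the
  0.70 baseline; the corticosteroid trajectory rises then wanes, consistent
  with short-lived steroid effect.
* SEs: $30 / $50 / $2 for costs, 0.02 for utilities — plausible standard
  errors of cohort means at n ≈ 30 knees. At these SEs the incremental cost
  separates the arms by ≈ 5.6 standard deviations and the incremental QALY
  by ≈ 9, so dominance in every one of 10,000 draws is the expected
  outcome; markedly wider SEs (e.g. a blanket 20% of mean) would make
  all-draw dominance essentially impossible, which is why the fixture
  carries explicit SEs instead of the fallback rule.

The corticosteroid arm's utilities are synthesized from the configured
profile, not taken from any comparator dataset.

## Synthetic cohort generator

Defaults are the study-scale conditions: 20 patients, 50% bilateral
(30 knees), two injections per knee three weeks apart with one randomly
chosen patient receiving a single injection (58–59 injections), three
whole-blood panels flagged invalid, K–L grades drawn from {1, 2, 3} with
probabilities 11/30, 12/30, 7/30.

* **Blood**: whole-blood platelets ~ N(183.0, 51.4) ×10³/µL over a fixed
  45 mL draw; PRP volume ~ N(14.9, 3.0) mL; true extraction ~ N(0.85, 0.08)
  truncated to (0.05, 1]; the PRP concentration is true extraction × whole-
  blood platelet mass over the PRP volume, perturbed by mean-one log-normal
  noise with CV 0.05. Multiplicative noise is what lets observed extraction
  exceed 1 without truncation, and mean-one noise keeps the observed mean
  at the configured truth (tested by 3-SE recovery at 200 patients).
  Platelet values and volumes are reported at counter granularity (0.1)
  *before* deriving the PRP concentration, so the zero-noise configuration
  yields exactly the configured extraction. WBC differentials are built as
  neutrophils + lymphocytes + other, so the differential invariant holds by
  construction (whole blood ≈ 3.1/1.4/0.4; PRP ≈ 0.08/2.6/0.6 — a
  neutrophil-depleted, lymphocyte-enriched profile).
* **WOMAC**: 24 Likert items (pain 5, stiffness 2, function 17; each 0–4)
  drawn Binomial(4, p) around a per-knee latent severity. The latent is
  gamma-distributed, with (shape, scale) solved numerically so that the
  **observed** total — the gamma-binomial mixture, computed by quadrature —
  has exactly the target baseline median 19.5 and IQR 12.5. Integer items
  guarantee ties and zero differences for the signed-rank edge cases.
  Follow-up severity is the baseline latent times the per-visit effect
  profile (defaults 7.0/19.5, 7.0/19.5, 5.5/19.5, 6.5/19.5), so expected
  follow-up totals are strictly decreasing in the configured improvement.
  Bilateral knees share a patient-level Gaussian-copula random effect
  (correlation 0.6 — a free choice in the plausible range for within-person
  joint severity, exercised but not asserted precisely by the tests).
* **Utilities and satisfaction**: per-visit normal draws (SD 0.10) around
  the arm's utility profile, clipped to [0, 1]; satisfaction as Bernoulli
  draws of the configured per-visit probabilities; global assessment normal
  around 60/70/75/80/70 (SD 12), clipped to [0, 100]. Two satisfaction
  fields are kept distinct — satisfaction with the knee (dissatisfaction
  85% at baseline) and satisfaction with the procedure (follow-ups only) —
  because they answer different questions.

**What passing tests show and do not show.** The generator reproduces
summary-level calibration targets (means, medians/IQRs, proportions,
correlation structure) and the qualitative improvement signal; it does not
reproduce any real patient's trajectory, the original per-visit p-values,
satisfaction percentages, or adverse-event rates, all of which depend on
unavailable individual-level data. Tests passing on synthetic cohorts
therefore validate the *machinery* (estimators, tests, model arithmetic,
calibration recovery), not clinical conclusions about PRP.

## Pipeline and reproducibility

`run_all` executes simulate → composition → outcomes → cost → CEA; a stage
failure halts downstream stages but upstream outputs and the manifest (with
SHA-256 digests of every file written) survive. One global seed fans out to
per-stage child seeds by SHA-256 of `"{seed}:{stage}"` folded below 2³¹, so
adding a stage never perturbs another stage's stream; all randomness flows
through numpy `default_rng`. Fixed seed ⇒ byte-identical outputs (tested).

Problem sizes used by the shipped checks: study scale (20 patients /
30 knees) for structure and significance checks, 200 patients for
parameter-recovery checks, 10⁶ draws for distribution-moment round trips,
10⁴ PSA draws for the dominance probability, 100 seeded replicates for the
signed-rank power estimate.

## Known limitations

* The CEA reference case is a calibration, not the original input table;
  conclusions transfer only insofar as the documented assumptions hold.
* The single-alive-state default ignores mortality and treatment switching;
  both would need explicit states and transition probabilities.
* The CI-disjointness comparison against published techniques is
  conservative; no formal meta-analytic comparison is attempted.
* The generator draws visits independently given the latent severity, so
  within-knee autocorrelation beyond the shared latent is not modelled.
* No multiplicity adjustment across measures/visits (matching the unadjusted
  0.05 convention of small pilot analyses).
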