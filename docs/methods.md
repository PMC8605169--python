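# Methods

## Scope and model

`usigma` evaluates the analytical performance of quantitative urinary
biochemical assays on the six-sigma scale and derives risk-based
statistical QC (SQC) designs from it.  The analysis is cross-sectional:
one IQC series and one EQA replicate panel per (laboratory, analyte,
control level) yield one performance verdict.  There is no longitudinal
drift monitoring and no post-improvement re-evaluation.

The performance model has three inputs, all expressed as percent of the
measured concentration and therefore scale- and unit-free:

* `CV%` — imprecision, from the IQC series: `100 · SD/mean` with the
  sample SD (n−1 denominator), the standard estimator for IQC
  imprecision.  No outlier exclusion is applied before the CV; any
  screening belongs to the laboratory's own IQC review, not this
  estimator.
* `bias%` — trueness, from EQA replicates measured in one batch against a
  peer-group consensus target.  Each replicate gives a signed percent
  difference; the default summary is **the absolute value of the signed
  mean** (`mean_then_abs`).  The alternative reading — mean of absolute
  differences (`abs_then_mean`) — is selectable, because QC practice is
  genuinely split on it; the two differ only when replicates straddle the
  target (a worked pair: offsets +2/−2/+2/−2/+2 % give 0.4 % vs 2.0 %).
  With a consensus target from ~140 peer laboratories the target is a
  convention, not a true value; bias here is relative trueness.
* `TEa%` — the quality goal.  The built-in table carries the
  state-of-the-art goals for the ten urinary analytes (K 29, Na 26,
  Cl 26, Ca 31, P 23, GLU 20, Urea 21, Crea 17, TP 44, mALB 30 %);
  custom goals load from JSON.

From these: `sigma = (TEa − |bias|)/CV`.  Sigma may be negative (bias
alone exceeding the goal) and is not clamped.  A zero CV yields an
infinite sentinel with a warning rather than an exception.

Defects per million uses the conventional one-sided 1.5σ-shift scale,
`DPM = 10⁶ · Φ̄(σ − 1.5)`; it is the only common convention that gives the
canonical 3.4 per million at six sigma.

## Decision chart

On normalized axes x = 100·CV/TEa, y = 100·bias/TEa every sigma level s is
the line `y = 100 − s·x`; the lines for s = 2..6 divide the plane into six
zones.  Bands are closed on their lower sigma edge (σ = 6.0 is
world-class; σ = 5.999 is not).  Values within 1e−9 of an edge are snapped
onto it so a point constructed exactly on a boundary line never falls to
the worse band through float rounding.  Axes are fixed at 0–100 %;
off-scale points are clamped to the margin and drawn as open triangles.
SVG is assembled by hand with fixed float formatting so output is
byte-identical for identical input — charts are diffable and testable.

## SQC strategy selection

The Westgard sigma-rules bands used are:

| effective σ | rules | N / event | events | run size |
|---|---|---|---|---|
| ≥ 6 | 1_3s | 2 | 1 | 1000 |
| 5 ≤ σ < 6 | 1_3s/2_2s/R_4s | 2 | 1 | 450 |
| 4 ≤ σ < 5 | 1_3s/2_2s/R_4s/4_1s | 4 | 1 | 200 |
| 3 ≤ σ < 4 | + 8_x | 4 | 1 | 45 |
| < 3 | + 8_x, improvement flag | 4 | 2 | 23 |

The effective sigma across the two control levels is their **minimum** —
the conservative policy, and the unique simple policy consistent with
every strategy cell of the reference survey in `usigma.datasets` (no
mixed-band pair occurs there, so min vs mean is empirically
indistinguishable on that surface; min is chosen as the design that
protects the worse level).  The two bands below 4σ follow the published
sigma-rules convention and are override-able (`select_strategy(bands=...)`)
since sub-4σ assays do not occur in the reference survey.  N = 4 is read
as 2 materials × 2 measurements per event; run size is patient samples
between bracketing QC events, distinct from QC events per run.

Rule semantics in the evaluation engine: limits are strict (`|z| > 2`,
not ≥ — boundary hits are measure-zero on continuous data); `2_2s`,
`4_1s`, `8_x` count consecutively across the two materials within a run
(level order) and then across runs, with a violation charged to the run
containing its final observation; `R_4s` is within-run only and requires
opposite-side excursions beyond ±2 SD with range > 4 SD.

## Synthetic data

The generator emulates the stated IQC cadence (two measurements a day for
six months → n = 360 per level) and 5-replicate EQA panels.  Measurement
noise is i.i.d. Gaussian with constant CV within a level; bias enters as
one multiplicative shift applied to both IQC material and EQA sample,
since sigma combines the two as properties of a single analytical state.
A master seed spawns per-scenario substreams keyed by a stable hash of
(lab, analyte, level), so adding scenarios never changes existing draws
and the fixture build is byte-identical for a fixed seed.  The default
grid (5 labs × 10 analytes × 2 levels) spreads true sigma evenly over
4–18, sets true bias at 6–14 % of TEa and derives CV from the two — which
lands CVs in the 1–10 % range typical of automated urinary chemistry.
Concentrations are plausible urinary levels per analyte but are
irrelevant to every statistic (all metrics are percent-based).

What the generator does **not** model: drift, shifts, autocorrelation,
between-lot reagent effects, non-Gaussian tails.  A green recovery test
therefore establishes that the estimators and pipeline are correctly
wired and calibrated for stationary Gaussian data — not that real-world
series behave this way.

### The EQA noise floor

A 5-replicate bias estimate has standard error `CV/√5` percent points,
which propagates to an **absolute** sigma error of about `1/√5 ≈ 0.45`
sigma units independent of CV (the CV cancels between numerator noise and
denominator).  Adding the IQC contribution, the sigma estimate's sd is
≈ `√(0.2 + (0.037·σ)²)`.  Consequences, verified by the test suite: for
true sigma near 4, only about two-thirds of realizations land within ±10 %
of truth; scenarios just above a band edge mis-band a few percent of the
time.  Tightening either figure requires more EQA replicates, not better
code — the dedicated recovery tests document the measured rates
(81.4 % within ±10 % for σ ≤ 10; 98.5 % band recovery ≥ 0.5σ from edges)
alongside a diagnostic that meets both bars when the exact bias is
substituted, isolating the noise floor as the cause.

## Improvement classification

QGI = |bias|/(1.5·CV) is computed only below six sigma (at goal there is
nothing to prioritise).  QGI < 0.8 → imprecision; QGI > 1.2 → trueness;
equality on either boundary belongs to the middle "both" class, following
the convention that the named classes are strict ("less than 0.8", "more
than 1.2").  In study reports the improvement table carries both levels'
sigma and QGI; per-level labels are collapsed to one only when they
agree, otherwise both are emitted joined — disagreement is never hidden.

## Reporting conventions

Report CSVs round floats half-even to 2 decimals (presentation
precision); `metrics.json` keeps full precision.  `provenance.json`
records input SHA-256 digests and the configuration, and contains no
timestamps, so the entire report directory is byte-identical across
reruns on fixed input.  An IQC key without a matching EQA key is listed
as skipped in the report rather than raised — partial studies are normal.

## Known limitations

* Bias is EQA-replicate based only; no method-comparison (regression
  against a reference procedure) bias, and no uncertainty intervals on
  sigma — the metric is reported as a point value, and the noise floor
  above shows those intervals would not be negligible.
* No probability-of-error-detection power curves or patient-risk
  (max E(Nuf)) computation behind the strategy bands; the bands are
  applied as published conventions.
* TEa goals are state-of-the-art (EQA-derived) rather than grounded in
  biological variation, which is unavailable for urinary analytes.
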