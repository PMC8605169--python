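# usigma — six-sigma analytical performance for urinary biochemistry QC

`usigma` turns the raw quality-control output of a clinical laboratory —
internal-QC (IQC) measurement series and external-quality-assessment (EQA)
replicate panels — into a quantitative verdict on each urinary biochemical
assay (potassium, sodium, chloride, calcium, phosphorus, glucose, urea,
creatinine, total protein, microalbumin) and a concrete, risk-based
statistical QC design for running it.  It is written for laboratorians and
QC software engineers who want the full chain — imprecision, trueness,
sigma metric, decision chart, Westgard rules, improvement priority — as one
tested, scriptable pipeline instead of a spreadsheet.

## The model

For each assay and control level:

* **Imprecision** `CV% = 100 · SD/mean` from the IQC series (sample SD,
  n−1 denominator).
* **Trueness** from an EQA sample measured five times against its
  peer-group target: per-replicate signed differences
  `bias_i = (x_i − target)/target × 100`, summarised (by default) as the
  absolute value of their mean.
* **Sigma metric** `σ = (TEa − |bias|)/CV`, where TEa is the total
  allowable error for the analyte (built-in goal table for urinary
  chemistry, or your own JSON).  σ counts how many analytical SDs fit
  between current performance and the quality goal; σ ≥ 6 is world-class
  (3.4 defects per million under the conventional 1.5σ long-term shift).
* **Decision chart**: plotting bias/TEa against CV/TEa makes every sigma
  level a straight line `y = 100 − σ·x`, dividing the plane into six
  performance zones (rendered as deterministic SVG).
* **SQC strategy** (Westgard sigma rules): the worst level's σ picks the
  control rules, number of control measurements N and run size — from a
  lone `1_3s` with N=2 and 1000 patient samples per run at σ ≥ 6 down to
  the full multirule set with shortened runs below 4σ.  A multirule engine
  (`1_3s`, `2_2s`, `R_4s`, `4_1s`, `8_x`) is included to apply the chosen
  strategy to control data.
* **Improvement priority** for sub-six-sigma assays via the quality goal
  index `QGI = bias/(1.5·CV)`: < 0.8 → fix imprecision first, > 1.2 → fix
  trueness first, between → both.

A synthetic-data module generates IQC/EQA fixtures with known true CV,
bias and sigma (Gaussian noise, constant CV, multiplicative bias shift) so
the whole pipeline is testable without confidential laboratory data.

## Worked example

```python
from usigma import PerformanceRecord, select_strategy

# Lab A, urinary urea, level-1 control: CV 3.48%, bias 1.20%, TEa 21%
r = PerformanceRecord("Lab A", "Urea", "level1",
                      cv_percent=3.48, bias_percent=1.20, tea_percent=21.0)
print(round(r.sigma, 2), round(r.qgi, 2), r.zone, r.improvement)
# 5.69 0.23 6>sigma>=5 imprecision

s = select_strategy({"level1": r.sigma, "level2": 5.16})
print(s.rules, s.n_controls, s.run_size)
# ('1_3s', '2_2s', 'R_4s') 2 450
```

Read: the assay sits at 5.69σ, just short of world-class, in the 5–6σ zone
of the decision chart.  Its QGI of 0.23 (< 0.8) says the shortfall is
imprecision, so tighten repeatability before chasing calibration.  Until
then it should be controlled with the `1_3s/2_2s/R_4s` multirule, two
control measurements per QC event, and a QC bracket every 450 patient
samples.

The same chain as one command, on synthetic data:

```bash
usigma simulate --seed 7 --out fixtures/
usigma run --iqc fixtures/iqc.csv --eqa fixtures/eqa.csv --out report/
```

which writes `metrics.csv`, `strategies.csv`, `improvement.csv`, one
decision-chart SVG per control level, `report.md` and `provenance.json`
(input SHA-256 digests; outputs are byte-identical across reruns).
Library users get the same result as a model fit:
`SixSigmaModel.from_csv(...).fit()` returns a results object with the
three tables, `summary()`, `plot_decision_chart()` and `save()`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package's strategy selection on the per-level
sigma pairs of a published five-laboratory urinary-chemistry survey
(shipped in `usigma.datasets`), the run sizes selected for three reference
assays, and writes them as JSON.

See `docs/methods.md` for the statistical conventions, synthetic-data
design and known limitations.
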