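"""Core analytical-performance statistics: CV, bias, sigma, DPM, QGI.

The sigma metric counts how many analytical standard deviations fit between
current performance and the quality goal::

    sigma = (TEa% - |bias%|) / CV%

where CV% is the imprecision estimated from an internal-QC series (sample SD
over mean, n-1 denominator) and bias% is the trueness error estimated from
EQA replicates against a peer-group target.  Six sigma corresponds, under
the conventional 1.5-sigma long-term shift, to 3.4 defects per million
results.  For assays below six sigma the quality goal index

    QGI = bias% / (1.5 * CV%)

apportions the shortfall: QGI < 0.8 points at imprecision, QGI > 1.2 at
trueness, values between at both.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ComputationError, InsufficientDataError
from .io import EQAReplicateSet, IQCSeries

__all__ = [
    "BiasResult",
    "PerformanceRecord",
    "compute_cv",
    "compute_bias",
    "sigma_metric",
    "sigma_to_dpm",
    "qgi",
    "classify_improvement",
    "BIAS_CONVENTIONS",
    "IMPROVEMENT_CLASSES",
]

BIAS_CONVENTIONS = ("mean_then_abs", "abs_then_mean")
IMPROVEMENT_CLASSES = ("none", "imprecision", "trueness", "both")

#: QGI thresholds separating the dominant-problem classes
QGI_LOW = 0.8
QGI_HIGH = 1.2

#: long-term process-shift allowance used on the defects-per-million scale
SIGMA_SHIFT = 1.5


def compute_cv(series: IQCSeries | np.ndarray) -> float:
    """Imprecision CV (%) of an IQC series: 100 * sample SD / mean.

    Uses the n-1 denominator, the standard choice for IQC imprecision.
    A zero-variance series returns 0.0 with a warning (it is almost always a
    transcription artefact, not real performance).
    """
    values = series.array if isinstance(series, IQCSeries) else np.asarray(series, float)
    if values.size < 2:
        raise InsufficientDataError(f"CV needs >=2 values, got {values.size}")
    mean = values.mean()
    if mean <= 0:
        raise ComputationError(f"CV undefined for non-positive mean {mean}")
    sd = values.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero-variance IQC series: CV = 0", stacklevel=2)
        return 0.0
    return 100.0 * sd / mean


@dataclass(frozen=True)
class BiasResult:
    """Per-replicate signed percent differences and their non-negative summary."""

    per_replicate_bias_percent: tuple[float, ...]
    bias_percent: float
    convention: str = "mean_then_abs"

    @property
    def signed_mean(self) -> float:
        return float(np.mean(self.per_replicate_bias_percent))


def compute_bias(eqa: EQAReplicateSet, convention: str = "mean_then_abs") -> BiasResult:
    """Trueness bias (%) of an EQA replicate set against its peer target.

    Each replicate yields a signed percent difference
    ``(measured - target) / target * 100``.  The summary is either the
    absolute value of their mean (``mean_then_abs``, the default — signed
    errors may cancel) or the mean of their absolute values
    (``abs_then_mean``); the two differ only when replicates straddle the
    target.
    """
    if convention not in BIAS_CONVENTIONS:
        raise ValueError(f"bias convention must be one of {BIAS_CONVENTIONS}, got {convention!r}")
    if eqa.target_value <= 0:
        raise ComputationError("bias undefined for non-positive target")
    diffs = (eqa.array - eqa.target_value) / eqa.target_value * 100.0
    if convention == "mean_then_abs":
        summary = abs(float(diffs.mean()))
    else:
        summary = float(np.abs(diffs).mean())
    return BiasResult(tuple(float(d) for d in diffs), summary, convention)


def sigma_metric(tea_percent: float, bias_percent: float, cv_percent: float) -> float:
    """Sigma = (TEa - |bias|) / CV, all in percent of the target concentration.

    May be negative when bias alone exceeds the goal; no clamping here.  A
    zero CV returns an infinite sentinel with a warning instead of raising —
    an exactly-zero imprecision estimate is an upstream data problem, but the
    metric's limit is well defined.
    """
    if cv_percent < 0:
        raise ComputationError(f"CV must be >= 0, got {cv_percent}")
    if cv_percent == 0:
        warnings.warn("CV is 0: sigma is infinite", stacklevel=2)
        return math.inf
    return (tea_percent - abs(bias_percent)) / cv_percent


def sigma_to_dpm(sigma: float) -> float:
    """Defects per million implied by a sigma level.

    Conventional one-sided scale with a 1.5-sigma long-term shift:
    ``DPM = 1e6 * P(Z > sigma - 1.5)``.  Six sigma gives the canonical 3.4
    per million; 1.5 sigma gives 500,000.  Strictly decreasing in sigma.
    """
    if not math.isfinite(sigma):
        if sigma > 0:
            return 0.0
        raise ComputationError("DPM undefined for -inf/NaN sigma")
    return 1e6 * float(norm.sf(sigma - SIGMA_SHIFT))


def qgi(bias_percent: float, cv_percent: float) -> float:
    """Quality goal index: |bias| / (1.5 * CV)."""
    if cv_percent <= 0:
        raise ComputationError(f"QGI undefined for CV {cv_percent}")
    return abs(bias_percent) / (SIGMA_SHIFT * cv_percent)


def classify_improvement(sigma: float, qgi_value: float | None = None) -> str:
    """Which performance component to improve first for a sub-six-sigma assay.

    Returns ``none`` at or above six sigma.  Below six sigma the QGI decides:
    < 0.8 -> ``imprecision``; > 1.2 -> ``trueness``; 0.8..1.2 inclusive ->
    ``both`` (equality belongs to the middle class).
    """
    if sigma >= 6:
        return "none"
    if qgi_value is None:
        raise ComputationError("QGI required to classify a sub-six-sigma assay")
    if qgi_value < QGI_LOW:
        return "imprecision"
    if qgi_value > QGI_HIGH:
        return "trueness"
    return "both"


@dataclass(frozen=True)
class PerformanceRecord:
    """The (CV, bias, TEa) triple for one lab/analyte/level with its derived metrics.

    ``qgi`` is populated only below six sigma (the index is an improvement
    diagnostic, meaningless for assays already at goal); ``zone`` is the
    method-decision-chart band label.
    """

    lab_id: str
    analyte_id: str
    level: str
    cv_percent: float
    bias_percent: float
    tea_percent: float
    sigma: float = field(init=False)
    qgi: float | None = field(init=False)
    zone: str = field(init=False)
    improvement: str = field(init=False)

    def __post_init__(self) -> None:
        from .chart import band  # local import: chart depends on metrics

        if self.cv_percent <= 0:
            raise ComputationError(f"record {self.key}: CV must be > 0")
        if self.bias_percent < 0:
            raise ComputationError(f"record {self.key}: bias must be non-negative")
        s = sigma_metric(self.tea_percent, self.bias_percent, self.cv_percent)
        q = qgi(self.bias_percent, self.cv_percent) if s < 6 else None
        object.__setattr__(self, "sigma", s)
        object.__setattr__(self, "qgi", q)
        object.__setattr__(self, "zone", band(s))
        object.__setattr__(self, "improvement", classify_improvement(s, q))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lab_id, self.analyte_id, self.level)

    @property
    def dpm(self) -> float:
        return sigma_to_dpm(self.sigma)
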