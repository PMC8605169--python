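"""Risk-based SQC strategy selection (Westgard sigma rules) and multirule evaluation.

The sigma-rules flowchart maps an assay's sigma level to the statistical QC
it deserves: a world-class assay (sigma >= 6) needs only the 1_3s rule on two
control materials with 1000 patient samples between QC events, while poorer
assays earn progressively larger multirule sets, more control measurements
(N) and shorter run sizes.  The bands below four sigma additionally flag
that method improvement, not just tighter QC, is required.

Rule grammar (z = (value - established mean)/established SD per material):

* ``1_3s`` — any single control beyond +-3 SD (random-error catch-all)
* ``2_2s`` — two consecutive controls beyond the same +-2 SD limit
* ``R_4s`` — within one run, range > 4 SD with controls on opposite sides
  beyond +-2 SD
* ``4_1s`` — four consecutive controls beyond the same +-1 SD limit
* ``8_x``  — eight consecutive controls on the same side of the mean

"Consecutive" counts across the two materials within a run (level order)
then across runs; R_4s is within-run only — classic multirule semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ComputationError, UnknownRuleError, ValidationError

__all__ = [
    "SQCStrategy",
    "QCRunSeries",
    "RuleEvaluation",
    "DEFAULT_BANDS",
    "select_strategy",
    "evaluate_rules",
    "schedule_qc",
    "KNOWN_RULES",
]

KNOWN_RULES = ("1_3s", "2_2s", "R_4s", "4_1s", "8_x")


@dataclass(frozen=True)
class SQCStrategy:
    """A selected SQC design: rules, N, QC events per run, and run size.

    ``n_controls`` is control measurements per QC event (two materials, so it
    is even); ``events`` is QC events per analytical run; ``run_size`` is the
    number of patient samples between bracketing QC events.
    """

    rules: tuple[str, ...]
    n_controls: int
    run_size: int
    band: str
    events: int = 1
    improvement_required: bool = False

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValidationError("strategy needs at least one rule")
        for code in self.rules:
            if code not in KNOWN_RULES:
                raise UnknownRuleError(code)
        if self.n_controls % 2:
            raise ValidationError("n_controls must be even (two control materials)")


# (sigma lower edge, rules, N per event, events per run, run size, improvement flag)
# The two bands below four sigma follow the published sigma-rules convention
# and are override-able via select_strategy(bands=...).
DEFAULT_BANDS: tuple[tuple[float, tuple[str, ...], int, int, int, bool], ...] = (
    (6.0, ("1_3s",), 2, 1, 1000, False),
    (5.0, ("1_3s", "2_2s", "R_4s"), 2, 1, 450, False),
    (4.0, ("1_3s", "2_2s", "R_4s", "4_1s"), 4, 1, 200, False),
    (3.0, ("1_3s", "2_2s", "R_4s", "4_1s", "8_x"), 4, 1, 45, False),
    (-math.inf, ("1_3s", "2_2s", "R_4s", "4_1s", "8_x"), 4, 2, 23, True),
)


def select_strategy(
    sigma_by_level: Mapping[str, float],
    policy: str = "min",
    bands: Sequence[tuple[float, tuple[str, ...], int, int, int, bool]] = DEFAULT_BANDS,
) -> SQCStrategy:
    """Select the SQC strategy for one assay from its per-level sigma values.

    The effective sigma across control levels is their minimum under the
    default ``min`` policy (conservative: QC must protect the worst level);
    ``per_level`` applies each level's own band and returns the stricter
    strategy, which for single-level input equals ``min``.
    """
    if not sigma_by_level:
        raise ComputationError("select_strategy needs at least one sigma value")
    finite = [s for s in sigma_by_level.values() if not math.isnan(s)]
    if not finite:
        raise ComputationError("select_strategy needs at least one non-NaN sigma")
    if policy not in ("min", "per_level"):
        raise ValueError(f"policy must be 'min' or 'per_level', got {policy!r}")
    effective = min(finite)  # per_level reduces to the strictest band = min sigma
    from .chart import band as band_label

    for lo, rules, n, events, run_size, flag in bands:
        if effective >= lo:
            return SQCStrategy(tuple(rules), n, run_size, band_label(effective), events, flag)
    raise ComputationError("band table does not cover the effective sigma")  # pragma: no cover


@dataclass(frozen=True)
class QCRunSeries:
    """Control observations over runs, plus established mean/SD per material.

    ``observations`` is a sequence of (run_index, level, value) triples;
    within each run materials are evaluated in sorted level order.
    """

    observations: tuple[tuple[object, str, float], ...]
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.observations:
            raise ValidationError("QCRunSeries needs at least one observation")
        for level, sd in self.sds.items():
            if sd <= 0:
                raise ValidationError(f"established SD for {level!r} must be > 0")
        for _, level, _ in self.observations:
            if level not in self.means or level not in self.sds:
                raise ValidationError(f"no established mean/SD for material {level!r}")

    def zscores(self) -> list[tuple[object, str, float]]:
        """(run, level, z) in run order, materials in level order within a run."""
        by_run: dict[object, list[tuple[str, float]]] = {}
        run_order: list[object] = []
        for run, level, value in self.observations:
            if run not in by_run:
                by_run[run] = []
                run_order.append(run)
            by_run[run].append((level, value))
        out = []
        for run in run_order:
            for level, value in sorted(by_run[run], key=lambda t: t[0]):
                out.append((run, level, (value - self.means[level]) / self.sds[level]))
        return out


@dataclass(frozen=True)
class RuleEvaluation:
    """Accept/reject verdict for one run."""

    run: object
    violated_rules: tuple[str, ...]
    decision: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "decision", "reject" if self.violated_rules else "accept")


def evaluate_rules(series: QCRunSeries, strategy: SQCStrategy) -> list[RuleEvaluation]:
    """Apply a strategy's Westgard rules to a control series, run by run.

    Limits are strict ("beyond 2 SD" means |z| > 2).  Cross-run rules
    (2_2s, 4_1s, 8_x) look back over the flattened observation sequence; a
    violation is charged to the run containing its final observation.  A run
    is rejected iff any selected rule fires in it.
    """
    for code in strategy.rules:
        if code not in KNOWN_RULES:
            raise UnknownRuleError(code)
    zs = series.zscores()
    runs_in_order: list[object] = []
    for run, _, _ in zs:
        if not runs_in_order or runs_in_order[-1] != run:
            runs_in_order.append(run)
    violated: dict[object, set[str]] = {run: set() for run in runs_in_order}
    z_flat = [z for _, _, z in zs]
    run_flat = [run for run, _, _ in zs]

    for i, z in enumerate(z_flat):
        run = run_flat[i]
        if "1_3s" in strategy.rules and abs(z) > 3:
            violated[run].add("1_3s")
        if "2_2s" in strategy.rules and i >= 1:
            a, b = z_flat[i - 1], z
            if (a > 2 and b > 2) or (a < -2 and b < -2):
                violated[run].add("2_2s")
        if "4_1s" in strategy.rules and i >= 3:
            w = z_flat[i - 3 : i + 1]
            if all(v > 1 for v in w) or all(v < -1 for v in w):
                violated[run].add("4_1s")
        if "8_x" in strategy.rules and i >= 7:
            w = z_flat[i - 7 : i + 1]
            if all(v > 0 for v in w) or all(v < 0 for v in w):
                violated[run].add("8_x")

    if "R_4s" in strategy.rules:
        for run in runs_in_order:
            zr = [z for r, z in zip(run_flat, z_flat) if r == run]
            if max(zr) > 2 and min(zr) < -2 and max(zr) - min(zr) > 4:
                violated[run].add("R_4s")

    return [RuleEvaluation(run, tuple(sorted(violated[run]))) for run in runs_in_order]


def schedule_qc(run_size: int, daily_sample_count: int) -> int:
    """QC events needed to bracket a day's workload: ceil(samples / run size)."""
    if run_size <= 0 or daily_sample_count <= 0:
        raise ValidationError("run_size and daily_sample_count must be positive")
    return -(-daily_sample_count // run_size)
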