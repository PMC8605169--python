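"""Synthetic IQC/EQA data with known truth for pipeline validation.

Real multicentre QC series are rarely shareable, so every pipeline stage is
exercised against generated data whose true mean, CV and bias are known.
The measurement model is the minimal one consistent with mean/SD/CV-based
QC practice: i.i.d. Gaussian noise with a constant CV within a control
level, and bias entering as a multiplicative shift of the true concentration
applied identically to IQC material and EQA sample (the two describe the
same analytical state).

The default study grid mimics a five-laboratory, ten-analyte, two-level
urinary biochemistry survey: 100 scenarios with true sigma spanning 4-18,
IQC cadence of two measurements a day over six months (n = 360), and
5-replicate EQA panels.  A master seed spawns per-scenario RNG substreams by
stable hashing of (lab, analyte, level), so adding a scenario never perturbs
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .goals import GoalTable, load_tea_goals
from .io import EQAReplicateSet, IQCSeries, write_eqa, write_iqc

__all__ = [
    "ScenarioConfig",
    "simulate_iqc",
    "simulate_eqa",
    "default_grid",
    "build_study_fixture",
    "true_sigma",
]

#: plausible urinary concentrations (assay units) per analyte: (level1, level2)
_TRUE_MEANS: dict[str, tuple[float, float]] = {
    "K": (25.0, 60.0),       # mmol/L
    "Na": (80.0, 180.0),     # mmol/L
    "Cl": (80.0, 180.0),     # mmol/L
    "Ca": (2.5, 6.0),        # mmol/L
    "P": (10.0, 25.0),       # mmol/L
    "GLU": (1.5, 10.0),      # mmol/L
    "Urea": (150.0, 350.0),  # mmol/L
    "Crea": (8.0, 16.0),     # mmol/L
    "TP": (0.08, 0.50),      # g/L
    "mALB": (20.0, 150.0),   # mg/L
}

_LABS = ("LabA", "LabB", "LabC", "LabD", "LabE")


@dataclass(frozen=True)
class ScenarioConfig:
    """True state of one simulated lab/analyte/level.

    ``n_iqc_values`` defaults to 360 — two control measurements a day for
    roughly six months, the cadence of a typical IQC scheme.  ``eqa_target``
    defaults to the true mean (EQA material chosen to match the IQC level).
    """

    lab_id: str
    analyte_id: str
    level: str
    true_mean: float
    true_cv_percent: float
    true_bias_percent: float  # signed
    n_iqc_values: int = 360
    n_eqa_replicates: int = 5
    eqa_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_cv_percent <= 0:
            raise ValidationError("true CV must be > 0")
        if self.n_iqc_values < 2:
            raise ValidationError("need at least 2 IQC values")
        if self.n_eqa_replicates < 2:
            raise ValidationError("need at least 2 EQA replicates")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lab_id, self.analyte_id, self.level)

    @property
    def target(self) -> float:
        return self.true_mean if self.eqa_target is None else self.eqa_target


def _rng(config: ScenarioConfig, stream: str) -> np.random.Generator:
    # stable per-scenario substream: master seed + crc32 of the scenario key
    token = "|".join((config.lab_id, config.analyte_id, config.level, stream))
    return np.random.default_rng([int(config.seed), zlib.crc32(token.encode())])


def true_sigma(tea_percent: float, config: ScenarioConfig) -> float:
    """Sigma implied by a scenario's true bias and CV against a TEa goal."""
    return (tea_percent - abs(config.true_bias_percent)) / config.true_cv_percent


def simulate_iqc(config: ScenarioConfig) -> IQCSeries:
    """Draw an IQC series: Gaussian around the bias-shifted mean, constant CV."""
    mean = config.true_mean * (1.0 + config.true_bias_percent / 100.0)
    sd = config.true_cv_percent / 100.0 * mean
    values = _rng(config, "iqc").normal(mean, sd, size=config.n_iqc_values)
    return IQCSeries(config.lab_id, config.analyte_id, config.level,
                     tuple(values), tuple(range(1, config.n_iqc_values + 1)))


def simulate_eqa(config: ScenarioConfig) -> EQAReplicateSet:
    """Draw an EQA replicate panel around the bias-shifted target."""
    center = config.target * (1.0 + config.true_bias_percent / 100.0)
    sd = config.true_cv_percent / 100.0 * center
    values = _rng(config, "eqa").normal(center, sd, size=config.n_eqa_replicates)
    return EQAReplicateSet(config.lab_id, config.analyte_id, config.level,
                           tuple(values), config.target)


def default_grid(seed: int = 0, goals: GoalTable | None = None,
                 n_iqc_values: int = 360) -> list[ScenarioConfig]:
    """The packaged 100-scenario study grid (5 labs x 10 analytes x 2 levels).

    True sigma is spread evenly over 4-18 across the 100 scenarios, level 2
    slightly above level 1 for the same assay (the usual concentration
    effect); true bias is a modest fraction of TEa (6-14%), and true CV
    follows from sigma = (TEa - |bias|)/CV.  These choices put CVs in the
    1-10% range typical of automated urinary chemistry.
    """
    goals = goals or load_tea_goals()
    analytes = [spec.analyte_id for spec in goals]
    grid: list[ScenarioConfig] = []
    for i, lab in enumerate(_LABS):
        for j, analyte in enumerate(analytes):
            tea = goals.tea(analyte)
            for l, level in enumerate(("level1", "level2")):
                slot = 2 * (i * len(analytes) + j) + l  # 0..99
                sigma = 4.0 + 14.0 * slot / 99.0
                bias = (0.06 + 0.04 * ((i + j) % 3)) * tea  # 6/10/14% of TEa
                cv = (tea - bias) / sigma
                mean = _TRUE_MEANS.get(analyte, (10.0, 30.0))[l]
                grid.append(ScenarioConfig(lab, analyte, level, mean, cv, bias,
                                           n_iqc_values=n_iqc_values, seed=seed))
    return grid


def build_study_fixture(grid: list[ScenarioConfig], out_dir,
                        goals: GoalTable | None = None) -> tuple[Path, Path, Path]:
    """Write pipeline-ready iqc.csv / eqa.csv plus a truth.csv recovery table.

    The truth table records each scenario's true CV, bias and implied sigma —
    the recovery target for synthetic runs.  Scenario keys must be unique.
    """
    goals = goals or load_tea_goals()
    seen = set()
    for cfg in grid:
        if cfg.key in seen:
            raise ValidationError(f"duplicate scenario key {cfg.key}")
        seen.add(cfg.key)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iqc_path = write_iqc([simulate_iqc(c) for c in grid], out_dir / "iqc.csv")
    eqa_path = write_eqa([simulate_eqa(c) for c in grid], out_dir / "eqa.csv")
    truth = pd.DataFrame(
        [
            {
                "lab": c.lab_id,
                "analyte": c.analyte_id,
                "level": c.level,
                "tea": goals.tea(c.analyte_id),
                "true_mean": c.true_mean,
                "true_cv": c.true_cv_percent,
                "true_bias": c.true_bias_percent,
                "true_sigma": true_sigma(goals.tea(c.analyte_id), c),
            }
            for c in grid
        ]
    )
    truth_path = out_dir / "truth.csv"
    truth.to_csv(truth_path, index=False)
    return iqc_path, eqa_path, truth_path


def reseed(grid: list[ScenarioConfig], seed: int) -> list[ScenarioConfig]:
    """Copy a grid with a different master seed (used for repeat experiments)."""
    return [replace(c, seed=seed) for c in grid]
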