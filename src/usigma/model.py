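"""Study-level model: fit sigma metrics to IQC/EQA data and report.

``SixSigmaModel`` is built from the raw quality-control data of a study
(internal-QC series, EQA replicate panels, a TEa goal table); ``fit()``
estimates each assay's imprecision, trueness and sigma metric and returns a
:class:`SixSigmaResults` carrying the three report tables —

* metrics: one row per (lab, analyte, level) with CV, bias, TEa, sigma,
  DPM, QGI, decision-chart zone and improvement class;
* strategies: one row per (lab, analyte) with the risk-based SQC design
  (Westgard rules, N, run size) selected from the worst level's sigma;
* improvement: the sub-six-sigma assays with per-level QGI and the
  component (imprecision / trueness / both) to fix first

— plus rendering of the normalized decision charts and a reproducible
on-disk report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .chart import normalize_point, render_chart
from .goals import GoalTable, load_tea_goals
from .io import EQAReplicateSet, IQCSeries, read_eqa, read_iqc
from .metrics import PerformanceRecord, compute_bias, compute_cv
from .westgard import SQCStrategy, select_strategy

__all__ = ["SixSigmaModel", "SixSigmaResults", "run_pipeline", "render_report"]

_LABELS = {"imprecision": "Imprecision", "trueness": "Trueness",
           "both": "Imprecision and trueness", "none": "None"}


class SixSigmaModel:
    """Six-sigma analytical-performance model for a multi-lab QC study.

    Parameters
    ----------
    iqc, eqa
        The raw data: IQC series and EQA replicate sets.  Every IQC key
        (lab, analyte, level) should have a matching EQA key; unmatched keys
        are reported as skipped by ``fit()``, not raised.
    goals
        TEa quality-goal table (default: the built-in urinary EQA goals).
    bias_convention
        ``mean_then_abs`` (default) or ``abs_then_mean``.
    policy
        How per-level sigma values combine into one SQC strategy per assay
        (default ``min``: protect the worst level).
    """

    def __init__(self, iqc: list[IQCSeries], eqa: list[EQAReplicateSet],
                 goals: GoalTable | None = None, *,
                 bias_convention: str = "mean_then_abs", policy: str = "min",
                 input_paths: dict[str, Path] | None = None):
        self.iqc = list(iqc)
        self.eqa = list(eqa)
        self.goals = goals or load_tea_goals()
        self.bias_convention = bias_convention
        self.policy = policy
        self.input_paths = dict(input_paths or {})

    @classmethod
    def from_csv(cls, iqc_path, eqa_path, tea_source="china_eqa_2020", **kwargs
                 ) -> "SixSigmaModel":
        """Build the model from the canonical CSV/JSON input files."""
        paths = {"iqc": Path(iqc_path), "eqa": Path(eqa_path)}
        if Path(str(tea_source)).is_file():
            paths["tea"] = Path(tea_source)
        return cls(read_iqc(iqc_path), read_eqa(eqa_path),
                   load_tea_goals(tea_source), input_paths=paths, **kwargs)

    def fit(self) -> "SixSigmaResults":
        """Estimate CV/bias/sigma for every matched key and derive the report tables."""
        eqa_by_key = {e.key: e for e in self.eqa}
        records: list[PerformanceRecord] = []
        skipped: list[tuple[str, str, str]] = []
        for series in sorted(self.iqc, key=lambda s: s.key):
            eqa = eqa_by_key.get(series.key)
            if eqa is None:
                skipped.append(series.key)
                continue
            records.append(PerformanceRecord(
                lab_id=series.lab_id,
                analyte_id=series.analyte_id,
                level=series.level,
                cv_percent=compute_cv(series),
                bias_percent=compute_bias(eqa, self.bias_convention).bias_percent,
                tea_percent=self.goals.tea(series.analyte_id),
            ))
        return SixSigmaResults(model=self, records=records, skipped_keys=skipped)


@dataclass
class SixSigmaResults:
    """Fitted study results: per-assay metrics, SQC strategies, improvement calls."""

    model: SixSigmaModel
    records: list[PerformanceRecord]
    skipped_keys: list[tuple[str, str, str]]
    strategies: dict[tuple[str, str], SQCStrategy] = field(init=False)

    def __post_init__(self) -> None:
        self.strategies = {
            (lab, analyte): select_strategy(sigmas, policy=self.model.policy)
            for (lab, analyte), sigmas in self._sigma_pairs().items()
        }

    def _sigma_pairs(self) -> dict[tuple[str, str], dict[str, float]]:
        pairs: dict[tuple[str, str], dict[str, float]] = {}
        for r in self.records:
            pairs.setdefault((r.lab_id, r.analyte_id), {})[r.level] = r.sigma
        return pairs

    # -- report tables -----------------------------------------------------

    @property
    def metrics(self) -> pd.DataFrame:
        """Tidy per-level metrics table (full precision)."""
        return pd.DataFrame(
            [
                {
                    "lab": r.lab_id, "analyte": r.analyte_id, "level": r.level,
                    "cv": r.cv_percent, "bias": r.bias_percent, "tea": r.tea_percent,
                    "sigma": r.sigma, "dpm": r.dpm, "qgi": r.qgi,
                    "zone": r.zone, "improvement": r.improvement,
                }
                for r in self.records
            ]
        )

    @property
    def strategy_table(self) -> pd.DataFrame:
        """One SQC strategy row per (lab, analyte)."""
        return pd.DataFrame(
            [
                {
                    "lab": lab, "analyte": analyte, "band": s.band,
                    "rules": "/".join(s.rules), "n_controls": s.n_controls,
                    "events": s.events, "run_size": s.run_size,
                    "improvement_required": s.improvement_required,
                }
                for (lab, analyte), s in sorted(self.strategies.items())
            ]
        )

    @property
    def improvement_table(self) -> pd.DataFrame:
        """Sub-six-sigma assays with per-level sigma/QGI and the improvement call.

        A (lab, analyte) pair appears iff its minimum-level sigma is below
        six.  Per-level labels are collapsed to one when all sub-six levels
        agree; disagreement joins them with ``"; "`` so it is never hidden.
        """
        by_pair: dict[tuple[str, str], dict[str, PerformanceRecord]] = {}
        for r in self.records:
            by_pair.setdefault((r.lab_id, r.analyte_id), {})[r.level] = r
        rows = []
        for (lab, analyte), recs in sorted(by_pair.items()):
            if min(r.sigma for r in recs.values()) >= 6:
                continue
            row: dict[str, object] = {"lab": lab, "analyte": analyte}
            labels: list[str] = []
            for level in sorted(recs):
                r = recs[level]
                row[f"sigma_{level}"] = r.sigma
                row[f"qgi_{level}"] = r.qgi if r.qgi is not None else np.nan
                if r.improvement != "none":
                    label = _LABELS[r.improvement]
                    if label not in labels:
                        labels.append(label)
            row["improvement"] = "; ".join(labels)
            rows.append(row)
        return pd.DataFrame(rows)

    # -- presentation ------------------------------------------------------

    def chart_points(self, level: str):
        return [normalize_point(r) for r in self.records if r.level == level]

    @property
    def levels(self) -> list[str]:
        return sorted({r.level for r in self.records})

    def plot_decision_chart(self, level: str, out_path) -> Path:
        """Render the normalized method decision chart for one control level."""
        return render_chart(self.chart_points(level), level, out_path)

    def summary(self) -> str:
        """Human-readable study summary (counts plus the three tables, 2 d.p.)."""
        lines = [
            "Six-sigma analytical performance summary",
            "=" * 40,
            f"assays (lab x analyte x level): {len(self.records)}",
            f"labs: {len({r.lab_id for r in self.records})}   "
            f"analytes: {len({r.analyte_id for r in self.records})}   "
            f"levels: {len(self.levels)}",
            f"sub-six-sigma assays (worst level): {len(self.improvement_table)}",
            f"skipped keys (no EQA match): {len(self.skipped_keys)}",
            "",
            "Per-level metrics",
            "-" * 17,
            _round2(self.metrics).to_string(index=False),
            "",
            "SQC strategies (min-sigma policy)" if self.model.policy == "min"
            else f"SQC strategies (policy={self.model.policy})",
            "-" * 17,
            self.strategy_table.to_string(index=False),
        ]
        imp = self.improvement_table
        if len(imp):
            lines += ["", "Improvement priorities (sigma < 6)", "-" * 17,
                      _round2(imp).to_string(index=False)]
        return "\n".join(lines)

    def save(self, out_dir) -> dict[str, Path]:
        """Write the full report to ``out_dir``; see :func:`render_report`."""
        return render_report(self, out_dir)


def _round2(df: pd.DataFrame) -> pd.DataFrame:
    """Round float columns half-even to 2 decimals (presentation precision)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(2)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _markdown_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "(empty)\n"
    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body]) + "\n"


def run_pipeline(iqc_path, eqa_path, tea_source="china_eqa_2020", *,
                 bias_convention: str = "mean_then_abs",
                 policy: str = "min") -> SixSigmaResults:
    """End-to-end study run: read inputs, fit, return the full results object."""
    model = SixSigmaModel.from_csv(iqc_path, eqa_path, tea_source,
                                   bias_convention=bias_convention, policy=policy)
    return model.fit()


def render_report(results: SixSigmaResults, out_dir) -> dict[str, Path]:
    """Write the study report: CSV tables, charts, markdown, provenance.

    Emits ``metrics.csv`` / ``strategies.csv`` / ``improvement.csv`` (floats
    rounded half-even to 2 decimals), ``metrics.json`` (full precision), one
    decision-chart SVG per control level, ``report.md`` mirroring the CSV
    tables, and ``provenance.json`` with input SHA-256 digests and the
    configuration.  Output is byte-identical across runs on fixed input.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tables = {
        "metrics": _round2(results.metrics),
        "strategies": results.strategy_table,
        "improvement": results.improvement_table if len(results.improvement_table)
        else pd.DataFrame(columns=["lab", "analyte", "improvement"]),
    }
    if len(tables["improvement"]):
        tables["improvement"] = _round2(tables["improvement"])
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    full = out_dir / "metrics.json"
    full.write_text(json.dumps(results.metrics.to_dict(orient="records"),
                               indent=2, allow_nan=True), encoding="utf-8")
    paths["metrics_json"] = full

    for level in results.levels:
        p = out_dir / f"{level}.svg"
        results.plot_decision_chart(level, p)
        paths[f"chart_{level}"] = p

    md = ["# Six-sigma analytical performance report", ""]
    for name, df in tables.items():
        md += [f"## {name.capitalize()}", "", _markdown_table(df)]
    if results.skipped_keys:
        md += ["## Skipped keys (IQC without matching EQA)", ""]
        md += [f"- {lab} / {analyte} / {level}" for lab, analyte, level in results.skipped_keys]
        md += [""]
    (out_dir / "report.md").write_text("\n".join(md), encoding="utf-8")
    paths["report"] = out_dir / "report.md"

    provenance = {
        "package": "usigma",
        "version": _version,
        "config": {
            "bias_convention": results.model.bias_convention,
            "policy": results.model.policy,
            "tea_goals": results.model.goals.to_dict(),
        },
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in sorted(results.model.input_paths.items())
                   if Path(p).is_file()},
        "n_records": len(results.records),
        "skipped_keys": [list(k) for k in results.skipped_keys],
    }
    prov = out_dir / "provenance.json"
    prov.write_text(json.dumps(provenance, indent=2, sort_keys=True), encoding="utf-8")
    paths["provenance"] = prov
    return paths
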