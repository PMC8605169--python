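"""Domain containers and CSV readers/writers for IQC and EQA data.

The canonical exchange format is long/tidy CSV, one measurement per row —
the layout most internal-QC software exports and the easiest to diff:

* ``iqc.csv``: columns ``lab,analyte,level,run,value``
* ``eqa.csv``: columns ``lab,analyte,level,replicate,value,target``

Run identifiers are opaque sortable tokens (ISO dates or integers); rows are
stably sorted by run, so within-run ties keep file order.  Units are never
converted — every downstream statistic (CV, bias, sigma) is percent-based and
scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "IQCSeries",
    "EQAReplicateSet",
    "read_iqc",
    "write_iqc",
    "read_eqa",
    "write_eqa",
]

IQC_COLUMNS = ("lab", "analyte", "level", "run", "value")
EQA_COLUMNS = ("lab", "analyte", "level", "replicate", "value", "target")
LEVELS = ("level1", "level2")


@dataclass(frozen=True)
class IQCSeries:
    """Ordered internal-QC measurements for one (lab, analyte, level).

    ``values`` are concentrations in assay units; ``runs`` are the matching
    run identifiers in non-decreasing order.  The series is the raw material
    for the imprecision estimate (CV).
    """

    lab_id: str
    analyte_id: str
    level: str
    values: tuple[float, ...]
    runs: tuple = field(default=())

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        runs = tuple(self.runs) if self.runs else tuple(range(1, len(values) + 1))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "runs", runs)
        if len(values) < 2:
            raise ValidationError(
                f"IQC series {self.key} needs >=2 values, got {len(values)}"
            )
        if any(v <= 0 for v in values):
            raise ValidationError(f"IQC series {self.key} has non-positive values")
        if len(runs) != len(values):
            raise ValidationError(
                f"IQC series {self.key}: {len(runs)} run ids for {len(values)} values"
            )
        if any(runs[i] > runs[i + 1] for i in range(len(runs) - 1)):
            raise ValidationError(f"IQC series {self.key}: run identifiers not ordered")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lab_id, self.analyte_id, self.level)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class EQAReplicateSet:
    """Replicate measurements of one EQA sample plus its peer-group target.

    The target is the consensus mean of the peer group; the replicates are
    the laboratory's within-batch repeat measurements, the raw material for
    the trueness estimate (bias %).
    """

    lab_id: str
    analyte_id: str
    level: str
    replicate_values: tuple[float, ...]
    target_value: float

    def __post_init__(self) -> None:
        reps = tuple(float(v) for v in self.replicate_values)
        object.__setattr__(self, "replicate_values", reps)
        object.__setattr__(self, "target_value", float(self.target_value))
        if len(reps) < 2:
            raise ValidationError(
                f"EQA set {self.key} needs >=2 replicates, got {len(reps)}"
            )
        if self.target_value <= 0:
            raise ValidationError(f"EQA set {self.key}: target must be > 0")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lab_id, self.analyte_id, self.level)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.replicate_values, dtype=float)


def _read_table(path, required: Sequence[str], dialect: Mapping[str, str] | None):
    path = Path(path)
    df = pd.read_csv(path, dtype={"lab": str, "analyte": str, "level": str})
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {', '.join(repr(c) for c in missing)}"
        )
    return df


def read_iqc(path, dialect: Mapping[str, str] | None = None) -> list[IQCSeries]:
    """Read a tidy IQC CSV into one :class:`IQCSeries` per (lab, analyte, level).

    Rows are stably sorted by run identifier within each key, so ties keep
    file order.  A non-positive concentration raises :class:`ValidationError`
    carrying the offending file row.
    """
    df = _read_table(path, IQC_COLUMNS, dialect)
    bad = df.index[pd.to_numeric(df["value"], errors="coerce").fillna(-1) <= 0]
    if len(bad):
        # +2: header is file row 1, pandas index is 0-based
        raise ValidationError("non-positive IQC value", row=int(bad[0]) + 2)
    out: list[IQCSeries] = []
    for (lab, analyte, level), grp in df.groupby(["lab", "analyte", "level"], sort=True):
        grp = grp.sort_values("run", kind="stable")
        out.append(
            IQCSeries(lab, analyte, level, tuple(grp["value"].astype(float)), tuple(grp["run"]))
        )
    return out


def write_iqc(series: Iterable[IQCSeries], path) -> Path:
    """Write IQC series back to the canonical tidy CSV (round-trips read_iqc)."""
    rows = [
        {"lab": s.lab_id, "analyte": s.analyte_id, "level": s.level, "run": r, "value": v}
        for s in series
        for r, v in zip(s.runs, s.values)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=list(IQC_COLUMNS)).to_csv(path, index=False)
    return path


def read_eqa(path, dialect: Mapping[str, str] | None = None,
             strict_n: int | None = 5) -> list[EQAReplicateSet]:
    """Read a tidy EQA CSV into one :class:`EQAReplicateSet` per key.

    ``strict_n`` enforces an exact replicate count (default 5, the usual
    within-batch EQA protocol); pass ``None`` to accept any n >= 2.  A key
    with inconsistent target values is rejected.
    """
    df = _read_table(path, EQA_COLUMNS, dialect)
    out: list[EQAReplicateSet] = []
    for (lab, analyte, level), grp in df.groupby(["lab", "analyte", "level"], sort=True):
        targets = grp["target"].astype(float).unique()
        if len(targets) != 1:
            raise ValidationError(
                f"EQA key ({lab}, {analyte}, {level}) has inconsistent targets {sorted(targets)}"
            )
        grp = grp.sort_values("replicate", kind="stable")
        values = tuple(grp["value"].astype(float))
        if strict_n is not None and len(values) != strict_n:
            raise ValidationError(
                f"EQA key ({lab}, {analyte}, {level}) has {len(values)} replicates, "
                f"expected {strict_n}"
            )
        out.append(EQAReplicateSet(lab, analyte, level, values, float(targets[0])))
    return out


def write_eqa(sets: Iterable[EQAReplicateSet], path) -> Path:
    """Write EQA replicate sets back to the canonical tidy CSV."""
    rows = [
        {
            "lab": e.lab_id,
            "analyte": e.analyte_id,
            "level": e.level,
            "replicate": i + 1,
            "value": v,
            "target": e.target_value,
        }
        for e in sets
        for i, v in enumerate(e.replicate_values)
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=list(EQA_COLUMNS)).to_csv(path, index=False)
    return path
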