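"""Quality goals: total allowable error (TEa) per analyte.

TEa is the quality specification an assay must meet — the largest combined
analytical error, as a percent of the target concentration, that still leaves
a result fit for clinical use.  The built-in table ``china_eqa_2020`` carries
the state-of-the-art goals for the ten routine urinary biochemical analytes
(potassium through microalbumin) used throughout this package; custom goals
are loaded from a JSON mapping ``{"K": 29, ...}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import UnknownAnalyteError, ValidationError

__all__ = ["AnalyteSpec", "GoalTable", "load_tea_goals", "BUILTIN_TAG"]

BUILTIN_TAG = "china_eqa_2020"

#: analyte code -> (display name, TEa %) for the built-in urinary goal table
_CHINA_EQA_2020: dict[str, tuple[str, float]] = {
    "K": ("potassium", 29.0),
    "Na": ("sodium", 26.0),
    "Cl": ("chloride", 26.0),
    "Ca": ("calcium", 31.0),
    "P": ("phosphorus", 23.0),
    "GLU": ("glucose", 20.0),
    "Urea": ("urea", 21.0),
    "Crea": ("creatinine", 17.0),
    "TP": ("total protein", 44.0),
    "mALB": ("microalbumin", 30.0),
}


@dataclass(frozen=True)
class AnalyteSpec:
    """An analyte identity plus its quality goal TEa (%)."""

    analyte_id: str
    display_name: str
    tea_percent: float

    def __post_init__(self) -> None:
        if not (0 < self.tea_percent <= 100):
            raise ValidationError(
                f"TEa for {self.analyte_id!r} must be in (0, 100], got {self.tea_percent}"
            )


class GoalTable:
    """Mapping from analyte code to :class:`AnalyteSpec`.

    Lookup of an analyte without a goal raises :class:`UnknownAnalyteError`
    naming the analyte, so a missing goal surfaces at the point of use.
    """

    def __init__(self, specs: list[AnalyteSpec]):
        self._specs: dict[str, AnalyteSpec] = {}
        for spec in specs:
            if spec.analyte_id in self._specs:
                raise ValidationError(f"duplicate analyte {spec.analyte_id!r} in goal table")
            self._specs[spec.analyte_id] = spec

    def __getitem__(self, analyte_id: str) -> AnalyteSpec:
        try:
            return self._specs[analyte_id]
        except KeyError:
            raise UnknownAnalyteError(analyte_id) from None

    def tea(self, analyte_id: str) -> float:
        """TEa (%) for ``analyte_id``."""
        return self[analyte_id].tea_percent

    def __contains__(self, analyte_id: str) -> bool:
        return analyte_id in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def to_dict(self) -> dict[str, float]:
        return {s.analyte_id: s.tea_percent for s in self}

    def __repr__(self) -> str:
        return f"GoalTable({self.to_dict()!r})"


def load_tea_goals(source: str | Path = BUILTIN_TAG) -> GoalTable:
    """Load a TEa goal table.

    Parameters
    ----------
    source
        Either the builtin tag ``"china_eqa_2020"`` or a path to a JSON file
        mapping analyte code to TEa percent, e.g. ``{"K": 29, "Na": 26}``.
    """
    if str(source) == BUILTIN_TAG:
        return GoalTable(
            [AnalyteSpec(aid, name, tea) for aid, (name, tea) in _CHINA_EQA_2020.items()]
        )
    with open(source, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"goal file {source} must contain a JSON object")
    return GoalTable(
        [AnalyteSpec(aid, aid, float(tea)) for aid, tea in raw.items()]
    )
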