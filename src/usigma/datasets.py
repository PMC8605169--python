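"""Reference dataset: a five-laboratory urinary biochemistry sigma survey.

Published multicentre surveys of urinary biochemical assays report only the
derived performance figures — per-level sigma metrics, the selected SQC
strategies, and QGI-based improvement calls — while the raw IQC/EQA series
stay in supplements.  This module ships one such survey (five laboratories
A-E, ten analytes, two control levels, Beckman AU-class platform, Chinese
EQA TEa goals) as plain data, for use as a regression/validation surface:
its strategy and improvement tables are pure functions of its sigma table
under this package's own logic.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SURVEY_TEA",
    "SURVEY_SIGMA",
    "SURVEY_STRATEGY",
    "SURVEY_QGI",
    "load_sigma_table",
    "load_qgi_table",
]

LABS = ("Lab A", "Lab B", "Lab C", "Lab D", "Lab E")
ANALYTES = ("K", "Na", "Cl", "Ca", "P", "GLU", "Urea", "Crea", "TP", "mALB")

#: TEa quality goals (%) of the survey (Chinese EQA standard)
SURVEY_TEA: dict[str, float] = {
    "K": 29, "Na": 26, "Cl": 26, "Ca": 31, "P": 23,
    "GLU": 20, "Urea": 21, "Crea": 17, "TP": 44, "mALB": 30,
}

#: analyte -> lab -> (level-1 sigma, level-2 sigma)
SURVEY_SIGMA: dict[str, dict[str, tuple[float, float]]] = {
    "K":    {"Lab A": (5.94, 5.97), "Lab B": (7.14, 7.46), "Lab C": (9.84, 10.89),
             "Lab D": (11.61, 12.60), "Lab E": (10.69, 10.90)},
    "Na":   {"Lab A": (13.56, 16.89), "Lab B": (16.05, 17.19), "Lab C": (17.50, 18.50),
             "Lab D": (11.40, 12.96), "Lab E": (9.70, 11.98)},
    "Cl":   {"Lab A": (11.77, 16.43), "Lab B": (11.54, 14.04), "Lab C": (16.31, 16.37),
             "Lab D": (9.91, 12.03), "Lab E": (7.04, 6.90)},
    "Ca":   {"Lab A": (11.23, 10.23), "Lab B": (8.44, 8.58), "Lab C": (5.66, 5.98),
             "Lab D": (6.03, 6.74), "Lab E": (9.33, 9.86)},
    "P":    {"Lab A": (5.14, 5.77), "Lab B": (4.77, 4.98), "Lab C": (5.71, 5.73),
             "Lab D": (5.90, 5.71), "Lab E": (6.16, 8.13)},
    "GLU":  {"Lab A": (11.14, 13.61), "Lab B": (6.08, 6.95), "Lab C": (5.36, 5.80),
             "Lab D": (5.72, 5.06), "Lab E": (5.59, 5.95)},
    "Urea": {"Lab A": (5.69, 5.16), "Lab B": (4.09, 4.87), "Lab C": (7.44, 7.04),
             "Lab D": (5.48, 5.85), "Lab E": (6.21, 6.59)},
    "Crea": {"Lab A": (6.16, 7.78), "Lab B": (5.27, 5.87), "Lab C": (5.24, 5.80),
             "Lab D": (6.06, 6.39), "Lab E": (5.25, 5.67)},
    "TP":   {"Lab A": (10.28, 17.83), "Lab B": (5.47, 5.86), "Lab C": (5.16, 5.92),
             "Lab D": (9.81, 11.97), "Lab E": (5.30, 5.94)},
    "mALB": {"Lab A": (10.63, 14.61), "Lab B": (7.03, 8.40), "Lab C": (5.05, 5.85),
             "Lab D": (6.16, 8.67), "Lab E": (5.55, 5.83)},
}

_R1000 = (("1_3s",), 2, 1000)
_R450 = (("1_3s", "2_2s", "R_4s"), 2, 450)
_R200 = (("1_3s", "2_2s", "R_4s", "4_1s"), 4, 200)

#: analyte -> lab -> (rules, N, run size) as the survey selected them
SURVEY_STRATEGY: dict[str, dict[str, tuple[tuple[str, ...], int, int]]] = {
    "K":    {"Lab A": _R450, "Lab B": _R1000, "Lab C": _R1000, "Lab D": _R1000, "Lab E": _R1000},
    "Na":   {lab: _R1000 for lab in LABS},
    "Cl":   {lab: _R1000 for lab in LABS},
    "Ca":   {"Lab A": _R1000, "Lab B": _R1000, "Lab C": _R450, "Lab D": _R1000, "Lab E": _R1000},
    "P":    {"Lab A": _R450, "Lab B": _R200, "Lab C": _R450, "Lab D": _R450, "Lab E": _R1000},
    "GLU":  {"Lab A": _R1000, "Lab B": _R1000, "Lab C": _R450, "Lab D": _R450, "Lab E": _R450},
    "Urea": {"Lab A": _R450, "Lab B": _R200, "Lab C": _R1000, "Lab D": _R450, "Lab E": _R1000},
    "Crea": {"Lab A": _R1000, "Lab B": _R450, "Lab C": _R450, "Lab D": _R1000, "Lab E": _R450},
    "TP":   {"Lab A": _R1000, "Lab B": _R450, "Lab C": _R450, "Lab D": _R1000, "Lab E": _R450},
    "mALB": {"Lab A": _R1000, "Lab B": _R1000, "Lab C": _R450, "Lab D": _R1000, "Lab E": _R450},
}

#: sub-six-sigma assays: (analyte, lab, sigma1, sigma2, qgi1, qgi2, label)
SURVEY_QGI: tuple[tuple[str, str, float, float, float, float, str], ...] = (
    ("K", "Lab A", 5.94, 5.97, 0.85, 1.15, "Imprecision and trueness"),
    ("Ca", "Lab C", 5.66, 5.98, 1.21, 1.47, "Trueness"),
    ("P", "Lab A", 5.14, 5.77, 2.61, 2.44, "Trueness"),
    ("P", "Lab B", 4.77, 4.98, 4.76, 3.68, "Trueness"),
    ("P", "Lab C", 5.71, 5.73, 1.61, 2.22, "Trueness"),
    ("P", "Lab D", 5.90, 5.71, 1.79, 1.36, "Trueness"),
    ("GLU", "Lab C", 5.36, 5.80, 4.46, 4.96, "Trueness"),
    ("GLU", "Lab D", 5.72, 5.06, 2.25, 1.35, "Trueness"),
    ("GLU", "Lab E", 5.59, 5.95, 1.73, 1.56, "Trueness"),
    ("Urea", "Lab A", 5.69, 5.16, 0.23, 0.35, "Imprecision"),
    ("Urea", "Lab B", 4.09, 4.87, 1.71, 1.30, "Trueness"),
    ("Urea", "Lab D", 5.48, 5.85, 1.53, 1.72, "Trueness"),
    ("Crea", "Lab B", 5.27, 5.87, 1.71, 3.00, "Trueness"),
    ("Crea", "Lab C", 5.24, 5.80, 1.23, 1.43, "Trueness"),
    ("Crea", "Lab E", 5.25, 5.67, 0.99, 0.92, "Imprecision and trueness"),
    ("TP", "Lab B", 5.47, 5.86, 2.05, 2.60, "Trueness"),
    ("TP", "Lab C", 5.16, 5.92, 4.28, 4.63, "Trueness"),
    ("TP", "Lab E", 5.30, 5.94, 4.40, 3.16, "Trueness"),
    ("mALB", "Lab C", 5.05, 5.85, 3.15, 2.95, "Trueness"),
    ("mALB", "Lab E", 5.55, 5.83, 2.08, 2.01, "Trueness"),
)


def load_sigma_table() -> pd.DataFrame:
    """Survey sigma metrics, tidy: lab, analyte, tea, sigma_level1, sigma_level2."""
    rows = [
        {"lab": lab, "analyte": analyte, "tea": SURVEY_TEA[analyte],
         "sigma_level1": s1, "sigma_level2": s2}
        for analyte in ANALYTES
        for lab, (s1, s2) in SURVEY_SIGMA[analyte].items()
    ]
    return pd.DataFrame(rows)


def load_qgi_table() -> pd.DataFrame:
    """Survey sub-six-sigma QGI rows, tidy."""
    return pd.DataFrame(
        SURVEY_QGI,
        columns=["analyte", "lab", "sigma_level1", "sigma_level2",
                 "qgi_level1", "qgi_level2", "improvement"],
    )
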