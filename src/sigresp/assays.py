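"""Phenotype assay quantification and phospho-grading summaries.

Covers the three readouts accompanying the expression analysis: the XTT
proliferation assay (treated/control mean absorbance), the spheroid
expansion migration assay (radial spreading area corrected for spheroid
size at time zero), and the seven-symbol ordinal grading of Western-blot
phosphorylation changes (++, +, 0, -, --, u.e., n.S.), plus the Pearson
correlation checks between phenotypes and between grades and phenotypes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError
from .synthetic import DECREASE_GRADES, GRADE_SYMBOLS, NON_EVALUABLE_GRADES

INCREASE_GRADES = ("+", "++")

#: symmetric 5-point scale for ordinal-to-integer mapping
GRADE_SCORES = {"++": 2, "+": 1, "0": 0, "-": -1, "--": -2}


def proliferation_response(absorbance_treated, absorbance_control) -> float:
    """Fraction-of-control viability: mean(treated) / mean(control)."""
    treated = np.asarray(absorbance_treated, dtype=float)
    control = np.asarray(absorbance_control, dtype=float)
    if treated.size < 1 or control.size < 1:
        raise AssayError("need at least one replicate per arm")
    control_mean = control.mean()
    if not control_mean > 0:
        raise AssayError(f"control mean must be positive, got {control_mean}")
    return float(treated.mean() / control_mean)


def migration_response(
    area_treated_t0: float,
    area_treated_t16: float,
    area_control_t0: float,
    area_control_t16: float,
) -> float:
    """Fraction-of-control spheroid expansion, corrected for size at t0:
    (treated t16/t0) / (control t16/t0)."""
    areas = {
        "area_treated_t0": area_treated_t0,
        "area_treated_t16": area_treated_t16,
        "area_control_t0": area_control_t0,
        "area_control_t16": area_control_t16,
    }
    for name, a in areas.items():
        if not a > 0:
            raise AssayError(f"{name} must be positive, got {a}")
    if area_treated_t16 < area_treated_t0 or area_control_t16 < area_control_t0:
        raise AssayError("spheroid area may not shrink below its size at time zero")
    return float(
        (area_treated_t16 / area_treated_t0) / (area_control_t16 / area_control_t0)
    )


def _validate_grades(table: pd.DataFrame) -> pd.DataFrame:
    required = {"protein", "condition", "line", "grade"}
    missing = required - set(table.columns)
    if missing:
        raise AssayError(f"grading table missing column(s): {sorted(missing)}")
    bad = set(table["grade"]) - set(GRADE_SYMBOLS)
    if bad:
        raise AssayError(f"unknown grade symbol(s): {sorted(bad)}")
    dup = table.duplicated(subset=["protein", "condition", "line"])
    if dup.any():
        raise AssayError("duplicate (protein, condition, line) entries in grading table")
    return table


def summarize_grading(
    table: pd.DataFrame, protein: str, condition: str
) -> tuple[int, int, int]:
    """Count decreased phospho-signals for one protein under one condition.

    Returns ``(n_decreased, n_evaluable, pct_decreased)`` where evaluable
    entries exclude ``u.e.`` and ``n.S.``, decreased pools ``-`` and ``--``,
    and the percentage is the floor of 100 * decreased / evaluable (the
    integer convention matching the published summary fractions).
    """
    table = _validate_grades(table)
    sub = table[(table["protein"] == protein) & (table["condition"] == condition)]
    if sub.empty:
        raise AssayError(f"no entries for protein {protein!r} under {condition!r}")
    grades = sub["grade"]
    evaluable = grades[~grades.isin(NON_EVALUABLE_GRADES)]
    n_evaluable = int(evaluable.size)
    if n_evaluable == 0:
        raise AssayError(
            f"all entries for {protein!r} under {condition!r} are unevaluable"
        )
    n_decreased = int(evaluable.isin(DECREASE_GRADES).sum())
    pct = math.floor(100 * n_decreased / n_evaluable)
    return n_decreased, n_evaluable, pct


def grading_scores(
    table: pd.DataFrame, protein: str, condition: str
) -> pd.Series:
    """Ordinal grades mapped to the symmetric integer scale, indexed by
    line; unevaluable entries are dropped."""
    table = _validate_grades(table)
    sub = table[(table["protein"] == protein) & (table["condition"] == condition)]
    sub = sub[~sub["grade"].isin(NON_EVALUABLE_GRADES)]
    return pd.Series(
        [GRADE_SCORES[g] for g in sub["grade"]], index=list(sub["line"]), dtype=float
    )


def correlate_responses(a, b, method: str = "pearson") -> tuple[float, float]:
    """Pearson (or rank) correlation between two per-line phenotype (or
    grade-score) vectors on their shared lines, with a two-sided t-based p.

    Accepts mappings/Series keyed by line, or equal-length sequences.
    """
    if isinstance(a, dict):
        a = pd.Series(a)
    if isinstance(b, dict):
        b = pd.Series(b)
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        shared = a.index.intersection(b.index)
        av = a.loc[shared].to_numpy(dtype=float)
        bv = b.loc[shared].to_numpy(dtype=float)
    else:
        av = np.asarray(a, dtype=float)
        bv = np.asarray(b, dtype=float)
        if av.size != bv.size:
            raise ValueError("a and b must share lines or have equal length")
    if av.size < 4:
        raise ValueError(f"need at least 4 shared lines, got {av.size}")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return 0.0, 1.0
    if method == "pearson":
        r, p = stats.pearsonr(av, bv)
    elif method == "spearman":
        r, p = stats.spearmanr(av, bv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
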