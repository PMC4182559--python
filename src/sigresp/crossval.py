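"""Leave-one-out cross-validation with per-fold signature selection.

Every fold re-derives the signature (genes, size, weights) from scratch on
the remaining patients, so no information about the held-out patient leaks
into gene selection — the guard against the optimism that nested feature
selection is meant to avoid.  The predicted-vs-observed scatter is tested
two ways: a t-test on the Pearson correlation (headline p-value) and a
median-split 2x2 chi-square without continuity correction, reported
alongside because the assay literature sometimes quotes the latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .signature import lars_path, predict, select_model_cp

log = logging.getLogger(__name__)

CONDITIONS = {
    "treated_gf": (True, True),
    "treated_nogf": (True, False),
    "untreated_gf": (False, True),
    "untreated_nogf": (False, False),
}


@dataclass
class CVPrediction:
    """Per-patient cross-validated predictions with significance tests."""

    per_patient: pd.DataFrame  # index patient; predicted, observed, fold_genes
    r: float
    p_correlation: float
    chisq: float
    p_chisq: float
    method_notes: list[str] = field(default_factory=list)


def correlation_significance(pred, obs, method: str = "pearson_t") -> tuple[float, float]:
    """Test association between predicted and observed responses.

    ``pearson_t``: Pearson r with two-sided p from
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    ``chisq_median_split``: both sequences dichotomized at their medians,
    2x2 table, chi-square with 1 df, no continuity correction.
    Degenerate inputs (zero variance) return (0, 1).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal length")
    n = pred.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0, 1.0

    if method == "pearson_t":
        r = float(np.corrcoef(pred, obs)[0, 1])
        if abs(r) >= 1.0:
            return float(np.sign(r)), 0.0
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        return r, float(p)
    if method == "chisq_median_split":
        hp = pred > np.median(pred)
        ho = obs > np.median(obs)
        table = np.array(
            [
                [np.sum(hp & ho), np.sum(hp & ~ho)],
                [np.sum(~hp & ho), np.sum(~hp & ~ho)],
            ],
            dtype=float,
        )
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        if np.any(expected == 0):
            return 0.0, 1.0
        chi2 = float(np.sum((table - expected) ** 2 / expected))
        return chi2, float(stats.chi2.sf(chi2, df=1))
    raise ValueError(f"unknown method {method!r}")


def loocv_predict(x: pd.DataFrame, y: pd.Series) -> CVPrediction:
    """Leave-one-out cross-validated prediction with nested gene selection.

    Parameters
    ----------
    x : DataFrame, patients x genes — one predictor profile per patient.
    y : Series indexed like ``x`` — observed response per patient.
    """
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float).ravel(), index=x.index)
    n = x.shape[0]
    if n < 6:
        raise ValueError(f"leave-one-out needs at least 6 patients, got {n}")

    notes: list[str] = []
    rows = []
    for patient in x.index:
        x_train = x.drop(index=patient)
        y_train = y.drop(index=patient)
        if np.ptp(y_train.to_numpy()) == 0:
            pred = float(y_train.mean())
            genes: list[str] = []
            notes.append(f"fold {patient}: constant training response, predicted mean")
            log.info("fold %s: constant training response", patient)
        else:
            path = lars_path(x_train, y_train)
            model = select_model_cp(path)
            pred = float(predict(model, x.loc[[patient]])[0])
            genes = list(model.genes)
        rows.append((patient, pred, float(y.loc[patient]), ";".join(genes)))

    per_patient = pd.DataFrame(
        rows, columns=["patient", "predicted", "observed", "fold_genes"]
    ).set_index("patient")

    pred = per_patient["predicted"].to_numpy()
    obs = per_patient["observed"].to_numpy()
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        r, p_corr = 0.0, 1.0
        chi2, p_chi = 0.0, 1.0
        notes.append("degenerate predicted/observed variance; r set to 0, p to 1")
    else:
        r, p_corr = correlation_significance(pred, obs, "pearson_t")
        chi2, p_chi = correlation_significance(pred, obs, "chisq_median_split")

    return CVPrediction(
        per_patient=per_patient,
        r=r,
        p_correlation=p_corr,
        chisq=chi2,
        p_chisq=p_chi,
        method_notes=notes,
    )


def condition_matrix(
    matrix: pd.DataFrame, design: pd.DataFrame, predictor_condition: str
) -> pd.DataFrame:
    """Extract the one sample per patient matching a factorial condition and
    return the patients x genes predictor matrix."""
    if predictor_condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {predictor_condition!r}; choose from {sorted(CONDITIONS)}"
        )
    treated, gf = CONDITIONS[predictor_condition]
    design = design.loc[[s for s in matrix.columns if s in design.index]]
    sel = design[(design["treated"] == treated) & (design["gf"] == gf)]
    per_patient = sel.groupby("patient", sort=False).groups
    patients = list(dict.fromkeys(design["patient"]))
    missing = [p for p in patients if p not in per_patient]
    if missing:
        raise DesignError(
            f"patients missing the {predictor_condition} condition: {missing}"
        )
    rows = {}
    for p in patients:
        samples = list(per_patient[p])
        if len(samples) > 1:
            log.info("patient %s has %d %s samples; averaging", p, len(samples), predictor_condition)
        rows[p] = matrix[samples].mean(axis=1)
    return pd.DataFrame(rows).T  # patients x genes


def contrast_conditions(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    y: pd.Series,
    predictor_condition: str = "treated_gf",
) -> CVPrediction:
    """Run leave-one-out prediction using one factorial condition's profiles.

    The same operation serves the proliferation and the migration response:
    pass the response of interest as ``y`` (indexed by patient).
    """
    x = condition_matrix(matrix, design, predictor_condition)
    y = pd.Series(y).loc[x.index]
    out = loocv_predict(x, y)
    out.method_notes.append(f"predictors: {predictor_condition} profiles")
    return out
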