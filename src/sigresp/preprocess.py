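"""Variance filtering and parametric empirical-Bayes batch adjustment.

Each patient's set of arrays is treated as one batch.  The adjustment
follows the classical parametric empirical-Bayes model for location/scale
batch effects in expression data: per-gene standardization against a model
with batch indicators (plus, optionally, treatment and growth-factor
covariates so their signal survives the adjustment), per-batch additive
(gamma) and multiplicative (delta^2) effect estimates, shrinkage of gamma
toward a per-batch normal prior and of delta^2 toward a per-batch
inverse-gamma prior with moment-matched hyperparameters, and a fixed-point
iteration of the conditional posterior means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8
EB_TOL = 1e-4
EB_MAX_ITER = 100


def filter_by_variance(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the ``k`` genes with the largest expression variance across all
    samples, preserving the input gene order; ties broken by input order."""
    n_genes = matrix.shape[0]
    if not 1 <= k <= n_genes:
        raise ValueError(f"k must lie in [1, {n_genes}], got {k}")
    variances = matrix.to_numpy().var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")
    keep = np.sort(order[:k])
    dropped = n_genes - k
    if dropped:
        log.info("variance filter kept %d of %d genes (dropped %d)", k, n_genes, dropped)
    return matrix.iloc[keep]


@dataclass
class BatchParams:
    """Fitted batch-adjustment parameters.

    ``gamma_star`` / ``delta2_star`` are the shrunken additive and
    multiplicative adjustments (batches x genes, on the standardized scale);
    ``gamma_hat`` / ``delta2_hat`` the unshrunken per-batch estimates;
    ``hyper`` holds one row per batch with the moment-matched prior
    parameters (gamma_bar, tau2, lambda_, theta); ``standardization``
    records the per-gene grand mean, pooled sd and covariate coefficients
    used to map data to and from the standardized scale.
    """

    batches: list[str]
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    hyper: pd.DataFrame
    standardization: dict
    n_iterations: dict[str, int]

    def __post_init__(self) -> None:
        if (self.delta2_star.to_numpy() <= 0).any():
            raise ValueError("delta2_star must be positive")
        if (self.hyper["tau2"].to_numpy() < 0).any():
            raise ValueError("tau2 must be non-negative")


def _check_design(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    missing = [s for s in matrix.columns if s not in design.index]
    if missing:
        raise DesignError(f"samples without design annotation: {missing[:5]}")
    return design.loc[matrix.columns]


def adjust_batches_eb(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    preserve_covariates: bool = True,
    anchor: str = "batch",
) -> tuple[pd.DataFrame, BatchParams]:
    """Remove per-patient (batch) location/scale effects by parametric
    empirical Bayes.

    Parameters
    ----------
    matrix : DataFrame, genes x samples, log2 scale.
    design : DataFrame indexed by sample with columns ``patient``,
        ``treated``, ``gf``.
    preserve_covariates : include treated/gf indicators in the
        standardization model so the treatment signal is not absorbed into
        the batch means (default on).
    anchor : which samples estimate each batch's location/scale parameters.
        ``"batch"`` (classical): all samples of the batch — note that with a
        treated/untreated pair per patient this subtracts half of any
        patient-specific treatment response and mirrors its negative into
        the control profiles.  ``"control"``: the batch's untreated samples
        only, so the patient baseline defines the batch location and the
        drug response is left intact (used by the prediction pipeline).

    Returns the adjusted matrix (same shape and identifiers) and the fitted
    :class:`BatchParams`.  A single-batch input is its own reference and is
    returned unchanged.
    """
    if anchor not in ("batch", "control"):
        raise ValueError(f"anchor must be 'batch' or 'control', got {anchor!r}")
    design = _check_design(matrix, design)
    x = matrix.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_genes < 2:
        raise DesignError("empirical-Bayes shrinkage needs at least 2 genes")

    batches = list(dict.fromkeys(design["patient"]))
    batch_of = design["patient"].to_numpy()
    counts = {b: int((batch_of == b).sum()) for b in batches}
    small = [b for b, c in counts.items() if c < 2]
    if small:
        raise DesignError(f"each batch needs >= 2 samples; too small: {small}")
    untreated = ~design["treated"].to_numpy(dtype=bool)
    if anchor == "control":
        few = [b for b in batches if (untreated & (batch_of == b)).sum() < 2]
        if few:
            raise DesignError(
                f"anchor='control' needs >= 2 untreated samples per batch; too few: {few}"
            )
    # samples used to estimate each batch's location/scale parameters
    est_mask = untreated if anchor == "control" else np.ones(n_samples, dtype=bool)

    n_b = len(batches)
    gene_index = matrix.index
    if n_b == 1:
        # the lone batch defines the reference; nothing to remove
        params = BatchParams(
            batches=batches,
            gamma_star=pd.DataFrame(0.0, index=batches, columns=gene_index),
            delta2_star=pd.DataFrame(1.0, index=batches, columns=gene_index),
            gamma_hat=pd.DataFrame(0.0, index=batches, columns=gene_index),
            delta2_hat=pd.DataFrame(1.0, index=batches, columns=gene_index),
            hyper=pd.DataFrame(
                {"gamma_bar": [0.0], "tau2": [0.0], "lambda_": [np.inf], "theta": [np.inf]},
                index=batches,
            ),
            standardization={"note": "single batch, identity adjustment"},
            n_iterations={batches[0]: 0},
        )
        return matrix.copy(), params

    batch_dummies = np.column_stack([(batch_of == b).astype(float) for b in batches])
    if preserve_covariates:
        cov = np.column_stack(
            [
                design["treated"].to_numpy(dtype=float),
                design["gf"].to_numpy(dtype=float),
            ]
        )
        full_design = np.hstack([batch_dummies, cov])
    else:
        cov = np.zeros((n_samples, 0))
        full_design = batch_dummies

    # per-gene OLS of expression on batch indicators (+ covariates)
    beta, *_ = np.linalg.lstsq(full_design, x.T, rcond=None)
    beta_batch = beta[:n_b]  # batches x genes
    beta_cov = beta[n_b:]  # covariates x genes

    weights = np.array([counts[b] / n_samples for b in batches])
    grand_mean = weights @ beta_batch  # per gene
    fitted = full_design @ beta
    var_pooled = np.maximum(((x.T - fitted) ** 2).mean(axis=0), VARIANCE_FLOOR)
    pooled_sd = np.sqrt(var_pooled)

    cov_fit = (cov @ beta_cov).T if preserve_covariates else np.zeros_like(x)
    z = (x - grand_mean[:, None] - cov_fit) / pooled_sd[:, None]

    gamma_hat = np.empty((n_b, n_genes))
    delta2_hat = np.empty((n_b, n_genes))
    for i, b in enumerate(batches):
        zb = z[:, (batch_of == b) & est_mask]
        gamma_hat[i] = zb.mean(axis=1)
        delta2_hat[i] = np.maximum(zb.var(axis=1, ddof=1), VARIANCE_FLOOR)

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lambda_ = np.where(s2 > 0, (2 * s2 + m**2) / np.where(s2 > 0, s2, 1.0), np.inf)
        theta = np.where(s2 > 0, (m * s2 + m**3) / np.where(s2 > 0, s2, 1.0), np.inf)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iterations: dict[str, int] = {}
    for i, b in enumerate(batches):
        zb = z[:, (batch_of == b) & est_mask]
        n_i = zb.shape[1]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        if not np.isfinite(lambda_[i]):
            # delta estimates are identical across genes: point-mass prior,
            # no scale shrinkage possible
            gamma_star[i] = (
                gamma_bar[i]
                if tau2[i] <= 0
                else (n_i * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i])
                / (n_i * tau2[i] + d_old)
            )
            delta2_star[i] = d_old
            n_iterations[b] = 0
            continue
        it = 0
        for it in range(1, EB_MAX_ITER + 1):
            g_new = (n_i * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                n_i * tau2[i] + d_old
            )
            sum2 = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[i] + 0.5 * sum2) / (n_i / 2 + lambda_[i] - 1)
            change = max(
                np.abs(g_new - g_old).max(),
                np.abs(d_new - d_old).max(),
            )
            g_old, d_old = g_new, d_new
            if change < EB_TOL:
                break
        else:
            log.warning("EB fixed point for batch %s hit iteration cap", b)
        gamma_star[i] = g_old
        delta2_star[i] = np.maximum(d_old, VARIANCE_FLOOR)
        n_iterations[b] = it

    z_adj = z.copy()
    for i, b in enumerate(batches):
        sel = batch_of == b
        z_adj[:, sel] = (z[:, sel] - gamma_star[i][:, None]) / np.sqrt(
            delta2_star[i][:, None]
        )
    adjusted = z_adj * pooled_sd[:, None] + grand_mean[:, None] + cov_fit

    params = BatchParams(
        batches=batches,
        gamma_star=pd.DataFrame(gamma_star, index=batches, columns=gene_index),
        delta2_star=pd.DataFrame(delta2_star, index=batches, columns=gene_index),
        gamma_hat=pd.DataFrame(gamma_hat, index=batches, columns=gene_index),
        delta2_hat=pd.DataFrame(delta2_hat, index=batches, columns=gene_index),
        hyper=pd.DataFrame(
            {"gamma_bar": gamma_bar, "tau2": tau2, "lambda_": lambda_, "theta": theta},
            index=batches,
        ),
        standardization={
            "grand_mean": pd.Series(grand_mean, index=gene_index),
            "pooled_sd": pd.Series(pooled_sd, index=gene_index),
            "cov_coef": pd.DataFrame(
                beta_cov,
                index=["treated", "gf"] if preserve_covariates else [],
                columns=gene_index,
            ),
        },
        n_iterations=n_iterations,
    )
    out = pd.DataFrame(adjusted, index=gene_index, columns=matrix.columns)
    return out, params
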