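"""Per-gene linear models with empirical-Bayes moderated variances.

Each gene is regressed on an intercept, a treatment indicator and a
growth-factor indicator (the growth-factor term adjusts for its confounding
effect on expression).  Residual variances are shrunk toward a pooled prior
under a scaled-F model: the prior degrees of freedom d0 and prior variance
s0^2 are estimated by moment matching on log residual variances (digamma /
trigamma relations, with the trigamma equation inverted by monotone Newton
steps), the posterior variance is the weighted combination
(d0*s0^2 + df*s2) / (d0 + df), and the treatment coefficient is tested with
a t reference on d0 + df degrees of freedom.  False discovery rates use the
Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DesignError
from .preprocess import _check_design

log = logging.getLogger(__name__)


@dataclass
class ModeratedFit:
    """Per-gene linear-model fit, optionally with moderated statistics."""

    genes: pd.Index
    coef: pd.DataFrame  # genes x {treated, gf}, log2 fold-change units
    s2: pd.Series  # residual mean square per gene
    df_residual: float
    se_unit: float  # sqrt of the unscaled variance of the treated coefficient
    d0: float | None = None
    s0_2: float | None = None
    s2_post: pd.Series | None = None
    t_mod: pd.Series | None = None
    p: pd.Series | None = None
    fdr: pd.Series | None = None
    notes: list[str] = field(default_factory=list)


def fit_gene_linear_models(matrix: pd.DataFrame, design: pd.DataFrame) -> ModeratedFit:
    """Ordinary least squares of each gene on intercept + treated + gf.

    Returns coefficients, residual variances and residual degrees of
    freedom (n - 3); moderation is applied separately by
    :func:`moderate_variances`.
    """
    design = _check_design(matrix, design)
    treated = design["treated"].to_numpy(dtype=float)
    gf = design["gf"].to_numpy(dtype=float)
    if treated.min() == treated.max():
        raise DesignError("design needs both treated and untreated samples")
    d = np.column_stack([np.ones_like(treated), treated, gf])
    if np.linalg.matrix_rank(d) < d.shape[1]:
        raise DesignError("rank-deficient design: treated and gf are confounded")
    n = d.shape[0]
    df_residual = n - d.shape[1]
    if df_residual < 1:
        raise DesignError("need at least one residual degree of freedom")

    x = matrix.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(d, x.T, rcond=None)
    resid = x.T - d @ beta
    s2 = (resid**2).sum(axis=0) / df_residual
    xtx_inv = np.linalg.inv(d.T @ d)
    se_unit = float(np.sqrt(xtx_inv[1, 1]))

    return ModeratedFit(
        genes=matrix.index,
        coef=pd.DataFrame(
            {"treated": beta[1], "gf": beta[2]}, index=matrix.index
        ),
        s2=pd.Series(s2, index=matrix.index),
        df_residual=float(df_residual),
        se_unit=se_unit,
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def moderate_variances(fit: ModeratedFit) -> ModeratedFit:
    """Empirical-Bayes moderation of the residual variances of ``fit``.

    Moment matching on log s2: under the scaled-F model,
    E[log s2] = log s0^2 + digamma(df/2) - log(df/2)
                - digamma(d0/2) + log(d0/2)
    Var[log s2] = trigamma(df/2) + trigamma(d0/2),
    so d0 solves a trigamma equation and s0^2 follows from the mean.
    If the observed log-variance spread does not exceed the sampling
    component trigamma(df/2) (e.g. all s2 identical), d0 is effectively
    infinite and the pooled variance is used for every gene.
    """
    df = fit.df_residual
    s2 = fit.s2.to_numpy(dtype=float)
    positive = s2 > 0
    if positive.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    # zero-variance genes (exact fits) are excluded from prior estimation
    z = np.log(s2[positive])
    e_mean = z.mean()
    e_var = z.var(ddof=1)

    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean - special.digamma(df / 2.0) + np.log(df / 2.0)))
        fit.notes.append(
            "log-variance spread at or below sampling level; "
            "d0 set to infinity (pooled variance)"
        )
        log.info("moderate_variances: d0 -> inf, pooling variances")
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_2 = float(
            np.exp(
                e_mean
                - special.digamma(df / 2.0)
                + np.log(df / 2.0)
                + special.digamma(d0 / 2.0)
                - np.log(d0 / 2.0)
            )
        )

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    coef_t = fit.coef["treated"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef_t / (np.sqrt(s2_post) * fit.se_unit)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    fit.d0 = float(d0)
    fit.s0_2 = s0_2
    fit.s2_post = pd.Series(s2_post, index=fit.genes)
    fit.t_mod = pd.Series(t_mod, index=fit.genes)
    fit.p = pd.Series(p, index=fit.genes)
    fit.fdr = pd.Series(bh_adjust(p), index=fit.genes)
    return fit


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


def top_table(fit: ModeratedFit, n_top: int, fdr_max: float) -> list[str]:
    """Genes with fdr < ``fdr_max`` ranked by \\|moderated t\\| descending,
    truncated to ``n_top``; ties broken by gene identifier."""
    if fit.t_mod is None or fit.fdr is None:
        raise ValueError("fit has no moderated statistics; run moderate_variances first")
    keep = fit.fdr.to_numpy() < fdr_max
    ids = fit.genes.to_numpy()[keep]
    abs_t = np.abs(fit.t_mod.to_numpy())[keep]
    # |t| descending, equal-|t| ties resolved lexicographically by gene id
    order = np.lexsort((ids, -abs_t))
    return list(ids[order][:n_top])


def results_table(fit: ModeratedFit) -> pd.DataFrame:
    """Tab-friendly per-gene results: coefficients, moderated t, p, fdr."""
    if fit.t_mod is None:
        raise ValueError("run moderate_variances first")
    return pd.DataFrame(
        {
            "coef_treated": fit.coef["treated"],
            "coef_gf": fit.coef["gf"],
            "t_mod": fit.t_mod,
            "p": fit.p,
            "fdr": fit.fdr,
        },
        index=fit.genes,
    )
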