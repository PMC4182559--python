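"""Least angle regression and Mallows-Cp model selection.

The signature learner is a from-scratch implementation of least angle
regression (LARS): predictors are centered and scaled to unit norm, the
response is centered, and at each step the predictor most correlated with
the current residual joins the active set, after which coefficients move
along the equiangular direction until another predictor attains the same
absolute correlation.  One breakpoint of the path — the one minimizing a
Mallows-Cp statistic — is returned as the sparse quantitative signature.

Because the intended use is p >> n (hundreds of candidate genes, <= 18
patients), the classical Cp noise estimate (residual mean square of the
largest path model) is not available there: the largest model has no
residual degrees of freedom and interpolates the data.  In that regime the
noise variance is estimated conservatively by the sample variance of the
response (the residual variance of the null model), which scores each
breakpoint against the no-signal alternative; see docs/methods.md.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CORRELATION_EPS = 1e-10
RSS_ZERO = 1e-10


@dataclass
class LarsPath:
    """A least-angle-regression coefficient path.

    Coefficients are stored per breakpoint on the standardized-predictor
    scale (``coef_path``, shape steps+1 x p, first row all zero) together
    with the standardization needed to map them back to raw units.
    """

    predictor_ids: list[str]
    entry_order: list[str]
    coef_path: np.ndarray
    rss: np.ndarray  # per breakpoint, including the empty model
    rss_refit: np.ndarray  # least-squares refit of each breakpoint's support
    cp: np.ndarray | None
    centers: np.ndarray
    scales: np.ndarray
    y_center: float
    y_var: float
    n_samples: int
    dropped: list[str]
    x_std: np.ndarray | None = None  # standardized predictors (for refits)
    y_centered: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return self.coef_path.shape[0] - 1


@dataclass
class SignatureModel:
    """Sparse linear signature: response ~ intercept + x[genes] . weights."""

    genes: list[str]
    weights: np.ndarray  # raw-predictor scale
    intercept: float

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError("a signature holds at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("signature weights must be finite")


def _as_matrix(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    x = np.asarray(x, dtype=float)
    return x, [f"x{j}" for j in range(x.shape[1])]


def lars_path(x, y) -> LarsPath:
    """Compute the full least-angle-regression path.

    Parameters
    ----------
    x : array or DataFrame, samples x predictors.
    y : response sequence.

    Predictors with zero variance after centering are dropped (logged).
    The path terminates after ``min(n_samples - 1, n_predictors)`` steps or
    when residual correlations fall below 1e-10.  When several predictors
    tie for entry, the lexicographically smallest identifier enters first;
    predictors lying in the span of the active set (exact duplicates) are
    skipped.
    """
    xmat, ids = _as_matrix(x)
    y = np.asarray(y, dtype=float).ravel()
    n, p = xmat.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if y.size != n:
        raise ValueError("response length does not match predictor rows")

    centers = xmat.mean(axis=0)
    xc = xmat - centers
    norms = np.sqrt((xc**2).sum(axis=0))
    keep = norms > 1e-12
    dropped = [ids[j] for j in range(p) if not keep[j]]
    if dropped:
        log.info("dropping %d constant predictors: %s", len(dropped), dropped[:5])
    xc = xc[:, keep]
    ids_kept = [i for i, k in zip(ids, keep) if k]
    scales = norms[keep]
    xs = xc / scales
    p_eff = xs.shape[1]
    if p_eff == 0:
        raise ValueError("no non-constant predictors")

    y_center = float(y.mean())
    yc = y - y_center
    y_var = float(yc @ yc / max(n - 1, 1))

    max_steps = min(n - 1, p_eff)
    # lexicographic priority for deterministic tie-breaking
    lex_rank = np.argsort(np.argsort(ids_kept))

    beta = np.zeros(p_eff)
    resid = yc.copy()
    active: list[int] = []
    skipped: set[int] = set()
    coef_path = [beta.copy()]
    rss = [float(resid @ resid)]
    entry_order: list[str] = []

    while len(active) < max_steps:
        c = xs.T @ resid
        inactive = [j for j in range(p_eff) if j not in active and j not in skipped]
        if not inactive:
            break
        cmax = np.max(np.abs(c[inactive]))
        if cmax < CORRELATION_EPS:
            break
        # candidates tied at the maximal absolute correlation
        tol = 1e-9 * max(1.0, cmax)
        tied = [j for j in inactive if np.abs(c[j]) >= cmax - tol]
        tied.sort(key=lambda j: lex_rank[j])
        entered = None
        for j in tied:
            trial = active + [j]
            g = xs[:, trial].T @ xs[:, trial]
            if np.linalg.matrix_rank(g) == len(trial):
                entered = j
                break
            skipped.add(j)
            log.info("predictor %s is collinear with the active set; skipped", ids_kept[j])
        if entered is None:
            continue
        active.append(entered)
        entry_order.append(ids_kept[entered])

        xa = xs[:, active]
        s = np.sign(c[active])
        s[s == 0] = 1.0
        g = xa.T @ xa
        ginv_s = np.linalg.solve(g, s)
        aa = 1.0 / np.sqrt(max(s @ ginv_s, 1e-300))
        w = aa * ginv_s
        u = xa @ w  # equiangular direction, unit norm
        cmax_cur = float(np.max(np.abs(xs[:, active].T @ resid)))

        others = [j for j in range(p_eff) if j not in active and j not in skipped]
        gamma = cmax_cur / aa  # full step to the joint least-squares fit
        if others:
            a = xs[:, others].T @ u
            cj = c[others]
            with np.errstate(divide="ignore", invalid="ignore"):
                cand = np.concatenate(
                    [
                        (cmax_cur - cj) / (aa - a),
                        (cmax_cur + cj) / (aa + a),
                    ]
                )
            cand = cand[np.isfinite(cand) & (cand > 1e-14)]
            if cand.size:
                gamma = min(gamma, float(cand.min()))

        for idx, j in enumerate(active):
            beta[j] += gamma * w[idx]
        resid = resid - gamma * u
        coef_path.append(beta.copy())
        rss.append(float(resid @ resid))

    # least-squares refit of every breakpoint support; Cp scores these
    # (the path proposes candidate supports, refits score them)
    rss_refit = [float(yc @ yc)]
    active_sets = [active[:k] for k in range(1, len(active) + 1)]
    for sub in active_sets:
        beta_sub, *_ = np.linalg.lstsq(xs[:, sub], yc, rcond=None)
        r_sub = yc - xs[:, sub] @ beta_sub
        rss_refit.append(float(r_sub @ r_sub))

    path = LarsPath(
        predictor_ids=ids_kept,
        entry_order=entry_order,
        coef_path=np.array(coef_path),
        rss=np.array(rss),
        rss_refit=np.array(rss_refit),
        cp=None,
        centers=centers[keep],
        scales=scales,
        y_center=y_center,
        y_var=y_var,
        n_samples=n,
        dropped=dropped,
        x_std=xs,
        y_centered=yc,
    )
    path.cp = _cp_statistics(path)
    return path


def _sigma2(path: LarsPath) -> tuple[float, str]:
    """Noise-variance estimate for Cp.

    Residual mean square of the largest path model when it leaves residual
    degrees of freedom; otherwise (p >= n - 1) the conservative null-model
    estimate var(y).
    """
    n = path.n_samples
    k_last = path.n_steps
    df_resid = n - k_last - 1
    if df_resid >= 1:
        s2 = path.rss_refit[-1] / df_resid
        if s2 > RSS_ZERO:
            return float(s2), "rms_largest"
        return 0.0, "interpolating"
    return path.y_var, "var_y"


def _cp_statistics(path: LarsPath) -> np.ndarray:
    n = path.n_samples
    s2, kind = _sigma2(path)
    ks = np.arange(path.n_steps + 1)
    if kind == "interpolating" or s2 <= 0:
        return np.full(ks.size, np.nan)
    return path.rss_refit / s2 - n + 2.0 * (ks + 1)


def select_model_cp(path: LarsPath) -> SignatureModel:
    """Pick the Cp-minimizing breakpoint of ``path`` as the signature.

    Cp_k = RSS_k / sigma^2 - n + 2 (k + 1) with RSS_k the least-squares
    refit of breakpoint k's support (so the score agrees with best-subset
    Cp whenever the subset optimum lies on the path); ties go to the
    smaller model.
    If the path interpolates exactly (zero-noise response), the smallest
    breakpoint with RSS < 1e-10 is selected instead.  Weights are returned
    on the raw predictor scale with a matching intercept.
    """
    if path.n_steps < 1:
        raise ValueError("path is empty; nothing to select")
    if path.cp is not None and np.all(np.isfinite(path.cp[1:])):
        ks = np.arange(1, path.n_steps + 1)
        cp = path.cp[1:]
        k = int(ks[np.argmin(cp)])  # argmin takes first minimum: smaller k on ties
    else:
        # interpolating path: smallest breakpoint that already fits exactly
        below = np.nonzero(path.rss_refit <= RSS_ZERO)[0]
        k = int(below[0]) if below.size else path.n_steps
        k = max(k, 1)
        log.info("interpolating path: selected smallest exact-fit breakpoint k=%d", k)

    beta_std = path.coef_path[k]
    nz = np.nonzero(beta_std)[0]
    if nz.size == 0:
        # Cp chose a breakpoint before any coefficient moved; keep the first
        # entered predictor with zero weight so the model is well-formed
        nz = np.array([path.predictor_ids.index(path.entry_order[0])])
    # the path proposes the support; the model is its least-squares refit
    # (unshrunken weights stabilize fold-to-fold prediction scale)
    beta_sub, *_ = np.linalg.lstsq(path.x_std[:, nz], path.y_centered, rcond=None)
    genes = [path.predictor_ids[j] for j in nz]
    weights = beta_sub / path.scales[nz]
    intercept = path.y_center - float(weights @ path.centers[nz])
    return SignatureModel(genes=genes, weights=weights, intercept=float(intercept))


def predict(model: SignatureModel, x) -> np.ndarray:
    """Apply a fitted signature: intercept + x[:, genes] . weights."""
    if isinstance(x, pd.DataFrame):
        missing = [g for g in model.genes if g not in x.columns]
        if missing:
            raise ValueError(f"predictor matrix is missing signature gene(s): {missing}")
        xm = x.loc[:, model.genes].to_numpy(dtype=float)
    else:
        xm = np.asarray(x, dtype=float)
        if xm.shape[1] != len(model.genes):
            raise ValueError(
                f"expected {len(model.genes)} predictor columns, got {xm.shape[1]}"
            )
    return model.intercept + xm @ model.weights


def best_subset_cp(x, y, max_size: int | None = None) -> tuple[tuple[str, ...], float]:
    """Exhaustive best-subset search scored by the same Cp statistic.

    Independent brute-force oracle for small p: every non-empty support is
    fit by ordinary least squares and scored with Cp using the noise
    estimate of the full model.  Returns the best support (gene identifiers)
    and its Cp.
    """
    xmat, ids = _as_matrix(x)
    y = np.asarray(y, dtype=float).ravel()
    n, p = xmat.shape
    if max_size is None:
        max_size = p
    ones = np.ones((n, 1))
    full = np.hstack([ones, xmat])
    rss_full = float(np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2))
    df_resid = n - p - 1
    if df_resid < 1:
        raise ValueError("best_subset_cp needs p < n - 1")
    s2 = rss_full / df_resid
    best: tuple[float, tuple[str, ...]] | None = None
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(range(p), size):
            d = np.hstack([ones, xmat[:, subset]])
            beta, *_ = np.linalg.lstsq(d, y, rcond=None)
            rss = float(np.sum((y - d @ beta) ** 2))
            cp = rss / s2 - n + 2 * (size + 1)
            key = (cp, tuple(ids[j] for j in subset))
            if best is None or key < best:
                best = key
    assert best is not None
    return best[1], best[0]
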