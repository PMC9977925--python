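"""Count-based differential hydroxymethylation testing.

The analysis treats RRHP junction counts like RNA-Seq gene counts: counts
are transformed to log2 counts-per-million, each observation receives a
precision weight from a fitted mean-variance trend (the voom recipe), a
two-group linear model is fitted per site by weighted least squares,
residual variances are shrunk toward a common prior by empirical-Bayes
moderation, and Benjamini-Hochberg adjustment controls the FDR.  Sites with
q < 0.05 are called differentially hydroxymethylated (DhmCs).

The voom transform of a count ``c`` in a library of size ``L`` is

    logcpm = log2((c + 0.5) / (L + 1) * 1e6)

Precision weights are the inverse fourth power of the trend's predicted
square-root residual standard deviation at each observation's fitted
log-count, the trend being a lowess fit of sqrt(residual SD) on average
log-count after an unweighted first pass.

Empirical-Bayes moderation estimates prior degrees of freedom d0 and prior
variance s0^2 by matching the first two moments of log s^2 to a scaled
F/log-chi-square law (digamma/trigamma equations), then forms the posterior

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and tests logFC / (s_tilde * stdev_unscaled) against t on d0 + d degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .quantify import CountMatrix


def trigamma(x):
    return polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the Newton step in 1/x space converges
    globally for y > 0.
    """
    if not np.isfinite(y):
        return np.inf
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return float(x)


@dataclass
class VoomResult:
    logcpm: pd.DataFrame            # sites x samples
    weights: np.ndarray             # sites x samples, > 0
    lib_sizes: pd.Series            # per sample (column sums of the input)
    trend_x: np.ndarray = field(repr=False, default=None)
    trend_y: np.ndarray = field(repr=False, default=None)


@dataclass
class SiteFit:
    coefficients: np.ndarray        # sites x 2 (intercept, group)
    stdev_unscaled: np.ndarray      # sites, for the group coefficient
    sigma: np.ndarray               # residual SD per site
    df_residual: int
    index: pd.Index


@dataclass
class ModeratedResult:
    d0: float
    s0_sq: float
    table: pd.DataFrame             # logFC, t, p, q, s2_post, mean_logcpm


def make_design(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + group indicator (large = 1) over non-control samples."""
    bio = samples[~samples["is_control"].astype(bool)]
    groups = set(bio["group"])
    if groups != {"large", "small"}:
        raise ValueError(f"expected groups {{large, small}}, got {sorted(groups)}")
    indicator = (bio["group"] == "large").astype(float).to_numpy()
    design = np.column_stack([np.ones(len(bio)), indicator])
    return design, list(bio.index)


def _ols_fit(y: np.ndarray, design: np.ndarray):
    """Unweighted per-site OLS: fitted values and residual SD."""
    pinv = np.linalg.pinv(design)
    beta = y @ pinv.T
    fitted = beta @ design.T
    resid = y - fitted
    df = y.shape[1] - np.linalg.matrix_rank(design)
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    return beta, fitted, sigma


def voom_transform(
    matrix: CountMatrix | pd.DataFrame,
    design: np.ndarray | None = None,
    span: float = 0.5,
    weight_ceiling: float = 1e6,
) -> VoomResult:
    """log2-CPM with mean-variance precision weights (the voom recipe)."""
    if isinstance(matrix, CountMatrix):
        counts = matrix.biological
        if design is None:
            design, _ = make_design(matrix.samples)
    else:
        counts = matrix
    y_counts = counts.to_numpy(dtype=float)
    lib = y_counts.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    if design is None:
        design = np.ones((y_counts.shape[1], 1))
    logcpm = np.log2((y_counts + 0.5) / (lib + 1.0) * 1e6)

    beta, fitted, sigma = _ols_fit(logcpm, design)
    # trend: sqrt(residual SD) against average log2 count
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    if np.ptp(sx) < 1e-12 or len(sx) < 3 or np.all(sy == sy[0]):
        # degenerate trend: constant predicted SD
        pred_sqrt_sd = np.full_like(fitted, max(sy.mean(), 0.0))
        trend_x = sx
        trend_y = sy
    else:
        smooth = lowess(
            sy, sx, frac=span, it=3, delta=0.01 * np.ptp(sx), return_sorted=True
        )
        trend_x, trend_y = smooth[:, 0], smooth[:, 1]
        fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
        pred_sqrt_sd = np.interp(fitted_logcount, trend_x, trend_y)
    with np.errstate(divide="ignore"):
        weights = pred_sqrt_sd**-4.0
    weights = np.clip(weights, 1.0 / weight_ceiling, weight_ceiling)
    return VoomResult(
        logcpm=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
        weights=weights,
        lib_sizes=pd.Series(lib, index=counts.columns),
        trend_x=trend_x,
        trend_y=trend_y,
    )


def weighted_lm_fit(voom: VoomResult, design: np.ndarray) -> SiteFit:
    """Per-site weighted least squares for a two-column design.

    Solved in closed form through the 2x2 weighted normal equations;
    ``stdev_unscaled`` is sqrt of the (1,1) element of (X'WX)^-1.
    """
    y = voom.logcpm.to_numpy()
    w = voom.weights
    n_sites, n_samples = y.shape
    x0 = design[:, 0]
    x1 = design[:, 1]
    a = w @ (x0 * x0)            # X'WX per site, elementwise
    b = w @ (x0 * x1)
    c = w @ (x1 * x1)
    det = a * c - b * b
    ty0 = (w * y) @ x0
    ty1 = (w * y) @ x1
    beta0 = (c * ty0 - b * ty1) / det
    beta1 = (a * ty1 - b * ty0) / det
    fitted = np.outer(beta0, x0) + np.outer(beta1, x1)
    resid = y - fitted
    df = n_samples - 2
    rss = (w * resid**2).sum(axis=1)
    sigma = np.sqrt(np.maximum(rss, 0.0) / df)
    stdev_unscaled = np.sqrt(a / det)
    return SiteFit(
        coefficients=np.column_stack([beta0, beta1]),
        stdev_unscaled=stdev_unscaled,
        sigma=sigma,
        df_residual=df,
        index=voom.logcpm.index,
    )


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to residual variances.

    Matches mean and variance of log(s^2) using digamma/trigamma identities
    for log chi-square; returns (d0, s0_sq) with d0 = inf when the observed
    spread does not exceed its sampling expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive finite variances to moderate")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(trigamma(df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # spread no larger than pure sampling noise: infinite prior df, and
        # the prior variance is the plain average of the observed variances
        d0 = math.inf
        s0_sq = float(s2[ok].mean())
    return d0, s0_sq


def ebayes_moderate(
    fit: SiteFit, d0: float | None = None, s0_sq: float | None = None
) -> ModeratedResult:
    """Empirical-Bayes variance moderation and moderated t-tests.

    Hyperparameters are estimated from the data unless supplied (d0 = 0
    reproduces the ordinary t-test; d0 = inf fully shrinks to the prior).
    """
    s2 = fit.sigma**2
    df = fit.df_residual
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = fit_f_dist(s2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    df_total = df + d0
    df_pooled = df * len(s2)
    df_total = min(df_total, df_pooled) if not math.isinf(d0) else df_pooled
    logfc = fit.coefficients[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * fit.stdev_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "q": q,
            "s2_post": s2_post,
            "sigma": fit.sigma,
        },
        index=fit.index,
    )
    return ModeratedResult(d0=float(d0), s0_sq=float(s0_sq), table=table)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j >= i} p(j) * m / j over the p-sorted order, capped at 1,
    returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_dhmc(result: ModeratedResult, q_max: float = 0.05) -> pd.DataFrame:
    """Sites with q strictly below ``q_max``, with direction, sorted by evidence."""
    table = result.table
    calls = table[table["q"] < q_max].copy()
    calls["direction"] = np.where(calls["logFC"] > 0, "up", "down")
    calls["abs_logFC"] = calls["logFC"].abs()
    calls = calls.sort_values(["q", "abs_logFC"], ascending=[True, False])
    return calls.drop(columns="abs_logFC")


def mds_coordinates(
    logcpm: pd.DataFrame | VoomResult, top_sites: int = 500
) -> pd.DataFrame:
    """Classical 2-D scaling of leading log-fold-change sample distances.

    The distance between two libraries is the root mean square of the
    ``top_sites`` largest absolute logCPM differences between them, computed
    pairwise — the largest fold changes lead each comparison.
    """
    if isinstance(logcpm, VoomResult):
        logcpm = logcpm.logcpm
    y = logcpm.to_numpy()
    n = y.shape[1]
    top = min(top_sites, y.shape[0])
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (y[:, i] - y[:, j]) ** 2
            largest = np.partition(diff2, len(diff2) - top)[len(diff2) - top:]
            d2[i, j] = d2[j, i] = largest.mean()
    dist = np.sqrt(d2)
    # classical (Torgerson) scaling
    jmat = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * jmat @ (dist**2) @ jmat
    vals, vecs = linalg.eigh(bmat)
    idx = np.argsort(vals)[::-1][:2]
    coords = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    return pd.DataFrame(coords, index=logcpm.columns, columns=["dim1", "dim2"])


def differential_analysis(
    matrix: CountMatrix,
    span: float = 0.5,
    q_max: float = 0.05,
) -> tuple[ModeratedResult, pd.DataFrame, VoomResult]:
    """Filtered count matrix -> moderated results, DhmC calls, voom object."""
    design, _ = make_design(matrix.samples)
    voom = voom_transform(matrix, design, span=span)
    fit = weighted_lm_fit(voom, design)
    moderated = ebayes_moderate(fit)
    moderated.table["mean_logcpm"] = voom.logcpm.mean(axis=1)
    calls = call_dhmc(moderated, q_max=q_max)
    return moderated, calls, voom
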