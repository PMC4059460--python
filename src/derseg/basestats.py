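"""Per-base linear models and empirical-Bayes moderated statistics.

Each row of the transformed coverage matrix is fitted with the same linear
model

    g(Y_ij) = alpha(l_j) + sum_p beta_p(l_j) X_pi + sum_k gamma_k(l_j) W_ik + e_ij

where g is log2 with a small offset, X are group indicators against the
reference category, and W are optional confounders (by convention the first
is a log library-size term).  Because the design is shared across bases the
whole genome is fitted with one pseudo-inverse and a pair of matrix
products.

Residual variances are then shrunk toward a common prior by the standard
moment-matching empirical-Bayes scheme on log sample variances (prior
degrees of freedom recovered by trigamma inversion), yielding a moderated
t-statistic per base for the two-group design, or a moderated F when more
than two groups are present.  Bases whose average raw coverage falls below
the expression cutoff are assigned statistic 0, keeping the genome track
contiguous for segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.special import digamma, polygamma

from .coverage import CoverageMatrix, DesignMatrix

__all__ = [
    "TransformSpec",
    "BaseFit",
    "BaseStats",
    "transform",
    "build_design",
    "fit_base_models",
    "moderate_statistics",
    "estimate_shrinkage_prior",
    "write_stat_track",
    "read_stat_track",
]


@dataclass(frozen=True)
class TransformSpec:
    """Elementwise count transform g(y) = log2(y + offset), offset > 0."""

    kind: str = "log2-offset"
    offset: float = 0.5

    def __post_init__(self) -> None:
        if self.kind != "log2-offset":
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.offset <= 0:
            raise ValueError("transform offset must be positive")


def transform(cov: CoverageMatrix, spec: TransformSpec = TransformSpec()) -> np.ndarray:
    """Apply g(y) = log2(y + offset) to the coverage matrix."""
    return np.log2(cov.counts + spec.offset)


@dataclass
class BaseFit:
    """Per-base OLS output under the shared design.

    ``contrast_cov`` is the (P-1, P-1) block of (X'X)^-1 for the group
    coefficients; for the two-group design its single entry is the variance
    multiplier v of the tested contrast.
    """

    alpha_hat: np.ndarray          # (L,)
    beta_hat: np.ndarray           # (L, P-1)
    gamma_hat: np.ndarray          # (L, K)
    resid_var: np.ndarray          # (L,)
    df_resid: int
    contrast_cov: np.ndarray       # (P-1, P-1)
    column_names: list[str]

    @property
    def contrast_scale(self) -> float:
        """Variance multiplier v of the single tested contrast (P=2)."""
        if self.beta_hat.shape[1] != 1:
            raise ValueError("scalar contrast scale is defined only for P=2")
        return float(self.contrast_cov[0, 0])


def build_design(
    design: DesignMatrix, library_norm: str = "log2"
) -> tuple[np.ndarray, list[str], int]:
    """Assemble the design matrix [1 | group indicators | confounders].

    ``library_norm="log2"`` appends log2(library_size) as a confounder
    column (the recommended depth adjustment); ``"none"`` omits it.
    Returns (X, column names, number of group-indicator columns).
    """
    parts = [np.ones((design.n_samples, 1))]
    names = ["intercept"]
    ind = design.group_indicators()
    parts.append(ind)
    names += [f"group[{lv}]" for lv in design.levels[1:]]
    if design.confounders is not None:
        parts.append(design.confounders)
        names += list(design.confounder_names)
    if library_norm == "log2":
        if design.library_size is None:
            raise ValueError("library_norm='log2' requires library_size")
        col = np.log2(design.library_size)
        # a constant depth summary (common on sparse spans where every
        # sample's median is the substituted floor) carries no information
        # and would be collinear with the intercept — omit it
        if np.ptp(col) > 1e-12:
            parts.append(col[:, None])
            names.append("log2_libsize")
    elif library_norm != "none":
        raise ValueError(f"unknown library_norm {library_norm!r}")
    return np.hstack(parts), names, ind.shape[1]


def fit_base_models(
    transformed: np.ndarray,
    design: DesignMatrix,
    library_norm: str = "log2",
) -> BaseFit:
    """Ordinary least squares for every base under the shared design.

    Raises
    ------
    ValueError
        If the design is rank deficient (naming the collinear columns) or
        leaves no residual degrees of freedom.
    """
    design.validate_for_fit()
    X, names, n_ind = build_design(design, library_norm)
    n, q = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        # pivoted QR: columns arriving after the rank-th pivot are the
        # linearly dependent ones
        _, _, piv = qr(X, pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    df = n - q
    if df < 1:
        raise ValueError(
            f"need at least rank+1={q + 1} samples, got {n}"
        )
    pinv = np.linalg.pinv(X)                       # (q, n)
    coef = transformed @ pinv.T                    # (L, q)
    resid = transformed - coef @ X.T
    resid_var = np.einsum("ij,ij->i", resid, resid) / df
    resid_var = np.maximum(resid_var, 0.0)
    xtx_inv = np.linalg.inv(X.T @ X)
    sl = slice(1, 1 + n_ind)
    return BaseFit(
        alpha_hat=coef[:, 0],
        beta_hat=coef[:, sl],
        gamma_hat=coef[:, 1 + n_ind :],
        resid_var=resid_var,
        df_resid=df,
        contrast_cov=xtx_inv[sl, sl],
        column_names=names,
    )


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_shrinkage_prior(
    sample_vars: np.ndarray, df: int
) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log sample variances.

    Treats d * s^2 / sigma^2 as chi^2_d with sigma^2 drawn from the scaled
    inverse-chi^2 prior (d0, s0^2); matches the mean and variance of
    log(s^2).  Returns d0 = inf (fully pooled variance) when the observed
    spread of log variances does not exceed the chi^2 sampling noise.
    """
    v = np.asarray(sample_vars, float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        return np.inf, float(np.mean(sample_vars)) if len(sample_vars) else 1.0
    z = np.log(v)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(polygamma(1, df / 2.0))
    # no spread beyond chi^2 sampling noise: fully pooled variance
    if excess <= 0:
        return np.inf, float(np.mean(v))
    half_d0 = _trigamma_inverse(excess)
    if not np.isfinite(half_d0):
        return np.inf, float(np.mean(v))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(mean_e + digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


@dataclass
class BaseStats:
    """Moderated statistic track with its shrinkage hyperparameters.

    ``stats`` is defined at every analyzed base: the moderated t (signed,
    two groups) or moderated F (non-negative, more groups) at expressed
    bases, exactly 0 at bases below the expression cutoff.
    """

    stats: np.ndarray
    expressed_mask: np.ndarray
    d0: float
    s0_sq: float
    cutoff_c: float
    kind: str = "t"                # "t" or "F"

    @property
    def n_expressed(self) -> int:
        return int(self.expressed_mask.sum())


def moderate_statistics(
    fit: BaseFit,
    cov: CoverageMatrix,
    cutoff_c: float = 5.0,
    d0: float | None = None,
    s0_sq: float | None = None,
    min_expressed: int = 10,
) -> BaseStats:
    """Shrink residual variances and form the per-base statistic track.

    The prior (d0, s0^2) is estimated from the expressed bases unless both
    are supplied.  Posterior variance per base is

        s~^2 = (d0 s0^2 + d s^2) / (d0 + d)

    and for the two-group design the statistic is beta_hat / sqrt(s~^2 v).
    Bases with across-sample average raw coverage below ``cutoff_c`` get
    statistic 0 and an unset expressed flag.
    """
    mask = cov.mean_coverage() >= cutoff_c
    n_exp = int(mask.sum())
    if n_exp < min_expressed:
        raise ValueError(
            f"only {n_exp} bases reach average coverage {cutoff_c}; "
            f"need at least {min_expressed} to estimate the variance prior"
        )
    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_shrinkage_prior(
            fit.resid_var[mask], fit.df_resid
        )
        if not np.isfinite(s0_est) or s0_est <= 0:
            warnings.warn(
                "variance-prior estimation degenerate; pooling all variances",
                RuntimeWarning,
                stacklevel=2,
            )
            d0_est, s0_est = np.inf, float(np.mean(fit.resid_var[mask]))
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    post_var = posterior_variance(fit.resid_var, fit.df_resid, d0, s0_sq)
    n_contrast = fit.beta_hat.shape[1]
    stats = np.zeros(cov.n_bases)
    if n_contrast == 1:
        v = fit.contrast_scale
        denom = np.sqrt(post_var[mask] * v)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = fit.beta_hat[mask, 0] / denom
        t[~np.isfinite(t)] = 0.0
        stats[mask] = t
        kind = "t"
    else:
        cinv = np.linalg.inv(fit.contrast_cov)
        b = fit.beta_hat[mask]
        quad = np.einsum("ij,jk,ik->i", b, cinv, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = quad / (n_contrast * post_var[mask])
        f[~np.isfinite(f)] = 0.0
        stats[mask] = f
        kind = "F"
    return BaseStats(
        stats=stats,
        expressed_mask=mask,
        d0=float(d0),
        s0_sq=float(s0_sq),
        cutoff_c=cutoff_c,
        kind=kind,
    )


def posterior_variance(
    sample_var: np.ndarray, df: float, d0: float, s0_sq: float
) -> np.ndarray:
    """Empirical-Bayes posterior variance (d0 s0^2 + d s^2)/(d0 + d)."""
    sample_var = np.asarray(sample_var, float)
    if np.isinf(d0):
        return np.full_like(sample_var, s0_sq)
    return (d0 * s0_sq + df * sample_var) / (d0 + df)


def write_stat_track(stats: BaseStats, cov: CoverageMatrix, path) -> None:
    """Dump the statistic track as tab-separated text (full float precision)."""
    df = pd.DataFrame(
        {
            "chrom": cov.chrom,
            "position": cov.positions,
            "stat": stats.stats,
            "expressed": stats.expressed_mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_stat_track(path) -> pd.DataFrame:
    """Read a statistic track written by :func:`write_stat_track`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
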