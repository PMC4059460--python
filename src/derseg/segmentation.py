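"""Genome segmentation of the per-base statistic track with a 3-state HMM.

The hidden state D(l) of each base is

    0 — essentially no expression (statistic pinned near 0),
    1 — expressed, not differentially expressed,
    2 — differentially expressed (the state of interest).

Emissions are normal: state 0 is N(0, delta) with delta a tiny fixed
variance, and states 1-2 are the two components of a normal mixture fitted
to the statistics at expressed bases (the two-groups / empirical-null
decomposition: a narrow null component and a wider "interesting" one).
The state prior for 0 is the fraction of bases whose average coverage
falls below the expression cutoff; the mixture weights, scaled by 1 - pi0,
give the priors for states 1 and 2.  The transition matrix is fixed with a
high self-retention probability reflecting the gene-scale sparsity of
expression — it is deliberately not estimated from data.  Decoding is the
joint maximum a posteriori path (Viterbi), and maximal runs of equal
decoded state become regions; runs in state 2 are the candidate
differentially expressed regions (DERs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix

__all__ = [
    "MixtureFit",
    "HMMParams",
    "Region",
    "estimate_pi0",
    "fit_mixture",
    "build_hmm",
    "viterbi_decode",
    "extract_regions",
    "regions_to_frame",
    "regions_to_bed",
]

_VAR_FLOOR = 1e-8
_WEIGHT_FLOOR = 1e-4


@dataclass
class MixtureFit:
    """Two-component normal mixture over expressed-base statistics.

    Component 1 is the null, component 2 the alternative.  Labels are
    assigned by second moment about zero (mu^2 + var): a null t-track
    concentrates near 0, so the component with the smaller mean-square
    statistic is the null.  In ordinary regimes (a dominant null peak at 0
    plus a wider differential component) this coincides with the variance
    ordering var2 >= var1.
    """

    pi1_star: float
    pi2_star: float
    mu1: float
    var1: float
    mu2: float
    var2: float
    loglik: float
    n_iter: int
    converged: bool


@dataclass
class HMMParams:
    """Fully specified 3-state HMM: priors, fixed transitions, emissions."""

    state_priors: np.ndarray       # (3,)
    transition: np.ndarray         # (3, 3)
    means: np.ndarray              # (3,)
    variances: np.ndarray          # (3,)
    cutoff_c: float = 5.0
    delta: float = 1e-4

    def __post_init__(self) -> None:
        self.state_priors = np.asarray(self.state_priors, float)
        self.transition = np.asarray(self.transition, float)
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        if not np.isclose(self.state_priors.sum(), 1.0):
            raise ValueError("state priors must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")


@dataclass
class Region:
    """Maximal run of contiguous bases sharing one decoded state."""

    chrom: str
    start: int                      # 0-based half-open
    end: int
    state: int
    mean_stat: float
    direction: str = "mixed"
    p: float | None = None
    q: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def estimate_pi0(cov: CoverageMatrix, cutoff_c: float = 5.0) -> float:
    """Fraction of analyzed bases with average raw coverage below cutoff_c."""
    if cov.n_bases == 0:
        raise ValueError("empty coverage matrix")
    if cutoff_c <= 0:
        raise ValueError("cutoff_c must be positive")
    return float(np.mean(cov.mean_coverage() < cutoff_c))


def _norm_logpdf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def fit_mixture(
    stats: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_points: int = 50,
    null_mean_bound: float = 2.0,
    null_var_bound: float = 9.0,
) -> MixtureFit:
    """EM fit of the two-groups normal mixture to expressed-base statistics.

    Initialization is robust: the null component starts at the median with
    scale 1.4826 * MAD and weight 0.95; the alternative starts centred in
    the heavier tail with four times the null variance.  Component
    variances are floored at 1e-8 and weights at 1e-4; throughout the fit
    the labels are kept ordered so that component 1 (the null) has the
    smaller second moment about zero.

    The null component is additionally constrained to look like a null:
    a moderated t under the null hypothesis has mean 0 and roughly unit
    variance, so mu1 is clamped to [-null_mean_bound, null_mean_bound] and
    var1 to at most null_var_bound (generous allowances for correlation
    and overdispersion).  The constraint is inactive on ordinary tracks;
    it matters when essentially every expressed base is differentially
    expressed (a group-specific chromosome), where an unconstrained EM
    would have no null mass to anchor to and would drift both components
    onto the signal.
    """
    s = np.asarray(stats, float)
    s = s[np.isfinite(s)]
    if s.size < min_points:
        raise ValueError(
            f"need at least {min_points} statistics to fit the mixture, got {s.size}"
        )
    mu1 = float(np.median(s))
    mad = float(np.median(np.abs(s - mu1)))
    var1 = max((1.4826 * mad) ** 2, _VAR_FLOOR)
    # centre component 2 on the extreme points: their mean sits in the
    # heavier tail when the alternative is one-sided, and near the null
    # centre — with a variance wide enough to cover both tails — when
    # differential signal runs in both directions
    dev = s - mu1
    k = max(int(0.05 * s.size), 5)
    extreme = s[np.argsort(-np.abs(dev))[:k]]
    mu2 = float(np.mean(extreme))
    var2 = max(4.0 * var1, float(np.mean((extreme - mu2) ** 2)))
    pi1, pi2 = 0.95, 0.05

    def _clamp_null(mu, var):
        mu = float(np.clip(mu, -null_mean_bound, null_mean_bound))
        var = float(np.clip(var, _VAR_FLOOR, null_var_bound))
        return mu, var

    mu1, var1 = _clamp_null(mu1, var1)

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        l1 = _norm_logpdf(s, mu1, var1) + np.log(pi1)
        l2 = _norm_logpdf(s, mu2, var2) + np.log(pi2)
        m = np.maximum(l1, l2)
        log_total = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
        new_loglik = float(np.sum(log_total))
        r2 = np.exp(l2 - log_total)
        r1 = 1.0 - r2
        n1, n2 = float(r1.sum()), float(r2.sum())
        pi1 = max(n1 / s.size, _WEIGHT_FLOOR)
        pi2 = max(n2 / s.size, _WEIGHT_FLOOR)
        norm = pi1 + pi2
        pi1, pi2 = pi1 / norm, pi2 / norm
        if n1 > 0:
            mu1 = float(np.sum(r1 * s) / n1)
            var1 = max(float(np.sum(r1 * (s - mu1) ** 2) / n1), _VAR_FLOOR)
        if n2 > 0:
            mu2 = float(np.sum(r2 * s) / n2)
            var2 = max(float(np.sum(r2 * (s - mu2) ** 2) / n2), _VAR_FLOOR)
        # keep component 1 the one concentrated nearest zero (the null)
        if mu2 * mu2 + var2 < mu1 * mu1 + var1:
            mu1, mu2 = mu2, mu1
            var1, var2 = var2, var1
            pi1, pi2 = pi2, pi1
        mu1, var1 = _clamp_null(mu1, var1)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (
            1.0 + abs(loglik)
        ):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    if not converged:
        warnings.warn(
            f"mixture EM did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    if mu2 * mu2 + var2 < mu1 * mu1 + var1:
        mu1, mu2 = mu2, mu1
        var1, var2 = var2, var1
        pi1, pi2 = pi2, pi1
        mu1, var1 = _clamp_null(mu1, var1)
    return MixtureFit(
        pi1_star=pi1,
        pi2_star=pi2,
        mu1=mu1,
        var1=var1,
        mu2=mu2,
        var2=var2,
        loglik=loglik,
        n_iter=it,
        converged=converged,
    )


def build_hmm(
    pi0: float,
    mix: MixtureFit,
    delta: float = 1e-4,
    retain_prob: float = 0.999,
    cutoff_c: float = 5.0,
) -> HMMParams:
    """Assemble HMM parameters from pi0 and the mixture fit.

    State priors are (pi0, (1-pi0) pi1*, (1-pi0) pi2*); the fixed
    transition matrix has ``retain_prob`` on the diagonal and splits the
    remainder evenly between the other two states.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    if not 0.0 < retain_prob < 1.0:
        raise ValueError("retain_prob must lie in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    priors = np.array([pi0, (1 - pi0) * mix.pi1_star, (1 - pi0) * mix.pi2_star])
    # guard against a degenerate all-or-nothing prior so decoding stays defined
    priors = np.maximum(priors, 1e-12)
    priors /= priors.sum()
    off = (1.0 - retain_prob) / 2.0
    trans = np.full((3, 3), off)
    np.fill_diagonal(trans, retain_prob)
    return HMMParams(
        state_priors=priors,
        transition=trans,
        means=np.array([0.0, mix.mu1, mix.mu2]),
        variances=np.array([delta, mix.var1, mix.var2]),
        cutoff_c=cutoff_c,
        delta=delta,
    )


def viterbi_decode(stats: np.ndarray, params: HMMParams) -> np.ndarray:
    """Jointly most probable state path, computed in log space.

    Ties are broken toward the lower-numbered (more conservative) state.
    Raises on non-finite statistics, naming the first offending position.
    """
    s = np.asarray(stats, float)
    if s.size == 0:
        raise ValueError("empty statistic track")
    bad = np.flatnonzero(~np.isfinite(s))
    if bad.size:
        raise ValueError(f"non-finite statistic at track index {bad[0]}")
    log_b = np.column_stack(
        [
            _norm_logpdf(s, params.means[d], params.variances[d])
            for d in range(3)
        ]
    )
    log_pi = np.log(params.state_priors)
    log_a = np.log(params.transition).tolist()
    lb = log_b.tolist()
    L = s.size
    psi = np.empty((L, 3), dtype=np.int8)
    row = lb[0]
    d0 = log_pi[0] + row[0]
    d1 = log_pi[1] + row[1]
    d2 = log_pi[2] + row[2]
    a = log_a
    for t in range(1, L):
        row = lb[t]
        pt = psi[t]
        prev0, prev1, prev2 = d0, d1, d2
        for j in range(3):
            best = prev0 + a[0][j]
            arg = 0
            v = prev1 + a[1][j]
            if v > best:
                best, arg = v, 1
            v = prev2 + a[2][j]
            if v > best:
                best, arg = v, 2
            pt[j] = arg
            if j == 0:
                n0 = best + row[0]
            elif j == 1:
                n1 = best + row[1]
            else:
                n2 = best + row[2]
        d0, d1, d2 = n0, n1, n2
    path = np.empty(L, dtype=np.int8)
    final = [d0, d1, d2]
    state = int(np.argmax(final))   # first max -> lower state on ties
    path[-1] = state
    for t in range(L - 1, 0, -1):
        state = int(psi[t, state])
        path[t - 1] = state
    return path


def extract_regions(
    path: np.ndarray,
    positions: np.ndarray,
    stats: np.ndarray,
    chrom: str = "chr",
    stat_mode: str = "mean",
    stat_kind: str = "t",
) -> list[Region]:
    """Collapse the state path into maximal same-state regions.

    ``stat_mode`` selects the region-level statistic: the mean of the
    base statistics over the run (default, comparable across region
    lengths) or their sum.  Direction is read from the sign of the region
    statistic for signed (t) tracks and reported as "mixed" for F tracks.
    The returned regions partition the analyzed span.
    """
    path = np.asarray(path)
    positions = np.asarray(positions)
    stats = np.asarray(stats, float)
    if not (path.shape == positions.shape == stats.shape):
        raise ValueError("path, positions, stats must be aligned")
    if path.size == 0:
        return []
    if stat_mode not in ("mean", "sum"):
        raise ValueError(f"unknown stat_mode {stat_mode!r}")
    boundaries = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [path.size]])
    regions = []
    for s, e in zip(starts, ends):
        seg = stats[s:e]
        val = float(seg.mean() if stat_mode == "mean" else seg.sum())
        if stat_kind == "t" and val != 0.0:
            direction = "up" if val > 0 else "down"
        else:
            direction = "mixed"
        regions.append(
            Region(
                chrom=chrom,
                start=int(positions[s]),
                end=int(positions[e - 1]) + 1,
                state=int(path[s]),
                mean_stat=val,
                direction=direction,
            )
        )
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Regions as a tidy table (one row per region, sorted by start)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length": [r.length for r in regions],
            "state": [r.state for r in regions],
            "mean_stat": [r.mean_stat for r in regions],
            "direction": [r.direction for r in regions],
            "p": [r.p for r in regions],
            "q": [r.q for r in regions],
        }
    )


def regions_to_bed(regions: list[Region], path) -> None:
    """Write regions as BED6: name=state, score=|region stat| clamped to 1000."""
    with open(path, "w") as fh:
        for r in regions:
            score = min(int(round(abs(r.mean_stat) * 100)), 1000)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tstate{r.state}\t{score}\t.\n"
            )
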