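"""Permutation-based significance for candidate DERs.

Region-level inference: group labels are permuted B times; for each
permutation the entire identification pipeline (per-base model refit,
variance moderation, mixture re-estimation, HMM decoding) is re-run and
the statistics of the resulting null state-2 regions are pooled.  A
candidate region's empirical p-value is the fraction of pooled null
region statistics at least as extreme as its own, and the p-values are
adjusted by Benjamini-Hochberg.

pi0 (the no-expression prior) is not recomputed inside permutations:
coverage, and hence the expressed/unexpressed split, is invariant under
label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import basestats, segmentation
from .config import RunConfig
from .coverage import CoverageMatrix, DesignMatrix
from .segmentation import Region

__all__ = [
    "NullPool",
    "SignificanceResult",
    "identify_candidates",
    "permutation_null",
    "empirical_pvalues",
    "adjust_fdr",
]

# fewest expressed-base statistics the mixture EM will accept; below this
# the track is treated as carrying no expression signal at all
_MIN_MIXTURE_POINTS = 50


@dataclass
class NullPool:
    """Null region statistics from B label permutations."""

    stats_per_perm: list[np.ndarray]
    seed: int

    @property
    def B(self) -> int:
        return len(self.stats_per_perm)

    @property
    def counts(self) -> np.ndarray:
        """P_b: number of null regions per permutation."""
        return np.array([len(s) for s in self.stats_per_perm])

    @property
    def pooled(self) -> np.ndarray:
        if not self.stats_per_perm:
            return np.empty(0)
        return np.concatenate([np.asarray(s, float) for s in self.stats_per_perm])


@dataclass
class SignificanceResult:
    """Empirical p-values and BH-adjusted q-values per candidate region."""

    p: np.ndarray
    q: np.ndarray
    n_null_ge: np.ndarray
    pool_size: int
    mode: str = "pseudocount"
    sided: str = "two"


def identify_candidates(
    transformed: np.ndarray,
    design: DesignMatrix,
    cov: CoverageMatrix,
    cfg: RunConfig,
    pi0: float,
) -> tuple[list[Region], basestats.BaseStats | None, segmentation.MixtureFit | None]:
    """One full identification pass: statistics -> mixture -> HMM -> regions.

    Shared verbatim between the observed data and every permutation so the
    two pipelines stay exchangeable.  If too few bases are expressed to
    estimate anything, the whole track is reported as one state-0 region
    (no candidates), which is the correct degenerate answer for empty or
    near-empty coverage.
    """
    n_expressed = int(np.sum(cov.mean_coverage() >= cfg.cutoff_c))
    if n_expressed < _MIN_MIXTURE_POINTS:
        regions = [
            Region(
                chrom=cov.chrom,
                start=int(cov.positions[0]),
                end=int(cov.positions[-1]) + 1,
                state=0,
                mean_stat=0.0,
            )
        ]
        return regions, None, None
    fit = basestats.fit_base_models(transformed, design, cfg.library_norm)
    stats = basestats.moderate_statistics(fit, cov, cutoff_c=cfg.cutoff_c)
    # segment on the magnitude track: differential signal can run in both
    # directions, and folding collapses the two symmetric modes into one so
    # the single-normal state-2 emission is well specified (the >2-group
    # F path is non-negative already); direction is recovered afterwards
    # from the signed statistics
    if stats.kind == "t" and cfg.segment_on == "magnitude":
        track = np.abs(stats.stats)
    else:
        track = stats.stats
    mix = segmentation.fit_mixture(
        track[stats.expressed_mask],
        max_iter=cfg.mixture_max_iter,
        tol=cfg.mixture_tol,
        min_points=_MIN_MIXTURE_POINTS,
    )
    params = segmentation.build_hmm(
        pi0, mix, delta=cfg.delta, retain_prob=cfg.retain_prob, cutoff_c=cfg.cutoff_c
    )
    path = segmentation.viterbi_decode(track, params)
    regions = segmentation.extract_regions(
        path,
        cov.positions,
        stats.stats,
        chrom=cov.chrom,
        stat_mode=cfg.stat_mode,
        stat_kind=stats.kind,
    )
    return regions, stats, mix


def permutation_null(
    cov: CoverageMatrix,
    design: DesignMatrix,
    cfg: RunConfig,
    B: int | None = None,
    seed: int | None = None,
    transformed: np.ndarray | None = None,
    pi0: float | None = None,
) -> NullPool:
    """Build the null pool from B uniform label permutations.

    Permutations are sampled uniformly with replacement over labelings; a
    permutation that happens to reproduce the observed labeling is kept
    (excluding it would bias the null).  Requires a two-group design with
    at least two samples per group.
    """
    if design.n_groups != 2:
        raise ValueError("permutation significance requires exactly two groups")
    design.validate_for_fit()
    B = cfg.B if B is None else B
    seed = cfg.seed if seed is None else seed
    if B < 1:
        raise ValueError("need at least one permutation")
    if transformed is None:
        transformed = basestats.transform(
            cov, basestats.TransformSpec(offset=cfg.offset)
        )
    if pi0 is None:
        pi0 = segmentation.estimate_pi0(cov, cfg.cutoff_c)
    rng = np.random.default_rng(seed)
    stats_per_perm: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(B):
            perm_design = design.permuted(rng)
            regions, _, _ = identify_candidates(
                transformed, perm_design, cov, cfg, pi0
            )
            null_stats = np.array(
                [r.mean_stat for r in regions if r.state == 2], float
            )
            stats_per_perm.append(null_stats)
    return NullPool(stats_per_perm=stats_per_perm, seed=seed)


def empirical_pvalues(
    observed: np.ndarray,
    pool: NullPool,
    mode: str = "pseudocount",
    sided: str = "two",
) -> SignificanceResult:
    """Empirical p-values of candidate region statistics against the pool.

    two-sided (default) counts null statistics with |s0| >= |s_r|;
    one-sided counts s0 > s_r (strict, as in the printed permutation
    formula).  "pseudocount" mode returns (1 + count) / (1 + pool size) so
    p is always positive; "exact" returns count / pool size and
    requires a non-empty pool.
    """
    observed = np.asarray(observed, float)
    null = pool.pooled
    n_pool = null.size
    if n_pool == 0:
        if mode == "exact":
            raise ValueError("empty null pool: cannot form exact p-values")
        warnings.warn(
            "empty null pool; all p-values set to 1", RuntimeWarning, stacklevel=2
        )
    if sided == "two":
        counts = np.array(
            [int(np.sum(np.abs(null) >= abs(o))) for o in observed]
        )
    elif sided == "one":
        counts = np.array([int(np.sum(null > o)) for o in observed])
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    if mode == "pseudocount":
        p = (1.0 + counts) / (1.0 + n_pool)
    elif mode == "exact":
        p = counts / n_pool
    else:
        raise ValueError(f"unknown p-value mode {mode!r}")
    q = adjust_fdr(np.clip(p, np.nextafter(0, 1), 1.0)) if p.size else p.copy()
    return SignificanceResult(
        p=p,
        q=q,
        n_null_ge=counts,
        pool_size=int(n_pool),
        mode=mode,
        sided=sided,
    )


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
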