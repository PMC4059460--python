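"""Model/Results interface over the full DER pipeline.

`DERModel` is built from a coverage matrix and a design (or directly from
bedGraph files plus a sample sheet); its `fit()` runs the whole
identify-then-annotate chain — per-base moderated statistics, mixture and
HMM estimation, Viterbi segmentation, permutation significance — and
returns a `DERResults` carrying the candidate regions with their p- and
q-values, the fitted nuisance parameters, and a `summary()` table.
Annotation against a feature reference hangs off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__  # noqa: F401  (recorded in run metadata)
from . import annotation as _annotation
from . import basestats, coverage, segmentation, significance
from .config import RunConfig
from .coverage import CoverageMatrix, DesignMatrix
from .segmentation import Region

__all__ = ["DERModel", "DERResults"]


class DERModel:
    """Differentially-expressed-region model for one chromosome.

    Parameters
    ----------
    cov : CoverageMatrix
        Base-by-sample read depth over a contiguous span.
    design : DesignMatrix
        Group labels (two groups for the permutation significance path)
        and optional confounders.
    config : RunConfig, optional
        Pipeline tunables; defaults are the documented ones.
    """

    def __init__(
        self,
        cov: CoverageMatrix,
        design: DesignMatrix,
        config: RunConfig | None = None,
    ) -> None:
        self.cov = cov
        self.design = design
        self.config = config or RunConfig()
        if self.config.library_norm == "log2" and design.library_size is None:
            # a genome-wide percentile summary degenerates to 0 on sparse
            # spans; fall back to the median over covered bases, which is
            # positive there and robust to composition bias
            method = self.config.library_method
            raw = coverage._depth_summary(cov, method)
            if method not in ("mean", "median-covered") and np.any(raw == 0):
                warnings.warn(
                    f"{method} depth summary is 0 for some sample; "
                    "using the median over covered bases as the library size",
                    RuntimeWarning,
                    stacklevel=2,
                )
                method = "median-covered"
            design.library_size = coverage.library_size(cov, method)

    @classmethod
    def from_bedgraphs(
        cls,
        files: Sequence[str | Path],
        chrom: str,
        groups: Sequence,
        config: RunConfig | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "DERModel":
        cov = coverage.read_coverage(files, chrom, sample_ids=sample_ids)
        return cls(cov, DesignMatrix(groups=list(groups)), config)

    @classmethod
    def from_sample_sheet(
        cls, sheet_path: str | Path, chrom: str, config: RunConfig | None = None
    ) -> "DERModel":
        sheet = coverage.read_sample_sheet(sheet_path)
        cov = coverage.read_coverage(
            sheet["file"].tolist(), chrom, sample_ids=sheet["sample_id"].tolist()
        )
        design = coverage.design_from_sheet(sheet)
        return cls(cov, design, config)

    def fit(self, B: int | None = None, seed: int | None = None) -> "DERResults":
        """Run identification and permutation significance.

        ``B`` label permutations (default from config) build the null
        pool; ``seed`` drives all randomness.  With ``B=0`` only the
        identification pass runs and candidates carry no p-values.
        """
        cfg = self.config
        B = cfg.B if B is None else B
        seed = cfg.seed if seed is None else seed
        transformed = basestats.transform(
            self.cov, basestats.TransformSpec(offset=cfg.offset)
        )
        pi0 = segmentation.estimate_pi0(self.cov, cfg.cutoff_c)
        regions, stats, mix = significance.identify_candidates(
            transformed, self.design, self.cov, cfg, pi0
        )
        hmm = (
            segmentation.build_hmm(
                pi0, mix, delta=cfg.delta, retain_prob=cfg.retain_prob,
                cutoff_c=cfg.cutoff_c,
            )
            if mix is not None
            else None
        )
        candidates = [r for r in regions if r.state == 2]
        pool = None
        sig = None
        if B > 0 and candidates:
            pool = significance.permutation_null(
                self.cov,
                self.design,
                cfg,
                B=B,
                seed=seed,
                transformed=transformed,
                pi0=pi0,
            )
            sig = significance.empirical_pvalues(
                np.array([r.mean_stat for r in candidates]),
                pool,
                mode=cfg.pvalue_mode,
                sided=cfg.sided,
            )
            for r, p, q in zip(candidates, sig.p, sig.q):
                r.p = float(p)
                r.q = float(q)
        elif B > 0 and not candidates:
            pool = significance.NullPool(stats_per_perm=[], seed=seed)
        return DERResults(
            model=self,
            regions=regions,
            base_stats=stats,
            mixture=mix,
            hmm=hmm,
            pi0=pi0,
            null_pool=pool,
            significance=sig,
            seed=seed,
            B=B,
        )


@dataclass
class DERResults:
    """Fitted pipeline output: regions, nuisance estimates, diagnostics."""

    model: DERModel
    regions: list[Region]
    base_stats: basestats.BaseStats | None
    mixture: segmentation.MixtureFit | None
    hmm: segmentation.HMMParams | None
    pi0: float
    null_pool: significance.NullPool | None
    significance: significance.SignificanceResult | None
    seed: int
    B: int
    annotated: list = field(default_factory=list, repr=False)

    @property
    def candidates(self) -> list[Region]:
        """State-2 regions (candidate DERs), genomic order."""
        return [r for r in self.regions if r.state == 2]

    def significant(self, q_threshold: float | None = None) -> list[Region]:
        thr = (
            self.model.config.fdr_threshold if q_threshold is None else q_threshold
        )
        return [r for r in self.candidates if r.q is not None and r.q < thr]

    def regions_frame(self) -> pd.DataFrame:
        return segmentation.regions_to_frame(self.regions)

    def candidates_frame(self) -> pd.DataFrame:
        return segmentation.regions_to_frame(self.candidates)

    def annotate(
        self, features: "_annotation.FeatureSet", q_threshold: float | None = None
    ):
        """Annotate candidate DERs and roll up exon/gene calls.

        Returns (annotated regions, exon table, gene table).
        """
        cfg = self.model.config
        thr = cfg.q_threshold if q_threshold is None else q_threshold
        annotated = _annotation.annotate_regions(self.candidates, features)
        exon_table, gene_table = _annotation.feature_rollup(
            annotated, features, thr, cfg.exon_frac_threshold
        )
        self.annotated = annotated
        return annotated, exon_table, gene_table

    def state_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0, 2: 0}
        for r in self.regions:
            counts[r.state] += 1
        return counts

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of a regression report."""
        cfg = self.model.config
        cov = self.model.cov
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Differentially expressed region model".center(w))
        lines.append("=" * w)
        n_exp = self.base_stats.n_expressed if self.base_stats else 0
        left = [
            f"Chromosome:        {cov.chrom}",
            f"Analyzed bases:    {cov.n_bases}",
            f"Samples:           {cov.n_samples} "
            f"({' vs '.join(str(l) for l in self.model.design.levels)})",
            f"Expressed bases:   {n_exp} (cutoff c={cfg.cutoff_c:g})",
            f"pi0 (state 0):     {self.pi0:.4f}",
        ]
        if self.base_stats:
            d0 = self.base_stats.d0
            left.append(
                f"Shrinkage prior:   d0={'inf' if np.isinf(d0) else f'{d0:.2f}'}, "
                f"s0^2={self.base_stats.s0_sq:.4f}"
            )
        if self.mixture:
            m = self.mixture
            left.append(
                f"Mixture (null):    pi1*={m.pi1_star:.3f}  "
                f"N({m.mu1:.3f}, {m.var1:.3f})"
            )
            left.append(
                f"Mixture (alt):     pi2*={m.pi2_star:.3f}  "
                f"N({m.mu2:.3f}, {m.var2:.3f})"
            )
        counts = self.state_counts()
        left.append(
            f"Regions:           {sum(counts.values())} "
            f"(state0={counts[0]}, state1={counts[1]}, state2={counts[2]})"
        )
        if self.null_pool is not None:
            left.append(
                f"Null pool:         {self.null_pool.pooled.size} statistics "
                f"from B={self.B} permutations (seed={self.seed})"
            )
            nsig = len(self.significant())
            left.append(
                f"Significant DERs:  {nsig} at q < {cfg.fdr_threshold:g}"
            )
        lines.extend(left)
        cands = self.candidates
        if cands:
            lines.append("-" * w)
            lines.append(
                f"{'start':>10} {'end':>10} {'length':>7} {'stat':>9} "
                f"{'dir':>5} {'p':>9} {'q':>9}"
            )
            for r in cands[:40]:
                p = f"{r.p:.4f}" if r.p is not None else "."
                q = f"{r.q:.4f}" if r.q is not None else "."
                lines.append(
                    f"{r.start:>10} {r.end:>10} {r.length:>7} "
                    f"{r.mean_stat:>9.3f} {r.direction:>5} {p:>9} {q:>9}"
                )
            if len(cands) > 40:
                lines.append(f"... ({len(cands) - 40} more candidate regions)")
        lines.append("=" * w)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write region tables, BED, and reproducibility metadata."""
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        rf = self.regions_frame()
        rf.to_csv(outdir / "regions.tsv", sep="\t", index=False)
        paths["regions"] = outdir / "regions.tsv"
        cf = self.candidates_frame()
        cf.to_csv(outdir / "candidate_ders.tsv", sep="\t", index=False)
        paths["candidates"] = outdir / "candidate_ders.tsv"
        segmentation.regions_to_bed(self.candidates, outdir / "candidate_ders.bed")
        paths["bed"] = outdir / "candidate_ders.bed"
        if self.null_pool is not None:
            np.savetxt(
                outdir / "null_pool.txt", self.null_pool.pooled, fmt="%.10g"
            )
            paths["null_pool"] = outdir / "null_pool.txt"
        meta = {
            "package": "derseg",
            "version": __version__,
            "seed": self.seed,
            "B": self.B,
            "pi0": float(self.pi0),
            "chrom": self.model.cov.chrom,
            "n_bases": int(self.model.cov.n_bases),
            "samples": list(self.model.cov.sample_ids),
            "groups": [str(g) for g in self.model.design.groups],
            "config": self.model.config.to_dict(),
        }
        with open(outdir / "run_metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
        paths["metadata"] = outdir / "run_metadata.yaml"
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        paths["summary"] = outdir / "summary.txt"
        return paths

    def plot_track(self, ax=None, window: tuple[int, int] | None = None):
        """Plot the statistic track with candidate regions shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        pos = self.model.cov.positions
        stats = (
            self.base_stats.stats if self.base_stats else np.zeros(pos.size)
        )
        if window:
            m = (pos >= window[0]) & (pos < window[1])
            pos, stats = pos[m], stats[m]
        ax.plot(pos, stats, lw=0.5, color="0.3")
        for r in self.candidates:
            ax.axvspan(r.start, r.end, color="crimson", alpha=0.25)
        ax.set_xlabel(f"position on {self.model.cov.chrom}")
        ax.set_ylabel("moderated statistic")
        return ax
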