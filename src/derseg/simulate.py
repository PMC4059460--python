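"""Synthetic two-group coverage with known expressed and DE regions.

The generator emulates the data the per-base model assumes: contiguous
expressed regions on an otherwise empty chromosome, negative-binomial
per-base counts (variance mu + phi mu^2; phi = 0 recovers Poisson),
per-sample library-size factors, and a fixed 20-base linear ramp at region
edges so boundaries blur the way read pileups do.  A configurable subset
of regions is differentially expressed at a given log2 fold change;
infinite fold changes plant group-specific regions (expressed in one group
and absent in the other — the sex-chromosome style contrast).

What it does not emulate: read-level structure (junctions, mapability,
GC-content trends) — coverage is drawn directly per base, independently
across bases given the region mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import CoverageMatrix, DesignMatrix, write_bedgraph
from .segmentation import Region

__all__ = [
    "SimRegion",
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "evaluate_calls",
    "write_outputs",
    "planted_scenario",
    "null_scenario",
    "group_specific_scenario",
]

EDGE_RAMP = 20  # bases of linear mean ramp at each region edge


@dataclass(frozen=True)
class SimRegion:
    """One planted expressed region.

    ``log2_fc`` is the group-2 vs group-1 log2 fold change: 0 means
    expressed but not DE; +inf/-inf plant group-specific expression
    (``base_mean`` is then the mean of the expressing group).
    """

    start: int
    end: int
    base_mean: float = 30.0
    log2_fc: float = 0.0

    @property
    def group_means(self) -> tuple[float, float]:
        if np.isposinf(self.log2_fc):
            return 0.0, self.base_mean
        if np.isneginf(self.log2_fc):
            return self.base_mean, 0.0
        return self.base_mean, self.base_mean * 2.0 ** self.log2_fc

    @property
    def is_de(self) -> bool:
        m1, m2 = self.group_means
        return m1 != m2

    @property
    def direction(self) -> str:
        """Direction of group 2 relative to group 1 ("up"/"down"/"none")."""
        m1, m2 = self.group_means
        if m2 > m1:
            return "up"
        if m2 < m1:
            return "down"
        return "none"


@dataclass
class SimConfig:
    genome_length: int = 100_000
    n_per_group: int = 5
    regions: list[SimRegion] = field(default_factory=list)
    dispersion: float = 0.1
    library_factor_sd: float = 0.15   # log-normal sd of per-sample depth factors
    seed: int = 1
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        regs = sorted(self.regions, key=lambda r: r.start)
        for r in regs:
            if not (0 <= r.start < r.end <= self.genome_length):
                raise ValueError(f"region {r.start}-{r.end} outside genome")
            if r.base_mean <= 0:
                raise ValueError("region base_mean must be positive")
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping expressed regions at {b.start} (truth must "
                    "be unambiguous)"
                )
        self.regions = regs


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    regions: list[SimRegion]
    library_factors: np.ndarray
    groups: list[str]
    seed: int
    chrom: str

    @property
    def expressed(self) -> list[SimRegion]:
        return list(self.regions)

    @property
    def de_regions(self) -> list[SimRegion]:
        return [r for r in self.regions if r.is_de]


def _edge_weights(length: int, ramp: int = EDGE_RAMP) -> np.ndarray:
    i = np.arange(length, dtype=float)
    up = np.minimum(1.0, (i + 1) / (ramp + 1))
    down = np.minimum(1.0, (length - i) / (ramp + 1))
    return np.minimum(up, down)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if phi == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / phi
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_experiment(cfg: SimConfig) -> tuple[CoverageMatrix, SimTruth]:
    """Draw one two-group experiment; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_group
    factors = np.exp(rng.normal(0.0, cfg.library_factor_sd, size=n))
    groups = ["g1"] * cfg.n_per_group + ["g2"] * cfg.n_per_group
    counts = np.zeros((cfg.genome_length, n), dtype=np.int64)
    for reg in cfg.regions:
        w = _edge_weights(reg.end - reg.start)
        m1, m2 = reg.group_means
        for i in range(n):
            mean_i = (m1 if i < cfg.n_per_group else m2) * factors[i]
            counts[reg.start : reg.end, i] = _nb_draw(rng, mean_i * w, cfg.dispersion)
    cov = CoverageMatrix(
        chrom=cfg.chrom,
        positions=np.arange(cfg.genome_length, dtype=np.int64),
        counts=counts,
        sample_ids=[f"s{i + 1:02d}" for i in range(n)],
    )
    truth = SimTruth(
        regions=list(cfg.regions),
        library_factors=factors,
        groups=groups,
        seed=cfg.seed,
        chrom=cfg.chrom,
    )
    return cov, truth


def design_from_truth(truth: SimTruth) -> DesignMatrix:
    return DesignMatrix(groups=truth.groups)


def evaluate_calls(
    called: list[Region],
    truth: SimTruth,
    q_threshold: float = 0.05,
    match_rule: str = "1bp",
) -> dict:
    """Score significant calls against the planted DE regions.

    sensitivity — fraction of true DE regions matched by a significant
    (q < threshold, state 2) call; precision — fraction of significant
    calls matching a true DE region; also the base-level Jaccard index of
    called vs true DE bases.  With no significant calls, precision is
    reported as 1.0 by convention with ``no_calls`` flagged.
    """
    if match_rule not in ("1bp", "jaccard0.5"):
        raise ValueError(f"unknown match rule {match_rule!r}")
    sig = [
        r
        for r in called
        if r.state == 2 and r.q is not None and r.q < q_threshold
    ]
    de = truth.de_regions

    def overlap(a_start, a_end, b_start, b_end):
        return max(0, min(a_end, b_end) - max(a_start, b_start))

    def matches(call, reg) -> bool:
        o = overlap(call.start, call.end, reg.start, reg.end)
        if o == 0:
            return False
        if match_rule == "1bp":
            return True
        union = max(call.end, reg.end) - min(call.start, reg.start)
        return o / union >= 0.5

    hit_truth = sum(1 for reg in de if any(matches(c, reg) for c in sig))
    sensitivity = hit_truth / len(de) if de else 1.0
    if sig:
        hit_calls = sum(1 for c in sig if any(matches(c, reg) for reg in de))
        precision = hit_calls / len(sig)
    else:
        precision = 1.0
    called_mask = np.zeros(max([r.end for r in truth.regions], default=1), bool)
    true_mask = np.zeros_like(called_mask)
    for c in sig:
        called_mask[c.start : min(c.end, called_mask.size)] = True
    for reg in de:
        true_mask[reg.start : reg.end] = True
    union = np.logical_or(called_mask, true_mask).sum()
    jaccard = (
        float(np.logical_and(called_mask, true_mask).sum() / union)
        if union
        else 1.0
    )
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "jaccard": jaccard,
        "n_significant": len(sig),
        "n_true_de": len(de),
        "no_calls": not sig,
    }


def write_outputs(
    cov: CoverageMatrix, truth: SimTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write bedGraphs, a sample sheet, and truth tables under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rows = []
    for i, sid in enumerate(cov.sample_ids):
        bg = outdir / f"{sid}.bedgraph"
        write_bedgraph(cov, i, bg)
        rows.append({"sample_id": sid, "file": bg.name, "group": truth.groups[i]})
        paths[sid] = bg
    sheet = outdir / "samples.tsv"
    pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
    paths["sample_sheet"] = sheet
    truth_tsv = outdir / "truth.tsv"
    pd.DataFrame(
        {
            "chrom": truth.chrom,
            "start": [r.start for r in truth.regions],
            "end": [r.end for r in truth.regions],
            "base_mean": [r.base_mean for r in truth.regions],
            "log2_fc": [r.log2_fc for r in truth.regions],
            "is_de": [r.is_de for r in truth.regions],
            "direction": [r.direction for r in truth.regions],
        }
    ).to_csv(truth_tsv, sep="\t", index=False)
    paths["truth"] = truth_tsv
    truth_bed = outdir / "truth_de.bed"
    with open(truth_bed, "w") as fh:
        for r in truth.de_regions:
            fh.write(f"{truth.chrom}\t{r.start}\t{r.end}\tde_{r.direction}\t0\t.\n")
    paths["truth_bed"] = truth_bed
    return paths


# ---------------------------------------------------------------------------
# Canned study scenarios (fixed conditions; only the seed varies)
# ---------------------------------------------------------------------------

def planted_scenario(seed: int = 1) -> SimConfig:
    """100 kb genome, 30 expressed 500 bp regions, 10 of them DE at |lfc|=2.

    DE regions alternate up/down; the remaining 20 regions are expressed
    but identical across groups, exercising the state-1/state-2 split.
    """
    regions = []
    start = 2_000
    gap = 2_800
    de_idx = set(range(0, 30, 3))
    sign = 1
    for i in range(30):
        fc = 0.0
        if i in de_idx:
            fc = 2.0 * sign
            sign = -sign
        regions.append(SimRegion(start=start, end=start + 500, base_mean=30.0, log2_fc=fc))
        start += 500 + gap
    return SimConfig(
        genome_length=100_000,
        n_per_group=5,
        regions=regions,
        dispersion=0.1,
        seed=seed,
    )


def null_scenario(seed: int = 1, genome_length: int = 20_000) -> SimConfig:
    """Expressed but nowhere-DE 20 kb genome for null calibration."""
    regions = [
        SimRegion(start=s, end=s + 500, base_mean=30.0, log2_fc=0.0)
        for s in range(1_000, genome_length - 1_000, 2_400)
    ]
    return SimConfig(
        genome_length=genome_length,
        n_per_group=5,
        regions=regions,
        dispersion=0.1,
        seed=seed,
    )


def group_specific_scenario(seed: int = 1) -> SimConfig:
    """Sex-chromosome analogue: regions expressed only in group 2.

    Eight 500 bp regions present in group 2 (mean 30) and absent in group
    1, so every one is differentially expressed with direction "up".
    """
    regions = [
        SimRegion(start=s, end=s + 500, base_mean=30.0, log2_fc=np.inf)
        for s in range(2_000, 48_000, 6_000)
    ]
    return SimConfig(
        genome_length=50_000,
        n_per_group=5,
        regions=regions,
        dispersion=0.1,
        seed=seed,
    )
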