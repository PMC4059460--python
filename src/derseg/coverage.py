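"""Per-base coverage tracks: bedGraph I/O and the base-by-sample coverage matrix.

The unit of data in this package is the *coverage matrix*: one row per
genomic base, one column per sample, entries the number of aligned reads
overlapping that base in that sample.  All coordinates are 0-based
half-open, the native bedGraph/BED convention; bases absent from a sample's
bedGraph are explicit zeros so every column spans the same contiguous run
of positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageMatrix",
    "DesignMatrix",
    "read_coverage",
    "write_bedgraph",
    "library_size",
    "read_sample_sheet",
]


class BedGraphError(ValueError):
    """Raised for malformed or inconsistent bedGraph input."""


@dataclass
class CoverageMatrix:
    """Base-by-sample read-depth counts over one contiguous chromosomal span.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    positions : ndarray of int
        Strictly increasing, contiguous 0-based base coordinates.
    counts : ndarray, shape (n_bases, n_samples)
        Non-negative integer coverage.
    sample_ids : list of str
        Column labels, in input order.
    """

    chrom: str
    positions: np.ndarray
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (bases x samples)")
        if self.counts.shape[0] != self.positions.shape[0]:
            raise ValueError("counts rows must match positions")
        if self.counts.shape[1] != len(self.sample_ids):
            raise ValueError("counts columns must match sample_ids")
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")
        if self.positions.size and np.any(np.diff(self.positions) != 1):
            raise ValueError("positions must be contiguous and increasing")

    @property
    def n_bases(self) -> int:
        return self.positions.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def span(self) -> tuple[int, int]:
        """Analyzed span as a 0-based half-open interval."""
        if self.n_bases == 0:
            return (0, 0)
        return (int(self.positions[0]), int(self.positions[-1]) + 1)

    def subset_samples(self, indices: Sequence[int]) -> "CoverageMatrix":
        """New matrix restricted to the given sample columns (in order)."""
        idx = list(indices)
        return CoverageMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            counts=self.counts[:, idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def mean_coverage(self) -> np.ndarray:
        """Across-sample average raw coverage per base."""
        return self.counts.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tab-friendly dump: position plus one column per sample."""
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "position", self.positions)
        df.insert(0, "chrom", self.chrom)
        return df


@dataclass
class DesignMatrix:
    """Per-sample group labels, optional confounders, and library sizes.

    ``groups`` holds one categorical label per sample; the first label
    encountered is the reference category.  ``confounders`` is an optional
    (n_samples, K) float array of nuisance covariates.  ``library_size``
    holds the per-sample depth summary conventionally used as the first
    confounder.
    """

    groups: Sequence
    confounders: np.ndarray | None = None
    library_size: np.ndarray | None = None
    confounder_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.groups = list(self.groups)
        if self.confounders is not None:
            self.confounders = np.atleast_2d(np.asarray(self.confounders, float))
            if self.confounders.shape[0] != len(self.groups):
                raise ValueError("confounder rows must match number of samples")
            if not self.confounder_names:
                self.confounder_names = [
                    f"w{k + 1}" for k in range(self.confounders.shape[1])
                ]
        if self.library_size is not None:
            self.library_size = np.asarray(self.library_size, float)
            if np.any(self.library_size <= 0):
                raise ValueError("library_size must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.groups)

    @property
    def levels(self) -> list:
        """Group levels in order of first appearance (first = reference)."""
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.levels)

    def group_indicators(self) -> np.ndarray:
        """(n_samples, P-1) 0/1 indicators for the non-reference groups."""
        levels = self.levels
        out = np.zeros((self.n_samples, len(levels) - 1))
        for i, g in enumerate(self.groups):
            p = levels.index(g)
            if p > 0:
                out[i, p - 1] = 1.0
        return out

    def validate_for_fit(self) -> None:
        counts = pd.Series(self.groups).value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(
                f"each group needs at least 2 samples for model fitting; "
                f"too small: {small}"
            )

    def permuted(self, rng: np.random.Generator) -> "DesignMatrix":
        """Return a copy with group labels permuted uniformly at random.

        Confounders and library sizes stay attached to their samples; only
        the covariate of interest is shuffled.
        """
        perm = rng.permutation(self.n_samples)
        return DesignMatrix(
            groups=[self.groups[i] for i in perm],
            confounders=self.confounders,
            library_size=self.library_size,
            confounder_names=list(self.confounder_names),
        )


def _read_bedgraph_intervals(
    path: str | Path, chrom: str
) -> list[tuple[int, int, float]]:
    """Parse one bedGraph file, returning sorted (start, end, value) on chrom."""
    intervals: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            c, s, e, v = parts[:4]
            if c != chrom:
                continue
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise BedGraphError(f"{path}:{lineno}: end <= start")
            if value < 0:
                raise BedGraphError(f"{path}:{lineno}: negative coverage")
            intervals.append((start, end, value))
    intervals.sort()
    for (s0, e0, _), (s1, _, _) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise BedGraphError(
                f"{path}: overlapping intervals on {chrom} near base {s1}"
            )
    return intervals


def read_coverage(
    files: Sequence[str | Path],
    chrom: str,
    span: tuple[int, int] | str = "auto",
    sample_ids: Sequence[str] | None = None,
) -> CoverageMatrix:
    """Assemble the coverage matrix from one bedGraph file per sample.

    Parameters
    ----------
    files : sequence of paths
        One 4-column bedGraph per sample; column order follows file order.
    chrom : str
        Chromosome to extract.
    span : (start, end) or "auto"
        Analyzed 0-based half-open span.  "auto" uses the union of covered
        intervals across all samples; uncovered bases inside the span are
        explicit zeros.
    sample_ids : optional sequence of names
        Defaults to file stems.

    Raises
    ------
    BedGraphError
        On malformed lines, within-file overlaps, or a chromosome absent
        from every file (empty matrix).
    """
    per_sample = [_read_bedgraph_intervals(f, chrom) for f in files]
    if sample_ids is None:
        sample_ids = [Path(f).stem for f in files]
    sample_ids = list(sample_ids)
    if span == "auto":
        covered = [iv for ivs in per_sample for iv in ivs]
        if not covered:
            raise BedGraphError(
                f"chromosome {chrom!r} absent from all input files"
            )
        lo = min(s for s, _, _ in covered)
        hi = max(e for _, e, _ in covered)
    else:
        lo, hi = span
        if hi <= lo:
            raise ValueError("span end must exceed span start")
    n = hi - lo
    counts = np.zeros((n, len(files)), dtype=np.int64)
    for i, ivs in enumerate(per_sample):
        for s, e, v in ivs:
            s, e = max(s, lo), min(e, hi)
            if e <= s:
                continue
            iv = int(round(v))
            if abs(v - iv) > 1e-6:
                raise BedGraphError(
                    f"{files[i]}: non-integral coverage value {v} on {chrom}"
                )
            counts[s - lo : e - lo, i] = iv
    return CoverageMatrix(
        chrom=chrom,
        positions=np.arange(lo, hi, dtype=np.int64),
        counts=counts,
        sample_ids=sample_ids,
    )


def write_bedgraph(cov: CoverageMatrix, sample: int | str, path: str | Path) -> None:
    """Write one sample's column as run-length-encoded bedGraph.

    Consecutive equal values are merged into one interval; a round-trip
    through :func:`read_coverage` reproduces the column exactly.
    """
    if isinstance(sample, str):
        sample = cov.sample_ids.index(sample)
    col = cov.counts[:, sample]
    pos = cov.positions
    with open(path, "w") as fh:
        if col.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(col)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [col.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{cov.chrom}\t{pos[s]}\t{pos[e - 1] + 1}\t{col[s]}\n")


def _depth_summary(cov: CoverageMatrix, method: str) -> np.ndarray:
    if method == "median":
        return np.median(cov.counts, axis=0).astype(float)
    if method == "q75":
        return np.percentile(cov.counts, 75, axis=0, method="linear")
    if method == "mean":
        return cov.counts.mean(axis=0).astype(float)
    if method == "median-covered":
        covered = cov.counts[cov.counts.mean(axis=1) > 0]
        if covered.size == 0:
            return np.zeros(cov.n_samples)
        return np.median(covered, axis=0).astype(float)
    raise ValueError(f"unknown library size method {method!r}")


def library_size(cov: CoverageMatrix, method: str = "median") -> np.ndarray:
    """Per-sample depth summary over all analyzed bases (zeros included).

    ``method`` is "median", "q75" (75th percentile, linear interpolation
    between order statistics — numpy's default definition), "mean"
    (average coverage, i.e. total coverage per analyzed base) or
    "median-covered" (median over the bases covered in at least one
    sample).  On sparse spans where most bases are empty, median and q75
    can be 0 for every sample; "median-covered" stays positive there while
    remaining robust to composition bias from strongly differential
    regions, unlike a total-count summary.  A sample whose summary is 0 gets
    the smallest positive summary across samples, with a warning, so
    downstream normalization never divides by zero.
    """
    if cov.n_bases == 0:
        raise ValueError("empty coverage matrix")
    vals = _depth_summary(cov, method)
    zero = vals == 0
    if zero.any():
        positive = vals[~zero]
        if positive.size == 0:
            warnings.warn(
                "all library-size summaries are zero; substituting 1.0",
                RuntimeWarning,
                stacklevel=2,
            )
            vals[:] = 1.0
        else:
            warnings.warn(
                f"{int(zero.sum())} sample(s) have a zero depth summary; "
                "substituting the smallest positive summary",
                RuntimeWarning,
                stacklevel=2,
            )
            vals[zero] = positive.min()
    return vals


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated sample sheet.

    Required columns: ``sample_id``, ``file``, ``group``; any further
    columns are treated as numeric covariates.  Relative file paths are
    resolved against the sheet's directory.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "file", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    base = Path(path).parent
    df["file"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["file"]
    ]
    return df


def design_from_sheet(
    sheet: pd.DataFrame, library_sizes: np.ndarray | None = None
) -> DesignMatrix:
    """Build a DesignMatrix from a sample sheet's group and covariate columns."""
    extra = [c for c in sheet.columns if c not in ("sample_id", "file", "group")]
    confounders = sheet[extra].to_numpy(float) if extra else None
    return DesignMatrix(
        groups=sheet["group"].tolist(),
        confounders=confounders,
        library_size=library_sizes,
        confounder_names=extra,
    )
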