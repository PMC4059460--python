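"""Annotation of DERs against a reference of known exons and genes.

Identify-then-annotate: the reference is consulted only after regions are
called.  Each region is classified as exonic (any exon overlap), intronic
(no exon overlap but inside a gene span, the min-start/max-end hull of the
gene's exons), or intergenic, and overlap fractions are reported both
relative to the region and to its best-overlapped exon.  Strand is carried
for reporting but ignored for overlap, since coverage is unstranded.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .segmentation import Region

__all__ = [
    "Exon",
    "FeatureSet",
    "AnnotatedRegion",
    "read_features",
    "annotate_regions",
    "feature_rollup",
    "annotated_to_frame",
]


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int          # 0-based half-open
    end: int
    exon_id: str
    gene_id: str
    strand: str = "."


@dataclass
class FeatureSet:
    """Deduplicated exons plus derived per-gene spans, all 0-based half-open."""

    exons: list[Exon]
    genes: dict = field(init=False)
    _exon_trees: dict = field(init=False, repr=False)
    _gene_trees: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.exons = sorted(set(self.exons), key=lambda e: (e.chrom, e.start, e.end))
        for e in self.exons:
            if e.end <= e.start:
                raise ValueError(f"exon {e.exon_id}: end <= start")
        spans: dict = {}
        for e in self.exons:
            key = (e.chrom, e.gene_id)
            lo, hi = spans.get(key, (e.start, e.end))
            spans[key] = (min(lo, e.start), max(hi, e.end))
        self.genes = spans
        self._exon_trees = defaultdict(IntervalTree)
        for e in self.exons:
            self._exon_trees[e.chrom].addi(e.start, e.end, e)
        self._gene_trees = defaultdict(IntervalTree)
        for (chrom, gid), (lo, hi) in spans.items():
            self._gene_trees[chrom].addi(lo, hi, gid)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(raw: str) -> dict:
    return dict(_GTF_ATTR.findall(raw))


def read_features(path: str | Path) -> FeatureSet:
    """Read exon features from GTF (1-based inclusive) or BED (0-based).

    GTF rows with feature type "exon" are used; each must carry a gene_id
    attribute (exon_id falls back to gene_id plus coordinates).  BED input
    uses the name column as exon_id and, lacking gene information, assigns
    each exon its own gene.  Identical duplicate exons are collapsed.
    """
    path = Path(path)
    exons: list[Exon] = []
    if path.suffix.lower() in (".gtf", ".gff"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
                if cols[2] != "exon":
                    continue
                attrs = _parse_gtf_attributes(cols[8])
                gene_id = attrs.get("gene_id")
                if not gene_id:
                    raise ValueError(f"{path}:{lineno}: exon without gene_id")
                start1, end1 = int(cols[3]), int(cols[4])
                start, end = start1 - 1, end1      # to 0-based half-open
                exon_id = attrs.get(
                    "exon_id", f"{gene_id}:{cols[0]}:{start}-{end}"
                )
                exons.append(Exon(cols[0], start, end, exon_id, gene_id, cols[6]))
    else:  # BED
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
                name = cols[3] if len(cols) > 3 else f"{chrom}:{start}-{end}"
                strand = cols[5] if len(cols) > 5 else "."
                exons.append(Exon(chrom, start, end, name, name, strand))
    return FeatureSet(exons=exons)


@dataclass
class AnnotatedRegion:
    """A region plus its overlap with the reference exons and genes."""

    region: Region
    klass: str                      # "exonic" | "intronic" | "intergenic"
    best_exon_id: str | None
    overlap_bases: int
    frac_region: float
    frac_exon: float
    gene_ids: list[str]


def annotate_regions(
    regions: list[Region], features: FeatureSet
) -> list[AnnotatedRegion]:
    """Classify each region and compute overlap fractions.

    Exonic if it overlaps any exon by at least one base; intronic if not
    but it lies within some gene span; intergenic otherwise.  The best
    exon is the one with most overlapping bases, ties broken toward the
    smaller exon start.
    """
    out = []
    for r in regions:
        tree = features._exon_trees.get(r.chrom)
        hits = sorted(tree.overlap(r.start, r.end)) if tree else []
        total = 0
        best = None
        best_olap = -1
        gene_ids: set[str] = set()
        for iv in hits:
            olap = min(r.end, iv.end) - max(r.start, iv.begin)
            total += olap
            gene_ids.add(iv.data.gene_id)
            if olap > best_olap or (
                olap == best_olap and best is not None and iv.begin < best.start
            ):
                best_olap = olap
                best = iv.data
        if best is not None:
            klass = "exonic"
            frac_region = best_olap / r.length
            frac_exon = best_olap / (best.end - best.start)
            out.append(
                AnnotatedRegion(
                    region=r,
                    klass=klass,
                    best_exon_id=best.exon_id,
                    overlap_bases=best_olap,
                    frac_region=frac_region,
                    frac_exon=frac_exon,
                    gene_ids=sorted(gene_ids),
                )
            )
            continue
        gtree = features._gene_trees.get(r.chrom)
        ghits = gtree.overlap(r.start, r.end) if gtree else []
        klass = "intronic" if ghits else "intergenic"
        out.append(
            AnnotatedRegion(
                region=r,
                klass=klass,
                best_exon_id=None,
                overlap_bases=0,
                frac_region=0.0,
                frac_exon=0.0,
                gene_ids=sorted(iv.data for iv in ghits),
            )
        )
    return out


def feature_rollup(
    annotated: list[AnnotatedRegion],
    features: FeatureSet,
    q_threshold: float = 0.05,
    exon_frac_threshold: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll significant regions up to exon- and gene-level calls.

    An exon is called differentially expressed when some region with
    q < ``q_threshold`` covers at least ``exon_frac_threshold`` of it;
    called genes are the distinct gene_ids of called exons.  Returns
    (exon table, gene table).
    """
    exon_calls: dict[str, dict] = {}
    for ann in annotated:
        r = ann.region
        if r.q is None or r.q >= q_threshold:
            continue
        tree = features._exon_trees.get(r.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(r.start, r.end):
            exon = iv.data
            olap = min(r.end, iv.end) - max(r.start, iv.begin)
            frac = olap / (exon.end - exon.start)
            rec = exon_calls.setdefault(
                exon.exon_id,
                {
                    "exon_id": exon.exon_id,
                    "gene_id": exon.gene_id,
                    "chrom": exon.chrom,
                    "start": exon.start,
                    "end": exon.end,
                    "best_frac": 0.0,
                    "n_regions": 0,
                },
            )
            rec["n_regions"] += 1
            rec["best_frac"] = max(rec["best_frac"], frac)
    rows = [
        rec for rec in exon_calls.values() if rec["best_frac"] >= exon_frac_threshold
    ]
    exon_table = pd.DataFrame(
        rows,
        columns=[
            "exon_id",
            "gene_id",
            "chrom",
            "start",
            "end",
            "best_frac",
            "n_regions",
        ],
    ).sort_values(["chrom", "start"], ignore_index=True) if rows else pd.DataFrame(
        columns=[
            "exon_id",
            "gene_id",
            "chrom",
            "start",
            "end",
            "best_frac",
            "n_regions",
        ]
    )
    if len(exon_table):
        gene_table = (
            exon_table.groupby("gene_id", as_index=False)
            .agg(n_exons=("exon_id", "nunique"))
            .sort_values("gene_id", ignore_index=True)
        )
    else:
        gene_table = pd.DataFrame(columns=["gene_id", "n_exons"])
    return exon_table, gene_table


def annotated_to_frame(annotated: list[AnnotatedRegion]) -> pd.DataFrame:
    """Annotated regions as a tidy table."""
    return pd.DataFrame(
        {
            "chrom": [a.region.chrom for a in annotated],
            "start": [a.region.start for a in annotated],
            "end": [a.region.end for a in annotated],
            "length": [a.region.length for a in annotated],
            "state": [a.region.state for a in annotated],
            "mean_stat": [a.region.mean_stat for a in annotated],
            "direction": [a.region.direction for a in annotated],
            "p": [a.region.p for a in annotated],
            "q": [a.region.q for a in annotated],
            "class": [a.klass for a in annotated],
            "best_exon_id": [a.best_exon_id for a in annotated],
            "overlap_bases": [a.overlap_bases for a in annotated],
            "frac_region": [a.frac_region for a in annotated],
            "frac_exon": [a.frac_exon for a in annotated],
            "gene_ids": [",".join(a.gene_ids) for a in annotated],
        }
    )
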