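"""Region analytics: genome tiling, anchored metaprofiles, scaled-gene
matrices, covariate binning and trend smoothing.

Matrix values are point densities per kb per bin, so rows are comparable
across bins of unequal width (scaled gene bodies vs fixed-width flanks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import Genome, RegionSet
from .preprocess import PointSet


@dataclass
class ProfileMatrix:
    """Anchors x positional bins matrix of mean coverage (or exchange)."""

    values: np.ndarray  # (n_anchors, n_bins)
    mode: str  # "center" | "TSS" | "scaled-gene"
    bin_bp: float | None = None  # fixed bin width, if uniform
    anchors: RegionSet | None = None

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def mean_profile(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin{j}" for j in range(self.n_bins)]
        return pd.DataFrame(self.values, columns=cols)


@dataclass
class BinSummary:
    """One covariate bin: membership and per-channel means."""

    index: int
    count: int
    mean_covariate: float
    member_index: np.ndarray
    means: dict[str, float] = field(default_factory=dict)


def tile_genome(genome: Genome, width: int = 5000,
                partial: str = "half") -> RegionSet:
    """Non-overlapping consecutive windows over every chromosome.

    ``partial`` controls the final short window: "half" keeps it iff it is at
    least half of ``width``, "always" keeps any remainder (tiles then cover
    the chromosome exactly), "never" drops it.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if partial not in ("half", "always", "never"):
        raise ValueError("partial must be half/always/never")
    chroms, starts, ends = [], [], []
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_full, rem = divmod(length, width)
        n = n_full
        if rem and (partial == "always" or
                    (partial == "half" and rem >= width / 2)):
            n += 1
        s = np.arange(n, dtype=np.int64) * width
        e = np.minimum(s + width, length)
        chroms.extend([name] * n)
        starts.append(s)
        ends.append(e)
    df = pd.DataFrame({
        "chrom": chroms,
        "start": np.concatenate(starts) if starts else np.array([], dtype=np.int64),
        "end": np.concatenate(ends) if ends else np.array([], dtype=np.int64),
    })
    return RegionSet(df, genome, validate=False)


def _binned_counts(points: PointSet, chroms, edges: np.ndarray) -> np.ndarray:
    """Counts of points within consecutive edge-delimited bins per anchor.

    ``edges``: (n_anchors, n_bins + 1) ascending genomic positions.
    """
    n, nb = edges.shape[0], edges.shape[1] - 1
    counts = np.zeros((n, nb), dtype=np.int64)
    chroms = np.asarray(chroms)
    for chrom, p in points.by_chrom.items():
        idx = np.flatnonzero(chroms == chrom)
        if idx.size == 0:
            continue
        pos = np.searchsorted(p, edges[idx].ravel(), side="left")
        pos = pos.reshape(idx.size, nb + 1)
        counts[idx] = np.diff(pos, axis=1)
    return counts


def anchored_matrix(points: PointSet, anchors: RegionSet,
                    flank_bp: int = 1000, bin_bp: int = 50,
                    strand_aware: bool = False) -> ProfileMatrix:
    """Metaprofile matrix around anchor centers: [c - flank, c + flank) in
    fixed ``bin_bp`` bins; minus-strand rows are reversed when
    ``strand_aware`` so columns read 5' to 3' of the anchor.
    """
    if flank_bp <= 0 or bin_bp <= 0:
        raise ValueError("flank_bp and bin_bp must be positive")
    if (2 * flank_bp) % bin_bp:
        raise ValueError("2*flank_bp must be a multiple of bin_bp")
    nb = 2 * flank_bp // bin_bp
    centers = anchors.centers
    offsets = np.arange(nb + 1, dtype=np.int64) * bin_bp - flank_bp
    edges = centers[:, None] + offsets[None, :]
    counts = _binned_counts(points, anchors.chroms, edges)
    values = counts / bin_bp * 1000.0
    if strand_aware:
        minus = anchors.strands == "-"
        values[minus] = values[minus, ::-1]
    return ProfileMatrix(values, mode="center", bin_bp=float(bin_bp),
                         anchors=anchors)


def scaled_region_matrix(points: PointSet, regions: RegionSet,
                         flank_bp: int = 5000, flank_bins: int = 10,
                         body_bins: int = 100,
                         strand_aware: bool = True) -> ProfileMatrix:
    """Scaled-body matrix: fixed-width upstream flank bins, ``body_bins``
    equal fractions of each region, fixed-width downstream flank bins.

    Rows of minus-strand regions are reversed so column 1 is the most 5'
    (upstream) flank bin. Values are densities per kb, so the scaled body
    bins (whose width varies with region length) remain comparable to the
    flanks. Regions shorter than ``body_bins`` bp are rejected.
    """
    if flank_bins <= 0 or body_bins <= 0 or flank_bp <= 0:
        raise ValueError("bin parameters must be positive")
    if flank_bp % flank_bins:
        raise ValueError("flank_bp must be a multiple of flank_bins")
    if (regions.lengths < body_bins).any():
        raise ValueError(f"all regions must be >= {body_bins} bp")
    n = len(regions)
    nb = 2 * flank_bins + body_bins
    fw = flank_bp // flank_bins
    starts = regions.starts
    ends = regions.ends
    up = starts[:, None] + (np.arange(flank_bins, dtype=np.int64)[None, :]
                            - flank_bins) * fw
    frac = np.arange(body_bins + 1, dtype=np.float64) / body_bins
    body = starts[:, None] + np.rint(
        (ends - starts)[:, None] * frac[None, :]).astype(np.int64)
    down = ends[:, None] + np.arange(1, flank_bins + 1,
                                     dtype=np.int64)[None, :] * fw
    edges = np.concatenate([up, body, down], axis=1)
    counts = _binned_counts(points, regions.chroms, edges)
    widths = np.diff(edges, axis=1).astype(float)
    widths[widths == 0] = np.nan  # degenerate body bin of a very short region
    values = counts / widths * 1000.0
    if strand_aware:
        minus = regions.strands == "-"
        values[minus] = values[minus, ::-1]
    assert values.shape == (n, nb)
    return ProfileMatrix(values, mode="scaled-gene", anchors=regions)


def scaled_gene_matrix(points: PointSet, genes: RegionSet,
                       flank_bp: int = 5000, flank_bins: int = 10,
                       body_bins: int = 100) -> ProfileMatrix:
    """Gene-body matrix: 10 x 500 bp upstream, 100 scaled body segments,
    10 x 500 bp downstream (120 columns), oriented 5' to 3'."""
    return scaled_region_matrix(points, genes, flank_bp=flank_bp,
                                flank_bins=flank_bins, body_bins=body_bins,
                                strand_aware=True)


def bin_by_covariate(regions: RegionSet, covariate, n_bins: int,
                     values: dict[str, np.ndarray] | None = None,
                     coverage=None, min_coverage: float | None = None,
                     descending: bool = False) -> list[BinSummary]:
    """Equal-count quantile bins of regions ranked by a covariate.

    Regions are optionally pre-filtered to ``coverage >= min_coverage`` (e.g.
    to drop low-MNase bins), ranked by the covariate (stable sort, so ties
    keep original order), and split into ``n_bins`` equal-count bins; when the
    count is not divisible the remainder is spread one region each over the
    leading bins. ``values`` maps channel names to per-region arrays whose
    per-bin means are reported.
    """
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != len(regions):
        raise ValueError("covariate length mismatch")
    idx = np.arange(len(regions))
    if min_coverage is not None:
        if coverage is None:
            raise ValueError("min_coverage requires coverage values")
        keep = np.asarray(coverage, dtype=float) >= min_coverage
        idx = idx[keep]
    n = idx.size
    if not (1 <= n_bins <= n):
        raise ValueError(f"n_bins must be in [1, {n}]")
    key = covariate[idx]
    order = idx[np.argsort(-key if descending else key, kind="stable")]
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    out = []
    for b in range(n_bins):
        members = order[bounds[b]:bounds[b + 1]]
        means = {}
        if values:
            for name, arr in values.items():
                means[name] = float(np.asarray(arr, dtype=float)[members].mean())
        out.append(BinSummary(index=b, count=len(members),
                              mean_covariate=float(covariate[members].mean()),
                              member_index=members, means=means))
    return out


def smooth_trend(x, y, span: float = 0.5) -> np.ndarray:
    """Locally weighted (LOESS) trendline, evaluated at the input x values.

    A display smoother for binned scatter trends; quantitative statements in
    the pipeline rest on binned means, not on the smoothed curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 points to smooth")
    return lowess(y, x, frac=span, return_sorted=False)


def top_fraction(regions: RegionSet, score, fraction: float) -> RegionSet:
    """The ceil(fraction * n) highest-scoring regions (stable under ties),
    returned in their original order."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    score = np.asarray(score, dtype=float)
    k = math.ceil(fraction * len(regions))
    order = np.argsort(-score, kind="stable")[:k]
    return regions.subset(np.sort(order))


def select_heterochromatin_regions(peaks: RegionSet, mnase_density,
                                   len_min: int = 150, len_max: int = 2000,
                                   top_n: int = 2000) -> RegionSet:
    """Heterochromatin proxy selection: peaks within the inclusive length
    window [len_min, len_max], then the ``top_n`` with highest MNase read
    density (all eligible peaks if fewer)."""
    mnase_density = np.asarray(mnase_density, dtype=float)
    lengths = peaks.lengths
    eligible = np.flatnonzero((lengths >= len_min) & (lengths <= len_max))
    k = min(top_n, eligible.size)
    order = eligible[np.argsort(-mnase_density[eligible], kind="stable")[:k]]
    return peaks.subset(np.sort(order))
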