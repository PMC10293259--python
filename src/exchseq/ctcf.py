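"""Strand-aware exchange analysis around CTCF motifs.

CTCF motif orientation defines chromatin-loop polarity, so signal around
motifs is aggregated after flipping minus-strand motifs — "downstream" always
means downstream of the motif in its own orientation. The analysis covers the
four nucleosomes flanking the motif (-2, -1, +1, +2; 180 bp each by default)
with 31 bins across the covered span, and scores per-motif asymmetry as the
mean exchange over the +1/+2 nucleosomes minus the mean over -1/-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RegionSet, overlap_flags
from .exchange import pooled_bin_exchange
from .preprocess import PointSet, count_points

ZONES = ("-2", "-1", "+1", "+2")


@dataclass(frozen=True)
class NucleosomeLayout:
    """Geometry of the motif-flanking nucleosome window.

    Four nucleosomes of ``nucleosome_bp`` are covered (two per side of the
    motif center); ``n_bins`` bins span the 4 x span window, the central bin
    absorbing the division remainder so the bin grid stays mirror-symmetric
    around the motif.
    """

    nucleosome_bp: int = 180
    n_bins: int = 31

    def __post_init__(self):
        if self.n_bins < 4:
            raise ValueError("need >= 4 bins")
        if self.nucleosome_bp <= 0:
            raise ValueError("nucleosome span must be positive")

    @property
    def span_bp(self) -> int:
        return 4 * self.nucleosome_bp

    def bin_edges(self) -> np.ndarray:
        """Offsets of the n_bins + 1 bin edges relative to the motif center.

        The grid is mirror-symmetric (edges(-x) = -edges(x)) so that
        reversing a minus-strand motif is an exact reflection. The division
        remainder of span/n_bins is absorbed centrally: by the straddling
        central bin when n_bins is odd, by the two innermost bins otherwise.
        """
        span, n = self.span_bp, self.n_bins
        w, rem = divmod(span, n)
        k = n // 2  # full-width bins per side
        if n % 2:  # odd: central bin [-c/2, c/2) of width w + rem
            c_half = (w + rem) // 2
            if (w + rem) % 2:
                raise ValueError("central bin width must be even for a "
                                 "symmetric grid; adjust nucleosome_bp")
            right = c_half + w * np.arange(k + 1, dtype=np.int64)
            left = -right[::-1]
        else:  # even: 0 is an edge; innermost bins get w + rem/2
            if rem % 2:
                raise ValueError("remainder must split evenly; adjust "
                                 "nucleosome_bp or n_bins")
            right = (w + rem // 2) + w * np.arange(k, dtype=np.int64)
            right = np.concatenate([[0], right])
            left = -right[::-1][:-1]  # drop the duplicate 0 edge
        return np.concatenate([left, right])


def _zone_edges(center: np.ndarray, layout: NucleosomeLayout) -> np.ndarray:
    L = layout.nucleosome_bp
    offs = np.array([-2 * L, -L, 0, L, 2 * L], dtype=np.int64)
    return center[:, None] + offs[None, :]


def nucleosome_bin_exchange(myc: PointSet, ha: PointSet,
                            motifs: RegionSet,
                            layout: NucleosomeLayout = NucleosomeLayout(),
                            eps: float = 0.05,
                            depth_factors: dict[str, float] | None = None
                            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Pooled per-bin exchange and per-motif per-zone coverage around motifs.

    Coordinates are flipped for minus-strand motifs before binning. For each
    bin the mean myc and mean HA coverage across motifs is computed first and
    the exchange taken on the bin means (the pooled estimator). Per-motif
    nucleosome-zone mean coverages are returned for asymmetry scoring.

    ``depth_factors`` maps {"myc": f, "HA": f} scaling factors (from depth
    normalization); omitted means both channels are used as-is.

    Genic motifs should be excluded by the caller (see
    :func:`exchseq.core.overlap_flags` against the gene set).
    """
    if len(motifs) == 0:
        raise ValueError("empty motif set")
    centers = motifs.centers
    minus = motifs.strands == "-"
    f_myc = depth_factors.get("myc", 1.0) if depth_factors else 1.0
    f_ha = depth_factors.get("HA", 1.0) if depth_factors else 1.0

    edges_off = NucleosomeLayout.bin_edges(layout)
    edges = centers[:, None] + edges_off[None, :]
    widths = np.diff(edges_off).astype(float)

    from .profiles import _binned_counts

    out = {}
    for name, pts, f in (("myc", myc, f_myc), ("HA", ha, f_ha)):
        counts = _binned_counts(pts, motifs.chroms, edges)
        dens = counts / widths[None, :] * 1000.0 * f
        # orientation correction: mirror rows of minus motifs; the edge grid
        # is symmetric around the center, so this is an exact reflection
        dens[minus] = dens[minus, ::-1]
        out[name] = dens
    bin_e = pooled_bin_exchange(out["myc"].mean(axis=0),
                                out["HA"].mean(axis=0), eps)

    zone_edges = _zone_edges(centers, layout)
    zw = float(layout.nucleosome_bp)
    zones = {}
    for name, pts, f in (("myc", myc, f_myc), ("HA", ha, f_ha)):
        counts = _binned_counts(pts, motifs.chroms, zone_edges)
        dens = counts / zw * 1000.0 * f
        dens[minus] = dens[minus, ::-1]
        zones[name] = dens
    per_motif = pd.DataFrame(
        {f"{ch}_{z}": zones[ch][:, j]
         for ch in ("myc", "HA") for j, z in enumerate(ZONES)})
    per_motif["strand"] = motifs.strands
    return bin_e, per_motif


def asymmetry_score(per_motif: pd.DataFrame, eps: float = 0.05) -> np.ndarray:
    """Per-motif asymmetry A = mean E(+1, +2) - mean E(-1, -2).

    Zone exchange is the log-ratio of the zone's myc and HA coverage. A is
    exactly negated by flipping every motif strand (the zones swap in
    mirrored pairs).
    """
    e = {z: (np.log2(per_motif[f"myc_{z}"].to_numpy() + eps)
             - np.log2(per_motif[f"HA_{z}"].to_numpy() + eps))
         for z in ZONES}
    return (e["+1"] + e["+2"]) / 2.0 - (e["-1"] + e["-2"]) / 2.0


def decile_contrast(mark_profile: np.ndarray, asymmetry: np.ndarray,
                    fraction: float = 0.10) -> np.ndarray:
    """Mark-enrichment contrast between the most and least asymmetric motifs.

    ``mark_profile`` is a motifs x positional-bins matrix (e.g. enrichment
    around each motif). The top ceil(fraction*n) motifs by asymmetry are
    compared against the bottom decile (the control set): returned is the
    per-bin difference of means.
    """
    mark_profile = np.asarray(mark_profile, dtype=float)
    asymmetry = np.asarray(asymmetry, dtype=float)
    n = asymmetry.size
    if n < 20:
        raise ValueError("need >= 20 motifs for a decile contrast")
    if mark_profile.shape[0] != n:
        raise ValueError("profile rows must match motif count")
    k = int(np.ceil(fraction * n))
    order = np.argsort(-asymmetry, kind="stable")
    top, bottom = order[:k], order[-k:]
    return mark_profile[top].mean(axis=0) - mark_profile[bottom].mean(axis=0)


def partition_by_occupancy(motifs: RegionSet,
                           chip_peaks: RegionSet) -> tuple[RegionSet, RegionSet]:
    """Split motifs into CTCF-occupied (>= 1 bp overlap with a ChIP peak)
    and unoccupied sets; the partition is exhaustive and disjoint."""
    occ = overlap_flags(motifs, chip_peaks)
    return motifs.subset(occ), motifs.subset(~occ)


def mean_zone_coverage(points: PointSet, motifs: RegionSet,
                       layout: NucleosomeLayout = NucleosomeLayout()
                       ) -> np.ndarray:
    """Per-motif mean coverage over the whole 4-nucleosome window (per kb)."""
    centers = motifs.centers
    half = layout.span_bp // 2
    df = motifs.df.copy()
    df["start"] = centers - half
    df["end"] = centers + half
    win = RegionSet(df, motifs.genome, validate=False)
    return count_points(points, win) / layout.span_bp * 1000.0
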