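"""Consensus repeat-library quantification: best-match multimapper
assignment, total-aligned normalization, abundance filters, pairwise
enrichment, and scaled windowed profiles over full-length elements.

The module consumes per-read hit lists (read_id, family, alignment score) or
pre-made count tables — alignment against the consensus library itself is an
upstream step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RegionSet
from .preprocess import PointSet
from .profiles import ProfileMatrix, scaled_region_matrix

logger = logging.getLogger(__name__)


@dataclass
class RepeatCountTable:
    """Per-family read counts per sample with totals and filter provenance."""

    counts: pd.DataFrame  # families (index) x samples, raw counts
    totals: dict[str, float]  # total aligned reads per sample
    normalized: pd.DataFrame | None = None
    dropped: dict[str, str] = field(default_factory=dict)  # family -> reason

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    totals: dict[str, float] | None = None):
        if totals is None:
            totals = {c: float(counts[c].sum()) for c in counts.columns}
        return cls(counts.astype(float), totals)


def assign_multimappers(hits: pd.DataFrame,
                        seed: int | None = 0) -> pd.Series:
    """Resolve each read's hit list to a single family.

    ``hits`` is tidy (read_id, family, score). Among a read's maximal-score
    hits one family is chosen uniformly at random (seeded, so the assignment
    is reproducible); reads with a unique best hit are assigned directly.
    Assignment conserves reads: every read appears exactly once.
    """
    required = {"read_id", "family", "score"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit list needs columns {sorted(required)}")
    if hits.empty:
        return pd.Series([], name="family", dtype=object)
    rng = np.random.default_rng(seed)
    df = hits.copy()
    best = df.groupby("read_id", sort=True)["score"].transform("max")
    df = df[df["score"] == best]
    # seeded uniform tie-break: random key, take min per read
    df = df.assign(_key=rng.random(len(df)))
    idx = df.groupby("read_id", sort=True)["_key"].idxmin()
    out = df.loc[idx].set_index("read_id")["family"]
    out.name = "family"
    return out


def counts_from_assignments(assignments: pd.Series, sample: str,
                            table: RepeatCountTable | None = None
                            ) -> RepeatCountTable:
    """Tally assigned reads into (or onto) a repeat count table."""
    counts = assignments.value_counts().rename(sample).to_frame()
    if table is not None:
        merged = table.counts.join(counts, how="outer").fillna(0.0)
        totals = dict(table.totals)
        totals[sample] = float(len(assignments))
        return RepeatCountTable(merged, totals)
    return RepeatCountTable(counts.astype(float),
                            {sample: float(len(assignments))})


def normalize_and_filter(table: RepeatCountTable, min_reads: int = 100,
                         drop_classes: set[str] = frozenset({"rRNA"}),
                         mode: str = "any",
                         class_of: dict[str, str] | None = None
                         ) -> RepeatCountTable:
    """Depth-normalize family counts and apply the abundance/class filters.

    Families whose raw count falls below ``min_reads`` are discarded —
    with ``mode="any"`` (default, conservative) when any sample is below the
    cutoff, with ``mode="all"`` only when every sample is. Families of the
    listed classes (default rRNA; matched on ``class_of`` or the family name
    itself) are dropped regardless. Remaining counts are divided by each
    sample's total aligned reads, so normalized x total reconstructs raw.
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    counts = table.counts
    if any(t <= 0 for t in table.totals.values()):
        raise ValueError("non-positive total aligned reads")
    dropped = dict(table.dropped)
    low = (counts < min_reads)
    low = low.any(axis=1) if mode == "any" else low.all(axis=1)
    for fam in counts.index[low]:
        dropped[fam] = f"<{min_reads} reads ({mode} sample)"
    for fam in counts.index:
        cls = (class_of or {}).get(fam, fam)
        if cls in drop_classes:
            dropped[fam] = f"class {cls}"
    keep = [f for f in counts.index if f not in dropped]
    if len(dropped) > len(table.dropped):
        logger.info("normalize_and_filter: dropped %d families",
                    len(dropped) - len(table.dropped))
    kept = counts.loc[keep]
    norm = kept / pd.Series(table.totals)[kept.columns]
    return RepeatCountTable(kept, dict(table.totals), normalized=norm,
                            dropped=dropped)


def repeat_enrichment(table: RepeatCountTable, sample_a: str,
                      sample_b: str) -> pd.Series:
    """Per-family log2 fold enrichment of sample_a over sample_b on the
    filtered, normalized counts (the >= min_reads filter guarantees
    positivity, so no pseudocount is needed)."""
    if table.normalized is None:
        raise ValueError("run normalize_and_filter first")
    a = table.normalized[sample_a]
    b = table.normalized[sample_b]
    return np.log2(a) - np.log2(b)


def element_profile(points: PointSet, elements: RegionSet,
                    body_windows: int = 250, flank_bp: int = 2500,
                    flank_windows: int = 5) -> ProfileMatrix:
    """Scaled windowed profile over full-length elements (e.g. IAPs):
    ``body_windows`` equal fractions of each element body plus fixed-width
    flank windows, strand-oriented. Callers wanting unique-read flank
    profiles should build ``points`` from a mapping-quality-filtered
    fragment collection."""
    return scaled_region_matrix(points, elements, flank_bp=flank_bp,
                                flank_bins=flank_windows,
                                body_bins=body_windows, strand_aware=True)


def rank_elements_by_external_signal(elements: RegionSet, signal,
                                     n_bins: int = 100):
    """Rank elements by an external per-element signal (e.g. H3.3 counts,
    descending) and split into equal-count bins; delegates to
    :func:`exchseq.profiles.bin_by_covariate`."""
    from .profiles import bin_by_covariate

    return bin_by_covariate(elements, signal, n_bins, descending=True)
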