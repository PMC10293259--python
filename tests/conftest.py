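import numpy as np
import pandas as pd
import pytest

from exchseq.core import FragmentCollection, Genome, RegionSet


@pytest.fixture
def tiny_genome():
    return Genome(("chr1", "chr2"), (10_000, 8_000))


@pytest.fixture
def mb_genome():
    return Genome(("chr1",), (1_000_000,))


def make_regions(rows, genome=None, **metadata):
    """rows: list of (chrom, start, end[, strand]) tuples."""
    recs = []
    for r in rows:
        chrom, start, end = r[:3]
        strand = r[3] if len(r) > 3 else "."
        recs.append({"chrom": chrom, "start": start, "end": end,
                     "strand": strand})
    df = pd.DataFrame(recs)
    for k, v in metadata.items():
        df[k] = v
    return RegionSet(df, genome)


def make_fragments(rows, sample="s", channel="myc"):
    """rows: list of (chrom, start, end, strand, mapq)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "mapq"])
    return FragmentCollection(df, sample=sample, channel=channel)


def brute_force_overlaps(regions, other, min_overlap=1):
    """Quadratic all-pairs oracle for overlap_flags."""
    flags = np.zeros(len(regions), dtype=bool)
    for i in range(len(regions)):
        a = regions[i]
        for j in range(len(other)):
            b = other[j]
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= min_overlap:
                flags[i] = True
                break
    return flags


def brute_force_count(points_by_chrom, regions):
    """Per-base tally oracle for point counting."""
    counts = np.zeros(len(regions), dtype=int)
    for i in range(len(regions)):
        r = regions[i]
        pts = points_by_chrom.get(r.chrom, np.array([], dtype=int))
        counts[i] = int(((pts >= r.start) & (pts < r.end)).sum())
    return counts
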