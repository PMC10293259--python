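"""Genomic data model and I/O for the exchange-sensor pipeline.

Coordinates are 0-based half-open (BED convention) everywhere. A fragment is
one sequenced template (both mates merged into a single interval); a region is
any annotated genomic interval, optionally stranded and carrying per-region
metadata columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: channels a fragment collection may belong to
CHANNELS = ("myc", "HA", "mark", "input", "ATAC", "mnase")


class BedParseError(ValueError):
    """Malformed BED/TSV record, reported with its line number."""


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths (a chrom.sizes table in memory)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("duplicate chromosome names")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names/lengths mismatch")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "Genome":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @classmethod
    def read_chrom_sizes(cls, path) -> "Genome":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls.from_dict(dict(zip(df["chrom"].astype(str), df["length"])))

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


_REGION_COLS = ["chrom", "start", "end", "strand"]


class RegionSet:
    """Ordered genomic intervals with optional strand and per-region metadata.

    Backed by a DataFrame with columns chrom/start/end/strand plus arbitrary
    metadata columns (score, label, expression, ...).
    """

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None,
                 validate: bool = True):
        df = df.copy().reset_index(drop=True)
        if "strand" not in df.columns:
            df["strand"] = "."
        missing = [c for c in _REGION_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if validate and len(df):
            bad = df["start"] >= df["end"]
            if bad.any():
                i = int(np.flatnonzero(bad.values)[0])
                raise ValueError(f"record {i}: start >= end "
                                 f"({df['start'].iat[i]} >= {df['end'].iat[i]})")
            if (df["start"] < 0).any():
                raise ValueError("negative start coordinate")
            if not df["strand"].isin(STRANDS).all():
                raise ValueError("invalid strand value")
            if genome is not None:
                sizes = genome.sizes
                unknown = set(df["chrom"]) - set(sizes)
                if unknown:
                    raise ValueError(f"unknown chromosomes: {sorted(unknown)}")
                lim = df["chrom"].map(sizes).to_numpy()
                if (df["end"].to_numpy() > lim).any():
                    raise ValueError("interval exceeds chromosome length")
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, i: int) -> GenomicInterval:
        r = self.df.iloc[i]
        return GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]),
                               r["strand"])

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def strands(self) -> np.ndarray:
        return self.df["strand"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def centers(self) -> np.ndarray:
        """Integer midpoints, (start + end) // 2."""
        return (self.starts + self.ends) // 2

    def metadata(self, column: str) -> np.ndarray:
        return self.df[column].to_numpy()

    def with_metadata(self, **columns) -> "RegionSet":
        df = self.df.copy()
        for name, values in columns.items():
            if len(values) != len(df):
                raise ValueError(f"metadata column {name!r} length mismatch")
            df[name] = np.asarray(values)
        return RegionSet(df, self.genome, validate=False)

    def subset(self, mask_or_index) -> "RegionSet":
        return RegionSet(self.df.iloc[np.asarray(mask_or_index)
                                      if not isinstance(mask_or_index, slice)
                                      else mask_or_index],
                         self.genome, validate=False)

    def sorted(self) -> "RegionSet":
        df = self.df.sort_values(["chrom", "start", "end"],
                                 kind="stable").reset_index(drop=True)
        return RegionSet(df, self.genome, validate=False)


@dataclass
class FragmentCollection:
    """Aligned paired-end fragments for one sample/channel.

    ``df`` has columns chrom/start/end/strand/mapq; strand is that of the
    first mate. Fragment length is end - start.
    """

    df: pd.DataFrame
    sample: str = "sample"
    channel: str = "myc"

    def __post_init__(self):
        cols = ["chrom", "start", "end", "strand", "mapq"]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing fragment columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def replace(self, df: pd.DataFrame) -> "FragmentCollection":
        return FragmentCollection(df, self.sample, self.channel)


@dataclass
class CountTable:
    """Regions x samples matrix of mean normalized coverage (per-kb units)."""

    regions: RegionSet
    values: pd.DataFrame  # one column per sample, non-negative reals
    depth_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.values) != len(self.regions):
            raise ValueError("value rows must match region count")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def column(self, sample: str) -> np.ndarray:
        return self.values[sample].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.regions.df[_REGION_COLS].copy()
        for c in self.values.columns:
            out[c] = self.values[c].to_numpy()
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path, genome: Genome | None = None, *,
             on_unknown_chrom: str = "fail",
             on_out_of_bounds: str = "fail") -> RegionSet:
    """Read a BED3/BED6/BED12 file into a RegionSet.

    Columns beyond the third are preserved: name, score, strand (named),
    further BED12 columns as ``col7``... Malformed lines raise
    :class:`BedParseError` with the 1-based line number.

    Parameters
    ----------
    on_unknown_chrom : "fail" | "skip"
        What to do with records on chromosomes absent from ``genome``.
    on_out_of_bounds : "fail" | "skip" | "clip"
        What to do with records exceeding the chromosome length.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"line {lineno}: invalid interval [{start},{end})")
            rows.append((lineno, parts))
    if not rows:
        df = pd.DataFrame(columns=_REGION_COLS)
        return RegionSet(df, genome, validate=False)

    ncol = max(len(p) for _, p in rows)
    recs = {}
    recs["chrom"] = [p[0] for _, p in rows]
    recs["start"] = [int(p[1]) for _, p in rows]
    recs["end"] = [int(p[2]) for _, p in rows]
    if ncol >= 4:
        recs["name"] = [p[3] if len(p) > 3 else "." for _, p in rows]
    if ncol >= 5:
        recs["score"] = [p[4] if len(p) > 4 else "0" for _, p in rows]
    if ncol >= 6:
        strands = [p[5] if len(p) > 5 else "." for _, p in rows]
        bad = [s for s in strands if s not in STRANDS]
        if bad:
            raise BedParseError(f"invalid strand value {bad[0]!r}")
        recs["strand"] = strands
    for j in range(6, ncol):
        recs[f"col{j + 1}"] = [p[j] if len(p) > j else "." for _, p in rows]
    df = pd.DataFrame(recs)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0.0)

    if genome is not None:
        sizes = genome.sizes
        known = df["chrom"].isin(sizes)
        if not known.all():
            if on_unknown_chrom == "skip":
                n = int((~known).sum())
                logger.info("read_bed: skipped %d records on unknown chromosomes", n)
                df = df[known].reset_index(drop=True)
            else:
                bad = df.loc[~known, "chrom"].iloc[0]
                raise BedParseError(f"unknown chromosome {bad!r}")
        if len(df):
            lim = df["chrom"].map(sizes).to_numpy()
            oob = df["end"].to_numpy() > lim
            if oob.any():
                if on_out_of_bounds == "skip":
                    logger.info("read_bed: dropped %d out-of-bounds records",
                                int(oob.sum()))
                    df = df[~oob].reset_index(drop=True)
                elif on_out_of_bounds == "clip":
                    df.loc[oob, "end"] = lim[oob]
                else:
                    raise BedParseError("record exceeds chromosome length")
    return RegionSet(df, genome)


def write_bed(regions: RegionSet, path) -> None:
    """Write a RegionSet as BED6 (name/score filled with defaults if absent)."""
    df = regions.df
    name = df["name"] if "name" in df.columns else pd.Series(["."] * len(df))
    score = df["score"] if "score" in df.columns else pd.Series([0] * len(df))
    with open(path, "w") as fh:
        for c, s, e, n, sc, st in zip(df["chrom"], df["start"], df["end"],
                                      name, score, df["strand"]):
            sc = int(sc) if float(sc) == int(sc) else sc
            fh.write(f"{c}\t{s}\t{e}\t{n}\t{sc}\t{st}\n")


def read_gene_table(path, genome: Genome | None = None, *,
                    min_length: int = 2000) -> RegionSet:
    """Read a gene-table TSV (gene_id, chrom, start, end, strand, expression).

    Transcripts shorter than ``min_length`` bp are discarded so that TSS and
    TES windows cannot blur into each other; set ``min_length=0`` to keep all.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand", "expression"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise BedParseError(f"gene table missing columns: {missing}")
    n0 = len(df)
    df = df[(df["end"] - df["start"]) >= min_length].reset_index(drop=True)
    if n0 - len(df):
        logger.info("read_gene_table: dropped %d transcripts < %d bp",
                    n0 - len(df), min_length)
    return RegionSet(df, genome)


def genes_to_models(genes: RegionSet) -> list["GeneModel"]:
    return [GeneModel(genes[i], genes.df["gene_id"].iat[i],
                      float(genes.df["expression"].iat[i]))
            for i in range(len(genes))]


@dataclass(frozen=True)
class GeneModel:
    """One gene (longest transcript): interval, id, expression level."""

    interval: GenomicInterval
    gene_id: str
    expression: float

    @property
    def tss(self) -> int:
        return (self.interval.start if self.interval.strand != "-"
                else self.interval.end - 1)

    @property
    def tes(self) -> int:
        return (self.interval.end - 1 if self.interval.strand != "-"
                else self.interval.start)


def promoters(genes: RegionSet, upstream_bp: int = 1000) -> RegionSet:
    """Regions ``upstream_bp`` upstream of each TSS (strand-aware)."""
    starts = genes.starts
    ends = genes.ends
    minus = genes.strands == "-"
    p_start = np.where(minus, ends, starts - upstream_bp)
    p_end = np.where(minus, ends + upstream_bp, starts)
    df = genes.df.copy()
    df["start"] = np.maximum(p_start, 0)
    df["end"] = p_end
    keep = df["start"] < df["end"]
    if genes.genome is not None:
        lim = df["chrom"].map(genes.genome.sizes).to_numpy()
        df["end"] = np.minimum(df["end"].to_numpy(), lim)
        keep &= df["start"] < df["end"]
    return RegionSet(df[keep], genes.genome, validate=False)


def read_fragments(path, min_mapq: int = 10, *, sample: str = "sample",
                   channel: str = "myc") -> FragmentCollection:
    """Read fragments from SAM/BAM (paired) or fragment-BED.

    SAM/BAM: one fragment per properly paired template, taken from the mate
    with template length > 0; unpaired/secondary/supplementary records are
    skipped with a logged count. Fragment-BED: 6 columns with mapping quality
    in the score slot (chrom, start, end, name, mapq, strand).

    Records with mapping quality below ``min_mapq`` are excluded.
    """
    path = str(path)
    if path.endswith((".sam", ".bam", ".cram")):
        df, skipped = _read_fragments_alignment(path, min_mapq)
        if skipped:
            logger.info("read_fragments: skipped %d non-proper records", skipped)
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "mapq",
                                "strand"])
        if (df["start"] >= df["end"]).any():
            raise BedParseError("fragment with start >= end")
        df["mapq"] = df["mapq"].astype(int)
        n0 = len(df)
        df = df[df["mapq"] >= min_mapq].reset_index(drop=True)
        if n0 - len(df):
            logger.info("read_fragments: removed %d fragments with MQ < %d",
                        n0 - len(df), min_mapq)
        df = df[["chrom", "start", "end", "strand", "mapq"]]
    return FragmentCollection(df, sample=sample, channel=channel)


def _read_fragments_alignment(path: str, min_mapq: int):
    import pysam

    mode = "r" if path.endswith(".sam") else "rb"
    rows, skipped = [], 0
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or not rec.is_proper_pair):
                skipped += 1
                continue
            # take the leftmost mate once per template
            if rec.template_length <= 0:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            start = rec.reference_start
            # strand of the first-in-pair mate (FR libraries)
            if rec.is_read1:
                strand = "-" if rec.is_reverse else "+"
            else:
                strand = "-" if rec.mate_is_reverse else "+"
            rows.append((rec.reference_name, start,
                         start + rec.template_length,
                         strand, rec.mapping_quality))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "mapq"])
    return df, skipped


def write_fragment_bed(frags: FragmentCollection, path) -> None:
    """Write the fragment-BED dialect (mapq in the BED score slot)."""
    df = frags.df
    with open(path, "w") as fh:
        for i, (c, s, e, st, mq) in enumerate(zip(
                df["chrom"], df["start"], df["end"], df["strand"],
                df["mapq"])):
            fh.write(f"{c}\t{s}\t{e}\tf{i}\t{mq}\t{st}\n")


# ---------------------------------------------------------------------------
# interval operations
# ---------------------------------------------------------------------------

def shift_regions(regions: RegionSet, offset_bp: int, genome: Genome, *,
                  strand_aware: bool = False) -> RegionSet:
    """Translate every interval by ``offset_bp`` (used for shifted controls).

    The default is a strand-ignorant literal translation; with
    ``strand_aware=True`` minus-strand intervals move the opposite way.
    Intervals that would leave [0, chrom length) are dropped and the drop
    count logged, so the shifted control set may be smaller than its target
    set (downstream statistics are means, which tolerates this).
    """
    offs = np.full(len(regions), offset_bp, dtype=np.int64)
    if strand_aware:
        offs[regions.strands == "-"] *= -1
    df = regions.df.copy()
    df["start"] = regions.starts + offs
    df["end"] = regions.ends + offs
    lim = df["chrom"].map(genome.sizes).to_numpy()
    keep = (df["start"].to_numpy() >= 0) & (df["end"].to_numpy() <= lim)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("shift_regions: dropped %d out-of-bounds intervals", dropped)
    out = RegionSet(df[keep], genome, validate=False)
    out.dropped = dropped
    return out


def overlap_flags(regions: RegionSet, other: RegionSet, *,
                  min_overlap_bp: int = 1) -> np.ndarray:
    """Per-region flag: does the region share >= min_overlap_bp with ``other``?

    Half-open semantics: [a,b) and [b,c) do not overlap. Implemented as a
    per-chromosome sweep over the merged intervals of ``other``.
    """
    flags = np.zeros(len(regions), dtype=bool)
    if len(other) == 0 or len(regions) == 0:
        return flags
    by_chrom = {}
    odf = other.df
    for chrom, grp in odf.groupby("chrom", sort=False):
        merged = _merge_intervals(grp["start"].to_numpy(),
                                  grp["end"].to_numpy())
        by_chrom[chrom] = merged
    chroms = regions.chroms
    starts = regions.starts
    ends = regions.ends
    for chrom, (ms, me) in by_chrom.items():
        idx = np.flatnonzero(chroms == chrom)
        if idx.size == 0:
            continue
        if min_overlap_bp == 1:
            # merged intervals are disjoint and sorted, so starts AND ends
            # are sorted: the only candidate is the last interval starting
            # before the region's end
            j = np.searchsorted(ms, ends[idx], side="left") - 1
            hit = (j >= 0) & (me[np.clip(j, 0, len(ms) - 1)] > starts[idx])
            flags[idx] = hit
        else:
            for i in idx:
                lo = np.searchsorted(me, starts[i], side="right")
                hi = np.searchsorted(ms, ends[i], side="left")
                if lo >= hi:
                    continue
                ov = (np.minimum(ends[i], me[lo:hi])
                      - np.maximum(starts[i], ms[lo:hi]))
                flags[i] = bool((ov >= min_overlap_bp).any())
    return flags


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [], []
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        if s[i] <= cur_e:
            cur_e = max(cur_e, int(e[i]))
        else:
            out_s.append(cur_s)
            out_e.append(cur_e)
            cur_s, cur_e = int(s[i]), int(e[i])
    out_s.append(cur_s)
    out_e.append(cur_e)
    return np.asarray(out_s), np.asarray(out_e)
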