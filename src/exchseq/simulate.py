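"""Synthetic dual-tag sensor data: a labeled genome fixture plus simulated
myc/HA (and mark/input/ATAC) ChIP-seq channels driven by per-locus exchange
kinetics.

Kinetic model
-------------
Each locus carries an occupancy O (expected tagged-nucleosome density, in
(0, 1]) and an exchange rate lambda (evictions per unit time). A bound sensor
histone is cleaved by the partner-histone TEV protease at first-order rate
kappa while it stays on DNA; eviction (rate lambda) ends the exposure. With
exponential residence, the probability that a histone leaves before cleavage
— i.e. retains its myc tag — is the race outcome

    f(lambda, kappa) = lambda / (lambda + kappa).

HA reports occupancy regardless of cleavage, so expected HA density at a
locus is proportional to O and expected myc density to O * f. Faster-turning
loci keep more myc: the myc/HA ratio encodes lambda. A non-cleavable sensor
is kappa = 0, where f = 1 and the two channels coincide in expectation.
This closed form is the package's own minimal formalization of the sensor
logic; histone recycling and the untagged pool are not modeled, so only
relative (between-locus) exchange is meaningful — channel depths are
arbitrary and all downstream statistics are ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FragmentCollection, Genome, RegionSet, write_bed, \
    write_fragment_bed

logger = logging.getLogger(__name__)

CLASSES = ("promoter", "gene_body", "enhancer_active", "enhancer_primed",
           "enhancer_poised", "ctcf_flank", "repeat", "heterochromatin",
           "background")

#: per-class mean exchange rate (evictions per unit time, kappa = 1 scale)
CLASS_LAMBDA = {
    "promoter": 8.0,
    "gene_body": 1.2,
    "enhancer_active": 6.0,
    "enhancer_primed": 0.8,
    "enhancer_poised": 2.0,
    "ctcf_flank": 4.0,
    "repeat": 2.0,
    "heterochromatin": 0.7,
    "background": 0.5,
}

#: per-class mean occupancy (tagged-nucleosome density)
CLASS_OCCUPANCY = {
    "promoter": 0.45,
    "gene_body": 0.75,
    "enhancer_active": 0.5,
    "enhancer_primed": 0.55,
    "enhancer_poised": 0.55,
    "ctcf_flank": 0.6,
    "repeat": 0.8,
    "heterochromatin": 0.9,
    "background": 0.25,
}

#: relative per-bp pull-down weight of mark channels by class (default 0.2)
MARK_PROFILES = {
    "h3k4me3": {"promoter": 10.0, "enhancer_active": 3.0,
                "enhancer_poised": 3.0},
    "h3k27ac": {"enhancer_active": 8.0, "promoter": 4.0},
    "h3k9me3": {"heterochromatin": 10.0, "repeat": 6.0},
    "h33": {"promoter": 6.0, "enhancer_active": 6.0, "enhancer_primed": 3.0,
            "enhancer_poised": 3.0},
}

_REPEAT_FAMILIES = (("IAP", 5000), ("L1", 6000), ("MERVL", 4500),
                    ("ETn", 4000), ("MuSat", 2000))


@dataclass(frozen=True)
class SimulationConfig:
    """Channel-simulation settings.

    ``cleavage_rate`` (kappa) is the first-order TEV cleavage rate while the
    sensor is DNA-bound; ``cleavable=False`` models the non-cleavable control
    (forces kappa = 0). Depth is the expected total fragments per channel.
    Fragment lengths are truncated-normal (default 160 +/- 40 bp, > 0).
    """

    cleavage_rate: float = 1.0
    depth: int = 1_000_000
    frag_len_mean: float = 160.0
    frag_len_sd: float = 40.0
    seed: int = 0
    cleavable: bool = True

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.frag_len_mean <= 0 or self.frag_len_sd < 0:
            raise ValueError("invalid fragment length distribution")
        if self.cleavage_rate < 0:
            raise ValueError("cleavage_rate must be >= 0")

    @property
    def kappa(self) -> float:
        return self.cleavage_rate if self.cleavable else 0.0


@dataclass(frozen=True)
class FixtureConfig:
    """Counts and geometry of the synthetic genome fixture."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    n_ctcf: int = 200
    n_repeats: int = 100
    n_enhancers: int = 150
    n_het_blocks: int = 20
    background_tile_bp: int = 5000

    def __post_init__(self):
        if self.n_chroms < 1 or self.chrom_length < 50_000:
            raise ValueError("fixture genome too small")


@dataclass
class SyntheticGenome:
    """Genome fixture: annotations plus the ground-truth locus model.

    ``loci`` tiles every base with exactly one class label and carries the
    simulation ground truth (occupancy O, exchange rate lambda).
    """

    genome: Genome
    loci: pd.DataFrame  # chrom,start,end,strand,label,occupancy,lam
    genes: RegionSet  # with gene_id, expression metadata
    ctcf_motifs: RegionSet  # stranded
    enhancers: RegionSet  # with label metadata (active/primed/poised)
    repeats: RegionSet  # with family metadata
    heterochromatin: RegionSet

    def loci_regions(self, label: str | None = None) -> RegionSet:
        df = self.loci if label is None else \
            self.loci[self.loci["label"] == label]
        return RegionSet(df.reset_index(drop=True), self.genome,
                         validate=False)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write_chrom_sizes(outdir / "genome.chrom.sizes")
        self.loci.assign(
            f_kappa1=steady_state_uncleaved(self.loci["lam"].to_numpy(), 1.0)
        ).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False,
                 float_format="%.6g")
        self.genes.df.to_csv(outdir / "genes.tsv", sep="\t", index=False,
                             float_format="%.6g")
        write_bed(self.ctcf_motifs, outdir / "ctcf_motifs.bed")
        write_bed(self.enhancers, outdir / "enhancers.bed")
        write_bed(self.repeats, outdir / "repeats.bed")
        write_bed(self.heterochromatin, outdir / "heterochromatin.bed")


def steady_state_uncleaved(lam, kappa: float):
    """Steady-state myc-retaining fraction f = lambda / (lambda + kappa).

    Strictly increasing in lambda (faster exchange leaves less time for
    cleavage) and decreasing in kappa; kappa = 0 gives f = 1 (non-cleavable
    control), lambda = kappa gives 1/2.
    """
    lam = np.asarray(lam, dtype=float)
    if (lam <= 0).any():
        raise ValueError("exchange rate lambda must be > 0")
    if kappa < 0:
        raise ValueError("cleavage rate kappa must be >= 0")
    out = lam / (lam + kappa)
    return float(out) if out.ndim == 0 else out


def _lognormal_around(rng, mean: float, sigma: float, size) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean."""
    mu = np.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size=size)


def build_genome_fixture(config: FixtureConfig = FixtureConfig(),
                         seed: int = 0) -> SyntheticGenome:
    """Lay out a labeled synthetic genome and assign ground-truth kinetics.

    Features (genes with 1 kb promoters, enhancers of three classes, CTCF
    motifs inside 760 bp flanking loci, repeat insertions from five families,
    heterochromatin blocks) are placed non-overlapping with random background
    gaps; gaps are tiled into background loci so every base has exactly one
    class label. Per-class exchange rates and occupancies get log-normal
    within-class spread; gene-body and promoter rates additionally scale with
    expression. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    genome = Genome(tuple(f"chr{i + 1}" for i in range(cfg.n_chroms)),
                    tuple([cfg.chrom_length] * cfg.n_chroms))

    # build the global feature list, then deal features across chromosomes
    features = []  # (kind, payload)
    for i in range(cfg.n_genes):
        length = int(np.clip(rng.lognormal(np.log(6000), 0.6), 2000, 40000))
        expr = float(rng.lognormal(1.0, 1.0))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(("gene", {"length": length, "expression": expr,
                                  "strand": strand, "gene_id": f"g{i:04d}"}))
    for i in range(cfg.n_ctcf):
        strand = "+" if i < cfg.n_ctcf // 2 else "-"
        features.append(("ctcf", {"strand": strand}))
    fam_idx = rng.integers(0, len(_REPEAT_FAMILIES), size=cfg.n_repeats)
    for i in range(cfg.n_repeats):
        fam, flen = _REPEAT_FAMILIES[fam_idx[i]]
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(("repeat", {"family": fam, "length": flen,
                                    "strand": strand}))
    enh_labels = rng.choice(["active", "primed", "poised"],
                            size=cfg.n_enhancers, p=[0.45, 0.45, 0.10])
    for i in range(cfg.n_enhancers):
        features.append(("enhancer", {"label": str(enh_labels[i])}))
    for i in range(cfg.n_het_blocks):
        features.append(("het", {"length": 50_000}))
    order = rng.permutation(len(features))
    features = [features[i] for i in order]

    loci_rows = []  # chrom,start,end,strand,label
    gene_rows, ctcf_rows, enh_rows, rep_rows, het_rows = [], [], [], [], []

    def feature_span(kind, p):
        if kind == "gene":
            return p["length"] + 1000
        if kind == "ctcf":
            return 760
        if kind == "repeat":
            return p["length"]
        if kind == "enhancer":
            return 1000
        return p["length"]  # het

    # deal features round-robin across chromosomes, then draw inter-feature
    # gaps that exactly partition each chromosome's free space, so every
    # requested feature is placed
    by_chrom: dict[str, list] = {name: [] for name in genome.chrom_names}
    for fi, feat in enumerate(features):
        by_chrom[genome.chrom_names[fi % cfg.n_chroms]].append(feat)
    placements = []  # (chrom, start, kind, payload)
    for chrom in genome.chrom_names:
        feats = by_chrom[chrom]
        L = genome.length_of(chrom)
        used = sum(feature_span(k, p) for k, p in feats)
        free = L - used
        if free < 0.05 * L:
            raise ValueError(f"fixture chromosome {chrom} too small for its "
                             f"features ({used} of {L} bp)")
        u = rng.random(len(feats) + 1)
        gaps = np.floor(u / u.sum() * free).astype(np.int64)
        cursor = 0
        for (kind, p), gap in zip(feats, gaps[:-1]):
            cursor += int(gap)
            placements.append((chrom, cursor, kind, p))
            cursor += feature_span(kind, p)

    for chrom, start, kind, p in placements:
        if kind == "gene":
            glen, strand = p["length"], p["strand"]
            if strand == "+":
                prom = (start, start + 1000)
                body = (start + 1000, start + 1000 + glen)
            else:
                body = (start, start + glen)
                prom = (start + glen, start + glen + 1000)
            loci_rows.append((chrom, *prom, strand, "promoter",
                              p["expression"]))
            loci_rows.append((chrom, *body, strand, "gene_body",
                              p["expression"]))
            gene_rows.append((p["gene_id"], chrom, body[0], body[1], strand,
                              p["expression"]))
            continue
        span = feature_span(kind, p)
        if kind == "ctcf":
            center = start + 380
            loci_rows.append((chrom, start, start + 760, p["strand"],
                              "ctcf_flank", np.nan))
            ctcf_rows.append((chrom, center - 10, center + 10, p["strand"]))
        elif kind == "repeat":
            loci_rows.append((chrom, start, start + span, p["strand"],
                              "repeat", np.nan))
            rep_rows.append((chrom, start, start + span, p["strand"],
                             p["family"]))
        elif kind == "enhancer":
            loci_rows.append((chrom, start, start + span, ".",
                              f"enhancer_{p['label']}", np.nan))
            enh_rows.append((chrom, start, start + span, p["label"]))
        else:
            loci_rows.append((chrom, start, start + span, ".",
                              "heterochromatin", np.nan))
            het_rows.append((chrom, start, start + span))

    # background loci: tile every unannotated gap
    loci = pd.DataFrame(loci_rows, columns=["chrom", "start", "end", "strand",
                                            "label", "expression"])
    bg_rows = []
    tile = cfg.background_tile_bp
    for chrom in genome.chrom_names:
        sub = loci[loci["chrom"] == chrom].sort_values("start")
        bounds = list(zip(sub["start"], sub["end"]))
        gaps, prev = [], 0
        for s, e in bounds:
            if s > prev:
                gaps.append((prev, s))
            prev = e
        L = genome.length_of(chrom)
        if prev < L:
            gaps.append((prev, L))
        for gs, ge in gaps:
            edges = list(range(gs, ge, tile)) + [ge]
            if len(edges) >= 3 and edges[-1] - edges[-2] < tile / 2:
                edges.pop(-2)  # merge short tail into the last tile
            for a, b in zip(edges[:-1], edges[1:]):
                bg_rows.append((chrom, a, b, ".", "background", np.nan))
    bg = pd.DataFrame(bg_rows, columns=loci.columns)
    loci = pd.concat([loci, bg], ignore_index=True)
    loci = loci.sort_values(["chrom", "start"], kind="stable",
                            ignore_index=True)

    # ground-truth kinetics: class mean x log-normal spread; transcription
    # scales promoter/gene-body exchange
    n = len(loci)
    lam = np.empty(n)
    occ = np.empty(n)
    labels = loci["label"].to_numpy()
    expr = loci["expression"].to_numpy()
    for cls in CLASSES:
        m = labels == cls
        k = int(m.sum())
        if not k:
            continue
        lam[m] = _lognormal_around(rng, CLASS_LAMBDA[cls], 0.5, k)
        sigma_o = 0.8 if cls == "background" else 0.3
        occ[m] = np.minimum(
            _lognormal_around(rng, CLASS_OCCUPANCY[cls], sigma_o, k), 1.0)
    transcribed = np.isin(labels, ["promoter", "gene_body"])
    scale = np.sqrt(np.where(transcribed, expr, 1.0)
                    / np.exp(1.0 + 0.5))  # mean of the expression law
    lam = lam * np.where(transcribed, scale, 1.0)
    loci["occupancy"] = occ
    loci["lam"] = np.maximum(lam, 1e-3)
    loci = loci.drop(columns=["expression"])

    genes = RegionSet(pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand",
                            "expression"]), genome)
    motifs = RegionSet(pd.DataFrame(
        ctcf_rows, columns=["chrom", "start", "end", "strand"]), genome)
    enh = RegionSet(pd.DataFrame(
        enh_rows, columns=["chrom", "start", "end", "label"]), genome)
    reps = RegionSet(pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end", "strand", "family"]),
        genome)
    het = RegionSet(pd.DataFrame(
        het_rows, columns=["chrom", "start", "end"]), genome)
    return SyntheticGenome(genome, loci, genes, motifs, enh, reps, het)


def custom_locus_genome(lam, occupancy=None, locus_bp: int = 1000,
                        gap_bp: int = 1000, label: str = "background"
                        ) -> SyntheticGenome:
    """A minimal fixture of equally sized, equally spaced loci with
    caller-supplied kinetics — the substrate for estimator-recovery and
    calibration studies where the locus layout should not matter.

    Only the loci themselves emit fragments (gaps are unannotated).
    """
    lam = np.asarray(lam, dtype=float)
    n = lam.size
    if occupancy is None:
        occupancy = np.full(n, 0.5)
    occupancy = np.asarray(occupancy, dtype=float)
    pitch = locus_bp + gap_bp
    starts = gap_bp // 2 + pitch * np.arange(n, dtype=np.int64)
    length = int(starts[-1] + locus_bp + gap_bp)
    genome = Genome(("chr1",), (length,))
    loci = pd.DataFrame({
        "chrom": "chr1", "start": starts, "end": starts + locus_bp,
        "strand": ".", "label": label, "occupancy": occupancy, "lam": lam,
    })
    empty = RegionSet(pd.DataFrame(columns=["chrom", "start", "end"]),
                      genome, validate=False)
    genes = RegionSet(pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand",
                 "expression"]), genome, validate=False)
    return SyntheticGenome(genome, loci, genes, empty, empty, empty, empty)


def _sample_fragments(rng, loci: pd.DataFrame, weights: np.ndarray,
                      depth: int, genome: Genome, len_mean: float,
                      len_sd: float, sample: str, channel: str,
                      short_component: np.ndarray | None = None
                      ) -> FragmentCollection:
    """Poisson fragment counts per locus with the given relative weights;
    midpoints uniform within the locus, truncated-normal lengths,
    Bernoulli(1/2) strands."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("all-zero channel weights")
    mean_counts = depth * w / w.sum()
    counts = rng.poisson(mean_counts)
    total = int(counts.sum())
    if total == 0:
        logger.warning("simulate[%s/%s]: empty channel at depth %d",
                       sample, channel, depth)
    li = np.repeat(np.arange(len(loci)), counts)
    starts = loci["start"].to_numpy()[li]
    spans = (loci["end"].to_numpy() - loci["start"].to_numpy())[li]
    mids = starts + np.floor(rng.random(total) * spans).astype(np.int64)
    if short_component is None:
        lengths = rng.normal(len_mean, len_sd, size=total)
    else:
        p_short = short_component[li]
        is_short = rng.random(total) < p_short
        lengths = np.where(is_short,
                           rng.normal(80.0, 15.0, size=total),
                           rng.normal(185.0, 25.0, size=total))
    lengths = np.maximum(np.rint(lengths), 1.0).astype(np.int64)
    fs = mids - lengths // 2
    chrom_len = loci["chrom"].map(genome.sizes).to_numpy()[li]
    fs = np.clip(fs, 0, np.maximum(chrom_len - lengths, 0))
    fe = np.minimum(fs + lengths, chrom_len)
    strand = np.where(rng.random(total) < 0.5, "+", "-")
    df = pd.DataFrame({
        "chrom": loci["chrom"].to_numpy()[li],
        "start": fs, "end": fe, "strand": strand,
        "mapq": np.full(total, 60, dtype=np.int64),
    })
    df = df.sort_values(["chrom", "start", "end"], kind="stable",
                        ignore_index=True)
    return FragmentCollection(df, sample=sample, channel=channel)


def simulate_channels(fix: SyntheticGenome,
                      cfg: SimulationConfig = SimulationConfig(),
                      channels: tuple[str, ...] = ("myc", "HA"),
                      sample: str = "sim",
                      tev_mask: np.ndarray | None = None
                      ) -> dict[str, FragmentCollection]:
    """Simulate sequencing channels from the fixture's ground truth.

    Expected HA density at locus i is proportional to O_i; expected myc
    density to O_i * f(lambda_i, kappa). Each channel is independently scaled
    to ``cfg.depth`` expected fragments (sequencing depth carries no
    information, matching the sensor's relative-only readout). Channels
    beyond myc/HA: "input" (uniform per bp), "mnase" (proportional to O),
    mark channels from :data:`MARK_PROFILES`, and "ATAC" (open-chromatin
    weights with a sub-120 bp nucleosome-free length component at promoters
    and active enhancers).

    ``tev_mask`` optionally marks loci where the TEV protease is absent
    (no cleavage there: f = 1), for proximity-confound checks.
    """
    loci = fix.loci
    lam = loci["lam"].to_numpy()
    occ = loci["occupancy"].to_numpy()
    spans = (loci["end"] - loci["start"]).to_numpy()
    f = steady_state_uncleaved(lam, cfg.kappa)
    if tev_mask is not None:
        f = np.where(np.asarray(tev_mask, dtype=bool), f, 1.0)
    labels = loci["label"].to_numpy()

    out = {}
    for ci, channel in enumerate(channels):
        rng = np.random.default_rng([cfg.seed, ci])
        short = None
        if channel == "myc":
            w = occ * f * spans
        elif channel == "HA":
            w = occ * spans
        elif channel == "input":
            w = spans.astype(float)
        elif channel == "mnase":
            w = occ * spans
        elif channel == "ATAC":
            open_w = {"promoter": 8.0, "enhancer_active": 8.0,
                      "enhancer_primed": 3.0}
            w = np.array([open_w.get(l, 0.3) for l in labels]) * spans
            short = np.where(np.isin(labels, ["promoter",
                                              "enhancer_active"]), 0.6, 0.2)
        elif channel in MARK_PROFILES:
            prof = MARK_PROFILES[channel]
            w = np.array([prof.get(l, 0.2) for l in labels]) * spans
        else:
            raise ValueError(f"unknown channel {channel!r}")
        out[channel] = _sample_fragments(
            rng, loci, w, cfg.depth, fix.genome, cfg.frag_len_mean,
            cfg.frag_len_sd, sample, channel, short_component=short)
    return out


def simulate_repeat_hits(fix: SyntheticGenome, cfg: SimulationConfig,
                         abundances: dict[str, float] | None = None,
                         n_reads: int = 100_000, tie_fraction: float = 0.3,
                         seed: int | None = None) -> pd.DataFrame:
    """Per-read consensus-alignment hit lists for the repeat module.

    Reads are drawn from family abundances (default: proportional to total
    fixture bp per family, plus an rRNA family at 5%); a ``tie_fraction`` of
    reads get a second equal-best hit on a random other family, emulating
    multimapping between related consensus sequences.

    Returns a tidy frame (read_id, family, score).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if abundances is None:
        fam = fix.repeats.metadata("family")
        lens = fix.repeats.lengths
        abundances = {f: float(lens[fam == f].sum()) for f in np.unique(fam)}
        abundances["rRNA"] = 0.05 * sum(abundances.values())
    families = sorted(abundances)
    p = np.array([abundances[f] for f in families], dtype=float)
    p /= p.sum()
    primary = rng.choice(len(families), size=n_reads, p=p)
    has_tie = rng.random(n_reads) < tie_fraction
    offset = rng.integers(1, len(families), size=n_reads)
    tie_fam = (primary + offset) % len(families)
    rows = {"read_id": [], "family": [], "score": []}
    for i in range(n_reads):
        rid = f"r{i:07d}"
        rows["read_id"].append(rid)
        rows["family"].append(families[primary[i]])
        rows["score"].append(0)
        if has_tie[i]:
            rows["read_id"].append(rid)
            rows["family"].append(families[tie_fam[i]])
            rows["score"].append(0)
    return pd.DataFrame(rows)


def save_channels(channels: dict[str, FragmentCollection], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frags in channels.items():
        write_fragment_bed(frags, outdir / f"{frags.sample}.{name}.bed")
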