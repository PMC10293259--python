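# Methods

## The measurement being modeled

A dual-tag exchange sensor is a histone carrying `myc–TEV site–HA` at its
C-terminus, paired with a TEV protease fused to a partner histone. The
protease can only reach the sensor while both sit in the same nucleosome on
DNA, so cleavage (loss of the myc epitope) integrates co-residence time. HA
ChIP-seq therefore measures occupancy of the tagged variant; myc ChIP-seq
measures the fraction of bound sensors that have not yet been cleaved —
histones that arrived recently. The per-region log-ratio of the two channels
is the exchange readout.

Two facts shape every quantitative choice downstream:

1. **Only relative exchange is identifiable.** Immunoprecipitation
   efficiencies and library depths differ arbitrarily between the myc and HA
   channels, so absolute incorporation rates are not measurable; all
   statistics are ratios or log-differences of depth-normalized coverage,
   and region-set results are reported against shifted control regions.
2. **Recycling is invisible.** Replacement of a tagged histone by an
   untagged one from the general pool produces no signal; the sensor sees
   only tagged-for-tagged turnover.

## Kinetic model in the simulator

Each locus carries an occupancy `O ∈ (0, 1]` and an exchange rate `λ > 0`
(evictions per unit time). A bound sensor is cleaved at first-order rate
`κ` while on DNA. With exponential residence, the probability that a sensor
leaves before cleavage — retaining myc — is the exponential-race outcome

    f(λ, κ) = λ / (λ + κ).

This closed form is the package's own minimal formalization of the sensor
logic (the qualitative behaviour it reproduces: `κ = 0` gives `f = 1`, the
non-cleavable control; faster exchange keeps more myc). It is cross-checked
in the tests against a direct Monte-Carlo race between exponential residence
and cleavage clocks. Expected HA coverage at a locus is `∝ O`, expected myc
coverage `∝ O · f`; each channel's fragment counts are Poisson with those
means scaled to the configured depth, fragment midpoints uniform within the
locus, lengths truncated-normal (160 ± 40 bp by default), strands fair
coins. Not modeled, deliberately: histone recycling and the untagged pool
(unobservable, see above), sequence composition, PCR duplicates, GC bias,
replication-coupled dilution. An optional per-locus TEV-presence mask can
emulate protease-availability confounds (`f = 1` where the protease is
absent).

Time units are arbitrary: only `λ/κ` matters, so `κ = 1` is the reference
scale and per-class `λ` values are expressed on it.

## The synthetic genome fixture

`build_genome_fixture` lays out, per default, 2 chromosomes × 5 Mb holding
300 genes (log-normal lengths 2–40 kb, each with a 1 kb promoter on its TSS
side), 200 CTCF motifs (100 per orientation, each inside a 760 bp flanking
locus), 150 enhancers (45% active / 45% primed / 10% poised), 100 repeat
insertions from five families (IAP/L1/MERVL/ETn/MuSat consensus lengths
2–6 kb), and 20 heterochromatin blocks of 50 kb. Features are dealt
round-robin across chromosomes and separated by random gaps drawn to exactly
partition the free space, so every requested feature is placed and every
base carries exactly one class label; gaps are tiled into ~5 kb background
loci.

Ground-truth kinetics per class (means; log-normal within-class spread,
σ = 0.5 for λ, σ = 0.3 for occupancy, σ = 0.8 for background occupancy so
tiles have realistic dynamic range):

| class | λ | O | rationale |
|---|---|---|---|
| promoter | 8.0 | 0.45 | fastest turnover, partially depleted nucleosomes |
| enhancer (active) | 6.0 | 0.50 | high turnover at open regulatory chromatin |
| CTCF flank | 4.0 | 0.60 | elevated exchange at architectural sites |
| enhancer (poised) | 2.0 | 0.55 | measurable but reduced turnover |
| repeat | 2.0 | 0.80 | moderate exchange, dense chromatin |
| gene body | 1.2 | 0.75 | transcription-coupled (scales with expression) |
| enhancer (primed) | 0.8 | 0.55 | near-background turnover |
| heterochromatin | 0.7 | 0.90 | dense, slowly exchanging |
| background | 0.5 | 0.25 | genomic baseline |

Gene expression is log-normal(μ=1, σ=1); promoter and gene-body λ scale
with √(expression/mean expression), encoding the exchange–transcription
coupling. Mark channels (H3K4me3, H3K27ac, H3K9me3, H3.3-like, MNase,
input, ATAC) are emitted from per-class relative weights; ATAC additionally
mixes a sub-120 bp nucleosome-free length component (60% of fragments at
promoters/active enhancers, 20% elsewhere).

What passing simulation tests do **not** show: the fixture has no sequence,
no mappability structure, no copy-number variation among repeats, and its
class landscape is far simpler than a real genome — tests on it validate
the estimators and the plumbing, not biological discovery on real data.

## Processing pipeline

Order matters and is fixed: mapping-quality filter (MQ ≥ 10) at read-in →
fragment-size filter (length > 300 bp removed; exactly 300 kept) → 5′-end
shift by 80 bp toward 3′ (half the mean fragment length, approximating the
dyad; on the minus strand the 5′ end is `end − 1` in half-open coordinates,
so the point is `end − 1 − shift`) → per-region point counting (points per
kb; the unit is immaterial because downstream statistics are ratio-based —
asserted by a scale-invariance test) → depth normalization scaling each
sample so its mean over the 5 kb genome tiling equals 0.4 → exchange
scoring with pseudocount ε = 0.05 (applied after normalization, which is
why normalization precedes it). ATAC uses the opposite size selection
(length < 120 bp removed; 120 kept). Replicates are pooled by seeded
down-sampling of deeper collections to the shallowest depth before
concatenation.

Two exchange estimators coexist because they answer different questions:

- `exchange_score`: per-region `log2(myc+ε) − log2(HA+ε)` — used for region
  tables, turnover classification, scatter analyses;
- `pooled_bin_exchange`: bin means of myc and HA computed across regions
  first, then one log-ratio per bin — used for positional profiles (CTCF
  nucleosome bins), where it weights regions by coverage instead of giving
  every region's noisy log-ratio equal weight.

Mark enrichment is `log2(mark+1) − log2(input+1)` (finite at zero
coverage). The PRC2 co-binding score used to rank bivalent promoters is the
raw read sum of SUZ12 + EZH2 + JARID2; the `log2(x+1)` transform applies
when a component is displayed or correlated individually. Turnover
stratification requires occupancy `log2(HA+ε) > 1`, then calls high
(`E > 1.55`) or low (`E < −0.45`); the gap between the cutoffs makes the
classes disjoint by construction.

## Geometry choices

- **Coordinates** are 0-based half-open throughout (adjacent intervals do
  not overlap); all window widths (1 kb promoters, 2 kb anchored windows,
  5 kb tiles and gene flanks) are honored as lengths.
- **Scaled-gene matrices**: 10 × 500 bp upstream + 100 scaled body segments
  + 10 × 500 bp downstream = 120 columns, rows oriented 5′→3′ (minus-strand
  rows reversed). Values are densities per kb so scaled body bins remain
  comparable to fixed flanks. Element (repeat) profiles use the same
  machinery with 250 body windows.
- **CTCF nucleosome layout**: four nucleosomes of 180 bp (−2, −1, +1, +2
  around the motif center; the 720 bp span is the package's geometric
  concretization and fully configurable), covered by 31 bins of 23 bp with
  the 30 bp division remainder absorbed by the central bin. The edge grid is
  mirror-symmetric around the center, so reversing a minus-strand motif is
  an exact reflection — which makes the asymmetry score
  `A = mean E(+1,+2) − mean E(−1,−2)` exactly antisymmetric under strand
  flips (a bit-exact test, not a statistical one). Motifs inside annotated
  genes are excluded before CTCF analyses.
- **Control regions** are literal 20 kb translations (strand-ignorant by
  default; a strand-aware mode exists). Shifted intervals leaving the
  chromosome are dropped, not clipped — target and control sets may then
  differ in size, which is safe because only control means are used. Whether
  real analyses clip, drop or wrap at chromosome ends is unknowable from the
  method description; dropping is the documented choice here.
- **Genome tiling** keeps a trailing partial window iff it is at least half
  the tile width (configurable to always/never).

## Binning and smoothing

Covariate binning (expression, PRC2 score, H3K27ac height, H3.3 counts) is
equal-count: regions are ranked (stable sort, ties keep input order) and
split into n bins, the remainder spread one region each over the leading
bins (10 regions in 3 bins → 4/3/3). An optional coverage pre-filter drops
regions below a threshold (e.g. low-MNase promoters) before binning.
Trendlines are LOESS (span 0.5). The choice of smoother is display-only:
every quantitative statement rests on the binned means, which are computed
exactly; LOESS was preferred over a supersmoother variant for being
well-maintained in statsmodels.

## Repeat quantification

Reads aligned to a consensus repeat library arrive as per-read hit lists
(read_id, family, score). Multimappers are assigned to one of their
maximal-score hits uniformly at random with a recorded seed — assignment
conserves reads and, over many tied reads, splits them evenly. Family
counts are divided by each sample's total aligned reads; families under 100
raw reads are discarded (default: dropped if *any* analyzed sample is below
the cutoff — the conservative reading; an "all-samples" mode exists) and
rRNA families are removed. Pairwise enrichment is a plain log2 ratio of
normalized counts, finite by construction after the abundance filter.

## Differential contrasts

The inference unit is the biological replicate. For each replicate one
delta is computed — mean statistic (exchange `E` or occupancy `HA`) over a
target region set minus the mean over a reference set — and conditions are
compared by a two-sided two-sample t-test on the deltas. The default pools
variances (classic Student): at n = 2 vs 2 the pooled test is exact under
normality, while the Welch approximation is markedly conservative there
(its true type-I rate is near 0.02 at nominal 0.05); `equal_var=False`
selects Welch for designs with suspect variance equality. No
multiple-testing correction is applied by default (contrasts are few and
pre-specified); Benjamini–Hochberg is available behind a flag. With two
replicates per condition the test has 2 degrees of freedom — significance
then requires |t| > 4.3, so only large, consistent effects are detectable;
this power caveat is inherent to the design, not to the implementation.

## Validation studies (exchseq.benchmarks)

- **Kinetics recovery**: 2,000 equal-occupancy loci, λ log-uniform in
  [0.05, 20], κ = 1, depth set to 50 expected HA fragments per locus; the
  Spearman correlation between the per-locus exchange score and true λ is
  ~0.94–0.95. At this depth the correlation is limited by Poisson rank
  noise itself — an ideal estimator with perfect counting achieves the same
  value, with `f = λ/(λ+1)` saturating above λ ≈ 5 contributing most of the
  rank scatter.
- **Non-cleavable control**: κ = 0 at 10⁶ fragments per channel over the
  10 Mb fixture; per-5kb-tile Pearson(myc, HA) ≈ 0.994 and mean exchange
  ≈ 0.
- **Asymmetry null**: with orientation-independent λ the mean per-motif
  CTCF asymmetry is zero within Monte-Carlo error.
- **Knockout study**: 150 enhancer-like targets (λ = 6) vs 150 primed-like
  references (λ = 0.8) plus a split heterochromatin control (λ = 0.7), 2 WT
  vs 2 KO replicates at 30,000 fragments per channel. Null runs hold the
  nominal 0.05 type-I rate (a 200-run binomial estimate of a calibrated
  test still lands outside ±0.02 of nominal in roughly one seed in ten);
  halving enhancer λ is detected (negative difference, p < 0.05) in ≥ 90%
  of runs while the untouched heterochromatin contrast stays non-significant.

Problem sizes (10 Mb fixtures, 10⁴–10⁶ fragments, 100–200 simulation runs)
were chosen so each study gives stable Monte-Carlo estimates while the whole
battery completes in about a minute on a single CPU.

## Known limitations

- The kinetic closed form assumes memoryless residence and cleavage; real
  cleavage kinetics may be multi-step, which would bend (but not reorder)
  the λ → myc/HA mapping — rank-based analyses are robust to this.
- No aligner is included: SAM/BAM or fragment-BED input is consumed as-is,
  and repeat hit lists must come from an upstream consensus alignment.
- Peak calling, chromatin-state segmentation and Hi-C compartment calls are
  inputs, not outputs; the compartment analysis is composed from overlap
  flags + nucleosome-bin exchange + control normalization.
- The per-kb coverage unit is arbitrary (scale cancels in every reported
  statistic after depth normalization); exported coverage columns should not
  be compared across packages without re-normalization.
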