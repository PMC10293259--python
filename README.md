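# exchseq

Quantitative analytics for **dual-tag histone-exchange sensor ChIP-seq**.

The sensor is a histone fused to `myc–TEV site–HA`, with a TEV protease
carried on a partner histone. While the tagged histone sits on DNA the
protease clips the myc tag, so after immunoprecipitation:

- **HA** reports total occupancy of the tagged histone, and
- **myc** survives only on histones that left DNA before cleavage — i.e. it
  marks recently exchanged (fast-turning-over) nucleosomes.

The per-region **exchange score** is the log-ratio of the two
depth-normalized channels,

```
E = log2(myc + 0.05) − log2(HA + 0.05)
```

optionally normalized by subtracting the mean `E` of control regions shifted
20 kb away. A non-cleavable sensor variant (mutated TEV site) is the
antibody-bias control: its two channels must coincide.

`exchseq` implements the full downstream analysis for this readout —
fragment filtering (MQ ≥ 10, ≤ 300 bp), 5′-end shifting (80 bp ≈ half the
mean fragment length), binned counting, depth normalization, replicate
pooling with depth matching, exchange and mark-enrichment scores, TSS/
scaled-gene/anchored metaprofile matrices, expression-quantile binning,
strand-aware CTCF-motif asymmetry analysis, consensus repeat-library
quantification with best-hit multimapper assignment, and replicate-level
knockout contrasts — plus a **sensor-kinetics simulator** that generates a
fully labeled synthetic genome with per-locus ground-truth exchange rates,
so every stage is testable without any sequencing data.

The simulator's kinetic core: with exponential residence at rate λ and
first-order cleavage at rate κ, the myc-retaining fraction of bound sensors
is `f = λ / (λ + κ)`; expected HA coverage at a locus is proportional to its
occupancy `O`, expected myc coverage to `O · f`.

## Worked example

Simulate a labeled 2 × 5 Mb genome, run the standard preprocessing, and
compare exchange across region classes:

```python
from exchseq import (SimulationConfig, build_genome_fixture,
                     simulate_channels, filter_fragments, shift_five_prime,
                     count_in_regions, tile_genome, exchange_score,
                     normalize_to_control, shift_regions)

fix = build_genome_fixture(seed=1)
channels = simulate_channels(fix, SimulationConfig(depth=500_000, seed=1))

tiles = tile_genome(fix.genome, 5000)
cov = {}
for name, frags in channels.items():
    pts = shift_five_prime(filter_fragments(frags, 300), 80, fix.genome)
    tile_cov = count_in_regions(pts, tiles)
    cov[name] = lambda regions, p=pts, f=0.4 / tile_cov.mean(): \
        count_in_regions(p, regions) * f

for label in ("promoter", "enhancer_active", "enhancer_primed",
              "heterochromatin", "background"):
    regions = fix.loci_regions(label)
    control = shift_regions(regions, 20_000, fix.genome)
    e = exchange_score(cov["myc"](regions), cov["HA"](regions))
    e_ctrl = exchange_score(cov["myc"](control), cov["HA"](control))
    e_norm, mu = normalize_to_control(e, e_ctrl)
    print(f"{label:18s} n={len(regions):4d}  exchange={e.mean():+.2f}  "
          f"vs 20kb-shifted control={e_norm.mean():+.2f}")
```

prints

```
promoter           n= 300  exchange=+0.84  vs 20kb-shifted control=+0.97
enhancer_active    n=  60  exchange=+0.85  vs 20kb-shifted control=+0.85
enhancer_primed    n=  73  exchange=-0.07  vs 20kb-shifted control=+0.11
heterochromatin    n=  20  exchange=-0.27  vs 20kb-shifted control=-0.05
background         n=1320  exchange=-0.35  vs 20kb-shifted control=-0.26
```

Promoters and active enhancers turn over fast (high myc/HA); primed
enhancers sit near background; heterochromatin exchanges little — exactly
the ordering encoded in the simulator's ground-truth rates (high positive
`E` means the channel ratio, not an absolute rate; only relative exchange is
identifiable from the sensor).

## Command line

```bash
exchseq simulate --out demo/ --seed 1 --depth 500000   # fixture + channels
exchseq preprocess demo/sim.myc.bed --genome demo/genome.chrom.sizes \
        --regions demo/enhancers.bed --out myc.cov.tsv
exchseq ctcf --myc demo/sim.myc.bed --ha demo/sim.HA.bed \
        --genome demo/genome.chrom.sizes --motifs demo/ctcf_motifs.bed \
        --out asymmetry.tsv
exchseq run --config demo.yaml        # full pipeline from a YAML manifest
```

Every printed method parameter (0.05 pseudocount, 80 bp shift, 300 bp
fragment cap, 0.4 depth target, 120 bp ATAC cutoff, 100-read repeat filter,
31 CTCF bins, 20 kb control shift, turnover thresholds 1.55 / −0.45) is a
config default and overridable.

## Layout

| module | contents |
|---|---|
| `exchseq.core` | genome/interval/fragment model, BED/SAM/BAM/TSV I/O, overlap and shift operations |
| `exchseq.simulate` | genome fixture generator, kinetic model, channel simulator |
| `exchseq.preprocess` | fragment filters, 5′ shifting, counting, depth normalization, pooling |
| `exchseq.exchange` | exchange/enrichment/PRC2 scores, turnover and dynamics-mode classification |
| `exchseq.profiles` | tiling, anchored and scaled-gene matrices, quantile binning, LOESS trends |
| `exchseq.ctcf` | nucleosome-bin exchange, asymmetry scores, decile contrasts, occupancy partition |
| `exchseq.repeats` | multimapper assignment, count normalization/filters, element profiles |
| `exchseq.differential` | replicate contrasts and two-sample t-tests |
| `exchseq.pipeline` / `exchseq.cli` | YAML-driven orchestration and the `exchseq` command |
| `exchseq.benchmarks` | the simulation studies used for validation |

See `docs/methods.md` for the model, parameter choices and limitations.
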