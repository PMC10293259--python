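"""Self-contained simulation studies exercising the whole pipeline.

Each function builds its inputs with the synthetic-data generator, runs the
relevant analysis stages end to end, and returns the summary statistic(s).
They double as the package's reproducibility checks: estimator recovery of
the ground-truth exchange rates, the non-cleavable control, CTCF asymmetry
null calibration, and the knockout contrast's type-I error and power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ctcf import asymmetry_score, nucleosome_bin_exchange
from .differential import condition_test
from .exchange import exchange_score
from .preprocess import (count_in_regions, count_points, filter_fragments,
                         shift_five_prime)
from .profiles import tile_genome
from .simulate import (FixtureConfig, SimulationConfig, build_genome_fixture,
                       custom_locus_genome, simulate_channels)


def _normalized_coverage(channels, genome, regions, shift_bp=80,
                         max_fragment_bp=300, target=0.4, tile_bp=5000):
    """Standard preprocessing: size filter, 5' shift, count, depth-normalize.

    Returns {channel: per-region coverage} with each channel scaled to a
    genome-tiling mean of ``target``.
    """
    tiles = tile_genome(genome, tile_bp)
    out = {}
    for name, frags in channels.items():
        pts = shift_five_prime(filter_fragments(frags, max_fragment_bp),
                               shift_bp, genome)
        tmean = count_in_regions(pts, tiles).mean()
        out[name] = count_in_regions(pts, regions) * (target / tmean)
    return out


def kinetics_recovery(seed: int = 0, n_loci: int = 2000,
                      mean_ha_fragments: float = 50.0,
                      kappa: float = 1.0) -> float:
    """Spearman correlation between estimated exchange and true lambda.

    Simulates ``n_loci`` equal-occupancy loci with lambda drawn
    log-uniformly from [0.05, 20], sequencing depth set so the mean HA count
    per locus is ``mean_ha_fragments``, runs the standard preprocessing and
    exchange scoring, and correlates the per-locus exchange score with the
    ground-truth rates.
    """
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.uniform(np.log(0.05), np.log(20.0), n_loci))
    fix = custom_locus_genome(lam)
    cfg = SimulationConfig(cleavage_rate=kappa,
                           depth=int(mean_ha_fragments * n_loci), seed=seed)
    channels = simulate_channels(fix, cfg)
    loci = fix.loci_regions()
    cov = _normalized_coverage(channels, fix.genome, loci)
    e = exchange_score(cov["myc"], cov["HA"])
    return float(stats.spearmanr(e, lam).statistic)


def nc_control(seed: int = 0, depth: int = 1_000_000,
               tile_bp: int = 5000) -> tuple[float, float]:
    """Non-cleavable sensor control on the default 10 Mb fixture.

    With cleavage disabled the myc and HA channels measure the same
    occupancy landscape: returns (per-tile Pearson(myc, HA), mean exchange
    score over tiles), which should be ~1 and ~0.
    """
    fix = build_genome_fixture(FixtureConfig(), seed=seed)
    cfg = SimulationConfig(depth=depth, seed=seed, cleavable=False)
    channels = simulate_channels(fix, cfg)
    tiles = tile_genome(fix.genome, tile_bp)
    cov = _normalized_coverage(channels, fix.genome, tiles, tile_bp=tile_bp)
    r = float(stats.pearsonr(cov["myc"], cov["HA"]).statistic)
    mean_e = float(exchange_score(cov["myc"], cov["HA"]).mean())
    return r, mean_e


def asymmetry_null(seed: int = 0, depth: int = 400_000):
    """CTCF asymmetry under orientation-independent kinetics.

    On the default fixture (lambda does not depend on motif orientation) the
    per-motif asymmetry must be centered at zero: returns (mean A, SE of A).
    """
    fix = build_genome_fixture(FixtureConfig(), seed=seed)
    cfg = SimulationConfig(depth=depth, seed=seed)
    channels = simulate_channels(fix, cfg)
    pts = {k: shift_five_prime(filter_fragments(v, 300), 80, fix.genome)
           for k, v in channels.items()}
    _, per_motif = nucleosome_bin_exchange(pts["myc"], pts["HA"],
                                           fix.ctcf_motifs)
    a = asymmetry_score(per_motif)
    return float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size))


class KnockoutStudy:
    """Replicated knockout contrast on a compact enhancer/heterochromatin
    scenario.

    The scenario holds 150 high-exchange target loci (active-enhancer-like,
    lambda = 6), 150 low-exchange reference loci (primed-enhancer-like,
    lambda = 0.8) and 100 heterochromatin-like loci (lambda = 0.7) split
    half/half into a target/reference pair for the specificity contrast.
    A knockout multiplies the enhancer-target lambda by ``ko_factor``
    (1 = null); heterochromatin is never touched. Each condition is measured
    in ``n_replicates`` independently simulated replicates at ``depth``
    fragments per channel, and contrasts are tested with the two-sided
    pooled t-test on per-replicate deltas.
    """

    N_ENH = 150
    N_REF = 150
    N_HET = 100

    def __init__(self, depth: int = 30_000, n_replicates: int = 2):
        self.depth = depth
        self.n_replicates = n_replicates
        n = self.N_ENH + self.N_REF + self.N_HET
        self.enh_idx = np.arange(self.N_ENH)
        self.ref_idx = np.arange(self.N_ENH, self.N_ENH + self.N_REF)
        het = np.arange(self.N_ENH + self.N_REF, n)
        self.het_t_idx = het[:self.N_HET // 2]
        self.het_r_idx = het[self.N_HET // 2:]
        self.base_lam = np.concatenate([
            np.full(self.N_ENH, 6.0),
            np.full(self.N_REF, 0.8),
            np.full(self.N_HET, 0.7),
        ])

    def _deltas(self, lam, seeds):
        fix = custom_locus_genome(lam)
        loci = fix.loci_regions()
        enh, het = [], []
        for s in seeds:
            ch = simulate_channels(fix, SimulationConfig(1.0, self.depth,
                                                         seed=int(s)))
            m = count_points(shift_five_prime(ch["myc"], 80, fix.genome),
                             loci).astype(float)
            h = count_points(shift_five_prime(ch["HA"], 80, fix.genome),
                             loci).astype(float)
            e = exchange_score(m * 0.4 / m.mean(), h * 0.4 / h.mean())
            enh.append(e[self.enh_idx].mean() - e[self.ref_idx].mean())
            het.append(e[self.het_t_idx].mean() - e[self.het_r_idx].mean())
        return enh, het

    def run_once(self, seed: int, ko_factor: float = 1.0):
        """One WT-vs-KO experiment; returns a two-row report frame."""
        ss = np.random.SeedSequence(seed)
        wt_seeds, ko_seeds = np.split(
            ss.generate_state(2 * self.n_replicates) % (2**31), 2)
        ko_lam = self.base_lam.copy()
        ko_lam[self.enh_idx] *= ko_factor
        wt_enh, wt_het = self._deltas(self.base_lam, wt_seeds)
        ko_enh, ko_het = self._deltas(ko_lam, ko_seeds)
        rows = []
        for name, wt, ko in (("enhancer", wt_enh, ko_enh),
                             ("heterochromatin", wt_het, ko_het)):
            diff, p, _ = condition_test(ko, wt)
            rows.append({"contrast": name, "difference": diff, "p_value": p})
        return pd.DataFrame(rows)

    def type_i_rate(self, seed: int = 0, n_runs: int = 200) -> float:
        """Fraction of null (no-knockout) runs where the enhancer contrast
        is called significant at 0.05."""
        rej = 0
        for i in range(n_runs):
            rep = self.run_once(seed * n_runs + i, ko_factor=1.0)
            rej += rep.loc[rep["contrast"] == "enhancer",
                           "p_value"].iat[0] < 0.05
        return rej / n_runs

    def power(self, seed: int = 0, n_runs: int = 100,
              ko_factor: float = 0.5):
        """(detection rate, specificity rate) under an enhancer knockout.

        Detection: enhancer contrast negative with p < 0.05. Specificity:
        untouched heterochromatin contrast non-significant (p >= 0.05).
        """
        detected = spared = 0
        for i in range(n_runs):
            rep = self.run_once((seed + 1) * n_runs + i, ko_factor=ko_factor)
            enh = rep[rep["contrast"] == "enhancer"].iloc[0]
            het = rep[rep["contrast"] == "heterochromatin"].iloc[0]
            detected += (enh["difference"] < 0) and (enh["p_value"] < 0.05)
            spared += het["p_value"] >= 0.05
        return detected / n_runs, spared / n_runs
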