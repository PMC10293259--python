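"""Replicate-level region-set contrasts and significance testing.

The inference unit is the biological replicate: for each replicate a single
delta (mean statistic over a target region set minus mean over a reference
set) is computed, and conditions are compared by a two-sided two-sample
t-test on those per-replicate deltas. This mirrors how chaperone-knockout
effects on exchange are assessed: e.g. H3.3-peak-overlapping enhancers and
promoters against their non-overlapping counterparts, and H3K9me3 peaks with
vs without H3.3, for both occupancy (HA) and exchange (E).

The default test pools variances (classic Student): at the tiny replicate
counts typical here (2 vs 2) the pooled test holds its nominal size exactly
under normality, whereas the Welch approximation is markedly conservative.
``equal_var=False`` switches to Welch for unbalanced-variance designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import RegionSet


@dataclass
class ContrastSpec:
    """One region-set contrast: target minus reference on a chosen statistic
    ("E" for exchange, "HA" for occupancy)."""

    name: str
    target: RegionSet
    reference: RegionSet
    statistic: str = "E"

    def __post_init__(self):
        if self.statistic not in ("E", "HA", "myc"):
            raise ValueError("statistic must be E, HA or myc")


def replicate_contrast(track: pd.DataFrame, target_index,
                       reference_index, statistic: str = "E") -> float:
    """Delta for one replicate: mean statistic over target regions minus mean
    over reference regions. ``track`` is a per-region exchange table (see
    :func:`exchseq.exchange.exchange_track`); the index arguments select its
    rows."""
    col = track[statistic].to_numpy()
    t = col[np.asarray(target_index)]
    r = col[np.asarray(reference_index)]
    if t.size == 0 or r.size == 0:
        raise ValueError("empty target or reference selection")
    return float(t.mean() - r.mean())


def condition_test(deltas_a, deltas_b, equal_var: bool = True):
    """Two-sided two-sample t-test between per-replicate deltas.

    Returns ``(difference of means a - b, p-value, (deltas_a, deltas_b))``;
    the replicate values are echoed for plotting (dots = replicates). Refuses
    groups with fewer than two replicates, where no variance estimate exists.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 replicates per condition (got {a.size} vs {b.size})")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    diff = float(a.mean() - b.mean())
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups, identical means
        p = 1.0 if diff == 0 else 0.0
    return diff, p, (a, b)


def ko_effect_pipeline(wt_tracks: list[pd.DataFrame],
                       ko_tracks: list[pd.DataFrame],
                       contrasts: list[ContrastSpec],
                       region_index: dict[str, tuple[np.ndarray, np.ndarray]],
                       equal_var: bool = True,
                       adjust: str | None = None) -> pd.DataFrame:
    """Run every contrast across WT and KO replicate exchange tracks.

    ``region_index`` maps contrast name to (target row index, reference row
    index) into the tracks (all replicates share region order). Returns a
    report with one row per contrast: per-condition means, difference
    (KO - WT), direction, p-value and the per-replicate deltas. ``adjust``
    may be "bh" for Benjamini-Hochberg across the report's contrasts; the
    default reports raw per-contrast p-values.
    """
    rows = []
    for spec in contrasts:
        ti, ri = region_index[spec.name]
        wt = [replicate_contrast(t, ti, ri, spec.statistic)
              for t in wt_tracks]
        ko = [replicate_contrast(t, ti, ri, spec.statistic)
              for t in ko_tracks]
        diff, p, _ = condition_test(ko, wt, equal_var=equal_var)
        rows.append({
            "contrast": spec.name,
            "statistic": spec.statistic,
            "wt_mean": float(np.mean(wt)),
            "ko_mean": float(np.mean(ko)),
            "difference": diff,
            "direction": "down" if diff < 0 else ("up" if diff > 0 else "none"),
            "p_value": p,
            "wt_deltas": list(np.round(wt, 10)),
            "ko_deltas": list(np.round(ko, 10)),
        })
    report = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        report["p_adjusted"] = multipletests(report["p_value"],
                                             method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    return report
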