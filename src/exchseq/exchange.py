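"""Exchange statistics for the dual-tag (myc/HA) histone sensor.

The sensor fuses myc--TEV-site--HA to a histone tail; a TEV protease on a
partner histone cleaves the myc tag during co-residence on DNA. HA therefore
reports total occupancy while surviving myc marks recently exchanged
histones. The per-region exchange score is

    E = log2(myc + eps) - log2(HA + eps),        eps = 0.05

computed on depth-normalized mean coverage; the pseudocount damps noise at
low-coverage regions. Two estimators coexist deliberately: the per-region
log-ratio above (used for most region analytics) and the mean-then-log-ratio
:func:`pooled_bin_exchange` (used for positional bin profiles, e.g. around
CTCF motifs). They differ by Jensen's inequality and each call site is bound
to one of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RegionSet


@dataclass(frozen=True)
class ExchangeParams:
    pseudocount: float = 0.05
    enrichment_pseudocount: float = 1.0

    def __post_init__(self):
        if self.pseudocount <= 0 or self.enrichment_pseudocount <= 0:
            raise ValueError("pseudocounts must be positive")


@dataclass(frozen=True)
class TurnoverThresholds:
    """Occupancy gate and exchange cutoffs for high/low turnover calls
    (log2 units on pseudocounted coverage)."""

    occupancy_min: float = 1.0
    high_exchange_min: float = 1.55
    low_exchange_max: float = -0.45

    def __post_init__(self):
        if self.high_exchange_min <= self.low_exchange_max:
            raise ValueError("high_exchange_min must exceed low_exchange_max")


def exchange_score(myc, ha, eps: float = 0.05) -> np.ndarray:
    """Per-region exchange: log2(myc + eps) - log2(HA + eps)."""
    myc = np.asarray(myc, dtype=float)
    ha = np.asarray(ha, dtype=float)
    if (myc < 0).any() or (ha < 0).any():
        raise ValueError("coverage values must be non-negative")
    return np.log2(myc + eps) - np.log2(ha + eps)


def pooled_bin_exchange(mean_myc, mean_ha, eps: float = 0.05) -> np.ndarray:
    """Bin-level exchange: log-ratio of the bin means (mean first, then log).

    For a single-region bin this coincides with :func:`exchange_score`; over
    many regions it weights by coverage rather than averaging per-region
    log-ratios.
    """
    return exchange_score(mean_myc, mean_ha, eps)


def enrichment_score(mark, input_, eps: float = 1.0) -> np.ndarray:
    """Mark-over-input enrichment: log2(mark + 1) - log2(input + 1)."""
    mark = np.asarray(mark, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if (mark < 0).any() or (input_ < 0).any():
        raise ValueError("coverage values must be non-negative")
    return np.log2(mark + eps) - np.log2(input_ + eps)


def normalize_to_control(values, control_values):
    """Subtract the mean of a control set (e.g. 20 kb-shifted regions).

    Returns ``(normalized values, subtracted control mean)`` so the raw
    values are reconstructible.
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValueError("control set is empty")
    mu = float(control_values.mean())
    return np.asarray(values, dtype=float) - mu, mu


def classify_turnover(myc, ha,
                      thresholds: TurnoverThresholds = TurnoverThresholds(),
                      eps: float = 0.05) -> np.ndarray:
    """Stratify regions into high / low / unclassified turnover.

    A region must first be occupied (log2(HA + eps) above the occupancy
    gate); among occupied regions, exchange above ``high_exchange_min`` is
    "high", below ``low_exchange_max`` is "low", anything else (or
    unoccupied) is "unclassified". The two classes are disjoint by
    construction.
    """
    myc = np.atleast_1d(np.asarray(myc, dtype=float))
    ha = np.atleast_1d(np.asarray(ha, dtype=float))
    occupied = np.log2(ha + eps) > thresholds.occupancy_min
    e = exchange_score(myc, ha, eps)
    labels = np.full(e.shape, "unclassified", dtype=object)
    labels[occupied & (e > thresholds.high_exchange_min)] = "high"
    labels[occupied & (e < thresholds.low_exchange_max)] = "low"
    return labels


def prc2_score(suz12, ezh2, jarid2) -> np.ndarray:
    """PRC2 co-binding score: raw read sum of SUZ12, EZH2 and JARID2.

    The sum of raw counts is the ranking/binning key for bivalent-promoter
    analyses; log2(x + 1) transforms apply when a component is displayed or
    correlated individually (see :func:`enrichment_score` with input absent).
    """
    arrs = [np.asarray(a, dtype=float) for a in (suz12, ezh2, jarid2)]
    if any((a < 0).any() for a in arrs):
        raise ValueError("counts must be non-negative")
    return arrs[0] + arrs[1] + arrs[2]


def classify_dynamics_mode(trend_myc: float, trend_ha: float,
                           tol: float = 0.1) -> str:
    """Read a (myc trend, HA trend) pair as a histone-dynamics mode.

    Trends are per-bin slopes of mean log2 signal against a covariate (e.g.
    PRC2-score bins). New deposition on free DNA raises both channels
    (incorporation); loss of nucleosomes lowers HA with flat myc (eviction);
    myc rising relative to HA marks a shift toward replacement
    (exchange_shift); anything within tolerance is stable.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if trend_myc > tol and trend_ha > tol:
        return "incorporation"
    if trend_ha < -tol and abs(trend_myc) <= tol:
        return "eviction"
    if trend_myc - trend_ha > tol:
        return "exchange_shift"
    return "stable"


def exchange_track(regions: RegionSet, myc, ha, eps: float = 0.05,
                   control_values=None, **marks) -> pd.DataFrame:
    """Assemble the per-region exchange table (ExchangeTrack export form).

    Columns: region coordinates, myc, HA, E and, when a control E vector is
    given, E_norm (control-subtracted) plus any keyword mark-enrichment
    columns.
    """
    out = regions.df[["chrom", "start", "end", "strand"]].copy()
    out["myc"] = np.asarray(myc, dtype=float)
    out["HA"] = np.asarray(ha, dtype=float)
    out["E"] = exchange_score(myc, ha, eps)
    if control_values is not None:
        out["E_norm"], out.attrs["control_mean"] = normalize_to_control(
            out["E"].to_numpy(), control_values)
    for name, vals in marks.items():
        out[name] = np.asarray(vals, dtype=float)
    return out
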