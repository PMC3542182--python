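"""Positional distribution of motif hits across peak regions.

Hit midpoints are recorded as fractions of each region's native width (no
trimming to a fixed size), binned into twenty 5% bins, loess-smoothed, and
scaled so that a uniform distribution sits at density 1. Scanning with a
motif unrelated to the peaks should therefore give a flat line at 1, which
`flatness_control` checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .motifs import PWM, MarkovBackground, MotifHit, scan_pwm
from .seqio import GenomicInterval, SequenceRecord

N_BINS = 20  # fixed: 5% bins, kept non-configurable so profiles stay comparable
BIN_EDGES = np.linspace(0.0, 1.0, N_BINS + 1)
BIN_CENTERS = (BIN_EDGES[:-1] + BIN_EDGES[1:]) / 2


@dataclass
class PositionalProfile:
    """Binned, scaled and smoothed distribution of hit positions in [0, 1]."""

    raw_counts: np.ndarray
    scaled_density: np.ndarray
    smoothed: np.ndarray
    loess_span: float
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())

    @property
    def n_hits(self) -> int:
        return int(self.raw_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": BIN_CENTERS,
                "raw": self.raw_counts,
                "scaled": self.scaled_density,
                "smoothed": self.smoothed,
            }
        )


def relative_positions(
    hits: Sequence[MotifHit],
    regions: Union[Sequence[GenomicInterval], Sequence[SequenceRecord]],
) -> list[float]:
    """Hit-midpoint positions as fractions of region width, clipped to [0, 1].

    Regions may be intervals (matched to hits by name) or the scanned
    sequence records themselves (matched by id); native widths are used.
    """
    widths: dict[str, int] = {}
    for region in regions:
        key = region.name if isinstance(region, GenomicInterval) else region.id
        widths[key] = len(region)
    out = []
    for hit in hits:
        if hit.region_id not in widths:
            raise LookupError(f"hit references unknown region {hit.region_id!r}")
        midpoint = hit.offset + hit.width / 2.0
        out.append(min(1.0, max(0.0, midpoint / widths[hit.region_id])))
    return out


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights, evaluated at each x.

    At each point the `span` fraction of nearest neighbours is fit with a
    weighted degree-`degree` polynomial; weights are tricube in scaled
    distance to the farthest neighbour.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = max(degree + 1, int(math.ceil(span * n)))
    q = min(q, n)
    fitted = np.empty(n)
    for j, x0 in enumerate(x):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[j] = y[idx].mean()
            continue
        w = np.clip(1.0 - (d[idx] / dmax) ** 3, 0.0, None) ** 3
        coeffs = np.polyfit(x[idx], y[idx], degree, w=np.sqrt(w))
        fitted[j] = np.polyval(coeffs, x0)
    return fitted


def profile(positions: Sequence[float], loess_span: float = 0.75) -> PositionalProfile:
    """Histogram relative positions into 5% bins; scale so uniform = 1; smooth.

    Bins are half-open [x, x+0.05) with the final bin closed at 1.0, so no
    position in [0, 1] is lost. scaled_density averages exactly 1.
    """
    positions = np.asarray(list(positions), dtype=float)
    if positions.size == 0:
        raise ValueError("profile requires at least one position")
    if ((positions < 0) | (positions > 1)).any():
        raise ValueError("positions must lie in [0, 1]")
    raw, _ = np.histogram(positions, bins=BIN_EDGES)
    scaled = raw / (positions.size / N_BINS)
    smoothed = loess_smooth(BIN_CENTERS, scaled, span=loess_span)
    return PositionalProfile(raw, scaled, smoothed, loess_span)


def flatness_control(
    regions: Sequence[SequenceRecord],
    unrelated_pwm: PWM,
    bg: MarkovBackground,
    threshold: float = 4.5,
    loess_span: float = 0.75,
) -> Optional[PositionalProfile]:
    """Profile an unrelated PWM over background peaks (expected: flat at 1).

    Returns None when the scan yields no hits (an empty profile is a valid
    outcome for a stringent threshold, not an error).
    """
    hits: list[MotifHit] = []
    for region in regions:
        hits.extend(scan_pwm(region, unrelated_pwm, bg, threshold))
    if not hits:
        return None
    return profile(relative_positions(hits, regions), loess_span=loess_span)


def flatness_se(profile_: PositionalProfile) -> float:
    """Binomial standard error of scaled bin density around 1 for N total hits."""
    n = profile_.n_hits
    p = 1.0 / N_BINS
    return math.sqrt(n * p * (1 - p)) / (n * p)
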