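"""Positional preference analyses: tube-end occupancy and zone occupancy.

Two long-term assays are covered.  In the two-choice food assay each tube
end is plugged with food (one side laced with ethanol) and preference is
scored as the percentage of time per hour the fly dwells within the last
two beams of each side; hourly preference is then correlated with Zeitgeber
time to detect circadian trends in ethanol seeking.  In the closed-loop
place-preference assay the tube is split into two illumination zones
(blue/green) and preference is the percentage of time per hour spent under
each color, following the zone→color mapping through any mid-session swap.

Scoring always uses the per-second position channel — "time spent" is
positional dwell, not movement.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .monitor_data import (
    ActivityTrace,
    BeamGeometry,
    Color,
    DEFAULT_GEOMETRY,
    UsageError,
    ValidationError,
    zt_hours,
)
from .protocol_engine import LEFT, FeedbackRule
from . import stats_core

__all__ = [
    "end_occupancy",
    "end_occupancy_cohort",
    "zone_occupancy",
    "zt_correlation",
]


def _bin_percentages(member: np.ndarray, bin_s: int, fly_id: str):
    """Per-bin percentage of True seconds; flags a trailing partial bin."""
    n = len(member)
    n_bins = n // bin_s
    if n % bin_s:
        warnings.warn(
            f"{fly_id}: trailing {n % bin_s} s do not fill a {bin_s}-s bin "
            f"and are ignored", stacklevel=3)
    full = member[:n_bins * bin_s].reshape(n_bins, bin_s)
    return 100.0 * full.mean(axis=1)


def end_occupancy(trace: ActivityTrace, geometry: BeamGeometry = DEFAULT_GEOMETRY,
                  end_beams: int = 2, bin_s: int = 3600,
                  start_s: int = 0) -> pd.DataFrame:
    """Percentage of time per bin spent at each tube end.

    Side A is the low-index end (beams ``1..end_beams``), side B the
    high-index end (the last ``end_beams`` beams).  The middle of the tube
    is unscored, so ``pct_side_a + pct_side_b <= 100``.  ``start_s`` drops
    an initial settling period (the food assay discards the first ~12 h and
    starts scoring at ZT0).
    """
    if trace.duration - start_s < bin_s:
        raise UsageError("trace must cover at least one full bin")
    pos = trace.position[start_s:]
    side_a = pos <= end_beams
    side_b = pos >= geometry.n_beams - end_beams + 1
    pct_a = _bin_percentages(side_a, bin_s, trace.fly_id)
    pct_b = _bin_percentages(side_b, bin_s, trace.fly_id)
    bins = np.arange(len(pct_a))
    bin_start_s = start_s + bins * bin_s
    return pd.DataFrame({
        "fly_id": trace.fly_id,
        "bin_h": bins,
        "pct_side_a": pct_a,
        "pct_side_b": pct_b,
        "zt": zt_hours(bin_start_s, trace.zt0),
    })


def end_occupancy_cohort(traces: Sequence[ActivityTrace],
                         geometry: BeamGeometry = DEFAULT_GEOMETRY,
                         end_beams: int = 2, bin_s: int = 3600,
                         start_s: int = 0) -> pd.DataFrame:
    """Concatenated :func:`end_occupancy` tables for a cohort."""
    return pd.concat(
        [end_occupancy(tr, geometry, end_beams, bin_s, start_s)
         for tr in traces],
        ignore_index=True)


def zone_occupancy(zones: np.ndarray, rule: FeedbackRule, bin_s: int = 3600,
                   start_s: int = 0,
                   fly_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Percentage of time per bin spent under blue vs green illumination.

    ``zones`` is the per-second zone assignment (``(n_flies, duration)`` or
    a single fly's vector); the zone→color mapping follows ``rule``,
    including the swap at ``rule.swap_at_s``.  Zones partition the tube, so
    ``pct_blue + pct_green == 100`` in every bin.
    """
    zones = np.atleast_2d(np.asarray(zones))
    n, duration = zones.shape
    if duration - start_s < bin_s:
        raise UsageError("assignment must cover at least one full bin")
    if np.any(zones < 0):
        raise ValidationError("gap (negative code) in zone assignment")
    if fly_ids is None:
        fly_ids = [f"tube{i + 1:02d}" for i in range(n)]

    t = np.arange(start_s, duration)
    # Time-varying mapping: before the swap the left zone has
    # rule.left_color, after it the colors interchange.
    if rule.swap_at_s is None:
        swapped = np.zeros(len(t), dtype=bool)
    else:
        swapped = t >= rule.swap_at_s
    left_is_blue = np.where(swapped, rule.right_color is Color.BLUE,
                            rule.left_color is Color.BLUE)
    frames = []
    for i in range(n):
        in_left = zones[i, start_s:] == LEFT
        in_blue = np.where(in_left, left_is_blue, ~left_is_blue)
        pct_blue = _bin_percentages(in_blue, bin_s, fly_ids[i])
        bins = np.arange(len(pct_blue))
        frames.append(pd.DataFrame({
            "fly_id": fly_ids[i],
            "bin_h": bins,
            "pct_blue": pct_blue,
            "pct_green": 100.0 - pct_blue,
        }))
    return pd.concat(frames, ignore_index=True)


def zt_correlation(series: pd.DataFrame, value_col: str = "pct_side_b",
                   zt_col: str = "zt"):
    """Pearson correlation between hourly preference and Zeitgeber time.

    Pools all fly-by-bin points into a single correlation; returns
    ``(r, p, n)``.  Requires at least 3 bins and non-degenerate variance.
    """
    x = np.asarray(series[zt_col], dtype=float)
    y = np.asarray(series[value_col], dtype=float)
    if len(x) < 3:
        raise UsageError("zt_correlation requires at least 3 points")
    return stats_core.pearson(x, y)
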