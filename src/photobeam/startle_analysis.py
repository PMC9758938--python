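"""Sudden-darkness startle analysis: delta index, exclusions, epochs.

The core quantity is the delta response index: for each 1-s lights-off
stimulus, the mean per-second beam-crossing count over the 30 s after the
stimulus minus the mean over the 30 s before it, with the stimulus second
itself excluded.  Positive deltas mean darkness-induced locomotion.  The
module also implements the dead-fly exclusion rule (no activity in any
pre/post window across the whole session), the increase/decrease/no-change
trial breakdown, 30-min epoch averaging for habituation trend analysis, and
baseline activity/speed over the window preceding the first stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .monitor_data import ActivityTrace, UsageError

__all__ = [
    "DeltaRecord",
    "ResponseBreakdown",
    "delta_index",
    "delta_matrix",
    "records_to_frame",
    "exclude_dead",
    "classify_responses",
    "epoch_average",
    "per_fly_epoch_means",
    "baseline_metrics",
]


@dataclass(frozen=True)
class DeltaRecord:
    """Startle response of one fly on one trial.

    ``delta = post_mean - pre_mean`` exactly, both means taken over
    ``window_s`` seconds flanking (and excluding) the stimulus second.
    """

    fly_id: str
    trial_index: int
    stim_time_s: int
    pre_mean: float
    post_mean: float
    delta: float


@dataclass(frozen=True)
class ResponseBreakdown:
    """Fractions of fly-by-trial cells with delta > 0, < 0 and == 0.

    Counts are integer sums over the two windows, so exact zero deltas are
    well defined; the three fractions sum to one.
    """

    fraction_increase: float
    fraction_decrease: float
    fraction_no_change: float
    n: int


def _window_sums(counts: np.ndarray, stim_times: np.ndarray, window_s: int):
    """(pre_sum, post_sum) per stimulus; pre = [t-w, t), post = (t, t+w]."""
    offsets_pre = np.arange(-window_s, 0)
    offsets_post = np.arange(1, window_s + 1)
    pre = counts[stim_times[:, None] + offsets_pre].sum(axis=1)
    post = counts[stim_times[:, None] + offsets_post].sum(axis=1)
    return pre, post


def _valid_stims(duration: int, stim_times: Sequence[int], window_s: int,
                 fly_id: str = "") -> np.ndarray:
    stim_times = np.asarray(stim_times, dtype=np.int64)
    ok = (stim_times - window_s >= 0) & (stim_times + window_s < duration)
    if not ok.all():
        skipped = stim_times[~ok].tolist()
        warnings.warn(
            f"{fly_id or 'trace'}: stimulus at {skipped} s too close to the "
            f"session edge for a {window_s}-s window; trial(s) skipped",
            stacklevel=3,
        )
    return ok


def delta_index(trace: ActivityTrace, stim_times: Sequence[int],
                window_s: int = 30) -> list:
    """Per-trial delta records for one fly.

    ``stim_times`` are the session seconds of the lights-off pulses.  Trials
    whose windows would run off the session edge are skipped with a warning.
    """
    stim_times = np.asarray(stim_times, dtype=np.int64)
    ok = _valid_stims(trace.duration, stim_times, window_s, trace.fly_id)
    kept = stim_times[ok]
    kept_idx = np.nonzero(ok)[0]
    pre, post = _window_sums(trace.counts, kept, window_s)
    records = []
    for j, t in enumerate(kept):
        pre_m = pre[j] / window_s
        post_m = post[j] / window_s
        records.append(DeltaRecord(
            fly_id=trace.fly_id, trial_index=int(kept_idx[j]),
            stim_time_s=int(t), pre_mean=float(pre_m), post_mean=float(post_m),
            delta=float(post_m - pre_m)))
    return records


def delta_matrix(counts: np.ndarray, stim_times: Sequence[int],
                 window_s: int = 30):
    """Vectorized deltas for a cohort counts matrix ``(n_flies, duration)``.

    Returns ``(pre_means, post_means, deltas)`` of shape
    ``(n_flies, n_trials)``; all stimuli must fit inside the session.
    Numerically identical to stacking :func:`delta_index` over flies.
    """
    counts = np.asarray(counts)
    stim_times = np.asarray(stim_times, dtype=np.int64)
    if np.any(stim_times - window_s < 0) or \
            np.any(stim_times + window_s >= counts.shape[1]):
        raise UsageError("delta_matrix requires all windows inside the session")
    pre_idx = stim_times[:, None] + np.arange(-window_s, 0)
    post_idx = stim_times[:, None] + np.arange(1, window_s + 1)
    pre = counts[:, pre_idx].sum(axis=2) / window_s
    post = counts[:, post_idx].sum(axis=2) / window_s
    return pre, post, post - pre


def records_to_frame(records: Iterable[DeltaRecord]) -> pd.DataFrame:
    """Tabulate delta records (one row per fly-by-trial)."""
    return pd.DataFrame([r.__dict__ for r in records],
                        columns=["fly_id", "trial_index", "stim_time_s",
                                 "pre_mean", "post_mean", "delta"])


def exclude_dead(traces: Sequence[ActivityTrace], stim_times: Sequence[int],
                 window_s: int = 30):
    """Split traces into (kept, excluded_ids) by the dead-fly rule.

    A fly is considered dead — and excluded — iff every pre and post window
    around every stimulus contains zero counts.  Activity outside the
    windows does not rescue a fly: the rule looks only at the windows.
    """
    stim_times = np.asarray(stim_times, dtype=np.int64)
    kept, excluded = [], []
    for tr in traces:
        ok = (stim_times - window_s >= 0) & (stim_times + window_s < tr.duration)
        pre, post = _window_sums(tr.counts, stim_times[ok], window_s)
        if len(pre) and (pre.sum() + post.sum()) == 0:
            excluded.append(tr.fly_id)
        else:
            kept.append(tr)
    return kept, excluded


def classify_responses(records: Sequence[DeltaRecord]) -> ResponseBreakdown:
    """Fractions of trials with increased / decreased / unchanged movement."""
    if not records:
        raise UsageError("classify_responses requires at least one record")
    deltas = np.array([r.delta for r in records])
    n = len(deltas)
    inc = int(np.sum(deltas > 0))
    dec = int(np.sum(deltas < 0))
    return ResponseBreakdown(
        fraction_increase=inc / n,
        fraction_decrease=dec / n,
        fraction_no_change=(n - inc - dec) / n,
        n=n)


def _epoch_of(stim_times: np.ndarray, epoch_len_s: int,
              origin_s: Optional[int]) -> np.ndarray:
    if origin_s is None:
        origin_s = int(stim_times.min())
    return (stim_times - origin_s) // epoch_len_s


def epoch_average(records: Sequence[DeltaRecord], epoch_len_s: int = 1800,
                  session_len_s: Optional[int] = None,
                  origin_s: Optional[int] = None) -> pd.DataFrame:
    """Bin trials into half-open epochs ``[k*L, (k+1)*L)`` by stimulus time
    and average the deltas per epoch.

    ``origin_s`` defaults to the first stimulus time, so a 2-h session has
    four 30-min epochs holding 6 deltas per fly at 5-min ITI and 30 at 1-min
    ITI.  Empty epochs (possible when ``session_len_s`` forces the epoch
    range) are flagged with ``n = 0`` and ``mean_delta = NaN``.
    """
    if not records:
        raise UsageError("epoch_average requires at least one record")
    times = np.array([r.stim_time_s for r in records])
    deltas = np.array([r.delta for r in records])
    if origin_s is None:
        origin_s = int(times.min())
    epochs = _epoch_of(times, epoch_len_s, origin_s)
    n_epochs = int(epochs.max()) + 1
    if session_len_s is not None:
        n_epochs = max(n_epochs, (session_len_s - origin_s) // epoch_len_s)
    rows = []
    for k in range(n_epochs):
        sel = epochs == k
        n_k = int(sel.sum())
        rows.append({
            "epoch": k,
            "start_s": origin_s + k * epoch_len_s,
            "mean_delta": float(deltas[sel].mean()) if n_k else float("nan"),
            "n": n_k,
        })
    return pd.DataFrame(rows)


def per_fly_epoch_means(records: Sequence[DeltaRecord],
                        epoch_len_s: int = 1800,
                        origin_s: Optional[int] = None) -> pd.DataFrame:
    """Per-fly epoch-average deltas, one row per fly, one column per epoch.

    This is the unit of analysis for the habituation trend test: each epoch
    group holds one averaged value per fly.
    """
    df = records_to_frame(records)
    if df.empty:
        raise UsageError("per_fly_epoch_means requires records")
    if origin_s is None:
        origin_s = int(df["stim_time_s"].min())
    df["epoch"] = (df["stim_time_s"] - origin_s) // epoch_len_s
    return df.pivot_table(index="fly_id", columns="epoch", values="delta",
                          aggfunc="mean")


def baseline_metrics(trace: ActivityTrace, t_end: int,
                     window_s: int = 1200):
    """Mean activity (counts/s) and speed (beam widths/s) before a session.

    Computed over ``[t_end - window_s, t_end)`` — typically the 20 min
    preceding the first stimulus.  Speed is the mean per-second absolute
    beam displacement, the only speed measure recoverable from the stored
    trace.  A window truncated by the session start is computed on the
    available span with a warning.
    """
    start = t_end - window_s
    if start < 0:
        warnings.warn(
            f"{trace.fly_id}: baseline window truncated to [0, {t_end})",
            stacklevel=2)
        start = 0
    if t_end <= start:
        raise UsageError("baseline window is empty")
    counts = trace.counts[start:t_end]
    mean_counts = float(counts.mean())
    pos = trace.position[start:t_end]
    speed = float(np.abs(np.diff(pos)).mean()) if len(pos) >= 2 else 0.0
    return mean_counts, speed
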