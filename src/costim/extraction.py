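"""Force-trace windowing: baseline demeaning, steady-state and 50 ms vectors.

Conventions: all windows are half-open ``[a, b)`` on the sample grid, so no
sample is counted twice by adjacent windows. Times are mapped to sample
indices by nearest-sample rounding with ties toward zero; on a uniform grid
at rate ``fs`` the mapping error is at most half a sample (0.5 ms at 1 kHz).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientBaselineError, WindowError
from .synthetic import ForceTrace

#: steady-state window: 200 ms starting 300 ms after stimulation onset
STEADY_WINDOW_START = 0.300
STEADY_WINDOW_LENGTH = 0.200
BASELINE_DURATION = 0.400
DEFAULT_WINDOW = 0.050


@dataclass(frozen=True)
class SteadyVector:
    """Steady-state isometric force vector of one trial."""

    vector: np.ndarray       # (3,) N
    window_start: float      # s relative to stimulation onset
    window_length: float     # s
    meta: dict


@dataclass(frozen=True)
class WindowedVectors:
    """Contiguous equal-length window means across the stimulation train."""

    window_starts: np.ndarray  # (k,) s relative to onset
    vectors: np.ndarray        # (k, 3) N
    window_length: float
    meta: dict


def _index(trace: ForceTrace, time: float) -> int:
    """Nearest sample index for an absolute time, ties toward zero."""
    x = (time - trace.t[0]) * trace.sample_rate
    return int(np.floor(x + 0.5 - 1e-9))


def demean_trace(trace: ForceTrace,
                 baseline_duration: float = BASELINE_DURATION) -> ForceTrace:
    """Subtract the per-axis mean force over the pre-stimulus baseline.

    The baseline is the ``baseline_duration`` (default 400 ms) immediately
    preceding stimulation onset. Idempotent up to float precision.
    """
    start = _index(trace, trace.stim_onset - baseline_duration)
    stop = _index(trace, trace.stim_onset)
    if start < 0:
        available = trace.stim_onset - trace.t[0]
        raise InsufficientBaselineError(
            f"need {baseline_duration * 1e3:.0f} ms of pre-stimulus baseline, "
            f"trace has only {available * 1e3:.0f} ms before onset")
    if stop <= start:
        raise InsufficientBaselineError("empty baseline window")
    baseline = trace.force[start:stop].mean(axis=0)
    return trace.copy_with(trace.force - baseline[None, :])


def _window_mean(trace: ForceTrace, start_s: float, stop_s: float) -> np.ndarray:
    i0 = _index(trace, start_s)
    i1 = _index(trace, stop_s)
    if i0 < 0 or i1 > len(trace.t):
        raise WindowError(
            f"window [{start_s:.3f}, {stop_s:.3f}) s exceeds the recorded trace "
            f"[{trace.t[0]:.3f}, {trace.t[-1]:.3f}] s")
    if i1 <= i0:
        raise WindowError("window contains no samples")
    return trace.force[i0:i1].mean(axis=0)


def steady_state_vector(trace: ForceTrace,
                        window_start: float = STEADY_WINDOW_START,
                        window_length: float = STEADY_WINDOW_LENGTH) -> SteadyVector:
    """Mean force over [onset+300 ms, onset+500 ms), per axis.

    The trace should already be demeaned; this function does not demean.
    """
    a = trace.stim_onset + window_start
    v = _window_mean(trace, a, a + window_length)
    return SteadyVector(v, window_start, window_length, dict(trace.meta))


def windowed_vectors(trace: ForceTrace,
                     window: float = DEFAULT_WINDOW) -> WindowedVectors:
    """Mean force in consecutive ``window``-second bins spanning the train.

    Bin k covers [onset + k*window, onset + (k+1)*window); bins run from
    stimulation onset to the largest multiple of ``window`` that fits inside
    the trace's ``train_duration``.
    """
    if window <= 0:
        raise WindowError(f"window must be positive, got {window}")
    k = int(np.floor(trace.train_duration / window + 1e-9))
    if k < 1:
        raise WindowError(
            f"window {window} s exceeds train duration {trace.train_duration} s")
    starts = np.arange(k) * window
    vecs = np.empty((k, 3))
    for i, s in enumerate(starts):
        a = trace.stim_onset + s
        vecs[i] = _window_mean(trace, a, a + window)
    return WindowedVectors(starts, vecs, window, dict(trace.meta))


# ---------------------------------------------------------------------------
# batch extraction to tabular form

_META_COLS = ["subject_id", "block_type", "block_id", "slot_order", "condition",
              "site_a", "site_b", "amplitude_a", "amplitude_b"]


def steady_table(traces: list[ForceTrace], demean: bool = True) -> pd.DataFrame:
    """Steady-state vectors of many trials as one DataFrame."""
    rows = []
    for tr in traces:
        sv = steady_state_vector(demean_trace(tr) if demean else tr)
        row = {k: sv.meta.get(k) for k in _META_COLS}
        row.update(fx=sv.vector[0], fy=sv.vector[1], fz=sv.vector[2])
        rows.append(row)
    return pd.DataFrame(rows)


def windowed_table(traces: list[ForceTrace], window: float = DEFAULT_WINDOW,
                   demean: bool = True) -> pd.DataFrame:
    """Windowed vectors of many trials, one row per (trial, window)."""
    rows = []
    for tr in traces:
        wv = windowed_vectors(demean_trace(tr) if demean else tr, window)
        for s, v in zip(wv.window_starts, wv.vectors):
            row = {k: wv.meta.get(k) for k in _META_COLS}
            row.update(window_start=float(s), window_length=window,
                       fx=v[0], fy=v[1], fz=v[2])
            rows.append(row)
    return pd.DataFrame(rows)
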