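"""Breath-by-breath analysis of ventilatory flow recordings.

A flow recording (inspiration positive, L/s, default 400 Hz sampling) is cut
into breaths at inspiratory-onset zero crossings; each breath yields the
inspiratory and expiratory durations Ti and Te, the inspired and expired
volumes, and the mean phase flows Vt/Ti and Vt/Te that the downstream
nonlinear pipeline analyzes breath by breath.  Linear descriptors are the
coefficient of variation and the lag-one-breath autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FlowRecording",
    "BreathSeries",
    "BreathStats",
    "discard_initial",
    "segment_breaths",
    "coefficient_of_variation",
    "autocorr_lag1",
    "read_flow_file",
]


@dataclass
class FlowRecording:
    """Signed airflow samples (L/s, inspiration positive) on a uniform grid."""

    flow: np.ndarray
    sampling_rate: float = 400.0

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.flow.size < 2:
            raise ValueError("recording must hold at least 2 samples")

    @property
    def duration(self) -> float:
        return self.flow.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.flow.size) / self.sampling_rate


@dataclass
class BreathSeries:
    """Per-breath timing, volumes and mean flows, ordered in time."""

    onset_times: np.ndarray   # inspiratory onset (s) of each breath
    Ti: np.ndarray            # inspiratory duration (s)
    Te: np.ndarray            # expiratory duration (s)
    Vt_i: np.ndarray          # inspired volume (L)
    Vt_e: np.ndarray          # expired volume (L, positive)

    @property
    def vt_ti(self) -> np.ndarray:
        """Mean inspiratory flow per breath (L/s)."""
        return self.Vt_i / self.Ti

    @property
    def vt_te(self) -> np.ndarray:
        """Mean expiratory flow per breath (L/s)."""
        return self.Vt_e / self.Te

    def __len__(self) -> int:
        return self.Ti.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onset_times,
                "Ti_s": self.Ti,
                "Te_s": self.Te,
                "Vt_i_L": self.Vt_i,
                "Vt_e_L": self.Vt_e,
                "Vt_over_Ti": self.vt_ti,
                "Vt_over_Te": self.vt_te,
            }
        )


@dataclass
class BreathStats:
    """Linear descriptors of a breath series."""

    CV: float  # coefficient of variation (sample SD / mean)
    AC: float  # autocorrelation at lag one breath


def read_flow_file(
    path, sampling_rate: Optional[float] = None, polarity: int = 1
) -> FlowRecording:
    """Read a delimited flow file: (time_s, flow) columns, or one flow column.

    With two columns the sampling rate is inferred from the time axis unless
    given; ``polarity = -1`` flips the inspiration sign convention.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df = df.dropna(axis=1, how="all")  # sniffer artifacts on 1-column files
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        flow = df.iloc[:, 1].to_numpy(dtype=float)
        if sampling_rate is None:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise ValueError(f"non-increasing time axis in {path}")
            sampling_rate = 1.0 / dt
    else:
        if sampling_rate is None:
            raise ValueError("single-column input requires a sampling rate")
        flow = df.iloc[:, 0].to_numpy(dtype=float)
    return FlowRecording(polarity * flow, sampling_rate)


def discard_initial(recording: FlowRecording, seconds: float = 120.0) -> FlowRecording:
    """Drop the first ``seconds`` of a recording (settling-in exclusion)."""
    n_drop = int(round(seconds * recording.sampling_rate))
    if n_drop >= recording.flow.size:
        raise ValueError(
            f"recording of {recording.duration:.1f} s is shorter than the "
            f"{seconds:.1f} s discard window"
        )
    return FlowRecording(recording.flow[n_drop:], recording.sampling_rate)


def segment_breaths(
    recording: FlowRecording,
    hysteresis_frac: float = 0.02,
    min_phase_s: float = 0.3,
) -> BreathSeries:
    """Delimit breaths at inspiratory-onset zero crossings.

    A crossing from negative to positive flow opens inspiration; the return
    crossing opens expiration.  A hysteresis band of ``hysteresis_frac`` of
    the flow range and a minimum phase duration reject chatter around zero.
    Volumes integrate each phase trapezoidally; partial first and last
    breaths are dropped.
    """
    flow = recording.flow
    fs = recording.sampling_rate
    rng = float(np.ptp(flow))
    if rng == 0 or not (np.any(flow > 0) and np.any(flow < 0)):
        warnings.warn("flow never crosses zero; no breaths detected")
        return _empty_breaths()
    band = hysteresis_frac * rng
    min_len = max(1, int(round(min_phase_s * fs)))

    # State machine: +1 inside inspiration, -1 inside expiration.
    insp_onsets: list[int] = []
    exp_onsets: list[int] = []
    state = 0
    count = 0
    for i, f in enumerate(flow):
        if state >= 0 and f <= -band:
            if state == 0 or count >= min_len:
                exp_onsets.append(i)
                state, count = -1, 0
        elif state <= 0 and f >= band:
            if state == 0 or count >= min_len:
                insp_onsets.append(i)
                state, count = 1, 0
        count += 1
    if len(insp_onsets) < 2:
        warnings.warn("fewer than two inspiratory onsets; no complete breaths")
        return _empty_breaths()

    onsets, ti, te, vi, ve = [], [], [], [], []
    for b in range(len(insp_onsets) - 1):
        start = insp_onsets[b]
        end = insp_onsets[b + 1]
        mid = [e for e in exp_onsets if start < e < end]
        if not mid:
            continue
        m = mid[0]
        ti_b = (m - start) / fs
        te_b = (end - m) / fs
        if ti_b <= 0 or te_b <= 0:
            continue
        onsets.append(start / fs)
        ti.append(ti_b)
        te.append(te_b)
        vi.append(np.trapezoid(np.clip(flow[start: m + 1], 0, None), dx=1 / fs))
        ve.append(-np.trapezoid(np.clip(flow[m: end + 1], None, 0), dx=1 / fs))
    return BreathSeries(
        onset_times=np.array(onsets),
        Ti=np.array(ti),
        Te=np.array(te),
        Vt_i=np.array(vi),
        Vt_e=np.array(ve),
    )


def _empty_breaths() -> BreathSeries:
    z = np.array([])
    return BreathSeries(z, z, z, z, z)


def coefficient_of_variation(series) -> float:
    """Sample standard deviation over the mean (ddof = 1)."""
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values")
    mean = y.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(np.std(y, ddof=1) / mean)


def autocorr_lag1(series) -> float:
    """Sample autocorrelation at a lag of one breath."""
    y = np.asarray(series, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 values")
    y = y - y.mean()
    var = float(y @ y)
    if var <= 0:
        raise ValueError("zero-variance series")
    return float((y[:-1] @ y[1:]) / var)
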