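"""Miniature EPSC detection and kinetic selection.

Detection operates on whole-cell voltage-clamp current traces (pA,
inward events negative-going).  Candidates are excursions below a rolling
baseline by more than an amplitude threshold in the −4 to −6 pA range,
lasting over 1 ms, with a 10 ms dead time after each detection.  Each
event is measured relative to its local pre-event baseline: peak
amplitude, 10–90% rise time, monotonicity of the rising phase, and the
decay time constant from a single-exponential fit.  Accepted events must
satisfy every selection rule (amplitude at or below threshold, duration
> 1 ms, monotonic rise, 10–90 rise < 6 ms, τ-decay < 25 ms), and cells
with accepted-event frequencies under 0.05 Hz are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: selection rules, as printed units
MAX_RISE_MS = 6.0
MAX_TAU_MS = 25.0
MIN_DURATION_MS = 1.0
DEAD_TIME_MS = 10.0
MIN_CELL_FREQ_HZ = 0.05
DEFAULT_AMPLITUDE_THRESHOLD_PA = -5.0  # midpoint of the −4 to −6 pA range


@dataclass
class CurrentTrace:
    samples_pa: np.ndarray
    sampling_rate: float
    holding_potential_mv: float = -70.0
    low_pass_cutoff_hz: float = 2000.0

    def __post_init__(self) -> None:
        self.samples_pa = np.asarray(self.samples_pa, dtype=float).reshape(-1)
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples_pa)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples_pa) / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples_pa)) / self.sampling_rate


@dataclass
class Candidate:
    start_idx: int   # first sample below threshold
    end_idx: int     # one past the last sample below threshold

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class MiniEvent:
    onset_time_s: float
    peak_time_s: float
    peak_amplitude_pa: float       # negative, relative to local baseline
    rise_10_90_ms: float
    tau_decay_ms: float
    duration_ms: float             # time spent below the detection threshold
    monotonic_rise: bool
    accepted: bool = False
    rejection_reason: str = ""


def rolling_baseline(trace: CurrentTrace, window_ms: float = 200.0) -> np.ndarray:
    """Rolling-median baseline (centred window, default 200 ms)."""
    win = int(round(window_ms * 1e-3 * trace.sampling_rate))
    if win < 3:
        raise ValueError("baseline window shorter than 3 samples")
    if len(trace.samples_pa) < win:
        raise ValueError("trace shorter than the baseline window")
    s = pd.Series(trace.samples_pa)
    return s.rolling(win, center=True, min_periods=1).median().to_numpy()


def estimate_noise_sd(trace: CurrentTrace, baseline: np.ndarray | None = None) -> float:
    """Robust noise SD of the baseline-subtracted trace (MAD/0.6745)."""
    if baseline is None:
        baseline = rolling_baseline(trace)
    d = trace.samples_pa - baseline
    return float(np.median(np.abs(d - np.median(d))) / 0.6745)


def detect_candidates(
    trace: CurrentTrace,
    amplitude_threshold_pa: float = DEFAULT_AMPLITUDE_THRESHOLD_PA,
    dead_time_ms: float = DEAD_TIME_MS,
    min_duration_ms: float = MIN_DURATION_MS,
    baseline_window_ms: float = 200.0,
    baseline: np.ndarray | None = None,
) -> list[Candidate]:
    """Threshold-crossing candidate search with dead-time suppression.

    Candidates are contiguous runs below ``baseline + threshold`` lasting
    strictly more than ``min_duration_ms``; after each accepted candidate,
    further detections are suppressed for ``dead_time_ms``.
    """
    if amplitude_threshold_pa >= 0:
        raise ValueError("amplitude threshold must be negative (inward events)")
    if dead_time_ms < 0:
        raise ValueError("dead time must be non-negative")
    if baseline is None:
        baseline = rolling_baseline(trace, baseline_window_ms)
    fs = trace.sampling_rate
    below = (trace.samples_pa - baseline) < amplitude_threshold_pa
    if not below.any():
        return []
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        stops = np.r_[stops, len(below)]
    min_samples = min_duration_ms * 1e-3 * fs
    dead_samples = dead_time_ms * 1e-3 * fs
    out: list[Candidate] = []
    last_onset = -np.inf
    for s, e in zip(starts, stops):
        if (e - s) <= min_samples:
            continue
        if s - last_onset < dead_samples:
            continue
        out.append(Candidate(int(s), int(e)))
        last_onset = s
    return out


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, idx: int) -> float:
    """Linear-interpolated time at which y crosses ``level`` between
    samples idx-1 and idx (y decreasing through level)."""
    if idx == 0:
        return float(t[0])
    y0, y1 = y[idx - 1], y[idx]
    if y1 == y0:
        return float(t[idx])
    frac = (level - y0) / (y1 - y0)
    return float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))


def measure_event(
    trace: CurrentTrace,
    candidate: Candidate,
    baseline: np.ndarray | None = None,
    next_start_idx: int | None = None,
    noise_sd: float | None = None,
    max_peak_window_ms: float = 50.0,
    tau_max_window_ms: float = 100.0,
) -> MiniEvent:
    """Measure peak amplitude and kinetics of one candidate event.

    The local baseline is the median of the 5 ms immediately preceding the
    threshold crossing.  The peak is located on a 3-point-median smoothed
    trace and its amplitude read as the mean of the raw samples within
    ±0.25 ms of that location.  Rise time is the 10→90% interval of peak
    amplitude (linear interpolation on the smoothed trace); monotonicity
    of the rising phase is tested with a tolerance of one noise SD.  The
    decay constant comes from a least-squares single-exponential fit from
    the peak toward baseline.
    """
    fs = trace.sampling_rate
    x = trace.samples_pa
    n = len(x)
    if not (0 <= candidate.start_idx < candidate.end_idx <= n):
        raise ValueError("candidate outside trace")
    if baseline is None:
        baseline = rolling_baseline(trace)
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace, baseline)

    s = candidate.start_idx
    # the 10% point precedes the threshold crossing: open the analysis
    # window a little before the candidate onset
    win0 = max(0, s - int(2e-3 * fs))
    pre0 = max(0, win0 - int(5e-3 * fs))
    b0 = float(np.median(x[pre0:win0])) if win0 > pre0 else float(baseline[s])

    stop = n if next_start_idx is None else min(n, next_start_idx)
    stop = min(stop, s + int(max_peak_window_ms * 1e-3 * fs))
    stop = max(stop, min(candidate.end_idx, n))

    seg = x[win0:stop]
    # 3-point median removes single-sample glitches without biasing kinetics
    smoothed = pd.Series(seg).rolling(3, center=True, min_periods=1).median().to_numpy()
    lo_search = s - win0  # peak cannot precede the threshold crossing
    pk_rel = lo_search + int(np.argmin(smoothed[lo_search:]))
    pk = win0 + pk_rel
    half = max(1, int(round(0.25e-3 * fs)))
    amp = float(np.mean(x[max(win0, pk - half):min(stop, pk + half + 1)]) - b0)

    # --- rise phase: walk back from the peak to the 10% and 90% levels
    t = np.arange(win0, stop) / fs
    rel = smoothed - b0
    lo_level, hi_level = 0.1 * amp, 0.9 * amp     # amp < 0
    i90 = pk_rel
    while i90 > 0 and rel[i90 - 1] <= hi_level:
        i90 -= 1
    i10 = i90
    while i10 > 0 and rel[i10 - 1] <= lo_level:
        i10 -= 1
    rise_start = i10
    t90 = _interp_crossing(t, rel, hi_level, i90)
    t10 = _interp_crossing(t, rel, lo_level, i10)
    rise_ms = max(0.0, (t90 - t10) * 1e3)
    onset_time = t10

    # monotonic rise: on the heavier-smoothed rising phase, no upward
    # counter-excursion (drawback) larger than one noise SD
    monotonic = _monotonic_rise(x[win0:stop] - b0, rise_start, pk_rel, fs, noise_sd)

    # --- decay fit: single exponential from the peak toward baseline
    tau_ms, fit_ok = _fit_decay(seg, pk_rel, amp, b0, fs, tau_max_window_ms)

    duration_ms = candidate.n_samples / fs * 1e3
    ev = MiniEvent(
        onset_time_s=onset_time,
        peak_time_s=pk / fs,
        peak_amplitude_pa=amp,
        rise_10_90_ms=rise_ms,
        tau_decay_ms=tau_ms,
        duration_ms=duration_ms,
        monotonic_rise=monotonic,
    )
    if not fit_ok:
        ev.accepted = False
        ev.rejection_reason = "fit_failed"
    return ev


def _monotonic_rise(rel, i0, i1, fs, noise_sd):
    """Monotonicity of the rising phase, with tolerance.

    The raw rise segment is Gaussian-smoothed (sigma 0.25 ms) and scanned
    for the largest counter-excursion away from the peak; a genuine bump
    rises by more than one noise SD, while sample-to-sample noise does
    not.  Literal sample-wise monotonicity would reject every noisy event.
    """
    rising = rel[i0:i1 + 1]
    if len(rising) < 3:
        return True
    from scipy.ndimage import gaussian_filter1d

    sm = gaussian_filter1d(rising, max(1.0, 0.25e-3 * fs), mode="nearest")
    drawback = float(np.max(sm - np.minimum.accumulate(sm)))
    return drawback <= max(noise_sd, 1e-12)


def _fit_decay(seg, pk_rel, amp, b0, fs, tau_max_window_ms):
    """Least-squares single-exponential decay fit; returns (tau_ms, ok)."""
    decay = seg[pk_rel:] - b0
    if len(decay) < 4 or amp >= 0:
        return float("nan"), False
    # initial guess: time to recover to amp/e
    above = np.flatnonzero(decay > amp / np.e)
    tau0 = (above[0] if len(above) else len(decay)) / fs
    tau0 = max(tau0, 2.0 / fs)
    n_fit = int(min(5 * tau0 * fs, tau_max_window_ms * 1e-3 * fs, len(decay)))
    if n_fit < 4:
        return float("nan"), False
    tt = np.arange(n_fit) / fs
    yy = decay[:n_fit]
    try:
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            tt, yy, p0=(amp, tau0),
            bounds=([-np.inf, 1e-5], [0.0, 10.0]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return float("nan"), False
    return float(popt[1] * 1e3), True


def filter_events(
    events: list[MiniEvent],
    amplitude_threshold_pa: float = DEFAULT_AMPLITUDE_THRESHOLD_PA,
    max_rise_ms: float = MAX_RISE_MS,
    max_tau_ms: float = MAX_TAU_MS,
    min_duration_ms: float = MIN_DURATION_MS,
) -> list[MiniEvent]:
    """Apply the selection rules in place; returns the accepted subset.

    Each rejected event carries the first failed rule in
    ``rejection_reason`` (amplitude, duration, non_monotonic_rise, rise,
    decay, or fit_failed from measurement).
    """
    accepted = []
    for ev in events:
        if ev.rejection_reason == "fit_failed":
            continue
        if not ev.peak_amplitude_pa <= amplitude_threshold_pa:
            ev.rejection_reason = "amplitude"
        elif not ev.duration_ms > min_duration_ms:
            ev.rejection_reason = "duration"
        elif not ev.monotonic_rise:
            ev.rejection_reason = "non_monotonic_rise"
        elif not ev.rise_10_90_ms < max_rise_ms:
            ev.rejection_reason = "rise"
        elif not (np.isfinite(ev.tau_decay_ms) and ev.tau_decay_ms < max_tau_ms):
            ev.rejection_reason = "decay"
        else:
            ev.accepted = True
            ev.rejection_reason = ""
            accepted.append(ev)
    return accepted


@dataclass
class MiniSummary:
    frequency_hz: float
    interevent_intervals_s: np.ndarray
    mean_amplitude_pa: float
    amplitude_ecdf: tuple[np.ndarray, np.ndarray]
    interval_ecdf: tuple[np.ndarray, np.ndarray]
    included: bool
    n_accepted: int


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        return v, v
    return v, np.arange(1, len(v) + 1) / len(v)


def summarize_cell(
    accepted: list[MiniEvent],
    duration_s: float,
    min_freq_hz: float = MIN_CELL_FREQ_HZ,
) -> MiniSummary:
    """Cell-level summary over accepted events.

    ``included`` is False when the accepted-event frequency falls below
    ``min_freq_hz`` (default 0.05 Hz) — such cells are omitted from group
    analyses.  Recordings are expected to last at least 2 min.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    times = np.sort([ev.peak_time_s for ev in accepted])
    amps = np.array([ev.peak_amplitude_pa for ev in accepted])
    freq = len(times) / duration_s
    intervals = np.diff(times) if len(times) >= 2 else np.empty(0)
    return MiniSummary(
        frequency_hz=freq,
        interevent_intervals_s=intervals,
        mean_amplitude_pa=float(np.mean(amps)) if len(amps) else float("nan"),
        amplitude_ecdf=_ecdf(-amps),
        interval_ecdf=_ecdf(intervals),
        included=freq >= min_freq_hz,
        n_accepted=len(times),
    )


def analyse_trace(
    trace: CurrentTrace,
    amplitude_threshold_pa: float = DEFAULT_AMPLITUDE_THRESHOLD_PA,
    dead_time_ms: float = DEAD_TIME_MS,
) -> tuple[list[MiniEvent], MiniSummary]:
    """Full per-cell chain: detect, measure, filter, summarise."""
    baseline = rolling_baseline(trace)
    noise_sd = estimate_noise_sd(trace, baseline)
    cands = detect_candidates(trace, amplitude_threshold_pa, dead_time_ms,
                              baseline=baseline)
    events = []
    for i, c in enumerate(cands):
        nxt = cands[i + 1].start_idx if i + 1 < len(cands) else None
        events.append(measure_event(trace, c, baseline, nxt, noise_sd))
    accepted = filter_events(events, amplitude_threshold_pa)
    return events, summarize_cell(accepted, trace.duration_s)


def events_table(events: list[MiniEvent]) -> pd.DataFrame:
    """Per-event DataFrame for CSV export."""
    return pd.DataFrame(
        {
            "onset_time_s": [e.onset_time_s for e in events],
            "peak_time_s": [e.peak_time_s for e in events],
            "peak_amplitude_pA": [e.peak_amplitude_pa for e in events],
            "rise_10_90_ms": [e.rise_10_90_ms for e in events],
            "tau_decay_ms": [e.tau_decay_ms for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "monotonic_rise": [e.monotonic_rise for e in events],
            "accepted": [e.accepted for e in events],
            "rejection_reason": [e.rejection_reason for e in events],
        }
    )
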