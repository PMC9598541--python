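"""Jerk-locked back-averaging of EEG and periodic-discharge interval metrics.

Periodic discharges with motor manifestations (e.g. the stereotyped jerks of
SSPE) produce an EMG burst time-locked to each EEG complex. Averaging EEG
epochs aligned on the EMG onsets ("jerk-locked back-averaging") cancels the
background and reveals the premotor cortical transient; its peak latency
(negative = EEG precedes EMG) and amplitude characterize the cortical event.

EMG onset detection: the channel is high-pass filtered, rectified and
smoothed; bursts are supra-threshold runs (baseline median + k*MAD) of a
minimum duration, separated by a refractory period. Because a threshold
crossing on a rising envelope is systematically late, the onset is refined by
fitting the rising flank and extrapolating back to the baseline level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigurationError, InsufficientEventsError


@dataclass
class PolygraphicRecording:
    """Multichannel EEG + EMG time series (µV) at a fixed sampling rate."""

    data: np.ndarray  # (n_channels, n_samples)
    sfreq: float
    ch_names: list[str]
    eeg_channels: list[str]
    emg_channels: list[str]
    montage: str = "referential"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        for name in list(self.eeg_channels) + list(self.emg_channels):
            if name not in self.ch_names:
                raise ConfigurationError(f"channel {name!r} not in recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]

    def eeg_array(self) -> np.ndarray:
        idx = [self.ch_names.index(n) for n in self.eeg_channels]
        return self.data[idx]

    def to_tsv(self, path) -> None:
        """First column: time (s); remaining columns: channels (µV)."""
        t = np.arange(self.n_samples) / self.sfreq
        frame = pd.DataFrame({"time": t})
        for i, name in enumerate(self.ch_names):
            frame[name] = self.data[i]
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path, emg_prefix: str = "EMG") -> "PolygraphicRecording":
        frame = pd.read_csv(path, sep="\t")
        t = frame["time"].to_numpy()
        if len(t) < 2:
            raise ValueError("time series too short")
        sfreq = 1.0 / float(np.median(np.diff(t)))
        names = [c for c in frame.columns if c != "time"]
        data = frame[names].to_numpy().T
        emg = [n for n in names if n.startswith(emg_prefix)]
        eeg = [n for n in names if n not in emg]
        return cls(data, sfreq, names, eeg, emg)

    @classmethod
    def from_edf(cls, path, emg_prefix: str = "EMG") -> "PolygraphicRecording":
        """Read an EDF recording (requires the optional mne dependency)."""
        import mne  # local import: EDF support is optional

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> µV
        names = list(raw.ch_names)
        emg = [n for n in names if n.upper().startswith(emg_prefix.upper())]
        eeg = [n for n in names if n not in emg]
        return cls(data, float(raw.info["sfreq"]), names, eeg, emg)


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Re-reference channels to their instantaneous mean (zero-sum montage)."""
    eeg = np.asarray(eeg, dtype=float)
    return eeg - eeg.mean(axis=0, keepdims=True)


def detect_emg_onsets(
    emg: np.ndarray,
    sfreq: float,
    *,
    highpass_hz: float = 20.0,
    k_mad: float = 5.0,
    refractory_s: float = 0.5,
    min_duration_s: float = 0.03,
    smooth_s: float = 0.02,
) -> np.ndarray:
    """Detect EMG burst onsets; returns strictly increasing times in seconds.

    A flat (or event-free) channel yields an empty array, not an error.
    """
    emg = np.asarray(emg, dtype=float)
    if not np.all(np.isfinite(emg)):
        raise ValueError("EMG contains non-finite samples")
    if emg.size == 0 or np.ptp(emg) == 0:
        return np.array([])

    nyq = sfreq / 2
    if 0 < highpass_hz < nyq:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=sfreq, output="sos")
        filtered = signal.sosfiltfilt(sos, emg)
    else:
        filtered = emg - emg.mean()
    rect = np.abs(filtered)
    win = max(1, int(round(smooth_s * sfreq)))
    # causal moving average: env[t] sees only past samples, so a burst can
    # never raise the envelope before its true onset
    env = np.convolve(rect, np.ones(win) / win)[: rect.size] if win > 1 else rect

    baseline = float(np.median(env))
    mad = float(np.median(np.abs(env - baseline)))
    # floor the scale at a fraction of the dynamic range: with (near-)zero
    # background the MAD collapses to filter round-off and everything fires
    scale = max(mad, 0.01 * (float(env.max()) - baseline))
    if scale <= 0:
        return np.array([])
    threshold = baseline + k_mad * scale

    above = env > threshold
    if not above.any():
        return np.array([])
    idx = np.flatnonzero(above)
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]

    # merge runs separated by brief sub-threshold dips (the noise-like EMG
    # carrier fragments one burst into several runs); the duration criterion
    # counts supra-threshold samples only, so merging cannot inflate it
    merge_gap = int(round(0.1 * sfreq))
    merged: list[list[int]] = []  # [start, end, n_above]
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = int(e)
            merged[-1][2] += int(e - s + 1)
        else:
            merged.append([int(s), int(e), int(e - s + 1)])

    min_len = int(round(min_duration_s * sfreq))
    refractory = int(round(refractory_s * sfreq))

    # robust background sd of the rectified signal (bursts are sparse)
    sigma0 = max(float(np.median(rect)) / 0.6745, 1e-6 * float(env.max()))

    onsets: list[int] = []
    for s, e, n_above in merged:
        if n_above < min_len:
            continue
        anchor = _flank_anchor(env, s, e, baseline, threshold)
        onset = _refine_onset(filtered, env, anchor, sfreq, sigma0)
        if onsets and onset - onsets[-1] < refractory:
            continue
        onsets.append(onset)
    return np.asarray(onsets, dtype=float) / sfreq


def _flank_anchor(env: np.ndarray, start: int, end: int, baseline: float,
                  threshold: float) -> int:
    """Coarse onset anchor: fit the envelope's rising flank (up to 60% of the
    burst peak) and extrapolate the line back to envelope zero."""
    seg = env[start : end + 1]
    peak = float(seg.max())
    hits = np.flatnonzero(seg >= baseline + 0.6 * (peak - baseline))
    t2 = start + (int(hits[0]) if hits.size else len(seg) - 1)
    if t2 - start < 2:
        return start
    x = np.arange(start, t2 + 1, dtype=float)
    slope, intercept = np.polyfit(x, env[start : t2 + 1], 1)
    if slope <= 0:
        return start
    onset = -intercept / slope
    return int(np.clip(round(onset), start - 2 * (t2 - start), start))


def _refine_onset(filtered: np.ndarray, env: np.ndarray, s: int, sfreq: float,
                  sigma0: float) -> int:
    """Localize the burst onset by a variance-ramp likelihood scan.

    A threshold crossing is systematically late on a ramping (diamond)
    envelope. The high-passed signal around the coarse crossing ``s`` is
    modeled as zero-mean Gaussian whose sd ramps linearly from the background
    ``sigma0`` to the burst amplitude over a rise time; onset time and rise
    time are scanned on a grid and the maximum-likelihood onset is returned.
    The burst amplitude is calibrated from the smoothed-envelope peak.
    """
    a = max(0, s - int(0.03 * sfreq))
    b = min(filtered.size, s + int(0.06 * sfreq))
    if b - a < 10:
        return s
    x2 = filtered[a:b] ** 2
    peak = float(env[s : min(env.size, s + int(0.2 * sfreq))].max())
    amplitude = peak / 0.8
    # keep the background sd bounded away from zero: with silent backgrounds
    # the likelihood would otherwise reward stretching a near-zero-variance
    # ramp across the silent samples, dragging the onset early
    sigma0 = max(sigma0, 0.02 * amplitude)
    idx = np.arange(a, b)
    t_hi = min(b - 5, s + int(0.02 * sfreq))
    best_ll, best_t = np.inf, s
    for rise_s in (0.005, 0.01, 0.02, 0.04):
        r = max(2, int(rise_s * sfreq))
        for t in range(a + 2, t_hi):
            ramp = np.clip((idx - t) / r, 0.0, 1.0)
            var = sigma0**2 + (amplitude * ramp) ** 2
            ll = float(np.sum(np.log(var) + x2 / var))
            if ll < best_ll:
                best_ll, best_t = ll, t
    # abrupt-onset hypothesis: a hard variance step (burst energy from sample
    # t onward) near the ramp optimum; wins decisively for square bursts,
    # where the ramp family would place the onset one or two samples early.
    # A clear margin is required so noise on ramping bursts cannot flip it.
    margin = 5.0
    step_ll, step_t = np.inf, best_t
    for t in range(best_t, min(best_t + 4, t_hi)):
        var = np.where(idx >= t, sigma0**2 + amplitude**2, sigma0**2)
        ll = float(np.sum(np.log(var) + x2 / var))
        if ll < step_ll:
            step_ll, step_t = ll, t
    if step_ll < best_ll - margin:
        best_t = step_t
    return best_t


@dataclass
class JerkLockedAverage:
    """Channel x time average of EEG epochs locked to EMG onsets.

    ``times`` are seconds relative to EMG onset (t = 0). Peak amplitude and
    latency are per channel, measured as the signed extremum of largest
    magnitude inside the peak-search window; latency is negative when the
    EEG transient precedes the EMG onset.
    """

    data: np.ndarray  # (n_channels, n_times)
    times: np.ndarray  # seconds, contains 0
    ch_names: list[str]
    n_events: int
    peak_window: tuple[float, float] = (-0.2, 0.0)
    peak_amplitude_uv: np.ndarray = field(default=None)
    peak_latency_ms: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.peak_amplitude_uv is None or self.peak_latency_ms is None:
            amp, lat = self.compute_peaks()
            self.peak_amplitude_uv = amp
            self.peak_latency_ms = lat

    def compute_peaks(self) -> tuple[np.ndarray, np.ndarray]:
        sel = (self.times >= self.peak_window[0]) & (self.times <= self.peak_window[1])
        window = self.data[:, sel]
        idx = np.argmax(np.abs(window), axis=1)
        amplitude = window[np.arange(window.shape[0]), idx]
        latency_ms = self.times[sel][idx] * 1000.0
        return amplitude, latency_ms

    def channel_peak(self, name: str) -> tuple[float, float]:
        i = self.ch_names.index(name)
        return float(self.peak_amplitude_uv[i]), float(self.peak_latency_ms[i])

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(self.data.T, columns=self.ch_names)
        frame.insert(0, "time", self.times)
        frame.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def summary(self) -> dict:
        return {
            "n_events": self.n_events,
            "channels": {
                name: {
                    "peak_uv": float(self.peak_amplitude_uv[i]),
                    "latency_ms": float(self.peak_latency_ms[i]),
                }
                for i, name in enumerate(self.ch_names)
            },
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def back_average(
    rec: PolygraphicRecording,
    onsets,
    window: tuple[float, float] = (-0.5, 0.5),
    *,
    baseline: tuple[float, float] = (-0.5, -0.3),
    peak_window: tuple[float, float] = (-0.2, 0.0),
    reref: str | None = "common_average",
) -> JerkLockedAverage:
    """Average EEG epochs locked to the given EMG onset times (seconds).

    EEG is re-referenced to the common average first (``reref=None`` keeps
    the stored montage), each epoch is baseline-corrected by the mean of its
    pre-event baseline segment, and epochs whose window extends outside the
    recording are dropped.
    """
    if window[0] >= 0 or window[1] <= 0:
        raise ValueError("epoch window must contain t=0")
    eeg = rec.eeg_array()
    if reref == "common_average":
        eeg = common_average_reference(eeg)
    elif reref is not None:
        raise ConfigurationError(f"unknown re-reference {reref!r}")

    sf = rec.sfreq
    lo = int(round(window[0] * sf))
    hi = int(round(window[1] * sf))
    times = np.arange(lo, hi + 1) / sf

    epochs = []
    for t in np.atleast_1d(np.asarray(onsets, dtype=float)):
        center = int(round(t * sf))
        start, stop = center + lo, center + hi + 1
        if start < 0 or stop > rec.n_samples:
            continue
        epochs.append(eeg[:, start:stop])
    if not epochs:
        raise InsufficientEventsError("no onset has a full epoch inside the recording")
    stack = np.stack(epochs)  # (n_events, n_ch, n_times)

    bl = (times >= baseline[0]) & (times <= baseline[1])
    if bl.any():
        stack = stack - stack[:, :, bl].mean(axis=2, keepdims=True)
    avg = stack.mean(axis=0)
    return JerkLockedAverage(
        data=avg,
        times=times,
        ch_names=list(rec.eeg_channels),
        n_events=stack.shape[0],
        peak_window=peak_window,
    )


def interdischarge_intervals(onsets) -> dict:
    """Summary of successive complex-to-complex intervals (seconds)."""
    onsets = np.sort(np.asarray(onsets, dtype=float))
    if onsets.size < 2:
        raise InsufficientEventsError("need at least 2 onsets to form intervals")
    intervals = np.diff(onsets)
    q1, q3 = np.percentile(intervals, [25, 75])
    return {
        "n_intervals": int(intervals.size),
        "median_s": float(np.median(intervals)),
        "iqr_s": float(q3 - q1),
        "min_s": float(intervals.min()),
        "max_s": float(intervals.max()),
        "intervals_s": intervals,
    }
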