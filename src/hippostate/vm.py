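"""Whole-cell membrane-potential preprocessing and decomposition.

The broadband V_m trace is reduced to a subthreshold signal by detecting
action potentials (local maxima with prominence >= 15 mV and width <= 10 ms)
and linearly interpolating over a window from 3 ms before to 5 ms after each
spike peak.  The subthreshold signal is low-pass filtered with a
Parks-McClellan equiripple FIR (250-350 Hz transition band), applied
zero-phase, and resampled to 2083 Hz.  It is then split into three additive
components:

* ``slow``  — running 1 s median, detrended;
* ``fast``  — residual above the running median (>~1 Hz content);
* ``drift`` — 60 s boxcar of the running median (resting potential and
  minutes-scale trends).

By construction ``fast + slow + drift`` reconstructs the subthreshold V_m
exactly at every sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .csd import median_filter_1s

__all__ = [
    "VmComponents",
    "CellQC",
    "detect_spikes",
    "interpolate_spikes",
    "lowpass_downsample",
    "decompose_vm",
    "spike_threshold",
    "qc_cell",
]

TARGET_FS = 2083.0
SPIKE_PROMINENCE_MV = 15.0
SPIKE_MAX_WIDTH_MS = 10.0
INTERP_PRE_MS = 3.0
INTERP_POST_MS = 5.0
QC_THRESHOLD_MV = -37.0


@dataclass
class VmComponents:
    fast: np.ndarray
    slow: np.ndarray
    drift: np.ndarray
    fs: float
    spike_times: np.ndarray
    edge_truncated: bool = False

    @property
    def total(self) -> np.ndarray:
        return self.fast + self.slow + self.drift


@dataclass
class CellQC:
    spike_threshold_mv: float | None
    included: bool


def detect_spikes(vm_broadband: np.ndarray, fs: float) -> np.ndarray:
    """Spike peak times (s): prominence >= 15 mV, width <= 10 ms."""
    vm_broadband = np.asarray(vm_broadband, dtype=float)
    if vm_broadband.size == 0:
        return np.array([])
    max_width = SPIKE_MAX_WIDTH_MS * 1e-3 * fs
    peaks, _ = sps.find_peaks(
        vm_broadband, prominence=SPIKE_PROMINENCE_MV, width=(None, max_width)
    )
    return peaks / fs


def _merged_windows(spike_times: np.ndarray, fs: float, n: int):
    """Interpolation windows [t-3ms, t+5ms] in samples, overlapping merged."""
    pre = int(round(INTERP_PRE_MS * 1e-3 * fs))
    post = int(round(INTERP_POST_MS * 1e-3 * fs))
    idx = np.sort(np.round(np.asarray(spike_times, dtype=float) * fs).astype(int))
    windows: list[list[int]] = []
    for i in idx:
        if i < 0 or i >= n:
            raise ValueError("spike time outside trace")
        lo, hi = max(i - pre, 0), min(i + post, n - 1)
        if windows and lo <= windows[-1][1] + 1:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    return windows


def interpolate_spikes(vm: np.ndarray, spike_times: np.ndarray, fs: float) -> np.ndarray:
    """Replace each (merged) spike window by a straight line between its ends."""
    out = np.array(vm, dtype=float, copy=True)
    if len(np.atleast_1d(spike_times)) == 0:
        return out
    for lo, hi in _merged_windows(np.atleast_1d(spike_times), fs, len(out)):
        a = out[lo - 1] if lo > 0 else out[hi + 1] if hi + 1 < len(out) else out[lo]
        b = out[hi + 1] if hi + 1 < len(out) else a
        out[lo : hi + 1] = np.linspace(a, b, hi - lo + 3)[1:-1]
    return out


@lru_cache(maxsize=8)
def _pm_lowpass(fs_in: float) -> np.ndarray:
    # Parks-McClellan equiripple design, 250-350 Hz transition band.
    numtaps = int(3.3 * fs_in / 100.0) | 1
    return sps.remez(numtaps, [0, 250, 350, fs_in / 2], [1, 0], fs=fs_in)


def lowpass_downsample(
    vm_sub: np.ndarray, fs_in: float, fs_out: float = TARGET_FS
) -> np.ndarray:
    """Zero-phase equiripple low-pass then resample onto the fs_out grid."""
    if fs_in <= 2 * TARGET_FS:
        raise ValueError(f"fs_in={fs_in} too low; need > {2 * TARGET_FS:.0f} Hz")
    taps = _pm_lowpass(float(fs_in))
    filtered = sps.filtfilt(taps, [1.0], np.asarray(vm_sub, dtype=float))
    duration = len(filtered) / fs_in
    t_out = np.arange(0.0, duration - 0.5 / fs_in, 1.0 / fs_out)
    t_in = np.arange(len(filtered)) / fs_in
    return np.interp(t_out, t_in, filtered)


def decompose_vm(
    vm_sub: np.ndarray,
    fs: float = TARGET_FS,
    spike_times: np.ndarray | None = None,
    median_window_s: float = 1.0,
    boxcar_s: float = 60.0,
) -> VmComponents:
    """Split subthreshold V_m into fast, slow (detrended) and drift parts."""
    vm_sub = np.asarray(vm_sub, dtype=float)
    slow_raw = median_filter_1s(vm_sub, fs, median_window_s)
    fast = vm_sub - slow_raw
    box = int(round(boxcar_s * fs))
    truncated = box > len(vm_sub)
    box = min(box, len(vm_sub))
    drift = uniform_filter1d(slow_raw, size=max(box, 1), mode="reflect")
    slow = slow_raw - drift
    spikes = np.array([]) if spike_times is None else np.asarray(spike_times, float)
    return VmComponents(
        fast=fast, slow=slow, drift=drift, fs=fs, spike_times=spikes,
        edge_truncated=truncated,
    )


def spike_threshold(
    vm_broadband: np.ndarray, fs: float, spike_times: np.ndarray, lookback_ms: float = 3.0
) -> float | None:
    """Median spike threshold: V_m at the maximum of the second derivative
    in the window preceding each spike peak."""
    spike_times = np.atleast_1d(spike_times)
    if spike_times.size == 0:
        return None
    look = int(round(lookback_ms * 1e-3 * fs))
    d2 = np.diff(vm_broadband, 2)
    thresholds = []
    for t in spike_times:
        i = int(round(t * fs))
        lo = max(i - look, 1)
        if i - 1 <= lo:
            continue
        j = lo + int(np.argmax(d2[lo - 1 : i - 1]))
        thresholds.append(vm_broadband[j])
    return float(np.median(thresholds)) if thresholds else None


def qc_cell(threshold_mv: float | None) -> CellQC:
    """Exclude cells whose spike threshold exceeds -37 mV (strictly above)."""
    if threshold_mv is None:
        return CellQC(spike_threshold_mv=None, included=True)
    return CellQC(
        spike_threshold_mv=float(threshold_mv), included=threshold_mv <= QC_THRESHOLD_MV
    )
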