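"""Sharp-wave-ripple detection from the CA1 pyramidal-layer LFP.

Ripple power is the square root of the 80-250 Hz band-passed LFP squared and
smoothed with a 10 ms Gaussian kernel.  Candidate events are segments more
than 3 SD above the session mean power; segments closer than 55 ms are
merged, merged segments shorter than 20 ms are rejected, and events that are
simultaneously detected on a reference channel (a site away from the CA1
cell layer that carries no ripples) are discarded as artifacts.

Sharp-wave size is the peak magnitude of the stratum-radiatum sink within
[onset - 50 ms, offset]; a per-session median (optionally mean) split
divides events into big and small classes, and events closer than a
configurable gap (default 200 ms) to a neighbour are labelled doublet
members rather than isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "RippleEvent",
    "ripple_power",
    "detect_ripples",
    "spw_size",
    "attach_spw_sizes",
    "split_big_small",
    "classify_isolation",
]

MERGE_GAP_S = 0.055
MIN_DURATION_S = 0.020
THRESHOLD_SD = 3.0


@dataclass(frozen=True)
class RippleEvent:
    onset_s: float
    offset_s: float
    peak_power_z: float
    spw_amplitude: float | None = None
    size_class: str | None = None  # {"big", "small"}
    isolation: str | None = None  # {"isolated", "doublet_member"}

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def ripple_power(
    lfp_channel: np.ndarray,
    fs: float,
    band: tuple[float, float] = (80.0, 250.0),
    smooth_ms: float = 10.0,
) -> np.ndarray:
    """Band-passed, squared, Gaussian-smoothed, square-rooted power envelope."""
    if fs < 2 * band[1]:
        raise ValueError(f"fs={fs} below Nyquist for the {band} Hz band")
    numtaps = int(4 * fs / band[0]) | 1
    taps = sps.firwin(numtaps, band, pass_zero=False, fs=fs)
    filtered = sps.filtfilt(taps, [1.0], np.asarray(lfp_channel, dtype=float))
    smoothed = gaussian_filter1d(filtered**2, sigma=smooth_ms * 1e-3 * fs)
    return np.sqrt(np.maximum(smoothed, 0.0))


def _supra_segments(power: np.ndarray, fs: float, threshold_sd: float):
    """Supra-threshold segments after the merge and minimum-length rules."""
    mu, sd = power.mean(), power.std()
    if sd == 0:
        return [], mu, sd
    above = power > mu + threshold_sd * sd
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    merged: list[list[int]] = []
    for s, e in zip(starts, stops):
        if merged and (s - merged[-1][1]) / fs < MERGE_GAP_S:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if (e - s) / fs >= MIN_DURATION_S]
    return kept, mu, sd


def detect_ripples(
    power: np.ndarray,
    ref_power: np.ndarray | None,
    fs: float,
    threshold_sd: float = THRESHOLD_SD,
) -> list[RippleEvent]:
    """Threshold, merge, length-filter and reference-reject ripple events."""
    power = np.asarray(power, dtype=float)
    if not np.any(np.isfinite(power)):
        raise ValueError("power trace is all-NaN")
    segs, mu, sd = _supra_segments(power, fs, threshold_sd)
    ref_segs = []
    if ref_power is not None:
        ref_segs, _, _ = _supra_segments(np.asarray(ref_power, float), fs, threshold_sd)
    events = []
    for s, e in segs:
        if any(s < re and rs < e for rs, re in ref_segs):
            continue  # artifact: any temporal intersection with a reference event
        peak_z = (power[s:e].max() - mu) / sd
        events.append(RippleEvent(onset_s=s / fs, offset_s=e / fs, peak_power_z=peak_z))
    return events


def spw_size(
    radiatum_trace: np.ndarray,
    fs: float,
    event: RippleEvent,
    pre_s: float = 0.050,
) -> float:
    """Peak magnitude of the radiatum sink in [onset - 50 ms, offset].

    The sink appears as a negative deflection relative to the session median
    of the supplied (LFP or CSD row) trace; a flat trace gives 0.
    """
    lo = int(round((event.onset_s - pre_s) * fs))
    hi = int(round(event.offset_s * fs))
    if hi <= 0 or lo >= len(radiatum_trace):
        raise ValueError("event lies outside the trace")
    lo = max(lo, 0)
    deflection = np.median(radiatum_trace) - np.asarray(radiatum_trace[lo:hi], float)
    return float(max(deflection.max(), 0.0))


def attach_spw_sizes(
    events: list[RippleEvent], radiatum_trace: np.ndarray, fs: float
) -> list[RippleEvent]:
    return [
        replace(ev, spw_amplitude=spw_size(radiatum_trace, fs, ev)) for ev in events
    ]


def split_big_small(
    events: list[RippleEvent], statistic: str = "median"
) -> list[RippleEvent]:
    """Median (or mean) split of events by sharp-wave amplitude."""
    amps = np.array([ev.spw_amplitude for ev in events], dtype=float)
    if np.any(np.isnan(amps)):
        raise ValueError("all events need spw_amplitude before splitting")
    if statistic == "median":
        cut = np.median(amps)
    elif statistic == "mean":
        cut = amps.mean()
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    return [
        replace(ev, size_class="big" if a > cut else "small")
        for ev, a in zip(events, amps)
    ]


def classify_isolation(
    events: list[RippleEvent], gap_ms: float = 200.0
) -> list[RippleEvent]:
    """Label events with a neighbour onset closer than ``gap_ms`` as doublets."""
    onsets = np.array([ev.onset_s for ev in events])
    if np.any(np.diff(onsets) < 0):
        raise ValueError("events must be time-sorted")
    gap = gap_ms * 1e-3
    out = []
    for i, ev in enumerate(events):
        near = (i > 0 and onsets[i] - onsets[i - 1] < gap) or (
            i + 1 < len(onsets) and onsets[i + 1] - onsets[i] < gap
        )
        out.append(replace(ev, isolation="doublet_member" if near else "isolated"))
    return out
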