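"""Unsupervised UP/DOWN state segmentation of DG CSD activity.

A two-component Gaussian mixture fitted to the activity distribution
initialises the emission densities of a two-state hidden Markov model whose
transition and emission parameters are then re-estimated from the data
(Baum-Welch).  The most likely state path is decoded with the Viterbi
algorithm on the activity anti-alias-downsampled to 4 Hz; the component with
the higher mean is labelled UP.  Each time point is then assigned a circular
UDS phase: UP epochs map linearly onto [0, pi] (0 at the DOWN->UP
transition) and DOWN epochs onto [pi, 2*pi].

The procedure is deterministic given the data: EM starts from the mixture
fit and no random restarts are used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import signal as sps
from sklearn.mixture import GaussianMixture

__all__ = [
    "Gmm2Fit",
    "UdsSegmentation",
    "UdsSegmenter",
    "fit_gmm2",
    "segment_uds",
    "phase_of",
    "event_phase_density",
    "transition_triggered",
]

FRAME_RATE_HZ = 4.0
UP, DOWN = 1, 0


@dataclass
class Gmm2Fit:
    means: np.ndarray  # (2,)
    sds: np.ndarray
    weights: np.ndarray
    up_component: int
    weak_bimodality: bool


@dataclass
class UdsSegmentation:
    """Viterbi state path at 4 Hz with epochs, transitions and phase support.

    ``epochs`` has columns (state, t_start_s, t_stop_s); boundary epochs are
    clipped at the trace edges, which act as pseudo-transitions for the phase
    map.  ``transition_times_s``/``transition_kinds`` list only the interior,
    genuine transitions ("DU" for DOWN->UP, "UD" for UP->DOWN).
    """

    frame_states: np.ndarray
    frame_rate: float
    epochs: pd.DataFrame
    transition_times_s: np.ndarray
    transition_kinds: np.ndarray
    gmm: Gmm2Fit | None = None

    @property
    def duration_s(self) -> float:
        return len(self.frame_states) / self.frame_rate

    def epoch_durations(self, state: int) -> np.ndarray:
        """Durations of interior (fully-bounded) epochs of a state."""
        df = self.epochs.iloc[1:-1] if len(self.epochs) > 2 else self.epochs
        sel = df[df.state == state]
        return (sel.t_stop_s - sel.t_start_s).to_numpy()

    def state_at(self, times_s: np.ndarray) -> np.ndarray:
        idx = np.clip(
            (np.asarray(times_s) * self.frame_rate).astype(int),
            0,
            len(self.frame_states) - 1,
        )
        return self.frame_states[idx]


def fit_gmm2(activity: np.ndarray, min_samples: int = 1000) -> Gmm2Fit:
    """EM fit of a two-component Gaussian mixture; UP = higher-mean component."""
    x = np.asarray(activity, dtype=float).reshape(-1, 1)
    if len(x) < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {len(x)}")
    q25, q75 = np.percentile(x, [25, 75])
    gm = GaussianMixture(
        n_components=2,
        means_init=[[q25], [q75]],
        n_init=1,
        random_state=0,
        max_iter=500,
    ).fit(x)
    if not gm.converged_:
        raise RuntimeError(
            f"GMM EM did not converge (lower bound {gm.lower_bound_:.4g})"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    pooled = np.sqrt(np.average(sds**2, weights=gm.weights_))
    return Gmm2Fit(
        means=means,
        sds=sds,
        weights=gm.weights_.copy(),
        up_component=int(np.argmax(means)),
        weak_bimodality=bool(abs(means[1] - means[0]) < pooled),
    )


def _downsample_to_frames(activity: np.ndarray, fs: float, frame_rate: float):
    """Anti-alias downsampling by per-frame averaging (integrate-and-dump).

    Frame-local averaging suppresses out-of-band noise without smearing
    state transitions beyond one frame, which a long FIR would do.
    """
    if fs < frame_rate:
        raise ValueError("activity rate below the 4 Hz frame rate")
    x = np.asarray(activity, dtype=float)
    if fs == frame_rate:
        return x
    n_frames = int(len(x) / fs * frame_rate)
    idx = np.minimum((np.arange(len(x)) / fs * frame_rate).astype(int), n_frames - 1)
    sums = np.bincount(idx, weights=x, minlength=n_frames)
    counts = np.bincount(idx, minlength=n_frames)
    return sums / np.maximum(counts, 1)


def _epochs_from_path(path: np.ndarray, frame_rate: float):
    change = np.nonzero(np.diff(path) != 0)[0]
    bounds = np.concatenate(([0], change + 1, [len(path)]))
    rows = [
        (int(path[bounds[i]]), bounds[i] / frame_rate, bounds[i + 1] / frame_rate)
        for i in range(len(bounds) - 1)
    ]
    epochs = pd.DataFrame(rows, columns=["state", "t_start_s", "t_stop_s"])
    t_trans = bounds[1:-1] / frame_rate
    kinds = np.array(
        ["DU" if path[i] == UP else "UD" for i in change + 1], dtype=object
    )
    return epochs, t_trans, kinds


def segment_uds(
    activity: np.ndarray,
    fs: float,
    frame_rate: float = FRAME_RATE_HZ,
    n_iter: int = 200,
) -> UdsSegmentation:
    """GMM-initialised two-state Gaussian HMM segmentation at 4 Hz."""
    activity = np.asarray(activity, dtype=float)
    if len(activity) / fs < 60:
        raise ValueError("need at least 60 s of activity")
    frames = _downsample_to_frames(activity, fs, frame_rate)
    if np.ptp(frames) == 0:
        path = np.zeros(len(frames), dtype=int)
        epochs, t_trans, kinds = _epochs_from_path(path, frame_rate)
        warnings.warn("constant activity: single-state segmentation")
        return UdsSegmentation(path, frame_rate, epochs, t_trans, kinds, None)
    gmm = fit_gmm2(frames, min_samples=2)
    order = np.argsort(gmm.means)  # component 0 = DOWN, 1 = UP
    hmm = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        init_params="",
        params="stmc",
        n_iter=n_iter,
        tol=1e-4,
        random_state=0,
    )
    hmm.startprob_ = np.array([0.5, 0.5])
    hmm.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    hmm.means_ = gmm.means[order].reshape(-1, 1)
    hmm.covars_ = np.maximum(gmm.sds[order] ** 2, 1e-6).reshape(-1, 1)
    obs = frames.reshape(-1, 1)
    monitor_log = logging.getLogger("hmmlearn.base")
    old_level = monitor_log.level
    monitor_log.setLevel(logging.ERROR)  # monitor chatter at EM convergence
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hmm.fit(obs)
            path = hmm.predict(obs)
    finally:
        monitor_log.setLevel(old_level)
    if hmm.means_[1, 0] < hmm.means_[0, 0]:  # keep UP = higher emission mean
        path = 1 - path
    epochs, t_trans, kinds = _epochs_from_path(path, frame_rate)
    if len(t_trans) == 0:
        warnings.warn("Viterbi path is entirely one state: zero transitions")
    return UdsSegmentation(
        frame_states=path,
        frame_rate=frame_rate,
        epochs=epochs,
        transition_times_s=t_trans,
        transition_kinds=kinds,
        gmm=gmm,
    )


def segmentation_from_epochs(
    epochs: pd.DataFrame, frame_rate: float = FRAME_RATE_HZ
) -> UdsSegmentation:
    """Build a segmentation directly from a known epoch table.

    Used with generator ground truth to exercise phase- and state-based
    statistics without running the HMM.
    """
    duration = float(epochs.t_stop_s.iloc[-1])
    n = int(round(duration * frame_rate))
    t = (np.arange(n) + 0.5) / frame_rate
    stops = epochs.t_stop_s.to_numpy()
    states = epochs.state.to_numpy()
    k = np.clip(np.searchsorted(stops, t, side="right"), 0, len(states) - 1)
    path = states[k].astype(int)
    eps, t_trans, kinds = _epochs_from_path(path, frame_rate)
    return UdsSegmentation(path, frame_rate, eps, t_trans, kinds, None)


def phase_of(times_s: np.ndarray, seg: UdsSegmentation) -> np.ndarray:
    """Circular UDS phase of each time: UP->[0,pi), DOWN->[pi,2*pi).

    Boundary epochs use the trace edges as pseudo-transition times.
    """
    times = np.atleast_1d(np.asarray(times_s, dtype=float))
    if np.any(times < 0) or np.any(times > seg.duration_s):
        raise ValueError("times outside the segmented span")
    starts = seg.epochs.t_start_s.to_numpy()
    stops = seg.epochs.t_stop_s.to_numpy()
    states = seg.epochs.state.to_numpy()
    k = np.clip(np.searchsorted(stops, times, side="right"), 0, len(starts) - 1)
    frac = (times - starts[k]) / np.maximum(stops[k] - starts[k], 1e-12)
    frac = np.clip(frac, 0.0, 1.0 - 1e-12)
    phase = np.where(states[k] == UP, frac * np.pi, np.pi + frac * np.pi)
    return phase if np.ndim(times_s) else float(phase[0])


def event_phase_density(
    event_times: np.ndarray, seg: UdsSegmentation, n_bins: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy-corrected density of events over UDS phase.

    Returns ``(bin_centers, density)`` normalised so that the integral over
    one cycle is 1.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events")
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    ev_phase = phase_of(event_times, seg)
    counts, _ = np.histogram(ev_phase, bins=edges)
    # occupancy: time spent in each phase bin, sampled on the frame grid
    t = (np.arange(int(seg.duration_s * seg.frame_rate * 4)) + 0.5) / (
        seg.frame_rate * 4
    )
    occ, _ = np.histogram(phase_of(t, seg), bins=edges)
    occ_time = occ / (seg.frame_rate * 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_time > 0, counts / occ_time, 0.0)
    width = edges[1] - edges[0]
    density = rate / (rate.sum() * width) if rate.sum() > 0 else rate
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def transition_triggered(
    signal: np.ndarray,
    fs: float,
    seg: UdsSegmentation,
    direction: str = "DU",
    window_s: tuple[float, float] = (-2.0, 2.0),
):
    """Average of a signal around DOWN->UP ("DU") or UP->DOWN ("UD") transitions."""
    from .events import triggered_average

    times = seg.transition_times_s[seg.transition_kinds == direction]
    return triggered_average(signal, fs, times, window_s)


class UdsSegmenter:
    """Model-style wrapper: ``UdsSegmenter(activity, fs).fit()`` -> segmentation."""

    def __init__(self, activity: np.ndarray, fs: float):
        self.activity = np.asarray(activity, dtype=float)
        self.fs = fs

    def fit(self, **kwargs) -> UdsSegmentation:
        return segment_uds(self.activity, self.fs, **kwargs)
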