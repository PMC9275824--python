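"""Ground-truth-annotated synthetic recording sessions.

The generator emulates the statistical structure the analysis pipeline
assumes: entorhinal input to the dentate gyrus alternates between UP and
DOWN states with exponentially distributed epoch durations; DG
molecular-layer synaptic events (biexponential current dipoles,
forward-projected through the same spline iCSD model used for estimation)
arrive at a state-dependent Poisson rate; CA1 pyramidal-layer ripple bursts
with radiatum sharp waves occur only in UP states; each cell's slow V_m is
the convolution of a ground-truth subfield kernel with the session's true
CSD-activity signal, plus peri-ripple fast-V_m templates, Gaussian noise
and stereotyped spikes drawn from an inhomogeneous Poisson process whose
rate increases exponentially with the subthreshold V_m; the pupil relaxes
toward a state-dependent set point (dilating in DOWN, constricting through
UP) and blinks occur only in DOWN states.

All randomness flows from one seed through ``numpy.random.SeedSequence``
substreams, spawned in a fixed order (uds, events, ripples, lfp noise, one
per cell, pupil), so components are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csd import ProbeGeometry, forward_matrix, median_filter_1s

__all__ = [
    "KernelSpec",
    "SyntheticConfig",
    "SyntheticSession",
    "SessionTruth",
    "generate_uds_truth",
    "generate_activity_trace",
    "generate_session",
    "kernel_on_grid",
]

MIN_EPOCH_S = 0.25  # one 4 Hz HMM frame
UP, DOWN = 1, 0


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian-bump impulse response ``gain * exp(-(lag-peak)^2 / 2 sigma^2)``,
    in mV s^-1 per activity-z (sustained unit input gives gain * sigma * sqrt(2 pi) mV)."""

    peak_lag_s: float
    sigma_s: float
    gain_mv_per_z: float


def _default_kernels():
    # extremum lags match the subfield medians the analysis should recover
    return {
        "DG": KernelSpec(0.037, 0.15, 4.0),
        "CA3": KernelSpec(0.296, 0.20, -4.0),
        "CA1": KernelSpec(-0.225, 0.15, 3.0),
    }


def _default_templates():
    # peri-ripple fast-V_m bumps: (lag_s, sigma_s, amp_mv)
    return {
        "DG": ((-0.100, 0.025, 1.5), (0.030, 0.020, 2.0)),
        "CA3": ((0.100, 0.040, -2.0),),
        "CA1": ((-0.100, 0.025, 1.0), (0.020, 0.015, 2.5)),
    }


@dataclass
class SyntheticConfig:
    duration_s: float = 120.0
    fs_lfp: float = 2000.0
    fs_vm: float = 20000.0
    fs_activity: float = 250.0
    fs_pupil: float = 20.0
    n_channels: int = 32
    channel_spacing_um: float = 100.0
    up_mean_s: float = 3.06
    down_mean_s: float = 3.25
    event_rate_up: float = 25.0
    event_rate_down: float = 4.0
    event_lfp_mv: float = 0.3
    ripple_rate_up: float = 0.4
    ripple_ramp_tau_s: float = 0.5  # rate ramps up through the UP state
    ripple_freq_hz: float = 150.0
    ripple_amp_mv: float = 0.4
    ripple_duration_s: float = 0.07
    spw_median_mv: float = 0.4
    subfield_kernels: dict = field(default_factory=_default_kernels)
    ripple_templates: dict = field(default_factory=_default_templates)
    cells: dict = field(default_factory=lambda: {"dg0": "DG", "ca3_0": "CA3", "ca1_0": "CA1"})
    noise_sd_mv: float = 0.3
    lfp_noise_sd_mv: float = 0.03
    vrest_mv: float = -60.0
    spike_rate0_hz: float = 1.0
    spike_dv_mv: float = 2.0
    spike_amp_mv: float = 60.0
    pupil_set_down: float = 1.4
    pupil_set_up: float = 0.7
    pupil_tau_s: float = 1.0
    blink_rate_down: float = 0.3
    seed: int = 0
    # probe layout (channel indices): CA1 pyramidal layer, stratum radiatum,
    # DG suprapyramidal molecular layer span, artifact reference site
    ca1_pyr_ch: int = 8
    radiatum_ch: int = 10
    dg_mol_chs: tuple = (16, 17, 18)
    ref_ch: int = 28

    def validate(self):
        if min(self.event_rate_up, self.event_rate_down, self.ripple_rate_up) < 0:
            raise ValueError("rates must be nonnegative")
        if self.up_mean_s <= 0 or self.down_mean_s <= 0:
            raise ValueError("epoch duration means must be positive")
        if not 80 <= self.ripple_freq_hz <= 250:
            raise ValueError("ripple frequency must lie in [80, 250] Hz")
        if self.fs_vm < 2.5 * self.ripple_freq_hz:
            raise ValueError("fs_vm below Nyquist for the ripple templates")
        if self.duration_s < MIN_EPOCH_S:
            raise ValueError("duration too short to contain one full epoch")

    def geometry(self) -> ProbeGeometry:
        depths = np.arange(self.n_channels) * self.channel_spacing_um
        return ProbeGeometry(channel_depths_um=depths)


@dataclass
class SessionTruth:
    epochs: pd.DataFrame  # (state, t_start_s, t_stop_s)
    activity: np.ndarray  # true z-scored DG CSD activity
    fs_activity: float
    event_times: np.ndarray
    ripple_times: np.ndarray
    spw_amps: np.ndarray
    spike_times: dict
    kernels: dict
    templates: dict
    pupil_diameter: np.ndarray
    fs_pupil: float
    blink_times: np.ndarray

    def state_at(self, times_s) -> np.ndarray:
        stops = self.epochs.t_stop_s.to_numpy()
        states = self.epochs.state.to_numpy()
        k = np.clip(np.searchsorted(stops, np.atleast_1d(times_s), "right"), 0,
                    len(states) - 1)
        return states[k]


@dataclass
class SyntheticSession:
    lfp: np.ndarray  # (channels, samples), mV
    fs_lfp: float
    vm: dict  # cell_id -> (subfield, broadband trace)
    fs_vm: float
    truth: SessionTruth
    config: SyntheticConfig
    geometry: ProbeGeometry


def generate_uds_truth(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Alternating UP/DOWN epochs with exponential durations.

    Durations are exponential with the configured means, clipped below at
    one 4 Hz HMM frame (0.25 s); clipping preserves the configured mean to
    within ~0.5% at the default parameters.  Sessions always open in DOWN.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    rows = []
    t, state = 0.0, DOWN
    while t < cfg.duration_s:
        mean = cfg.up_mean_s if state == UP else cfg.down_mean_s
        dur = max(rng.exponential(mean), MIN_EPOCH_S)
        rows.append((state, t, min(t + dur, cfg.duration_s)))
        t += dur
        state = 1 - state
    return pd.DataFrame(rows, columns=["state", "t_start_s", "t_stop_s"])


def _state_signal(epochs: pd.DataFrame, fs: float, duration_s: float) -> np.ndarray:
    t = (np.arange(int(round(duration_s * fs))) + 0.5) / fs
    stops = epochs.t_stop_s.to_numpy()
    states = epochs.state.to_numpy()
    k = np.clip(np.searchsorted(stops, t, "right"), 0, len(states) - 1)
    return states[k]


def generate_activity_trace(
    cfg: SyntheticConfig,
    fs: float = 20.83,
    delta: float = 2.0,
    sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic DG CSD activity with well-separated state emissions.

    State-conditional emissions are Gaussian around -delta/2 (DOWN) and
    +delta/2 (UP) with SD ``sd``.  Returns ``(activity, truth_epochs)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    epochs = generate_uds_truth(cfg, rng)
    states = _state_signal(epochs, fs, cfg.duration_s)
    mean = np.where(states == UP, delta / 2.0, -delta / 2.0)
    return mean + sd * rng.standard_normal(len(states)), epochs


def kernel_on_grid(spec: KernelSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a kernel on a lag grid covering peak +- 4 sigma (and lag 0)."""
    lo = min(spec.peak_lag_s - 4 * spec.sigma_s, 0.0)
    hi = max(spec.peak_lag_s + 4 * spec.sigma_s, 0.0)
    lags = np.arange(int(np.floor(lo * fs)), int(np.ceil(hi * fs)) + 1) / fs
    vals = spec.gain_mv_per_z * np.exp(
        -0.5 * ((lags - spec.peak_lag_s) / spec.sigma_s) ** 2
    )
    return lags, vals


def _convolve_kernel(activity: np.ndarray, lags: np.ndarray, vals: np.ndarray,
                     fs: float) -> np.ndarray:
    """y[t] = sum_k h(lag_k) a[t - k] / fs  (continuous-time impulse response).

    The kernel is a continuous impulse response in mV * s^-1 per activity-z;
    the 1/fs factor makes the output independent of the evaluation rate.
    """
    n_neg = int(round(-lags[0] * fs))
    full = np.convolve(activity, vals)
    return full[n_neg : n_neg + len(activity)] / fs


def _biexp(fs: float, rise_s: float, decay_s: float, length_s: float) -> np.ndarray:
    t = np.arange(int(round(length_s * fs))) / fs
    shape = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return shape / shape.max()


def _poisson_times(rate: float, t0: float, t1: float, rng) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def _add_at(trace: np.ndarray, idx: int, template: np.ndarray):
    lo = max(idx, 0)
    hi = min(idx + len(template), len(trace))
    if hi > lo:
        trace[lo:hi] += template[lo - idx : hi - idx]


def generate_session(cfg: SyntheticConfig) -> SyntheticSession:
    """Full synthetic session: LFP, membrane potentials, pupil and truth."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    subs = ss.spawn(5 + len(cfg.cells))
    rng_uds, rng_ev, rng_rip, rng_lfp, rng_pupil = (
        np.random.default_rng(s) for s in subs[:5]
    )
    cell_rngs = {cid: np.random.default_rng(s) for cid, s in
                 zip(cfg.cells, subs[5:])}

    epochs = generate_uds_truth(cfg, rng_uds)
    geometry = cfg.geometry()
    fmat, basis, depth_grid = forward_matrix(geometry)
    n_lfp = int(round(cfg.duration_s * cfg.fs_lfp))

    # --- DG molecular-layer synaptic events as forward-projected dipoles ---
    mol = cfg.dg_mol_chs
    dipole = np.zeros(cfg.n_channels)
    dipole[mol[len(mol) // 2]] = -1.0  # sink in the molecular layer
    dipole[mol[0] - 1] = 1.0  # return source just above
    lfp_gain = np.abs(fmat @ dipole).max()
    csd_amp = cfg.event_lfp_mv / lfp_gain

    ev_times = []
    for _, ep in epochs.iterrows():
        rate = cfg.event_rate_up if ep.state == UP else cfg.event_rate_down
        if rate > 0:
            ev_times.append(_poisson_times(rate, ep.t_start_s, ep.t_stop_s, rng_ev))
    ev_times = np.sort(np.concatenate(ev_times)) if ev_times else np.array([])

    ev_shape = _biexp(cfg.fs_lfp, 0.002, 0.008, 0.05)
    node_csd = np.zeros((cfg.n_channels, n_lfp))
    ev_amps = rng_ev.lognormal(0.0, 0.4, len(ev_times)) * csd_amp
    for t_ev, amp in zip(ev_times, ev_amps):
        idx = int(round(t_ev * cfg.fs_lfp))
        for ch, sign in ((mol[len(mol) // 2], -1.0), (mol[0] - 1, 1.0)):
            _add_at(node_csd[ch], idx, sign * amp * ev_shape)

    lfp = fmat @ node_csd
    lfp += cfg.lfp_noise_sd_mv * rng_lfp.standard_normal(lfp.shape)

    # --- true DG CSD activity from the noiseless fine-grid CSD ---
    fs_act = cfg.fs_activity
    step = int(round(cfg.fs_lfp / fs_act))
    fs_act = cfg.fs_lfp / step
    depth_lo = geometry.channel_depths_um[mol[0]]
    depth_hi = geometry.channel_depths_um[mol[-1]]
    rows = np.nonzero((depth_grid >= depth_lo) & (depth_grid <= depth_hi))[0]
    true_csd_mol = basis[rows] @ node_csd
    raw_act = np.abs(true_csd_mol).mean(axis=0)
    raw_act = raw_act.reshape(-1, step).mean(axis=1)  # decimate to fs_act
    act = median_filter_1s(raw_act, fs_act)
    act = (act - act.mean()) / act.std() if act.std() > 0 else act * 0.0

    # --- ripples: only inside UP epochs, with radiatum sharp waves ---
    rip_times, spw_amps = [], []
    margin = cfg.ripple_duration_s + 0.03
    for _, ep in epochs.iterrows():
        if ep.state != UP or cfg.ripple_rate_up == 0:
            continue
        t0, t1 = ep.t_start_s + margin, ep.t_stop_s - margin
        if t1 <= t0:
            continue
        # occurrence rate ramps up through the UP state (thinning of a
        # homogeneous process) and terminates abruptly at the UP->DOWN edge
        cand = _poisson_times(cfg.ripple_rate_up, t0, t1, rng_rip)
        ramp = 1.0 - np.exp(-(cand - ep.t_start_s) / cfg.ripple_ramp_tau_s)
        for t_r in cand[rng_rip.random(len(cand)) < ramp]:
            rip_times.append(t_r)
            spw_amps.append(cfg.spw_median_mv * rng_rip.lognormal(0.0, 0.5))
    rip_times = np.array(rip_times)
    spw_amps = np.array(spw_amps)

    n_burst = int(round(cfg.ripple_duration_s * cfg.fs_lfp))
    t_burst = np.arange(n_burst) / cfg.fs_lfp
    burst = (
        cfg.ripple_amp_mv
        * np.hanning(n_burst)
        * np.sin(2 * np.pi * cfg.ripple_freq_hz * t_burst)
    )
    spw_shape = _biexp(cfg.fs_lfp, 0.005, 0.020, 0.12)
    for t_r, amp in zip(rip_times, spw_amps):
        idx = int(round(t_r * cfg.fs_lfp))
        _add_at(lfp[cfg.ca1_pyr_ch], idx, burst)
        _add_at(lfp[cfg.radiatum_ch], idx - int(0.01 * cfg.fs_lfp), -amp * spw_shape)

    # --- membrane potentials ---
    n_vm = int(round(cfg.duration_s * cfg.fs_vm))
    t_vm = np.arange(n_vm) / cfg.fs_vm
    t_act = np.arange(len(act)) / fs_act
    vm_traces = {}
    spike_truth = {}
    kernels = {}
    n_spk_wave = int(round(0.002 * cfg.fs_vm)) | 1
    spk_wave = cfg.spike_amp_mv * np.exp(
        -0.5 * ((np.arange(n_spk_wave) - n_spk_wave // 2) / (0.0003 * cfg.fs_vm)) ** 2
    )
    for cid, subfield in cfg.cells.items():
        rng_c = cell_rngs[cid]
        spec = cfg.subfield_kernels[subfield]
        lags, vals = kernel_on_grid(spec, fs_act)
        kernels[cid] = (lags, vals)
        slow_act = _convolve_kernel(act, lags, vals, fs_act)
        slow = np.interp(t_vm, t_act, slow_act)
        fast = np.zeros(n_vm)
        for lag_s, sigma_s, amp in cfg.ripple_templates[subfield]:
            half = int(round(4 * sigma_s * cfg.fs_vm))
            t_tpl = np.arange(-half, half + 1) / cfg.fs_vm
            tpl = amp * np.exp(-0.5 * (t_tpl / sigma_s) ** 2)
            for t_r in rip_times:
                _add_at(fast, int(round((t_r + lag_s) * cfg.fs_vm)) - half, tpl)
        drift = cfg.vrest_mv + 0.5 * np.sin(2 * np.pi * 0.003 * t_vm)
        sub_vm = slow + fast + drift + cfg.noise_sd_mv * rng_c.standard_normal(n_vm)
        # inhomogeneous Poisson spiking, rate increasing with subthreshold V_m
        lam = cfg.spike_rate0_hz * np.exp((slow + fast) / cfg.spike_dv_mv)
        fs_spk = 1000.0
        p = np.interp(np.arange(int(cfg.duration_s * fs_spk)) / fs_spk, t_vm, lam) / fs_spk
        hits = np.nonzero(rng_c.random(len(p)) < p)[0] / fs_spk
        spikes = []
        for t_s in hits:
            if not spikes or t_s - spikes[-1] > 0.005:
                spikes.append(t_s)
        spikes = np.array(spikes)
        trace = sub_vm.copy()
        for t_s in spikes:
            _add_at(trace, int(round(t_s * cfg.fs_vm)) - n_spk_wave // 2, spk_wave)
        vm_traces[cid] = (subfield, trace)
        spike_truth[cid] = spikes

    # --- pupil: dilate at UP->DOWN transitions, constrict through UP ---
    n_pup = int(round(cfg.duration_s * cfg.fs_pupil))
    states_pup = _state_signal(epochs, cfg.fs_pupil, cfg.duration_s)
    target = np.where(states_pup == DOWN, cfg.pupil_set_down, cfg.pupil_set_up)
    diam = np.empty(n_pup)
    d = target[0]
    alpha = 1.0 - np.exp(-1.0 / (cfg.pupil_tau_s * cfg.fs_pupil))
    for i in range(n_pup):
        d += alpha * (target[i] - d)
        diam[i] = d
    diam += 0.01 * rng_pupil.standard_normal(n_pup)
    blink_times = []
    for _, ep in epochs.iterrows():
        if ep.state == DOWN and cfg.blink_rate_down > 0:
            blink_times.extend(
                _poisson_times(cfg.blink_rate_down, ep.t_start_s, ep.t_stop_s, rng_pupil)
            )
    truth = SessionTruth(
        epochs=epochs,
        activity=act,
        fs_activity=fs_act,
        event_times=ev_times,
        ripple_times=rip_times,
        spw_amps=spw_amps,
        spike_times=spike_truth,
        kernels=kernels,
        templates=dict(cfg.ripple_templates),
        pupil_diameter=diam,
        fs_pupil=cfg.fs_pupil,
        blink_times=np.array(blink_times),
    )
    return SyntheticSession(
        lfp=lfp,
        fs_lfp=cfg.fs_lfp,
        vm=vm_traces,
        fs_vm=cfg.fs_vm,
        truth=truth,
        config=cfg,
        geometry=geometry,
    )


def pupil_landmarks(
    session: SyntheticSession, n_points: int = 8, px_scale: float = 10.0
) -> list[np.ndarray]:
    """Per-frame landmark point sets (x, y, likelihood) for the pupil module.

    Points lie on the truth pupil circle with high likelihood; blink frames
    carry uniformly low likelihoods.
    """
    truth = session.truth
    rng = np.random.default_rng(
        np.random.SeedSequence(session.config.seed).spawn(6)[-1]
    )
    blink_idx = set(np.round(truth.blink_times * truth.fs_pupil).astype(int))
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    frames = []
    for i, d in enumerate(truth.pupil_diameter):
        r = max(px_scale * d / 2.0, 0.5)
        x = 50.0 + r * np.cos(theta) + 0.05 * rng.standard_normal(n_points)
        y = 50.0 + r * np.sin(theta) + 0.05 * rng.standard_normal(n_points)
        like = np.full(n_points, 0.99)
        if i in blink_idx:
            like[:] = 0.1
        frames.append(np.column_stack([x, y, like]))
    return frames
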