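"""Event-triggered and state-conditioned statistics of V_m and spiking.

Covers ripple-triggered averages (RTAs) of the fast and slow V_m components
and of spiking, UDS-phase-conditioned profiles in 20 phase bins, the battery
of UP/DOWN modulation significance tests, the big/small sharp-wave
comparison, and PCA-based ordering of cells for population images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .uds import DOWN, UP, UdsSegmentation, phase_of

__all__ = [
    "TriggeredAverage",
    "PhaseProfile",
    "UdsTestReport",
    "triggered_average",
    "spike_rate_response",
    "phase_profile",
    "uds_modulation_tests",
    "compare_big_small",
    "rank_cells",
]

N_PHASE_BINS = 20
FRAME_S = 0.25  # spike-probability unit interval (4 Hz frames)


@dataclass
class TriggeredAverage:
    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    component: str = ""


@dataclass
class PhaseProfile:
    bin_centers: np.ndarray
    vm_mean: np.ndarray  # slow+fast V_m mean per bin (mV)
    fast_sd: np.ndarray  # fast-component SD per bin (mV)
    spike_prob: np.ndarray  # spikes per 4 Hz frame per bin
    empty_bins: np.ndarray


@dataclass
class UdsTestReport:
    mean_t_p: float | None
    mean_wilcoxon_p: float | None
    var_f_p: float | None
    var_ansari_p: float | None
    spike_chi2_p: float | None
    phase_bin_significant: np.ndarray
    phase_modulated: bool
    skipped: list


def triggered_average(
    signal: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window_s: tuple[float, float] = (-1.0, 1.0),
    component: str = "",
) -> TriggeredAverage:
    """Per-lag mean and SEM of a signal across events with full coverage."""
    event_times = np.asarray(event_times, dtype=float)
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    idx = np.round(event_times * fs).astype(int)
    keep = idx[(idx - pre >= 0) & (idx + post < len(signal))]
    if keep.size == 0:
        raise ValueError("no events with full window coverage")
    snips = np.stack([signal[i - pre : i + post + 1] for i in keep])
    mean = snips.mean(axis=0)
    sd = snips.std(axis=0, ddof=1) if len(keep) > 1 else np.zeros_like(mean)
    return TriggeredAverage(
        lags_s=np.arange(-pre, post + 1) / fs,
        mean=mean,
        sem=sd / np.sqrt(len(keep)),
        n_events=len(keep),
        component=component,
    )


def spike_rate_response(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    duration_s: float,
    window_s: tuple[float, float] = (-1.0, 1.0),
    bin_s: float = 0.025,
):
    """Peri-event spike rate normalised by the session baseline rate.

    Returns ``(lag_centers, normalized_rate, low_count_flag)``; cells with
    fewer than 100 spikes are flagged rather than rejected.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    low_count = spike_times.size < 100
    baseline = spike_times.size / duration_s
    if baseline == 0:
        edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, np.zeros(len(centers)), True
    edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
    counts = np.zeros(len(edges) - 1)
    for t0 in event_times:
        counts += np.histogram(spike_times - t0, bins=edges)[0]
    rate = counts / (len(event_times) * bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate / baseline, low_count


def phase_profile(
    vm_total: np.ndarray,
    vm_fast: np.ndarray,
    fs: float,
    spike_times: np.ndarray,
    seg: UdsSegmentation,
    n_bins: int = N_PHASE_BINS,
) -> PhaseProfile:
    """Per-phase-bin V_m mean, fast-V_m SD and spike probability."""
    n = min(len(vm_total), int(seg.duration_s * fs))
    t = np.arange(n) / fs
    ph = phase_of(t, seg)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    which = np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1)
    vm_mean = np.full(n_bins, np.nan)
    fast_sd = np.full(n_bins, np.nan)
    spike_prob = np.full(n_bins, np.nan)
    spikes = np.asarray(spike_times, dtype=float)
    spikes = spikes[spikes < seg.duration_s]
    sp_ph = phase_of(spikes, seg) if spikes.size else np.array([])
    sp_counts, _ = np.histogram(sp_ph, bins=edges)
    for b in range(n_bins):
        sel = which == b
        n_in = int(sel.sum())
        if n_in == 0:
            continue
        vm_mean[b] = vm_total[:n][sel].mean()
        fast_sd[b] = vm_fast[:n][sel].std()
        time_in_bin = n_in / fs
        spike_prob[b] = min(sp_counts[b] / (time_in_bin / FRAME_S), 1.0)
    return PhaseProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        vm_mean=vm_mean,
        fast_sd=fast_sd,
        spike_prob=spike_prob,
        empty_bins=np.isnan(vm_mean),
    )


def _subsample(x: np.ndarray, fs: float, every_s: float):
    step = max(int(round(every_s * fs)), 1)
    idx = np.arange(0, len(x), step)
    return idx / fs, x[idx]


def uds_modulation_tests(
    vm_total: np.ndarray,
    vm_fast: np.ndarray,
    fs: float,
    spike_times: np.ndarray,
    seg: UdsSegmentation,
    alpha: float = 0.05,
    min_samples: int = 10,
) -> UdsTestReport:
    """Significance battery for UP/DOWN modulation of one cell.

    Mean tests (Welch t, Wilcoxon rank-sum) use the V_m sampled every 2 s;
    variance tests (F, Ansari-Bradley) use the fast component sampled every
    1 s; the spike test is a chi-square of observed state spike counts
    against the session mean rate; phase modulation uses one-sample Z-tests
    in 20 phase bins at ``alpha/20`` with a >= 5-of-20 rule.
    """
    skipped: list[str] = []
    n = min(len(vm_total), int(seg.duration_s * fs))
    t2, v2 = _subsample(vm_total[:n], fs, 2.0)
    t1, f1 = _subsample(vm_fast[:n], fs, 1.0)
    st2 = seg.state_at(t2)
    st1 = seg.state_at(t1)
    up2, dn2 = v2[st2 == UP], v2[st2 == DOWN]
    up1, dn1 = f1[st1 == UP], f1[st1 == DOWN]

    mean_t_p = mean_w_p = var_f_p = var_a_p = chi2_p = None
    if len(up2) >= min_samples and len(dn2) >= min_samples:
        mean_t_p = float(stats.ttest_ind(up2, dn2, equal_var=False).pvalue)
        mean_w_p = float(stats.ranksums(up2, dn2).pvalue)
    else:
        skipped.append("mean tests: a state has < %d retained samples" % min_samples)
    if len(up1) >= min_samples and len(dn1) >= min_samples:
        fstat = np.var(up1, ddof=1) / np.var(dn1, ddof=1)
        cdf = stats.f.cdf(fstat, len(up1) - 1, len(dn1) - 1)
        var_f_p = float(2 * min(cdf, 1 - cdf))
        var_a_p = float(stats.ansari(up1, dn1).pvalue)
    else:
        skipped.append("variance tests: a state has < %d retained samples" % min_samples)

    spikes = np.asarray(spike_times, dtype=float)
    spikes = spikes[spikes < seg.duration_s]
    time_up = float((seg.frame_states == UP).sum()) / seg.frame_rate
    time_dn = seg.duration_s - time_up
    if spikes.size and time_up > 0 and time_dn > 0:
        obs_up = int((seg.state_at(spikes) == UP).sum())
        obs = np.array([obs_up, spikes.size - obs_up])
        rate = spikes.size / seg.duration_s
        exp = np.array([rate * time_up, rate * time_dn])
        chi2_p = float(stats.chisquare(obs, exp).pvalue)
    else:
        skipped.append("spike chi-square: no spikes or a missing state")

    # phase-bin Z-tests on the 2 s subsampled total (detrended) V_m
    ph = phase_of(t2, seg)
    edges = np.linspace(0, 2 * np.pi, N_PHASE_BINS + 1)
    which = np.clip(np.digitize(ph, edges) - 1, 0, N_PHASE_BINS - 1)
    sd_all = v2.std(ddof=1) if len(v2) > 1 else 0.0
    sig = np.zeros(N_PHASE_BINS, dtype=bool)
    if sd_all > 0:
        for b in range(N_PHASE_BINS):
            grp = v2[which == b]
            if len(grp) < 2:
                continue
            z = grp.mean() / (sd_all / np.sqrt(len(grp)))
            p = 2 * stats.norm.sf(abs(z))
            sig[b] = p < alpha / N_PHASE_BINS
    return UdsTestReport(
        mean_t_p=mean_t_p,
        mean_wilcoxon_p=mean_w_p,
        var_f_p=var_f_p,
        var_ansari_p=var_a_p,
        spike_chi2_p=chi2_p,
        phase_bin_significant=sig,
        phase_modulated=bool(sig.sum() >= 5),
        skipped=skipped,
    )


def compare_big_small(
    big: np.ndarray, small: np.ndarray, lags_s: np.ndarray, alpha: float = 0.01
):
    """Pointwise paired t-test of big vs small sharp-wave RTAs across cells.

    ``big`` and ``small`` are (cells x lags).  Returns
    ``(pvalues, mask, runs)`` where runs is a list of (onset_s, duration_s)
    for contiguous significant stretches.  Exact ties give p = 1.
    """
    big = np.asarray(big, dtype=float)
    small = np.asarray(small, dtype=float)
    if big.shape != small.shape or big.shape[0] < 3:
        raise ValueError("need matching class RTAs for >= 3 cells")
    diffs = big - small
    pvals = np.ones(big.shape[1])
    for j in range(big.shape[1]):
        d = diffs[:, j]
        if np.allclose(d, 0):
            continue  # exact tie -> p = 1 by convention
        pvals[j] = stats.ttest_rel(big[:, j], small[:, j]).pvalue
    mask = pvals < alpha
    runs = []
    j = 0
    dt = lags_s[1] - lags_s[0] if len(lags_s) > 1 else 0.0
    while j < len(mask):
        if mask[j]:
            k = j
            while k + 1 < len(mask) and mask[k + 1]:
                k += 1
            runs.append((float(lags_s[j]), float((k - j + 1) * dt)))
            j = k + 1
        else:
            j += 1
    return pvals, mask, runs


def rank_cells(matrix: np.ndarray):
    """Order cells by loading on the first principal component of the
    stacked response matrix (rows = cells).

    Returns ``(order, loadings, degenerate_flag)``; the component sign is
    fixed so that the mean loading of the top quartile is positive.  A
    rank-0 matrix returns the input order with a flag.
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    centered = mat - mat.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        return np.arange(mat.shape[0]), np.zeros(mat.shape[0]), True
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    loadings = u[:, 0] * s[0]
    top = np.sort(loadings)[-max(len(loadings) // 4, 1):]
    if top.mean() < 0:
        loadings = -loadings
    return np.argsort(-loadings), loadings, False
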