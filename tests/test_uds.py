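"""Gaussian-mixture fit, HMM segmentation, UDS phase and event densities."""

import numpy as np
import pytest
from scipy import stats

from hippostate import synth, uds


class TestFitGmm2:
    def test_recovers_separated_mixture(self, rng):
        x = np.concatenate(
            [rng.normal(-1, 0.3, 50000), rng.normal(1, 0.3, 50000)]
        )
        fit = uds.fit_gmm2(x)
        means = np.sort(fit.means)
        assert means[0] == pytest.approx(-1.0, abs=0.05)
        assert means[1] == pytest.approx(1.0, abs=0.05)
        assert not fit.weak_bimodality

    def test_symmetric_two_point_data(self):
        x = np.tile([-1.0, 1.0], 2000)
        fit = uds.fit_gmm2(x)
        np.testing.assert_allclose(np.sort(fit.means), [-1, 1], atol=0.01)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.01)

    def test_unimodal_data_components_overlap_labeling_defined(self, rng):
        """On single-Gaussian data the two components overlap heavily but
        up/down labelling is still defined by mean ordering."""
        fit = uds.fit_gmm2(rng.normal(0, 1, 20000))
        assert fit.means[fit.up_component] >= fit.means[1 - fit.up_component]
        sep = abs(fit.means[1] - fit.means[0])
        assert sep < 2 * fit.sds.max()  # overlapping, unlike a true mixture

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            uds.fit_gmm2(np.zeros(100))


class TestSegmentUds:
    def test_well_separated_states_recovered(self):
        cfg = synth.SyntheticConfig(duration_s=600.0, seed=11)
        act, epochs = synth.generate_activity_trace(cfg, fs=20.0, delta=2.0, sd=0.5)
        seg = uds.segment_uds(act, 20.0)
        truth = synth._state_signal(epochs, seg.frame_rate, cfg.duration_s)
        n = min(len(truth), len(seg.frame_states))
        assert (truth[:n] == seg.frame_states[:n]).mean() >= 0.95

    def test_constant_activity_single_state(self):
        with pytest.warns(UserWarning):
            seg = uds.segment_uds(np.zeros(2000), 20.0)
        assert len(seg.transition_times_s) == 0
        assert len(seg.epochs) == 1

    def test_mean_up_duration_within_10pct(self):
        cfg = synth.SyntheticConfig(duration_s=3000.0, seed=1)
        act, _ = synth.generate_activity_trace(cfg, fs=20.83)
        seg = uds.segment_uds(act, 20.83)
        assert seg.epoch_durations(uds.UP).mean() == pytest.approx(3.06, rel=0.10)

    def test_states_alternate(self, session_pipeline):
        states = session_pipeline["seg"].epochs.state.to_numpy()
        assert np.all(np.diff(states) != 0)


@pytest.fixture(scope="module")
def seg():
    import pandas as pd

    epochs = pd.DataFrame(
        {"state": [0, 1, 0, 1], "t_start_s": [0.0, 10.0, 20.0, 30.0],
         "t_stop_s": [10.0, 20.0, 30.0, 40.0]}
    )
    return uds.segmentation_from_epochs(epochs)


@pytest.fixture(scope="module")
def density_seg():
    cfg = synth.SyntheticConfig(duration_s=400.0, seed=2)
    epochs = synth.generate_uds_truth(cfg)
    return uds.segmentation_from_epochs(epochs)


@pytest.fixture(scope="module")
def seg_and_state():
    cfg = synth.SyntheticConfig(duration_s=600.0, seed=4)
    epochs = synth.generate_uds_truth(cfg)
    seg = uds.segmentation_from_epochs(epochs)
    fs = 20.0
    state = synth._state_signal(epochs, fs, cfg.duration_s).astype(float)
    return seg, state, fs


class TestPhase:
    def test_up_midpoint_is_half_pi(self, seg):
        assert uds.phase_of(15.0, seg) == pytest.approx(np.pi / 2, abs=0.05)

    def test_down_to_up_transition_is_zero(self, seg):
        assert uds.phase_of(10.0, seg) == pytest.approx(0.0, abs=0.05)

    def test_down_midpoint_is_three_half_pi(self, seg):
        assert uds.phase_of(25.0, seg) == pytest.approx(3 * np.pi / 2, abs=0.05)

    def test_outside_span_raises(self, seg):
        with pytest.raises(ValueError):
            uds.phase_of(99.0, seg)

    def test_phase_monotone_within_epochs(self, seg):
        t = np.linspace(10.01, 19.99, 200)
        ph = uds.phase_of(t, seg)
        assert np.all(np.diff(ph) >= 0)


class TestEventPhaseDensity:
    def test_up_events_leave_down_halfcycle_empty(self, density_seg, rng):
        up = density_seg.epochs[density_seg.epochs.state == uds.UP]
        times = np.concatenate(
            [rng.uniform(r.t_start_s + 0.05, r.t_stop_s - 0.05, 3)
             for r in up.iloc[1:-1].itertuples()]
        )
        centers, density = uds.event_phase_density(times, density_seg)
        assert density[centers > np.pi].sum() == 0

    def test_density_integrates_to_one(self, density_seg, rng):
        times = rng.uniform(1, density_seg.duration_s - 1, 200)
        centers, density = uds.event_phase_density(times, density_seg)
        width = centers[1] - centers[0]
        assert density.sum() * width == pytest.approx(1.0)

    def test_transition_events_fill_first_bin(self, density_seg):
        du = density_seg.transition_times_s[density_seg.transition_kinds == "DU"]
        centers, density = uds.event_phase_density(du + 1e-6, density_seg)
        assert np.argmax(density) == 0

    def test_zero_events_raise(self, density_seg):
        with pytest.raises(ValueError):
            uds.event_phase_density([], density_seg)


class TestTransitionTriggered:
    def test_state_indicator_steps_up(self, seg_and_state):
        seg, state, fs = seg_and_state
        ta = uds.transition_triggered(state, fs, seg, "DU", (-2.0, 2.0))
        pre = ta.mean[ta.lags_s < -0.5].mean()
        post = ta.mean[ta.lags_s > 0.5].mean()
        assert pre < 0.35 and post > 0.65

    def test_constant_signal_flat(self, seg_and_state):
        seg, state, fs = seg_and_state
        ta = uds.transition_triggered(np.full_like(state, 2.5), fs, seg, "DU")
        np.testing.assert_allclose(ta.mean, 2.5)
        np.testing.assert_allclose(ta.sem, 0.0, atol=1e-12)

    def test_sign_flip_equivariance(self, seg_and_state):
        seg, state, fs = seg_and_state
        ta1 = uds.transition_triggered(state, fs, seg, "UD")
        ta2 = uds.transition_triggered(-state, fs, seg, "UD")
        np.testing.assert_allclose(ta2.mean, -ta1.mean)


class TestDurationDistributions:
    def test_ks_against_generating_exponential(self):
        """Recovered durations look exponential in >= 8/10 seeds."""
        passes = 0
        for seed in range(10):
            cfg = synth.SyntheticConfig(duration_s=1500.0, seed=seed)
            act, _ = synth.generate_activity_trace(cfg, fs=20.83)
            seg = uds.segment_uds(act, 20.83)
            ok = True
            for state, mean in [(uds.UP, cfg.up_mean_s), (uds.DOWN, cfg.down_mean_s)]:
                durs = seg.epoch_durations(state)
                # generating law as observed through the 4 Hz frame grid:
                # clipped exponential, quantised to 0.25 s frames
                sim = np.maximum(
                    np.random.default_rng(seed + 100).exponential(mean, 20000),
                    synth.MIN_EPOCH_S,
                )
                sim = np.maximum(np.round(sim * 4) / 4, synth.MIN_EPOCH_S)
                if stats.ks_2samp(durs, sim).pvalue < 0.01:
                    ok = False
            passes += ok
        assert passes >= 8
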