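"""Triggered averages, phase profiles, the UDS test battery and cell ranking."""

import numpy as np
import pytest

from hippostate import events, synth, uds


class TestTriggeredAverage:
    fs = 100.0

    def test_identical_template_mean_and_zero_sem(self):
        sig = np.zeros(10000)
        tpl = np.sin(np.linspace(0, np.pi, 21))
        onsets = [20.0, 40.0, 60.0]
        for t0 in onsets:
            i = int(t0 * self.fs)
            sig[i : i + 21] += tpl
        ta = events.triggered_average(sig, self.fs, onsets, (-0.05, 0.25))
        i0 = np.searchsorted(ta.lags_s, 0)
        np.testing.assert_allclose(ta.mean[i0 : i0 + 21], tpl, atol=1e-12)
        np.testing.assert_allclose(ta.sem, 0.0, atol=1e-12)

    def test_sem_scales_with_noise(self, rng):
        n_ev, s = 400, 0.5
        sig = s * rng.standard_normal(int(1000 * self.fs))
        onsets = np.arange(1, n_ev + 1) * 2.0
        ta = events.triggered_average(sig, self.fs, onsets, (-0.1, 0.1))
        assert ta.sem.mean() == pytest.approx(s / np.sqrt(n_ev), rel=0.1)

    def test_additivity_of_components(self, rng):
        fast = rng.standard_normal(5000)
        slow = rng.standard_normal(5000)
        onsets = [10.0, 20.0, 30.0]
        ta_f = events.triggered_average(fast, self.fs, onsets, (-0.2, 0.2))
        ta_s = events.triggered_average(slow, self.fs, onsets, (-0.2, 0.2))
        ta_t = events.triggered_average(fast + slow, self.fs, onsets, (-0.2, 0.2))
        np.testing.assert_allclose(ta_f.mean + ta_s.mean, ta_t.mean, atol=1e-12)

    def test_no_covered_events_raises(self):
        with pytest.raises(ValueError):
            events.triggered_average(np.zeros(100), self.fs, [50.0], (-1, 1))


class TestSpikeRateResponse:
    def test_homogeneous_poisson_flat_at_one(self, rng):
        duration = 2000.0
        spikes = np.sort(rng.uniform(0, duration, 10000))
        onsets = rng.uniform(10, duration - 10, 300)
        lags, rate, flag = events.spike_rate_response(spikes, onsets, duration)
        assert not flag
        assert rate.mean() == pytest.approx(1.0, abs=0.05)
        np.testing.assert_allclose(rate, 1.0, atol=0.5)

    def test_event_locked_spikes_peak_at_zero(self):
        onsets = np.arange(10, 500, 5.0)
        spikes = onsets + 0.001
        lags, rate, flag = events.spike_rate_response(spikes, onsets, 500.0)
        assert abs(lags[np.argmax(rate)]) <= 0.025  # within one bin of onset
        assert rate.max() > 10

    def test_low_spike_count_flagged(self):
        _, _, flag = events.spike_rate_response(
            np.array([1.0, 2.0]), np.array([5.0]), 100.0
        )
        assert flag


@pytest.fixture(scope="module")
def truth_seg():
    cfg = synth.SyntheticConfig(duration_s=500.0, seed=9)
    return uds.segmentation_from_epochs(synth.generate_uds_truth(cfg))


@pytest.fixture(scope="module")
def long_seg():
    cfg = synth.SyntheticConfig(duration_s=1000.0, seed=17)
    return uds.segmentation_from_epochs(synth.generate_uds_truth(cfg))


class TestPhaseProfile:
    def test_sinusoid_of_phase_traced(self, truth_seg):
        fs = 50.0
        t = np.arange(int(truth_seg.duration_s * fs)) / fs
        vm_tot = np.sin(uds.phase_of(t, truth_seg))
        prof = events.phase_profile(vm_tot, vm_tot * 0, fs, [], truth_seg)
        expected = np.sin(prof.bin_centers)
        assert np.corrcoef(prof.vm_mean, expected)[0, 1] > 0.99

    def test_phase_independent_noise_flat(self, truth_seg, rng):
        fs = 50.0
        x = rng.standard_normal(int(truth_seg.duration_s * fs))
        prof = events.phase_profile(x, x, fs, [], truth_seg)
        assert np.nanstd(prof.vm_mean) < 0.1

    def test_up_only_spikes_leave_down_bins_empty(self, truth_seg, rng):
        fs = 50.0
        x = np.zeros(int(truth_seg.duration_s * fs))
        up = truth_seg.epochs[truth_seg.epochs.state == uds.UP].iloc[1:-1]
        spikes = np.concatenate(
            [rng.uniform(r.t_start_s + 0.02, r.t_stop_s - 0.02, 5)
             for r in up.itertuples()]
        )
        prof = events.phase_profile(x, x, fs, spikes, truth_seg)
        down_bins = prof.bin_centers > np.pi
        np.testing.assert_allclose(prof.spike_prob[down_bins], 0.0, atol=1e-12)


class TestUdsModulationTests:
    def _state_trace(self, seg, fs):
        t = np.arange(int(seg.duration_s * fs)) / fs
        return seg.state_at(t).astype(float), t

    def test_power_at_two_mv_shift(self, long_seg, rng):
        fs = 10.0
        state, t = self._state_trace(long_seg, fs)
        vm_tot = 2.0 * state + 1.0 * rng.standard_normal(len(state))
        rep = events.uds_modulation_tests(
            vm_tot, rng.standard_normal(len(state)), fs, [], long_seg
        )
        assert rep.mean_t_p < 0.001
        assert rep.mean_wilcoxon_p < 0.001

    def test_variance_jump_detected(self, long_seg, rng):
        fs = 10.0
        state, t = self._state_trace(long_seg, fs)
        fast = rng.standard_normal(len(state)) * (1.0 + 2.0 * state)
        rep = events.uds_modulation_tests(
            rng.standard_normal(len(state)), fast, fs, [], long_seg
        )
        assert rep.var_f_p < 0.01
        assert rep.var_ansari_p < 0.01

    def test_state_locked_spiking_detected(self, long_seg, rng):
        up = long_seg.epochs[long_seg.epochs.state == uds.UP]
        spikes = np.concatenate(
            [rng.uniform(r.t_start_s, r.t_stop_s, 8) for r in up.itertuples()]
        )
        fs = 10.0
        n = int(long_seg.duration_s * fs)
        rep = events.uds_modulation_tests(
            rng.standard_normal(n), rng.standard_normal(n), fs, spikes, long_seg
        )
        assert rep.spike_chi2_p < 0.001

    def test_phase_modulation_verdict(self, long_seg, rng):
        fs = 10.0
        state, t = self._state_trace(long_seg, fs)
        vm_tot = 2.0 * (state - state.mean()) + 0.3 * rng.standard_normal(len(state))
        rep = events.uds_modulation_tests(
            vm_tot, vm_tot, fs, [], long_seg
        )
        assert rep.phase_modulated
        flat = 0.3 * rng.standard_normal(len(state))
        rep0 = events.uds_modulation_tests(flat, flat, fs, [], long_seg)
        assert not rep0.phase_modulated


class TestCompareBigSmall:
    lags = np.linspace(-0.5, 0.5, 41)

    def test_identical_classes_no_significance(self, rng):
        rtas = rng.standard_normal((8, len(self.lags)))
        pvals, mask, runs = events.compare_big_small(rtas, rtas.copy(), self.lags)
        assert not mask.any()
        np.testing.assert_allclose(pvals, 1.0)

    def test_offset_interval_detected(self, rng):
        small = rng.standard_normal((10, len(self.lags))) * 0.1
        big = small.copy()
        sel = (self.lags >= 0) & (self.lags <= 0.1)
        big[:, sel] += 1.0
        pvals, mask, runs = events.compare_big_small(big, small, self.lags)
        assert mask[sel].all()
        assert mask[~sel].mean() < 0.2
        assert len(runs) >= 1 and runs[0][0] == pytest.approx(0.0, abs=0.03)

    def test_permuted_labels_near_nominal_rate(self, rng):
        n_cells = 12
        frac = []
        for _ in range(50):
            a = rng.standard_normal((n_cells, len(self.lags)))
            b = rng.standard_normal((n_cells, len(self.lags)))
            _, mask, _ = events.compare_big_small(a, b, self.lags)
            frac.append(mask.mean())
        assert np.mean(frac) == pytest.approx(0.01, abs=0.01)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            events.compare_big_small(
                rng.standard_normal((2, 10)), rng.standard_normal((2, 10)),
                np.arange(10.0),
            )


class TestRankCells:
    def test_rank_one_matrix_sorts_by_coefficient(self, rng):
        v = rng.standard_normal(30)
        c = np.array([3.0, -1.0, 5.0, 0.5, -2.0])
        order, loadings, flag = events.rank_cells(np.outer(c, v))
        assert not flag
        by_c = np.argsort(-c)
        assert list(order) == list(by_c) or list(order) == list(by_c[::-1])

    def test_row_permutation_equivariance(self, rng):
        mat = rng.standard_normal((6, 40))
        perm = rng.permutation(6)
        order1, load1, _ = events.rank_cells(mat)
        order2, load2, _ = events.rank_cells(mat[perm])
        np.testing.assert_allclose(np.abs(load2), np.abs(load1[perm]), atol=1e-9)

    def test_opposite_clusters_separated(self, rng):
        pattern = np.sin(np.linspace(0, np.pi, 50))
        a = pattern + 0.05 * rng.standard_normal((5, 50))
        b = -pattern + 0.05 * rng.standard_normal((5, 50))
        order, _, _ = events.rank_cells(np.vstack([a, b]))
        first_half = set(order[:5].tolist())
        assert first_half in ({0, 1, 2, 3, 4}, {5, 6, 7, 8, 9})

    def test_degenerate_matrix_flagged(self):
        order, _, flag = events.rank_cells(np.ones((4, 10)))
        assert flag
        assert list(order) == [0, 1, 2, 3]


class TestRtaOnSyntheticSession:
    def test_population_fast_rtas_match_templates(
        self, small_session, processed_cells
    ):
        """Recovered fast RTAs reproduce the generator's subfield templates:
        pre-ripple and post-onset depolarisation in DG/CA1, post-onset
        trough in CA3."""
        truth = small_session.truth
        for cid, res in processed_cells.items():
            comps = res["components"]
            ta = events.triggered_average(
                comps.fast, comps.fs, truth.ripple_times, (-0.3, 0.3)
            )
            tpl = np.zeros_like(ta.lags_s)
            for lag, sig, amp in truth.templates[res["subfield"]]:
                tpl += amp * np.exp(-0.5 * ((ta.lags_s - lag) / sig) ** 2)
            assert np.corrcoef(ta.mean, tpl)[0, 1] > 0.9
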