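import warnings

import numpy as np
import pytest

from hippostate import synth

warnings.filterwarnings("ignore", message="Model is not converging")


@pytest.fixture(scope="session")
def small_session():
    """One 120 s synthetic session shared across the suite."""
    cfg = synth.SyntheticConfig(duration_s=120.0, seed=3)
    return synth.generate_session(cfg)


@pytest.fixture(scope="session")
def session_pipeline(small_session):
    """CSD activity, segmentation and detected ripples for the shared session."""
    from hippostate import csd, ripples, uds

    ses = small_session
    cfg = ses.config
    cmap = csd.inverse_csd(ses.lfp, ses.geometry, ses.fs_lfp)
    lo = ses.geometry.channel_depths_um[cfg.dg_mol_chs[0]]
    hi = ses.geometry.channel_depths_um[cfg.dg_mol_chs[-1]]
    act = csd.dg_activity(cmap, cmap.rows_in(lo, hi))
    seg = uds.segment_uds(act.values, act.fs)
    power = ripples.ripple_power(ses.lfp[cfg.ca1_pyr_ch], ses.fs_lfp)
    ref = ripples.ripple_power(ses.lfp[cfg.ref_ch], ses.fs_lfp)
    events = ripples.detect_ripples(power, ref, ses.fs_lfp)
    return {"csd": cmap, "activity": act, "seg": seg, "ripples": events}


@pytest.fixture(scope="session")
def processed_cells(small_session):
    """Spike-removed, decomposed V_m components for every cell."""
    from hippostate import vm

    out = {}
    ses = small_session
    for cid, (subfield, trace) in ses.vm.items():
        spikes = vm.detect_spikes(trace, ses.fs_vm)
        sub = vm.interpolate_spikes(trace, spikes, ses.fs_vm)
        sub = vm.lowpass_downsample(sub, ses.fs_vm)
        comps = vm.decompose_vm(sub, spike_times=spikes)
        out[cid] = {"subfield": subfield, "components": comps, "spikes": spikes,
                    "sub_2083": sub}
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
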