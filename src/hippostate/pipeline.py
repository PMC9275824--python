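"""End-to-end orchestration of the analysis stages on one session.

``run_all`` executes V_m processing -> ripple detection -> CSD estimation ->
UDS segmentation -> transfer models -> event statistics on a session
container with a single validated configuration, writing every intermediate
artifact as CSV, and is deterministic given (session, config).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import csd, events, ripples, transfer, uds, vm
from .synth import SyntheticSession

__all__ = ["PipelineConfig", "PipelineResults", "run_all"]


@dataclass
class PipelineConfig:
    """Stage parameters; unknown keys are rejected at construction.

    ``provenance`` records, for every defaulted value, whether it comes from
    the published analysis ("paper") or is a package design choice
    ("decision").
    """

    ripple_threshold_sd: float = 3.0  # paper
    ripple_gap_ms: float = 200.0  # decision
    spw_statistic: str = "median"  # paper
    csd_lambda: float | None = None  # paper: cross-validated
    uds_frame_rate: float = 4.0  # paper
    fir_n_taps: int = 75  # paper
    fir_n_negative: int = 18  # decision (resolves the printed tap arithmetic)
    rta_window_fast_s: tuple = (-1.0, 1.0)  # decision
    rta_window_slow_s: tuple = (-5.0, 5.0)  # decision
    out_dir: str | None = None
    seed: int = 0

    provenance: dict = field(
        default_factory=lambda: {
            "ripple_threshold_sd": "paper",
            "ripple_gap_ms": "decision",
            "spw_statistic": "paper",
            "csd_lambda": "paper (cross-validated)",
            "uds_frame_rate": "paper",
            "fir_n_taps": "paper",
            "fir_n_negative": "decision",
            "rta_window_fast_s": "decision",
            "rta_window_slow_s": "decision",
        }
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResults:
    segmentation: uds.UdsSegmentation
    activity: csd.DgCsdActivity
    ripple_events: list
    cells: dict  # cell_id -> per-cell results dict
    notices: list


def run_all(
    session: SyntheticSession, config: PipelineConfig | None = None
) -> PipelineResults:
    cfg = config or PipelineConfig()
    notices: list[str] = []
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- CSD and DG activity ---
    layout = session.config
    csd_map = csd.inverse_csd(
        session.lfp, session.geometry, session.fs_lfp, lam=cfg.csd_lambda
    )
    depth_lo = session.geometry.channel_depths_um[layout.dg_mol_chs[0]]
    depth_hi = session.geometry.channel_depths_um[layout.dg_mol_chs[-1]]
    activity = csd.dg_activity(csd_map, csd_map.rows_in(depth_lo, depth_hi))

    # --- UDS segmentation ---
    seg = uds.segment_uds(activity.values, activity.fs, frame_rate=cfg.uds_frame_rate)

    # --- ripple detection ---
    power = ripples.ripple_power(session.lfp[layout.ca1_pyr_ch], session.fs_lfp)
    ref_power = ripples.ripple_power(session.lfp[layout.ref_ch], session.fs_lfp)
    evs = ripples.detect_ripples(
        power, ref_power, session.fs_lfp, threshold_sd=cfg.ripple_threshold_sd
    )
    if evs:
        evs = ripples.attach_spw_sizes(
            evs, session.lfp[layout.radiatum_ch], session.fs_lfp
        )
        evs = ripples.split_big_small(evs, statistic=cfg.spw_statistic)
        evs = ripples.classify_isolation(evs, gap_ms=cfg.ripple_gap_ms)
    else:
        notices.append("no ripples detected: ripple analyses skipped")
    onsets = np.array([ev.onset_s for ev in evs])

    # --- per-cell V_m processing, transfer models and event statistics ---
    cells = {}
    for cid, (subfield, trace) in session.vm.items():
        spikes = vm.detect_spikes(trace, session.fs_vm)
        sub = vm.interpolate_spikes(trace, spikes, session.fs_vm)
        sub = vm.lowpass_downsample(sub, session.fs_vm)
        comps = vm.decompose_vm(sub, spike_times=spikes)
        thr = vm.spike_threshold(trace, session.fs_vm, spikes)
        qc = vm.qc_cell(thr)
        res = {"subfield": subfield, "components": comps, "qc": qc, "spikes": spikes}
        act_model = transfer.downsample_to_model_rate(activity.values, activity.fs)
        try:
            fir = transfer.FirTransfer(
                activity.values,
                comps.slow,
                activity.fs,
                fs_output=comps.fs,
                n_taps=cfg.fir_n_taps,
                n_negative=cfg.fir_n_negative,
            ).fit()
            res["fir"] = fir
            res["step_response"] = fir.step_response()
            res["predicted_slow"] = fir.predict(act_model)
        except ValueError as exc:
            notices.append(f"{cid}: transfer model skipped ({exc})")
        res["crosscov"] = transfer.sliding_crosscov(
            transfer.downsample_to_model_rate(activity.values, activity.fs),
            transfer.downsample_to_model_rate(comps.slow, comps.fs),
            transfer.MODEL_RATE_HZ,
        )
        if len(onsets) > 0:
            try:
                res["rta_fast"] = events.triggered_average(
                    comps.fast, comps.fs, onsets, cfg.rta_window_fast_s, "fast"
                )
                res["rta_slow"] = events.triggered_average(
                    comps.slow, comps.fs, onsets, cfg.rta_window_slow_s, "slow"
                )
            except ValueError as exc:
                notices.append(f"{cid}: RTA skipped ({exc})")
        res["phase_profile"] = events.phase_profile(
            comps.slow + comps.fast, comps.fast, comps.fs, spikes, seg
        )
        res["uds_tests"] = events.uds_modulation_tests(
            comps.slow + comps.fast, comps.fast, comps.fs, spikes, seg
        )
        cells[cid] = res

    if out_dir:
        seg.epochs.to_csv(out_dir / "uds_epochs.csv", index=False)
        from .io import ripples_to_csv

        ripples_to_csv(evs, out_dir / "ripples.csv")
        rows = []
        for cid, res in cells.items():
            if "fir" in res:
                for lag, coef in zip(res["fir"].lags_s, res["fir"].coefficients):
                    rows.append((cid, res["subfield"], lag, "fir_coef", coef))
        pd.DataFrame(
            rows, columns=["cell_id", "subfield", "lag_or_bin", "statistic", "value"]
        ).to_csv(out_dir / "cell_results.csv", index=False)

    for msg in notices:
        warnings.warn(msg)
    return PipelineResults(
        segmentation=seg,
        activity=activity,
        ripple_events=evs,
        cells=cells,
        notices=notices,
    )
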