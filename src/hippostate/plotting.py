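"""Figure helpers: phase-plane portraits and event-triggered averages."""

from __future__ import annotations

import numpy as np

from .ramodel import RAParams, find_fixed_points, logistic

__all__ = ["plot_phase_plane", "plot_triggered_average"]


def plot_phase_plane(
    params: RAParams,
    regime: str = "EC",
    clamp=None,
    trajectory=None,
    ax=None,
):
    """Nullclines, fixed points and (optionally) a trajectory in the r-a plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if regime == "EC":
        w, b, i0 = params.ec_w, params.ec_b, params.ec_i
    else:
        r_ec, a_ec = clamp
        w = params.ca3_w0 + params.ca3_wg * a_ec
        b, i0 = params.ca3_b, params.ca3_i0 - params.ca3_ig * r_ec
    r = np.linspace(0, 1, 400)
    a = np.linspace(0, 1, 400)
    rr, aa = np.meshgrid(r, a)
    dr = -rr + logistic(w * rr - b * aa + i0, params.r_k, params.r_x0)
    da = -aa + params.a_inf(rr)
    ax.contour(rr, aa, dr, levels=[0], colors="k")
    ax.contour(rr, aa, da, levels=[0], colors="tab:blue")
    for r_star, a_star, stability in find_fixed_points(params, regime, clamp):
        ax.plot(
            r_star,
            a_star,
            "o",
            mfc="k" if stability == "stable" else "none",
            mec="k",
            ms=8,
        )
    if trajectory is not None:
        ax.plot(trajectory[0], trajectory[1], color="purple", lw=0.5, alpha=0.7)
    ax.set_xlabel("population rate r")
    ax.set_ylabel("adaptation a")
    ax.set_title(f"{regime} phase plane")
    return ax


def plot_triggered_average(ta, ax=None, color="tab:blue", label=None):
    """Mean +- SEM band of a TriggeredAverage."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ta.lags_s, ta.mean, color=color, label=label)
    ax.fill_between(
        ta.lags_s, ta.mean - ta.sem, ta.mean + ta.sem, color=color, alpha=0.3
    )
    ax.axvline(0, color="k", ls="--", lw=0.5)
    ax.set_xlabel("lag (s)")
    return ax
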