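"""Adapting recurrent rate model of UDS-gated ripple excitability.

Two Wilson-Cowan-type populations with activity-driven adaptation:

    tau_r * dr/dt = -r + R_inf(w r - b a + I + xi(t))
    tau_a * da/dt = -a + A_inf(r)

with logistic activations R_inf (k=1, x0=5) and A_inf (k=15, x0=0.5) and
Ornstein-Uhlenbeck noise ``d xi = -theta xi dt + sigma sqrt(2 theta) dW``
(stationary SD sigma).  The EC population has fixed parameters
(w=6.8, b=1, I=2.1) and is bistable: UP and DOWN states with noise-driven
transitions.  The CA3 population receives a drive ``I = I0 - Ig * r_ec``
(net inhibition from EC activity) and a recurrent strength
``w = w0 + wg * a_ec`` (cholinergic-tone-like potentiation in the UP
state), so that CA3 sits at a *lower* mean rate in the EC UP state but is
excitable there, producing transient population bursts ("ripples") only in
UP states.

Time units are arbitrary (tau_r = 1).  Integration is Euler-Maruyama for
the rate equations with the OU noise updated by its exact discretisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, isfinite

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

__all__ = [
    "RAParams",
    "RATrajectory",
    "logistic",
    "ou_path",
    "simulate",
    "find_fixed_points",
    "detect_bursts",
    "model_uds",
]


def logistic(x, k: float, x0: float):
    return 1.0 / (1.0 + np.exp(-k * (x - x0)))


def _dlogistic(x, k: float, x0: float):
    f = logistic(x, k, x0)
    return k * f * (1.0 - f)


@dataclass(frozen=True)
class RAParams:
    """Published parameter set of the two-population model."""

    tau_r: float = 1.0
    tau_a: float = 25.0
    r_k: float = 1.0
    r_x0: float = 5.0
    a_k: float = 15.0
    a_x0: float = 0.5
    ec_w: float = 6.8
    ec_b: float = 1.0
    ec_i: float = 2.1
    ou_theta: float = 0.05
    ec_sigma: float = 0.1
    ca3_i0: float = 2.5
    ca3_ig: float = 0.6
    ca3_w0: float = 3.5
    ca3_wg: float = 2.5
    ca3_b: float = 1.0
    ca3_sigma: float = 0.25

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")
        if self.ec_sigma < 0 or self.ca3_sigma < 0:
            raise ValueError("noise SDs must be nonnegative")

    def r_inf(self, x):
        return logistic(x, self.r_k, self.r_x0)

    def a_inf(self, r):
        return logistic(r, self.a_k, self.a_x0)


@dataclass
class RATrajectory:
    t: np.ndarray
    r_ec: np.ndarray
    a_ec: np.ndarray
    r_ca3: np.ndarray
    a_ca3: np.ndarray
    xi_ec: np.ndarray
    xi_ca3: np.ndarray
    dt: float
    seed: int | None = None
    params: RAParams = field(default_factory=RAParams)


def ou_path(
    theta: float,
    sigma: float,
    dt: float,
    n: int,
    rng: np.random.Generator | int | None = None,
    x0: float = 0.0,
) -> np.ndarray:
    """Exact-discretisation OU path with stationary SD ``sigma``."""
    if theta <= 0 or dt <= 0:
        raise ValueError("theta and dt must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    alpha = np.exp(-theta * dt)
    innov_sd = sigma * np.sqrt(1.0 - alpha**2)
    eps = rng.standard_normal(n)
    # xi[i] = alpha * xi[i-1] + innov_sd * eps[i], xi[-1] = x0
    path = lfilter([innov_sd], [1.0, -alpha], eps, zi=[alpha * x0])[0]
    return path


def simulate(
    params: RAParams,
    duration: float,
    dt: float = 0.01,
    seed: int | None = None,
    r0: tuple[float, float] | None = None,
) -> RATrajectory:
    """Euler-Maruyama integration of the coupled EC -> CA3 system.

    The two OU noise streams are independent.  By default both populations
    start at the EC DOWN fixed point's rate level.
    """
    if dt > 0.05 * params.tau_r:
        raise ValueError("dt must be <= 0.05 * tau_r")
    n = int(round(duration / dt))
    ss = np.random.SeedSequence(seed)
    rng_ec, rng_ca3 = [np.random.default_rng(s) for s in ss.spawn(2)]
    xi_ec = ou_path(params.ou_theta, params.ec_sigma, dt, n, rng_ec)
    xi_ca3 = ou_path(params.ou_theta, params.ca3_sigma, dt, n, rng_ca3)
    if r0 is None:
        fps = find_fixed_points(params, "EC")
        stable = [r for r, _, s in fps if s == "stable"]
        r_start = min(stable) if stable else 0.1
    else:
        r_start = r0[0]
    r_ec = np.empty(n)
    a_ec = np.empty(n)
    r_ca3 = np.empty(n)
    a_ca3 = np.empty(n)
    re, ae = r_start, params.a_inf(r_start)
    rc, ac = r_start, params.a_inf(r_start)
    inv_tr, inv_ta = dt / params.tau_r, dt / params.tau_a
    # scalar hot loop: local bindings and guarded math.exp for speed
    r_k, r_x0, a_k, a_x0 = params.r_k, params.r_x0, params.a_k, params.a_x0
    ec_w, ec_b, ec_i = params.ec_w, params.ec_b, params.ec_i
    i0, ig, w0, wg, b3 = (
        params.ca3_i0, params.ca3_ig, params.ca3_w0, params.ca3_wg, params.ca3_b,
    )
    xe = xi_ec.tolist()
    xc = xi_ca3.tolist()

    def logi(x, k, x0):
        z = -k * (x - x0)
        if z > 500.0:
            return 0.0
        if z < -500.0:
            return 1.0
        return 1.0 / (1.0 + exp(z))

    for i in range(n):
        drive_ec = ec_w * re - ec_b * ae + ec_i + xe[i]
        drive_ca3 = (w0 + wg * ae) * rc - b3 * ac + (i0 - ig * re) + xc[i]
        re += inv_tr * (logi(drive_ec, r_k, r_x0) - re)
        ae += inv_ta * (logi(re, a_k, a_x0) - ae)
        rc += inv_tr * (logi(drive_ca3, r_k, r_x0) - rc)
        ac += inv_ta * (logi(rc, a_k, a_x0) - ac)
        if not (isfinite(re) and isfinite(rc)):
            raise FloatingPointError(f"non-finite state at step {i}")
        r_ec[i], a_ec[i], r_ca3[i], a_ca3[i] = re, ae, rc, ac
    return RATrajectory(
        t=np.arange(1, n + 1) * dt,
        r_ec=r_ec,
        a_ec=a_ec,
        r_ca3=r_ca3,
        a_ca3=a_ca3,
        xi_ec=xi_ec,
        xi_ca3=xi_ca3,
        dt=dt,
        seed=seed,
        params=params,
    )


def _regime_wbi(params: RAParams, regime, clamp):
    if regime == "EC":
        return params.ec_w, params.ec_b, params.ec_i
    if regime == "CA3":
        if clamp is None:
            raise ValueError("CA3 regime needs clamp=(r_ec, a_ec)")
        r_ec, a_ec = clamp
        return (
            params.ca3_w0 + params.ca3_wg * a_ec,
            params.ca3_b,
            params.ca3_i0 - params.ca3_ig * r_ec,
        )
    raise ValueError("regime must be 'EC' or 'CA3'")


def find_fixed_points(
    params: RAParams, regime: str = "EC", clamp: tuple[float, float] | None = None
) -> list[tuple[float, float, str]]:
    """Fixed points of the noiseless vector field with linear stability.

    Roots of ``-r + R_inf(w r - b A_inf(r) + I)`` are bracketed on a dense
    grid and refined by bisection; stability comes from the eigenvalues of
    the 2x2 Jacobian.  ``regime='CA3'`` clamps the EC state at
    ``clamp=(r_ec, a_ec)``.
    """
    w, b, i0 = _regime_wbi(params, regime, clamp)

    def g(r):
        return -r + params.r_inf(w * r - b * params.a_inf(r) + i0)

    grid = np.linspace(0.0, 1.0, 4001)
    vals = g(grid)
    out = []
    for j in range(len(grid) - 1):
        if vals[j] == 0.0 and grid[j] not in [r for r, _, _ in out]:
            root = grid[j]
        elif vals[j] * vals[j + 1] < 0:
            root = brentq(g, grid[j], grid[j + 1], xtol=1e-12)
        else:
            continue
        a_star = params.a_inf(root)
        x_star = w * root - b * a_star + i0
        rp = _dlogistic(x_star, params.r_k, params.r_x0)
        ap = _dlogistic(root, params.a_k, params.a_x0)
        jac = np.array(
            [
                [(-1.0 + w * rp) / params.tau_r, -b * rp / params.tau_r],
                [ap / params.tau_a, -1.0 / params.tau_a],
            ]
        )
        stable = np.all(np.linalg.eigvals(jac).real < 0)
        out.append((float(root), float(a_star), "stable" if stable else "unstable"))
    return out


def detect_bursts(
    r_ca3: np.ndarray, dt: float, threshold: float = 0.5, refractory: float = 25.0
) -> np.ndarray:
    """Times of upward threshold crossings with a refractory gap."""
    r = np.asarray(r_ca3, dtype=float)
    above = r > threshold
    ups = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times = []
    for i in ups:
        t = i * dt
        if not times or t - times[-1] >= refractory:
            times.append(t)
    return np.array(times)


def model_uds(
    r_ec: np.ndarray,
    params: RAParams,
    hysteresis_frac: float = 0.1,
    gate_tau: float | None = "auto",
    dt: float = 0.01,
) -> np.ndarray:
    """UP/DOWN labels of the EC population by hysteresis thresholding.

    The central threshold is the unstable fixed point's rate; the hysteresis
    band is ``+- hysteresis_frac`` of the stable-point separation.  Raises if
    the EC regime is monostable.

    By default the rate is first smoothed with a causal exponential filter
    of time constant ``tau_a`` (``gate_tau="auto"``), so that the labels
    track the state the EC population *transmits to CA3*: the CA3 drive and
    recurrent gain follow ``r_ec`` through the adaptation variable on the
    ``tau_a`` timescale, and CA3 excitability therefore outlasts the raw
    rate drop at an UP->DOWN transition by a few ``tau_a``-fractions.
    ``gate_tau=None`` thresholds the raw rate instead.
    """
    fps = find_fixed_points(params, "EC")
    stable = sorted(r for r, _, s in fps if s == "stable")
    unstable = [r for r, _, s in fps if s == "unstable"]
    if len(stable) != 2 or not unstable:
        raise ValueError("EC regime is not bistable; model UDS undefined")
    # threshold at the unstable point nearest the midpoint of the stable pair
    mid = 0.5 * (stable[0] + stable[1])
    thr = min(unstable, key=lambda r: abs(r - mid))
    band = hysteresis_frac * (stable[1] - stable[0])
    r = np.asarray(r_ec, dtype=float)
    if gate_tau == "auto":
        gate_tau = params.tau_a
    if gate_tau:
        alpha = dt / gate_tau
        r = lfilter([alpha], [1.0, -(1.0 - alpha)], r, zi=[(1 - alpha) * r[0]])[0]
    labels = np.empty(len(r), dtype=int)
    state = 1 if r[0] > thr else 0
    for i, ri in enumerate(r):
        if state == 0 and ri > thr + band:
            state = 1
        elif state == 1 and ri < thr - band:
            state = 0
        labels[i] = state
    return labels
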