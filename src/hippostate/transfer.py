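"""Regularised nonparametric FIR transfer models from DG CSD activity to V_m.

The slow membrane-potential component of a cell is modelled as the output of
a finite impulse response filter driven by the z-scored DG CSD activity,

    y[t] = sum_k h_k u[t - k] + e[t],

with the lag grid allowing *negative* lags (the output may lead the input).
At the ~20 Hz model rate the filter has 75 taps spanning 3.6 s, 18 of them
at negative lags down to -0.86 s.  The coefficients carry a first-order
stable-spline ("tuned/correlated", TC) Gaussian prior

    K[i, j] = c * rho^max(i, j),   0 < rho < 1,

indexed from the most negative lag, and the hyperparameters (c, rho, noise
variance) are selected by marginal-likelihood maximisation (empirical
Bayes).  The posterior-mean filter is the ridge-type estimate
``(X'X + s2 K^-1)^-1 X'y``.

`FirTransfer` / `FirTransferResults` follow the statsmodels model/results
convention; `estimate_fir` is the functional entry point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import signal as sps

__all__ = [
    "FirTransfer",
    "FirTransferResults",
    "CrossCovResult",
    "estimate_fir",
    "step_response",
    "simulate_slow_vm",
    "sliding_crosscov",
    "coherence",
    "downsample_to_model_rate",
]

MODEL_RATE_HZ = 2083.0 / 100.0  # ~20.83 Hz
N_TAPS = 75
N_NEGATIVE = 18  # lags down to -18 / 20.83 Hz ~ -0.86 s


def downsample_to_model_rate(
    x: np.ndarray, fs_in: float, fs_out: float = MODEL_RATE_HZ
) -> np.ndarray:
    """Anti-alias low-pass then sample onto the model-rate grid."""
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x
    if fs_in < fs_out:
        raise ValueError("cannot upsample to the model rate")
    cutoff = 0.4 * fs_out
    numtaps = min(int(4 * fs_in / cutoff) | 1, len(x) // 3 * 2 - 1)
    taps = sps.firwin(numtaps, cutoff, fs=fs_in)
    smooth = sps.filtfilt(taps, [1.0], x)
    t_out = np.arange(int(len(x) / fs_in * fs_out)) / fs_out
    return np.interp(t_out, np.arange(len(x)) / fs_in, smooth)


def _lag_matrix(u: np.ndarray, n_neg: int, n_taps: int):
    """Design matrix with columns u[t - k] for k = -n_neg .. n_taps-n_neg-1."""
    n_pos = n_taps - n_neg - 1
    rows = len(u) - n_neg - n_pos
    if rows < n_taps:
        raise ValueError("input too short for the requested lag grid")
    cols = [u[n_pos + n_neg - (k + n_neg) : len(u) - (k + n_neg)] for k in
            range(-n_neg, n_pos + 1)]
    # column for lag k holds u[t - k] aligned to y rows t = n_pos .. len(u)-n_neg-1
    return np.column_stack(cols)


def _neg_log_marglik(theta, xtx, xty, yty, n):
    log_c, log_rho, log_s2 = theta
    c, rho, s2 = np.exp(log_c), np.exp(log_rho), np.exp(log_s2)
    p = xtx.shape[0]
    idx = np.arange(p)
    kmat = c * rho ** np.maximum(idx[:, None], idx[None, :])
    try:
        lchol = np.linalg.cholesky(kmat + 1e-12 * c * np.eye(p))
    except np.linalg.LinAlgError:
        return 1e12
    ata = lchol.T @ xtx @ lchol
    w = lchol.T @ xty
    b = s2 * np.eye(p) + ata
    sign, logdet_b = np.linalg.slogdet(b)
    if sign <= 0:
        return 1e12
    try:
        quad = yty - w @ np.linalg.solve(b, w)
    except np.linalg.LinAlgError:
        return 1e12
    nll = 0.5 * ((n - p) * np.log(s2) + logdet_b + quad / s2)
    return nll if np.isfinite(nll) else 1e12


@dataclass
class FirTransferResults:
    """Estimated FIR filter with its lag grid, prior hyperparameters and fit."""

    lags_s: np.ndarray
    coefficients: np.ndarray
    fs_model: float
    hyperparameters: dict
    rsquared: float
    n_obs: int
    model: "FirTransfer" = field(repr=False, default=None)

    def step_response(self) -> np.ndarray:
        return np.cumsum(self.coefficients)

    def predict(self, activity: np.ndarray) -> np.ndarray:
        return simulate_slow_vm(self, activity)

    def summary(self) -> str:
        hp = self.hyperparameters
        peak = int(np.argmax(np.abs(self.coefficients)))
        lines = [
            "FIR transfer model (TC-regularised, empirical Bayes)",
            "=" * 54,
            f"taps: {len(self.coefficients)}   model rate: {self.fs_model:.2f} Hz",
            f"lag span: [{self.lags_s[0]:+.2f}, {self.lags_s[-1]:+.2f}] s",
            f"n obs: {self.n_obs}   R^2: {self.rsquared:.3f}",
            f"prior scale c: {hp['c']:.3g}   decay rho: {hp['rho']:.3g}",
            f"noise SD: {np.sqrt(hp['noise_var']):.3g} mV",
            f"extremum: {self.coefficients[peak]:+.3g} mV/z "
            f"at lag {self.lags_s[peak]:+.3f} s",
        ]
        return "\n".join(lines)


class FirTransfer:
    """FIR transfer model from an input trace to an output trace.

    Parameters
    ----------
    input_z, output
        Time-aligned traces; the input is typically the z-scored DG CSD
        activity and the output a cell's slow V_m component (mV).
    fs, fs_output
        Sampling rates of input and output (``fs_output`` defaults to
        ``fs``); both traces are anti-alias downsampled onto the common
        ``fs_model`` grid before fitting.
    """

    def __init__(
        self,
        input_z: np.ndarray,
        output: np.ndarray,
        fs: float,
        fs_output: float | None = None,
        fs_model: float = MODEL_RATE_HZ,
        n_taps: int = N_TAPS,
        n_negative: int = N_NEGATIVE,
    ):
        u = downsample_to_model_rate(input_z, fs, fs_model)
        y = downsample_to_model_rate(output, fs_output or fs, fs_model)
        n = min(len(u), len(y))
        self.u, self.y = u[:n], y[:n]
        self.fs_model = fs_model
        self.n_taps = n_taps
        self.n_negative = n_negative
        if np.ptp(self.u) == 0:
            raise ValueError("constant input: transfer model unidentifiable")
        if n / fs_model < 60:
            raise ValueError("need at least 60 s of data")

    @property
    def lags_s(self) -> np.ndarray:
        return (np.arange(self.n_taps) - self.n_negative) / self.fs_model

    def fit(self, n_restarts: int = 3) -> FirTransferResults:
        n_pos = self.n_taps - self.n_negative - 1
        xmat = _lag_matrix(self.u, self.n_negative, self.n_taps)
        yvec = self.y[n_pos : len(self.y) - self.n_negative]
        yvec = yvec - yvec.mean()
        xtx, xty, yty = xmat.T @ xmat, xmat.T @ yvec, yvec @ yvec
        n = len(yvec)
        var_y = yvec.var() + 1e-12
        starts = [
            (np.log(var_y), np.log(0.9), np.log(0.5 * var_y)),
            (np.log(10 * var_y), np.log(0.7), np.log(0.1 * var_y)),
            (np.log(0.1 * var_y), np.log(0.99), np.log(var_y)),
        ][:n_restarts]
        best = None
        bounds = [(-25, 25), (-8, -1e-6), (-25, 25)]
        for x0 in starts:
            res = optimize.minimize(
                _neg_log_marglik,
                x0,
                args=(xtx, xty, yty, n),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        c, rho, s2 = np.exp(best.x)
        p = self.n_taps
        idx = np.arange(p)
        kmat = c * rho ** np.maximum(idx[:, None], idx[None, :])
        coefs = np.linalg.solve(
            xtx + s2 * np.linalg.inv(kmat + 1e-12 * c * np.eye(p)), xty
        )
        resid = yvec - xmat @ coefs
        r2 = 1.0 - resid.var() / var_y
        return FirTransferResults(
            lags_s=self.lags_s,
            coefficients=coefs,
            fs_model=self.fs_model,
            hyperparameters={"c": c, "rho": rho, "noise_var": s2},
            rsquared=float(r2),
            n_obs=n,
            model=self,
        )


def estimate_fir(
    input_z: np.ndarray, output: np.ndarray, fs: float, **kwargs
) -> FirTransferResults:
    """Fit a TC-regularised FIR model; see :class:`FirTransfer`."""
    return FirTransfer(input_z, output, fs, **kwargs).fit()


def step_response(model: FirTransferResults) -> np.ndarray:
    """Response to a unit input step at lag 0 (cumulative impulse response)."""
    return model.step_response()


def simulate_slow_vm(model: FirTransferResults, activity: np.ndarray) -> np.ndarray:
    """Non-causal convolution of activity with the filter; edges are NaN."""
    u = np.asarray(activity, dtype=float)
    h = model.coefficients
    n_neg = int(round(-model.lags_s[0] * model.fs_model))
    n_pos = len(h) - n_neg - 1
    full = np.convolve(u, h)  # full[t] = sum_j h_j u[t-j], taps indexed 0..74
    out = np.full(len(u), np.nan)
    # tap j corresponds to lag k = j - n_neg; y[t] = sum_k h_{k+n_neg} u[t-k]
    valid = slice(n_pos, len(u) - n_neg) if len(u) > n_neg + n_pos else slice(0, 0)
    shifted = full[n_neg:][: len(u)]
    out[valid] = shifted[valid]
    return out


@dataclass
class CrossCovResult:
    lags_s: np.ndarray
    values: np.ndarray  # session-average over windows
    window_values: np.ndarray  # (n_windows, n_lags)
    window_starts_s: np.ndarray
    extremum: tuple  # (lag_s, value, sign)
    normalized: bool


def _xcov(x: np.ndarray, y: np.ndarray, max_lag: int, normalized: bool):
    """c[k] = E[x(t) y(t+k)]; positive lag means y follows x."""
    x = x - x.mean()
    y = y - y.mean()
    if normalized:
        sx, sy = x.std(), y.std()
        if sx > 0:
            x = x / sx
        if sy > 0:
            y = y / sy
    n = len(x)
    vals = np.empty(2 * max_lag + 1)
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            vals[i] = np.dot(x[: n - k], y[k:]) / (n - k)
        else:
            vals[i] = np.dot(x[-k:], y[: n + k]) / (n + k)
    return vals


def sliding_crosscov(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 30.0,
    max_lag_s: float = 2.0,
    overlap: float = 0.5,
    normalized: bool = True,
) -> CrossCovResult:
    """Cross-covariance of mean-removed signals over sliding windows.

    With ``normalized=True`` each window is z-scored, i.e. the values are
    correlations.  The extremum is the lag of the maximum absolute
    session-average value, with its sign.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(len(x), len(y))
    win = int(round(window_s * fs))
    if win > n:
        raise ValueError("window longer than the trace")
    max_lag = int(round(max_lag_s * fs))
    step = max(int(win * (1 - overlap)), 1)
    starts = np.arange(0, n - win + 1, step)
    mats = np.stack(
        [_xcov(x[s : s + win], y[s : s + win], max_lag, normalized) for s in starts]
    )
    mean_vals = mats.mean(axis=0)
    lags = np.arange(-max_lag, max_lag + 1) / fs
    i = int(np.argmax(np.abs(mean_vals)))
    extremum = (float(lags[i]), float(mean_vals[i]), int(np.sign(mean_vals[i])))
    return CrossCovResult(
        lags_s=lags,
        values=mean_vals,
        window_values=mats,
        window_starts_s=starts / fs,
        extremum=extremum,
        normalized=normalized,
    )


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    nperseg: int | None = None,
    alpha: float = 0.05,
):
    """Welch magnitude-squared coherence with an analytic significance floor.

    Returns ``(freqs, coh, floor)`` where ``floor = 1 - alpha**(1/(L-1))``
    for ``L`` averaged segments (50% overlap Hann windows count as
    independent segments for the floor, a slightly conservative choice).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(len(x), len(y))
    if nperseg is None:
        nperseg = n // 8
    n_seg = max(n // nperseg, 1)
    if n_seg < 8:
        raise ValueError("need >= 8 averaging segments for coherence")
    freqs, coh = sps.coherence(x[:n], y[:n], fs=fs, nperseg=nperseg)
    floor = 1.0 - alpha ** (1.0 / (n_seg - 1))
    return freqs, coh, floor
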