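"""One-dimensional inverse current-source-density (iCSD) estimation.

Laminar LFP recorded on a linear probe is modelled as arising from planar
current sources of finite lateral extent (disks) centred on the probe axis.
The depth profile of the CSD is parameterised by its values at the electrode
depths and interpolated between them with a natural cubic spline; the forward
matrix maps those spline node values to electrode potentials.  Inversion is
ridge-regularised, with the regularisation parameter chosen by
leave-one-channel-out cross-validation, so no additional spatial smoothing is
applied to the estimate.

The scalar "DG CSD activity" signal — the proxy for entorhinal input used by
the UP/DOWN segmentation — is the rectified CSD averaged over the dentate
molecular-layer rows, median-filtered with a 1 s window and z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "ProbeGeometry",
    "CsdMap",
    "DgCsdActivity",
    "forward_matrix",
    "spline_basis",
    "inverse_csd",
    "dg_activity",
    "triggered_rectified_csd",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Linear probe geometry used by the spline iCSD model.

    Parameters
    ----------
    channel_depths_um
        Depth of each recording site in micrometres, strictly increasing.
    bad_channels
        Indices (into ``channel_depths_um``) excluded from the inversion.
    conductivity
        Homogeneous extracellular conductivity (arbitrary units; it only
        scales the CSD amplitude).
    source_diameter_um
        Assumed lateral diameter of the disk sources.
    """

    channel_depths_um: np.ndarray
    bad_channels: frozenset = field(default_factory=frozenset)
    conductivity: float = 0.3
    source_diameter_um: float = 500.0

    def __post_init__(self):
        depths = np.asarray(self.channel_depths_um, dtype=float)
        object.__setattr__(self, "channel_depths_um", depths)
        object.__setattr__(self, "bad_channels", frozenset(self.bad_channels))
        good = self.good_depths_um
        if len(good) < 4:
            raise ValueError("need at least 4 good channels for the spline iCSD")
        if np.any(np.diff(good) <= 0):
            raise ValueError("channel depths must be strictly monotone")

    @property
    def good_channels(self) -> np.ndarray:
        return np.array(
            [i for i in range(len(self.channel_depths_um)) if i not in self.bad_channels]
        )

    @property
    def good_depths_um(self) -> np.ndarray:
        return self.channel_depths_um[self.good_channels]


@dataclass
class CsdMap:
    """Depth x time current-density estimate on a fine depth grid."""

    depth_grid_um: np.ndarray
    values: np.ndarray  # (n_depths, n_samples)
    fs: float
    lam: float | None = None

    def rows_in(self, depth_lo_um: float, depth_hi_um: float) -> np.ndarray:
        """Indices of depth rows with ``depth_lo_um <= z <= depth_hi_um``."""
        z = self.depth_grid_um
        return np.nonzero((z >= depth_lo_um) & (z <= depth_hi_um))[0]


@dataclass
class DgCsdActivity:
    """Z-scored scalar activity of the DG molecular layer."""

    values: np.ndarray
    fs: float
    layer_rows: np.ndarray


def spline_basis(node_depths_um: np.ndarray, depth_grid_um: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline interpolation matrix from node values to a grid.

    ``S[g, i]`` is the value at ``depth_grid_um[g]`` of the natural cubic
    spline that equals 1 at node ``i`` and 0 at every other node.
    """
    nodes = np.asarray(node_depths_um, dtype=float)
    n = len(nodes)
    basis = np.empty((len(depth_grid_um), n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        basis[:, i] = CubicSpline(nodes, e, bc_type="natural")(depth_grid_um)
    return basis


def _disk_kernel(z_obs_um, z_src_um, conductivity, source_diameter_um):
    """Potential at depth ``z_obs`` from a unit planar CSD sheet at ``z_src``."""
    radius = 0.5 * source_diameter_um
    dz = z_obs_um[:, None] - z_src_um[None, :]
    return (np.sqrt(dz**2 + radius**2) - np.abs(dz)) / (2.0 * conductivity)


def make_depth_grid(geometry: ProbeGeometry, resolution_um: float = 17.0) -> np.ndarray:
    depths = geometry.good_depths_um
    n = int(np.ceil((depths[-1] - depths[0]) / resolution_um)) + 1
    return np.linspace(depths[0], depths[-1], n)


def forward_matrix(
    geometry: ProbeGeometry, depth_grid_um: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward matrix of the spline iCSD model.

    Returns ``(F, S, depth_grid_um)`` where ``F`` (channels x nodes) maps
    spline node CSD values to channel potentials and ``S`` (grid x nodes)
    evaluates the interpolated CSD on the fine depth grid, so that the full
    forward map onto the grid CSD is ``F = K @ S * h`` with ``K`` the disk
    source kernel and ``h`` the grid step.
    """
    if depth_grid_um is None:
        depth_grid_um = make_depth_grid(geometry)
    depths = geometry.good_depths_um
    basis = spline_basis(depths, depth_grid_um)
    h = depth_grid_um[1] - depth_grid_um[0]
    kern = _disk_kernel(
        depths, depth_grid_um, geometry.conductivity, geometry.source_diameter_um
    )
    fmat = kern @ basis * h
    return fmat, basis, depth_grid_um


def _loocv_lambda(fmat: np.ndarray, lfp: np.ndarray, grid: np.ndarray) -> float:
    """Leave-one-channel-out prediction error over a lambda grid."""
    n_ch = fmat.shape[0]
    errs = np.zeros(len(grid))
    # subsample time columns: CV error is an average, a few thousand
    # samples estimate it accurately
    n_t = lfp.shape[1]
    cols = slice(None) if n_t <= 20000 else slice(0, n_t, n_t // 20000 + 1)
    lfp_cv = lfp[:, cols]
    for j in range(n_ch):
        keep = np.arange(n_ch) != j
        f_j = fmat[keep]
        gram = f_j.T @ f_j
        rhs = f_j.T @ lfp_cv[keep]
        for k, lam in enumerate(grid):
            coef = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), rhs)
            pred = fmat[j] @ coef
            errs[k] += np.mean((pred - lfp_cv[j]) ** 2)
    return float(grid[int(np.argmin(errs))])


def inverse_csd(
    lfp: np.ndarray,
    geometry: ProbeGeometry,
    fs: float,
    lam: float | None = None,
    depth_grid_um: np.ndarray | None = None,
) -> CsdMap:
    """Ridge-regularised inversion of the spline iCSD forward model.

    Solves, jointly for all time samples,
    ``min_c ||F c - lfp||^2 + lam ||c||^2`` and returns the interpolated CSD
    on the fine depth grid.  When ``lam`` is None it is selected by
    leave-one-channel-out cross-validation on a 25-point log grid spanning
    ``[1e-8, 1e2] * trace(F'F)/n``.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim == 1:
        lfp = lfp[None, :]
    if not np.all(np.isfinite(lfp)):
        raise ValueError("LFP contains non-finite values")
    good = geometry.good_channels
    if lfp.shape[0] == len(geometry.channel_depths_um):
        lfp = lfp[good]
    elif lfp.shape[0] != len(good):
        raise ValueError("LFP row count matches neither all nor good channels")
    fmat, basis, depth_grid_um = forward_matrix(geometry, depth_grid_um)
    if np.linalg.matrix_rank(fmat) < fmat.shape[1]:
        raise ValueError("forward matrix is rank deficient")
    scale = np.trace(fmat.T @ fmat) / fmat.shape[1]
    if lam is None:
        grid = np.logspace(-8, 2, 25) * scale
        lam = _loocv_lambda(fmat, lfp, grid)
    gram = fmat.T @ fmat + lam * np.eye(fmat.shape[1])
    coef = np.linalg.solve(gram, fmat.T @ lfp)
    return CsdMap(depth_grid_um=depth_grid_um, values=basis @ coef, fs=fs, lam=lam)


def median_filter_1s(x: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Centered running median with reflect padding (edge-transient free)."""
    win = int(round(window_s * fs))
    win = max(win | 1, 3)
    half = win // 2
    padded = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    med = (
        pd.Series(padded).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    return med[half:-half]


def dg_activity(
    csd_map: CsdMap, layer_rows: np.ndarray, smooth_s: float = 1.0
) -> DgCsdActivity:
    """Rectified, layer-averaged, median-filtered, z-scored DG CSD signal."""
    layer_rows = np.asarray(layer_rows, dtype=int)
    if layer_rows.size == 0:
        raise ValueError("layer_rows is empty")
    raw = np.abs(csd_map.values[layer_rows]).mean(axis=0)
    smooth = median_filter_1s(raw, csd_map.fs, smooth_s)
    sd = smooth.std()
    if sd == 0:
        raise ValueError("degenerate session: zero-variance DG CSD activity")
    return DgCsdActivity(
        values=(smooth - smooth.mean()) / sd, fs=csd_map.fs, layer_rows=layer_rows
    )


def triggered_rectified_csd(
    signal: np.ndarray,
    fs: float,
    onset_times_s: np.ndarray,
    window_s: tuple[float, float] = (-0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Event-onset-triggered average of a (rectified) CSD-derived signal.

    Returns ``(lags_s, mean_trace)`` over the events whose window lies fully
    inside the trace.
    """
    onset_times_s = np.asarray(onset_times_s, dtype=float)
    if onset_times_s.size == 0:
        raise ValueError("no events supplied")
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    idx = np.round(onset_times_s * fs).astype(int)
    keep = (idx - pre >= 0) & (idx + post < len(signal))
    if not np.any(keep):
        raise ValueError("no events with full window coverage")
    snips = np.stack([signal[i - pre : i + post + 1] for i in idx[keep]])
    lags = np.arange(-pre, post + 1) / fs
    return lags, snips.mean(axis=0)
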