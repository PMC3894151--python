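"""Two-dimensional energy landscapes: PCA projection + kernel smoothing.

Conformer descriptors are projected onto their first two principal components,
and scattered energies are turned into a smooth surface with the
Nadaraya-Watson estimator (Gaussian kernel, per-axis bandwidths from the
normal reference rule h = 1.06 * sigma * m^(-1/5), scaled by a smoothing
factor, default 0.3). Smoothed values are convex combinations of the data, so
the surface never over- or undershoots the observed energy range; grid cells
that no data point reaches are masked rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

GRID_PAD_FRACTION = 0.05
DEFAULT_SMOOTHING_FACTOR = 0.3


@dataclass
class Projection2D:
    """PCA scores and the information needed to project new points."""

    scores: np.ndarray  # (m, 2)
    explained_variance_ratio: np.ndarray  # (2,)
    loadings: np.ndarray  # (d, 2), orthonormal columns
    center: np.ndarray  # (d,)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new descriptor rows into the fitted 2-D space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center) @ self.loadings


@dataclass
class SmoothedGrid:
    """Locally weighted energy averages on a regular grid; ``values`` is a
    masked array (masked where no data point carries weight)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ma.MaskedArray  # (len(grid_y), len(grid_x))
    bandwidths: tuple[float, float]
    smoothing_factor: float


def pca_project(X: np.ndarray, n_components: int = 2) -> Projection2D:
    """Project descriptor rows onto their top principal components.

    Components carry a deterministic sign: the largest-magnitude loading of
    each component is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 3:
        raise ValueError("PCA projection needs at least 3 samples")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # (d, k)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return Projection2D(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        center=pca.mean_.copy(),
    )


def normal_reference_bandwidth(x: np.ndarray) -> float:
    """Normal reference rule for one axis: h = 1.06 * sigma * m^(-1/5)."""
    x = np.asarray(x, dtype=float)
    return 1.06 * float(x.std()) * len(x) ** (-1.0 / 5.0)


def smooth_landscape(
    points: np.ndarray,
    values: np.ndarray,
    grid_size: int = 200,
    bandwidth_rule: str = "normal_reference",
    smoothing_factor: float = DEFAULT_SMOOTHING_FACTOR,
) -> SmoothedGrid:
    """Nadaraya-Watson surface of ``values`` over 2-D ``points``.

    The grid spans the data bounding box padded by 5% per side. At grid point
    g the value is sum_i w_i v_i / sum_i w_i with Gaussian weights
    w_i = exp(-0.5 * [((gx-px_i)/hx)^2 + ((gy-py_i)/hy)^2]).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if points.shape != (len(values), 2):
        raise ValueError("points must be (m, 2) matching len(values)")
    if len(values) < 2:
        raise ValueError("need at least 2 data points to smooth")
    if not np.all(np.isfinite(points)) or not np.all(np.isfinite(values)):
        raise ValueError("points and values must be finite")
    if bandwidth_rule != "normal_reference":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if smoothing_factor <= 0:
        raise ValueError("smoothing_factor must be positive")
    hx = normal_reference_bandwidth(points[:, 0]) * smoothing_factor
    hy = normal_reference_bandwidth(points[:, 1]) * smoothing_factor
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate data: zero spread along one axis")
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    pad = GRID_PAD_FRACTION * (hi - lo)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
    # row-chunked accumulation keeps memory at O(grid_size * m)
    ex = np.exp(-0.5 * ((gx[:, None] - points[None, :, 0]) / hx) ** 2)  # (gx, m)
    out = np.empty((grid_size, grid_size))
    wsum = np.empty((grid_size, grid_size))
    for iy, gyv in enumerate(gy):
        wy = np.exp(-0.5 * ((gyv - points[:, 1]) / hy) ** 2)  # (m,)
        w = ex * wy[None, :]  # (gx, m)
        s = w.sum(axis=1)
        wsum[iy] = s
        with np.errstate(invalid="ignore", divide="ignore"):
            out[iy] = (w @ values) / s
    masked = np.ma.masked_array(out, mask=~np.isfinite(out) | (wsum == 0.0))
    return SmoothedGrid(gx, gy, masked, (hx, hy), smoothing_factor)


def plot_landscape(grid: SmoothedGrid, path, points=None, title=None) -> None:
    """Render a smoothed landscape to file (blue = low, red = high energy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    pcm = ax.pcolormesh(grid.grid_x, grid.grid_y, grid.values, cmap="jet", shading="auto")
    fig.colorbar(pcm, ax=ax, label="relative energy (kJ/mol)")
    if points is not None:
        ax.plot(points[:, 0], points[:, 1], "k.", ms=2, alpha=0.5)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
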