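"""Orientation-averaged scattering of arbitrary point clouds.

A particle, cluster or nanocrystal is represented by N point scatterers
with positions r_i and scattering lengths b_i (optionally a shared
normalized subparticle amplitude f_a(q)).  For each momentum-transfer
magnitude q the coherent amplitude A(q u) = sum_i b_i f_a(q) exp(i q u.r_i)
is evaluated on a spherical grid of directions u (Fibonacci lattice or
pseudorandom) and averaged:

    I(q)    = <|A|^2>_u            (Debye-equation equivalent)
    beta(q) = |<A>_u|^2 / <|A|^2>_u   (asymmetry factor in [0, 1])

Gaussian positional disorder with rms displacement sigma enters through
the Debye-Waller factor DW = exp(-q^2 sigma^2) as the standard
coherent + diffuse decomposition

    I(q) = DW(q) <|A|^2> + (1 - DW(q)) sum_i b_i^2 f_a^2 .

Lattice-cluster builders (sc/bcc/fcc clipped to a cube or sphere) feed the
same machinery; dividing the cluster intensity by N yields the cluster
structure factor used to cross-check the analytic lattice models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .datacore import DataCollection, DataSet, parse_ascii, write_ascii

__all__ = [
    "PointCloud",
    "OrientationGrid",
    "fibonacci_sphere",
    "random_sphere",
    "build_lattice_cloud",
    "cloud_intensity",
    "load_cloud",
    "save_cloud",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass
class PointCloud:
    """Positions (N x 3), per-point scattering lengths b and optional
    shared normalized amplitude function fa(q) (fa(0) = 1)."""

    positions: np.ndarray
    b: np.ndarray | float = 1.0
    fa: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.positions.shape[0] < 1:
            raise ValueError("cloud needs at least one point")
        self.b = np.broadcast_to(np.asarray(self.b, dtype=float),
                                 (self.positions.shape[0],)).copy()
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.b))):
            raise ValueError("positions and b must be finite")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def extent(self) -> float:
        """Largest pairwise distance estimate (diameter of bounding box)."""
        span = self.positions.max(axis=0) - self.positions.min(axis=0)
        return float(np.linalg.norm(span))

    def translated(self, shift) -> "PointCloud":
        return PointCloud(self.positions + np.asarray(shift, dtype=float),
                          self.b.copy(), self.fa)

    def rotated(self, matrix) -> "PointCloud":
        R = np.asarray(matrix, dtype=float)
        return PointCloud(self.positions @ R.T, self.b.copy(), self.fa)


@dataclass
class OrientationGrid:
    """Unit direction vectors with uniform weights."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        norms = np.linalg.norm(self.vectors, axis=1)
        if self.vectors.shape[0] == 0:
            raise ValueError("empty orientation grid")
        if np.max(np.abs(norms - 1.0)) > 1e-12:
            self.vectors = self.vectors / norms[:, None]

    @property
    def m(self) -> int:
        return self.vectors.shape[0]


def fibonacci_sphere(n: int) -> OrientationGrid:
    """Deterministic golden-angle spiral of exactly 2n+1 points."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(-n, n + 1)
    m = 2 * n + 1
    sin_lat = 2.0 * i / m
    cos_lat = np.sqrt(np.clip(1.0 - sin_lat**2, 0.0, None))
    lon = 2.0 * np.pi * i / _GOLDEN
    v = np.column_stack([cos_lat * np.cos(lon), cos_lat * np.sin(lon), sin_lat])
    return OrientationGrid(v)


def random_sphere(m: int, seed: int = 12345) -> OrientationGrid:
    """m pseudorandom directions, uniform on the sphere."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1.0, 1.0, m)
    phi = rng.uniform(0.0, 2.0 * np.pi, m)
    s = np.sqrt(1.0 - z**2)
    return OrientationGrid(np.column_stack([s * np.cos(phi), s * np.sin(phi), z]))


_BASIS = {
    "sc": np.array([[0.0, 0.0, 0.0]]),
    "bcc": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
    "fcc": np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                     [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]),
}


def build_lattice_cloud(lattice: str, a: float, shape: str = "cube",
                        size: float = 3.0) -> PointCloud:
    """Conventional-cell lattice points clipped to a cube or sphere.

    For ``shape='cube'`` the cloud contains every lattice point with all
    coordinates in [0, size] (inclusive edges, so an sc cube of edge m*a
    holds (m+1)^3 points); for ``shape='sphere'`` every point within
    distance ``size`` of the origin.  All scattering lengths are 1.
    """
    if lattice not in _BASIS:
        raise ValueError(f"unknown lattice {lattice!r}")
    if a <= 0 or size <= 0:
        raise ValueError("a and size must be > 0")
    ncell = int(np.ceil(size / a)) + 1
    ii = np.arange(-ncell, ncell + 1)
    cells = np.array(np.meshgrid(ii, ii, ii, indexing="ij")).reshape(3, -1).T
    pts = (cells[:, None, :] + _BASIS[lattice][None, :, :]).reshape(-1, 3) * a
    if shape == "cube":
        eps = 1e-9 * a
        keep = np.all((pts >= -eps) & (pts <= size + eps), axis=1)
    elif shape == "sphere":
        keep = np.einsum("ij,ij->i", pts, pts) <= (size + 1e-9 * a) ** 2
    else:
        raise ValueError(f"unknown shape {shape!r}")
    pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("no lattice points inside the requested shape")
    return PointCloud(pts, 1.0)


def default_grid(qmax: float, cloud: PointCloud) -> OrientationGrid:
    """Adaptive Fibonacci grid: n = max(100, qmax * extent) points."""
    n = int(max(100, qmax * cloud.extent()))
    return fibonacci_sphere(n)


def cloud_intensity(cloud: PointCloud, q, grid: OrientationGrid | None = None,
                    rms_displacement: float = 0.0) -> DataSet:
    """Orientation-averaged intensity and asymmetry factor of a cloud.

    Returns a DataSet with columns [q, I, beta]; beta(q) =
    |<A>|^2 / <|A|^2> corrects structure factors for particle asymmetry.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    if rms_displacement < 0:
        raise ValueError("rms_displacement must be >= 0")
    if grid is None:
        grid = default_grid(q.max() if q.size else 1.0, cloud)
    if grid.m == 0:
        raise ValueError("empty orientation grid")

    fa2 = cloud.fa(q) ** 2 if cloud.fa is not None else np.ones_like(q)
    sum_b2 = float(np.sum(cloud.b**2))

    I = np.empty_like(q)
    beta = np.empty_like(q)
    # chunk over q to bound the (nq, m, N) intermediate
    chunk = max(1, int(2e7 / max(1, grid.m * cloud.n)))
    proj = grid.vectors @ cloud.positions.T  # (m, N) projections u.r
    for s in range(0, q.size, chunk):
        qs = q[s:s + chunk]
        phase = qs[:, None, None] * proj[None, :, :]
        amp = np.einsum("j,qmj->qm", cloud.b.astype(complex), np.exp(1j * phase))
        mean_amp2 = np.mean(np.abs(amp) ** 2, axis=1)
        mean_amp = np.mean(amp, axis=1)
        I[s:s + chunk] = mean_amp2
        with np.errstate(invalid="ignore", divide="ignore"):
            beta[s:s + chunk] = np.where(
                mean_amp2 > 0, np.abs(mean_amp) ** 2 / mean_amp2, 1.0
            )
    I *= fa2
    beta = np.clip(beta, 0.0, 1.0)
    if rms_displacement > 0:
        dw = np.exp(-(q * rms_displacement) ** 2)
        I = dw * I + (1.0 - dw) * sum_b2 * fa2
    return DataSet(np.column_stack([q, I, beta]),
                   {"n_points": cloud.n, "sum_b": float(np.sum(cloud.b)),
                    "rms_displacement": rms_displacement,
                    "n_orientations": grid.m},
                   [], {"X": 0, "Y": 1})


# ---------------------------------------------------------------------------
# 4-column ASCII [x y z b] import/export in the datacore dialect
# ---------------------------------------------------------------------------

def save_cloud(cloud: PointCloud, sink) -> str:
    ds = DataSet(np.column_stack([cloud.positions, cloud.b]),
                 {"n_points": cloud.n}, ["point cloud: x y z b"],
                 {"X": 0, "Y": 1})
    return write_ascii(DataCollection([ds]), sink)


def load_cloud(source) -> PointCloud:
    coll = parse_ascii(source)
    if len(coll) != 1:
        raise ValueError(f"expected one block, found {len(coll)}")
    ds = coll[0]
    if ds.ncols < 4:
        raise ValueError("cloud file needs 4 columns x y z b")
    return PointCloud(ds.data[:, :3], ds.data[:, 3])
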