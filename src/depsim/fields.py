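"""Tapered-microelectrode geometry and the 2D electro-quasistatic field solve.

The device is a pair of coplanar tapered electrodes on the floor of a
rectangular fluid chamber.  Driven at ±V₀, the potential in the homogeneous
fluid obeys Laplace's equation with Dirichlet values on the electrode
surfaces and insulating (zero normal current) walls elsewhere.  Because the
fluid is a single uniform phase, one real solve serves every drive
frequency; frequency enters the force only through Re[f_CM].

The solver discretises the chamber on a uniform grid with a standard
5-point Laplacian (mirror ghost nodes for the Neumann walls) and a direct
sparse factorisation.  From the potential it derives the field phasor
E = −∇V and the DEP drive term ∇|E_rms|², with E_rms = |E|/√2 for a
sinusoidal drive of amplitude V₀.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from shapely.geometry import Polygon

__all__ = [
    "TABLE_DIMS",
    "ElectrodeGeometry",
    "FieldSolution",
    "build_geometry",
    "solve_potential",
    "gradient_field_intensity",
    "sample",
]

#: Default device dimensions (µm / degrees): electrode base widths W1, W3 =
#: 100, gap W2 = 80, chamber W4 × H3 = 280 × 80, electrode height H1 = 4,
#: sidewall angle A1 = 75° (A2 = 15° is its complement to the vertical and
#: carries no independent information).
TABLE_DIMS: dict[str, float] = {
    "w1": 100.0,
    "w2": 80.0,
    "w3": 100.0,
    "w4": 280.0,
    "a1": 75.0,
    "a2": 15.0,
    "h1": 4.0,
    "h2": 4.0,
    "h3": 80.0,
}


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Two tapered electrodes on the floor of a rectangular chamber.

    All lengths in µm, angles in degrees.  Electrodes sit flush with the
    left and right chamber walls; the inner sidewall of each is inclined at
    ``a1`` from the horizontal, so the top face is set back from the gap by
    h1/tan(a1).
    """

    w1: float = TABLE_DIMS["w1"]
    w2: float = TABLE_DIMS["w2"]
    w3: float = TABLE_DIMS["w3"]
    w4: float = TABLE_DIMS["w4"]
    a1: float = TABLE_DIMS["a1"]
    a2: float = TABLE_DIMS["a2"]
    h1: float = TABLE_DIMS["h1"]
    h2: float = TABLE_DIMS["h2"]
    h3: float = TABLE_DIMS["h3"]

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "h1", "h3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.a1 <= 90:
            raise ValueError(f"sidewall angle a1 must be in (0, 90], got {self.a1}")
        if not math.isclose(self.w1 + self.w2 + self.w3, self.w4, rel_tol=1e-9):
            raise ValueError(
                f"inconsistent widths: W1+W2+W3 = {self.w1 + self.w2 + self.w3} "
                f"!= W4 = {self.w4}"
            )
        if self.h1 > self.h3:
            raise ValueError("electrode height h1 cannot exceed chamber height h3")

    @property
    def _setback(self) -> float:
        """Horizontal set-back of the electrode top edge due to the taper."""
        return self.h1 / math.tan(math.radians(self.a1))

    @cached_property
    def left_polygon(self) -> Polygon:
        s = self._setback
        return Polygon([(0, 0), (self.w1, 0), (self.w1 - s, self.h1), (0, self.h1)])

    @cached_property
    def right_polygon(self) -> Polygon:
        s = self._setback
        x0 = self.w1 + self.w2
        return Polygon([(x0, 0), (self.w4, 0), (self.w4, self.h1), (x0 + s, self.h1)])

    @property
    def inner_corners(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Top inner electrode corners (µm) — the high-field-intensity spots."""
        s = self._setback
        return ((self.w1 - s, self.h1), (self.w1 + self.w2 + s, self.h1))

    def contains(self, x, y) -> np.ndarray:
        """True where (x, y) µm lies inside or on either electrode.

        Vectorised analytic trapezoid test; agrees with the shapely polygons
        (the two representations are cross-checked in the test suite).
        """
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        cot = 1.0 / math.tan(math.radians(self.a1))
        off = y * cot
        in_band = (y >= 0) & (y <= self.h1)
        left = in_band & (x >= 0) & (x <= self.w1 - off)
        right = in_band & (x <= self.w4) & (x >= self.w1 + self.w2 + off)
        return left | right

    def in_domain(self, x, y) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= 0) & (x <= self.w4) & (y >= 0) & (y <= self.h3)


def build_geometry(dims: dict[str, float] | None = None) -> ElectrodeGeometry:
    """Construct an :class:`ElectrodeGeometry`, overriding default dimensions.

    ``dims`` maps lower-case symbol names (``w1`` ... ``h3``, ``a1``) to
    values in µm / degrees; omitted entries keep the defaults.
    """
    merged = dict(TABLE_DIMS)
    if dims:
        unknown = set(dims) - set(TABLE_DIMS)
        if unknown:
            raise ValueError(f"unknown geometry parameters: {sorted(unknown)}")
        merged.update(dims)
    return ElectrodeGeometry(**merged)


@dataclass
class FieldSolution:
    """Gridded potential, field phasor and DEP drive term over the chamber.

    ``x`` and ``y`` are node coordinates in µm; ``potential`` (V), ``ex``/``ey``
    (V/m, phasor amplitude) and ``grad_e2x``/``grad_e2y`` (V²/m³, gradient of
    |E_rms|²) are (ny, nx) arrays.  ``solid`` marks nodes inside an electrode.
    """

    geometry: ElectrodeGeometry
    x: np.ndarray
    y: np.ndarray
    potential: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    grad_e2x: np.ndarray
    grad_e2y: np.ndarray
    solid: np.ndarray
    v_left: float
    v_right: float
    resolution: float
    residual: float

    @property
    def e_magnitude(self) -> np.ndarray:
        """|E| phasor amplitude (V/m) per node."""
        return np.hypot(self.ex, self.ey)


def _electrode_mask(geometry: ElectrodeGeometry, X: np.ndarray, Y: np.ndarray, resolution: float):
    # tiny dilation so nodes numerically on the sloped face count as electrode
    eps = 1e-6 * resolution
    left = geometry.left_polygon.buffer(eps)
    right = geometry.right_polygon.buffer(eps)
    pts = shapely.points(X.ravel(), Y.ravel())
    on_left = shapely.covers(left, pts).reshape(X.shape)
    on_right = shapely.covers(right, pts).reshape(X.shape)
    return on_left, on_right


def solve_potential(
    geometry: ElectrodeGeometry,
    v_left: float = 10.0,
    v_right: float = -10.0,
    resolution: float = 0.5,
) -> FieldSolution:
    """Solve the Laplace problem for the drive (v_left, v_right) volts.

    ``resolution`` is the uniform grid spacing in µm; it must put at least
    40 nodes across the electrode gap so the high-field corners are
    resolved.  Raises RuntimeError if the discrete residual exceeds 1e-8
    relative to the drive scale.
    """
    if geometry.w2 / resolution < 40:
        raise ValueError(
            f"resolution {resolution} µm too coarse: need >= 40 nodes across "
            f"the {geometry.w2} µm gap"
        )
    nx = int(round(geometry.w4 / resolution)) + 1
    ny = int(round(geometry.h3 / resolution)) + 1
    x = np.linspace(0.0, geometry.w4, nx)
    y = np.linspace(0.0, geometry.h3, ny)
    X, Y = np.meshgrid(x, y)

    on_left, on_right = _electrode_mask(geometry, X, Y, resolution)
    dirichlet = on_left | on_right
    bc = np.where(on_left, v_left, 0.0) + np.where(on_right, v_right, 0.0)

    n = nx * ny
    idx = np.arange(n).reshape(ny, nx)
    free = ~dirichlet.ravel()

    # 5-point Laplacian with mirror (ghost) reflection at the chamber walls:
    # the out-of-domain neighbour of a wall node is replaced by its interior
    # mirror, which enforces a zero normal derivative to second order.
    rows, cols, vals = [], [], []
    J, I = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni = np.clip(I + di, None, nx - 1)
        ni = np.where(I + di < 0, 1, ni)
        ni = np.where(I + di > nx - 1, nx - 2, ni)
        nj = np.where(J + dj < 0, 1, np.where(J + dj > ny - 1, ny - 2, J + dj))
        rows.append(idx.ravel())
        cols.append(idx[nj.ravel(), ni.ravel()])
        vals.append(np.ones(n))
    rows = np.concatenate(rows + [idx.ravel()])
    cols = np.concatenate(cols + [idx.ravel()])
    vals = np.concatenate(vals + [-4.0 * np.ones(n)])

    keep = free[rows]
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    # Dirichlet rows: identity
    dir_idx = idx.ravel()[~free]
    rows = np.concatenate([rows, dir_idx])
    cols = np.concatenate([cols, dir_idx])
    vals = np.concatenate([vals, np.ones(dir_idx.size)])

    a = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    b = np.where(free, 0.0, bc.ravel())

    u = spsolve(a, b)
    scale = max(abs(v_left), abs(v_right), 1.0)
    residual = float(np.max(np.abs(a @ u - b)) / scale)
    if residual > 1e-8:
        raise RuntimeError(f"Laplace solve failed to converge: residual {residual:.3e}")

    v = u.reshape(ny, nx)
    h = resolution * 1e-6  # metres
    ey_neg, ex_neg = np.gradient(v, h, h)
    ex, ey = -ex_neg, -ey_neg
    ex[dirichlet] = 0.0
    ey[dirichlet] = 0.0

    sol = FieldSolution(
        geometry=geometry,
        x=x,
        y=y,
        potential=v,
        ex=ex,
        ey=ey,
        grad_e2x=np.zeros_like(v),
        grad_e2y=np.zeros_like(v),
        solid=dirichlet,
        v_left=v_left,
        v_right=v_right,
        resolution=resolution,
        residual=residual,
    )
    gradient_field_intensity(sol)
    return sol


def gradient_field_intensity(solution: FieldSolution) -> tuple[np.ndarray, np.ndarray]:
    """Compute ∇|E_rms|² (V²/m³) by centred differences and store it in place.

    The drive voltages are sinusoidal amplitudes, so |E_rms|² = |E|²/2.
    Values on electrode nodes are zeroed: the field is undefined in the
    solid and particles freeze on contact before entering it.
    """
    h = solution.resolution * 1e-6
    e2_rms = 0.5 * (solution.ex**2 + solution.ey**2)
    gy, gx = np.gradient(e2_rms, h, h)
    gx[solution.solid] = 0.0
    gy[solution.solid] = 0.0
    solution.grad_e2x = gx
    solution.grad_e2y = gy
    return gx, gy


def sample(solution: FieldSolution, point: tuple[float, float]) -> dict:
    """Bilinearly interpolate the solution at ``point`` (µm coordinates).

    Returns a dict with keys ``potential`` (V), ``e`` (V/m vector),
    ``grad_e2`` (V²/m³ vector) and ``solid`` (True when the point lies in an
    electrode, where the interpolated values are not physical).
    Raises ValueError for points outside the chamber.
    """
    px, py = float(point[0]), float(point[1])
    if not solution.geometry.in_domain(px, py):
        raise ValueError(f"point {point} outside the {solution.geometry.w4} x "
                         f"{solution.geometry.h3} µm domain")
    fields = np.stack([
        solution.potential,
        solution.ex,
        solution.ey,
        solution.grad_e2x,
        solution.grad_e2y,
    ])
    vals = _bilinear(solution, fields, np.array([[px, py]]))[0]
    in_solid = bool(solution.geometry.contains(px, py))
    return {
        "potential": float(vals[0]),
        "e": np.array([vals[1], vals[2]]),
        "grad_e2": np.array([vals[3], vals[4]]),
        "solid": in_solid,
    }


def _bilinear(solution: FieldSolution, fields: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of stacked (k, ny, nx) fields at (m, 2) µm points."""
    res = solution.resolution
    fx = np.clip(points[:, 0] / res, 0, solution.x.size - 1 - 1e-12)
    fy = np.clip(points[:, 1] / res, 0, solution.y.size - 1 - 1e-12)
    i0 = fx.astype(int)
    j0 = fy.astype(int)
    tx = fx - i0
    ty = fy - j0
    f00 = fields[:, j0, i0]
    f10 = fields[:, j0, i0 + 1]
    f01 = fields[:, j0 + 1, i0]
    f11 = fields[:, j0 + 1, i0 + 1]
    out = (
        f00 * (1 - tx) * (1 - ty)
        + f10 * tx * (1 - ty)
        + f01 * (1 - tx) * ty
        + f11 * tx * ty
    )
    return out.T
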