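"""Particle trajectories under DEP force and Stokes drag in the solved field.

The time-averaged DEP force on a small sphere of radius r in a medium of
relative permittivity ε_m is

    F_DEP = 2π r³ ε₀ ε_m Re[f_CM] ∇|E_rms|².

Drag follows Stokes' law, F_drag = 6πµr (u − v), with u the fluid velocity
(zero for the quiescent chamber: no inlet, no pressure head, no-slip walls).
Particle inertia relaxes on the timescale τ_p = ρ_p (2r)² / (18µ) — well
under a millisecond for micron beads — so the default integrator is the
overdamped limit v = u + F_DEP / (6πµr); an inertial mode (exact
exponential update of the linear drag equation over each step) is provided
to verify that the limit is innocuous.

Particles released on a grid drift until they touch a wall or an electrode,
where they freeze permanently (the "freeze" wall condition); afterwards the
trajectory is classified as positive DEP (arrived at a high-field electrode
corner), negative DEP (pushed away into the low-field region) or crossover
(net displacement below a static threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dielectrics import VACUUM_PERMITTIVITY, RegimeLabel
from .fields import ElectrodeGeometry, FieldSolution, _bilinear

__all__ = [
    "ParticleSpec",
    "FluidSpec",
    "ReleaseGrid",
    "Trajectory",
    "expand_release_grid",
    "dep_force",
    "stokes_params",
    "simulate",
    "classify_trajectory",
]


@dataclass(frozen=True)
class ParticleSpec:
    """What the tracer needs to know about one particle species."""

    radius: float          # m
    density: float         # kg/m3
    re_fcm: float          # Re[f_CM] at the drive frequency
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not -0.5 <= self.re_fcm <= 1.0:
            raise ValueError(f"re_fcm must lie in [-0.5, 1], got {self.re_fcm}")


@dataclass(frozen=True)
class FluidSpec:
    """Suspending fluid: viscosity, density, ε_m, and an optional flow field.

    ``velocity_field`` maps a (x, y) µm point to a fluid velocity in m/s;
    None means the quiescent default u = 0 everywhere.
    """

    viscosity: float = 8.9e-4           # Pa s (water at ~25 C)
    density: float = 997.0              # kg/m3
    relative_permittivity: float = 78.0
    velocity_field: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")

    def velocity(self, point: np.ndarray) -> np.ndarray:
        if self.velocity_field is None:
            return np.zeros(2)
        return np.asarray(self.velocity_field(point), dtype=float)


@dataclass(frozen=True)
class ReleaseGrid:
    """Release positions as (start, step, stop) µm triplets per axis."""

    x_spec: tuple[float, float, float]
    y_spec: tuple[float, float, float]

    def __post_init__(self) -> None:
        for start, step, stop in (self.x_spec, self.y_spec):
            if step <= 0:
                raise ValueError("grid step must be > 0")
            if start > stop:
                raise ValueError("grid start must not exceed stop")


def expand_release_grid(grid: ReleaseGrid) -> list[tuple[float, float]]:
    """Cartesian product of the two arithmetic sequences start, start+step, ... <= stop."""

    def seq(spec: tuple[float, float, float]) -> np.ndarray:
        start, step, stop = spec
        n = int(math.floor((stop - start) / step + 1e-9)) + 1
        return start + step * np.arange(n)

    xs, ys = seq(grid.x_spec), seq(grid.y_spec)
    return [(float(x), float(y)) for x in xs for y in ys]


def dep_force(particle: ParticleSpec, fluid: FluidSpec, grad_e2: np.ndarray) -> np.ndarray:
    """DEP force vector (N): 2π r³ ε₀ ε_m Re[f_CM] ∇|E_rms|²."""
    pref = (
        2.0 * math.pi
        * particle.radius**3
        * VACUUM_PERMITTIVITY
        * fluid.relative_permittivity
        * particle.re_fcm
    )
    return pref * np.asarray(grad_e2, dtype=float)


def stokes_params(particle: ParticleSpec, fluid: FluidSpec) -> tuple[float, float]:
    """(drag coefficient 6πµr in N·s/m, velocity response time τ_p in s)."""
    drag = 6.0 * math.pi * fluid.viscosity * particle.radius
    tau = particle.density * (2.0 * particle.radius) ** 2 / (18.0 * fluid.viscosity)
    return drag, tau


@dataclass
class Trajectory:
    """Timestamped path of one released particle (positions in µm, v in m/s)."""

    particle: ParticleSpec
    release: tuple[float, float]
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    velocities: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    frozen: bool = False
    freeze_time: float | None = None
    regime: RegimeLabel | None = None

    @property
    def net_displacement(self) -> float:
        """|final − initial| in µm."""
        if len(self.positions) < 2:
            return 0.0
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


class _FieldSampler:
    """Fast repeated bilinear sampling of ∇|E_rms|² at µm points."""

    def __init__(self, solution: FieldSolution):
        self._sol = solution
        self._stack = np.stack([solution.grad_e2x, solution.grad_e2y])

    def grad_e2(self, point: np.ndarray) -> np.ndarray:
        return _bilinear(self._sol, self._stack, point[None, :])[0]


def _is_valid(geometry: ElectrodeGeometry, p: np.ndarray) -> bool:
    if not (0.0 <= p[0] <= geometry.w4 and 0.0 <= p[1] <= geometry.h3):
        return False
    return not bool(geometry.contains(p[0], p[1]))


def _contact_point(geometry: ElectrodeGeometry, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bisect the segment a→b (a valid, b not) down to the contact point."""
    lo, hi = a.copy(), b.copy()
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if _is_valid(geometry, mid):
            lo = mid
        else:
            hi = mid
    return lo


def simulate(
    particles: Sequence[ParticleSpec],
    grids: Sequence[ReleaseGrid],
    solution: FieldSolution,
    fluid: FluidSpec,
    duration: float = 20.0,
    mode: str = "overdamped",
    dt_max: float = 0.01,
    record_interval: float = 0.1,
) -> list[Trajectory]:
    """Trace every release of every particle species for ``duration`` seconds.

    ``particles`` and ``grids`` are paired index-by-index when the lists have
    equal length (species i released from grid i); a single grid is shared by
    all species.  ``mode`` is "overdamped" (v = u + F/6πµr, the default for
    micron-scale beads) or "inertial" (exponential integrator for the full
    m dv/dt equation).  The time step adapts so no step moves a particle more
    than half a grid cell; a particle whose step would still jump more than
    two cells triggers step halving, and a step below 1e-12 s aborts.

    Positions are recorded roughly every ``record_interval`` seconds plus at
    release and at freeze.
    """
    if mode not in ("overdamped", "inertial"):
        raise ValueError(f"unknown mode {mode!r}")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if len(grids) == 1:
        pairing = [(p, grids[0]) for p in particles]
    elif len(grids) == len(particles):
        pairing = list(zip(particles, grids))
    else:
        raise ValueError(
            f"cannot pair {len(particles)} particle specs with {len(grids)} grids"
        )

    sampler = _FieldSampler(solution)
    geometry = solution.geometry
    out: list[Trajectory] = []
    for spec, grid in pairing:
        for release in expand_release_grid(grid):
            out.append(
                _trace_one(
                    spec, np.array(release, float), sampler, geometry, fluid,
                    duration, mode, dt_max, record_interval,
                )
            )
    return out


def _trace_one(
    spec: ParticleSpec,
    release: np.ndarray,
    sampler: _FieldSampler,
    geometry: ElectrodeGeometry,
    fluid: FluidSpec,
    duration: float,
    mode: str,
    dt_max: float,
    record_interval: float,
) -> Trajectory:
    drag, tau = stokes_params(spec, fluid)

    max_step_um = 0.5 * sampler._sol.resolution
    dt_cap = min(dt_max, 10.0 * tau) if mode == "inertial" else dt_max

    t = 0.0
    p = release.copy()
    v = np.zeros(2)  # m/s; released at rest
    times = [0.0]
    positions = [p.copy()]
    velocities = [v.copy()]
    frozen = False
    freeze_time: float | None = None
    next_record = record_interval

    if not _is_valid(geometry, p):
        raise ValueError(f"release position {tuple(release)} is inside a solid region")

    # Trapped-particle detection: near the singular field maxima at the
    # electrode corners the drift velocity diverges and a displacement-capped
    # step oscillates across the attractor without ever entering the solid.
    # When every step in a window was velocity-limited yet the position went
    # nowhere, the particle is held at the corner: freeze it there.
    check_every = 64
    window_start = p.copy()
    window_limited = True
    step_count = 0

    while t < duration - 1e-12:
        g = sampler.grad_e2(p)
        f_dep = dep_force(spec, fluid, g)
        u = fluid.velocity(p)
        v_drift = u + f_dep / drag

        speed_um = np.linalg.norm(v_drift) * 1e6  # µm/s
        dt = dt_cap if speed_um == 0.0 else min(dt_cap, max_step_um / speed_um)
        dt = min(dt, duration - t)

        while True:
            if mode == "overdamped":
                v_new = v_drift
                step_m = v_drift * dt
            else:
                decay = math.exp(-dt / tau)
                v_new = v_drift + (v - v_drift) * decay
                step_m = v_drift * dt + (v - v_drift) * tau * (1.0 - decay)
            step_um = step_m * 1e6
            if np.linalg.norm(step_um) <= 2.0 * sampler._sol.resolution:
                break
            dt *= 0.5
            if dt < 1e-12:
                raise RuntimeError(
                    f"time step underflow at t={t:.3g}s, position {tuple(p)}"
                )

        p_new = p + step_um
        t += dt
        if not _is_valid(geometry, p_new):
            p_new = _contact_point(geometry, p, p_new)
            frozen = True
            freeze_time = t
        p = p_new
        v = v_new

        step_count += 1
        window_limited &= dt < 0.99 * dt_cap
        if not frozen and step_count % check_every == 0:
            if window_limited and np.linalg.norm(p - window_start) < 0.05 * sampler._sol.resolution:
                frozen = True
                freeze_time = t
            window_start = p.copy()
            window_limited = True

        if frozen or t >= next_record - 1e-12 or t >= duration - 1e-12:
            times.append(t)
            positions.append(p.copy())
            velocities.append(np.zeros(2) if frozen else v.copy())
            next_record = t + record_interval
        if frozen:
            break

    if frozen and times[-1] < duration:
        # hold the frozen particle in place to the end of the run
        times.append(duration)
        positions.append(p.copy())
        velocities.append(np.zeros(2))

    return Trajectory(
        particle=spec,
        release=(float(release[0]), float(release[1])),
        times=np.asarray(times),
        positions=np.asarray(positions),
        velocities=np.asarray(velocities),
        frozen=frozen,
        freeze_time=freeze_time,
    )


def classify_trajectory(
    traj: Trajectory,
    geometry: ElectrodeGeometry,
    static_displacement: float = 2.0,
    capture_distance: float = 3.0,
) -> RegimeLabel:
    """Label a finished trajectory PDEP, NDEP or CROSSOVER.

    A particle that barely moved (net displacement below
    ``static_displacement`` µm) sits at a crossover.  Otherwise the
    high-field spots — the top inner electrode corners — discriminate:
    arriving within ``capture_distance`` µm of a corner (or closing in on
    one) is positive DEP; retreating from them into the low-field region is
    negative DEP.
    """
    if len(traj.positions) < 2:
        return RegimeLabel.CROSSOVER
    if traj.net_displacement < static_displacement:
        return RegimeLabel.CROSSOVER
    corners = np.asarray(geometry.inner_corners)
    d_final = np.min(np.linalg.norm(corners - traj.positions[-1], axis=1))
    if d_final <= capture_distance:
        return RegimeLabel.PDEP
    d_initial = np.min(np.linalg.norm(corners - traj.positions[0], axis=1))
    return RegimeLabel.PDEP if d_final < d_initial else RegimeLabel.NDEP
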