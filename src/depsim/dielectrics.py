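"""Complex permittivities, Clausius-Mossotti spectra and DEP crossover frequencies.

The sign and magnitude of the time-averaged dielectrophoretic (DEP) force on
a small sphere are governed by the real part of the Clausius-Mossotti factor

    f_CM(ω) = (ε_p* − ε_m*) / (ε_p* + 2 ε_m*),

where ε* = ε₀ε_r − j σ/ω is the complex permittivity of the particle (p) and
suspending medium (m).  Re[f_CM] ranges over [−1/2, 1]: positive values mean
attraction toward field maxima (positive DEP), negative values repulsion
toward field minima (negative DEP).  The frequency at which Re[f_CM] changes
sign is the crossover frequency f_XO.

Two particle models are provided:

* :class:`HomogeneousBead` — a solid dielectric sphere (e.g. a polystyrene
  bead) whose effective conductivity includes a surface-conductance term,
  σ_p = σ_bulk + 2 K_s / r.
* :class:`ShelledCellModel` — a biological cell idealised as a conducting
  cytoplasm sphere coated by a thin, poorly conducting membrane; the two
  layers are reduced to one equivalent complex permittivity with the
  standard confocal single-shell formula.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "VACUUM_PERMITTIVITY",
    "DielectricMaterial",
    "HomogeneousBead",
    "ShelledCellModel",
    "CMFSpectrum",
    "RegimeLabel",
    "complex_permittivity",
    "bead_conductivity",
    "shell_equivalent_permittivity",
    "particle_complex_permittivity",
    "clausius_mossotti",
    "cmf_spectrum",
    "find_crossovers",
    "closed_form_crossover",
    "classify_regime",
]

#: Vacuum permittivity in F/m.
VACUUM_PERMITTIVITY: float = 8.8541878128e-12


@dataclass(frozen=True)
class DielectricMaterial:
    """A lossy dielectric phase: bulk conductivity (S/m) and relative permittivity.

    Used both for suspending media (DI water, culture media) and for the
    individual layers of a shelled cell (membrane, cytoplasm).
    """

    conductivity: float
    relative_permittivity: float

    def __post_init__(self) -> None:
        if self.conductivity < 0:
            raise ValueError(f"conductivity must be >= 0, got {self.conductivity}")
        if self.relative_permittivity < 1:
            raise ValueError(
                f"relative_permittivity must be >= 1, got {self.relative_permittivity}"
            )


@dataclass(frozen=True)
class HomogeneousBead:
    """A solid dielectric sphere with surface conduction.

    Parameters
    ----------
    radius
        Sphere radius r_ext in metres.
    bulk_conductivity
        Bulk (volume) conductivity σ_bulk in S/m.  For polystyrene this is
        negligible (~1e-16 S/m); conduction is dominated by the surface term.
    surface_conductance
        Surface conductance K_s in siemens; enters the effective particle
        conductivity as 2 K_s / r.
    relative_permittivity
        Relative permittivity of the sphere material.
    """

    radius: float
    bulk_conductivity: float
    surface_conductance: float
    relative_permittivity: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.bulk_conductivity < 0:
            raise ValueError("bulk_conductivity must be >= 0")
        if self.surface_conductance < 0:
            raise ValueError("surface_conductance must be >= 0")
        if self.relative_permittivity < 1:
            raise ValueError("relative_permittivity must be >= 1")


@dataclass(frozen=True)
class ShelledCellModel:
    """Single-shell cell: cytoplasm sphere coated by a thin membrane.

    ``outer_dimensions`` are the three overall cell dimensions in µm as
    measured (cells are rarely perfect spheres); the model sphere uses the
    volume-equivalent radius r_eq = (abc)^(1/3) / 2.
    """

    outer_dimensions: tuple[float, float, float]
    membrane: DielectricMaterial
    cytoplasm: DielectricMaterial
    membrane_thickness: float = 7e-9
    label: str = ""

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.outer_dimensions):
            raise ValueError("all outer dimensions must be positive")
        if not 0 < self.membrane_thickness < self.equivalent_radius:
            raise ValueError(
                "membrane_thickness must lie in (0, equivalent_radius); got "
                f"{self.membrane_thickness} vs r_eq={self.equivalent_radius:.3e}"
            )

    @property
    def equivalent_radius(self) -> float:
        """Volume-equivalent sphere radius in metres."""
        a, b, c = self.outer_dimensions
        return (a * b * c) ** (1.0 / 3.0) / 2.0 * 1e-6


Particle = Union[HomogeneousBead, ShelledCellModel]


class RegimeLabel(str, enum.Enum):
    """DEP response regime of a particle at a given drive frequency."""

    PDEP = "PDEP"
    NDEP = "NDEP"
    CROSSOVER = "CROSSOVER"


@dataclass(frozen=True)
class CMFSpectrum:
    """Clausius-Mossotti factor evaluated on a log-spaced frequency grid."""

    frequencies: np.ndarray
    re_fcm: np.ndarray
    im_fcm: np.ndarray
    crossovers: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be a strictly increasing 1-D grid")
        tol = 1e-9
        if np.any(self.re_fcm < -0.5 - tol) or np.any(self.re_fcm > 1.0 + tol):
            raise ValueError("Re[f_CM] out of the physical band [-1/2, 1]")
        if np.any(np.abs(self.im_fcm) > 0.75 + tol):
            raise ValueError("|Im[f_CM]| exceeds the physical bound 3/4")


def complex_permittivity(material: DielectricMaterial, frequency: float) -> complex:
    """Complex permittivity ε* = ε₀ε_r − j σ/ω of a lossy dielectric, in F/m.

    ``frequency`` is the drive frequency in Hz (must be positive).
    """
    if np.any(np.asarray(frequency) <= 0):
        raise ValueError(f"frequency must be > 0, got {frequency}")
    omega = 2.0 * math.pi * np.asarray(frequency, dtype=float)
    out = VACUUM_PERMITTIVITY * material.relative_permittivity - 1j * material.conductivity / omega
    return complex(out) if np.isscalar(frequency) else out


def bead_conductivity(bead: HomogeneousBead) -> float:
    """Effective conductivity σ_p = σ_bulk + 2 K_s / r_ext of a solid sphere (S/m).

    Surface conduction scales inversely with radius, so smaller beads are
    effectively more conductive.
    """
    return bead.bulk_conductivity + 2.0 * bead.surface_conductance / bead.radius


def shell_equivalent_permittivity(cell: ShelledCellModel, frequency: float):
    """Equivalent complex permittivity of a single-shell cell (confocal formula).

    The membrane (shell, thickness d) and cytoplasm (core) are smeared into
    one homogeneous sphere with

        ε*_eq = ε*_mem (γ³ + 2K) / (γ³ − K),
        K = (ε*_cyt − ε*_mem) / (ε*_cyt + 2 ε*_mem),
        γ = r_ext / (r_ext − d).

    The result replaces ε_p* in the Clausius-Mossotti factor.  Accepts a
    scalar or an array of frequencies.
    """
    r = cell.equivalent_radius
    d = cell.membrane_thickness
    if d >= r:
        raise ValueError("membrane thickness must be smaller than the cell radius")
    e_cyt = complex_permittivity(cell.cytoplasm, frequency)
    e_mem = complex_permittivity(cell.membrane, frequency)
    gamma3 = (r / (r - d)) ** 3
    k = (e_cyt - e_mem) / (e_cyt + 2.0 * e_mem)
    return e_mem * (gamma3 + 2.0 * k) / (gamma3 - k)


def particle_complex_permittivity(particle: Particle, frequency: float):
    """Complex permittivity of either particle model at ``frequency`` (Hz)."""
    if isinstance(particle, HomogeneousBead):
        mat = DielectricMaterial(
            conductivity=bead_conductivity(particle),
            relative_permittivity=particle.relative_permittivity,
        )
        return complex_permittivity(mat, frequency)
    if isinstance(particle, ShelledCellModel):
        return shell_equivalent_permittivity(particle, frequency)
    raise TypeError(f"unsupported particle model: {type(particle).__name__}")


def clausius_mossotti(particle_permittivity, medium_permittivity):
    """Clausius-Mossotti factor (ε_p* − ε_m*)/(ε_p* + 2 ε_m*).

    Raises ZeroDivisionError when the denominator vanishes (an unphysical
    index-matched resonance the spherical model cannot represent).
    """
    denom = particle_permittivity + 2.0 * medium_permittivity
    if np.any(np.abs(denom) == 0.0):
        raise ZeroDivisionError("vanishing denominator in Clausius-Mossotti factor")
    return (particle_permittivity - medium_permittivity) / denom


def _re_fcm(particle: Particle, medium: DielectricMaterial, frequency) -> float:
    ep = particle_complex_permittivity(particle, frequency)
    em = complex_permittivity(medium, frequency)
    return np.real(clausius_mossotti(ep, em))


def cmf_spectrum(
    particle: Particle,
    medium: DielectricMaterial,
    f_min: float = 1e3,
    f_max: float = 1e9,
    n_points: int = 400,
) -> CMFSpectrum:
    """Evaluate f_CM on a log-spaced grid and locate every crossover in range."""
    if not 0 < f_min < f_max:
        raise ValueError(f"need 0 < f_min < f_max, got [{f_min}, {f_max}]")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    freqs = np.logspace(math.log10(f_min), math.log10(f_max), n_points)
    ep = particle_complex_permittivity(particle, freqs)
    em = complex_permittivity(medium, freqs)
    fcm = clausius_mossotti(ep, em)
    xos = find_crossovers(particle, medium, f_min, f_max, n_scan=n_points)
    return CMFSpectrum(
        frequencies=freqs,
        re_fcm=np.real(fcm),
        im_fcm=np.imag(fcm),
        crossovers=tuple(xos),
    )


def find_crossovers(
    particle: Particle,
    medium: DielectricMaterial,
    f_min: float = 1e3,
    f_max: float = 1e9,
    n_scan: int = 400,
    rtol: float = 1e-6,
) -> list[float]:
    """All roots of Re[f_CM](f) in [f_min, f_max], ascending.

    A sign-change scan on a log-spaced grid brackets each root; brackets are
    then refined by bisection to relative tolerance ``rtol``.  Returns an
    empty list when Re[f_CM] never changes sign in the window.
    """
    if not 0 < f_min < f_max:
        raise ValueError(f"need 0 < f_min < f_max, got [{f_min}, {f_max}]")
    freqs = np.logspace(math.log10(f_min), math.log10(f_max), max(int(n_scan), 2))
    vals = np.asarray(_re_fcm(particle, medium, freqs))
    roots: list[float] = []
    for i in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        root = bisect(
            lambda f: _re_fcm(particle, medium, f),
            freqs[i],
            freqs[i + 1],
            rtol=rtol,
        )
        roots.append(float(root))
    # grid nodes that are exact zeros (rare but possible with synthetic params)
    for f, v in zip(freqs, vals):
        if v == 0.0:
            roots.append(float(f))
    return sorted(roots)


def closed_form_crossover(
    sigma_p: float, sigma_m: float, eps_p: float, eps_m: float
) -> float | None:
    """Analytic crossover of a homogeneous sphere, or None when there is none.

    Setting Re[f_CM] = 0 for frequency-independent σ and ε gives

        ω² = −(σ_p − σ_m)(σ_p + 2σ_m) / ((ε_p − ε_m)(ε_p + 2ε_m)),

    with ε in absolute units (F/m).  A real crossover exists only when the
    right-hand side is positive, i.e. when the conductivity and permittivity
    contrasts have opposite signs.
    """
    num = -(sigma_p - sigma_m) * (sigma_p + 2.0 * sigma_m)
    den = (eps_p - eps_m) * (eps_p + 2.0 * eps_m)
    if den == 0.0 or num / den <= 0.0:
        return None
    return math.sqrt(num / den) / (2.0 * math.pi)


def classify_regime(
    particle: Particle,
    medium: DielectricMaterial,
    frequency: float,
    static_threshold: float = 0.01,
) -> RegimeLabel:
    """Label the DEP response at ``frequency``: PDEP, NDEP or CROSSOVER.

    The CROSSOVER band is |Re[f_CM]| <= ``static_threshold``, within which the
    DEP force is too weak to displace the particle appreciably.
    """
    re = _re_fcm(particle, medium, float(frequency))
    if re > static_threshold:
        return RegimeLabel.PDEP
    if re < -static_threshold:
        return RegimeLabel.NDEP
    return RegimeLabel.CROSSOVER
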