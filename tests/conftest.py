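import pytest

import depsim


@pytest.fixture(scope="session")
def fx():
    """Packaged parameter fixtures (media, beads, cells, geometry, grids)."""
    return depsim.fixtures()


@pytest.fixture(scope="session")
def solution(fx):
    """Default field solve: ±10 V drive, 0.5 µm grid."""
    return depsim.solve_potential(fx["geometry"], 10.0, -10.0, 0.5)


@pytest.fixture(scope="session")
def water_fluid(fx):
    return depsim.FluidSpec(
        viscosity=fx["fluid"]["viscosity_pa_s"],
        density=fx["fluid"]["density_kg_m3"],
        relative_permittivity=fx["di_water"].relative_permittivity,
    )


def bead_particle_spec(fx, bead_name, frequency, medium_name="di_water"):
    """ParticleSpec for a bead fixture with Re[f_CM] evaluated at frequency."""
    from depsim.dielectrics import _re_fcm

    bead = fx[bead_name]
    return depsim.ParticleSpec(
        radius=bead.radius,
        density=fx["densities"]["polystyrene_kg_m3"],
        re_fcm=float(_re_fcm(bead, fx[medium_name], frequency)),
        label=bead_name,
    )


@pytest.fixture(scope="session")
def pdep_trajectories(fx, solution, water_fluid):
    """Both bead sizes traced at 140 kHz (positive DEP for both) for 20 s."""
    specs = [
        bead_particle_spec(fx, "ps_3p2um", 140e3),
        bead_particle_spec(fx, "ps_4p8um_printed", 140e3),
    ]
    return depsim.simulate(
        specs, [fx["grid_1"], fx["grid_2"]], solution, water_fluid, duration=20.0
    )
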