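"""Complex permittivity, Clausius-Mossotti factors and crossover frequencies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depsim.dielectrics import (
    VACUUM_PERMITTIVITY as EPS0,
    CMFSpectrum,
    DielectricMaterial,
    HomogeneousBead,
    RegimeLabel,
    ShelledCellModel,
    bead_conductivity,
    classify_regime,
    clausius_mossotti,
    closed_form_crossover,
    cmf_spectrum,
    complex_permittivity,
    find_crossovers,
    particle_complex_permittivity,
    shell_equivalent_permittivity,
)


class TestComplexPermittivity:
    def test_lossless_limit_is_purely_real(self):
        mat = DielectricMaterial(conductivity=0.0, relative_permittivity=2.56)
        eps = complex_permittivity(mat, 1e6)
        assert eps == pytest.approx(2.56 * EPS0)
        assert eps.imag == 0.0

    def test_di_water_loss_term(self):
        water = DielectricMaterial(conductivity=2e-4, relative_permittivity=78)
        f = 425.02e3
        eps = complex_permittivity(water, f)
        assert eps.real == pytest.approx(78 * EPS0)
        assert eps.imag == pytest.approx(-2e-4 / (2 * math.pi * f))

    def test_unit_conductivity_at_unit_angular_frequency(self):
        mat = DielectricMaterial(conductivity=1.0, relative_permittivity=1.0)
        eps = complex_permittivity(mat, 1.0 / (2 * math.pi))
        assert eps == pytest.approx(EPS0 - 1j)

    @pytest.mark.parametrize("freq", [0.0, -10.0])
    def test_rejects_nonpositive_frequency(self, freq):
        mat = DielectricMaterial(conductivity=0.1, relative_permittivity=10)
        with pytest.raises(ValueError):
            complex_permittivity(mat, freq)

    def test_material_invariants(self):
        with pytest.raises(ValueError):
            DielectricMaterial(conductivity=-1e-3, relative_permittivity=78)
        with pytest.raises(ValueError):
            DielectricMaterial(conductivity=0.1, relative_permittivity=0.5)


class TestBeadConductivity:
    def test_small_bead_matches_quoted_value(self):
        bead = HomogeneousBead(1.6e-6, 1e-16, 2e-9, 2.56)
        # 1e-16 + 2*2e-9/1.6e-6 = 2.5e-3 S/m to two significant figures
        assert bead_conductivity(bead) == pytest.approx(2.5e-3, rel=1e-3)

    def test_large_bead_rounds_to_quoted_value(self):
        bead = HomogeneousBead(2.4e-6, 1e-16, 2e-9, 2.56)
        sigma = bead_conductivity(bead)
        # exact value 1.667e-3 S/m, commonly quoted truncated as 1.6e-3
        assert sigma == pytest.approx(1.667e-3, rel=1e-3)
        assert math.floor(sigma * 1e4) / 1e4 == pytest.approx(1.6e-3)

    def test_no_surface_conduction_gives_bulk(self):
        bead = HomogeneousBead(1e-6, 0.025, 0.0, 2.56)
        assert bead_conductivity(bead) == 0.025

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            HomogeneousBead(0.0, 1e-16, 2e-9, 2.56)


class TestSingleShell:
    def test_degenerate_shell_equals_cytoplasm(self):
        mat = DielectricMaterial(0.5, 60)
        cell = ShelledCellModel((10, 10, 10), membrane=mat, cytoplasm=mat)
        for f in (1e4, 1e6, 1e9):
            eq = shell_equivalent_permittivity(cell, f)
            assert eq == pytest.approx(complex_permittivity(mat, f), rel=1e-12)

    def test_vanishing_shell_converges_to_cytoplasm(self):
        cyt = DielectricMaterial(0.12, 50)
        mem = DielectricMaterial(1e-6, 9.04)
        cell = ShelledCellModel((10, 10, 10), membrane=mem, cytoplasm=cyt,
                                membrane_thickness=5e-6 * 1e-9)
        f = 1e6
        eq = shell_equivalent_permittivity(cell, f)
        ref = complex_permittivity(cyt, f)
        assert abs(eq - ref) / abs(ref) < 1e-6

    def test_membrane_transparent_at_high_frequency(self, fx):
        ker = fx["keratinocyte"]
        f = 28e6
        eq = shell_equivalent_permittivity(ker, f)
        cyt = complex_permittivity(ker.cytoplasm, f)
        assert abs(eq - cyt) / abs(cyt) < 0.05

    def test_thick_membrane_rejected(self):
        mat = DielectricMaterial(0.5, 60)
        with pytest.raises(ValueError):
            ShelledCellModel((2, 2, 2), membrane=mat, cytoplasm=mat,
                             membrane_thickness=2e-6)

    def test_equivalent_radius_volume_rule(self, fx):
        a, b, c = fx["keratinocyte"].outer_dimensions
        assert fx["keratinocyte"].equivalent_radius == pytest.approx(
            (a * b * c) ** (1 / 3) / 2 * 1e-6
        )


class TestClausiusMossotti:
    def test_index_matching_is_zero(self):
        assert clausius_mossotti(3.1 - 0.2j, 3.1 - 0.2j) == 0.0

    def test_low_frequency_limit_is_conductivity_ratio(self, fx):
        bead = fx["ps_3p2um"]
        water = fx["di_water"]
        sp, sm = bead_conductivity(bead), water.conductivity
        expected = (sp - sm) / (sp + 2 * sm)
        ep = particle_complex_permittivity(bead, 1.0)
        em = complex_permittivity(water, 1.0)
        assert clausius_mossotti(ep, em).real == pytest.approx(expected, abs=1e-4)

    def test_high_frequency_limit_is_permittivity_ratio(self, fx):
        bead = fx["ps_3p2um"]
        water = fx["di_water"]
        expected = (2.56 - 78) / (2.56 + 2 * 78)
        ep = particle_complex_permittivity(bead, 1e12)
        em = complex_permittivity(water, 1e12)
        assert clausius_mossotti(ep, em).real == pytest.approx(expected, abs=1e-4)

    def test_vanishing_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            clausius_mossotti(2.0 + 0j, -1.0 + 0j)


class TestSpectrum:
    def test_bead_in_water_has_single_sign_change(self, fx):
        spec = cmf_spectrum(fx["ps_3p2um"], fx["di_water"], 1e3, 1e9, 400)
        signs = np.sign(spec.re_fcm)
        changes = np.nonzero(np.diff(signs))[0]
        assert len(changes) == 1
        assert spec.re_fcm[0] > 0 and spec.re_fcm[-1] < 0
        assert len(spec.crossovers) == 1

    def test_keratinocyte_in_culture_medium_always_negative(self, fx):
        spec = cmf_spectrum(fx["keratinocyte"], fx["dmem_f12"], 1e4, 7.5e8, 400)
        assert np.all(spec.re_fcm < 0)

    def test_identical_particle_and_medium_is_identically_zero(self, fx):
        water = fx["di_water"]
        bead = HomogeneousBead(1e-6, water.conductivity, 0.0,
                               water.relative_permittivity)
        spec = cmf_spectrum(bead, water, 1e3, 1e9, 50)
        assert np.allclose(spec.re_fcm, 0) and np.allclose(spec.im_fcm, 0)

    def test_invalid_range_rejected(self, fx):
        with pytest.raises(ValueError):
            cmf_spectrum(fx["ps_3p2um"], fx["di_water"], 1e6, 1e3)
        with pytest.raises(ValueError):
            cmf_spectrum(fx["ps_3p2um"], fx["di_water"], 1e3, 1e9, n_points=1)

    def test_spectrum_invariant_validation(self):
        with pytest.raises(ValueError):
            CMFSpectrum(
                frequencies=np.array([1.0, 10.0]),
                re_fcm=np.array([1.5, 0.0]),
                im_fcm=np.array([0.0, 0.0]),
            )


class TestCrossovers:
    def test_small_bead_crossover(self, fx):
        roots = find_crossovers(fx["ps_3p2um"], fx["di_water"], 1e4, 1e7)
        assert len(roots) == 1
        assert roots[0] == pytest.approx(425.02e3, rel=0.01)

    def test_large_bead_crossover_with_rounded_conductivity(self, fx):
        roots = find_crossovers(fx["ps_4p8um_printed"], fx["di_water"], 1e4, 1e7)
        assert len(roots) == 1
        assert roots[0] == pytest.approx(275.37e3, rel=0.02)

    def test_no_crossover_in_conductive_medium(self, fx):
        assert find_crossovers(fx["keratinocyte"], fx["dmem_f12"], 1e4, 7.5e8) == []

    def test_closed_form_agrees_with_root_finder(self, fx):
        bead = fx["ps_3p2um"]
        water = fx["di_water"]
        f_analytic = closed_form_crossover(
            bead_conductivity(bead), water.conductivity,
            2.56 * EPS0, 78 * EPS0,
        )
        f_numeric = find_crossovers(bead, water, 1e4, 1e7)[0]
        assert f_analytic == pytest.approx(f_numeric, rel=1e-3)
        assert f_analytic == pytest.approx(4.25e5, rel=0.01)

    def test_closed_form_none_when_no_contrast(self):
        assert closed_form_crossover(0.1, 0.1, 5 * EPS0, 5 * EPS0) is None

    def test_closed_form_none_when_both_contrasts_positive(self):
        # particle more conductive AND more polarisable: Re never changes sign
        assert closed_form_crossover(1.0, 0.1, 80 * EPS0, 10 * EPS0) is None


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "bead,freq,expected",
        [
            ("ps_3p2um", 200e3, RegimeLabel.PDEP),
            ("ps_3p2um", 350e3, RegimeLabel.PDEP),
            ("ps_4p8um_printed", 350e3, RegimeLabel.NDEP),
            ("ps_3p2um", 1e6, RegimeLabel.NDEP),
        ],
    )
    def test_bead_regimes_in_di_water(self, fx, bead, freq, expected):
        assert classify_regime(fx[bead], fx["di_water"], freq) is expected

    def test_matched_particle_sits_at_crossover(self, fx):
        water = fx["di_water"]
        bead = HomogeneousBead(1e-6, water.conductivity, 0.0,
                               water.relative_permittivity)
        assert classify_regime(bead, water, 1e5) is RegimeLabel.CROSSOVER


# -- randomized physical-bounds and oracle-agreement properties ---------------

physical_sigma = st.floats(min_value=1e-6, max_value=3.0)
physical_eps = st.floats(min_value=2.0, max_value=90.0)
log_freq = st.floats(min_value=3.0, max_value=9.0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(sp=physical_sigma, sm=physical_sigma, ep=physical_eps, em=physical_eps,
       lf=log_freq)
def test_cmf_bounds_hold_for_random_parameters(sp, sm, ep, em, lf):
    """Re[f_CM] in [-1/2, 1] and |Im[f_CM]| <= 3/4 for any lossy sphere."""
    f = 10.0**lf
    pe = complex_permittivity(DielectricMaterial(sp, ep), f)
    me = complex_permittivity(DielectricMaterial(sm, em), f)
    k = clausius_mossotti(pe, me)
    assert -0.5 - 1e-9 <= k.real <= 1.0 + 1e-9
    assert abs(k.imag) <= 0.75 + 1e-9


@settings(max_examples=200, derandomize=True, deadline=None)
@given(sp=physical_sigma, sm=physical_sigma, ep=physical_eps, em=physical_eps)
def test_root_finder_matches_closed_form(sp, sm, ep, em):
    """Numeric crossover agrees with the analytic sphere formula to 0.1%."""
    analytic = closed_form_crossover(sp, sm, ep * EPS0, em * EPS0)
    bead = HomogeneousBead(1e-6, sp, 0.0, ep)
    medium = DielectricMaterial(sm, em)
    if analytic is None or not 1e1 < analytic < 1e12:
        return
    roots = find_crossovers(bead, medium, analytic / 100, analytic * 100, n_scan=600)
    assert any(r == pytest.approx(analytic, rel=1e-3) for r in roots)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(d_nm=st.floats(min_value=4.0, max_value=10.0))
def test_high_frequency_crossover_insensitive_to_membrane_thickness(d_nm):
    """The cell's high-f crossover is set by the cytoplasm, not the membrane."""
    import depsim

    fx = depsim.fixtures()
    ker = fx["keratinocyte"]
    cell = ShelledCellModel(ker.outer_dimensions, membrane=ker.membrane,
                           cytoplasm=ker.cytoplasm, membrane_thickness=d_nm * 1e-9)
    roots = find_crossovers(cell, fx["di_water"], 1e6, 1e9)
    assert roots and roots[-1] == pytest.approx(28.06e6, rel=0.01)
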