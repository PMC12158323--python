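"""Forward equivalent-circuit model: CPE physics, limits, phase accessors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dentaleis import (
    DM_PARAMS,
    ND_PARAMS,
    CircuitParams,
    FrequencyGrid,
    circuit_impedance,
    cpe_impedance,
    phase_at_frequency,
    simulate_spectrum,
    standard_grid,
)

param_strategy = st.builds(
    CircuitParams,
    r1=st.floats(1e2, 1e6),
    r2=st.floats(1e5, 1e9),
    q=st.floats(1e-9, 1e-5),
    n=st.floats(0.3, 1.0),
)


class TestCPE:
    def test_unit_capacitor_limit(self):
        # n=1, q=1 at omega=1 is a pure unit capacitor: Z = -j
        z = cpe_impedance(1.0, 1.0, 1.0 / (2 * np.pi))
        assert z == pytest.approx(-1j, abs=1e-12)

    def test_resistor_limit(self):
        for f in (0.1, 15.0, 1e4):
            assert cpe_impedance(0.5, 0.0, f) == pytest.approx(2.0 + 0j, abs=1e-12)

    def test_demineralized_cpe_at_15hz(self):
        # direct complex evaluation with the demineralized Q, N values
        z = cpe_impedance(2.1e-7, 0.86, 15.0)
        assert abs(z) == pytest.approx(9.548e4, rel=1e-3)
        assert np.degrees(np.angle(z)) == pytest.approx(-77.4, abs=1e-9)

    def test_phase_is_exactly_minus_n_times_90(self):
        for n in (0.2, 0.5, 0.81, 1.0):
            z = cpe_impedance(3e-7, n, 42.0)
            assert np.degrees(np.angle(z)) == pytest.approx(-n * 90.0, abs=1e-9)

    @pytest.mark.parametrize("q,n,f", [(0.0, 0.5, 1.0), (-1.0, 0.5, 1.0),
                                       (1.0, 0.5, 0.0), (1.0, 0.5, -2.0)])
    def test_domain_errors(self, q, n, f):
        with pytest.raises(ValueError):
            cpe_impedance(q, n, f)

    def test_agrees_with_ideal_capacitor_closed_form(self):
        c = 18.2e-9
        for f in (1.0, 15.0, 100.0):
            expected = 1.0 / (1j * 2 * np.pi * f * c)
            assert cpe_impedance(c, 1.0, f) == pytest.approx(expected, rel=1e-14)


class TestCircuitImpedance:
    def test_high_frequency_limit_is_r1(self):
        z = circuit_impedance(ND_PARAMS, 1e9)
        assert abs(z) == pytest.approx(ND_PARAMS.r1, rel=1e-2)
        assert np.degrees(np.angle(z)) == pytest.approx(0.0, abs=1.0)

    def test_low_frequency_limit_is_r1_plus_r2(self):
        z = circuit_impedance(ND_PARAMS, 1e-12)
        assert abs(z) == pytest.approx(ND_PARAMS.r1 + ND_PARAMS.r2, rel=1e-2)

    def test_nondemineralized_at_15hz(self):
        # independent complex-arithmetic evaluation froze these values
        z = circuit_impedance(ND_PARAMS, 15.0)
        assert abs(z) == pytest.approx(7.745e4, rel=1e-3)
        assert np.degrees(np.angle(z)) == pytest.approx(-69.98, abs=0.05)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=param_strategy, logf=st.floats(-1.0, 4.0))
    def test_phase_in_physical_range(self, p, logf):
        z = circuit_impedance(p, 10.0 ** logf)
        ph = np.degrees(np.angle(z))
        assert -90.0 < ph <= 1e-9

    def test_magnitude_nonincreasing_in_frequency(self):
        rng = np.random.default_rng(0)
        f = np.logspace(-1, 4, 200)
        for _ in range(100):
            p = CircuitParams(r1=10 ** rng.uniform(2, 6), r2=10 ** rng.uniform(5, 9),
                              q=10 ** rng.uniform(-9, -5), n=rng.uniform(0.3, 1.0))
            mag = np.abs(circuit_impedance(p, f))
            assert np.all(np.diff(mag) <= mag[:-1] * 1e-12)


class TestSpectrum:
    def test_standard_grid_has_26_points(self, grid):
        assert len(grid) == 26
        assert grid.fmin == pytest.approx(0.1)
        assert grid.fmax == pytest.approx(1e4)
        # log-uniform spacing
        assert np.allclose(np.diff(np.log10(grid.frequencies)), 0.2)

    def test_simulation_matches_pointwise_evaluation(self, grid, nd_spectrum):
        for i in (0, 7, 25):
            f = grid.frequencies[i]
            assert nd_spectrum.z[i] == pytest.approx(circuit_impedance(ND_PARAMS, f))

    def test_singleton_grid(self):
        g = FrequencyGrid(np.array([15.0]))
        s = simulate_spectrum(DM_PARAMS, g)
        assert len(s.z) == 1
        assert s.z[0] == pytest.approx(circuit_impedance(DM_PARAMS, 15.0))

    def test_forward_spectra_are_capacitive(self, nd_spectrum, dm_spectrum):
        for s in (nd_spectrum, dm_spectrum):
            assert np.all(s.z.imag <= 0)
            assert np.all(s.magnitude > 0)

    def test_demineralized_magnitude_monotone(self, dm_spectrum):
        assert np.all(np.diff(dm_spectrum.magnitude) <= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CircuitParams(r1=-1, r2=1, q=1, n=0.5)
        with pytest.raises(ValueError):
            CircuitParams(r1=1, r2=1, q=1, n=0.0)
        with pytest.raises(ValueError):
            CircuitParams(r1=1, r2=1, q=1, n=1.2)

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([10.0, 1.0]))


class TestPhaseAtFrequency:
    def test_identity_on_grid_points(self, nd_spectrum, grid):
        for i in (0, 13, 25):
            f = grid.frequencies[i]
            assert phase_at_frequency(nd_spectrum, f) == pytest.approx(
                nd_spectrum.phase_deg[i], abs=1e-9)

    def test_constant_phase_interpolates_to_itself(self, grid):
        # a pure CPE has the same phase at every frequency
        z = cpe_impedance(3e-7, 70.0 / 90.0, grid.frequencies)
        from dentaleis import ImpedanceSpectrum
        s = ImpedanceSpectrum(grid=grid, z=z)
        assert phase_at_frequency(s, 3.3) == pytest.approx(70.0, abs=1e-9)

    def test_interpolation_error_below_half_degree_at_15hz(self, nd_spectrum):
        exact = -np.degrees(np.angle(circuit_impedance(ND_PARAMS, 15.0)))
        assert exact == pytest.approx(70.0, abs=0.1)
        assert phase_at_frequency(nd_spectrum, 15.0) == pytest.approx(exact, abs=0.5)

    def test_out_of_range_rejected(self, nd_spectrum):
        with pytest.raises(ValueError):
            phase_at_frequency(nd_spectrum, 0.01)
        with pytest.raises(ValueError):
            phase_at_frequency(nd_spectrum, 2e4)
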