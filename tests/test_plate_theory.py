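"""Closed-form plate theory: eigenvalue roots, rigidity algebra, mode shapes."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import holovib as hv
from holovib.plate_theory import _clamped_char


class TestCharacteristicLambda:
    # frozen from a sign-scan/bisection oracle over the characteristic equations
    @pytest.mark.parametrize("n,m,boundary,nu,lam_sq", [
        (0, 1, "clamped", None, 10.2158),
        (0, 2, "clamped", None, 39.7711),
        (1, 1, "clamped", None, 21.2604),
        (2, 1, "clamped", None, 34.8770),
        (0, 1, "simply_supported", 0.3, 4.9351),
    ])
    def test_known_roots(self, n, m, boundary, nu, lam_sq):
        lam = hv.characteristic_lambda(hv.ModeIdentity(n, m), boundary, nu)
        assert lam ** 2 == pytest.approx(lam_sq, rel=1e-4)

    def test_simply_supported_matches_printed_coefficient(self):
        """The fundamental SS root at nu=0.3 reproduces the classic 4.9."""
        lam = hv.characteristic_lambda(hv.ModeIdentity(0, 1), "simply_supported", 0.3)
        assert lam ** 2 == pytest.approx(4.9, rel=0.02)

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_roots_strictly_increase_with_mode(self, n):
        lams = [hv.characteristic_lambda(hv.ModeIdentity(n, m), "clamped")
                for m in range(1, 5)]
        assert all(b > a for a, b in zip(lams, lams[1:]))

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_roots_match_fine_sign_scan(self, n):
        """Independent oracle: dense sign scan of the clamped equation."""
        grid = np.linspace(1e-6, 18, 400_000)
        vals = _clamped_char(grid, n)
        crossings = grid[:-1][np.sign(vals[:-1]) != np.sign(vals[1:])]
        for m, approx_root in enumerate(crossings[:4], start=1):
            lam = hv.characteristic_lambda(hv.ModeIdentity(n, m), "clamped")
            assert abs(lam - approx_root) < 1e-4

    def test_unsupported_boundary_raises(self):
        with pytest.raises(ValueError, match="fe_modal"):
            hv.characteristic_lambda(hv.ModeIdentity(0, 1), "free")
        with pytest.raises(ValueError):
            hv.characteristic_lambda(hv.ModeIdentity(0, 1), "simply_supported")


class TestRigidity:
    def test_membrane_rigidity_value(self):
        # 20 um plastic membrane at 2.3 GPa, nu = 0.33
        assert hv.flexural_rigidity(2.3e9, 20e-6, 0.33) == pytest.approx(
            1.7208e-6, rel=1e-3)

    def test_scaling(self):
        d = hv.flexural_rigidity(1e6, 1e-4, 0.4)
        assert hv.flexural_rigidity(2e6, 1e-4, 0.4) == pytest.approx(2 * d)
        assert hv.flexural_rigidity(1e6, 2e-4, 0.4) == pytest.approx(8 * d)

    def test_invalid_inputs(self):
        for bad in [(-1, 1e-4, 0.3), (1e6, 0, 0.3), (1e6, 1e-4, 0.6)]:
            with pytest.raises(ValueError):
                hv.flexural_rigidity(*bad)


class TestLaminate:
    def test_single_layer_reduces_to_flexural_rigidity(self):
        layer = hv.LayerSpec("x", 3e-4, 5e4, 0.45, 997.0)
        lam = hv.laminate_rigidity([layer])
        assert lam.d_eff == pytest.approx(
            hv.flexural_rigidity(5e4, 3e-4, 0.45), rel=1e-12)
        assert lam.per_layer_share == (1.0,)

    def test_partition_invariance(self):
        """Splitting a layer into sublayers leaves the effective rigidity alone."""
        whole = hv.laminate_rigidity([hv.LayerSpec("x", 4e-4, 5e4, 0.45, 997.0)])
        for k in (2, 3, 5):
            split = hv.laminate_rigidity(
                [hv.LayerSpec(f"x{i}", 4e-4 / k, 5e4, 0.45, 997.0) for i in range(k)])
            assert split.d_eff == pytest.approx(whole.d_eff, rel=1e-10)

    def test_apligraf_membrane_dominance(self, apligraf):
        """The stiff thin membrane carries ~90% of the stack's rigidity
        (frozen from direct evaluation of the neutral-axis laminate formula)."""
        lam = hv.laminate_rigidity(apligraf.layers)
        assert lam.per_layer_share[0] == pytest.approx(0.8951, abs=1e-3)
        assert lam.per_layer_share[0] == max(lam.per_layer_share)
        assert sum(lam.per_layer_share) == pytest.approx(1.0, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hv.laminate_rigidity([])


class TestFrequencyRelation:
    def test_worked_forward_value(self):
        # D=1 N*m, rho=997 kg/m^3, a=0.02 m, lam^2=4.9, literal volume density
        layer = hv.LayerSpec("w", 1e-3, 1e6, 0.3, 997.0)
        asm = hv.PlateAssembly(0.02, (layer,), density_convention="paper_literal_volume")
        mode = hv.modal_frequency(4.9, asm, D=1.0)
        assert mode.frequency_hz == pytest.approx(61.7, abs=0.1)
        assert mode.angular_frequency == pytest.approx(2 * math.pi * mode.frequency_hz)
        assert mode.lam_sq == pytest.approx(mode.lam ** 2)

    def test_frequency_scales_inverse_radius_squared(self):
        layer = hv.LayerSpec("w", 1e-3, 1e6, 0.3, 997.0)
        f = [hv.modal_frequency(4.9, hv.PlateAssembly(a, (layer,)), D=1.0).frequency_hz
             for a in (0.02, 0.04)]
        assert f[0] / f[1] == pytest.approx(4.0, rel=1e-12)

    @given(st.floats(1e-8, 1e3), st.floats(1.0, 200.0), st.floats(5e-3, 5e-2),
           st.floats(100.0, 3000.0))
    def test_rigidity_round_trip(self, D, lam_sq, radius, rho):
        omega = lam_sq / radius ** 2 * math.sqrt(D / rho)
        back = hv.invert_rigidity(omega / (2 * math.pi), lam_sq, radius, rho)
        assert back == pytest.approx(D, rel=1e-12)

    @given(st.floats(1e3, 1e10), st.floats(1e-6, 1e-2), st.floats(0.05, 0.49))
    def test_modulus_thickness_round_trips(self, E, h, nu):
        D = hv.flexural_rigidity(E, h, nu)
        assert hv.invert_modulus(D, h, nu) == pytest.approx(E, rel=1e-12)
        assert hv.invert_thickness(D, E, nu) == pytest.approx(h, rel=1e-12)

    def test_back_calculated_membrane_dominated_modulus_is_implausibly_high(self):
        """Single-layer inversion of a 147 Hz fundamental gives E >> 1 GPa,
        the membrane-dominance signature for Transwell-grown tissue."""
        D = hv.invert_rigidity(147.0, 4.9, 0.022, 997.0, "paper_literal_volume")
        E = hv.invert_modulus(D, 400e-6, 0.48)
        assert E > 1e9


class TestModeShape:
    def _radial_profile(self, field):
        n = field.n
        ci = (n - 1) // 2
        return field.values[ci, ci:]

    def test_fundamental_has_no_interior_nodal_circle(self, apligraf):
        shape = hv.mode_shape(hv.ModeIdentity(0, 1), "clamped", apligraf, grid=129)
        prof = self._radial_profile(shape)
        prof = prof[np.isfinite(prof)]
        interior = prof[np.abs(prof) > 1e-6]
        assert (np.diff(np.sign(interior)) == 0).all()

    def test_second_mode_has_one_nodal_circle(self, apligraf):
        shape = hv.mode_shape(hv.ModeIdentity(0, 2), "clamped", apligraf, grid=129)
        prof = self._radial_profile(shape)
        prof = prof[np.isfinite(prof)]
        interior = prof[np.abs(prof) > 1e-6]
        assert (np.diff(np.sign(interior)) != 0).sum() == 1

    @pytest.mark.parametrize("boundary", ["clamped", "simply_supported"])
    def test_zero_on_edge_and_normalized(self, apligraf, boundary):
        shape = hv.mode_shape(hv.ModeIdentity(0, 1), boundary, apligraf, grid=129)
        assert shape.max_abs() == pytest.approx(1.0)
        x, y = shape.coords()
        r = np.hypot(x, y)
        rim = shape.mask & (r > 0.99 * apligraf.radius)
        assert np.nanmax(np.abs(shape.values[rim])) < 0.05


class TestString:
    def test_worked_value_and_scalings(self):
        assert hv.string_frequency(1.0, 0.01, 0.1, 1) == pytest.approx(50.0)
        assert hv.string_frequency(1.0, 0.01, 0.1, 2) == pytest.approx(100.0)
        assert hv.string_frequency(4.0, 0.01, 0.1, 1) == pytest.approx(100.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            hv.string_frequency(-1.0, 0.01, 0.1)


class TestAssemblySerialization:
    def test_json_round_trip_is_exact(self, apligraf):
        back = hv.PlateAssembly.from_json(apligraf.to_json())
        assert back == apligraf
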