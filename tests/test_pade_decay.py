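import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from nanofret import (
    LaplaceDecayModel,
    PadeValidityWarning,
    ReducedVariables,
    f2_approx,
    f2_exact,
    f3_eval,
    g3_eval,
    gD_transform,
    invert_to_decay,
)
from nanofret.pade_decay import A3, B3, F2_COEFF, K3, dehoog_invert, talbot_invert


def f2_quadrature(eps: float, xi_a: float) -> float:
    """Independent surface-integral oracle (1/S) int w/(eps + w) dA on the unit sphere."""

    def integrand(theta):
        r = 2.0 * np.sin(theta / 2.0)
        w = (xi_a / r) ** 6
        return 0.5 * w / (eps + w) * np.sin(theta)

    value, _ = quad(integrand, 0.0, np.pi, limit=400, epsabs=1e-14, epsrel=1e-13)
    return value


class TestSpecialFunctions:
    @pytest.mark.parametrize("xi_a", [0.05, 0.1, 0.2])
    @pytest.mark.parametrize("eps", [0.5, 1.0, 2.0])
    def test_f2_exact_matches_surface_quadrature(self, eps, xi_a):
        assert f2_exact(eps, xi_a) == pytest.approx(f2_quadrature(eps, xi_a), rel=1e-8)

    def test_f2_approx_reference_value(self):
        # coefficient sqrt(3)*pi/18 ~ 0.302300 times xi_a**2 = 0.01
        assert f2_approx(1.0, 0.1) == pytest.approx(0.0030230, abs=2e-7)

    def test_f2_exact_approaches_approx_for_small_a(self):
        for xi_a in (0.02, 0.05, 0.1):
            ratio = f2_exact(1.0, xi_a) / f2_approx(1.0, xi_a)
            assert ratio == pytest.approx(1.0, abs=0.01)
        # and the ratio tends to 1 as a -> 0
        assert abs(f2_exact(1.0, 0.01) / f2_approx(1.0, 0.01) - 1) < abs(
            f2_exact(1.0, 0.2) / f2_approx(1.0, 0.2) - 1
        )

    def test_f2_approx_scalings(self):
        assert f2_approx(8.0, 0.1) == pytest.approx(0.5 * f2_approx(1.0, 0.1), rel=1e-12)
        assert f2_approx(1.0, 0.2) == pytest.approx(4.0 * f2_approx(1.0, 0.1), rel=1e-12)

    def test_f2_invalid_inputs(self):
        with pytest.raises(ValueError):
            f2_exact(-1.0, 0.1)
        with pytest.raises(ValueError):
            f2_approx(0.0, 0.1)

    def test_f2_exact_warns_outside_domain(self):
        with pytest.warns(PadeValidityWarning):
            f2_exact(1.0, 2.1)  # a > 1

    def test_j3_from_printed_constants(self):
        assert 1.0 / (A3 + B3) == pytest.approx(13.5851, abs=2e-4)

    def test_f3_reference_value(self):
        # R = 50 nm, R0_DD = 4.6 nm, R0_DA = 5 nm
        assert f3_eval(1.0, 0.1, 0.092) == pytest.approx(1.633e-6, rel=1e-3)

    def test_f3_positive_and_eps_scaling(self):
        assert f3_eval(1.0, 0.1, 0.092) > 0
        assert f3_eval(8.0, 0.1, 0.092) == pytest.approx(
            0.25 * f3_eval(1.0, 0.1, 0.092), rel=1e-12
        )

    def test_g3_reference_value_and_sign(self):
        assert g3_eval(1.0, 0.1) == pytest.approx(-5.1728e-6, rel=1e-4)
        for eps in (0.3, 1.0, 5.0):
            assert g3_eval(eps, 0.25) < 0

    def test_g3_quartic_scaling(self):
        assert g3_eval(1.0, 0.2) == pytest.approx(16.0 * g3_eval(1.0, 0.1), rel=1e-12)


class TestTransform:
    def test_no_acceptors_is_pure_pole(self):
        red = ReducedVariables(0.1, 0.092)
        model = LaplaceDecayModel(10, 0, red)
        for eps in (0.2, 1.0, 4.0):
            assert gD_transform(model, eps) == pytest.approx(1.0 / eps, rel=1e-14)

    def test_three_body_terms_vanish_for_single_pair(self):
        """(N-1)M and M(M-1) prefactors kill f3 and g3 at N = M = 1."""
        red = ReducedVariables(0.1, 0.092)
        two = LaplaceDecayModel(1, 1, red, order="two_body")
        three = LaplaceDecayModel(1, 1, red, order="three_body")
        for eps in (0.3, 1.0, 3.0):
            assert gD_transform(three, eps) == pytest.approx(gD_transform(two, eps), rel=1e-14)

    def test_monotone_decreasing_in_acceptor_count(self):
        red = ReducedVariables(0.1, 0.092)
        values = [
            gD_transform(LaplaceDecayModel(100, m, red), 1.0) for m in (0, 10, 50, 100, 200)
        ]
        assert np.all(np.diff(values) < 0)

    def test_validity_warning_at_high_acceptor_load(self):
        red = ReducedVariables(0.1, 0.092)
        with pytest.warns(PadeValidityWarning):
            LaplaceDecayModel(500, 400, red).check_validity()

    def test_no_warning_in_comfort_zone(self, recwarn):
        red = ReducedVariables(0.1, 0.092)
        LaplaceDecayModel(100, 100, red).check_validity()
        assert not any(isinstance(w.message, PadeValidityWarning) for w in recwarn)


class TestInversion:
    def test_known_pairs_recovered(self):
        t = np.geomspace(0.01, 10.0, 40)
        for invert in (talbot_invert, dehoog_invert):
            assert np.abs(invert(lambda s: 1.0 / s, t) - 1.0).max() < 1e-6
            assert np.abs(invert(lambda s: 1.0 / (s + 1.0), t) - np.exp(-t)).max() < 1e-6

    @pytest.mark.parametrize("n_donors, n_acceptors", [(1, 10), (10, 50), (100, 100), (500, 100)])
    @pytest.mark.parametrize("order", ["two_body", "three_body"])
    def test_contour_and_series_methods_agree(self, n_donors, n_acceptors, order):
        """Fixed-Talbot and de Hoog must agree on every shipped model."""
        red = ReducedVariables(0.1, 0.092)
        model = LaplaceDecayModel(n_donors, n_acceptors, red, order=order)
        t = np.geomspace(0.01, 10.0, 25)
        a = talbot_invert(model, t)
        b = dehoog_invert(model, t)
        assert np.abs((a - b) / a).max() < 1e-6

    def test_no_acceptors_curve_is_exact(self):
        red = ReducedVariables(0.1, 0.092)
        model = LaplaceDecayModel(10, 0, red)
        t = np.geomspace(0.01, 5.0, 10)
        reduced = invert_to_decay(model, t, include_natural_decay=False)
        physical = invert_to_decay(model, t, include_natural_decay=True)
        np.testing.assert_allclose(reduced.values, 1.0, atol=1e-12)
        np.testing.assert_allclose(physical.values, np.exp(-t), rtol=1e-12)

    def test_small_density_first_order_series(self):
        """For M*f2 << 1 the two-body curve matches the term-by-term inverse
        1 - M*c*xi_a**2 * t**(1/3) / Gamma(4/3) of the leading series term."""
        red = ReducedVariables(0.1, 0.092)
        model = LaplaceDecayModel(1, 1, red, order="two_body")
        assert model.n_acceptors * f2_approx(1.0, red.xi_a) <= 0.02
        t = np.geomspace(0.01, 2.0, 20)
        curve = invert_to_decay(model, t, include_natural_decay=False)
        series = 1.0 - F2_COEFF * red.xi_a**2 * t ** (1.0 / 3.0) / gamma_fn(4.0 / 3.0)
        assert np.abs(curve.values - series).max() < 1e-3

    def test_g3_slows_decay_for_single_donor(self):
        """With N = 1 only the negative g3 term differs: 3-body is slower."""
        red = ReducedVariables(0.1, 0.092)
        t = np.geomspace(0.01, 10.0, 30)
        two = invert_to_decay(LaplaceDecayModel(1, 10, red, order="two_body"), t, False)
        three = invert_to_decay(LaplaceDecayModel(1, 10, red, order="three_body"), t, False)
        assert np.all(three.values >= two.values - 1e-10)
        assert three.values.max() <= 1.0 + 1e-9

    def test_f3_accelerates_decay_for_many_donors(self):
        """Migration-assisted trapping (f3) dominates at N >> M: 3-body is faster."""
        red = ReducedVariables(0.1, 0.092)
        t = np.geomspace(0.01, 10.0, 30)
        two = invert_to_decay(LaplaceDecayModel(500, 2, red, order="two_body"), t, False)
        three = invert_to_decay(LaplaceDecayModel(500, 2, red, order="three_body"), t, False)
        assert np.all(three.values <= two.values + 1e-10)

    def test_nonpositive_times_rejected(self):
        red = ReducedVariables(0.1, 0.092)
        with pytest.raises(ValueError):
            invert_to_decay(LaplaceDecayModel(10, 5, red), np.array([0.0, 1.0]))
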