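"""Closed-form volume-conduction physics: potentials, pair differences,
CMRR and SNR algebra, checked against coordinate-evaluation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfpvc import (
    CurrentSource,
    ElectrodePair,
    Medium,
    SingularityError,
    cmrr,
    current_density,
    gain_unity_ratio,
    pair_difference,
    pair_potentials,
    point_potential,
    snr_dr,
    snr_gain,
    snr_global,
    snr_rr,
)

SIGMA1 = Medium(1.0)


def _source_at(r, alpha, amplitude=1.0):
    """Point source at distance r and angle alpha from an x-axis pair at the
    origin."""
    return CurrentSource(
        [r * np.cos(alpha), r * np.sin(alpha), 0.0], amplitude
    )


def _pair(eps=1e-4):
    return ElectrodePair([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], eps)


class TestCurrentDensity:
    @pytest.mark.parametrize("r, expected", [(1.0, 1.0), (2.0, 0.25)])
    def test_inverse_square(self, r, expected):
        src = CurrentSource([0, 0, 0], 4 * np.pi)
        assert current_density(src, r) == pytest.approx(expected)

    def test_total_flux_is_conserved(self):
        # integrating the radial density over a sphere of any radius must
        # return the injected current: 4*pi*r^2 * J(r) == I
        src = CurrentSource([0, 0, 0], 2.7e-6)
        for r in (1e-4, 3.3e-3, 1.0, 250.0):
            assert 4 * np.pi * r**2 * current_density(src, r) == pytest.approx(
                src.amplitude, rel=1e-12
            )

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            current_density(CurrentSource([0, 0, 0], 1.0), 0.0)


class TestPointPotential:
    def test_unit_constants(self):
        src = CurrentSource([0, 0, 0], 4 * np.pi)
        assert point_potential(src, [1, 0, 0], SIGMA1) == pytest.approx(1.0)

    def test_inverse_distance(self):
        src = CurrentSource([0, 0, 0], 1.0)
        v1 = point_potential(src, [0, 1e-3, 0], SIGMA1)
        v2 = point_potential(src, [0, 2e-3, 0], SIGMA1)
        assert v1 == pytest.approx(2 * v2)

    def test_superposition(self, rng):
        sources = [
            CurrentSource(rng.normal(size=3), rng.normal()) for _ in range(4)
        ]
        point = rng.normal(size=3) * 5
        total = sum(point_potential(s, point, SIGMA1) for s in sources)
        merged = sum(
            s.amplitude / (4 * np.pi * np.linalg.norm(point - s.position))
            for s in sources
        )
        assert total == pytest.approx(merged, rel=1e-12)

    def test_singularity(self):
        src = CurrentSource([1, 2, 3], 1.0)
        with pytest.raises(SingularityError):
            point_potential(src, [1, 2, 3], SIGMA1)

    @settings(deadline=None, derandomize=True)
    @given(
        amp=st.floats(0.1, 10.0),
        sigma=st.floats(0.05, 5.0),
        d=st.floats(1e-4, 1e-1),
    )
    def test_linear_in_current_inverse_in_conductivity(self, amp, sigma, d):
        src = CurrentSource([0, 0, 0], amp)
        v = point_potential(src, [d, 0, 0], Medium(sigma))
        v2 = point_potential(CurrentSource([0, 0, 0], 2 * amp), [d, 0, 0], Medium(sigma))
        v3 = point_potential(src, [d, 0, 0], Medium(2 * sigma))
        assert v2 == pytest.approx(2 * v, rel=1e-12)
        assert v3 == pytest.approx(v / 2, rel=1e-12)


class TestPairPotentials:
    def test_perpendicular_source_is_equidistant(self):
        v1, v2 = pair_potentials(_source_at(5e-4, np.pi / 2), _pair(), SIGMA1)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_on_axis_ratio_three(self):
        # source on the pair axis at r = 2*eps: contact distances are eps and
        # 3*eps, so the potentials are in ratio 3 (hand geometry)
        eps = 1e-4
        v1, v2 = pair_potentials(_source_at(2 * eps, 0.0), _pair(eps), SIGMA1)
        assert v1 / v2 == pytest.approx(3.0, rel=1e-12)

    def test_matches_coordinate_oracle(self, rng):
        # the pair formula must agree with evaluating the monopole potential
        # at the explicit contact coordinates for arbitrary geometry
        for _ in range(25):
            mid = rng.normal(size=3) * 1e-3
            axis = rng.normal(size=3)
            pair = ElectrodePair(mid, axis, float(rng.uniform(2e-5, 3e-4)))
            src = CurrentSource(rng.normal(size=3) * 2e-3, float(rng.normal()))
            v1, v2 = pair_potentials(src, pair, SIGMA1)
            p1, p2 = pair.electrode_positions
            assert v1 == pytest.approx(point_potential(src, p1, SIGMA1), rel=1e-12)
            assert v2 == pytest.approx(point_potential(src, p2, SIGMA1), rel=1e-12)


class TestPairDifference:
    def test_exact_is_potential_difference(self):
        src = _source_at(7e-4, 0.8)
        v1, v2 = pair_potentials(src, _pair(), SIGMA1)
        d = pair_difference(src, _pair(), SIGMA1, "exact")
        assert d.value == pytest.approx(v1 - v2, rel=1e-12)
        assert d.regime == "exact"

    def test_distal_vanishes_perpendicular(self):
        d = pair_difference(_source_at(1e-2, np.pi / 2), _pair(), SIGMA1, "distal")
        assert d.value == pytest.approx(0.0, abs=1e-12)

    def test_local_vanishes_perpendicular(self):
        # cos(45 deg) - sin(45 deg) = 0
        d = pair_difference(_source_at(1e-4, np.pi / 2), _pair(), SIGMA1, "local")
        assert d.value == pytest.approx(0.0, abs=1e-12)

    def test_local_singular_on_axis(self):
        with pytest.raises(SingularityError):
            pair_difference(_source_at(1e-4, 0.0), _pair(), SIGMA1, "local")

    def test_local_matches_general_law_collapsed_to_eps(self):
        # the local closed form must equal the exact law-of-cosines
        # difference evaluated at r = eps (surd identity check)
        eps = 1e-4
        for alpha in np.linspace(0.05, np.pi - 0.05, 37):
            exact_at_eps = pair_difference(
                _source_at(eps, alpha), _pair(eps), SIGMA1, "exact"
            ).value
            local = pair_difference(
                _source_at(eps, alpha), _pair(eps), SIGMA1, "local"
            ).value
            assert local == pytest.approx(exact_at_eps, rel=1e-9)

    def test_on_axis_relative_error_is_eps_over_r_squared(self):
        # exact on-axis difference has closed form 2*I*eps/(4*pi*sigma*(r^2-eps^2))
        eps, r = 1e-4, 1e-2  # r = 100 eps
        exact = pair_difference(_source_at(r, 0.0), _pair(eps), SIGMA1, "exact").value
        closed = 2 * eps / (4 * np.pi * (r**2 - eps**2))
        assert exact == pytest.approx(closed, rel=1e-10)
        distal = pair_difference(_source_at(r, 0.0), _pair(eps), SIGMA1, "distal").value
        assert abs(exact - distal) / abs(exact) == pytest.approx(
            (eps / r) ** 2, rel=1e-3
        )

    def test_distal_error_decreases_with_distance(self):
        eps = 1e-4
        errors = []
        for ratio in (10, 30, 100, 300):
            src = _source_at(ratio * eps, 0.0)
            ex = pair_difference(src, _pair(eps), SIGMA1, "exact").value
            di = pair_difference(src, _pair(eps), SIGMA1, "distal").value
            errors.append(abs(ex - di) / abs(ex))
        assert all(a > b for a, b in zip(errors, errors[1:]))
        assert errors[2] <= 1e-3  # r >= 100 eps on axis

    def test_distal_second_order_error_bound(self):
        # the exact second-order coefficient of the distal-law relative error
        # is |3/2 - (5/2) cos^2(alpha)|, bounded by 3/2; verified against the
        # coordinate-evaluation oracle on a dense grid
        eps = 1e-4
        for ratio in (10, 30, 100):
            for alpha in np.radians(np.arange(5, 90, 5)):
                src = _source_at(ratio * eps, alpha)
                ex = pair_difference(src, _pair(eps), SIGMA1, "exact").value
                di = pair_difference(src, _pair(eps), SIGMA1, "distal").value
                assert abs(ex - di) / abs(ex) <= 1.55 / ratio**2

    def test_distal_antisymmetric_about_perpendicular(self):
        r = 5e-3
        for alpha in (0.2, 0.7, 1.2):
            plus = pair_difference(_source_at(r, np.pi / 2 - alpha), _pair(),
                                   SIGMA1, "distal").value
            minus = pair_difference(_source_at(r, np.pi / 2 + alpha), _pair(),
                                    SIGMA1, "distal").value
            assert plus == pytest.approx(-minus, rel=1e-12)
        on_axis = pair_difference(_source_at(r, 0.0), _pair(), SIGMA1, "distal").value
        assert on_axis >= plus  # maximal at alpha = 0


class TestCmrrAndSnr:
    def test_printed_values(self):
        assert round(cmrr(10.0, 1.0)) == 35
        assert float(f"{cmrr(100.0, 1.0):.2g}") == 3500
        assert snr_rr(6.0, 1.0) == 6.0
        assert int(snr_dr(6.0, 1.0)) == 12
        assert snr_global(6.0, 1.0, dims=3) == 8

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(1e-3, 1e3), eps=st.floats(1e-6, 1e-2))
    def test_identities(self, r, eps):
        assert snr_dr(r, eps) == cmrr(r, eps)
        assert snr_gain(r, eps) * snr_rr(r, eps) == pytest.approx(
            snr_dr(r, eps), rel=1e-12
        )
        assert cmrr(2 * r, eps) == pytest.approx(4 * cmrr(r, eps), rel=1e-12)

    def test_gain_crosses_unity_at_two_root_two(self):
        ratio = gain_unity_ratio()
        assert ratio == pytest.approx(2 * np.sqrt(2), abs=1e-9)
        assert snr_gain(ratio, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_domain_errors(self):
        for fn in (cmrr, snr_rr, snr_dr, snr_gain):
            with pytest.raises(ValueError):
                fn(-1.0, 1.0)
            with pytest.raises(ValueError):
                fn(1.0, 0.0)
        with pytest.raises(ValueError):
            snr_global(6.0, 1.0, dims=0)
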