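"""Pade linear systems, rational PSD objects, validation, peak and band
power functionals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from padepsd import (
    PadePSDError,
    RationalPSD,
    build_block,
    entrainment_score,
    exact_pade_derivatives,
    fixtures,
    linearize,
    peak_frequency,
    resolvent_G,
    solve_pade,
    total_power,
    validate,
)

from _oracles import TruncatedOracle


@pytest.fixture(scope="module")
def gene_mats():
    net = fixtures.gene_expression()
    return net, linearize(net)


class TestBlocks:
    def test_infinity_block_order_one(self):
        # p=1, rho=2: kappa_0 = D_0 and -D_0 beta_0 = D_1
        D = np.array([1.0, -1.0])
        A, b = build_block(np.inf, 2, D, 1)
        assert np.allclose(A, [[1.0, 0.0], [0.0, -1.0]])
        assert np.allclose(b, D)

    def test_infinity_first_row_is_unit_vector(self):
        D = np.arange(1.0, 5.0)
        for p in (2, 3):
            A, _ = build_block(np.inf, 4, D, p)
            row = np.zeros(2 * p)
            row[p - 1] = 1.0
            assert np.allclose(A[0], row)

    def test_finite_block_binomial_structure(self):
        # row j=0, numerator columns carry s^i; row j=1 carries i * s^(i-1)
        s, p = 2.0, 3
        D = np.array([0.3, -0.1])
        A, b = build_block(s, 2, D, p)
        assert np.allclose(A[0, :p], [1.0, s, s**2])
        assert np.allclose(A[1, :p], [0.0, 1.0, 2.0 * s])
        # b_0 = s^p D_0
        assert b[0] == pytest.approx(s**p * D[0])

    def test_order_zero_rejected(self):
        with pytest.raises(PadePSDError):
            build_block(1.0, 1, [0.5], 0)


class TestSolve:
    def test_birth_death_exact_single_mode(self):
        # one eigenmode: p=1 recovers G(s) = Var/(s + gamma) exactly
        mats = linearize(fixtures.birth_death())
        D = exact_pade_derivatives(mats, 0, np.inf, 4)
        rat = solve_pade([(np.inf, D)], p=1)
        assert np.allclose(rat.numerator, [1.0], atol=1e-12)
        assert np.allclose(rat.denominator, [1.0, 1.0], atol=1e-12)
        assert rat.psd(0.0) == pytest.approx(2.0)
        assert rat.psd(1.0) == pytest.approx(1.0)

    def test_gene_expression_exact_recovery(self, gene_mats):
        net, mats = gene_mats
        D = exact_pade_derivatives(mats, 1, np.inf, 4)
        rat = solve_pade([(np.inf, D)], p=2)
        num_u, den_u = rat.psd_rational()
        assert np.allclose(num_u, [120.0, 40.0], rtol=1e-9)
        assert np.allclose(den_u, [0.25, 1.25, 1.0], rtol=1e-9)
        for s in (0.21, 0.9, 3.3, 11.0):
            assert rat.G(s) == pytest.approx(resolvent_G(mats, 1, s), rel=1e-9)

    def test_multipoint_exact_recovery_at_random_points(self, gene_mats):
        net, mats = gene_mats
        blocks = [(s, exact_pade_derivatives(mats, 1, s, 2)) for s in (1.0, 1.5, 2.0)]
        blocks.append((np.inf, exact_pade_derivatives(mats, 1, np.inf, 3)))
        rat = solve_pade(blocks, p=2)
        rng = np.random.default_rng(0)
        for s in rng.uniform(0.05, 20.0, size=10):
            exact = resolvent_G(mats, 1, s)
            assert abs(rat.G(s) - exact) <= 1e-8 * abs(exact)

    def test_known_factor_q0_is_identical(self, gene_mats):
        _, mats = gene_mats
        D = exact_pade_derivatives(mats, 1, np.inf, 4)
        plain = solve_pade([(np.inf, D)], p=2)
        kf = solve_pade([(np.inf, D)], p=2, known_factor=())
        assert np.array_equal(plain.numerator, kf.numerator)
        assert np.array_equal(plain.denominator, kf.denominator)

    def test_known_factor_imposes_denominator_root(self, gene_mats):
        # forcing the true factor (s + 1) leaves the true denominator intact
        _, mats = gene_mats
        D = exact_pade_derivatives(mats, 1, np.inf, 4)
        rat = solve_pade([(np.inf, D)], p=2, known_factor=(1.0,))
        assert np.allclose(rat.denominator, [0.5, 1.5, 1.0], rtol=1e-9)

    def test_cell_cycle_known_factor_values(self):
        assert fixtures.known_factor_for_cell_cycle(4, 1.0) == pytest.approx((2.0, 2.0))
        assert fixtures.known_factor_for_cell_cycle(2, 1.0) == pytest.approx((4.0, 4.0))
        B0a, B1a = fixtures.known_factor_for_cell_cycle(4, 3.0)
        B0, B1 = fixtures.known_factor_for_cell_cycle(4, 1.0)
        assert (B0a, B1a) == pytest.approx((9.0 * B0, 3.0 * B1))

    def test_degenerate_factor_degree_rejected(self):
        with pytest.raises(PadePSDError):
            solve_pade([(np.inf, [1.0, -1.0])], p=1, known_factor=(1.0, 2.0))


class TestRationalPSD:
    def test_psd_rational_matches_pointwise_evaluation(self):
        rng = np.random.default_rng(4)
        rat = RationalPSD(numerator=[3.0, 1.2], denominator=[2.0, 0.7, 1.0])
        num_u, den_u = rat.psd_rational()
        for w in rng.uniform(0.0, 6.0, size=12):
            direct = rat.psd(w)
            viapoly = (np.polynomial.polynomial.polyval(w**2, num_u)
                       / np.polynomial.polynomial.polyval(w**2, den_u))
            assert direct == pytest.approx(viapoly, rel=1e-10)

    def test_unstable_denominator_flagged_not_rejected(self):
        with pytest.warns(UserWarning, match="non-negative real part"):
            rat = solve_pade([(np.inf, [1.0, 1.0])], p=1)
        assert not rat.stable

    def test_clipping_of_negative_evaluations(self):
        rat = RationalPSD(numerator=[-1.0], denominator=[1.0, 1.0])
        assert rat.psd(0.0) < 0
        assert rat.psd(0.0, clip=True) == 0.0

    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0))
    @settings(deadline=None, max_examples=25)
    def test_psd_even_in_omega(self, k, g):
        rat = RationalPSD(numerator=[k], denominator=[g, 1.0])
        for w in (0.3, 1.7):
            assert rat.psd(w) == pytest.approx(rat.psd(-w))


class TestValidation:
    def test_exact_case_zero_error(self, gene_mats):
        _, mats = gene_mats
        D = exact_pade_derivatives(mats, 1, np.inf, 4)
        rat = solve_pade([(np.inf, D)], p=2)
        direct = {s: (float(resolvent_G(mats, 1, s).real), 1e-6) for s in (0.5, 1.0, 2.0)}
        report = validate(rat, direct)
        assert report.passed
        assert all(e.relative_error < 1e-8 for e in report.entries)

    def test_underordered_model_fails_validation(self):
        # RNA splicing has three significant modes; p=1 cannot represent G
        net = fixtures.rna_splicing()
        mats = linearize(net)
        n = net.output_index
        D = exact_pade_derivatives(mats, n, np.inf, 2)
        rat = solve_pade([(np.inf, D)], p=1)
        direct = {s: (float(resolvent_G(mats, n, s).real), 1e-9) for s in (0.2, 0.5, 1.0)}
        report = validate(rat, direct, threshold=0.1)
        assert not report.passed

    def test_empty_direct_estimates_rejected(self, gene_mats):
        _, mats = gene_mats
        rat = solve_pade([(np.inf, exact_pade_derivatives(mats, 1, np.inf, 4))], p=2)
        with pytest.raises(PadePSDError):
            validate(rat, {})


class TestPeakAndPower:
    def test_monotone_psd_peaks_at_zero(self):
        rat = RationalPSD(numerator=[1.0], denominator=[1.0, 1.0])  # Cauchy shape
        assert peak_frequency(rat) == 0.0

    def test_nfb_table_peak_location(self):
        # stationary point of (66.6667 u + 200)/(u^2 - 0.75 u + 2.25):
        # root of u^2 + 6u - 4.5 -> omega = 0.8211
        net = fixtures.nfb()
        mats = linearize(net)
        from padepsd.linear import psd_exact
        peak = peak_frequency(lambda w: psd_exact(mats, 1, w), omega_hi=5.0)
        assert peak == pytest.approx(np.sqrt((-6 + np.sqrt(54)) / 2), abs=2e-4)
        assert peak == pytest.approx(0.8211, abs=2e-4)

    def test_total_power_equals_variance(self, gene_mats):
        # (1/2pi) integral of S over R equals Var_pi(X_n)
        _, mats = gene_mats
        rat = solve_pade([(np.inf, exact_pade_derivatives(mats, 1, np.inf, 4))], p=2)
        assert total_power(rat) == pytest.approx(mats.Sigma[1, 1], rel=1e-6)

    @pytest.mark.parametrize("name", ["birth_death", "iff", "nfb", "rna_splicing"])
    def test_total_power_parseval_all_fixtures(self, name):
        net = fixtures.make(name)
        mats = linearize(net)
        n = net.output_index
        count = 2 * mats.d
        blocks = [(np.inf, exact_pade_derivatives(mats, n, np.inf, count))]
        rat = solve_pade(blocks, p=mats.d)
        assert total_power(rat) == pytest.approx(mats.Sigma[n, n], rel=1e-6)

    def test_entrainment_score_cauchy_band(self):
        # closed form: (2/pi)(arctan 1.1 - arctan 0.9) for band [0.9, 1.1]*gamma
        rat = RationalPSD(numerator=[1.0], denominator=[1.0, 1.0])
        score = entrainment_score(rat, omega0=1.0)
        assert score == pytest.approx(2 / np.pi * (np.arctan(1.1) - np.arctan(0.9)), abs=1e-6)

    def test_entrainment_score_degenerate_band(self):
        rat = RationalPSD(numerator=[1.0], denominator=[1.0, 1.0])
        assert entrainment_score(rat, omega0=1.0, band_frac=0.0) == 0.0

    def test_non_integrable_psd_rejected(self):
        # G = (1+s)/(1+s): S(omega) = 2 everywhere, no decaying tail
        rat = RationalPSD(numerator=[1.0, 1.0], denominator=[1.0, 1.0])
        with pytest.raises(PadePSDError):
            entrainment_score(rat, omega0=1.0)

    def test_truncated_oracle_psd_matches_closed_form(self):
        # independent route to S(omega) for birth-death
        oracle = TruncatedOracle(fixtures.birth_death(), caps=(40,))
        for w in (0.0, 0.5, 1.0, 2.0):
            assert oracle.psd(w) == pytest.approx(2.0 / (1.0 + w**2), abs=1e-8)
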