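"""Linear-network machinery: Lyapunov covariance, exact PSD, the
decomposition theorem, composite spectra and the NFB oscillation criterion."""

import numpy as np
import pytest

from padepsd import (
    ErgodicityError,
    InputSignalSpec,
    NonAffinePropensityError,
    composite_psd,
    decompose,
    fixtures,
    linearize,
    nfb_oscillation_criterion,
    peak_frequency,
    psd_exact,
    rational_psd_exact,
)


class TestLinearize:
    def test_gene_expression_matrices(self):
        mats = linearize(fixtures.gene_expression())
        assert np.allclose(mats.A, [[-1.0, 0.0], [2.0, -0.5]])
        assert np.allclose(mats.xbar, [10.0, 40.0])
        assert np.allclose(mats.Sigma, [[10.0, 40 / 3], [40 / 3, 280 / 3]], atol=1e-9)

    def test_birth_death_poisson_covariance(self):
        mats = linearize(fixtures.birth_death(k=3.0, gamma=1.5))
        assert mats.A[0, 0] == pytest.approx(-1.5)
        assert mats.Sigma[0, 0] == pytest.approx(2.0)

    def test_telegraph_stationary_mean(self):
        mats = linearize(fixtures.telegraph(k_on=1.0, k_off=3.0))
        assert mats.xbar[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("name", ["birth_death", "gene_expression", "iff", "nfb", "rna_splicing"])
    def test_lyapunov_residual(self, name):
        mats = linearize(fixtures.make(name))
        resid = mats.A @ mats.Sigma + mats.Sigma @ mats.A.T + mats.DDt
        assert np.linalg.norm(resid) <= 1e-10 * max(np.linalg.norm(mats.DDt), 1.0)

    def test_nonlinear_propensity_rejected_with_reaction_name(self):
        net = fixtures.self_regulating_gene()
        with pytest.raises(NonAffinePropensityError, match="autoregulated"):
            linearize(net)

    def test_bimolecular_rejected(self):
        net = fixtures.aif_gene_expression()
        with pytest.raises(NonAffinePropensityError):
            linearize(net)

    def test_non_hurwitz_rejected(self):
        from padepsd import MassAction, Reaction, ReactionNetwork, Fixed
        # pure birth: A = 0, no stationary law
        r = Reaction((0,), MassAction(1.0), Fixed((1,)))
        with pytest.raises(ErgodicityError):
            linearize(ReactionNetwork(["X"], [r], "X"))


class TestExactPSD:
    def test_gene_expression_values(self):
        mats = linearize(fixtures.gene_expression())
        assert psd_exact(mats, 1, 0.0) == pytest.approx(480.0)
        for w in (0.5, 1.0, 3.0):
            expect = (40 * w**2 + 120) / (w**4 + 1.25 * w**2 + 0.25)
            assert psd_exact(mats, 1, w) == pytest.approx(expect, rel=1e-10)

    def test_birth_death_cauchy(self):
        mats = linearize(fixtures.birth_death())
        assert psd_exact(mats, 0, 1.0) == pytest.approx(1.0)

    def test_telegraph_zero_frequency(self):
        mats = linearize(fixtures.telegraph(k_on=1.0, k_off=3.0))
        assert psd_exact(mats, 0, 0.0) == pytest.approx(0.09375)

    @pytest.mark.parametrize("name", ["gene_expression", "iff", "nfb", "rna_splicing"])
    def test_nonnegative_on_grid(self, name):
        net = fixtures.make(name)
        mats = linearize(net)
        vals = psd_exact(mats, net.output_index, np.linspace(0.0, 12.0, 200))
        assert np.all(vals >= 0)


class TestDecomposition:
    def test_gene_expression_translation_transcription_split(self):
        # downstream protein alone, driven by mRNA: the two closed-form terms
        net = fixtures.gene_expression()
        k_r, g_r, k_p, g_p = 10.0, 1.0, 2.0, 0.5
        from padepsd import MassAction, Reaction, ReactionNetwork, Fixed
        down = ReactionNetwork(
            ["protein"],
            [Reaction((0,), MassAction(k_p * k_r / g_r), Fixed((1,))),
             Reaction((1,), MassAction(g_p), Fixed((-1,)))],
            "protein",
        )
        mats = linearize(down)
        spec = InputSignalSpec(theta=k_p, c=np.array([1]),
                               psd=lambda w: 2 * k_r / (g_r**2 + w**2), mean=k_r / g_r)
        for w in (0.0, 0.4, 1.1, 2.5):
            intrinsic, (extrinsic,) = decompose(mats, 0, [spec], w)
            assert intrinsic == pytest.approx(2 * k_r * k_p / (g_r * (g_p**2 + w**2)), rel=1e-9)
            assert extrinsic == pytest.approx(
                k_p**2 / (g_p**2 + w**2) * 2 * k_r / (g_r**2 + w**2), rel=1e-9)
            # the sum is the full two-species PSD
            full = psd_exact(linearize(net), 1, w)
            assert intrinsic + extrinsic == pytest.approx(full, rel=1e-8)

    def test_rna_splicing_decomposition_additivity(self):
        # (unspliced, spliced) downstream driven by the telegraph gene
        from padepsd import AffineClamped, MassAction, Reaction, ReactionNetwork, Fixed
        k_on, k_off = 1.0, 3.0
        a_on, a_off, beta, g_u, g_r = 6.0, 0.4, 1.0, 2.0, 0.5
        gbar = k_on / (k_on + k_off)
        down = ReactionNetwork(
            ["unspliced", "spliced"],
            [Reaction((0, 0), AffineClamped(a_off + (a_on - a_off) * gbar, (0.0, 0.0)),
                      Fixed((1, 0))),
             Reaction((1, 0), MassAction(beta), Fixed((-1, 1))),
             Reaction((1, 0), MassAction(g_u), Fixed((-1, 0))),
             Reaction((0, 1), MassAction(g_r), Fixed((0, -1)))],
            "spliced",
        )
        mats = linearize(down)
        s_gene = lambda w: 2 * k_on * k_off / ((k_on + k_off) * ((k_on + k_off) ** 2 + w**2))
        spec = InputSignalSpec(theta=a_on - a_off, c=np.array([1, 0]), psd=s_gene, mean=gbar)
        full_mats = linearize(fixtures.rna_splicing())
        for w in (0.0, 0.7, 1.9, 4.0):
            intrinsic, (extrinsic,) = decompose(mats, 1, [spec], w)
            # closed-form splicing and transcription terms
            assert intrinsic == pytest.approx(
                2 * beta * (a_off * k_off + a_on * k_on)
                / ((beta + g_u) * (k_on + k_off) * (g_r**2 + w**2)), rel=1e-9)
            assert extrinsic == pytest.approx(
                beta**2 * (a_on - a_off) ** 2
                / (((beta + g_u) ** 2 + w**2) * (g_r**2 + w**2)) * s_gene(w), rel=1e-9)
            assert intrinsic + extrinsic == pytest.approx(psd_exact(full_mats, 2, w), rel=1e-8)

    def test_zero_theta_input_contributes_nothing(self):
        mats = linearize(fixtures.gene_expression())
        spec = InputSignalSpec(theta=0.0, c=np.array([1, 0]), psd=lambda w: 1.0, mean=5.0)
        _, (extrinsic,) = decompose(mats, 1, [spec], 0.7)
        assert extrinsic == 0.0

    def test_missing_input_mean_rejected(self):
        from padepsd import PadePSDError
        mats = linearize(fixtures.gene_expression())
        spec = InputSignalSpec(theta=1.0, c=np.array([1, 0]), psd=lambda w: 1.0, mean=None)
        with pytest.raises(PadePSDError):
            decompose(mats, 1, [spec], 0.5)


class TestComposite:
    def test_theta_zero_reduces_to_isolated(self):
        iso = fixtures.entrainment_circuit(k_fb=0.5)
        mats = linearize(iso)
        total, intrinsic, extrinsic = composite_psd(mats, 1, lambda w: 10.0, 0.0, [1, 0], 0.9)
        assert extrinsic == 0.0
        assert total == pytest.approx(psd_exact(mats, 1, 0.9))

    def test_isolated_entrainment_circuit_peak(self):
        # same quartic as the NFB benchmark: omega_max = 0.8211
        iso = fixtures.entrainment_circuit(k_fb=0.5)
        mats = linearize(iso)
        peak = peak_frequency(lambda w: psd_exact(mats, 1, w), omega_hi=5.0)
        assert peak == pytest.approx(0.8211, abs=2e-4)

    def test_composite_matches_closed_form(self):
        # gain = theta^2 k_p^2 / |quartic|, applied to an arbitrary input PSD
        k_r, k_fb, k_p, g_r, g_p, theta, ybar = 50.0, 0.5, 2.0, 1.0, 0.5, 0.7, 30.0
        net = fixtures.entrainment_circuit(k_r=k_r, k_fb=k_fb, theta=theta, upstream_mean=ybar)
        mats = linearize(net)
        up = lambda w: 5.0 / (1.0 + (w - 1.3) ** 2)
        for w in (0.2, 0.9, 1.3, 2.4):
            total, intrinsic, extrinsic = composite_psd(mats, 1, up, theta, [1, 0], w,
                                                        upstream_mean=ybar)
            denom = ((g_r * g_p + k_p * k_fb) ** 2
                     + w**2 * (g_r**2 + g_p**2 - 2 * k_p * k_fb) + w**4)
            assert extrinsic == pytest.approx(theta**2 * k_p**2 / denom * up(w), rel=1e-9)
            prefac = 2 * g_p * k_p * (theta * ybar + k_r) / (g_r * g_p + k_p * k_fb)
            assert intrinsic == pytest.approx(
                prefac * (g_r**2 + k_p * g_r + w**2) / denom, rel=1e-9)


class TestNFBCriterion:
    def test_reference_parameter_set_oscillates(self):
        # left side 1.0 vs threshold ~0.4687
        assert nfb_oscillation_criterion(1.0, 0.5, 2.0, 0.05, 10.0)

    def test_vanishing_input_no_oscillation(self):
        assert not nfb_oscillation_criterion(1.0, 0.5, 2.0, 0.05, 1e-6)

    def test_boundary_equality_is_non_oscillatory(self):
        g_c, g_o, k_o = 1.0, 0.5, 2.0
        top = g_c**4 + g_c**3 * k_o + g_o**2 * g_c * k_o
        base = g_c * g_o + g_c**2 + k_o * g_c
        thr = top / (np.sqrt(base**2 + top) + base)
        I0 = 10.0
        beta_fb = thr / (k_o * I0)
        assert not nfb_oscillation_criterion(g_c, g_o, k_o, beta_fb, I0)
        assert nfb_oscillation_criterion(g_c, g_o, k_o, beta_fb * (1 + 1e-9), I0)

    def test_matches_peak_frequency_on_parameter_grid(self):
        # boolean criterion agrees with the presence of a positive PSD peak
        # across a 10 x 10 grid in (beta_fb, I_0)
        g_c, g_o, k_o = 1.0, 0.5, 2.0
        for beta_fb in np.geomspace(0.002, 0.3, 10):
            for I0 in np.geomspace(0.5, 40.0, 10):
                osc = nfb_oscillation_criterion(g_c, g_o, k_o, beta_fb, I0)
                net = fixtures.nfb(I_0=I0, beta_fb=beta_fb, k_o=k_o,
                                   gamma_c=g_c, gamma_o=g_o)
                mats = linearize(net)
                peak = peak_frequency(lambda w: psd_exact(mats, 1, w),
                                      omega_hi=6.0, n_grid=4001)
                assert osc == (peak > 0), (beta_fb, I0, peak)


class TestIFF:
    def test_output_psd_monotone_decreasing(self):
        net = fixtures.iff()
        mats = linearize(net)
        grid = np.linspace(0.0, 10.0, 500)
        vals = psd_exact(mats, net.output_index, grid)
        assert np.all(np.diff(vals) < 0)

    def test_iff_never_peaks_regardless_of_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            beta_ff = rng.uniform(0.05, 1.0)
            I0 = rng.uniform(2.0, 30.0)
            net = fixtures.iff(I_0=I0, beta_ff=beta_ff)
            mats = linearize(net)
            assert peak_frequency(lambda w: psd_exact(mats, 1, w), omega_hi=8.0) == 0.0


class TestRationalForm:
    @pytest.mark.parametrize(
        "name,num,den",
        [
            ("gene_expression", [120.0, 40.0], [0.25, 1.25, 1.0]),
            ("iff", [112.0, 94.0], [0.25, 1.25, 1.0]),
            ("nfb", [200.0, 66.0 + 2.0 / 3.0], [2.25, -0.75, 1.0]),
            ("rna_splicing", [219.84, 30.0, 1.2], [36.0, 150.25, 25.25, 1.0]),
        ],
    )
    def test_benchmark_coefficients(self, name, num, den):
        net = fixtures.make(name)
        got_num, got_den = rational_psd_exact(linearize(net), net.output_index)
        assert np.allclose(got_num, num, rtol=1e-7)
        assert np.allclose(got_den, den, rtol=1e-7)
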