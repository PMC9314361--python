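"""Fixture catalog: construction, serialisation round-trips, and the
qualitative behaviours of the nonlinear circuits."""

import numpy as np
import pytest

from padepsd import EnsembleConfig, NetworkSpecError, fixtures, run_ensemble, simulate
from padepsd.config import from_dict, to_dict
from padepsd.estimators import ensemble_moments
from padepsd.fixtures import known_factor_for_cell_cycle, make, synthetic_experiment_traces


class TestCatalog:
    def test_unknown_name_lists_catalog(self):
        with pytest.raises(NetworkSpecError, match="birth_death"):
            make("no_such_network")

    @pytest.mark.parametrize("name", sorted(fixtures.CATALOG))
    def test_every_fixture_simulates(self, name):
        net = make(name)
        traj = simulate(net, net.default_initial_state(), 5.0, seed=0)
        assert traj.horizon == 5.0
        assert np.all(traj.states >= 0)

    @pytest.mark.parametrize("name", ["birth_death", "gene_expression", "iff", "nfb",
                                      "rna_splicing", "telegraph", "entrainment_circuit"])
    def test_linear_fixtures_linearize(self, name):
        from padepsd import linearize
        linearize(make(name))

    @pytest.mark.parametrize("name", ["gene_expression", "nfb", "self_regulating_gene",
                                      "aif_gene_expression", "cell_cycle_host"])
    def test_config_round_trip(self, name):
        net = make(name)
        clone = from_dict(to_dict(net))
        assert clone.species_names == net.species_names
        assert clone.output_species == net.output_species
        assert np.array_equal(clone.default_initial_state(), net.default_initial_state())
        assert len(clone.reactions) == len(net.reactions)
        # propensities agree pointwise on random states
        from padepsd import propensity
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 15, size=net.d)
            for a, b in zip(net.reactions, clone.reactions):
                assert propensity(a, x) == pytest.approx(propensity(b, x))


class TestCellCycle:
    def test_mean_cycle_duration(self):
        # N/alpha: stage advances are exponential(alpha), N of them per cycle
        N, alpha = 4, 1.0
        cc = fixtures.cell_cycle_host(N=N, alpha=alpha)
        traj = simulate(cc, cc.default_initial_state(), 400.0, seed=2)
        stage = traj.states[:, cc.d - 1]
        n_div = int(np.sum((stage[1:] == 0) & (stage[:-1] == N - 1)))
        assert n_div > 50
        assert 400.0 / n_div == pytest.approx(N / alpha, rel=0.15)

    def test_known_factor_values(self):
        assert known_factor_for_cell_cycle(4, 1.0) == pytest.approx((2.0, 2.0))
        with pytest.raises(Exception):
            known_factor_for_cell_cycle(1, 1.0)

    def test_strict_binary_partition_never_deviates_from_half(self):
        cc = fixtures.cell_cycle_host(N=3, alpha=2.0, partition="strict_binary")
        traj = simulate(cc, cc.default_initial_state(), 60.0, seed=3)
        stage = traj.states[:, cc.d - 1]
        div_rows = np.nonzero((stage[1:] == 0) & (stage[:-1] == N_ if (N_ := 3) else 3 - 1))[0]
        div_rows = np.nonzero((stage[1:] == 0) & (stage[:-1] == 2))[0]
        assert len(div_rows) > 10
        for i in div_rows:
            pre = traj.states[i, :2]
            post = traj.states[i + 1, :2]
            assert np.all(np.abs(post - pre / 2.0) <= 0.5)


class TestAIF:
    @pytest.fixture(scope="class")
    @staticmethod
    def aif_runs():
        out = {}
        for key, kfb, fb in [("open", 0.0, "none"), ("hill", 0.25, "hill"),
                             ("prop", 0.25, "proportional")]:
            net = fixtures.aif_gene_expression(k_fb=kfb, feedback=fb)
            res = run_ensemble(net, EnsembleConfig(Q=10, T_f=3000.0, T_c=200.0, base_seed=7))
            out[key] = ensemble_moments(res)
        return out

    def test_set_point_tracking(self, aif_runs):
        # robust perfect adaptation: mean protein = mu/theta = 40 with and
        # without the extra feedback
        for key in ("open", "hill", "prop"):
            mean, _, mean_se, _ = aif_runs[key]
            assert abs(mean - 40.0) < 3 * mean_se + 0.15

    def test_feedback_reduces_variance(self, aif_runs):
        _, v0, _, se0 = aif_runs["open"]
        for key in ("hill", "prop"):
            _, v1, _, se1 = aif_runs[key]
            assert v1 + 3 * np.hypot(se0, se1) < v0

    def test_unknown_feedback_rejected(self):
        with pytest.raises(NetworkSpecError):
            fixtures.aif_gene_expression(feedback="quadratic")


class TestSyntheticTraces:
    def test_normalised_psd_scale_invariance(self):
        # the proportionality constant cancels exactly after normalisation
        from padepsd.dft import SampledSeries, periodogram
        net = fixtures.self_regulating_gene()
        kw = dict(Q=3, dt=0.1, seed=9, T_f=200.0, T_c=20.0)
        a = synthetic_experiment_traces(net, proportionality=1.0, **kw)
        b = synthetic_experiment_traces(net, proportionality=7.3, **kw)
        for q in range(3):
            _, pa = periodogram(SampledSeries(0.1, a[q]).demeaned())
            _, pb = periodogram(SampledSeries(0.1, b[q]).demeaned())
            na, nb = pa / pa.sum(), pb / pb.sum()
            assert np.max(np.abs(na - nb)) < 1e-10

    def test_invalid_requests_rejected(self):
        net = fixtures.self_regulating_gene()
        with pytest.raises(Exception):
            synthetic_experiment_traces(net, Q=0, dt=0.1, proportionality=1.0, seed=0)
        with pytest.raises(Exception):
            synthetic_experiment_traces(net, Q=2, dt=0.1, proportionality=-1.0, seed=0)


class TestHillInference:
    def test_cooperativity_recovered_from_normalised_psd(self):
        """Traces generated at H = 1 are closest (L2 on normalised PSDs) to
        the parametric estimate with H = 1 among candidate cooperativities."""
        from padepsd import pade_psd
        from padepsd.dft import SampledSeries, periodogram

        target = fixtures.self_regulating_gene(H=1.0)
        traces = synthetic_experiment_traces(target, Q=40, dt=0.05, proportionality=7.3,
                                             seed=21, T_f=500.0, T_c=25.0)
        psds = []
        for q in range(traces.shape[0]):
            om, p = periodogram(SampledSeries(0.05, traces[q]).demeaned())
            psds.append(p)
        exp_psd = np.mean(psds, axis=0)
        mask = om <= 6.0
        exp_norm = exp_psd[mask] / np.trapezoid(exp_psd[mask], om[mask])
        dists = {}
        for H in (0.5, 1.0, 2.0, 3.0):
            res = pade_psd(fixtures.self_regulating_gene(H=H), p=2, s_points=(np.inf,),
                           rho=(4,), test_points=(0.5, 1.0, 2.0),
                           Q=10, T_f=2000.0, T_c=50.0, seed=5)
            cur = res.rational.psd(om[mask], clip=True)
            cur_n = cur / np.trapezoid(cur, om[mask])
            dists[H] = float(np.sqrt(np.trapezoid((cur_n - exp_norm) ** 2, om[mask])))
        assert min(dists, key=dists.get) == 1.0

    def test_cooperativity_changes_the_normalised_psd(self):
        """H = 1 vs H = 3 give detectably different normalised spectra."""
        from padepsd import pade_psd
        curves = {}
        om = np.linspace(0.0, 6.0, 200)
        for H in (1.0, 3.0):
            res = pade_psd(fixtures.self_regulating_gene(H=H), p=2, s_points=(np.inf,),
                           rho=(4,), test_points=(1.0,), Q=10, T_f=2000.0, T_c=50.0, seed=5)
            c = res.rational.psd(om, clip=True)
            curves[H] = c / np.trapezoid(c, om)
        assert np.max(np.abs(curves[1.0] - curves[3.0])) > 0.05
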