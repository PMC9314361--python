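"""Shared (session-scoped) Monte-Carlo runs so the expensive simulations are
paid for once per test session."""

import warnings

import numpy as np
import pytest

from padepsd import EnsembleConfig, augment, fixtures, pade_psd, run_ensemble

warnings.filterwarnings("ignore", message="Pade denominator has roots")


@pytest.fixture(scope="session")
def gene_pipeline():
    """Full estimator on the gene expression benchmark (s = inf, rho = 4, p = 2)."""
    return pade_psd(fixtures.gene_expression(), p=2, s_points=(np.inf,), rho=(4,),
                    test_points=(0.5, 1.0, 2.0), Q=10, T_f=1e4, T_c=1e2, seed=1)


@pytest.fixture(scope="session")
def nfb_pipeline():
    return pade_psd(fixtures.nfb(), p=2, s_points=(np.inf,), rho=(4,),
                    test_points=(0.5, 1.0, 2.0), Q=10, T_f=1e4, T_c=1e2, seed=1)


@pytest.fixture(scope="session")
def splicing_pipeline():
    """Multipoint configuration for the RNA splicing network."""
    return pade_psd(fixtures.rna_splicing(), p=3, s_points=(1.0, 1.5, 2.0, np.inf),
                    rho=(2, 2, 2, 3), test_points=(0.5, 1.0, 2.0),
                    Q=10, T_f=1e4, T_c=1e2, seed=1)


@pytest.fixture(scope="session")
def birth_death_ensemble():
    """Augmented birth-death ensemble with registers at s = 1 and occupancy."""
    net = fixtures.birth_death()
    aug = augment(net, s_points=[1.0], rho=[2], test_points=[1.0, 3.0])
    cfg = EnsembleConfig(Q=10, T_f=4000.0, T_c=50.0, base_seed=3)
    return run_ensemble(aug, cfg, collect_occupancy=True)


@pytest.fixture(scope="session")
def telegraph_ensemble():
    net = fixtures.telegraph()
    aug = augment(net, s_points=[1.0], rho=[2], test_points=[1.0, 3.0])
    cfg = EnsembleConfig(Q=10, T_f=4000.0, T_c=50.0, base_seed=3)
    return run_ensemble(aug, cfg, collect_occupancy=True)


@pytest.fixture(scope="session")
def gene_expr_ensemble():
    """Gene-expression occupancy ensemble for estimator variance comparisons."""
    net = fixtures.gene_expression()
    aug = augment(net, s_points=[], rho=[], test_points=[])
    cfg = EnsembleConfig(Q=10, T_f=2000.0, T_c=50.0, base_seed=6)
    return run_ensemble(aug, cfg, collect_occupancy=True)


@pytest.fixture(scope="session")
def repressilator_pipeline():
    """Finite-point estimate of the repressilator (H = 1.5, no sponge)."""
    return pade_psd(fixtures.repressilator(H=1.5), p=3, s_points=(0.8, 2.4, 4.8, 10.0),
                    rho=(2, 2, 2, 2), test_points=(1.6, 4.0),
                    Q=10, T_f=600.0, T_c=30.0, seed=11)


@pytest.fixture(scope="session")
def cell_cycle_pipeline():
    """Dividing-cell host with a high-expression gene module; known-factor fit."""
    inner = fixtures.gene_expression(k_r=40, gamma_r=1, k_p=4, gamma_p=0.5)
    cc = fixtures.cell_cycle_host(N=16, alpha=4.0, partition="binomial", inner=inner)
    B = fixtures.known_factor_for_cell_cycle(16, 4.0)
    res = pade_psd(cc, p=3, s_points=(0.3, 1.0, 3.0, 8.0), rho=(2, 2, 2, 2),
                   test_points=(0.5, 2.0), Q=10, T_f=3000.0, T_c=50.0, seed=5,
                   known_factor=B)
    return res
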