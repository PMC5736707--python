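"""Growth-rate inference: exponential fits, MCMC behavior, rate statistics."""

import numpy as np
import pytest

from clonedyn.ccf import GRID_SIZE
from clonedyn.clustering import CloneCluster, _stack_log_posteriors
from clonedyn.kinetics import (
    back_extrapolate,
    ccf_rate_stats,
    cell_scale,
    clone_cell_count,
    fit_exponential,
    kinetics_mcmc,
)
from clonedyn.phylogeny import PhylogenyTree
from _util import oracle_clusters
from clonedyn.simulate import SimulationConfig, simulate_patient


class TestCellCount:
    def test_arithmetic(self):
        assert clone_cell_count(0.5, 10_000, 0.9, 5.0e6) == pytest.approx(2.25e10)
        assert clone_cell_count(0.0, 10_000, 0.9, 5.0e6) == 0.0

    def test_linearity_in_volume(self):
        one = clone_cell_count(0.3, 5_000, 0.8, 5.0e6)
        assert clone_cell_count(0.3, 5_000, 0.8, 1.0e7) == pytest.approx(2 * one)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            clone_cell_count(-0.1, 10_000, 0.9)


class TestExponentialFit:
    def test_noiseless_recovery_exact(self):
        days = np.array([0.0, 30.0, 60.0])
        counts = 1000.0 * np.exp(0.02 * days)
        fit = fit_exponential(counts, days)
        assert fit.g == pytest.approx(0.02, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.n0 == pytest.approx(1000.0, rel=1e-10)

    def test_two_points_saturate(self):
        fit = fit_exponential(np.array([100.0, 250.0]), np.array([0.0, 50.0]))
        assert fit.two_point and fit.r2 == 1.0 and fit.n_points == 2

    def test_zero_counts_excluded_with_warning(self):
        days = np.array([0.0, 30.0, 60.0, 90.0])
        counts = np.array([1000.0, 0.0, 1000.0 * np.e, 0.0])
        with pytest.warns(UserWarning, match="zero-count"):
            fit = fit_exponential(counts, days)
        assert fit.n_points == 2

    def test_insufficient_points_gives_none(self):
        assert fit_exponential(np.array([100.0, 0.0]), np.array([0.0, 30.0])) is None

    def test_mean_bias_small_under_lognormal_noise(self):
        rng = np.random.default_rng(42)
        days = np.array([0.0, 30.0, 60.0, 90.0])
        errs = []
        for _ in range(500):
            counts = 1e6 * np.exp(0.01 * days) * rng.lognormal(0.0, 0.2, size=4)
            errs.append(fit_exponential(counts, days).g - 0.01)
        assert abs(np.mean(errs)) < 0.001


class TestBackExtrapolation:
    def test_closed_form(self):
        n0, _ = back_extrapolate(0.01, 300.0, 100.0 * np.e**3)
        assert n0 == pytest.approx(100.0, rel=1e-12)
        assert back_extrapolate(0.0, 123.0, 777.0)[0] == pytest.approx(777.0)

    def test_forward_backward_identity(self):
        n_start, g, t = 12345.678, 0.0234, 250.0
        grown = n_start * np.exp(g * t)
        back, _ = back_extrapolate(g, t, grown)
        assert back == pytest.approx(n_start, rel=1e-14)

    def test_ci_sorted_from_rate_bounds(self):
        _, (lo, hi) = back_extrapolate(0.01, 100.0, 1e6, g_ci=(0.005, 0.02))
        assert lo < hi
        assert lo == pytest.approx(1e6 * np.exp(-0.02 * 100))


def degenerate_patient():
    """Two clones with point-mass posteriors at fixed grid CCFs."""
    days = np.array([0.0, 50.0, 100.0])
    trunk = [1.0, 1.0, 1.0]
    child = [0.6, 0.4, 0.2]
    clusters, posteriors = [], {}
    for cid, ccfs in ((1, trunk), (2, child)):
        probs = np.zeros((3, GRID_SIZE))
        members = []
        for t, v in enumerate(ccfs):
            probs[t, int(round(v * 100))] = 1.0
        for j in range(3):
            mid = f"c{cid}m{j}"
            members.append(mid)
            posteriors[mid] = probs
        clusters.append(CloneCluster(cid, tuple(members), probs))
    ids = tuple(sorted(posteriors))
    logp = np.stack([np.log(posteriors[m] + 1e-300) for m in ids])
    return clusters, ids, logp, days


class TestKineticsMCMC:
    def test_degenerate_chain_equals_deterministic_fit(self):
        clusters, ids, logp, days = degenerate_patient()
        tree = PhylogenyTree.from_dict({1: None, 2: 1}, 1)
        scale = np.full(3, 1e10)
        fits = kinetics_mcmc(
            clusters, tree, logp, ids, days, scale, n_iter=1, seed=0, smooth_cells=False
        )
        child = clusters[1]
        direct = fit_exponential(child.ccf_point * scale, days)
        assert fits[2].g == pytest.approx(direct.g, abs=1e-12)
        # trunk-exclusive fraction: 1 - child
        trunk_counts = (clusters[0].ccf_point - child.ccf_point) * scale
        assert fits[1].g == pytest.approx(fit_exponential(trunk_counts, days).g, abs=1e-12)

    def test_seed_reproducibility(self):
        clusters, ids, logp, days = degenerate_patient()
        tree = PhylogenyTree.from_dict({1: None, 2: 1}, 1)
        scale = np.full(3, 1e10)
        a = kinetics_mcmc(clusters, tree, logp, ids, days, scale, n_iter=50, seed=3)
        b = kinetics_mcmc(clusters, tree, logp, ids, days, scale, n_iter=50, seed=3)
        assert a[2].g == b[2].g and a[2].n0_ci == b[2].n0_ci

    def test_low_ccf_clone_excluded(self):
        clusters, ids, logp, days = degenerate_patient()
        # shrink the child below the 0.1 inclusion rule
        small = np.zeros((3, GRID_SIZE))
        for t, v in enumerate([0.05, 0.04, 0.03]):
            small[t, int(round(v * 100))] = 1.0
        clusters[1] = CloneCluster(2, clusters[1].member_ids, small)
        tree = PhylogenyTree.from_dict({1: None, 2: 1}, 1)
        fits = kinetics_mcmc(clusters, tree, logp, ids, days, np.full(3, 1e10), n_iter=20, seed=0)
        assert 2 not in fits

    def test_mcmc_median_within_regression_ci_for_separated_clones(self):
        cfg = SimulationConfig(
            shift_prevalence=1.0,
            n_clones_range=(2, 2),
            mutations_per_clone=25,
            rate_spread=0.005,
            min_clone_fraction=0.2,
        )
        patient = simulate_patient(cfg, 1, "P1")
        clusters, ids, logp, inp = oracle_clusters(patient)
        tree = PhylogenyTree.from_dict(patient.tree_parent, 1)
        scale = cell_scale(inp.alc, inp.purity)
        fits = kinetics_mcmc(clusters, tree, logp, ids, inp.days, scale, n_iter=200, seed=5)
        for cid, fit in fits.items():
            cluster = next(c for c in clusters if c.cluster_id == cid)
            from clonedyn.phylogeny import exclusive_ccf

            excl = exclusive_ccf(tree, {c.cluster_id: c.ccf_point for c in clusters})
            direct = fit_exponential(excl[cid] * scale, inp.days, clone_id=cid)
            assert direct.ci_low - 0.002 <= fit.g <= direct.ci_high + 0.002

    def test_singleton_cluster_uses_regression_fallback(self):
        clusters, ids, logp, days = degenerate_patient()
        lone_probs = np.zeros((3, GRID_SIZE))
        for t, v in enumerate([0.3, 0.25, 0.2]):
            lone_probs[t, int(round(v * 100))] = 1.0
        clusters.append(
            CloneCluster(3, ("c2m0",), lone_probs, low_confidence=True)
        )
        tree = PhylogenyTree.from_dict({1: None, 2: 1, 3: 1}, 1)
        fits = kinetics_mcmc(clusters, tree, logp, ids, days, np.full(3, 1e10), n_iter=20, seed=0)
        assert fits[3].method == "singleton_regression"


class TestRateStats:
    def test_first_period_rate(self):
        stats = ccf_rate_stats(np.array([0.50, 0.38]), np.array([0.0, 30.0]))
        assert stats.rate1 == pytest.approx(0.004)

    def test_linear_decline_has_zero_deceleration(self):
        days = np.array([0.0, 30.0, 180.0, 365.0])
        ccf = 0.8 - 0.001 * days
        stats = ccf_rate_stats(ccf, days)
        assert stats.deceleration == pytest.approx(0.0, abs=1e-12)
        assert stats.concordant

    def test_missing_boundary_sample_uses_nearest(self):
        days = np.array([0.0, 56.0, 180.0])
        stats = ccf_rate_stats(np.array([0.5, 0.4, 0.3]), days)
        assert stats.window1 == (0, 56)
        assert stats.rate1 == pytest.approx(0.1 / 56)

    def test_relapse_horizon_cut(self):
        days = np.array([0.0, 30.0, 600.0])
        stats = ccf_rate_stats(np.array([0.5, 0.4, 0.1]), days, horizon=365)
        assert np.isnan(stats.rate2)
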