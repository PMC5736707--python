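"""Clonal-shift detection: band probability, BH adjustment, cohort calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonedyn.ccf import CCF_GRID, GRID_SIZE
from clonedyn.clustering import CloneCluster
from clonedyn.shifts import (
    band_probability,
    bh_adjust,
    classify_cohort,
    max_shift_clusters,
    select_comparison_timepoints,
)
from clonedyn.simulate import SimulationConfig, simulate_patient
from _util import oracle_clusters


def point_cluster(cid, ccfs):
    probs = np.zeros((len(ccfs), GRID_SIZE))
    for t, v in enumerate(ccfs):
        probs[t, int(round(v * 100))] = 1.0
    return CloneCluster(cid, (f"m{cid}",), probs)


def smooth_cluster(cid, centers, width=0.05):
    probs = np.stack([np.exp(-0.5 * ((CCF_GRID - c) / width) ** 2) for c in centers])
    probs /= probs.sum(axis=1, keepdims=True)
    return CloneCluster(cid, (f"m{cid}",), probs)


class TestMaxShift:
    def test_rising_and_falling_candidates(self):
        clusters = [
            point_cluster(1, [0.2, 0.5]),  # +0.3
            point_cluster(2, [0.5, 0.25]),  # -0.25
            point_cluster(3, [0.3, 0.3]),  # 0
        ]
        rising, falling = max_shift_clusters(clusters, 0, 1)
        assert rising.cluster_id == 1 and falling.cluster_id == 2

    def test_single_cluster_is_both(self):
        (c,) = [point_cluster(1, [0.2, 0.6])]
        assert max_shift_clusters([c], 0, 1) == (c, c)

    def test_tie_goes_to_smaller_id(self):
        clusters = [point_cluster(2, [0.2, 0.5]), point_cluster(1, [0.3, 0.6])]
        rising, _ = max_shift_clusters(clusters, 0, 1)
        assert rising.cluster_id == 1

    def test_absent_direction_is_none(self):
        clusters = [point_cluster(1, [0.2, 0.5]), point_cluster(2, [0.3, 0.4])]
        rising, falling = max_shift_clusters(clusters, 0, 1)
        assert rising.cluster_id == 1 and falling is None


class TestBandProbability:
    def test_point_masses(self):
        assert band_probability(point_cluster(1, [0.5, 0.5]), 0, 1) == pytest.approx(1.0)
        assert band_probability(point_cluster(1, [0.9, 0.3]), 0, 1) == pytest.approx(0.0)

    def test_uniform_band_equals_brute_force(self):
        probs = np.full((2, GRID_SIZE), 1.0 / GRID_SIZE)
        cluster = CloneCluster(1, ("m",), probs)
        # independent brute-force double sum over the grid
        expected = sum(
            probs[0, i] * probs[1, j]
            for i in range(GRID_SIZE)
            for j in range(GRID_SIZE)
            if abs(CCF_GRID[i] - CCF_GRID[j]) <= 0.1 + 1e-12
        )
        assert expected == pytest.approx(2011 / 10201)
        assert band_probability(cluster, 0, 1, 0.1) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_monotone_in_delta(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(GRID_SIZE), size=2)
        cluster = CloneCluster(1, ("m",), probs)
        assert band_probability(cluster, 0, 1) == pytest.approx(
            band_probability(cluster, 1, 0), abs=1e-12
        )
        deltas = [0.0, 0.05, 0.1, 0.2, 0.5, 1.0]
        values = [band_probability(cluster, 0, 1, d) for d in deltas]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0)


class TestBH:
    def test_step_up_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert (adj < 0.1).sum() == 3

    @pytest.mark.parametrize("p", [0.001, 0.2, 1.0])
    def test_single_and_equal_values(self, p):
        assert bh_adjust(np.array([p]))[0] == pytest.approx(p)
        assert np.allclose(bh_adjust(np.full(5, p)), p)

    @given(
        pvals=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=10)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        pvals = np.array(pvals)
        # oracle: adjusted p_(i) = min_{j >= i} m * p_(j) / j on sorted values
        order = np.argsort(pvals, kind="stable")
        m = len(pvals)
        sorted_adj = np.minimum.accumulate(
            (m * pvals[order] / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(sorted_adj, 1.0)
        assert np.allclose(bh_adjust(pvals), oracle, atol=1e-12)


class TestCohortClassification:
    def test_comparison_window_excludes_relapse_and_late_samples(self):
        days = [0, 30, 180, 365, 540]
        relapse = [False, False, False, False, True]
        assert select_comparison_timepoints(days, relapse) == (0, 3)
        assert select_comparison_timepoints([0, 400, 540], [False, False, False]) is None

    def test_true_half_ccf_shift_is_called_evolved(self):
        # generator draw with a known large (~0.5) true CCF shift
        cfg = SimulationConfig(
            shift_prevalence=1.0, n_clones_range=(2, 3), mutations_per_clone=30, depth_mean=100.0
        )
        patient = simulate_patient(cfg, 3, "P1")
        assert patient.true_shift > 0.45
        clusters, _, _, inp = oracle_clusters(patient)
        result = classify_cohort(
            {"P1": clusters}, {"P1": [int(d) for d in inp.days]}, {"P1": list(inp.is_relapse)}
        )
        assert result.evolved["P1"]
        assert result.max_significant_shift["P1"] >= 0.3

    def test_looser_threshold_flags_superset(self):
        cfg = SimulationConfig(n_patients=12, shift_prevalence=0.5)
        patients = [simulate_patient(cfg, s, f"P{s}") for s in range(12)]
        pc, pdays, prel = {}, {}, {}
        for p in patients:
            clusters, _, _, inp = oracle_clusters(p)
            pc[p.patient_id] = clusters
            pdays[p.patient_id] = [int(d) for d in inp.days]
            prel[p.patient_id] = list(inp.is_relapse)
        strict = classify_cohort(pc, pdays, prel, tau=0.1)
        loose = classify_cohort(pc, pdays, prel, tau=0.05)
        strict_set = {pid for pid, e in strict.evolved.items() if e}
        loose_set = {pid for pid, e in loose.evolved.items() if e}
        assert strict_set <= loose_set

    def test_q_values_dominate_raw_band_probabilities(self):
        clusters = {
            "P1": [smooth_cluster(1, [0.9, 0.3]), smooth_cluster(2, [0.2, 0.6])],
            "P2": [smooth_cluster(1, [0.5, 0.5])],
        }
        days = {"P1": [0, 180], "P2": [0, 180]}
        result = classify_cohort(clusters, days)
        for t in result.tests:
            assert t.q_adj >= t.band_prob - 1e-12
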