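"""Detection of significant early clonal shifts with cohort-level FDR.

For each patient we compare the baseline sample with the latest pre-relapse
sample inside the first year of therapy.  The clusters with the maximal
positive and maximal negative change in CCF point estimate are the rising
and falling candidates.  For each candidate, the null hypothesis "the clone
CCF did not change" is scored by the posterior probability that the
two-dimensional (baseline, later) cluster CCF distribution lies within a
band of +/-0.1 around the diagonal; these band probabilities are pooled
across the whole cohort into one Benjamini-Hochberg family.  A patient is
called evolved when any of its tests has an adjusted value below ``q_cut``
together with an absolute CCF change above ``tau`` (defaults 0.1 and 0.1;
a sensitivity re-analysis uses ``tau = 0.05``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ccf import CCF_GRID
from .clustering import CloneCluster

DEFAULT_BAND = 0.1
DEFAULT_CCF_THRESHOLD = 0.1
DEFAULT_Q_CUT = 0.1
EARLY_HORIZON_DAYS = 365


@dataclass
class ShiftTest:
    """One rising-or-falling clonal-shift test for one patient."""

    patient_id: str
    cluster_id: int
    direction: str  # "rising" | "falling"
    t0: int
    t1: int
    delta_ccf: float
    band_prob: float
    q_adj: float = np.nan
    significant: bool = False


def max_shift_clusters(
    clusters: list[CloneCluster], i0: int, i1: int
) -> tuple[CloneCluster | None, CloneCluster | None]:
    """Clusters with maximal positive / negative CCF change between two timepoints.

    Returns ``(rising, falling)``; a direction in which no cluster moves is
    ``None``.  A single cluster is both candidates.  Ties go to the smaller
    cluster_id (clusters are scanned in cluster_id order).
    """
    if not clusters:
        return None, None
    ordered = sorted(clusters, key=lambda c: c.cluster_id)
    if len(ordered) == 1:
        return ordered[0], ordered[0]
    deltas = np.array([c.ccf_point[i1] - c.ccf_point[i0] for c in ordered])
    rising = ordered[int(np.argmax(deltas))] if deltas.max() > 0 else None
    falling = ordered[int(np.argmin(deltas))] if deltas.min() < 0 else None
    return rising, falling


def band_probability(
    cluster: CloneCluster, i0: int, i1: int, delta: float = DEFAULT_BAND
) -> float:
    """Posterior mass of |CCF(t1) - CCF(t0)| <= delta.

    The two marginal grid posteriors are treated as independent; the band
    probability is the double sum of their product over grid pairs within
    ``delta`` of the diagonal.
    """
    p0 = cluster.ccf_probs[i0]
    p1 = cluster.ccf_probs[i1]
    mask = np.abs(CCF_GRID[:, None] - CCF_GRID[None, :]) <= delta + 1e-12
    return float(p0 @ mask @ p1)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class CohortShiftResult:
    tests: list[ShiftTest]
    evolved: dict[str, bool]
    max_significant_shift: dict[str, float]

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": t.patient_id,
                "cluster_id": t.cluster_id,
                "direction": t.direction,
                "t0": t.t0,
                "t1": t.t1,
                "delta_ccf": t.delta_ccf,
                "band_prob": t.band_prob,
                "q_adj": t.q_adj,
                "significant": t.significant,
            }
            for t in self.tests
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "cluster_id",
                "direction",
                "t0",
                "t1",
                "delta_ccf",
                "band_prob",
                "q_adj",
                "significant",
            ],
        )

    @property
    def n_evolved(self) -> int:
        return sum(self.evolved.values())


def select_comparison_timepoints(
    days: list[int], is_relapse: list[bool] | None = None, horizon: int = EARLY_HORIZON_DAYS
) -> tuple[int, int] | None:
    """Indices of the baseline and latest pre-relapse sample within ``horizon`` days.

    Relapse timepoints are excluded so that early shifts are quantified in
    the absence of overt progression.  Returns ``None`` when no later
    eligible sample exists.
    """
    if is_relapse is None:
        is_relapse = [False] * len(days)
    eligible = [i for i, (d, rel) in enumerate(zip(days, is_relapse)) if not rel and d <= horizon]
    if not eligible:
        return None
    i0 = min(eligible, key=lambda i: days[i])
    i1 = max(eligible, key=lambda i: days[i])
    if i0 == i1:
        return None
    return i0, i1


def classify_cohort(
    patient_clusters: dict[str, list[CloneCluster]],
    patient_days: dict[str, list[int]],
    patient_relapse: dict[str, list[bool]] | None = None,
    delta: float = DEFAULT_BAND,
    tau: float = DEFAULT_CCF_THRESHOLD,
    q_cut: float = DEFAULT_Q_CUT,
    horizon: int = EARLY_HORIZON_DAYS,
) -> CohortShiftResult:
    """Run the clonal-shift test for every patient and control cohort FDR.

    All rising/falling band probabilities enter a single BH family; a
    patient is evolved when any test satisfies ``q_adj < q_cut`` and
    ``|delta_ccf| > tau``.
    """
    tests: list[ShiftTest] = []
    evolved = {pid: False for pid in patient_clusters}
    max_shift = {pid: 0.0 for pid in patient_clusters}

    for pid in sorted(patient_clusters):
        clusters = patient_clusters[pid]
        days = patient_days[pid]
        relapse = (patient_relapse or {}).get(pid)
        picked = select_comparison_timepoints(days, relapse, horizon)
        if picked is None or not clusters:
            continue
        i0, i1 = picked
        rising, falling = max_shift_clusters(clusters, i0, i1)
        for direction, cluster in (("rising", rising), ("falling", falling)):
            if cluster is None:
                continue
            tests.append(
                ShiftTest(
                    patient_id=pid,
                    cluster_id=cluster.cluster_id,
                    direction=direction,
                    t0=days[i0],
                    t1=days[i1],
                    delta_ccf=float(cluster.ccf_point[i1] - cluster.ccf_point[i0]),
                    band_prob=band_probability(cluster, i0, i1, delta),
                )
            )

    if tests:
        q = bh_adjust(np.array([t.band_prob for t in tests]))
        for t, q_i in zip(tests, q):
            t.q_adj = float(q_i)
            t.significant = bool(q_i < q_cut and abs(t.delta_ccf) > tau)
            if t.significant:
                evolved[t.patient_id] = True
                max_shift[t.patient_id] = max(max_shift[t.patient_id], abs(t.delta_ccf))

    return CohortShiftResult(tests=tests, evolved=evolved, max_significant_shift=max_shift)
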