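"""Shared helpers for the test suite: oracle constructions from simulation truth."""

from __future__ import annotations

import numpy as np

from clonedyn.clustering import clusters_from_assignment, _stack_log_posteriors
from clonedyn.io import SegmentIndex, SegmentRecord
from clonedyn.pipeline import build_patient_inputs

DIPLOID = SegmentRecord("s", "1", 1, 10**9, 2.0, 1, 1)


def patient_inputs(patient):
    """PatientInput for one synthetic patient."""
    return build_patient_inputs(patient.mutations, SegmentIndex(patient.segments), patient.timeline)[0]


def oracle_clusters(patient, inp=None):
    """Clusters built from the true mutation-to-clone map, relabeled so that
    cluster_id equals the true clone id (majority vote of members)."""
    if inp is None:
        inp = patient_inputs(patient)
    ids, logp = _stack_log_posteriors(inp.posteriors)
    labels = np.array([patient.mutation_clone[m] for m in ids])
    clusters = clusters_from_assignment(ids, labels, logp)
    for c in clusters:
        true_ids = [patient.mutation_clone[m] for m in c.member_ids]
        c.cluster_id = max(set(true_ids), key=true_ids.count)
    return clusters, ids, logp, inp


def binomial_posteriors(ccf_vectors, members_per_cluster, depth, seed, purity=1.0):
    """Simulate per-mutation CCF posteriors for clusters with known CCF
    trajectories (diploid het loci), returning (posteriors dict, truth dict)."""
    from clonedyn.ccf import vaf_to_ccf_posterior

    rng = np.random.default_rng(seed)
    posteriors, truth = {}, {}
    for k, ccfs in enumerate(ccf_vectors):
        for j in range(members_per_cluster):
            mid = f"c{k}m{j:03d}"
            per_t = []
            for ccf in ccfs:
                alt = rng.binomial(depth, max(purity * ccf / 2.0, 1e-9))
                per_t.append(vaf_to_ccf_posterior(alt, depth - alt, purity, DIPLOID))
            posteriors[mid] = per_t
            truth[mid] = k
    return posteriors, truth


def pairwise_accuracy(labels_true: dict, clusters) -> float:
    """Fraction of mutation pairs whose co-clustering matches the truth."""
    ids = sorted(labels_true)
    member_of = {}
    for c in clusters:
        for m in c.member_ids:
            member_of[m] = c.cluster_id
    agree = total = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            same_true = labels_true[ids[i]] == labels_true[ids[j]]
            same_est = member_of[ids[i]] == member_of[ids[j]]
            agree += same_true == same_est
            total += 1
    return agree / total
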