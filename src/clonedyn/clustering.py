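"""Multi-timepoint Dirichlet-process mixture clustering of mutations.

Mutations sampled serially from one patient are clustered jointly across all
timepoints: a subclone is a set of mutations sharing a latent CCF vector
``phi_k`` over the patient's timepoints.  Each mutation contributes a
discretized CCF posterior per timepoint (see :mod:`clonedyn.ccf`); a
cluster's CCF distribution at a timepoint is the normalized product of its
members' posteriors, and a mutation's likelihood under a cluster is the grid
dot product of the cluster distribution with the mutation's posterior,
multiplied across timepoints.  The number of clusters is unbounded a priori
(Dirichlet process with concentration gamma, Gamma(1,1) hyperprior, gamma
resampled each sweep by the auxiliary-variable scheme of Escobar & West).

The collapsed Gibbs chain records an assignment vector per kept iteration;
the consensus partition is an average-linkage cut of the co-clustering
frequency matrix at distance 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ccf import CCF_GRID, GRID_SIZE, CCFPosterior

_LOG_TINY = 1e-300


@dataclass
class CloneCluster:
    """A subclone: member mutations plus a per-timepoint CCF posterior."""

    cluster_id: int
    member_ids: tuple[str, ...]
    ccf_probs: np.ndarray  # (n_timepoints, GRID_SIZE)
    low_confidence: bool = False  # singleton clusters are flagged

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_timepoints(self) -> int:
        return self.ccf_probs.shape[0]

    @property
    def ccf_point(self) -> np.ndarray:
        """Per-timepoint posterior mode (first grid point on ties)."""
        return CCF_GRID[np.argmax(self.ccf_probs, axis=1)]

    def ccf_std(self, t: int) -> float:
        p = self.ccf_probs[t]
        mu = p @ CCF_GRID
        return float(np.sqrt(p @ (CCF_GRID - mu) ** 2))


@dataclass
class ClusterChain:
    """Post-burn-in Gibbs samples of the mutation-to-cluster assignment."""

    mutation_ids: tuple[str, ...]
    assignments: np.ndarray  # (n_kept, n_mutations) relabeled ints
    gamma_trace: np.ndarray  # (n_kept,)
    log_posteriors: np.ndarray = field(repr=False)  # (n_mutations, T, GRID_SIZE)

    def cocluster_matrix(self) -> np.ndarray:
        """Pairwise co-assignment frequency; symmetric, unit diagonal."""
        n_kept, n = self.assignments.shape
        freq = np.zeros((n, n))
        for it in range(n_kept):
            same = self.assignments[it][:, None] == self.assignments[it][None, :]
            freq += same
        return freq / n_kept


def _stack_log_posteriors(
    posteriors: dict[str, list[CCFPosterior]],
) -> tuple[tuple[str, ...], np.ndarray]:
    ids = tuple(sorted(posteriors))
    if not ids:
        raise ValueError("at least one mutation is required")
    n_t = len(posteriors[ids[0]])
    if n_t == 0:
        raise ValueError("at least one timepoint is required")
    logp = np.empty((len(ids), n_t, GRID_SIZE))
    for j, mid in enumerate(ids):
        posts = posteriors[mid]
        if len(posts) != n_t:
            raise ValueError(f"mutation {mid} has {len(posts)} timepoints, expected {n_t}")
        for t, post in enumerate(posts):
            logp[j, t] = np.log(post.probs + _LOG_TINY)
    return ids, logp


def _cluster_distributions(log_sums: np.ndarray) -> np.ndarray:
    """Softmax over the grid axis of summed member log posteriors."""
    shifted = log_sums - log_sums.max(axis=-1, keepdims=True)
    p = np.exp(shifted)
    return p / p.sum(axis=-1, keepdims=True)


def _resample_concentration(
    gamma: float, n: int, k: int, rng: np.random.Generator, a: float = 1.0, b: float = 1.0
) -> float:
    # Escobar & West (1995) auxiliary-variable update under Gamma(a, b).
    eta = rng.beta(gamma + 1.0, n)
    rate = b - np.log(eta)
    odds = (a + k - 1.0) / (n * rate)
    shape = a + k if rng.random() < odds / (1.0 + odds) else a + k - 1.0
    return float(rng.gamma(shape, 1.0 / rate))


def gibbs_cluster(
    posteriors: dict[str, list[CCFPosterior]],
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
) -> ClusterChain:
    """Run the collapsed Gibbs sampler over mutation-to-subclone assignments.

    Parameters
    ----------
    posteriors
        Mapping mutation_id -> list of per-timepoint CCF posteriors; all
        mutations must share the same timepoint list.
    n_iter, burn_in
        Total sweeps and discarded prefix; ``n_iter`` must exceed ``burn_in``.
    seed
        Seed for the chain's random generator.
    """
    if n_iter <= burn_in:
        raise ValueError(f"n_iter ({n_iter}) must exceed burn_in ({burn_in})")
    ids, logp = _stack_log_posteriors(posteriors)
    n, n_t, _ = logp.shape
    probs_flat = np.exp(logp)
    rng = np.random.default_rng(seed)

    # state: all mutations start in a single cluster
    labels = np.zeros(n, dtype=int)
    log_sums: dict[int, np.ndarray] = {0: logp.sum(axis=0)}
    counts: dict[int, int] = {0: n}
    next_label = 1
    gamma = 1.0
    log_new = -n_t * np.log(GRID_SIZE)  # uniform-grid prior predictive

    kept_assign = np.empty((n_iter - burn_in, n), dtype=int)
    kept_gamma = np.empty(n_iter - burn_in)

    for sweep in range(n_iter):
        for j in range(n):
            lab = labels[j]
            counts[lab] -= 1
            if counts[lab] == 0:
                del counts[lab], log_sums[lab]
            else:
                log_sums[lab] -= logp[j]

            active = list(counts)
            if active:
                stacked = np.stack([log_sums[k] for k in active])  # (K, T, G)
                dists = _cluster_distributions(stacked)
                overlap = np.einsum("ktg,tg->kt", dists, probs_flat[j])
                loglik = np.log(overlap + _LOG_TINY).sum(axis=1)
                weights = np.log([counts[k] for k in active]) + loglik
                weights = np.append(weights, np.log(gamma) + log_new)
            else:
                weights = np.array([np.log(gamma) + log_new])
            weights -= weights.max()
            probs = np.exp(weights)
            probs /= probs.sum()
            choice = rng.choice(len(probs), p=probs)
            if choice == len(active):
                lab = next_label
                next_label += 1
                counts[lab] = 1
                log_sums[lab] = logp[j].copy()
            else:
                lab = active[choice]
                counts[lab] += 1
                log_sums[lab] += logp[j]
            labels[j] = lab

        gamma = _resample_concentration(gamma, n, len(counts), rng)
        if sweep >= burn_in:
            kept_assign[sweep - burn_in] = labels
            kept_gamma[sweep - burn_in] = gamma

    return ClusterChain(
        mutation_ids=ids,
        assignments=kept_assign,
        gamma_trace=kept_gamma,
        log_posteriors=logp,
    )


def clusters_from_assignment(
    mutation_ids: tuple[str, ...],
    labels: np.ndarray,
    log_posteriors: np.ndarray,
) -> list[CloneCluster]:
    """Build CloneClusters (product posteriors) from one assignment vector.

    Clusters are ordered by descending mean CCF at the first timepoint, ties
    broken by the lexicographically smallest member mutation_id.
    """
    groups: dict[int, list[int]] = {}
    for j, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(j)
    built = []
    for members in groups.values():
        log_sum = log_posteriors[members].sum(axis=0)
        probs = _cluster_distributions(log_sum)
        member_ids = tuple(sorted(mutation_ids[j] for j in members))
        baseline_mean = probs[0] @ CCF_GRID
        built.append((baseline_mean, member_ids, probs, len(members)))
    built.sort(key=lambda item: (-item[0], item[1]))
    return [
        CloneCluster(
            cluster_id=i + 1,
            member_ids=member_ids,
            ccf_probs=probs,
            low_confidence=(n == 1),
        )
        for i, (_, member_ids, probs, n) in enumerate(built)
    ]


def consensus_clusters(chain: ClusterChain, cut: float = 0.5) -> list[CloneCluster]:
    """Consensus partition: average-linkage cut of the co-clustering matrix.

    Pairs co-assigned in more than ``1 - cut`` of kept iterations tend to end
    up together; the cluster CCF posterior per timepoint is the normalized
    product of member posteriors.
    """
    n = len(chain.mutation_ids)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        freq = chain.cocluster_matrix()
        dist = 1.0 - freq
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, t=cut, criterion="distance")
    return clusters_from_assignment(chain.mutation_ids, labels, chain.log_posteriors)
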