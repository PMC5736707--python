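"""Cancer cell fraction (CCF) inference from allele read counts.

Given the variant allele fraction (VAF) of a somatic mutation, the sample
purity ``alpha`` and the local copy number, the expected VAF of a mutation
present at multiplicity ``m`` in a fraction ``ccf`` of tumor cells is

    E[VAF] = alpha * m * ccf / (alpha * q_t + (1 - alpha) * q_n)

where ``q_t`` is the total tumor copy number at the locus and ``q_n`` the
normal copy number (2 for autosomes).  Inverting this relationship under a
binomial read-count model yields a posterior distribution over CCF, which we
discretize on a uniform 101-point grid {0, 0.01, ..., 1.00} with a uniform
prior.  Mutations force-called with zero alternate reads are first-class
inputs: their posterior simply concentrates near zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .io import SegmentRecord

logger = logging.getLogger(__name__)

#: Number of points on the CCF grid (resolution 0.01).
GRID_SIZE = 101

#: The shared CCF grid {0.00, 0.01, ..., 1.00}.
CCF_GRID: np.ndarray = np.linspace(0.0, 1.0, GRID_SIZE)

_VAF_FLOOR = 1e-6
_VAF_CEIL = 1.0 - 1e-6


@dataclass
class CCFPosterior:
    """Discretized posterior over cancer cell fraction for one mutation.

    Attributes
    ----------
    probs : np.ndarray
        Probability vector over :data:`CCF_GRID`, normalized to 1.
    multiplicity : int
        Number of mutant-allele copies per carrying tumor cell.
    """

    probs: np.ndarray
    multiplicity: int = 1
    grid: np.ndarray = field(default_factory=lambda: CCF_GRID, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (GRID_SIZE,):
            raise ValueError(f"probs must have shape ({GRID_SIZE},)")
        total = self.probs.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("posterior probabilities must sum to a positive number")
        if abs(total - 1.0) > 1e-9:
            self.probs = self.probs / total

    @property
    def point_estimate(self) -> float:
        """Mode of the posterior (first grid point on ties)."""
        return float(self.grid[int(np.argmax(self.probs))])

    @property
    def mean(self) -> float:
        return float(self.probs @ self.grid)

    @property
    def std(self) -> float:
        mu = self.mean
        return float(np.sqrt(self.probs @ (self.grid - mu) ** 2))


def expected_vaf(
    ccf: float | np.ndarray,
    purity: float,
    m: int,
    q_t: float,
    q_n: float = 2.0,
) -> float | np.ndarray:
    """Expected variant allele fraction for a mutation at a given CCF.

    Parameters
    ----------
    ccf : float or array
        Cancer cell fraction in [0, 1].
    purity : float
        Tumor purity alpha in (0, 1].
    m : int
        Mutant-allele multiplicity (copies per carrying cell), 1 <= m <= q_t.
    q_t, q_n : float
        Total tumor and normal copy number at the locus.

    Returns
    -------
    The expected VAF, clipped to [1e-6, 1 - 1e-6] so that binomial
    likelihoods remain finite at ccf = 0 or saturating inputs.
    """
    if m > q_t:
        raise ValueError(f"multiplicity m={m} exceeds total tumor copy number q_t={q_t}")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    denom = purity * q_t + (1.0 - purity) * q_n
    vaf = purity * m * np.asarray(ccf, dtype=float) / denom
    clipped = np.clip(vaf, _VAF_FLOOR, _VAF_CEIL)
    if np.isscalar(ccf) or np.ndim(ccf) == 0:
        return float(clipped)
    return clipped


def choose_multiplicity(alt: int, ref: int, purity: float, segment: SegmentRecord) -> int:
    """Pick the mutant multiplicity best supported by the read counts.

    Scores each candidate m in {1, ..., major_cn} by the marginal likelihood
    of the counts under a uniform prior over the CCF grid and returns the
    maximizer (smallest m on ties).
    """
    major = max(1, int(segment.major_cn))
    candidates = [m for m in range(1, major + 1) if m <= segment.total_cn]
    if not candidates:
        candidates = [1]
    n = alt + ref
    if n == 0:
        return 1
    best_m, best_marg = 1, -np.inf
    for m in candidates:
        p = expected_vaf(CCF_GRID, purity, m, segment.total_cn)
        marg = binom.pmf(alt, n, p).mean()
        if marg > best_marg + 1e-15:
            best_m, best_marg = m, marg
    return best_m


def vaf_to_ccf_posterior(
    alt: int,
    ref: int,
    purity: float,
    segment: SegmentRecord,
    multiplicity: int | None = None,
) -> CCFPosterior:
    """Posterior over CCF from alt/ref read counts at one locus in one sample.

    probs[i] is proportional to Binomial(alt | alt+ref, expected_vaf(grid[i]))
    under a uniform prior on the grid.  Zero total depth returns a uniform
    posterior with a warning.
    """
    if alt < 0 or ref < 0:
        raise ValueError("read counts must be non-negative")
    n = alt + ref
    if n == 0:
        warnings.warn("zero total depth: returning uniform CCF posterior", stacklevel=2)
        return CCFPosterior(np.full(GRID_SIZE, 1.0 / GRID_SIZE), multiplicity=1)
    m = multiplicity if multiplicity is not None else choose_multiplicity(alt, ref, purity, segment)
    p = expected_vaf(CCF_GRID, purity, m, segment.total_cn)
    loglik = binom.logpmf(alt, n, p)
    loglik -= loglik.max()
    probs = np.exp(loglik)
    probs /= probs.sum()
    return CCFPosterior(probs, multiplicity=m)


def batch_posteriors(
    alts: np.ndarray,
    refs: np.ndarray,
    purity: float,
    q_t: float = 2.0,
    m: int = 1,
) -> np.ndarray:
    """Posterior probability matrix (n_mutations x grid) at fixed multiplicity.

    Vectorized equivalent of :func:`vaf_to_ccf_posterior` for a batch of
    mutations sharing one sample's purity and copy number; zero-depth rows
    get a uniform posterior.
    """
    alts = np.asarray(alts, dtype=int)
    refs = np.asarray(refs, dtype=int)
    n = alts + refs
    p = expected_vaf(CCF_GRID, purity, m, q_t)
    safe_n = np.maximum(n, 1)
    loglik = binom.logpmf(alts[:, None], safe_n[:, None], p[None, :])
    loglik -= loglik.max(axis=1, keepdims=True)
    probs = np.exp(loglik)
    probs /= probs.sum(axis=1, keepdims=True)
    probs[n == 0] = 1.0 / GRID_SIZE
    return probs
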