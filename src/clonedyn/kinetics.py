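"""Clone growth-rate inference from serial CCF measurements.

Clone CCFs are converted to absolute circulating cell numbers as

    N_clone(t) = ALC(t) [cells/µL] x blood volume [µL] x purity(t) x CCF(t)

and fitted with exponential growth/decline, N(t) = N0 * exp(g t), by least
squares of log N on time.  Uncertainty is quantified by a fixed-tree,
fixed-cluster MCMC: in each iteration every mutation is reassigned to a
clone by a multinomial draw proportional to its likelihood under each
clone's CCF distribution, each clone's per-timepoint CCF is drawn from the
grid posterior given the iteration's members, and the exponential model is
refitted; the growth rate g and the back-extrapolated day-0 size N0 are
reported as the median and 2.5/97.5 percentiles across iterations.

Clones whose CCF never reaches ``min_ccf`` (default 0.1) at any timepoint
are excluded from rate inference.  Singleton clusters, whose membership the
reassignment step cannot anchor, fall back to a deterministic regression on
their CCF point estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ccf import CCF_GRID, GRID_SIZE
from .clustering import CloneCluster, _cluster_distributions

logger = logging.getLogger(__name__)

#: Default blood volume, µL (5 liters of peripheral blood).
DEFAULT_BLOOD_VOLUME_UL = 5.0e6

#: Clones must reach this CCF at one timepoint or more to enter rate inference.
MIN_KINETICS_CCF = 0.1


@dataclass
class GrowthFit:
    """Exponential fit of one clone's circulating cell count."""

    clone_id: int
    g: float  # per day, signed
    ci_low: float
    ci_high: float
    r2: float
    n_points: int
    n0: float  # cells at day 0
    n0_ci: tuple[float, float]
    two_point: bool = False
    method: str = "ols"

    def __post_init__(self) -> None:
        if self.n_points == 2:
            self.two_point = True


@dataclass
class RateStats:
    """Absolute CCF change rates by treatment period for one clone."""

    clone_id: int
    rate1: float  # |dCCF/dt|, day 0 -> ~boundary
    rate2: float  # |dCCF/dt|, ~boundary -> last sample within horizon
    deceleration: float  # (rate2 - rate1) / (midpoint2 - midpoint1), per day^2
    concordant: bool  # signed changes agree in direction
    window1: tuple[int, int]
    window2: tuple[int, int]


def clone_cell_count(
    ccf: float | np.ndarray,
    alc: float | np.ndarray,
    purity: float | np.ndarray,
    blood_volume_ul: float = DEFAULT_BLOOD_VOLUME_UL,
) -> float | np.ndarray:
    """Circulating cells in a clone: ALC x blood volume x purity x CCF."""
    ccf, alc, purity = np.asarray(ccf), np.asarray(alc), np.asarray(purity)
    if np.any(ccf < 0) or np.any(alc < 0) or np.any(purity < 0) or blood_volume_ul < 0:
        raise ValueError("all factors must be non-negative")
    out = alc * blood_volume_ul * purity * ccf
    return float(out) if out.ndim == 0 else out


def cell_scale(alc: np.ndarray, purity: np.ndarray, blood_volume_ul: float = DEFAULT_BLOOD_VOLUME_UL) -> np.ndarray:
    """Per-timepoint CCF -> cells multiplier (ALC x volume x purity)."""
    return np.asarray(alc, dtype=float) * blood_volume_ul * np.asarray(purity, dtype=float)


def fit_exponential(counts: np.ndarray, days: np.ndarray, clone_id: int = -1) -> GrowthFit | None:
    """Least-squares exponential fit: slope of ln(count) on day.

    Timepoints with zero count are excluded (with a warning when any remain);
    fewer than two positive counts yields ``None``.  With exactly two points
    the fit is saturated: R^2 = 1 and the two-point flag is set.  The CI is
    the t-based 95% interval on the slope (degenerate at n = 2).
    """
    counts = np.asarray(counts, dtype=float)
    days = np.asarray(days, dtype=float)
    pos = counts > 0
    if pos.sum() < 2:
        return None
    if not pos.all():
        warnings.warn(
            f"excluding {int((~pos).sum())} zero-count timepoint(s) from exponential fit",
            stacklevel=2,
        )
    x, y = days[pos], np.log(counts[pos])
    n = int(pos.sum())
    if np.ptp(y) == 0.0:  # constant count: flat line fits exactly
        g, n0 = 0.0, float(np.exp(y[0]))
        return GrowthFit(
            clone_id=clone_id, g=g, ci_low=0.0, ci_high=0.0, r2=1.0,
            n_points=n, n0=n0, n0_ci=(n0, n0),
        )
    res = stats.linregress(x, y)
    g = float(res.slope)
    n0 = float(np.exp(res.intercept))
    if n == 2:
        r2, lo, hi = 1.0, g, g
    else:
        ss_res = float(np.sum((y - (res.intercept + g * x)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        tcrit = stats.t.ppf(0.975, n - 2)
        lo, hi = g - tcrit * res.stderr, g + tcrit * res.stderr
    # intercept CI via its standard error (day-0 size)
    if n > 2:
        n0_lo = float(np.exp(res.intercept - stats.t.ppf(0.975, n - 2) * res.intercept_stderr))
        n0_hi = float(np.exp(res.intercept + stats.t.ppf(0.975, n - 2) * res.intercept_stderr))
    else:
        n0_lo = n0_hi = n0
    return GrowthFit(
        clone_id=clone_id,
        g=g,
        ci_low=float(lo),
        ci_high=float(hi),
        r2=r2,
        n_points=n,
        n0=n0,
        n0_ci=(n0_lo, n0_hi),
    )


def back_extrapolate(
    g: float, t_ref: float, n_ref: float, g_ci: tuple[float, float] | None = None
) -> tuple[float, tuple[float, float]]:
    """Clone size at treatment initiation: N0 = n_ref * exp(-g * t_ref).

    The CI applies the rate credible bounds; since a larger rate implies a
    smaller day-0 size, the bounds are sorted after transformation.
    """
    n0 = float(n_ref * np.exp(-g * t_ref))
    if g_ci is None:
        return n0, (n0, n0)
    bounds = sorted(float(n_ref * np.exp(-gi * t_ref)) for gi in g_ci)
    return n0, (bounds[0], bounds[1])


def _sample_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of a (rows, k) probability matrix."""
    c = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1] + (1,))
    return (u > c).sum(axis=-1)


def kinetics_mcmc(
    clusters: list[CloneCluster],
    tree,
    log_posteriors: np.ndarray,
    mutation_ids: tuple[str, ...],
    days: np.ndarray,
    scale: np.ndarray,
    n_iter: int = 10_000,
    seed: int = 0,
    min_ccf: float = MIN_KINETICS_CCF,
    smooth_cells: bool = True,
) -> dict[int, GrowthFit]:
    """Posterior growth rates by mutation-reassignment MCMC on a fixed tree.

    Parameters
    ----------
    clusters
        Consensus subclones; their CCF distributions define the (fixed)
        reassignment likelihood of every mutation under every clone.
    tree
        The selected :class:`~clonedyn.phylogeny.PhylogenyTree`; exponential
        fits apply to each clone's exclusive fraction (cluster CCF minus its
        children's).
    log_posteriors, mutation_ids
        Per-mutation grid log posteriors, aligned with the clustering input.
    days, scale
        Sample days and CCF -> cells multipliers per timepoint.
    """
    from .phylogeny import GERMLINE_ID

    days = np.asarray(days, dtype=float)
    n_mut, n_t, _ = log_posteriors.shape
    post_probs = np.exp(log_posteriors)

    multi = [c for c in clusters if not c.low_confidence]
    singletons = [c for c in clusters if c.low_confidence]
    included = [c for c in multi if c.ccf_point.max() >= min_ccf]
    for c in multi:
        if c not in included:
            logger.info("clone %d excluded from kinetics: max CCF < %.2f", c.cluster_id, min_ccf)

    results: dict[int, GrowthFit] = {}

    # Singleton fallback: deterministic regression on the CCF point estimates.
    for c in singletons:
        if c.ccf_point.max() < min_ccf:
            logger.info("singleton clone %d excluded from kinetics: max CCF < %.2f", c.cluster_id, min_ccf)
            continue
        fit = fit_exponential(c.ccf_point * scale, days, clone_id=c.cluster_id)
        if fit is not None:
            fit.method = "singleton_regression"
            results[c.cluster_id] = fit
    if not included:
        return results

    rng = np.random.default_rng(seed)
    k = len(multi)
    idx_of = {c.cluster_id: i for i, c in enumerate(multi)}
    cluster_dists = np.stack([c.ccf_probs for c in multi])  # (K, T, G)

    # fixed reassignment weights: likelihood of each mutation under each clone
    overlap = np.einsum("ktg,ntg->nkt", cluster_dists, post_probs)
    logw = np.log(overlap + 1e-300).sum(axis=2)  # (N, K)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)

    child_idx = {
        i: [idx_of[ch] for ch in tree.children(c.cluster_id) if ch != GERMLINE_ID and ch in idx_of]
        for i, c in enumerate(multi)
    }

    # fixed per-timepoint detection mask: a clone enters the fit only where
    # its consensus exclusive CCF clears two grid cells — below that the
    # grid cannot resolve the fraction and draws near the detection limit
    # would select themselves into the regression
    from .phylogeny import exclusive_ccf

    excl_consensus = exclusive_ccf(tree, {c.cluster_id: c.ccf_point for c in multi})
    detected = np.stack([excl_consensus[c.cluster_id] >= 0.02 for c in multi])  # (K, T)

    g_draws = np.full((n_iter, k), np.nan)
    n0_draws = np.full((n_iter, k), np.nan)
    r2_draws = np.full((n_iter, k), np.nan)

    for it in range(n_iter):
        labels = _sample_rows(rng, w)  # (N,)
        # per-clone product posterior over the grid, given this assignment
        log_sums = np.zeros((k, n_t, GRID_SIZE))
        occupied = np.zeros(k, dtype=bool)
        for ki in range(k):
            members = labels == ki
            if members.any():
                occupied[ki] = True
                log_sums[ki] = log_posteriors[members].sum(axis=0)
        dists = _cluster_distributions(log_sums)
        idx = _sample_rows(rng, dists)
        phi = CCF_GRID[idx]  # (K, T)
        if smooth_cells:
            # continuity correction: the grid posterior is a histogram of a
            # continuous density, so draw uniformly within the chosen cell
            # (half-width 0.005, reflected at the [0, 1] boundaries)
            phi = phi + rng.uniform(-0.005, 0.005, size=phi.shape)
            phi = np.abs(phi)
            phi = 1.0 - np.abs(1.0 - phi)
        phi[~occupied] = np.nan
        for ki in range(k):
            if not occupied[ki]:
                continue
            kids = child_idx[ki]
            excl = phi[ki] - (phi[kids].sum(axis=0) if kids else 0.0)
            counts = np.clip(excl, 0.0, None) * scale
            pos = detected[ki] & (excl > 0)
            if pos.sum() < 2:
                continue
            x, y = days[pos], np.log(counts[pos])
            slope, intercept = np.polyfit(x, y, 1)
            yhat = intercept + slope * x
            ss_res = float(np.sum((y - yhat) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            g_draws[it, ki] = slope
            n0_draws[it, ki] = np.exp(intercept)
            r2_draws[it, ki] = 1.0 if ss_tot == 0 or pos.sum() == 2 else 1.0 - ss_res / ss_tot

    for c in included:
        ki = idx_of[c.cluster_id]
        gs = g_draws[:, ki]
        gs = gs[np.isfinite(gs)]
        if gs.size == 0:
            logger.info("clone %d: no MCMC iteration produced a fit", c.cluster_id)
            continue
        n0s = n0_draws[:, ki]
        n0s = n0s[np.isfinite(n0s)]
        r2s = r2_draws[:, ki]
        r2s = r2s[np.isfinite(r2s)]
        n_points = int(detected[ki].sum())
        results[c.cluster_id] = GrowthFit(
            clone_id=c.cluster_id,
            g=float(np.median(gs)),
            ci_low=float(np.percentile(gs, 2.5)),
            ci_high=float(np.percentile(gs, 97.5)),
            r2=float(np.median(r2s)) if r2s.size else np.nan,
            n_points=n_points,
            n0=float(np.median(n0s)),
            n0_ci=(float(np.percentile(n0s, 2.5)), float(np.percentile(n0s, 97.5))),
            method="mcmc",
        )
    return results


def ccf_rate_stats(
    ccf_series: np.ndarray,
    days: np.ndarray,
    clone_id: int = -1,
    boundary: int = 30,
    horizon: int = 365,
) -> RateStats:
    """Absolute CCF change per day in two treatment periods, plus deceleration.

    Period 1 runs from baseline to the sample nearest ``boundary`` (day 30);
    period 2 from there to the last sample within ``horizon``.  Deceleration
    is the difference of the two absolute rates divided by the separation of
    the period midpoints.
    """
    ccf_series = np.asarray(ccf_series, dtype=float)
    days = np.asarray(days, dtype=float)
    within = days <= horizon
    ccf_series, days = ccf_series[within], days[within]
    if len(days) < 2:
        raise ValueError("need at least two samples within the horizon")
    i0 = int(np.argmin(days))
    ib = int(np.argmin(np.abs(days - boundary) + np.where(days == days[i0], np.inf, 0.0)))
    if abs(days[ib] - boundary) > 1:
        logger.info(
            "clone %d: no sample at day %d; period boundary moved to day %d",
            clone_id,
            boundary,
            int(days[ib]),
        )
    il = int(np.argmax(days))
    change1 = ccf_series[ib] - ccf_series[i0]
    rate1 = abs(change1) / (days[ib] - days[i0])
    if il == ib:
        rate2, deceleration, concordant = np.nan, np.nan, True
        win2 = (int(days[ib]), int(days[ib]))
    else:
        change2 = ccf_series[il] - ccf_series[ib]
        rate2 = abs(change2) / (days[il] - days[ib])
        mid1 = (days[i0] + days[ib]) / 2.0
        mid2 = (days[ib] + days[il]) / 2.0
        deceleration = (rate2 - rate1) / (mid2 - mid1)
        concordant = bool(np.sign(change1) == np.sign(change2)) or change1 == change2 == 0
        win2 = (int(days[ib]), int(days[il]))
    return RateStats(
        clone_id=clone_id,
        rate1=float(rate1),
        rate2=float(rate2),
        deceleration=float(deceleration),
        concordant=concordant,
        window1=(int(days[i0]), int(days[ib])),
        window2=win2,
    )
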