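"""End-to-end orchestration: CCF -> clustering -> shifts -> phylogeny ->
kinetics -> survival, from the tabular inputs to the report tables.

Each stage is an importable function; the CLI wraps this module thinly.
Intermediates are plain TSVs, so a run can resume from any stage's output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from . import io as cio
from .clustering import CloneCluster, consensus_clusters, gibbs_cluster, _stack_log_posteriors
from .cohort import SurvivalResult, km_logrank
from .kinetics import (
    DEFAULT_BLOOD_VOLUME_UL,
    GrowthFit,
    RateStats,
    ccf_rate_stats,
    cell_scale,
    kinetics_mcmc,
)
from .phylogeny import (
    DEFAULT_EPS,
    NoFeasibleTreeError,
    PhylogenyTree,
    feasible_trees,
    select_tree,
)
from .shifts import CohortShiftResult, classify_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a pipeline run; echoed into the summary output."""

    cluster_iters: int = 1000
    cluster_burn_in: int = 500
    band_delta: float = 0.1
    ccf_threshold: float = 0.1
    q_cut: float = 0.1
    horizon_days: int = 365
    boundary_days: int = 30
    blood_volume_ul: float = DEFAULT_BLOOD_VOLUME_UL
    mcmc_iters: int = 10_000
    tree_eps: float = DEFAULT_EPS
    max_tree_clusters: int = 8
    seed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PatientInput:
    """One patient's observations, timepoint-ordered."""

    patient_id: str
    days: np.ndarray
    is_relapse: np.ndarray
    purity: np.ndarray
    alc: np.ndarray
    posteriors: dict[str, list[ccf_mod.CCFPosterior]]


@dataclass
class PatientResult:
    patient_id: str
    days: np.ndarray
    is_relapse: np.ndarray
    clusters: list[CloneCluster]
    tree: PhylogenyTree | None
    fits: dict[int, GrowthFit]
    rate_stats: dict[int, RateStats]
    scale: np.ndarray


@dataclass
class CohortResult:
    patients: dict[str, PatientResult]
    shifts: CohortShiftResult
    survival: SurvivalResult | None
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _patient_seed(base: int, index: int) -> int:
    return int((base + 7919 * (index + 1)) % (2**31 - 1))


def build_patient_inputs(
    mutations: list[cio.MutationObservation],
    segments: cio.SegmentIndex,
    timeline: list[cio.SampleTimepoint],
) -> list[PatientInput]:
    """Compute per-mutation CCF posteriors at every timepoint of every patient."""
    by_patient_tl: dict[str, list[cio.SampleTimepoint]] = {}
    for tp in timeline:
        by_patient_tl.setdefault(tp.patient_id, []).append(tp)
    by_patient_mut: dict[str, list[cio.MutationObservation]] = {}
    for mut in mutations:
        by_patient_mut.setdefault(mut.patient_id, []).append(mut)

    inputs = []
    for pid in sorted(by_patient_tl):
        tps = sorted(by_patient_tl[pid], key=lambda t: t.day)
        muts = by_patient_mut.get(pid, [])
        if not muts:
            logger.warning("patient %s has no mutations; skipped", pid)
            continue
        posteriors: dict[str, list[ccf_mod.CCFPosterior]] = {m.mutation_id: [] for m in muts}
        for tp in tps:
            segs = [segments.lookup(tp.sample_id, m.chrom, m.pos) for m in muts]
            # fast path: batch all diploid-het loci (m = 1) in one call
            simple = [
                j for j, s in enumerate(segs) if s.major_cn == 1 and s.total_cn == 2.0
            ]
            if simple:
                alts = np.array([muts[j].alt_counts[tp.sample_id] for j in simple])
                refs = np.array([muts[j].ref_counts[tp.sample_id] for j in simple])
                probs = ccf_mod.batch_posteriors(alts, refs, tp.purity)
                for row, j in enumerate(simple):
                    posteriors[muts[j].mutation_id].append(
                        ccf_mod.CCFPosterior(probs[row], multiplicity=1)
                    )
            simple_set = set(simple)
            for j, seg in enumerate(segs):
                if j in simple_set:
                    continue
                mut = muts[j]
                posteriors[mut.mutation_id].append(
                    ccf_mod.vaf_to_ccf_posterior(
                        mut.alt_counts[tp.sample_id],
                        mut.ref_counts[tp.sample_id],
                        tp.purity,
                        seg,
                    )
                )
        inputs.append(
            PatientInput(
                patient_id=pid,
                days=np.array([t.day for t in tps], dtype=float),
                is_relapse=np.array([t.is_relapse for t in tps]),
                purity=np.array([t.purity for t in tps]),
                alc=np.array([t.alc for t in tps]),
                posteriors=posteriors,
            )
        )
    return inputs


def analyze_patient(patient: PatientInput, config: RunConfig, seed: int) -> PatientResult:
    """Cluster one patient's mutations, infer the phylogeny and clone kinetics."""
    t_start = time.perf_counter()
    chain = gibbs_cluster(
        patient.posteriors,
        n_iter=config.cluster_iters,
        burn_in=config.cluster_burn_in,
        seed=seed,
    )
    clusters = consensus_clusters(chain)
    scale = cell_scale(patient.alc, patient.purity, config.blood_volume_ul)

    tree: PhylogenyTree | None = None
    substantial = [c for c in clusters if not c.low_confidence]
    if 0 < len(substantial) <= config.max_tree_clusters:
        eps = config.tree_eps
        while tree is None and eps <= 0.2:
            try:
                trees = feasible_trees(substantial, eps=eps)
                tree = select_tree(trees, substantial, patient.days, scale)
            except NoFeasibleTreeError:
                eps *= 2
                logger.info("patient %s: no feasible tree, retrying with eps=%.3f", patient.patient_id, eps)
        if tree is None:
            logger.warning("patient %s: no feasible phylogeny up to eps=0.2", patient.patient_id)
    elif len(substantial) > config.max_tree_clusters:
        logger.warning(
            "patient %s: %d clusters exceed the enumeration limit; skipping tree/kinetics",
            patient.patient_id,
            len(substantial),
        )

    fits: dict[int, GrowthFit] = {}
    if tree is not None:
        ids, logp = _stack_log_posteriors(patient.posteriors)
        fits = kinetics_mcmc(
            clusters,
            tree,
            logp,
            ids,
            patient.days,
            scale,
            n_iter=config.mcmc_iters,
            seed=seed,
        )

    rate_stats: dict[int, RateStats] = {}
    early = (~patient.is_relapse) & (patient.days <= config.horizon_days)
    if early.sum() >= 2:
        for c in clusters:
            rate_stats[c.cluster_id] = ccf_rate_stats(
                c.ccf_point[early],
                patient.days[early],
                clone_id=c.cluster_id,
                boundary=config.boundary_days,
                horizon=config.horizon_days,
            )

    logger.info("patient %s analyzed in %.1fs", patient.patient_id, time.perf_counter() - t_start)
    return PatientResult(
        patient_id=patient.patient_id,
        days=patient.days,
        is_relapse=patient.is_relapse,
        clusters=clusters,
        tree=tree,
        fits=fits,
        rate_stats=rate_stats,
        scale=scale,
    )


def run_cohort(
    mutations: list[cio.MutationObservation],
    segments: cio.SegmentIndex,
    timeline: list[cio.SampleTimepoint],
    outcomes: list[cio.OutcomeRecord] | None = None,
    config: RunConfig | None = None,
) -> CohortResult:
    """Run every stage on a cohort held in memory."""
    config = config or RunConfig()
    inputs = build_patient_inputs(mutations, segments, timeline)
    results: dict[str, PatientResult] = {}
    for i, patient in enumerate(inputs):
        results[patient.patient_id] = analyze_patient(
            patient, config, _patient_seed(config.seed, i)
        )

    shifts = classify_cohort(
        {pid: r.clusters for pid, r in results.items()},
        {pid: [int(d) for d in r.days] for pid, r in results.items()},
        {pid: list(r.is_relapse) for pid, r in results.items()},
        delta=config.band_delta,
        tau=config.ccf_threshold,
        q_cut=config.q_cut,
        horizon=config.horizon_days,
    )

    survival = None
    if outcomes:
        evolved = shifts.evolved
        rows = [(o.followup_day, int(o.progressed), evolved.get(o.patient_id, False)) for o in outcomes]
        groups = np.array([r[2] for r in rows])
        if len(set(groups.tolist())) == 2:
            survival = km_logrank(
                np.array([r[0] for r in rows], dtype=float),
                np.array([r[1] for r in rows]),
                groups,
            )
        else:
            logger.warning("survival comparison skipped: need both evolved and non-evolved patients")

    result = CohortResult(patients=results, shifts=shifts, survival=survival, config=config)
    result.tables = build_tables(result)
    return result


def build_tables(result: CohortResult) -> dict[str, pd.DataFrame]:
    cluster_rows, kinetics_rows, survival_rows = [], [], []
    trees = {}
    for pid, pr in result.patients.items():
        for c in pr.clusters:
            row = {
                "patient_id": pid,
                "cluster_id": c.cluster_id,
                "n_mutations": c.n_members,
                "low_confidence": c.low_confidence,
            }
            for t, day in enumerate(pr.days):
                row[f"ccf_d{int(day)}"] = c.ccf_point[t]
            cluster_rows.append(row)
        for cid, fit in sorted(pr.fits.items()):
            kinetics_rows.append(
                {
                    "patient_id": pid,
                    "cluster_id": cid,
                    "g_per_day": fit.g,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "r2": fit.r2,
                    "two_point": fit.two_point,
                    "n_points": fit.n_points,
                    "n0_cells": fit.n0,
                    "n0_ci_low": fit.n0_ci[0],
                    "n0_ci_high": fit.n0_ci[1],
                    "method": fit.method,
                }
            )
        if pr.tree is not None:
            trees[pid] = pr.tree.newick()
    if result.survival is not None:
        for lab, curve in result.survival.curves.items():
            for _, row in curve.iterrows():
                survival_rows.append(
                    {
                        "group": lab,
                        "time": row["time"],
                        "at_risk": row["at_risk"],
                        "events": row["events"],
                        "survival": row["survival"],
                    }
                )
    summary = {
        "n_patients": len(result.patients),
        "n_evolved": result.shifts.n_evolved,
        "config": result.config.as_dict(),
    }
    if result.survival is not None:
        summary["logrank_chi2"] = result.survival.chi2
        summary["logrank_p"] = result.survival.p
        summary["hazard_ratio"] = result.survival.hr
    return {
        "clusters": pd.DataFrame(cluster_rows),
        "shifts": result.shifts.table,
        "kinetics": pd.DataFrame(kinetics_rows),
        "survival": pd.DataFrame(survival_rows),
        "trees": trees,
        "summary": summary,
    }


def run_pipeline(
    mutations_path: str | Path,
    segments_path: str | Path,
    timeline_path: str | Path,
    outcomes_path: str | Path | None,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> CohortResult:
    """File-to-file pipeline entry point."""
    config = config or RunConfig()
    mutations = cio.read_mutation_table(mutations_path)
    segments = cio.read_segments(segments_path)
    timeline = cio.read_timeline(timeline_path)
    outcomes = cio.read_outcomes(outcomes_path) if outcomes_path else None
    result = run_cohort(mutations, segments, timeline, outcomes, config)
    cio.write_report(result.tables, outdir, seed=config.seed)
    return result
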