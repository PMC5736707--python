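"""Synthetic longitudinal cohorts with known clonal ground truth.

The generator mirrors the structure of a serial-sequencing study of
ibrutinib-treated CLL: each patient carries 2-6 subclones arranged on a
feasible phylogeny, each subclone follows exponential kinetics in absolute
cell number, blood draws at days 0/30/60/90/180/365 measure a declining
absolute lymphocyte count (ALC), and every mutation is force-called in
every sample with read depth around x107 (negative binomial, IQR ~97-119)
and binomial allele counts at the VAF implied by the clone's true CCF,
purity and local copy number.  Mutation burden defaults to ~1.13/Mb over a
37 Mb exome.  Progression times are exponential with a hazard multiplied
for patients whose clonal composition truly shifts, and censored at the
configured follow-up.

Everything downstream of the generator can therefore be validated against
exact truth: the clone tree, per-clone growth rates, the mutation-to-clone
map and per-day cell counts are all retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as cio
from .ccf import expected_vaf

EXOME_MB = 37.0


@dataclass
class SimulationConfig:
    """Cohort-level generative settings (defaults emulate the study design)."""

    n_patients: int = 61
    timepoint_days: tuple[int, ...] = (0, 30, 60, 90, 180, 365)
    relapse_days: tuple[int, ...] = ()  # appended, flagged is_relapse
    depth_mean: float = 107.0
    depth_dispersion: float = 77.0  # negative binomial r; IQR ~ 97-119 at mean 107
    n_clones_range: tuple[int, int] = (2, 6)
    branched_fraction: float = 15 / 19  # branched vs linear topology mix
    g_range: tuple[float, float] = (-0.05, 0.06)  # per day
    decline_rate: float = -0.012  # shared rate of non-shifting patients, per day
    rate_spread: float | None = None  # clone rates = base +/- spread (slow relative drift)
    min_clone_fraction: float = 0.0  # floor on day-0 exclusive clone fractions
    mutation_rate_per_mb: float = 1.13
    mutations_per_clone: int | None = None  # override Poisson burden split
    min_mutations_per_clone: int = 4
    # baseline blood is tumor-dominated in CLL: the normal-lymphocyte
    # compartment is alc0 * (1 - purity0), typically 1-3k cells/µL
    purity_range: tuple[float, float] = (0.96, 0.995)
    baseline_alc_range: tuple[float, float] = (30_000.0, 200_000.0)  # cells/µL
    blood_volume_ul: float = 5.0e6
    shift_prevalence: float = 19 / 61
    hazard_multiplier: float = 3.0
    baseline_hazard: float = 1.46e-4  # per day; ~28% events at 48 months
    followup_days: int = 1460
    resistant_clone_cells: float | None = None  # seed size of a relapse clone
    resistant_clone_rate: float = 0.02  # per day
    seed: int = 0


@dataclass
class SyntheticPatient:
    patient_id: str
    tree_parent: dict[int, int | None]  # clone 1 is the trunk
    clone_rates: dict[int, float]  # exclusive-population growth rates, per day
    clone_cells0: dict[int, float]  # exclusive cells at day 0
    mutation_clone: dict[str, int]
    days: np.ndarray
    is_relapse: np.ndarray
    cluster_ccf: np.ndarray  # (n_clones, n_timepoints) true subtree CCF
    purity: np.ndarray
    alc: np.ndarray
    mutations: list[cio.MutationObservation]
    timeline: list[cio.SampleTimepoint]
    segments: list[cio.SegmentRecord]
    truly_evolved: bool
    true_shift: float


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    patients: list[SyntheticPatient]
    outcomes: list[cio.OutcomeRecord]

    @property
    def mutations(self) -> list[cio.MutationObservation]:
        return [m for p in self.patients for m in p.mutations]

    @property
    def timeline(self) -> list[cio.SampleTimepoint]:
        return [t for p in self.patients for t in p.timeline]

    @property
    def segments(self) -> list[cio.SegmentRecord]:
        return [s for p in self.patients for s in p.segments]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": outdir / "mutations.tsv",
            "segments": outdir / "segments.tsv",
            "timeline": outdir / "timeline.tsv",
            "outcomes": outdir / "outcomes.tsv",
        }
        cio.write_mutation_table(self.mutations, paths["mutations"])
        cio.write_segments(cio.SegmentIndex(self.segments), paths["segments"])
        cio.write_timeline(self.timeline, paths["timeline"])
        cio.write_outcomes(self.outcomes, paths["outcomes"])
        import json

        truth = {
            p.patient_id: {
                "tree_parent": {str(k): v for k, v in p.tree_parent.items()},
                "clone_rates": p.clone_rates,
                "clone_cells0": p.clone_cells0,
                "mutation_clone": p.mutation_clone,
                "truly_evolved": p.truly_evolved,
                "true_shift": p.true_shift,
            }
            for p in self.patients
        }
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, default=float)
        return paths


def _sample_tree(n_clones: int, branched_fraction: float, rng: np.random.Generator) -> dict[int, int | None]:
    """Random clone tree rooted at the trunk (clone 1)."""
    parent: dict[int, int | None] = {1: None}
    last = 1
    for cid in range(2, n_clones + 1):
        # sibling of previous subclones (branched) or its progeny (linear)
        parent[cid] = 1 if (last == 1 or rng.random() < branched_fraction) else last
        last = cid
    return parent


def _subtree_ccf(parent: dict[int, int | None], cells: np.ndarray) -> np.ndarray:
    """Cluster CCF matrix from exclusive cell trajectories (clones x time)."""
    n = cells.shape[0]
    total = cells.sum(axis=0)
    subtree = cells.copy()
    # accumulate children into parents; clone ids are topologically ordered
    for cid in range(n, 0, -1):
        p = parent[cid]
        if p is not None:
            subtree[p - 1] += subtree[cid - 1]
    return subtree / total


def _nb_depth(rng: np.random.Generator, mean: float, r: float, size: int) -> np.ndarray:
    p = r / (r + mean)
    return np.maximum(rng.negative_binomial(r, p, size=size), 1)


def simulate_patient(config: SimulationConfig, seed: int, patient_id: str = "P01") -> SyntheticPatient:
    """Generate one patient: tree, kinetics, samples and force-called counts."""
    rng = np.random.default_rng([config.seed, seed])
    days = np.array(list(config.timepoint_days) + list(config.relapse_days), dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("timepoint days must be strictly increasing")
    is_relapse = np.array(
        [False] * len(config.timepoint_days) + [True] * len(config.relapse_days)
    )
    n_t = len(days)

    lo, hi = config.n_clones_range
    n_clones = int(rng.integers(lo, hi + 1))
    parent = _sample_tree(n_clones, config.branched_fraction, rng)

    purity0 = float(rng.uniform(*config.purity_range))
    alc0 = float(rng.uniform(*config.baseline_alc_range))
    tumor0 = alc0 * config.blood_volume_ul * purity0
    normal = alc0 * config.blood_volume_ul * (1.0 - purity0)

    # exclusive day-0 fractions: Dirichlet with a heavier trunk
    alpha = np.full(n_clones, 1.0)
    alpha[0] = 2.0
    fractions = rng.dirichlet(alpha)
    if config.min_clone_fraction > 0:
        floor = config.min_clone_fraction
        fractions = floor + (1.0 - n_clones * floor) * fractions
    cells0 = fractions * tumor0

    shifting = rng.random() < config.shift_prevalence
    if not shifting:
        rates = np.full(n_clones, config.decline_rate)
    elif config.rate_spread is not None:
        # clones drift slowly relative to one another around a shared base
        # rate, keeping their CCF trajectories apart
        lo_g, hi_g = config.g_range
        base = rng.uniform(lo_g + config.rate_spread, hi_g - config.rate_spread)
        rates = base + rng.uniform(-config.rate_spread, config.rate_spread, size=n_clones)
    else:
        rates = rng.uniform(*config.g_range, size=n_clones)

    resistant_id = None
    if config.resistant_clone_cells is not None:
        # seed a small resistant clone as a child of the trunk
        n_clones += 1
        resistant_id = n_clones
        parent[resistant_id] = 1
        cells0 = np.append(cells0, config.resistant_clone_cells)
        rates = np.append(rates, config.resistant_clone_rate)

    cells = cells0[:, None] * np.exp(rates[:, None] * days[None, :])
    cluster_ccf = _subtree_ccf(parent, cells)
    tumor_t = cells.sum(axis=0)
    alc_t = (tumor_t + normal) / config.blood_volume_ul
    purity_t = tumor_t / (tumor_t + normal)

    # truth label: did any clone shift CCF by > 0.1 before relapse within a year?
    early = (~is_relapse) & (days <= 365)
    i0 = int(np.argmin(np.where(early, days, np.inf)))
    i1 = int(np.argmax(np.where(early, days, -np.inf)))
    true_shift = float(np.max(np.abs(cluster_ccf[:, i1] - cluster_ccf[:, i0])))
    truly_evolved = true_shift > 0.1

    # mutation burden split across clones
    if config.mutations_per_clone is not None:
        per_clone = np.full(n_clones, config.mutations_per_clone)
    else:
        total = max(
            int(rng.poisson(config.mutation_rate_per_mb * EXOME_MB)),
            config.min_mutations_per_clone * n_clones,
        )
        per_clone = np.full(n_clones, config.min_mutations_per_clone)
        extra = total - per_clone.sum()
        if extra > 0:
            per_clone += rng.multinomial(extra, np.full(n_clones, 1.0 / n_clones))

    sample_ids = [f"{patient_id}_T{t}" for t in range(n_t)]
    timeline = [
        cio.SampleTimepoint(
            patient_id=patient_id,
            sample_id=sample_ids[t],
            day=int(days[t]),
            alc=float(alc_t[t]),
            purity=float(purity_t[t]),
            is_relapse=bool(is_relapse[t]),
        )
        for t in range(n_t)
    ]
    segments = [
        cio.SegmentRecord(sample_id=sid, chrom="1", start=1, end=249_000_000, total_cn=2.0, major_cn=1, minor_cn=1)
        for sid in sample_ids
    ]

    n_total = int(per_clone.sum())
    positions = np.unique(rng.integers(1_000_000, 200_000_000, size=2 * n_total + 16))
    rng.shuffle(positions)
    positions = positions[:n_total]
    mutations: list[cio.MutationObservation] = []
    mutation_clone: dict[str, int] = {}
    mut_idx = 0
    bases = np.array(list("ACGT"))
    for clone_idx in range(n_clones):
        cid = clone_idx + 1
        for _ in range(per_clone[clone_idx]):
            pos = int(positions[mut_idx])
            mut_idx += 1
            ref, alt = rng.choice(bases, size=2, replace=False)
            mut_id = f"1:{pos}:{ref}>{alt}"
            obs = cio.MutationObservation(
                patient_id=patient_id,
                mutation_id=mut_id,
                chrom="1",
                pos=pos,
                ref_allele=str(ref),
                alt_allele=str(alt),
            )
            depths = _nb_depth(rng, config.depth_mean, config.depth_dispersion, n_t)
            for t in range(n_t):
                vaf = expected_vaf(cluster_ccf[clone_idx, t], purity_t[t], 1, 2.0)
                alt_n = int(rng.binomial(depths[t], vaf))
                obs.alt_counts[sample_ids[t]] = alt_n
                obs.ref_counts[sample_ids[t]] = int(depths[t]) - alt_n
            mutations.append(obs)
            mutation_clone[mut_id] = cid

    return SyntheticPatient(
        patient_id=patient_id,
        tree_parent=parent,
        clone_rates={i + 1: float(rates[i]) for i in range(n_clones)},
        clone_cells0={i + 1: float(cells0[i]) for i in range(n_clones)},
        mutation_clone=mutation_clone,
        days=days,
        is_relapse=is_relapse,
        cluster_ccf=cluster_ccf,
        purity=purity_t,
        alc=alc_t,
        mutations=mutations,
        timeline=timeline,
        segments=segments,
        truly_evolved=truly_evolved,
        true_shift=true_shift,
    )


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort of independent patients with clinical outcomes.

    Progression times are exponential with the baseline hazard, multiplied
    by ``hazard_multiplier`` for truly-evolved patients, censored at
    ``followup_days``.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    patients = [
        simulate_patient(config, i, patient_id=f"P{i + 1:03d}")
        for i in range(config.n_patients)
    ]
    rng = np.random.default_rng([config.seed, 10**6])
    outcomes = []
    for p in patients:
        hazard = config.baseline_hazard * (
            config.hazard_multiplier if p.truly_evolved else 1.0
        )
        t_event = rng.exponential(1.0 / hazard)
        progressed = t_event <= config.followup_days
        outcomes.append(
            cio.OutcomeRecord(
                patient_id=p.patient_id,
                followup_day=int(min(t_event, config.followup_days)) or 1,
                progressed=bool(progressed),
                covariates=(("truly_evolved", p.truly_evolved),),
            )
        )
    return SyntheticCohort(config=config, patients=patients, outcomes=outcomes)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def preset(name: str, **overrides) -> SimulationConfig:
    """Named study scenarios: 'null', 'shift', 'relapse'."""
    if name == "null":
        cfg = SimulationConfig(shift_prevalence=0.0, hazard_multiplier=1.0)
    elif name == "shift":
        cfg = SimulationConfig()
    elif name == "relapse":
        cfg = SimulationConfig(
            n_patients=1,
            relapse_days=(600, 840),
            shift_prevalence=0.0,
            decline_rate=-0.01,
            n_clones_range=(2, 3),
            resistant_clone_cells=1.0e3,
            resistant_clone_rate=0.02,
            mutations_per_clone=15,
        )
    else:
        raise ValueError(f"unknown preset '{name}' (choose null, shift or relapse)")
    return replace(cfg, **overrides)
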