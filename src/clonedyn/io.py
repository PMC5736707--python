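"""Tabular input/output for serial tumor sequencing cohorts.

All tables are tab-separated with a header row; '.' or empty fields are
missing.  Genomic coordinates are 1-based inclusive, following MAF/seg file
conventions.  Four inputs describe a cohort:

* ``mutations.tsv`` — force-called alt/ref read counts, one row per
  (patient, mutation, sample),
* ``segments.tsv`` — allelic copy number segments per sample,
* ``timeline.tsv`` — collection day, absolute lymphocyte count (ALC,
  cells/µL) and purity per sample,
* ``outcomes.tsv`` — progression/censoring day per patient.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = {".", "", "NA", "nan"}


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass
class MutationObservation:
    """One somatic variant with per-sample alt/ref read counts."""

    patient_id: str
    mutation_id: str  # chrom:pos:ref>alt
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_counts: dict[str, int] = field(default_factory=dict)
    ref_counts: dict[str, int] = field(default_factory=dict)
    gene_label: str | None = None
    is_driver: bool = False

    @property
    def samples(self) -> list[str]:
        return sorted(self.alt_counts)

    def depth(self, sample_id: str) -> int:
        return self.alt_counts[sample_id] + self.ref_counts[sample_id]


@dataclass(frozen=True)
class SegmentRecord:
    """Allelic copy number over [start, end] (1-based inclusive) in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if self.major_cn < 1 or self.minor_cn < 0:
            raise ValidationError("major_cn must be >= 1 and minor_cn >= 0")
        if abs(self.major_cn + self.minor_cn - self.total_cn) > 0.5:
            raise ValidationError(
                f"major+minor ({self.major_cn}+{self.minor_cn}) inconsistent with "
                f"total_cn {self.total_cn}"
            )


#: Diploid heterozygous fallback used when a locus has no covering segment.
DIPLOID_SEGMENT = SegmentRecord("", "", 1, 2**31 - 1, 2.0, 1, 1)


@dataclass(frozen=True)
class SampleTimepoint:
    """One blood draw: day from treatment start, ALC and purity."""

    patient_id: str
    sample_id: str
    day: int
    alc: float  # cells per microliter
    purity: float
    is_relapse: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError(f"purity {self.purity} outside [0, 1]")
        if self.alc < 0:
            raise ValidationError(f"ALC {self.alc} negative")


@dataclass(frozen=True)
class OutcomeRecord:
    """Clinical follow-up: day of progression or censoring."""

    patient_id: str
    followup_day: int
    progressed: bool
    covariates: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.followup_day <= 0:
            raise ValidationError(f"followup_day must be positive, got {self.followup_day}")


class SegmentIndex:
    """Per-sample interval lookup over validated, non-overlapping segments."""

    def __init__(self, segments: list[SegmentRecord]):
        self._by_sample: dict[tuple[str, str], list[SegmentRecord]] = {}
        for seg in segments:
            self._by_sample.setdefault((seg.sample_id, seg.chrom), []).append(seg)
        for key, segs in self._by_sample.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValidationError(
                        f"overlapping segments in sample {key[0]} chrom {key[1]}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )
        self.segments = segments

    def lookup(self, sample_id: str, chrom: str, pos: int) -> SegmentRecord:
        """Covering segment, or a diploid default with a logged warning."""
        for seg in self._by_sample.get((sample_id, chrom), ()):
            if seg.start <= pos <= seg.end:
                return seg
        logger.warning(
            "no segment covers %s:%s:%d; assuming diploid (q_t=2, 1+1)", sample_id, chrom, pos
        )
        return DIPLOID_SEGMENT


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _to_int(value: str, path: Path | str, line: int, col: str) -> int:
    if value in MISSING:
        raise ValidationError(f"{path} line {line}: missing value in column '{col}'")
    try:
        return int(value)
    except ValueError as exc:
        raise ValidationError(f"{path} line {line}: bad integer '{value}' in '{col}'") from exc


def _to_float(value: str, path: Path | str, line: int, col: str) -> float:
    if value in MISSING:
        raise ValidationError(f"{path} line {line}: missing value in column '{col}'")
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"{path} line {line}: bad number '{value}' in '{col}'") from exc


_TRUE = {"1", "true", "True", "TRUE", "yes"}


def read_mutation_table(path: str | Path) -> list[MutationObservation]:
    """Read force-called mutation counts (long format, one row per sample).

    Every mutation of a patient must carry counts for every sample the
    patient has rows for; a missing (mutation, sample) pair is an error, a
    zero count is not.
    """
    df = _read_tsv(
        path,
        ["patient_id", "sample_id", "chrom", "pos", "ref", "alt", "t_alt_count", "t_ref_count"],
    )
    records: dict[tuple[str, str], MutationObservation] = {}
    patient_samples: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        pos = _to_int(row.pos, path, i, "pos")
        alt_n = _to_int(row.t_alt_count, path, i, "t_alt_count")
        ref_n = _to_int(row.t_ref_count, path, i, "t_ref_count")
        if alt_n < 0 or ref_n < 0:
            raise ValidationError(f"{path} line {i}: negative read count")
        mut_id = f"{row.chrom}:{pos}:{row.ref}>{row.alt}"
        key = (row.patient_id, mut_id)
        rec = records.get(key)
        if rec is None:
            gene = getattr(row, "gene", ".")
            driver = getattr(row, "is_driver", "0")
            rec = MutationObservation(
                patient_id=row.patient_id,
                mutation_id=mut_id,
                chrom=str(row.chrom),
                pos=pos,
                ref_allele=row.ref,
                alt_allele=row.alt,
                gene_label=None if gene in MISSING else gene,
                is_driver=driver in _TRUE,
            )
            records[key] = rec
        if row.sample_id in rec.alt_counts:
            raise ValidationError(
                f"{path} line {i}: duplicated mutation {mut_id} for sample {row.sample_id}"
            )
        rec.alt_counts[row.sample_id] = alt_n
        rec.ref_counts[row.sample_id] = ref_n
        patient_samples.setdefault(row.patient_id, set()).add(row.sample_id)

    for (patient, mut_id), rec in records.items():
        absent = patient_samples[patient] - set(rec.alt_counts)
        if absent:
            raise ValidationError(
                f"{path}: mutation {mut_id} of patient {patient} lacks counts "
                f"for samples {sorted(absent)}"
            )
    return list(records.values())


def read_segments(path: str | Path) -> SegmentIndex:
    """Read the per-sample allelic copy number segment table."""
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "total_cn", "major_cn", "minor_cn"])
    segs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segs.append(
                SegmentRecord(
                    sample_id=row.sample_id,
                    chrom=str(row.chrom),
                    start=_to_int(row.start, path, i, "start"),
                    end=_to_int(row.end, path, i, "end"),
                    total_cn=_to_float(row.total_cn, path, i, "total_cn"),
                    major_cn=_to_int(row.major_cn, path, i, "major_cn"),
                    minor_cn=_to_int(row.minor_cn, path, i, "minor_cn"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return SegmentIndex(segs)


def read_timeline(path: str | Path) -> list[SampleTimepoint]:
    """Read sample collection days, ALC and purity; sorted by (patient, day)."""
    df = _read_tsv(path, ["patient_id", "sample_id", "day", "alc_per_ul", "purity"])
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SampleTimepoint(
                    patient_id=row.patient_id,
                    sample_id=row.sample_id,
                    day=_to_int(row.day, path, i, "day"),
                    alc=_to_float(row.alc_per_ul, path, i, "alc_per_ul"),
                    purity=_to_float(row.purity, path, i, "purity"),
                    is_relapse=getattr(row, "is_relapse", "0") in _TRUE,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    by_patient: dict[str, list[int]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec.day)
    for patient, days in by_patient.items():
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"{path}: days not strictly increasing for patient {patient}")
    records.sort(key=lambda r: (r.patient_id, r.day))
    return records


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    """Read clinical outcome (progression or censoring day) per patient."""
    df = _read_tsv(path, ["patient_id", "followup_day", "progressed"])
    extra = [c for c in df.columns if c not in ("patient_id", "followup_day", "progressed")]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            covs = tuple((c, getattr(row, c) in _TRUE) for c in extra)
            records.append(
                OutcomeRecord(
                    patient_id=row.patient_id,
                    followup_day=_to_int(row.followup_day, path, i, "followup_day"),
                    progressed=row.progressed in _TRUE,
                    covariates=covs,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_mutation_table(mutations: list[MutationObservation], path: str | Path) -> None:
    rows = []
    for mut in mutations:
        for sample in mut.samples:
            rows.append(
                {
                    "patient_id": mut.patient_id,
                    "sample_id": sample,
                    "chrom": mut.chrom,
                    "pos": mut.pos,
                    "ref": mut.ref_allele,
                    "alt": mut.alt_allele,
                    "t_alt_count": mut.alt_counts[sample],
                    "t_ref_count": mut.ref_counts[sample],
                    "gene": mut.gene_label or ".",
                    "is_driver": int(mut.is_driver),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_segments(index: SegmentIndex, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "total_cn": s.total_cn,
            "major_cn": s.major_cn,
            "minor_cn": s.minor_cn,
        }
        for s in index.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_timeline(timeline: list[SampleTimepoint], path: str | Path) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "sample_id": t.sample_id,
            "day": t.day,
            "alc_per_ul": repr(t.alc),
            "purity": repr(t.purity),
            "is_relapse": int(t.is_relapse),
        }
        for t in timeline
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_outcomes(outcomes: list[OutcomeRecord], path: str | Path) -> None:
    extra = sorted({name for o in outcomes for name, _ in o.covariates})
    rows = []
    for o in outcomes:
        row = {
            "patient_id": o.patient_id,
            "followup_day": o.followup_day,
            "progressed": int(o.progressed),
        }
        covs = dict(o.covariates)
        for name in extra:
            row[name] = int(covs.get(name, False))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x) -> str:
    """Numeric formatting for report tables: >= 6 significant digits."""
    if x is None:
        return "."
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float) and not np.isfinite(x):
        return "."
    return f"{x:.6g}"


def write_report(results: dict, outdir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write the analysis report: cluster, shift, kinetics tables and summary.

    ``results`` holds DataFrames under keys 'clusters', 'shifts', 'kinetics',
    'survival' (any may be absent or empty) plus optional 'trees' (patient ->
    newick string) and a 'summary' mapping echoed into summary.json with the
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("clusters", "shifts", "kinetics", "survival"):
        df = results.get(name)
        if df is None:
            df = pd.DataFrame()
        path = outdir / f"{name}.tsv"
        df = df.copy()
        for col in df.columns:
            if df[col].dtype.kind == "f":
                df[col] = df[col].map(_fmt)
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    trees = results.get("trees") or {}
    tree_path = outdir / "trees.nwk"
    with open(tree_path, "w") as fh:
        for patient, newick in trees.items():
            fh.write(f"{patient}\t{newick}\n")
    written["trees"] = tree_path
    summary = dict(results.get("summary") or {})
    summary["seed"] = seed
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    written["summary"] = summary_path
    return written


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
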