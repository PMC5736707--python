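# clonedyn

Longitudinal subclonal reconstruction and clone growth kinetics from serial
tumor sequencing, built for studies that draw blood repeatedly during
targeted therapy (the motivating setting is chronic lymphocytic leukemia on
BTK-inhibitor treatment) and ask two questions: *which subclones shift under
therapy, and how fast do resistant clones grow?*

## What it computes

Given force-called allele counts for the union of a patient's somatic
mutations across serial samples, per-sample purity and allelic copy number,
and a clinical timeline (collection day, absolute lymphocyte count ALC,
progression/censoring):

1. **CCF posteriors** — each mutation's variant allele fraction is inverted
   to a cancer cell fraction under the standard allele-fraction model,
   E[VAF] = α·m·CCF / (α·q_t + (1−α)·q_n), as a discretized posterior on a
   101-point grid (binomial likelihood, uniform prior). Force-called zeros
   are first-class: their posterior concentrates near 0.
2. **Multi-timepoint Dirichlet-process clustering** — mutations are
   clustered jointly across all timepoints by a collapsed Gibbs sampler
   with concentration γ ~ Gamma(1,1); the consensus partition cuts the
   co-clustering frequency matrix at average-linkage distance 0.5. Each
   cluster is a subclone with a CCF trajectory.
3. **Clonal-shift tests** — per patient, the largest rising and falling
   clones between baseline and the latest pre-relapse sample (≤ 365 d) are
   scored by the posterior probability that the two-timepoint CCF pair lies
   within ±0.1 of the diagonal; these probabilities enter one cohort-wide
   Benjamini–Hochberg family, and a patient is *evolved* when |ΔCCF| > 0.1
   with Q < 0.1.
4. **Phylogeny** — exhaustive enumeration of clone trees under the
   pigeonhole constraints (parent CCF ≥ child CCF in every sample; sibling
   CCFs sum to at most the parent's, or 1 at the root), with ties resolved
   by the summed R² of per-clone exponential fits.
5. **Growth kinetics** — clone CCFs convert to circulating cell numbers
   (ALC × blood volume × purity × CCF); exponential rates g and day-0 sizes
   N₀ = N(t)·e^(−g·t) are inferred by a fixed-tree MCMC that multinomially
   reassigns mutations to clones each iteration, with medians and 2.5/97.5
   percentiles reported. CCF change rates per treatment period (d|CCF|/dt)
   and their deceleration are also computed.
6. **Cohort statistics** — two-sided Fisher exact tests, Kaplan–Meier
   curves and the log-rank test with an O/E hazard-ratio summary.

A synthetic-cohort generator (`clonedyn.simulate`) emulates the study
design — 3–8 samples per patient at days 0/30/60/90/180/365 (plus relapse
draws), depth ~×107, ~1.13 mutations/Mb, 2–6 subclones on branched or
linear topologies, exponential per-clone kinetics, declining ALC, and
progression hazards tied to true clonal evolution — so every stage is
testable against exact ground truth.

## Worked example

```bash
python examples/04_phylogeny_and_growth.py
```

```
inferred tree (newick): (C2,C3)C1;
clone    g/day               95% CI    R2   N0 (day-0 cells)
    1 -0.0081   [-0.0105, -0.0070]  0.95           1.67e+11
    2 -0.0100   [-0.0106, -0.0095]  1.00           5.23e+10
    3 +0.0199   [+0.0189, +0.0210]  1.00           1.02e+03

resistant clone: 1.99%/day, back-extrapolated size 1019 cells (seeded at 1000)
```

The scenario seeds a resistant subclone at 1,000 cells growing at 2%/day
while the bulk leukemia declines at 1%/day. The pipeline recovers the two
declining populations (clones 1–2, ~10¹¹ cells at baseline), finds the
resistant clone's rate to ±0.1 percentage points, and back-extrapolates its
size at treatment initiation to within 2% — the kind of inference used to
argue that resistance pre-exists therapy. The other `examples/` scripts
cover CCF posteriors, clustering, shift detection and survival association,
each printing what its numbers mean.

Command line, for file-based runs:

```bash
clonedyn simulate --preset shift --seed 1 --out data/
clonedyn run --mutations data/mutations.tsv --segments data/segments.tsv \
    --timeline data/timeline.tsv --outcomes data/outcomes.tsv --out results/ --seed 1
```

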