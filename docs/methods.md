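# Methods

This note documents the models behind `clonedyn`, the assumptions they
make, the defaults and why, and what the synthetic-data experiments do and
do not demonstrate.

## CCF model

A somatic mutation present at multiplicity `m` (mutant copies per carrying
cell) in a fraction `CCF` of tumor cells, in a sample of purity `α` with
local total copy number `q_t` (tumor) and `q_n = 2` (normal), has expected
variant allele fraction

    E[VAF] = α · m · CCF / (α · q_t + (1 − α) · q_n),

clipped to [1e−6, 1 − 1e−6] so binomial likelihoods stay finite. The
posterior over CCF is computed on a uniform 101-point grid {0, 0.01, …, 1}
with a uniform prior and a Binomial(alt | depth, E[VAF]) likelihood. The
grid matches two-decimal CCF reporting and makes the diagonal-band
integral of the shift test exact. Multiplicity is chosen per mutation from
{1, …, major_cn} by maximizing the marginal likelihood over the grid
(smallest m on ties); purity and segments come from upstream estimation
and are not re-fitted. When the closed-form inversion exceeds 1 the grid
simply piles mass at 1.0 — no clipping of the data. Zero-depth input
returns a uniform posterior with a warning.

Assumptions: read counts are binomial at the expected VAF (no sequencing
error model, no strand artifacts — upstream QC territory); one multiplicity
per mutation per sample; subclonal copy number is out of scope.

## Dirichlet-process clustering

A subclone is a set of mutations sharing a latent CCF vector over the
patient's timepoints. The model is a Dirichlet-process mixture: cluster
parameters live on the CCF grid, a cluster's distribution at a timepoint is
the normalized product of its members' posteriors, and a mutation's
likelihood under a cluster is the grid dot product of the two
distributions, multiplied across timepoints (timepoints independent given
the clone). A collapsed Gibbs sweep reassigns each mutation given the
others, with new-cluster probability γ · (1/101)^T; γ has a Gamma(1,1)
prior resampled by the Escobar–West auxiliary scheme. Chains start from a
single cluster. Defaults: 1,000 sweeps, 500 burn-in — at the tested
problem sizes (≤ ~200 mutations, ≤ 8 timepoints) label trajectories mix
within tens of sweeps, and doubling the chain does not change consensus
partitions; both are configurable.

The consensus partition cuts the co-clustering frequency matrix (fraction
of kept sweeps in which two mutations share a cluster) by average-linkage
hierarchical clustering at distance 0.5, i.e. pairs together in a majority
of sweeps tend to stay together. Mutation ids are processed in sorted
order, so input order cannot affect results. Singleton consensus clusters
are retained but flagged low-confidence; downstream they bypass the
reassignment MCMC (see kinetics) because a one-mutation cluster has no
stable identity under reassignment.

## Clonal-shift testing

For each patient the baseline sample and the latest non-relapse sample
within 365 days are compared (relapse draws are excluded so early dynamics
are not conflated with outgrowth at progression). The clusters with
maximal positive and maximal negative change in CCF point estimate are the
rising/falling candidates; a direction in which nothing moves is skipped,
and a lone cluster serves as both. The test statistic is the posterior
mass of |CCF(t1) − CCF(t0)| ≤ 0.1, treating the two marginal grid
posteriors as independent (the chain stores marginals; the band is read as
±10% of the CCF scale, i.e. an absolute 0.1, matching the companion call
threshold). These band probabilities act as the p-like quantities of the
null "no change" and enter a single Benjamini–Hochberg family across all
patients and both directions; a patient is *evolved* when some test has
Q < 0.1 and |ΔCCF| > 0.1 (0.05 as a sensitivity setting).

With many mutations per cluster the band probability is near 0 or 1, so
the procedure is conservative on null cohorts — measured evolved-call
rates on flat-truth simulations are ≈ 0 (≤ the 0.1 target by a wide
margin).

## Phylogeny

Trees over clusters must satisfy, at every timepoint, (i) parent CCF ≥
child CCF − ε and (ii) Σ sibling CCFs ≤ parent CCF + ε (≤ 1 + ε at the
root). ε defaults to 0.02 because the constraints are evaluated on noisy
posterior modes; the pipeline doubles ε (up to 0.2) when nothing is
feasible rather than failing a patient outright. A cluster with baseline
CCF ≥ 0.9 roots the tree; otherwise a synthetic germline node (CCF 1) is
added. Enumeration is exhaustive over parent maps (≤ 8 clusters) and every
candidate is re-verified by an independent constraint checker. When
several trees survive, the one maximizing Σ R² of per-clone exponential
fits — applied to each clone's *exclusive* fraction, its cluster CCF minus
its children's, clipped at 0 — is selected; ties prefer the shallowest
tree, then the lexicographically smallest parent map.

## Growth kinetics

Clone CCFs become absolute circulating cell numbers via
ALC [cells/µL] × blood volume [µL] × purity × CCF. Blood volume defaults
to 5 L (5 × 10⁶ µL) and is configurable; all absolute sizes scale linearly
with it. Exponential dynamics N(t) = N₀ e^{g·t} are fitted by least
squares of ln N on t; R² is reported on the log scale, and a two-point fit
is flagged (its R² = 1 is vacuous). Back-extrapolation to treatment
initiation is N₀ = N(t_ref) · e^{−g·t_ref}, with the rate bounds mapped
through the same formula.

Uncertainty comes from a fixed-tree, fixed-cluster MCMC (default 10,000
iterations; the validation suite uses 300–500, which already stabilizes
the percentile summaries at these problem sizes). Each iteration:

1. every mutation is reassigned to a clone by a multinomial draw with
   probabilities proportional to its grid-overlap likelihood under each
   clone's (fixed) consensus distribution;
2. each clone's per-timepoint CCF distribution is recomputed as the
   product posterior of the iteration's members, and a CCF value is drawn
   from it. Because the grid is a histogram of a continuous quantity, the
   draw is smoothed uniformly within the selected 0.01-wide cell
   (reflected at 0 and 1); without this, posterior width collapses at
   small CCFs and credible intervals become overconfident. Exact point
   masses stay put, and `smooth_cells=False` disables the correction, in
   which case a degenerate (point-mass) problem reduces exactly to the
   deterministic fit;
3. exclusive fractions are formed down the tree and fitted; g and N₀ are
   collected.

Medians and 2.5/97.5 percentiles summarize the draws. Two further rules
keep the regression honest near the detection limit: clones whose cluster
CCF never reaches 0.1 are excluded from rate inference entirely, and a
fixed per-timepoint mask admits only timepoints where the consensus
exclusive CCF clears two grid cells (0.02) — below that the grid cannot
resolve the fraction, and letting individual draws decide their own
inclusion biases declining rates upward. Singleton clusters fall back to a
deterministic regression on their CCF point estimates with t-based
regression intervals.

CCF rate statistics split the first year at day 30 (nearest sample wins,
with a log note when it is far): period rates are |ΔCCF|/Δt, and the
deceleration is the difference of the two absolute rates divided by the
separation of the period midpoints — a finite-difference reconstruction,
as only the symbol, not the formula, is standard. Direction concordance
compares the signs of the two signed changes.

## Cohort statistics

Fisher exact tests are two-sided by hypergeometric probability-mass
ordering. Kaplan–Meier curves and the log-rank χ² come from lifelines; the
hazard-ratio summary is the Mantel–Haenszel-style (O₁/E₁)/(O₂/E₂) with
expected counts from explicit risk-set bookkeeping, not a proportional-
hazards fit — adequate for a univariate two-group comparison and checked
against a hand-computed six-subject example.

## Synthetic cohorts

`simulate_patient` draws 2–6 clones on a random tree (branched attachments
with probability 15/19, else linear), assigns exclusive day-0 fractions by
a trunk-weighted Dirichlet, and evolves each exclusive population
exponentially. Observables follow the measurement model exactly: ALC =
(tumor + normal)/volume with a constant normal-lymphocyte compartment,
purity = tumor/(tumor + normal), depth ~ negative binomial (mean 107,
dispersion 77, giving IQR ≈ 97–119), alt counts binomial at the model VAF,
and mutation burden ~1.13/Mb over a 37 Mb exome (≥ 4 mutations per clone
so clusters are identifiable). Baseline purity is drawn from (0.96, 0.995):
CLL blood at enrollment is tumor-dominated, which puts the normal
compartment at ~1–3k cells/µL and keeps purity meaningful through the
on-treatment nadir. With probability `shift_prevalence` (default 19/61) a
patient's clones get heterogeneous rates (otherwise all clones share one
decline rate, so the truth is exactly flat); the *truly evolved* label is
computed from the noiseless CCF trajectories with the same >0.1 criterion
the detector uses. Progression times are exponential, hazard ×3 for truly
evolved patients, censored at 48 months. The `relapse` preset seeds a
resistant clone at 10³ cells growing 2%/day against a 1%/day declining
bulk, with relapse-phase draws at days 600/840 during the rebound.

Two generator options exist for inference-validation experiments:
`rate_spread` draws all of a patient's clone rates within ± spread of a
shared base rate (slow relative drift keeps clone CCF trajectories apart —
the "well-separated clones" regime in which reassignment-based rate
inference is designed to operate), and `min_clone_fraction` floors the
day-0 fractions. The growth-rate coverage experiment uses
`rate_spread=0.006` with `min_clone_fraction=0.15`: clone rates still span
the full [−0.05, 0.06]/day range across patients, but trajectories rarely
cross. With fully independent per-clone rates, trajectories cross and
overlap within a year; mutation reassignment then mixes overlapping
clusters and the resulting rate bias is not representable in the credible
interval — a limitation of the reassignment design itself, documented
here rather than hidden.

What the simulations do not emulate: sequencing error and contamination,
subclonal copy number, purity estimation error (true purity is recorded in
the timeline), sampling jitter in collection days, and any non-exponential
growth. Passing tests therefore validate the inference machinery under its
own measurement model, not robustness to upstream artifacts.

## Validation problem sizes

The statistical checks run at desk scale, chosen so the whole suite
completes in minutes: clustering recovery at 100–150 mutations and two to
three timepoints (chains of 400–1,000 sweeps); shift-test calibration on
200 cohorts of 6 flat patients with clusters formed from the true
assignments (the calibration exercises the band/BH decision rule — cluster
recovery is validated separately); credible-interval coverage on 100
patients at 300 MCMC iterations; and the end-to-end relapse scenario with
600-sweep chains and 500 kinetics iterations. Defaults in the package
remain at the larger production values (1,000/10,000).

## Known limitations

- Marginal independence across timepoints in the band probability; the
  joint two-timepoint distribution from chain samples is a possible
  refinement.
- The reassignment MCMC quantifies counting and assignment noise, not
  model error from overlapping clusters (see above).
- Exhaustive tree enumeration caps at 8 clusters; patients with more
  clusters skip tree/kinetics with a logged warning.
- The O/E hazard ratio is not a Cox estimate; with heavy censoring
  imbalance it can differ from a model-based HR.
- Absolute clone sizes inherit the uncertainty of the assumed 5 L blood
  volume linearly.
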