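"""Detect significant early clonal shifts with cohort-wide FDR control.

Runs the full pipeline on a small simulated cohort and prints, per
patient, the largest rising/falling clone shift, its diagonal-band
probability, the BH-adjusted value and the evolved call
(|dCCF| > 0.1 and Q < 0.1).
"""

from clonedyn.io import SegmentIndex
from clonedyn.pipeline import RunConfig, run_cohort
from clonedyn.simulate import SimulationConfig, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(n_patients=4, shift_prevalence=0.5, mutations_per_clone=15), seed=8
)
config = RunConfig(cluster_iters=300, cluster_burn_in=150, mcmc_iters=100, seed=8)
result = run_cohort(
    cohort.mutations, SegmentIndex(cohort.segments), cohort.timeline, cohort.outcomes, config
)

truth = {p.patient_id: p.truly_evolved for p in cohort.patients}
print(f"{'patient':8} {'dir':7} {'dCCF':>6} {'band_p':>7} {'q_adj':>6}  call   truth")
for t in result.shifts.tests:
    call = "EVOLVED" if t.significant else "-"
    print(
        f"{t.patient_id:8} {t.direction:7} {t.delta_ccf:+.2f} {t.band_prob:7.3f} "
        f"{t.q_adj:6.3f}  {call:7} {'shift' if truth[t.patient_id] else 'flat'}"
    )
print("Low band probability = little posterior mass near 'no change';")
print("patients whose adjusted value clears Q < 0.1 with |dCCF| > 0.1 are called evolved.")
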