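"""Cohort-level association statistics.

Associations between early clonal evolution and clinical outcome use the
two-sided Fisher exact test on 2x2 tables and the Kaplan-Meier /
log-rank machinery for time-to-progression, with a Mantel-Haenszel-style
observed/expected hazard-ratio summary HR = (O1/E1) / (O2/E2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import fisher_exact as _scipy_fisher


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = outcome (event, no event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if (self.a + self.b == 0) or (self.c + self.d == 0):
            raise ValueError("both row margins must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves per group plus the log-rank comparison."""

    curves: dict[object, pd.DataFrame]  # time, at_risk, events, survival
    chi2: float
    p: float
    hr: float  # (O1/E1) / (O2/E2), group order = sorted labels
    observed: dict[object, float]
    expected: dict[object, float]


def fisher_exact(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p by hypergeometric probability-mass ordering."""
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    return float(_scipy_fisher(arr, alternative="two-sided")[1])


def _oe_counts(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray, labels: list
) -> tuple[dict, dict]:
    """Observed and expected event counts per group by risk-set bookkeeping."""
    observed = {lab: 0.0 for lab in labels}
    expected = {lab: 0.0 for lab in labels}
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        n_risk = at_risk.sum()
        d_total = int(((times == t) & events.astype(bool)).sum())
        for lab in labels:
            in_g = groups == lab
            observed[lab] += int(((times == t) & events.astype(bool) & in_g).sum())
            expected[lab] += d_total * (at_risk & in_g).sum() / n_risk
    return observed, expected


def km_logrank(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> SurvivalResult:
    """Kaplan-Meier estimation per group and a two-group log-rank test.

    ``events`` is 1 for an observed event (progression) and 0 for censoring.
    The hazard ratio is the ratio of observed/expected event counts between
    the two groups (first group label in sorted order is the numerator).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"log-rank comparison requires exactly 2 groups, got {len(labels)}")

    curves = {}
    for lab in labels:
        mask = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].to_numpy(dtype=float),
                "events": tbl["observed"].to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            }
        )

    g1 = groups == labels[0]
    res = logrank_test(times[g1], times[~g1], events[g1], events[~g1])
    observed, expected = _oe_counts(times, events, groups, labels)
    num = observed[labels[0]] / expected[labels[0]] if expected[labels[0]] > 0 else np.nan
    den = observed[labels[1]] / expected[labels[1]] if expected[labels[1]] > 0 else np.nan
    hr = num / den if den and np.isfinite(den) and den > 0 else np.inf

    return SurvivalResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        hr=float(hr),
        observed=observed,
        expected=expected,
    )
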