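"""Weighted descriptives and age-scale Kaplan-Meier cumulative incidence."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort, FirstOnsetRecord
from .errors import EstimationError

AGE_GROUPS = {
    "45-64": (45, 64),
    "65+": (65, np.inf),
    "overall": (-np.inf, np.inf),
}


@dataclass
class KMCurve:
    disease: str
    age_group: str
    ages: np.ndarray  # event/censor ages, ascending
    cumulative_incidence: np.ndarray  # 1 - S(age), non-decreasing in [0, 1]
    at_risk: np.ndarray  # risk-set size just before each age

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "cumulative_incidence": self.cumulative_incidence,
                "n_at_risk": self.at_risk,
            }
        )


def onset_age_summary(records: Iterable[FirstOnsetRecord]) -> pd.DataFrame:
    """Per-disease median and IQR of first-onset age.

    Quantiles use linear interpolation between order statistics. Diseases
    with zero records are simply absent from the output.
    """
    by_disease: dict[str, list[int]] = {}
    for r in records:
        by_disease.setdefault(r.disease, []).append(r.onset_age)
    rows = []
    for disease in sorted(by_disease):
        ages = np.asarray(by_disease[disease], dtype=float)
        q1, med, q3 = np.percentile(ages, [25, 50, 75])
        rows.append(
            {"disease": disease, "n": len(ages), "median": med, "q1": q1, "q3": q3}
        )
    return pd.DataFrame(rows, columns=["disease", "n", "median", "q1", "q3"])


def km_cumulative_incidence(
    cohort: Cohort,
    disease: str,
    age_group: str = "overall",
    left_truncation: bool = True,
    include_prevalent: bool = True,
) -> KMCurve:
    """Product-limit cumulative incidence of ``disease`` on the age scale.

    Participants enter the risk set at ``entry_age`` (left truncation) and
    exit at the earlier of onset and ``exit_age``. Pre-entry (prevalent)
    onsets are, by default, kept as events at their reported age with the
    entry clamped to that age; with ``include_prevalent=False`` they are
    dropped from the curve. ``age_group`` selects on entry age.
    """
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age_group {age_group!r}; use one of {list(AGE_GROUPS)}")
    lo, hi = AGE_GROUPS[age_group]
    onset_by_person = {
        e.person_id: e.onset_age for e in cohort.events if e.disease == disease
    }

    durations, observed, entries = [], [], []
    for p in cohort.participants:
        if not (lo <= p.entry_age <= hi):
            continue
        onset = onset_by_person.get(p.person_id)
        entry = float(p.entry_age) if left_truncation else 0.0
        if onset is not None:
            if onset <= entry:
                if not include_prevalent:
                    continue
                # prevalent (recalled) onset: enter the risk set the year
                # before the event so the person is at risk for it
                entry = float(onset) - 1.0
            durations.append(float(onset))
            observed.append(1)
        else:
            durations.append(float(p.exit_age))
            observed.append(0)
        entries.append(entry)

    if not durations:
        raise EstimationError(
            f"no participants at risk for {disease!r} in age group {age_group!r}"
        )

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed, entry=entries if left_truncation else None)
    table = kmf.event_table
    # effective risk set excludes same-age entrants, matching the estimator
    effective = table["at_risk"] - table["entrance"]
    event_rows = table[table["observed"] > 0]
    empty = event_rows[effective.loc[event_rows.index] <= 0]
    if len(empty):
        raise EstimationError(
            f"empty risk set at event age {float(empty.index[0])} for {disease!r}"
        )
    surv = kmf.survival_function_["KM_estimate"]
    ages = surv.index.to_numpy(dtype=float)
    keep = ages >= 0  # lifelines inserts a 0-age anchor row
    at_risk = effective.reindex(surv.index).ffill().fillna(0).to_numpy()
    return KMCurve(
        disease=disease,
        age_group=age_group,
        ages=ages[keep],
        cumulative_incidence=(1.0 - surv.to_numpy())[keep],
        at_risk=at_risk[keep],
    )


def onset_age_histogram(cohort: Cohort) -> dict[str, dict[int, int]]:
    """Per-disease counts of onsets by single year of age; counts sum to the
    per-disease event totals."""
    hist: dict[str, Counter] = {}
    for e in cohort.events:
        hist.setdefault(e.disease, Counter())[e.onset_age] += 1
    return {d: dict(sorted(c.items())) for d, c in sorted(hist.items())}


def weighted_prevalence(
    cohort: Cohort,
    disease: Optional[str] = None,
    predicate: Optional[Callable] = None,
) -> float:
    """Survey-weighted percent positive for a disease or a covariate predicate.

    Exactly one of ``disease`` / ``predicate`` must be given; the result is
    ``100 * sum(w_positive) / sum(w_all)`` and is invariant to uniform
    weight rescaling.
    """
    if (disease is None) == (predicate is None):
        raise ValueError("give exactly one of disease= or predicate=")
    total = sum(p.weight for p in cohort.participants)
    if total <= 0:
        raise EstimationError("zero total weight")
    if disease is not None:
        positive_ids = {e.person_id for e in cohort.events if e.disease == disease}
        pos = sum(p.weight for p in cohort.participants if p.person_id in positive_ids)
    else:
        pos = sum(p.weight for p in cohort.participants if predicate(p))
    return 100.0 * pos / total
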