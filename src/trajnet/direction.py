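"""Temporal ordering of disease pairs and the exact binomial direction test.

For each unordered pair (d1, d2), N1 counts persons whose d1 onset strictly
precedes d2, N2 the reverse; same-year onsets are simultaneous and excluded
from N = N1 + N2. Under no preferred direction, N1 ~ Binomial(N, 0.5); the
two-sided exact test decides whether the majority ordering is a direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from scipy.stats import binomtest

from .cohort import Cohort

ThresholdPolicy = Literal["bonferroni_pairs", "per_pair_n"]


@dataclass(frozen=True)
class DirectionCount:
    d1: str
    d2: str
    n1: int  # persons with d1 strictly before d2
    n2: int  # persons with d2 strictly before d1
    n_sim: int  # same-year onsets of both

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n_sim) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        """Consecutive developers only; simultaneous onsets excluded."""
        return self.n1 + self.n2


@dataclass(frozen=True)
class DirectedPairResult:
    source: str
    target: str
    counts: DirectionCount
    p_value: float
    threshold: float
    significant: bool
    testable: bool = True
    alternative: str = "two-sided"


def enumerate_pairs(diseases: Sequence[str]) -> list[tuple[str, str]]:
    """All k(k-1)/2 unordered pairs in canonical (sorted-input) order."""
    if len(set(diseases)) != len(diseases):
        raise ValueError("duplicate disease codes")
    return list(combinations(diseases, 2))


def count_directions(cohort: Cohort, pair: tuple[str, str]) -> DirectionCount:
    d1, d2 = pair
    ages = cohort.onset_ages()
    n1 = n2 = n_sim = 0
    for person_ages in ages.values():
        a1 = person_ages.get(d1)
        a2 = person_ages.get(d2)
        if a1 is None or a2 is None:
            continue
        if a1 < a2:
            n1 += 1
        elif a2 < a1:
            n2 += 1
        else:
            n_sim += 1
    return DirectionCount(d1=d1, d2=d2, n1=n1, n2=n2, n_sim=n_sim)


def count_all_directions(
    cohort: Cohort, pairs: Iterable[tuple[str, str]]
) -> list[DirectionCount]:
    """Vectorised variant of :func:`count_directions` over many pairs."""
    ages = cohort.onset_ages()
    frame = pd.DataFrame.from_dict(ages, orient="index")
    out = []
    for d1, d2 in pairs:
        if d1 not in frame.columns or d2 not in frame.columns:
            out.append(DirectionCount(d1, d2, 0, 0, 0))
            continue
        a1, a2 = frame[d1], frame[d2]
        both = a1.notna() & a2.notna()
        out.append(
            DirectionCount(
                d1=d1,
                d2=d2,
                n1=int((a1[both] < a2[both]).sum()),
                n2=int((a2[both] < a1[both]).sum()),
                n_sim=int((a1[both] == a2[both]).sum()),
            )
        )
    return out


def exact_binomial_direction_test(
    counts: DirectionCount,
    threshold: float,
    alternative: str = "two-sided",
) -> DirectedPairResult:
    """Exact binomial test of the majority ordering against p0 = 0.5.

    With N = 0 the pair is untestable: flagged, never significant. The
    direction (source -> target) is the majority side; on an exact tie the
    canonical (d1, d2) order is kept and p = 1.
    """
    n = counts.n
    if n == 0:
        return DirectedPairResult(
            source=counts.d1,
            target=counts.d2,
            counts=counts,
            p_value=1.0,
            threshold=threshold,
            significant=False,
            testable=False,
            alternative=alternative,
        )
    k = max(counts.n1, counts.n2)
    if alternative == "two-sided":
        p = binomtest(k, n, p=0.5, alternative="two-sided").pvalue
    elif alternative == "one-sided":
        p = binomtest(k, n, p=0.5, alternative="greater").pvalue
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if counts.n2 > counts.n1:
        source, target = counts.d2, counts.d1
    else:
        source, target = counts.d1, counts.d2
    return DirectedPairResult(
        source=source,
        target=target,
        counts=counts,
        p_value=float(p),
        threshold=threshold,
        significant=bool(p < threshold),
        alternative=alternative,
    )


def direction_threshold(
    policy: ThresholdPolicy,
    alpha: float,
    n_pairs: int,
    counts: Optional[DirectionCount] = None,
) -> float:
    """Significance cutoff for one pair under the chosen correction policy.

    ``bonferroni_pairs`` divides alpha by the number of pairs tested (the
    default); ``per_pair_n`` divides by that pair's participant count N, a
    replication alternative for the ambiguous published rule.
    """
    if policy == "bonferroni_pairs":
        return alpha / max(n_pairs, 1)
    if policy == "per_pair_n":
        if counts is None:
            raise ValueError("per_pair_n policy needs the pair's counts")
        return alpha / max(counts.n, 1)
    raise ValueError(f"unknown threshold policy {policy!r}")


def run_pair_tests(
    cohort: Cohort,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    policy: ThresholdPolicy = "bonferroni_pairs",
    alternative: str = "two-sided",
) -> list[DirectedPairResult]:
    all_counts = count_all_directions(cohort, pairs)
    results = []
    for counts in all_counts:
        thr = direction_threshold(policy, alpha, len(pairs), counts)
        results.append(exact_binomial_direction_test(counts, thr, alternative))
    return results


def select_directed_pairs(
    results: Iterable[DirectedPairResult],
) -> list[DirectedPairResult]:
    """Significant pairs only, in canonical input order."""
    return [r for r in results if r.significant]


def results_frame(results: Iterable[DirectedPairResult]) -> pd.DataFrame:
    """One row per pair, stable column order, for delimited-text export."""
    rows = [
        {
            "d1": r.counts.d1,
            "d2": r.counts.d2,
            "n1": r.counts.n1,
            "n2": r.counts.n2,
            "n_sim": r.counts.n_sim,
            "p_value": r.p_value,
            "threshold": r.threshold,
            "source": r.source,
            "target": r.target,
            "significant": r.significant,
            "testable": r.testable,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "d1", "d2", "n1", "n2", "n_sim", "p_value", "threshold",
            "source", "target", "significant", "testable",
        ],
    )
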