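"""Nested case-control odds ratios for directed disease pairs.

For a directed pair d1 -> d2: cases are participants with incident d2 after
baseline; each case is matched at its d2 onset age (incidence-density
sampling) to controls who are at risk of d2 at that age, free of both d1
and d2 at their own baseline, of the same sex, and within an age caliper.
Exposure is a d1 onset strictly before the case's index age.

The conditional-logistic likelihood for one case per set,

    l(beta) = sum_sets [ beta*x_case - log sum_j exp(beta*x_j) ],

is maximised by a safeguarded Newton-Raphson written from scratch (no
library fitter), and confidence intervals come from a set-level percentile
bootstrap.
"""

from __future__ import annotations

import math
import zlib
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import EstimationError, UnidentifiableError

SEPARATION_BETA = 15.0  # |beta| beyond this is treated as separation


@dataclass(frozen=True)
class MatchConfig:
    ratio: int = 3
    age_caliper: float = 2.0
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    min_controls: int = 1
    match_sex: bool = True
    exact_age: bool = False  # caliper 0: exact baseline-age match
    allow_control_reuse: bool = True  # reuse across sets (incidence density)

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio >= 1 required")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps >= 1 required")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.min_controls < 1:
            raise ValueError("min_controls >= 1 required")


@dataclass(frozen=True)
class MatchedSet:
    set_id: int
    case_id: str
    index_age: int  # case's d2 onset age
    control_ids: tuple[str, ...]
    case_exposed: bool
    control_exposed: tuple[bool, ...]

    @property
    def size(self) -> int:
        return 1 + len(self.control_ids)

    @property
    def n_exposed(self) -> int:
        return int(self.case_exposed) + sum(self.control_exposed)

    @property
    def discordant(self) -> bool:
        return 0 < self.n_exposed < self.size


@dataclass
class ClogitResult:
    beta: float
    or_point: float
    n_sets: int
    n_discordant: int
    converged: bool
    separated: bool = False
    n_iter: int = 0


@dataclass
class BootstrapCI:
    ci_low: float
    ci_high: float
    mean_or: float
    n_reps: int
    n_failed: int
    unreliable: bool


@dataclass
class PairEstimate:
    source: str
    target: str
    beta: float
    or_point: float
    ci_low: float
    ci_high: float
    mean_or: float
    n_sets: int
    n_discordant: int
    selected: bool
    separated: bool = False
    error: Optional[str] = None


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def build_case_control(
    cohort: Cohort,
    pair: tuple[str, str],
    config: MatchConfig = MatchConfig(),
    rng: Optional[np.random.Generator] = None,
) -> list[MatchedSet]:
    """Incidence-density matched sets for the directed pair d1 -> d2.

    Cases with fewer than ``min_controls`` eligible controls are dropped
    (recorded in the cohort provenance is the caller's job); an empty case
    list yields an empty result.
    """
    d1, d2 = pair
    if rng is None:
        rng = np.random.default_rng(config.seed)

    pids = np.array([p.person_id for p in cohort.participants])
    entry = np.array([p.entry_age for p in cohort.participants], dtype=float)
    exit_ = np.array([p.exit_age for p in cohort.participants], dtype=float)
    sex = np.array([p.sex if p.sex is not None else "" for p in cohort.participants])
    ages = cohort.onset_ages()
    nan = np.nan
    age1 = np.array([ages.get(pid, {}).get(d1, nan) for pid in pids], dtype=float)
    age2 = np.array([ages.get(pid, {}).get(d2, nan) for pid in pids], dtype=float)

    caliper = 0.0 if config.exact_age else config.age_caliper

    # bucket candidate controls by (sex, integer baseline age) for fast lookup
    buckets: dict[tuple[str, int], list[int]] = defaultdict(list)
    for i in range(len(pids)):
        buckets[(str(sex[i]), int(entry[i]))].append(i)

    is_case = ~np.isnan(age2) & (age2 > entry)  # incident d2 after baseline
    case_order = np.argsort(age2[is_case], kind="stable")
    case_indices = np.nonzero(is_case)[0][case_order]

    used: set[int] = set()
    sets: list[MatchedSet] = []
    set_id = 0
    for ci in case_indices:
        t = age2[ci]  # index age
        lo = int(math.floor(entry[ci] - caliper))
        hi = int(math.ceil(entry[ci] + caliper))
        cand: list[int] = []
        sexes = [str(sex[ci])] if config.match_sex else sorted({str(s) for s in sex})
        for s in sexes:
            for a in range(lo, hi + 1):
                cand.extend(buckets.get((s, a), ()))
        cand_arr = np.array([j for j in cand if j != ci], dtype=int)
        if cand_arr.size == 0:
            continue
        ok = (
            (np.abs(entry[cand_arr] - entry[ci]) <= caliper)
            & (entry[cand_arr] <= t)  # under observation at index age
            & (exit_[cand_arr] >= t)
            & ~(age2[cand_arr] <= t)  # at risk of d2 at index age
            & ~(age2[cand_arr] <= entry[cand_arr])  # d2-free at own baseline
            & ~(age1[cand_arr] <= entry[cand_arr])  # d1-free at own baseline
        )
        eligible = cand_arr[ok]
        if not config.allow_control_reuse:
            eligible = np.array([j for j in eligible if j not in used], dtype=int)
        if eligible.size < config.min_controls:
            continue
        k = min(config.ratio, eligible.size)
        chosen = rng.choice(np.sort(eligible), size=k, replace=False)
        chosen = np.sort(chosen)
        if not config.allow_control_reuse:
            used.update(int(j) for j in chosen)
        sets.append(
            MatchedSet(
                set_id=set_id,
                case_id=str(pids[ci]),
                index_age=int(t),
                control_ids=tuple(str(pids[j]) for j in chosen),
                case_exposed=bool(age1[ci] < t),
                control_exposed=tuple(bool(age1[j] < t) for j in chosen),
            )
        )
        set_id += 1
    return sets


def sets_frame(sets: Iterable[MatchedSet]) -> pd.DataFrame:
    """Audit export: one row per set member."""
    rows = []
    for s in sets:
        rows.append(
            {"set_id": s.set_id, "role": "case", "person_id": s.case_id,
             "index_age": s.index_age, "exposed": s.case_exposed}
        )
        for pid, exp in zip(s.control_ids, s.control_exposed):
            rows.append(
                {"set_id": s.set_id, "role": "control", "person_id": pid,
                 "index_age": s.index_age, "exposed": exp}
            )
    return pd.DataFrame(rows, columns=["set_id", "role", "person_id", "index_age", "exposed"])


# ---------------------------------------------------------------------------
# Conditional logistic likelihood (scalar binary exposure, one case per set)
# ---------------------------------------------------------------------------

def _set_stats(sets: Sequence[MatchedSet]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sufficient statistics per set: size m, exposed count k, case exposure c."""
    m = np.array([s.size for s in sets], dtype=float)
    k = np.array([s.n_exposed for s in sets], dtype=float)
    c = np.array([s.case_exposed for s in sets], dtype=float)
    return m, k, c


def _loglik(beta: float, m: np.ndarray, k: np.ndarray, c: np.ndarray) -> float:
    return float(np.sum(beta * c - np.log(k * np.exp(beta) + (m - k))))


def _score_hess(beta: float, m, k, c) -> tuple[float, float]:
    e = np.exp(beta)
    denom = k * e + (m - k)
    score = float(np.sum(c - k * e / denom))
    hess = float(-np.sum(k * (m - k) * e / denom**2))
    return score, hess


def clogit_fit(sets: Sequence[MatchedSet], tol: float = 1e-10) -> ClogitResult:
    """Safeguarded Newton-Raphson maximiser of the conditional log-likelihood.

    Concordant sets contribute constants and are only reported in the
    diagnostics. Complete separation (all discordant sets exposed on one
    side) is detected and returned as an infinite-OR flag, not a number.
    """
    sets = list(sets)
    if not sets:
        raise UnidentifiableError("no matched sets")
    m, k, c = _set_stats(sets)
    disc = (k > 0) & (k < m)
    n_discordant = int(disc.sum())
    if n_discordant == 0:
        raise UnidentifiableError("no exposure-discordant sets; beta unidentifiable")
    md, kd, cd = m[disc], k[disc], c[disc]

    beta, n_iter = _newton(md, kd, cd)
    if beta is None:
        score, _ = _score_hess(0.0, md, kd, cd)
        return ClogitResult(
            beta=math.copysign(math.inf, score),
            or_point=math.inf if score > 0 else 0.0,
            n_sets=len(sets),
            n_discordant=n_discordant,
            converged=False,
            separated=True,
            n_iter=n_iter,
        )
    return ClogitResult(
        beta=beta,
        or_point=math.exp(beta),
        n_sets=len(sets),
        n_discordant=n_discordant,
        converged=True,
        n_iter=n_iter,
    )


def bootstrap_ci(
    sets: Sequence[MatchedSet],
    config: MatchConfig = MatchConfig(),
    rng: Optional[np.random.Generator] = None,
) -> BootstrapCI:
    """Set-level percentile bootstrap of the odds ratio.

    Matched sets are resampled with replacement (size = n_sets); replicates
    that separate or lose identifiability are dropped and counted. More
    than 50% failures flags the interval unreliable.
    """
    sets = list(sets)
    clogit_fit(sets)  # must be identifiable on the original data
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m, k, c = _set_stats(sets)
    n = len(sets)
    ors: list[float] = []
    n_failed = 0
    for _ in range(config.bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        mb, kb, cb = m[idx], k[idx], c[idx]
        disc = (kb > 0) & (kb < mb)
        if not disc.any():
            n_failed += 1
            continue
        res = _fit_stats(mb[disc], kb[disc], cb[disc])
        if res is None:
            n_failed += 1
            continue
        ors.append(math.exp(res))
    if not ors:
        raise EstimationError("all bootstrap replicates failed")
    alpha = 1.0 - config.ci_level
    lo, hi = np.percentile(ors, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(
        ci_low=float(lo),
        ci_high=float(hi),
        mean_or=float(np.mean(ors)),
        n_reps=len(ors),
        n_failed=n_failed,
        unreliable=n_failed > config.bootstrap_reps / 2,
    )


def _newton(md, kd, cd) -> tuple[Optional[float], int]:
    """Safeguarded Newton on discordant-set statistics.

    Returns (beta, n_iter); beta is None when |beta| escapes the separation
    bound before the score vanishes.
    """
    beta = 0.0
    ll = _loglik(beta, md, kd, cd)
    for n_iter in range(1, 101):
        score, hess = _score_hess(beta, md, kd, cd)
        if abs(score) < 1e-8:
            return beta, n_iter
        step = -score / hess if hess < 0 else math.copysign(1.0, score)
        for _ in range(60):  # step halving
            new_beta = beta + step
            new_ll = _loglik(new_beta, md, kd, cd)
            if new_ll >= ll - 1e-14:
                break
            step /= 2.0
        beta, ll = new_beta, new_ll
        if abs(beta) > SEPARATION_BETA:
            return None, n_iter
    return beta, 100


def _fit_stats(md, kd, cd) -> Optional[float]:
    return _newton(md, kd, cd)[0]


# ---------------------------------------------------------------------------
# Per-pair pipeline
# ---------------------------------------------------------------------------

def _pair_rng(base_seed: int, d1: str, d2: str) -> np.random.Generator:
    """Seed derived from the pair labels so results are order-independent."""
    return np.random.default_rng(
        [base_seed, zlib.crc32(d1.encode()), zlib.crc32(d2.encode())]
    )


def estimate_pair(
    cohort: Cohort,
    pair: tuple[str, str],
    config: MatchConfig = MatchConfig(),
) -> PairEstimate:
    d1, d2 = pair
    rng = _pair_rng(config.seed, d1, d2)
    sets = build_case_control(cohort, pair, config, rng=rng)
    try:
        fit = clogit_fit(sets)
        if fit.separated:
            return PairEstimate(
                source=d1, target=d2, beta=fit.beta, or_point=fit.or_point,
                ci_low=math.nan, ci_high=math.nan, mean_or=math.nan,
                n_sets=fit.n_sets, n_discordant=fit.n_discordant,
                selected=False, separated=True, error="separation",
            )
        ci = bootstrap_ci(sets, config, rng=rng)
    except (EstimationError, UnidentifiableError) as exc:
        return PairEstimate(
            source=d1, target=d2, beta=math.nan, or_point=math.nan,
            ci_low=math.nan, ci_high=math.nan, mean_or=math.nan,
            n_sets=len(sets), n_discordant=0, selected=False, error=str(exc),
        )
    selected = bool(ci.ci_low > 1.0 and fit.or_point > 1.0)
    return PairEstimate(
        source=d1, target=d2, beta=fit.beta, or_point=fit.or_point,
        ci_low=ci.ci_low, ci_high=ci.ci_high, mean_or=ci.mean_or,
        n_sets=fit.n_sets, n_discordant=fit.n_discordant, selected=selected,
    )


def estimate_all_pairs(
    cohort: Cohort,
    directed_pairs: Sequence[tuple[str, str]],
    config: MatchConfig = MatchConfig(),
) -> list[PairEstimate]:
    """One estimate per directed pair, sorted by descending odds ratio.

    Per-pair failures are recorded on the estimate and do not stop the run.
    """
    estimates = [estimate_pair(cohort, pair, config) for pair in directed_pairs]
    return sorted(
        estimates,
        key=lambda e: (-(e.or_point if math.isfinite(e.or_point) else -math.inf),
                       e.source, e.target),
    )


def estimates_frame(estimates: Iterable[PairEstimate]) -> pd.DataFrame:
    rows = [
        {
            "d1": e.source, "d2": e.target, "n_sets": e.n_sets,
            "n_discordant": e.n_discordant, "or_point": e.or_point,
            "ci_low": e.ci_low, "ci_high": e.ci_high, "mean_or": e.mean_or,
            "selected": e.selected, "error": e.error or "",
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["d1", "d2", "n_sets", "n_discordant", "or_point",
                 "ci_low", "ci_high", "mean_or", "selected", "error"],
    )
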