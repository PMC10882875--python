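"""Synthetic longitudinal cohort with known ground truth.

Discrete-time (yearly) onset simulation on an age scale: each year, each
not-yet-onset disease fires with probability ``baseline(age) * prod(HR)``
over already-onset predecessor diseases. Dependencies act from the year
*after* the predecessor's onset, so planted direction is unambiguous;
same-year co-onsets are a real, testable phenomenon.

Wave attendance with permanent dropout converts to exit-age censoring at
the last attended wave; covariates and weights are drawn from simple
configurable distributions. Identical config + seed gives an identical
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np

from .cohort import Cohort, OnsetEvent, Participant
from .errors import ConfigurationError
from .vocab import SURVEY_WAVES

#: hazard spec: constant per-year probability, or age bands [(lo, hi, p), ...]
HazardSpec = Union[float, Sequence[tuple[float, float, float]]]


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int
    seed: int
    baseline_hazards: Mapping[str, HazardSpec]
    dependency_matrix: Mapping[tuple[str, str], float] = field(default_factory=dict)
    age_entry_range: tuple[int, int] = (45, 70)
    waves: tuple[int, ...] = SURVEY_WAVES
    dropout_per_wave: float = 0.05
    weight_distribution: tuple[str, float] = ("lognormal", 0.4)
    history_years: int = 0  # simulate this many years before entry (prevalent onsets)
    sex_male_prob: float = 0.48

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(self.baseline_hazards)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not self.baseline_hazards:
            raise ConfigurationError("baseline_hazards must name at least one disease")
        for d, spec in self.baseline_hazards.items():
            for p in _band_probs(spec):
                if not (0.0 <= p < 1.0):
                    raise ConfigurationError(
                        f"per-year probability for {d!r} must be in [0, 1), got {p}"
                    )
        for (a, b), hr in self.dependency_matrix.items():
            if hr <= 0:
                raise ConfigurationError(f"hazard ratio for ({a}, {b}) must be > 0")
            if a == b:
                raise ConfigurationError(f"self-dependency ({a}, {b}) not allowed")
            if a not in self.baseline_hazards or b not in self.baseline_hazards:
                raise ConfigurationError(f"dependency ({a}, {b}) names unknown disease")
        if any(b <= a for a, b in zip(self.waves, self.waves[1:])):
            raise ConfigurationError("waves must be strictly increasing")
        if not (0.0 <= self.dropout_per_wave <= 1.0):
            raise ConfigurationError("dropout_per_wave must be in [0, 1]")
        lo, hi = self.age_entry_range
        if hi < lo:
            raise ConfigurationError("age_entry_range must satisfy lo <= hi")
        if self.history_years < 0:
            raise ConfigurationError("history_years must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    baseline_hazards: dict[str, HazardSpec]
    dependent_pairs: dict[tuple[str, str], float]  # entries with HR != 1 only


def _band_probs(spec: HazardSpec) -> list[float]:
    if isinstance(spec, (int, float)):
        return [float(spec)]
    return [float(p) for _, _, p in spec]


def _hazard_at(spec: HazardSpec, age: float) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    for lo, hi, p in spec:
        if lo <= age < hi:
            return float(p)
    return 0.0


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Run the simulation; deterministic under fixed seed."""
    config.validate()
    truth = GroundTruth(
        baseline_hazards=dict(config.baseline_hazards),
        dependent_pairs={k: v for k, v in config.dependency_matrix.items() if v != 1.0},
    )
    n = config.n_participants
    diseases = config.diseases
    nd = len(diseases)
    if n == 0:
        return Cohort(participants=[], events=[], provenance=["simulated: n=0"]), truth

    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_entry_range
    entry_age = rng.integers(lo, hi + 1, size=n)
    sex = np.where(rng.random(n) < config.sex_male_prob, "male", "female")
    education = np.where(rng.random(n) < 0.85, "low", "high")
    residence = np.where(rng.random(n) < 0.53, "rural", "urban")
    smoking = np.where(rng.random(n) < 0.30, "yes", "no")
    drinking = np.where(rng.random(n) < 0.33, "yes", "no")

    kind, param = config.weight_distribution
    if kind == "lognormal":
        weight = rng.lognormal(mean=0.0, sigma=param, size=n)
    elif kind == "constant":
        weight = np.full(n, float(param))
    else:
        raise ConfigurationError(f"unknown weight distribution {kind!r}")

    # permanent dropout: first missed follow-up wave truncates attendance
    n_followups = len(config.waves) - 1
    miss = rng.random((n, n_followups)) < config.dropout_per_wave
    attended_followups = np.where(
        miss.any(axis=1), miss.argmax(axis=1), n_followups
    )  # number of follow-up waves attended
    wave_years = np.asarray(config.waves)
    last_year = wave_years[attended_followups]  # index 0 = baseline year
    exit_age = entry_age + (last_year - wave_years[0])

    start_age = entry_age - config.history_years
    birth_year = wave_years[0] - entry_age

    # planted dependency matrix on the log scale, indexed [predecessor, target]
    log_hr = np.zeros((nd, nd))
    d_index = {d: i for i, d in enumerate(diseases)}
    for (a, b), hr in config.dependency_matrix.items():
        log_hr[d_index[a], d_index[b]] = np.log(hr)

    sentinel = np.iinfo(np.int32).max
    onset = np.full((n, nd), sentinel, dtype=np.int64)
    # draws run over ages strictly after the observation start, so with
    # history_years=0 every onset is incident (no baseline prevalence)
    for age in range(int(start_age.min()) + 1, int(exit_age.max()) + 1):
        active = (start_age < age) & (age <= exit_age)
        base = np.array([_hazard_at(config.baseline_hazards[d], age) for d in diseases])
        before = (onset < age).astype(float)  # strict: effect starts year after onset
        mult = np.exp(before @ log_hr)
        p_eff = base[None, :] * mult
        at_risk = active[:, None] & (onset == sentinel)
        if np.any(p_eff[at_risk] >= 1.0):
            raise ConfigurationError(
                f"effective per-year onset probability >= 1 at age {age}"
            )
        draws = rng.random((n, nd))
        fired = at_risk & (draws < p_eff)
        onset[fired] = age

    participants = [
        Participant(
            person_id=f"p{i:06d}",
            sex=str(sex[i]),
            birth_year=int(birth_year[i]),
            education=str(education[i]),
            residence=str(residence[i]),
            smoking=str(smoking[i]),
            drinking=str(drinking[i]),
            weight=float(weight[i]),
            entry_age=int(entry_age[i]),
            exit_age=int(exit_age[i]),
        )
        for i in range(n)
    ]

    events: list[OnsetEvent] = []
    for i, j in zip(*np.nonzero(onset != sentinel)):
        onset_year = int(birth_year[i]) + int(onset[i, j])
        attended = wave_years[: attended_followups[i] + 1]
        later = attended[attended >= onset_year]
        report_wave = int(later[0]) if later.size else int(wave_years[0])
        events.append(
            OnsetEvent(
                person_id=f"p{i:06d}",
                disease=diseases[j],
                onset_age=int(onset[i, j]),
                report_wave=report_wave,
                confirmed=report_wave < int(last_year[i]),
            )
        )

    cohort = Cohort(
        participants=participants,
        events=events,
        provenance=[
            f"simulated: n={n}, seed={config.seed}, diseases={list(diseases)}",
        ],
    )
    return cohort, truth


def null_cohort(config: SimulationConfig) -> Cohort:
    """Simulate with every pairwise hazard ratio forced to 1 (no dependencies)."""
    cohort, truth = simulate_cohort(replace(config, dependency_matrix={}))
    assert not truth.dependent_pairs
    return cohort


def config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a config from a parsed YAML/JSON mapping.

    Dependencies are given as a nested map ``{d1: {d2: hr}}``; hazards as
    either a number or a list of ``[age_lo, age_hi, p]`` bands.
    """
    dep: dict[tuple[str, str], float] = {}
    for d1, targets in dict(data.get("dependency_matrix", {})).items():
        for d2, hr in dict(targets).items():
            dep[(d1, d2)] = float(hr)
    hazards: dict[str, HazardSpec] = {}
    for d, spec in dict(data["baseline_hazards"]).items():
        if isinstance(spec, (int, float)):
            hazards[d] = float(spec)
        else:
            hazards[d] = [tuple(map(float, band)) for band in spec]
    kwargs = {}
    for key in ("dropout_per_wave", "history_years", "sex_male_prob"):
        if key in data:
            kwargs[key] = data[key]
    if "age_entry_range" in data:
        kwargs["age_entry_range"] = tuple(data["age_entry_range"])
    if "waves" in data:
        kwargs["waves"] = tuple(data["waves"])
    if "weight_distribution" in data:
        kwargs["weight_distribution"] = tuple(data["weight_distribution"])
    return SimulationConfig(
        n_participants=int(data["n_participants"]),
        seed=int(data["seed"]),
        baseline_hazards=hazards,
        dependency_matrix=dep,
        **kwargs,
    )
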