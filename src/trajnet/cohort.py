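"""Cohort domain model: types, delimited-text IO, cleaning, and first onsets.

The cohort is a pair of tables: one row per participant (covariates, survey
weight, observation window in age years) and one row per retained disease
onset (year resolution). Cleaning applies the exclusion rules in a fixed,
documented order and records a per-rule count log.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import CohortValidationError, IntegrityError, SchemaError

PARTICIPANT_COLUMNS = (
    "person_id",
    "sex",
    "birth_year",
    "education",
    "residence",
    "smoking",
    "drinking",
    "weight",
    "entry_age",
    "exit_age",
)
EVENT_COLUMNS = ("person_id", "disease", "onset_age", "report_wave", "confirmed")

#: demographic fields whose absence triggers the missing-demographics exclusion
DEMOGRAPHIC_FIELDS = ("sex", "birth_year", "education", "residence", "smoking", "drinking")


@dataclass(frozen=True)
class Participant:
    person_id: str
    sex: Optional[str]  # "male" / "female"; None = missing
    birth_year: Optional[int]
    education: Optional[str]  # "low" / "high"
    residence: Optional[str]  # "urban" / "rural"
    smoking: Optional[str]  # "yes" / "no"
    drinking: Optional[str]  # "yes" / "no"
    weight: float
    entry_age: int
    exit_age: int

    def missing_demographics(self) -> list[str]:
        return [f for f in DEMOGRAPHIC_FIELDS if getattr(self, f) is None]


@dataclass(frozen=True)
class OnsetEvent:
    person_id: str
    disease: str
    onset_age: int
    report_wave: int
    confirmed: bool = False


@dataclass(frozen=True)
class FirstOnsetRecord:
    person_id: str
    disease: str
    onset_age: int
    tied: bool = False


@dataclass
class Cohort:
    participants: list[Participant]
    events: list[OnsetEvent]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.person_id for p in self.participants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate person_id in participants: {dupes}")
        known = set(ids)
        for ev in self.events:
            if ev.person_id not in known:
                raise IntegrityError(
                    f"event references unknown person_id {ev.person_id!r}"
                )
        seen: set[tuple[str, str]] = set()
        for ev in self.events:
            key = (ev.person_id, ev.disease)
            if key in seen:
                raise IntegrityError(f"duplicate event for {key}")
            seen.add(key)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def participant_index(self) -> dict[str, Participant]:
        return {p.person_id: p for p in self.participants}

    def events_by_person(self) -> dict[str, list[OnsetEvent]]:
        out: dict[str, list[OnsetEvent]] = defaultdict(list)
        for ev in self.events:
            out[ev.person_id].append(ev)
        return dict(out)

    def onset_ages(self) -> dict[str, dict[str, int]]:
        """Map person_id -> {disease -> onset_age}."""
        out: dict[str, dict[str, int]] = defaultdict(dict)
        for ev in self.events:
            out[ev.person_id][ev.disease] = ev.onset_age
        return dict(out)


@dataclass(frozen=True)
class ExclusionConfig:
    """Exclusion rules, applied in declaration order.

    A participant failing several rules is counted only under the first
    rule that removed them.
    """

    require_followup: bool = True
    require_demographics: bool = True
    min_entry_age: Optional[int] = 45


@dataclass
class ExclusionLog:
    counts: dict[str, int]
    n_input: int
    n_retained: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded": dict(self.counts),
        }


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------

def _clean_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_cohort(
    events_path: str | Path,
    participants_path: str | Path,
    sep: str = ",",
) -> Cohort:
    """Load and validate a cohort from two delimited-text files.

    Lines starting with ``#`` are treated as comments (run-manifest headers
    written by the pipeline). Row-level validation failures are collected
    into a single :class:`CohortValidationError` carrying the full report.
    """
    pdf = pd.read_csv(participants_path, sep=sep, comment="#", dtype={"person_id": str})
    edf = pd.read_csv(events_path, sep=sep, comment="#", dtype={"person_id": str})

    missing = [c for c in PARTICIPANT_COLUMNS if c not in pdf.columns]
    if missing:
        raise SchemaError(f"participants file missing column(s): {missing}")
    missing = [c for c in EVENT_COLUMNS if c not in edf.columns]
    if missing:
        raise SchemaError(f"events file missing column(s): {missing}")

    report: list[str] = []
    participants: list[Participant] = []
    for i, row in enumerate(pdf.itertuples(index=False)):
        pid = _clean_str(row.person_id)
        if pid is None:
            report.append(f"participants row {i}: empty person_id")
            continue
        try:
            weight = float(row.weight)
            entry = int(row.entry_age)
            exit_ = int(row.exit_age)
        except (TypeError, ValueError):
            report.append(f"participants row {i} ({pid}): non-numeric weight/ages")
            continue
        if not weight > 0:
            report.append(f"participants row {i} ({pid}): weight must be > 0")
            continue
        if exit_ < entry:
            report.append(f"participants row {i} ({pid}): exit_age < entry_age")
            continue
        by = row.birth_year
        birth_year = None if pd.isna(by) else int(by)
        participants.append(
            Participant(
                person_id=pid,
                sex=_clean_str(row.sex),
                birth_year=birth_year,
                education=_clean_str(row.education),
                residence=_clean_str(row.residence),
                smoking=_clean_str(row.smoking),
                drinking=_clean_str(row.drinking),
                weight=weight,
                entry_age=entry,
                exit_age=exit_,
            )
        )

    exit_by_id = {p.person_id: p.exit_age for p in participants}
    events: list[OnsetEvent] = []
    for i, row in enumerate(edf.itertuples(index=False)):
        pid = _clean_str(row.person_id)
        disease = _clean_str(row.disease)
        if pid is None or disease is None:
            report.append(f"events row {i}: empty person_id or disease")
            continue
        try:
            onset = int(row.onset_age)
            wave = int(row.report_wave)
        except (TypeError, ValueError):
            report.append(f"events row {i} ({pid}, {disease}): non-integer onset/wave")
            continue
        if onset < 0:
            report.append(f"events row {i} ({pid}, {disease}): onset_age {onset} < 0")
            continue
        if pid in exit_by_id and onset > exit_by_id[pid]:
            report.append(
                f"events row {i} ({pid}, {disease}): onset_age {onset} exceeds "
                f"exit_age {exit_by_id[pid]}"
            )
            continue
        events.append(
            OnsetEvent(
                person_id=pid,
                disease=disease,
                onset_age=onset,
                report_wave=wave,
                confirmed=bool(row.confirmed),
            )
        )

    if report:
        raise CohortValidationError(report)
    return Cohort(participants=participants, events=events)


def write_cohort(
    cohort: Cohort,
    events_path: str | Path,
    participants_path: str | Path,
    sep: str = ",",
    header_lines: Sequence[str] = (),
) -> None:
    """Write the two cohort tables; ``header_lines`` become ``#`` comments."""
    prefix = "".join(f"# {line}\n" for line in header_lines)
    pdf = participants_frame(cohort)
    edf = events_frame(cohort)
    for path, frame in ((participants_path, pdf), (events_path, edf)):
        with open(path, "w") as fh:
            fh.write(prefix)
            frame.to_csv(fh, sep=sep, index=False)


def participants_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "sex": p.sex,
                "birth_year": p.birth_year,
                "education": p.education,
                "residence": p.residence,
                "smoking": p.smoking,
                "drinking": p.drinking,
                "weight": p.weight,
                "entry_age": p.entry_age,
                "exit_age": p.exit_age,
            }
            for p in cohort.participants
        ],
        columns=list(PARTICIPANT_COLUMNS),
    )


def events_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": e.person_id,
                "disease": e.disease,
                "onset_age": e.onset_age,
                "report_wave": e.report_wave,
                "confirmed": e.confirmed,
            }
            for e in cohort.events
        ],
        columns=list(EVENT_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def apply_exclusions(
    raw: Cohort, rules: ExclusionConfig = ExclusionConfig()
) -> tuple[Cohort, ExclusionLog]:
    """Apply exclusion rules in fixed order and log per-rule counts.

    Order: no-follow-up first, then missing demographics, then the entry-age
    floor. ``retained + sum(excluded) == n_input`` always holds.
    """
    counts = {"no_followup": 0, "missing_demog": 0, "below_age_floor": 0}
    retained: list[Participant] = []
    for p in raw.participants:
        if rules.require_followup and p.exit_age <= p.entry_age:
            counts["no_followup"] += 1
            continue
        if rules.require_demographics and p.missing_demographics():
            counts["missing_demog"] += 1
            continue
        if rules.min_entry_age is not None and p.entry_age < rules.min_entry_age:
            counts["below_age_floor"] += 1
            continue
        retained.append(p)

    keep_ids = {p.person_id for p in retained}
    events = [e for e in raw.events if e.person_id in keep_ids]
    log = ExclusionLog(counts=counts, n_input=raw.n_participants, n_retained=len(retained))
    provenance = raw.provenance + [
        f"exclusions: {counts} -> retained {len(retained)}/{raw.n_participants}"
    ]
    return Cohort(participants=retained, events=events, provenance=provenance), log


# ---------------------------------------------------------------------------
# Recall resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveReport:
    """One wave's statement about one (person, disease).

    ``accurate=True`` with an age is a (re)assertion; with ``onset_age=None``
    it confirms the previously reported age. ``accurate=False`` with an age
    corrects the earlier report; with ``onset_age=None`` it retracts it.
    """

    person_id: str
    disease: str
    wave: int
    onset_age: Optional[int] = None
    accurate: bool = True


def resolve_recall(reports: Iterable[WaveReport]) -> list[OnsetEvent]:
    """Collapse per-wave reports to at most one event per (person, disease).

    The most recent wave's statement is authoritative: later corrections
    replace earlier ages, and a retraction without a replacement deletes the
    event entirely.
    """
    grouped: dict[tuple[str, str], list[WaveReport]] = defaultdict(list)
    for r in reports:
        grouped[(r.person_id, r.disease)].append(r)

    events: list[OnsetEvent] = []
    for (pid, disease), rows in sorted(grouped.items()):
        by_wave: dict[int, list[WaveReport]] = defaultdict(list)
        for r in rows:
            by_wave[r.wave].append(r)
        for wave, same in by_wave.items():
            ages = {r.onset_age for r in same}
            if len(same) > 1 and len(ages) > 1:
                raise IntegrityError(
                    f"conflicting duplicate reports for ({pid}, {disease}) at wave {wave}"
                )

        current_age: Optional[int] = None
        current_wave: Optional[int] = None
        confirmed = False
        for wave in sorted(by_wave):
            r = by_wave[wave][0]
            if r.accurate:
                if r.onset_age is not None:
                    if current_age is None:
                        current_age, current_wave = r.onset_age, wave
                    elif r.onset_age == current_age:
                        confirmed = True
                    else:  # re-assertion of a different age supersedes
                        current_age, current_wave = r.onset_age, wave
                        confirmed = False
                elif current_age is not None:
                    confirmed = True
            else:
                if r.onset_age is not None:  # correction
                    current_age, current_wave = r.onset_age, wave
                    confirmed = False
                else:  # retraction without replacement
                    current_age = current_wave = None
                    confirmed = False
        if current_age is not None:
            events.append(
                OnsetEvent(
                    person_id=pid,
                    disease=disease,
                    onset_age=current_age,
                    report_wave=current_wave,
                    confirmed=confirmed,
                )
            )
    return events


# ---------------------------------------------------------------------------
# Derived summaries
# ---------------------------------------------------------------------------

def first_onsets(cohort: Cohort) -> list[FirstOnsetRecord]:
    """One record per diseased participant; same-year ties yield co-first
    records flagged ``tied`` (downstream direction counting treats them as
    simultaneous)."""
    records: list[FirstOnsetRecord] = []
    for pid, evs in sorted(cohort.events_by_person().items()):
        min_age = min(e.onset_age for e in evs)
        firsts = sorted(e.disease for e in evs if e.onset_age == min_age)
        tied = len(firsts) > 1
        for d in firsts:
            records.append(FirstOnsetRecord(pid, d, min_age, tied=tied))
    return records


MULTIMORBIDITY_CATEGORIES = ("0", "1", "2", "3", "4+")


def multimorbidity_distribution(cohort: Cohort, weighted: bool = False) -> dict[str, float]:
    """Percent of participants by disease count, categories 0/1/2/3/4+.

    Percentages sum to 100 and are invariant to uniform weight rescaling.
    """
    if not cohort.participants:
        return {c: 0.0 for c in MULTIMORBIDITY_CATEGORIES}
    n_by_person = {pid: len(evs) for pid, evs in cohort.events_by_person().items()}
    mass = {c: 0.0 for c in MULTIMORBIDITY_CATEGORIES}
    total = 0.0
    for p in cohort.participants:
        k = n_by_person.get(p.person_id, 0)
        cat = str(k) if k < 4 else "4+"
        w = p.weight if weighted else 1.0
        mass[cat] += w
        total += w
    return {c: 100.0 * m / total for c, m in mass.items()}


def multimorbidity_share(distribution: Mapping[str, float], min_count: int = 2) -> float:
    """Percent of participants with at least ``min_count`` diseases."""
    share = 0.0
    for cat, pct in distribution.items():
        k = 4 if cat == "4+" else int(cat)
        if k >= min_count:
            share += pct
    return share


def filter_by_sex(cohort: Cohort, sex: str) -> Cohort:
    """Sex-stratified sub-cohort (for stratified replication runs)."""
    keep = [p for p in cohort.participants if p.sex == sex]
    ids = {p.person_id for p in keep}
    return Cohort(
        participants=keep,
        events=[e for e in cohort.events if e.person_id in ids],
        provenance=cohort.provenance + [f"filtered to sex={sex}"],
    )
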