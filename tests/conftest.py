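import pytest

from trajnet.cohort import Cohort, OnsetEvent, Participant


def make_participant(pid, sex="female", birth_year=1960, education="low",
                     residence="rural", smoking="no", drinking="no",
                     weight=1.0, entry_age=51, exit_age=58, **overrides):
    kw = dict(
        person_id=pid, sex=sex, birth_year=birth_year, education=education,
        residence=residence, smoking=smoking, drinking=drinking,
        weight=weight, entry_age=entry_age, exit_age=exit_age,
    )
    kw.update(overrides)
    return Participant(**kw)


def make_event(pid, disease, onset_age, report_wave=2013, confirmed=True):
    return OnsetEvent(person_id=pid, disease=disease, onset_age=onset_age,
                      report_wave=report_wave, confirmed=confirmed)


def make_cohort(participants, events):
    return Cohort(participants=list(participants), events=list(events))


@pytest.fixture
def tiny_cohort():
    """Three participants, four events."""
    parts = [make_participant(f"p{i}") for i in range(3)]
    events = [
        make_event("p0", "arthritis", 48),
        make_event("p0", "hypertension", 55),
        make_event("p1", "diabetes", 52),
        make_event("p2", "stroke", 57),
    ]
    return make_cohort(parts, events)
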