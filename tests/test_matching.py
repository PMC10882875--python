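import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajnet.errors import UnidentifiableError
from trajnet.matching import (
    MatchConfig,
    MatchedSet,
    bootstrap_ci,
    build_case_control,
    clogit_fit,
    estimate_all_pairs,
    estimate_pair,
    sets_frame,
)
from trajnet.simulate import SimulationConfig, simulate_cohort

from conftest import make_cohort, make_event, make_participant


def pair_set(set_id, case_exposed, control_exposed):
    return MatchedSet(
        set_id=set_id, case_id=f"c{set_id}", index_age=60,
        control_ids=tuple(f"k{set_id}_{i}" for i in range(len(control_exposed))),
        case_exposed=case_exposed, control_exposed=tuple(control_exposed),
    )


def grid_search_beta(sets, lo=-5.0, hi=5.0):
    """Independent oracle: maximise the written likelihood on a fine grid."""
    def ll(beta):
        total = 0.0
        for s in sets:
            x = [s.case_exposed] + list(s.control_exposed)
            total += beta * x[0] - math.log(sum(math.exp(beta * xi) for xi in x))
        return total

    grid = np.arange(lo, hi, 1e-3)
    best = grid[int(np.argmax([ll(b) for b in grid]))]
    fine = np.arange(best - 2e-3, best + 2e-3, 1e-5)
    return fine[int(np.argmax([ll(b) for b in fine]))]


class TestBuildCaseControl:
    def _cohort(self):
        parts = [make_participant("case", sex="female", entry_age=50, exit_age=62)]
        for i in range(5):
            parts.append(
                make_participant(f"ctl{i}", sex="female", entry_age=50, exit_age=62)
            )
        events = [make_event("case", "d2", 60), make_event("case", "d1", 55)]
        return parts, events

    def test_ratio_respected(self):
        parts, events = self._cohort()
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1)
        )
        assert len(sets) == 1
        assert len(sets[0].control_ids) == 3
        assert sets[0].case_exposed  # d1@55 < index 60

    def test_control_with_prior_d2_ineligible(self):
        parts, events = self._cohort()
        events.append(make_event("ctl0", "d2", 58))  # d2 before index age 60
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1, ratio=5)
        )
        # ctl0 is itself an incident case now; look at the original case's set
        (main_set,) = [s for s in sets if s.case_id == "case"]
        assert "ctl0" not in main_set.control_ids
        assert len(main_set.control_ids) == 4

    def test_control_with_later_d2_is_eligible(self):
        # incidence-density sampling: future cases may serve as controls
        parts, events = self._cohort()
        events.append(make_event("ctl0", "d2", 61))
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1, ratio=5)
        )
        (main_set,) = [s for s in sets if s.case_id == "case"]
        assert "ctl0" in main_set.control_ids

    def test_sex_mismatch_ineligible(self):
        parts, events = self._cohort()
        parts[1] = make_participant("ctl0", sex="male", entry_age=50, exit_age=62)
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1, ratio=5)
        )
        assert "ctl0" not in sets[0].control_ids

    def test_age_caliper(self):
        parts, events = self._cohort()
        parts[1] = make_participant("ctl0", entry_age=56, exit_age=66)  # |56-50| > 2
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1, ratio=5)
        )
        assert "ctl0" not in sets[0].control_ids

    def test_control_with_baseline_d1_excluded(self):
        parts, events = self._cohort()
        events.append(make_event("ctl0", "d1", 49))  # d1 before control's baseline
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1, ratio=5)
        )
        assert "ctl0" not in sets[0].control_ids

    def test_no_cases_empty(self):
        parts = [make_participant("a"), make_participant("b")]
        assert build_case_control(make_cohort(parts, []), ("d1", "d2"), MatchConfig()) == []

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(
            n_participants=2000, seed=3,
            baseline_hazards={"d1": 0.05, "d2": 0.02},
            dependency_matrix={("d1", "d2"): 2.0},
        )
        cohort, _ = simulate_cohort(cfg)
        a = build_case_control(cohort, ("d1", "d2"), MatchConfig(seed=9))
        b = build_case_control(cohort, ("d1", "d2"), MatchConfig(seed=9))
        assert a == b

    def test_exposure_prevalence_higher_in_cases_when_planted(self):
        cfg = SimulationConfig(
            n_participants=8000, seed=4,
            baseline_hazards={"d1": 0.05, "d2": 0.015},
            dependency_matrix={("d1", "d2"): 3.0},
            age_entry_range=(45, 55),
        )
        cohort, _ = simulate_cohort(cfg)
        sets = build_case_control(cohort, ("d1", "d2"), MatchConfig(seed=5))
        case_rate = np.mean([s.case_exposed for s in sets])
        ctl_rate = np.mean([e for s in sets for e in s.control_exposed])
        assert case_rate > ctl_rate

    def test_audit_frame_shape(self):
        parts, events = self._cohort()
        sets = build_case_control(
            make_cohort(parts, events), ("d1", "d2"), MatchConfig(seed=1)
        )
        df = sets_frame(sets)
        assert list(df.columns) == ["set_id", "role", "person_id", "index_age", "exposed"]
        assert (df["role"] == "case").sum() == len(sets)


class TestClogitFit:
    def test_discordant_pair_closed_form(self):
        # 1:1 sets, 6 case-only exposed, 3 control-only exposed -> OR 6/3
        sets = [pair_set(i, True, [False]) for i in range(6)]
        sets += [pair_set(10 + i, False, [True]) for i in range(3)]
        fit = clogit_fit(sets)
        assert math.isclose(fit.or_point, 2.0, abs_tol=1e-6)
        assert math.isclose(fit.beta, grid_search_beta(sets), abs_tol=1e-4)

    @pytest.mark.parametrize("a,b", [(5, 5), (8, 1), (2, 7), (12, 4)])
    def test_one_to_one_designs_match_ratio(self, a, b):
        sets = [pair_set(i, True, [False]) for i in range(a)]
        sets += [pair_set(100 + i, False, [True]) for i in range(b)]
        assert math.isclose(clogit_fit(sets).or_point, a / b, rel_tol=1e-6)

    def test_all_concordant_unidentifiable(self):
        sets = [pair_set(0, True, [True, True, True]),
                pair_set(1, False, [False, False, False])]
        with pytest.raises(UnidentifiableError):
            clogit_fit(sets)

    def test_empty_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            clogit_fit([])

    def test_separation_flagged(self):
        # every discordant set has the case exposed: likelihood increases in
        # beta without bound
        sets = [pair_set(i, True, [False, False, False]) for i in range(5)]
        fit = clogit_fit(sets)
        assert fit.separated
        assert fit.or_point == math.inf

    def test_small_one_to_three_matches_grid_search(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sets = []
            for i in range(8):
                sets.append(pair_set(i, bool(rng.random() < 0.5),
                                     [bool(rng.random() < 0.4) for _ in range(3)]))
            try:
                fit = clogit_fit(sets)
            except UnidentifiableError:
                continue
            if fit.separated:
                continue
            assert math.isclose(fit.beta, grid_search_beta(sets), abs_tol=1e-4)

    @given(st.lists(
        st.tuples(st.booleans(), st.lists(st.booleans(), min_size=1, max_size=3)),
        min_size=2, max_size=10,
    ))
    @settings(max_examples=50, deadline=None)
    def test_flipping_exposures_negates_beta(self, spec):
        sets = [pair_set(i, c, ctl) for i, (c, ctl) in enumerate(spec)]
        flipped = [pair_set(i, not c, [not x for x in ctl])
                   for i, (c, ctl) in enumerate(spec)]
        try:
            fit = clogit_fit(sets)
        except UnidentifiableError:
            with pytest.raises(UnidentifiableError):
                clogit_fit(flipped)
            return
        fit_f = clogit_fit(flipped)
        if fit.separated:
            assert fit_f.separated
        else:
            assert math.isclose(fit.beta, -fit_f.beta, abs_tol=1e-6)


class TestBootstrap:
    def _sets(self):
        sets = [pair_set(i, True, [False]) for i in range(12)]
        sets += [pair_set(100 + i, False, [True]) for i in range(6)]
        return sets

    def test_deterministic_under_seed(self):
        cfg = MatchConfig(seed=3, bootstrap_reps=100)
        a = bootstrap_ci(self._sets(), cfg)
        b = bootstrap_ci(self._sets(), cfg)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_single_repeated_pattern_is_separation(self):
        # with one case per set and a binary exposure, identical copies of a
        # single discordant pattern cannot have an interior maximum: the
        # per-set case-exposure indicator is constant, so the score never
        # vanishes and the fit is flagged as separation rather than
        # producing a degenerate zero-width interval
        sets = [pair_set(i, True, [False, True]) for i in range(10)]
        fit = clogit_fit(sets)
        assert fit.separated

    def test_ci_brackets_point_estimate_typically(self):
        ci = bootstrap_ci(self._sets(), MatchConfig(seed=2, bootstrap_reps=200))
        fit = clogit_fit(self._sets())
        assert ci.ci_low <= fit.or_point <= ci.ci_high

    def test_ci_width_shrinks_with_more_sets(self):
        small = self._sets()
        big = []
        for rep in range(4):
            for s in small:
                big.append(pair_set(1000 * rep + s.set_id, s.case_exposed,
                                    list(s.control_exposed)))
        cfg = MatchConfig(seed=5, bootstrap_reps=200)
        wide = bootstrap_ci(small, cfg)
        narrow = bootstrap_ci(big, cfg)
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)


class TestEstimateAllPairs:
    def test_selection_rule(self):
        # selected iff ci_low > 1 and or_point > 1
        cfg = SimulationConfig(
            n_participants=6000, seed=7,
            baseline_hazards={"d1": 0.05, "d2": 0.02, "d3": 0.02},
            dependency_matrix={("d1", "d2"): 3.0},
            age_entry_range=(45, 55),
        )
        cohort, _ = simulate_cohort(cfg)
        mc = MatchConfig(seed=11, bootstrap_reps=100)
        estimates = estimate_all_pairs(cohort, [("d1", "d2"), ("d1", "d3")], mc)
        by_pair = {(e.source, e.target): e for e in estimates}
        assert by_pair[("d1", "d2")].selected
        assert by_pair[("d1", "d2")].ci_low > 1
        null = by_pair[("d1", "d3")]
        assert null.selected == (null.ci_low > 1 and null.or_point > 1)

    def test_sorted_descending_or(self):
        cfg = SimulationConfig(
            n_participants=4000, seed=13,
            baseline_hazards={"a": 0.05, "b": 0.02, "c": 0.02},
            dependency_matrix={("a", "b"): 3.0, ("a", "c"): 1.5},
            age_entry_range=(45, 55),
        )
        cohort, _ = simulate_cohort(cfg)
        mc = MatchConfig(seed=1, bootstrap_reps=50)
        estimates = estimate_all_pairs(cohort, [("a", "c"), ("a", "b")], mc)
        ors = [e.or_point for e in estimates if math.isfinite(e.or_point)]
        assert ors == sorted(ors, reverse=True)

    def test_order_independence_of_pair_seeds(self):
        cfg = SimulationConfig(
            n_participants=3000, seed=17,
            baseline_hazards={"a": 0.05, "b": 0.02, "c": 0.02},
            dependency_matrix={("a", "b"): 2.0},
            age_entry_range=(45, 55),
        )
        cohort, _ = simulate_cohort(cfg)
        mc = MatchConfig(seed=2, bootstrap_reps=50)
        fwd = estimate_all_pairs(cohort, [("a", "b"), ("a", "c")], mc)
        rev = estimate_all_pairs(cohort, [("a", "c"), ("a", "b")], mc)
        assert fwd == rev

    def test_failure_recorded_not_raised(self):
        parts = [make_participant("x")]
        est = estimate_pair(make_cohort(parts, []), ("d1", "d2"), MatchConfig())
        assert est.error is not None
        assert not est.selected
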