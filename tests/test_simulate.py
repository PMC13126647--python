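"""Patient-path generation, event timing, weekly counts, and the full
trial loop."""

import numpy as np
import pytest

from smartrar import (accumulate_counts, draw_enrollment_weeks, make_scenario,
                      records_from_frame, records_to_frame, true_value)
from smartrar.randomization import RandomizationPolicy
from smartrar.scenarios import ScenarioSpec
from smartrar.simulate import Timing, run_trial, simulate_patient_path


def _fixed_a2(a2):
    return lambda week, a1: (a2, 1.0)


def test_enrollment_weeks_uniform_sorted(rng):
    weeks = draw_enrollment_weeks(5000, 130, rng)
    assert np.all(np.diff(weeks) >= 0)
    assert weeks.min() >= 1 and weeks.max() <= 130
    # uniform over 130 integers: every bin within 5 sigma of its expectation
    counts = np.bincount(weeks, minlength=131)[1:]
    expect = 5000 / 130
    assert np.all(np.abs(counts - expect) < 5 * np.sqrt(expect))
    again = draw_enrollment_weeks(50, 130, np.random.default_rng(9))
    assert np.array_equal(again, draw_enrollment_weeks(50, 130, np.random.default_rng(9)))
    assert np.all(draw_enrollment_weeks(10, 1, rng) == 1)


def test_patient_path_certain_responder(rng):
    spec = make_scenario(1).replace(p1=np.ones(2), lambda_sens=1.0)
    rec = simulate_patient_path(spec, 0, _fixed_a2(0), rng, enroll_week=5)
    assert rec.r1 == 1 and rec.y_final == 1 and rec.a2 is None
    assert rec.week_r1 == 17 and rec.week_y1 == 18


def test_patient_path_event_weeks(rng):
    spec = make_scenario(1).replace(p1=np.zeros(2), lambda_spec=1.0)
    rec = simulate_patient_path(spec, 0, _fixed_a2(1), rng, enroll_week=1)
    assert rec.r1 == 0 and rec.week_stage2 == 13 and rec.week_r2 == 25
    if rec.r2:
        assert rec.week_y2 == 26
    else:
        assert rec.week_y3 == 37


def test_patient_path_all_reach_rescue_closed_form(rng):
    """With a classifier that never sends anyone to surgery, final pCR is
    1 - (1-p1)(1-p2)(1-p3)."""
    spec = ScenarioSpec(p1=np.full(2, 0.3), p2=np.full((2, 3), 0.4),
                        p3=np.full((2, 3), 0.2), lambda_sens=0.0,
                        lambda_spec=1.0)
    n = 20000
    y = [simulate_patient_path(spec, 0, _fixed_a2(0), rng).y_final
         for _ in range(n)]
    expect = 1 - 0.7 * 0.6 * 0.8
    assert np.mean(y) == pytest.approx(expect, abs=3 * np.sqrt(expect * (1 - expect) / n))


@pytest.mark.parametrize("sid", range(6))
def test_forced_regime_pcr_matches_closed_form(sid, rng):
    """Generator-vs-oracle: the simulated pCR rate under every forced
    regime agrees with the closed-form value within 3 Monte-Carlo SEs."""
    spec = make_scenario(sid)
    n = 6000
    for a1 in range(spec.k1):
        for a2 in range(spec.k2):
            y = np.array([simulate_patient_path(spec, a1, _fixed_a2(a2), rng).y_final
                          for _ in range(n)])
            mu = true_value(spec, (a1, a2))
            se = np.sqrt(mu * (1 - mu) / n)
            assert abs(y.mean() - mu) < 3 * se, (sid, a1, a2)


def test_counts_availability_rule(rng):
    """A variable enters the counts only once its observation week has
    passed: R1 observed at week 13 and Y1 at week 14 contribute n1 and
    r1_plus but not n1_star when tallying at week 14."""
    spec = make_scenario(1).replace(p1=np.ones(2), lambda_sens=1.0)
    rec = simulate_patient_path(spec, 0, _fixed_a2(0), rng, enroll_week=1)
    assert (rec.week_r1, rec.week_y1) == (13, 14)
    c = accumulate_counts([rec], 14)
    assert c.n1[0] == 1 and c.r1_plus[0] == 1 and c.n1_star[0] == 0
    c_before = accumulate_counts([rec], 13)
    assert c_before.n1[0] == 0
    c_final = accumulate_counts([rec], None)
    assert c_final.n1_star[0] == 1 and c_final.y1_plus[0] == 1


def test_sr_trial_uniform_history_and_assignment(sr_trial, scenario1):
    assert np.allclose(sr_trial.prob1_history, 0.5)
    assert np.allclose(sr_trial.prob2_history, 1 / 3)
    for rec in sr_trial.records:
        assert rec.pi1_used == 0.5
        if rec.a2 is not None:
            assert rec.pi2_used == pytest.approx(1 / 3)
        rec.check_composition()


def test_sr_empirical_theta1_matches_implied():
    """Large-trial empirical surgery rates agree with the observable-scale
    parameters implied by the generative truth."""
    from smartrar import implied_regime_params
    spec = make_scenario(1).replace(n_patients=20000, t_enroll=130)
    res = run_trial(spec, RandomizationPolicy.from_label("SR"), seed=1)
    imp = implied_regime_params(spec)
    # 4-sigma bands: four simultaneous comparisons below
    for a1 in range(2):
        grp = [r for r in res.records if r.a1 == a1]
        frac_a1 = len(grp) / len(res.records)
        assert frac_a1 == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / 20000))
        th = np.mean([r.r1 for r in grp])
        se = np.sqrt(imp.theta1[a1] * (1 - imp.theta1[a1]) / len(grp))
        assert th == pytest.approx(imp.theta1[a1], abs=4 * se)


def test_burn_in_and_clipping_of_probabilities_used(br_trial):
    lo, hi = 0.05, 0.95
    for rec in br_trial.records:
        if rec.burn_in:
            assert rec.pi1_used == 0.5
            if rec.a2 is not None:
                assert rec.pi2_used == pytest.approx(1 / 3)
        else:
            assert lo - 1e-12 <= rec.pi1_used <= hi + 1e-12
            if rec.a2 is not None:
                assert lo - 1e-12 <= rec.pi2_used <= hi + 1e-12
    n_burn = sum(r.burn_in for r in br_trial.records)
    assert n_burn >= 20  # ties within the 20th enrollment week all count


def test_trial_counts_match_streaming_tallies(br_trial):
    """The incremental weekly counts inside the trial loop equal a from-
    scratch tally of the records at the final horizon."""
    c = accumulate_counts(br_trial.records, None)
    assert c.n1.sum() == len(br_trial.records)
    n_stage2 = sum(1 for r in br_trial.records if r.a2 is not None)
    assert c.n2.sum() == n_stage2
    assert c.n3.sum() == sum(1 for r in br_trial.records if r.r2 == 0)
    # far-future week equals the final tally
    c_inf = accumulate_counts(br_trial.records, 10 ** 6)
    assert np.array_equal(c_inf.y3_plus, c.y3_plus)


def test_trial_reproducible_and_history_shape(scenario3):
    spec = scenario3.replace(n_patients=40, t_enroll=30)
    policy = RandomizationPolicy.from_label("BR(0.5)", M=100)
    r1 = run_trial(spec, policy, seed=11)
    r2 = run_trial(spec, policy, seed=11)
    assert [(r.a1, r.a2, r.y_final) for r in r1.records] == \
           [(r.a1, r.a2, r.y_final) for r in r2.records]
    assert np.array_equal(r1.prob1_history, r2.prob1_history)
    assert r1.prob1_history.shape == (30 + 12, 2)
    assert np.allclose(r1.prob1_history.sum(axis=1), 1.0)
    assert np.allclose(r1.prob2_history.sum(axis=2), 1.0)


def test_patient_table_round_trip(br_trial, tmp_path):
    df = records_to_frame(br_trial.records)
    path = tmp_path / "patients.csv"
    df.to_csv(path, index=False)
    import pandas as pd
    back = records_from_frame(pd.read_csv(path))
    assert len(back) == len(br_trial.records)
    from dataclasses import fields
    for a, b in zip(back, br_trial.records):
        for f in fields(a):
            x, y = getattr(a, f.name), getattr(b, f.name)
            if isinstance(x, float):
                assert x == pytest.approx(y, rel=1e-12), f.name
            else:
                assert x == y, f.name
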