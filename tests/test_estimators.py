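"""Post-trial value estimators: Bayesian, plug-in, and weighted."""

import numpy as np
import pytest

from smartrar import (RegimeId, accumulate_counts, bayes_value_estimates,
                      identify_optimal, make_scenario, plugin_value_estimates,
                      true_value, true_value_table, wald_ci,
                      weighted_value_estimates)
from smartrar.estimators import ValueEstimate
from smartrar.posterior import CountSummary
from smartrar.randomization import RandomizationPolicy
from smartrar.simulate import run_trial


def test_wald_ci_values():
    lo, hi, length = wald_ci(0.5, 0.1, 0.95)
    assert (lo, hi) == (pytest.approx(0.30400360155, abs=1e-6),
                        pytest.approx(0.69599639845, abs=1e-6))
    assert length == pytest.approx(hi - lo)
    assert wald_ci(0.7, 0.0)[:2] == (0.7, 0.7)
    lo, hi, length = wald_ci(0.99, 0.1)
    assert hi == 1.0 and length > 1.0 - lo  # truncated above, raw length kept
    with pytest.raises(ValueError):
        wald_ci(0.5, -0.1)


def test_bayes_prior_only_estimate_is_half():
    """With no data every regime value has posterior mean
    E[t1*g1 + (1-t1)*t2*g2 + (1-t1)(1-t2)*g3] = 1/4 + 1/8 + 1/8 = 1/2."""
    c = CountSummary.zeros(2, 3)
    ests = bayes_value_estimates(c, M=200_000, rng=0)
    for est in ests.values():
        assert est.estimate == pytest.approx(0.5, abs=0.005)


def test_bayes_estimates_reproducible_and_consistent():
    c = CountSummary.zeros(2, 3)
    e1 = bayes_value_estimates(c, M=500, rng=3)
    e2 = bayes_value_estimates(c, M=500, rng=3)
    assert all(e1[r].estimate == e2[r].estimate for r in e1)


def test_bayes_concentrates_on_truth_at_huge_counts():
    """Posterior concentration: with ~1e6 patients' worth of counts at the
    scenario-1 truth, the Bayesian estimate approaches the true value with
    vanishing posterior SD, and matches the plug-in within 1e-2."""
    from smartrar import implied_regime_params
    spec = make_scenario(1)
    imp = implied_regime_params(spec)
    n = 10 ** 5
    c = CountSummary.zeros(2, 3)
    c.n1 += n
    c.r1_plus += np.round(n * imp.theta1).astype(int)
    c.n1_star += c.r1_plus
    c.y1_plus += np.round(c.r1_plus * imp.gamma1).astype(int)
    c.n2 += n
    c.r2_plus += np.round(n * imp.theta2).astype(int)
    c.n2_star += c.r2_plus
    c.y2_plus += np.round(c.r2_plus * imp.gamma2).astype(int)
    c.n3 += n - c.r2_plus
    c.y3_plus += np.round(c.n3 * imp.gamma3).astype(int)

    bayes = bayes_value_estimates(c, M=2000, rng=1)
    plug = plugin_value_estimates(c)
    target = true_value(spec, RegimeId(1, 0))
    assert bayes[RegimeId(1, 0)].estimate == pytest.approx(target, abs=0.005)
    assert bayes[RegimeId(1, 0)].se < 0.005
    for regime in plug:
        assert bayes[regime].estimate == pytest.approx(plug[regime].estimate,
                                                       abs=1e-2)


def test_plugin_hand_dataset():
    """theta1=0.5, gamma1=0.5, theta2=0.5, gamma2=1, gamma3=0 gives
    0.5*0.5 + 0.5*0.5*1 + 0.5*0.5*0 = 0.5."""
    c = CountSummary.zeros(1, 1)
    c.n1[0], c.r1_plus[0], c.n1_star[0], c.y1_plus[0] = 4, 2, 2, 1
    c.n2[0, 0], c.r2_plus[0, 0], c.n2_star[0, 0], c.y2_plus[0, 0] = 2, 1, 1, 1
    c.n3[0, 0], c.y3_plus[0, 0] = 1, 0
    est = plugin_value_estimates(c)[RegimeId(0, 0)]
    assert est.estimate == pytest.approx(0.5)
    assert est.se > 0


def test_plugin_all_respond_with_pcr():
    c = CountSummary.zeros(2, 3)
    c.n1[0], c.r1_plus[0], c.n1_star[0], c.y1_plus[0] = 10, 10, 10, 10
    ests = plugin_value_estimates(c)
    for a2 in range(3):
        assert ests[RegimeId(0, a2)].estimate == pytest.approx(1.0)


def test_plugin_empty_cells_flagged_and_imputed():
    c = CountSummary.zeros(2, 3)
    ests = plugin_value_estimates(c)
    for est in ests.values():
        assert est.degenerate
        assert est.estimate == pytest.approx(0.5)


def test_weighted_equals_plugin_under_sr(sr_trial):
    """Unit-weight identity: with uniform randomization the weighted and
    plug-in estimators coincide exactly on every dataset."""
    counts = accumulate_counts(sr_trial.records, None)
    plug = plugin_value_estimates(counts)
    wt = weighted_value_estimates(sr_trial.records)
    for regime in plug:
        assert wt[regime].estimate == pytest.approx(plug[regime].estimate,
                                                    abs=1e-12)
        assert wt[regime].se == pytest.approx(plug[regime].se, rel=1e-9)


def test_weighted_requires_probabilities(sr_trial):
    import copy
    records = copy.deepcopy(sr_trial.records[:10])
    records[0].pi1_used = None
    with pytest.raises(ValueError, match="pi1_used"):
        weighted_value_estimates(records)


def test_estimator_recovery_under_sr_large_n():
    """Parameter recovery: under uniform randomization with n = 10^4 every
    estimator's value for every regime is within 0.02 of the truth."""
    spec = make_scenario(1).replace(n_patients=10_000)
    res = run_trial(spec, RandomizationPolicy.from_label("SR"), seed=2)
    counts = accumulate_counts(res.records, None)
    truth = true_value_table(spec)
    for ests in (bayes_value_estimates(counts, M=1000, rng=0),
                 plugin_value_estimates(counts),
                 weighted_value_estimates(res.records)):
        for regime, est in ests.items():
            assert est.estimate == pytest.approx(truth[regime.a1, regime.a2],
                                                 abs=0.02), est.estimator


def test_plugin_se_agrees_with_bootstrap(sr_trial):
    """Delta-method SE versus a nonparametric bootstrap over patients
    (independent oracle), within 15% for a full-size uniform trial."""
    rng = np.random.default_rng(17)
    records = sr_trial.records
    n = len(records)
    regime = RegimeId(1, 0)
    boot = []
    for _ in range(300):
        sample = [records[i] for i in rng.integers(0, n, size=n)]
        counts = accumulate_counts(sample, None)
        boot.append(plugin_value_estimates(counts)[regime].estimate)
    se_boot = np.std(boot, ddof=1)
    se_delta = plugin_value_estimates(
        accumulate_counts(records, None))[regime].se
    assert se_delta == pytest.approx(se_boot, rel=0.15)


def test_identify_optimal_truth_tables():
    def as_estimates(table):
        return {RegimeId(a1, a2): ValueEstimate(
            regime=RegimeId(a1, a2), estimate=float(table[a1, a2]), se=0.0,
            ci_lo=0.0, ci_hi=1.0, ci_length=1.0, estimator="samp")
            for a1 in range(table.shape[0]) for a2 in range(table.shape[1])}

    assert identify_optimal(as_estimates(true_value_table(make_scenario(3)))) == (0, 0)
    # two maxima in scenario 5 -> lexicographic tie-break picks {0,0}
    assert identify_optimal(as_estimates(true_value_table(make_scenario(5)))) == (0, 0)
    assert identify_optimal(as_estimates(np.full((2, 3), 0.4))) == (0, 0)
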