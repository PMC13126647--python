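"""Post-trial estimators of embedded-regime values.

Three estimators of the population pCR probability mu(a1, a2) of each
embedded regime from the final trial data:

* ``bayes``   posterior mean of mu over M joint Beta-posterior draws, with
  the posterior standard deviation as the uncertainty measure;
* ``samp``    plug-in of the sample proportions for theta1, gamma1, theta2,
  gamma2, gamma3 into the g-computation formula, with a delta-method
  standard error treating the five proportions as independent binomials;
* ``wtsamp``  the same plug-in built from weighted sample proportions, each
  patient weighted by the stabilized assignment ratio (uniform reference
  probability / probability actually used) for every randomization she
  contributed.  Under adaptive randomization the weights restore the
  fixed-design structure (martingale increments with zero mean); under
  uniform randomization all weights are 1 and wtsamp coincides exactly
  with samp.

All confidence intervals are Wald intervals, truncated to [0, 1]; the
reported length is the pre-truncation length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .posterior import (CountSummary, posterior_params, regime_value_table,
                        sample_theta)
from .scenarios import RegimeId, RegimeParams

__all__ = [
    "ValueEstimate",
    "bayes_value_estimates",
    "plugin_value_estimates",
    "weighted_value_estimates",
    "identify_optimal",
    "wald_ci",
]


@dataclass
class ValueEstimate:
    """Point estimate, standard error, and Wald interval for one regime."""

    regime: RegimeId
    estimate: float
    se: float
    ci_lo: float
    ci_hi: float
    ci_length: float           # pre-truncation length
    estimator: str             # "bayes" | "samp" | "wtsamp"
    degenerate: bool = False   # some cell had no data and was imputed


def wald_ci(estimate: float, se: float,
            level: float = 0.95) -> tuple[float, float, float]:
    """Wald interval truncated to [0, 1]; returns (lo, hi, raw length)."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = estimate - z * se, estimate + z * se
    return max(lo, 0.0), min(hi, 1.0), hi - lo


def _estimates_from_tables(point: np.ndarray, se: np.ndarray,
                           degenerate: np.ndarray, label: str,
                           level: float) -> dict[RegimeId, ValueEstimate]:
    k1, k2 = point.shape
    out = {}
    for a1 in range(k1):
        for a2 in range(k2):
            lo, hi, length = wald_ci(float(point[a1, a2]), float(se[a1, a2]),
                                     level)
            out[RegimeId(a1, a2)] = ValueEstimate(
                regime=RegimeId(a1, a2), estimate=float(point[a1, a2]),
                se=float(se[a1, a2]), ci_lo=lo, ci_hi=hi, ci_length=length,
                estimator=label, degenerate=bool(degenerate[a1, a2]))
    return out


# ---------------------------------------------------------------------------
# Bayesian estimator


def bayes_value_estimates(counts_final: CountSummary, M: int = 1000,
                          rng: np.random.Generator | int | None = None,
                          level: float = 0.95) -> dict[RegimeId, ValueEstimate]:
    """Posterior mean +/- posterior SD of each regime value from ``M`` joint
    posterior draws given the final counts."""
    if M < 2:
        raise ValueError("M must be at least 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = sample_theta(posterior_params(counts_final), M, rng)
    values = regime_value_table(draws)          # (M, k1, k2)
    point = values.mean(axis=0)
    se = values.std(axis=0, ddof=1)
    degenerate = np.zeros_like(point, dtype=bool)
    return _estimates_from_tables(point, se, degenerate, "bayes", level)


# ---------------------------------------------------------------------------
# plug-in (sample proportion) estimator


def _proportion(successes: np.ndarray, n: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample proportion with posterior-mean imputation for empty cells.

    Returns (p_hat, variance of p_hat, degenerate flag).  An empty
    denominator yields the uniform-prior posterior mean (1+s)/(2+n) = 0.5
    and the Beta(1, 1) variance 1/12.
    """
    successes = np.asarray(successes, dtype=float)
    n = np.asarray(n, dtype=float)
    empty = n == 0
    p = np.where(empty, (1.0 + successes) / (2.0 + n), successes / np.where(empty, 1.0, n))
    var = np.where(empty, 1.0 / 12.0, p * (1.0 - p) / np.where(empty, 1.0, n))
    return p, var, empty


def _delta_method_se(theta1, gamma1, theta2, gamma2, gamma3,
                     v_t1, v_g1, v_t2, v_g2, v_g3) -> np.ndarray:
    """SE of mu via the gradient of the g-computation formula; stage-1
    terms broadcast over the stage-2 grid."""
    t1 = theta1[:, None]
    g1 = gamma1[:, None]
    mu2 = theta2 * gamma2 + (1.0 - theta2) * gamma3
    d_t1 = g1 - mu2
    d_g1 = t1
    d_t2 = (1.0 - t1) * (gamma2 - gamma3)
    d_g2 = (1.0 - t1) * theta2
    d_g3 = (1.0 - t1) * (1.0 - theta2)
    var = (d_t1 ** 2 * v_t1[:, None] + d_g1 ** 2 * v_g1[:, None]
           + d_t2 ** 2 * v_t2 + d_g2 ** 2 * v_g2 + d_g3 ** 2 * v_g3)
    return np.sqrt(var)


def plugin_value_estimates(counts_final: CountSummary,
                           level: float = 0.95) -> dict[RegimeId, ValueEstimate]:
    """Sample-proportion plug-in estimator with delta-method SEs."""
    c = counts_final
    t1, v_t1, e_t1 = _proportion(c.r1_plus, c.n1)
    g1, v_g1, e_g1 = _proportion(c.y1_plus, c.n1_star)
    t2, v_t2, e_t2 = _proportion(c.r2_plus, c.n2)
    g2, v_g2, e_g2 = _proportion(c.y2_plus, c.n2_star)
    g3, v_g3, e_g3 = _proportion(c.y3_plus, c.n3)

    params = RegimeParams(theta1=t1, gamma1=g1, theta2=t2, gamma2=g2, gamma3=g3)
    point = regime_value_table(params)
    se = _delta_method_se(t1, g1, t2, g2, g3, v_t1, v_g1, v_t2, v_g2, v_g3)
    degenerate = (e_t1[:, None] | e_g1[:, None] | e_t2 | e_g2 | e_g3)
    return _estimates_from_tables(point, se, degenerate, "samp", level)


# ---------------------------------------------------------------------------
# weighted (stabilized inverse-assignment-probability) estimator


def _weighted_proportion(x: np.ndarray, w: np.ndarray
                         ) -> tuple[float, float, bool]:
    """Weighted proportion with ratio-estimator variance; empty cells are
    imputed as in the unweighted plug-in."""
    if x.size == 0:
        return 0.5, 1.0 / 12.0, True
    W = w.sum()
    p = float((w * x).sum() / W)
    var = float((w ** 2 * (x - p) ** 2).sum() / W ** 2)
    return p, var, False


def weighted_value_estimates(records: Sequence, level: float = 0.95
                             ) -> dict[RegimeId, ValueEstimate]:
    """Weighted plug-in estimator from per-patient records.

    Each patient's stage-1 contributions carry weight (1/k1)/pi1_used, and
    her stage-2/3 contributions additionally (1/k2)/pi2_used.  With uniform
    randomization all weights are 1, so the output equals
    :func:`plugin_value_estimates` on the same data exactly.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    for r in records:
        if r.pi1_used is None or (r.r1 == 0 and r.pi2_used is None):
            raise ValueError("records must carry the randomization "
                             "probabilities actually used (pi1_used/pi2_used)")
    k1 = max(r.a1 for r in records) + 1
    k2 = max((r.a2 for r in records if r.a2 is not None), default=0) + 1

    t1 = np.empty(k1); v_t1 = np.empty(k1); e_t1 = np.zeros(k1, bool)
    g1 = np.empty(k1); v_g1 = np.empty(k1); e_g1 = np.zeros(k1, bool)
    shape2 = (k1, k2)
    t2 = np.empty(shape2); v_t2 = np.empty(shape2); e_t2 = np.zeros(shape2, bool)
    g2 = np.empty(shape2); v_g2 = np.empty(shape2); e_g2 = np.zeros(shape2, bool)
    g3 = np.empty(shape2); v_g3 = np.empty(shape2); e_g3 = np.zeros(shape2, bool)

    for a1 in range(k1):
        grp = [r for r in records if r.a1 == a1]
        w1 = np.array([(1.0 / k1) / r.pi1_used for r in grp])
        r1 = np.array([r.r1 for r in grp], dtype=float)
        t1[a1], v_t1[a1], e_t1[a1] = _weighted_proportion(r1, w1)
        resp = [(w, r) for w, r in zip(w1, grp) if r.r1 == 1]
        g1[a1], v_g1[a1], e_g1[a1] = _weighted_proportion(
            np.array([r.y1_obs for _, r in resp], dtype=float),
            np.array([w for w, _ in resp]))
        for a2 in range(k2):
            cell = [((1.0 / k2) / r.pi2_used * w, r)
                    for w, r in zip(w1, grp) if r.r1 == 0 and r.a2 == a2]
            w12 = np.array([w for w, _ in cell])
            r2 = np.array([r.r2 for _, r in cell], dtype=float)
            t2[a1, a2], v_t2[a1, a2], e_t2[a1, a2] = _weighted_proportion(r2, w12)
            surg = [(w, r) for w, r in cell if r.r2 == 1]
            g2[a1, a2], v_g2[a1, a2], e_g2[a1, a2] = _weighted_proportion(
                np.array([r.y2_obs for _, r in surg], dtype=float),
                np.array([w for w, _ in surg]))
            resc = [(w, r) for w, r in cell if r.r2 == 0]
            g3[a1, a2], v_g3[a1, a2], e_g3[a1, a2] = _weighted_proportion(
                np.array([r.y3_obs for _, r in resc], dtype=float),
                np.array([w for w, _ in resc]))

    params = RegimeParams(theta1=np.clip(t1, 0, 1), gamma1=np.clip(g1, 0, 1),
                          theta2=np.clip(t2, 0, 1), gamma2=np.clip(g2, 0, 1),
                          gamma3=np.clip(g3, 0, 1))
    point = regime_value_table(params)
    se = _delta_method_se(params.theta1, params.gamma1, params.theta2,
                          params.gamma2, params.gamma3,
                          v_t1, v_g1, v_t2, v_g2, v_g3)
    degenerate = (e_t1[:, None] | e_g1[:, None] | e_t2 | e_g2 | e_g3)
    return _estimates_from_tables(point, se, degenerate, "wtsamp", level)


def identify_optimal(estimates: Mapping[RegimeId, ValueEstimate]) -> RegimeId:
    """Regime with the largest estimated value; lexicographic tie-break."""
    if not estimates:
        raise ValueError("no estimates")
    best = None
    for regime in sorted(estimates):
        value = estimates[regime].estimate
        if best is None or value > best[1]:
            best = (regime, value)
    return RegimeId(*best[0])
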