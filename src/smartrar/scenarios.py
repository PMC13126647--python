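"""Generative scenarios and closed-form truths for the two-stage SMART.

A scenario specifies, for one tumor subtype, the latent pathological-complete-
response (pCR) probabilities after each block of neoadjuvant therapy together
with the operating characteristics of the imaging/biopsy response classifier
("preRCB") that decides whether a patient proceeds to surgery.  The six
shipped scenarios cover a null configuration, no delayed effects, purely
delayed effects, antagonism, synergy, and a two-optimum variant.

Notation (per subtype, stage-1 options ``a1``, stage-2 options ``a2``):

* ``p1(a1)``       latent pCR probability after stage 1,
* ``p2(a1, a2)``   latent pCR probability after stage 2 given no pCR yet,
* ``p3(a1, a2)``   pCR probability after rescue therapy given no pCR yet,
* ``lambda_sens``  sensitivity of the preRCB classifier,
* ``lambda_spec``  specificity of the preRCB classifier.

A patient who achieves latent pCR keeps it: her final surgical pCR status is 1
regardless of the path taken afterwards, and later response indicators are
drawn with probability ``lambda_sens``.  Under that persistence rule the value
(population pCR probability) of embedded regime ``{a1, a2}`` has the closed
form implemented by :func:`true_value`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import yaml

__all__ = [
    "RegimeId",
    "ScenarioSpec",
    "RegimeParams",
    "make_scenario",
    "scenario_from_config",
    "scenario_to_config",
    "true_value",
    "true_value_table",
    "implied_regime_params",
    "optimal_regimes",
    "worst_regime",
    "sr_expected_overall_pcr",
    "sr_consistency_probability",
    "SCENARIO_IDS",
]

SCENARIO_IDS = (0, 1, 2, 3, 4, 5)


class RegimeId(NamedTuple):
    """An embedded regime: give ``a1``; if no surgery after stage 1, give
    ``a2`` followed by rescue therapy."""

    a1: int
    a2: int


@dataclass
class ScenarioSpec:
    """Generative truth for one subtype-specific sub-SMART.

    ``p1`` has shape ``(k1,)``; ``p2`` and ``p3`` have shape ``(k1, k2)``
    where ``k1``/``k2`` are the numbers of stage-1/stage-2 options.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    lambda_sens: float = 0.53
    lambda_spec: float = 0.90
    n_patients: int = 200
    t_enroll: int = 130
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.p3 = np.asarray(self.p3, dtype=float)
        if self.p1.ndim != 1 or self.p1.size == 0:
            raise ValueError("p1 must be a non-empty 1-d array of probabilities")
        if self.p2.shape != (self.k1, self.k2) or self.p2.ndim != 2:
            raise ValueError("p2 must have shape (k1, k2)")
        if self.p3.shape != self.p2.shape:
            raise ValueError("p3 must have the same shape as p2")
        for label, arr in [("p1", self.p1), ("p2", self.p2), ("p3", self.p3),
                           ("lambda_sens", np.asarray(self.lambda_sens)),
                           ("lambda_spec", np.asarray(self.lambda_spec))]:
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{label} must lie in [0, 1]")
        if self.n_patients < 1 or self.t_enroll < 1:
            raise ValueError("n_patients and t_enroll must be positive")

    @property
    def k1(self) -> int:
        return self.p1.shape[0]

    @property
    def k2(self) -> int:
        return self.p2.shape[1]

    @property
    def regimes(self) -> list[RegimeId]:
        return [RegimeId(a1, a2) for a1 in range(self.k1) for a2 in range(self.k2)]

    def replace(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


@dataclass
class RegimeParams:
    """Observable-scale conditional probabilities entering the g-computation
    value formula.

    * ``theta1[a1]``      P(proceed to surgery after stage 1 | A1=a1)
    * ``gamma1[a1]``      P(pCR at surgery | A1=a1, surgery after stage 1)
    * ``theta2[a1, a2]``  P(surgery after stage 2 | stage-2 entrant, A2=a2)
    * ``gamma2[a1, a2]``  P(pCR | surgery after stage 2)
    * ``gamma3[a1, a2]``  P(pCR after rescue | no surgery after stage 2)

    Arrays may carry leading axes (e.g. an axis of posterior draws); the
    trailing axes are ``(k1,)`` and ``(k1, k2)`` respectively.
    """

    theta1: np.ndarray
    gamma1: np.ndarray
    theta2: np.ndarray
    gamma2: np.ndarray
    gamma3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("theta1", "gamma1", "theta2", "gamma2", "gamma3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.theta1.shape != self.gamma1.shape:
            raise ValueError("theta1 and gamma1 must share a shape")
        if not (self.theta2.shape == self.gamma2.shape == self.gamma3.shape):
            raise ValueError("theta2, gamma2, gamma3 must share a shape")

    @property
    def k1(self) -> int:
        return self.theta1.shape[-1]

    @property
    def k2(self) -> int:
        return self.theta2.shape[-1]


# ---------------------------------------------------------------------------
# scenario construction and (de)serialization


def _spec_from_mapping(cfg: Mapping) -> ScenarioSpec:
    p1_map = {int(k): float(v) for k, v in cfg["p1"].items()}
    k1 = max(p1_map) + 1
    p2_map = {tuple(int(x) for x in k.split(",")): float(v)
              for k, v in cfg["p2"].items()}
    k2 = max(a2 for _, a2 in p2_map) + 1
    p1 = np.array([p1_map[a1] for a1 in range(k1)])
    p2 = np.array([[p2_map[(a1, a2)] for a2 in range(k2)] for a1 in range(k1)])
    p3_cfg = cfg.get("p3", 0.15)
    if isinstance(p3_cfg, Mapping):
        p3_map = {tuple(int(x) for x in k.split(",")): float(v)
                  for k, v in p3_cfg.items()}
        p3 = np.array([[p3_map[(a1, a2)] for a2 in range(k2)]
                       for a1 in range(k1)])
    else:
        p3 = np.full_like(p2, float(p3_cfg))
    return ScenarioSpec(
        p1=p1, p2=p2, p3=p3,
        lambda_sens=float(cfg.get("lambda_sens", 0.53)),
        lambda_spec=float(cfg.get("lambda_spec", 0.90)),
        n_patients=int(cfg.get("n_patients", 200)),
        t_enroll=int(cfg.get("t_enroll", 130)),
        name=str(cfg.get("name", "")),
        description=str(cfg.get("description", "")),
    )


def scenario_from_config(source) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from a YAML path, text, or mapping."""
    if isinstance(source, Mapping):
        return _spec_from_mapping(source)
    text = source.read_text() if hasattr(source, "read_text") else None
    if text is None:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)
    return _spec_from_mapping(yaml.safe_load(text))


def scenario_to_config(spec: ScenarioSpec) -> dict:
    """Plain key/value mapping, one probability per (stage, options) key."""
    return {
        "name": spec.name,
        "description": spec.description,
        "p1": {a1: float(spec.p1[a1]) for a1 in range(spec.k1)},
        "p2": {f"{a1},{a2}": float(spec.p2[a1, a2])
               for a1 in range(spec.k1) for a2 in range(spec.k2)},
        "p3": {f"{a1},{a2}": float(spec.p3[a1, a2])
               for a1 in range(spec.k1) for a2 in range(spec.k2)},
        "lambda_sens": spec.lambda_sens,
        "lambda_spec": spec.lambda_spec,
        "n_patients": spec.n_patients,
        "t_enroll": spec.t_enroll,
    }


def make_scenario(scenario_id: int) -> ScenarioSpec:
    """Load one of the six packaged generative scenarios (ids 0-5)."""
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario id {scenario_id!r}; valid ids are {SCENARIO_IDS}")
    path = resources.files("smartrar.data") / f"scenario{scenario_id}.yaml"
    return scenario_from_config(path)


# ---------------------------------------------------------------------------
# closed-form truths


def true_value(spec: ScenarioSpec, regime: RegimeId | tuple[int, int]) -> float:
    """Population pCR probability of an embedded regime, in closed form.

    mu(a1, a2) = p1 + (1 - p1) * lspec * [p2 + (1 - p2) * lspec * p3]

    derived by g-computation under the generative model: a latent pCR
    persists to surgery, a patient without pCR exits early only through a
    classifier false positive (probability 1 - lambda_spec), and rescue
    therapy gives a last chance at pCR with probability p3.
    """
    a1, a2 = regime
    if not (0 <= a1 < spec.k1 and 0 <= a2 < spec.k2):
        raise ValueError(f"regime {regime} outside option sets")
    return float(true_value_table(spec)[a1, a2])


def true_value_table(spec: ScenarioSpec) -> np.ndarray:
    """Matrix of true regime values, shape ``(k1, k2)``."""
    ls = spec.lambda_spec
    p1 = spec.p1[:, None]
    inner = spec.p2 + (1.0 - spec.p2) * ls * spec.p3
    return p1 + (1.0 - p1) * ls * inner


def optimal_regimes(spec: ScenarioSpec, atol: float = 1e-12) -> list[RegimeId]:
    """All regimes attaining the maximal true value (possibly several)."""
    table = true_value_table(spec)
    best = table.max()
    return [RegimeId(a1, a2)
            for a1 in range(spec.k1) for a2 in range(spec.k2)
            if table[a1, a2] >= best - atol]


def worst_regime(spec: ScenarioSpec) -> RegimeId:
    """Minimum-value regime, ties broken lexicographically."""
    table = true_value_table(spec)
    flat = int(np.argmin(table))
    return RegimeId(*divmod(flat, spec.k2))


def implied_regime_params(spec: ScenarioSpec) -> RegimeParams:
    """Map the generative truth onto the observable-scale probabilities.

    Stage 1 is a direct mixture of the classifier over the latent state:
    ``theta1 = p1*lsens + (1-p1)*(1-lspec)`` and ``gamma1 = p1*lsens/theta1``.
    Stage-2 entrants are a mixture of persisting pCR patients (classifier
    false negatives, weight ``w = p1*(1-lsens)/(1-theta1)``) and patients
    without pCR; marginalizing the latent state over that mixture gives
    theta2, gamma2, gamma3.  Substituting the result into the g-computation
    formula recovers :func:`true_value` exactly.
    """
    lsens, lspec = spec.lambda_sens, spec.lambda_spec
    p1, p2, p3 = spec.p1, spec.p2, spec.p3

    theta1 = p1 * lsens + (1.0 - p1) * (1.0 - lspec)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma1 = np.where(theta1 > 0, p1 * lsens / np.where(theta1 > 0, theta1, 1.0), 0.0)

    denom1 = 1.0 - theta1
    # weight of persisting-pCR (false negative) patients among stage-2 entrants
    w = np.where(denom1 > 0, p1 * (1.0 - lsens) / np.where(denom1 > 0, denom1, 1.0), 0.0)
    w = w[:, None]

    resp_no_pcr = p2 * lsens + (1.0 - p2) * (1.0 - lspec)  # P(R2=1 | entrant without pCR)
    theta2 = w * lsens + (1.0 - w) * resp_no_pcr
    num_g2 = w * lsens + (1.0 - w) * p2 * lsens  # surgery-and-pCR at stage 2
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma2 = np.where(theta2 > 0, num_g2 / np.where(theta2 > 0, theta2, 1.0), 0.0)

    denom3 = 1.0 - theta2
    num_g3 = (w * (1.0 - lsens)
              + (1.0 - w) * p2 * (1.0 - lsens)
              + (1.0 - w) * (1.0 - p2) * lspec * p3)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma3 = np.where(denom3 > 0, num_g3 / np.where(denom3 > 0, denom3, 1.0), 0.0)

    return RegimeParams(theta1=theta1, gamma1=np.clip(gamma1, 0, 1),
                        theta2=theta2, gamma2=np.clip(gamma2, 0, 1),
                        gamma3=np.clip(gamma3, 0, 1))


def sr_expected_overall_pcr(spec: ScenarioSpec) -> float:
    """Exact expected final pCR rate under uniform randomization at both
    stages: the average of the regime-value inner expression over a uniform
    stage-2 option, then over a uniform stage-1 option."""
    ls = spec.lambda_spec
    inner = spec.p2 + (1.0 - spec.p2) * ls * spec.p3  # (k1, k2)
    per_a1 = spec.p1 + (1.0 - spec.p1) * ls * inner.mean(axis=1)
    return float(per_a1.mean())


def sr_consistency_probability(spec: ScenarioSpec,
                               regime: RegimeId | tuple[int, int]) -> float:
    """P(a patient's in-trial experience is consistent with ``regime``)
    under uniform randomization.

    A patient is consistent with {a1, a2} when she received a1 and either
    proceeded to surgery after stage 1 or received a2 at stage 2:
    (1/k1) * [theta1(a1) + (1 - theta1(a1)) / k2].
    """
    a1, a2 = regime
    if not (0 <= a1 < spec.k1 and 0 <= a2 < spec.k2):
        raise ValueError(f"regime {regime} outside option sets")
    theta1 = float(implied_regime_params(spec).theta1[a1])
    return (theta1 + (1.0 - theta1) / spec.k2) / spec.k1
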