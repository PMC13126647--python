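"""Conjugate Beta posteriors for the regime-value parameters.

Every conditional probability in the g-computation value formula gets an
independent Beta(1, 1) (uniform) prior.  With binomial count data the
posterior for each component is Beta(1 + successes, 1 + failures), so joint
posterior draws are formed by sampling each component independently.  From
those draws we compute the posterior probability that each stage-1 or
stage-2 option belongs to the optimal embedded regime; these probabilities
drive the response-adaptive randomizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenarios import RegimeId, RegimeParams

__all__ = [
    "CountSummary",
    "PosteriorSet",
    "posterior_params",
    "sample_theta",
    "regime_value",
    "regime_value_table",
    "stage2_value",
    "stage2_value_table",
    "optimal_regime",
    "optimal_stage2",
    "posterior_prob_stage1_optimal",
    "posterior_prob_stage2_optimal",
]


@dataclass
class CountSummary:
    """Sufficient counts for every Beta posterior, as of a given week.

    Stage-1 arrays have shape ``(k1,)``; stage-2/3 arrays ``(k1, k2)``:

    * ``n1``       patients with the stage-1 surgery decision observed
    * ``r1_plus``  of those, number who proceeded to surgery
    * ``n1_star``  stage-1 surgery patients with pCR status observed
    * ``y1_plus``  of those, number with pCR
    * ``n2``, ``r2_plus``, ``n2_star``, ``y2_plus``  stage-2 analogues
    * ``n3``       stage-3 (rescue) completers with pCR observed
    * ``y3_plus``  of those, number with pCR
    """

    n1: np.ndarray
    r1_plus: np.ndarray
    n1_star: np.ndarray
    y1_plus: np.ndarray
    n2: np.ndarray
    r2_plus: np.ndarray
    n2_star: np.ndarray
    y2_plus: np.ndarray
    n3: np.ndarray
    y3_plus: np.ndarray
    as_of_week: int | None = None

    def __post_init__(self) -> None:
        for name in ("n1", "r1_plus", "n1_star", "y1_plus",
                     "n2", "r2_plus", "n2_star", "y2_plus", "n3", "y3_plus"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.validate()

    @classmethod
    def zeros(cls, k1: int, k2: int, as_of_week: int | None = None) -> "CountSummary":
        z1 = np.zeros(k1, dtype=np.int64)
        z2 = np.zeros((k1, k2), dtype=np.int64)
        return cls(n1=z1.copy(), r1_plus=z1.copy(), n1_star=z1.copy(),
                   y1_plus=z1.copy(), n2=z2.copy(), r2_plus=z2.copy(),
                   n2_star=z2.copy(), y2_plus=z2.copy(), n3=z2.copy(),
                   y3_plus=z2.copy(), as_of_week=as_of_week)

    @property
    def k1(self) -> int:
        return self.n1.shape[0]

    @property
    def k2(self) -> int:
        return self.n2.shape[1]

    def validate(self) -> None:
        checks = [
            ("counts nonnegative", all(np.all(getattr(self, f) >= 0) for f in (
                "n1", "r1_plus", "n1_star", "y1_plus", "n2", "r2_plus",
                "n2_star", "y2_plus", "n3", "y3_plus"))),
            ("r1_plus <= n1", np.all(self.r1_plus <= self.n1)),
            ("n1_star <= r1_plus", np.all(self.n1_star <= self.r1_plus)),
            ("y1_plus <= n1_star", np.all(self.y1_plus <= self.n1_star)),
            ("r2_plus <= n2", np.all(self.r2_plus <= self.n2)),
            ("n2_star <= r2_plus", np.all(self.n2_star <= self.r2_plus)),
            ("y2_plus <= n2_star", np.all(self.y2_plus <= self.n2_star)),
            ("n3 <= n2 - r2_plus", np.all(self.n3 <= self.n2 - self.r2_plus)),
            ("y3_plus <= n3", np.all(self.y3_plus <= self.n3)),
        ]
        for label, ok in checks:
            if not ok:
                raise ValueError(f"count invariant violated: {label}")


@dataclass
class PosteriorSet:
    """Beta(alpha, beta) parameters for every component, mutually independent."""

    a_theta1: np.ndarray
    b_theta1: np.ndarray
    a_gamma1: np.ndarray
    b_gamma1: np.ndarray
    a_theta2: np.ndarray
    b_theta2: np.ndarray
    a_gamma2: np.ndarray
    b_gamma2: np.ndarray
    a_gamma3: np.ndarray
    b_gamma3: np.ndarray

    @property
    def k1(self) -> int:
        return self.a_theta1.shape[0]

    @property
    def k2(self) -> int:
        return self.a_theta2.shape[1]


def posterior_params(counts: CountSummary) -> PosteriorSet:
    """Componentwise Beta(1 + successes, 1 + failures) posteriors."""
    counts.validate()
    one = 1.0
    return PosteriorSet(
        a_theta1=one + counts.r1_plus, b_theta1=one + counts.n1 - counts.r1_plus,
        a_gamma1=one + counts.y1_plus, b_gamma1=one + counts.n1_star - counts.y1_plus,
        a_theta2=one + counts.r2_plus, b_theta2=one + counts.n2 - counts.r2_plus,
        a_gamma2=one + counts.y2_plus, b_gamma2=one + counts.n2_star - counts.y2_plus,
        a_gamma3=one + counts.y3_plus, b_gamma3=one + counts.n3 - counts.y3_plus,
    )


def sample_theta(posteriors: PosteriorSet, M: int,
                 rng: np.random.Generator) -> RegimeParams:
    """Draw ``M`` independent joint posterior realizations.

    Returns a :class:`RegimeParams` whose arrays carry a leading axis of
    length ``M`` (a struct-of-arrays representation of the draw sequence).
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    k1, k2 = posteriors.k1, posteriors.k2
    a = np.concatenate([posteriors.a_theta1, posteriors.a_gamma1,
                        posteriors.a_theta2.ravel(), posteriors.a_gamma2.ravel(),
                        posteriors.a_gamma3.ravel()])
    b = np.concatenate([posteriors.b_theta1, posteriors.b_gamma1,
                        posteriors.b_theta2.ravel(), posteriors.b_gamma2.ravel(),
                        posteriors.b_gamma3.ravel()])
    draws = rng.beta(a, b, size=(M, a.size))
    i = 0
    theta1 = draws[:, i:i + k1]; i += k1
    gamma1 = draws[:, i:i + k1]; i += k1
    theta2 = draws[:, i:i + k1 * k2].reshape(M, k1, k2); i += k1 * k2
    gamma2 = draws[:, i:i + k1 * k2].reshape(M, k1, k2); i += k1 * k2
    gamma3 = draws[:, i:i + k1 * k2].reshape(M, k1, k2)
    return RegimeParams(theta1=theta1, gamma1=gamma1, theta2=theta2,
                        gamma2=gamma2, gamma3=gamma3)


# ---------------------------------------------------------------------------
# regime values and argmaxes


def stage2_value_table(theta: RegimeParams) -> np.ndarray:
    """Stage-2-onward value mu2 = theta2*gamma2 + (1-theta2)*gamma3,
    shape ``(..., k1, k2)``."""
    return theta.theta2 * theta.gamma2 + (1.0 - theta.theta2) * theta.gamma3


def regime_value_table(theta: RegimeParams) -> np.ndarray:
    """Full regime value for every (a1, a2), shape ``(..., k1, k2)``:
    mu = theta1*gamma1 + (1 - theta1) * mu2."""
    mu2 = stage2_value_table(theta)
    head = (theta.theta1 * theta.gamma1)[..., None]
    return head + (1.0 - theta.theta1)[..., None] * mu2


def regime_value(theta: RegimeParams, regime: RegimeId | tuple[int, int]):
    """Value of one regime; scalar for point parameters, an array when
    ``theta`` carries a leading draw axis."""
    a1, a2 = regime
    out = regime_value_table(theta)[..., a1, a2]
    return float(out) if out.ndim == 0 else out


def stage2_value(theta: RegimeParams, a1: int, a2: int):
    """Stage-2-onward value with the stage-1 option held fixed."""
    out = stage2_value_table(theta)[..., a1, a2]
    return float(out) if out.ndim == 0 else out


def optimal_regime(theta: RegimeParams) -> RegimeId:
    """Exhaustive argmax of the regime value over all (a1, a2); ties broken
    lexicographically by option index."""
    table = regime_value_table(theta)
    if table.ndim != 2:
        raise ValueError("optimal_regime expects point parameters; "
                         "use posterior_prob_* for draw stacks")
    flat = int(np.argmax(table))  # row-major argmax == lexicographic tie-break
    return RegimeId(*divmod(flat, theta.k2))


def optimal_stage2(theta: RegimeParams, a1: int) -> int:
    """Argmax over stage-2 options of the stage-2-onward value, a1 fixed."""
    row = stage2_value_table(theta)[..., a1, :]
    if row.ndim != 1:
        raise ValueError("optimal_stage2 expects point parameters")
    return int(np.argmax(row))


def _optimal_flat(draws: RegimeParams) -> np.ndarray:
    """Flat (row-major) argmax regime index per draw, shape ``(M,)``."""
    table = regime_value_table(draws)
    return np.argmax(table.reshape(table.shape[0], -1), axis=1)


def posterior_prob_stage1_optimal(draws: RegimeParams) -> np.ndarray:
    """Fraction of joint draws whose optimal regime starts with each stage-1
    option; a probability vector of length ``k1``."""
    if draws.theta1.ndim != 2 or draws.theta1.shape[0] < 1:
        raise ValueError("draws must be a non-empty stack of joint samples")
    M = draws.theta1.shape[0]
    a1_opt = _optimal_flat(draws) // draws.k2
    return np.bincount(a1_opt, minlength=draws.k1) / M


def posterior_prob_stage2_optimal(draws: RegimeParams, a1: int) -> np.ndarray:
    """Fraction of joint draws whose best stage-2 option, given ``a1``, is
    each option; a probability vector of length ``k2``."""
    if draws.theta2.ndim != 3 or draws.theta2.shape[0] < 1:
        raise ValueError("draws must be a non-empty stack of joint samples")
    M = draws.theta2.shape[0]
    a2_opt = np.argmax(stage2_value_table(draws)[:, a1, :], axis=1)
    return np.bincount(a2_opt, minlength=draws.k2) / M
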