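"""Response-adaptive randomization probabilities.

Posterior probabilities that options belong to the optimal embedded regime
are turned into randomization probabilities by damping (raising to a power
``psi`` in [0, 1] and renormalizing), then clipping to an exploration box
[clip_lo, clip_hi].  ``psi = 0`` gives uniform randomization, ``psi = 1``
uses the posterior-optimality probabilities directly, and linear schedules
``psi_t = slope * t / T_end`` let adaptation grow more aggressive over the
course of enrollment.  A burn-in period keeps randomization uniform until
enough patients have entered to inform the posteriors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .posterior import (CountSummary, posterior_params,
                        posterior_prob_stage1_optimal,
                        posterior_prob_stage2_optimal, sample_theta)

__all__ = [
    "RandomizationPolicy",
    "SCHEME_LABELS",
    "psi_at",
    "damp",
    "clip_and_renormalize",
    "stage1_probs",
    "stage2_probs",
    "randomization_tables",
]

SCHEME_LABELS = ("SR", "BR(0.25)", "BR(0.5)", "BR(0.75)", "BR(1)",
                 "BR(0.5t/Tend)", "BR(t/Tend)")

_CONST_RE = re.compile(r"^BR\((\d*\.?\d+)\)$")
_LINEAR_RE = re.compile(r"^BR\((\d*\.?\d+)?\s*\*?\s*t/Tend\)$", re.IGNORECASE)


@dataclass
class RandomizationPolicy:
    """A randomization scheme plus its operating constants.

    ``kind`` is one of ``"sr"`` (uniform throughout), ``"constant"``
    (fixed damping ``psi``), or ``"linear"`` (``psi_t = psi_slope*t/T_end``,
    capped at 1).
    """

    label: str = "SR"
    kind: str = "sr"
    psi: float = 0.0
    psi_slope: float = 0.0
    clip_lo: float = 0.05
    clip_hi: float = 0.95
    burn_in_count: int = 20
    update_interval: int = 1
    M: int = 1000

    def __post_init__(self) -> None:
        if self.kind not in ("sr", "constant", "linear"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not (0.0 < self.clip_lo < self.clip_hi < 1.0):
            raise ValueError("require 0 < clip_lo < clip_hi < 1")
        if self.kind == "constant" and not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if self.kind == "linear" and not 0.0 <= self.psi_slope <= 1.0:
            raise ValueError("psi_slope must lie in [0, 1]")
        if self.burn_in_count < 0 or self.M < 1 or self.update_interval < 1:
            raise ValueError("burn_in_count >= 0, M >= 1, update_interval >= 1")

    @property
    def adaptive(self) -> bool:
        return self.kind != "sr"

    @classmethod
    def from_label(cls, label: str, **overrides) -> "RandomizationPolicy":
        """Parse a scheme label: ``"SR"``, ``"BR(0.5)"``, ``"BR(t/Tend)"``,
        ``"BR(0.5t/Tend)"`` ..."""
        text = label.strip()
        if text.upper() == "SR":
            return cls(label="SR", kind="sr", **overrides)
        m = _LINEAR_RE.match(text)
        if m:
            slope = float(m.group(1)) if m.group(1) else 1.0
            return cls(label=text, kind="linear", psi_slope=slope, **overrides)
        m = _CONST_RE.match(text)
        if m:
            return cls(label=text, kind="constant", psi=float(m.group(1)),
                       **overrides)
        raise ValueError(f"cannot parse scheme label {label!r}")

    def replace(self, **kwargs) -> "RandomizationPolicy":
        return replace(self, **kwargs)


def psi_at(policy: RandomizationPolicy, t: float, t_end: float) -> float:
    """Damping value in force at week ``t`` of a trial ending at ``t_end``."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not 0 <= t <= t_end:
        raise ValueError("require 0 <= t <= t_end")
    if policy.kind == "sr":
        return 0.0
    if policy.kind == "constant":
        return policy.psi
    return min(policy.psi_slope * t / t_end, 1.0)


def damp(rho: np.ndarray, psi: float) -> np.ndarray:
    """Normalized componentwise power rho^psi / sum(rho^psi).

    Preserves the rank order of ``rho``; psi=0 returns the uniform vector
    (0^0 taken as 1) and psi=1 returns ``rho`` unchanged.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    if not np.isclose(rho.sum(), 1.0, atol=1e-8):
        raise ValueError("rho must sum to 1")
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    powered = rho ** psi
    total = powered.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero vector")
    return powered / total


def clip_and_renormalize(pi: np.ndarray, lo: float, hi: float,
                         max_iter: int = 100) -> np.ndarray:
    """Project a probability vector into the box [lo, hi] on the simplex.

    Iterated clip-then-redistribute: entries outside the box are pinned to
    the bound and the mass surplus/deficit is redistributed among the
    entries able to absorb it, in proportion to their current mass, until a
    fixed point.  Rank order is preserved.
    """
    pi = np.asarray(pi, dtype=float)
    k = pi.size
    if not (lo * k <= 1.0 + 1e-12 and 1.0 <= hi * k + 1e-12):
        raise ValueError(f"infeasible bounds: need lo*{k} <= 1 <= hi*{k}")
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must be a probability vector")
    x = np.clip(pi, lo, hi)
    for _ in range(max_iter):
        excess = x.sum() - 1.0
        if abs(excess) < 1e-12:
            break
        if excess > 0:  # remove mass from entries above the floor
            free = x > lo + 1e-15
        else:           # add mass to entries below the ceiling
            free = x < hi - 1e-15
        if not np.any(free):
            raise ValueError("clipping cannot reach the simplex")
        x[free] -= excess * x[free] / x[free].sum()
        x = np.clip(x, lo, hi)
    return x


def randomization_tables(counts: CountSummary, policy: RandomizationPolicy,
                         t: float, t_end: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive stage-1 and stage-2 probability tables for week ``t``.

    One shared set of ``policy.M`` joint posterior draws feeds both stages:
    stage-1 probabilities come from the posterior probability that each
    stage-1 option belongs to the optimal regime; stage-2 rows (one per a1)
    from the posterior probability that each stage-2 option is best given
    a1.  Each vector is damped by ``psi_t`` and clipped.
    """
    post = posterior_params(counts)
    draws = sample_theta(post, policy.M, rng)
    psi = psi_at(policy, t, t_end)
    lo, hi = policy.clip_lo, policy.clip_hi

    rho1 = posterior_prob_stage1_optimal(draws)
    pi1 = clip_and_renormalize(damp(rho1, psi), lo, hi)

    pi2 = np.empty((counts.k1, counts.k2))
    for a1 in range(counts.k1):
        rho2 = posterior_prob_stage2_optimal(draws, a1)
        pi2[a1] = clip_and_renormalize(damp(rho2, psi), lo, hi)
    return pi1, pi2


def stage1_probs(counts: CountSummary, policy: RandomizationPolicy,
                 t: float, t_end: float, burn_in_active: bool,
                 rng: np.random.Generator) -> np.ndarray:
    """Stage-1 randomization probabilities in force at week ``t``."""
    if not policy.adaptive or burn_in_active:
        return np.full(counts.k1, 1.0 / counts.k1)
    pi1, _ = randomization_tables(counts, policy, t, t_end, rng)
    return pi1


def stage2_probs(counts: CountSummary, a1: int, policy: RandomizationPolicy,
                 t: float, t_end: float, burn_in_active: bool,
                 rng: np.random.Generator) -> np.ndarray:
    """Stage-2 randomization probabilities given stage-1 option ``a1``."""
    if not policy.adaptive or burn_in_active:
        return np.full(counts.k2, 1.0 / counts.k2)
    _, pi2 = randomization_tables(counts, policy, t, t_end, rng)
    return pi2[a1]
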