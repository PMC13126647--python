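"""Event-driven simulator for the two-stage SMART.

Patients enroll at integer weeks drawn uniformly over the accrual window and
move through up to three blocks of therapy.  Stage-1 therapy lasts ``d1``
weeks, after which the response classifier decides surgery (R1); pCR is
ascertained ``d_surgery`` weeks later for patients who proceed.  Patients
with R1 = 0 are re-randomized the same week, complete stage 2 after ``d2``
weeks (R2), and stage-2 nonresponders finish rescue therapy ``d3`` weeks
later.  Randomization-probability tables are recomputed at every integer
week from the counts observed strictly before that week and applied to all
randomizations falling in [t, t+1).

The generative model: latent pCR after stage 1 occurs with probability
``p1(a1)``; a patient with latent pCR keeps it for the rest of the trial
(her surgical pCR status is 1 whichever path she takes) and her response
indicators are drawn with probability ``lambda_sens``.  A patient without
pCR proceeds to surgery only through a classifier false positive
(probability ``1 - lambda_spec``), gains pCR at stage 2 with probability
``p2(a1, a2)``, and at rescue with probability ``p3(a1, a2)``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .posterior import CountSummary
from .randomization import RandomizationPolicy, randomization_tables
from .scenarios import ScenarioSpec

__all__ = [
    "Timing",
    "PatientRecord",
    "TrialResult",
    "draw_enrollment_weeks",
    "simulate_patient_path",
    "run_trial",
    "accumulate_counts",
    "records_to_frame",
    "records_from_frame",
    "history_to_frame",
]


@dataclass(frozen=True)
class Timing:
    """Stage durations and the surgery delay, in weeks."""

    d1: int = 12        # stage-1 therapy; R1 read at enroll + d1
    d2: int = 12        # stage-2 therapy; R2 read at enroll + d1 + d2
    d3: int = 12        # rescue therapy; Y3 read at enroll + d1 + d2 + d3
    d_surgery: int = 1  # delay from R=1 to surgery / pCR ascertainment


@dataclass
class PatientRecord:
    """One patient's latent and observed trajectory.

    Stage-2 fields are ``None`` for patients who proceed to surgery after
    stage 1; ``y2_obs`` / ``y3_obs`` are ``None`` unless observed.  Event
    weeks record when each variable becomes part of the accruing data.
    """

    patient_id: int
    enroll_week: int
    a1: int
    pi1_used: float
    y1_latent: int
    r1: int
    burn_in: bool
    week_r1: int
    y1_obs: int | None = None
    week_y1: int | None = None
    a2: int | None = None
    pi2_used: float | None = None
    week_stage2: int | None = None
    y2_latent: int | None = None
    r2: int | None = None
    week_r2: int | None = None
    y2_obs: int | None = None
    week_y2: int | None = None
    y3_obs: int | None = None
    week_y3: int | None = None
    y_final: int = 0

    def check_composition(self) -> None:
        """Final pCR must equal the stage outcome at which surgery occurred."""
        if self.r1 == 1:
            ok = self.y_final == self.y1_obs
        elif self.r2 == 1:
            ok = self.y_final == self.y2_obs
        else:
            ok = self.y_final == self.y3_obs
        if not ok:
            raise AssertionError(f"y_final composition violated: {self}")


@dataclass
class TrialResult:
    """Carrier for one simulated trial."""

    records: list[PatientRecord]
    prob1_history: np.ndarray          # (t_end, k1)
    prob2_history: np.ndarray          # (t_end, k1, k2)
    final_stage1_probs: np.ndarray
    final_stage2_probs: np.ndarray
    scenario: str
    scheme: str
    seed: int | None
    t_end: int

    def patient_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def history_frame(self) -> pd.DataFrame:
        return history_to_frame(self.prob1_history, self.prob2_history)


def draw_enrollment_weeks(n: int, t_enroll: int,
                          rng: np.random.Generator) -> np.ndarray:
    """``n`` enrollment weeks uniform on {1, ..., t_enroll}, sorted (stable)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    weeks = rng.integers(1, t_enroll + 1, size=n)
    return np.sort(weeks, kind="stable")


# ---------------------------------------------------------------------------
# single-patient generative draws (shared by the path simulator and run_trial)


def _draw_stage1(spec: ScenarioSpec, a1: int,
                 rng: np.random.Generator) -> tuple[int, int]:
    y1 = int(rng.random() < spec.p1[a1])
    p_r1 = spec.lambda_sens if y1 else 1.0 - spec.lambda_spec
    r1 = int(rng.random() < p_r1)
    return y1, r1


def _draw_stage2(spec: ScenarioSpec, a1: int, a2: int, y1_latent: int,
                 rng: np.random.Generator) -> dict:
    """Stage-2 and rescue outcomes for a patient with R1 = 0."""
    if y1_latent:
        # pCR persists: surgery at any point reveals pCR = 1
        r2 = int(rng.random() < spec.lambda_sens)
        return {"y2_latent": 1, "r2": r2,
                "y2_obs": 1 if r2 else None,
                "y3_obs": None if r2 else 1, "y_final": 1}
    y2 = int(rng.random() < spec.p2[a1, a2])
    p_r2 = spec.lambda_sens if y2 else 1.0 - spec.lambda_spec
    r2 = int(rng.random() < p_r2)
    if r2:
        return {"y2_latent": y2, "r2": 1, "y2_obs": y2, "y3_obs": None,
                "y_final": y2}
    y3 = 1 if y2 else int(rng.random() < spec.p3[a1, a2])
    return {"y2_latent": y2, "r2": 0, "y2_obs": None, "y3_obs": y3,
            "y_final": y3}


def simulate_patient_path(spec: ScenarioSpec, a1: int,
                          a2_supplier: Callable[[int, int], tuple[int, float]],
                          rng: np.random.Generator,
                          enroll_week: int = 1,
                          timing: Timing = Timing(),
                          patient_id: int = 0,
                          pi1_used: float = 1.0,
                          burn_in: bool = False) -> PatientRecord:
    """Simulate one patient given her stage-1 assignment.

    ``a2_supplier(week, a1) -> (a2, pi2_used)`` is called at the stage-2
    randomization week only if the patient does not proceed to surgery
    after stage 1.
    """
    if not 0 <= a1 < spec.k1:
        raise ValueError(f"a1={a1} outside the stage-1 option set")
    y1, r1 = _draw_stage1(spec, a1, rng)
    week_r1 = enroll_week + timing.d1
    rec = PatientRecord(patient_id=patient_id, enroll_week=enroll_week,
                        a1=a1, pi1_used=pi1_used, y1_latent=y1, r1=r1,
                        burn_in=burn_in, week_r1=week_r1)
    if r1:
        rec.y1_obs = y1
        rec.week_y1 = week_r1 + timing.d_surgery
        rec.y_final = y1
        return rec
    rec.week_stage2 = week_r1
    a2, pi2 = a2_supplier(week_r1, a1)
    rec.a2, rec.pi2_used = int(a2), float(pi2)
    out = _draw_stage2(spec, a1, rec.a2, y1, rng)
    rec.y2_latent, rec.r2 = out["y2_latent"], out["r2"]
    rec.week_r2 = enroll_week + timing.d1 + timing.d2
    if out["r2"]:
        rec.y2_obs = out["y2_obs"]
        rec.week_y2 = rec.week_r2 + timing.d_surgery
    else:
        rec.y3_obs = out["y3_obs"]
        rec.week_y3 = rec.week_r2 + timing.d3
    rec.y_final = out["y_final"]
    return rec


# ---------------------------------------------------------------------------
# counts


_STAGE1_FIELDS = (("week_r1", "r1", "n1", "r1_plus"),
                  ("week_y1", "y1_obs", "n1_star", "y1_plus"))


def accumulate_counts(records: Iterable[PatientRecord],
                      week: int | float | None = None) -> CountSummary:
    """Tally the sufficient counts from variables observed strictly before
    ``week`` (``None`` means all observations, the final data)."""
    records = list(records)
    if not records:
        raise ValueError("no records to accumulate")
    k1 = max(r.a1 for r in records) + 1
    k2 = max((r.a2 for r in records if r.a2 is not None), default=-1) + 1
    k2 = max(k2, 1)
    c = CountSummary.zeros(k1, k2, as_of_week=None if week is None else int(week))

    def seen(w: int | None) -> bool:
        return w is not None and (week is None or w < week)

    for r in records:
        if seen(r.week_r1):
            c.n1[r.a1] += 1
            c.r1_plus[r.a1] += r.r1
        if r.r1 == 1 and seen(r.week_y1):
            c.n1_star[r.a1] += 1
            c.y1_plus[r.a1] += r.y1_obs
        if r.r1 == 0 and r.a2 is not None:
            key = (r.a1, r.a2)
            if seen(r.week_r2):
                c.n2[key] += 1
                c.r2_plus[key] += r.r2
            if r.r2 == 1 and seen(r.week_y2):
                c.n2_star[key] += 1
                c.y2_plus[key] += r.y2_obs
            if r.r2 == 0 and seen(r.week_y3):
                c.n3[key] += 1
                c.y3_plus[key] += r.y3_obs
    c.validate()
    return c


# ---------------------------------------------------------------------------
# full-trial loop


def _pick(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an index from a probability vector with one uniform draw."""
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return int(np.searchsorted(cum, rng.random(), side="right"))


def run_trial(spec: ScenarioSpec, policy: RandomizationPolicy,
              seed: int | np.random.SeedSequence | None = None,
              timing: Timing = Timing()) -> TrialResult:
    """Run one trial: staggered enrollment, weekly probability updates,
    burn-in, and adaptive assignment at both stages.

    Four independent random substreams are derived from ``seed`` (enrollment,
    patient trajectories, posterior draws, assignments), so patient-level
    randomness is unchanged when the policy or ``M`` changes — supporting
    common-random-number comparisons between schemes.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng_enroll, rng_path, rng_post, rng_assign = \
        (np.random.default_rng(c) for c in ss.spawn(4))

    n, k1, k2 = spec.n_patients, spec.k1, spec.k2
    enroll = draw_enrollment_weeks(n, spec.t_enroll, rng_enroll)
    if policy.burn_in_count > 0:
        burn_week = int(enroll[min(policy.burn_in_count, n) - 1])
    else:
        burn_week = 0  # enrollment weeks start at 1, so nothing is burn-in
    t_end = spec.t_enroll + timing.d1

    uniform1 = np.full(k1, 1.0 / k1)
    uniform2 = np.full((k1, k2), 1.0 / k2)
    counts = CountSummary.zeros(k1, k2)
    obs_events: dict[int, list] = defaultdict(list)
    stage2_due: dict[int, list[int]] = defaultdict(list)
    enroll_by_week: dict[int, list[int]] = defaultdict(list)
    for pid, w in enumerate(enroll):
        enroll_by_week[int(w)].append(pid)

    records: list[PatientRecord | None] = [None] * n
    hist1 = np.tile(uniform1, (t_end, 1))
    hist2 = np.tile(uniform2, (t_end, 1, 1))

    def apply_observations(before_week: int) -> None:
        for w in [w for w in obs_events if w < before_week]:
            for kind, a1, a2, value in obs_events.pop(w):
                if kind == "r1":
                    counts.n1[a1] += 1
                    counts.r1_plus[a1] += value
                elif kind == "y1":
                    counts.n1_star[a1] += 1
                    counts.y1_plus[a1] += value
                elif kind == "r2":
                    counts.n2[a1, a2] += 1
                    counts.r2_plus[a1, a2] += value
                elif kind == "y2":
                    counts.n2_star[a1, a2] += 1
                    counts.y2_plus[a1, a2] += value
                else:
                    counts.n3[a1, a2] += 1
                    counts.y3_plus[a1, a2] += value

    pi1, pi2 = uniform1, uniform2
    for t in range(1, t_end + 1):
        apply_observations(t)
        counts.as_of_week = t
        if policy.adaptive:
            pi1, pi2 = randomization_tables(counts, policy, t, t_end, rng_post)
            hist1[t - 1] = pi1
            hist2[t - 1] = pi2

        for pid in enroll_by_week.get(t, ()):
            is_burn = enroll[pid] <= burn_week
            tab1 = uniform1 if (not policy.adaptive or is_burn) else pi1
            a1 = _pick(tab1, rng_assign)
            y1, r1 = _draw_stage1(spec, a1, rng_path)
            week_r1 = t + timing.d1
            rec = PatientRecord(patient_id=pid, enroll_week=int(t), a1=a1,
                                pi1_used=float(tab1[a1]), y1_latent=y1,
                                r1=r1, burn_in=bool(is_burn), week_r1=week_r1)
            obs_events[week_r1].append(("r1", a1, None, r1))
            if r1:
                rec.y1_obs = y1
                rec.week_y1 = week_r1 + timing.d_surgery
                rec.y_final = y1
                obs_events[rec.week_y1].append(("y1", a1, None, y1))
            else:
                rec.week_stage2 = week_r1
                stage2_due[week_r1].append(pid)
            records[pid] = rec

        for pid in stage2_due.pop(t, ()):
            rec = records[pid]
            tab2 = uniform2[rec.a1] if (not policy.adaptive or rec.burn_in) \
                else pi2[rec.a1]
            a2 = _pick(tab2, rng_assign)
            rec.a2, rec.pi2_used = a2, float(tab2[a2])
            out = _draw_stage2(spec, rec.a1, a2, rec.y1_latent, rng_path)
            rec.y2_latent, rec.r2 = out["y2_latent"], out["r2"]
            rec.week_r2 = rec.enroll_week + timing.d1 + timing.d2
            obs_events[rec.week_r2].append(("r2", rec.a1, a2, rec.r2))
            if rec.r2:
                rec.y2_obs = out["y2_obs"]
                rec.week_y2 = rec.week_r2 + timing.d_surgery
                obs_events[rec.week_y2].append(("y2", rec.a1, a2, rec.y2_obs))
            else:
                rec.y3_obs = out["y3_obs"]
                rec.week_y3 = rec.week_r2 + timing.d3
                obs_events[rec.week_y3].append(("y3", rec.a1, a2, rec.y3_obs))
            rec.y_final = out["y_final"]

    for rec in records:
        rec.check_composition()

    return TrialResult(records=list(records), prob1_history=hist1,
                       prob2_history=hist2, final_stage1_probs=hist1[-1].copy(),
                       final_stage2_probs=hist2[-1].copy(),
                       scenario=spec.name, scheme=policy.label,
                       seed=None if isinstance(seed, np.random.SeedSequence) else seed,
                       t_end=t_end)


# ---------------------------------------------------------------------------
# flat-table serialization

_COLUMNS = ["patient_id", "enroll_week", "burn_in", "a1", "pi1_used",
            "y1_latent", "r1", "week_r1", "y1_obs", "week_y1",
            "a2", "pi2_used", "week_stage2", "y2_latent", "r2", "week_r2",
            "y2_obs", "week_y2", "y3_obs", "week_y3", "y_final"]

_INT_COLUMNS = ["patient_id", "enroll_week", "a1", "y1_latent", "r1",
                "week_r1", "y1_obs", "week_y1", "a2", "week_stage2",
                "y2_latent", "r2", "week_r2", "y2_obs", "week_y2",
                "y3_obs", "week_y3", "y_final"]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """One row per patient; missing stage-2 fields become NA."""
    rows = [{c: getattr(r, c) for c in _COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    for c in _INT_COLUMNS:
        df[c] = df[c].astype("Int64")
    df["burn_in"] = df["burn_in"].astype(bool)
    return df


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame` (CSV round trip)."""
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _COLUMNS:
            v = row[c]
            if pd.isna(v):
                kwargs[c] = None
            elif c in _INT_COLUMNS:
                kwargs[c] = int(v)
            elif c == "burn_in":
                kwargs[c] = bool(v)
            else:
                kwargs[c] = float(v)
        out.append(PatientRecord(**kwargs))
    return out


def history_to_frame(prob1: np.ndarray, prob2: np.ndarray) -> pd.DataFrame:
    """Per-week probability tables, one row per week."""
    t_end, k1 = prob1.shape
    k2 = prob2.shape[2]
    data = {"week": np.arange(1, t_end + 1)}
    for a1 in range(k1):
        data[f"pi1_{a1}"] = prob1[:, a1]
    for a1 in range(k1):
        for a2 in range(k2):
            data[f"pi2_{a1}_{a2}"] = prob2[:, a1, a2]
    return pd.DataFrame(data)
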