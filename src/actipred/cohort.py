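"""Synthetic inpatient cohort generator.

Emulates minute-level activity-state streams for a ward of depressed
inpatients observed over a daily 2-hour unstructured block.  Each patient
carries a latent linear trend of normalized activity against Progress
Towards Discharge (PTD = day of admission / total length of stay):

    fraction_ij = w_j . (1, ptd_ij) + eps_ij,   w_j ~ N(mu_w, Sigma_w)

The realized fraction drives an alternating activity/rest bout process whose
per-minute states are drawn from the five activity-recognition labels
(running, walking, standing, sitting, lying).  The true per-patient weights
are retained so model-recovery experiments can compare estimates against
generative truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ACTIVITY_STATES: tuple[str, ...] = ("running", "walking", "standing")
REST_STATES: tuple[str, ...] = ("sitting", "lying")
ALL_STATES: tuple[str, ...] = ACTIVITY_STATES + REST_STATES

# How minutes inside each broad category split across concrete labels.
# Acute depressed inpatients essentially never run; walking/standing dominate.
_ACTIVITY_MIX = (0.02, 0.48, 0.50)
_REST_MIX = (0.45, 0.55)


def _as_matrix(sigma_w) -> np.ndarray:
    m = np.asarray(sigma_w, dtype=float)
    if m.shape == ():
        m = np.eye(2) * float(m)
    if m.shape != (2, 2):
        raise ValueError(f"sigma_w must be 2x2, got shape {m.shape}")
    return m


@dataclass
class CohortConfig:
    """Generative truth for one synthetic cohort.

    Defaults mirror the study regime: 23 patients, lengths of stay 5-64 days
    with median ~20.5 (clipped log-normal), population activity trend
    mu_w = (0.445, 0.123) on the normalized 0-1 activity scale, and
    day-level noise sigma_eps = 0.28 (~8.4 min on the 0-30 minute scale).
    """

    n_patients: int = 23
    los_min: int = 5
    los_max: int = 64
    los_log_mean: float = math.log(20.5)
    los_log_sd: float = 0.65
    mu_w: tuple[float, float] = (0.445, 0.123)
    sigma_w: object = field(default_factory=lambda: np.diag([0.01, 0.017]))
    sigma_eps: float = 0.28
    window_minutes: int = 120
    mean_bout_minutes: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sigma_w = _as_matrix(self.sigma_w)
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (1 <= self.los_min <= self.los_max):
            raise ValueError("need 1 <= los_min <= los_max")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if self.window_minutes < 30:
            raise ValueError("window_minutes must be >= 30")
        if self.mean_bout_minutes < 1:
            raise ValueError("mean_bout_minutes must be >= 1")
        eig = np.linalg.eigvalsh(self.sigma_w)
        if not np.allclose(self.sigma_w, self.sigma_w.T) or eig.min() < -1e-10:
            raise ValueError("sigma_w must be symmetric positive semi-definite")


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    w_true: tuple[float, float]
    length_of_stay: int
    archetype: int = 0


@dataclass(frozen=True)
class DayStateSequence:
    patient_id: str
    doa: int
    states: tuple[str, ...]


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[PatientTruth]
    days: list[DayStateSequence]

    def states_frame(self) -> pd.DataFrame:
        """Long table: patient_id, doa, minute_index, state."""
        rows = {
            "patient_id": [], "doa": [], "minute_index": [], "state": [],
        }
        for day in self.days:
            n = len(day.states)
            rows["patient_id"].extend([day.patient_id] * n)
            rows["doa"].extend([day.doa] * n)
            rows["minute_index"].extend(range(n))
            rows["state"].extend(day.states)
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "intercept_true": [p.w_true[0] for p in self.patients],
                "slope_true": [p.w_true[1] for p in self.patients],
                "length_of_stay": [p.length_of_stay for p in self.patients],
                "archetype": [p.archetype for p in self.patients],
            }
        )


def sample_patient_truth(
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str = "p00",
    archetype: int = 0,
) -> PatientTruth:
    """Draw one patient's latent trend and length of stay.

    w_true ~ N(mu_w, Sigma_w); length of stay from the log-normal law
    clipped to [los_min, los_max] and rounded to whole days.
    """
    w = rng.multivariate_normal(np.asarray(config.mu_w, float), config.sigma_w)
    los = float(np.exp(rng.normal(config.los_log_mean, config.los_log_sd)))
    los = int(round(min(max(los, config.los_min), config.los_max)))
    los = min(max(los, config.los_min), config.los_max)
    return PatientTruth(patient_id, (float(w[0]), float(w[1])), los, archetype)


def target_activity_fraction(
    truth: PatientTruth,
    ptd: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> float:
    """The day's intended fraction of minutes in activity-category states.

    clip(w_true . (1, ptd) + eps, 0, 1) with eps ~ N(0, sigma_eps^2).
    """
    if not (0 < ptd <= 1):
        raise ValueError("ptd must lie in (0, 1]")
    w0, w1 = truth.w_true
    eps = rng.normal(0.0, config.sigma_eps) if config.sigma_eps > 0 else 0.0
    return float(np.clip(w0 + w1 * ptd + eps, 0.0, 1.0))


def generate_day_states(
    fraction: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Realize one day's minute-level state labels.

    The activity/rest category alternates in geometric bouts whose means are
    scaled so the stationary activity occupancy equals `fraction` exactly
    (geometric bouts are memoryless, so starting the first bout from the
    stationary category distribution keeps every minute at that occupancy).
    Within each category, labels are drawn from a fixed mix.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    n = config.window_minutes
    if fraction <= 0.0:
        cat = np.zeros(n, dtype=bool)
    elif fraction >= 1.0:
        cat = np.ones(n, dtype=bool)
    else:
        b = config.mean_bout_minutes
        m_act = 2.0 * b * fraction
        m_rest = 2.0 * b * (1.0 - fraction)
        # geometric bouts need mean >= 1; rescale both to preserve the ratio
        lo = min(m_act, m_rest)
        if lo < 1.0:
            m_act /= lo
            m_rest /= lo
        cat = np.empty(n, dtype=bool)
        active = bool(rng.random() < fraction)
        i = 0
        while i < n:
            mean = m_act if active else m_rest
            bout = int(rng.geometric(1.0 / mean))
            cat[i : i + bout] = active
            i += bout
            active = not active
    labels = np.empty(n, dtype=object)
    n_act = int(cat.sum())
    if n_act:
        labels[cat] = rng.choice(ACTIVITY_STATES, size=n_act, p=_ACTIVITY_MIX)
    if n_act < n:
        labels[~cat] = rng.choice(REST_STATES, size=n - n_act, p=_REST_MIX)
    return tuple(labels)


def generate_cohort(config: CohortConfig, archetype: int = 0) -> Cohort:
    """Generate a full cohort, deterministic in (config, config.seed)."""
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_patients)
    width = max(2, len(str(config.n_patients - 1)))
    patients: list[PatientTruth] = []
    days: list[DayStateSequence] = []
    for k, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"p{k:0{width}d}"
        truth = sample_patient_truth(config, rng, pid, archetype)
        patients.append(truth)
        for doa in range(1, truth.length_of_stay + 1):
            ptd = doa / truth.length_of_stay
            frac = target_activity_fraction(truth, ptd, config, rng)
            states = generate_day_states(frac, config, rng)
            days.append(DayStateSequence(pid, doa, states))
    return Cohort(config, patients, days)


def two_archetype_configs(n_per_arm: int = 4) -> list[CohortConfig]:
    """Canonical clustered-ward condition: fast improvers vs. slow improvers.

    Arm 0: short stays (~1 week), high and steeply rising activity.
    Arm 1: long stays (~4 weeks), low activity rising slowly.  Within-arm
    heterogeneity and day noise are kept small so the arms are genuinely
    distinct trajectories rather than one smeared population.
    """
    short = CohortConfig(
        n_patients=n_per_arm, los_min=5, los_max=10,
        los_log_mean=math.log(7.0), los_log_sd=0.2,
        mu_w=(0.62, 0.28), sigma_w=np.diag([0.002, 0.002]), sigma_eps=0.05,
    )
    long = CohortConfig(
        n_patients=n_per_arm, los_min=20, los_max=40,
        los_log_mean=math.log(27.0), los_log_sd=0.15,
        mu_w=(0.22, 0.12), sigma_w=np.diag([0.002, 0.002]), sigma_eps=0.05,
    )
    return [short, long]


def generate_clustered_cohort(
    archetypes: Sequence[CohortConfig], seed: int = 0
) -> Cohort:
    """Concatenate one sub-cohort per archetype config (distinct patient ids).

    Used for experiments where the ward mixes distinct clinical trajectories,
    e.g. short-stay fast improvers vs. long-stay slow improvers.
    """
    if len(archetypes) < 2:
        raise ValueError("need >= 2 archetype configs")
    patients: list[PatientTruth] = []
    days: list[DayStateSequence] = []
    base = archetypes[0]
    for a, cfg_a in enumerate(archetypes):
        sub_cfg = CohortConfig(
            **{**cfg_a.__dict__, "seed": seed * 1009 + a}
        )
        sub = generate_cohort(sub_cfg, archetype=a)
        rename = {p.patient_id: f"a{a}_{p.patient_id}" for p in sub.patients}
        patients.extend(
            PatientTruth(rename[p.patient_id], p.w_true, p.length_of_stay, a)
            for p in sub.patients
        )
        days.extend(
            DayStateSequence(rename[d.patient_id], d.doa, d.states)
            for d in sub.days
        )
    return Cohort(base, patients, days)
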