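"""Hierarchical Gaussian-process prediction of admission progress and discharge.

The regression target is PTD (Progress Towards Discharge) as a function of
the day's Activity Time, Rest Time and day of admission (DoA).  Two additive
GP levels share the work:

    y = g(x) + f_n(x) + noise

where g ~ GP(0, k_g) is an upper-level function common to the whole ward and
f_n ~ GP(0, k_f) are independent per-patient deviations.  Marginally this is
one Gaussian over all training days whose covariance is k_g everywhere plus
k_f between days of the same patient plus noise on the diagonal.  Both
kernels are squared-exponential with per-dimension lengthscales on
standardized inputs; hyperparameters maximize the joint log marginal
likelihood (multi-restart L-BFGS with analytic gradients).

Discharge estimation for a new patient runs a recursive similarity search:
each day, the training patient under whose posterior the new patient's
accumulated days are most probable is selected (leave-one-out probability
maximization), the selected patient's deviation is borrowed to predict
today's PTD, and the estimated total stay is DoA / PTD.  Because the new
patient's true PTD is unknown during the stay, each candidate n is scored
against the targets the new patient would have if they shared n's course,
Y_i = doa_i / L_n (L_n the candidate's known length of stay): the candidate
whose activity-to-progress relation makes the new patient's days most
probable wins.  Scoring a guessed trajectory shared by all candidates
instead would systematically favour candidates with vague (high-variance)
predictions over near-misses, which inverts the archetype match.

By default the two kernels are isotropic on standardized inputs (one
lengthscale per level).  With independent per-dimension lengthscales the
marginal likelihood prunes the activity inputs entirely — within a patient
PTD is an exact function of DoA, so the per-patient level can memorize it —
leaving the similarity search blind to activity; tying the lengthscales
keeps activity in the metric.  Per-dimension scaling remains available via
``ard=True``.  A noise floor prevents the matching zero-noise memorization
collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

FEATURE_COLS = ["activity_time", "rest_time", "doa"]
LOS_CAP = 64  # largest observed length of stay; floors predicted PTD at doa/64


@dataclass
class KernelSpec:
    upper_variance: float = 0.1
    upper_lengthscales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lower_variance: float = 0.03
    lower_lengthscales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_variance: float = 0.01

    def __post_init__(self):
        ls = list(self.upper_lengthscales) + list(self.lower_lengthscales)
        if any(v <= 0 for v in ls):
            raise ValueError("lengthscales must be > 0")
        if self.upper_variance <= 0 or self.noise_variance <= 0:
            raise ValueError("variances must be > 0")
        if self.lower_variance < 0:
            raise ValueError("lower_variance must be >= 0")

    def to_log_vector(self) -> np.ndarray:
        return np.log(
            np.array(
                [self.upper_variance, *self.upper_lengthscales,
                 max(self.lower_variance, 1e-12), *self.lower_lengthscales,
                 self.noise_variance]
            )
        )

    @classmethod
    def from_log_vector(cls, theta: np.ndarray) -> "KernelSpec":
        v = np.exp(np.asarray(theta, float))
        return cls(v[0], tuple(v[1:4]), v[4], tuple(v[5:8]), v[8])


@dataclass
class PTDPrediction:
    mean: float
    sd: float
    interval: tuple[float, float] = field(init=False)

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        self.interval = (self.mean - self.sd, self.mean + self.sd)


@dataclass
class DischargeEstimate:
    doa: int
    ptd_hat: float
    total_hat: float
    remaining_hat: float
    ptd_sd: float = 0.0
    selected_patient: Optional[str] = None
    patient_id: Optional[str] = None
    error: Optional[float] = None


def _sqdists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-dimension squared distances, shape (len(a), len(b), d)."""
    return (a[:, None, :] - b[None, :, :]) ** 2


def _rbf(sq: np.ndarray, variance: float, lengthscales) -> np.ndarray:
    ls = np.asarray(lengthscales, float)
    return variance * np.exp(-0.5 * np.sum(sq / ls**2, axis=2))


def _chol_with_jitter(k: np.ndarray, base: float = 1e-8, top: float = 1e-4):
    jitter = base
    while jitter <= top:
        try:
            return cho_factor(k + jitter * np.eye(k.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        "covariance not positive definite after jitter escalation to "
        f"{top:g}; condition number ~{np.linalg.cond(k):.3g}"
    )


@dataclass
class HGPModel:
    x_train: np.ndarray          # standardized inputs, (n, 3)
    y_train: np.ndarray          # centered PTD targets, (n,)
    groups: np.ndarray           # patient id per row, (n,)
    spec: KernelSpec
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    lengths: dict = field(default_factory=dict)  # patient id -> length of stay
    log_marginal: float = 0.0
    _chol: object = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)
    _sq: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self._sq = _sqdists(self.x_train, self.x_train)
        mask = self.groups[:, None] == self.groups[None, :]
        k = self._cov(mask)
        self._chol, _ = _chol_with_jitter(k)
        self._alpha = cho_solve(self._chol, self.y_train)

    def _cov(self, mask: np.ndarray) -> np.ndarray:
        k = _rbf(self._sq, self.spec.upper_variance, self.spec.upper_lengthscales)
        k = k + mask * _rbf(self._sq, self.spec.lower_variance,
                            self.spec.lower_lengthscales)
        k[np.diag_indices_from(k)] += self.spec.noise_variance
        return k

    @property
    def patient_ids(self) -> list:
        return sorted(set(self.groups.tolist()))

    def standardize(self, x_raw: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x_raw, float))
        return (x - self.x_mean) / self.x_std

    def cross_cov(self, x_new_std: np.ndarray, patient_id: Optional[str]) -> np.ndarray:
        """k_g to every training day, plus k_f to the chosen patient's days."""
        sq = _sqdists(x_new_std, self.x_train)
        ks = _rbf(sq, self.spec.upper_variance, self.spec.upper_lengthscales)
        if patient_id is not None:
            sel = self.groups == patient_id
            if not sel.any():
                raise KeyError(f"unknown patient id: {patient_id!r}")
            ks[:, sel] += _rbf(
                sq[:, sel, :], self.spec.lower_variance,
                self.spec.lower_lengthscales,
            )
        return ks


def _neg_log_marginal(theta, sq, mask, y):
    spec = KernelSpec.from_log_vector(theta)
    ls_u = np.asarray(spec.upper_lengthscales)
    ls_l = np.asarray(spec.lower_lengthscales)
    kg = _rbf(sq, spec.upper_variance, ls_u)
    kf = mask * _rbf(sq, spec.lower_variance, ls_l)
    k = kg + kf
    k[np.diag_indices_from(k)] += spec.noise_variance
    try:
        chol, _ = _chol_with_jitter(k)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    alpha = cho_solve(chol, y)
    n = len(y)
    nll = 0.5 * y @ alpha + np.sum(np.log(np.diag(chol[0]))) \
        + 0.5 * n * np.log(2.0 * np.pi)
    kinv = cho_solve(chol, np.eye(n))
    w = np.outer(alpha, alpha) - kinv  # d(lml)/dK = 0.5 * w
    grad = np.empty(9)
    grad[0] = 0.5 * np.sum(w * kg)
    for d in range(3):
        grad[1 + d] = 0.5 * np.sum(w * kg * sq[:, :, d] / ls_u[d] ** 2)
    grad[4] = 0.5 * np.sum(w * kf)
    for d in range(3):
        grad[5 + d] = 0.5 * np.sum(w * kf * sq[:, :, d] / ls_l[d] ** 2)
    grad[8] = 0.5 * spec.noise_variance * np.trace(w)
    return float(nll), -grad


# full 9-parameter box; the isotropic path maps 5 tied parameters into it
def _bounds(noise_floor: float):
    return (
        [(np.log(1e-6), np.log(1e3))]
        + [(np.log(0.05), np.log(30.0))] * 3
        + [(np.log(1e-9), np.log(1e3))]
        + [(np.log(0.05), np.log(30.0))] * 3
        + [(np.log(noise_floor), np.log(10.0))]
    )


# rows: tied parameters (uv, ls_upper, lv, ls_lower, nv); columns: full theta
_TIE = np.zeros((5, 9))
_TIE[0, 0] = 1.0
_TIE[1, 1:4] = 1.0
_TIE[2, 4] = 1.0
_TIE[3, 5:8] = 1.0
_TIE[4, 8] = 1.0


def fit_hgp(
    features: pd.DataFrame,
    spec: Optional[KernelSpec] = None,
    optimize: bool = True,
    ard: bool = False,
    n_restarts: int = 5,
    maxiter: int = 200,
    noise_floor: float = 1e-3,
    seed: int = 0,
) -> HGPModel:
    """Fit the two-level GP to a feature table (requires known PTD targets).

    Inputs are standardized to zero mean / unit variance with training
    statistics; targets are centered.  By default both kernels are isotropic
    (one lengthscale per level); ``ard=True`` frees per-dimension
    lengthscales.  ``noise_floor`` bounds the observation-noise variance away
    from the degenerate interpolation regime.  With ``optimize=False`` the
    supplied KernelSpec is used as-is (useful for controlled experiments).
    """
    feats = features.dropna(subset=["ptd"])
    counts = feats.groupby("patient_id").size()
    if (counts < 2).any() or len(counts) < 1:
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"every patient needs >= 2 days with known PTD; bad: {bad}")
    x_raw = feats[FEATURE_COLS].to_numpy(float)
    y_raw = feats["ptd"].to_numpy(float)
    groups = feats["patient_id"].to_numpy()
    x_mean = x_raw.mean(axis=0)
    x_std = x_raw.std(axis=0)
    x_std[x_std == 0] = 1.0
    y_mean = float(y_raw.mean())
    x = (x_raw - x_mean) / x_std
    y = y_raw - y_mean
    vy = max(float(y.var()), 1e-4)
    if spec is None:
        spec = KernelSpec(vy, (1.0, 1.0, 1.0), 0.3 * vy, (1.0, 1.0, 1.0),
                          max(0.1 * vy, noise_floor))
    # length of stay per training patient, implied by doa/ptd
    lengths = {
        pid: float(np.median(grp["doa"].to_numpy(float) / grp["ptd"].to_numpy(float)))
        for pid, grp in feats.groupby("patient_id")
    }
    best_theta = spec.to_log_vector()
    if optimize:
        sq = _sqdists(x, x)
        mask = groups[:, None] == groups[None, :]
        rng = np.random.default_rng(seed)
        bounds9 = _bounds(noise_floor)
        if ard:
            bounds = bounds9
            expand = np.eye(9)
        else:
            # tie lengthscales within each level: optimize 5 parameters
            bounds = [bounds9[i] for i in (0, 1, 4, 5, 8)]
            expand = _TIE
        norm = expand.sum(axis=1)

        def objective(theta_small):
            nll, g9 = _neg_log_marginal(expand.T @ theta_small, sq, mask, y)
            return nll, expand @ g9

        theta_full0 = np.clip(
            spec.to_log_vector(),
            [b[0] for b in bounds9], [b[1] for b in bounds9],
        )
        theta_small0 = (expand @ theta_full0) / norm
        best_nll = np.inf
        best_small = theta_small0
        for r in range(max(1, n_restarts)):
            t0 = theta_small0 if r == 0 else (
                theta_small0 + rng.normal(0.0, 0.7, size=theta_small0.shape)
            )
            t0 = np.clip(t0, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(
                objective, t0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
            if res.fun < best_nll:
                best_nll, best_small = res.fun, res.x
        best_theta = expand.T @ best_small
        spec = KernelSpec.from_log_vector(best_theta)
    model = HGPModel(x, y, groups, spec, x_mean, x_std, y_mean, lengths)
    mask = groups[:, None] == groups[None, :]
    nll, _ = _neg_log_marginal(spec.to_log_vector(), model._sq, mask, y)
    model.log_marginal = -nll
    return model


def predict_ptd(
    model: HGPModel, patient_id: Optional[str], x_new, include_noise: bool = False
) -> PTDPrediction:
    """Posterior predictive PTD at one input, borrowing `patient_id`'s deviation.

    The predictive conditions on all training days; `patient_id` determines
    which lower-level function the point is attributed to (None: upper level
    only).  The 78% interval is mean ± one predictive SD.
    """
    mean, sd = predict_ptd_batch(model, patient_id, np.atleast_2d(x_new),
                                 include_noise=include_noise)
    return PTDPrediction(float(mean[0]), float(sd[0]))


def predict_ptd_batch(model, patient_id, x_new, include_noise=False):
    xs = model.standardize(x_new)
    ks = model.cross_cov(xs, patient_id)
    mean = ks @ model._alpha + model.y_mean
    v = cho_solve(model._chol, ks.T)
    prior = model.spec.upper_variance + (
        model.spec.lower_variance if patient_id is not None else 0.0
    )
    var = prior - np.sum(ks.T * v, axis=0)
    if include_noise:
        var = var + model.spec.noise_variance
    return mean, np.sqrt(np.clip(var, 0.0, None))


def patient_loglik(model: HGPModel, patient_id: str, x_new, y_new) -> float:
    """Log predictive density of new (X, Y) days under one patient's posterior.

    The new days are treated as further observations of `patient_id` (upper
    level plus that patient's deviation plus observation noise), conditioned
    on the whole training set.
    """
    y_new = np.atleast_1d(np.asarray(y_new, float))
    xs = model.standardize(x_new)
    if len(xs) != len(y_new):
        raise ValueError("x_new and y_new must have equal length")
    ks = model.cross_cov(xs, patient_id)
    sq = _sqdists(xs, xs)
    kss = _rbf(sq, model.spec.upper_variance, model.spec.upper_lengthscales) \
        + _rbf(sq, model.spec.lower_variance, model.spec.lower_lengthscales)
    kss[np.diag_indices_from(kss)] += model.spec.noise_variance
    mean = ks @ model._alpha + model.y_mean
    v = cho_solve(model._chol, ks.T)
    cov = kss - ks @ v
    chol, _ = _chol_with_jitter(cov)
    resid = y_new - mean
    alpha = cho_solve(chol, resid)
    return float(
        -0.5 * resid @ alpha - np.sum(np.log(np.diag(chol[0])))
        - 0.5 * len(y_new) * np.log(2.0 * np.pi)
    )


def select_similar_patient(model: HGPModel, x_new, y_new) -> str:
    """Training patient maximizing the predictive log-density of the new days.

    Ties break toward the smallest patient id (deterministic).
    """
    best_id, best_ll = None, -np.inf
    for pid in model.patient_ids:
        ll = patient_loglik(model, pid, x_new, y_new)
        if ll > best_ll + 1e-12:
            best_id, best_ll = pid, ll
    return best_id


def select_by_implied_course(model: HGPModel, x_new, doas) -> str:
    """Similarity selection when the new patient's PTD is unknown.

    Candidate n is scored with the targets the new patient would carry if
    they followed n's course — Y_i = min(1, doa_i / L_n), with L_n the
    candidate's own length of stay — so the score asks: under patient n's
    posterior, how probable is this activity pattern at n's pace of
    progress?  The alternative of scoring one guessed trajectory shared by
    all candidates rewards candidates whose predictions are merely vague.
    Ties break toward the smallest patient id.
    """
    doas = np.atleast_1d(np.asarray(doas, float))
    best_id, best_ll = None, -np.inf
    for pid in model.patient_ids:
        length = model.lengths.get(pid)
        if length is None or length <= 0:
            raise ValueError(f"no length of stay recorded for patient {pid!r}")
        implied = np.minimum(1.0, doas / length)
        ll = patient_loglik(model, pid, x_new, implied)
        if ll > best_ll + 1e-12:
            best_id, best_ll = pid, ll
    return best_id


def estimate_discharge(
    doa: int,
    pred: PTDPrediction,
    true_length: Optional[float] = None,
    los_cap: int = LOS_CAP,
    patient_id: Optional[str] = None,
    selected_patient: Optional[str] = None,
) -> DischargeEstimate:
    """Convert a PTD prediction at day `doa` into a discharge-date estimate.

    total_hat = doa / ptd_hat with ptd_hat clipped to [doa/los_cap, 1]; the
    floor (doa over the largest observed stay, 64 days) prevents unbounded
    estimates when the predicted progress is near or below zero.  The signed
    error is estimated minus real length: negative means discharge was
    predicted earlier than observed.
    """
    if doa < 1:
        raise ValueError("doa must be >= 1")
    if pred.mean <= 0:
        logger.info("non-positive predicted PTD %.3g at day %d clipped", pred.mean, doa)
    lo = min(1.0, doa / los_cap)
    ptd_hat = float(np.clip(pred.mean, lo, 1.0))
    total = doa / ptd_hat
    err = (total - true_length) if true_length is not None else None
    return DischargeEstimate(
        doa=doa, ptd_hat=ptd_hat, total_hat=total, remaining_hat=total - doa,
        ptd_sd=pred.sd, selected_patient=selected_patient,
        patient_id=patient_id, error=err,
    )


def recursive_predict(
    model: HGPModel,
    new_patient_days: pd.DataFrame,
    true_length: Optional[float] = None,
    los_cap: int = LOS_CAP,
) -> list[DischargeEstimate]:
    """Per-day discharge estimates for a new patient, in admission order.

    At day d the accumulated days 1..d are scored against every training
    patient: candidate n is evaluated on the targets the new patient would
    have if they shared n's course, Y_i = doa_i / L_n, under n's posterior
    (see `select_by_implied_course`).  The most similar patient's deviation
    is borrowed, today's PTD prediction is converted to a discharge date,
    and the output at day d depends only on days <= d.
    """
    days = new_patient_days
    doas = days["doa"].to_numpy(int)
    if len(doas) == 0:
        return []
    if not np.all(np.diff(doas) > 0):
        raise ValueError("days must arrive in strictly increasing doa order")
    x_all = days[FEATURE_COLS].to_numpy(float)
    pid = days["patient_id"].iloc[0] if "patient_id" in days else None
    estimates: list[DischargeEstimate] = []
    for d in range(1, len(doas) + 1):
        sel = select_by_implied_course(model, x_all[:d], doas[:d])
        pred = predict_ptd(model, sel, x_all[d - 1])
        estimates.append(
            estimate_discharge(
                int(doas[d - 1]), pred, true_length=true_length,
                los_cap=los_cap, patient_id=pid, selected_patient=sel,
            )
        )
    return estimates
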