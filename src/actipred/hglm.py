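"""Two-level hierarchical Bayesian linear model of activity vs. admission progress.

Model, per patient j and day i:

    y_ij = w_j^T x_ij + eps_ij,   eps_ij ~ N(0, sigma_eps^2)
    w_j ~ N(mu_w, Sigma_w)

with x_ij = (1, ptd_ij) and y_ij the normalized Activity Time
(minutes / 30).  The population parameters (mu_w, Sigma_w, sigma_eps^2) are
estimated by empirical Bayes: an exact generalized-least-squares update for
mu_w interleaved with a conjugate-Gaussian EM step for Sigma_w and
sigma_eps^2.  Every step is a coordinate-ascent / EM step on the log
marginal likelihood, so the objective is non-decreasing across iterations.
Because the design has rank 2, all marginal quantities reduce to 2x2
sufficient statistics (X^T X, X^T y, y^T y) via the Woodbury identity, which
keeps the many EM iterations the variance components need essentially free.

The study's "78% credible interval" is taken at its operational definition,
[mu - sigma, mu + sigma]; for the population trend the sigma is the
between-patient spread sqrt(diag(Sigma_w)) (the band that brackets the
individual patients' lines), exposed via `population_interval`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

_JITTER = 1e-12
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HGLMData:
    """Per-patient design/response arrays: x = PTD, y = activity_time / 30."""

    patient_ids: list
    x: list  # list of 1-d arrays
    y: list  # list of 1-d arrays

    def __post_init__(self):
        if len(self.x) != len(self.y) or len(self.x) != len(self.patient_ids):
            raise ValueError("patient_ids, x, y must have equal length")
        self.x = [np.asarray(v, float) for v in self.x]
        self.y = [np.asarray(v, float) for v in self.y]
        for pid, xv, yv in zip(self.patient_ids, self.x, self.y):
            if xv.shape != yv.shape:
                raise ValueError(f"x/y length mismatch for patient {pid}")
            if xv.size < 2:
                raise ValueError(f"patient {pid} has < 2 observations")
        # rank-2 sufficient statistics, fixed for the whole fit
        self.xtx = np.stack([xm.T @ xm for xm in self.designs()])
        self.xty = np.stack([xm.T @ yv for xm, yv in zip(self.designs(), self.y)])
        self.yty = np.array([float(yv @ yv) for yv in self.y])
        self.n_obs = np.array([len(yv) for yv in self.y])

    @classmethod
    def from_features(cls, features: pd.DataFrame, y_scale: float = 30.0) -> "HGLMData":
        feats = features.dropna(subset=["ptd"])
        ids, xs, ys = [], [], []
        for pid, grp in feats.groupby("patient_id", sort=True):
            if len(grp) < 2:
                warnings.warn(f"patient {pid} excluded: < 2 observations")
                continue
            ids.append(pid)
            xs.append(grp["ptd"].to_numpy(float))
            ys.append(grp["activity_time"].to_numpy(float) / y_scale)
        return cls(ids, xs, ys)

    def designs(self) -> list:
        return [np.column_stack([np.ones_like(xv), xv]) for xv in self.x]


@dataclass
class HGLMHyper:
    mu_w: np.ndarray
    sigma_w: np.ndarray
    sigma_eps2: float

    def __post_init__(self):
        self.mu_w = np.asarray(self.mu_w, float).reshape(2)
        self.sigma_w = np.asarray(self.sigma_w, float).reshape(2, 2)
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be > 0")
        eig = np.linalg.eigvalsh(self.sigma_w)
        if eig.min() < -1e-10:
            raise ValueError("sigma_w must be positive semi-definite")


@dataclass
class HGLMPosterior:
    patient_ids: list
    means: dict          # patient_id -> (2,) posterior mean of w_j
    covs: dict           # patient_id -> (2,2) posterior covariance
    hyper: HGLMHyper
    mu_cov: np.ndarray   # GLS covariance of the mu_w estimate
    log_marginal: float
    trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def _spd_inv(a: np.ndarray) -> np.ndarray:
    a = a + _JITTER * np.eye(a.shape[0])
    c = cho_factor(a, lower=True)
    return cho_solve(c, np.eye(a.shape[0]))


def _woodbury(data: HGLMData, hyper: HGLMHyper):
    """Batched Woodbury factors for S_j = X_j Sigma_w X_j^T + eps I.

    Returns (C, logdet) with C_j = (Sigma_w^{-1} + X^T X / eps)^{-1} / eps
    (shape (J, 2, 2)) so that v^T S_j^{-1} u = [v^T u - (X^T v)^T C_j
    (X^T u)] / eps for vectors in observation space, and logdet_j = log|S_j|.
    The form C_j = Sigma_w (eps I + X^T X Sigma_w)^{-1} avoids inverting
    Sigma_w, so the degenerate Sigma_w -> 0 limit is exact.
    """
    eps = hyper.sigma_eps2
    sig = hyper.sigma_w
    b = eps * np.eye(2) + data.xtx @ sig
    c = np.einsum("ab,jbc->jac", sig, np.linalg.inv(b))
    c = 0.5 * (c + np.transpose(c, (0, 2, 1)))
    logdet = (data.n_obs - 2) * np.log(eps) + np.log(np.abs(np.linalg.det(b)))
    return c, logdet


def log_marginal_likelihood(data: HGLMData, hyper: HGLMHyper) -> float:
    """Sum over patients of log N(y_j; X_j mu_w, X_j Sigma_w X_j^T + sigma_eps^2 I)."""
    eps = hyper.sigma_eps2
    mu = hyper.mu_w
    c, logdet = _woodbury(data, hyper)
    xtr = data.xty - data.xtx @ mu             # X^T (y - X mu), (J, 2)
    rtr = data.yty - 2.0 * data.xty @ mu + np.einsum("a,jab,b->j", mu, data.xtx, mu)
    quad = (rtr - np.einsum("ja,jab,jb->j", xtr, c, xtr)) / eps
    return float(-0.5 * np.sum(quad + logdet + data.n_obs * _LOG2PI))


def _posterior_arrays(data: HGLMData, hyper: HGLMHyper):
    """Conjugate per-patient posteriors as stacked arrays.

    Equivalent to precision Sigma_w^{-1} + X^T X / eps with mean
    A^{-1}(Sigma_w^{-1} mu_w + X^T y / eps), computed as m_j = mu_w +
    C_j X^T (y - X mu_w) and cov_j = eps C_j.  A patient whose design is
    singular (all x identical) simply keeps the prior along the
    unidentified direction — no special casing needed.
    """
    c, _ = _woodbury(data, hyper)
    xtr = data.xty - data.xtx @ hyper.mu_w
    means = hyper.mu_w + np.einsum("jab,jb->ja", c, xtr)
    covs = hyper.sigma_eps2 * c
    return means, covs


def posterior_weights(data: HGLMData, hyper: HGLMHyper):
    """Per-patient Gaussian posterior of w_j given the hyperparameters."""
    means, covs = _posterior_arrays(data, hyper)
    return (
        {pid: means[j] for j, pid in enumerate(data.patient_ids)},
        {pid: covs[j] for j, pid in enumerate(data.patient_ids)},
    )


def _gls_mu(data: HGLMData, hyper: HGLMHyper):
    """Exact maximizer of the marginal likelihood in mu_w (others fixed)."""
    eps = hyper.sigma_eps2
    c, _ = _woodbury(data, hyper)
    xcx = np.einsum("jab,jbc,jcd->jad", data.xtx, c, data.xtx)
    xcy = np.einsum("jab,jbc,jc->ja", data.xtx, c, data.xty)
    info = np.sum(data.xtx - xcx, axis=0) / eps
    rhs = np.sum(data.xty - xcy, axis=0) / eps
    mu_cov = _spd_inv(info)
    return mu_cov @ rhs, mu_cov


def _pooled_ols(data: HGLMData):
    xall = np.vstack(data.designs())
    yall = np.concatenate(data.y)
    coef, *_ = np.linalg.lstsq(xall, yall, rcond=None)
    resid = yall - xall @ coef
    dof = max(len(yall) - 2, 1)
    return coef, float(resid @ resid / dof)


def default_init(data: HGLMData) -> HGLMHyper:
    """mu_w from pooled least squares; Sigma_w from the spread of per-patient fits."""
    mu0, s2 = _pooled_ols(data)
    fits = []
    for xtx, xty in zip(data.xtx, data.xty):
        fits.append(np.linalg.solve(xtx + 1e-6 * np.eye(2), xty))
    fits = np.asarray(fits)
    sw = np.cov(fits.T) if len(fits) > 1 else np.eye(2) * 0.01
    sw = np.atleast_2d(sw) + 1e-4 * np.eye(2)
    return HGLMHyper(mu0, sw, max(s2, 1e-8))


def fit_hglm(
    data: HGLMData,
    init: Optional[HGLMHyper] = None,
    tol: float = 1e-8,
    max_iter: int = 20_000,
    update_mu: bool = True,
    update_sigma_w: bool = True,
    update_sigma_eps: bool = True,
    sigma_w_floor: float = 1e-10,
    sigma_eps2_floor: float = 1e-12,
) -> HGLMPosterior:
    """Empirical-Bayes fit of the two-level model.

    The `update_*` switches freeze individual hyperparameters (useful for
    limit checks and for conditioning on externally supplied values); floors
    keep the covariances numerically positive definite.  Convergence is a
    relative tolerance on the log marginal likelihood; the variance
    components approach their optimum geometrically, so thousands of the
    cheap rank-2 iterations are allowed by default.
    """
    if len(data.x) < 1:
        raise ValueError("need at least one patient")
    hyper = init or default_init(data)
    n_total = sum(data.n_obs)
    trace = [log_marginal_likelihood(data, hyper)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if update_mu:
            mu_new, _ = _gls_mu(data, hyper)
            hyper = HGLMHyper(mu_new, hyper.sigma_w, hyper.sigma_eps2)
        # one E-step; the M-step over (Sigma_w, sigma_eps2) separates in Q,
        # so both closed forms use the same posteriors (standard joint EM)
        means, covs = _posterior_arrays(data, hyper)
        sw_new, eps_new = hyper.sigma_w, hyper.sigma_eps2
        if update_sigma_w:
            dev = means - hyper.mu_w
            sw = covs.sum(axis=0) + np.einsum("ja,jb->ab", dev, dev)
            sw_new = sw / len(data.patient_ids) + sigma_w_floor * np.eye(2)
        if update_sigma_eps:
            rss = np.sum(
                data.yty
                - 2.0 * np.einsum("ja,ja->j", means, data.xty)
                + np.einsum("ja,jab,jb->j", means, data.xtx, means)
                + np.einsum("jab,jba->j", data.xtx, covs)
            )
            eps_new = max(float(rss) / n_total, sigma_eps2_floor)
        hyper = HGLMHyper(hyper.mu_w, sw_new, eps_new)
        lml = log_marginal_likelihood(data, hyper)
        trace.append(lml)
        if abs(lml - trace[-2]) < tol * (1.0 + abs(lml)):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"hierarchical linear model did not converge in {max_iter} "
            f"iterations (last improvement {trace[-1] - trace[-2]:.3g})"
        )
    means, covs = posterior_weights(data, hyper)
    _, mu_cov = _gls_mu(data, hyper)
    return HGLMPosterior(
        patient_ids=list(data.patient_ids),
        means=means,
        covs=covs,
        hyper=hyper,
        mu_cov=mu_cov,
        log_marginal=trace[-1],
        trace=trace,
        converged=converged,
        n_iter=it,
    )


def population_line(post: HGLMPosterior) -> tuple[float, float]:
    """(intercept, slope) of the fitted population mean line mu_w."""
    return float(post.hyper.mu_w[0]), float(post.hyper.mu_w[1])


def credible_interval(mean: float, sd: float, level: float = 0.78):
    """Interval around a posterior/predictive mean.

    At the study's 0.78 level this is the operational [mean - sd, mean + sd];
    other levels use Gaussian quantiles.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if abs(level - 0.78) < 1e-9:
        z = 1.0
    else:
        if not (0 < level < 1):
            raise ValueError("level must lie in (0, 1)")
        z = float(norm.ppf(0.5 + level / 2.0))
    return (mean - z * sd, mean + z * sd)


def population_interval(post: HGLMPosterior, component: int = 1,
                        level: float = 0.78):
    """Band for a population-line component using the between-patient spread.

    sigma is sqrt(Sigma_w[k, k]) — the SD of the individual patients' weights
    around the population mean, i.e. the band that brackets the per-patient
    lines (slope reported as mean ± population SD).
    """
    mu = float(post.hyper.mu_w[component])
    sd = float(np.sqrt(post.hyper.sigma_w[component, component]))
    return credible_interval(mu, sd, level)


def fixed_effect_interval(post: HGLMPosterior, component: int = 1,
                          level: float = 0.78):
    """Interval for mu_w itself from the GLS information (standard error)."""
    mu = float(post.hyper.mu_w[component])
    sd = float(np.sqrt(post.mu_cov[component, component]))
    return credible_interval(mu, sd, level)
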