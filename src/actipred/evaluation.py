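"""Leave-one-patient-out evaluation of discharge-date predictors.

Each patient is held out in turn; a predictor is trained on the remaining
patients and produces one discharge estimate per admission day of the
held-out patient.  Signed errors (estimated minus real length of stay, in
days; negative = discharge predicted too early) are aggregated by day of
admission over the patients still admitted, summarized per patient, and
bucketed by per-patient mean absolute error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .baselines import MeanPTDBaseline, RandomForestBaseline
from .hgp import (
    KernelSpec, LOS_CAP, PTDPrediction, estimate_discharge, fit_hgp,
    recursive_predict,
)

logger = logging.getLogger(__name__)

BUCKET_EDGES = [0.0, 1.0, 3.0, 5.0, 10.0, np.inf]
BUCKET_LABELS = ["<1", "1-3", "3-5", "5-10", ">10"]


class HGPPredictor:
    """Hierarchical-GP predictor conforming to the harness interface."""

    def __init__(self, spec: Optional[KernelSpec] = None, optimize: bool = True,
                 n_restarts: int = 2, maxiter: int = 100, seed: int = 0,
                 los_cap: int = LOS_CAP):
        self.opts = dict(spec=spec, optimize=optimize, n_restarts=n_restarts,
                         maxiter=maxiter, seed=seed)
        self.los_cap = los_cap
        self.model = None

    def fit(self, train_features: pd.DataFrame):
        self.model = fit_hgp(train_features, **self.opts)
        return self

    def predict_stream(self, days: pd.DataFrame, true_length=None):
        return recursive_predict(self.model, days, true_length=true_length,
                                 los_cap=self.los_cap)


class OraclePredictor:
    """Returns the true PTD of every day — a correctness probe for the harness."""

    def fit(self, train_features: pd.DataFrame):
        return self

    def predict_stream(self, days: pd.DataFrame, true_length=None):
        pid = days["patient_id"].iloc[0] if "patient_id" in days else None
        out = []
        for _, row in days.iterrows():
            pred = PTDPrediction(float(row["ptd"]), 0.0)
            out.append(
                estimate_discharge(int(row["doa"]), pred,
                                   true_length=true_length, patient_id=pid)
            )
        return out


PREDICTOR_FACTORIES: dict[str, Callable[[], object]] = {
    "hgp": HGPPredictor,
    "mean_ptd": MeanPTDBaseline,
    "rf": RandomForestBaseline,
    "oracle": OraclePredictor,
}


@dataclass
class EvaluationResult:
    predictor: str
    errors: pd.DataFrame      # long: patient_id, doa, error, total_hat, ...
    per_day: pd.DataFrame     # ErrorTableRow analog
    per_patient: pd.DataFrame
    buckets: pd.Series
    overall_mean: float       # signed mean error, days
    overall_sd: float
    overall_mae: float        # mean absolute error, days
    overall_mae_sd: float
    skipped_folds: list = field(default_factory=list)


def _per_day_table(features: pd.DataFrame, errors: pd.DataFrame) -> pd.DataFrame:
    """Aggregate true PTD and LOO errors by day of admission.

    n_admitted is the number of patients whose stay reaches that day, so it
    reproduces the survival pattern of lengths of stay; with fewer than two
    patients the SD and CI are undefined and left blank.
    """
    lengths = features.groupby("patient_id")["length_of_stay"].first()
    rows = []
    for doa in sorted(errors["doa"].unique()):
        admitted = lengths[lengths >= doa]
        day_feats = features[features["doa"] == doa]
        errs = errors.loc[errors["doa"] == doa, "error"].to_numpy(float)
        n = len(errs)
        mean = float(errs.mean()) if n else np.nan
        if n >= 2:
            sd = float(errs.std(ddof=1))
            half = float(student_t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            sd = lo = hi = np.nan
        rows.append(
            {"doa": int(doa), "n_admitted": int(len(admitted)),
             "ptd_mean": float(day_feats["ptd"].mean()),
             "ptd_sd": float(day_feats["ptd"].std(ddof=1))
             if len(day_feats) >= 2 else np.nan,
             "error_mean": mean, "error_sd": sd,
             "ci95_lo": lo, "ci95_hi": hi}
        )
    return pd.DataFrame(rows)


def error_buckets(per_patient: pd.DataFrame) -> pd.Series:
    """Counts of patients by mean-absolute-error band (partition of the cohort)."""
    cut = pd.cut(per_patient["mean_abs_error"], BUCKET_EDGES,
                 labels=BUCKET_LABELS, right=False, include_lowest=True)
    return cut.value_counts().reindex(BUCKET_LABELS).fillna(0).astype(int)


def loo_evaluate(
    predictor_factory: Callable[[], object],
    features: pd.DataFrame,
    name: str = "predictor",
) -> EvaluationResult:
    """Leave-one-patient-out evaluation over a feature table with known PTD."""
    pids = sorted(features["patient_id"].unique())
    if len(pids) < 3:
        raise ValueError("need >= 3 patients for leave-one-out evaluation")
    records = []
    skipped = []
    for pid in pids:
        train = features[features["patient_id"] != pid]
        test = features[features["patient_id"] == pid].sort_values("doa")
        true_len = float(test["length_of_stay"].iloc[0])
        try:
            predictor = predictor_factory()
            predictor.fit(train)
            ests = predictor.predict_stream(test, true_length=true_len)
        except Exception as exc:  # fold-level robustness, reported in summary
            logger.warning("fold %s skipped: %s", pid, exc)
            skipped.append({"patient_id": pid, "reason": str(exc)})
            continue
        for est in ests:
            records.append(
                {"patient_id": pid, "doa": est.doa, "ptd_hat": est.ptd_hat,
                 "ptd_sd": est.ptd_sd, "total_hat": est.total_hat,
                 "remaining_hat": est.remaining_hat,
                 "selected_patient": est.selected_patient,
                 "true_length": true_len, "error": est.error}
            )
    errors = pd.DataFrame(records)
    if errors.empty:
        raise RuntimeError("every fold failed; nothing to aggregate")
    per_day = _per_day_table(features, errors)
    per_patient = (
        errors.groupby("patient_id")
        .agg(true_length=("true_length", "first"),
             mean_estimate=("total_hat", "mean"),
             sd_estimate=("total_hat", "std"),
             mean_error=("error", "mean"),
             mean_abs_error=("error", lambda e: float(np.abs(e).mean())))
        .reset_index()
    )
    buckets = error_buckets(per_patient)
    err = errors["error"].to_numpy(float)
    return EvaluationResult(
        predictor=name,
        errors=errors,
        per_day=per_day,
        per_patient=per_patient,
        buckets=buckets,
        overall_mean=float(err.mean()),
        overall_sd=float(err.std(ddof=1)) if len(err) > 1 else 0.0,
        overall_mae=float(np.abs(err).mean()),
        overall_mae_sd=float(np.abs(err).std(ddof=1)) if len(err) > 1 else 0.0,
        skipped_folds=skipped,
    )


def best_prediction_day(per_day: pd.DataFrame, min_admitted: int = 3) -> int:
    """Day of admission with the smallest |mean error| among days with
    at least `min_admitted` patients still on the ward (ties: earliest day)."""
    eligible = per_day[per_day["n_admitted"] >= min_admitted]
    if eligible.empty:
        raise ValueError("no day satisfies the n_admitted floor")
    idx = eligible["error_mean"].abs().to_numpy()
    return int(eligible["doa"].to_numpy()[int(np.argmin(idx))])


def render_reports(results: dict[str, EvaluationResult], out_dir) -> dict:
    """Write per-day error curves, real-vs-estimated scatter, and bucket tables.

    Returns the summary dict also written to summary.json.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, res in results.items():
        day = res.per_day
        ax.plot(day["doa"], day["error_mean"], marker="o", label=name)
        ax.fill_between(day["doa"], day["ci95_lo"], day["ci95_hi"], alpha=0.2)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("day of admission")
    ax.set_ylabel("error of predicted discharge (days)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "error_by_day.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, res in results.items():
        pp = res.per_patient
        ax.errorbar(pp["true_length"], pp["mean_estimate"],
                    yerr=pp["sd_estimate"].fillna(0.0), fmt="o", label=name,
                    alpha=0.7)
    lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.plot([0, lim], [0, lim], "k--", lw=0.5)
    ax.set_xlabel("real admission length (days)")
    ax.set_ylabel("mean estimated length (days)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "real_vs_estimated.svg")
    plt.close(fig)

    summary = {}
    for name, res in results.items():
        res.per_day.to_csv(out / f"error_table_{name}.csv", index=False)
        res.per_patient.to_csv(out / f"per_patient_{name}.csv", index=False)
        res.buckets.rename_axis("band").to_frame("n_patients").to_csv(
            out / f"buckets_{name}.csv"
        )
        summary[name] = {
            "overall_mean_error_days": res.overall_mean,
            "overall_sd_days": res.overall_sd,
            "overall_mae_days": res.overall_mae,
            "best_day": best_prediction_day(res.per_day)
            if (res.per_day["n_admitted"] >= 3).any() else None,
            "skipped_folds": res.skipped_folds,
            "ci_formula": "mean +/- t(0.975, n-1) * sd / sqrt(n)",
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
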