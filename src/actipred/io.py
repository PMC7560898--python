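"""CSV/JSON interchange for states, features, truth tables and fitted models."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ALL_STATES, Cohort

STATES_COLUMNS = ["patient_id", "doa", "minute_index", "state"]
FEATURES_COLUMNS = ["patient_id", "doa", "activity_time", "rest_time", "ptd",
                    "length_of_stay"]


def write_states_csv(cohort_or_frame, path) -> None:
    frame = (
        cohort_or_frame.states_frame()
        if isinstance(cohort_or_frame, Cohort)
        else cohort_or_frame
    )
    frame.to_csv(path, index=False, columns=STATES_COLUMNS)


def read_states_csv(path) -> pd.DataFrame:
    """Validated minute-level state records.

    The header must be exactly patient_id,doa,minute_index,state; rows with
    unknown state labels are rejected with their row numbers.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    if list(frame.columns) != STATES_COLUMNS:
        raise ValueError(
            f"states CSV header must be {','.join(STATES_COLUMNS)}, "
            f"got {','.join(frame.columns)}"
        )
    if frame.empty:
        warnings.warn(f"states file {path} contains no records")
        return frame
    bad = ~frame["state"].isin(ALL_STATES)
    if bad.any():
        rows = (frame.index[bad] + 2).tolist()  # 1-based incl. header
        labels = sorted(frame.loc[bad, "state"].unique())
        raise ValueError(
            f"unknown state label(s) {labels} at file row(s) {rows[:10]}"
        )
    return frame


def write_truth_csv(cohort: Cohort, path) -> None:
    cohort.truth_frame().to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, columns=FEATURES_COLUMNS)


def read_features_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(FEATURES_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"features CSV missing column(s): {sorted(missing)}")
    return frame


def hglm_model_to_json(post) -> dict:
    h = post.hyper
    return {
        "mu_w": h.mu_w.tolist(),
        "sigma_w": h.sigma_w.tolist(),
        "sigma_eps2": h.sigma_eps2,
        "mu_cov": post.mu_cov.tolist(),
        "log_marginal": post.log_marginal,
        "n_iter": post.n_iter,
        "converged": bool(post.converged),
        "patients": {
            str(pid): {"mean": post.means[pid].tolist(),
                       "cov": post.covs[pid].tolist()}
            for pid in post.patient_ids
        },
    }


def hgp_model_to_json(model) -> dict:
    s = model.spec
    return {
        "kernel": {
            "family": "squared-exponential",
            "upper_variance": float(s.upper_variance),
            "upper_lengthscales": list(map(float, s.upper_lengthscales)),
            "lower_variance": float(s.lower_variance),
            "lower_lengthscales": list(map(float, s.lower_lengthscales)),
            "noise_variance": float(s.noise_variance),
        },
        "standardization": {
            "x_mean": model.x_mean.tolist(),
            "x_std": model.x_std.tolist(),
            "y_mean": model.y_mean,
        },
        "log_marginal": model.log_marginal,
        "n_train": int(len(model.y_train)),
    }


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping for run manifests."""
    canon = json.dumps(config, sort_keys=True, default=_json_default)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
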