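"""Comparison predictors: mean-trained-PTD table and random-forest regression.

Both emit the same per-day DischargeEstimate records as the hierarchical GP
so the evaluation harness can swap them in directly.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .hgp import FEATURE_COLS, LOS_CAP, PTDPrediction, estimate_discharge

logger = logging.getLogger(__name__)


class MeanPTDBaseline:
    """Predicts a new patient's PTD at day d as the mean trained PTD at day d.

    The mean is taken over the training patients still admitted at that day
    (their PTD there being d / own length of stay); the SD over the same
    patients provides the uncertainty.  Days beyond the training support
    fall back to the nearest observed day.
    """

    def __init__(self):
        self.table: Optional[pd.DataFrame] = None

    def fit(self, train_features: pd.DataFrame) -> "MeanPTDBaseline":
        feats = train_features.dropna(subset=["ptd"])
        grp = feats.groupby("doa")["ptd"]
        self.table = pd.DataFrame(
            {"mean": grp.mean(), "sd": grp.std(ddof=1).fillna(0.0),
             "n": grp.size()}
        ).sort_index()
        return self

    def predict(self, doa: int) -> PTDPrediction:
        if self.table is None:
            raise RuntimeError("baseline not fitted")
        if doa not in self.table.index:
            nearest = int(
                self.table.index[np.argmin(np.abs(self.table.index - doa))]
            )
            logger.info("doa %d outside training support; using day %d", doa, nearest)
            doa = nearest
        row = self.table.loc[doa]
        return PTDPrediction(float(row["mean"]), float(row["sd"]))

    def predict_stream(
        self, days: pd.DataFrame, true_length: Optional[float] = None,
        los_cap: int = LOS_CAP,
    ):
        pid = days["patient_id"].iloc[0] if "patient_id" in days else None
        return [
            estimate_discharge(int(d), self.predict(int(d)),
                               true_length=true_length, los_cap=los_cap,
                               patient_id=pid)
            for d in days["doa"]
        ]


def mean_ptd_predict(model: MeanPTDBaseline, doa: int) -> PTDPrediction:
    return model.predict(doa)


class RandomForestBaseline:
    """Random-forest regression of PTD on (Activity Time, Rest Time, DoA).

    Hyperparameters: 500 trees, unlimited depth, fixed seed; the per-tree
    spread supplies a predictive SD.  Discharge estimation reuses the same
    arithmetic as the GP predictor.
    """

    def __init__(self, n_trees: int = 500, max_depth: Optional[int] = None,
                 seed: int = 0):
        self.params = {"n_trees": n_trees, "max_depth": max_depth, "seed": seed}
        self.forest: Optional[RandomForestRegressor] = None

    def fit(self, train_features: pd.DataFrame) -> "RandomForestBaseline":
        feats = train_features.dropna(subset=["ptd"])
        self.forest = RandomForestRegressor(
            n_estimators=self.params["n_trees"],
            max_depth=self.params["max_depth"],
            random_state=self.params["seed"],
        )
        self.forest.fit(feats[FEATURE_COLS].to_numpy(float),
                        feats["ptd"].to_numpy(float))
        return self

    def predict(self, x_row) -> PTDPrediction:
        if self.forest is None:
            raise RuntimeError("forest not fitted")
        x = np.atleast_2d(np.asarray(x_row, float))
        per_tree = np.stack([t.predict(x) for t in self.forest.estimators_])
        return PTDPrediction(float(per_tree.mean()), float(per_tree.std()))

    def predict_stream(
        self, days: pd.DataFrame, true_length: Optional[float] = None,
        los_cap: int = LOS_CAP,
    ):
        pid = days["patient_id"].iloc[0] if "patient_id" in days else None
        out = []
        for _, row in days.iterrows():
            pred = self.predict(row[FEATURE_COLS].to_numpy(float))
            out.append(
                estimate_discharge(int(row["doa"]), pred,
                                   true_length=true_length, los_cap=los_cap,
                                   patient_id=pid)
            )
        return out


def rf_fit_predict(
    train_features: pd.DataFrame,
    test_days: pd.DataFrame,
    true_length: Optional[float] = None,
    seed: int = 0,
):
    """Fit the forest on training features and emit per-day estimates."""
    model = RandomForestBaseline(seed=seed).fit(train_features)
    return model.predict_stream(test_days, true_length=true_length)
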