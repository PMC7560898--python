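"""Hierarchical GP: dense-Gaussian oracle equivalence, collapse limits,
discharge arithmetic, and the recursive similarity algorithm."""

import numpy as np
import pandas as pd
import pytest

from actipred.hgp import (
    KernelSpec,
    PTDPrediction,
    _neg_log_marginal,
    _rbf,
    _sqdists,
    estimate_discharge,
    fit_hgp,
    patient_loglik,
    predict_ptd,
    recursive_predict,
    select_by_implied_course,
    select_similar_patient,
)

SPEC = KernelSpec(0.3, (1.2, 0.8, 1.5), 0.1, (0.9, 1.1, 0.7), 0.05)


def _toy_frame(n_patients=3, n_days=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        length = 4 + i
        for d in range(1, n_days + 1):
            rows.append({
                "patient_id": f"p{i}", "doa": d,
                "activity_time": 10 + 3 * i + d + rng.normal(0, 0.5),
                "rest_time": 20 - 2 * i - d + rng.normal(0, 0.5),
                "ptd": d / length, "length_of_stay": length,
            })
    return pd.DataFrame(rows)


def _dense_cov(model, a, b, ga, gb):
    spec = model.spec
    k = _rbf(_sqdists(a, b), spec.upper_variance, spec.upper_lengthscales)
    k = k + (ga[:, None] == gb[None, :]) * _rbf(
        _sqdists(a, b), spec.lower_variance, spec.lower_lengthscales
    )
    return k


@pytest.fixture(scope="module")
def toy_model():
    return fit_hgp(_toy_frame(), spec=SPEC, optimize=False)


def test_predictive_moments_match_dense_conditioning(toy_model):
    """Predictions equal brute-force conditioning of the full joint Gaussian."""
    m = toy_model
    n = len(m.y_train)
    k_full = _dense_cov(m, m.x_train, m.x_train, m.groups, m.groups)
    k_full += (SPEC.noise_variance + 1e-8) * np.eye(n)
    x_raw = np.array([12.3, 17.0, 2.5])
    xs = m.standardize(x_raw)
    for pid in ["p0", "p1", "p2"]:
        garr = np.array([pid], dtype=object)
        ks = _dense_cov(m, xs, m.x_train, garr, m.groups)
        mean_bf = float((ks @ np.linalg.solve(k_full, m.y_train))[0]) + m.y_mean
        var_bf = (SPEC.upper_variance + SPEC.lower_variance
                  - float((ks @ np.linalg.solve(k_full, ks.T))[0, 0]))
        pred = predict_ptd(m, pid, x_raw)
        assert pred.mean == pytest.approx(mean_bf, abs=1e-8)
        assert pred.sd == pytest.approx(np.sqrt(var_bf), abs=1e-8)
        assert pred.interval == (pred.mean - pred.sd, pred.mean + pred.sd)


def test_patient_loglik_matches_dense_conditional(toy_model):
    from scipy.stats import multivariate_normal

    m = toy_model
    n = len(m.y_train)
    k_full = _dense_cov(m, m.x_train, m.x_train, m.groups, m.groups)
    k_full += (SPEC.noise_variance + 1e-8) * np.eye(n)
    x_raw = np.array([[12.3, 17.0, 2.5], [14.0, 15.5, 3.5]])
    xs = m.standardize(x_raw)
    y_new = np.array([0.5, 0.7])
    for pid in ["p0", "p1", "p2"]:
        garr = np.array([pid] * 2, dtype=object)
        ks = _dense_cov(m, xs, m.x_train, garr, m.groups)
        kss = _dense_cov(m, xs, xs, garr, garr) + SPEC.noise_variance * np.eye(2)
        mean_bf = ks @ np.linalg.solve(k_full, m.y_train) + m.y_mean
        cov_bf = kss - ks @ np.linalg.solve(k_full, ks.T)
        ll_bf = multivariate_normal.logpdf(y_new, mean_bf, cov_bf,
                                           allow_singular=True)
        assert patient_loglik(m, pid, x_raw, y_new) == pytest.approx(
            ll_bf, abs=1e-6
        )


def test_marginal_likelihood_gradient_matches_finite_differences(toy_model):
    m = toy_model
    mask = m.groups[:, None] == m.groups[None, :]
    sq = _sqdists(m.x_train, m.x_train)
    theta = SPEC.to_log_vector()
    _, grad = _neg_log_marginal(theta, sq, mask, m.y_train)
    for i in range(len(theta)):
        e = np.zeros_like(theta)
        e[i] = 1e-6
        fp, _ = _neg_log_marginal(theta + e, sq, mask, m.y_train)
        fm, _ = _neg_log_marginal(theta - e, sq, mask, m.y_train)
        assert grad[i] == pytest.approx((fp - fm) / 2e-6, abs=1e-5)


def test_single_patient_collapses_to_standard_gp():
    """One patient: the hierarchy is a plain GP with kernel k_g + k_f."""
    frame = _toy_frame(n_patients=1, n_days=6)
    m = fit_hgp(frame, spec=SPEC, optimize=False)
    n = len(m.y_train)
    k = (_rbf(_sqdists(m.x_train, m.x_train), SPEC.upper_variance,
              SPEC.upper_lengthscales)
         + _rbf(_sqdists(m.x_train, m.x_train), SPEC.lower_variance,
                SPEC.lower_lengthscales)
         + (SPEC.noise_variance + 1e-8) * np.eye(n))
    x_raw = np.array([13.0, 18.0, 2.0])
    xs = m.standardize(x_raw)
    ks = (_rbf(_sqdists(xs, m.x_train), SPEC.upper_variance,
               SPEC.upper_lengthscales)
          + _rbf(_sqdists(xs, m.x_train), SPEC.lower_variance,
                 SPEC.lower_lengthscales))
    mean_gp = float((ks @ np.linalg.solve(k, m.y_train))[0]) + m.y_mean
    var_gp = (SPEC.upper_variance + SPEC.lower_variance
              - float((ks @ np.linalg.solve(k, ks.T))[0, 0]))
    pred = predict_ptd(m, "p0", x_raw)
    assert pred.mean == pytest.approx(mean_gp, abs=1e-6)
    assert pred.sd == pytest.approx(np.sqrt(var_gp), abs=1e-6)


def test_zero_lower_variance_makes_patients_exchangeable():
    spec = KernelSpec(0.3, (1.0, 1.0, 1.0), 1e-12, (1.0, 1.0, 1.0), 0.05)
    m = fit_hgp(_toy_frame(), spec=spec, optimize=False)
    x_raw = np.array([12.0, 18.0, 2.0])
    preds = [predict_ptd(m, pid, x_raw) for pid in ["p0", "p1", "p2"]]
    for p in preds[1:]:
        assert p.mean == pytest.approx(preds[0].mean, abs=1e-9)
        assert p.sd == pytest.approx(preds[0].sd, abs=1e-9)


def test_identical_patients_have_identical_posteriors():
    frame = _toy_frame(n_patients=1, n_days=4)
    twin = frame.assign(patient_id="p9")
    both = pd.concat([frame, twin], ignore_index=True)
    m = fit_hgp(both, spec=SPEC, optimize=False)
    x_raw = np.array([[11.0, 19.0, 1.5]])
    y_new = np.array([0.4])
    assert patient_loglik(m, "p0", x_raw, y_new) == pytest.approx(
        patient_loglik(m, "p9", x_raw, y_new), abs=1e-9
    )
    p0 = predict_ptd(m, "p0", x_raw[0])
    p9 = predict_ptd(m, "p9", x_raw[0])
    assert p0.mean == pytest.approx(p9.mean, abs=1e-9)


def test_self_similarity_and_tie_breaking():
    frame = _toy_frame()
    spec = KernelSpec(0.3, (1.2, 0.8, 1.5), 0.1, (0.9, 1.1, 0.7), 1e-6)
    m = fit_hgp(frame, spec=spec, optimize=False)
    own = frame[frame.patient_id == "p1"]
    sel = select_similar_patient(
        m, own[["activity_time", "rest_time", "doa"]].to_numpy(),
        own["ptd"].to_numpy(),
    )
    assert sel == "p1"
    # single training patient trivially wins
    solo = fit_hgp(_toy_frame(n_patients=1, n_days=4), spec=SPEC, optimize=False)
    assert select_similar_patient(solo, np.array([[10.0, 20.0, 1.0]]),
                                  np.array([0.3])) == "p0"


def test_interpolation_limit_reproduces_training_target():
    spec = KernelSpec(0.3, (1.2, 0.8, 1.5), 0.1, (0.9, 1.1, 0.7), 1e-8)
    frame = _toy_frame()
    m = fit_hgp(frame, spec=spec, optimize=False)
    row = frame.iloc[4]
    pred = predict_ptd(m, row["patient_id"],
                       row[["activity_time", "rest_time", "doa"]].to_numpy(float))
    assert pred.mean == pytest.approx(row["ptd"], abs=1e-3)


def test_far_extrapolation_reverts_to_prior_variance(toy_model):
    pred = predict_ptd(toy_model, "p0", np.array([500.0, -400.0, 300.0]))
    assert pred.sd == pytest.approx(
        np.sqrt(SPEC.upper_variance + SPEC.lower_variance), abs=1e-3
    )


def test_adding_training_point_reduces_predictive_variance():
    frame = _toy_frame()
    x_new = {"patient_id": "p0", "doa": 4, "activity_time": 16.0,
             "rest_time": 12.0, "ptd": 0.9, "length_of_stay": 4}
    m0 = fit_hgp(frame, spec=SPEC, optimize=False)
    m1 = fit_hgp(pd.concat([frame, pd.DataFrame([x_new])], ignore_index=True),
                 spec=SPEC, optimize=False)
    x_raw = np.array([16.0, 12.0, 4.0])
    # same standardization for a clean comparison
    m1.x_mean, m1.x_std = m0.x_mean, m0.x_std
    assert predict_ptd(m1, "p0", x_raw).sd <= predict_ptd(m0, "p0", x_raw).sd + 1e-9


def test_estimate_discharge_worked_example_and_arithmetic():
    est = estimate_discharge(10, PTDPrediction(0.5, 0.1))
    assert est.total_hat == pytest.approx(20.0)
    assert est.remaining_hat == pytest.approx(10.0)
    today = estimate_discharge(7, PTDPrediction(1.0, 0.0))
    assert today.total_hat == pytest.approx(7.0)
    assert today.remaining_hat == pytest.approx(0.0)
    # strictly decreasing in predicted progress, floored at doa/64
    totals = [estimate_discharge(10, PTDPrediction(p, 0.0)).total_hat
              for p in (0.2, 0.4, 0.6, 0.8, 1.0)]
    assert all(b < a for a, b in zip(totals, totals[1:]))
    assert all(t >= 10 for t in totals)
    floored = estimate_discharge(10, PTDPrediction(-0.3, 0.0))
    assert floored.total_hat == pytest.approx(64.0)
    with_truth = estimate_discharge(10, PTDPrediction(0.5, 0.0), true_length=25)
    assert with_truth.error == pytest.approx(-5.0)


def test_recursive_prediction_is_prefix_consistent(toy_model):
    days = _toy_frame().query("patient_id == 'p2'").assign(patient_id="new")
    full = recursive_predict(toy_model, days)
    for d in range(1, len(days) + 1):
        prefix = recursive_predict(toy_model, days.iloc[:d])
        assert prefix[-1].total_hat == pytest.approx(full[d - 1].total_hat)
        assert prefix[-1].selected_patient == full[d - 1].selected_patient


def test_recursive_rejects_out_of_order_days(toy_model):
    days = _toy_frame().query("patient_id == 'p0'").iloc[::-1]
    with pytest.raises(ValueError, match="increasing doa"):
        recursive_predict(toy_model, days)


def test_clone_of_training_patient_is_recognized():
    """A new patient repeating a training patient's days converges to that
    patient's course and true length."""
    frame = _toy_frame(n_patients=3, n_days=4, seed=2)
    spec = KernelSpec(0.3, (1.2, 0.8, 1.5), 0.1, (0.9, 1.1, 0.7), 1e-4)
    m = fit_hgp(frame, spec=spec, optimize=False)
    target = "p1"
    clone = frame[frame.patient_id == target].assign(patient_id="new")
    length = float(frame.loc[frame.patient_id == target,
                             "length_of_stay"].iloc[0])
    ests = recursive_predict(m, clone, true_length=length)
    assert all(e.selected_patient == target for e in ests)
    for e in ests[1:]:
        assert e.total_hat == pytest.approx(length, abs=0.5)


def test_archetype_selection_recovers_cluster(clustered_features):
    """Across held-out patients of a two-archetype ward, the selected
    regressor belongs to the correct archetype in >= 80% of later days."""
    table, truth = clustered_features
    hits = total = 0
    for held in sorted(table.patient_id.unique()):
        train = table[table.patient_id != held]
        test = table[table.patient_id == held].sort_values("doa")
        model = fit_hgp(train, n_restarts=2, maxiter=100, seed=0)
        for est in recursive_predict(model, test):
            if est.doa <= 3:
                continue
            total += 1
            hits += truth[est.selected_patient].archetype == truth[held].archetype
    assert hits / total >= 0.8
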