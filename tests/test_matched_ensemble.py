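"""Ridge-logistic members and bagged ensembles over matched cohorts."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logit

from matchedcv import (
    Ensemble,
    MatchedSet,
    RidgeLogitMember,
    fit_member,
    fit_prep,
    fit_ridge_logit,
    predict_proba,
    train_ensemble,
)
from matchedcv.matched_ensemble import deserialize_ensemble, serialize_ensemble

from conftest import toy_cohort


def separable_toy():
    """10 cases at x=+1, 10 controls at x=-1."""
    labels = [1] * 10 + [0] * 10
    markers = {"x": [1.0] * 10 + [-1.0] * 10}
    fold = toy_cohort(labels, [0.5] * 20, markers=markers)
    matched = MatchedSet(tuple(fold.case_ids), tuple(fold.control_ids))
    prep = fit_prep(fold, 0.9, np.random.default_rng(0))
    return fold, matched, prep


def test_one_dimensional_fit_matches_scalar_oracle():
    fold, matched, prep = separable_toy()
    member = fit_member(fold, matched, prep, lam=1.0)

    x = np.array([1.0] * 10 + [-1.0] * 10)  # already standardized (mean 0, sd 1)
    y = np.array([1.0] * 10 + [0.0] * 10)
    n = 20

    def objective(w):
        z = w * x  # intercept 0 by symmetry
        return float(np.mean(np.logaddexp(0.0, z) - y * z) + 0.5 / n * w * w)

    oracle = minimize_scalar(objective, bounds=(0.0, 10.0), method="bounded",
                             options={"xatol": 1e-12})
    assert abs(member.weights[0] - oracle.x) < 1e-6
    assert abs(member.intercept) < 1e-8


def test_noise_weights_shrink_with_stronger_penalty():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 6))
    y = np.array([1, 0] * 20)
    w_weak, _, _ = fit_ridge_logit(X, y, lam=1e-6)
    w_strong, _, _ = fit_ridge_logit(X, y, lam=1.0)
    assert np.max(np.abs(w_strong)) < np.max(np.abs(w_weak))


def test_shrinkage_is_monotone_in_lambda():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((60, 5))
    y = (X[:, 0] + 0.5 * rng.standard_normal(60) > 0).astype(int)
    norms = [
        np.linalg.norm(fit_ridge_logit(X, y, lam=lam)[0])
        for lam in (0.01, 0.1, 1.0, 10.0)
    ]
    assert all(a >= b for a, b in zip(norms, norms[1:]))


def test_convex_fit_is_initialization_independent():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((50, 4))
    y = (X[:, 1] > 0).astype(int)
    ref, b_ref, _ = fit_ridge_logit(X, y, lam=0.5)
    for s in range(5):
        init = np.random.default_rng(s).normal(0, 3, 5)
        w, b, gnorm = fit_ridge_logit(X, y, lam=0.5, init=init)
        assert gnorm < 1e-8
        np.testing.assert_allclose(w, ref, atol=1e-6)
        assert abs(b - b_ref) < 1e-6


def test_fit_matches_sklearn_ridge_logistic():
    sklearn_lm = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(3)
    X = rng.standard_normal((80, 5))
    y = (X @ rng.standard_normal(5) + 0.3 * rng.standard_normal(80) > 0).astype(int)
    lam = 0.7
    w, b, _ = fit_ridge_logit(X, y, lam=lam)
    clf = sklearn_lm.LogisticRegression(
        C=1.0 / lam, solver="lbfgs", tol=1e-12, max_iter=10_000
    ).fit(X, y)
    np.testing.assert_allclose(w, clf.coef_[0], atol=1e-5)
    assert abs(b - clf.intercept_[0]) < 1e-5


def test_non_finite_inputs_rejected():
    X = np.array([[1.0], [np.nan]])
    with pytest.raises(ValueError, match="non-finite"):
        fit_ridge_logit(X, np.array([1, 0]), lam=1.0)


def test_single_class_matched_set_rejected():
    cohort = toy_cohort([1, 1, 0, 0], [0.5] * 4, markers={"x": [1.0, 2.0, 3.0, 4.0]})
    prep = fit_prep(cohort, 0.9, np.random.default_rng(0))
    cohort.data["label"] = 1  # degenerate labels: no controls left
    pair = MatchedSet(("t000",), ("t001",))
    with pytest.raises(ValueError, match="both classes"):
        fit_member(cohort, pair, prep, lam=1.0)


def test_single_member_ensemble_equals_member(small_cohort):
    prep = fit_prep(small_cohort, 0.9, np.random.default_rng(0))
    ens = train_ensemble(small_cohort, prep, N=1, k=10, lam=1.0,
                         rng=np.random.default_rng(4))
    from matchedcv.feature_prep import apply_prep

    X = apply_prep(prep, small_cohort).to_numpy()
    np.testing.assert_allclose(
        predict_proba(ens, small_cohort), ens.members[0].proba(X), atol=1e-15
    )


def test_ensemble_probability_is_mean_of_members():
    fold = toy_cohort([1, 0], [0.5, 0.5], markers={"x": [0.0, 0.0]})
    prep = fit_prep(
        toy_cohort([1, 0], [0.5, 0.5], markers={"x": [1.0, -1.0]}),
        0.9,
        np.random.default_rng(0),
    )
    mk = lambda b: RidgeLogitMember(
        weights=np.zeros(1), intercept=float(b), lam=1.0, background=np.zeros(1)
    )
    ens = Ensemble(members=[mk(logit(0.2)), mk(logit(0.8))], prep=prep)
    np.testing.assert_allclose(predict_proba(ens, fold), [0.5, 0.5], atol=1e-12)


def test_separable_toy_orders_cases_above_half():
    fold, matched, prep = separable_toy()
    member = fit_member(fold, matched, prep, lam=1.0)
    ens = Ensemble(members=[member], prep=prep)
    p = predict_proba(ens, fold)
    assert np.all(p[:10] > 0.5) and np.all(p[10:] < 0.5)


def test_distinct_master_seeds_give_distinct_members(small_cohort):
    prep = fit_prep(small_cohort, 0.9, np.random.default_rng(0))
    a = train_ensemble(small_cohort, prep, N=3, k=10, rng=np.random.default_rng(1))
    b = train_ensemble(small_cohort, prep, N=3, k=10, rng=np.random.default_rng(2))
    diffs = [
        not np.allclose(ma.weights, mb.weights)
        for ma, mb in zip(a.members, b.members)
    ]
    assert any(diffs)


def test_bagging_reduces_prediction_variance(small_cohort):
    """Across master seeds, held-out probabilities vary less for N=10 than N=1."""
    prep = fit_prep(small_cohort, 0.9, np.random.default_rng(0))
    probe = small_cohort.subset(small_cohort.ids[:50])
    preds = {1: [], 10: []}
    for s in range(12):
        for N in (1, 10):
            ens = train_ensemble(
                small_cohort, prep, N=N, k=10, rng=np.random.default_rng(1000 + s)
            )
            preds[N].append(predict_proba(ens, probe))
    var1 = np.mean(np.var(np.stack(preds[1]), axis=0))
    var10 = np.mean(np.var(np.stack(preds[10]), axis=0))
    assert var10 < var1


def test_ensemble_round_trips_through_text(small_cohort):
    prep = fit_prep(small_cohort, 0.9, np.random.default_rng(0))
    ens = train_ensemble(small_cohort, prep, N=2, k=10, rng=np.random.default_rng(5))
    back = deserialize_ensemble(serialize_ensemble(ens))
    assert back.n_members == 2
    for ma, mb in zip(ens.members, back.members):
        np.testing.assert_allclose(ma.weights, mb.weights)
        assert ma.matched.case_ids == mb.matched.case_ids
    np.testing.assert_allclose(
        predict_proba(back, small_cohort), predict_proba(ens, small_cohort)
    )
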