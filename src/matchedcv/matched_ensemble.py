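"""Bagged ensembles of ridge-penalized logistic models over matched cohorts.

Each ensemble member is trained on its own stochastic 1:1 matched realization
of the training fold, and the ensemble prediction is the arithmetic mean of
the member probabilities — standard bagging for probabilistic classifiers.
The member objective is

    J(w, b) = (1/n) sum_i log(1 + exp(-s_i (x_i'w + b))) + (lam / (2 n)) ||w||^2

with s_i = ±1 and the intercept unpenalized (on 1:1 matched cohorts the
intercept is a base-rate term that should float). The penalty is scaled per
sample, so ``lam`` plays the role of 1/C in the usual ridge-logistic
parameterization. The objective is strictly convex for lam > 0, so the fit is
deterministic up to solver tolerance regardless of initialization; a damped
Newton iteration drives the gradient infinity-norm below 1e-10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .feature_prep import PrepState, apply_prep
from .matching import MatchedSet, match_within_fold
from .synthetic_cohort import CohortTable

__all__ = [
    "RidgeLogitMember",
    "Ensemble",
    "fit_ridge_logit",
    "fit_member",
    "fit_unmatched_member",
    "train_ensemble",
    "predict_proba",
    "serialize_ensemble",
    "deserialize_ensemble",
]

GRAD_TOL = 1e-10


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _objective(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    n, d = X.shape
    w, b = theta[:d], theta[d]
    z = X @ w + b
    nll = float(np.mean(np.logaddexp(0.0, z) - y * z))
    obj = nll + 0.5 * lam / n * float(w @ w)
    p = _sigmoid(z)
    grad = np.empty(d + 1)
    grad[:d] = X.T @ (p - y) / n + lam / n * w
    grad[d] = float(np.mean(p - y))
    return obj, grad


def fit_ridge_logit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 1.0,
    *,
    init: np.ndarray | None = None,
    tol: float = GRAD_TOL,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, float]:
    """Damped Newton fit of the penalized logistic objective.

    Returns (weights, intercept, achieved gradient infinity-norm). Converges
    from any initialization because the objective is convex; backtracking
    halves the step until the objective decreases.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the training data")
    if lam <= 0:
        raise ValueError("lam must be positive")
    n, d = X.shape
    theta = np.zeros(d + 1) if init is None else np.asarray(init, dtype=float).copy()
    if theta.shape != (d + 1,):
        raise ValueError("init must have length n_features + 1")

    obj, grad = _objective(theta, X, y, lam)
    for _ in range(max_iter):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            break
        w = theta[:d]
        z = X @ w + theta[d]
        p = _sigmoid(z)
        W = p * (1.0 - p)
        H = np.empty((d + 1, d + 1))
        H[:d, :d] = (X.T * W) @ X / n
        H[:d, :d][np.diag_indices(d)] += lam / n
        H[:d, d] = H[d, :d] = X.T @ W / n
        H[d, d] = float(np.mean(W))
        H[np.diag_indices(d + 1)] += 1e-12  # guards near-separated intercept rows
        step = np.linalg.solve(H, grad)
        alpha = 1.0
        for _ in range(60):
            cand = theta - alpha * step
            cobj, cgrad = _objective(cand, X, y, lam)
            if cobj <= obj:
                theta, obj, grad = cand, cobj, cgrad
                break
            alpha *= 0.5
        else:  # pragma: no cover - convexity makes this unreachable in practice
            break
    gnorm = float(np.max(np.abs(grad)))
    return theta[:d], float(theta[d]), gnorm


@dataclass
class RidgeLogitMember:
    """One fitted ridge-logistic member bound to its matched training cohort."""

    weights: np.ndarray
    intercept: float
    lam: float
    background: np.ndarray  # standardized means of the member's training rows
    matched: MatchedSet | None = None
    tol: float = GRAD_TOL
    grad_norm: float = float("nan")

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Log-odds margin per row of standardized markers."""
        return X @ self.weights + self.intercept

    def proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision(X))


@dataclass
class Ensemble:
    """N ridge-logistic members sharing one feature-prep state."""

    members: list[RidgeLogitMember]
    prep: PrepState
    retained: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        d = len(self.prep.retained)
        for m in self.members:
            if m.weights.shape != (d,):
                raise ValueError("member weight length must match retained markers")
        self.retained = self.prep.retained

    @property
    def n_members(self) -> int:
        return len(self.members)


def fit_member(
    cohort: CohortTable,
    matched: MatchedSet,
    prep: PrepState,
    lam: float = 1.0,
    *,
    init: np.ndarray | None = None,
) -> RidgeLogitMember:
    """Fit one member on the rows of a matched realization."""
    rows = cohort.subset(matched.ids)
    X = apply_prep(prep, rows).to_numpy()
    y = rows.labels.to_numpy()
    if y.min() == y.max():
        raise ValueError("matched training set must contain both classes")
    w, b, gnorm = fit_ridge_logit(X, y, lam, init=init)
    return RidgeLogitMember(
        weights=w,
        intercept=b,
        lam=lam,
        background=X.mean(axis=0),
        matched=matched,
        grad_norm=gnorm,
    )


def fit_unmatched_member(
    train_fold: CohortTable, prep: PrepState, lam: float = 1.0
) -> RidgeLogitMember:
    """Fit one member on the full (imbalanced, unmatched) training fold.

    Used by the unmatched evaluation pathway that quantifies how much of the
    apparent signal is demographic confounding.
    """
    X = apply_prep(prep, train_fold).to_numpy()
    y = train_fold.labels.to_numpy()
    if y.min() == y.max():
        raise ValueError("training fold must contain both classes")
    w, b, gnorm = fit_ridge_logit(X, y, lam)
    return RidgeLogitMember(
        weights=w,
        intercept=b,
        lam=lam,
        background=X.mean(axis=0),
        matched=None,
        grad_norm=gnorm,
    )


def train_ensemble(
    train_fold: CohortTable,
    prep: PrepState,
    N: int = 10,
    k: int = 10,
    lam: float = 1.0,
    rng: np.random.Generator | int | None = None,
    *,
    fold_id: int = -1,
) -> Ensemble:
    """Train N members, one per independent matched realization of the fold."""
    if N < 1:
        raise ValueError("ensemble size N must be positive")
    rng = np.random.default_rng(rng)
    members = []
    for i, child in enumerate(rng.spawn(N)):
        matched = match_within_fold(
            train_fold, k, child, fold_id=fold_id, realization=i
        )
        members.append(fit_member(train_fold, matched, prep, lam))
    return Ensemble(members=members, prep=prep)


def predict_proba(ensemble: Ensemble, rows: CohortTable) -> np.ndarray:
    """Arithmetic mean of member probabilities, per participant."""
    X = apply_prep(ensemble.prep, rows).to_numpy()
    probs = np.mean([m.proba(X) for m in ensemble.members], axis=0)
    return probs


def serialize_ensemble(ensemble: Ensemble) -> str:
    """Plain-text (JSON) artifact with weights, intercepts, lam and prep."""
    return json.dumps(
        {
            "prep": json.loads(ensemble.prep.to_text()),
            "members": [
                {
                    "weights": list(m.weights),
                    "intercept": m.intercept,
                    "lam": m.lam,
                    "background": list(m.background),
                    "case_ids": list(m.matched.case_ids) if m.matched else None,
                    "control_ids": list(m.matched.control_ids) if m.matched else None,
                    "grad_norm": m.grad_norm,
                }
                for m in ensemble.members
            ],
        },
        indent=2,
    )


def deserialize_ensemble(text: str) -> Ensemble:
    d = json.loads(text)
    prep = PrepState.from_text(json.dumps(d["prep"]))
    members = []
    for m in d["members"]:
        matched = None
        if m["case_ids"] is not None:
            matched = MatchedSet(tuple(m["case_ids"]), tuple(m["control_ids"]))
        members.append(
            RidgeLogitMember(
                weights=np.array(m["weights"]),
                intercept=float(m["intercept"]),
                lam=float(m["lam"]),
                background=np.array(m["background"]),
                matched=matched,
                grad_norm=float(m["grad_norm"]),
            )
        )
    return Ensemble(members=members, prep=prep)
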