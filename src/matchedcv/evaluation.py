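"""Stratified repeated K-fold CV with matched-validation scoring.

One repetition = one fresh stratified fold plan. In every CV iteration the
feature-prep state is fitted on the training folds, a bagged ensemble is
trained on N independent matched realizations of the training folds, and
exactly one matched realization of the held-out fold is scored. Out-of-fold
matched-validation predictions are pooled within the repetition and the five
metrics (AUC-ROC, AUC-PR, accuracy, sensitivity, specificity) are computed
once per repetition; percentile confidence intervals are taken across
repetitions (2.5th / 97.5th). The modality-ablation harness repeats this per
condition (a named subset of modalities) and reports one summary row each.

Seeding is hierarchical — master seed -> condition -> repetition -> fold ->
(prep, training realizations, validation realization) — so a full run is
reproducible bit-for-bit while every stochastic matching realization draws
from its own independent stream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .feature_prep import fit_prep
from .importance import ImportanceAccumulator
from .matched_ensemble import (
    Ensemble,
    fit_unmatched_member,
    predict_proba,
    train_ensemble,
)
from .matching import match_within_fold
from .synthetic_cohort import (
    IMAGING_MODALITIES,
    PHYSICAL_MODALITIES,
    CohortTable,
)

__all__ = [
    "PipelineConfig",
    "Condition",
    "FoldPlan",
    "ConditionResult",
    "make_folds",
    "compute_metrics",
    "percentile_ci",
    "run_condition",
    "run_ablation",
    "summarize",
    "ablation_report",
    "study_conditions",
    "METRIC_NAMES",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc_roc", "auc_pr", "accuracy", "sensitivity", "specificity")


@dataclass(frozen=True)
class Condition:
    """A named modality subset; empty ``modalities`` means all markers."""

    name: str
    modalities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "modalities", tuple(self.modalities))


def study_conditions(available: Sequence[str]) -> list[Condition]:
    """The uni- and multimodal condition grid used in the reference study."""
    avail = set(available)
    conditions = []
    for m in IMAGING_MODALITIES + PHYSICAL_MODALITIES:
        if m in avail:
            conditions.append(Condition(m, (m,)))
    imaging = tuple(m for m in IMAGING_MODALITIES if m in avail)
    physical = tuple(m for m in PHYSICAL_MODALITIES if m in avail)
    if len(imaging) > 1:
        conditions.append(Condition("imaging-All", imaging))
    if len(physical) > 1:
        conditions.append(Condition("physical-All", physical))
    if imaging and physical:
        conditions.append(Condition("All", imaging + physical))
    return conditions


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of one full run.

    Defaults follow the reference configuration: 5 folds, k=10 neighbors,
    N=10 ensemble members, correlation threshold 0.90, decision threshold
    0.5. Repetitions default to the desk-scale 50; the study-scale value is
    300.
    """

    k_folds: int = 5
    repetitions: int = 50
    n_neighbors: int = 10
    ensemble_size: int = 10
    corr_threshold: float = 0.90
    decision_threshold: float = 0.5
    lam: float = 1.0
    seed: int = 0
    conditions: tuple[Condition, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        for name in ("repetitions", "n_neighbors", "ensemble_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in (0, 1]")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partition of participant ids into K folds."""

    fold_ids: tuple[tuple[str, ...], ...]

    @property
    def k(self) -> int:
        return len(self.fold_ids)

    def train_ids(self, fold: int) -> list[str]:
        out: list[str] = []
        for f, ids in enumerate(self.fold_ids):
            if f != fold:
                out.extend(ids)
        return out


def make_folds(
    cohort: CohortTable, K: int, rng: np.random.Generator | int | None = None
) -> FoldPlan:
    """Stratified K-fold partition: per-fold case counts differ by at most 1."""
    rng = np.random.default_rng(rng)
    labels = cohort.labels.to_numpy()
    n_cases = int(labels.sum())
    n_controls = int(len(labels) - n_cases)
    if n_cases < K or n_controls < K:
        raise ValueError(
            f"need at least K={K} cases and controls to stratify "
            f"(got {n_cases} cases, {n_controls} controls)"
        )
    skf = StratifiedKFold(
        n_splits=K, shuffle=True, random_state=int(rng.integers(2**31))
    )
    ids = np.asarray(cohort.ids, dtype=object)
    folds = tuple(
        tuple(ids[test]) for _, test in skf.split(np.zeros(len(ids)), labels)
    )
    return FoldPlan(fold_ids=folds)


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC-ROC, AUC-PR (average precision) and thresholded 2x2 metrics.

    AUC-ROC equals the probability that a random case outscores a random
    control (ties counted 1/2); predicted case means score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute metrics")
    pred = scores >= threshold
    pos = labels == 1
    return {
        "auc_roc": float(roc_auc_score(labels, scores)),
        "auc_pr": float(average_precision_score(labels, scores)),
        "accuracy": float(np.mean(pred == pos)),
        "sensitivity": float(np.mean(pred[pos])),
        "specificity": float(np.mean(~pred[~pos])),
    }


def percentile_ci(values: Sequence[float]) -> tuple[float, float]:
    """Empirical 2.5th/97.5th percentiles with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("at least 2 values are required for a percentile CI")
    lo, hi = np.percentile(values, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


@dataclass
class ConditionResult:
    """Per-repetition metrics and side artifacts for one condition."""

    condition: Condition
    metrics: pd.DataFrame  # one row per repetition, columns = METRIC_NAMES
    n_selected: list[int]  # retained-marker count per repetition x fold
    n_markers: int
    importance: pd.DataFrame | None = None
    audit: list[dict] | None = None
    error: str | None = None


def _condition_seed_sequence(seed: int, condition: Condition) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, zlib.crc32(condition.name.encode())])


def run_condition(
    cohort: CohortTable,
    condition: Condition,
    config: PipelineConfig,
    *,
    matched: bool = True,
    collect_importance: bool = False,
    audit: bool = False,
) -> ConditionResult:
    """Run repeated stratified CV for one modality condition.

    ``matched=True`` is the pipeline proper: ensembles trained on matched
    realizations, one matched validation realization scored per held-out
    fold. ``matched=False`` is the diagnostic unmatched pathway: a single
    ridge member per fold trained on the full training fold and scored on the
    full held-out fold (no matching anywhere), which retains any demographic
    confounding in the estimate.
    """
    sub = cohort.select_modalities(condition.modalities) if condition.modalities else cohort
    if not sub.marker_names:
        raise ValueError(f"condition {condition.name!r} selects no markers")
    rep_seqs = _condition_seed_sequence(config.seed, condition).spawn(
        config.repetitions
    )
    rows = []
    n_selected: list[int] = []
    acc = ImportanceAccumulator(sub.modality_map) if collect_importance else None
    audit_log: list[dict] | None = [] if audit else None

    for rep, rep_seq in enumerate(rep_seqs):
        fold_seq, *fold_children = rep_seq.spawn(1 + config.k_folds)
        plan = make_folds(sub, config.k_folds, np.random.default_rng(fold_seq))
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        for f in range(config.k_folds):
            prep_seq, train_seq, val_seq = fold_children[f].spawn(3)
            train = sub.subset(plan.train_ids(f))
            val = sub.subset(plan.fold_ids[f])
            try:
                prep = fit_prep(
                    train, config.corr_threshold, np.random.default_rng(prep_seq)
                )
                n_selected.append(len(prep.retained))
                if matched:
                    ensemble = train_ensemble(
                        train,
                        prep,
                        N=config.ensemble_size,
                        k=config.n_neighbors,
                        lam=config.lam,
                        rng=np.random.default_rng(train_seq),
                        fold_id=f,
                    )
                    val_set = match_within_fold(
                        val,
                        config.n_neighbors,
                        np.random.default_rng(val_seq),
                        fold_id=f,
                    )
                    val_rows = val.subset(val_set.ids)
                else:
                    member = fit_unmatched_member(train, prep, config.lam)
                    ensemble = Ensemble(members=[member], prep=prep)
                    val_set = None
                    val_rows = val
            except Exception as exc:  # add run context, then re-raise
                raise type(exc)(
                    f"repetition {rep}, fold {f}: {exc}"
                ) from exc
            scores = predict_proba(ensemble, val_rows)
            pooled_scores.append(scores)
            pooled_labels.append(val_rows.labels.to_numpy())
            if acc is not None:
                acc.add(ensemble, val_rows)
            if audit_log is not None:
                audit_log.append(
                    {
                        "repetition": rep,
                        "fold": f,
                        "train_matched_ids": sorted(
                            {pid for m in ensemble.members if m.matched for pid in m.matched.ids}
                        ),
                        "validation_matched_ids": sorted(val_set.ids) if val_set else [],
                        "retained": list(prep.retained),
                    }
                )
        metrics = compute_metrics(
            np.concatenate(pooled_scores),
            np.concatenate(pooled_labels),
            config.decision_threshold,
        )
        rows.append(metrics)
        logger.info(
            "condition=%s repetition=%d/%d folds=%d auc_roc=%.3f",
            condition.name,
            rep + 1,
            config.repetitions,
            config.k_folds,
            metrics["auc_roc"],
        )
    return ConditionResult(
        condition=condition,
        metrics=pd.DataFrame(rows),
        n_selected=n_selected,
        n_markers=len(sub.marker_names),
        importance=acc.table(condition=condition.name) if acc is not None else None,
        audit=audit_log,
    )


def run_ablation(
    cohort: CohortTable,
    config: PipelineConfig,
    conditions: Sequence[Condition] | None = None,
    *,
    collect_importance: bool = False,
) -> list[ConditionResult]:
    """Run every condition; a failing condition is reported, not fatal."""
    if conditions is None:
        conditions = config.conditions or study_conditions(cohort.modalities)
    results = []
    for cond in conditions:
        try:
            results.append(
                run_condition(
                    cohort, cond, config, collect_importance=collect_importance
                )
            )
        except Exception as exc:
            logger.error("condition %s failed: %s", cond.name, exc)
            results.append(
                ConditionResult(
                    condition=cond,
                    metrics=pd.DataFrame(columns=list(METRIC_NAMES)),
                    n_selected=[],
                    n_markers=0,
                    error=str(exc),
                )
            )
    return results


def summarize(results: Sequence[ConditionResult]) -> pd.DataFrame:
    """One summary row per condition, sorted ascending by median AUC-ROC.

    Columns mirror the standard report layout: total and mean-selected marker
    counts, then median and 95% percentile CI for each of the five metrics.
    """
    rows = []
    for res in results:
        row: dict[str, object] = {
            "condition": res.condition.name,
            "modalities": "+".join(res.condition.modalities) or "all",
            "markers_total": res.n_markers,
            "markers_mean_selected": (
                float(np.mean(res.n_selected)) if res.n_selected else np.nan
            ),
        }
        for m in METRIC_NAMES:
            if res.error is None and len(res.metrics):
                vals = res.metrics[m].to_numpy()
                lo, hi = percentile_ci(vals)
                row[f"{m}_median"] = float(np.median(vals))
                row[f"{m}_lo"], row[f"{m}_hi"] = lo, hi
            else:
                row[f"{m}_median"] = row[f"{m}_lo"] = row[f"{m}_hi"] = np.nan
        row["error"] = res.error
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        "auc_roc_median", na_position="first", kind="mergesort"
    ).reset_index(drop=True)


def ablation_report(
    cohort: CohortTable,
    config: PipelineConfig,
    conditions: Sequence[Condition] | None = None,
    *,
    collect_importance: bool = False,
) -> pd.DataFrame:
    """Run the ablation grid and return the ordered summary table."""
    return summarize(
        run_ablation(
            cohort, config, conditions, collect_importance=collect_importance
        )
    )
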