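"""Stochastic 1:1 propensity-score matching within a cross-validation fold.

For each case, the k controls closest in propensity score are located and one
is drawn uniformly at random; the drawn control leaves the pool, so every
participant appears at most once per matched realization. Cases are processed
in random order to avoid a systematic order bias, and distance ties are broken
by participant id before sampling so that a seeded random stream fully
determines the realization. Repeating the procedure with fresh streams yields
the distinct randomized matched cohorts that the bagged ensemble and the
matched-validation estimator consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import DEMOGRAPHIC_COLUMNS, CohortTable

__all__ = ["MatchedSet", "MatchingError", "match_within_fold", "balance_report"]


class MatchingError(RuntimeError):
    """Raised when a fold cannot supply a 1:1 matched set."""


@dataclass(frozen=True)
class MatchedSet:
    """One balanced case/control realization drawn from a single fold."""

    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    fold_id: int = -1
    realization: int = -1

    def __post_init__(self) -> None:
        if len(self.case_ids) != len(self.control_ids):
            raise ValueError("matched set must pair every case with one control")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError("case and control id sets must be disjoint")
        all_ids = self.case_ids + self.control_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("participant ids must be distinct within a matched set")

    @property
    def ids(self) -> tuple[str, ...]:
        return self.case_ids + self.control_ids

    def __len__(self) -> int:
        return len(self.case_ids)


def match_within_fold(
    fold: CohortTable,
    k: int,
    rng: np.random.Generator,
    *,
    fold_id: int = -1,
    realization: int = -1,
) -> MatchedSet:
    """Draw one stochastic k-nearest-neighbor matched realization from a fold.

    Only the propensity column is consulted; markers play no role. Controls
    are drawn without reuse: each case (visited in random order) receives one
    control sampled uniformly from its k nearest remaining neighbors in
    propensity-score space.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    case_ids = np.asarray(fold.case_ids, dtype=object)
    control_ids = np.asarray(sorted(fold.control_ids), dtype=object)
    if case_ids.size == 0:
        raise MatchingError(f"fold {fold_id}: no cases to match")
    if control_ids.size < case_ids.size:
        raise MatchingError(
            f"fold {fold_id}: controls exhausted "
            f"({control_ids.size} controls for {case_ids.size} cases)"
        )
    if k > control_ids.size:
        warnings.warn(
            f"fold {fold_id}: k={k} exceeds the {control_ids.size} available "
            "controls; truncating",
            UserWarning,
            stacklevel=2,
        )

    prop = fold.propensity
    case_p = prop.loc[list(case_ids)].to_numpy(float)
    pool_ids = control_ids.copy()
    pool_p = prop.loc[list(pool_ids)].to_numpy(float)

    order = rng.permutation(case_ids.size)
    chosen: dict[str, str] = {}
    for ci in order:
        dist = np.abs(pool_p - case_p[ci])
        # ties in distance broken by id order, then uniform among the k nearest
        nearest = np.lexsort((pool_ids, dist))[: min(k, pool_ids.size)]
        pick = nearest[rng.integers(nearest.size)]
        chosen[case_ids[ci]] = pool_ids[pick]
        keep = np.ones(pool_ids.size, dtype=bool)
        keep[pick] = False
        pool_ids = pool_ids[keep]
        pool_p = pool_p[keep]

    return MatchedSet(
        case_ids=tuple(case_ids),
        control_ids=tuple(chosen[c] for c in case_ids),
        fold_id=fold_id,
        realization=realization,
    )


def _indicator_frame(
    data: pd.DataFrame, demographics: Sequence[str]
) -> pd.DataFrame:
    """Numeric view of demographic columns; categoricals become indicators."""
    pieces = []
    for col in demographics:
        s = data[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float).to_frame(col))
        else:
            pieces.append(pd.get_dummies(s, prefix=col).astype(float))
    return pd.concat(pieces, axis=1)


def _smd(x1: np.ndarray, x0: np.ndarray) -> tuple[float, bool]:
    pooled = np.sqrt((np.var(x1) + np.var(x0)) / 2.0)
    if pooled == 0.0:
        return 0.0, True
    return float((x1.mean() - x0.mean()) / pooled), False


def balance_report(
    matched: MatchedSet,
    cohort: CohortTable,
    demographics: Sequence[str] = DEMOGRAPHIC_COLUMNS,
    *,
    repetition: int | None = None,
) -> pd.DataFrame:
    """Standardized mean differences of demographics, before vs after matching.

    "Before" compares all cases with all controls in ``cohort``; "after"
    compares the matched groups. Categorical variables are expanded into
    indicator columns. A zero pooled SD yields SMD 0 with ``zero_variance``
    flagged. The matched set's fold and realization tags (plus an optional
    ``repetition``) are carried into the output so reports from many
    realizations concatenate into one audit CSV.
    """
    if len(matched) == 0:
        raise ValueError("matched set is empty")
    ind = _indicator_frame(cohort.data, demographics)
    labels = cohort.labels
    rows = []
    for col in ind.columns:
        before, deg_b = _smd(
            ind.loc[labels == 1, col].to_numpy(),
            ind.loc[labels == 0, col].to_numpy(),
        )
        after, deg_a = _smd(
            ind.loc[list(matched.case_ids), col].to_numpy(),
            ind.loc[list(matched.control_ids), col].to_numpy(),
        )
        rows.append(
            {
                "variable": col,
                "smd_before": before,
                "smd_after": after,
                "zero_variance": deg_b or deg_a,
            }
        )
    out = pd.DataFrame(rows)
    out["realization"] = matched.realization
    out["fold"] = matched.fold_id
    if repetition is not None:
        out["repetition"] = repetition
    return out
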