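"""Exact Shapley attribution for the linear log-odds model.

For a linear scoring function f(x) = w'x + b with features treated as
independent (interventional background), the Shapley value of feature i at a
point x relative to a reference point r has the closed form

    phi_i = w_i * (x_i - r_i)

because every coalition's marginal contribution of feature i is identical.
Attribution is done on the log-odds margin, where the closed form is exact;
local accuracy (sum phi = f(x) - f(r)) then holds to machine precision. Each
ensemble member uses its own matched training cohort's standardized means as
the reference, member attributions are averaged into an ensemble attribution
per validation row, and marker importance is the arithmetic mean of absolute
ensemble attributions over all validation rows, folds and repetitions.
Direction signs come from the mean fitted weight, matching the convention of
reporting regression-coefficient signs alongside importance ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_prep import apply_prep
from .matched_ensemble import Ensemble, RidgeLogitMember
from .synthetic_cohort import (
    IMAGING_MODALITIES,
    PHYSICAL_MODALITIES,
    CohortTable,
)

__all__ = [
    "shapley_linear",
    "ensemble_shapley",
    "ImportanceAccumulator",
    "ensemble_importance",
    "importance_report",
    "rank_overlap",
    "plot_importance",
]


def shapley_linear(
    member: RidgeLogitMember | np.ndarray,
    x: np.ndarray,
    background: np.ndarray,
) -> np.ndarray:
    """Exact per-feature Shapley values of the linear log-odds margin."""
    w = member.weights if isinstance(member, RidgeLogitMember) else np.asarray(member, float)
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    if x.shape[-1] != w.shape[0] or background.shape != w.shape:
        raise ValueError("weights, x and background dimensions must agree")
    if not (
        np.all(np.isfinite(w))
        and np.all(np.isfinite(x))
        and np.all(np.isfinite(background))
    ):
        raise ValueError("non-finite inputs to Shapley attribution")
    return w * (x - background)


def ensemble_shapley(ensemble: Ensemble, rows: CohortTable) -> pd.DataFrame:
    """Per-row ensemble attribution: mean over members of member phi."""
    X = apply_prep(ensemble.prep, rows).to_numpy()
    phi = np.zeros_like(X)
    for m in ensemble.members:
        phi += shapley_linear(m, X, m.background)
    phi /= ensemble.n_members
    return pd.DataFrame(phi, index=rows.ids, columns=list(ensemble.retained))


_SIGN = {1: "+", -1: "-", 0: "0"}


@dataclass
class ImportanceAccumulator:
    """Streams |ensemble phi| over validation rows across folds/repetitions.

    A marker pruned in some folds is averaged over the folds where it was
    retained; ``coverage`` reports the retained fraction.
    """

    modality_map: Mapping[str, str]
    _abs_sum: dict[str, float] = field(default_factory=dict)
    _row_count: dict[str, int] = field(default_factory=dict)
    _weight_sum: dict[str, float] = field(default_factory=dict)
    _member_count: dict[str, int] = field(default_factory=dict)
    _fold_hits: dict[str, int] = field(default_factory=dict)
    _n_folds: int = 0

    def add(self, ensemble: Ensemble, rows: CohortTable) -> None:
        if rows.n == 0:
            raise ValueError("at least one validation row is required")
        phi = ensemble_shapley(ensemble, rows)
        abs_sum = phi.abs().sum(axis=0)
        wsum = np.sum([m.weights for m in ensemble.members], axis=0)
        self._n_folds += 1
        for j, marker in enumerate(ensemble.retained):
            self._abs_sum[marker] = self._abs_sum.get(marker, 0.0) + float(abs_sum.iloc[j])
            self._row_count[marker] = self._row_count.get(marker, 0) + rows.n
            self._weight_sum[marker] = self._weight_sum.get(marker, 0.0) + float(wsum[j])
            self._member_count[marker] = (
                self._member_count.get(marker, 0) + ensemble.n_members
            )
            self._fold_hits[marker] = self._fold_hits.get(marker, 0) + 1

    def table(self, condition: str | None = None) -> pd.DataFrame:
        """Importance table: mean |phi|, rank (1 = most important), sign."""
        if not self._abs_sum:
            raise ValueError("no attributions accumulated")
        markers = sorted(self._abs_sum)
        value = np.array([self._abs_sum[m] / self._row_count[m] for m in markers])
        mean_w = np.array(
            [self._weight_sum[m] / self._member_count[m] for m in markers]
        )
        order = np.lexsort((markers, -value))
        rank = np.empty(len(markers), dtype=int)
        rank[order] = np.arange(1, len(markers) + 1)
        df = pd.DataFrame(
            {
                "marker": markers,
                "modality": [self.modality_map.get(m, "unknown") for m in markers],
                "mean_abs_shap": value,
                "direction": [_SIGN[int(np.sign(w))] for w in mean_w],
                "rank": rank,
                "coverage": [self._fold_hits[m] / self._n_folds for m in markers],
                "n_rows": [self._row_count[m] for m in markers],
            }
        )
        if condition is not None:
            df["condition"] = condition
        return df.sort_values("rank").reset_index(drop=True)


def ensemble_importance(
    ensemble: Ensemble,
    rows: CohortTable,
    condition: str | None = None,
) -> pd.DataFrame:
    """One-shot importance table for a single ensemble and validation rows."""
    acc = ImportanceAccumulator(rows.modality_map)
    acc.add(ensemble, rows)
    return acc.table(condition=condition)


def rank_overlap(
    table_a: pd.DataFrame, table_b: pd.DataFrame, top: int = 10
) -> int:
    """How many of table_a's top-``top`` markers appear in table_b's top-``top``."""
    top_a = set(table_a.nsmallest(top, "rank")["marker"])
    top_b = set(table_b.nsmallest(top, "rank")["marker"])
    return len(top_a & top_b)


def _default_groups() -> dict[str, tuple[str, ...]]:
    return {"imaging": IMAGING_MODALITIES, "physical-health": PHYSICAL_MODALITIES}


def importance_report(
    tables: Sequence[pd.DataFrame],
    top_m: int = 15,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Top markers per modality group, with cross-condition ranks.

    ``tables`` are condition-labelled importance tables (see
    :meth:`ImportanceAccumulator.table`). The first table defines the values
    and ordering; each further condition contributes a ``rank_<condition>``
    column so the report mirrors a side-by-side rank comparison.
    """
    if not tables:
        raise ValueError("at least one importance table is required")
    groups = dict(groups) if groups is not None else _default_groups()
    base = tables[0].copy()
    base_cond = str(base["condition"].iloc[0]) if "condition" in base else "condition_0"
    base = base.rename(columns={"rank": f"rank_{base_cond}"})
    for i, other in enumerate(tables[1:], start=1):
        cond = str(other["condition"].iloc[0]) if "condition" in other else f"condition_{i}"
        base = base.merge(
            other[["marker", "rank"]].rename(columns={"rank": f"rank_{cond}"}),
            on="marker",
            how="left",
        )

    def group_of(modality: str) -> str:
        for g, mods in groups.items():
            if modality in mods:
                return g
        return modality

    base["group"] = base["modality"].map(group_of)
    pieces = []
    for g, sub in base.groupby("group", sort=True):
        pieces.append(sub.nsmallest(min(top_m, len(sub)), f"rank_{base_cond}"))
    out = pd.concat(pieces).reset_index(drop=True)
    drop = [c for c in ("condition",) if c in out.columns]
    return out.drop(columns=drop)


def plot_importance(
    table: pd.DataFrame, path: str, top_m: int = 15
) -> None:
    """Horizontal bar chart of the top markers by mean |Shapley value|."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = table.nsmallest(min(top_m, len(table)), "rank").iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(top) + 1.2))
    colors = ["#4878d0" if d == "+" else "#d65f5f" for d in top["direction"]]
    ax.barh(top["marker"], top["mean_abs_shap"], color=colors)
    ax.set_xlabel("mean |Shapley value| (log-odds units)")
    ax.set_title("Marker importance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
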