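"""Train-fold marker standardization and correlation-threshold pruning.

Both statistics and the retained-marker set are estimated on training rows
only and then applied unchanged to held-out rows, so no information leaks
from the validation fold. Pruning removes one member of every marker pair
whose training |Pearson r| exceeds the threshold; which member survives is
random (seeded), since the pair is statistically interchangeable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import CohortTable

__all__ = ["PrepState", "fit_prep", "apply_prep"]


@dataclass(frozen=True)
class PrepState:
    """Frozen standardization and pruning state fitted on one training fold."""

    means: pd.Series
    sds: pd.Series
    retained: tuple[str, ...]
    threshold: float
    dropped_correlated: tuple[str, ...] = ()
    dropped_zero_variance: tuple[str, ...] = ()

    def to_text(self) -> str:
        """Plain-text audit artifact; round-trips via :meth:`from_text`."""
        return json.dumps(
            {
                "threshold": self.threshold,
                "retained": list(self.retained),
                "dropped_correlated": list(self.dropped_correlated),
                "dropped_zero_variance": list(self.dropped_zero_variance),
                "means": {m: self.means[m] for m in self.retained},
                "sds": {m: self.sds[m] for m in self.retained},
            },
            indent=2,
        )

    @classmethod
    def from_text(cls, text: str) -> "PrepState":
        d = json.loads(text)
        return cls(
            means=pd.Series(d["means"]),
            sds=pd.Series(d["sds"]),
            retained=tuple(d["retained"]),
            threshold=float(d["threshold"]),
            dropped_correlated=tuple(d["dropped_correlated"]),
            dropped_zero_variance=tuple(d["dropped_zero_variance"]),
        )


def _marker_frame(rows: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return rows.markers if isinstance(rows, CohortTable) else rows


def fit_prep(
    train_rows: CohortTable | pd.DataFrame,
    threshold: float = 0.90,
    rng: np.random.Generator | int | None = None,
) -> PrepState:
    """Fit standardization statistics and prune correlated markers.

    Zero-variance markers are dropped first (with a warning). Then, while any
    retained pair has training |Pearson r| above ``threshold``, one violating
    pair is chosen at random and one of its two members is dropped uniformly
    at random. Means and SDs (population, ddof=0) come from the training rows
    only.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    rng = np.random.default_rng(rng)
    X = _marker_frame(train_rows)
    if len(X) < 2:
        raise ValueError("at least 2 training rows are required")

    means = X.mean()
    sds = X.std(ddof=0)
    zero_var = tuple(sds.index[sds == 0.0])
    if zero_var:
        warnings.warn(
            f"dropping {len(zero_var)} zero-variance marker(s): "
            + ", ".join(zero_var),
            UserWarning,
            stacklevel=2,
        )
    markers = [m for m in X.columns if m not in zero_var]
    if not markers:
        raise ValueError("all markers dropped: nothing to model")

    Z = (X[markers] - means[markers]) / sds[markers]
    corr = np.corrcoef(Z.to_numpy().T) if len(markers) > 1 else np.ones((1, 1))
    active = np.ones(len(markers), dtype=bool)
    dropped: list[str] = []
    while True:
        iu, ju = np.triu_indices(len(markers), k=1)
        mask = active[iu] & active[ju] & (np.abs(corr[iu, ju]) > threshold)
        viol_i, viol_j = iu[mask], ju[mask]
        if viol_i.size == 0:
            break
        pick = int(rng.integers(viol_i.size))
        victim = viol_i[pick] if rng.integers(2) == 0 else viol_j[pick]
        active[victim] = False
        dropped.append(markers[victim])

    retained = tuple(m for m, a in zip(markers, active) if a)
    if not retained:
        raise ValueError("all markers dropped: nothing to model")
    return PrepState(
        means=means,
        sds=sds,
        retained=retained,
        threshold=threshold,
        dropped_correlated=tuple(dropped),
        dropped_zero_variance=zero_var,
    )


def apply_prep(
    state: PrepState, rows: CohortTable | pd.DataFrame
) -> pd.DataFrame:
    """Standardize ``rows`` with the frozen training statistics.

    Pure function of (state, rows): no statistic is recomputed from the input.
    """
    X = _marker_frame(rows)
    missing = [m for m in state.retained if m not in X.columns]
    if missing:
        raise ValueError(
            "rows are missing retained marker column(s): " + ", ".join(missing)
        )
    cols = list(state.retained)
    return (X[cols] - state.means[cols]) / state.sds[cols]
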