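"""Synthetic multimodal cohort generation.

The analysis pipeline in this package was designed for a large pediatric
cohort in which a rare, strongly sex-skewed outcome (parent-reported autism
spectrum disorder, ~1.4% prevalence, >80% male among cases) is to be
classified from tabulated neuroimaging and physical-health markers. Access to
the real cohort is controlled, so this module generates cohorts with the same
statistical structure: demographics that confound both the outcome and the
markers, block-correlated marker panels grouped into modalities, optional
near-duplicate marker pairs (to exercise correlation pruning), and planted
case/control effects of configurable size.

The generative model, in order:

1. demographics — age ~ Normal, sex ~ Bernoulli, race/ethnicity ~ 5-level
   categorical with cohort-like frequencies;
2. outcome — Bernoulli with logistic probability in the demographics; the
   intercept is solved numerically so the expected case fraction equals the
   configured prevalence exactly (prevalence is a contract, not an accident);
3. markers — one shared latent factor per modality block (pairwise
   within-block correlation equal to the block's ``correlation`` parameter)
   plus independent noise, plus ``confounding_strength`` times the
   standardized demographic log-odds, plus any planted label effects;
4. propensity — the true demographic-model probability (the matching stage
   consumes propensities that are supplied externally, exactly as in the
   study design), clipped away from {0, 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ModalityBlock",
    "PlantedEffect",
    "SimConfig",
    "CohortTable",
    "generate_cohort",
    "compute_propensity",
    "demographic_log_odds",
    "write_cohort",
    "read_cohort",
    "default_blocks",
    "default_planted_effects",
    "RESERVED_COLUMNS",
    "DEMOGRAPHIC_COLUMNS",
    "PROPENSITY_EPS",
    "IMAGING_MODALITIES",
    "PHYSICAL_MODALITIES",
]

RESERVED_COLUMNS = ("label", "age", "sex", "race_ethnicity", "propensity")
DEMOGRAPHIC_COLUMNS = ("age", "sex", "race_ethnicity")

#: Propensities are clipped into [eps, 1-eps] to avoid degenerate distance
#: ties at the boundary of the unit interval.
PROPENSITY_EPS = 1e-6

IMAGING_MODALITIES = ("RSI", "DTI", "s-MRI", "f-MRI Rest")
PHYSICAL_MODALITIES = ("Anthropometrics", "Medical-History", "SDSC")

RACE_LEVELS = ("White", "Hispanic", "Black", "Asian", "Other")
RACE_FREQUENCIES = (0.544, 0.204, 0.132, 0.018, 0.102)

# Outcome log odds-ratios vs the White reference level, chosen so the
# rare-outcome case mix reproduces the cohort's reported racial/ethnic skews.
RACE_LOG_ODDS = {
    "White": 0.0,
    "Hispanic": -0.19,
    "Black": -0.10,
    "Asian": -0.81,
    "Other": 0.45,
}

AGE_MEAN = 9.93
AGE_SD = 0.63
AGE_LOG_ODDS = 0.18  # per year of age

_MODALITY_PREFIX = {
    "s-MRI": "smri",
    "DTI": "dti",
    "RSI": "rsi",
    "f-MRI Rest": "fmri",
    "Anthropometrics": "anthro",
    "Medical-History": "medhx",
    "SDSC": "sdsc",
}

#: Target empirical correlation for planted near-duplicate marker pairs.
NEAR_DUPLICATE_R = 0.95


def _prefix(modality: str) -> str:
    if modality in _MODALITY_PREFIX:
        return _MODALITY_PREFIX[modality]
    return "".join(c for c in modality.lower() if c.isalnum()) or "mod"


@dataclass(frozen=True)
class ModalityBlock:
    """A group of markers sharing one latent factor.

    ``correlation`` is the pairwise Pearson correlation between any two
    markers of the block induced by the shared factor (before confounding
    and planted effects are added); it must lie in [0, 1).
    """

    modality: str
    n_markers: int
    correlation: float

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError(f"block {self.modality!r}: n_markers must be >= 1")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError(
                f"block {self.modality!r}: correlation must be in [0, 1)"
            )

    def marker_ids(self) -> list[str]:
        p = _prefix(self.modality)
        return [f"{p}_{i + 1:03d}" for i in range(self.n_markers)]


@dataclass(frozen=True)
class PlantedEffect:
    """A direct label effect on one marker.

    ``size`` is the standardized mean shift (in units of the marker's
    pre-confounding noise SD) added to cases; ``sign`` gives its direction.
    """

    marker: str
    size: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("planted effect size must be nonnegative")
        if self.sign not in (-1, 0, 1):
            raise ValueError("planted effect sign must be -1, 0 or +1")


def default_blocks() -> tuple[ModalityBlock, ...]:
    """Seven modality blocks mirroring the study's marker panels at ~1/4 scale."""
    return (
        ModalityBlock("s-MRI", 20, 0.3),
        ModalityBlock("DTI", 15, 0.4),
        ModalityBlock("RSI", 10, 0.4),
        ModalityBlock("f-MRI Rest", 15, 0.2),
        ModalityBlock("Anthropometrics", 4, 0.5),
        ModalityBlock("Medical-History", 3, 0.1),
        ModalityBlock("SDSC", 10, 0.3),
    )


def default_planted_effects() -> tuple[PlantedEffect, ...]:
    """Modest signal concentrated in SDSC, f-MRI and s-MRI; RSI carries none.

    This reproduces, qualitatively, the modality ordering observed in the
    study population: sleep-function markers strongest among physical-health
    modalities, functional and structural MRI strongest among imaging
    modalities, restriction-spectrum imaging and anthropometrics near chance.
    """
    return (
        PlantedEffect("sdsc_001", 0.30, +1),
        PlantedEffect("sdsc_002", 0.25, +1),
        PlantedEffect("sdsc_003", 0.20, -1),
        PlantedEffect("fmri_001", 0.25, +1),
        PlantedEffect("fmri_002", 0.20, -1),
        PlantedEffect("smri_001", 0.25, +1),
        PlantedEffect("smri_002", 0.20, -1),
        PlantedEffect("medhx_001", 0.25, +1),
        PlantedEffect("anthro_001", 0.15, +1),
        PlantedEffect("dti_001", 0.10, +1),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort.

    Defaults are the reference study conditions: 8503 participants, 1.4%
    prevalence, 82.2% male among cases vs 49.3% among controls, seven
    modality blocks, weak demographic confounding of the markers, and two
    near-duplicate marker pairs.
    """

    n_participants: int = 8503
    prevalence: float = 0.014
    male_fraction_cases: float = 0.822
    male_fraction_controls: float = 0.493
    modality_blocks: tuple[ModalityBlock, ...] = field(default_factory=default_blocks)
    planted_effects: tuple[PlantedEffect, ...] = field(
        default_factory=default_planted_effects
    )
    confounding_strength: float = 0.2
    near_duplicate_pairs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modality_blocks", tuple(self.modality_blocks))
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for name, v in (
            ("prevalence", self.prevalence),
            ("male_fraction_cases", self.male_fraction_cases),
            ("male_fraction_controls", self.male_fraction_controls),
        ):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.prevalence * self.n_participants < 2:
            raise ValueError(
                "prevalence * n_participants < 2: expected case count too small "
                "to stratify or match"
            )
        if self.confounding_strength < 0:
            raise ValueError("confounding_strength must be nonnegative")
        if self.near_duplicate_pairs < 0:
            raise ValueError("near_duplicate_pairs must be nonnegative")
        if not self.modality_blocks:
            raise ValueError("at least one modality block is required")
        ids = self.marker_ids()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids across blocks")
        known = set(ids)
        for pe in self.planted_effects:
            if pe.marker not in known:
                raise ValueError(
                    f"planted effect refers to unknown marker {pe.marker!r}"
                )
        self._duplicate_pairs()  # raises if not enough non-planted markers

    def marker_ids(self) -> list[str]:
        out: list[str] = []
        for b in self.modality_blocks:
            out.extend(b.marker_ids())
        return out

    def modality_map(self) -> dict[str, str]:
        return {
            mid: b.modality for b in self.modality_blocks for mid in b.marker_ids()
        }

    def _duplicate_pairs(self) -> list[tuple[str, str]]:
        """Deterministic choice of near-duplicate pairs among non-planted markers."""
        planted = {pe.marker for pe in self.planted_effects}
        pairs: list[tuple[str, str]] = []
        for b in self.modality_blocks:
            free = [m for m in b.marker_ids() if m not in planted]
            for i in range(0, len(free) - 1, 2):
                pairs.append((free[i], free[i + 1]))
        if len(pairs) < self.near_duplicate_pairs:
            raise ValueError(
                "near_duplicate_pairs exceeds the number of available "
                "non-planted within-block marker pairs"
            )
        return pairs[: self.near_duplicate_pairs]


@dataclass
class CohortTable:
    """Participant-level table plus its marker-to-modality dictionary.

    ``data`` is indexed by participant id and holds, in order: label (0/1),
    age, sex, race_ethnicity, propensity, then one column per marker.
    ``true_log_odds`` carries the generator's demographic linear predictor in
    synthetic mode (used by :func:`compute_propensity`); it is ``None`` for
    cohorts loaded from disk.
    """

    data: pd.DataFrame
    modality_map: dict[str, str]
    true_log_odds: pd.Series | None = None

    def __post_init__(self) -> None:
        markers = [c for c in self.data.columns if c not in RESERVED_COLUMNS]
        unmapped = [m for m in markers if m not in self.modality_map]
        if unmapped:
            raise ValueError(
                "marker columns missing from the data dictionary: "
                + ", ".join(sorted(unmapped))
            )
        extra = [m for m in self.modality_map if m not in self.data.columns]
        if extra:
            raise ValueError(
                "data dictionary entries with no matching marker column: "
                + ", ".join(sorted(extra))
            )
        if "propensity" in self.data.columns:
            p = self.data["propensity"].to_numpy(float)
            finite = p[np.isfinite(p)]
            if finite.size and ((finite <= 0.0) | (finite >= 1.0)).any():
                raise ValueError("propensity values must lie strictly in (0, 1)")
        if self.marker_names and self.markers.isna().any().any():
            raise ValueError("marker values must not be missing")

    # -- views -------------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def markers(self) -> pd.DataFrame:
        return self.data[self.marker_names]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"].astype(int)

    @property
    def propensity(self) -> pd.Series:
        return self.data["propensity"]

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index[self.data["label"] == 1])

    @property
    def control_ids(self) -> list[str]:
        return list(self.data.index[self.data["label"] == 0])

    @property
    def modalities(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.marker_names:
            seen.setdefault(self.modality_map[m], None)
        return list(seen)

    # -- subsetting --------------------------------------------------------
    def subset(self, ids: Iterable[str]) -> "CohortTable":
        ids = list(ids)
        tlo = None if self.true_log_odds is None else self.true_log_odds.loc[ids]
        return CohortTable(self.data.loc[ids], dict(self.modality_map), tlo)

    def select_modalities(self, modalities: Sequence[str]) -> "CohortTable":
        wanted = set(modalities)
        missing = wanted - set(self.modality_map.values())
        if missing:
            raise ValueError(
                "modalities absent from the data dictionary: "
                + ", ".join(sorted(missing))
            )
        keep = [m for m in self.marker_names if self.modality_map[m] in wanted]
        cols = [c for c in RESERVED_COLUMNS if c in self.data.columns] + keep
        return CohortTable(
            self.data[cols],
            {m: self.modality_map[m] for m in keep},
            self.true_log_odds,
        )


def demographic_log_odds(
    data: pd.DataFrame,
    *,
    intercept: float = 0.0,
    male_log_odds: float,
    age_log_odds: float = AGE_LOG_ODDS,
    race_log_odds: Mapping[str, float] = RACE_LOG_ODDS,
    age_center: float = AGE_MEAN,
) -> np.ndarray:
    """Linear predictor of the demographic outcome model, per participant."""
    male = (data["sex"].to_numpy() == "M").astype(float)
    age = data["age"].to_numpy(float)
    race = np.array([race_log_odds[r] for r in data["race_ethnicity"]])
    return intercept + male_log_odds * male + age_log_odds * (age - age_center) + race


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept a such that mean(sigmoid(a + lp)) == prevalence."""

    def gap(a: float) -> float:
        return float(np.mean(expit(a + lp))) - prevalence

    return brentq(gap, -40.0, 40.0, xtol=1e-12)


def generate_cohort(config: SimConfig) -> CohortTable:
    """Draw one cohort from the generative model; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    age = rng.normal(AGE_MEAN, AGE_SD, n)
    sex = np.where(rng.random(n) < config.male_fraction_controls, "M", "F")
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_FREQUENCIES)

    demo = pd.DataFrame({"age": age, "sex": sex, "race_ethnicity": race})
    # Rare-outcome approximation: controls mirror the population, so the sex
    # log odds-ratio that produces the target case mix is the logit difference.
    b_sex = float(
        logit(config.male_fraction_cases) - logit(config.male_fraction_controls)
    )
    lp = demographic_log_odds(demo, male_log_odds=b_sex)
    intercept = _solve_intercept(lp, config.prevalence)
    log_odds = intercept + lp
    y = (rng.random(n) < expit(log_odds)).astype(int)

    sd_lp = float(np.std(lp))
    z_lp = (lp - lp.mean()) / sd_lp if sd_lp > 0 else np.zeros(n)

    marker_ids = config.marker_ids()
    index = pd.Index([f"p{i:05d}" for i in range(n)], name="participant_id")
    X = np.empty((n, len(marker_ids)))
    col = 0
    for b in config.modality_blocks:
        latent = rng.standard_normal(n)
        noise = rng.standard_normal((n, b.n_markers))
        r = b.correlation
        X[:, col : col + b.n_markers] = (
            np.sqrt(r) * latent[:, None] + np.sqrt(1.0 - r) * noise
        )
        col += b.n_markers

    X += config.confounding_strength * z_lp[:, None]

    col_of = {m: j for j, m in enumerate(marker_ids)}
    for pe in config.planted_effects:
        X[:, col_of[pe.marker]] += pe.sign * pe.size * y

    for a, b_ in config._duplicate_pairs():
        xa = X[:, col_of[a]]
        za = (xa - xa.mean()) / xa.std()
        X[:, col_of[b_]] = NEAR_DUPLICATE_R * za + np.sqrt(
            1.0 - NEAR_DUPLICATE_R**2
        ) * rng.standard_normal(n)

    data = pd.concat(
        [
            pd.DataFrame(
                {
                    "label": y,
                    "age": age,
                    "sex": sex,
                    "race_ethnicity": race,
                    "propensity": np.nan,
                },
                index=index,
            ),
            pd.DataFrame(X, index=index, columns=marker_ids),
        ],
        axis=1,
    )
    cohort = CohortTable(
        data,
        config.modality_map(),
        true_log_odds=pd.Series(log_odds, index=index),
    )
    return compute_propensity(cohort)


def compute_propensity(
    cohort: CohortTable, eps: float = PROPENSITY_EPS
) -> CohortTable:
    """Fill the propensity column from demographics only.

    In synthetic mode (``true_log_odds`` present) the propensity is the true
    demographic-model probability — mirroring a study design where scores are
    supplied externally. Otherwise a demographic-only logistic model is fitted
    to (age, sex, race/ethnicity); markers are never consulted.
    """
    if cohort.true_log_odds is not None:
        p = expit(cohort.true_log_odds.to_numpy(float))
    else:
        demo = pd.get_dummies(
            cohort.data[list(DEMOGRAPHIC_COLUMNS)],
            columns=["sex", "race_ethnicity"],
            drop_first=True,
        ).to_numpy(float)
        if demo.size == 0 or np.all(demo.std(axis=0) == 0):
            warnings.warn(
                "degenerate demographics (no variation): all propensities equal",
                UserWarning,
                stacklevel=2,
            )
            p = np.full(cohort.n, float(cohort.labels.mean()))
        else:
            from sklearn.linear_model import LogisticRegression

            # C=inf: unpenalized maximum-likelihood fit
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
            model.fit(demo, cohort.labels.to_numpy())
            p = model.predict_proba(demo)[:, 1]
    data = cohort.data.copy()
    data["propensity"] = np.clip(p, eps, 1.0 - eps)
    return CohortTable(data, dict(cohort.modality_map), cohort.true_log_odds)


def write_cohort(cohort: CohortTable, directory: str | Path) -> tuple[Path, Path]:
    """Write ``cohort.csv`` and ``data_dictionary.csv``; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort_path = directory / "cohort.csv"
    dict_path = directory / "data_dictionary.csv"
    # %.17g guarantees float64 round-trips exactly through text
    cohort.data.to_csv(cohort_path, float_format="%.17g")
    pd.DataFrame(
        {
            "marker_name": cohort.marker_names,
            "description": [
                f"synthetic {cohort.modality_map[m]} marker" for m in cohort.marker_names
            ],
            "modality": [cohort.modality_map[m] for m in cohort.marker_names],
        }
    ).to_csv(dict_path, index=False)
    return cohort_path, dict_path


def read_cohort(
    cohort_path: str | Path, dictionary_path: str | Path | None = None
) -> CohortTable:
    """Load a cohort written by :func:`write_cohort` (lossless round trip).

    ``cohort_path`` may be the directory produced by :func:`write_cohort` or
    an explicit CSV path accompanied by ``dictionary_path``.
    """
    cohort_path = Path(cohort_path)
    if cohort_path.is_dir():
        dictionary_path = cohort_path / "data_dictionary.csv"
        cohort_path = cohort_path / "cohort.csv"
    if dictionary_path is None:
        raise ValueError("dictionary_path is required when cohort_path is a file")
    data = pd.read_csv(cohort_path, index_col=0, float_precision="round_trip")
    dictionary = pd.read_csv(dictionary_path)
    modality_map = dict(zip(dictionary["marker_name"], dictionary["modality"]))
    return CohortTable(data, modality_map)
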