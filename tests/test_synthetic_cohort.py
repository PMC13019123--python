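"""Generator contract: determinism, prevalence, confounding, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import binom

from matchedcv import (
    SimConfig,
    compute_propensity,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from matchedcv.synthetic_cohort import (
    IMAGING_MODALITIES,
    PHYSICAL_MODALITIES,
    ModalityBlock,
    PlantedEffect,
    demographic_log_odds,
)

from conftest import SMALL_CONFIG, toy_cohort


def test_identical_config_gives_bitwise_identical_cohort():
    a = generate_cohort(SMALL_CONFIG)
    b = generate_cohort(SMALL_CONFIG)
    pd.testing.assert_frame_equal(a.data, b.data, check_exact=True)
    assert a.modality_map == b.modality_map


def test_case_count_within_binomial_99_interval():
    lo = binom.ppf(0.005, 10_000, 0.014)
    hi = binom.ppf(0.995, 10_000, 0.014)
    counts = [
        len(generate_cohort(
            SimConfig(n_participants=10_000, prevalence=0.014, seed=s)
        ).case_ids)
        for s in range(5)
    ]
    # each count falls outside the 99% interval with probability ~0.01
    assert sum(lo <= c <= hi for c in counts) >= 4


def test_defaults_mirror_study_cohort():
    config = SimConfig()
    assert config.prevalence == 0.014
    assert config.male_fraction_cases == 0.822
    modalities = {b.modality for b in config.modality_blocks}
    assert modalities == set(IMAGING_MODALITIES) | set(PHYSICAL_MODALITIES)


def test_case_sex_skew_matches_configuration():
    cohort = generate_cohort(SimConfig(n_participants=20_000, seed=2))
    male_cases = (cohort.data.loc[cohort.case_ids, "sex"] == "M").mean()
    # 280 expected cases; binomial SE ~ 0.023 at p=0.822
    assert abs(male_cases - 0.822) < 0.08


def test_null_model_markers_independent_of_label():
    config = SimConfig(
        n_participants=3000,
        prevalence=0.05,
        planted_effects=(),
        confounding_strength=0.0,
        seed=7,
    )
    cohort = generate_cohort(config)
    y = cohort.labels.to_numpy(float)
    X = cohort.markers.to_numpy()
    corr = [np.corrcoef(X[:, j], y)[0, 1] for j in range(X.shape[1])]
    assert np.max(np.abs(corr)) < 0.1  # null point-biserial at n=3000


def test_near_duplicate_pairs_exceed_r_090():
    config = SimConfig(n_participants=1500, near_duplicate_pairs=2, seed=3)
    cohort = generate_cohort(config)
    corr = np.corrcoef(cohort.markers.to_numpy().T)
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    n_high = int(np.sum(np.abs(corr[iu, ju]) > 0.9))
    assert n_high >= 2


def test_confounded_markers_have_no_partial_association_given_demographics():
    config = SimConfig(
        n_participants=4000,
        prevalence=0.05,
        planted_effects=(),
        confounding_strength=1.0,
        near_duplicate_pairs=0,
        seed=9,
    )
    cohort = generate_cohort(config)
    y = cohort.labels.to_numpy(float)
    lp = cohort.true_log_odds.to_numpy()
    z = (lp - lp.mean()) / lp.std()
    X = cohort.markers.to_numpy()
    marginal, partial = [], []
    for j in range(X.shape[1]):
        x = X[:, j]
        marginal.append(abs(np.corrcoef(x, y)[0, 1]))
        resid = x - z * np.dot(x - x.mean(), z) / np.dot(z, z)
        partial.append(abs(np.corrcoef(resid, y)[0, 1]))
    assert np.mean(marginal) > 3 * np.mean(partial)


def test_rejects_cohorts_too_small_to_stratify():
    with pytest.raises(ValueError, match="< 2"):
        SimConfig(n_participants=50, prevalence=0.014)


def test_rejects_planted_effect_on_unknown_marker():
    with pytest.raises(ValueError, match="unknown marker"):
        SimConfig(planted_effects=(PlantedEffect("nope_001", 0.5),))


def test_propensity_matches_hand_evaluated_logistic():
    data = pd.DataFrame(
        {
            "age": [9.0, 11.0],
            "sex": ["M", "F"],
            "race_ethnicity": ["White", "Asian"],
        }
    )
    lp = demographic_log_odds(
        data,
        intercept=-3.0,
        male_log_odds=1.5,
        age_log_odds=0.2,
        race_log_odds={"White": 0.0, "Asian": -0.8},
        age_center=10.0,
    )
    # by hand: -3 + 1.5 + 0.2*(-1) + 0 = -1.7 ; -3 + 0 + 0.2*(1) - 0.8 = -3.6
    np.testing.assert_allclose(lp, [-1.7, -3.6], atol=1e-12)
    np.testing.assert_allclose(
        expit(lp), [1 / (1 + np.exp(1.7)), 1 / (1 + np.exp(3.6))], atol=1e-12
    )


def test_propensity_depends_only_on_demographics():
    cohort = generate_cohort(SMALL_CONFIG)
    bare = toy_cohort(
        cohort.labels.to_numpy(),
        np.full(cohort.n, 0.5),
        markers={"m1": np.arange(cohort.n, dtype=float)},
        ids=cohort.ids,
        age=cohort.data["age"].to_numpy(),
        sex=list(cohort.data["sex"]),
        race_ethnicity=list(cohort.data["race_ethnicity"]),
    )
    fitted = compute_propensity(bare)
    shuffled = bare.data.copy()
    shuffled["m1"] = shuffled["m1"].to_numpy()[::-1]
    refit = compute_propensity(
        type(bare)(shuffled, dict(bare.modality_map))
    )
    np.testing.assert_array_equal(
        fitted.propensity.to_numpy(), refit.propensity.to_numpy()
    )


def test_degenerate_demographics_warn_and_give_equal_propensities():
    bare = toy_cohort([1, 0, 0, 1], [0.5] * 4)
    with pytest.warns(UserWarning, match="degenerate demographics"):
        out = compute_propensity(bare)
    p = out.propensity.to_numpy()
    assert np.all(p == p[0])
    assert 0.0 < p[0] < 1.0


def test_write_read_round_trip_is_lossless(tmp_path):
    cohort = generate_cohort(SMALL_CONFIG)
    write_cohort(cohort, tmp_path)
    loaded = read_cohort(tmp_path)
    pd.testing.assert_frame_equal(cohort.data, loaded.data, check_exact=True)
    assert loaded.modality_map == cohort.modality_map


def test_dictionary_missing_marker_column_names_it(tmp_path):
    cohort = generate_cohort(SMALL_CONFIG)
    cohort_path, dict_path = write_cohort(cohort, tmp_path)
    d = pd.read_csv(dict_path)
    dropped = d["marker_name"].iloc[0]
    d.iloc[1:].to_csv(dict_path, index=False)
    with pytest.raises(ValueError, match=dropped):
        read_cohort(cohort_path, dict_path)


def test_dictionary_vocabulary_matches_study_modalities(tmp_path):
    _, dict_path = write_cohort(generate_cohort(SimConfig(seed=1, n_participants=500, prevalence=0.05)), tmp_path)
    vocab = set(pd.read_csv(dict_path)["modality"])
    assert vocab == {
        "s-MRI", "DTI", "RSI", "f-MRI Rest",
        "Anthropometrics", "Medical-History", "SDSC",
    }


def test_block_correlation_matches_shared_factor_model():
    config = SimConfig(
        n_participants=5000,
        prevalence=0.05,
        modality_blocks=(ModalityBlock("DTI", 8, 0.4),),
        planted_effects=(),
        confounding_strength=0.0,
        near_duplicate_pairs=0,
        seed=21,
    )
    cohort = generate_cohort(config)
    corr = np.corrcoef(cohort.markers.to_numpy().T)
    iu, ju = np.triu_indices(8, k=1)
    assert abs(np.mean(corr[iu, ju]) - 0.4) < 0.05
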