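import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from spinedef.stats import (
    AttractivenessRecord,
    ClimbComparison,
    ComparisonConfig,
    ContrastUndefinedError,
    DebarkComparison,
    NutritionComparison,
    StatsValidationError,
    classify_attractiveness,
    fit_nutrition_model,
)
from spinedef.synth import NutritionEffects, generate_nutrition_table


def binomial_frame(logits_a, logits_b, n_cells=4800):
    n = len(logits_a)
    return pd.DataFrame(
        {
            "syndrome": ["A"] * n + ["B"] * n,
            "accessible_fraction": expit(np.r_[logits_a, logits_b]),
            "n_cells": n_cells,
            "bite_size_cm": 4.0,
        }
    )


def test_debark_model_recovers_strong_contrast():
    rng = np.random.default_rng(1)
    df = binomial_frame(
        np.log(0.2 / 0.8) + rng.normal(0, 0.3, 10),
        np.log(0.8 / 0.2) + rng.normal(0, 0.3, 10),
    )
    res = DebarkComparison(df).fit()
    row = res.contrasts.iloc[0]
    assert row.estimate < 0
    assert row.excludes_zero
    assert row.evidence_ratio > 19  # decisive for a huge effect
    assert abs(row.estimate - 2 * np.log(0.2 / 0.8)) < 4 * row.se
    assert "Pairwise contrasts" in res.summary()


def test_debark_model_validates_fractions_and_groups():
    df = binomial_frame(np.zeros(3), np.zeros(3))
    bad = df.copy()
    bad.loc[0, "accessible_fraction"] = 1.5
    with pytest.raises(StatsValidationError):
        DebarkComparison(bad)
    single = df[df.syndrome == "A"]
    with pytest.raises(ContrastUndefinedError):
        DebarkComparison(single)


def test_climb_model_recovers_ratio_two():
    rng = np.random.default_rng(2)
    n = 15
    df = pd.DataFrame(
        {
            "syndrome": ["A"] * n + ["B"] * n,
            "best_cost": np.r_[
                rng.poisson(np.exp(np.log(60) + rng.normal(0, 0.2, n))),
                rng.poisson(np.exp(np.log(120) + rng.normal(0, 0.2, n))),
            ].astype(float),
            "paw_size_cm": 4.0,
        }
    )
    res = ClimbComparison(df).fit()
    row = res.contrasts.iloc[0]
    assert abs(row.estimate + np.log(2.0)) < 0.15
    assert row.excludes_zero


def test_climb_model_rejects_negative_costs():
    df = pd.DataFrame(
        {"syndrome": ["A", "B"], "best_cost": [10.0, -1.0], "paw_size_cm": 2.0}
    )
    with pytest.raises(StatsValidationError):
        ClimbComparison(df)


def test_nutrition_model_detects_thickness_doubling():
    eff = NutritionEffects()  # prickly inner bark x2 by default
    tab = generate_nutrition_table(eff, 15, 3, seed=3)
    res = NutritionComparison(
        tab, response="inner_bark_thickness", organ="inner_bark"
    ).fit()
    c = res.contrasts
    row = c[(c.group_a == "non_spiny") & (c.group_b == "prickly")].iloc[0]
    assert abs(row.estimate + np.log(2.0)) < 0.15
    assert row.excludes_zero
    # contrasts among the unaffected groups stay modest
    others = c[(c.group_a != "prickly") & (c.group_b != "prickly")]
    assert (others.estimate.abs() < 0.3).all()


def test_nutrition_model_validation():
    eff = NutritionEffects()
    tab = generate_nutrition_table(eff, 3, 2, seed=4)
    bad = tab.copy()
    bad.loc[bad.index[0], "nitrogen"] = -1.0
    with pytest.raises(StatsValidationError):
        NutritionComparison(bad, response="nitrogen")
    single = tab[tab.group == "prickly"]
    with pytest.raises(ContrastUndefinedError):
        fit_nutrition_model(single, response="nitrogen")


def test_evidence_ratio_monotone_in_effect_size():
    ers = []
    for ratio in (1.0, 1.5, 2.5):
        rng = np.random.default_rng(5)
        n = 8
        df = binomial_frame(
            np.log(0.3 / 0.7) + rng.normal(0, 0.3, n),
            np.log(0.3 / 0.7) + np.log(ratio) + rng.normal(0, 0.3, n),
        )
        row = DebarkComparison(df).fit().contrasts.iloc[0]
        ers.append(row.evidence_ratio)
    assert ers[0] < ers[1] < ers[2]


def test_null_contrasts_mostly_cover_zero():
    """Quick 6-replicate null check (the full 20-replicate calibration for
    all three models runs in the acceptance suite)."""
    excl = 0
    for rep in range(6):
        rng = np.random.default_rng(100 + rep)
        df = binomial_frame(
            np.log(0.3 / 0.7) + rng.normal(0, 0.3, 8),
            np.log(0.3 / 0.7) + rng.normal(0, 0.3, 8),
        )
        excl += int(DebarkComparison(df).fit().contrasts.excludes_zero.iloc[0])
    assert excl <= 1


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(fleshy=True, smelly_colourful=True, large_unprotected_seeds=False,
              anemochorous_or_small_seeds=False, corolla_diameter_cm=5.0),
         ("high", "large")),
        (dict(fleshy=False, smelly_colourful=False, large_unprotected_seeds=True,
              anemochorous_or_small_seeds=False, corolla_diameter_cm=3.0),
         ("medium", "large")),
        (dict(fleshy=False, smelly_colourful=False, large_unprotected_seeds=False,
              anemochorous_or_small_seeds=True, corolla_diameter_cm=2.0),
         ("low", "small")),  # corolla exactly 2 cm counts as small
    ],
)
def test_attractiveness_rules(kwargs, expected):
    rec = AttractivenessRecord(species_id="sp", **kwargs)
    assert classify_attractiveness(rec) == expected


def test_attractiveness_contradictions_rejected():
    with pytest.raises(StatsValidationError):
        classify_attractiveness(
            AttractivenessRecord("sp", True, True, False, True, 3.0)
        )
    with pytest.raises(StatsValidationError):
        classify_attractiveness(
            AttractivenessRecord("sp", False, False, True, True, 3.0)
        )
    with pytest.raises(StatsValidationError):
        AttractivenessRecord("sp", True, True, False, False, 0.0)
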