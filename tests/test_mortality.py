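"""Brass chain: aggregation, Trussell multipliers, q(x)/l(x), levels.

The worked-example oracle is the classic Panama 1976 application of the
children-ever-born/children-dead method (West family). The expected
numbers below were recomputed by literal hand arithmetic from the
published W/B/D tallies and are frozen here, independent of the package's
code path.
"""

import numpy as np
import pandas as pd
import pytest

from icebrass import (
    SyntheticConfig,
    aggregate_by_age,
    aggregates_from_counts,
    brass_chain,
    child_mortality,
    generate_population,
    ground_truth,
    load_model_lifetable,
    load_trussell_coefficients,
    mortality_by_bmi_group,
    mortality_grid_wide,
    mortality_levels,
    multipliers,
)
from icebrass.errors import DataError
from icebrass.lifetables import TrussellCoefficients
from icebrass.schema import AGE5_LABELS

from helpers import PANAMA_B, PANAMA_D, PANAMA_K, PANAMA_Q, PANAMA_W


def test_panama_worked_example_multipliers_and_q():
    agg = aggregates_from_counts(PANAMA_W, PANAMA_B, PANAMA_D)
    est = child_mortality(agg, load_trussell_coefficients())
    np.testing.assert_allclose(est["k"], PANAMA_K, atol=5e-4)
    np.testing.assert_allclose(est["q"], PANAMA_Q, atol=5e-4)
    np.testing.assert_allclose(est["l"], 1 - np.asarray(PANAMA_Q), atol=5e-4)


def test_aggregate_by_age_small_arithmetic():
    table = pd.DataFrame(
        {
            "age_group5": ["20-24"] * 3,
            "ceb": [2, 1, 0],
            "children_dead": [1, 0, 0],
            "weight": [1.0, 1.0, 1.0],
        }
    )
    agg = aggregate_by_age(table).set_index("age_group5")
    row = agg.loc["20-24"]
    assert row["W"] == 3 and row["B"] == 3 and row["D"] == 1
    assert row["d"] == pytest.approx(1 / 3)
    assert row["P"] == pytest.approx(1.0)
    # groups with no women have W = 0 and undefined d
    assert agg.loc["45-49", "W"] == 0
    assert np.isnan(agg.loc["45-49", "d"])


def test_weighted_aggregation_with_unit_weights_equals_unweighted(harmonized):
    a = aggregate_by_age(harmonized.assign(weight=1.0), weighted=True)
    b = aggregate_by_age(harmonized, weighted=False)
    pd.testing.assert_frame_equal(a, b)


def test_degenerate_coefficients_give_unit_multipliers():
    frame = pd.DataFrame(
        {"i": range(1, 8), "age_group": AGE5_LABELS, "a": 1.0, "b": 0.0, "c": 0.0}
    )
    k = multipliers(0.2, 1.5, 3.0, TrussellCoefficients(frame=frame))
    np.testing.assert_allclose(k, 1.0)


def test_multipliers_linear_in_first_parity_ratio():
    coeffs = load_trussell_coefficients()
    eps, P2 = 0.01, 1.5
    k0 = multipliers(0.2, P2, 3.0, coeffs)
    k1 = multipliers(0.2 + eps, P2, 3.0, coeffs)
    np.testing.assert_allclose(
        (k1 - k0).to_numpy(), coeffs.frame["b"].to_numpy() * eps / P2, atol=1e-12
    )


def test_zero_parity_ratios_rejected():
    with pytest.raises(DataError, match="P2"):
        multipliers(0.1, 0.0, 1.0)
    with pytest.raises(DataError, match="P3"):
        multipliers(0.1, 1.0, 0.0)


def test_no_deaths_gives_zero_q_and_full_survival():
    agg = aggregates_from_counts(
        PANAMA_W, PANAMA_B, [0] * 7
    )
    est = child_mortality(agg)
    assert (est["q"] == 0).all()
    assert (est["l"] == 1).all()


def test_q_l_exact_complement(harmonized):
    est = brass_chain(harmonized)
    valid = est[~est["undefined"]]
    np.testing.assert_array_equal(valid["l"].to_numpy(), 1 - valid["q"].to_numpy())


def test_more_deaths_weakly_raise_q_and_lower_level():
    base = aggregates_from_counts(PANAMA_W, PANAMA_B, PANAMA_D)
    more = aggregates_from_counts(
        PANAMA_W, PANAMA_B, [d + 40 for d in PANAMA_D]
    )
    lt = load_model_lifetable()
    est0 = mortality_levels(child_mortality(base), lt)
    est1 = mortality_levels(child_mortality(more), lt)
    assert (est1["q"] >= est0["q"]).all()
    # Coale-Demeny convention: higher level = higher survival
    assert (est1["level"] <= est0["level"]).all()


def test_chain_recovers_generator_survival(harmonized, small_config):
    est = brass_chain(harmonized)
    truth = ground_truth(small_config)
    merged = est.merge(truth, on="age_group5")
    # groups 20-24 .. 40-44 (the reliable core of the method)
    core = merged[merged["age_group5"].isin(AGE5_LABELS[1:6])]
    assert np.allclose(core["l"], core["l_true"], atol=0.03)


def test_bmi_grid_shape_and_pooling(harmonized):
    tidy = mortality_by_bmi_group(harmonized)
    waves = harmonized["wave_year"].nunique()
    assert set(tidy["stratum"]) == {"total", "underweight", "normal",
                                    "overweight_obese"}
    assert len(tidy) == 7 * 4 * waves
    # the total stratum equals the unstratified chain
    for wave, sub in harmonized.groupby("wave_year"):
        total = tidy[(tidy.wave_year == wave) & (tidy.stratum == "total")]
        direct = brass_chain(sub)
        np.testing.assert_allclose(
            total["level"].to_numpy(), direct["level"].to_numpy(), equal_nan=True
        )
    wide = mortality_grid_wide(tidy)
    assert list(wide.index) == AGE5_LABELS
    assert wide.shape == (7, 4 * waves)


def test_bmi_differential_mortality_shows_in_grid():
    cfg = SyntheticConfig(
        n_per_wave={2010: 30000},
        n_clusters=80,
        seed=5,
        pregnancy_rate=0.0,
        bmi_mortality_rr={"underweight": 1.6, "normal": 1.0,
                          "overweight": 1.6, "obese": 1.6},
    )
    from icebrass.survey import derive_fields

    table = derive_fields(generate_population(cfg))
    tidy = mortality_by_bmi_group(table)
    core = tidy[tidy["age_group5"].isin(AGE5_LABELS[1:6])]
    mean_level = core.groupby("stratum")["level"].mean()
    assert mean_level["underweight"] < mean_level["normal"]
    assert mean_level["overweight_obese"] < mean_level["normal"]


def test_null_bmi_strata_agree():
    """With BMI-independent generation all strata estimate the same level
    up to sampling noise (the underweight and obese strata are small, so a
    large sample is needed for tight cell estimates)."""
    cfg = SyntheticConfig(
        n_per_wave={2010: 40000}, n_clusters=100, seed=31, pregnancy_rate=0.0
    )
    from icebrass.survey import derive_fields

    table = derive_fields(generate_population(cfg))
    tidy = mortality_by_bmi_group(table)
    core = tidy[tidy["age_group5"].isin(AGE5_LABELS[1:6])].dropna(subset=["level"])
    spread = core.groupby("age_group5")["level"].agg(lambda s: s.max() - s.min())
    assert spread.mean() < 2.0  # sampling noise only


def test_tally_exceeding_births_rejected():
    with pytest.raises(DataError):
        aggregates_from_counts([10] * 7, [5] * 7, [6] * 7)
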