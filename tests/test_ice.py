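"""Index of concentration at the extremes: anchors, invariances, oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icebrass import SyntheticConfig, generate_population, ice, ice_by, ice_by_area
from icebrass.errors import DataError
from icebrass.ice import bootstrap_ci, to_geojson
from icebrass.schema import BMI_CATEGORIES, WEALTH_QUINTILES


from helpers import brute_force_ice


def test_complete_concentration_anchors():
    assert ice(H=10, L=0, T=10) == 1.0
    assert ice(H=0, L=10, T=10) == -1.0


def test_balance_gives_zero():
    assert ice(H=4, L=4, T=20) == 0.0


def test_invalid_groups_rejected():
    with pytest.raises(DataError):
        ice(1, 1, 0)
    with pytest.raises(DataError):
        ice(6, 6, 10)
    with pytest.raises(DataError):
        ice(-1, 0, 10)


def test_small_stratum_arithmetic():
    table = pd.DataFrame(
        {
            "wave_year": 2000,
            "residence": "rural",
            "bmi_category": ["obese"] * 3 + ["underweight"] * 2 + ["normal"] * 5,
            "weight": 1.0,
        }
    )
    out = ice_by(table, "residence", weighted=False)
    assert out["ice"].iloc[0] == pytest.approx(0.1)
    assert out[["H", "L", "T"]].iloc[0].tolist() == [3, 2, 10]


def test_uniform_reweighting_leaves_ice_unchanged(harmonized):
    a = ice_by(harmonized, "wealth_quintile")
    b = ice_by(harmonized.assign(weight=harmonized["weight"] * 2), "wealth_quintile")
    np.testing.assert_allclose(a["ice"], b["ice"])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.data())
def test_matches_brute_force_oracle_on_random_tables(data):
    n = data.draw(st.integers(1, 20))
    table = pd.DataFrame(
        {
            "wave_year": data.draw(
                st.lists(st.sampled_from([2000, 2015]), min_size=n, max_size=n)
            ),
            "residence": data.draw(
                st.lists(st.sampled_from(["urban", "rural"]), min_size=n, max_size=n)
            ),
            "bmi_category": data.draw(
                st.lists(st.sampled_from(BMI_CATEGORIES), min_size=n, max_size=n)
            ),
            "weight": data.draw(
                st.lists(
                    st.floats(0.1, 5, allow_nan=False), min_size=n, max_size=n
                )
            ),
        }
    )
    for weighted in (False, True):
        got = ice_by(table, "residence", weighted=weighted)
        oracle = brute_force_ice(table, "residence", weighted)
        assert len(got) == len(oracle)
        for _, row in got.iterrows():
            expect = oracle[(row["wave_year"], row["residence"])]
            assert row["ice"] == pytest.approx(expect, abs=1e-12)
            assert -1.0 <= row["ice"] <= 1.0


def test_overweight_rows_only_affect_totals(harmonized):
    """Moving a row between normal and overweight never moves any ICE."""
    flipped = harmonized.copy()
    mask = flipped["bmi_category"] == "overweight"
    flipped.loc[mask, "bmi_category"] = "normal"
    a = ice_by(harmonized, "education")
    b = ice_by(flipped, "education")
    np.testing.assert_allclose(a["ice"], b["ice"])
    # unless overweight is pooled into the high extreme (sensitivity variant)
    c = ice_by(harmonized, "education", include_overweight_high=True)
    assert not np.allclose(a["ice"], c["ice"])


def test_wealth_gradient_monotone_at_large_n():
    cfg = SyntheticConfig(n_per_wave={2010: 40000}, n_clusters=100, seed=2)
    from icebrass.survey import derive_fields

    table = derive_fields(generate_population(cfg))
    out = ice_by(table, "wealth_quintile").set_index("wealth_quintile")
    values = out.loc[WEALTH_QUINTILES, "ice"].to_numpy()
    assert (np.diff(values) >= 0).all()


def test_single_district_reduces_to_stratum_computation(harmonized):
    one = harmonized[harmonized["district"] == harmonized["district"].iloc[0]]
    by_area = ice_by_area(one, "district")
    direct = ice_by(one.assign(residence="all"), "residence")
    np.testing.assert_allclose(
        by_area.sort_values("wave_year")["ice"].to_numpy(),
        direct.sort_values("wave_year")["ice"].to_numpy(),
    )


def test_regional_bmi_shift_orders_regional_ice():
    cfg = SyntheticConfig(n_per_wave={2010: 40000}, n_clusters=120, seed=9)
    cfg.bmi_means = {**cfg.bmi_means, "region_North": -1.2, "region_South": 0.8}
    from icebrass.survey import derive_fields

    table = derive_fields(generate_population(cfg))
    out = ice_by_area(table, "region").set_index("region")
    assert out.loc["North", "ice"] < out.loc["South", "ice"]
    assert out["ice"].between(-1, 1).all()


def test_area_output_carries_centroids_and_geojson(harmonized_with_gps):
    table, _ = harmonized_with_gps
    out = ice_by_area(table, "district")
    assert {"longitude", "latitude"} <= set(out.columns)
    geo = to_geojson(out)
    assert geo["type"] == "FeatureCollection"
    assert len(geo["features"]) == len(out)
    props = geo["features"][0]["properties"]
    assert set(props) >= {"area", "wave_year", "H", "L", "T", "ice"}


def test_cluster_bootstrap_brackets_point_estimate(harmonized):
    out = bootstrap_ci(harmonized, "residence", n_boot=30, seed=4)
    ok = (out["ice_lo"] <= out["ice"] + 1e-9) & (out["ice"] <= out["ice_hi"] + 1e-9)
    assert ok.mean() > 0.8
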