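"""Survey I/O, dialects, joins, derivations, merging, harmonize order."""

import warnings

import numpy as np
import pandas as pd
import pytest

from icebrass import (
    Dialect,
    derive_fields,
    exclude_pregnant,
    generate_gps,
    harmonize,
    join_gps,
    merge_surveys,
    read_survey,
    write_survey,
)
from icebrass.errors import DataError, SchemaError
from icebrass.schema import RAW_COLUMNS
from icebrass.survey import DHS_DIALECT, read_gps


def test_csv_round_trip_identity(tmp_path, population):
    path = tmp_path / "wave.csv"
    write_survey(population, path)
    back = read_survey(path)
    pd.testing.assert_frame_equal(
        back, population[RAW_COLUMNS], check_dtype=False
    )


def test_dhs_dialect_rescales_bmi_and_weight(tmp_path, population):
    path = tmp_path / "dhs.csv"
    stored = population.copy()
    stored["bmi"] = (stored["bmi"] * 100).round(0)
    stored.loc[stored.index[0], "bmi"] = 2243
    stored["weight"] = stored["weight"] * 1_000_000
    write_survey(stored, path)
    back = read_survey(path, DHS_DIALECT)
    assert back["bmi"].iloc[0] == pytest.approx(22.43)
    np.testing.assert_allclose(back["weight"], population["weight"], rtol=1e-9)


def test_dialect_renames_and_decodes(tmp_path, population):
    path = tmp_path / "coded.csv"
    stored = population.rename(columns={"bmi": "v445", "residence": "v025"}).copy()
    stored["v025"] = stored["v025"].map({"urban": 1, "rural": 2})
    stored.to_csv(path, index=False)
    dialect = Dialect(
        column_map={"v445": "bmi", "v025": "residence"},
        category_maps={"residence": {1: "urban", 2: "rural"}},
    )
    back = read_survey(path, dialect)
    assert set(back["residence"]) <= {"urban", "rural"}


def test_empty_file_with_header_is_fine(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(",".join(RAW_COLUMNS) + "\n")
    table = read_survey(path)
    assert table.empty and list(table.columns) == RAW_COLUMNS


def test_missing_column_named_in_error(tmp_path, population):
    path = tmp_path / "broken.csv"
    population.drop(columns=["wealth_quintile"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="wealth_quintile"):
        read_survey(path)


def test_unparseable_value_reports_line_number(tmp_path, population):
    path = tmp_path / "bad.csv"
    broken = population.head(5).copy().astype({"ceb": object})
    broken.loc[broken.index[2], "ceb"] = "three"
    broken.to_csv(path, index=False)
    with pytest.raises(DataError, match=r"ceb.*\[4\]"):
        read_survey(path)


def test_join_gps_marks_unmatched_cluster(small_config, population):
    gps = generate_gps(small_config)
    drop = gps.iloc[1:]  # remove one cluster's coordinates
    with pytest.warns(UserWarning, match="no matching GPS"):
        joined = join_gps(population, drop)
    lost = (population["cluster_id"] == gps.iloc[0]["cluster_id"]) & (
        population["wave_year"] == gps.iloc[0]["wave_year"]
    )
    assert joined["longitude"].isna().sum() == lost.sum()
    full = join_gps(population, gps)
    assert full["longitude"].notna().all()


def test_join_gps_rejects_duplicate_keys(small_config, population):
    gps = generate_gps(small_config)
    with pytest.raises(DataError, match="duplicate"):
        join_gps(population, pd.concat([gps, gps.head(1)]))


def test_exclude_pregnant_counts_and_idempotence():
    table = pd.DataFrame(
        {"pregnant": [True] * 7 + [False] * 93, "x": range(100)}
    )
    out = exclude_pregnant(table)
    assert len(out) == 93
    pd.testing.assert_frame_equal(exclude_pregnant(out), out)


def test_derive_fields_small_cases():
    table = pd.DataFrame(
        {
            "age_years": [24, 35],
            "sons_dead": [2, 0],
            "daughters_dead": [1, 0],
            "ceb": [5, 0],
            "bmi": [22.0, 31.0],
        }
    )
    out = derive_fields(table)
    assert out.loc[0, "children_dead"] == 3
    assert out.loc[0, "age_group3"] == "15-24"
    assert out.loc[0, "age_group5"] == "20-24"
    assert out.loc[1, "age_group3"] == "35-49"
    assert out.loc[1, "age_group5"] == "35-39"
    assert out.loc[1, "bmi_category"] == "obese"


def test_derive_fields_rejects_bad_rows():
    table = pd.DataFrame(
        {
            "age_years": [24, 12, 30],
            "sons_dead": [0, 0, 4],
            "daughters_dead": [0, 0, 0],
            "ceb": [1, 1, 2],
            "bmi": [22.0, 22.0, 22.0],
        }
    )
    with pytest.warns(UserWarning):
        out = derive_fields(table)
    assert len(out) == 1  # age 12 rejected; children dead 4 > ceb 2 rejected
    assert (out["children_dead"] <= out["ceb"]).all()


def test_merge_requires_identical_schemas(population):
    waves = [g.reset_index(drop=True) for _, g in population.groupby("wave_year")]
    merged = merge_surveys(waves)
    assert len(merged) == len(population)
    with pytest.raises(SchemaError, match="bmi"):
        merge_surveys([waves[0], waves[1].drop(columns=["bmi"])])


def test_merge_single_wave_identity_and_order_invariance(population):
    waves = [g.reset_index(drop=True) for _, g in population.groupby("wave_year")]
    pd.testing.assert_frame_equal(merge_surveys([waves[0]]), waves[0])
    a = merge_surveys(waves).sort_values(RAW_COLUMNS).reset_index(drop=True)
    b = merge_surveys(waves[::-1]).sort_values(RAW_COLUMNS).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_harmonize_logs_every_stage(harmonized_with_gps, small_config, population):
    table, log = harmonized_with_gps
    assert log["stage_order"] == [
        "read", "join_gps", "impute", "derive", "exclude_pregnant"
    ]
    for year in small_config.wave_years:
        counts = log["waves"][year]
        n_read = (population["wave_year"] == year).sum()
        assert counts["read"] == n_read
        assert counts["exclude_pregnant"] <= counts["derive"] <= counts["read"]
    assert log["merged_rows"] == len(table)
    assert not table["pregnant"].any()
    assert {"children_dead", "age_group3", "age_group5", "bmi_category"} <= set(
        table.columns
    )


def test_read_gps_schema(tmp_path, small_config):
    gps = generate_gps(small_config)
    path = tmp_path / "gps.csv"
    gps.to_csv(path, index=False)
    back = read_gps(path)
    assert len(back) == len(gps)
    bad = tmp_path / "bad_gps.csv"
    gps.drop(columns=["latitude"]).to_csv(bad, index=False)
    with pytest.raises(SchemaError, match="latitude"):
        read_gps(bad)
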