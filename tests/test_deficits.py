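"""Deficit-accumulation engine: range, monotonicity, splitting, brute-force
recount equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietfrail.deficits import (
    DeficitDefinitionSet,
    DeficitItem,
    all_deficit_record,
    no_deficit_record,
    score_deficit_index,
    score_record,
    split_nutrition_index,
    validate_frailty_independence,
)
from dietfrail.errors import ConfigurationError
from dietfrail.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="module")
def ni():
    return DeficitDefinitionSet.default_nutrition_index()


@pytest.fixture(scope="module")
def fi():
    return DeficitDefinitionSet.default_frailty_index()


from oracles import brute_force_deficit_score as brute_force_score


class TestStructure:
    def test_default_item_counts(self, ni, fi):
        assert len(ni) == 31
        assert len(fi) == 36

    def test_split_partitions_18_nutrient_13_labexam(self, ni):
        nut, lab = split_nutrition_index(ni)
        assert len(nut) == 18 and len(lab) == 13
        names = {i.name for i in nut.items} | {i.name for i in lab.items}
        assert names == {i.name for i in ni.items}
        assert not ({i.name for i in nut.items} & {i.name for i in lab.items})

    def test_split_rejects_untagged_item(self):
        items = [
            DeficitItem(f"item{k}", "self_report", f"c{k}", {"type": "band", "low": 0, "high": 1})
            for k in range(2)
        ]
        ds = DeficitDefinitionSet("toy", items, expected_count=2)
        with pytest.raises(ConfigurationError, match="item0"):
            split_nutrition_index(ds)

    def test_wrong_item_count_rejected(self, ni):
        with pytest.raises(ConfigurationError, match="31"):
            DeficitDefinitionSet("bad_ni", ni.items[:30], expected_count=31)

    def test_duplicate_names_rejected(self, ni):
        items = list(ni.items[:30]) + [ni.items[0]]
        with pytest.raises(ConfigurationError, match="duplicate"):
            DeficitDefinitionSet("dup", items, expected_count=31)


class TestScoring:
    def test_all_deficits_scores_one(self, ni, fi):
        assert score_record(all_deficit_record(ni), ni).value == 1.0
        assert score_record(all_deficit_record(fi), fi).value == 1.0

    def test_no_deficits_scores_zero(self, ni):
        assert score_record(no_deficit_record(ni), ni).value == 0.0

    def test_nine_of_thirtysix(self, fi):
        rec = no_deficit_record(fi)
        for item in fi.items[:9]:
            rec[item.column] = item.example_value(deficit=True, sex="female")
        got = score_record(rec, fi)
        assert got.value == pytest.approx(9 / 36)
        assert got.n_assessed == 36

    def test_all_items_missing_gives_missing_score(self, ni):
        got = score_record({"sex": "female"}, ni)
        assert np.isnan(got.value) and got.n_assessed == 0

    def test_completeness_threshold(self, fi):
        # 27/36 assessed < 0.8 -> missing; 29/36 >= 0.8 -> scored
        rec = no_deficit_record(fi)
        cols = [it.column for it in fi.items]
        low = {c: (rec[c] if i < 27 else np.nan) for i, c in enumerate(cols)}
        low["sex"] = "female"
        assert np.isnan(score_record(low, fi).value)
        ok = {c: (rec[c] if i < 29 else np.nan) for i, c in enumerate(cols)}
        ok["sex"] = "female"
        assert score_record(ok, fi).value == 0.0

    def test_denominator_is_items_assessed(self, fi):
        rec = all_deficit_record(fi)
        for item in fi.items[:4]:  # 4 missing, 32 assessed, all deficits
            rec[item.column] = np.nan
        got = score_record(rec, fi)
        assert got.n_assessed == 32
        assert got.value == pytest.approx(1.0)

    @pytest.mark.parametrize("defs_name", ["ni", "fi"])
    def test_brute_force_recount_on_random_records(self, defs_name, request):
        defs = request.getfixturevalue(defs_name)
        cohort = generate_cohort(SimulationConfig(n=1000, seed=99))
        from dietfrail.cohort import add_derived_columns

        cohort = add_derived_columns(cohort)
        # knock out a sprinkling of values so the denominator path is hit
        rng = np.random.default_rng(5)
        for item in defs.items:
            if item.column in cohort.columns:
                mask = rng.random(len(cohort)) < 0.03
                cohort.loc[mask, item.column] = np.nan
        got = score_deficit_index(cohort, defs)
        for i in range(len(cohort)):
            row = cohort.iloc[i].to_dict()
            exp_value, exp_def, exp_assessed = brute_force_score(row, defs)
            assert got["n_assessed"].iloc[i] == exp_assessed
            assert got["n_deficits"].iloc[i] == pytest.approx(exp_def)
            if np.isnan(exp_value):
                assert np.isnan(got["value"].iloc[i])
            else:
                assert got["value"].iloc[i] == pytest.approx(exp_value, abs=1e-15)

    @given(flip=st.integers(min_value=0, max_value=35), data=st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_single_item_flip(self, flip, data):
        """Turning one non-deficit item into a deficit never lowers the index."""
        fi = DeficitDefinitionSet.default_frailty_index()
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        rec = {}
        deficits = rng.random(36) < 0.3
        for item, d in zip(fi.items, deficits):
            rec[item.column] = item.example_value(deficit=bool(d), sex="female")
        rec["sex"] = "female"
        base = score_record(rec, fi).value
        item = fi.items[flip]
        rec[item.column] = item.example_value(deficit=True, sex="female")
        assert score_record(rec, fi).value >= base - 1e-12

    def test_values_always_in_unit_interval(self, ni, fi, small_cohort):
        for defs in (ni, fi):
            vals = score_deficit_index(small_cohort, defs)["value"].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()


class TestIndependence:
    def test_default_fi_and_ni_share_no_source(self, ni, fi):
        assert validate_frailty_independence(fi, ni) == []

    def test_constructed_clash_is_reported(self, ni, fi):
        items = list(fi.items[:-1]) + [
            DeficitItem(
                "albumin_clone",
                "lab",
                "lab_albumin_g_dl",
                {"type": "threshold", "direction": "low", "cutoff": 3.5},
            )
        ]
        clashed = DeficitDefinitionSet("fi_bad", items, expected_count=36)
        assert validate_frailty_independence(clashed, ni) == ["lab_albumin_g_dl"]

    def test_disjoint_toy_sets_empty(self):
        a = DeficitDefinitionSet(
            "a",
            [DeficitItem("x", "lab", "col_x", {"type": "band", "low": 0, "high": 1})],
            expected_count=1,
        )
        b = DeficitDefinitionSet(
            "b",
            [DeficitItem("y", "lab", "col_y", {"type": "band", "low": 0, "high": 1})],
            expected_count=1,
        )
        assert validate_frailty_independence(a, b) == []


def test_subindex_consistency(ni, small_cohort):
    """Full NI = (18 * NI_nutrient + 13 * NI_labexam) / 31 when complete."""
    nut, lab = split_nutrition_index(ni)
    full = score_deficit_index(small_cohort, ni)
    part_n = score_deficit_index(small_cohort, nut)
    part_l = score_deficit_index(small_cohort, lab)
    complete = full["n_assessed"] == 31
    lhs = full.loc[complete, "value"]
    rhs = (18 * part_n.loc[complete, "value"] + 13 * part_l.loc[complete, "value"]) / 31
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)
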