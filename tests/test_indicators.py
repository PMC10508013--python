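import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finprot import indicators as ind
from finprot.estimation import weighted_incidence

from conftest import random_table

NONFOOD_40 = ind.CheDefinition("nonfood_capacity", 0.40)
TOTAL_10 = ind.CheDefinition("total_consumption", 0.10)
TOTAL_25 = ind.CheDefinition("total_consumption", 0.25)


def record(consumption=10000.0, food=4000.0, oop=0.0, size=1.0, income=20000.0):
    return {
        "consumption_total": consumption,
        "food_expenditure": food,
        "oop_health_expenditure": oop,
        "family_size": size,
        "income_total": income,
    }


class TestCapacityToPay:
    def test_forced_arithmetic(self):
        assert ind.capacity_to_pay(record(10000, 4000)) == 6000

    def test_nonpositive_passthrough(self):
        assert ind.capacity_to_pay(record(6000, 8000)) == -2000

    def test_zero_food_identity(self):
        assert ind.capacity_to_pay(record(12345.0, 0.0)) == 12345.0


class TestClassifyChe:
    def test_exact_boundary_is_che(self):
        # "at least" => >= at exactly 40% of nonfood capacity
        assert ind.classify_che(record(10000, 4000, oop=2400), NONFOOD_40)

    def test_just_below_boundary(self):
        assert not ind.classify_che(record(20000, 0, oop=1999.99), TOTAL_10)

    def test_zero_oop_never_che(self):
        for d in (NONFOOD_40, TOTAL_10, TOTAL_25):
            assert not ind.classify_che(record(oop=0.0), d)
        # even with nonpositive capacity
        assert not ind.classify_che(record(6000, 8000, oop=0.0), NONFOOD_40)

    def test_positive_oop_with_nonpositive_capacity_is_che(self):
        assert ind.classify_che(record(6000, 8000, oop=50), NONFOOD_40)

    def test_bad_definition_rejected(self):
        with pytest.raises(ValueError):
            ind.CheDefinition("income", 0.4)
        with pytest.raises(ValueError):
            ind.CheDefinition("total_consumption", 0.0)


class TestAbsolutePovertyLine:
    def test_value_19usd_per_day(self):
        line = ind.absolute_poverty_line(1.9, 3.52, 1.13)
        assert round(line.provenance["value_per_day"], 2) == 7.56

    def test_value_31usd_per_day(self):
        line = ind.absolute_poverty_line(3.1, 3.52, 1.13)
        assert round(line.provenance["value_per_day"], 2) == 12.33

    def test_identity_conversion(self):
        line = ind.absolute_poverty_line(1.9, 1, 1, 365)
        assert line.value == pytest.approx(693.5)

    def test_annual_value(self):
        line = ind.absolute_poverty_line(1.9, 3.52, 1.13, 365)
        assert round(line.value, 2) == 2758.47

    def test_provenance_recorded(self):
        line = ind.absolute_poverty_line(3.1, 3.52, 1.13)
        assert line.provenance["ppp_factor"] == 3.52
        assert line.kind == "absolute"

    @pytest.mark.parametrize("args", [(0, 3.52, 1.13), (1.9, -1, 1.13), (1.9, 3.52, 0)])
    def test_nonpositive_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            ind.absolute_poverty_line(*args)


class TestRelativePovertyLine:
    def table(self, pcs, weights, sizes=None):
        sizes = sizes or [1.0] * len(pcs)
        return pd.DataFrame(
            {
                "consumption_total": [p * s for p, s in zip(pcs, sizes)],
                "family_size": sizes,
                "weight": weights,
            }
        )

    def test_median_of_one(self):
        line = ind.relative_poverty_line(self.table([10000], [1.0]))
        assert line.value == pytest.approx(6000)

    def test_equal_weight_median(self):
        line = ind.relative_poverty_line(self.table([10000, 20000, 40000], [1, 1, 1]))
        assert line.value == pytest.approx(12000)

    def test_lower_weighted_median_at_ties(self):
        line = ind.relative_poverty_line(self.table([10000, 30000], [3, 1]))
        assert line.value == pytest.approx(6000)

    def test_uses_per_capita_values(self):
        line = ind.relative_poverty_line(self.table([10000], [1.0], sizes=[4.0]))
        assert line.value == pytest.approx(6000)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            ind.relative_poverty_line(self.table([], []))


class TestClassifyPoorAndMi:
    LINE = ind.PovertyLine("absolute", 2757.46, "paper_line")

    def test_on_the_line_is_not_poor(self):
        r = record(consumption=2757.46, food=0, size=1)
        assert not ind.classify_poor(r, self.LINE, net_of_oop=False)

    def test_negative_net_consumption_is_poor(self):
        r = record(consumption=4000, oop=5000, size=1)
        assert ind.classify_poor(r, self.LINE, net_of_oop=True)

    def test_zero_oop_gross_equals_net(self, rng):
        t = random_table(rng, 100)
        t["oop_health_expenditure"] = 0.0
        for _, r in t.iterrows():
            assert ind.classify_poor(r, self.LINE, False) == ind.classify_poor(
                r, self.LINE, True
            )

    def test_mi_crossing_household(self):
        r = record(consumption=3000, food=0, oop=500, size=1)
        assert ind.classify_mi(r, self.LINE)

    def test_gross_poor_is_never_mi(self):
        r = record(consumption=2000, food=0, oop=1999, size=1)
        assert not ind.classify_mi(r, self.LINE)

    def test_zero_oop_is_never_mi(self):
        r = record(consumption=3000, food=0, oop=0, size=1)
        assert not ind.classify_mi(r, self.LINE)


def loop_flag_table(records, che_definitions, poverty_lines):
    """Independent oracle: scalar classifiers applied row by row."""
    rows = []
    for _, r in records.iterrows():
        row = {"household_id": r["household_id"]}
        for d in che_definitions:
            row[d.label] = ind.classify_che(r, d)
        for line in poverty_lines:
            row[f"poor_gross_{line.label}"] = ind.classify_poor(r, line, False)
        for line in poverty_lines:
            row[f"poor_net_{line.label}"] = ind.classify_poor(r, line, True)
        for line in poverty_lines:
            row[f"mi_{line.label}"] = ind.classify_mi(r, line)
        rows.append(row)
    return pd.DataFrame(rows)


def standard_lines(records):
    return [
        ind.absolute_poverty_line(1.9),
        ind.absolute_poverty_line(3.1),
        ind.relative_poverty_line(records),
    ]


class TestBuildFlagTable:
    def test_matches_per_household_loop(self, rng):
        t = random_table(rng, 10)
        defs = ind.canonical_che_definitions()
        lines = standard_lines(t)
        got = ind.build_flag_table(t, defs, lines)
        expected = loop_flag_table(t, defs, lines)
        for col in expected.columns:
            assert list(got[col]) == list(expected[col]), col

    def test_empty_definition_lists_keep_grouping_only(self, small_table):
        out = ind.build_flag_table(small_table)
        assert set(out.columns) == {
            "household_id", "survey_id", "wave_year", "urban", "province", "weight"
        }

    def test_che_flags_scale_invariant(self, small_table):
        defs = ind.canonical_che_definitions()
        base = ind.build_flag_table(small_table, defs)
        doubled = small_table.copy()
        for col in ("income_total", "consumption_total", "food_expenditure",
                    "oop_health_expenditure"):
            doubled[col] = 2.0 * doubled[col]
        out = ind.build_flag_table(doubled, defs)
        for d in defs:
            assert list(out[d.label]) == list(base[d.label])

    def test_mi_flags_invariant_under_joint_rescale(self, small_table):
        line = ind.absolute_poverty_line(1.9)
        scaled_line = ind.PovertyLine("absolute", line.value * 3.0, line.label)
        base = ind.build_flag_table(small_table, poverty_lines=[line])
        scaled = small_table.copy()
        for col in ("consumption_total", "food_expenditure", "oop_health_expenditure"):
            scaled[col] = 3.0 * scaled[col]
        out = ind.build_flag_table(scaled, poverty_lines=[scaled_line])
        assert list(out[f"mi_{line.label}"]) == list(base[f"mi_{line.label}"])


class TestFlagProperties:
    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 120))
    def test_oracle_equivalence_random_tables(self, seed, n):
        t = random_table(np.random.default_rng(seed), n)
        defs = ind.canonical_che_definitions()
        lines = standard_lines(t)
        got = ind.build_flag_table(t, defs, lines)
        expected = loop_flag_table(t, defs, lines)
        for col in expected.columns:
            assert list(got[col]) == list(expected[col]), col

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_headcount_identity_and_gross_implies_net(self, seed):
        t = random_table(np.random.default_rng(seed), 80)
        lines = standard_lines(t)
        flags = ind.build_flag_table(t, poverty_lines=lines)
        w = flags["weight"].to_numpy(float)
        for line in lines:
            g = flags[f"poor_gross_{line.label}"].to_numpy(float)
            n_ = flags[f"poor_net_{line.label}"].to_numpy(float)
            mi = flags[f"mi_{line.label}"].to_numpy(float)
            assert np.all(n_ >= g)  # gross poor => net poor
            h_gross = weighted_incidence(g, w).estimate
            h_net = weighted_incidence(n_, w).estimate
            h_mi = weighted_incidence(mi, w).estimate
            assert h_mi == pytest.approx(h_net - h_gross, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_threshold_monotonicity(self, seed):
        t = random_table(np.random.default_rng(seed), 60)
        flags = ind.build_flag_table(t, [TOTAL_10, TOTAL_25])
        assert flags["che_total_25"].sum() <= flags["che_total_10"].sum()

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_threshold_grid_weakly_decreasing(self, seed):
        t = random_table(np.random.default_rng(seed), 60)
        grid = [0.05, 0.1, 0.2, 0.25, 0.4, 0.6]
        defs = [ind.CheDefinition("total_consumption", th) for th in grid]
        flags = ind.build_flag_table(t, defs)
        counts = [flags[d.label].sum() for d in defs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_canonical_set_is_the_six_definitions(small_table):
    defs = ind.canonical_che_definitions()
    assert [(d.denominator, d.threshold) for d in defs] == [
        ("nonfood_capacity", 0.40),
        ("total_consumption", 0.10),
        ("total_consumption", 0.25),
    ]
    lines = ind.canonical_poverty_lines(small_table)
    assert [line.kind for line in lines] == ["absolute", "absolute", "relative"]
    assert round(lines[0].provenance["value_per_day"], 2) == 7.56
    assert round(lines[1].provenance["value_per_day"], 2) == 12.33
    assert lines[2].provenance["median_share"] == 0.60
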