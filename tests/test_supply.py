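"""FBS matching, per-item supply arithmetic and group aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from iodapport import supply


def _db(entries):
    return pd.DataFrame([{"key": k, "n": 1, "median": v, "q1": v, "q3": v,
                          "min": v, "max": v, "mean": v, "n_below_lod": 0}
                         for k, v in entries.items()])


def _items(rows):
    return pd.DataFrame(rows, columns=supply.SUPPLY_COLUMNS)


class TestItemSupply:
    def test_direct_product(self):
        assert supply.item_supply(100, 1.0, 0.51) == pytest.approx(51.0)

    def test_zero_concentration_gives_zero(self):
        assert supply.item_supply(500, 0.5, 0.0) == 0.0

    def test_fresh_to_dry_conversion(self):
        assert supply.item_supply(250, 0.88, 0.01) == pytest.approx(2.2)

    @pytest.mark.parametrize("dw", [0.0, -0.1, 1.5])
    def test_dw_fraction_outside_unit_interval_rejected(self, dw):
        with pytest.raises(ValueError):
            supply.item_supply(100, dw, 0.5)


class TestMatchComposition:
    db = _db({"maize grain": 0.01, "grain": 0.012, "root": 0.008})

    def test_item_level_match_preferred(self):
        items = _items([("maize", "Cereals", 300, 1.0, "maize grain")])
        matched, unmatched = supply.match_composition(items, self.db,
                                                      {"Cereals": "grain"})
        assert unmatched == []
        assert matched.iloc[0]["matched_key"] == "maize grain"
        assert matched.iloc[0]["conc_dw"] == 0.01

    def test_group_fallback_used_when_item_absent(self):
        items = _items([("sweet potato", "Roots and tubers", 100, 1.0,
                         "sweet potato")])
        matched, unmatched = supply.match_composition(
            items, self.db, {"Roots and tubers": "root"})
        assert unmatched == []
        assert matched.iloc[0]["matched_key"] == "root"

    def test_unresolved_item_excluded_and_reported(self):
        items = _items([("mystery", "Other", 10, 1.0, "mystery")])
        matched, unmatched = supply.match_composition(items, self.db, {})
        assert unmatched == ["mystery"]
        assert len(matched) == 0

    def test_strict_mode_raises_listing_items(self):
        items = _items([("mystery", "Other", 10, 1.0, "mystery")])
        with pytest.raises(ValueError, match="mystery"):
            supply.match_composition(items, self.db, {}, strict=True)

    def test_full_synthetic_table_has_zero_unmatched(self, demo_dir, gen_config):
        from iodapport import composition, io, pipeline
        path, _ = demo_dir
        db = composition.build_composition(
            io.read_measurements(path / "measurements.csv"))
        items = io.read_fbs(path / "fbs.csv")
        assert len(items) == 92
        _, unmatched = supply.match_composition(items, db,
                                                pipeline.DEFAULT_FALLBACK)
        assert unmatched == []

    def test_demo_supply_reproduces_survey_group_structure(self, demo_dir):
        """The generator's FBS masses are calibrated so that, at the true
        composition medians, the national supply is 7.8 μg/d with Cereals 40%
        and Animal products 33%; at the sampled medians (n per the survey)
        the recovered structure should be close."""
        from iodapport import composition, io, pipeline
        path, _ = demo_dir
        db = composition.build_composition(
            io.read_measurements(path / "measurements.csv"))
        items = io.read_fbs(path / "fbs.csv")
        result = supply.compute_supply(items, db, pipeline.DEFAULT_FALLBACK)
        assert result.total == pytest.approx(7.8, rel=0.5)
        top = result.per_group.index[0]
        assert top in ("Cereals", "Animal products")


class TestAggregate:
    def test_single_item_carries_full_share(self):
        items = _items([("maize", "Cereals", 300, 1.0, "maize grain")])
        matched, _ = supply.match_composition(items, _db({"maize grain": 0.01}))
        result = supply.aggregate(matched)
        assert result.shares == {"Cereals": 100}
        assert result.total == pytest.approx(3.0)

    def test_total_equals_brute_force_sum(self):
        rng = np.random.default_rng(2)
        rows, expected = [], 0.0
        db_entries = {}
        for i in range(20):
            conc = float(rng.lognormal(0, 1))
            mass = float(rng.uniform(1, 400))
            dw = float(rng.uniform(0.1, 1.0))
            key = f"food_{i}"
            db_entries[key] = conc
            rows.append((key, "Other", mass, dw, key))
            expected += mass * dw * conc
        matched, _ = supply.match_composition(_items(rows), _db(db_entries))
        result = supply.aggregate(matched)
        assert result.total == pytest.approx(expected)
        assert result.per_item.sum() == pytest.approx(expected)
        assert result.per_group.sum() == pytest.approx(expected)

    def test_scaling_concentrations_scales_total(self):
        rows = [("a", "Cereals", 100, 1.0, "a"), ("b", "Other", 50, 0.5, "b")]
        base = supply.compute_supply(_items(rows), _db({"a": 0.2, "b": 0.4}))
        scaled = supply.compute_supply(_items(rows), _db({"a": 0.6, "b": 1.2}))
        assert scaled.total == pytest.approx(3 * base.total)
        assert scaled.shares == base.shares

    def test_shares_sum_to_about_100(self):
        rng = np.random.default_rng(3)
        rows = [(f"f{i}", f"G{i % 5}", float(rng.uniform(1, 100)), 1.0, f"f{i}")
                for i in range(25)]
        db = _db({f"f{i}": float(rng.lognormal(0, 1)) for i in range(25)})
        result = supply.compute_supply(_items(rows), db)
        assert abs(sum(result.shares.values()) - 100) <= 2
        assert result.shares_exact.sum() == pytest.approx(100.0)


class TestGroupShares:
    def test_survey_group_supplies_round_to_printed_shares(self):
        groups = {"Cereals": 3.1, "Animal products": 2.6,
                  "Roots and tubers": 1.1, "Fruits and vegetables": 0.6,
                  "Pulses and beans": 0.3, "Other": 0.1}
        shares = supply.group_shares(groups, total=7.8)
        assert shares["Cereals"] == 40
        assert shares["Animal products"] == 33
        assert shares["Roots and tubers"] == 14

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            supply.group_shares({"Cereals": 0.0})

    @given(st.dictionaries(st.sampled_from(supply.FOOD_GROUPS),
                           st.floats(min_value=0.01, max_value=100),
                           min_size=1))
    def test_shares_invariant_to_common_unit_change(self, groups):
        base = supply.group_shares(groups)
        rescaled = supply.group_shares({g: 1000 * v for g, v in groups.items()})
        assert base == rescaled
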