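"""Half-LOD substitution, quartiles and per-group composition summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from iodapport import composition


class TestSubstituteBelowLod:
    def test_value_below_solid_lod_becomes_half_lod(self, simple_measurements):
        out = composition.substitute_below_lod(simple_measurements)
        assert out.loc[0, "value"] == pytest.approx(0.005)
        assert bool(out.loc[0, "below_lod"]) is True

    def test_values_above_lod_unchanged(self, simple_measurements):
        out = composition.substitute_below_lod(simple_measurements)
        assert out.loc[1, "value"] == 0.02
        assert out.loc[2, "value"] == 0.51

    def test_flagged_liquid_record_uses_liquid_lod(self, simple_measurements):
        out = composition.substitute_below_lod(simple_measurements)
        assert out.loc[3, "value"] == pytest.approx(0.125)

    def test_forced_censoring_all_half_lod(self):
        df = pd.DataFrame({
            "sample_id": [f"w{i}" for i in range(100)],
            "basis": "liquid",
            "value": np.linspace(0.0, 0.24, 100),
            "below_lod": False,
        })
        out = composition.substitute_below_lod(df, lod=0.25)
        assert (out["value"] == 0.125).all()
        assert out["below_lod"].all()

    def test_explicit_single_lod_overrides_basis(self, simple_measurements):
        out = composition.substitute_below_lod(simple_measurements, lod=0.01)
        assert out.loc[3, "value"] == pytest.approx(0.005)

    def test_preserves_input_order(self, simple_measurements):
        out = composition.substitute_below_lod(simple_measurements)
        assert list(out["sample_id"]) == list(simple_measurements["sample_id"])

    def test_negative_value_rejected_naming_sample(self, simple_measurements):
        bad = simple_measurements.copy()
        bad.loc[1, "value"] = -0.1
        with pytest.raises(ValueError, match="b"):
            composition.substitute_below_lod(bad)

    def test_missing_value_without_flag_rejected(self, simple_measurements):
        bad = simple_measurements.copy()
        bad.loc[3, "below_lod"] = False
        with pytest.raises(ValueError, match="d"):
            composition.substitute_below_lod(bad)

    @given(st.lists(st.floats(min_value=0, max_value=1.0, allow_nan=False),
                    min_size=1, max_size=30))
    def test_idempotent(self, values):
        df = pd.DataFrame({
            "sample_id": [str(i) for i in range(len(values))],
            "basis": "DW",
            "value": values,
            "below_lod": False,
        })
        once = composition.substitute_below_lod(df)
        twice = composition.substitute_below_lod(once)
        pd.testing.assert_frame_equal(once, twice)


class TestQuartiles:
    def test_exact_order_statistics(self):
        assert composition.quartiles([1, 2, 3, 4, 5]) == (2, 3, 4)

    def test_constant_input(self):
        assert composition.quartiles([1, 1, 1, 1]) == (1, 1, 1)

    def test_single_value(self):
        assert composition.quartiles([7.0]) == (7.0, 7.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            composition.quartiles([])

    def test_matches_interpolation_oracle_on_random_inputs(self):
        """Independent oracle: q_p from sorted values with h = (n-1)p."""
        rng = np.random.default_rng(42)

        def oracle(vals, p):
            s = np.sort(vals)
            h = (len(s) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (h - lo) * (s[hi] - s[lo])

        for _ in range(200):
            vals = rng.lognormal(0, 1, rng.integers(1, 200))
            q1, med, q3 = composition.quartiles(vals)
            assert q1 == pytest.approx(oracle(vals, 0.25))
            assert med == pytest.approx(oracle(vals, 0.50))
            assert q3 == pytest.approx(oracle(vals, 0.75))

    @given(st.lists(st.floats(min_value=0, max_value=1e3, allow_nan=False),
                    min_size=2, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert composition.quartiles(values) == composition.quartiles(shuffled)


class TestSummarize:
    def _table(self, values, group="leaves", basis="DW"):
        return pd.DataFrame({
            "sample_id": [str(i) for i in range(len(values))],
            "item": "x", "group": group, "basis": basis,
            "value": values, "below_lod": False,
        })

    def test_single_value_entry(self):
        out = composition.summarize(self._table([1.0]))
        row = out.iloc[0]
        assert (row["median"], row["q1"], row["q3"], row["min"], row["max"]) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)
        assert row["n"] == 1

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(0)
        out = composition.summarize(self._table(rng.lognormal(0, 1, 50)))
        row = out.iloc[0]
        assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]

    def test_lognormal_median_recovery(self):
        """n=1000 draws: summary median equals a sort-based oracle and is
        within 5% of the generating median 0.155."""
        rng = np.random.default_rng(123)
        draws = rng.lognormal(np.log(0.155), 0.6, 1000)
        out = composition.summarize(self._table(draws))
        med = out.iloc[0]["median"]
        s = np.sort(draws)
        assert med == pytest.approx((s[499] + s[500]) / 2)
        assert med == pytest.approx(0.155, rel=0.05)

    def test_recovery_tolerance_shrinks_with_n(self):
        """Median recovery spread over replicates shrinks from n=30 to n=300."""
        rng = np.random.default_rng(5)
        spread = {}
        for n in (30, 300):
            meds = [composition.summarize(
                self._table(rng.lognormal(0, 0.8, n))).iloc[0]["median"]
                for _ in range(40)]
            spread[n] = np.std(meds)
        assert spread[300] < spread[30]

    def test_mixed_basis_within_key_rejected(self):
        df = pd.concat([self._table([1.0], group="g", basis="DW"),
                        self._table([2.0], group="g", basis="liquid")])
        with pytest.raises(ValueError, match="mixed"):
            composition.summarize(df)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        df = self._table(rng.lognormal(0, 1, 60))
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(composition.summarize(df),
                                      composition.summarize(shuffled))

    def test_raising_a_value_never_lowers_the_median(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(0, 1, 31)
        base = composition.summarize(self._table(values)).iloc[0]["median"]
        for idx in (0, 15, 30):
            bumped = values.copy()
            bumped[idx] *= 10
            new = composition.summarize(self._table(bumped)).iloc[0]["median"]
            assert new >= base

    def test_counts_censored_records(self, simple_measurements):
        sub = composition.substitute_below_lod(simple_measurements)
        out = composition.summarize(sub, by="group")
        grain = out[out["key"] == "grain"].iloc[0]
        assert grain["n_below_lod"] == 1
        assert grain["n"] == 2
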