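"""Share change, Gini preference, TC-prefix algebra, neighbour features,
lag bookkeeping and the no-peeking guarantee."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortcast.features import (
    assemble_features,
    din_share,
    gini_preference,
    max_share_change,
    neighbour_shortage,
    tc_prefix,
)
from shortcast.pipeline import score_world

from conftest import make_catalog, make_dispense
from oracles import gini_pairwise_oracle


class TestDinShare:
    def test_patient_shares(self):
        disp = make_dispense([
            ("x", "IGW", "2018-03", 100, 80),
            ("y", "IGW", "2018-03", 100, 10),
            ("z", "IGW", "2018-03", 100, 10),
        ])
        s = din_share(disp, "IGW", "2018-03", basis="patients")
        assert s.to_dict() == pytest.approx({"x": 0.8, "y": 0.1, "z": 0.1})

    def test_single_din_share_one(self):
        disp = make_dispense([("x", "IGW", "2018-03", 100, 7)])
        assert din_share(disp, "IGW", "2018-03").to_dict() == {"x": 1.0}

    def test_dos_basis(self):
        disp = make_dispense([
            ("x", "IGW", "2018-03", 60, 1),
            ("y", "IGW", "2018-03", 40, 1),
        ])
        s = din_share(disp, "IGW", "2018-03", basis="dos")
        assert s.to_dict() == pytest.approx({"x": 0.6, "y": 0.4})

    def test_zero_total_gives_uniform(self):
        disp = make_dispense([
            ("x", "IGW", "2018-03", 0, 0),
            ("y", "IGW", "2018-03", 0, 0),
        ])
        s = din_share(disp, "IGW", "2018-03")
        assert s.to_dict() == pytest.approx({"x": 0.5, "y": 0.5})


class TestMaxShareChange:
    def test_worked_example_thirty_percent(self):
        t0 = pd.Series({"x": 0.8, "y": 0.1, "z": 0.1})
        t1 = pd.Series({"x": 0.5, "y": 0.3, "z": 0.2})
        assert max_share_change(t1, t0) == pytest.approx(30.0)

    def test_identical_distributions_zero(self):
        s = pd.Series({"x": 0.7, "y": 0.3})
        assert max_share_change(s, s) == 0.0

    def test_total_swap_hundred(self):
        a = pd.Series({"x": 1.0, "y": 0.0})
        b = pd.Series({"x": 0.0, "y": 1.0})
        assert max_share_change(a, b) == pytest.approx(100.0)

    def test_symmetry(self):
        a = pd.Series({"x": 0.6, "y": 0.4})
        b = pd.Series({"x": 0.15, "y": 0.85})
        assert max_share_change(a, b) == max_share_change(b, a)

    def test_missing_din_counts_as_zero_share(self):
        a = pd.Series({"x": 1.0})
        b = pd.Series({"y": 1.0})
        assert max_share_change(a, b) == pytest.approx(100.0)


class TestGini:
    @pytest.mark.parametrize("n", [2, 3, 4, 10])
    def test_uniform_is_zero(self, n):
        assert gini_preference(pd.Series(np.full(n, 1.0 / n))) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 10])
    def test_total_preference_is_one(self, n):
        shares = np.zeros(n)
        shares[0] = 1.0
        assert gini_preference(pd.Series(shares)) == pytest.approx(1.0)

    def test_single_din_is_zero(self):
        assert gini_preference(pd.Series([1.0])) == 0.0

    @given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=2, max_size=8))
    @settings(max_examples=120, deadline=None)
    def test_matches_pairwise_oracle(self, vals):
        if sum(vals) <= 0:
            return
        got = gini_preference(pd.Series(vals))
        assert got == pytest.approx(gini_pairwise_oracle(vals), abs=1e-12)

    def test_permutation_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random(6)
        base = gini_preference(pd.Series(vals))
        assert gini_preference(pd.Series(vals[::-1].copy())) == pytest.approx(base, abs=1e-12)
        assert gini_preference(pd.Series(vals * 37.5)) == pytest.approx(base, abs=1e-12)


class TestTcPrefix:
    def test_levels_of_reference_code(self):
        assert tc_prefix("84:04.08.28", 0) == "84:04.08.28"
        assert tc_prefix("84:04.08.28", 1) == "84:04.08"
        assert tc_prefix("84:04.08.28", 2) == "84:04"
        assert tc_prefix("84:04.08.28", 3) == "84"

    def test_prefix_algebra_composes(self):
        code = "84:04.08.28"
        for j in range(3):
            for k in range(j, 4 - 1):
                # truncating j then k-j more equals truncating k at once
                assert tc_prefix(tc_prefix(code, j), k - j) == tc_prefix(code, k)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            tc_prefix("84:04.08.28", 4)


class TestNeighbourShortage:
    catalog = make_catalog(
        {"A": ["a1"], "B": ["b1"], "C": ["c1"], "FAR": ["f1"]},
        tc={"A": "84:04.08.20", "B": "84:04.08.24", "C": "84:04.08.28", "FAR": "10:00.00.00"},
    )

    def _impact(self, scores: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            [{"ig_code": ig, "month": "2018-03", "score": s} for ig, s in scores.items()]
        )

    def _dispense(self, dos: dict[str, int]) -> pd.DataFrame:
        return make_dispense([(f"{ig.lower()}1", ig, "2018-02", d, 1) for ig, d in dos.items()])

    def test_no_neighbours_is_zero(self):
        imp = self._impact({"A": 1.0, "B": 1.0, "C": 1.0, "FAR": 0.0})
        disp = self._dispense({"A": 100, "B": 100, "C": 100, "FAR": 100})
        assert neighbour_shortage("FAR", 1, "2018-03", imp, self.catalog, disp) == 0.0

    def test_equal_dos_neighbours_average(self):
        imp = self._impact({"A": 0.0, "B": 1.0, "C": 0.0, "FAR": 0.0})
        disp = self._dispense({"A": 100, "B": 100, "C": 100, "FAR": 100})
        assert neighbour_shortage("A", 1, "2018-03", imp, self.catalog, disp) == pytest.approx(0.5)

    def test_dos_weighting(self):
        imp = self._impact({"A": 0.0, "B": 1.0, "C": 0.0, "FAR": 0.0})
        disp = self._dispense({"A": 100, "B": 300, "C": 100, "FAR": 100})
        assert neighbour_shortage("A", 1, "2018-03", imp, self.catalog, disp) == pytest.approx(0.75)

    def test_self_exclusion(self):
        disp = self._dispense({"A": 100, "B": 100, "C": 100, "FAR": 100})
        lo = neighbour_shortage("A", 1, "2018-03", self._impact({"A": 0.0, "B": 1.0, "C": 0.0, "FAR": 0.0}),
                                self.catalog, disp)
        hi = neighbour_shortage("A", 1, "2018-03", self._impact({"A": 1.0, "B": 1.0, "C": 0.0, "FAR": 0.0}),
                                self.catalog, disp)
        assert lo == hi


@pytest.fixture(scope="module")
def world_features(small_world):
    _, _, imp = score_world(small_world)
    feats = assemble_features(small_world.dispense, imp, small_world.catalog)
    return small_world, imp, feats


class TestAssembleFeatures:
    def test_lag_columns_are_shifted_copies(self, world_features):
        world, imp, feats = world_features
        for ig, table in feats.frames.items():
            series = imp[imp["ig_code"] == ig].set_index("month")["score"]
            for k in range(1, 5):
                for m in table.index:
                    lagged_month = str(pd.Period(m, freq="M") - k)
                    assert table.loc[m, f"shortage_impact_lag{k}"] == pytest.approx(
                        series[lagged_month]
                    )

    def test_per_din_column_block_shape(self, world_features):
        world, _, feats = world_features
        for ig, table in feats.frames.items():
            n_dins = (world.catalog["ig_code"] == ig).sum()
            for family in ("avgdos_pat", "tot_dos", "tot_qty_disp", "tot_rx"):
                cols = [c for c in table.columns if c.startswith(family + ".")]
                assert len(cols) == n_dins * 4  # one block per DIN x 4 lags

    def test_rows_with_incomplete_lag_window_dropped(self, world_features):
        world, _, feats = world_features
        months = world.config.month_index
        for table in feats.frames.values():
            assert table.index[0] == str(months[4])
            assert not table.drop(columns="target").isna().any().any()

    def test_constant_series_yields_zero_changes(self):
        catalog = make_catalog({"IGW": ["x", "y"]}, tc={"IGW": "84:04.08.28"})
        rows = [(d, "IGW", str(m), 100, 10)
                for d in ("x", "y")
                for m in pd.period_range("2018-01", "2019-12", freq="M")]
        disp = make_dispense(rows)
        imp = pd.DataFrame([{"ig_code": "IGW", "month": str(m), "score": 0.0}
                            for m in pd.period_range("2018-01", "2019-12", freq="M")])
        feats = assemble_features(disp, imp, catalog)
        table = feats.frames["IGW"]
        for base in ("chg_dist_pat", "chg_dist_dos"):
            for k in range(1, 5):
                assert (table[f"{base}_lag{k}"] == 0.0).all()
        # all lag copies of a constant feature are equal
        for k in (2, 3, 4):
            assert (table["dos_lag1"] == table[f"dos_lag{k}"]).all()

    def test_no_peeking_truncation_invariance(self, world_features):
        """Recomputing after dropping future months leaves earlier rows unchanged."""
        world, imp, feats = world_features
        months = world.config.month_index
        cut = str(months[-6])
        keep = {str(m) for m in months if m <= months[-6]}
        disp_cut = world.dispense[world.dispense["month"].isin(keep)]
        imp_cut = imp[imp["month"].isin(keep)]
        feats_cut = assemble_features(disp_cut, imp_cut, world.catalog)
        for ig, table in feats_cut.frames.items():
            full = feats.frames[ig].loc[table.index]
            pd.testing.assert_frame_equal(table, full)

    def test_schema_covers_every_predictor_column(self, world_features):
        _, _, feats = world_features
        for ig, table in feats.frames.items():
            listed = set(feats.schema.loc[feats.schema["ig_code"] == ig, "column"])
            assert listed == set(table.columns) - {"target"}
        assert set(feats.schema["lag"].unique()) == {1, 2, 3, 4}
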