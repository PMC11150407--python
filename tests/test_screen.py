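"""Screen scoring: POC/ΔPOC arithmetic, ANOVA, BH, hit gating, spatial QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import offsig
from offsig import simulate
from offsig.screen import (
    DegeneratePlateError, ScreenConfigError, bh_adjust, compound_anova,
    delta_poc, poc_per_well, read_screen_table, screen_stats, select_hits,
    spatial_bias_report, write_screen_table,
)

from conftest import make_plateset


class TestReadScreenTable:
    def test_six_row_fixture_parses(self, tiny_plate, tmp_path):
        path = tmp_path / "screen.csv"
        write_screen_table(tiny_plate, path)
        ps = read_screen_table(path)
        assert len(ps.wells) == 6
        assert ps.plate_ids == ["P1"]

    def test_missing_role_column_names_it(self, tiny_plate, tmp_path):
        path = tmp_path / "bad.csv"
        tiny_plate.wells.drop(columns=["role"]).to_csv(path, index=False)
        with pytest.raises(ScreenConfigError, match="role"):
            read_screen_table(path)

    def test_generator_output_round_trips(self, tmp_path):
        ps, _ = simulate.gen_screen(n_compounds=176, seed=7)
        path = tmp_path / "gen.csv"
        write_screen_table(ps, path)
        back = read_screen_table(path)
        pd.testing.assert_frame_equal(back.wells, ps.wells)

    def test_dialect_remaps_columns(self, tiny_plate, tmp_path):
        path = tmp_path / "alias.csv"
        tiny_plate.wells.rename(columns={"luminescence": "RLU"}).to_csv(
            path, index=False)
        ps = read_screen_table(path, dialect={"luminescence": "RLU"})
        assert "luminescence" in ps.wells.columns

    def test_well_outside_grid_rejected(self):
        with pytest.raises(Exception, match="grid"):
            make_plateset([
                ("P1", "A", 1, "", "vehicle", 1.0),
                ("P1", "A", 2, "", "vehicle", 1.0),
                ("P1", "Z", 30, "c", "sample", 1.0),
            ])


class TestPoc:
    def test_vehicle_mean_maps_to_100_and_zero_to_zero(self, tiny_plate):
        poc = poc_per_well(tiny_plate)
        veh = poc[poc["role"] == "vehicle"]
        assert veh["poc"].mean() == pytest.approx(100.0)
        assert poc.loc[poc["luminescence"] == 0, "poc"].iloc[0] == 0.0
        assert poc.loc[poc["luminescence"] == 10000, "poc"].iloc[0] == (
            pytest.approx(100.0))

    def test_sample_5000_over_vehicle_10000_is_50(self, tiny_plate):
        poc = poc_per_well(tiny_plate)
        assert poc.loc[poc["compound_id"] == "cpdX", "poc"].iloc[0] == (
            pytest.approx(50.0))

    def test_zero_vehicle_mean_is_degenerate(self):
        ps = make_plateset([
            ("P1", "A", 1, "", "vehicle", 0.0),
            ("P1", "A", 2, "", "vehicle", 0.0),
            ("P1", "B", 1, "c", "sample", 5.0),
        ])
        with pytest.raises(DegeneratePlateError):
            poc_per_well(ps)


class TestDeltaPoc:
    def test_no_effect_full_kill_and_duplicates(self, tiny_plate):
        assert delta_poc(tiny_plate, "cpdX") == pytest.approx(50.0)
        # duplicate average of cpdY is (10000 + 0)/2 = 5000 → ΔPOC 50
        assert delta_poc(tiny_plate, "cpdY") == pytest.approx(50.0)

    def test_quoted_formula_arithmetic(self):
        ps = make_plateset(
            [("P1", "A", c, "", "vehicle", 10000.0) for c in (1, 2)]
            + [("P1", "B", 1, "c1", "sample", 3000.0),
               ("P1", "B", 2, "c1", "sample", 2000.0),
               ("P1", "C", 1, "c2", "sample", 10000.0),
               ("P1", "C", 2, "c2", "sample", 0.0)])
        assert delta_poc(ps, "c1") == pytest.approx(75.0)

    def test_extremes(self):
        ps = make_plateset(
            [("P1", "A", c, "", "vehicle", 8000.0) for c in (1, 2)]
            + [("P1", "B", 1, "same", "sample", 8000.0),
               ("P1", "C", 1, "dead", "sample", 0.0)])
        assert delta_poc(ps, "same") == pytest.approx(0.0)
        assert delta_poc(ps, "dead") == pytest.approx(100.0)

    def test_unknown_compound_is_lookup_error(self, tiny_plate):
        with pytest.raises(KeyError):
            delta_poc(tiny_plate, "nope")


def _brute_force_anova_p(y1, y0):
    """Textbook one-way F from sums of squares, independent of the module."""
    y = np.concatenate([y1, y0])
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_within = ((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum()
    ss_between = ss_total - ss_within
    f = (ss_between / 1) / (ss_within / (len(y) - 2))
    return sps.f.sf(f, 1, len(y) - 2)


class TestCompoundAnova:
    def _plateset(self, comp_values, veh_values):
        recs = [("P1", "A", i + 1, "", "vehicle", v)
                for i, v in enumerate(veh_values)]
        recs += [("P1", "B", i + 1, "c", "sample", v)
                 for i, v in enumerate(comp_values)]
        return make_plateset(recs)

    def test_null_case_p_near_one(self):
        ps = self._plateset([99.0, 101.0], [99.0, 101.0, 99.0, 101.0])
        assert compound_anova(ps, "c") > 0.9

    def test_equals_pooled_t_test(self, rng):
        for _ in range(20):
            y1 = rng.normal(90, 10, size=rng.integers(2, 6))
            y0 = rng.normal(100, 10, size=rng.integers(2, 25))
            ps = self._plateset(y1, y0)
            p_t = sps.ttest_ind(y1, y0, equal_var=True).pvalue
            assert compound_anova(ps, "c") == pytest.approx(p_t, abs=1e-10)

    def test_matches_textbook_f_with_2v24_wells(self, rng):
        y1 = rng.normal(40, 5, size=2)
        y0 = rng.normal(100, 8, size=24)
        ps = self._plateset(y1, y0)
        assert compound_anova(ps, "c") == pytest.approx(
            _brute_force_anova_p(y1, y0), rel=1e-12)

    def test_degenerate_variance_gives_nan(self):
        ps = self._plateset([5.0, 5.0], [5.0, 5.0, 5.0])
        assert np.isnan(compound_anova(ps, "c"))


def _bh_oracle(p):
    """Independent step-up BH."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_four_value_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_stepup_oracle_elementwise(self, rng):
        p = rng.random(50)
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_permutation_invariance_and_never_decreases(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj[perm], bh_adjust(p[perm]))
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_nan_passthrough_and_domain_error(self):
        out = bh_adjust([0.1, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])
        with pytest.raises(Exception):
            bh_adjust([1.5])


class TestSelectHits:
    def test_all_inert_gives_empty_set(self):
        ps, _ = simulate.gen_screen(n_compounds=100, active_fraction=0.0,
                                    seed=3)
        hits = select_hits(screen_stats(ps))
        assert hits.empty

    def test_single_dominant_compound(self):
        stats_df = pd.DataFrame({
            "compound_id": [f"c{i}" for i in range(20)],
            "cell_line": "CL1",
            "delta_poc": [100.0] + [0.0] * 19,
            "adj_p": [1e-6] * 20,
        })
        hits = select_hits(stats_df)
        assert hits["compound_id"].tolist() == ["c0"]

    def test_hit_count_monotone_in_alpha_and_percentile(self):
        ps, _ = simulate.gen_screen(n_compounds=352, seed=5)
        st = screen_stats(ps)
        n = [len(select_hits(st, alpha=a)) for a in (0.001, 0.05, 0.5)]
        assert n == sorted(n)
        m = [len(select_hits(st, percentile=q)) for q in (99, 95, 50)]
        assert m == sorted(m)

    def test_significant_reference_population_option(self):
        ps, _ = simulate.gen_screen(n_compounds=352, seed=5)
        st = screen_stats(ps)
        h_all = select_hits(st, percentile_over="all")
        h_sig = select_hits(st, percentile_over="significant")
        assert set(h_sig["compound_id"]) <= set(h_all["compound_id"])

    def test_planted_actives_recovered(self):
        ps, truth = simulate.gen_screen(n_compounds=520, seed=11)
        hits = select_hits(screen_stats(ps))
        active = set(truth.loc[truth["planted"] == "active", "entity_id"])
        got = set(hits["compound_id"])
        assert len(got & active) / len(active) >= 0.95
        assert not got - active


class TestScreenStatsInvariants:
    def test_poc_delta_poc_complementarity_exact(self):
        ps, _ = simulate.gen_screen(n_compounds=352, seed=2)
        st = screen_stats(ps)
        np.testing.assert_array_equal(st["poc"] + st["delta_poc"], 100.0)

    def test_adj_p_at_least_p(self):
        ps, _ = simulate.gen_screen(n_compounds=352, seed=2)
        st = screen_stats(ps)
        ok = st.dropna(subset=["p_anova"])
        assert (ok["adj_p"] >= ok["p_anova"] - 1e-15).all()


class TestSpatialBias:
    def test_planted_edge_bias_is_flagged(self):
        ps, _ = simulate.gen_screen(n_compounds=176, spatial_bias=20.0,
                                    seed=4)
        rep = spatial_bias_report(ps)
        assert rep["flagged"].all()
        assert (rep["edge_effect"] > 5).all()

    def test_unbiased_plates_flag_near_nominal_rate(self):
        flags = 0
        n_plates = 60
        for seed in range(n_plates):
            ps, _ = simulate.gen_screen(n_compounds=176, seed=1000 + seed)
            flags += int(spatial_bias_report(ps)["flagged"].iloc[0])
        # two BH-corrected tests at alpha 0.05: expect ~5%, allow slack
        assert flags / n_plates <= 0.15

    def test_constant_poc_not_computable(self):
        recs = [("P1", "A", c, "", "vehicle", 100.0) for c in (1, 2)]
        recs += [("P1", r, c, f"c{r}{c}", "sample", 100.0)
                 for r in "BCD" for c in (1, 2, 3)]
        rep = spatial_bias_report(make_plateset(recs))
        assert not rep["computable"].iloc[0]
        assert not rep["flagged"].iloc[0]
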