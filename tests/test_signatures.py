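"""Signature construction, ssGSEA, per-cell rank scores, GMT I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from offsig import simulate
from offsig.signatures import (
    ExpressionMatrix, GeneSignature, build_signature, cell_signature_score,
    rank_cells, read_gmt, score_cells, snr_rank, ssgsea, ttest_filter,
    write_gmt,
)


def _matrix(values, n_a, n_b, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=cols)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols),
                            groups)


class TestTtestFilter:
    def test_constant_gene_flagged_degenerate(self):
        expr = _matrix([[1, 1, 1, 1, 1, 1], [0, 0, 0, 5, 5, 5]], 3, 3)
        out = ttest_filter(expr)
        assert out.loc["g0", "degenerate"]
        assert not out.loc["g0", "keep"]

    def test_extreme_separation_kept(self, rng):
        vals = np.array([[0, 0, 0, 5, 5, 5]], float) + rng.normal(
            0, 1e-3, (1, 6))
        out = ttest_filter(_matrix(vals, 3, 3))
        assert out["keep"].iloc[0]
        assert out["p"].iloc[0] < 1e-6

    def test_matches_pooled_t_oracle(self, rng):
        vals = rng.normal(0, 1, size=(200, 8))
        out = ttest_filter(_matrix(vals, 4, 4))
        # independent pooled-variance formula
        a, b = vals[:, :4], vals[:, 4:]
        sp = np.sqrt(((3 * a.var(axis=1, ddof=1) + 3 * b.var(axis=1, ddof=1))
                      / 6) * (1 / 4 + 1 / 4))
        t = (a.mean(axis=1) - b.mean(axis=1)) / sp
        p = 2 * sps.t.sf(np.abs(t), 6)
        np.testing.assert_allclose(out["p"], p, atol=1e-12)


class TestSnrRank:
    def test_equal_means_zero_snr(self):
        expr = _matrix([[1, 2, 3, 1, 2, 3]], 3, 3)
        assert snr_rank(expr).iloc[0] == pytest.approx(0.0)

    def test_label_swap_negates(self, rng):
        vals = rng.normal(0, 1, size=(50, 8))
        fwd = snr_rank(_matrix(vals, 4, 4))
        # swapping group blocks negates every SNR
        swapped = np.concatenate([vals[:, 4:], vals[:, :4]], axis=1)
        rev = snr_rank(_matrix(swapped, 4, 4))
        np.testing.assert_allclose(fwd.sort_index(), -rev.sort_index(),
                                   atol=1e-12)

    def test_arithmetic_above_floor(self):
        # mu_a 2, mu_b 1, sd 0.5 in both groups (above the 0.2|mu| floor)
        a = 2 + np.array([-1, 1, -1, 1]) * 0.5 / np.std(
            [-1, 1, -1, 1], ddof=1)
        b = 1 + np.array([-1, 1, -1, 1]) * 0.5 / np.std(
            [-1, 1, -1, 1], ddof=1)
        expr = _matrix([np.concatenate([a, b])], 4, 4)
        assert snr_rank(expr).iloc[0] == pytest.approx(1.0)


class TestBuildSignature:
    def test_short_supply_keeps_all_split_by_sign(self, rng):
        vals = np.zeros((10, 12))
        vals[:5, :6] = 3.0   # 5 up genes
        vals[5:, :6] = -3.0  # 5 down genes
        vals += rng.normal(0, 0.05, vals.shape)
        expr = _matrix(vals, 6, 6)
        sig = build_signature(ttest_filter(expr), snr_rank(expr), k=100)
        assert sorted(sig.up) == [f"g{i}" for i in range(5)]
        assert sorted(sig.down) == [f"g{i}" for i in range(5, 10)]

    def test_top_100_of_150_graded_effects(self, rng):
        # 150 up genes with strictly increasing effects; k=100 must take
        # the 100 largest
        n = 200
        effects = np.zeros(n)
        effects[:150] = np.linspace(1.0, 4.0, 150)
        vals = rng.normal(0, 0.01, size=(n, 40))
        vals[:, :20] += effects[:, None]
        expr = _matrix(vals, 20, 20)
        sig = build_signature(ttest_filter(expr), snr_rank(expr), k=100)
        assert len(sig.up) == 100
        expected = {f"g{i}" for i in range(50, 150)}  # largest 100 effects
        assert set(sig.up) == expected

    def test_k_zero_empty(self, rng):
        vals = rng.normal(0, 1, size=(20, 8))
        expr = _matrix(vals, 4, 4)
        sig = build_signature(ttest_filter(expr), snr_rank(expr), k=0)
        assert sig.up == [] and sig.down == []

    def test_up_down_disjoint_with_correct_signs(self):
        mat, _ = simulate.gen_expression(n_genes=500, n_up=30, n_down=30,
                                         seed=9)
        sig = build_signature(ttest_filter(mat), snr_rank(mat), k=100)
        assert not set(sig.up) & set(sig.down)
        assert (sig.scores.loc[sig.up] > 0).all()
        assert (sig.scores.loc[sig.down] < 0).all()

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError):
            GeneSignature(["a", "b"], ["b"])


def _ssgsea_oracle(values, gene_set, w):
    """Brute-force cumulative-sum ssGSEA, written independently."""
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    in_set = [g in gene_set for g, _ in items]
    weights = [abs(v) ** w if ins else 0.0 for (_, v), ins in
               zip(items, in_set)]
    tot_in = sum(weights)
    n_out = sum(1 for x in in_set if not x)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for wt, ins in zip(weights, in_set):
        cum_in += wt
        if not ins:
            cum_out += 1
        es += cum_in / tot_in - cum_out / n_out
    return es


class TestSsgsea:
    def test_three_gene_hand_enumeration(self):
        sv = pd.Series([3.0, 2.0, 1.0], index=["g1", "g2", "g3"])
        assert ssgsea(sv, ["g1"], alpha_weight=0.0) == pytest.approx(1.5)

    def test_top_set_beats_bottom_set(self, rng):
        vals = pd.Series(np.sort(rng.random(30))[::-1],
                         index=[f"g{i}" for i in range(30)])
        top = [f"g{i}" for i in range(5)]
        bottom = [f"g{i}" for i in range(25, 30)]
        assert ssgsea(vals, top) > ssgsea(vals, bottom)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            vals = pd.Series(rng.normal(0, 1, 20),
                             index=[f"g{i}" for i in range(20)])
            gene_set = list(rng.choice(vals.index, size=5, replace=False))
            assert ssgsea(vals, gene_set, 0.25) == pytest.approx(
                _ssgsea_oracle(dict(vals), set(gene_set), 0.25), abs=1e-12)

    def test_rank_invariance_at_weight_zero(self, rng):
        vals = pd.Series(rng.normal(2, 1, 25),
                         index=[f"g{i}" for i in range(25)])
        gene_set = [f"g{i}" for i in range(0, 25, 5)]
        a = ssgsea(vals, gene_set, alpha_weight=0.0)
        b = ssgsea(np.exp(vals), gene_set, alpha_weight=0.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        sv = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea(sv, ["zzz"])
        with pytest.raises(ValueError):
            ssgsea(sv, ["a", "b"])


class TestCellSignatureScore:
    def test_perfect_and_absent_signatures(self):
        score, lp = cell_signature_score({"a": 1, "b": 2, "c": 3},
                                         ["a", "b", "c"])
        assert score == 1.0 and lp
        # genes absent from the rank universe: clipped at r_max + 1, the
        # score collapses to (n-1)/(2 r_max), i.e. essentially zero
        score, lp = cell_signature_score({}, ["x", "y"], r_max=1500)
        assert score == pytest.approx(1 / 3000)
        assert not lp

    def test_two_gene_arithmetic(self):
        score, lp = cell_signature_score({"a": 1, "b": 751}, ["a", "b"])
        assert score == pytest.approx(1 - 749 / 3000)
        assert lp

    def test_score_bounded_and_monotone_in_rank(self, rng):
        sig = [f"g{i}" for i in range(5)]
        ranks = {f"g{i}": int(r) for i, r in
                 enumerate(rng.integers(1, 2000, size=5))}
        s0, _ = cell_signature_score(ranks, sig)
        assert 0.0 <= s0 <= 1.0
        worse = dict(ranks)
        worse["g0"] = min(worse["g0"] + 100, 3000)
        s1, _ = cell_signature_score(worse, sig)
        assert s1 <= s0 + 1e-12

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            cell_signature_score({"a": 1}, [])

    def test_score_cells_matches_scalar_version(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 4)),
                            index=[f"g{i}" for i in range(50)],
                            columns=list("wxyz"))
        ranks = rank_cells(expr)
        sig = [f"g{i}" for i in range(8)]
        frame = score_cells(ranks, sig, r_max=30)
        for cell in expr.columns:
            s, lp = cell_signature_score(dict(ranks[cell]), sig, r_max=30)
            assert frame.loc[cell, "score"] == pytest.approx(s)
            assert frame.loc[cell, "lp"] == lp


class TestGmt:
    def test_read_valid_line(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("SET1\tdesc\tA\tB\tC\tD\tE\n")
        sets = read_gmt(p)
        assert sets["SET1"] == list("ABCDE")

    def test_duplicate_member_dedup_with_warning(self, tmp_path):
        p = tmp_path / "dup.gmt"
        p.write_text("SET1\tdesc\tA\tB\tA\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sets = read_gmt(p)
        assert sets["SET1"] == ["A", "B"]

    def test_short_line_names_location(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("SET1\tdesc\tA\nBROKEN\tonly_desc\n")
        with pytest.raises(ValueError, match="2"):
            read_gmt(p)

    def test_round_trip_identity(self, tmp_path):
        sets = {"S1": ["A", "B"], "S2": ["C", "D", "E"]}
        p = tmp_path / "rt.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets


def test_signature_recovery_on_planted_matrix():
    mat, truth = simulate.gen_expression(seed=21)
    sig = build_signature(ttest_filter(mat), snr_rank(mat), k=100)
    up = set(truth.loc[truth["planted"] == "up", "entity_id"])
    down = set(truth.loc[truth["planted"] == "down", "entity_id"])
    rec = (len(set(sig.up) & up) + len(set(sig.down) & down)) / 200
    assert rec >= 0.95
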