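import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from chromoscore.immune import (
    cell_ratios,
    cytokine_ratio,
    geometric_mean_scores,
    pathway_differential,
    read_gmt,
    ssgsea,
    total_infiltration,
    write_gmt,
)


def ssgsea_oracle(values, in_set, weight=0.25, normalize=True):
    """Independent brute-force running-sum ssGSEA for one sample.

    ``values``: expression vector; ``in_set``: boolean membership.
    Written as explicit loops, separately from the vectorised code path.
    """
    n = len(values)
    ranks = rankdata(values)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    denom_in = sum(ranks[i] ** weight for i in order if in_set[i])
    n_out = sum(1 for i in order if not in_set[i])
    p_in = p_out = 0.0
    running = []
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** weight / denom_in
        elif n_out:
            p_out += 1.0 / n_out
        running.append(p_in - p_out)
    es = sum(running)
    if normalize:
        rng = max(running) - min(running)
        if rng > 0:
            es /= rng
    return es


def random_expr(rng, n_genes=50, n_samples=4):
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(
        rng.normal(0, 2, size=(n_genes, n_samples)),
        index=genes,
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestSSGSEA:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            expr = random_expr(rng)
            members = list(rng.choice(expr.index, size=8, replace=False))
            scores = ssgsea(expr, {"set": members})
            in_set = expr.index.isin(members)
            for j, col in enumerate(expr.columns):
                expected = ssgsea_oracle(expr[col].values, in_set)
                assert scores.loc["set", col] == pytest.approx(expected, abs=1e-9)

    def test_all_genes_set_matches_oracle_limit(self, rng):
        expr = random_expr(rng, n_genes=20, n_samples=2)
        scores = ssgsea(expr, {"all": list(expr.index)})
        in_set = np.ones(20, dtype=bool)
        for col in expr.columns:
            expected = ssgsea_oracle(expr[col].values, in_set)
            assert scores.loc["all", col] == pytest.approx(expected, abs=1e-9)

    def test_top_ranked_placement_maximises_raw_score(self):
        # over all placements of a 3-gene set in a 10-gene list, occupying
        # the top ranks maximises the raw running-sum integral (exhaustive
        # check; range normalisation intentionally rescales per placement)
        values = np.arange(10, 0, -1, dtype=float)  # gene i has rank 10-i
        genes = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame({"s": values}, index=genes)
        best_combo, best_score = None, -np.inf
        for combo in itertools.combinations(range(10), 3):
            members = [genes[i] for i in combo]
            s = ssgsea(expr, {"set": members}, normalize=False).loc["set", "s"]
            if s > best_score:
                best_combo, best_score = combo, s
        assert best_combo == (0, 1, 2)

    def test_identical_samples_identical_scores(self, rng):
        expr = random_expr(rng, n_samples=1)
        expr["s1"] = expr["s0"]
        scores = ssgsea(expr, {"set": list(expr.index[:5])})
        assert scores["s0"].equals(scores["s1"])

    def test_no_overlap_set_flagged_and_skipped(self, rng):
        expr = random_expr(rng)
        with pytest.warns(UserWarning, match="no overlap"):
            scores = ssgsea(expr, {"ghost": ["nope1", "nope2"]})
        assert scores.empty


class TestGeometricMean:
    def test_four_nine_gives_six(self):
        expr = pd.DataFrame({"s": [4.0, 9.0]}, index=["a", "b"])
        scores = geometric_mean_scores(expr, {"set": ["a", "b"]}, pseudocount=0.0)
        assert scores.loc["set", "s"] == pytest.approx(6.0)

    def test_single_gene_set_is_identity(self):
        expr = pd.DataFrame({"s": [7.0]}, index=["a"])
        scores = geometric_mean_scores(expr, {"set": ["a"]}, pseudocount=0.0)
        assert scores.loc["set", "s"] == pytest.approx(7.0)

    def test_homogeneous_scaling(self, rng):
        expr = np.abs(random_expr(rng)) + 1
        sets = {"set": list(expr.index[:6])}
        s1 = geometric_mean_scores(expr, sets, pseudocount=0.0)
        s2 = geometric_mean_scores(expr * 3.0, sets, pseudocount=0.0)
        np.testing.assert_allclose(s2.values, 3.0 * s1.values, rtol=1e-12)

    def test_nonpositive_value_names_gene_and_sample(self):
        expr = pd.DataFrame({"bad_sample": [-2.0]}, index=["bad_gene"])
        with pytest.raises(ValueError, match="bad_gene"):
            geometric_mean_scores(expr, {"set": ["bad_gene"]}, pseudocount=0.0)


class TestRatios:
    def make_scores(self, data):
        df = pd.DataFrame(data)
        df.attrs["method"] = "geometric_mean"
        return df

    def test_equal_rows_give_unit_ratio(self):
        scores = self.make_scores(
            {f"s{i}": {"CD8_T_cells": 2.0, "Tregs": 2.0, "TAM": 2.0, "MDSC": 2.0}
             for i in range(3)}
        )
        out = cell_ratios(scores)
        assert (out["cd8_treg"] == 1.0).all()
        assert (out["log2_cd8_treg"] == 0.0).all()

    def test_doubling_cd8_doubles_all_ratios(self):
        base = self.make_scores(
            {"s": {"CD8_T_cells": 2.0, "Tregs": 1.0, "TAM": 4.0, "MDSC": 0.5}}
        )
        doubled = base.copy()
        doubled.attrs["method"] = "geometric_mean"
        doubled.loc["CD8_T_cells"] *= 2
        r1, r2 = cell_ratios(base), cell_ratios(doubled)
        for col in ("cd8_treg", "cd8_tam", "cd8_mdsc"):
            np.testing.assert_allclose(r2[col], 2 * r1[col])

    def test_ssgsea_scores_rejected(self):
        scores = self.make_scores({"s": {"CD8_T_cells": 1, "Tregs": 1, "TAM": 1, "MDSC": 1}})
        scores.attrs["method"] = "ssgsea"
        with pytest.raises(ValueError, match="geometric"):
            cell_ratios(scores)

    def test_planted_cd8_deficit_detected_by_wilcoxon(self):
        """Lower CD8 signal in chromothripsis-labelled samples shows up as
        lower CD8/Treg ratios by rank-sum test (power check)."""
        from chromoscore.simulate import SimConfig, simulate_expression, substream

        cfg = SimConfig(n_samples=200, seed=8)
        labels = np.arange(200) % 2 == 0
        expr, sets, _ = simulate_expression(cfg, labels, substream(cfg, "expression"))
        gm = geometric_mean_scores(expr, sets, expr_scale="log2")
        ratios = cell_ratios(gm)
        ct = ratios.loc[expr.columns[labels], "cd8_treg"]
        non_ct = ratios.loc[expr.columns[~labels], "cd8_treg"]
        stat = mannwhitneyu(ct, non_ct, alternative="less")
        assert stat.pvalue < 1e-6
        assert ct.median() < non_ct.median()


class TestCytokineRatio:
    def test_identical_panels_zero(self, rng):
        expr = np.abs(random_expr(rng)) + 1
        genes = list(expr.index[:4])
        out = cytokine_ratio(expr, pro=genes, anti=genes)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_fourfold_pro_gives_two(self):
        expr = pd.DataFrame({"s": [8.0, 8.0, 2.0, 2.0]}, index=["p1", "p2", "a1", "a2"])
        out = cytokine_ratio(expr, pro=["p1", "p2"], anti=["a1", "a2"], pseudocount=0.0)
        assert out["s"] == pytest.approx(2.0)

    def test_composes_from_geometric_means(self, rng):
        expr = np.abs(random_expr(rng)) + 1
        pro, anti = list(expr.index[:3]), list(expr.index[3:7])
        out = cytokine_ratio(expr, pro=pro, anti=anti, pseudocount=1.0)
        gm = geometric_mean_scores(expr, {"p": pro, "a": anti}, pseudocount=1.0)
        np.testing.assert_allclose(out.values, np.log2(gm.loc["p"] / gm.loc["a"]).values)


class TestPathwayDifferential:
    def make_scores(self, rng, n_sets=5, n_per_group=10):
        cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
        scores = pd.DataFrame(rng.normal(size=(n_sets, 2 * n_per_group)),
                              index=[f"set{i}" for i in range(n_sets)], columns=cols)
        groups = pd.Series([False] * n_per_group + [True] * n_per_group, index=cols)
        return scores, groups

    def test_identical_groups_t_zero_p_one(self):
        cols = [f"s{i}" for i in range(8)]
        scores = pd.DataFrame([[1, 2, 3, 4, 1, 2, 3, 4]], index=["set"], columns=cols)
        groups = pd.Series([False] * 4 + [True] * 4, index=cols)
        out = pathway_differential(scores.astype(float), groups)
        assert out.loc["set", "t"] == pytest.approx(0.0)
        assert out.loc["set", "p"] == pytest.approx(1.0)

    def test_antisymmetric_under_label_swap(self, rng):
        scores, groups = self.make_scores(rng)
        out1 = pathway_differential(scores, groups)
        out2 = pathway_differential(scores, ~groups)
        np.testing.assert_allclose(out1["t"].values, -out2["t"].values)
        np.testing.assert_allclose(out1["p"].values, out2["p"].values)

    def test_planted_shift_has_largest_statistic(self, rng):
        hits = 0
        for _ in range(20):
            scores, groups = self.make_scores(rng, n_sets=20, n_per_group=50)
            scores.loc["set0", ~groups.values] += 2.0  # +2 SD in non-flagged group
            out = pathway_differential(scores, groups)
            hits += out["t"].abs().idxmax() == "set0"
        assert hits >= 19

    def test_sign_convention_positive_for_non_flagged_group(self, rng):
        scores, groups = self.make_scores(rng)
        scores.loc["set0", ~groups.values] += 5.0
        out = pathway_differential(scores, groups)
        assert out.loc["set0", "t"] > 0


class TestGMTAndTotals:
    def test_gmt_round_trip(self, tmp_path):
        sets = {"A": ["g1", "g2"], "B": ["g3"]}
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_total_infiltration_is_mean(self, rng):
        scores = pd.DataFrame(rng.normal(size=(4, 3)))
        np.testing.assert_allclose(total_infiltration(scores).values,
                                   scores.mean(axis=0).values)
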