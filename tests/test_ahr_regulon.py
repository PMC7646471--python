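import numpy as np
import pandas as pd
import pytest

from apohot.ahr_regulon import (
    RegulonModel,
    activity_group_tests,
    de_ranking,
    dependency_quantile_comparison,
    finalise_regulon,
    nb_differential_expression,
    ranksum_randomisation_test,
    regulon_activity_score,
    select_regulon_candidates,
    size_factors,
)
from apohot.io_formats import ExpressionMatrix
from apohot.synthetic_data import SimConfig, TruthManifest, simulate_knockdown


def _coexpression_matrix(rng, n_samples=80, n_targets=10, n_noise=60, n_flat=20):
    """TF + prototype + co-regulated targets + independent noise genes."""
    activity = rng.normal(0, 1, n_samples)
    rows = {
        "AHR": activity + rng.normal(0, 0.7, n_samples),
        "CYP1A1": activity + rng.normal(0, 0.7, n_samples),
    }
    for i in range(n_targets):
        rows[f"TGT{i:02d}"] = activity + rng.normal(0, 0.5, n_samples)
    for i in range(n_noise):
        rows[f"NOISE{i:02d}"] = rng.normal(0, 1, n_samples)
    for i in range(n_flat):  # low-variance genes removed by the filter
        rows[f"FLAT{i:02d}"] = rng.normal(0, 0.01, n_samples)
    values = pd.DataFrame(rows).T - pd.DataFrame(rows).T.min().min() + 1.0
    values.columns = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(values=values)


class TestCandidateSelection:
    def test_targets_selected_noise_excluded(self):
        rng = np.random.default_rng(0)
        expr = _coexpression_matrix(rng)
        model = select_regulon_candidates(expr)
        targets = {g for g in model.candidates if g.startswith("TGT")}
        noise = {g for g in model.candidates if g.startswith("NOISE")}
        assert len(targets) >= 8
        assert len(noise) <= 6
        assert "AHR" not in model.candidates  # anchors excluded
        assert model.rho_threshold > 0

    def test_tf_copy_is_candidate(self):
        rng = np.random.default_rng(1)
        expr = _coexpression_matrix(rng)
        expr.values.loc["TFCOPY"] = expr.values.loc["AHR"]
        model = select_regulon_candidates(expr)
        # identical to the TF: rho = 1 with the TF and the anchors'
        # mutual rho with the prototype, hence always past threshold
        assert "TFCOPY" in model.candidates

    def test_noise_exclusion_improves_with_samples(self):
        rates = []
        for n in (30, 200):
            rng = np.random.default_rng(2)
            expr = _coexpression_matrix(rng, n_samples=n, n_noise=100)
            model = select_regulon_candidates(expr)
            noise = sum(g.startswith("NOISE") for g in model.candidates)
            rates.append(noise / 100)
        assert rates[1] <= rates[0]


class TestDifferentialExpression:
    def test_size_factor_of_depth_doubled_duplicate(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(50, size=(200,)).astype(float) + 1
        counts = pd.DataFrame({"a": base, "b": base * 2, "c": base})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-6)

    def test_null_design_mostly_non_significant(self):
        cfg = SimConfig(seed=4, kd_n_genes=300, n_regulon_genes=20, kd_fold_change=1.0)
        man = TruthManifest(
            sites=[], exposures=pd.DataFrame(), apobec_score=pd.Series(dtype=float),
            emission_tally=pd.DataFrame(),
        )
        counts, cond = simulate_knockdown(cfg, man)
        de = nb_differential_expression(counts, cond)
        assert (de["FDR"].fillna(1.0) < 0.05).mean() <= 0.05
        assert de["log2FC"].abs().median() < 0.35

    def test_planted_knockdown_detected(self):
        cfg = SimConfig(seed=5, kd_n_genes=300, n_regulon_genes=20)
        man = TruthManifest(
            sites=[], exposures=pd.DataFrame(), apobec_score=pd.Series(dtype=float),
            emission_tally=pd.DataFrame(),
        )
        counts, cond = simulate_knockdown(cfg, man)
        de = nb_differential_expression(counts, cond)
        planted = de.loc[[g for g in man.regulon_genes if g in de.index]]
        assert (planted["FDR"] < 0.05).mean() >= 0.9
        assert (planted["log2FC"] < 0).all()


class TestRandomisation:
    def test_top_ranked_candidates_reach_minimum_p(self):
        ranking = pd.Series(
            np.arange(1, 1001, dtype=float), index=[f"g{i}" for i in range(1000)]
        )
        candidates = [f"g{i}" for i in range(20)]  # exactly the top 20
        p = ranksum_randomisation_test(ranking, candidates, n_rand=5000, seed=0)
        assert p == pytest.approx(1 / 5001)

    def test_p_never_zero_and_bounded_below(self):
        ranking = pd.Series(
            np.arange(1, 201, dtype=float), index=[f"g{i}" for i in range(200)]
        )
        p = ranksum_randomisation_test(ranking, [f"g{i}" for i in range(5)],
                                       n_rand=1000, seed=1)
        assert p >= 1 / 1001

    def test_random_candidates_calibrated(self):
        ranking = pd.Series(
            np.arange(1, 501, dtype=float), index=[f"g{i}" for i in range(500)]
        )
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(60):
            cand = [f"g{i}" for i in rng.choice(500, size=15, replace=False)]
            ps.append(ranksum_randomisation_test(ranking, cand, n_rand=2000,
                                                 seed=int(rng.integers(2**31))))
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.1).mean() < 0.3


class TestFinalise:
    def _model(self, candidates):
        return RegulonModel(
            tf="AHR", prototype="CYP1A1", rho_threshold=0.3, anchor_p=1e-9,
            candidates=candidates,
        )

    def test_no_significant_candidate_gives_empty_set(self):
        de = pd.DataFrame(
            {"log2FC": [0.5, -0.2], "p": [0.5, 0.4], "FDR": [0.9, 0.8]},
            index=["a", "b"],
        )
        model = finalise_regulon(self._model(["a", "b"]), de)
        assert model.validated_set == []

    def test_planted_regulon_fully_recovered(self):
        de = pd.DataFrame(
            {
                "log2FC": [-2.0, -1.5, 0.8, -0.1],
                "p": [1e-8, 1e-6, 0.01, 0.6],
                "FDR": [1e-6, 1e-4, 0.04, 0.9],
            },
            index=["r1", "r2", "up", "ns"],
        )
        model = finalise_regulon(self._model(["r1", "r2", "up", "ns"]), de)
        assert model.validated_set == ["r1", "r2"]

    def test_ranking_puts_significant_downregulation_on_top(self):
        de = pd.DataFrame(
            {
                "log2FC": [-3.0, -0.5, 2.0, -2.0],
                "p": [1e-9, 0.2, 1e-9, 1e-5],
                "FDR": [1e-7, 0.5, 1e-7, 1e-3],
            },
            index=["strong_dn", "weak_dn", "strong_up", "mid_dn"],
        )
        ranks = de_ranking(de)
        assert ranks["strong_dn"] == 1.0
        assert ranks["strong_up"] > ranks["mid_dn"] > ranks["strong_dn"]


class TestActivity:
    def _expr(self, rng, n_genes=200, n_samples=12):
        values = pd.DataFrame(
            rng.lognormal(0, 1, size=(n_genes, n_samples)),
            index=[f"g{i:03d}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        return ExpressionMatrix(values=values)

    def test_top_ranked_regulon_maximises_score(self):
        rng = np.random.default_rng(6)
        expr = self._expr(rng)
        gene_set = [f"g{i:03d}" for i in range(10)]
        expr.values.loc[gene_set, "s0"] = expr.values["s0"].max() * 10
        expr.values.loc[gene_set, "s1"] = expr.values["s1"].min() / 10
        scores = regulon_activity_score(expr, gene_set)
        assert scores["s0"] == scores.max()
        assert scores["s1"] == scores.min()

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        expr = self._expr(rng)
        gene_set = [f"g{i:03d}" for i in range(8)]
        s1 = regulon_activity_score(expr, gene_set)
        expr.values["s3"] = expr.values["s3"] ** 2  # strictly monotone
        s2 = regulon_activity_score(expr, gene_set)
        assert s1["s3"] == pytest.approx(s2["s3"])

    def test_missing_genes_raise(self):
        rng = np.random.default_rng(8)
        expr = self._expr(rng)
        with pytest.raises(ValueError, match="absent"):
            regulon_activity_score(expr, ["g000", "g001", "g002", "g003", "NOPE"])

    def test_altered_groups_detected(self):
        """Samples with shifted regulon expression separate by activity."""
        rng = np.random.default_rng(9)
        expr = self._expr(rng, n_samples=90)
        gene_set = [f"g{i:03d}" for i in range(12)]
        groups = pd.Series(
            ["altered"] * 30 + ["wild"] * 30 + ["other"] * 30,
            index=expr.values.columns,
        )
        expr.values.loc[gene_set, groups == "altered"] *= 6
        scores = regulon_activity_score(expr, gene_set)
        out = activity_group_tests(scores, groups)
        assert out["kruskal_p"] < 0.05
        dunn = out["dunn"].set_index(["group_a", "group_b"])
        assert dunn.loc[("altered", "wild"), "p_adj"] < 0.05


class TestDependency:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(10)
        b = rng.normal(-0.3, 0.2, size=22)
        out = dependency_quantile_comparison(b, b)
        assert np.allclose(out["deltas"], 0, atol=1e-9)
        assert out["p"] == pytest.approx(1.0)

    def test_planted_shift_detected_in_most_replicates(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            b = rng.normal(-0.2, 0.25, size=22)
            a = rng.choice(b, size=6, replace=False) - 0.3
            out = dependency_quantile_comparison(a, b, alternative="less")
            hits += out["p"] < 0.05
        assert hits >= 40  # >= 80% of replicates

    def test_singleton_group_b_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            dependency_quantile_comparison([0.1, 0.2], [0.3])
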