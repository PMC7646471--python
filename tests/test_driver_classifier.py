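from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apohot.driver_classifier import (
    IterativeSimilarityClassifier,
    TwoStepGLRClassifier,
    WeightedKMeans1D,
    clonality_tests,
    iterative_similarity_classify,
    mutability_adjusted_recurrence,
    permutation_fdr,
    univariate_two_cluster,
)
from apohot.hotspots import HotspotEntry, HotspotPanel
from apohot.io_formats import CohortTable

from conftest import make_record


def seed_cloud(rng, n_driver=9, n_passenger=7, spread_d=0.05, spread_p=0.15):
    drivers = rng.normal([0.85, 0.85], spread_d, size=(n_driver, 2))
    passengers = rng.normal([0.15, 0.15], spread_p, size=(n_passenger, 2))
    X = np.clip(np.vstack([drivers, passengers]), 0, 1)
    y = np.array(["driver"] * n_driver + ["passenger"] * n_passenger, dtype=object)
    return X, y


class TestIterativeClassifier:
    def test_point_on_driver_assigned_first_iteration(self):
        rng = np.random.default_rng(0)
        X, y = seed_cloud(rng)
        est = IterativeSimilarityClassifier().fit(X, y)
        res = est.classify(np.array([[0.85, 0.85]]))
        assert res.loc[0, "label"] == "driver"
        assert res.loc[0, "iteration"] == 1
        assert res.loc[0, "mdod"] > 0

    def test_symmetric_point_undetermined(self):
        X = np.array(
            [[0.2, 0.2], [0.25, 0.2], [0.2, 0.25],
             [0.8, 0.8], [0.75, 0.8], [0.8, 0.75]]
        )
        y = np.array(["driver"] * 3 + ["passenger"] * 3, dtype=object)
        est = IterativeSimilarityClassifier().fit(X, y)
        res = est.classify(np.array([[0.5, 0.5]]))
        assert res.loc[0, "label"] == "undetermined"

    def test_too_few_seeds_raise(self):
        X = np.array([[0, 0], [1, 1], [0.5, 0.5]])
        y = np.array(["driver", "passenger", "passenger"], dtype=object)
        with pytest.raises(ValueError, match=">= 2"):
            IterativeSimilarityClassifier().fit(X, y)

    def test_recovery_of_generating_classes(self):
        """>=90% of resolvable simulated unknowns recover their class."""
        rng = np.random.default_rng(1)
        X, y = seed_cloud(rng)
        n_d, n_p = 16, 12
        unknown = np.clip(
            np.vstack(
                [
                    rng.normal([0.85, 0.85], 0.05, size=(n_d, 2)),
                    rng.normal([0.15, 0.15], 0.15, size=(n_p, 2)),
                ]
            ),
            0,
            1,
        )
        truth = np.array(["driver"] * n_d + ["passenger"] * n_p, dtype=object)
        est = IterativeSimilarityClassifier().fit(X, y)
        res = est.classify(unknown)
        resolved = res["label"] != "undetermined"
        assert resolved.sum() >= 20
        acc = (res.loc[resolved, "label"].to_numpy() == truth[resolved]).mean()
        assert acc >= 0.9

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        X, y = seed_cloud(rng)
        unknown = rng.uniform(0, 1, size=(10, 2))
        est = IterativeSimilarityClassifier().fit(X, y)
        res1 = est.classify(unknown)
        perm = rng.permutation(10)
        res2 = est.classify(unknown[perm])
        assert list(res2["label"]) == list(res1["label"].iloc[perm])

    def test_functional_wrapper_round_trip(self):
        rng = np.random.default_rng(3)
        X, y = seed_cloud(rng)
        points = pd.DataFrame(
            {
                "x1": np.concatenate([X[:, 0], [0.9, 0.1]]),
                "x2": np.concatenate([X[:, 1], [0.9, 0.1]]),
                "seed_label": ["known_driver"] * 9 + ["known_passenger"] * 7
                + ["unknown"] * 2,
            }
        )
        res = iterative_similarity_classify(points)
        assert list(res["label"]) == ["driver", "passenger"]


class TestPermutationFDR:
    def _result_frame(self, points, labels):
        return pd.DataFrame(
            {
                "x1": points[:, 0],
                "x2": points[:, 1],
                "label": labels,
                "iteration": 1,
                "mdod": np.nan,
                "t_p": np.nan,
            }
        )

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        X, y = seed_cloud(rng)
        pt = X[y == "driver"].mean(axis=0)
        res = self._result_frame(pt[None, :], ["driver"])
        out = permutation_fdr(res, X, y)
        # independent oracle: direct loop over all C(16, 9) relabelings
        d = np.sqrt(((X - pt) ** 2).sum(axis=1))
        count = 0
        total = 0
        obs = d[y == "passenger"].mean() - d[y == "driver"].mean()
        for combo in combinations(range(16), 9):
            mask = np.zeros(16, dtype=bool)
            mask[list(combo)] = True
            mdod = d[~mask].mean() - d[mask].mean()
            count += mdod >= obs
            total += 1
        assert total == 11440
        assert out.loc[0, "p_perm"] == pytest.approx(count / total)
        # well separated seeds put the centroid at the extreme tail
        assert out.loc[0, "p_perm"] <= 5 / 11440

    def test_undetermined_points_get_no_fdr(self):
        rng = np.random.default_rng(5)
        X, y = seed_cloud(rng)
        res = self._result_frame(np.array([[0.5, 0.5]]), ["undetermined"])
        out = permutation_fdr(res, X, y)
        assert np.isnan(out.loc[0, "fdr"])

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(6)
        X, y = seed_cloud(rng)
        pts = rng.uniform(0, 1, size=(15, 2))
        res = self._result_frame(pts, ["driver"] * 15)
        out = permutation_fdr(res, X, y)
        srt = out.sort_values("p_perm")
        assert (np.diff(srt["fdr"]) >= -1e-12).all()


class TestTwoStepGLR:
    def test_probabilities_bounded_and_monotone(self):
        rng = np.random.default_rng(7)
        ranks = rng.uniform(0, 1, 200)
        y_gene = (ranks + rng.normal(0, 0.3, 200) > 0.5).astype(int)
        loops = rng.uniform(0, 1, 60)
        y_mut = (loops + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        glr = TwoStepGLRClassifier().fit(ranks, y_gene, loops, y_mut)
        grid = np.linspace(0, 1, 21)
        proba = glr.predict_proba(np.full_like(grid, 0.5), grid)
        assert ((proba >= 0) & (proba <= 1)).all()
        assert (np.diff(proba) >= -1e-12).all()  # positive fitted slope

    def test_perfect_separation_falls_back_penalised(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        glr = TwoStepGLRClassifier().fit(x, y, x, y)
        assert any(glr.penalised_)
        proba = glr.predict_proba(np.array([0.5]), np.array([0.5]))
        assert 0 <= proba[0] <= 1

    def test_concordance_with_iterative_method(self):
        """Iterative drivers occupy the top GLR driverness stratum."""
        rng = np.random.default_rng(8)
        X, y = seed_cloud(rng)
        unknown = np.clip(
            np.vstack(
                [
                    rng.normal([0.85, 0.85], 0.05, size=(10, 2)),
                    rng.normal([0.15, 0.15], 0.15, size=(10, 2)),
                ]
            ),
            0,
            1,
        )
        est = IterativeSimilarityClassifier().fit(X, y)
        res = est.classify(unknown)
        ranks = np.concatenate([X[:, 1], unknown[:, 1]])
        y_gene = (ranks > 0.5).astype(int)
        glr = TwoStepGLRClassifier().fit(
            ranks, y_gene, X[:, 0], (y == "driver").astype(int)
        )
        proba = glr.predict_proba(unknown[:, 1], unknown[:, 0])
        drv = res["label"] == "driver"
        psg = res["label"] == "passenger"
        assert proba[drv.to_numpy()].min() > proba[psg.to_numpy()].max()


def _clonality_cohort(rng, n_genes=20, or_planted=True):
    records = []
    sample_counter = 0
    for g in range(n_genes):
        gene = f"g{g:02d}"
        # one recurrent (hotspot) site per gene
        for _ in range(8):
            p_clonal = 0.8 if or_planted else 0.5
            records.append(
                make_record(
                    f"s{sample_counter:04d}", 1000 + g, gene=gene,
                    clonality="clonal" if rng.random() < p_clonal else "subclonal",
                )
            )
            sample_counter += 1
        # non-hotspot mutations with varying recurrence (1-3 carriers),
        # so the mutation-count covariate is not collinear with hotspot status
        for j in range(10):
            n_carriers = 1 + (j % 3)
            for _ in range(n_carriers):
                records.append(
                    make_record(
                        f"s{sample_counter:04d}", 5000 + 100 * g + j, gene=gene,
                        clonality="clonal" if rng.random() < 0.5 else "subclonal",
                    )
                )
                sample_counter += 1
    panel = HotspotPanel(
        threshold=4,
        hotspots=[
            HotspotEntry(
                key=("chr1", 1000 + g, "C", "T"), count=8, gene=f"g{g:02d}",
                protein_change=None, motif_class="APOBEC_TCN", subclass="YTCN",
            )
            for g in range(n_genes)
        ],
    )
    return CohortTable(records=records), panel


class TestClonality:
    def test_fisher_matches_hypergeometric_oracle(self):
        """Sample OR and p agree with the exact hypergeometric computation."""
        a, b, c, d = 30, 10, 40, 40
        rng = np.random.default_rng(9)
        records = []
        i = 0
        for clonal, hotspot, n in [(1, 1, a), (0, 1, b), (1, 0, c), (0, 0, d)]:
            for _ in range(n):
                records.append(
                    make_record(
                        f"s{i:04d}", 1000 if hotspot else 2000 + i, gene="g",
                        clonality="clonal" if clonal else "subclonal",
                    )
                )
                i += 1
        panel = HotspotPanel(
            threshold=4,
            hotspots=[
                HotspotEntry(
                    key=("chr1", 1000, "C", "T"), count=a + b, gene="g",
                    protein_change=None, motif_class="APOBEC_TCN", subclass="YTCN",
                )
            ],
        )
        out = clonality_tests(CohortTable(records=records), panel)
        assert out["table"] == (a, b, c, d)
        assert out["fisher_or"] == pytest.approx((a * d) / (b * c))  # 3.0
        # oracle: two-sided exact p by hypergeometric enumeration
        M, n_draw, N_succ = a + b + c + d, a + b, a + c
        rv = stats.hypergeom(M, N_succ, n_draw)
        p_obs = rv.pmf(a)
        p_two = sum(
            rv.pmf(k)
            for k in range(max(0, n_draw - (M - N_succ)), min(n_draw, N_succ) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9)
        )
        assert out["fisher_p"] == pytest.approx(p_two, rel=1e-6)

    def test_identical_fractions_give_or_near_one(self):
        rng = np.random.default_rng(10)
        cohort, panel = _clonality_cohort(rng, or_planted=False)
        out = clonality_tests(cohort, panel)
        assert 0.6 < out["fisher_or"] < 1.6
        assert out["fisher_p"] > 0.05

    def test_glmm_recovers_planted_enrichment(self):
        rng = np.random.default_rng(11)
        cohort, panel = _clonality_cohort(rng, or_planted=True)
        out = clonality_tests(cohort, panel)
        assert out["glmm_or"] > 1
        assert out["glmm_p"] < 0.05


class TestSelectionSurrogate:
    def test_uniform_mutability_enrichment_proportional_to_counts(self, sig_reference):
        from apohot.signatures import ExposureMatrix

        samples = [f"s{i}" for i in range(10)]
        flat = pd.DataFrame(
            1.0 / 30, index=samples, columns=sig_reference.signature_ids
        )
        exp = ExposureMatrix(
            exposures=flat,
            apobec_score=pd.Series(0.1, index=samples),
            undefined=pd.Series(False, index=samples),
        )
        # two sites in the SAME channel with different observed counts
        recs = [make_record(f"s{i}", 100) for i in range(6)] + [
            make_record(f"s{i}", 200) for i in range(2)
        ]
        table = mutability_adjusted_recurrence(recs, exp, sig_reference)
        table = table.set_index("pos")
        assert table.loc[100, "enrichment"] / table.loc[200, "enrichment"] == pytest.approx(3.0)

    def test_two_cluster_worked_example(self):
        labels = univariate_two_cluster([1.0, 2.0, 100.0, 110.0])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_two_cluster_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            x = rng.normal(0, 5, size=n)
            w = rng.uniform(0.5, 2.0, size=n)
            est = WeightedKMeans1D().fit(x, w)

            def wcss(mask):
                out = 0.0
                for m in (mask, ~mask):
                    if m.sum() == 0:
                        return np.inf
                    mu = np.average(x[m], weights=w[m])
                    out += float((w[m] * (x[m] - mu) ** 2).sum())
                return out

            best = min(
                wcss(np.array([(i >> b) & 1 == 1 for b in range(n)]))
                for i in range(1, 2**n - 1)
            )
            assert est.inertia_ == pytest.approx(best, abs=1e-9)
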