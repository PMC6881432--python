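"""Network scorers (CLR, ARACNE/DPI, TOM, trees, partial correlation,
module surrogate) and the Borda ensemble with promiscuity filtering."""

import numpy as np
import pandas as pd
import pytest

from phasecore.trn import (ScoreMatrix, dpi_prune, ensemble_network,
                           kmeans_bic, per_tf_network, score_aracne,
                           score_mi_clr, score_modules,
                           score_partial_correlation, score_tom,
                           score_tree_importance, MI_CAP, ModuleClustering)


def _matrix(rng, n=40, p=12, prefix="g"):
    cols = [f"{prefix}{i}" for i in range(p)]
    return pd.DataFrame(rng.normal(size=(n, p)), columns=cols)


class TestCLR:
    def test_signal_pair_beats_null_background(self, rng):
        x = _matrix(rng, n=60, p=15)
        x["g1"] = x["g0"] * 0.9 + 0.3 * rng.normal(size=60)
        sm = score_mi_clr(x, ["g0"])
        scores = sm.scores.loc["g0"].drop("g0")
        assert scores.idxmax() == "g1"
        null_mean = scores.drop("g1").mean()
        assert scores["g1"] > null_mean + 3

    def test_perfect_correlation_capped_and_top_ranked(self, rng):
        x = _matrix(rng, n=30, p=6)
        x["g1"] = 2 * x["g0"]
        sm = score_aracne(x, ["g0"])
        assert sm.scores.loc["g0", "g1"] == MI_CAP
        assert sm.pair_ranking().iloc[0]["target"] == "g1"

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            score_mi_clr(_matrix(rng, n=5), ["g0"])

    def test_binned_estimator_ranks_strong_pair_first(self, rng):
        x = _matrix(rng, n=100, p=8)
        x["g1"] = x["g0"] + 0.05 * rng.normal(size=100)
        sm = score_mi_clr(x, ["g0"], estimator="binned")
        assert sm.scores.loc["g0"].drop("g0").idxmax() == "g1"


class TestARACNE:
    def test_dpi_removes_only_weakest_triangle_edge(self):
        mi = np.array([[0.0, 0.9, 0.3],
                       [0.9, 0.0, 0.8],
                       [0.3, 0.8, 0.0]])
        removed = dpi_prune(mi, np.arange(3))
        # AC (0.3) is the weakest edge of triangle ABC: removed both ways
        assert removed[0, 2] and removed[2, 0]
        assert not removed[0, 1] and not removed[1, 0]
        assert not removed[1, 2] and not removed[2, 1]

    def test_never_removes_strongest_edge(self, rng):
        mi = np.abs(rng.normal(size=(8, 8)))
        mi = (mi + mi.T) / 2
        np.fill_diagonal(mi, 0.0)
        removed = dpi_prune(mi, np.arange(8))
        i, j = np.unravel_index(np.argmax(mi), mi.shape)
        assert not removed[i, j]

    def test_output_subset_of_mi_edges(self, rng):
        x = _matrix(rng, n=50, p=10)
        raw = score_mi_clr(x, ["g0", "g1"])  # background for shape only
        pruned = score_aracne(x, ["g0", "g1"])
        # pruned scores are either 0 or the raw gaussian MI
        assert ((pruned.scores.to_numpy() >= 0)
                | ~np.isfinite(pruned.scores.to_numpy())).all()


class TestTOM:
    def test_matches_connectivity_internals(self, rng):
        from phasecore.features import tom_matrix
        x = _matrix(rng, n=20, p=6)
        sm = score_tom(x, ["g0", "g3"], beta=4)
        tom = tom_matrix(x, beta=4).loc[["g0", "g3"]]
        tom.loc["g0", "g0"] = tom.loc["g3", "g3"] = -np.inf  # self-edges masked
        pd.testing.assert_frame_equal(sm.scores, tom)

    def test_multiple_datasets_merged_by_borda(self, rng):
        x = _matrix(rng, n=20, p=6)
        single = score_tom(x, ["g0"], beta=4).pair_ranking()
        merged = score_tom([x, x.copy()], ["g0"], beta=4).pair_ranking()
        assert list(single["target"]) == list(merged["target"])


class TestTrees:
    def test_driving_tf_has_top_importance(self, rng):
        tfs = [f"tf{i}" for i in range(20)]
        x = pd.DataFrame(rng.normal(size=(60, 21)), columns=tfs + ["target"])
        x["target"] = 5 * x["tf0"] + 0.1 * rng.normal(size=60)
        sm = score_tree_importance(x, tfs, n_trees=50, seed=3)
        assert sm.scores["target"].idxmax() == "tf0"
        noise_max = sm.scores["tf5"].drop(labels=["tf5"]).max()
        assert sm.scores.loc["tf0", "target"] > noise_max

    def test_deterministic_under_seed(self, rng):
        x = _matrix(rng, n=30, p=8)
        a = score_tree_importance(x, ["g0", "g1"], n_trees=20, seed=5)
        b = score_tree_importance(x, ["g0", "g1"], n_trees=20, seed=5)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_no_tfs_rejected(self, rng):
        with pytest.raises(ValueError):
            score_tree_importance(_matrix(rng, n=30), [])


class TestPartialCorrelation:
    def test_chain_mediation_suppressed(self, rng):
        n = 500
        x = rng.normal(size=n)
        y = x + 0.5 * rng.normal(size=n)
        z = y + 0.5 * rng.normal(size=n)
        m = pd.DataFrame({"x": x, "y": y, "z": z})
        sm = score_partial_correlation(m, ["x", "y"])
        assert abs(sm.pcor.loc["x", "z"]) < abs(np.corrcoef(x, z)[0, 1])
        assert sm.scores.loc["x", "z"] < sm.scores.loc["x", "y"]
        assert sm.scores.loc["x", "z"] < sm.scores.loc["y", "z"]

    def test_independent_genes_near_zero(self, rng):
        m = _matrix(rng, n=400, p=5)
        sm = score_partial_correlation(m, ["g0"])
        assert sm.scores.loc["g0"].drop("g0").abs().max() < 0.15

    def test_matches_analytic_inverse_no_shrinkage(self, rng):
        n = 20_000
        a = rng.normal(size=n)
        b = 0.6 * a + 0.8 * rng.normal(size=n)
        c = 0.4 * a + 0.3 * b + rng.normal(size=n)
        m = pd.DataFrame({"a": a, "b": b, "c": c})
        sm = score_partial_correlation(m, ["a"], shrinkage=0.0)
        r = np.corrcoef(m.to_numpy().T)
        omega = np.linalg.inv(r)
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        assert sm.pcor.loc["a", "b"] == pytest.approx(expected[0, 1],
                                                      abs=0.02)
        assert sm.pcor.loc["a", "c"] == pytest.approx(expected[0, 2],
                                                      abs=0.02)


class TestKMeansBIC:
    def test_recovers_well_separated_clusters(self, rng):
        # fixed centers with pairwise separation 50 x the within-cluster s.d.
        centers = np.array([[0, 0, 0, 0], [50, 0, 0, 0], [0, 50, 0, 0],
                            [0, 0, 50, 0], [25, 25, 25, 25]], float)
        x = np.vstack([c + rng.normal(scale=1.0, size=(20, 4))
                       for c in centers])
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(100)])
        res = kmeans_bic(df, k_range=(3, 10), iters=5, seed=0)
        assert res.k == 5

    def test_penalty_term_arithmetic(self, rng):
        # log(N) * M * K at N=100, M=4, K=10
        assert np.log(100) * 4 * 10 == pytest.approx(184.2, abs=0.05)
        x = pd.DataFrame(rng.normal(size=(100, 4)))
        res = kmeans_bic(x, k_range=(3, 3), iters=2, seed=0)
        assert res.k == 3
        assert res.sigma_eps > 0

    def test_bad_range_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError):
            kmeans_bic(x, k_range=(1, 5))


class TestModules:
    def _clustering(self, centroids, assignments, genes):
        return ModuleClustering(
            k=len(centroids), assignments=pd.Series(assignments, index=genes),
            centroids=np.asarray(centroids, float), sigma_eps=1.0,
            bic_curve=pd.Series(dtype=float))

    def test_tf_equal_to_centroid_scores_members_one(self, rng):
        genes = [f"g{i}" for i in range(4)]
        cent = rng.normal(size=(2, 10))
        x = pd.DataFrame(rng.normal(size=(10, 4)), columns=genes)
        x["g0"] = cent[0]  # TF profile equals centroid 0
        clustering = self._clustering(cent, [0, 0, 1, 1], genes)
        sm = score_modules(clustering, x, ["g0"])
        assert sm.scores.loc["g0", "g1"] == pytest.approx(1.0)

    def test_orthogonal_tf_scores_near_zero(self, rng):
        genes = [f"g{i}" for i in range(3)]
        n = 2000
        cent = rng.normal(size=(1, n))
        x = pd.DataFrame(rng.normal(size=(n, 3)), columns=genes)
        clustering = self._clustering(cent, [0, 0, 0], genes)
        sm = score_modules(clustering, x, ["g0"])
        assert sm.scores.loc["g0", "g1"] < 0.1


def _ranking_to_scores(order, tfs, genes):
    """Build a ScoreMatrix whose pair ranking equals ``order``."""
    s = pd.DataFrame(0.0, index=pd.Index(tfs), columns=pd.Index(genes))
    for r, (tf, g) in enumerate(order):
        s.loc[tf, g] = len(order) - r
    return s


class TestEnsemble:
    def test_identical_rankings_preserved(self):
        tfs, genes = ["t0", "t1"], ["t0", "t1", "g0", "g1", "g2", "g3"]
        order = [("t0", "g0"), ("t1", "g2"), ("t0", "g1"), ("t1", "g3")]
        mats = [ScoreMatrix(_ranking_to_scores(order, tfs, genes), f"m{i}")
                for i in range(3)]
        net = ensemble_network(mats, top_k_per_method=4, top_k_final=4)
        got = list(zip(net.edges["tf"], net.edges["target"]))
        assert got == order

    def test_method_order_exchangeable(self, rng):
        tfs = ["t0", "t1"]
        genes = tfs + [f"g{i}" for i in range(6)]
        mats = []
        for i in range(3):
            s = pd.DataFrame(rng.normal(size=(2, 8)), index=tfs,
                             columns=genes)
            mats.append(ScoreMatrix(s, f"m{i}"))
        a = ensemble_network(mats, top_k_per_method=10, top_k_final=10)
        b = ensemble_network(mats[::-1], top_k_per_method=10, top_k_final=10)
        ka = a.edges.set_index(["tf", "target"])["agg_rank"]
        kb = b.edges.set_index(["tf", "target"])["agg_rank"]
        pd.testing.assert_series_equal(ka.sort_index(), kb.sort_index())

    def test_promiscuous_target_filtered_and_refilled(self, rng):
        tfs = [f"t{i}" for i in range(10)]
        genes = tfs + [f"g{i}" for i in range(30)] + ["bad"]
        mats = []
        for i in range(2):
            s = pd.DataFrame(rng.uniform(size=(10, len(genes))), index=tfs,
                             columns=genes)
            s["bad"] = 10.0  # every TF's top target in every method
            mats.append(ScoreMatrix(s, f"m{i}"))
        net = ensemble_network(mats, top_k_per_method=50, top_k_final=50,
                               promiscuity_fraction=1.0)
        assert "bad" in net.filtered_targets
        assert not (net.edges["target"] == "bad").any()
        assert net.n_edges == 50  # refilled after the filter

    def test_single_matrix_rejected(self, rng):
        s = pd.DataFrame(rng.uniform(size=(2, 4)), index=["t0", "t1"],
                         columns=["t0", "t1", "g0", "g1"])
        with pytest.raises(ValueError):
            ensemble_network([ScoreMatrix(s, "m")])


class TestPerTF:
    def test_every_tf_gets_top_m_targets(self, rng):
        tfs = ["t0", "t1", "t2"]
        genes = tfs + [f"g{i}" for i in range(10)]
        mats = [ScoreMatrix(pd.DataFrame(rng.uniform(size=(3, 13)),
                                         index=tfs, columns=genes), f"m{i}")
                for i in range(2)]
        net = per_tf_network(mats, top_m=5)
        counts = net.edges.groupby("tf").size()
        assert (counts == 5).all()

    def test_single_method_is_score_order(self, rng):
        tfs = ["t0"]
        genes = tfs + [f"g{i}" for i in range(6)]
        s = pd.DataFrame(rng.uniform(size=(1, 7)), index=tfs, columns=genes)
        sm = ScoreMatrix(s.copy(), "m")
        net = per_tf_network([sm], top_m=3)
        expected = s.loc["t0"].drop("t0").sort_values(ascending=False)
        assert list(net.edges["target"]) == list(expected.index[:3])
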