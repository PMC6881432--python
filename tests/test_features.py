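"""Gene features: specificity index, CpG o/e, methylation summarization,
TOM connectivity, the no-replicate count test, PRG calls and bin trends."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasecore.features import (audic_claverie_p, bin_feature_trends, cpg_oe,
                                detect_prgs, methylation_gene_level, tau,
                                tom_connectivity, tom_matrix)


class TestTau:
    @pytest.mark.parametrize("row,expected", [
        ((5, 5, 5), 0.0),
        ((0, 0, 8), 1.0),
        ((1, 3), 0.5),  # 1 - log2(2)/log2(4)
    ])
    def test_spot_values(self, row, expected):
        assert tau(row) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_missing(self):
        assert np.isnan(tau((0, 0, 0)))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tau((5,))

    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2,
                    max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, row):
        t = tau(row)
        if not np.isnan(t):
            assert -1e-9 <= t <= 1 + 1e-9


class TestCpGOE:
    @pytest.mark.parametrize("seq,expected", [
        ("CGCG", (2 / 3) / 0.25),       # 8/3
        ("ACGT", (1 / 3) / (0.25 * 0.25)),  # 16/3
        ("cgcg", (2 / 3) / 0.25),       # case-insensitive
    ])
    def test_hand_counted(self, seq, expected):
        assert cpg_oe(seq) == pytest.approx(expected)

    def test_no_c_or_g_missing(self):
        assert np.isnan(cpg_oe("AATT"))

    def test_ambiguity_codes_excluded(self):
        assert cpg_oe("ACNNGT") == pytest.approx(cpg_oe("ACGT"))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cpg_oe("A")


class TestMethylation:
    def test_site_count_filter(self):
        rows = ([("few", i, 0.3) for i in range(18)]
                + [("enough", i, 0.5) for i in range(20)]
                + [("edge", i, 0.7) for i in range(19)])
        table = pd.DataFrame(rows, columns=["gene_id", "site_pos", "beta"])
        out = methylation_gene_level(table, min_sites=19)
        assert "few" not in out.index
        assert out.loc["enough"] == pytest.approx(0.5)
        assert out.loc["edge"] == pytest.approx(0.7)

    def test_empty_table(self):
        out = methylation_gene_level(pd.DataFrame(columns=["gene_id", "beta"]))
        assert out.empty


class TestTOM:
    def test_two_perfectly_correlated_genes(self, rng):
        x = rng.normal(size=10)
        expr = pd.DataFrame({"a": x, "b": 2 * x + 1})
        conn = tom_connectivity(expr, beta=1)
        np.testing.assert_allclose(conn, 1.0, atol=1e-9)

    def test_values_bounded(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 8)))
        t = tom_matrix(expr, beta=6).to_numpy()
        assert (t >= -1e-12).all() and (t <= 1 + 1e-9).all()

    def test_gene_permutation_equivariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 6)),
                            columns=[f"g{i}" for i in range(6)])
        conn = tom_connectivity(expr, beta=4)
        perm = ["g3", "g0", "g5", "g1", "g4", "g2"]
        conn_p = tom_connectivity(expr[perm], beta=4)
        np.testing.assert_allclose(conn_p, conn.loc[perm], atol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            tom_matrix(pd.DataFrame(rng.normal(size=(2, 4))), beta=2)


def ac_p_exact(x, y, n1, n2):
    """Exact-rational oracle for the no-replicate count test (two-sided)."""

    def lower_tail(a, b, r):
        return sum(r ** t * comb(a + t, t) / (1 + r) ** (a + t + 1)
                   for t in range(b + 1))

    r = Fraction(int(n2), int(n1))
    tails = (lower_tail(x, y, r), lower_tail(y, x, 1 / r))
    return float(min(Fraction(2) * min(tails), Fraction(1)))


class TestAudicClaverie:
    def test_zero_counts_equal_libraries(self):
        assert audic_claverie_p(0, 0, 1e6, 1e6) == pytest.approx(1.0)

    def test_exchangeable_under_equal_libraries(self):
        for x, y in [(3, 10), (0, 7), (25, 12)]:
            assert audic_claverie_p(x, y, 5e5, 5e5) == pytest.approx(
                audic_claverie_p(y, x, 5e5, 5e5), rel=1e-9)

    def test_strong_difference_small_p(self):
        p = audic_claverie_p(5, 40, 1e6, 1e6)
        assert p < 1e-6
        assert p == pytest.approx(ac_p_exact(5, 40, 1e6, 1e6), rel=1e-12)

    @pytest.mark.parametrize("x,y,n1,n2", [
        (0, 0, 10, 10), (3, 3, 100, 100), (10, 30, 1000, 2000),
        (200, 150, 1e6, 1e6), (7, 120, 1e5, 3e5), (50, 50, 1e6, 2e6),
    ])
    def test_matches_exact_rational_oracle(self, x, y, n1, n2):
        assert audic_claverie_p(x, y, n1, n2) == pytest.approx(
            ac_p_exact(x, y, int(n1), int(n2)), rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 2, 10, 10)


def _paired_counts_dataset(counts_g, counts_s, n_levels=3):
    """Counts dataset with one matched G/S pair per confounder level."""
    from phasecore.datasets import ExpressionDataset
    genes = pd.Index([f"g{i}" for i in range(len(counts_g))], name="gene_id")
    cols, data, meta_rows = [], [], []
    for lev in range(n_levels):
        for phase, counts in (("G", counts_g), ("S", counts_s)):
            sid = f"l{lev}_{phase}"
            cols.append(sid)
            data.append(np.asarray(counts))
            meta_rows.append((sid, phase, f"lev{lev}", "toy"))
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "phase",
                                            "confounder_level", "dataset"]
                        ).set_index("sample_id")
    return ExpressionDataset(values, meta, kind="counts")


class TestPRGs:
    def test_identical_phases_no_prgs(self):
        c = np.arange(100, 200)
        ds = _paired_counts_dataset(c, c)
        assert len(detect_prgs(ds)) == 0

    def test_separable_planted_genes_all_detected(self):
        base = np.full(200, 500)
        up = base.copy()
        up[:20] *= 4  # 2 log2 units, large counts -> unambiguous
        ds = _paired_counts_dataset(up, base)
        prgs = detect_prgs(ds)
        assert set(prgs) == {f"g{i}" for i in range(20)}

    def test_null_false_positive_rate_controlled(self):
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = rng.uniform(50, 500, size=300)
            ds = _paired_counts_dataset(rng.poisson(mu), rng.poisson(mu),
                                        n_levels=1)
            rates.append(len(detect_prgs(ds)) / 300)
        assert np.mean(rates) <= 0.07

    def test_unmatched_design_rejected(self):
        ds = _paired_counts_dataset(np.arange(10), np.arange(10))
        ds.meta.loc[:, "confounder_level"] = "same"
        with pytest.raises(ValueError):
            detect_prgs(ds)


def test_feature_table_assembles_with_explicit_missing(small_study):
    from phasecore.features import feature_table
    from phasecore.preprocess import counts_to_rpkm
    rpkm = counts_to_rpkm(small_study.datasets["tissue"]).values
    table = feature_table(rpkm=rpkm, sequences=small_study.sequences,
                          methylation=small_study.methylation,
                          prgs=list(small_study.truth_core.index[:5]),
                          gene_ids=rpkm.index)
    assert list(table.index) == list(rpkm.index)
    assert table["is_prg"].sum() == 5
    # genes filtered by the methylation site threshold stay missing, not 0
    site_counts = small_study.methylation.groupby("gene_id").size()
    few = site_counts.index[site_counts < 19]
    if len(few):
        assert table.loc[few, "methylation_mean"].isna().all()


class TestBinTrends:
    def test_published_bin_scheme(self):
        genes = [f"g{i:05d}" for i in range(15_360)]
        features = pd.DataFrame({"tau": np.linspace(1, 0, 15_360)},
                                index=genes)
        out = bin_feature_trends(genes, features, bin_size=1700, n_top=15_300)
        assert len(out) == 9
        assert out.attrs["spearman_rho"]["tau"] == pytest.approx(-1.0)

    def test_constant_feature_flat(self):
        genes = [f"g{i}" for i in range(100)]
        features = pd.DataFrame({"f": np.ones(100)}, index=genes)
        out = bin_feature_trends(genes, features, bin_size=20, n_top=100)
        assert out["f_mean"].nunique() == 1
        assert out.attrs["spearman_rho"]["f"] == 0.0

    def test_elevated_core_feature_in_first_bin(self, rng):
        genes = [f"g{i}" for i in range(90)]
        vals = rng.uniform(0.2, 0.4, size=90)
        vals[:30] += 0.5  # top bin planted high
        features = pd.DataFrame({"tau": vals}, index=genes)
        out = bin_feature_trends(genes, features, bin_size=30, n_top=90)
        assert out["tau_mean"].iloc[0] > out["tau_mean"].iloc[-1]

    def test_indivisible_rejected(self):
        genes = [f"g{i}" for i in range(100)]
        features = pd.DataFrame({"f": np.ones(100)}, index=genes)
        with pytest.raises(ValueError):
            bin_feature_trends(genes, features, bin_size=30, n_top=100)
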