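import numpy as np
import pandas as pd
import pytest

from ccckit.cluster_stats import ClusterStatTable, summarize_clusters
from ccckit.resources import InteractionRecord, ProteinEntity
from ccckit.scoring import (
    MethodConfig,
    _mutual_information_bits,
    score_cellphonedb,
    score_connectome,
    score_crosstalk,
    score_logfc_mean,
    score_methods,
    score_natmi,
    score_sca,
)

from conftest import make_dataset
from test_cluster_stats import with_floor


def rec(t, r):
    return InteractionRecord(ProteinEntity(t), ProteinEntity(r))


def row(df, source, target, lig, recp):
    m = df[
        (df.source == source)
        & (df.target == target)
        & (df.ligand_complex == lig)
        & (df.receptor_complex == recp)
    ]
    return m.iloc[0] if len(m) else None


def manual_stats(mean_log: pd.DataFrame, mu: float, **overrides) -> ClusterStatTable:
    """A hand-built stat table; unspecified fields default to permissive values."""
    ones = pd.DataFrame(1.0, index=mean_log.index, columns=mean_log.columns)
    defaults = dict(
        mean_lin=np.expm1(mean_log),
        mean_log=mean_log,
        prop=ones,
        log2fc=ones * 2.0,
        zscore=ones * 0.0,
        de_p=ones * 0.01,
        mu=mu,
        cluster_sizes=pd.Series(10, index=mean_log.columns),
        dataset=None,
    )
    defaults.update(overrides)
    return ClusterStatTable(**defaults)


@pytest.fixture(scope="module")
def planted_3cluster():
    """Ligand L specific to cluster a, receptor R specific to cluster b."""
    rng = np.random.default_rng(42)
    base = rng.poisson(2.0, size=(6, 30)) + 1
    counts = base.astype(float)
    clusters = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    counts[0, :10] *= 8  # L up in a
    counts[1, 10:20] *= 8  # R up in b
    ds = make_dataset(counts, clusters, genes=["L", "R", "X", "Y", "Z", "W"])
    stats = summarize_clusters(ds)
    resource = {rec("L", "R"), rec("X", "Y"), rec("Z", "W")}
    return ds, stats, resource


class TestCellPhoneDB:
    def test_identical_cells_give_p_one(self):
        counts = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 8))
        ds = make_dataset(counts, ["a"] * 4 + ["b"] * 4, genes=["L", "R", "X"])
        stats = summarize_clusters(ds)
        out = score_cellphonedb(stats, {rec("L", "R")}, MethodConfig(seed=0, n_permutations=50))
        assert (out.p_value == 1.0).all()

    def test_low_proportion_filtered(self):
        counts = np.ones((2, 40))
        counts[0, :20] = 0
        counts[0, 0] = 5  # ligand in 5% of source cells
        ds = make_dataset(with_floor(counts), ["a"] * 20 + ["b"] * 20,
                          genes=["L", "R", "PAD"])
        stats = summarize_clusters(ds)
        out = score_cellphonedb(stats, {rec("L", "R")}, MethodConfig(seed=0, n_permutations=10))
        assert row(out, "a", "b", "L", "R") is None

    def test_deterministic_given_seed(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        cfg = MethodConfig(seed=5, n_permutations=100)
        a = score_cellphonedb(stats, resource, cfg)
        b = score_cellphonedb(stats, resource, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_pair_low_p(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        out = score_cellphonedb(stats, resource, MethodConfig(seed=1, n_permutations=500))
        assert row(out, "a", "b", "L", "R").p_value <= 0.02

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            MethodConfig(n_permutations=0)


class TestConnectome:
    def test_uniform_gene_zero_weight_scale(self):
        counts = np.vstack([np.full(20, 3.0), np.full(20, 2.0)])
        ds = make_dataset(counts, ["a"] * 10 + ["b"] * 10, genes=["L", "R"])
        stats = summarize_clusters(ds)
        out = score_connectome(stats, {rec("L", "R")}, MethodConfig(de_p_threshold=1.0))
        assert np.allclose(out.score_specificity, 0.0)

    def test_zero_mean_gives_zero_weight_norm(self):
        counts = np.array([[0, 0, 2, 2], [2, 2, 2, 2.0]])
        ds = make_dataset(with_floor(counts), ["a", "a", "b", "b"], genes=["L", "R", "PAD"])
        stats = summarize_clusters(ds)
        out = score_connectome(
            stats, {rec("L", "R")}, MethodConfig(prop_threshold=0.0, de_p_threshold=1.0)
        )
        assert row(out, "a", "b", "L", "R").score_magnitude == 0.0

    @staticmethod
    def _crafted():
        """Noise-free normalized layer: L specific to a, R to b, decoys flat."""
        from ccckit.cluster_stats import ExpressionDataset

        n = 30
        clusters = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        norm = np.vstack(
            [
                np.where(np.arange(n) < 10, 2.0, 0.2),  # L
                np.where((np.arange(n) >= 10) & (np.arange(n) < 20), 2.0, 0.2),  # R
                np.full(n, 1.0),  # X
                np.full(n, 1.0),  # Y
            ]
        )
        ds = ExpressionDataset((norm > 0).astype(float), norm, ["L", "R", "X", "Y"],
                               [f"c{i}" for i in range(n)], clusters)
        return summarize_clusters(ds), {rec("L", "R"), rec("X", "Y")}

    def test_planted_pair_top_weight_scale(self):
        stats, resource = self._crafted()
        out = score_connectome(stats, resource, MethodConfig(de_p_threshold=1.0))
        r = row(out, "a", "b", "L", "R")
        expected = (stats.zscore.loc["L", "a"] + stats.zscore.loc["R", "b"]) / 2
        assert r.score_specificity == pytest.approx(expected)
        assert expected == pytest.approx(2 / np.sqrt(3))  # z of (2, .2, .2) at the peak
        assert r.score_specificity == out.score_specificity.max()

    def test_de_filter_drops_nonsignificant(self):
        stats, resource = self._crafted()
        out = score_connectome(stats, resource, MethodConfig(de_p_threshold=0.05))
        kept = set(zip(out.ligand_complex, out.receptor_complex))
        assert ("L", "R") in kept
        # constant decoys carry no differential-expression signal
        assert ("X", "Y") not in kept


class TestNatmi:
    def test_exclusive_expression_specificity_one(self):
        mean = pd.DataFrame(
            {"a": [2.0, 0.0], "b": [0.0, 3.0]}, index=["L", "R"]
        )
        stats = manual_stats(mean, mu=1.0)
        out = score_natmi(stats, {rec("L", "R")})
        assert row(out, "a", "b", "L", "R").score_specificity == pytest.approx(1.0)

    def test_uniform_expression_one_over_c_squared(self):
        mean = pd.DataFrame(
            np.ones((2, 4)) * 2.0, index=["L", "R"], columns=list("abcd")
        )
        stats = manual_stats(mean, mu=1.0)
        out = score_natmi(stats, {rec("L", "R")})
        assert np.allclose(out.score_specificity, 1 / 16)

    def test_specificity_normalization_identity(self, planted_3cluster):
        # f_l and f_r each sum to 1 across clusters, so for one interaction
        # the specificity summed over all ordered cluster pairs is exactly 1
        ds, stats, resource = planted_3cluster
        out = score_natmi(stats, resource, MethodConfig(prop_threshold=0.0))
        sums = out.groupby(["ligand_complex", "receptor_complex"]).score_specificity.sum()
        assert np.allclose(sums, 1.0)


class TestSca:
    def test_lrscore_half_when_root_equals_mu(self):
        mean = pd.DataFrame({"a": [2.0, 1.0], "b": [1.0, 2.0]}, index=["L", "R"])
        stats = manual_stats(mean, mu=2.0)
        out = score_sca(stats, {rec("L", "R")},
                        MethodConfig(sca_apply_lr_threshold=False, sca_apply_logfc_filter=False))
        assert row(out, "a", "b", "L", "R").score_magnitude == pytest.approx(0.5)
        # boundary semantics: a score exactly at the threshold is kept
        kept = score_sca(stats, {rec("L", "R")}, MethodConfig(sca_apply_logfc_filter=False))
        assert row(kept, "a", "b", "L", "R") is not None

    def test_zero_expression_zero_score(self):
        mean = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 1.0]}, index=["L", "R"])
        stats = manual_stats(mean, mu=1.0)
        out = score_sca(stats, {rec("L", "R")},
                        MethodConfig(sca_apply_lr_threshold=False, sca_apply_logfc_filter=False))
        assert row(out, "a", "b", "L", "R").score_magnitude == 0.0

    def test_monotone_increasing_in_expression(self):
        scores = []
        for l in (0.5, 1.0, 2.0, 4.0, 64.0):
            mean = pd.DataFrame({"a": [l, 1.0], "b": [1.0, 1.0]}, index=["L", "R"])
            stats = manual_stats(mean, mu=1.0)
            out = score_sca(stats, {rec("L", "R")},
                            MethodConfig(sca_apply_lr_threshold=False,
                                         sca_apply_logfc_filter=False))
            scores.append(row(out, "a", "b", "L", "R").score_magnitude)
        assert np.all(np.diff(scores) > 0) and scores[-1] < 1.0

    def test_degenerate_mu_rejected(self):
        mean = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]}, index=["L", "R"])
        stats = manual_stats(mean, mu=0.0)
        with pytest.raises(ValueError, match="mu"):
            score_sca(stats, {rec("L", "R")})


class TestLogfcMean:
    def test_uniform_zero(self):
        counts = np.vstack([np.full(8, 3.0), np.full(8, 2.0)])
        ds = make_dataset(counts, ["a"] * 4 + ["b"] * 4, genes=["L", "R"])
        out = score_logfc_mean(summarize_clusters(ds), {rec("L", "R")})
        assert np.allclose(out.score_specificity, 0.0)

    def test_arithmetic_mean_of_fold_changes(self):
        mean = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]}, index=["L", "R"])
        lfc = pd.DataFrame({"a": [2.0, 0.5], "b": [1.0, 1.0]}, index=["L", "R"])
        stats = manual_stats(mean, mu=1.0, log2fc=lfc)
        out = score_logfc_mean(stats, {rec("L", "R")})
        assert row(out, "a", "a", "L", "R").score_specificity == pytest.approx(1.25)

    def test_sign_flips_when_clusters_swap(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(4, 8)) + 1.0
        counts[0, :4] *= 4
        counts[1, 4:] *= 4
        ds = make_dataset(counts, ["a"] * 4 + ["b"] * 4, genes=["L", "R", "X", "Y"])
        out = score_logfc_mean(summarize_clusters(ds), {rec("L", "R")},
                               MethodConfig(prop_threshold=0.0))
        fwd = row(out, "a", "b", "L", "R").score_specificity
        rev = row(out, "b", "a", "L", "R").score_specificity
        assert fwd == pytest.approx(-rev)
        assert fwd > 0


class TestCrosstalk:
    def test_uniform_matrix_all_zero(self):
        counts = np.vstack([np.full(20, 2.0), np.full(20, 2.0)])
        ds = make_dataset(counts, ["a"] * 10 + ["b"] * 10, genes=["L", "R"])
        stats = summarize_clusters(ds)
        out = score_crosstalk(stats, {rec("L", "R")})
        assert np.allclose(out.score_magnitude, 0.0)

    def test_scores_within_unit_interval(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        out = score_crosstalk(stats, resource)
        assert out.score_magnitude.between(0, 1).all()

    def test_planted_pair_ranks_top(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        out = score_crosstalk(stats, resource)
        assert row(out, "a", "b", "L", "R").score_magnitude == out.score_magnitude.max()

    def test_independent_genes_low_mutual_information(self):
        rng = np.random.default_rng(0)
        x = rng.negative_binomial(2, 0.4, size=2000).astype(float)
        y = rng.negative_binomial(2, 0.4, size=2000).astype(float)
        assert _mutual_information_bits(x, y, bins=4) < 0.05

    def test_dependent_genes_high_mutual_information(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        assert _mutual_information_bits(x, x + rng.normal(scale=0.01, size=2000), 4) > 1.0


class TestSharedInvariants:
    def test_cell_permutation_invariance(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(ds.cell_ids))
        ds2 = make_dataset(ds.counts[:, perm], [ds.clusters[i] for i in perm],
                           genes=ds.gene_ids)
        stats2 = summarize_clusters(ds2)
        cfg = MethodConfig(de_p_threshold=1.0)
        for fn in (score_connectome, score_natmi, score_logfc_mean, score_crosstalk):
            a = fn(stats, resource, cfg).sort_values(
                ["source", "target", "ligand_complex"]).reset_index(drop=True)
            b = fn(stats2, resource, cfg).sort_values(
                ["source", "target", "ligand_complex"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, atol=1e-12)

    def test_complex_never_outranks_weakest_subunit(self):
        counts = np.array(
            [
                [8, 8, 1, 1],  # A strong
                [2, 2, 1, 1],  # B weak
                [4, 4, 4, 4],  # R receptor
            ],
            dtype=float,
        )
        ds = make_dataset(with_floor(counts), ["a", "a", "b", "b"],
                          genes=["A", "B", "R", "PAD"])
        stats = summarize_clusters(ds)
        out = score_natmi(stats, {rec("A_B", "R"), rec("B", "R")},
                          MethodConfig(prop_threshold=0.0))
        cx = row(out, "a", "b", "A_B", "R")
        single = row(out, "a", "b", "B", "R")
        assert cx.score_magnitude == pytest.approx(single.score_magnitude)
        assert cx.score_specificity == pytest.approx(single.score_specificity)

    def test_unknown_method_rejected(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        with pytest.raises(ValueError, match="unknown methods"):
            score_methods(ds, resource, ["nope"])

    def test_score_methods_long_format(self, planted_3cluster):
        ds, stats, resource = planted_3cluster
        out = score_methods(ds, resource, ["natmi", "logfc"], MethodConfig())
        assert set(out.method.unique()) == {"natmi", "logfc"}
        assert {"source", "target", "ligand_complex", "receptor_complex",
                "score_magnitude", "score_specificity", "p_value"} <= set(out.columns)
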