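import numpy as np
import pandas as pd
import pytest

from ccckit.agreement import (
    ModalityCalls,
    build_pseudobulk,
    call_active_cytokines,
    clr_transform,
    cluster_activities,
    colocalization_from_proportions,
    colocalization_from_zscores,
    fisher_or,
    mlm_activities,
    odds_ratio_curve,
    receptor_specificity_eval,
)

from conftest import make_dataset
from test_resources import fisher_p_oracle


class TestPseudobulk:
    def _dataset(self, gene_counts):
        """One cluster of 10 cells with given per-cell counts for gene g0."""
        counts = np.vstack([gene_counts, np.ones(len(gene_counts))])
        clusters = ["a"] * (len(gene_counts) // 2) + ["b"] * (len(gene_counts) // 2)
        return make_dataset(counts, clusters, genes=["g0", "pad"])

    def test_summed_count_five_excluded_six_included(self):
        # cluster a: 5 total -> excluded; cluster b: 6 total -> included
        ds = self._dataset([5, 0, 0, 0, 0, 6, 0, 0, 0, 0])
        pb = build_pseudobulk(ds)
        assert np.isnan(pb.loc["g0", "a"])
        # but b has only 1/5 cells expressing with default 10% filter -> kept
        assert pb.loc["g0", "b"] == pytest.approx(np.log2(7))

    def test_proportion_and_zero_gene(self):
        counts = np.zeros((2, 20))
        counts[0, 0] = 7  # 1 of 10 cells in cluster a = 10% exactly, sum 7 > 5
        ds = make_dataset(np.vstack([counts, np.ones(20)]),
                          ["a"] * 10 + ["b"] * 10, genes=["g0", "g1", "pad"])
        pb = build_pseudobulk(ds)
        assert pb.loc["g0", "a"] == pytest.approx(np.log2(8))
        assert np.isnan(pb.loc["g1", "a"]) and np.isnan(pb.loc["g1", "b"])


def orthogonal_signatures(n_genes=80, n_sigs=3, genes_per_sig=20):
    """Disjoint 0/1 signatures plus an unassigned background block."""
    sig = pd.DataFrame(
        0.0,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=[f"cyt{j}" for j in range(n_sigs)],
    )
    for j in range(n_sigs):
        sig.iloc[j * genes_per_sig : (j + 1) * genes_per_sig, j] = 1.0
    assert n_sigs * genes_per_sig < n_genes
    return sig


class TestMlmActivities:
    def test_recovers_single_active_signature(self):
        sig = orthogonal_signatures()
        rng = np.random.default_rng(0)
        y = pd.Series(3.0 * sig["cyt1"] + rng.normal(0, 0.1, len(sig)), index=sig.index)
        out = mlm_activities(y, sig).set_index("cytokine")
        assert out.loc["cyt1", "t"] == out["t"].max()
        assert out.loc["cyt1", "t"] > 10
        assert abs(out.loc["cyt0", "t"]) < 3

    def test_orthogonal_profile_no_signal(self):
        sig = orthogonal_signatures()
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=len(sig)), index=sig.index)
        out = mlm_activities(y, sig)
        assert (out["fdr"] > 0.05).all() or (np.abs(out["t"]) < 3).all()

    def test_gene_order_invariance(self):
        sig = orthogonal_signatures()
        rng = np.random.default_rng(2)
        y = pd.Series(2.0 * sig["cyt0"] + rng.normal(0, 0.2, len(sig)), index=sig.index)
        a = mlm_activities(y, sig)
        perm = rng.permutation(len(sig))
        b = mlm_activities(y.iloc[perm], sig)
        assert np.allclose(a["t"], b["t"])

    def test_rank_deficient_design_names_culprit(self):
        sig = orthogonal_signatures(n_sigs=2)
        sig["dup"] = sig["cyt0"]
        y = pd.Series(np.arange(len(sig), dtype=float), index=sig.index)
        with pytest.raises(ValueError, match="rank-deficient"):
            mlm_activities(y, sig)

    def test_planted_sign_recovery_rate(self):
        # y = S beta + eps with |beta|/sigma >= 3: sign of t matches >= 95%
        sig = orthogonal_signatures(n_genes=90, n_sigs=3, genes_per_sig=25)
        rng = np.random.default_rng(3)
        hits = 0
        runs = 60
        for _ in range(runs):
            beta = rng.choice([-3.0, 3.0], size=3)
            y = pd.Series(sig.to_numpy() @ beta + rng.normal(0, 1.0, len(sig)),
                          index=sig.index)
            out = mlm_activities(y, sig)
            hits += int((np.sign(out["t"]) == np.sign(beta)).all())
        assert hits / runs >= 0.95


class TestActiveCytokineCalls:
    def test_boundary_fdr_inclusive(self):
        acts = pd.DataFrame(
            {
                "cluster": ["a", "a", "a"],
                "cytokine": ["c1", "c2", "c3"],
                "t": [2.0, -2.0, 2.0],
                "p": [0.01, 0.01, 0.5],
                "fdr": [0.05, 0.01, 0.5],
            }
        )
        calls = call_active_cytokines(acts)
        assert ("c1", "a") in calls.positives  # fdr exactly 0.05 is positive
        assert ("c2", "a") in calls.negatives  # negative score
        assert ("c3", "a") in calls.negatives

    def test_empty_table_empty_calls(self):
        calls = call_active_cytokines(pd.DataFrame(columns=["cluster", "cytokine", "t", "fdr"]))
        assert not calls.universe


class TestColocalization:
    def test_identical_proportions_positive(self):
        rng = np.random.default_rng(0)
        base = rng.dirichlet(np.ones(4), size=30)
        props = pd.DataFrame(base, columns=list("abcd"))
        props["e"] = props["a"]  # duplicate column -> correlation 1
        props = props.div(props.sum(axis=1), axis=0)
        calls = colocalization_from_proportions(props)
        assert ("a", "e") in calls.positives

    def test_independent_proportions_near_five_percent_positive(self):
        rng = np.random.default_rng(1)
        props = pd.DataFrame(rng.dirichlet(np.ones(20), size=400),
                             columns=[f"c{i}" for i in range(20)])
        calls = colocalization_from_proportions(props)
        rate = len(calls.positives) / len(calls.universe)
        assert rate <= 0.12  # z >= 1.645 is the ~95th percentile

    def test_too_few_spots_rejected(self):
        props = pd.DataFrame(np.full((5, 2), 0.5), columns=["a", "b"])
        with pytest.raises(ValueError, match="spots"):
            colocalization_from_proportions(props)

    def test_zscore_matrix_boundary_positive(self):
        z = pd.DataFrame(
            [[0.0, 1.645, 0.2], [1.645, 0.0, -1.0], [0.2, -1.0, 0.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        calls = colocalization_from_zscores(z)
        assert ("a", "b") in calls.positives
        assert ("a", "c") in calls.negatives and ("b", "c") in calls.negatives

    def test_zscore_all_zero_no_positives(self):
        z = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        assert not colocalization_from_zscores(z).positives

    def test_zscore_nonsquare_rejected(self):
        z = pd.DataFrame(np.zeros((2, 3)), index=list("ab"), columns=list("abc"))
        with pytest.raises(ValueError):
            colocalization_from_zscores(z)


def simple_ranking(n, keys):
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1, dtype=float),
            "key": keys,
        }
    )


class TestOddsRatioCurve:
    def test_planted_top_positives_high_or(self):
        keys = [f"p{i}" for i in range(20)] + [f"n{i}" for i in range(180)]
        calls = ModalityCalls(
            frozenset(f"p{i}" for i in range(20)),
            frozenset(f"n{i}" for i in range(180)),
        )
        curve = odds_ratio_curve(
            simple_ranking(200, keys), calls, lambda r: r["key"], cutoffs=[25, 100]
        )
        assert (curve.odds_ratio > 1).all()
        assert curve.loc[curve.cutoff == 25, "fisher_p"].iloc[0] < 1e-6

    def test_independent_calls_or_near_one(self):
        rng = np.random.default_rng(5)
        n = 400
        keys = [f"k{i}" for i in range(n)]
        ors = []
        for _ in range(300):
            pos = set(rng.choice(keys, size=100, replace=False))
            calls = ModalityCalls(frozenset(pos), frozenset(set(keys) - pos))
            curve = odds_ratio_curve(
                simple_ranking(n, keys), calls, lambda r: r["key"], cutoffs=[100]
            )
            ors.append(np.log(curve.odds_ratio.iloc[0]))
        assert abs(float(np.mean(ors))) < 0.05

    def test_universe_restriction_and_empty_error(self):
        calls = ModalityCalls(frozenset({"x"}), frozenset({"y"}))
        with pytest.raises(ValueError, match="universe"):
            odds_ratio_curve(simple_ranking(3, ["a", "b", "c"]), calls, lambda r: r["key"])

    def test_fisher_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p, _ = fisher_or(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_p_oracle(a, b, c, d), rel=1e-9)

    def test_haldane_or_on_zero_cell(self):
        odds, _, degenerate = fisher_or(5, 0, 2, 7)
        assert degenerate
        assert odds == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))


class TestReceptorSpecificity:
    def _abundance(self):
        rng = np.random.default_rng(0)
        ab = pd.DataFrame(
            rng.gamma(100, 0.1, size=(20, 6)),
            index=[f"R{i}" for i in range(20)],
            columns=[f"c{j}" for j in range(6)],
        )
        for i in range(5):
            ab.iloc[i, i] += 10.0  # strong planted specificity
        return ab

    def _predictions(self, scores_by_key):
        rows = [
            {"receptor_complex": r, "target": c, "score_specificity": s}
            for (r, c), s in scores_by_key.items()
        ]
        return pd.DataFrame(rows)

    def test_perfect_separation(self):
        ab = self._abundance()
        preds = self._predictions(
            {(f"R{i}", f"c{i}"): 10.0 for i in range(5)}
            | {(f"R{i}", f"c{j}"): 0.0 for i in range(5, 20) for j in range(6)}
        )
        auroc, auprc = receptor_specificity_eval(preds, ab, seed=0)
        # tolerate spurious z-threshold positives in the noise rows
        assert auroc > 0.8 and auprc > 0.75

    def test_order_preserving_transform_leaves_auroc(self):
        ab = self._abundance()
        rng = np.random.default_rng(1)
        scores = {(f"R{i}", f"c{j}"): rng.uniform() for i in range(20) for j in range(6)}
        a1, _ = receptor_specificity_eval(self._predictions(scores), ab, seed=0)
        squashed = {k: np.tanh(5 * v) for k, v in scores.items()}
        a2, _ = receptor_specificity_eval(self._predictions(squashed), ab, seed=0)
        assert a1 == pytest.approx(a2)

    def test_too_few_positives_rejected(self):
        ab = pd.DataFrame(np.ones((3, 3)), index=list("xyz"), columns=list("abc"))
        with pytest.raises(ValueError, match="positive"):
            receptor_specificity_eval(self._predictions({}), ab)

    def test_clr_transform_centres_profiles(self):
        ab = self._abundance()
        clr = clr_transform(ab)
        assert np.allclose(clr.mean(axis=0), 0.0)
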