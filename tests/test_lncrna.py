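"""JSD specificity, adjacency scanning and conservation comparison."""
from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import jensenshannon

import abcatlas as abc
from abcatlas.annotation import GeneModel, GeneModelSet
from abcatlas.lncrna import interval_gap


class TestJSD:
    def test_identical_distributions_diverge_zero(self):
        assert abc.jsd([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_disjoint_supports_are_maximal(self):
        assert abc.jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_half_overlap_entropy_arithmetic(self):
        """JSD((.5,.5),(1,0)) = H(.75,.25) - 0.5 = 0.311278."""
        assert abc.jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.311278, abs=1e-6)

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
        st.data(),
    )
    def test_symmetric_bounded_and_matches_scipy(self, weights, data):
        other = data.draw(
            st.lists(
                st.floats(0.01, 10.0),
                min_size=len(weights),
                max_size=len(weights),
            )
        )
        p = np.array(weights) / np.sum(weights)
        q = np.array(other) / np.sum(other)
        d_pq = abc.jsd(p, q)
        assert d_pq == pytest.approx(abc.jsd(q, p), abs=1e-12)
        assert 0.0 <= d_pq <= 1.0
        # scipy returns sqrt(JSD) for base 2
        assert d_pq == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            abc.jsd([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError):
            abc.jsd([-0.1, 1.1], [0.5, 0.5])
        with pytest.raises(ValueError):
            abc.jsd([1.0], [0.5, 0.5])


def _norm(X, labels):
    return ad.AnnData(
        X=np.asarray(X, dtype=float),
        obs=pd.DataFrame({"cell_type": labels},
                         index=[f"c{i}" for i in range(len(labels))]),
        var=pd.DataFrame(index=pd.Index([f"g{j}" for j in range(X.shape[1])],
                                        name="gene_id")),
    )


class TestSpecificity:
    def test_single_type_expression_scores_one(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [0.0, 1.5], [0.0, 0.5]])
        norm = _norm(X, ["a", "a", "b", "b"])
        table = abc.specificity_scores(norm)
        assert table.scores.loc["g0", "a"] == pytest.approx(1.0)
        assert table.top_type["g0"] == "a"

    def test_uniform_over_two_types_worked_value(self):
        """Equal mean expression in two types scores 1 - sqrt(0.311278) =
        0.44207 at either type."""
        X = np.array([[3.0], [3.0], [3.0], [3.0]])
        norm = _norm(X, ["a", "a", "b", "b"])
        table = abc.specificity_scores(norm)
        assert table.scores.loc["g0", "a"] == pytest.approx(0.44207, abs=1e-5)
        assert table.scores.loc["g0", "b"] == pytest.approx(0.44207, abs=1e-5)

    def test_matches_direct_jsd_oracle(self, processed):
        """The vectorized table equals gene-by-gene evaluation of
        1 - sqrt(JSD(profile, one-hot))."""
        _, _, norm_lnc = processed
        sub = norm_lnc[:, :40].copy()
        table = abc.specificity_scores(sub)
        labels = sub.obs["cell_type"]
        types = sorted(labels.unique())
        X = np.asarray(sub.X, dtype=float)
        rng = np.random.default_rng(0)
        for j in rng.choice(sub.n_vars, size=10, replace=False):
            means = np.array([X[(labels == t).to_numpy(), j].mean() for t in types])
            if means.sum() == 0:
                assert np.isnan(table.scores.iloc[j]).all()
                continue
            e = means / means.sum()
            for t_idx in rng.choice(len(types), size=4, replace=False):
                onehot = np.zeros(len(types))
                onehot[t_idx] = 1.0
                expected = 1.0 - np.sqrt(abc.jsd(e, onehot))
                assert table.scores.iloc[j, t_idx] == pytest.approx(
                    expected, abs=1e-9
                )

    def test_zero_gene_flagged_na(self):
        X = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 1.0], [0.0, 3.0]])
        norm = _norm(X, ["a", "a", "b", "b"])
        table = abc.specificity_scores(norm)
        assert np.isnan(table.max_score["g0"])
        assert pd.isna(table.top_type["g0"])

    def test_label_permutation_lowers_max_scores(self, processed):
        """Permuting cell labels destroys type-specific structure, so the
        max-score distribution shifts down (checked at a fixed seed)."""
        _, _, norm_lnc = processed
        sub = norm_lnc[:, :300].copy()
        observed = abc.specificity_scores(sub).max_score.dropna()
        shuffled = sub.copy()
        rng = np.random.default_rng(9)
        shuffled.obs["cell_type"] = rng.permutation(
            shuffled.obs["cell_type"].to_numpy()
        )
        permuted = abc.specificity_scores(shuffled).max_score.dropna()
        assert observed.mean() > permuted.mean()
        assert observed.quantile(0.9) > permuted.quantile(0.9)


def _annotation_from_arrays(chroms, starts, ends, biotypes):
    genes = [
        GeneModel(f"x{i}", c, int(s), int(e), "+", b)
        for i, (c, s, e, b) in enumerate(zip(chroms, starts, ends, biotypes))
    ]
    return GeneModelSet(genes)


class TestAdjacencyScan:
    def test_worked_example_and_boundaries(self):
        annotation = _annotation_from_arrays(
            ["chr1"] * 4,
            [10000, 14000, 20000, 30000],
            [11000, 15000, 21000, 31000],
            ["lncRNA", "coding", "coding", "coding"],
        )
        adjacency = abc.adjacency_scan(annotation)
        hits = dict(adjacency.neighbors_of("x0"))
        assert hits == {"x1": 3000}  # 3 kb away -> adjacent; others too far

    @pytest.mark.parametrize("gap,expected", [(4999, True), (5000, False)])
    def test_strictly_less_than_five_kb(self, gap, expected):
        annotation = _annotation_from_arrays(
            ["chr1", "chr1"],
            [0, 1000 + gap],
            [1000, 2000 + gap],
            ["lncRNA", "coding"],
        )
        adjacency = abc.adjacency_scan(annotation)
        assert (len(adjacency.neighbors_of("x0")) == 1) is expected

    def test_overlapping_intervals_have_gap_zero(self):
        annotation = _annotation_from_arrays(
            ["chr1", "chr1"], [100, 50], [500, 200], ["lncRNA", "coding"]
        )
        adjacency = abc.adjacency_scan(annotation)
        assert adjacency.neighbors_of("x0") == [("x1", 0)]

    def test_different_chromosomes_never_adjacent(self):
        annotation = _annotation_from_arrays(
            ["chr1", "chr2"], [0, 100], [1000, 1100], ["lncRNA", "coding"]
        )
        assert len(abc.adjacency_scan(annotation)) == 0

    def test_matches_all_pairs_brute_force(self):
        """20 random 500-gene annotations against an O(n^2) oracle."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            chroms = rng.choice(["chr1", "chr2", "chr3"], size=n)
            starts = rng.integers(0, 2_000_000, size=n)
            lengths = rng.integers(200, 5000, size=n)
            biotypes = rng.choice(["coding", "lncRNA"], size=n)
            annotation = _annotation_from_arrays(
                chroms, starts, starts + lengths, biotypes
            )
            adjacency = abc.adjacency_scan(annotation)
            df = annotation.df
            expected: dict[str, set] = {}
            for li, lrow in df[df["biotype"] == "lncRNA"].iterrows():
                for ci, crow in df[df["biotype"] == "coding"].iterrows():
                    if lrow["chrom"] != crow["chrom"]:
                        continue
                    gap = interval_gap(
                        lrow["start"], lrow["end"], crow["start"], crow["end"]
                    )
                    if gap < 5000:
                        expected.setdefault(li, set()).add((ci, gap))
            got = {k: set(v) for k, v in adjacency.neighbors.items()}
            assert got == expected


class TestSignatureAdjacencyProportion:
    @staticmethod
    def _sigset(mapping):
        rows = [
            {"cell_type": t, "gene_id": g, "log2fc": 2.0, "p": 1e-4, "q": 1e-3,
             "pct_in": 0.8, "pct_out": 0.1}
            for t, genes in mapping.items()
            for g in genes
        ]
        return abc.SignatureSet(pd.DataFrame(rows), thresholds={})

    def test_no_neighbors_gives_zero_and_empty_type_nan(self):
        sig_lnc = self._sigset({"a": ["l1", "l2"], "b": []})
        sig_coding = self._sigset({"a": ["c1"], "b": ["c2"]})
        adjacency = abc.AdjacencyMap(neighbors={}, max_dist=5000)
        props = abc.signature_adjacency_proportion(sig_lnc, sig_coding, adjacency)
        assert props["a"] == 0.0
        assert np.isnan(props["b"])

    def test_full_same_type_coupling_gives_one(self):
        sig_lnc = self._sigset({"a": ["l1", "l2"]})
        sig_coding = self._sigset({"a": ["c1", "c2"]})
        adjacency = abc.AdjacencyMap(
            neighbors={"l1": [("c1", 10)], "l2": [("c2", 100)]}, max_dist=5000
        )
        props = abc.signature_adjacency_proportion(sig_lnc, sig_coding, adjacency)
        assert props["a"] == 1.0

    def test_cross_type_neighbors_ignored_in_same_type_mode(self):
        sig_lnc = self._sigset({"a": ["l1"]})
        sig_coding = self._sigset({"a": ["c1"], "b": ["c2"]})
        adjacency = abc.AdjacencyMap(neighbors={"l1": [("c2", 10)]}, max_dist=5000)
        props = abc.signature_adjacency_proportion(sig_lnc, sig_coding, adjacency)
        assert props["a"] == 0.0
        cross = abc.signature_adjacency_proportion(
            sig_lnc, sig_coding, adjacency, same_type=False
        )
        assert cross["a"] == 1.0


class TestConservationCompare:
    def test_null_shift_rejects_at_nominal_rate(self):
        """With no planted shift the one-sided test rejects at alpha=0.05
        in at most ~7% of 200 seeds."""
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            scores = pd.Series(
                rng.beta(1.2, 6.8, size=120),
                index=[f"g{i}" for i in range(120)],
            )
            sig = [f"g{i}" for i in range(40)]
            bg = [f"g{i}" for i in range(40, 120)]
            rejections += abc.conservation_compare(scores, sig, bg).p < 0.05
        assert rejections <= 14  # 7% of 200

    def test_planted_shift_detected(self):
        """A +0.3 mean shift at n=200 per group is overwhelming."""
        rng = np.random.default_rng(1)
        sig_scores = rng.beta(0.45 * 8, 0.55 * 8, size=200)
        bg_scores = rng.beta(0.15 * 8, 0.85 * 8, size=200)
        scores = pd.Series(
            np.r_[sig_scores, bg_scores],
            index=[f"g{i}" for i in range(400)],
        )
        cmp = abc.conservation_compare(
            scores, [f"g{i}" for i in range(200)],
            [f"g{i}" for i in range(200, 400)],
        )
        assert cmp.p < 1e-3
        assert cmp.delta_median > 0.2

    def test_degenerate_separation_is_minimal_p(self):
        scores = pd.Series(
            [1.0] * 5 + [0.0] * 5, index=[f"g{i}" for i in range(10)]
        )
        cmp = abc.conservation_compare(
            scores, [f"g{i}" for i in range(5)], [f"g{i}" for i in range(5, 10)]
        )
        # minimal attainable one-sided p for 5 vs 5: 1 / C(10,5)
        assert cmp.p == pytest.approx(1 / 252)

    def test_overlapping_sets_rejected(self):
        scores = pd.Series([0.5, 0.6], index=["g0", "g1"])
        with pytest.raises(ValueError, match="overlap"):
            abc.conservation_compare(scores, ["g0"], ["g0", "g1"])


class TestNeighborSignatureOverlap:
    def test_counts_and_hypergeometric_tail(self):
        sig_lnc = TestSignatureAdjacencyProportion._sigset({"a": ["l1", "l2"]})
        adjacency = abc.AdjacencyMap(
            neighbors={"l1": [("c1", 5), ("c2", 10)], "l2": [("c3", 7)]},
            max_dist=5000,
        )
        overlap, p = abc.neighbor_signature_overlap(
            adjacency, sig_lnc, ["c1", "c3", "c9"], universe_size=100
        )
        assert overlap == 2
        assert p == pytest.approx(
            abc.hypergeometric_overlap_test(2, 3, 3, 100)
        )
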