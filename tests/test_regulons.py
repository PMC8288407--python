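"""Regulon activity scores, binarization, cluster states and novelty flags."""
from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import abcatlas as abc
from abcatlas.regulons import Regulon, read_gmt, write_gmt


def _norm(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )


class TestRegulonType:
    def test_tf_always_included_in_targets(self):
        regulon = Regulon(tf="t1", targets=frozenset({"a", "b"}))
        assert "t1" in regulon.targets
        assert len(regulon) == 3

    def test_gmt_round_trip(self, tmp_path):
        regulons = [
            Regulon("tf1", frozenset({"a", "b", "c"})),
            Regulon("tf2", frozenset({"d", "e"})),
        ]
        path = tmp_path / "regulons.gmt"
        write_gmt(regulons, path)
        loaded = read_gmt(path)
        assert loaded == regulons


class TestRasAuc:
    def test_target_at_top_scores_one(self):
        """A single-target regulon whose target tops the ranking recovers
        fully at every window position."""
        X = np.array([[9.0, 1.0, 0.5, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0]])
        norm = _norm(X)
        ras = abc.ras_auc(norm, Regulon("g0"), top_fraction=0.3)
        assert ras.iloc[0] == 1.0

    def test_targets_outside_window_score_zero(self):
        X = np.array([np.arange(10, 0, -1, dtype=float)])
        norm = _norm(X)
        ras = abc.ras_auc(norm, Regulon("g9"), top_fraction=0.3)
        assert ras.iloc[0] == 0.0

    def test_matches_step_curve_oracle_on_small_instances(self):
        """Explicit per-cell recovery-curve integration on <= 50 genes."""
        rng = np.random.default_rng(2)
        for trial in range(10):
            n_genes = int(rng.integers(10, 51))
            n_cells = int(rng.integers(3, 8))
            X = rng.poisson(2.0, size=(n_cells, n_genes)).astype(float)
            norm = _norm(X)
            targets = frozenset(
                f"g{j}" for j in rng.choice(n_genes, size=5, replace=False)
            )
            tf = sorted(targets)[0]
            regulon = Regulon(tf, targets)
            top_fraction = float(rng.uniform(0.1, 0.6))
            ras = abc.ras_auc(norm, regulon, top_fraction=top_fraction)
            top_x = int(np.floor(top_fraction * n_genes))
            for i in range(n_cells):
                # ranking by descending value, ties by gene index
                order = sorted(range(n_genes), key=lambda j: (-X[i, j], j))
                hits = 0
                area = 0.0
                for k in range(top_x):
                    hits += f"g{order[k]}" in regulon.targets
                    area += hits / len(regulon.targets)
                assert ras.iloc[i] == pytest.approx(area / top_x, abs=1e-12)

    def test_invariant_to_monotone_transform(self, processed):
        """RAS is rank-based: cubing expression changes nothing."""
        _, norm_coding, _ = processed
        sub = norm_coding[:50].copy()
        regulon = Regulon("PCG00010", frozenset(list(sub.var_names[5:40])))
        base = abc.ras_auc(sub, regulon)
        cubed = sub.copy()
        cubed.X = np.asarray(cubed.X) ** 3
        np.testing.assert_array_equal(base.values, abc.ras_auc(cubed, regulon).values)

    def test_mean_over_random_regulons_matches_expected_area(self):
        """For random target sets the expected recovery curve is r(k)=k/G,
        so mean RAS over 1000 draws approaches (X+1)/(2G) within 0.005."""
        rng = np.random.default_rng(3)
        g = 2000
        X = rng.normal(size=(1, g))
        norm = _norm(X)
        regulons = []
        for i in range(1000):
            members = rng.choice(g, size=20, replace=False)
            regulons.append(
                Regulon(f"g{members[0]}", frozenset(f"g{j}" for j in members))
            )
        ras = abc.ras_matrix(norm, regulons, top_fraction=0.05)
        top_x = int(0.05 * g)
        expected = (top_x + 1) / (2 * g)
        assert ras.iloc[0].mean() == pytest.approx(expected, abs=0.005)

    def test_unresolvable_regulon_is_error(self):
        norm = _norm(np.ones((2, 5)))
        with pytest.raises(ValueError, match="no targets"):
            abc.ras_matrix(
                norm, [Regulon("zz", frozenset({"yy"}))],
                top_fraction=0.4, min_targets=1,
            )

    def test_small_regulon_dropped_with_warning(self):
        norm = _norm(np.ones((2, 10)))
        regs = [
            Regulon("g0", frozenset({"g1", "g2", "g3"})),  # 4 with the TF
            Regulon("g5", frozenset({f"g{j}" for j in range(5, 10)})),
        ]
        with pytest.warns(UserWarning, match="dropping regulon g0"):
            ras = abc.ras_matrix(norm, regs, top_fraction=0.4, min_targets=5)
        assert list(ras.columns) == ["g5"]


class TestBinarizeRas:
    def test_bimodal_clusters_split_perfectly(self):
        """RAS drawn around 0.1 and 0.9 binarizes with a threshold inside
        (0.2, 0.8) and recovers the planted membership exactly."""
        rng = np.random.default_rng(4)
        low = rng.normal(0.1, 0.02, size=60).clip(0, 1)
        high = rng.normal(0.9, 0.02, size=40).clip(0, 1)
        ras = pd.DataFrame({"r": np.r_[low, high]},
                           index=[f"c{i}" for i in range(100)])
        result = abc.binarize_ras(ras)
        assert 0.2 < result.thresholds["r"] < 0.8
        np.testing.assert_array_equal(
            result.binary["r"].values, np.r_[np.zeros(60), np.ones(40)]
        )

    def test_single_active_cell_is_the_only_on(self):
        ras = pd.DataFrame({"r": [0.0] * 19 + [1.0]},
                           index=[f"c{i}" for i in range(20)])
        result = abc.binarize_ras(ras)
        assert result.binary["r"].sum() == 1
        assert result.binary["r"].iloc[-1] == 1

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(5)
        values = np.r_[rng.normal(0.2, 0.05, 30), rng.normal(0.7, 0.05, 30)]
        ras = pd.DataFrame({"r": values}, index=[f"c{i}" for i in range(60)])
        perm = rng.permutation(60)
        shuffled = ras.iloc[perm]
        a = abc.binarize_ras(ras)
        b = abc.binarize_ras(shuffled)
        assert a.thresholds["r"] == b.thresholds["r"]
        assert a.binary["r"].loc[shuffled.index].equals(b.binary["r"])

    def test_constant_column_dropped_and_too_few_cells_rejected(self):
        ras = pd.DataFrame(
            {"flat": [0.5] * 12, "ok": [0.1] * 6 + [0.9] * 6},
            index=[f"c{i}" for i in range(12)],
        )
        with pytest.warns(UserWarning, match="constant"):
            result = abc.binarize_ras(ras)
        assert result.dropped == ["flat"]
        with pytest.raises(ValueError, match="at least 10"):
            abc.binarize_ras(ras.head(5))


class TestClusterStates:
    @staticmethod
    def _binary(rows, labels):
        binary = pd.DataFrame(
            rows, index=[f"c{i}" for i in range(len(rows))], columns=["r1", "r2"]
        )
        return binary, labels

    def test_always_on_regulon_is_on_everywhere_and_nonspecific(self):
        binary, labels = self._binary(
            [[1, 0]] * 6 + [[1, 1]] * 6, ["a"] * 6 + ["b"] * 6
        )
        states = abc.cluster_regulon_states(binary, labels, max_other_on=1)
        assert (states.states["r1"] == 1).all()
        assert "r1" not in states.specific["a"] and "r1" not in states.specific["b"]
        assert states.specific["b"] == ["r2"]

    def test_unanimity_required_when_min_on_fraction_is_one(self):
        binary, labels = self._binary(
            [[1, 1]] * 5 + [[0, 1]] + [[1, 1]] * 5 + [[0, 1]],
            ["a"] * 6 + ["b"] * 6,
        )
        states = abc.cluster_regulon_states(binary, labels, min_on_fraction=1.0)
        assert (states.states["r1"] == 0).all()
        assert (states.states["r2"] == 1).all()

    def test_empty_cluster_rejected(self):
        binary = pd.DataFrame(
            [[1, 0]] * 4, index=[f"c{i}" for i in range(4)], columns=["r1", "r2"]
        )
        labels = pd.Categorical(
            ["a", "a", "b", "b"], categories=["a", "b", "ghost"]
        )
        with pytest.raises(ValueError, match="empty"):
            abc.cluster_regulon_states(binary, labels)


class TestFlagNovel:
    def test_canonical_covers_everything_or_nothing(self):
        binary = pd.DataFrame(
            {"r1": [1] * 6 + [0] * 6, "r2": [0] * 12},
            index=[f"c{i}" for i in range(12)],
        )
        states = abc.cluster_regulon_states(binary, ["a"] * 6 + ["b"] * 6)
        assert abc.flag_novel_regulons(states, {"r1", "r2"}) == set()
        assert abc.flag_novel_regulons(states, set()) == {"r1"}  # r2 never on

    def test_planted_lineage_structure_recovered(self, default_atlas, processed):
        """On the default atlas: lineage regulons binarize on in exactly
        their own family cluster, and the planted activated non-canonical
        TFs — and only those — are flagged novel."""
        _, norm_coding, _ = processed
        ras = abc.ras_matrix(norm_coding, default_atlas.regulons)
        binarized = abc.binarize_ras(ras)
        families = norm_coding.obs["cell_type"].map(default_atlas.config.families)
        states = abc.cluster_regulon_states(binarized, families)
        plan = default_atlas.truth.regulon_plan
        for tf, meta in plan.items():
            if meta["kind"] != "lineage":
                continue
            assert states.states.loc[meta["family"], tf] == 1
            assert states.states[tf].sum() == 1  # nowhere else
            assert tf in states.specific[meta["family"]]
        novel = abc.flag_novel_regulons(states, default_atlas.canonical_tfs)
        planted_novel = {
            tf
            for tf, meta in plan.items()
            if meta["kind"] == "lineage" and not meta["canonical"]
        }
        assert novel == planted_novel


def test_load_canonical_tf_resource():
    tfs = abc.load_canonical_tfs()
    assert {"GATA1", "SPI1", "EBF1", "TBX21"} <= tfs
    assert all(t and not t.startswith("#") for t in tfs)
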