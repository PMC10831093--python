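"""GRN: downsampling, importance scoring, reproducibility aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from striaseq import grn


class TestDownsample:
    def test_majority_reduced_to_second_most_prevalent(self):
        labels = np.array(["A"] * 600 + ["B"] * 80 + ["C"] * 20)
        idx = np.arange(700)
        keep = grn.downsample_majority(idx, labels, seed=0)
        kept_labels = labels[keep]
        assert (kept_labels == "A").sum() == 80
        assert (kept_labels == "B").sum() == 80
        assert (kept_labels == "C").sum() == 20
        assert len(keep) == 180

    def test_tie_for_most_prevalent_is_untouched(self):
        labels = np.array(["A"] * 50 + ["B"] * 50 + ["C"] * 10)
        keep = grn.downsample_majority(np.arange(110), labels, seed=0)
        assert len(keep) == 110

    def test_seed_determinism_and_single_type_warning(self):
        labels = np.array(["A"] * 300 + ["B"] * 100)
        k1 = grn.downsample_majority(np.arange(400), labels, seed=5)
        k2 = grn.downsample_majority(np.arange(400), labels, seed=5)
        assert np.array_equal(k1, k2)
        with pytest.warns(UserWarning, match="single cell type"):
            out = grn.downsample_majority(np.arange(10), np.repeat("A", 10), seed=0)
        assert len(out) == 10


class TestImportance:
    def _planted(self, seed=0, n_cells=300, n_decoys=10, n_targets=20):
        rng = np.random.default_rng(seed)
        tf = rng.lognormal(2, 0.5, n_cells)
        decoys = rng.lognormal(2, 0.5, (n_cells, n_decoys))
        targets = 0.8 * tf[:, None] * rng.lognormal(0, 0.3, (n_cells, n_targets))
        counts = np.round(np.column_stack([tf, decoys.reshape(n_cells, -1), targets]))
        genes = (
            ["TF0"]
            + [f"DECOY{i}" for i in range(n_decoys)]
            + [f"T{i}" for i in range(n_targets)]
        )
        tfs = ["TF0"] + [f"DECOY{i}" for i in range(n_decoys)]
        return counts, np.array(genes), tfs

    def test_planted_tf_is_top_predictor_for_most_targets(self):
        counts, genes, tfs = self._planted()
        edges = grn.score_tf_importance(counts, tfs, genes, seed=1)
        top = (
            edges.sort_values("importance", ascending=False)
            .groupby("target", sort=False)
            .head(1)
        )
        planted = top[top["target"].str.startswith("T")]
        assert (planted["tf"] == "TF0").mean() >= 0.9

    def test_identical_seed_gives_identical_edges(self):
        counts, genes, tfs = self._planted(seed=3)
        e1 = grn.score_tf_importance(counts, tfs, genes, seed=7)
        e2 = grn.score_tf_importance(counts, tfs, genes, seed=7)
        pd.testing.assert_frame_equal(e1, e2)

    def test_independent_target_keeps_no_more_edges_than_decoy_baseline(self):
        rng = np.random.default_rng(4)
        counts, genes, tfs = self._planted(seed=4, n_targets=5)
        # append pure-noise targets
        noise = np.round(rng.lognormal(2, 0.5, (counts.shape[0], 5)))
        counts = np.column_stack([counts, noise])
        genes = np.concatenate([genes, [f"N{i}" for i in range(5)]])
        edges = grn.score_tf_importance(counts, tfs, genes, seed=1)
        per_target = edges.groupby("target").size()
        planted_edges = per_target[[t for t in per_target.index if t.startswith("T")]]
        noise_edges = per_target.reindex([f"N{i}" for i in range(5)]).fillna(0)
        # signal targets concentrate importance -> fewer retained edges
        assert planted_edges.mean() <= noise_edges.mean()

    def test_constant_target_yields_no_edges(self):
        counts, genes, tfs = self._planted(seed=5, n_targets=3)
        counts[:, -1] = 7.0  # constant in raw counts but not after log-CPM...
        lib = counts.sum(axis=1)
        counts[:, -1] = np.round(lib * 0.01)  # constant after CPM normalization
        edges = grn.score_tf_importance(counts, tfs, genes, seed=1)
        # the truly degenerate case: too few cells raises
        with pytest.raises(ValueError, match="cells"):
            grn.score_tf_importance(counts[:10], tfs, genes, seed=1)
        assert isinstance(edges, pd.DataFrame)


def _edges(pairs_with_imp):
    return pd.DataFrame(pairs_with_imp, columns=["tf", "target", "importance"])


class TestAggregation:
    def test_run_rule_mean_and_threshold(self):
        runs = [_edges([("t", "g", i)]) for i in (1.0, 2.0, 3.0, 4.0)]
        out = grn.aggregate_runs(runs)
        assert out["importance"].iloc[0] == pytest.approx(2.5)
        runs3 = runs[:3] + [_edges([("t", "h", 1.0)])]
        out = grn.aggregate_runs(runs3)  # g in 3/4 = 0.75 < 0.8 -> dropped
        assert len(out) == 0
        out = grn.aggregate_runs(runs[:2] + [runs[0]])  # g in 3/3 -> kept
        assert len(out) == 1

    def test_individual_rule_10_of_12_passes_9_fails(self):
        present = [_edges([("t", "g", 2.0)])] * 10 + [_edges([("t", "h", 1.0)])] * 2
        out = grn.aggregate_individuals(present)
        assert len(out) == 1 and out["individual_support"].iloc[0] == pytest.approx(10 / 12)
        present = [_edges([("t", "g", 2.0)])] * 9 + [_edges([("t", "h", 1.0)])] * 3
        assert len(grn.aggregate_individuals(present)) == 0

    def test_consensus_importance_is_mean_of_individual_means(self):
        out = grn.aggregate_individuals([_edges([("t", "g", 2.0)]), _edges([("t", "g", 4.0)])])
        assert out["importance"].iloc[0] == pytest.approx(3.0)

    def test_exhaustive_support_pattern_enumeration(self):
        """The run/individual keep rules match direct enumeration over all
        support counts for R <= 5 runs and N <= 12 individuals."""
        for R in range(2, 6):
            for present in range(0, R + 1):
                runs = [_edges([("t", "g", 1.0)])] * present + [
                    _edges([("t", f"other{i}", 1.0)]) for i in range(R - present)
                ]
                kept = ("t", "g") in set(
                    zip(*[grn.aggregate_runs(runs)[c] for c in ("tf", "target")])
                ) if len(grn.aggregate_runs(runs)) else False
                assert kept == (present >= int(np.ceil(0.8 * R - 1e-9)))
        for N in range(2, 13):
            for present in range(0, N + 1):
                ind = [_edges([("t", "g", 1.0)])] * present + [
                    _edges([("t", f"o{i}", 1.0)]) for i in range(N - present)
                ]
                res = grn.aggregate_individuals(ind)
                kept = ("g" in set(res["target"])) if len(res) else False
                assert kept == (present >= int(np.ceil(0.8 * N - 1e-9)))

    def test_raising_thresholds_never_adds_edges(self):
        rng = np.random.default_rng(0)
        runs = []
        for r in range(5):
            pairs = [(f"t{i}", f"g{j}", rng.random()) for i in range(3) for j in range(4)
                     if rng.random() < 0.7]
            runs.append(_edges(pairs))
        loose = grn.aggregate_runs(runs, run_threshold=0.6)
        tight = grn.aggregate_runs(runs, run_threshold=0.9)
        assert set(zip(tight["tf"], tight["target"])) <= set(zip(loose["tf"], loose["target"]))

    def test_strict_mode_requires_unanimity_for_small_r(self):
        runs = [_edges([("t", "g", 1.0)])] * 4
        assert len(grn.aggregate_runs(runs, strict=True)) == 1
        runs = [_edges([("t", "g", 1.0)])] * 3 + [_edges([("t", "h", 1.0)])]
        assert len(grn.aggregate_runs(runs[:4], strict=True)) == 0


class TestPruning:
    def test_allowlist_semantics(self):
        edges = _edges([("t1", "a", 1.0), ("t1", "b", 1.0), ("t1", "c", 1.0),
                        ("t1", "d", 1.0), ("t1", "e", 1.0), ("t2", "x", 1.0)])
        allow = pd.DataFrame({"tf": ["t1", "t1", "t1"], "target": ["a", "b", "c"]})
        with pytest.warns(UserWarning, match="t2"):
            regs = grn.prune_edges(edges, allow)
        assert set(regs) == {"t1"}
        assert len(regs["t1"]) == 3

    def test_absent_allowlist_is_identity(self):
        edges = _edges([("t1", "a", 1.0), ("t2", "b", 2.0)])
        regs = grn.prune_edges(edges, None)
        assert set(regs) == {"t1", "t2"}


def test_consensus_recovery_of_planted_regulons(grn_cohort):
    """5 planted regulons among 200 genes, 12 individuals x 4 runs:
    consensus precision >= 0.8 and recall >= 0.6."""
    adata, tfs, truth = grn_cohort
    consensus, regulons = grn.run_grn(adata, tfs, n_runs=4, seed=5)
    true_edges = set(zip(truth.regulon_truth["tf"], truth.regulon_truth["target"]))
    pred = set(zip(consensus["tf"], consensus["target"]))
    tp = len(pred & true_edges)
    assert tp / max(len(pred), 1) >= 0.8
    assert tp / len(true_edges) >= 0.6
    # relabeling individuals does not change the consensus edge set
    assert set(regulons) <= set(consensus["tf"])
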