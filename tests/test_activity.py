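"""AUCell recovery-curve scoring and the activity regressions."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from striaseq import activity


def brute_force_auc(ranks_row, set_positions, top_frac):
    """Literal recovery-curve oracle: R(j) counted step by step."""
    n = len(ranks_row)
    k = max(1, int(np.floor(top_frac * n)))
    R = [sum(1 for p in set_positions if ranks_row[p] <= j) for j in range(1, k + 1)]
    m = min(len(set_positions), k)
    max_sum = sum(min(j, m) for j in range(1, k + 1))
    return sum(R) / max_sum


class TestRanking:
    def test_strictly_decreasing_counts_give_identity_ranking(self):
        counts = np.array([[9, 7, 5, 3, 1]])
        ranks, zero = activity.rank_cells(counts, seed=0)
        assert ranks.tolist() == [[1, 2, 3, 4, 5]]
        assert not zero[0]

    def test_tie_rules_and_seeded_determinism(self):
        counts = np.array([[5, 3, 3, 0]])
        r1, _ = activity.rank_cells(counts, seed=4)
        r2, _ = activity.rank_cells(counts, seed=4)
        assert np.array_equal(r1, r2)
        assert r1[0, 0] == 1 and r1[0, 3] == 4
        assert sorted(r1[0, 1:3].tolist()) == [2, 3]
        # some seed resolves the tie the other way
        orders = {tuple(activity.rank_cells(counts, seed=s)[0][0, 1:3]) for s in range(20)}
        assert len(orders) == 2

    def test_all_zero_cells_are_flagged(self):
        counts = np.array([[0, 0, 0], [1, 0, 0]])
        _, zero = activity.rank_cells(counts, seed=0)
        assert zero.tolist() == [True, False]


class TestAUCell:
    def test_worked_example_two_thirds(self):
        """5 genes, k = 2, set at ranks {1, 3}: recovery (1, 1), max 3."""
        ranks = np.array([[1, 2, 3, 4, 5]])
        auc = activity.aucell_score(ranks, np.array([0, 2]), top_frac=0.4)
        assert auc[0] == pytest.approx(2 / 3)

    def test_top_block_scores_one_bottom_scores_zero(self):
        ranks = np.array([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10]])
        assert activity.aucell_score(ranks, np.array([0, 1]), top_frac=0.5)[0] == 1.0
        assert activity.aucell_score(ranks, np.array([8, 9]), top_frac=0.5)[0] == 0.0

    def test_exhaustive_oracle_on_small_instances(self):
        """For every ranking of <= 10 genes and every subset, the score
        equals the brute-force recovery-curve AUC."""
        rng = np.random.default_rng(0)
        for n in range(2, 11):
            counts = rng.integers(0, 4, size=(2, n))
            ranks, zero = activity.rank_cells(counts, seed=1)
            for row in range(2):
                if zero[row]:
                    continue
                for size in range(1, n + 1):
                    for subset in itertools.combinations(range(n), size):
                        for tf in (0.25, 0.5, 1.0):
                            got = activity.aucell_score(
                                ranks[row : row + 1], np.array(subset), top_frac=tf
                            )[0]
                            ref = brute_force_auc(ranks[row], subset, tf)
                            assert got == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_monotone_count_transforms(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(20, 100))
        r1, _ = activity.rank_cells(counts, seed=3)
        r2, _ = activity.rank_cells(counts * 17, seed=3)
        assert np.array_equal(r1, r2)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="no members"):
            activity.aucell_score(np.array([[1, 2]]), np.array([], dtype=int))


class TestScoring:
    def test_planted_shift_separates_cases_from_controls(self, cohort):
        """Cells with the planted gene-set up-shift score higher than
        matched control cells (AUROC >= 0.9 at a 2x shift)."""
        _, adata, _, truth = cohort
        row = truth.activity_truth.iloc[0]
        sets = {row["gene_set"]: row["genes"].split(";")}
        mask = (
            (adata.obs["cell_type"] == row["cell_type"])
            & (adata.obs["artifact"] == "clean")
        ).to_numpy()
        sub = adata[mask]
        scores = activity.score_cells(sub, sets, seed=3)
        s = scores.iloc[:, 0].to_numpy()
        case = (sub.obs["Dx"] == "OUD").to_numpy()
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(s[case], s[~case]).statistic
        auroc = u / (case.sum() * (~case).sum())
        assert auroc >= 0.9

    def test_unknown_gene_set_raises(self, cohort):
        _, adata, _, _ = cohort
        with pytest.raises(ValueError, match="shares no genes"):
            activity.score_cells(adata[:10], {"bad": ["NOT_A_GENE"]})


class TestPseudobulkActivity:
    def _scores_meta(self):
        rng = np.random.default_rng(0)
        n = 120
        scores = pd.DataFrame({"s": rng.uniform(size=n)}, index=[f"c{i}" for i in range(n)])
        meta = pd.DataFrame(
            {
                "individual": np.repeat(["i1", "i2"], 60),
                "region": "R",
                "cell_type": np.tile(np.repeat(["A", "B"], 30), 2),
            },
            index=scores.index,
        )
        return scores, meta

    def test_mean_and_bounds_and_order_invariance(self):
        scores, meta = self._scores_meta()
        pb = activity.pseudobulk_activity(scores, meta, min_cells=10)
        grp = scores.join(meta).groupby(["individual", "cell_type"])["s"]
        for _, row in pb.iterrows():
            vals = grp.get_group((row["individual"], row["cell_type"]))
            assert row["s"] == pytest.approx(vals.mean())
            assert vals.min() <= row["s"] <= vals.max()
        perm = np.random.default_rng(1).permutation(len(scores))
        pb2 = activity.pseudobulk_activity(scores.iloc[perm], meta.iloc[perm], min_cells=10)
        pd.testing.assert_frame_equal(pb, pb2)

    def test_small_groups_are_dropped(self):
        scores, meta = self._scores_meta()
        with pytest.warns(UserWarning, match="below 40"):
            pb = activity.pseudobulk_activity(scores, meta, min_cells=40)
        assert len(pb) == 0


def _simulate_pb(seed, shift=0.0, n_indiv=12, n_types=6, sd=0.03):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_indiv):
        dx = "OUD" if i % 2 == 0 else "UC"
        for reg in ("C", "P"):
            for t in range(n_types):
                mu = 0.2 + (shift if (dx == "OUD" and t == 0) else 0.0)
                rows.append(
                    {
                        "individual": f"I{i}",
                        "region": reg,
                        "cell_type": f"T{t}",
                        "sig": rng.normal(mu, sd),
                        "n_cells": int(rng.integers(25, 60)),
                    }
                )
    cov = pd.DataFrame(
        {
            "individual": [f"I{i}" for i in range(n_indiv)],
            "Dx": ["OUD" if i % 2 == 0 else "UC" for i in range(n_indiv)],
            "Sex": ["F" if (i // 2) % 2 == 0 else "M" for i in range(n_indiv)],
            "Age": np.random.default_rng(seed + 1).normal(45, 8, n_indiv),
            "PMI": np.random.default_rng(seed + 2).normal(14, 4, n_indiv),
            "RIN": np.random.default_rng(seed + 3).normal(8, 0.5, n_indiv),
            "Pair": [f"P{i // 2}" for i in range(n_indiv)],
        }
    )
    return pd.DataFrame(rows), cov


class TestRegression:
    def test_planted_shift_detected_in_celltype_mode(self):
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(40):
                pb, cov = _simulate_pb(s, shift=0.1)
                res = activity.test_activity(pb, cov, ["sig"], mode="human_celltype")
                row = res[res["cell_type"] == "T0"]
                wins += float(row["p"].iloc[0]) < 0.05
        assert wins / 40 >= 0.9

    def test_location_shift_leaves_group_estimate_unchanged(self):
        pb, cov = _simulate_pb(0, shift=0.1)
        r1 = activity.test_activity(pb, cov, ["sig"], mode="human_sample")
        pb2 = pb.copy()
        pb2["sig"] += 10.0
        r2 = activity.test_activity(pb2, cov, ["sig"], mode="human_sample")
        assert r1["estimate"].iloc[0] == pytest.approx(r2["estimate"].iloc[0])

    def test_macaque_paired_design_and_rank_deficiency(self):
        pb, cov = _simulate_pb(1, shift=0.1, n_indiv=8)
        cov = cov.rename(columns={"Dx": "Tx"})
        cov["Tx"] = cov["Tx"].map({"OUD": "Morphine", "UC": "Control"})
        pb = pb.merge(cov[["individual"]], on="individual")
        res = activity.test_activity(pb, cov, ["sig"], mode="macaque_celltype")
        assert (res["term"] == "Tx:Celltype").all()
        assert len(res) == 6
        # Pair perfectly collinear with Tx -> rank deficiency error
        bad = cov.copy()
        bad["Pair"] = bad["Tx"]
        with pytest.raises(ValueError, match="aliased"):
            activity.test_activity(pb, bad, ["sig"], mode="macaque_sample")

    def test_single_cell_type_reduces_celltype_to_sample_estimate(self):
        pb, cov = _simulate_pb(2, shift=0.1, n_types=1)
        r_ct = activity.test_activity(
            pb.drop(columns="n_cells"), cov, ["sig"], mode="human_celltype"
        )
        r_s = activity.test_activity(pb, cov, ["sig"], mode="human_sample")
        # same diagnosis effect up to the Sex covariate present only in
        # sample mode; compare against a fit without Sex
        assert r_ct["estimate"].iloc[0] == pytest.approx(r_s["estimate"].iloc[0], abs=0.02)
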