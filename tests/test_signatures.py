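"""Normalization, DE ranking, LOOCV consensus and predictor search."""

import numpy as np
import pytest

import organodx as ox
from organodx import signatures as sg


def balanced_matrix(counts, n_each=2):
    labels = ["OS"] * n_each + ["OR"] * n_each
    nf = counts.shape[0]
    return ox.CountMatrix(
        [f"f{i}" for i in range(nf)],
        [f"s{j}" for j in range(2 * n_each)],
        counts,
        labels,
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = balanced_matrix(np.tile([[10], [20], [5]], (1, 4)))
        assert np.allclose(sg.size_factors(cm), 1.0)

    def test_hand_enumerated_example(self):
        # feature ratios to geomeans: (0.5, 2) and (1, 1); medians 0.75 and 1.5
        assert np.allclose(sg.size_factors(np.array([[2, 8], [2, 2]])), [0.75, 1.5])

    def test_scale_equivariance_of_factor_ratios(self):
        # scaling one library by 10 multiplies its factor by 10 relative to
        # the others (absolute factors shift together via the geometric means)
        rng = np.random.default_rng(0)
        mat = rng.integers(1, 100, size=(50, 4))
        base = sg.size_factors(mat)
        scaled = mat.astype(float).copy()
        scaled[:, 2] *= 10
        got = sg.size_factors(scaled)
        assert np.allclose(got[2] / np.delete(got, 2), 10 * base[2] / np.delete(base, 2))

    def test_infeasible_without_all_positive_feature(self):
        mat = np.array([[0, 5], [5, 0]])
        with pytest.raises(sg.NormalizationError):
            sg.size_factors(mat)

    def test_equal_libraries_no_de_near_unity(self):
        cm = ox.gen_counts(ox.CountScenario(
            n_features=2000, planted_idx=(), dispersion=0.05,
            size_factor_range=(1.0, 1.0), seed=0))
        assert np.all((sg.size_factors(cm) > 0.9) & (sg.size_factors(cm) < 1.1))


class TestDeRank:
    def test_identical_groups_null_feature(self):
        counts = np.tile([[100], [30], [800]], (1, 8)).astype(int)
        cm = balanced_matrix(counts, n_each=4)
        table = sg.de_rank(cm)
        assert np.allclose(table["log2fc"], 0.0)
        assert np.all(table["p_value"] > 0.99)

    def test_planted_feature_passes_deg_filter(self):
        cm = ox.gen_counts(ox.CountScenario(
            n_features=200, planted_idx=(0,), planted_log2fc=3.0,
            dispersion=0.01, seed=1))
        table = sg.de_rank(cm)
        row = table[table["feature_id"] == cm.feature_ids[0]].iloc[0]
        assert abs(row["log2fc"]) >= 1.0 and row["adj_p"] < 0.05
        assert cm.feature_ids[0] in sg.top_features(table, 100)

    def test_bh_matches_step_up_enumeration(self):
        # independent step-up oracle: adj_p_(i) = min over j>=i of p_(j)*m/j
        from statsmodels.stats.multitest import multipletests

        p = np.round(np.arange(1, 11) * 0.01, 2)
        m = len(p)
        oracle = np.empty(m)
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, p[i] * m / (i + 1))
            oracle[i] = running
        assert np.allclose(multipletests(p, method="fdr_bh")[1], oracle)

    def test_null_pvalues_super_uniform(self):
        cm = ox.gen_counts(ox.CountScenario(
            n_features=2000, planted_idx=(), dispersion=0.1, seed=2))
        table = sg.de_rank(cm)
        assert (table["p_value"] < 0.05).mean() <= 0.07

    def test_small_group_rejected(self):
        counts = np.abs(np.arange(30).reshape(10, 3)) + 1
        with pytest.raises(ValueError, match="at least 2"):
            ox.CountMatrix([f"f{i}" for i in range(10)], ["a", "b", "c"],
                           counts, ["OS", "OS", "OR"])

    def test_rank_deterministic(self):
        cm = ox.gen_counts(ox.CountScenario(n_features=300, seed=3))
        t1, t2 = sg.de_rank(cm), sg.de_rank(cm)
        assert t1["feature_id"].tolist() == t2["feature_id"].tolist()


class TestLoocvConsensus:
    def test_fold_structure_and_exact_top_k(self):
        # enough strong planted features that every fold has >= 100 DEGs
        rng = np.random.default_rng(4)
        planted = tuple(sorted(int(i) for i in rng.choice(1000, 120, replace=False)))
        signs = np.where(np.arange(120) % 2 == 0, 3.0, -3.0)
        cm = ox.gen_counts(ox.CountScenario(
            n_features=1000, planted_idx=planted, planted_log2fc=tuple(signs),
            dispersion=0.01, seed=4))
        cons = ox.loocv_consensus(cm, k=100)
        assert cons.n_folds == 16
        assert all(len(v) == 100 for v in cons.fold_tops.values())
        for fold in cons.fold_tops.values():
            assert set(cons.consensus) <= set(fold)

    def test_strong_separator_in_consensus(self, planted_counts):
        cm, planted = planted_counts
        cons = ox.loocv_consensus(cm, k=100)
        assert planted[0] in cons.consensus

    def test_planted_recovery(self, planted_counts):
        cm, planted = planted_counts
        cons = ox.loocv_consensus(cm, k=100)
        recovered = set(planted) & set(cons.consensus)
        false_pos = set(cons.consensus) - set(planted)
        assert len(recovered) >= 18
        assert len(false_pos) <= 5

    def test_too_few_samples_rejected(self):
        counts = np.ones((10, 3), dtype=int)
        with pytest.raises(ValueError):
            cm = ox.CountMatrix([f"f{i}" for i in range(10)], ["a", "b", "c"],
                                counts, ["OS", "OS", "OR"])
            ox.loocv_consensus(cm, k=5)


class TestSingleFeatureLR:
    def test_complete_separator_scores_one(self, planted_counts):
        cm, planted = planted_counts
        models = ox.single_feature_lr_search(cm, planted[:3])
        assert all(m.loocv_score == 1.0 for m in models)

    def test_constant_feature_skipped_with_warning(self):
        counts = np.vstack([np.full(8, 50), np.arange(1, 9) * 10]).astype(int)
        cm = balanced_matrix(counts, n_each=4)
        with pytest.warns(UserWarning, match="constant"):
            models = ox.single_feature_lr_search(cm, ["f0", "f1"])
        assert [m.feature_id for m in models] == ["f1"]

    def test_label_independent_feature_near_chance(self):
        # Monte-Carlo null: mean LOOCV accuracy ~ 0.5 over 200 simulations
        rng = np.random.default_rng(5)
        scores = []
        for _ in range(200):
            counts = np.vstack([
                rng.integers(50, 150, size=16),
                np.full(16, 100),  # keeps normalization feasible
            ])
            cm = balanced_matrix(counts, n_each=8)
            models = ox.single_feature_lr_search(cm, ["f0"])
            scores.append(models[0].loocv_score)
        # no spurious predictive signal; LOOCV on balanced null data is
        # pessimistically biased, so the mean sits at or below chance
        assert np.mean(scores) <= 0.55
        assert max(scores) < 1.0

    def test_unknown_candidate_rejected(self, planted_counts):
        cm, _ = planted_counts
        with pytest.raises(KeyError):
            ox.single_feature_lr_search(cm, ["missing"])


class TestClassifierPanel:
    def test_perfect_separation_all_classifiers(self, planted_counts):
        cm, planted = planted_counts
        table = ox.classifier_panel(cm, planted, seed=0)
        assert set(table["classifier"]) == set(sg.CLASSIFIERS)
        assert np.allclose(table["loocv_accuracy"], 1.0)

    def test_permuted_labels_near_chance(self, planted_counts):
        cm, planted = planted_counts
        rng = np.random.default_rng(6)
        fast = ("logistic_regression", "knn", "naive_bayes", "decision_tree")
        accs = []
        for _ in range(10):
            labels = list(rng.permutation(cm.labels))
            shuffled = ox.CountMatrix(cm.feature_ids, cm.sample_ids, cm.counts, labels)
            table = ox.classifier_panel(shuffled, planted[:5], classifiers=fast, seed=0)
            accs.extend(table["loocv_accuracy"])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.15)

    def test_constant_feature_gives_majority_fraction(self):
        counts = np.vstack([np.full(16, 100), np.full(16, 200)]).astype(int)
        labels = ["OS"] * 10 + ["OR"] * 6
        cm = ox.CountMatrix(["f0", "f1"], [f"s{i}" for i in range(16)], counts, labels)
        table = ox.classifier_panel(cm, ["f0"], classifiers=("logistic_regression",), seed=0)
        assert table["loocv_accuracy"].iloc[0] == pytest.approx(10 / 16)

    def test_unknown_classifier_rejected(self, planted_counts):
        cm, planted = planted_counts
        with pytest.raises(KeyError):
            ox.classifier_panel(cm, planted[:2], classifiers=("quantum_forest",))


class TestExport:
    def test_signature_files(self, planted_counts, tmp_path):
        cm, planted = planted_counts
        table = sg.de_rank(cm)
        cons = ox.loocv_consensus(cm, k=100)
        out = sg.export_signature(table, cons, tmp_path)
        up = (tmp_path / "signature_up.txt").read_text().split()
        down = (tmp_path / "signature_down.txt").read_text().split()
        assert set(up) | set(down) == set(cons.consensus)
        assert not set(up) & set(down)
        rnk = (tmp_path / "signature.rnk").read_text().strip().splitlines()
        assert len(rnk) == len(table)
        first_stat = float(rnk[0].split("\t")[1])
        last_stat = float(rnk[-1].split("\t")[1])
        assert first_stat >= last_stat
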