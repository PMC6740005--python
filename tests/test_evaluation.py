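import numpy as np
import pytest

from nemii.data_model import AssociationDataset
from nemii.evaluation import (
    compute_metrics,
    evaluate_fold,
    five_fold_split,
    per_disease_metrics,
    rank_candidates,
    recovery_experiment,
    remove_associations,
    run_cv,
)

from .oracles import brute_auc, hand_confusion_metrics


class TestFiveFoldSplit:
    def test_partition_of_positives(self, small_data):
        ds = small_data[0]
        plans = five_fold_split(ds, seed=1)
        held = [set(map(tuple, p.held_out.tolist())) for p in plans]
        union = set().union(*held)
        positives = set(map(tuple, np.column_stack(np.nonzero(ds.A)).tolist()))
        assert union == positives
        for a in range(5):
            for b in range(a + 1, 5):
                assert not held[a] & held[b]

    def test_fold_sizes_near_equal(self, small_data):
        ds = small_data[0]
        sizes = [len(p.held_out) for p in five_fold_split(ds, seed=2)]
        assert max(sizes) - min(sizes) <= 1

    def test_training_matrix_zeroes_held_out(self, small_data):
        ds = small_data[0]
        for plan in five_fold_split(ds, seed=3):
            assert plan.A_train[plan.held_out[:, 0], plan.held_out[:, 1]].sum() == 0
            assert plan.A_train.sum() == ds.A.sum() - len(plan.held_out)

    def test_too_few_positives_fatal(self):
        ds = AssociationDataset(["m1"], ["d1", "d2"], np.array([[1, 0]]))
        with pytest.raises(ValueError):
            five_fold_split(ds, seed=0)


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.AUC == 1.0
        assert m.AUPR == 1.0

    def test_hand_worked_auc(self):
        m = compute_metrics([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert m.AUC == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        m = compute_metrics(scores, labels)
        assert abs(m.AUC - 0.5) < 0.05

    def test_auc_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(10, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            m = compute_metrics(scores, labels)
            assert m.AUC == pytest.approx(brute_auc(scores, labels), abs=1e-10)

    def test_thresholded_metrics_match_confusion_matrix(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            scores = rng.random(60)
            labels = rng.integers(0, 2, size=60)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            m = compute_metrics(scores, labels, threshold=0.4)
            hand = hand_confusion_metrics(scores, labels, 0.4)
            for key, val in hand.items():
                assert getattr(m, key) == pytest.approx(val, abs=1e-12)

    def test_no_predicted_positives_convention(self):
        with pytest.warns(UserWarning, match="PRE and F1"):
            m = compute_metrics([0.1, 0.2, 0.3], [0, 1, 0], threshold=0.9)
        assert m.PRE == 0.0 and m.F1 == 0.0

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            compute_metrics([0.1, 0.9], [1, 1])


class TestEvaluateFold:
    def test_evaluation_set_accounting(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        plan = five_fold_split(ds, seed=4)[0]
        scores, labels, pairs = evaluate_fold(plan, ds, fam.Z, SS, tiny_pipeline)
        assert len(scores) == ds.m * ds.n - plan.A_train.sum()
        assert labels.sum() == len(plan.held_out)
        held = set(map(tuple, plan.held_out.tolist()))
        flagged = {tuple(p) for p, l in zip(pairs.tolist(), labels) if l == 1}
        assert flagged == held

    def test_held_out_score_above_background(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        plan = five_fold_split(ds, seed=5)[0]
        scores, labels, _ = evaluate_fold(plan, ds, fam.Z, SS, tiny_pipeline)
        assert scores[labels == 1].mean() > scores[labels == 0].mean()


class TestRunCV:
    def test_smoke_and_determinism(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        r1 = run_cv(ds, fam.Z, SS, tiny_pipeline, runs=1, master_seed=9)
        r2 = run_cv(ds, fam.Z, SS, tiny_pipeline, runs=1, master_seed=9)
        assert r1.mean() == r2.mean()
        for value in r1.mean().values():
            assert 0.0 <= value <= 1.0

    def test_std_computed_over_runs(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        res = run_cv(ds, fam.Z, SS, tiny_pipeline, runs=2, master_seed=1)
        assert len(res.per_run) == 2
        assert all(v >= 0 for v in res.std().values())


class TestRemoveAssociations:
    def test_removed_count(self, small_data):
        ds = small_data[0]
        total = ds.n_associations
        reduced, removed = remove_associations(ds, 0.2, seed=0)
        assert len(removed) == round(0.2 * total)
        assert reduced.n_associations == total - len(removed)

    def test_fraction_zero_identity(self, small_data):
        ds = small_data[0]
        reduced, removed = remove_associations(ds, 0.0, seed=0)
        assert len(removed) == 0
        assert (reduced.A == ds.A).all()

    def test_bad_fraction(self, small_data):
        with pytest.raises(ValueError):
            remove_associations(small_data[0], 1.0, seed=0)


class TestRecovery:
    def test_oracle_scorer_full_recall(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        res = recovery_experiment(
            ds, fam.Z, SS, tiny_pipeline, fraction=0.1, master_seed=0,
            scorer=lambda i, j: 1.0,
        )
        assert res["recall"] == 1.0

    def test_zero_scorer_no_recall(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        res = recovery_experiment(
            ds, fam.Z, SS, tiny_pipeline, fraction=0.1, master_seed=0,
            scorer=lambda i, j: 0.0,
        )
        assert res["recall"] == 0.0

    def test_model_recovery_returns_score_sets(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        res = recovery_experiment(ds, fam.Z, SS, tiny_pipeline, fraction=0.1, master_seed=0)
        assert res["n_removed"] == len(res["removed_scores"])
        assert 0.0 <= res["recall"] <= 1.0


class TestPerDisease:
    def test_top_ranked_disease_gets_unit_aupr(self):
        pairs = np.array([[0, 0], [1, 0], [2, 0], [0, 1]])
        scores = np.array([0.9, 0.8, 0.1, 0.5])
        labels = np.array([1, 1, 0, 0])
        m = per_disease_metrics(scores, labels, pairs, disease_index=0)
        assert m.AUPR == 1.0

    def test_disease_without_positives_is_missing(self):
        pairs = np.array([[0, 0], [1, 0]])
        m = per_disease_metrics(np.array([0.2, 0.4]), np.array([0, 0]), pairs, 0)
        assert m is None

    def test_block_disease_matches_planted_signal(self, small_data, tiny_pipeline):
        ds, fam, _, truth, SS = small_data
        plan = five_fold_split(ds, seed=6)[0]
        scores, labels, pairs = evaluate_fold(plan, ds, fam.Z, SS, tiny_pipeline)
        aucs = []
        for j in range(ds.n):
            m = per_disease_metrics(scores, labels, pairs, j)
            if m is not None:
                aucs.append(m.AUC)
        assert np.mean(aucs) > 0.5  # block signal visible per disease


class TestRankCandidates:
    def test_k_zero_empty(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        assert rank_candidates(ds, fam.Z, SS, tiny_pipeline, k=0) == []

    def test_known_pairs_excluded_and_sorted(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        rows = rank_candidates(ds, fam.Z, SS, tiny_pipeline, k=20)
        known = set(ds.pairs())
        assert all((mirna, dis) not in known for mirna, dis, _ in rows)
        scores = [s for _, _, s in rows]
        assert scores == sorted(scores, reverse=True)

    def test_withheld_association_ranks_high(self, tiny_pipeline):
        # strong-signal data (p_in=0.9) leaves few unknown within-block
        # cells, so a withheld planted association must surface near the
        # top of the candidate list
        from nemii.disease_similarity import similarity_matrix
        from nemii.synthetic import SyntheticConfig, generate_dataset

        ds, fam, onto, truth = generate_dataset(
            SyntheticConfig(m=30, n=20, t=3, n_blocks=3, p_in=0.9, p_out=0.01, seed=8)
        )
        SS = similarity_matrix(ds.disease_ids, onto).SS
        i, j = next(
            (i, j)
            for i, j in np.column_stack(np.nonzero(ds.A))
            if truth.mirna_block[i] == truth.disease_block[j]
        )
        A = ds.A.copy()
        A[i, j] = 0
        reduced = AssociationDataset(list(ds.mirna_ids), list(ds.disease_ids), A)
        rows = rank_candidates(reduced, fam.Z, SS, tiny_pipeline, k=ds.m * ds.n)
        target = (ds.mirna_ids[i], ds.disease_ids[j])
        position = [(mi, di) for mi, di, _ in rows].index(target)
        assert position < 0.05 * len(rows)

    def test_disease_restriction(self, small_data, tiny_pipeline):
        ds, fam, _, _, SS = small_data
        disease = ds.disease_ids[0]
        rows = rank_candidates(ds, fam.Z, SS, tiny_pipeline, k=5, disease=disease)
        assert all(dis == disease for _, dis, _ in rows)
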