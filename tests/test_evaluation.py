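import numpy as np
import pytest

from lncpi.evaluation import (
    CVScheme,
    RankMode,
    compute_metrics,
    fit_stack,
    labeled_pairs,
    make_splits,
    rank_for_entity,
    run_experiment,
    sample_negatives,
)
from lncpi.io_formats import InteractionMatrix
from lncpi.sequence_features import (
    build_pair_matrix,
    encode_lncrna_set,
    encode_protein_set,
)


def _matrix(rng, n_l=8, n_p=6, density=0.3):
    Y = (rng.random((n_l, n_p)) < density).astype(int)
    Y[0, 0] = 1  # at least one positive
    return InteractionMatrix(
        [f"l{i}" for i in range(n_l)], [f"p{j}" for j in range(n_p)], Y
    )


def pairwise_auc(y_true, scores):
    """O(n^2) oracle: P(random positive outranks random negative), ties 1/2."""
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSampleNegatives:
    def test_count_and_disjointness(self, rng):
        Y = _matrix(rng)
        n_pos = int(Y.Y.sum())
        negs = sample_negatives(Y, 1.0, seed=3)
        assert len(negs) == n_pos
        assert set(negs).isdisjoint(set(Y.positive_pairs()))
        assert len(set(negs)) == len(negs)

    def test_reproducible(self, rng):
        Y = _matrix(rng)
        assert sample_negatives(Y, 1.0, seed=5) == sample_negatives(Y, 1.0, seed=5)

    def test_uniform_over_zero_cells(self):
        Y = InteractionMatrix(
            ["l0", "l1", "l2"], ["p0", "p1", "p2"], np.eye(3, dtype=int)[:, ::-1] * 0
        )
        Y.Y[0, 0] = 1
        counts = {}
        for seed in range(1000):
            ((l, p),) = sample_negatives(Y, 1.0, seed=seed)
            counts[(l, p)] = counts.get((l, p), 0) + 1
        freqs = np.array(list(counts.values())) / 1000
        assert len(counts) == 8
        assert (np.abs(freqs - 0.125) <= 0.04).all()

    def test_insufficient_zeros_raises(self):
        Y = InteractionMatrix(["l0"], ["p0", "p1"], np.array([[1, 1]]))
        with pytest.raises(ValueError):
            sample_negatives(Y, 1.0, seed=0)


class TestMakeSplits:
    def test_cv_l_partitions_entities(self, rng):
        Y = _matrix(rng, n_l=10, n_p=4)
        pairs = labeled_pairs(Y, sample_negatives(Y, 1.0, seed=0))
        splits = make_splits(CVScheme.CV_L, Y, pairs, 5, seed=1)
        held = [set(p[0] for p in s.test_pairs) for s in splits]
        test_sets = []
        for s in splits:
            test_lncs = {p[0] for p in s.test_pairs}
            train_lncs = {p[0] for p in s.train_pairs}
            assert test_lncs.isdisjoint(train_lncs)
            test_sets.append(frozenset(test_lncs))
        # folds partition the lncRNA set: disjoint, union covers all with pairs
        for a in range(5):
            for b in range(a + 1, 5):
                assert held[a].isdisjoint(held[b])
        assert len(splits) == 5

    def test_cv_lp_partitions_pairs(self, rng):
        Y = _matrix(rng)
        pairs = labeled_pairs(Y, sample_negatives(Y, 1.0, seed=0))
        splits = make_splits(CVScheme.CV_LP, Y, pairs, 5, seed=2)
        all_test = [p for s in splits for p in s.test_pairs]
        assert sorted(all_test) == sorted(pairs)
        for s in splits:
            assert sorted(s.train_pairs + s.test_pairs) == sorted(pairs)

    def test_cv_ind_toy_counts(self):
        """5x5 complete bipartite, 1 test lncRNA and 1 test protein."""
        Y = InteractionMatrix(
            [f"l{i}" for i in range(5)],
            [f"p{j}" for j in range(5)],
            np.ones((5, 5), dtype=int),
        )
        pairs = [(l, p, 1) for l in Y.lnc_ids for p in Y.prot_ids]
        splits = make_splits(CVScheme.CV_IND, Y, pairs, 5, seed=0)
        for s in splits:
            assert len(s.train_pairs) == 16
            assert len(s.test_pairs) == 1
            discarded = 25 - len(s.train_pairs) - len(s.test_pairs)
            assert discarded == 8

    @pytest.mark.parametrize(
        "scheme", [CVScheme.CV_L, CVScheme.CV_P, CVScheme.CV_IND]
    )
    def test_leakage_audit_random_instances(self, scheme):
        """Node-disjointness invariant holds on 100 random instances."""
        for instance in range(100):
            rng = np.random.default_rng(instance)
            Y = _matrix(rng, n_l=int(rng.integers(6, 12)), n_p=int(rng.integers(6, 12)))
            pairs = labeled_pairs(Y, sample_negatives(Y, 1.0, seed=instance))
            splits = make_splits(scheme, Y, pairs, 5, seed=instance)
            for s in splits:
                train_l = {p[0] for p in s.train_pairs}
                train_p = {p[1] for p in s.train_pairs}
                test_l = {p[0] for p in s.test_pairs}
                test_p = {p[1] for p in s.test_pairs}
                if scheme is CVScheme.CV_L:
                    assert train_l.isdisjoint(test_l)
                elif scheme is CVScheme.CV_P:
                    assert train_p.isdisjoint(test_p)
                else:
                    assert train_l.isdisjoint(test_l)
                    assert train_p.isdisjoint(test_p)

    def test_too_few_entities_raises(self, rng):
        Y = _matrix(rng, n_l=3, n_p=6)
        pairs = labeled_pairs(Y, sample_negatives(Y, 1.0, seed=0))
        with pytest.raises(ValueError):
            make_splits(CVScheme.CV_L, Y, pairs, 5, seed=0)


class TestComputeMetrics:
    def test_perfect_ranking(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.2, 0.1])
        m = compute_metrics(y, s)
        assert m.auc == 1.0 and m.aupr == pytest.approx(1.0)
        assert m.precision == m.recall == m.accuracy == m.f1 == 1.0

    def test_constant_scores_tie_rule(self):
        m = compute_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.7))
        assert m.auc == 0.5

    def test_worked_auc_example(self):
        m = compute_metrics(
            np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.4, 0.1])
        )
        assert m.auc == pytest.approx(0.75)

    def test_no_positive_predictions_zero_precision_f1(self):
        m = compute_metrics(np.array([1, 0]), np.array([0.2, 0.1]))
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(4), np.linspace(0, 1, 4))

    def test_auc_matches_pairwise_oracle(self):
        """Tie-aware AUC equals the O(n^2) comparison count."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 200))
            y = rng.choice([0, 1], size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # forces ties
            m = compute_metrics(y, scores)
            assert m.auc == pytest.approx(pairwise_auc(y, scores), abs=1e-12)

    def test_f1_is_harmonic_mean(self, rng):
        y = rng.choice([0, 1], size=100)
        s = rng.random(100)
        m = compute_metrics(y, s)
        if m.precision + m.recall > 0:
            expected = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert m.f1 == pytest.approx(expected)


class TestRunExperiment:
    def test_deterministic_given_seed(self, small_dataset, fast_config):
        lnc, prot, Y, _ = small_dataset
        r1 = run_experiment(lnc, prot, Y, CVScheme.CV_LP, fast_config, seed=4)
        r2 = run_experiment(lnc, prot, Y, CVScheme.CV_LP, fast_config, seed=4)
        assert r1.table.equals(r2.table)
        assert r1.mean.auc > 0.5  # sanity: learns something on motif data

    def test_cv_ind_no_endpoint_leakage(self, small_dataset, fast_config):
        lnc, prot, Y, _ = small_dataset
        # audit the splits the driver would use, over repeats
        from lncpi.evaluation import sample_negatives as sn

        for repeat in range(3):
            pairs = labeled_pairs(Y, sn(Y, 1.0, seed=repeat))
            for s in make_splits(CVScheme.CV_IND, Y, pairs, 3, seed=repeat):
                train_nodes = {p[0] for p in s.train_pairs} | {
                    p[1] for p in s.train_pairs
                }
                for l, p, _ in s.test_pairs:
                    assert l not in train_nodes and p not in train_nodes

    def test_standard_error_shrinks_with_repeats(self, small_dataset, fast_config):
        lnc, prot, Y, _ = small_dataset
        r5 = run_experiment(lnc, prot, Y, CVScheme.CV_LP, fast_config, n_repeats=2, seed=9)
        r20 = run_experiment(lnc, prot, Y, CVScheme.CV_LP, fast_config, n_repeats=6, seed=9)
        se5 = r5.repeat_means["auc"].std(ddof=1) / np.sqrt(len(r5.repeat_means))
        se20 = r20.repeat_means["auc"].std(ddof=1) / np.sqrt(len(r20.repeat_means))
        assert se20 <= se5


class TestRanking:
    def test_ranked_partners_flag_known_edges(self, small_dataset, fast_config):
        lnc, prot, Y, _ = small_dataset
        lf = encode_lncrna_set(lnc)
        pf = encode_protein_set(prot)
        negs = sample_negatives(Y, 1.0, seed=2)
        pairs = labeled_pairs(Y, negs)
        X = build_pair_matrix(lf, pf, [(p[0], p[1]) for p in pairs])
        y = np.array([p[2] for p in pairs])
        stack = fit_stack(X, y, fast_config, seed=2)
        ranking = rank_for_entity(
            stack, lf, pf, Y.lnc_ids[0], RankMode.PROTEINS_FOR_LNCRNA, Y
        )
        assert len(ranking) == len(Y.prot_ids)
        known = {(l, p) for l, p, s, k in ranking if k}
        assert known == {
            (Y.lnc_ids[0], p)
            for j, p in enumerate(Y.prot_ids)
            if Y.Y[0, j]
        }

    def test_unknown_entity_raises(self, small_dataset, fast_config):
        lnc, prot, Y, _ = small_dataset
        lf = encode_lncrna_set(lnc)
        pf = encode_protein_set(prot)
        with pytest.raises(KeyError):
            rank_for_entity(None, lf, pf, "nope", RankMode.PROTEINS_FOR_LNCRNA, Y)
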