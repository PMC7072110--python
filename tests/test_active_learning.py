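"""Committee disagreement, query selection and the annotation loop."""

import dataclasses
import itertools

import numpy as np
import pytest

from boneal import active_learning as al
from boneal import phantoms as ph
from boneal.preprocessing import standardize
from boneal.unet import UNetConfig

SMALL_NET = UNetConfig(depth=2, base_filters=2, input_size=(32, 32), seed=0, batch_size=4)


def _prep_pool(n, seed, shape=(32, 32)):
    recs = ph.generate_records(n, seed=seed, shape=shape)
    return [(r.id, standardize(r.image).pixels.astype(np.float32), r.mask) for r in recs]


class TestCosine:
    def test_self_similarity(self):
        v = np.array([3.0, -1.0, 2.0])
        assert al.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert al.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_45_degrees(self):
        assert al.cosine_similarity([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(al.DegenerateVectorError):
            al.cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            al.cosine_similarity([1.0], [1.0, 2.0])


class TestDisagreement:
    def test_identical_vectors_score_one(self):
        v = np.array([1.0, 2.0])
        assert al.pairwise_similarity_score([v, v, v]) == pytest.approx(1.0)

    def test_hand_computed_three_member_mean(self):
        vs = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 0.0])]
        # pairwise sims {0, 1, 0} -> mean 1/3
        assert al.pairwise_similarity_score(vs) == pytest.approx(1 / 3)

    def test_min_aggregate(self):
        vs = [np.array([1.0, 0.0]), np.array([0.0, 1.0]), np.array([1.0, 0.0])]
        assert al.pairwise_similarity_score(vs, aggregate="min") == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_matches_brute_force_over_pairs(self, k, rng):
        for _ in range(20):
            vs = [rng.standard_normal(6) for _ in range(k)]
            sims = [
                al.cosine_similarity(a, b) for a, b in itertools.combinations(vs, 2)
            ]
            assert al.pairwise_similarity_score(vs) == pytest.approx(np.mean(sims), abs=1e-12)
            assert -1.0 <= al.pairwise_similarity_score(vs) <= 1.0

    def test_single_member_rejected(self):
        with pytest.raises(al.ConfigurationError):
            al.pairwise_similarity_score([np.ones(3)])


class TestSelectQueries:
    def test_lowest_scores_selected_in_order(self):
        scores = {"a": 0.9, "b": 0.2, "c": 0.5}
        assert al.select_queries(scores, 2) == ["b", "c"]

    def test_batch_equals_pool(self):
        scores = {"a": 0.9, "b": 0.2, "c": 0.5}
        assert al.select_queries(scores, 3) == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        scores = {"d": 0.5, "b": 0.5, "a": 0.5, "c": 0.5}
        assert al.select_queries(scores, 2) == ["a", "b"]

    def test_matches_sort_oracle(self, rng):
        ids = [f"i{j:02d}" for j in range(30)]
        scores = {i: float(rng.choice([0.1, 0.5, 0.9])) for i in ids}
        expected = sorted(ids, key=lambda i: (scores[i], i))[:7]
        assert al.select_queries(scores, 7) == expected

    def test_empty_pool_rejected(self):
        with pytest.raises(al.ConfigurationError):
            al.select_queries({}, 1)


class TestCommittee:
    def test_member_seeds_distinct_and_derived_from_master(self):
        c = al.build_committee(SMALL_NET, k=3, master_seed=10)
        assert c.member_seeds == [10, 11, 12]
        assert len({m.config.seed for m in c.members}) == 3

    def test_duplicate_seeds_rejected(self):
        c = al.build_committee(SMALL_NET, k=2, master_seed=0)
        with pytest.raises(al.ConfigurationError):
            al.Committee(members=c.members, member_seeds=[5, 5])


@pytest.fixture(scope="module")
def small_run():
    pool = _prep_pool(30, seed=21)
    labeled = al.LabeledPool(items=list(pool[:6]))
    unlabeled = al.UnlabeledPool(items=[(i, x) for i, x, _ in pool[6:]])
    oracle = al.GroundTruthOracle({i: m for i, _, m in pool})
    cfg = al.ALConfig(k=2, initial_labeled=6, queries_per_epoch=3, query_epochs=4,
                      post_epochs=2, master_seed=5)
    committee, history = al.run_active_learning(labeled, unlabeled, oracle, cfg, SMALL_NET)
    return pool, labeled, unlabeled, committee, history, cfg


class TestALLoop:
    def test_labeled_size_accounting(self, small_run):
        _, labeled, _, _, history, cfg = small_run
        for rec in history.epochs:
            expected = cfg.initial_labeled + cfg.queries_per_epoch * min(rec.epoch, cfg.query_epochs)
            assert rec.labeled_size == expected
        assert len(labeled) == 18

    def test_pool_conservation_and_disjointness(self, small_run):
        pool, labeled, unlabeled, _, _, _ = small_run
        assert len(labeled) + len(unlabeled) == len(pool)
        assert not (labeled.ids & unlabeled.ids)

    def test_oracle_call_count(self, small_run):
        _, _, _, _, history, cfg = small_run
        assert history.oracle_calls == cfg.queries_per_epoch * cfg.query_epochs

    def test_provenance_records_query_epoch(self, small_run):
        _, labeled, _, _, history, _ = small_run
        for rec in history.epochs:
            for qid in rec.queried_ids:
                assert labeled.provenance[qid] == f"queried-at-epoch-{rec.epoch}"

    def test_queried_scores_are_the_ascending_minima(self, small_run):
        _, _, _, _, history, _ = small_run
        for rec in history.epochs:
            assert list(rec.queried_scores) == sorted(rec.queried_scores)

    def test_first_epoch_queries_replay_exactly(self, small_run):
        """Reproduce epoch 1 (same seeds) and re-derive its query set."""
        pool, _, _, _, history, cfg = small_run
        committee = al.build_committee(SMALL_NET, cfg.k, cfg.master_seed)
        items = [(x, m) for _, x, m in pool[:6]]
        for member in committee.members:
            member.train_epoch(items)
        unlabeled = al.UnlabeledPool(items=[(i, x) for i, x, _ in pool[6:]])
        scores = al.score_unlabeled(committee, unlabeled, cfg.aggregate)
        assert tuple(al.select_queries(scores, cfg.queries_per_epoch)) == history.epochs[0].queried_ids

    def test_pool_size_mismatch_rejected(self):
        pool = _prep_pool(8, seed=1)
        labeled = al.LabeledPool(items=list(pool[:3]))
        unlabeled = al.UnlabeledPool(items=[(i, x) for i, x, _ in pool[3:]])
        cfg = al.ALConfig(k=2, initial_labeled=5, queries_per_epoch=1, query_epochs=1, post_epochs=0)
        with pytest.raises(al.ConfigurationError):
            al.run_active_learning(labeled, unlabeled, al.GroundTruthOracle({}), cfg, SMALL_NET)

    def test_degenerate_schedule_is_plain_supervised_training(self):
        pool = _prep_pool(8, seed=2)
        labeled = al.LabeledPool(items=list(pool[:4]))
        unlabeled = al.UnlabeledPool(items=[(i, x) for i, x, _ in pool[4:]])

        class FailingOracle:
            def annotate(self, image_id):
                raise AssertionError("oracle must not be called")

        cfg = al.ALConfig(k=2, initial_labeled=4, queries_per_epoch=1, query_epochs=0,
                          post_epochs=2, master_seed=0)
        committee, history = al.run_active_learning(labeled, unlabeled, FailingOracle(), cfg, SMALL_NET)
        assert history.oracle_calls == 0
        assert len(history.epochs) == 2
        assert all(m.trained_epochs == 2 for m in committee.members)

    def test_exhausted_pool_stops_querying_and_keeps_training(self):
        pool = _prep_pool(10, seed=3)
        labeled = al.LabeledPool(items=list(pool[:4]))
        unlabeled = al.UnlabeledPool(items=[(i, x) for i, x, _ in pool[4:]])
        oracle = al.GroundTruthOracle({i: m for i, _, m in pool})
        cfg = al.ALConfig(k=2, initial_labeled=4, queries_per_epoch=4, query_epochs=3,
                          post_epochs=1, master_seed=0)
        committee, history = al.run_active_learning(labeled, unlabeled, oracle, cfg, SMALL_NET)
        assert history.oracle_calls == 6  # all unlabeled items, then nothing left
        assert len(unlabeled) == 0
        assert len(history.epochs) == 4
        assert all(m.trained_epochs == 4 for m in committee.members)

    def test_oracle_failure_aborts_with_the_id(self):
        pool = _prep_pool(8, seed=4)
        labeled = al.LabeledPool(items=list(pool[:4]))
        unlabeled = al.UnlabeledPool(items=[(i, x) for i, x, _ in pool[4:]])
        cfg = al.ALConfig(k=2, initial_labeled=4, queries_per_epoch=1, query_epochs=1, post_epochs=0)
        with pytest.raises(al.OracleError, match="ph000"):
            al.run_active_learning(labeled, unlabeled, al.GroundTruthOracle({}), cfg, SMALL_NET)


class TestFSLBaseline:
    def test_seeded_subset_reproducible(self):
        pool = _prep_pool(12, seed=6)
        labeled = al.LabeledPool(items=list(pool))
        a = al.run_fully_supervised_baseline(labeled, SMALL_NET, epochs=2, budget=6, seed=3)
        b = al.run_fully_supervised_baseline(labeled, SMALL_NET, epochs=2, budget=6, seed=3)
        img = pool[0][1]
        assert np.array_equal(a.predict_probability_map(img), b.predict_probability_map(img))

    def test_zero_epochs_returns_untrained_model(self):
        pool = _prep_pool(4, seed=7)
        labeled = al.LabeledPool(items=list(pool))
        model = al.run_fully_supervised_baseline(labeled, SMALL_NET, epochs=0)
        assert model.trained_epochs == 0
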