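"""The M-training loop: voting, noise bounds, sub-sampling, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtraining import (ClassifierSpec, EnsembleConfig, LabeledSet, MTrainingClassifier,
                       PseudoLabeledSet, UnlabeledSet, estimate_error, init_ensemble,
                       noise_rate, predict_ensemble, propose_labels, refine, run,
                       should_update, subsample, utility_u)
from mtraining.ensemble import ClassifierSlot, _slot_rng

from conftest import make_labeled, make_unlabeled

NC = ClassifierSpec("nearest_centroid")


class FixedPredictor:
    """Stub model that looks predictions up by sample position."""

    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype=object)

    def predict(self, X):
        return self.labels[: len(X)]


def stub_slots(vote_rows, pool):
    return [ClassifierSlot(index=i, initial_pool=pool, model=FixedPredictor(row))
            for i, row in enumerate(vote_rows)]


# ---------------------------------------------------------------------------
# should_update / noise arithmetic
# ---------------------------------------------------------------------------

class TestShouldUpdate:
    def test_subsample_branch_worked_example(self):
        d = should_update(e_t=0.1, e_prev=0.2, size_t=30, size_prev=10)
        assert d.kind == "update_after_subsample"
        assert d.s_i == 19
        # the returned size restores the noise product and still grows
        assert 0.1 * d.s_i < 0.2 * 10
        assert d.s_i > 10

    def test_error_increase_skips(self):
        assert should_update(0.3, 0.2, 30, 10).kind == "skip"
        assert should_update(0.2, 0.2, 30, 10).kind == "skip"

    def test_product_condition_updates(self):
        d = should_update(e_t=0.05, e_prev=0.2, size_t=30, size_prev=10)
        assert d.kind == "update"  # 0.05*30 = 1.5 < 2 = 0.2*10

    def test_bootstrap_virtual_previous_size(self):
        # first productive round: size_prev=0 bootstraps to floor(e/(e_prev-e))+1
        d = should_update(e_t=0.2, e_prev=0.5, size_t=2, size_prev=0)
        assert d.kind == "update_with_bootstrap_prev"
        assert d.virtual_size_prev == 1
        assert d.s_i is None  # 0.2*2 = 0.4 < 0.5*1
        d2 = should_update(e_t=0.2, e_prev=0.5, size_t=100, size_prev=0)
        assert d2.kind == "update_with_bootstrap_prev"
        assert d2.s_i == 2  # ceil(0.5*1/0.2 - 1)

    def test_zero_measured_noise_updates_without_division(self):
        d = should_update(e_t=0.0, e_prev=0.2, size_t=500, size_prev=10)
        assert d.is_update and d.s_i is None

    def test_no_pseudo_labels_skips(self):
        assert should_update(0.1, 0.5, 0, 0).kind == "skip"

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(e_t=st.floats(0, 0.5), e_prev=st.floats(0, 0.5),
           size_t=st.integers(0, 500), size_prev=st.integers(0, 200))
    def test_subsample_size_always_restores_product(self, e_t, e_prev, size_t, size_prev):
        d = should_update(e_t, e_prev, size_t, size_prev)
        if d.s_i is not None:
            prev = d.virtual_size_prev if d.virtual_size_prev is not None else size_prev
            assert e_t * d.s_i < e_prev * prev
            assert d.s_i > prev
            assert d.s_i < size_t


def test_noise_rate_examples():
    assert noise_rate(0.0, 100, 0.0, 50) == 0.0
    assert noise_rate(0.0, 100, 0.1, 50) == pytest.approx(5 / 150)
    assert noise_rate(0.07, 80, 0.3, 0) == pytest.approx(0.07)
    with pytest.raises(ValueError):
        noise_rate(0.0, 0, 0.1, 0)


def test_utility_examples_and_compound_identity():
    assert utility_u(123, 0.5) == 0.0
    assert utility_u(100, 0.0) == 100.0
    rng = np.random.default_rng(0)
    for _ in range(50):
        nL, nP = rng.integers(1, 200, size=2)
        eta_L, e = rng.uniform(0, 0.5, size=2)
        eta = noise_rate(eta_L, nL, e, nP)
        m = nL + nP
        # expanded bound form equals utility_u of the combined noise rate
        direct = m * (1 - 2 * (eta_L * nL + e * nP) / m) ** 2
        assert utility_u(m, eta) == pytest.approx(direct)


# ---------------------------------------------------------------------------
# Committee voting
# ---------------------------------------------------------------------------

class TestProposeLabels:
    def setup_method(self):
        self.pool = make_labeled(n_per_class=5, n_classes=3, labels=("1", "2", "3"))
        self.U = make_unlabeled(n=1)

    def test_majority_of_three_co_votes_accepted(self):
        # M=4: co-votes {1, 2, 1} on one sample -> accepted as "1", share 2/3
        slots = stub_slots([["9"], ["1"], ["2"], ["1"]], self.pool)
        pseudo = propose_labels(0, slots, self.U, 2 / 3, classes=("1", "2", "9"))
        assert len(pseudo) == 1
        assert pseudo.labels[0] == "1"
        assert pseudo.agreement[0] == pytest.approx(2 / 3)

    def test_tri_training_disagreement_rejected(self):
        # M=3: co-votes {1, 2} -> max share 1/2 < 2/3 -> rejected
        slots = stub_slots([["9"], ["1"], ["2"]], self.pool)
        pseudo = propose_labels(0, slots, self.U, 2 / 3, classes=("1", "2", "9"))
        assert len(pseudo) == 0

    def test_identical_constant_committee_accepts_everything(self):
        U = make_unlabeled(n=17)
        slots = stub_slots([["2"] * 17] * 5, self.pool)
        pseudo = propose_labels(2, slots, U, 1.0, classes=("1", "2"))
        assert len(pseudo) == 17
        assert set(pseudo.labels) == {"2"}
        assert np.all(pseudo.agreement == 1.0)

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(11)
        U = make_unlabeled(n=40)
        votes = rng.choice(["a", "b", "c"], size=(5, 40))
        slots = stub_slots(list(votes), self.pool)
        sizes = []
        for theta in (0.51, 0.6, 2 / 3, 0.75, 0.9, 1.0):
            sizes.append(len(propose_labels(1, slots, U, theta, classes=("a", "b", "c"))))
        assert sizes == sorted(sizes, reverse=True)


class TestEstimateError:
    def test_perfect_committee(self):
        L = make_labeled(n_per_class=6, n_classes=2, labels=("a", "b"))
        slots = stub_slots([L.y, L.y, L.y], L)
        e, ok = estimate_error(0, slots, L, 2 / 3)
        assert ok and e == 0.0

    def test_hand_counted_fixture(self):
        # 10 samples, truth all "a"; committee of 2 (M=3) agrees on 6,
        # and 2 of the agreed labels are wrong -> e = 2/6
        truth = np.array(["a"] * 10, dtype=object)
        L = LabeledSet(np.array([f"s{i}" for i in range(10)], dtype=object),
                       np.arange(20, dtype=float).reshape(10, 2), truth)
        c1 = ["a", "a", "a", "a", "b", "b", "a", "b", "a", "b"]
        c2 = ["a", "a", "a", "a", "b", "b", "b", "a", "b", "a"]
        # agreement on indices 0-5; wrong agreed labels at 4, 5
        slots = stub_slots([["a"] * 10, c1, c2], L)
        e, ok = estimate_error(0, slots, L, 2 / 3, classes=("a", "b"))
        assert ok and e == pytest.approx(2 / 6)

    def test_no_agreement_falls_back(self):
        truth = np.array(["a", "b"] * 3, dtype=object)
        L = LabeledSet(np.array([f"s{i}" for i in range(6)], dtype=object),
                       np.arange(12, dtype=float).reshape(6, 2), truth)
        slots = stub_slots([["a"] * 6, ["a"] * 6, ["b"] * 6], L)
        e, ok = estimate_error(0, slots, L, theta=1.0)
        assert not ok and e == 0.5


# ---------------------------------------------------------------------------
# subsample / refine / init
# ---------------------------------------------------------------------------

def make_pseudo(n, n_features=4, prefix="p", round_t=1):
    rng = np.random.default_rng(3)
    return PseudoLabeledSet(
        ids=np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        X=rng.normal(size=(n, n_features)),
        labels=np.array([["a", "b"][i % 2] for i in range(n)], dtype=object),
        agreement=np.full(n, 1.0), round=round_t)


class TestSubsample:
    def test_exact_size_and_membership(self):
        pseudo = make_pseudo(30)
        out = subsample(pseudo, 19, _slot_rng(0, 9))
        assert len(out) == 19
        assert set(out.ids) <= set(pseudo.ids)

    def test_drop_one(self):
        out = subsample(make_pseudo(5), 4, _slot_rng(1, 1))
        assert len(out) == 4

    def test_deterministic(self):
        a = subsample(make_pseudo(30), 10, _slot_rng(7, 2, 3))
        b = subsample(make_pseudo(30), 10, _slot_rng(7, 2, 3))
        assert list(a.ids) == list(b.ids)

    def test_bad_size_is_caller_bug(self):
        with pytest.raises(ValueError):
            subsample(make_pseudo(5), 5, _slot_rng(0, 0))


class TestInitEnsemble:
    @pytest.mark.parametrize("n,expected", [(198, 149), (99, 74), (297, 223)])
    def test_pool_sizes_round_half_up(self, n, expected):
        L = make_labeled(n_per_class=n // 3, n_classes=3)
        assert len(L) == n
        slots = init_ensemble(L, EnsembleConfig(M=4, base_spec=NC, seed=0))
        for s in slots:
            assert len(s.initial_pool) == expected

    def test_init_fraction_one_shares_full_pool(self):
        L = make_labeled(n_per_class=8, n_classes=3)
        cfg = EnsembleConfig(M=3, init_fraction=1.0, base_spec=NC)
        slots = init_ensemble(L, cfg)
        for s in slots:
            assert sorted(s.initial_pool.ids) == sorted(L.ids)

    def test_every_pool_covers_every_class(self):
        L = make_labeled(n_per_class=4, n_classes=3)
        cfg = EnsembleConfig(M=6, init_fraction=0.4, base_spec=NC, seed=5)
        for s in init_ensemble(L, cfg):
            assert len(s.initial_pool.class_counts()) == 3
            assert s.e_prev == 0.5 and s.size_prev == 0


class TestRefine:
    def test_pool_union_counts(self):
        L = make_labeled(n_per_class=50, n_classes=3, labels=("a", "b", "c"))
        slot = ClassifierSlot(0, L.subset(np.arange(149)),
                              model=None)
        pseudo = make_pseudo(454)
        refine(slot, pseudo, e_t=0.1, base_spec=NC)
        assert slot.current_pool_size == 603
        assert slot.e_prev == 0.1 and slot.size_prev == 454 and slot.changed

    def test_duplicate_ids_deduplicated_labeled_wins(self):
        L = make_labeled(n_per_class=10, n_classes=2, labels=("a", "b"))
        slot = ClassifierSlot(0, L, model=None)
        dup = PseudoLabeledSet(ids=L.ids[:3].copy(), X=L.X[:3] + 100,
                               labels=np.array(["b", "b", "b"], dtype=object),
                               agreement=np.ones(3), round=1)
        refine(slot, dup, e_t=0.2, base_spec=NC)
        assert slot.current_pool_size == len(L)  # nothing added


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------

class TestRun:
    def test_empty_U_fixed_point_round_one(self):
        L = make_labeled(n_per_class=10, n_classes=3)
        U = UnlabeledSet.empty(4)
        cfg = EnsembleConfig(M=4, base_spec=NC, seed=0)
        slots, hist = run(L, U, cfg)
        assert hist.n_rounds == 1
        assert hist.termination_reason == "fixed_point"
        assert all(r["decision"] == "skip" for r in hist.records)
        fresh = init_ensemble(L, cfg)
        probe = make_unlabeled(n=25, seed=42).X
        np.testing.assert_array_equal(
            predict_ensemble(slots, probe, L.label_set),
            predict_ensemble(fresh, probe, L.label_set))

    def test_noise_guard_holds_at_every_refine(self):
        L = make_labeled(n_per_class=20, n_classes=3, sep=2.0, seed=6)
        U = make_unlabeled(n=80, seed=7)
        slots, hist = run(L, U, EnsembleConfig(M=4, base_spec=NC, seed=1))
        executed = [r for r in hist.records if r["decision"] != "skip"]
        assert executed, "fixture produced no refinement at all"
        for r in executed:
            prev = r["virtual_size_prev"] if r["virtual_size_prev"] is not None else r["size_prev"]
            assert r["e_t"] * r["size_t"] < r["e_prev"] * prev

    def test_determinism_identical_histories(self):
        L = make_labeled(n_per_class=15, n_classes=3, sep=2.5, seed=2)
        U = make_unlabeled(n=60, seed=3)
        cfg = EnsembleConfig(M=4, base_spec=NC, seed=11)
        _, h1 = run(L, U, cfg)
        _, h2 = run(L, U, cfg)
        assert h1.records == h2.records

    def test_terminates_within_max_rounds(self):
        L = make_labeled(n_per_class=12, n_classes=3, sep=1.0, seed=5)
        U = make_unlabeled(n=50, seed=6)
        cfg = EnsembleConfig(M=3, base_spec=NC, seed=2, max_rounds=4)
        _, hist = run(L, U, cfg)
        assert hist.n_rounds <= 4
        assert hist.termination_reason in ("fixed_point", "max_rounds")

    def test_history_jsonl_fields(self):
        L = make_labeled(n_per_class=10, n_classes=2)
        _, hist = run(L, UnlabeledSet.empty(4), EnsembleConfig(M=3, base_spec=NC))
        import json
        line = json.loads(hist.to_jsonl().splitlines()[0])
        for key in ("e_t", "size_t", "decision", "pool_before", "pool_after"):
            assert key in line


class TestTriTrainingEquivalence:
    """With M = 3 and theta = 2/3, acceptance reduces to the two
    co-classifiers agreeing — checked against a brute-force oracle."""

    def oracle(self, co_votes, U):
        keep = [j for j in range(len(U)) if co_votes[0][j] == co_votes[1][j]]
        return keep, [co_votes[0][j] for j in keep]

    @pytest.mark.parametrize("seed", range(10))
    def test_vote_level_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        U = make_unlabeled(n=n, seed=seed)
        pool = make_labeled(n_per_class=4, n_classes=3, labels=("a", "b", "c"))
        votes = rng.choice(["a", "b", "c"], size=(3, n))
        slots = stub_slots(list(votes), pool)
        pseudo = propose_labels(0, slots, U, 2 / 3, classes=("a", "b", "c"))
        keep, labels = self.oracle(votes[1:], U)
        assert list(pseudo.ids) == [U.ids[j] for j in keep]
        assert list(pseudo.labels) == labels

    def test_model_level_equivalence(self):
        L = make_labeled(n_per_class=10, n_classes=3, sep=2.0, seed=13)
        U = make_unlabeled(n=40, seed=14)
        cfg = EnsembleConfig(M=3, base_spec=NC, seed=3)
        slots = init_ensemble(L, cfg)
        for i in range(3):
            pseudo = propose_labels(i, slots, U, 2 / 3, classes=L.label_set)
            co = [s for s in slots if s.index != i]
            votes = [np.asarray(s.model.predict(U.X), dtype=object) for s in co]
            keep, labels = self.oracle(votes, U)
            assert list(pseudo.ids) == [U.ids[j] for j in keep]
            assert list(pseudo.labels) == labels


class TestPredictEnsemble:
    def test_plurality_and_ties(self):
        pool = make_labeled(n_per_class=3, n_classes=3, labels=("a", "b", "c"))
        X = np.zeros((1, 4))
        slots = stub_slots([["a"], ["a"], ["b"], ["c"]], pool)
        assert predict_ensemble(slots, X, ("a", "b", "c"))[0] == "a"
        slots = stub_slots([["a"], ["a"], ["b"], ["b"]], pool)
        assert predict_ensemble(slots, X, ("a", "b", "c"))[0] == "a"
        slots = stub_slots([["b"], ["b"], ["a"], ["a"]], pool)
        assert predict_ensemble(slots, X, ("a", "b", "c"))[0] == "a"

    def test_identical_models_equal_single_model(self):
        L = make_labeled(n_per_class=10, n_classes=3)
        cfg = EnsembleConfig(M=4, init_fraction=1.0, base_spec=NC)
        slots = init_ensemble(L, cfg)
        probe = make_unlabeled(n=20, seed=5).X
        single = np.asarray(slots[0].model.predict(probe), dtype=object)
        np.testing.assert_array_equal(
            predict_ensemble(slots, probe, L.label_set), single)


class TestSklearnFacade:
    def test_fit_predict_with_minus_one_unlabeled(self):
        L = make_labeled(n_per_class=20, n_classes=3, sep=4.0, seed=0)
        U = make_unlabeled(n=30, seed=1)
        X = np.vstack([L.X, U.X])
        y = np.concatenate([L.y, np.full(len(U), -1, dtype=object)])
        clf = MTrainingClassifier(n_classifiers=3, base_estimator="nearest_centroid",
                                  random_state=0)
        clf.fit(X, y)
        assert sorted(clf.classes_) == sorted(L.label_set)
        pred = clf.predict(L.X)
        assert set(pred) <= set(L.label_set)
        assert clf.n_rounds_ >= 1

    def test_get_set_params_clone(self):
        from sklearn.base import clone
        clf = MTrainingClassifier(n_classifiers=5, theta=0.75)
        c2 = clone(clf)
        assert c2.get_params()["n_classifiers"] == 5
        c2.set_params(theta=0.8)
        assert c2.theta == 0.8 and clf.theta == 0.75

    def test_config_validation(self):
        with pytest.raises(ValueError, match="M must be >= 3"):
            EnsembleConfig(M=2)
        with pytest.raises(ValueError, match="theta"):
            EnsembleConfig(theta=0.5)
        with pytest.raises(ValueError, match="theta"):
            EnsembleConfig(theta=1.2)
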