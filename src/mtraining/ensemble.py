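"""The M-training semi-supervised ensemble algorithm.

M-training generalizes tri-training to M >= 3 base classifiers.  Each
classifier c_i owns a diversified initial pool (a random 75% draw of the
labeled set L).  In every round, the committee C_i of the other M - 1
classifiers votes on every unlabeled sample; samples on which a single
label reaches an agreement fraction of at least theta are pseudo-labeled
for c_i.  A noise-compensation condition derived from the Angluin–Laird
bound m = sigma * xi^2 / (1 - 2*eta)^2 decides whether refitting on the
pseudo-labeled pool can improve c_i despite pseudo-label noise: writing
e_t for the committee's measured error and n_t = |L_i(t)|, an update is
safe when e_t * n_t < e_prev * n_prev, and otherwise the pseudo pool is
randomly sub-sampled to s_i = ceil(e_prev * n_prev / e_t - 1) entries
whenever n_prev > e_t / (e_prev - e_t), which makes the product condition
hold again.  The loop ends at a fixed point (a round in which no
classifier changes) or at a safety cap; prediction is a plurality vote
over all M classifiers, ties broken by the lowest label in sorted order.

With M = 3 and theta = 2/3 the acceptance rule degenerates exactly to
tri-training's "both co-classifiers agree".
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .base import ClassifierSpec, DEFAULT_SPEC, fit_classifier, predict_labels
from .data import LabeledSet, UnlabeledSet, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig", "ClassifierSlot", "PseudoLabeledSet", "Decision", "RunHistory",
    "init_ensemble", "propose_labels", "estimate_error", "should_update", "subsample",
    "refine", "run", "predict_ensemble", "noise_rate", "utility_u",
    "MTrainingClassifier",
]


# ---------------------------------------------------------------------------
# Configuration and state types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleConfig:
    """Parameters of one M-training run.

    theta is the agreement *fraction* over the M - 1 co-classifiers,
    constrained to (0.5, 1] so an accepted label is always the unique
    majority.  eta_L is the assumed label-noise rate of L (0 for a
    curated dataset).
    """

    M: int = 4
    theta: float = 2.0 / 3.0
    init_fraction: float = 0.75
    max_rounds: int = 50
    seed: int = 0
    base_spec: ClassifierSpec | BaseEstimator = DEFAULT_SPEC
    eta_L: float = 0.0
    refit_with_full_labeled: bool = False   # prose reading: refit on L ∪ pseudo
    sequential: bool = False                # update slots within the round
    error_on_all_labeled: bool = False      # e_i(t) over all of L, not agreed subset

    def __post_init__(self) -> None:
        if self.M < 3:
            raise ValueError("M must be >= 3")
        if not 0.5 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0.5, 1]")
        if not 0.0 < self.init_fraction <= 1.0:
            raise ValueError("init_fraction must lie in (0, 1]")
        if not 0.0 <= self.eta_L < 0.5:
            raise ValueError("eta_L must lie in [0, 0.5)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class ClassifierSlot:
    """One base classifier c_i with its noise-bound bookkeeping."""

    index: int
    initial_pool: LabeledSet
    model: BaseEstimator
    e_prev: float = 0.5
    size_prev: int = 0
    changed: bool = False
    current_pool_size: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_prev <= 0.5:
            raise ValueError("e_prev must start in [0, 0.5]")
        if self.current_pool_size == 0:
            self.current_pool_size = len(self.initial_pool)


@dataclass
class PseudoLabeledSet:
    """Unlabeled samples plus committee-agreed labels for one slot/round."""

    ids: np.ndarray
    X: np.ndarray
    labels: np.ndarray
    agreement: np.ndarray
    round: int

    def __post_init__(self) -> None:
        assert len(self.ids) == len(self.X) == len(self.labels) == len(self.agreement)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: np.ndarray) -> "PseudoLabeledSet":
        indices = np.asarray(indices)
        return PseudoLabeledSet(self.ids[indices], self.X[indices],
                                self.labels[indices], self.agreement[indices],
                                self.round)


@dataclass(frozen=True)
class Decision:
    """Outcome of the noise-compensation check for one slot/round.

    kind is one of ``skip``, ``update``, ``update_after_subsample`` or
    ``update_with_bootstrap_prev`` (first productive round, where the
    previous pool size is virtually bootstrapped).  ``s_i`` is the
    sub-sample size when sub-sampling applies.
    """

    kind: str
    s_i: int | None = None
    virtual_size_prev: int | None = None
    reason: str = ""

    @property
    def is_update(self) -> bool:
        return self.kind != "skip"


@dataclass
class RunHistory:
    """Append-only per-(round, slot) trace of an M-training run."""

    records: list[dict[str, Any]] = field(default_factory=list)
    termination_reason: str = ""
    n_rounds: int = 0

    def append(self, **rec: Any) -> None:
        self.records.append(rec)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r) for r in self.records)

    def rounds(self, t: int) -> list[dict[str, Any]]:
        return [r for r in self.records if r["round"] == t]


# ---------------------------------------------------------------------------
# Noise-bound arithmetic
# ---------------------------------------------------------------------------

def noise_rate(eta_L: float, size_L: int, e: float, size_pseudo: int) -> float:
    """Combined classification noise rate of a labeled + pseudo-labeled pool:
    (eta_L*|L| + e*|pseudo|) / (|L| + |pseudo|)."""
    if size_L < 0 or size_pseudo < 0:
        raise ValueError("sizes must be non-negative")
    total = size_L + size_pseudo
    if total == 0:
        raise ValueError("pool is empty")
    return (eta_L * size_L + e * size_pseudo) / total


def utility_u(m: int, eta: float) -> float:
    """The bound utility u = m * (1 - 2*eta)^2; improvement requires u to
    grow between rounds."""
    if m < 0:
        raise ValueError("m must be non-negative")
    return m * (1.0 - 2.0 * eta) ** 2


def should_update(e_t: float, e_prev: float, size_t: int, size_prev: int) -> Decision:
    """Decide whether a slot may refit on its round-t pseudo pool.

    Requires e_t < e_prev and a non-empty pseudo pool.  On the first
    productive round (size_prev == 0) the previous size is virtually
    bootstrapped to floor(e_t / (e_prev - e_t)) + 1 and the check is
    re-evaluated against it.  Otherwise the pseudo pool must have grown
    (size_prev < size_t); the update is immediate if
    e_t*size_t < e_prev*size_prev and goes through sub-sampling to
    s_i = ceil(e_prev*size_prev/e_t - 1) when size_prev > e_t/(e_prev-e_t).
    """
    if e_t < 0 or e_prev < 0 or size_t < 0 or size_prev < 0:
        raise ValueError("negative inputs")
    if not e_t < e_prev:
        return Decision("skip", reason="error did not decrease")
    if size_t == 0:
        return Decision("skip", reason="no pseudo-labels proposed")
    bootstrap = False
    virtual = None
    if size_prev == 0:
        # first productive round: virtual previous size from the
        # tri-training lineage, making the growth/sub-sampling checks
        # meaningful
        virtual = math.floor(e_t / (e_prev - e_t)) + 1
        size_prev = virtual
        bootstrap = True
    if not size_prev < size_t:
        return Decision("skip", virtual_size_prev=virtual,
                        reason="pseudo pool did not grow past previous size")
    kind = "update_with_bootstrap_prev" if bootstrap else "update"
    if e_t * size_t < e_prev * size_prev:
        return Decision(kind, virtual_size_prev=virtual,
                        reason="noise product decreased")
    if e_t == 0.0:
        # zero measured pseudo-label noise: the product condition holds
        # trivially; guard against the division below
        return Decision(kind, virtual_size_prev=virtual, reason="zero measured noise")
    if size_prev > e_t / (e_prev - e_t):
        s_i = math.ceil(e_prev * size_prev / e_t - 1)
        return Decision(kind if bootstrap else "update_after_subsample",
                        s_i=s_i, virtual_size_prev=virtual,
                        reason="sub-sampled to restore the noise product bound")
    return Decision("skip", virtual_size_prev=virtual,
                    reason="sub-sampling bound not satisfiable")


# ---------------------------------------------------------------------------
# Committee voting
# ---------------------------------------------------------------------------

def _committee_votes(vote_idx: np.ndarray, n_classes: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Modal label index and agreement fraction per column of an
    (n_voters, n_samples) integer vote matrix.  Modal ties resolve to the
    lowest label index (irrelevant whenever theta > 0.5 filters later)."""
    n_voters, n_samples = vote_idx.shape
    counts = np.zeros((n_classes, n_samples), dtype=int)
    for v in range(n_voters):
        counts[vote_idx[v], np.arange(n_samples)] += 1
    modal = counts.argmax(axis=0)
    share = counts.max(axis=0) / n_voters
    return modal, share


def _predict_index(model: BaseEstimator, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    pred = predict_labels(model, X)
    lookup = {c: k for k, c in enumerate(classes)}
    try:
        return np.array([lookup[p] for p in pred], dtype=int)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"model predicted unknown label {exc}") from exc


def propose_labels(slot_index: int, slots: Sequence[ClassifierSlot], U: UnlabeledSet,
                   theta: float, classes: Sequence[str],
                   votes: np.ndarray | None = None, round_t: int = 0
                   ) -> PseudoLabeledSet:
    """Pseudo-label U for one slot by committee agreement.

    The M - 1 co-classifiers (every slot except ``slot_index``) vote on
    each unlabeled sample; samples whose modal label reaches a vote
    share >= theta are emitted with that label.  ``votes`` may carry
    precomputed label indices for all M slots (shape (M, |U|)) so one
    round predicts U only once.
    """
    classes = np.asarray(classes, dtype=object)
    if len(U) == 0:
        return PseudoLabeledSet(np.array([], dtype=object), np.empty((0, U.n_features)),
                                np.array([], dtype=object), np.array([]), round_t)
    if votes is None:
        votes = np.vstack([_predict_index(s.model, U.X, classes) for s in slots])
    co = np.vstack([votes[j] for j in range(len(slots)) if j != slot_index])
    modal, share = _committee_votes(co, len(classes))
    accept = share >= theta
    return PseudoLabeledSet(
        ids=U.ids[accept],
        X=U.X[accept],
        labels=classes[modal[accept]],
        agreement=share[accept],
        round=round_t,
    )


def estimate_error(slot_index: int, slots: Sequence[ClassifierSlot], L: LabeledSet,
                   theta: float, classes: Sequence[str] | None = None,
                   votes: np.ndarray | None = None,
                   on_all_labeled: bool = False) -> tuple[float, bool]:
    """Estimate the committee's pseudo-labeling error bound e_i(t) on L.

    The committee's accuracy on unlabeled data cannot be measured, so it
    is estimated on the labeled pool under the assumption that L and U
    share a distribution: over the samples of L where the committee
    reaches agreement >= theta, e = (# agreed labels wrong) / (# agreed).
    Returns (e, has_evidence); with no agreed sample, (0.5, False) — the
    caller must skip the round.  ``on_all_labeled`` instead scores the
    committee's plurality label on every sample of L.
    """
    if classes is None:
        classes = L.label_set
    classes = np.asarray(classes, dtype=object)
    if votes is None:
        votes = np.vstack([_predict_index(s.model, L.X, classes) for s in slots])
    co = np.vstack([votes[j] for j in range(len(slots)) if j != slot_index])
    modal, share = _committee_votes(co, len(classes))
    truth = np.array([np.flatnonzero(classes == t)[0] for t in L.y.astype(str)])
    if on_all_labeled:
        return float((modal != truth).mean()), True
    agreed = share >= theta
    if not agreed.any():
        return 0.5, False
    wrong = (modal[agreed] != truth[agreed]).sum()
    return float(wrong / agreed.sum()), True


def subsample(pseudo: PseudoLabeledSet, s_i: int, rng: np.random.Generator
              ) -> PseudoLabeledSet:
    """Uniform random subset of exactly s_i pseudo-labeled entries."""
    if not 0 < s_i < len(pseudo):
        raise ValueError(f"s_i must be in (0, {len(pseudo)}), got {s_i}")
    keep = np.sort(rng.choice(len(pseudo), size=s_i, replace=False))
    return pseudo.subset(keep)


# ---------------------------------------------------------------------------
# Ensemble lifecycle
# ---------------------------------------------------------------------------

def _slot_rng(seed: int, *key: int) -> np.random.Generator:
    # documented substream scheme: root seed + structured spawn key, so
    # runs reproduce regardless of M or round count
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def init_ensemble(L: LabeledSet, config: EnsembleConfig) -> list[ClassifierSlot]:
    """Diversify and fit the M base classifiers.

    Each slot trains on an independent random draw (without replacement)
    of round_half_up(init_fraction * |L|) samples of L; a draw missing a
    class is retried with a derived substream.
    """
    n = len(L)
    if n < config.M:
        raise ValueError(f"|L| = {n} < M = {config.M}")
    n_classes = len(L.label_set)
    if n_classes < 2:
        raise ValueError("L must contain at least 2 classes")
    pool_size = round_half_up(config.init_fraction * n)
    if pool_size < n_classes:
        raise ValueError(f"initial pool size {pool_size} < number of classes {n_classes}")
    slots = []
    for i in range(config.M):
        pool = None
        for attempt in range(32):
            rng = _slot_rng(config.seed, 0, i, attempt)
            idx = np.sort(rng.choice(n, size=pool_size, replace=False))
            cand = L.subset(idx)
            if len(set(cand.y.astype(str))) == n_classes:
                pool = cand
                if attempt:
                    logger.info("init_ensemble: slot %d redrew pool %d time(s)", i, attempt)
                break
        if pool is None:
            raise ValueError(f"slot {i}: could not draw a pool covering all classes")
        slots.append(ClassifierSlot(index=i, initial_pool=pool,
                                    model=fit_classifier(config.base_spec, pool)))
    return slots


def refine(slot: ClassifierSlot, pseudo: PseudoLabeledSet, e_t: float,
           base_spec: ClassifierSpec | BaseEstimator,
           labeled_pool: LabeledSet | None = None) -> ClassifierSlot:
    """Refit a slot on its pool united with the pseudo-labeled set.

    The refit pool is slot.initial_pool ∪ pseudo (or L ∪ pseudo when
    ``labeled_pool`` is given), deduplicated by sample id with the
    labeled copy winning.  Updates the slot's noise bookkeeping
    (e_prev <- e_t, size_prev <- |pseudo|) in place and returns it.
    """
    pool = labeled_pool if labeled_pool is not None else slot.initial_pool
    known = set(pool.ids.tolist())
    fresh = np.array([k for k, sid in enumerate(pseudo.ids) if sid not in known], dtype=int)
    union = LabeledSet(
        ids=np.concatenate([pool.ids, pseudo.ids[fresh]]),
        X=np.vstack([pool.X, pseudo.X[fresh]]),
        y=np.concatenate([pool.y, pseudo.labels[fresh]]),
        label_set=pool.label_set,
    )
    slot.model = fit_classifier(base_spec, union)
    slot.e_prev = e_t
    slot.size_prev = len(pseudo)
    slot.changed = True
    slot.current_pool_size = len(union)
    return slot


def run(L: LabeledSet, U: UnlabeledSet, config: EnsembleConfig
        ) -> tuple[list[ClassifierSlot], RunHistory]:
    """Execute the full M-training loop; see the module docstring.

    Rounds are synchronous by default: every slot's error estimate and
    pseudo-label proposal is computed against the start-of-round models,
    then all refits apply together (order-invariant).  The previous
    round's pseudo-labels are implicitly returned to U because the whole
    of U is re-voted every round.
    """
    classes = np.asarray(L.label_set, dtype=object)
    slots = init_ensemble(L, config)
    history = RunHistory()

    for t in range(1, config.max_rounds + 1):
        for s in slots:
            s.changed = False
        # synchronous rounds score every committee against start-of-round
        # models; sequential mode recomputes votes per slot instead
        if config.sequential:
            votes_L = votes_U = None
        else:
            votes_L = np.vstack([_predict_index(s.model, L.X, classes) for s in slots])
            votes_U = (np.vstack([_predict_index(s.model, U.X, classes) for s in slots])
                       if len(U) else np.empty((config.M, 0), dtype=int))
        pending: list[tuple[ClassifierSlot, PseudoLabeledSet, float, dict]] = []

        for s in slots:
            e_t, has_evidence = estimate_error(
                s.index, slots, L, config.theta, classes, votes=votes_L,
                on_all_labeled=config.error_on_all_labeled)
            pool_before = s.current_pool_size
            if not has_evidence or not e_t < s.e_prev:
                decision = Decision("skip", reason=(
                    "no committee agreement on L" if not has_evidence
                    else "error did not decrease"))
                pseudo = None
            else:
                pseudo = propose_labels(s.index, slots, U, config.theta, classes,
                                        votes=votes_U, round_t=t)
                size_proposed = len(pseudo)
                decision = should_update(e_t, s.e_prev, len(pseudo), s.size_prev)
                if decision.s_i is not None:
                    rng = _slot_rng(config.seed, 1, t, s.index)
                    pseudo = subsample(pseudo, decision.s_i, rng)
            size_used = len(pseudo) if (pseudo is not None and decision.is_update) else 0
            rec = dict(
                round=t, slot=s.index, e_t=float(e_t), e_prev=float(s.e_prev),
                size_t=size_used,
                size_proposed=0 if pseudo is None else size_proposed,
                size_prev=s.size_prev,
                virtual_size_prev=decision.virtual_size_prev,
                decision=decision.kind, reason=decision.reason,
                pool_before=pool_before, pool_after=pool_before,
            )
            history.append(**rec)
            if decision.is_update:
                if config.sequential:
                    refine(s, pseudo, e_t, config.base_spec,
                           labeled_pool=L if config.refit_with_full_labeled else None)
                    history.records[-1]["pool_after"] = s.current_pool_size
                else:
                    pending.append((s, pseudo, e_t, history.records[-1]))

        for s, pseudo, e_t, rec in pending:
            refine(s, pseudo, e_t, config.base_spec,
                   labeled_pool=L if config.refit_with_full_labeled else None)
            rec["pool_after"] = s.current_pool_size

        history.n_rounds = t
        if not any(s.changed for s in slots):
            history.termination_reason = "fixed_point"
            break
    else:
        history.termination_reason = "max_rounds"
    return slots, history


def predict_ensemble(slots: Sequence[ClassifierSlot], X: np.ndarray,
                     classes: Sequence[str]) -> np.ndarray:
    """Plurality vote over all M models; ties go to the lowest label in
    the dataset's sorted label ordering."""
    classes = np.asarray(classes, dtype=object)
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return np.array([], dtype=object)
    votes = np.vstack([_predict_index(s.model, X, classes) for s in slots])
    modal, _ = _committee_votes(votes, len(classes))
    return classes[modal]


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class MTrainingClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised M-training ensemble as a sklearn classifier.

    Follows the semi-supervised convention of
    :class:`~sklearn.semi_supervised.SelfTrainingClassifier`: pass the
    full training matrix to ``fit`` with unlabeled samples marked by
    ``-1`` (or ``None``/NaN) in ``y``.

    Parameters
    ----------
    n_classifiers : number of base classifiers M (>= 3; 3 is tri-training).
    theta : committee agreement-fraction threshold in (0.5, 1].
    base_estimator : sklearn classifier, ClassifierSpec or kind string;
        default is the RBF-kernel SVM at the tuned hyperparameters.
    init_fraction : fraction of L drawn for each slot's initial pool.
    eta_L : assumed label-noise rate of the labeled pool.
    random_state : seed for pool draws and sub-sampling.

    Attributes
    ----------
    classes_ : sorted class labels.
    slots_ : the fitted :class:`ClassifierSlot` list.
    history_ : the :class:`RunHistory` of the refinement loop.
    n_rounds_ : number of refinement rounds executed.
    """

    def __init__(self, n_classifiers: int = 4, theta: float = 2.0 / 3.0,
                 base_estimator=None, init_fraction: float = 0.75,
                 max_rounds: int = 50, eta_L: float = 0.0,
                 refit_with_full_labeled: bool = False, sequential: bool = False,
                 error_on_all_labeled: bool = False, random_state: int = 0):
        self.n_classifiers = n_classifiers
        self.theta = theta
        self.base_estimator = base_estimator
        self.init_fraction = init_fraction
        self.max_rounds = max_rounds
        self.eta_L = eta_L
        self.refit_with_full_labeled = refit_with_full_labeled
        self.sequential = sequential
        self.error_on_all_labeled = error_on_all_labeled
        self.random_state = random_state

    def _config(self) -> EnsembleConfig:
        base = self.base_estimator if self.base_estimator is not None else DEFAULT_SPEC
        if isinstance(base, str):
            base = ClassifierSpec(base)
        return EnsembleConfig(
            M=self.n_classifiers, theta=self.theta, init_fraction=self.init_fraction,
            max_rounds=self.max_rounds, seed=self.random_state, base_spec=base,
            eta_L=self.eta_L, refit_with_full_labeled=self.refit_with_full_labeled,
            sequential=self.sequential, error_on_all_labeled=self.error_on_all_labeled,
        )

    @staticmethod
    def _unlabeled_mask(y: np.ndarray) -> np.ndarray:
        def is_unlabeled(v) -> bool:
            if v is None:
                return True
            if isinstance(v, float) and math.isnan(v):
                return True
            return v == -1 or v == "-1" or v == ""
        return np.array([is_unlabeled(v) for v in y])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label (or -1) per row")
        unlabeled = self._unlabeled_mask(y)
        ids = np.array([f"s{k}" for k in range(len(y))], dtype=object)
        L = LabeledSet(ids[~unlabeled], X[~unlabeled], y[~unlabeled].astype(str))
        U = UnlabeledSet(ids[unlabeled], X[unlabeled])
        return self.fit_sets(L, U)

    def fit_sets(self, L: LabeledSet, U: UnlabeledSet) -> "MTrainingClassifier":
        """Fit from explicit labeled/unlabeled pools."""
        self.slots_, self.history_ = run(L, U, self._config())
        self.classes_ = np.asarray(L.label_set, dtype=object)
        self.n_rounds_ = self.history_.n_rounds
        self.n_features_in_ = L.n_features
        return self

    def predict(self, X):
        if not hasattr(self, "slots_"):
            raise ValueError("MTrainingClassifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return predict_ensemble(self.slots_, X, self.classes_)
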