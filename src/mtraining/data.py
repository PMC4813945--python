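"""Sample pools and feature-table I/O for e-nose datasets.

An e-nose feature table has one row per sampling experiment: a sample id,
one steady-state feature per gas sensor (four for the TGS array), an
optional gas-class label and an optional concentration in ppm.  Rows with
an empty label form the unlabeled pool ``U``; labeled rows form ``L``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sample",
    "LabeledSet",
    "UnlabeledSet",
    "DatasetSplit",
    "round_half_up",
    "read_feature_table",
    "write_feature_table",
    "split_train_test",
    "split_labeled_unlabeled",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    Used for every fractional subset size in the package (0.75 * 198 ->
    149, 0.75 * 99 -> 74) so all split arithmetic follows one convention.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Sample:
    """One e-nose measurement: a feature vector with optional label."""

    sample_id: str
    features: tuple[float, ...]
    label: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        feats = tuple(float(v) for v in self.features)
        if not all(np.isfinite(feats)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite feature")
        object.__setattr__(self, "features", feats)


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D (n_samples, n_features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


class _SampleSet:
    """Shared array-backed storage for labeled/unlabeled pools."""

    ids: np.ndarray
    X: np.ndarray
    concentrations: np.ndarray  # NaN where unknown

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def _check_ids(self) -> None:
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate sample ids within a set")


@dataclass
class LabeledSet(_SampleSet):
    """The labeled pool ``L``: feature matrix, ids and one label per row."""

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    concentrations: np.ndarray = None  # type: ignore[assignment]
    label_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = _as_2d(self.X)
        self.y = np.asarray(self.y, dtype=object)
        if self.concentrations is None:
            self.concentrations = np.full(len(self.ids), np.nan)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if not (len(self.ids) == len(self.X) == len(self.y) == len(self.concentrations)):
            raise ValueError("ids, X, y, concentrations must have equal length")
        if any(lbl is None or lbl == "" for lbl in self.y):
            raise ValueError("LabeledSet contains a sample without a label")
        self._check_ids()
        observed = sorted({str(v) for v in self.y})
        if not self.label_set:
            self.label_set = tuple(observed)
        else:
            self.label_set = tuple(self.label_set)
            unknown = set(observed) - set(self.label_set)
            if unknown:
                raise ValueError(f"labels outside declared label set: {sorted(unknown)}")

    @classmethod
    def from_samples(cls, samples: Iterable[Sample], label_set: Sequence[str] = ()) -> "LabeledSet":
        samples = list(samples)
        return cls(
            ids=np.array([s.sample_id for s in samples], dtype=object),
            X=np.array([s.features for s in samples], dtype=float).reshape(len(samples), -1),
            y=np.array([s.label for s in samples], dtype=object),
            concentrations=np.array(
                [np.nan if s.concentration is None else s.concentration for s in samples]
            ),
            label_set=tuple(label_set),
        )

    def to_samples(self) -> list[Sample]:
        return [
            Sample(
                str(i),
                tuple(x),
                str(lbl),
                None if np.isnan(c) else float(c),
            )
            for i, x, lbl, c in zip(self.ids, self.X, self.y, self.concentrations)
        ]

    def subset(self, indices: np.ndarray) -> "LabeledSet":
        indices = np.asarray(indices)
        return LabeledSet(
            self.ids[indices],
            self.X[indices],
            self.y[indices],
            self.concentrations[indices],
            label_set=self.label_set,
        )

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class UnlabeledSet(_SampleSet):
    """The unlabeled pool ``U``.

    Ground-truth labels for synthetic pools may be kept in ``true_y`` for
    pseudo-label diagnostics; the learner never reads them.
    """

    ids: np.ndarray
    X: np.ndarray
    concentrations: np.ndarray = None  # type: ignore[assignment]
    true_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = _as_2d(self.X)
        if self.concentrations is None:
            self.concentrations = np.full(len(self.ids), np.nan)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.true_y is not None:
            self.true_y = np.asarray(self.true_y, dtype=object)
            if len(self.true_y) != len(self.ids):
                raise ValueError("true_y length mismatch")
        if not (len(self.ids) == len(self.X) == len(self.concentrations)):
            raise ValueError("ids, X, concentrations must have equal length")
        self._check_ids()

    @classmethod
    def empty(cls, n_features: int) -> "UnlabeledSet":
        return cls(
            ids=np.array([], dtype=object),
            X=np.empty((0, n_features)),
        )

    def subset(self, indices: np.ndarray) -> "UnlabeledSet":
        indices = np.asarray(indices)
        return UnlabeledSet(
            self.ids[indices],
            self.X[indices],
            self.concentrations[indices],
            None if self.true_y is None else self.true_y[indices],
        )


def _assert_disjoint(*sets: _SampleSet) -> None:
    seen: set = set()
    for s in sets:
        ids = set(s.ids.tolist())
        if seen & ids:
            raise ValueError(f"sample ids shared between parts: {sorted(seen & ids)[:5]}")
        seen |= ids


@dataclass
class DatasetSplit:
    """An L/U(/test) partition at a given unlabeled rate |U|/(|L|+|U|)."""

    L: LabeledSet
    U: UnlabeledSet
    test: LabeledSet | None
    unlabeled_rate: float

    def __post_init__(self) -> None:
        parts: list[_SampleSet] = [self.L, self.U]
        if self.test is not None:
            parts.append(self.test)
        _assert_disjoint(*parts)
        n = len(self.L) + len(self.U)
        if n and abs(len(self.U) / n - self.unlabeled_rate) > 1.0 / n:
            raise ValueError(
                f"|U|/(|L|+|U|) = {len(self.U) / n:.4f} inconsistent with "
                f"unlabeled_rate = {self.unlabeled_rate}"
            )


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------

_RESERVED = ("sample_id", "label", "concentration")


def read_feature_table(source, feature_columns: Sequence[str] | None = None
                       ) -> tuple[LabeledSet, UnlabeledSet]:
    """Read a CSV feature table into (LabeledSet, UnlabeledSet).

    Header must contain ``sample_id`` and ``label``; ``concentration`` is
    optional.  Every other column (or ``feature_columns``, in order) is a
    numeric feature.  Rows with an empty label populate the unlabeled
    pool; row order is preserved within each pool.
    """
    try:
        df = pd.read_csv(source, dtype={"sample_id": str, "label": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError("empty feature table") from None
    if df.empty:
        raise ValueError("feature table has a header but no rows")
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"feature table missing required column {col!r}")
    if feature_columns is None:
        feature_columns = [c for c in df.columns if c not in _RESERVED]
    if not feature_columns:
        raise ValueError("feature table has no feature columns")
    for col in feature_columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric feature cell at row {row}, column {col!r}: {df[col][row]!r}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValueError(f"missing feature cell at row {row}, column {col!r}")
        df[col] = coerced

    X = df[list(feature_columns)].to_numpy(dtype=float)
    ids = df["sample_id"].to_numpy(dtype=object)
    conc = (
        pd.to_numeric(df["concentration"], errors="raise").to_numpy(dtype=float)
        if "concentration" in df.columns
        else np.full(len(df), np.nan)
    )
    labels = df["label"].to_numpy(dtype=object)
    labeled_mask = np.array([isinstance(v, str) and v != "" for v in labels])

    L = LabeledSet(ids[labeled_mask], X[labeled_mask], labels[labeled_mask],
                   conc[labeled_mask])
    U = UnlabeledSet(ids[~labeled_mask], X[~labeled_mask], conc[~labeled_mask])
    return L, U


def write_feature_table(L: LabeledSet | None, U: UnlabeledSet | None, sink,
                        feature_names: Sequence[str] | None = None) -> None:
    """Write L then U as one CSV; unlabeled rows get an empty label field."""
    frames = []
    n_feat = None
    for part, labeled in ((L, True), (U, False)):
        if part is None or len(part) == 0:
            continue
        if n_feat is None:
            n_feat = part.n_features
        elif part.n_features != n_feat:
            raise ValueError("L and U feature lengths differ")
        names = list(feature_names) if feature_names else [
            f"sensor_{k + 1}" for k in range(part.n_features)
        ]
        frame = pd.DataFrame(part.X, columns=names)
        frame.insert(0, "sample_id", part.ids)
        frame["label"] = part.y if labeled else ""
        frame["concentration"] = part.concentrations
        frames.append(frame)
    if not frames:
        raise ValueError("nothing to write: both pools empty")
    out = pd.concat(frames, ignore_index=True)
    out["concentration"] = out["concentration"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    # repr() keeps float features bit-exact through the round trip
    for c in out.columns:
        if c not in _RESERVED:
            out[c] = out[c].map(lambda v: repr(float(v)))
    out.to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def split_train_test(data: LabeledSet, train_fraction: float, seed: int,
                     stratified: bool = True) -> tuple[LabeledSet, LabeledSet]:
    """Random train/test split; stratified draws round_half_up(f * n_class)
    training samples per class, matching a 75%-per-gas protocol."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(data)
    if stratified:
        train_idx: list[int] = []
        for label in data.label_set:
            cls_idx = np.flatnonzero(data.y.astype(str) == label)
            if len(cls_idx) < 2:
                raise ValueError(f"class {label!r} has fewer than 2 samples")
            k = round_half_up(train_fraction * len(cls_idx))
            picked = rng.choice(cls_idx, size=k, replace=False)
            train_idx.extend(picked.tolist())
        train_idx = sorted(train_idx)
    else:
        k = round_half_up(train_fraction * n)
        train_idx = sorted(rng.choice(n, size=k, replace=False).tolist())
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return data.subset(np.flatnonzero(mask)), data.subset(np.flatnonzero(~mask))


def split_labeled_unlabeled(train: LabeledSet, unlabeled_rate: float, seed: int,
                            stratified: bool = False, max_retries: int = 32
                            ) -> DatasetSplit:
    """Hide labels on a random unlabeled_rate fraction of the training pool.

    |L| = round_half_up((1 - rate) * |train|).  The hidden labels are kept
    as ``U.true_y`` for pseudo-label diagnostics only.  If the drawn L
    misses a class entirely the draw is retried with a derived seed.
    """
    if not 0 <= unlabeled_rate < 1:
        raise ValueError("unlabeled_rate must be in [0, 1)")
    n = len(train)
    n_L = round_half_up((1 - unlabeled_rate) * n)
    if unlabeled_rate == 0:
        return DatasetSplit(train, UnlabeledSet.empty(train.n_features), None, 0.0)

    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        if stratified:
            idx: list[int] = []
            for label in train.label_set:
                cls_idx = np.flatnonzero(train.y.astype(str) == label)
                k = round_half_up((1 - unlabeled_rate) * len(cls_idx))
                idx.extend(rng.choice(cls_idx, size=k, replace=False).tolist())
            L_idx = np.array(sorted(idx))
        else:
            L_idx = np.sort(rng.choice(n, size=n_L, replace=False))
        L = train.subset(L_idx)
        if set(np.unique(L.y.astype(str))) == set(train.label_set):
            if attempt:
                logger.info("split_labeled_unlabeled: retried %d time(s) to cover all classes",
                            attempt)
            mask = np.zeros(n, dtype=bool)
            mask[L_idx] = True
            U_idx = np.flatnonzero(~mask)
            U = UnlabeledSet(
                train.ids[U_idx], train.X[U_idx], train.concentrations[U_idx],
                true_y=train.y[U_idx],
            )
            return DatasetSplit(L, U, None, unlabeled_rate)
    raise ValueError(
        f"could not draw an L of size {n_L} covering all {len(train.label_set)} classes"
    )
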