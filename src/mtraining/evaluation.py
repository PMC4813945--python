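"""Accuracy metrics, the Impro statistic and the experiment harness.

Impro is the relative improvement of the refined ensemble over its
initial (labeled-only) state: Impro = (final - initial) / initial x 100,
reported at two decimal places like every accuracy in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Any, Sequence

import numpy as np

from .base import ClassifierSpec, fit_classifier, predict_labels
from .data import DatasetSplit, LabeledSet
from .ensemble import EnsembleConfig, RunHistory, predict_ensemble, run
from .synthetic import DEFAULT_SEPARATION, study_benchmark

logger = logging.getLogger(__name__)

__all__ = ["accuracy", "impro", "per_class_accuracy", "loo_accuracy",
           "ExperimentReport", "run_experiment", "round2"]


def round2(x: float) -> float:
    """Two-decimal round-half-up, the reporting convention for accuracies."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _check_lengths(predicted, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=object)
    t = np.asarray(true, dtype=object)
    if len(p) != len(t):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(t)} truths")
    if len(p) == 0:
        raise ValueError("empty label sequences")
    return p, t


def accuracy(predicted, true) -> float:
    """Percent of matching labels, unrounded (round2 at reporting time)."""
    p, t = _check_lengths(predicted, true)
    return 100.0 * float((p.astype(str) == t.astype(str)).mean())


def impro(initial: float, final: float) -> float:
    """Relative improvement (final - initial)/initial x 100, at 2 dp."""
    if initial <= 0:
        raise ValueError("initial accuracy must be positive")
    return round2(100.0 * (final - initial) / initial)


def per_class_accuracy(predicted, true, label_set: Sequence[str]) -> dict[str, float]:
    """Class-conditional accuracies; the size-weighted mean equals the
    overall accuracy."""
    p, t = _check_lengths(predicted, true)
    t = t.astype(str)
    p = p.astype(str)
    out: dict[str, float] = {}
    for label in label_set:
        mask = t == str(label)
        if not mask.any():
            raise ValueError(f"class {label!r} absent from the true labels")
        out[str(label)] = 100.0 * float((p[mask] == t[mask]).mean())
    return out


def loo_accuracy(spec: ClassifierSpec | Any, data: LabeledSet) -> float:
    """Leave-one-out accuracy of a base classifier on a labeled pool."""
    n = len(data)
    if n < 2:
        raise ValueError("LOO needs at least 2 samples")
    hits = 0
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        fold = data.subset(keep)
        if len(set(fold.y.astype(str))) < 2:
            raise ValueError(f"fold {i}: training part has a single class")
        model = fit_classifier(spec, fold)
        pred = predict_labels(model, data.X[i:i + 1])[0]
        hits += int(str(pred) == str(data.y[i]))
    return 100.0 * hits / n


@dataclass
class ExperimentReport:
    """One cell of the experiment grid: accuracies before/after refinement."""

    config: dict[str, Any]
    initial_accuracy: float
    final_accuracy: float
    impro: float
    per_class_initial: dict[str, float]
    per_class_final: dict[str, float]
    pool_sizes_initial: list[int]
    pool_sizes_final: list[int]
    n_rounds: int
    termination_reason: str
    history: RunHistory | None = None

    def __post_init__(self) -> None:
        for a in (self.initial_accuracy, self.final_accuracy):
            if not 0.0 <= a <= 100.0:
                raise ValueError("accuracies must lie in [0, 100]")
        if self.impro != impro(self.initial_accuracy, self.final_accuracy):
            raise ValueError("impro inconsistent with its definition")

    def to_dict(self) -> dict[str, Any]:
        d = {k: v for k, v in self.__dict__.items() if k != "history"}
        d["initial_accuracy"] = round2(self.initial_accuracy)
        d["final_accuracy"] = round2(self.final_accuracy)
        d["per_class_initial"] = {k: round2(v) for k, v in self.per_class_initial.items()}
        d["per_class_final"] = {k: round2(v) for k, v in self.per_class_final.items()}
        return d


def evaluate_split(split: DatasetSplit, config: EnsembleConfig) -> ExperimentReport:
    """Run M-training on one L/U split and score it on the fixed test set."""
    if split.test is None:
        raise ValueError("split has no test part")
    test = split.test
    slots, history = run(split.L, split.U, config)
    classes = split.L.label_set

    # initial state: refit the same diversified pools (deterministic under
    # the same seed) so "initial" is exactly the pre-refinement ensemble
    from .ensemble import init_ensemble
    initial_slots = init_ensemble(split.L, config)
    pred0 = predict_ensemble(initial_slots, test.X, classes)
    pred1 = predict_ensemble(slots, test.X, classes)
    acc0 = accuracy(pred0, test.y)
    acc1 = accuracy(pred1, test.y)
    return ExperimentReport(
        config={"M": config.M, "theta": config.theta,
                "init_fraction": config.init_fraction, "seed": config.seed,
                "unlabeled_rate": split.unlabeled_rate,
                "eta_L": config.eta_L},
        initial_accuracy=acc0,
        final_accuracy=acc1,
        impro=impro(acc0, acc1),
        per_class_initial=per_class_accuracy(pred0, test.y, classes),
        per_class_final=per_class_accuracy(pred1, test.y, classes),
        pool_sizes_initial=[len(s.initial_pool) for s in slots],
        pool_sizes_final=[s.current_pool_size for s in slots],
        n_rounds=history.n_rounds,
        termination_reason=history.termination_reason,
        history=history,
    )


def run_experiment(M_grid: Sequence[int] = (4,),
                   rate_grid: Sequence[float] = (0.25, 0.5, 0.75),
                   n_seeds: int = 20, root_seed: int = 0,
                   base_spec: ClassifierSpec | Any = None,
                   separation: float = DEFAULT_SEPARATION,
                   theta: float = 2.0 / 3.0,
                   keep_history: bool = False) -> list[ExperimentReport]:
    """Sweep (M, unlabeled_rate, seed) cells on the default benchmark.

    Each cell uses a seed derived from (root_seed, cell index) so cells
    are independent and the grid is reproducible.  A failing cell is
    logged and skipped rather than aborting the sweep.
    """
    from .base import DEFAULT_SPEC
    base_spec = base_spec if base_spec is not None else DEFAULT_SPEC
    reports: list[ExperimentReport] = []
    cell = 0
    for M in M_grid:
        for rate in rate_grid:
            for s in range(n_seeds):
                cell += 1
                seed = int(np.random.SeedSequence((root_seed, cell)).generate_state(1)[0]
                           % (2 ** 31))
                try:
                    split = study_benchmark(seed=seed, unlabeled_rate=rate,
                                            separation=separation)
                    config = EnsembleConfig(M=M, theta=theta, seed=seed,
                                            base_spec=base_spec)
                    report = evaluate_split(split, config)
                    if not keep_history:
                        report.history = None
                    reports.append(report)
                except Exception:
                    logger.exception("experiment cell failed: M=%s rate=%s seed=%s",
                                     M, rate, seed)
    return reports


def median_summary(reports: Sequence[ExperimentReport]) -> list[dict[str, Any]]:
    """Median initial/final accuracy per (M, rate) cell group."""
    groups: dict[tuple, list[ExperimentReport]] = {}
    for r in reports:
        groups.setdefault((r.config["M"], r.config["unlabeled_rate"]), []).append(r)
    rows = []
    for (M, rate), rs in sorted(groups.items()):
        med0 = float(np.median([r.initial_accuracy for r in rs]))
        med1 = float(np.median([r.final_accuracy for r in rs]))
        rows.append({
            "M": M, "unlabeled_rate": rate, "n_seeds": len(rs),
            "median_initial_accuracy": round2(med0),
            "median_final_accuracy": round2(med1),
            "median_impro": impro(med0, med1),
            "frac_improved_or_equal": float(np.mean(
                [r.final_accuracy >= r.initial_accuracy for r in rs])),
        })
    return rows
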