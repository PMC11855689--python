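"""Motif-based off-target classifiers and benchmarking.

The deaminase domain of rAPOBEC1-based editors prefers cytosines in weak
(A/T) neighborhoods: the canonical substrate motif is ACW (A immediately
5' of the edited C, W = A or T immediately 3'), and the broader WCW motif
captures many non-canonical edits. Both are expressed as a
:class:`MotifRule` over the two neighbors of a C-centered window; the
nonspecific NNN rule predicts every window positive and serves as the
prevalence baseline.

Metrics are macro-averaged over the positive and negative classes with a
zero-division -> 0 convention, the scheme under which the always-positive
baseline evaluates to accuracy = prevalence, macro recall = 0.5,
macro precision = prevalence/2 and macro F1 = prevalence/(1+prevalence).

`benchmark_stratified` reproduces the canonical / non-canonical benchmark
design: windows are stratified by presence of the ACW motif, fixed-size
class-balanced subsets are drawn repeatedly, every classifier is scored on
every subset, and classifiers are compared per metric and stratum with
two-tailed Welch's t-tests.
"""

from __future__ import annotations

import itertools
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .errors import (
    ContractViolationError,
    OrientationError,
    StratumTooSmallError,
)
from .stats import welch_two_tailed
from .variant_profile import ContextWindow

__all__ = [
    "MotifRule",
    "ACW", "WCW", "NNN",
    "Classifier",
    "MotifClassifier",
    "ClassifierMetrics",
    "StratifiedBenchmarkResult",
    "motif_predict",
    "evaluate_classifier",
    "stratify_canonical",
    "benchmark_stratified",
    "external_scorer_adapter",
    "get_classifier",
]


@dataclass(frozen=True)
class MotifRule:
    """Neighbor-context rule at a C-centered site.

    Predicts positive iff the 5' neighbor is in ``five_prime_allowed`` and
    the 3' neighbor is in ``three_prime_allowed`` (or unconditionally for
    ``always_positive``). An N neighbor never satisfies a motif.
    """

    name: str
    five_prime_allowed: frozenset[str] = frozenset()
    three_prime_allowed: frozenset[str] = frozenset()
    always_positive: bool = False


ACW = MotifRule("ACW", frozenset("A"), frozenset("AT"))
WCW = MotifRule("WCW", frozenset("AT"), frozenset("AT"))
NNN = MotifRule("NNN", always_positive=True)


def motif_predict(window: ContextWindow, rule: MotifRule) -> bool:
    """Predict whether a C-centered window matches the motif rule."""
    if window.central_base != "C":
        raise OrientationError(
            f"central base {window.central_base!r} is not C; orient windows first"
        )
    if rule.always_positive:
        return True
    return (
        window.five_prime_neighbor in rule.five_prime_allowed
        and window.three_prime_neighbor in rule.three_prime_allowed
    )


class Classifier:
    """Minimal classifier contract: a name and a per-window boolean predict."""

    name: str

    def predict(self, window: ContextWindow) -> bool:  # pragma: no cover
        raise NotImplementedError

    def predict_many(self, windows: Sequence[ContextWindow]) -> np.ndarray:
        return np.array([self.predict(w) for w in windows], dtype=bool)


@dataclass
class MotifClassifier(Classifier):
    rule: MotifRule

    def __post_init__(self) -> None:
        self.name = self.rule.name

    def predict(self, window: ContextWindow) -> bool:
        return motif_predict(window, self.rule)


def external_scorer_adapter(
    scorer: Callable[[str], float],
    threshold: float = 0.5,
    name: str = "external",
) -> Classifier:
    """Wrap a sequence -> score-in-[0,1] function as a boolean classifier.

    This is the plug-in point for learned models (e.g. a fine-tuned language
    model served elsewhere): prediction is score >= threshold. Scores
    outside [0, 1] violate the contract and raise.
    """

    class _ScorerClassifier(Classifier):
        def __init__(self) -> None:
            self.name = name

        def predict(self, window: ContextWindow) -> bool:
            score = scorer(window.sequence)
            if not 0.0 <= score <= 1.0:
                raise ContractViolationError(
                    f"scorer {name!r} returned {score} outside [0, 1]"
                )
            return score >= threshold

    return _ScorerClassifier()


_BUILTIN = {"acw": ACW, "wcw": WCW, "nnn": NNN}


def get_classifier(name: str) -> Classifier:
    """Look up a built-in motif classifier by (case-insensitive) name."""
    try:
        return MotifClassifier(_BUILTIN[name.lower()])
    except KeyError:
        raise KeyError(
            f"unknown classifier {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None


@dataclass
class ClassifierMetrics:
    """Accuracy plus macro-averaged precision/recall/F1 with per-class values."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame | None = None  # index: [negative, positive]

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def evaluate_classifier(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> ClassifierMetrics:
    """Accuracy and macro precision/recall/F1 of boolean predictions.

    Macro averages treat positive and negative as two classes of equal
    weight; a per-class value with a zero denominator contributes 0.
    """
    predictions = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} vs {labels.shape}"
        )
    acc = accuracy_score(labels, predictions)
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, predictions, labels=[False, True], zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=["negative", "positive"],
    )
    return ClassifierMetrics(
        accuracy=float(acc),
        precision=float(prec.mean()),
        recall=float(rec.mean()),
        f1=float(f1.mean()),
        per_class=per_class,
    )


def stratify_canonical(
    windows: Sequence[ContextWindow],
    labels: Sequence[bool],
) -> tuple[tuple[list[ContextWindow], list[bool]], tuple[list[ContextWindow], list[bool]]]:
    """Partition windows into canonical (ACW present) and non-canonical."""
    if len(windows) != len(labels):
        raise ValueError("windows/labels length mismatch")
    canonical: tuple[list[ContextWindow], list[bool]] = ([], [])
    non_canonical: tuple[list[ContextWindow], list[bool]] = ([], [])
    for w, y in zip(windows, labels):
        bucket = canonical if motif_predict(w, ACW) else non_canonical
        bucket[0].append(w)
        bucket[1].append(bool(y))
    return canonical, non_canonical


@dataclass
class StratifiedBenchmarkResult:
    """Long-format per-subset metrics and pairwise Welch comparisons.

    ``metrics`` columns: classifier, stratum, subset, metric, value.
    ``welch`` columns: stratum, metric, classifier_a, classifier_b, t, p.
    """

    metrics: pd.DataFrame
    welch: pd.DataFrame
    n_subsets: int
    per_class: int

    def values(
        self, classifier: str, stratum: str, metric: str
    ) -> np.ndarray:
        m = self.metrics
        sel = (
            (m["classifier"] == classifier)
            & (m["stratum"] == stratum)
            & (m["metric"] == metric)
        )
        return m.loc[sel, "value"].to_numpy()


def benchmark_stratified(
    windows: Sequence[ContextWindow],
    labels: Sequence[bool],
    classifiers: Sequence[Classifier],
    n_subsets: int = 10,
    per_class: int = 1000,
    seed: int = 0,
) -> StratifiedBenchmarkResult:
    """Canonical / non-canonical benchmark with repeated subsampling.

    For each stratum, draw ``n_subsets`` class-balanced subsets of
    ``per_class`` positives and negatives (without replacement within a
    subset, one seeded stream per run), score every classifier on every
    subset, then compare each classifier pair per metric with two-tailed
    Welch's t-tests across subsets.
    """
    rng = np.random.default_rng(seed)
    strata = dict(zip(("canonical", "non_canonical"),
                      stratify_canonical(windows, labels)))
    rows: list[dict] = []
    metric_names = ("accuracy", "precision", "recall", "f1")
    for stratum, (s_windows, s_labels) in strata.items():
        s_labels = np.asarray(s_labels, dtype=bool)
        pos_idx = np.flatnonzero(s_labels)
        neg_idx = np.flatnonzero(~s_labels)
        for kind, idx in (("positive", pos_idx), ("negative", neg_idx)):
            if len(idx) < per_class:
                raise StratumTooSmallError(
                    f"stratum {stratum!r} has {len(idx)} {kind} windows, "
                    f"needs {per_class}"
                )
        # score each classifier once over the stratum, subset by indexing
        preds = {c.name: c.predict_many(s_windows) for c in classifiers}
        for subset in range(n_subsets):
            take = np.concatenate([
                rng.choice(pos_idx, size=per_class, replace=False),
                rng.choice(neg_idx, size=per_class, replace=False),
            ])
            y = s_labels[take]
            for c in classifiers:
                m = evaluate_classifier(preds[c.name][take], y)
                for metric, value in m.as_dict().items():
                    rows.append({
                        "classifier": c.name,
                        "stratum": stratum,
                        "subset": subset,
                        "metric": metric,
                        "value": value,
                    })
    metrics = pd.DataFrame(rows)
    welch_rows: list[dict] = []
    for stratum in strata:
        for metric in metric_names:
            for ca, cb in itertools.combinations(
                [c.name for c in classifiers], 2
            ):
                a = metrics.query(
                    "classifier == @ca and stratum == @stratum and metric == @metric"
                )["value"].to_numpy()
                b = metrics.query(
                    "classifier == @cb and stratum == @stratum and metric == @metric"
                )["value"].to_numpy()
                t, p = welch_two_tailed(a, b)
                welch_rows.append({
                    "stratum": stratum, "metric": metric,
                    "classifier_a": ca, "classifier_b": cb, "t": t, "p": p,
                })
    return StratifiedBenchmarkResult(
        metrics=metrics,
        welch=pd.DataFrame(welch_rows),
        n_subsets=n_subsets,
        per_class=per_class,
    )
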