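"""Labeled window dataset construction.

Two construction styles are provided, mirroring the two ways off-target
training corpora are commonly assembled from editor-treated ("positive")
and control ("negative") samples:

* sample-paired ("STL-style"): one positive and one negative source sample
  per split, 101-bp windows, with positives that also occur in the negative
  set subtracted (they evidence background substitution, not editing);
* pooled ("SNL-style"): all samples pooled per class, 40-bp windows,
  deduplicated within each class, cross-class duplicates removed from the
  positives and retained in the negatives, split 7:1.5:1.5, then balanced
  by downsampling the larger class per split.

Every removal/retention step is accounted for in a BookkeepingReport whose
counts are conserved (input = retained + removed at each stage).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyClassError, InconsistentWindowError
from .variant_profile import ContextWindow

__all__ = [
    "LabeledWindowSet",
    "BookkeepingReport",
    "subtract_overlaps",
    "deduplicate",
    "split_dataset",
    "split_sizes",
    "balance_classes",
    "build_stl_datasets",
    "build_snl_datasets",
]

SPLITS = ("train", "eval", "test")


@dataclass
class LabeledWindowSet:
    """A named collection of labeled context windows, optionally split-tagged."""

    windows: list[ContextWindow]
    name: str = ""
    split: str = "unsplit"  # train | eval | test | unsplit

    def __post_init__(self) -> None:
        if any(w.label is None for w in self.windows):
            raise InconsistentWindowError(f"unlabeled window in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    def count(self, label: str) -> int:
        return sum(1 for w in self.windows if w.label == label)


@dataclass
class BookkeepingReport:
    """Counts before/after each dataset-construction rule.

    ``stages`` maps a stage name to a dict of counts; conservation
    (input = retained + removed) is checkable per stage.
    """

    stages: dict[str, dict[str, int]] = field(default_factory=dict)

    def record(self, stage: str, **counts: int) -> None:
        self.stages[stage] = dict(counts)

    def conserved(self) -> bool:
        for counts in self.stages.values():
            if {"input", "retained", "removed"} <= counts.keys():
                if counts["input"] != counts["retained"] + counts["removed"]:
                    return False
        return True


def _label_all(windows: Sequence[ContextWindow], label: str) -> list[ContextWindow]:
    out = []
    for w in windows:
        if w.label != label:
            w = ContextWindow(
                sequence=w.sequence,
                site_offset=w.site_offset,
                upstream_len=w.upstream_len,
                downstream_len=w.downstream_len,
                label=label,
                origin=w.origin,
            )
        out.append(w)
    return out


def subtract_overlaps(
    positives: Sequence[ContextWindow],
    negatives: Sequence[ContextWindow],
    by_locus: bool = False,
) -> tuple[list[ContextWindow], list[ContextWindow], BookkeepingReport]:
    """Remove positives whose sequence occurs (exact match) among negatives.

    Negatives are returned unchanged; such sequences evidence substitutions
    present without the editor and stay negative. ``by_locus`` switches the
    overlap criterion from sequence identity to genomic origin identity
    (chrom, pos, strand); windows without an origin then never overlap.
    """
    if by_locus:
        neg_keys = {w.origin for w in negatives if w.origin is not None}
        kept = [w for w in positives
                if w.origin is None or w.origin not in neg_keys]
    else:
        neg_seqs = {w.sequence for w in negatives}
        kept = [w for w in positives if w.sequence not in neg_seqs]
    report = BookkeepingReport()
    report.record(
        "subtract_overlaps",
        input=len(positives),
        retained=len(kept),
        removed=len(positives) - len(kept),
    )
    return kept, list(negatives), report


def deduplicate(
    windows: Sequence[ContextWindow],
) -> tuple[list[ContextWindow], int]:
    """Drop exact duplicate sequences, keeping first occurrence in input order."""
    seen: set[str] = set()
    unique: list[ContextWindow] = []
    for w in windows:
        if w.sequence not in seen:
            seen.add(w.sequence)
            unique.append(w)
    return unique, len(windows) - len(unique)


def split_sizes(
    n: int, ratios: tuple[float, float, float] = (7.0, 1.5, 1.5)
) -> tuple[int, int, int]:
    """Split sizes: floor for eval and test, remainder to train.

    E.g. 68,380 items at 7:1.5:1.5 give 47,866 / 10,257 / 10,257.
    """
    if any(r <= 0 or not np.isfinite(r) for r in ratios):
        raise ConfigurationError(f"ratios must be positive finite, got {ratios}")
    total = sum(ratios)
    n_eval = int(n * ratios[1] / total)
    n_test = int(n * ratios[2] / total)
    return n - n_eval - n_test, n_eval, n_test


def split_dataset(
    windows: Sequence[ContextWindow],
    ratios: tuple[float, float, float] = (7.0, 1.5, 1.5),
    seed: int = 0,
) -> tuple[list[ContextWindow], list[ContextWindow], list[ContextWindow]]:
    """Random disjoint train/eval/test split at the given ratios.

    Sizes follow :func:`split_sizes` (floor for eval/test, remainder to
    train); membership is a seeded permutation, so identical seeds give
    identical splits.
    """
    n = len(windows)
    n_train, n_eval, n_test = split_sizes(n, ratios)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    items = [windows[i] for i in order]
    return (
        items[:n_train],
        items[n_train:n_train + n_eval],
        items[n_train + n_eval:],
    )


def balance_classes(
    positives: Sequence[ContextWindow],
    negatives: Sequence[ContextWindow],
    seed: int = 0,
) -> tuple[list[ContextWindow], list[ContextWindow]]:
    """Downsample the larger class (without replacement) to equal sizes."""
    if not positives or not negatives:
        raise EmptyClassError("both classes must be non-empty")
    target = min(len(positives), len(negatives))
    rng = np.random.default_rng(seed)

    def _sample(items: Sequence[ContextWindow]) -> list[ContextWindow]:
        if len(items) == target:
            return list(items)
        keep = np.sort(rng.choice(len(items), size=target, replace=False))
        return [items[i] for i in keep]

    return _sample(positives), _sample(negatives)


def build_stl_datasets(
    pos_by_sample: Mapping[str, Sequence[ContextWindow]],
    neg_by_sample: Mapping[str, Sequence[ContextWindow]],
    pairing: Mapping[str, tuple[str, str]],
) -> tuple[dict[str, LabeledWindowSet], BookkeepingReport]:
    """Sample-paired dataset construction (101-bp style).

    ``pairing`` maps each split name to a (positive sample, negative sample)
    pair. Per split, positives overlapping the paired negative set are
    subtracted; negatives pass through unchanged. No balancing or pooling.
    """
    report = BookkeepingReport()
    out: dict[str, LabeledWindowSet] = {}
    for split in SPLITS:
        if split not in pairing:
            raise ConfigurationError(f"pairing missing split {split!r}")
        pos_key, neg_key = pairing[split]
        if pos_key not in pos_by_sample or neg_key not in neg_by_sample:
            raise ConfigurationError(
                f"pairing for {split!r} names unknown sample(s) "
                f"{pos_key!r}/{neg_key!r}"
            )
        pos = _label_all(pos_by_sample[pos_key], "positive")
        neg = _label_all(neg_by_sample[neg_key], "negative")
        kept, neg, sub_report = subtract_overlaps(pos, neg)
        counts = sub_report.stages["subtract_overlaps"]
        report.record(
            f"{split}:subtract_overlaps",
            input=counts["input"],
            retained=counts["retained"],
            removed=counts["removed"],
            negatives=len(neg),
        )
        out[split] = LabeledWindowSet(
            windows=kept + neg, name=f"stl-{split}", split=split
        )
    return out, report


def build_snl_datasets(
    pos_pooled: Sequence[ContextWindow],
    neg_pooled: Sequence[ContextWindow],
    seed: int = 0,
    ratios: tuple[float, float, float] = (7.0, 1.5, 1.5),
    window_length: int | None = 40,
) -> tuple[dict[str, LabeledWindowSet], BookkeepingReport]:
    """Pooled dataset construction (40-bp style).

    Deduplicate within each class; remove cross-class duplicate sequences
    from the positives (retained in the negatives); split each class at
    ``ratios``; balance each split by downsampling the larger class.
    After construction no sequence string carries both labels.
    """
    if window_length is not None:
        for w in list(pos_pooled) + list(neg_pooled):
            if len(w.sequence) != window_length:
                raise InconsistentWindowError(
                    f"expected {window_length}-base windows, got {len(w.sequence)}"
                )
    report = BookkeepingReport()
    pos = _label_all(pos_pooled, "positive")
    neg = _label_all(neg_pooled, "negative")

    pos_unique, pos_dups = deduplicate(pos)
    neg_unique, neg_dups = deduplicate(neg)
    report.record(
        "dedup_positive",
        input=len(pos), retained=len(pos_unique), removed=pos_dups,
    )
    report.record(
        "dedup_negative",
        input=len(neg), retained=len(neg_unique), removed=neg_dups,
    )

    pos_clean, neg_unique, cross = subtract_overlaps(pos_unique, neg_unique)
    report.record(
        "cross_class_dedup",
        input=len(pos_unique),
        retained=len(pos_clean),
        removed=cross.stages["subtract_overlaps"]["removed"],
    )

    rng = np.random.default_rng(seed)
    pos_splits = split_dataset(pos_clean, ratios, seed=int(rng.integers(2**31)))
    neg_splits = split_dataset(neg_unique, ratios, seed=int(rng.integers(2**31)))

    out: dict[str, LabeledWindowSet] = {}
    for split, p, n in zip(SPLITS, pos_splits, neg_splits):
        p_bal, n_bal = balance_classes(p, n, seed=int(rng.integers(2**31)))
        report.record(
            f"{split}:balance",
            positives_in=len(p), negatives_in=len(n),
            positives=len(p_bal), negatives=len(n_bal),
        )
        out[split] = LabeledWindowSet(
            windows=p_bal + n_bal, name=f"snl-{split}", split=split
        )
    return out, report
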