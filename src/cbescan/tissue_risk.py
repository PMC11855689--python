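"""Tissue-level aggregation of per-transcript off-target risk.

Transcripts are grouped by a RefEx-style tissue-specificity table (1 =
tissue-specific high expression, -1 = tissue-specific low expression, 0 =
neither). Each tissue's group — the transcripts marked 1 for it — is
compared against the "All" background (every transcript with any nonzero
entry in any tissue) by a two-tailed Welch's t-test on ESD values; a tissue
is called "elevated" or "reduced" only when significant. High-risk
transcripts are those whose ESD exceeds the upper bound of the two-sided
95% t-interval for individual values fitted to the background
(mean + t_{0.975, n-1} * sd).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    DegenerateDistributionError,
    InsufficientReplicatesError,
)
from .stats import benjamini_hochberg, welch_two_tailed

__all__ = [
    "read_tissue_table",
    "collect_groups",
    "welch_two_tailed",
    "summarize",
    "high_risk_threshold",
    "extract_high_risk",
    "TissueRiskSummary",
    "HighRiskList",
]

ALL_GROUP = "All"


def read_tissue_table(path: str) -> pd.DataFrame:
    """Read a tissue-specificity TSV: first column transcript id, one column
    per tissue, entries in {1, -1, 0}. Lines starting with '#' are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    validate_tissue_table(df)
    return df


def validate_tissue_table(table: pd.DataFrame) -> None:
    if table.shape[1] < 1:
        raise ConfigurationError("tissue table needs at least one tissue column")
    values = table.to_numpy()
    if not np.isin(values, (-1, 0, 1)).all():
        bad = sorted(set(values.ravel()) - {-1, 0, 1})
        raise ConfigurationError(f"tissue table entries must be in {{1,-1,0}}, found {bad}")


def collect_groups(
    esd: Mapping[str, float], table: pd.DataFrame
) -> tuple[dict[str, np.ndarray], int]:
    """Per-tissue ESD vectors plus the "All" background vector.

    A tissue's group holds the ESDs of transcripts marked 1 for it; "All"
    holds transcripts with any nonzero entry in any tissue (a transcript
    may sit in several tissue groups). Table transcripts without an ESD
    record are dropped and counted in the returned integer.
    """
    validate_tissue_table(table)
    have = table.index.isin(esd.keys())
    dropped = int((~have).sum())
    table = table.loc[have]
    groups: dict[str, np.ndarray] = {}
    any_nonzero = (table != 0).any(axis=1)
    groups[ALL_GROUP] = np.array(
        [esd[t] for t in table.index[any_nonzero]], dtype=float
    )
    for tissue in table.columns:
        members = table.index[table[tissue] == 1]
        groups[str(tissue)] = np.array([esd[t] for t in members], dtype=float)
    return groups, dropped


@dataclass
class TissueRiskSummary:
    """Per-tissue ESD statistics and Welch-test results.

    ``table`` columns: tissue, n, mean, sem, t, p, p_adj, direction.
    The "All" row carries the background statistics (no test).
    """

    table: pd.DataFrame
    alpha: float
    dropped_transcripts: int = 0

    def row(self, tissue: str) -> pd.Series:
        return self.table.set_index("tissue").loc[tissue]


def summarize(
    esd: Mapping[str, float],
    table: pd.DataFrame,
    alpha: float = 0.05,
    adjust_flags: bool = False,
    exclude_self: bool = False,
) -> TissueRiskSummary:
    """Tissue summary: group means/SEMs, Welch tests vs "All", BH adjustment.

    Direction is "elevated"/"reduced" by the sign of (tissue mean - All
    mean) when the (raw, or BH-adjusted if ``adjust_flags``) p-value is
    below ``alpha``, else "n.s.". ``exclude_self`` removes the tested
    tissue's own transcripts from the background of its test (default: the
    literal all-transcripts background).
    """
    groups, dropped = collect_groups(esd, table)
    background = groups[ALL_GROUP]
    self_excluded: dict[str, np.ndarray] = {}
    if exclude_self:
        have = table.index.isin(esd.keys())
        sub = table.loc[have]
        any_nonzero = (sub != 0).any(axis=1)
        for tissue in sub.columns:
            members = sub.index[any_nonzero & (sub[tissue] != 1)]
            self_excluded[str(tissue)] = np.array(
                [esd[t] for t in members], dtype=float)
    rows: list[dict] = []
    for tissue, values in groups.items():
        row: dict = {
            "tissue": tissue,
            "n": len(values),
            "mean": float(np.mean(values)) if len(values) else np.nan,
            "sem": float(np.std(values, ddof=1) / np.sqrt(len(values)))
            if len(values) > 1
            else np.nan,
        }
        if tissue != ALL_GROUP:
            ref = self_excluded.get(tissue, background) if exclude_self \
                else background
            try:
                t, p = welch_two_tailed(values, ref)
            except InsufficientReplicatesError:
                t, p = np.nan, np.nan
            row["t"], row["p"] = t, p
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["p_adj"] = np.nan
    df.loc[tested, "p_adj"] = benjamini_hochberg(df.loc[tested, "p"])
    flag_p = df["p_adj"] if adjust_flags else df["p"]
    all_mean = df.loc[df["tissue"] == ALL_GROUP, "mean"].iloc[0]
    direction = []
    for _, row in df.iterrows():
        p = flag_p[row.name]
        if row["tissue"] == ALL_GROUP or not np.isfinite(p) or p >= alpha:
            direction.append("n.s.")
        else:
            direction.append("elevated" if row["mean"] > all_mean else "reduced")
    df["direction"] = direction
    return TissueRiskSummary(table=df, alpha=alpha, dropped_transcripts=dropped)


def high_risk_threshold(
    all_esds: Sequence[float],
    level: float = 0.95,
    scale: str = "sd",
    two_sided: bool = True,
) -> float:
    """Upper bound of the t-interval fitted to the background ESDs.

    Default: mean + t_{1-(1-level)/2, n-1} * sd — the two-sided interval
    for individual values. ``scale="sem"`` uses the interval of the mean
    instead; ``two_sided=False`` uses the one-sided quantile.
    """
    values = np.asarray(all_esds, dtype=float)
    if values.size < 3:
        raise InsufficientReplicatesError(
            f"need >=3 values to fit a t-interval, got {values.size}"
        )
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        return float(mean)
    if scale == "sem":
        sd = sd / np.sqrt(values.size)
    elif scale != "sd":
        raise ConfigurationError(f"scale must be 'sd' or 'sem', got {scale!r}")
    q = 1 - (1 - level) / 2 if two_sided else level
    return float(mean + sps.t.ppf(q, values.size - 1) * sd)


@dataclass
class HighRiskList:
    """Per-classifier high-risk transcript lists and intersection counts."""

    cutoff: float
    per_classifier: dict[str, list[str]]
    common: list[str]           # identified by every classifier
    unique: dict[str, list[str]]  # identified by exactly one
    union_count: int

    @property
    def common_count(self) -> int:
        return len(self.common)


def extract_high_risk(
    esd_by_classifier: Mapping[str, Mapping[str, float]],
    cutoff: float,
) -> HighRiskList:
    """Transcripts with ESD strictly above the cutoff, per classifier.

    Also reports the transcripts common to all classifiers and those unique
    to each; all lists are id-sorted for deterministic export.
    """
    if not esd_by_classifier:
        raise ConfigurationError("no classifiers given")
    per: dict[str, list[str]] = {}
    for name, esd in esd_by_classifier.items():
        per[name] = sorted(t for t, v in esd.items() if v > cutoff)
    sets = {name: set(ids) for name, ids in per.items()}
    common = set.intersection(*sets.values()) if sets else set()
    union = set.union(*sets.values()) if sets else set()
    unique = {
        name: sorted(
            ids - set.union(set(), *(s for n, s in sets.items() if n != name))
        )
        for name, ids in sets.items()
    }
    return HighRiskList(
        cutoff=cutoff,
        per_classifier=per,
        common=sorted(common),
        unique=unique,
        union_count=len(union),
    )
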