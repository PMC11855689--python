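"""Shared statistical primitives.

All two-group comparisons in the toolkit use Welch's unequal-variance
t-test, two-tailed. The test is delegated to scipy; the only additions are
the degenerate cases scipy leaves as NaN (two identical constant groups are
reported as t=0, p=1: no evidence of a difference, rather than undefined).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientReplicatesError

__all__ = ["welch_two_tailed", "benjamini_hochberg"]


def welch_two_tailed(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Welch's two-sample t statistic and two-tailed p-value.

    Raises :class:`InsufficientReplicatesError` for groups of size < 2.
    When both groups are constant and equal the test is reported as
    (t=0.0, p=1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"need >=2 values per group, got {a.size} and {b.size}"
        )
    # constant groups (up to float noise): no within-group variation
    scale = max(float(np.abs(a).max()), float(np.abs(b).max()), 1.0e-300)
    tol = 1e-9 * scale
    if a.std() <= tol and b.std() <= tol:
        if abs(a.mean() - b.mean()) <= tol:
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trip scipy's catastrophic-cancellation
        # warning; the exact-degenerate cases are handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (via statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]
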