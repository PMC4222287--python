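"""Moderated two-sample t-statistic and its permutation null distribution.

For each bin j the statistic is

    TS_j = (xbar_j1 - xbar_j2) / (S_j + cf)

with S_j the pooled standard error of the group-mean difference and cf a
small correction factor — the 5th percentile of all the S_j — that keeps
near-zero-intensity bins from producing 0/0-style statistics.  Rather than
assuming a t distribution, the null law of TS is estimated empirically by
recomputing the statistic under random permutations of the group labels,
which preserves the between-bin correlation structure of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateDataError,
    DegenerateStatisticError,
    DomainError,
)
from .models import SpectralMatrix, as_rng

#: Percentile of the pooled standard errors used as the correction factor.
CF_PERCENTILE = 5.0


@dataclass
class TestStatistics:
    """Per-bin statistics TS, their pooled SEs S, and the correction factor."""

    TS: np.ndarray
    S: np.ndarray
    cf: float


@dataclass
class PermutationNull:
    """T permutation replicates of the per-bin statistics.

    ``TS_perm`` and ``S_perm`` are T x p; row t corresponds to the label
    vector ``permutations[t]``.
    """

    TS_perm: np.ndarray
    S_perm: np.ndarray
    permutations: np.ndarray  # T x n array of group labels


def _group_stats(Xmat: np.ndarray, groups: np.ndarray):
    """Group-mean difference and pooled SE per column for a label vector."""
    mask1 = groups == 1
    mask2 = ~mask1
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError(
            f"each group needs >= 2 samples (got n1={n1}, n2={n2})"
        )
    X1 = Xmat[mask1]
    X2 = Xmat[mask2]
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    v1 = X1.var(axis=0, ddof=1)
    v2 = X2.var(axis=0, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    S = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)
    return m1 - m2, S


def pooled_se(X: SpectralMatrix) -> np.ndarray:
    """Pooled standard error of the two-group mean difference, per bin.

    S_j = sqrt[(1/n1 + 1/n2) * ((n1-1) s_j1^2 + (n2-1) s_j2^2) / (n1+n2-2)].
    """
    _, S = _group_stats(X.X, np.asarray(X.groups))
    return S


def correction_factor(S) -> float:
    """5th percentile of the pooled SEs, by linear interpolation.

    Uses the linear-interpolation percentile convention (NumPy's default,
    "type 7"): for S = (1, ..., 100) this gives 5.95.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise DomainError("cannot take a percentile of an empty SE vector")
    if (S < 0).any():
        raise DomainError("standard errors must be non-negative")
    return float(np.percentile(S, CF_PERCENTILE))


def _ts_from(diff: np.ndarray, S: np.ndarray, cf: float) -> np.ndarray:
    denom = S + cf
    zero = denom == 0
    if zero.any():
        bad = zero & (diff != 0)
        if bad.any():
            bins = np.flatnonzero(bad)
            raise DegenerateStatisticError(
                f"test statistic is x/0 for bins {bins.tolist()} "
                "(zero pooled SE and zero correction factor)",
                bins=bins,
            )
        # 0/0: identical data in both groups carry no evidence -> TS = 0
        denom = np.where(zero, 1.0, denom)
    return diff / denom


def t_statistics(X: SpectralMatrix, cf: float) -> TestStatistics:
    """Moderated statistics TS_j = (xbar_j1 - xbar_j2) / (S_j + cf).

    ``cf`` is held fixed (computed once from the unpermuted data) so that it
    describes the dataset's error scale, not any particular labelling.
    A bin with S_j = 0 *and* cf = 0 is the 0/0 case: if its group-mean
    difference is also 0 the statistic is defined as 0, otherwise a
    :class:`DegenerateStatisticError` names the offending bins.
    """
    if cf < 0:
        raise DomainError("correction factor must be non-negative")
    diff, S = _group_stats(X.X, np.asarray(X.groups))
    return TestStatistics(TS=_ts_from(diff, S, cf), S=S, cf=float(cf))


def permutation_null(X: SpectralMatrix, T: int, cf: float,
                     rng=None) -> PermutationNull:
    """Estimate the null law of TS by T random group-label permutations.

    Each permutation is an independent uniform draw over relabelings that
    preserve the group sizes (duplicates, including the identity, are
    permitted); the correction factor is held fixed across permutations.
    """
    if T < 1:
        raise DomainError(f"need at least one permutation, got T={T}")
    rng = as_rng(rng)
    labels = np.asarray(X.groups)
    TS_rows = np.empty((T, X.p))
    S_rows = np.empty((T, X.p))
    perms = np.empty((T, X.n), dtype=labels.dtype)
    for t in range(T):
        perm = rng.permutation(labels)
        diff, S = _group_stats(X.X, perm)
        TS_rows[t] = _ts_from(diff, S, cf)
        S_rows[t] = S
        perms[t] = perm
    return PermutationNull(TS_perm=TS_rows, S_perm=S_rows, permutations=perms)
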