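"""Permutation tests and FDR correction shared by the spectral and ERP stats.

Two nulls are implemented, both vectorised over an arbitrary trailing
feature axis (electrodes, or electrode x time points):

* paired: random sign flips of per-subject difference maps (the null of
  exchangeable condition labels within subject);
* unpaired: random relabelings of group membership.

When the full orbit (2^n sign patterns, or C(n, n_a) splits) does not
exceed the requested permutation count the test enumerates it exhaustively
and the p-value is exact. Otherwise p = (1 + #{perm >= observed}) / (1 + B)
with the identity permutation implicitly included.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests


@dataclass
class PermTestResult:
    """Per-feature permutation statistics with BH-FDR across features."""

    statistic: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    n_permutations: int
    tail: str
    kind: str
    exact: bool = False
    significant_fdr: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.significant_fdr is None:
            self.significant_fdr = self.p_fdr <= 0.05


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (shape preserved)."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    _, p_adj, _, _ = multipletests(flat, alpha=alpha, method="fdr_bh")
    return p_adj.reshape(p.shape)


def _tail_compare(null: np.ndarray, obs: np.ndarray, tail: str) -> np.ndarray:
    # permutation orbits contain exact ties up to round-off (e.g. a split and
    # its complement); count them as hits so exhaustive p-values are exact
    eps = 1e-10 * (1.0 + np.abs(obs))
    if tail == "greater":
        return null >= obs - eps
    if tail == "less":
        return null <= obs + eps
    if tail == "two-sided":
        return np.abs(null) >= np.abs(obs) - eps
    raise ValueError(f"unknown tail {tail!r}")


def paired_signflip_test(
    diffs: np.ndarray,
    tail: str = "greater",
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    kind: str = "paired-vs-neighbours",
) -> PermTestResult:
    """Sign-flip permutation test of mean(diffs) against zero.

    ``diffs``: (n_subjects, ...) per-subject difference maps. The test
    statistic is the subject mean per feature.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    obs = diffs.mean(axis=0)
    feat_shape = obs.shape
    flat = diffs.reshape(n, -1)

    exact = 2**n <= n_perm
    if exact:
        signs = np.array(
            [[1 if (m >> k) & 1 == 0 else -1 for k in range(n)] for m in range(2**n)],
            dtype=float,
        )
        null = signs @ flat / n
        hits = _tail_compare(null, obs.ravel()[None, :], tail).sum(axis=0)
        p = hits / signs.shape[0]  # identity pattern included -> p > 0
        b = signs.shape[0]
    else:
        rng = (
            np.random.default_rng(seed)
            if isinstance(seed, (int, np.integer))
            else seed
        )
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        null = signs @ flat / n
        hits = _tail_compare(null, obs.ravel()[None, :], tail).sum(axis=0)
        p = (1.0 + hits) / (1.0 + n_perm)
        b = n_perm
    p = p.reshape(feat_shape)
    return PermTestResult(obs, p, fdr_bh(p), b, tail, kind, exact)


def unpaired_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    tail: str = "two-sided",
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    kind: str = "unpaired-between-groups",
) -> PermTestResult:
    """Label-permutation test of mean(A) - mean(B).

    ``group_a``/``group_b``: (n_a, ...) and (n_b, ...) per-subject maps.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    obs = a.mean(axis=0) - b.mean(axis=0)
    feat_shape = obs.shape
    flat = pooled.reshape(na + nb, -1)
    total = flat.sum(axis=0)

    def stat_for(idx_a: np.ndarray) -> np.ndarray:
        sum_a = flat[idx_a].sum(axis=0)
        return sum_a / na - (total - sum_a) / nb

    n_splits = comb(na + nb, na)
    exact = n_splits <= n_perm
    if exact:
        null = np.stack(
            [stat_for(np.array(c)) for c in combinations(range(na + nb), na)]
        )
        hits = _tail_compare(null, obs.ravel()[None, :], tail).sum(axis=0)
        p = hits / n_splits
        nb_perm = n_splits
    else:
        rng = (
            np.random.default_rng(seed)
            if isinstance(seed, (int, np.integer))
            else seed
        )
        null = np.stack(
            [
                stat_for(rng.choice(na + nb, size=na, replace=False))
                for _ in range(n_perm)
            ]
        )
        hits = _tail_compare(null, obs.ravel()[None, :], tail).sum(axis=0)
        p = (1.0 + hits) / (1.0 + n_perm)
        nb_perm = n_perm
    p = p.reshape(feat_shape)
    return PermTestResult(obs, p, fdr_bh(p), nb_perm, tail, kind, exact)
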