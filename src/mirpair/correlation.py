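"""Spearman rank correlation over short ordered profiles, with an exact permutation test.

A miRNA that represses an mRNA should show an anti-monotone expression profile
across the six ordered cellular states, i.e. a strongly negative Spearman rho.
With only n = 6 observations per profile the null distribution of rho is
discrete (720 rank permutations), so the two-tailed p-value is computed by
exact enumeration rather than an asymptotic formula; a t-approximation is
provided for longer profiles. Ties (possible in synthetic or degenerate data)
are handled with midranks, in which case rho is the Pearson correlation of the
rank vectors — identical to the classical 1 - 6*sum(d_i^2)/(n(n^2-1)) formula
when ranks are tie-free.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

#: Numerical tolerance when counting permutations at the observed |rho|;
#: guards against float-boundary undercounting on the discrete rho grid.
RHO_TOL = 1e-12

EXACT_MAX_N = 8


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    """All n! orderings of positions 0..n-1, as an (n!, n) index array."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def rank_with_midranks(values) -> np.ndarray:
    """Ascending ranks with tied values receiving the mean of their positional ranks."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to rank")
    return stats.rankdata(values)


def _is_tie_free(ranks: np.ndarray) -> bool:
    return len(np.unique(ranks)) == len(ranks)


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """rho from two rank vectors; nan when either has zero rank variance."""
    n = len(rx)
    if _is_tie_free(rx) and _is_tie_free(ry):
        sd2 = float(((rx - ry) ** 2).sum())
        return 1.0 - 6.0 * sd2 / (n * (n * n - 1))
    ax = rx - rx.mean()
    ay = ry - ry.mean()
    vx = float((ax * ax).sum())
    vy = float((ay * ay).sum())
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float((ax * ay).sum() / math.sqrt(vx * vy))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation between two equal-length profiles (n >= 3).

    Tie-free profiles use the classical difference-of-ranks formula; ties fall
    back to the Pearson correlation of midranks (the two coincide when ranks
    are tie-free). Returns nan when either profile is constant after ranking
    (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    return _rho_from_ranks(rank_with_midranks(x), rank_with_midranks(y))


def exact_permutation_pvalue(rx, ry) -> float:
    """Exact two-tailed p from the rank vectors: the fraction of all n! permutations
    of ``ry`` whose |rho| reaches |rho_observed| (within RHO_TOL)."""
    rx = np.asarray(rx, dtype=float)
    ry = np.asarray(ry, dtype=float)
    n = rx.size
    if n > EXACT_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_MAX_N}")
    rho_obs = _rho_from_ranks(rx, ry)
    if math.isnan(rho_obs):
        return 1.0
    perms = ry[_permutation_matrix(n)]
    if _is_tie_free(rx) and _is_tie_free(ry):
        sd2 = ((perms - rx[None, :]) ** 2).sum(axis=1)
        rho_perm = 1.0 - 6.0 * sd2 / (n * (n * n - 1))
    else:
        ax = rx - rx.mean()
        b = perms - ry.mean()
        denom = math.sqrt(float((ax * ax).sum()) * float((b[0] * b[0]).sum()))
        rho_perm = (b @ ax) / denom
    m = int(np.count_nonzero(np.abs(rho_perm) >= abs(rho_obs) - RHO_TOL))
    return m / math.factorial(n)


def spearman_pvalue(rho: float, n: int, method: str = "exact-permutation") -> float:
    """Two-tailed p for an observed rho on tie-free profiles of length n.

    ``exact-permutation`` (default, n <= 8) enumerates all n! rank
    permutations — at n = 6 the attainable p-values form the grid m/720.
    ``t-approx`` uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df and falls back
    to the exact value at |rho| = 1 where the statistic diverges.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 - RHO_TOL <= rho <= 1.0 + RHO_TOL:
        raise ValueError("rho must lie in [-1, 1]")
    if method == "exact-permutation":
        base = np.arange(1.0, n + 1)
        perms = base[_permutation_matrix(n)]
        sd2 = ((perms - base[None, :]) ** 2).sum(axis=1)
        rho_perm = 1.0 - 6.0 * sd2 / (n * (n * n - 1))
        m = int(np.count_nonzero(np.abs(rho_perm) >= abs(rho) - RHO_TOL))
        return m / math.factorial(n)
    if method == "t-approx":
        if abs(abs(rho) - 1.0) < RHO_TOL:
            return spearman_pvalue(rho, n, method="exact-permutation")
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    raise ValueError(f"unknown method {method!r}")


def correlate_pair(x, y, method: str = "exact-permutation") -> tuple[float, float, str]:
    """(rho, two-tailed p, sign class) for one profile pair.

    Sign class is "positive"/"negative"/"none" per the sign of rho; an
    undefined rho (constant ranks) yields ("none", p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return float("nan"), 1.0, "none"
    rx, ry = rank_with_midranks(x), rank_with_midranks(y)
    if method == "exact-permutation":
        p = exact_permutation_pvalue(rx, ry)
    else:
        p = spearman_pvalue(rho, len(x), method=method)
    sign = "positive" if rho > 0 else ("negative" if rho < 0 else "none")
    return rho, p, sign


def correlate_all(
    mirna_profiles: pd.DataFrame,
    mrna_profiles: pd.DataFrame,
    rho_cut: float = 0.8,
    alpha: float = 0.05,
    method: str = "exact-permutation",
) -> tuple[pd.DataFrame, dict]:
    """Screen every miRNA x mRNA profile pair; keep |rho| > rho_cut (strict) and p <= alpha.

    Both inputs are transcripts x conditions DataFrames sharing the same
    ordered condition columns. Returns the passing pairs (columns mirna, mrna,
    rho, p, sign_class; negative pairs first, then by ascending rho magnitude
    is NOT imposed — rows are sorted by (sign_class, mirna, mrna) for
    determinism) plus a summary with partition counts and the number of
    unique mRNAs involved.
    """
    if list(mirna_profiles.columns) != list(mrna_profiles.columns):
        raise ValueError("profile condition order mismatch between channels")
    summary = {
        "n_mirnas": int(mirna_profiles.shape[0]),
        "n_mrnas": int(mrna_profiles.shape[0]),
        "n_pairs_tested": int(mirna_profiles.shape[0] * mrna_profiles.shape[0]),
    }
    if mirna_profiles.empty or mrna_profiles.empty:
        pairs = pd.DataFrame(columns=["mirna", "mrna", "rho", "p", "sign_class"])
        summary.update(
            n_negative=0, n_positive=0, n_unique_mrnas=0, n_constant_profiles=0
        )
        return pairs, summary

    rank_m = np.apply_along_axis(stats.rankdata, 1, mirna_profiles.to_numpy(dtype=float))
    rank_g = np.apply_along_axis(stats.rankdata, 1, mrna_profiles.to_numpy(dtype=float))

    def _normalize(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = rows - rows.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        constant = norms == 0
        norms[constant] = 1.0
        return centered / norms[:, None], constant

    a, const_m = _normalize(rank_m)
    b, const_g = _normalize(rank_g)
    rho_matrix = np.clip(a @ b.T, -1.0, 1.0)
    candidate = np.abs(rho_matrix) > rho_cut
    candidate[const_m, :] = False
    candidate[:, const_g] = False

    records = []
    mirna_ids = list(mirna_profiles.index)
    mrna_ids = list(mrna_profiles.index)
    for i, j in zip(*np.nonzero(candidate)):
        rx, ry = rank_m[i], rank_g[j]
        rho = _rho_from_ranks(rx, ry)
        if not abs(rho) > rho_cut:  # recheck with the canonical formula
            continue
        if method == "exact-permutation":
            p = exact_permutation_pvalue(rx, ry)
        else:
            p = spearman_pvalue(rho, rx.size, method=method)
        if p <= alpha:
            sign = "positive" if rho > 0 else "negative"
            records.append((mirna_ids[i], mrna_ids[j], rho, p, sign))
    pairs = pd.DataFrame(records, columns=["mirna", "mrna", "rho", "p", "sign_class"])
    pairs = pairs.sort_values(["sign_class", "mirna", "mrna"]).reset_index(drop=True)
    summary.update(
        n_negative=int((pairs["sign_class"] == "negative").sum()),
        n_positive=int((pairs["sign_class"] == "positive").sum()),
        n_unique_mrnas=int(pairs["mrna"].nunique()),
        n_constant_profiles=int(const_m.sum() + const_g.sum()),
    )
    return pairs, summary
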