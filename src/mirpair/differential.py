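"""Differential-expression calling: fold change gated by ANOVA / Mann-Whitney.

Each contrast compares one test condition against a reference (receptor-positive
vs receptor-negative at baseline, then each hormone time point vs
receptor-positive). A transcript is called up/down in a contrast iff its signed
fold change on the condition geometric means strictly exceeds the threshold in
magnitude AND its adjusted p-value is at most alpha. The Mann-Whitney test is
computed exactly at replicate scale by enumerating all C(n+m, n) labelings of
the pooled midranks, which remains valid under ties.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import StudyDesign
from .expression import ExpressionMatrix

_GATES = ("either", "both", "anova", "mw")


def signed_fold_change(ref_mean: float, test_mean: float) -> float:
    """Signed expression ratio: test/ref if test >= ref, else -(ref/test).

    Magnitude is always >= 1; the sign carries the direction of change.
    """
    if ref_mean <= 0 or test_mean <= 0:
        raise ValueError("fold change requires positive means")
    if test_mean >= ref_mean:
        return test_mean / ref_mean
    return -(ref_mean / test_mean)


def anova_pvalue(groups) -> float:
    """One-way fixed-effects ANOVA p-value across >= 2 replicate groups.

    Degenerate inputs use the natural limits: all values identical -> p = 1
    (no evidence of separation); zero within-group variance with unequal
    means -> p = 0 (perfect separation).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    if ss_within == 0.0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.f_oneway(*arrays).pvalue
    return 1.0 if math.isnan(p) else float(p)


def mann_whitney_pvalue(a, b, mode: str = "exact") -> float:
    """Two-sided Mann-Whitney p-value.

    ``exact`` enumerates every C(|a|+|b|, |a|) assignment of the pooled
    midranks to group a and doubles the smaller tail (capped at 1); this is
    feasible at replicate scale and correct under ties. ``normal-approx``
    delegates to the asymptotic normal test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "normal-approx":
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    n, m = a.size, b.size
    if math.comb(n + m, n) > 500_000:
        raise ValueError("exact enumeration infeasible at this size; use normal-approx")
    pooled_ranks = stats.rankdata(np.concatenate([a, b]))
    observed = float(pooled_ranks[:n].sum())
    tol = 1e-9
    lo = hi = total = 0
    for combo in itertools.combinations(range(n + m), n):
        s = float(pooled_ranks[list(combo)].sum())
        total += 1
        if s <= observed + tol:
            lo += 1
        if s >= observed - tol:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``fdr_bh`` (default) is the Benjamini-Hochberg step-up with enforced
    monotonicity; ``bonferroni`` and ``none`` are also accepted.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=method)[1]


def _gate(p_anova: np.ndarray, p_mw: np.ndarray, gate: str) -> np.ndarray:
    if gate == "both":
        return np.maximum(p_anova, p_mw)
    if gate == "either":
        return np.minimum(p_anova, p_mw)
    if gate == "anova":
        return p_anova
    if gate == "mw":
        return p_mw
    raise ValueError(f"unknown gate {gate!r}; expected one of {_GATES}")


def call_differential(
    profiles: pd.DataFrame,
    matrix: ExpressionMatrix,
    design: StudyDesign,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    gate: str = "either",
    adjust_method: str = "fdr_bh",
    mw_mode: str = "exact",
) -> pd.DataFrame:
    """Call differential transcripts for the baseline and each treatment contrast.

    Fold change is computed on the per-condition geometric means (``profiles``);
    the two tests run on the replicate intensities. ``gate`` picks which raw
    p-value feeds adjustment: "either" = min of the two tests, "both" = max,
    or a single test. Adjustment is applied per contrast across all
    transcripts. Status is up/down iff |fold_change| > fc_threshold (strict)
    and p_adj <= alpha (inclusive).

    Returns one row per (transcript, contrast) with columns
    transcript, contrast, reference, test, fold_change, p_anova, p_mw,
    p_adj, status.
    """
    if gate not in _GATES:
        raise ValueError(f"unknown gate {gate!r}; expected one of {_GATES}")
    for _, ref, test in design.contrasts():
        for cond in (ref, test):
            if cond not in design.conditions:
                raise ValueError(f"unknown condition {cond!r}")
    transcripts = list(profiles.index)
    values = matrix.values.loc[transcripts]
    frames = []
    for name, ref, test in design.contrasts():
        ref_reps = values[design.samples_for(ref)].to_numpy()
        test_reps = values[design.samples_for(test)].to_numpy()
        fc = np.array(
            [
                signed_fold_change(r, t)
                for r, t in zip(profiles[ref].to_numpy(), profiles[test].to_numpy())
            ]
        )
        p_anova = np.array(
            [anova_pvalue([ref_reps[i], test_reps[i]]) for i in range(len(transcripts))]
        )
        p_mw = np.array(
            [
                mann_whitney_pvalue(ref_reps[i], test_reps[i], mode=mw_mode)
                for i in range(len(transcripts))
            ]
        )
        p_adj = adjust_pvalues(_gate(p_anova, p_mw, gate), method=adjust_method)
        called = (np.abs(fc) > fc_threshold) & (p_adj <= alpha)
        status = np.where(called, np.where(fc > 0, "up", "down"), "unchanged")
        frames.append(
            pd.DataFrame(
                {
                    "transcript": transcripts,
                    "contrast": name,
                    "reference": ref,
                    "test": test,
                    "fold_change": fc,
                    "p_anova": p_anova,
                    "p_mw": p_mw,
                    "p_adj": p_adj,
                    "status": status,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def differential_transcripts(calls: pd.DataFrame, contrasts=None) -> set[str]:
    """Transcripts with status != unchanged in any of the given contrasts (default: all)."""
    mask = calls["status"] != "unchanged"
    if contrasts is not None:
        mask &= calls["contrast"].isin(set(contrasts))
    return set(calls.loc[mask, "transcript"])


def treatment_responsive(calls: pd.DataFrame, design: StudyDesign) -> set[str]:
    """Transcripts differential in at least one hormone-treatment contrast."""
    names = [name for name, _, _ in design.treatment_contrasts()]
    return differential_transcripts(calls, contrasts=names)
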