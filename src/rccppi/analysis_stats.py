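"""Separability diagnostics and per-feature screening.

Two complementary views of how positive and negative PPI clouds sit in RCC
space:

* geometry — the diameter D of the negative set (largest within-set
  Euclidean distance) against the smallest between-set distance d.  The
  clouds are "distance separable" when the gap exceeds the negative set's
  spread (d > D).  Linear separability is decided exactly, as feasibility of
  a strict-margin hyperplane.
* per-feature statistics — a two-sided rank-sum (Mann-Whitney/Wilcoxon)
  test per feature with Bonferroni or Benjamini-Hochberg correction, and the
  fraction of instances with a nonzero value per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from scipy.optimize import linprog
from scipy.spatial.distance import cdist, pdist
from statsmodels.stats.multitest import multipletests

#: Combined sample size below which the rank-sum p-value is computed by
#: exhaustive enumeration of group assignments (handles ties exactly).
EXACT_ENUMERATION_MAX_N = 20


@dataclass(frozen=True)
class SeparabilityReport:
    D: float  # diameter of the designated (negative) set
    d: float  # minimum inter-set distance
    distance_separable: bool
    D_pos: float = float("nan")  # diameter of the positive set, for reference
    configuration: str = ""


@dataclass(frozen=True)
class FeatureScreenReport:
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    degenerate: np.ndarray
    method: str
    alpha: float


def set_diameter(vectors: np.ndarray) -> float:
    """Maximum Euclidean distance between any pair of rows (0 for one row)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] == 0:
        raise ValueError("need at least one vector")
    if vectors.shape[0] == 1:
        return 0.0
    return float(pdist(vectors).max())


def inter_set_min_distance(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Smallest Euclidean distance across the two sets."""
    set_a = np.atleast_2d(np.asarray(set_a, dtype=float))
    set_b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if set_a.shape[0] == 0 or set_b.shape[0] == 0:
        raise ValueError("both sets must be non-empty")
    return float(cdist(set_a, set_b).min())


def distance_separability(
    pos: np.ndarray, neg: np.ndarray, configuration: str = ""
) -> SeparabilityReport:
    """d > D test with D computed on the negative set.

    The positive set's diameter is reported alongside for reference.
    """
    D = set_diameter(neg)
    d = inter_set_min_distance(pos, neg)
    return SeparabilityReport(
        D=D, d=d, distance_separable=d > D,
        D_pos=set_diameter(pos), configuration=configuration,
    )


def linear_separability(pos: np.ndarray, neg: np.ndarray) -> tuple[bool, np.ndarray | None]:
    """Exact strict linear separability via LP feasibility.

    Feasible iff there exist w, b with w.x + b >= 1 on pos and <= -1 on neg
    (any strictly separating hyperplane can be rescaled to this margin), so
    the answer does not depend on a soft-margin tolerance.  Returns
    ``(flag, witness)`` where witness = (w_1..w_d, b) when separable.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if pos.shape[0] == 0 or neg.shape[0] == 0:
        raise ValueError("both sets must be non-empty")
    d = pos.shape[1]
    # variables: w (d) then b; constraints A_ub x <= b_ub
    A = np.vstack(
        [
            np.hstack([-pos, -np.ones((pos.shape[0], 1))]),  # -(w.x + b) <= -1
            np.hstack([neg, np.ones((neg.shape[0], 1))]),  # w.x + b <= -1
        ]
    )
    b_ub = -np.ones(A.shape[0])
    res = linprog(
        c=np.zeros(d + 1), A_ub=A, b_ub=b_ub,
        bounds=[(None, None)] * (d + 1), method="highs",
    )
    if res.status == 0:
        return True, res.x
    return False, None


def _exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Tie-averaged ranks are fixed under permutation, so the statistic for an
    assignment is just the rank sum of the first group.  The permutation
    distribution of U is symmetric about mn/2 (with or without ties), and
    the two-sided p is P(|U - mn/2| >= |u_obs - mn/2|).
    """
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    mid = n1 * n2 / 2.0
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    dev = abs(u_obs - mid)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mid) >= dev - 1e-9:
            hits += 1
    return hits / comb(n1 + n2, n1)


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum test of two independent samples.

    Exact enumeration for combined n below ``EXACT_ENUMERATION_MAX_N``;
    tie-corrected normal approximation (with continuity correction)
    otherwise.  Degenerate input (all values identical across both groups)
    returns 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(pooled) < EXACT_ENUMERATION_MAX_N:
        return _exact_ranksum_pvalue(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``bh`` (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        key = "bonferroni"
    elif method in ("bh", "benjamini-hochberg", "fdr_bh"):
        key = "fdr_bh"
    else:
        raise ValueError(f"unknown correction method: {method!r}")
    return multipletests(p, method=key)[1]


def feature_screen(
    pos: np.ndarray, neg: np.ndarray, correction: str = "bonferroni", alpha: float = 0.05
) -> FeatureScreenReport:
    """Per-feature rank-sum screen of positive vs negative instances.

    Each of the 26 (or 52) features is tested for a class-conditional
    location difference; the correction is applied across features.
    Features constant across both classes are marked degenerate (p = 1).
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("both classes need at least two instances")
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("feature counts differ between classes")
    n_feat = pos.shape[1]
    p_raw = np.empty(n_feat)
    degenerate = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        col = np.concatenate([pos[:, j], neg[:, j]])
        if np.all(col == col[0]):
            degenerate[j] = True
            p_raw[j] = 1.0
        else:
            p_raw[j] = rank_sum_pvalue(pos[:, j], neg[:, j])
    p_adj = adjust_pvalues(p_raw, correction)
    return FeatureScreenReport(
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=p_adj < alpha,
        degenerate=degenerate,
        method=correction,
        alpha=alpha,
    )


def nonzero_fraction_profile(features: np.ndarray) -> np.ndarray:
    """Per-feature fraction of instances with a strictly nonzero value."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] == 0:
        raise ValueError("dataset must be non-empty")
    return np.mean(features != 0, axis=0)
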