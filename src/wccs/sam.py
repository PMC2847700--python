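"""Permutation-based differential expression in the SAM style.

Two flavours are provided:

* :func:`sam_two_class` — unpaired two-class comparison. The per-feature
  statistic is ``d = (mean_case - mean_control) / (s + s0)`` where ``s`` is
  the pooled standard error and ``s0`` a small exchangeability constant
  (a fixed percentile of the ``s`` distribution) that damps features with
  tiny scatter. False-discovery rates come from permuting group labels.

* :func:`sam_quantitative` — each feature's expression regressed on a
  continuous covariate; the statistic is the slope over its (damped)
  standard error, with FDR from permuting the covariate.

q-values are reported on a 0-100 percent scale. The null proportion pi0 is
taken as 1, which makes the FDR estimate conservative: under a global null
the realized call rate at nominal q stays at or below nominal.

All randomness flows through an explicit integer seed; when the number of
distinct label assignments is small (<= n_perm) the permutation set is
enumerated exhaustively instead of sampled, making small-pool designs
(e.g. 4 vs 4 pools) exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .datamodel import ExpressionMatrix, PhenotypeTable

_EPS = 1e-12


@dataclass
class DiffResult:
    """Per-feature differential-expression record.

    fold_change is the linear ratio on group means, folded to >= 1 with the
    sign carried by ``direction`` ("up" = higher in the case group). For the
    quantitative test, where a case/control ratio is undefined, fold_change
    is fixed at 1.0 and direction carries the sign of the association.
    q_value is percent FDR in [0, 100].
    """

    feature_id: str
    d_stat: float
    fold_change: float
    q_value: float
    direction: str  # "up" | "down" | "none"


def results_to_frame(results: list[DiffResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "d_stat": [r.d_stat for r in results],
            "fold_change": [r.fold_change for r in results],
            "q_value": [r.q_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# internals


def _two_class_scatter(X: np.ndarray, case: np.ndarray, ctrl: np.ndarray):
    """Mean difference and pooled standard error per feature (rows of X)."""
    n1, n2 = len(ctrl), len(case)
    m_ctrl = X[:, ctrl].mean(axis=1)
    m_case = X[:, case].mean(axis=1)
    ss = X[:, ctrl].var(axis=1, ddof=1) * (n1 - 1) + X[:, case].var(axis=1, ddof=1) * (n2 - 1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m_case - m_ctrl, s


def _two_class_d_matrix(
    X: np.ndarray, assignments: np.ndarray, n_case: int, s0: float
) -> np.ndarray:
    """d-statistics for every permuted labelling, vectorised.

    assignments: (K, n) boolean, True marks the permuted case group.
    Returns (p, K).
    """
    n = X.shape[1]
    n_ctrl = n - n_case
    A = assignments.T.astype(float)  # n x K
    X2 = X**2
    sum_case = X @ A
    sum_all = X.sum(axis=1, keepdims=True)
    sum_ctrl = sum_all - sum_case
    m_case = sum_case / n_case
    m_ctrl = sum_ctrl / n_ctrl
    sq_case = X2 @ A
    sq_ctrl = X2.sum(axis=1, keepdims=True) - sq_case
    ss = (sq_case - n_case * m_case**2) + (sq_ctrl - n_ctrl * m_ctrl**2)
    ss = np.maximum(ss, 0.0)
    s = np.sqrt((1.0 / n_ctrl + 1.0 / n_case) * ss / (n - 2))
    return (m_case - m_ctrl) / (s + s0)


def _permutation_assignments(
    n: int, n_case: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (K, n) case-group assignments: exhaustive when feasible."""
    total = comb(n, n_case)
    if total <= n_perm:
        out = np.zeros((total, n), dtype=bool)
        for k, idx in enumerate(combinations(range(n), n_case)):
            out[k, list(idx)] = True
        return out
    out = np.zeros((n_perm, n), dtype=bool)
    for k in range(n_perm):
        out[k, rng.choice(n, size=n_case, replace=False)] = True
    return out


def _q_values(d: np.ndarray, d_null: np.ndarray) -> np.ndarray:
    """Percent q-values from observed and permuted statistics.

    For each threshold t = |d_(i)| (descending), the FDR estimate is the
    mean number of null statistics at or beyond t per permutation, over the
    observed number of calls; the q-value of a feature is the minimum FDR
    over all thresholds that include it, which makes q monotone
    non-decreasing down the ranking.
    """
    p = d.size
    k_perm = d_null.shape[1]
    a = np.abs(d)
    order = np.argsort(-a, kind="stable")
    thresholds = a[order]
    null_sorted = np.sort(np.abs(d_null).ravel())
    n_null = null_sorted.size
    exceed = n_null - np.searchsorted(null_sorted, thresholds, side="left")
    expected_false = exceed / k_perm
    called = np.arange(1, p + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = 100.0 * expected_false / called
    fdr = np.minimum(fdr, 100.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(p)
    q[order] = q_sorted
    return q


def _fold_and_direction(m_case: np.ndarray, m_ctrl: np.ndarray):
    """Linear fold magnitude (>=1) and direction from group means."""
    fc = np.ones_like(m_case)
    direction = np.full(m_case.shape, "none", dtype=object)
    up = m_case > m_ctrl
    down = m_case < m_ctrl
    with np.errstate(divide="ignore"):
        fc[up] = m_case[up] / np.maximum(m_ctrl[up], _EPS)
        fc[down] = m_ctrl[down] / np.maximum(m_case[down], _EPS)
    direction[up] = "up"
    direction[down] = "down"
    return fc, direction


# ---------------------------------------------------------------------------
# public API


def sam_two_class(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    case_group: str = "T2D",
    control_group: str = "NGT",
    n_perm: int = 1000,
    seed: int = 0,
    s0_percentile: float = 5.0,
) -> list[DiffResult]:
    """SAM-style unpaired two-class test of case vs control samples.

    Results come back in the input feature order. Deterministic given
    ``seed``; swapping case and control flips every d sign and leaves
    q-values unchanged (the statistic is label-antisymmetric and the
    permutation null is sign-symmetric).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    case_samples = [s for s in m.sample_ids if s in set(pheno.samples_in(case_group))]
    ctrl_samples = [s for s in m.sample_ids if s in set(pheno.samples_in(control_group))]
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError(
            f"each group needs >=2 samples (case {case_group}: {len(case_samples)}, "
            f"control {control_group}: {len(ctrl_samples)})"
        )
    # canonical sample order + permuted subsets of the smaller group size
    # make the permutation null identical whichever group plays "case", so
    # swapping labels flips d exactly and preserves q
    samples = sorted(ctrl_samples + case_samples)
    X = m.values[samples].to_numpy(dtype=float)
    n = len(samples)
    n_case = len(case_samples)
    case_set = set(case_samples)
    case_idx = np.array([i for i, s in enumerate(samples) if s in case_set])
    ctrl_idx = np.array([i for i, s in enumerate(samples) if s not in case_set])

    diff, s = _two_class_scatter(X, case_idx, ctrl_idx)
    s0 = float(np.percentile(s, s0_percentile))
    d = diff / (s + s0)

    rng = np.random.default_rng(seed)
    k = min(n_case, n - n_case)
    assignments = _permutation_assignments(n, k, n_perm, rng)
    if n_case != k:
        assignments = ~assignments
    # chunk the permutation block to bound peak memory on large matrices
    chunk = max(1, int(2e7) // max(X.shape[0], 1))
    d_null = np.hstack(
        [
            _two_class_d_matrix(X, assignments[i:i + chunk], n_case, s0)
            for i in range(0, assignments.shape[0], chunk)
        ]
    )
    q = _q_values(d, d_null)

    m_case = X[:, case_idx].mean(axis=1)
    m_ctrl = X[:, ctrl_idx].mean(axis=1)
    fc, direction = _fold_and_direction(m_case, m_ctrl)
    return [
        DiffResult(fid, float(d[i]), float(fc[i]), float(q[i]), str(direction[i]))
        for i, fid in enumerate(m.feature_ids)
    ]


def sam_quantitative(
    m: ExpressionMatrix,
    covariate_values,
    n_perm: int = 1000,
    seed: int = 0,
    s0_percentile: float = 5.0,
    method: str = "slope",
) -> list[DiffResult]:
    """Quantitative SAM: per-feature association with a continuous covariate.

    ``method='slope'`` uses the least-squares slope over its damped standard
    error; ``method='pearson'`` uses the t-transformed correlation. q-values
    come from permuting the covariate across samples.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    y = np.asarray(covariate_values, dtype=float)
    if y.ndim != 1 or y.size != len(m.sample_ids):
        raise ValueError("covariate length must match the number of samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("covariate contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("covariate is constant; quantitative SAM is undefined")
    if method not in ("slope", "pearson"):
        raise ValueError(f"unknown method {method!r}")

    X = m.values.to_numpy(dtype=float)
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)

    def stats_for(yv: np.ndarray, s0: float | None):
        yc = yv - yv.mean()
        denom = float(yc @ yc)
        b = Xc @ yc / denom
        if method == "pearson":
            sx2 = (Xc**2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(sx2 > 0, (Xc @ yc) / np.sqrt(sx2 * denom), 0.0)
            r = np.clip(r, -0.999999999, 0.999999999)
            se = np.sqrt((1 - r**2) / (n - 2))
            if s0 is None:
                s0 = float(np.percentile(se, s0_percentile))
            return r / (se + s0), s0, b
        rss = np.maximum((Xc**2).sum(axis=1) - b**2 * denom, 0.0)
        se = np.sqrt(rss / (n - 2) / denom)
        if s0 is None:
            s0 = float(np.percentile(se, s0_percentile))
        return b / (se + s0), s0, b

    d, s0, slope = stats_for(y, None)
    rng = np.random.default_rng(seed)
    d_null = np.empty((X.shape[0], n_perm))
    for k in range(n_perm):
        d_null[:, k] = stats_for(rng.permutation(y), s0)[0]
    q = _q_values(d, d_null)

    results = []
    for i, fid in enumerate(m.feature_ids):
        di = float(d[i])
        direction = "up" if slope[i] > 0 else ("down" if slope[i] < 0 else "none")
        results.append(DiffResult(fid, di, 1.0, float(q[i]), direction))
    return results
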