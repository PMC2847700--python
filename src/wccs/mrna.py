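"""mRNA-side analyses: detection-call filtering and gene-subset statistics.

The differential machinery itself lives in :mod:`wccs.sam`; this module
adds the Affymetrix-style pre-filter (drop probe sets absent on every
chip) and the subset-comparison statistics used to probe coordinated
shifts of curated gene collections (e.g. an OXPHOS set) against clinical
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, PhenotypeTable
from .sam import sam_quantitative, sam_two_class  # noqa: F401  (re-exported surface)


def filter_absent(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features whose detection call is 'A' on every sample.

    A feature survives if at least one call is P or M. Requires calls;
    matrices without calls must skip this stage explicitly.
    """
    if m.calls is None:
        raise ValueError(
            "matrix has no P/M/A calls; skip absent filtering explicitly "
            "for call-free data"
        )
    keep_mask = (m.calls != "A").any(axis=1)
    keep = [f for f, k in zip(m.feature_ids, keep_mask) if k]
    return m.subset_features(keep)


@dataclass
class SubsetComparison:
    """Group medians and regression statistics for a gene subset.

    medians: per-feature median intensity within each group (features x
    groups). median_slope is the least-squares slope of the second group's
    per-feature medians on the first's (the line-of-equality diagnostic).
    slope/intercept/r_squared/p_value describe the regression of the
    per-sample subset summary on the clinical covariate (NaN when no
    covariate was supplied).
    """

    medians: pd.DataFrame
    median_slope: float
    summary: pd.Series
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def subset_comparison(
    m: ExpressionMatrix,
    subset_ids: Iterable[str],
    pheno: PhenotypeTable,
    groups: Sequence[str] = ("NGT", "T2D"),
    covariate: str | Sequence[float] | None = None,
    summary: str = "median",
) -> SubsetComparison:
    """Compare a gene subset across clinical groups and against a covariate.

    The per-sample subset summary defaults to the median over the subset's
    features (mean available via ``summary='mean'``).
    """
    subset = [f for f in m.feature_ids if f in set(subset_ids)]
    if not subset:
        raise ValueError("subset is empty or disjoint from the matrix features")
    missing = set(subset_ids) - set(m.feature_ids)
    if missing:
        raise ValueError(f"subset ids not in matrix: {sorted(missing)[:5]}")
    sub = m.values.loc[subset]

    med = {}
    for g in groups:
        samples = [s for s in m.sample_ids if s in set(pheno.samples_in(g))]
        if not samples:
            raise ValueError(f"group {g!r} has no samples in the matrix")
        med[g] = sub[samples].median(axis=1)
    medians = pd.DataFrame(med)

    if len(groups) >= 2:
        x, y = medians[groups[0]].to_numpy(), medians[groups[1]].to_numpy()
        if np.ptp(x) == 0:
            median_slope = float("nan") if np.ptp(y) else 1.0  # degenerate: flat subset
        else:
            median_slope = float(stats.linregress(x, y).slope)
    else:
        median_slope = float("nan")

    if summary == "median":
        per_sample = sub.median(axis=0)
    elif summary == "mean":
        per_sample = sub.mean(axis=0)
    else:
        raise ValueError(f"unknown summary {summary!r}")

    slope = intercept = r2 = p = float("nan")
    if covariate is not None:
        if isinstance(covariate, str):
            cov = pheno.covariate(covariate, m.sample_ids).to_numpy()
        else:
            cov = np.asarray(covariate, dtype=float)
            if cov.size != len(m.sample_ids):
                raise ValueError("covariate length must match sample count")
        fit = stats.linregress(cov, per_sample.to_numpy())
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2, p = float(fit.rvalue**2), float(fit.pvalue)

    return SubsetComparison(
        medians=medians,
        median_slope=median_slope,
        summary=per_sample,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
    )
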