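"""miRNA array processing and validation statistics.

Covers the miRNA arm of the study design: quantile normalization of pooled
array profiles, the 400-unit expressed cutoff, SAM-based differential
calling gated by fold change, classification of the NGT->IGT->T2D
trajectory of each differential miRNA, comparison against an external
direction map (e.g. myogenic-differentiation profiles), and TaqMan
delta-Ct statistics normalized to a small-RNA reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CLINICAL_GROUPS, ExpressionMatrix, PhenotypeTable
from .sam import DiffResult, sam_two_class

log = logging.getLogger(__name__)

DEFAULT_EXPRESSED_CUTOFF = 400.0


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-mean) intensity distribution.

    Each column's sorted values are replaced by the across-column means of
    the sorted columns, assigned back in rank order; within-column ranks
    are preserved and the operation is idempotent.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    X = m.values.to_numpy(dtype=float)
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = mean_sorted[ranks]
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, calls=None if m.calls is None else m.calls.copy(),
                            platform=m.platform)


def expressed_filter(
    m: ExpressionMatrix, cutoff: float = DEFAULT_EXPRESSED_CUTOFF
) -> ExpressionMatrix:
    """Keep miRNAs whose median intensity across samples is >= cutoff.

    The cutoff separates expressed probes from background signal on
    quantile-normalized data; the comparison is inclusive.
    """
    medians = m.values.median(axis=1)
    keep = [f for f, v in medians.items() if v >= cutoff]
    return m.subset_features(keep)


def diff_mirnas(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    case_group: str = "T2D",
    control_group: str = "NGT",
    fdr_pct: float = 10.0,
    min_fold: float = 1.3,
    n_perm: int = 1000,
    seed: int = 0,
    only_called: bool = True,
) -> list[DiffResult]:
    """Differential miRNAs: SAM two-class then a strict fold-change gate.

    A miRNA is called when q <= fdr_pct AND its linear fold magnitude
    exceeds min_fold strictly (>30% modulation at the default 1.3). Pools
    are the statistical unit: n per group is the number of pooled profiles.
    Set ``only_called=False`` to get the full table.
    """
    results = sam_two_class(
        m, pheno, case_group=case_group, control_group=control_group,
        n_perm=n_perm, seed=seed,
    )
    if not only_called:
        return results
    return [
        r
        for r in results
        if r.q_value <= fdr_pct and r.fold_change > min_fold and r.direction != "none"
    ]


@dataclass
class PatternClass:
    """Trajectory class of a differential miRNA across NGT -> IGT -> T2D.

    progressive: shifts at IGT and keeps going (or holds) into T2D;
    transient_igt: shifts at IGT then reverts to near-control in T2D;
    late_t2d: near-control at IGT, shifted only in T2D.
    A differential miRNA matching none of the rules is reported with
    pattern None (unclassified) and a warning.
    """

    mirna_id: str
    direction: str  # "up" | "down"
    pattern: str | None  # "progressive" | "transient_igt" | "late_t2d" | None


def classify_patterns(
    means_ngt: Mapping[str, float],
    means_igt: Mapping[str, float],
    means_t2d: Mapping[str, float],
    diff_calls: list[DiffResult],
    tol: float | Mapping[str, float],
) -> list[PatternClass]:
    """Assign each differential miRNA one trajectory class (or none).

    ``tol`` is the intensity tolerance deciding "within control range";
    pass a mapping for per-miRNA tolerances (e.g. 0.5x the pooled
    within-group SD).
    """
    out: list[PatternClass] = []
    for call in diff_calls:
        mid = call.mirna_id if hasattr(call, "mirna_id") else call.feature_id
        t = float(tol[mid]) if isinstance(tol, Mapping) else float(tol)
        ngt, igt, t2d = float(means_ngt[mid]), float(means_igt[mid]), float(means_t2d[mid])
        sign = 1.0 if call.direction == "up" else -1.0
        d_igt = sign * (igt - ngt)   # progression at IGT, in the called direction
        d_t2d = sign * (t2d - ngt)
        d_step = sign * (t2d - igt)
        if d_igt > t and abs(d_t2d) <= t:
            pattern = "transient_igt"
        elif abs(d_igt) <= t and d_t2d > t:
            pattern = "late_t2d"
        elif d_igt > t and d_t2d > t and d_step > -t:
            pattern = "progressive"
        else:
            pattern = None
            log.warning(
                "miRNA %s (direction %s) matches no trajectory class "
                "(NGT=%.3g IGT=%.3g T2D=%.3g tol=%.3g)", mid, call.direction, ngt, igt, t2d, t,
            )
        out.append(PatternClass(mirna_id=mid, direction=call.direction, pattern=pattern))
    return out


def pattern_tolerances(
    m: ExpressionMatrix, pheno: PhenotypeTable, scale: float = 0.5
) -> dict[str, float]:
    """Per-miRNA tolerance: ``scale`` x pooled within-group SD of intensity."""
    parts = []
    for g in CLINICAL_GROUPS:
        samples = [s for s in m.sample_ids if s in set(pheno.samples_in(g))]
        if len(samples) >= 2:
            sub = m.values[samples]
            parts.append(((sub.sub(sub.mean(axis=1), axis=0)) ** 2).sum(axis=1))
    if not parts:
        raise ValueError("no group has >=2 samples; cannot estimate tolerances")
    ss = sum(parts)
    dof = sum(
        max(len([s for s in m.sample_ids if s in set(pheno.samples_in(g))]) - 1, 0)
        for g in CLINICAL_GROUPS
    )
    pooled_sd = np.sqrt(ss / max(dof, 1))
    return {f: float(scale * pooled_sd[f]) for f in m.feature_ids}


def group_means(m: ExpressionMatrix, pheno: PhenotypeTable) -> dict[str, pd.Series]:
    """Per-group mean intensity per miRNA, keyed by clinical group."""
    out = {}
    for g in CLINICAL_GROUPS:
        samples = [s for s in m.sample_ids if s in set(pheno.samples_in(g))]
        if samples:
            out[g] = m.values[samples].mean(axis=1)
    return out


def inverse_profile_overlap(
    disease_dirs: Mapping[str, str], differentiation_dirs: Mapping[str, str]
) -> tuple[int, list[str]]:
    """miRNAs whose disease direction is the exact opposite of a reference.

    Both maps use "up"/"down" over a shared miRNA id space; the overlap is
    the ids present in both maps with strictly opposite directions.
    """
    shared = set(disease_dirs) & set(differentiation_dirs)
    if not shared:
        log.warning("direction maps share no miRNA ids")
        return 0, []
    flipped = sorted(
        mid
        for mid in shared
        if {disease_dirs[mid], differentiation_dirs[mid]} == {"up", "down"}
    )
    return len(flipped), flipped


# ---------------------------------------------------------------------------
# TaqMan delta-Ct statistics


@dataclass
class DeltaCtResult:
    """Per-assay qPCR summary from delta-Ct quantification.

    Fold change vs NGT is 2^-(ddCt); post hoc p-values are Welch t-tests
    per group pair (optionally Holm-adjusted). Regression fields describe
    delta-Ct against the chosen clinical covariate.
    """

    mirna_id: str
    mean_dct: dict[str, float]
    fold_change: dict[str, float]
    anova_f: float
    anova_p: float
    posthoc_p: dict[tuple[str, str], float] = field(default_factory=dict)
    r_squared: float = float("nan")
    regression_p: float = float("nan")


def delta_ct_stats(
    ct_table: pd.DataFrame,
    pheno: PhenotypeTable,
    reference_id: str = "RNU48",
    covariate: str | None = None,
    holm: bool = True,
) -> list[DeltaCtResult]:
    """Delta-Ct statistics for every assay in a replicate Ct table.

    ``ct_table`` is long-format with columns sample_id, assay_id, ct (one
    row per technical replicate). Replicates are averaged per (sample,
    assay) before differencing against the reference assay; higher delta-Ct
    means lower expression.
    """
    for col in ("sample_id", "assay_id", "ct"):
        if col not in ct_table.columns:
            raise ValueError(f"ct_table missing column {col!r}")
    mean_ct = ct_table.groupby(["sample_id", "assay_id"])["ct"].mean().unstack()
    if reference_id not in mean_ct.columns:
        raise ValueError(f"reference assay {reference_id!r} not in Ct table")
    dct = mean_ct.drop(columns=[reference_id]).sub(mean_ct[reference_id], axis=0)

    groups = [g for g in CLINICAL_GROUPS if pheno.samples_in(g)]
    results: list[DeltaCtResult] = []
    for assay in dct.columns:
        per_group = {
            g: dct.loc[[s for s in dct.index if s in set(pheno.samples_in(g))], assay].dropna()
            for g in groups
        }
        means = {g: float(v.mean()) for g, v in per_group.items()}
        ngt = means.get("NGT", float("nan"))
        fold = {g: float(2.0 ** (-(means[g] - ngt))) for g in means}
        arrays = [v.to_numpy() for v in per_group.values() if len(v) >= 2]
        if len(arrays) < 2:
            f_stat, p = float("nan"), float("nan")
        elif np.ptp(np.concatenate(arrays)) == 0:  # all values identical
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*arrays)
            if not np.isfinite(f_stat):
                f_stat, p = 0.0, 1.0
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        raw = {}
        for a, b in pairs:
            if len(per_group[a]) >= 2 and len(per_group[b]) >= 2:
                tp = stats.ttest_ind(per_group[a], per_group[b], equal_var=False).pvalue
                raw[(a, b)] = 1.0 if not np.isfinite(tp) else float(tp)
        posthoc = dict(raw)
        if holm and raw:
            from statsmodels.stats.multitest import multipletests

            keys = list(raw)
            adj = multipletests([raw[k] for k in keys], method="holm")[1]
            posthoc = {k: float(v) for k, v in zip(keys, adj)}
        r2 = reg_p = float("nan")
        if covariate is not None:
            cov = pheno.covariate(covariate, dct.index).to_numpy()
            vals = dct[assay].to_numpy()
            ok = np.isfinite(cov) & np.isfinite(vals)
            if ok.sum() >= 3 and np.ptp(cov[ok]) > 0:
                fit = stats.linregress(cov[ok], vals[ok])
                r2, reg_p = float(fit.rvalue**2), float(fit.pvalue)
        results.append(
            DeltaCtResult(
                mirna_id=str(assay),
                mean_dct=means,
                fold_change=fold,
                anova_f=float(f_stat),
                anova_p=float(p),
                posthoc_p=posthoc,
                r_squared=r2,
                regression_p=reg_p,
            )
        )
    return results
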