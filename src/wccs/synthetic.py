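"""Synthetic microarray inputs with planted ground truth.

Every pipeline input can be generated at a chosen scale with known truth:
a (by default null) mRNA intensity matrix over three clinical groups with
P/M/A detection calls; a pooled miRNA matrix with a planted fraction of
expressed miRNAs shifted up or down between control and disease, realizing
progressive / transient / late trajectories across the intermediate group;
a target-site database with predominantly negative, right-skewed context
scores and optional coherent targeting of chosen gene sets; gene-set
collections; and a triplicate qPCR Ct table.

Intensities are log-normal with array-like dynamic range (~2 to ~50,000)
so the 400-unit expressed cutoff is meaningful. All generators are fully
deterministic given their integer seed (NumPy PCG64 via default_rng).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    CLINICAL_GROUPS,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
    SITE_COLUMNS,
    TargetSiteTable,
)

# Clinical covariate (mean, sd) per group, in the units of the phenotype
# table: fasting glucose and 2-h glucose mmol/L, fasting insulin pmol/L,
# HbA1c %, BMI kg/m^2. Values follow the cohort characteristics the study
# design emulates.
_COVARIATE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "fasting_glucose": {"NGT": (5.0, 0.4), "IGT": (5.9, 0.5), "T2D": (9.8, 4.4)},
    "fasting_insulin": {"NGT": (56.6, 8.3), "IGT": (88.2, 13.5), "T2D": (91.2, 8.9)},
    "hba1c": {"NGT": (5.5, 0.2), "IGT": (5.8, 0.3), "T2D": (7.4, 1.8)},
    "glucose_2h": {"NGT": (5.5, 1.2), "IGT": (7.4, 2.4), "T2D": (17.9, 5.5)},
    "bmi": {"NGT": (31.1, 7.2), "IGT": (30.9, 6.1), "T2D": (31.4, 6.2)},
}


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to score every downstream stage."""

    modulated_mirnas: dict[str, tuple[str, float]] = field(default_factory=dict)
    pattern_classes: dict[str, str] = field(default_factory=dict)
    expressed_mirnas: list[str] = field(default_factory=list)
    below_cutoff_mirnas: list[str] = field(default_factory=list)
    shifted_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    all_absent_genes: list[str] = field(default_factory=list)
    targeted_genes_up: list[str] = field(default_factory=list)
    targeted_genes_down: list[str] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["modulated_mirnas"] = {
            k: [d, float(f)] for k, (d, f) in self.modulated_mirnas.items()
        }
        payload["shifted_genes"] = {
            k: [d, float(f)] for k, (d, f) in self.shifted_genes.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["modulated_mirnas"] = {
            k: (d, float(f)) for k, (d, f) in payload.get("modulated_mirnas", {}).items()
        }
        payload["shifted_genes"] = {
            k: (d, float(f)) for k, (d, f) in payload.get("shifted_genes", {}).items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# mRNA matrix


@dataclass(frozen=True)
class PlantedEffect:
    """A block of features shifted by a common linear fold in one group."""

    n_genes: int
    fold: float
    direction: str = "up"
    group: str = "T2D"


def gen_mrna_matrix(
    n_genes: int = 20_000,
    n_per_group: Mapping[str, int] | None = None,
    effect_spec: Sequence[PlantedEffect] | None = None,
    noise_sd: float = 0.25,
    frac_all_absent: float = 0.1,
    seed: int = 0,
    call_threshold: float = 50.0,
) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Generate an mRNA intensity matrix, phenotypes and truth.

    Baseline log2 intensities are gene-specific Normal(7, 2.5) draws
    (linear scale roughly 2-50,000); per-sample noise is Normal(0,
    noise_sd) on log2. ``effect_spec=None`` is the null (invariant
    transcriptome) case; planted effects multiply the stated group's
    intensities. A ``frac_all_absent`` fraction of features is generated
    at background level and flagged 'A' on every chip; other features are
    guaranteed at least one non-absent call.
    """
    if n_per_group is None:
        n_per_group = {"NGT": 47, "IGT": 26, "T2D": 45}
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"group {g} needs >=2 samples, got {n}")
    effects = list(effect_spec or [])
    for e in effects:
        if e.direction not in ("up", "down") or e.fold < 1 or e.group not in n_per_group:
            raise ValueError(f"invalid planted effect: {e}")
    if sum(e.n_genes for e in effects) > n_genes * (1 - frac_all_absent):
        raise ValueError("planted effects exceed the number of non-absent features")

    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    samples, group_of = [], {}
    for g in CLINICAL_GROUPS:
        for i in range(n_per_group.get(g, 0)):
            sid = f"{g}_{i:03d}"
            samples.append(sid)
            group_of[sid] = g
    n_samples = len(samples)

    n_absent = int(round(frac_all_absent * n_genes))
    absent_idx = rng.choice(n_genes, size=n_absent, replace=False)
    is_absent = np.zeros(n_genes, dtype=bool)
    is_absent[absent_idx] = True

    base = rng.normal(7.0, 2.5, size=n_genes)
    base = np.clip(base, np.log2(call_threshold) + 1.0, 15.6)  # expressed floor
    base[is_absent] = rng.normal(2.5, 0.8, size=n_absent)  # background level

    log2x = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    # planted shifts on distinct non-absent features
    truth = SyntheticTruth(params={"seed": seed, "n_genes": n_genes,
                                   "n_per_group": dict(n_per_group),
                                   "noise_sd": noise_sd,
                                   "frac_all_absent": frac_all_absent})
    available = list(np.flatnonzero(~is_absent))
    rng.shuffle(available)
    cursor = 0
    for e in effects:
        idx = available[cursor:cursor + e.n_genes]
        cursor += e.n_genes
        cols = [j for j, s in enumerate(samples) if group_of[s] == e.group]
        shift = np.log2(e.fold) * (1 if e.direction == "up" else -1)
        log2x[np.ix_(idx, cols)] += shift
        for i in idx:
            truth.shifted_genes[genes[i]] = (e.direction, float(e.fold))
    truth.all_absent_genes = sorted(genes[i] for i in absent_idx)

    X = 2.0 ** log2x
    calls = np.where(X >= call_threshold, "P", np.where(X >= call_threshold / 2, "M", "A"))
    calls[is_absent, :] = "A"
    # guarantee the planted-absent set is exactly the all-absent set
    for i in np.flatnonzero(~is_absent):
        if (calls[i] == "A").all():
            calls[i, int(np.argmax(X[i]))] = "M"

    values = pd.DataFrame(X, index=genes, columns=samples)
    calls_df = pd.DataFrame(calls, index=genes, columns=samples)
    m = ExpressionMatrix(values=values, calls=calls_df, platform="synthetic-mrna")

    pheno_rows = {}
    for sid in samples:
        g = group_of[sid]
        row = {"group": g}
        for cov, params in _COVARIATE_PARAMS.items():
            mu, sd = params[g]
            row[cov] = float(np.clip(rng.normal(mu, sd), 0.1, None))
        pheno_rows[sid] = row
    pheno = PhenotypeTable(pd.DataFrame.from_dict(pheno_rows, orient="index"))
    return m, pheno, truth


# ---------------------------------------------------------------------------
# miRNA matrix


def gen_mirna_matrix(
    n_mirnas: int = 245,
    n_pools_per_group: int = 4,
    frac_up: float = 29 / 171,
    frac_down: float = 33 / 171,
    fold_range: tuple[float, float] = (1.5, 3.0),
    frac_below_cutoff: float = 0.30,
    noise_sd: float = 0.15,
    frac_transient: float = 0.08,
    progressive_frac: float = 0.7,
    cutoff: float = 400.0,
    log2_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Generate pooled miRNA array profiles with planted directional shifts.

    Baseline intensities are a single continuous log-normal distribution —
    log2 intensity Normal(mu, log2_sd) with mu placed so that an expected
    ``frac_below_cutoff`` of miRNAs fall below the expressed ``cutoff``;
    the cutoff then splits one distribution, as on a real chip, rather than
    separating artificial intensity blocks (a discontinuous baseline
    interacts pathologically with rank-based quantile normalization). Of
    the expressed miRNAs, ``frac_up``/``frac_down`` are shifted up/down in
    T2D pools by a fold drawn from ``fold_range``; shifts are planted on
    robustly expressed miRNAs (baseline >= 2.5x the cutoff) so the planted
    truth survives the expressed filter. Each shifted miRNA follows either
    a progressive trajectory (half the log2 shift already present at IGT)
    or a late one (IGT at control level), in ``progressive_frac``
    proportion. A further ``frac_transient`` of unmodulated expressed
    miRNAs carry an IGT-only excursion (the transient class) and, having
    no NGT-vs-T2D shift, are not part of the modulated truth.
    """
    if frac_up + frac_down >= 1:
        raise ValueError("frac_up + frac_down must be < 1")
    if not (0 <= frac_below_cutoff < 1):
        raise ValueError("frac_below_cutoff must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mirnas = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    samples, group_of = [], {}
    for g in CLINICAL_GROUPS:
        for i in range(n_pools_per_group):
            sid = f"{g}_pool{i}"
            samples.append(sid)
            group_of[sid] = g

    from scipy.stats import norm

    mu = np.log2(cutoff) - log2_sd * norm.ppf(frac_below_cutoff)
    base = rng.normal(mu, log2_sd, size=n_mirnas)
    is_below = base < np.log2(cutoff)
    expressed_idx = np.flatnonzero(~is_below)
    n_expressed = expressed_idx.size

    n_up = int(round(frac_up * n_expressed))
    n_down = int(round(frac_down * n_expressed))
    robust = np.flatnonzero(base >= np.log2(2.5 * cutoff))
    if n_up + n_down > robust.size:
        raise ValueError(
            f"cannot plant {n_up + n_down} modulated miRNAs: only "
            f"{robust.size} are robustly expressed"
        )
    shuffled = robust.copy()
    rng.shuffle(shuffled)
    up_idx = shuffled[:n_up]
    down_idx = shuffled[n_up:n_up + n_down]
    rest = np.array([i for i in expressed_idx if i not in set(shuffled[:n_up + n_down])])
    n_transient = int(round(frac_transient * n_expressed))
    transient_idx = rest[:n_transient] if rest.size else rest

    truth = SyntheticTruth(params={
        "seed": seed, "n_mirnas": n_mirnas, "n_pools_per_group": n_pools_per_group,
        "frac_up": frac_up, "frac_down": frac_down, "fold_range": list(fold_range),
        "frac_below_cutoff": frac_below_cutoff, "noise_sd": noise_sd,
        "frac_transient": frac_transient, "progressive_frac": progressive_frac,
    })
    truth.expressed_mirnas = sorted(mirnas[i] for i in expressed_idx)
    truth.below_cutoff_mirnas = sorted(mirnas[i] for i in np.flatnonzero(is_below))

    # per-miRNA log2 shift for IGT and T2D columns
    shift_igt = np.zeros(n_mirnas)
    shift_t2d = np.zeros(n_mirnas)
    for idx, direction in ((up_idx, "up"), (down_idx, "down")):
        sign = 1.0 if direction == "up" else -1.0
        folds = rng.uniform(*fold_range, size=idx.size)
        progressive = rng.random(idx.size) < progressive_frac
        for j, i in enumerate(idx):
            mid = mirnas[i]
            truth.modulated_mirnas[mid] = (direction, float(folds[j]))
            lf = np.log2(folds[j]) * sign
            shift_t2d[i] = lf
            if progressive[j]:
                shift_igt[i] = lf / 2.0
                truth.pattern_classes[mid] = "progressive"
            else:
                truth.pattern_classes[mid] = "late_t2d"
    t_folds = rng.uniform(1.5, 2.0, size=transient_idx.size)
    t_signs = rng.choice([-1.0, 1.0], size=transient_idx.size)
    for j, i in enumerate(transient_idx):
        shift_igt[i] = np.log2(t_folds[j]) * t_signs[j]
        truth.pattern_classes[mirnas[i]] = "transient_igt"

    log2x = np.empty((n_mirnas, len(samples)))
    for j, sid in enumerate(samples):
        g = group_of[sid]
        shift = shift_t2d if g == "T2D" else (shift_igt if g == "IGT" else 0.0)
        log2x[:, j] = base + shift + rng.normal(0.0, noise_sd, size=n_mirnas)

    values = pd.DataFrame(2.0 ** log2x, index=mirnas, columns=samples)
    m = ExpressionMatrix(values=values, platform="synthetic-mirna")
    pheno = PhenotypeTable(
        pd.DataFrame({"group": [group_of[s] for s in samples]}, index=samples)
    )
    return m, pheno, truth


# ---------------------------------------------------------------------------
# target-site database


def gen_target_db(
    genes: Sequence[str],
    mirna_changes: Mapping[str, tuple[str, float]],
    mean_sites_per_pair: float = 0.005,
    coherent_sets: Mapping[str, tuple[Sequence[str], str]] | None = None,
    sites_per_coherent_gene: int = 3,
    coherent_score_range: tuple[float, float] = (-0.45, -0.25),
    extra_mirnas: Sequence[str] = (),
    seed: int = 0,
) -> tuple[TargetSiteTable, SyntheticTruth]:
    """Generate a target-site table with negative, right-skewed scores.

    Background sites are sprinkled Poisson(mean_sites_per_pair) per
    (miRNA, gene) pair with scores drawn as -(0.02 + Gamma(2, 0.05)):
    bulk near -0.1, tail to about -0.6. The default density puts roughly a
    quarter of the expressed genes under at least one conserved site of a
    ~60-strong modulated miRNA cohort, the proportion seen on real
    tissue-restricted conserved-site tables. ``coherent_sets`` maps a term id
    to (member genes, direction): each member receives
    ``sites_per_coherent_gene`` extra strong sites from distinct miRNAs
    modulated in that direction, so the term's genes should surface in
    the corresponding Q1 list. ``extra_mirnas`` adds unmodulated miRNAs
    to the background (their sites are dropped by target restriction).
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    all_mirnas = list(mirna_changes) + list(extra_mirnas)
    site_types = np.array(["8mer", "7mer-m8", "7mer-1a"])

    records: list[tuple[str, str, str, float]] = []
    if mean_sites_per_pair > 0 and genes and all_mirnas:
        counts = rng.poisson(mean_sites_per_pair, size=(len(all_mirnas), len(genes)))
        mi_idx, ge_idx = np.nonzero(counts)
        for mi, ge in zip(mi_idx, ge_idx):
            for _ in range(counts[mi, ge]):
                score = -(0.02 + rng.gamma(2.0, 0.05))
                st = site_types[rng.integers(len(site_types))]
                records.append((all_mirnas[mi], genes[ge], str(st), float(score)))

    truth = SyntheticTruth(params={
        "seed": seed, "mean_sites_per_pair": mean_sites_per_pair,
        "sites_per_coherent_gene": sites_per_coherent_gene,
        "coherent_score_range": list(coherent_score_range),
    })
    up_pool = [m for m, (d, _) in mirna_changes.items() if d == "up"]
    down_pool = [m for m, (d, _) in mirna_changes.items() if d == "down"]
    for term, (members, direction) in (coherent_sets or {}).items():
        pool = down_pool if direction == "down" else up_pool
        if len(pool) < sites_per_coherent_gene:
            raise ValueError(
                f"term {term}: not enough {direction}-regulated miRNAs "
                f"({len(pool)} < {sites_per_coherent_gene})"
            )
        for gene in members:
            chosen = rng.choice(len(pool), size=sites_per_coherent_gene, replace=False)
            for c in chosen:
                score = float(rng.uniform(*coherent_score_range))
                st = site_types[rng.integers(len(site_types))]
                records.append((pool[c], gene, str(st), score))
        truth.enriched_terms.append(term)
        if direction == "down":
            truth.targeted_genes_up.extend(members)   # de-repressed -> protein up
        else:
            truth.targeted_genes_down.extend(members)

    df = pd.DataFrame(records, columns=SITE_COLUMNS)
    return TargetSiteTable(df), truth


def gen_gene_sets(
    genes: Sequence[str],
    n_terms: int = 30,
    size_range: tuple[int, int] = (10, 40),
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random flat gene-set collection, with optional planted terms included."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    mapping: dict[str, Iterable[str]] = {}
    for t, members in (planted or {}).items():
        mapping[t] = list(members)
    for i in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        idx = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        mapping[f"RAND{i:04d}"] = [genes[j] for j in idx]
    return GeneSetCollection.from_mapping(mapping)


# ---------------------------------------------------------------------------
# qPCR Ct table


def gen_ct_table(
    fold_changes: Mapping[str, Mapping[str, float]],
    n_per_group: int = 10,
    replicate_sd: float = 0.1,
    n_replicates: int = 3,
    base_ct: float = 25.0,
    reference_id: str = "RNU48",
    reference_ct: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PhenotypeTable]:
    """Triplicate Ct values consistent with planted 2^-ddCt fold changes.

    ``fold_changes`` maps assay id to {group: linear fold vs NGT}; a fold
    of 0.5 in T2D plants a 1-cycle increase in delta-Ct there. With
    ``replicate_sd=0`` recovery is exact.
    """
    rng = np.random.default_rng(seed)
    samples, group_of = [], {}
    for g in CLINICAL_GROUPS:
        for i in range(n_per_group):
            sid = f"{g}_{i:02d}"
            samples.append(sid)
            group_of[sid] = g
    rows = []
    for sid in samples:
        g = group_of[sid]
        for _ in range(n_replicates):
            rows.append((sid, reference_id, reference_ct + rng.normal(0, replicate_sd)))
        for assay, folds in fold_changes.items():
            fold = float(folds.get(g, 1.0))
            ct = base_ct - np.log2(fold)
            for _ in range(n_replicates):
                rows.append((sid, assay, ct + rng.normal(0, replicate_sd)))
    ct_table = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct"])
    pheno = PhenotypeTable(
        pd.DataFrame({"group": [group_of[s] for s in samples]}, index=samples)
    )
    return ct_table, pheno
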