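"""Cumulative and weighted cumulative context scoring of miRNA target genes.

The scoring model: every conserved target site carries a context score
(<= 0; more negative = stronger predicted repression). Summing a gene's
site scores over all disease-modulated miRNAs gives its cumulative context
score (CCS). Weighting each site score by the linear fold-change magnitude
of its miRNA's disease shift — sites of up-regulated miRNAs accumulating
separately from sites of down-regulated ones — gives the weighted CCS
(wCCS). The most negative quartile (Q1) of each directional wCCS
distribution is the candidate list: Q1 targets of down-regulated miRNAs
are predicted de-repressed (protein up), Q1 targets of up-regulated
miRNAs predicted further repressed (protein down).

Genes landing in both Q1 lists are resolved by the net score
``net = wccs_from_down - wccs_from_up``: a gene is retained only in the
direction whose targeting dominates, and only if the imbalance is itself
of Q1 strength; balanced genes are predicted unchanged — the behaviour
expected for proteins targeted equally by both miRNA cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix, PhenotypeTable, TargetSiteTable


@dataclass
class GeneTargetScore:
    """Aggregate targeting scores for one expressed gene."""

    gene_id: str
    ccs: float = 0.0
    wccs_from_up: float = 0.0
    wccs_from_down: float = 0.0
    net_wccs: float = 0.0
    quartile_up: int | None = None
    quartile_down: int | None = None
    predicted_direction: str = "none"  # "protein_up" | "protein_down" | "none"


@dataclass
class WccsLists:
    """Final directional predictions with the overlap audit trail.

    q1_protein_up: genes dominated by down-regulated miRNAs (de-repressed).
    q1_protein_down: genes dominated by up-regulated miRNAs.
    overlap_resolved: per-gene audit of every double-Q1 gene (scores, net,
    boundary used, outcome). The two lists are disjoint by construction.
    """

    q1_protein_up: list[str]
    q1_protein_down: list[str]
    overlap_resolved: pd.DataFrame
    boundary_up: float = float("nan")
    boundary_down: float = float("nan")


def restrict_targets(
    sites: TargetSiteTable,
    expressed_genes: Iterable[str],
    modulated_mirnas: Iterable[str],
) -> TargetSiteTable:
    """Keep sites whose gene is tissue-expressed AND whose miRNA is modulated."""
    genes = set(expressed_genes)
    mirnas = set(modulated_mirnas)
    df = sites.sites
    kept = df[df["gene_id"].isin(genes) & df["mirna_id"].isin(mirnas)]
    if kept.empty:
        raise ValueError(
            "no target sites survive restriction to expressed genes and "
            "modulated miRNAs; the ranking has no input"
        )
    return TargetSiteTable(kept.reset_index(drop=True))


def compute_ccs(sites: TargetSiteTable) -> dict[str, float]:
    """Per-gene sum of context scores over all sites (the CCS)."""
    s = sites.sites.groupby("gene_id")["context_score"].sum()
    return {str(g): float(v) for g, v in s.items()}


def compute_wccs(
    sites: TargetSiteTable,
    mirna_changes: Mapping[str, tuple[str, float]],
    weight: str = "linear",
) -> dict[str, GeneTargetScore]:
    """Weight each site score by its miRNA's disease fold change.

    ``mirna_changes`` maps miRNA id to (direction, linear fold magnitude
    >= 1). Per site, the weighted score is context_score x weight(fold);
    sites of up-regulated miRNAs accumulate into wccs_from_up, of
    down-regulated into wccs_from_down. ``weight='linear'`` uses the fold
    magnitude itself; ``weight='log2'`` uses 1 + log2(fold) (identical at
    fold 1, gentler growth).
    """
    if weight not in ("linear", "log2"):
        raise ValueError(f"unknown weight mode {weight!r}")
    df = sites.sites
    missing = sorted(set(df["mirna_id"]) - set(mirna_changes))
    if missing:
        raise ValueError(f"site miRNAs missing from mirna_changes: {missing}")
    for mid, (direction, fold) in mirna_changes.items():
        if direction not in ("up", "down"):
            raise ValueError(f"miRNA {mid}: direction must be 'up' or 'down'")
        if not fold >= 1.0:
            raise ValueError(f"miRNA {mid}: fold magnitude must be >= 1, got {fold}")

    def w(fold: float) -> float:
        return fold if weight == "linear" else 1.0 + float(np.log2(fold))

    scores: dict[str, GeneTargetScore] = {}
    for row in df.itertuples(index=False):
        direction, fold = mirna_changes[row.mirna_id]
        g = scores.setdefault(row.gene_id, GeneTargetScore(gene_id=row.gene_id))
        g.ccs += row.context_score
        weighted = row.context_score * w(fold)
        if direction == "up":
            g.wccs_from_up += weighted
        else:
            g.wccs_from_down += weighted
    for g in scores.values():
        g.net_wccs = g.wccs_from_down - g.wccs_from_up
    return scores


def quartile_stratify(scores: Mapping[str, float]) -> dict[str, int]:
    """Quartile assignment: Q1 = the most negative (most targeted) 25%.

    Boundaries are rank-based on the ascending sort; genes tied on a
    boundary score all take the better (lower-numbered) quartile, so Q1
    may slightly exceed 25% under ties — with all scores equal, every gene
    is Q1.
    """
    items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    if n < 4:
        raise ValueError(f"quartile stratification needs >=4 genes, got {n}")
    vals = [v for _, v in items]
    cuts = [vals[int(np.ceil(n * k / 4)) - 1] for k in (1, 2, 3)]
    out = {}
    for g, v in items:
        if v <= cuts[0]:
            out[g] = 1
        elif v <= cuts[1]:
            out[g] = 2
        elif v <= cuts[2]:
            out[g] = 3
        else:
            out[g] = 4
    return out


def _q1_boundary(scores: Mapping[str, float], quartiles: Mapping[str, int]) -> float:
    """Least negative score still inside Q1 (the Q1/Q2 cut value)."""
    return max(scores[g] for g, q in quartiles.items() if q == 1)


def resolve_overlap(
    gene_scores: Mapping[str, GeneTargetScore],
    quartiles_up: Mapping[str, int],
    quartiles_down: Mapping[str, int],
) -> WccsLists:
    """Resolve double-Q1 genes into disjoint directional prediction lists.

    Inputs are the quartile maps computed independently on the two
    directional wCCS distributions (over genes with any site in that
    direction). Genes only in Q1 of the down-miRNA distribution pass
    through as protein_up (reduced repression), mirror for up. A gene in
    both Q1 lists is retained in the dominant direction only when
    ``|net| = |wccs_from_down - wccs_from_up|`` reaches that direction's
    Q1 boundary magnitude; otherwise it is removed from both with
    predicted direction none.
    """
    q1_up_targets = {g for g, q in quartiles_up.items() if q == 1}      # -> protein_down
    q1_down_targets = {g for g, q in quartiles_down.items() if q == 1}  # -> protein_up
    boundary_up = _q1_boundary(
        {g: gene_scores[g].wccs_from_up for g in quartiles_up}, quartiles_up
    ) if quartiles_up else float("nan")
    boundary_down = _q1_boundary(
        {g: gene_scores[g].wccs_from_down for g in quartiles_down}, quartiles_down
    ) if quartiles_down else float("nan")

    for g, s in gene_scores.items():
        s.quartile_up = quartiles_up.get(g)
        s.quartile_down = quartiles_down.get(g)

    overlap = q1_up_targets & q1_down_targets
    protein_up = set(q1_down_targets - overlap)
    protein_down = set(q1_up_targets - overlap)
    audit_rows = []
    for g in sorted(overlap):
        s = gene_scores[g]
        net = s.net_wccs
        outcome = "removed"
        if net < 0 and abs(net) >= abs(boundary_down):
            protein_up.add(g)
            outcome = "retained_protein_up"
        elif net > 0 and abs(net) >= abs(boundary_up):
            protein_down.add(g)
            outcome = "retained_protein_down"
        audit_rows.append(
            {
                "gene_id": g,
                "wccs_from_up": s.wccs_from_up,
                "wccs_from_down": s.wccs_from_down,
                "net_wccs": net,
                "boundary_up": boundary_up,
                "boundary_down": boundary_down,
                "outcome": outcome,
            }
        )
    for g, s in gene_scores.items():
        if g in protein_up:
            s.predicted_direction = "protein_up"
        elif g in protein_down:
            s.predicted_direction = "protein_down"
        else:
            s.predicted_direction = "none"

    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "gene_id", "wccs_from_up", "wccs_from_down", "net_wccs",
            "boundary_up", "boundary_down", "outcome",
        ],
    )
    return WccsLists(
        q1_protein_up=sorted(protein_up),
        q1_protein_down=sorted(protein_down),
        overlap_resolved=audit,
        boundary_up=boundary_up,
        boundary_down=boundary_down,
    )


def score_and_rank(
    sites: TargetSiteTable,
    mirna_changes: Mapping[str, tuple[str, float]],
    weight: str = "linear",
) -> tuple[dict[str, GeneTargetScore], WccsLists]:
    """wCCS scoring + per-direction quartiles + overlap resolution, end to end.

    ``sites`` must already be restricted to expressed genes and modulated
    miRNAs (see :func:`restrict_targets`).
    """
    scores = compute_wccs(sites, mirna_changes, weight=weight)
    up_dist = {g: s.wccs_from_up for g, s in scores.items() if s.wccs_from_up != 0}
    down_dist = {g: s.wccs_from_down for g, s in scores.items() if s.wccs_from_down != 0}
    quartiles_up = quartile_stratify(up_dist) if len(up_dist) >= 4 else {}
    quartiles_down = quartile_stratify(down_dist) if len(down_dist) >= 4 else {}
    lists = resolve_overlap(scores, quartiles_up, quartiles_down)
    return scores, lists


def scores_to_frame(scores: Mapping[str, GeneTargetScore]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "ccs": s.ccs,
            "wccs_from_up": s.wccs_from_up,
            "wccs_from_down": s.wccs_from_down,
            "net_wccs": s.net_wccs,
            "quartile_up": s.quartile_up,
            "quartile_down": s.quartile_down,
            "predicted_direction": s.predicted_direction,
        }
        for s in scores.values()
    ]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# CCS quartiles vs expression


@dataclass
class AssociationReport:
    """Median expression per CCS quartile per clinical group, with tests.

    q1_vs_q4_p: two-sided rank-sum p comparing per-gene control-group
    median intensities of Q1 vs Q4 genes. between_group_p: per quartile,
    Kruskal-Wallis p across clinical groups of the per-gene group medians.
    """

    median_by_quartile_group: pd.DataFrame
    q1_vs_q4_p: float
    between_group_p: dict[int, float] = field(default_factory=dict)


def ccs_expression_association(
    ccs_quartiles: Mapping[str, int],
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    control_group: str = "NGT",
) -> AssociationReport:
    """Test whether targeting strength tracks expression level.

    Requires the quartile map and expression matrix to share gene ids.
    """
    genes = [g for g in ccs_quartiles if g in set(m.feature_ids)]
    if not genes:
        raise ValueError("no genes shared between quartile map and expression matrix")
    groups = [g for g in ("NGT", "IGT", "T2D") if pheno.samples_in(g)]
    per_gene = {}
    for grp in groups:
        samples = [s for s in m.sample_ids if s in set(pheno.samples_in(grp))]
        per_gene[grp] = m.values.loc[genes, samples].median(axis=1)

    rows = []
    for q in (1, 2, 3, 4):
        qgenes = [g for g in genes if ccs_quartiles[g] == q]
        rows.append(
            {"quartile": q, **{grp: float(per_gene[grp].loc[qgenes].median()) if qgenes else float("nan") for grp in groups}}
        )
    medians = pd.DataFrame(rows).set_index("quartile")

    q1_genes = [g for g in genes if ccs_quartiles[g] == 1]
    q4_genes = [g for g in genes if ccs_quartiles[g] == 4]
    if q1_genes and q4_genes and control_group in per_gene:
        a = per_gene[control_group].loc[q1_genes].to_numpy()
        b = per_gene[control_group].loc[q4_genes].to_numpy()
        q1_vs_q4_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        q1_vs_q4_p = float("nan")

    between = {}
    for q in (1, 2, 3, 4):
        qgenes = [g for g in genes if ccs_quartiles[g] == q]
        if len(qgenes) >= 2 and len(groups) >= 2:
            arrays = [per_gene[grp].loc[qgenes].to_numpy() for grp in groups]
            if np.ptp(np.concatenate(arrays)) == 0:
                between[q] = 1.0
            else:
                between[q] = float(stats.kruskal(*arrays).pvalue)
    return AssociationReport(
        median_by_quartile_group=medians,
        q1_vs_q4_p=q1_vs_q4_p,
        between_group_p=between,
    )
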