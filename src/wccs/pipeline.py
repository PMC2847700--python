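"""End-to-end orchestration: mRNA invariance check -> miRNA differential
calling -> wCCS ranking -> background-controlled enrichment.

A run is driven by a single :class:`RunConfig` (YAML round-trippable).
Inputs come either from files or from a named synthetic preset with
planted truth. Every stage logs its input/output dimensions and the exact
thresholds applied; all intermediates are written as TSV next to a YAML
metadata sidecar so a run can be audited or resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import io as wio
from . import mirna as mir
from . import mrna
from . import ranking
from . import synthetic as synth
from .datamodel import ExpressionMatrix, GeneSetCollection, PhenotypeTable, TargetSiteTable
from .sam import results_to_frame

log = logging.getLogger(__name__)

#: Named synthetic presets (scales chosen for desk-size runs; "study-scale"
#: mirrors the study's dimensions).
PRESETS: dict[str, dict] = {
    "study-scale": dict(
        n_genes=20_000, n_per_group={"NGT": 47, "IGT": 26, "T2D": 45},
        n_mirnas=245, n_pools_per_group=4,
        frac_up=29 / 171, frac_down=33 / 171,
        coherent=True, null_mirnas=False,
    ),
    "demo": dict(
        n_genes=3_000, n_per_group={"NGT": 10, "IGT": 6, "T2D": 10},
        n_mirnas=245, n_pools_per_group=4,
        frac_up=29 / 171, frac_down=33 / 171,
        coherent=True, null_mirnas=False,
    ),
    "null": dict(
        n_genes=3_000, n_per_group={"NGT": 10, "IGT": 6, "T2D": 10},
        n_mirnas=245, n_pools_per_group=4,
        frac_up=0.0, frac_down=0.0,
        coherent=False, null_mirnas=True,
    ),
}


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    out_dir: str = "wccs_run"
    seed: int = 0
    # inputs: either a synth preset name, or explicit file paths
    synth_preset: str | None = None
    mrna_path: str | None = None
    mrna_calls_path: str | None = None
    mirna_path: str | None = None
    pheno_path: str | None = None
    mirna_pheno_path: str | None = None
    sites_path: str | None = None
    gene_sets_path: str | None = None
    gene_sets_format: str = "gmt"
    # thresholds
    expressed_cutoff: float = 400.0
    fdr_pct: float = 10.0
    min_fold: float = 1.3
    min_term_size: int = 3
    weight: str = "linear"  # wCCS weight mode: linear | log2
    n_perm: int = 1000
    case_group: str = "T2D"
    control_group: str = "NGT"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_pct <= 100:
            raise ValueError(f"fdr_pct must be in (0, 100], got {self.fdr_pct}")
        if self.min_fold < 1:
            raise ValueError(f"min_fold must be >= 1, got {self.min_fold}")
        if self.expressed_cutoff < 0:
            raise ValueError("expressed_cutoff must be >= 0")
        if self.weight not in ("linear", "log2"):
            raise ValueError(f"unknown weight mode {self.weight!r}")
        if self.synth_preset is not None and self.synth_preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.synth_preset!r}; choose from {sorted(PRESETS)}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    """Machine-readable stage counts and headline outputs of one run."""

    counts: dict[str, int] = field(default_factory=dict)
    q1_protein_up: list[str] = field(default_factory=list)
    q1_protein_down: list[str] = field(default_factory=list)
    enrichment_q1: pd.DataFrame | None = None
    enrichment_q4: pd.DataFrame | None = None
    truth: synth.SyntheticTruth | None = None
    out_dir: str = ""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the run directory."""


def _load_inputs(cfg: RunConfig):
    """Resolve config to in-memory inputs (files or synthetic preset)."""
    if cfg.synth_preset is not None:
        p = PRESETS[cfg.synth_preset]
        m_mrna, pheno, mrna_truth = synth.gen_mrna_matrix(
            n_genes=p["n_genes"], n_per_group=p["n_per_group"], seed=cfg.seed,
        )
        m_mir, mir_pheno, mir_truth = synth.gen_mirna_matrix(
            n_mirnas=p["n_mirnas"], n_pools_per_group=p["n_pools_per_group"],
            frac_up=p["frac_up"], frac_down=p["frac_down"], seed=cfg.seed + 1,
        )
        expressed_genes = [
            g for g, keep in (m_mrna.calls != "A").any(axis=1).items() if keep
        ]
        coherent = None
        if p["coherent"]:
            rng_genes = expressed_genes
            coherent = {
                "TERM_UP": (rng_genes[: 30], "down"),   # de-repressed -> protein up
                "TERM_DOWN": (rng_genes[30: 60], "up"),
            }
        sites, db_truth = synth.gen_target_db(
            genes=expressed_genes,
            mirna_changes=mir_truth.modulated_mirnas,
            coherent_sets=coherent,
            extra_mirnas=[
                x for x in mir_truth.expressed_mirnas
                if x not in mir_truth.modulated_mirnas
            ][:20],
            seed=cfg.seed + 2,
        ) if (mir_truth.modulated_mirnas or not p["null_mirnas"]) else (None, synth.SyntheticTruth())
        planted = {t: list(members) for t, (members, _) in (coherent or {}).items()}
        gene_sets = synth.gen_gene_sets(
            expressed_genes, n_terms=30, planted=planted, seed=cfg.seed + 3
        )
        truth = mir_truth
        truth.shifted_genes = mrna_truth.shifted_genes
        truth.all_absent_genes = mrna_truth.all_absent_genes
        truth.targeted_genes_up = db_truth.targeted_genes_up
        truth.targeted_genes_down = db_truth.targeted_genes_down
        truth.enriched_terms = db_truth.enriched_terms
        return m_mrna, pheno, m_mir, mir_pheno, sites, gene_sets, truth

    missing = [
        name for name, path in [
            ("mrna_path", cfg.mrna_path), ("mirna_path", cfg.mirna_path),
            ("pheno_path", cfg.pheno_path), ("sites_path", cfg.sites_path),
            ("gene_sets_path", cfg.gene_sets_path),
        ] if path is None
    ]
    if missing:
        raise StageError(f"inputs: no synth preset and missing path(s): {missing}")
    m_mrna = wio.read_expression_matrix(cfg.mrna_path, calls_path=cfg.mrna_calls_path)
    pheno = wio.read_phenotype(cfg.pheno_path)
    m_mir = wio.read_expression_matrix(cfg.mirna_path)
    mir_pheno = (
        wio.read_phenotype(cfg.mirna_pheno_path) if cfg.mirna_pheno_path else pheno
    )
    sites = wio.read_target_sites(cfg.sites_path)
    gene_sets = wio.read_gene_sets(cfg.gene_sets_path, format=cfg.gene_sets_format)
    return m_mrna, pheno, m_mir, mir_pheno, sites, gene_sets, None


def run_full(cfg: RunConfig) -> RunReport:
    """Execute every stage and write all intermediates to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report = RunReport(out_dir=str(out))
    counts = report.counts

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - re-tag with stage name
                raise StageError(f"stage {name!r} failed: {e}") from e
        return deco

    m_mrna, pheno, m_mir, mir_pheno, sites, gene_sets, truth = stage("inputs")(
        lambda: _load_inputs(cfg)
    )
    report.truth = truth
    counts["mrna_features"] = m_mrna.shape[0]
    counts["mrna_samples"] = m_mrna.shape[1]

    @stage("mrna_invariance")
    def _mrna():
        filtered = mrna.filter_absent(m_mrna) if m_mrna.calls is not None else m_mrna
        log.info("mRNA stage: %d -> %d features after absent filtering",
                 m_mrna.shape[0], filtered.shape[0])
        res = mrna.sam_two_class(
            filtered, pheno, case_group=cfg.case_group,
            control_group=cfg.control_group, n_perm=cfg.n_perm, seed=cfg.seed,
        )
        results_to_frame(res).to_csv(out / "mrna_diff.tsv", sep="\t", index=False)
        called = [r for r in res if r.q_value <= cfg.fdr_pct]
        counts["mrna_expressed"] = filtered.shape[0]
        counts["mrna_called"] = len(called)
        return filtered

    mrna_filtered = _mrna

    @stage("mirna_diff")
    def _mirna():
        norm = mir.quantile_normalize(m_mir)
        expressed = mir.expressed_filter(norm, cutoff=cfg.expressed_cutoff)
        log.info("miRNA stage: %d probes, %d expressed at cutoff %g",
                 m_mir.shape[0], expressed.shape[0], cfg.expressed_cutoff)
        calls = mir.diff_mirnas(
            expressed, mir_pheno, case_group=cfg.case_group,
            control_group=cfg.control_group, fdr_pct=cfg.fdr_pct,
            min_fold=cfg.min_fold, n_perm=cfg.n_perm, seed=cfg.seed,
        )
        results_to_frame(calls).to_csv(out / "mirna_diff.tsv", sep="\t", index=False)
        means = mir.group_means(expressed, mir_pheno)
        patterns = []
        if calls and all(g in means for g in ("NGT", "IGT", "T2D")):
            tol = mir.pattern_tolerances(expressed, mir_pheno)
            patterns = mir.classify_patterns(
                means["NGT"], means["IGT"], means["T2D"], calls, tol
            )
        pd.DataFrame(
            [{"mirna_id": p.mirna_id, "direction": p.direction,
              "pattern": p.pattern or "unclassified"} for p in patterns]
        ).to_csv(out / "mirna_patterns.tsv", sep="\t", index=False)
        counts["mirna_probes"] = m_mir.shape[0]
        counts["mirna_expressed"] = expressed.shape[0]
        counts["mirna_up"] = sum(1 for c in calls if c.direction == "up")
        counts["mirna_down"] = sum(1 for c in calls if c.direction == "down")
        counts["mirna_called"] = len(calls)
        return expressed, calls

    mir_expressed, mir_calls = _mirna

    expressed_genes = (
        list(mrna_filtered.feature_ids) if m_mrna.calls is not None
        else list(m_mrna.feature_ids)
    )

    if not mir_calls or sites is None:
        log.info("no differential miRNAs: ranking and enrichment stages are empty")
        counts.update(
            target_genes=0, q1_protein_up=0, q1_protein_down=0, q1_overlap=0
        )
        for name in ("gene_scores.tsv", "overlap_audit.tsv"):
            pd.DataFrame().to_csv(out / name, sep="\t", index=False)
        wio.write_gene_list([], out / "q1_protein_up.txt")
        wio.write_gene_list([], out / "q1_protein_down.txt")
        _write_summary(out, cfg, counts)
        return report

    @stage("wccs")
    def _wccs():
        changes = {c.feature_id: (c.direction, c.fold_change) for c in mir_calls}
        restricted = ranking.restrict_targets(sites, expressed_genes, changes)
        log.info("wCCS stage: %d sites retained over %d genes",
                 len(restricted), len(set(restricted.sites['gene_id'])))
        scores, lists = ranking.score_and_rank(restricted, changes, weight=cfg.weight)
        ranking.scores_to_frame(scores).to_csv(out / "gene_scores.tsv", sep="\t", index=False)
        lists.overlap_resolved.to_csv(out / "overlap_audit.tsv", sep="\t", index=False)
        wio.write_gene_list(lists.q1_protein_up, out / "q1_protein_up.txt")
        wio.write_gene_list(lists.q1_protein_down, out / "q1_protein_down.txt")
        counts["target_genes"] = len(scores)
        counts["q1_protein_up"] = len(lists.q1_protein_up)
        counts["q1_protein_down"] = len(lists.q1_protein_down)
        counts["q1_overlap"] = len(lists.overlap_resolved)
        return scores, lists

    scores, lists = _wccs
    report.q1_protein_up = lists.q1_protein_up
    report.q1_protein_down = lists.q1_protein_down

    @stage("enrichment")
    def _enrich():
        q1 = sorted(set(lists.q1_protein_up) | set(lists.q1_protein_down))
        q4 = sorted(
            g for g, s in scores.items()
            if (s.quartile_up == 4 or s.quartile_down == 4)
            and s.quartile_up != 1 and s.quartile_down != 1
        )
        target_bg = sorted(scores)
        contrast = enr.quartile_contrast(
            q1, q4, expressed_genes, target_bg, gene_sets,
            min_term_size=cfg.min_term_size,
        )
        eq1 = enr.enrichment_to_frame(contrast.q1_tissue)
        eq4 = enr.enrichment_to_frame(contrast.q4_tissue)
        eq1.to_csv(out / "enrichment_q1.tsv", sep="\t", index=False)
        eq4.to_csv(out / "enrichment_q4.tsv", sep="\t", index=False)
        enr.enrichment_to_frame(contrast.q1_targets).to_csv(
            out / "enrichment_q1_targetbg.tsv", sep="\t", index=False)
        counts["q1_terms_significant"] = len(contrast.significant("q1_tissue"))
        counts["q4_terms_significant"] = len(contrast.significant("q4_tissue"))
        return eq1, eq4

    report.enrichment_q1, report.enrichment_q4 = _enrich

    if truth is not None:
        truth.to_yaml(out / "truth.yaml")
    _write_summary(out, cfg, counts)
    return report


def _write_summary(out: Path, cfg: RunConfig, counts: dict) -> None:
    wio.write_run_metadata(
        out / "summary.yaml",
        {
            "seed": cfg.seed,
            "thresholds": {
                "expressed_cutoff": cfg.expressed_cutoff,
                "fdr_pct": cfg.fdr_pct,
                "min_fold": cfg.min_fold,
                "min_term_size": cfg.min_term_size,
                "weight": cfg.weight,
                "n_perm": cfg.n_perm,
            },
            "counts": {k: int(v) for k, v in counts.items()},
        },
    )
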