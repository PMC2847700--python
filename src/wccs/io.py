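"""Readers and writers for the pipeline's external table formats.

All matrices and tables travel as plain TSV. Parsers are total on their
declared dialects: any malformed input raises a diagnostic error naming
the offending row/column — nothing is silently dropped. Writers round-trip
at full float precision (Python's shortest round-trippable repr).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .datamodel import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeTable,
    SITE_COLUMNS,
    TargetSiteTable,
    ValidationError,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    calls_path: str | Path | None = None,
    platform: str = "",
) -> ExpressionMatrix:
    """Read a features x samples TSV of linear intensities.

    First column holds feature ids; the header row holds sample ids.
    ``calls_path``, if given, is a parallel TSV of P/M/A detection calls
    with identical feature and sample ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    calls = None
    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        calls.index = calls.index.astype(str)
        calls.columns = calls.columns.astype(str)
        if list(calls.index) != list(df.index) or list(calls.columns) != list(df.columns):
            raise FormatError(
                f"{calls_path}: feature/sample ids do not match {path}"
            )
    try:
        return ExpressionMatrix(values=df.astype(float), calls=calls, platform=platform)
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


def write_expression_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    calls_path: str | Path | None = None,
) -> None:
    m.values.to_csv(path, sep="\t", index_label="feature_id")
    if calls_path is not None:
        if m.calls is None:
            raise ValueError("matrix has no calls to write")
        m.calls.to_csv(calls_path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    try:
        return PhenotypeTable(df)
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


def write_phenotype(p: PhenotypeTable, path: str | Path) -> None:
    p.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# target sites

#: Column positions in a tab-delimited conserved-site file. TargetScan file
#: layouts changed across releases, so positions are configuration, not code;
#: this default matches the compact dialect (miRNA family, gene symbol/id,
#: site type, context score).
@dataclass(frozen=True)
class TargetScanDialect:
    mirna_col: int = 0
    gene_col: int = 1
    site_type_col: int = 2
    score_col: int = 3
    has_header: bool = True


def read_target_sites(
    path: str | Path, dialect: TargetScanDialect = TargetScanDialect()
) -> TargetSiteTable:
    """Parse a TargetScan-style tab-delimited site file.

    One output record per line; genes with several sites for a miRNA yield
    several records. An unparseable context score raises a FormatError with
    the 1-based line number.
    """
    records = []
    needed = max(dialect.mirna_col, dialect.gene_col, dialect.site_type_col, dialect.score_col)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if dialect.has_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) <= needed:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {needed + 1} columns, got {len(parts)}"
                )
            try:
                score = float(parts[dialect.score_col])
            except ValueError as e:
                raise FormatError(
                    f"{path}:{lineno}: unparseable context score {parts[dialect.score_col]!r}"
                ) from e
            records.append(
                (
                    parts[dialect.mirna_col],
                    parts[dialect.gene_col],
                    parts[dialect.site_type_col],
                    score,
                )
            )
    if not records:
        log.warning("%s: no target-site records parsed (empty table)", path)
    df = pd.DataFrame(records, columns=SITE_COLUMNS)
    return TargetSiteTable(df)


def write_target_sites(t: TargetSiteTable, path: str | Path) -> None:
    t.sites[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(path: str | Path, format: str = "gmt") -> GeneSetCollection:
    """Read a gene-set collection.

    ``format='gmt'``: one term per line — term id, description, members...
    ``format='flat'``: two columns (gene, term), duplicates collapsed.
    """
    if format == "gmt":
        terms: dict[str, tuple[str, set[str]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: GMT line needs term, description, >=1 member"
                    )
                term, desc, members = parts[0], parts[1], parts[2:]
                if term in terms:
                    raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
                terms[term] = (desc or term, set(m for m in members if m))
        from .datamodel import GeneSet

        return GeneSetCollection({t: GeneSet(d, frozenset(m)) for t, (d, m) in terms.items()})
    if format == "flat":
        inverted: dict[str, set[str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns (gene, term)")
                gene, term = parts
                inverted.setdefault(term, set()).add(gene)
        return GeneSetCollection.from_mapping(inverted)
    raise FormatError(f"unknown gene-set format {format!r} (expected 'gmt' or 'flat')")


def write_gene_sets(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(c.terms):
            gs = c.terms[term_id]
            fh.write("\t".join([term_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# gene lists and run metadata


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_run_metadata(path: str | Path, metadata: dict) -> None:
    """YAML sidecar recording seed, thresholds and package version."""
    from . import __version__

    payload = {"package_version": __version__, **metadata}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_run_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
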