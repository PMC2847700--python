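"""Typed containers for the tables the pipeline consumes and produces.

Expression data are kept as linear-scale intensities (features x samples)
with optional Affymetrix-style present/marginal/absent detection calls.
Target-site records follow the TargetScan conserved-site convention: one
row per predicted 3'UTR site with a (typically negative) context score —
more negative means stronger predicted repression.

Gene and miRNA identifiers are opaque strings throughout; any probe-to-gene
remapping is expected to have been applied upstream and supplied as an
explicit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_CALLS = frozenset({"P", "M", "A"})
CLINICAL_GROUPS = ("NGT", "IGT", "T2D")


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Linear-intensity expression matrix with optional detection calls.

    Parameters
    ----------
    values
        features x samples DataFrame of finite, non-negative linear
        intensities. Row order is meaningful and preserved by every
        operation in the package.
    calls
        Optional DataFrame of the same shape with entries in {P, M, A}.
    platform
        Free-text tag (e.g. array platform) carried through unchanged.
    """

    values: pd.DataFrame
    calls: pd.DataFrame | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("intensities must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = self.values.index[~np.isfinite(arr).all(axis=1)][0]
            raise ValidationError(f"non-finite intensity in feature {bad!r}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative intensity at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.calls is not None:
            if self.calls.shape != self.values.shape:
                raise ValidationError(
                    f"calls shape {self.calls.shape} != values shape {self.values.shape}"
                )
            self.calls = self.calls.set_axis(self.values.index, axis=0).set_axis(
                self.values.columns, axis=1
            )
            bad = ~self.calls.isin(VALID_CALLS)
            if bad.to_numpy().any():
                i, j = np.argwhere(bad.to_numpy())[0]
                raise ValidationError(
                    f"invalid call {self.calls.iat[i, j]!r} at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``ids`` (original order kept)."""
        keep = [f for f in self.feature_ids if f in set(ids)]
        return ExpressionMatrix(
            values=self.values.loc[keep].copy(),
            calls=None if self.calls is None else self.calls.loc[keep].copy(),
            platform=self.platform,
        )

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            values=self.values[ids].copy(),
            calls=None if self.calls is None else self.calls[ids].copy(),
            platform=self.platform,
        )


@dataclass
class PhenotypeTable:
    """Per-sample clinical annotations.

    ``table`` is indexed by sample id and must carry a ``group`` column with
    values in {NGT, IGT, T2D}; clinical covariates (fasting glucose mmol/L,
    fasting insulin pmol/L, HbA1c %, 2-h glucose mmol/L, BMI kg/m^2, ...)
    are optional numeric columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample id")
        if "group" not in self.table.columns:
            raise ValidationError("phenotype table must have a 'group' column")
        bad = set(self.table["group"]) - set(CLINICAL_GROUPS)
        if bad:
            raise ValidationError(f"unknown clinical group(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "group"])

    def covariate(self, name: str, samples: Iterable[str] | None = None) -> pd.Series:
        s = self.table[name].astype(float)
        return s if samples is None else s.loc[list(samples)]

    def check_paired(self, m: ExpressionMatrix, require_all_groups: bool = False) -> None:
        """Validate that every sample of ``m`` is annotated exactly once."""
        missing = [s for s in m.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples without phenotype: {missing}")
        if require_all_groups:
            present = set(self.table.loc[m.sample_ids, "group"])
            empty = [g for g in CLINICAL_GROUPS if g not in present]
            if empty:
                raise ValidationError(f"empty clinical group(s): {empty}")


SITE_COLUMNS = ["mirna_id", "gene_id", "site_type", "context_score"]


@dataclass
class TargetSiteTable:
    """Per-site miRNA target predictions with context scores.

    One row per predicted site; a gene with several sites for the same
    miRNA appears several times. Context scores must be finite (they are
    typically <= 0: TargetScan's repression convention).
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValidationError(f"target-site table missing column(s): {missing}")
        scores = self.sites["context_score"].to_numpy(dtype=float)
        if np.isnan(scores).any():
            row = int(np.argwhere(np.isnan(scores))[0][0])
            raise ValidationError(f"NaN context score at site row {row}")
        self.sites = self.sites.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.sites["mirna_id"].unique())

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.sites["gene_id"].unique())


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Flat term -> member-gene mapping (no ontology-graph propagation)."""

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.terms and all(len(gs.members) == 0 for gs in self.terms.values()):
            raise ValidationError("all gene sets are empty")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id].members

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = set(universe)
        return GeneSetCollection(
            {
                t: GeneSet(gs.name, gs.members & uni)
                for t, gs in self.terms.items()
                if gs.members & uni
            }
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls({t: GeneSet(t, frozenset(g)) for t, g in mapping.items()})
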