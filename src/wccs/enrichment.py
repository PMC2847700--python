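"""Gene-set over-representation with explicit background control.

The test is the one-sided hypergeometric upper tail with equality,
P[X >= k], per term, Benjamini-Hochberg adjusted across the tested terms.
The background is an explicit argument, never a genome-wide default:
against a tissue-restricted universe, sets that merely mirror what the
tissue expresses stop looking enriched — which is the point of passing a
tissue background in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSetCollection


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # hits in the list
    K: int  # term size within the background
    n: int  # list size
    N: int  # background size
    p: float  # hypergeometric upper-tail P[X >= k]
    p_bh: float


def ora(
    gene_list: Iterable[str],
    background: Iterable[str],
    gene_sets: GeneSetCollection,
    min_term_size: int = 3,
    max_term_frac: float = 0.5,
) -> list[EnrichmentResult]:
    """Over-representation of ``gene_list`` terms against ``background``.

    Terms are intersected with the background before testing; terms
    smaller than ``min_term_size`` or covering more than ``max_term_frac``
    of the background (uninformative) are skipped. Results are sorted by
    adjusted then raw p.
    """
    bg = set(background)
    lst = set(gene_list)
    offenders = sorted(lst - bg)
    if offenders:
        raise ValueError(f"gene list not contained in background: {offenders[:10]}")
    N, n = len(bg), len(lst)
    rows = []
    for term_id in sorted(gene_sets.terms):
        gs = gene_sets.terms[term_id]
        members = gs.members & bg
        K = len(members)
        if K < min_term_size or K > max_term_frac * N:
            continue
        k = len(members & lst)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P[X >= k]
        rows.append((term_id, gs.name, k, K, p))
    if not rows:
        return []
    p_adj = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term_id=t, term_name=name, k=k, K=K, n=n, N=N, p=p, p_bh=float(q))
        for (t, name, k, K, p), q in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_bh, r.p, r.term_id))
    return results


@dataclass
class QuartileContrast:
    """ORA of the Q1 and Q4 lists under two background choices."""

    q1_tissue: list[EnrichmentResult]
    q4_tissue: list[EnrichmentResult]
    q1_targets: list[EnrichmentResult]
    q4_targets: list[EnrichmentResult]

    def significant(self, which: str, alpha: float = 0.05) -> list[str]:
        return [r.term_id for r in getattr(self, which) if r.p_bh < alpha]


def quartile_contrast(
    q1_list: Sequence[str],
    q4_list: Sequence[str],
    tissue_background: Iterable[str],
    target_background: Iterable[str],
    gene_sets: GeneSetCollection,
    min_term_size: int = 3,
) -> QuartileContrast:
    """Contrast most- vs least-targeted quartiles under both backgrounds.

    Mode (a): the tissue transcriptome as background; mode (b): the
    predicted-target list itself, isolating what distinguishes the top of
    the ranking from the rest of the targeted genes.
    """
    return QuartileContrast(
        q1_tissue=ora(q1_list, tissue_background, gene_sets, min_term_size),
        q4_tissue=ora(q4_list, tissue_background, gene_sets, min_term_size),
        q1_targets=ora(q1_list, target_background, gene_sets, min_term_size),
        q4_targets=ora(q4_list, target_background, gene_sets, min_term_size),
    )


def enrichment_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "p_bh": r.p_bh,
            }
            for r in results
        ]
    )
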