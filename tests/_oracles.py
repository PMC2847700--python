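"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit loops and elementary arithmetic,
deliberately sharing no code with the package, so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

from math import comb, ceil


# ---------------------------------------------------------------------------
# wCCS pipeline, gene by gene


def brute_ccs(site_rows):
    """site_rows: list of (mirna, gene, score). Per-gene plain sum."""
    out = {}
    for _, gene, score in site_rows:
        out[gene] = out.get(gene, 0.0) + score
    return out


def brute_wccs(site_rows, changes):
    """Directional weighted sums; changes: mirna -> (direction, fold)."""
    up, down = {}, {}
    for mirna, gene, score in site_rows:
        direction, fold = changes[mirna]
        weighted = score * fold
        if direction == "up":
            up[gene] = up.get(gene, 0.0) + weighted
        else:
            down[gene] = down.get(gene, 0.0) + weighted
    return up, down


def brute_quartiles(scores):
    """Explicit sort-and-split; boundary ties take the better quartile."""
    items = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    vals = [v for _, v in items]
    c1 = vals[ceil(n / 4) - 1]
    c2 = vals[ceil(n / 2) - 1]
    c3 = vals[ceil(3 * n / 4) - 1]
    out = {}
    for g, v in items:
        if v <= c1:
            out[g] = 1
        elif v <= c2:
            out[g] = 2
        elif v <= c3:
            out[g] = 3
        else:
            out[g] = 4
    return out


def brute_resolve(up_scores, down_scores):
    """Full downstream ranking: quartiles, overlap resolution, final lists.

    Returns (protein_up, protein_down, removed) as sorted lists. Genes in
    Q1 of the down-miRNA distribution are protein-up candidates; a gene in
    both Q1 lists is kept only where net targeting dominates by at least
    the dominant side's Q1 boundary magnitude.
    """
    qup = brute_quartiles(up_scores) if len(up_scores) >= 4 else {}
    qdn = brute_quartiles(down_scores) if len(down_scores) >= 4 else {}
    q1_up = {g for g, q in qup.items() if q == 1}
    q1_dn = {g for g, q in qdn.items() if q == 1}
    b_up = max(up_scores[g] for g in q1_up) if q1_up else None
    b_dn = max(down_scores[g] for g in q1_dn) if q1_dn else None
    protein_up, protein_down, removed = set(), set(), set()
    for g in q1_dn - q1_up:
        protein_up.add(g)
    for g in q1_up - q1_dn:
        protein_down.add(g)
    for g in q1_up & q1_dn:
        net = down_scores.get(g, 0.0) - up_scores.get(g, 0.0)
        if net < 0 and abs(net) >= abs(b_dn):
            protein_up.add(g)
        elif net > 0 and abs(net) >= abs(b_up):
            protein_down.add(g)
        else:
            removed.add(g)
    return sorted(protein_up), sorted(protein_down), sorted(removed)


# ---------------------------------------------------------------------------
# enrichment


def exact_hypergeom_upper(N, K, n, k):
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    denom = comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += comb(K, j) * comb(N - K, n - j)
    return total / denom


def brute_bh(pvalues):
    """Step-up Benjamini-Hochberg from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvalues[i] * m / rank_from_end)
        adjusted[i] = val
        prev = val
    return adjusted
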