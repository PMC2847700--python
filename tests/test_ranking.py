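"""wCCS scoring, quartile stratification and overlap resolution, checked
against independent brute-force references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wccs.ranking import (
    ccs_expression_association,
    compute_ccs,
    compute_wccs,
    quartile_stratify,
    resolve_overlap,
    restrict_targets,
    score_and_rank,
)
from wccs.synthetic import gen_mrna_matrix

from _oracles import brute_ccs, brute_quartiles, brute_resolve, brute_wccs
from conftest import make_matrix, make_pheno, make_sites, random_wccs_instance


class TestRestrictTargets:
    def test_drops_unexpressed_genes_and_unmodulated_mirnas(self):
        sites = make_sites([("m1", "G1", -0.2), ("m1", "G2", -0.3), ("m2", "G1", -0.1)])
        out = restrict_targets(sites, expressed_genes=["G1"], modulated_mirnas=["m1"])
        assert len(out) == 1
        assert out.sites.iloc[0]["gene_id"] == "G1"
        assert out.sites.iloc[0]["mirna_id"] == "m1"

    def test_empty_result_is_an_error(self):
        sites = make_sites([("m1", "G1", -0.2)])
        with pytest.raises(ValueError, match="no target sites"):
            restrict_targets(sites, ["G2"], ["m1"])

    def test_matches_double_membership_filter(self, rng):
        rows, changes = random_wccs_instance(rng, max_genes=40)
        sites = make_sites(rows)
        genes = {f"G{i}" for i in range(0, 40, 2)}
        mirnas = set(list(changes)[::2])
        if not any(m in mirnas and g in genes for m, g, _ in rows):
            pytest.skip("degenerate draw")
        out = restrict_targets(sites, genes, mirnas)
        expected = [r for r in rows if r[0] in mirnas and r[1] in genes]
        assert len(out) == len(expected)


class TestComputeCcs:
    def test_two_sites_sum(self):
        assert compute_ccs(make_sites([("m", "G1", -0.2), ("m", "G1", -0.3)])) == {
            "G1": pytest.approx(-0.5)
        }

    def test_single_site(self):
        assert compute_ccs(make_sites([("m", "G1", -0.41)])) == {"G1": pytest.approx(-0.41)}

    def test_matches_group_and_sum(self, rng):
        rows, _ = random_wccs_instance(rng)
        got = compute_ccs(make_sites(rows))
        expected = brute_ccs(rows)
        assert set(got) == set(expected)
        for g in got:
            assert got[g] == pytest.approx(expected[g], abs=1e-12)


class TestComputeWccs:
    def test_single_upregulated_site(self):
        scores = compute_wccs(make_sites([("m", "G1", -0.4)]), {"m": ("up", 1.5)})
        assert scores["G1"].wccs_from_up == pytest.approx(-0.6)
        assert scores["G1"].wccs_from_down == 0.0
        assert scores["G1"].ccs == pytest.approx(-0.4)

    def test_identity_weight_reduces_to_ccs_partition(self, rng):
        rows, changes = random_wccs_instance(rng)
        unit = {m: (d, 1.0) for m, (d, _) in changes.items()}
        scores = compute_wccs(make_sites(rows), unit)
        for g, s in scores.items():
            assert s.wccs_from_up + s.wccs_from_down == pytest.approx(s.ccs, abs=1e-9)

    def test_missing_mirna_listed_in_error(self):
        sites = make_sites([("mA", "G1", -0.2), ("mB", "G1", -0.2)])
        with pytest.raises(ValueError, match="mB"):
            compute_wccs(sites, {"mA": ("up", 2.0)})

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            compute_wccs(make_sites([("m", "G", -0.1)]), {"m": ("up", 0.5)})

    def test_matches_site_by_site_accumulation(self, rng):
        rows, changes = random_wccs_instance(rng)
        scores = compute_wccs(make_sites(rows), changes)
        up, down = brute_wccs(rows, changes)
        for g, s in scores.items():
            assert s.wccs_from_up == pytest.approx(up.get(g, 0.0), abs=1e-12)
            assert s.wccs_from_down == pytest.approx(down.get(g, 0.0), abs=1e-12)

    def test_monotone_in_single_fold(self, rng):
        while True:
            rows, changes = random_wccs_instance(rng)
            ups = [m for m, (d, _) in changes.items() if d == "up"]
            if ups and any(r[0] == ups[0] for r in rows):
                break
        target = ups[0]
        before = compute_wccs(make_sites(rows), changes)
        bumped = dict(changes)
        bumped[target] = ("up", changes[target][1] + 1.0)
        after = compute_wccs(make_sites(rows), bumped)
        targets = {g for m, g, _ in rows if m == target}
        for g in before:
            if g in targets:
                assert after[g].wccs_from_up <= before[g].wccs_from_up
            else:
                assert after[g].wccs_from_up == pytest.approx(before[g].wccs_from_up)
                assert after[g].wccs_from_down == pytest.approx(before[g].wccs_from_down)


class TestQuartileStratify:
    def test_eight_distinct_scores_split_two_per_quartile(self):
        scores = {f"g{i}": -float(i + 1) for i in range(8)}
        q = quartile_stratify(scores)
        assert sorted(q.values()) == [1, 1, 2, 2, 3, 3, 4, 4]
        assert q["g7"] == 1 and q["g6"] == 1  # most negative pair

    def test_all_equal_scores_collapse_to_q1(self):
        q = quartile_stratify({f"g{i}": -0.5 for i in range(6)})
        assert set(q.values()) == {1}

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">=4"):
            quartile_stratify({"a": -1.0, "b": -2.0, "c": -3.0})

    def test_matches_sort_and_split_on_large_random_input(self, rng):
        scores = {f"g{i}": float(-rng.gamma(2, 0.2)) for i in range(1000)}
        assert quartile_stratify(scores) == brute_quartiles(scores)


class TestResolveOverlap:
    def _rank(self, rows, changes):
        return score_and_rank(make_sites(rows), changes)

    def test_equally_targeted_gene_predicted_unchanged(self):
        # a gene pulled identically by up- and down-regulated miRNAs nets
        # to zero and must drop out of both lists
        rows = [("u", "SHARED", -0.5), ("d", "SHARED", -0.5)]
        for i in range(6):  # distinct-score padding in both directions
            rows.append(("u", f"UG{i}", -0.05 * (i + 1)))
            rows.append(("d", f"DG{i}", -0.05 * (i + 1)))
        changes = {"u": ("up", 2.0), "d": ("down", 2.0)}
        scores, lists = self._rank(rows, changes)
        assert scores["SHARED"].net_wccs == pytest.approx(0.0)
        assert scores["SHARED"].predicted_direction == "none"
        assert "SHARED" not in lists.q1_protein_up
        assert "SHARED" not in lists.q1_protein_down
        assert lists.overlap_resolved.set_index("gene_id").loc["SHARED", "outcome"] == "removed"

    def test_single_direction_q1_gene_passes_through(self):
        rows = [("u", f"G{i}", -0.1 * (i + 1)) for i in range(8)]
        changes = {"u": ("up", 1.5)}
        scores, lists = self._rank(rows, changes)
        assert lists.q1_protein_up == []
        assert set(lists.q1_protein_down) == {"G7", "G6"}
        assert scores["G7"].predicted_direction == "protein_down"

    def test_lists_are_disjoint(self, rng):
        for _ in range(20):
            rows, changes = random_wccs_instance(rng)
            _, lists = self._rank(rows, changes)
            assert not set(lists.q1_protein_up) & set(lists.q1_protein_down)

    def test_matches_brute_force_resolution(self, rng):
        for _ in range(50):
            rows, changes = random_wccs_instance(rng)
            scores, lists = self._rank(rows, changes)
            up, down = brute_wccs(rows, changes)
            exp_up, exp_down, _ = brute_resolve(up, down)
            assert lists.q1_protein_up == exp_up
            assert lists.q1_protein_down == exp_down

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_direction_swap_swaps_lists_exactly(self, seed):
        rng = np.random.default_rng(seed)
        rows, changes = random_wccs_instance(rng)
        flipped = {
            m: ("down" if d == "up" else "up", f) for m, (d, f) in changes.items()
        }
        _, lists = score_and_rank(make_sites(rows), changes)
        _, swapped = score_and_rank(make_sites(rows), flipped)
        assert lists.q1_protein_up == swapped.q1_protein_down
        assert lists.q1_protein_down == swapped.q1_protein_up


class TestCcsExpressionAssociation:
    def _setup(self, rng, suppress_q1=False):
        genes = [f"G{i}" for i in range(200)]
        quartiles = {g: 1 + (i % 4) for i, g in enumerate(genes)}
        X = rng.lognormal(6, 0.4, size=(200, 12))
        if suppress_q1:
            q1_rows = [i for i, g in enumerate(genes) if quartiles[g] == 1]
            X[q1_rows] /= 2.0
        m = make_matrix(X, feature_ids=genes,
                        sample_ids=[f"s{j}" for j in range(12)])
        groups = {f"s{j}": ("NGT" if j < 6 else "T2D") for j in range(12)}
        return quartiles, m, make_pheno(groups)

    def test_planted_q1_suppression_detected(self, rng):
        quartiles, m, pheno = self._setup(rng, suppress_q1=True)
        rep = ccs_expression_association(quartiles, m, pheno)
        med = rep.median_by_quartile_group
        assert med.loc[1, "NGT"] < med.loc[4, "NGT"]
        assert rep.q1_vs_q4_p < 0.01

    def test_null_pvalues_not_systematically_small(self, rng):
        pvals = []
        for _ in range(20):
            quartiles, m, pheno = self._setup(rng)
            pvals.append(ccs_expression_association(quartiles, m, pheno).q1_vs_q4_p)
        assert sum(p < 0.05 for p in pvals) <= 4
        assert max(pvals) > 0.3

    def test_identical_group_matrices_show_no_group_effect(self, rng):
        genes = [f"G{i}" for i in range(40)]
        quartiles = {g: 1 + (i % 4) for i, g in enumerate(genes)}
        block = rng.lognormal(6, 0.5, size=(40, 3))
        m = make_matrix(np.hstack([block, block]), feature_ids=genes)
        groups = {f"s{j}": ("NGT" if j < 3 else "T2D") for j in range(6)}
        rep = ccs_expression_association(quartiles, m, make_pheno(groups))
        assert all(p > 0.9 for p in rep.between_group_p.values())

    def test_disjoint_gene_ids_rejected(self, rng):
        m = make_matrix(rng.uniform(1, 10, size=(4, 4)))
        with pytest.raises(ValueError, match="no genes shared"):
            ccs_expression_association(
                {"X1": 1}, m, make_pheno({f"s{j}": "NGT" for j in range(4)})
            )
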