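"""Quantile normalization, expressed filtering, differential calling,
trajectory classes and delta-Ct statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wccs.mirna import (
    DeltaCtResult,
    classify_patterns,
    delta_ct_stats,
    diff_mirnas,
    expressed_filter,
    inverse_profile_overlap,
    quantile_normalize,
)
from wccs.sam import DiffResult
from wccs.synthetic import gen_ct_table, gen_mirna_matrix

from conftest import make_matrix, make_pheno


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = np.array([5.0, 1.0, 9.0])
        m = make_matrix(np.column_stack([col, col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_closed_form_two_columns(self):
        m = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_idempotent_on_random_matrices(self, rng):
        for _ in range(100):
            m = make_matrix(rng.lognormal(5, 2, size=(20, 5)))
            once = quantile_normalize(m)
            twice = quantile_normalize(once)
            np.testing.assert_allclose(
                twice.values.to_numpy(), once.values.to_numpy(), rtol=1e-12
            )

    def test_equalizes_distributions_and_preserves_ranks(self, rng):
        X = rng.lognormal(5, 2, size=(50, 4))
        out = quantile_normalize(make_matrix(X)).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)
            # within-column order preserved
            assert (np.argsort(out[:, j]) == np.argsort(X[:, j])).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            quantile_normalize(make_matrix([[1.0], [2.0]]))


class TestExpressedFilter:
    def test_cutoff_is_inclusive(self):
        m = make_matrix(
            [[399.0] * 4, [400.0] * 4], feature_ids=["dim", "bright"]
        )
        assert expressed_filter(m).feature_ids == ["bright"]

    def test_zero_cutoff_is_identity(self, rng):
        m = make_matrix(rng.uniform(1, 10, size=(20, 3)))
        assert expressed_filter(m, cutoff=0).feature_ids == m.feature_ids

    def test_matches_brute_force_median_scan(self, rng):
        X = rng.lognormal(np.log(400), 1.5, size=(200, 7))
        m = make_matrix(X)
        kept = expressed_filter(m).feature_ids
        expected = [
            m.feature_ids[i] for i in range(200) if np.median(X[i]) >= 400
        ]
        assert kept == expected


def _pool_pheno(n=4):
    groups = {}
    for g in ("NGT", "IGT", "T2D"):
        for i in range(n):
            groups[f"{g}_pool{i}"] = g
    return make_pheno(groups)


class TestDiffMirnas:
    def test_significant_but_small_fold_excluded(self, rng):
        # one miRNA with a noiseless 1.25-fold shift: highly significant,
        # but below the >1.3 modulation gate
        n = 4
        base = rng.lognormal(np.log(2000), 0.05, size=(30, 3 * n))
        base[0] = 1000.0
        cols = [f"{g}_pool{i}" for g in ("NGT", "IGT", "T2D") for i in range(n)]
        m = make_matrix(base, sample_ids=cols)
        m.values.loc[m.feature_ids[0], [c for c in cols if c.startswith("T2D")]] = 1250.0
        full = diff_mirnas(m, _pool_pheno(n), only_called=False, n_perm=100, seed=0)
        target = full[0]
        assert target.q_value <= 5
        assert target.fold_change == pytest.approx(1.25)
        called = diff_mirnas(m, _pool_pheno(n), n_perm=100, seed=0)
        assert target.feature_id not in {r.feature_id for r in called}

    def test_null_generator_yields_almost_no_calls(self):
        total_called = total_features = 0
        for seed in range(20):
            m, pheno, _ = gen_mirna_matrix(frac_up=0, frac_down=0, seed=seed)
            expressed = expressed_filter(quantile_normalize(m))
            called = diff_mirnas(expressed, pheno, n_perm=200, seed=seed + 50)
            total_called += len(called)
            total_features += expressed.shape[0]
        assert total_called <= 0.01 * total_features

    def test_planted_upshift_recovered_with_direction(self):
        m, pheno, truth = gen_mirna_matrix(
            n_mirnas=243, frac_up=20 / 170, frac_down=0.0,
            fold_range=(2.0, 2.0), noise_sd=0.05, seed=13,
        )
        expressed = expressed_filter(quantile_normalize(m))
        called = {r.feature_id: r for r in diff_mirnas(expressed, pheno, n_perm=200, seed=3)}
        planted = set(truth.modulated_mirnas)
        assert len(planted) >= 18
        recovered = [
            mid for mid in planted
            if mid in called and called[mid].direction == "up"
        ]
        assert len(recovered) >= 0.8 * len(planted)


class TestClassifyPatterns:
    CASES = [
        ((100.0, 150.0, 200.0), "up", "progressive"),
        ((100.0, 160.0, 105.0), "up", "transient_igt"),
        ((100.0, 104.0, 180.0), "up", "late_t2d"),
        ((200.0, 150.0, 100.0), "down", "progressive"),
        ((200.0, 140.0, 195.0), "down", "transient_igt"),
        ((200.0, 196.0, 120.0), "down", "late_t2d"),
    ]

    @pytest.mark.parametrize("means,direction,expected", CASES)
    def test_worked_examples(self, means, direction, expected):
        call = DiffResult("m1", 3.0, 2.0, 1.0, direction)
        out = classify_patterns(
            {"m1": means[0]}, {"m1": means[1]}, {"m1": means[2]}, [call], tol=20.0
        )
        assert out[0].pattern == expected
        assert out[0].direction == direction

    def test_contradictory_trajectory_is_unclassified_with_warning(self, caplog):
        call = DiffResult("m1", 3.0, 2.0, 1.0, "up")
        with caplog.at_level("WARNING"):
            out = classify_patterns({"m1": 100.0}, {"m1": 60.0}, {"m1": 200.0}, [call], tol=20.0)
        assert out[0].pattern is None
        assert any("no trajectory class" in r.message for r in caplog.records)

    def test_each_call_gets_exactly_one_record(self):
        calls = [DiffResult(f"m{i}", 3.0, 2.0, 1.0, "up") for i in range(5)]
        means = {f"m{i}": 100.0 for i in range(5)}
        ups = {f"m{i}": 100.0 + 10 * i for i in range(5)}
        t2d = {f"m{i}": 100.0 + 20 * i for i in range(5)}
        out = classify_patterns(means, ups, t2d, calls, tol=15.0)
        assert [p.mirna_id for p in out] == [c.feature_id for c in calls]


class TestInverseProfileOverlap:
    def test_worked_example(self):
        count, ids = inverse_profile_overlap(
            {"a": "up", "b": "down", "c": "up"},
            {"a": "down", "b": "down", "c": "down"},
        )
        assert (count, ids) == (2, ["a", "c"])

    def test_identical_maps_have_no_overlap(self):
        dirs = {"a": "up", "b": "down"}
        assert inverse_profile_overlap(dirs, dirs) == (0, [])

    def test_disjoint_id_spaces_warn(self, caplog):
        with caplog.at_level("WARNING"):
            out = inverse_profile_overlap({"a": "up"}, {"b": "down"})
        assert out == (0, [])
        assert any("share no miRNA ids" in r.message for r in caplog.records)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"m{i}" for i in range(30)]
        a = {i: ("up", "down")[int(rng.integers(2))] for i in ids if rng.random() < 0.7}
        b = {i: ("up", "down")[int(rng.integers(2))] for i in ids if rng.random() < 0.7}
        count, flipped = inverse_profile_overlap(a, b)
        expected = sorted(
            i for i in ids if i in a and i in b and a[i] != b[i]
        )
        assert flipped == expected
        assert count == len(expected)


class TestDeltaCt:
    def test_ddct_of_minus_one_is_twofold(self):
        ct, pheno = gen_ct_table(
            {"miR-x": {"T2D": 2.0}}, n_per_group=4, replicate_sd=0.0, seed=0
        )
        res = delta_ct_stats(ct, pheno)[0]
        assert res.fold_change["T2D"] == pytest.approx(2.0)
        assert res.fold_change["NGT"] == pytest.approx(1.0)

    def test_identical_groups_flat(self):
        ct, pheno = gen_ct_table({"miR-x": {}}, n_per_group=5, replicate_sd=0.0, seed=1)
        res = delta_ct_stats(ct, pheno)[0]
        assert res.anova_p > 0.99
        for fold in res.fold_change.values():
            assert fold == pytest.approx(1.0)

    def test_dct_tracking_covariate_gives_high_r2(self, rng):
        samples = [f"{g}_{i}" for g in ("NGT", "IGT", "T2D") for i in range(5)]
        cov = {s: float(rng.uniform(4, 12)) for s in samples}
        rows = []
        for s in samples:
            for _ in range(3):
                rows.append((s, "RNU48", 20.0))
                rows.append((s, "miR-y", 20.0 + cov[s] + rng.normal(0, 0.01)))
        ct = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct"])
        pheno = make_pheno({s: s.split("_")[0] for s in samples},
                           covariates={"glucose": cov})
        res = delta_ct_stats(ct, pheno, covariate="glucose")[0]
        assert res.r_squared > 0.99

    def test_missing_reference_rejected(self):
        ct = pd.DataFrame(
            [("s1", "miR-x", 25.0)], columns=["sample_id", "assay_id", "ct"]
        )
        pheno = make_pheno({"s1": "NGT"})
        with pytest.raises(ValueError, match="RNU48"):
            delta_ct_stats(ct, pheno)

    def test_planted_downregulation_recovered(self):
        ct, pheno = gen_ct_table(
            {"miR-z": {"T2D": 0.5}}, n_per_group=8, replicate_sd=0.1, seed=5
        )
        res = delta_ct_stats(ct, pheno)[0]
        assert res.fold_change["T2D"] == pytest.approx(0.5, rel=0.10)
        assert res.anova_p < 0.01
        assert res.posthoc_p[("NGT", "T2D")] < 0.05

    def test_generator_seed_reproducibility(self):
        a, _ = gen_ct_table({"m": {"T2D": 2.0}}, seed=9)
        b, _ = gen_ct_table({"m": {"T2D": 2.0}}, seed=9)
        pd.testing.assert_frame_equal(a, b)
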