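"""Spearman screen, permutation null, BH adjustment, ROC, superiority calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isomirome import (
    CountMatrix,
    InputError,
    PermutationConfig,
    bh_adjust,
    compare_isomir_vs_parent,
    permutation_pvalue,
    roc_auc_ci,
    screen,
    spearman_rho,
    stratify_high_low,
)


def brute_spearman(x, y):
    """Definition-level oracle: Pearson correlation of midranks."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_bh(p):
    """Step-up definition: q(i) = min_{j>=i} p(j)·m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def brute_auc(values, labels):
    """All-pairs concordance count with ties worth 1/2."""
    pos = values[labels]
    neg = values[~labels]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_rho([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_rank_formula_example(self):
        # 1 − 6·Σd²/(n(n²−1)) with Σd² = 10, n = 4 → 0
        assert spearman_rho([1, 2, 3, 4], [3, 1, 4, 2]) == pytest.approx(0.0)

    def test_constant_vector_undefined(self):
        assert np.isnan(spearman_rho([5, 5, 5, 5], [1, 2, 3, 4]))

    def test_length_mismatch_raises(self):
        with pytest.raises(InputError):
            spearman_rho([1, 2, 3], [1, 2])

    @given(st.lists(st.integers(0, 20), min_size=4, max_size=15))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, xs):
        ys = list(range(len(xs)))
        if len(set(xs)) < 2:
            return
        base = spearman_rho(xs, ys)
        transformed = spearman_rho([np.exp(0.3 * x) for x in xs], ys)
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(200):
            n = rng.integers(4, 15)
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.integers(0, 8, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_rho(x, y) == pytest.approx(brute_spearman(x, y), abs=1e-10)


class TestPermutation:
    def test_monotone_feature_small_p(self, rng):
        scores = rng.permutation(np.arange(12)).astype(float)
        values = 2.0 * scores + 1.0  # perfectly rank-correlated
        p = permutation_pvalue(values, scores, PermutationConfig(n_perm=10_000, rng_seed=3))
        assert p <= 0.001  # P(|rho_perm| = 1) = 2/12! per shuffle

    def test_seeded_determinism(self, rng):
        scores = rng.integers(0, 99, size=10).astype(float)
        values = rng.gamma(2.0, 10.0, size=10)
        cfg = PermutationConfig(n_perm=100, rng_seed=9)
        assert permutation_pvalue(values, scores, cfg) == permutation_pvalue(
            values, scores, cfg
        )

    def test_add_one_smoothing_strictly_positive(self, rng):
        scores = rng.permutation(np.arange(12)).astype(float)
        cfg = PermutationConfig(n_perm=500, rng_seed=1, add_one_smoothing=True)
        p = permutation_pvalue(2.0 * scores, scores, cfg)
        assert 0 < p <= 1 / 500

    def test_constant_feature_raises(self):
        with pytest.raises(InputError):
            permutation_pvalue([1.0] * 8, np.arange(8.0), PermutationConfig(n_perm=100))


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert adj == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_out_of_range_raises(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(brute_bh(p), abs=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(expected, abs=1e-12)

    def test_extended_family_treats_missing_tests_as_one(self, rng):
        p = rng.random(8)
        padded = np.concatenate([p, np.ones(12)])
        assert bh_adjust(p, family_size=20) == pytest.approx(
            brute_bh(padded)[:8], abs=1e-12
        )

    def test_monotone_under_rank_preservation(self, rng):
        p = np.sort(rng.random(20))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestStratify:
    @pytest.mark.parametrize("score, high", [(66, False), (75, True), (99, True)])
    def test_cutoff_boundary(self, score, high):
        labels = stratify_high_low([score, 0 if high else 99])
        assert labels[0] == high

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            stratify_high_low([10, 20, 30])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc_ci(np.array([10, 9, 8, 1, 2, 3.0]), np.array([1, 1, 1, 0, 0, 0], bool))
        assert res.auc == pytest.approx(1.0)
        assert res.discriminative

    def test_concordant_pair_count(self):
        res = roc_auc_ci(np.array([3, 1, 2, 0.0]), np.array([1, 1, 0, 0], bool))
        assert res.auc == pytest.approx(0.75)

    def test_all_ties_is_half_not_discriminative(self):
        res = roc_auc_ci(np.full(8, 2.0), np.array([1, 1, 1, 1, 0, 0, 0, 0], bool))
        assert res.auc == pytest.approx(0.5)
        assert not res.discriminative

    def test_one_class_raises(self):
        with pytest.raises(InputError):
            roc_auc_ci(np.arange(4.0), np.ones(4, bool))

    def test_matches_bruteforce_and_complement(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 14))
            values = rng.integers(0, 6, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc_auc_ci(values, labels)
            assert res.auc == pytest.approx(brute_auc(values, labels), abs=1e-12)
            flipped = roc_auc_ci(values, ~labels)
            assert res.auc + flipped.auc == pytest.approx(1.0, abs=1e-12)

    def test_ci_contains_auc(self, rng):
        values = rng.normal(size=20)
        labels = np.arange(20) < 8
        res = roc_auc_ci(values, labels)
        assert res.ci_low <= res.auc <= res.ci_high


def _rpm_matrix(values, level="isomir"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        arr,
        index=pd.Index([f"f{i}" for i in range(arr.shape[0])], name="feature_id"),
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )
    return CountMatrix(df, level=level, normalized=True)


class TestScreen:
    def test_candidate_flag_consistency(self, rng):
        scores = rng.integers(0, 99, size=12).astype(float)
        m = _rpm_matrix(rng.gamma(2.0, 50.0, size=(30, 12)))
        out = screen(m, scores, perm_config=PermutationConfig(n_perm=200, rng_seed=0))
        cand = out["candidate"]
        assert (cand == (out["rho"].abs() >= 0.55)).loc[out["rho"].notna()].all()
        assert out.loc[~cand, "p_perm"].isna().all()
        assert (out.loc[out["significant"], "candidate"]).all()

    def test_negative_rho_is_eligible(self):
        scores = np.array([10, 20, 30, 40, 80, 90.0])
        values = 1000.0 - 10.0 * scores + np.array([0.1, -0.2, 0.3, 0.0, -0.1, 0.2])
        m = _rpm_matrix([values])
        out = screen(m, scores, perm_config=PermutationConfig(n_perm=200, rng_seed=0))
        assert out["rho"].iloc[0] < -0.9
        assert bool(out["candidate"].iloc[0])

    def test_impossible_threshold_empties_funnel(self, rng):
        scores = rng.integers(0, 99, size=10).astype(float)
        m = _rpm_matrix(rng.gamma(2.0, 50.0, size=(15, 10)))
        out = screen(m, scores, rho_threshold=1.01)
        assert not out["candidate"].any()
        assert not out["significant"].any()


class TestSuperiority:
    def _assoc_row(self, fid, level, rho, padj, dyn, auc, sig, cand=True):
        return pd.DataFrame(
            {
                "level": level,
                "mean_rpm": 100.0,
                "sd_rpm": 10.0,
                "dynamic_range": dyn,
                "rho": rho,
                "candidate": cand,
                "p_perm": padj,
                "p_adj": padj,
                "significant": sig,
                "auc": auc,
                "auc_ci_low": auc - 0.1,
                "auc_ci_high": auc + 0.1,
                "discriminative": False,
                "note": "",
            },
            index=pd.Index([fid], name="feature_id"),
        )

    def test_all_four_criteria_superior(self):
        iso = self._assoc_row("p1|AAA", "isomir", 0.8, 0.01, 9.0, 0.9, True)
        mir = self._assoc_row("p1", "mirna", 0.6, 0.04, 4.0, 0.7, True)
        out = compare_isomir_vs_parent(iso, mir, {"p1|AAA": "p1"})
        row = out.loc["p1|AAA"]
        assert row["superior"] and not row["isomir_only"]

    def test_identical_stats_never_superior(self):
        iso = self._assoc_row("p1|AAA", "isomir", 0.7, 0.02, 5.0, 0.8, True)
        mir = self._assoc_row("p1", "mirna", 0.7, 0.02, 5.0, 0.8, True)
        out = compare_isomir_vs_parent(iso, mir, {"p1|AAA": "p1"})
        assert not out.loc["p1|AAA", "superior"]

    def test_non_candidate_parent_counts_as_padj_one(self):
        iso = self._assoc_row("p1|AAA", "isomir", 0.8, 0.01, 9.0, 0.9, True)
        mir = self._assoc_row("p1", "mirna", 0.2, np.nan, 4.0, 0.7, False, cand=False)
        out = compare_isomir_vs_parent(iso, mir, {"p1|AAA": "p1"})
        row = out.loc["p1|AAA"]
        assert row["p_adj_mirna"] == 1.0
        assert row["isomir_only"] and row["superior"]

    def test_undefined_dynamic_range_never_larger(self):
        iso = self._assoc_row("p1|AAA", "isomir", 0.8, 0.01, np.nan, 0.9, True)
        mir = self._assoc_row("p1", "mirna", 0.6, 0.04, 4.0, 0.7, True)
        out = compare_isomir_vs_parent(iso, mir, {"p1|AAA": "p1"})
        assert not out.loc["p1|AAA", "larger_dynamic_range"]
        assert not out.loc["p1|AAA", "superior"]
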