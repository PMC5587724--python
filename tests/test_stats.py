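"""Statistical primitives: size factors, fold-changes, BH, Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ribolife import stats


def _cm(counts, conditions=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    if conditions is None:
        conditions = {c: "A" for c in df.columns}
    return stats.CountMatrix(df, conditions)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = _cm({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(stats.size_factors(m), [1.0, 1.0])

    def test_exact_doubling(self):
        m = _cm({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = stats.size_factors(m)
        assert np.allclose(f, [1 / math.sqrt(2), math.sqrt(2)])

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = rng.integers(1, 1000, size=(50, 4))
            m = _cm({f"s{j}": counts[:, j] for j in range(4)})
            f = stats.size_factors(m).to_numpy()
            ref = np.exp(np.mean(np.log(counts), axis=1))
            expected = [np.median(counts[:, j] / ref) for j in range(4)]
            assert np.allclose(f, expected)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 1000, size=(100, 3))
        m1 = _cm({f"s{j}": counts[:, j] for j in range(3)})
        scaled = counts.astype(float).copy()
        scaled[:, 0] *= 4
        m2 = _cm({f"s{j}": scaled[:, j].astype(int) for j in range(3)})
        f1, f2 = stats.size_factors(m1), stats.size_factors(m2)
        # ratio structure: sample 0's factor rises by 4 / shared-reference shift
        assert np.isclose((f2[0] / f1[0]) / (f2[1] / f1[1]), 4.0, rtol=1e-9)

    def test_all_zero_row_fallback_warns(self, caplog):
        m = _cm({"s1": [0, 5], "s2": [3, 0]})
        with caplog.at_level("WARNING"):
            f = stats.size_factors(m)
        assert "total-count" in caplog.text
        assert np.isclose(np.prod(f), 1.0)


class TestFoldChanges:
    def _two_cond(self, a, b, reps=3):
        cols, conds = {}, {}
        for r in range(reps):
            cols[f"a{r}"] = a
            conds[f"a{r}"] = "A"
            cols[f"b{r}"] = b
            conds[f"b{r}"] = "B"
        return _cm(cols, conds)

    def test_identical_groups_are_unchanged(self):
        m = self._two_cond([100, 200, 50], [100, 200, 50])
        fc = stats.fold_changes(m, "A", "B")
        assert np.allclose(fc["log2fc"], 0.0)
        assert (fc["status"] == "unchanged").all()

    def test_fourfold_at_large_counts(self):
        m = self._two_cond([1000, 4000], [4000, 16000])
        fc = stats.fold_changes(m, "A", "B")
        # size factors absorb half the global shift; use a spiked-null design
        m2 = self._two_cond([1000] * 20 + [1000], [1000] * 20 + [4000])
        fc2 = stats.fold_changes(m2, "A", "B")
        assert abs(fc2["log2fc"].iloc[-1] - 2.0) < 0.01

    def test_low_count_gate(self):
        m = self._two_cond([1, 1000], [2, 1000])
        fc = stats.fold_changes(m, "A", "B", min_total=10)
        assert fc["status"].iloc[0] == stats.STATUS_LOW_DATA
        assert fc["p_value"].iloc[0] == 1.0

    def test_single_replicate_reports_fc_only(self):
        m = self._two_cond([100, 500], [200, 500], reps=1)
        fc = stats.fold_changes(m, "A", "B")
        assert np.isnan(fc["p_value"]).all()
        assert np.isfinite(fc["log2fc"]).all()

    def test_library_rescaling_leaves_foldchanges_unchanged(self):
        rng = np.random.default_rng(3)
        base = rng.integers(50, 2000, size=30)
        m1 = self._two_cond(base, base * 2)
        cols = {c: (m1.counts[c] * (5 if c == "a0" else 1)) for c in m1.counts}
        m2 = stats.CountMatrix(pd.DataFrame(cols, index=m1.counts.index), m1.conditions)
        fc1 = stats.fold_changes(m1, "A", "B")
        fc2 = stats.fold_changes(m2, "A", "B")
        assert np.allclose(fc1["log2fc"], fc2["log2fc"], atol=1e-6)


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "fc,q,expected",
        [
            (2.5, 0.005, "up"),
            (1.9, 0.001, "unchanged"),  # strictly more-than-2-fold
            (3.0, 0.02, "unchanged"),   # FDR gate
            (1 / 2.5, 0.005, "down"),
        ],
    )
    def test_gate(self, fc, q, expected):
        assert stats.classify_regulation(math.log2(fc), q) == expected


class TestTranslationEfficiency:
    def test_log_ratio_of_foldchanges(self):
        ribo = pd.DataFrame({"log2fc": [2.0, 1.0, 0.0]}, index=["a", "b", "c"])
        mrna = pd.DataFrame({"log2fc": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        te = stats.translation_efficiency(ribo, mrna)
        assert te.loc["a", "te_log2fc"] == 1.0   # FC 4 / FC 2 = 2
        assert te.loc["b", "te_log2fc"] == 0.0   # equal fold-changes
        assert te.loc["c", "te_log2fc"] == -1.0  # FC 1 / FC 2 = 0.5

    def test_genes_missing_from_one_side_are_dropped(self):
        ribo = pd.DataFrame({"log2fc": [1.0]}, index=["a"])
        mrna = pd.DataFrame({"log2fc": [1.0, 2.0]}, index=["a", "b"])
        assert list(stats.translation_efficiency(ribo, mrna).index) == ["a"]


def _bh_oracle(p):
    """Hand-applied step-up: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBhFdr:
    def test_hand_example(self):
        assert np.allclose(stats.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        assert np.allclose(stats.bh_fdr([1.0, 1.0]), [1.0, 1.0])
        assert np.allclose(stats.bh_fdr([0.2]), [0.2])
        assert stats.bh_fdr([]).size == 0

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40)).tolist()
            assert np.allclose(stats.bh_fdr(p), _bh_oracle(p))

    def test_permutation_equivariance_and_monotonicity(self):
        rng = np.random.default_rng(12)
        p = rng.random(25)
        perm = rng.permutation(25)
        assert np.allclose(stats.bh_fdr(p)[perm], stats.bh_fdr(p[perm]))
        order = np.argsort(p)
        q_sorted = stats.bh_fdr(p)[order]
        assert (np.diff(q_sorted) >= -1e-12).all()


def _mwu_enumeration(a, b, alternative="two-sided"):
    """Brute-force exact p over all C(n, n_a) labelings (tie-free only)."""
    pooled = sorted(list(a) + list(b))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = [
        sum(combo) - n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    n_le = sum(u <= u_obs for u in us)
    n_ge = sum(u >= u_obs for u in us)
    if alternative == "greater":
        return u_obs, n_ge / len(us)
    if alternative == "less":
        return u_obs, n_le / len(us)
    return u_obs, min(1.0, 2 * min(n_le, n_ge) / len(us))


class TestMannWhitneyU:
    def test_disjoint_small_sample_exact(self):
        u, p = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert np.isclose(p, 0.1)  # 2 * 1/20

    def test_identical_samples_p_one(self):
        u, p = stats.mann_whitney_u([5, 5, 5, 5], [5, 5, 5, 5])
        assert p == 1.0

    def test_matches_enumeration_oracle_all_small_sizes(self):
        rng = np.random.default_rng(21)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                if n1 + n2 > 10:
                    continue
                for _ in range(3):
                    a = rng.normal(size=n1)
                    b = rng.normal(size=n2)
                    for alt in ("two-sided", "greater", "less"):
                        u, p = stats.mann_whitney_u(a, b, alternative=alt)
                        u_ref, p_ref = _mwu_enumeration(list(a), list(b), alt)
                        assert u == u_ref
                        assert np.isclose(p, p_ref)

    def test_exact_branch_matches_scipy(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            u, p = stats.mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert np.isclose(u, ref.statistic)
            assert np.isclose(p, ref.pvalue)

    def test_tied_large_sample_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(23)
        a = rng.integers(0, 10, size=40)
        b = rng.integers(2, 12, size=35)
        u, p = stats.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert np.isclose(u, ref.statistic)
        assert np.isclose(p, ref.pvalue, rtol=1e-6)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1.0])
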