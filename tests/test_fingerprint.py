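import numpy as np
import pandas as pd
import pytest
from scipy import stats

import natfreq as nf
from natfreq.fingerprint import FingerprintResult, PermutationNull


def tau_b_oracle(u, v):
    """O(n^2) pair-counting Kendall tau-b on pairwise-complete positions."""
    ok = np.isfinite(u) & np.isfinite(v)
    x, y = u[ok], v[ok]
    n = len(x)
    C = D = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                C += 1
            else:
                D += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((C + D + tx) * (C + D + ty))
    return (C - D) / denom


class TestKendallTau:
    def test_identity_and_reversal(self):
        u = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert nf.kendall_tau(u, u) == pytest.approx(1.0)
        ranks = np.argsort(np.argsort(u)).astype(float)
        assert nf.kendall_tau(u, -ranks) == pytest.approx(-1.0)

    def test_hand_counted_example(self):
        # (1,2,3,4) vs (1,3,2,4): C=5, D=1 -> (5-1)/6
        got = nf.kendall_tau(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert got == pytest.approx(4 / 6, abs=1e-12)

    def test_too_few_complete_pairs_rejected(self):
        u = np.array([1.0, 2.0, np.nan, np.nan])
        v = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError, match="complete pairs"):
            nf.kendall_tau(u, v)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            nf.kendall_tau(np.ones(5), np.arange(5.0))

    def test_matches_brute_force_oracle_with_ties_and_missing(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            n = rng.integers(5, 51)
            u = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            v = (u + rng.integers(-2, 3, size=n)).astype(float)
            u[rng.random(n) < 0.15] = np.nan
            v[rng.random(n) < 0.15] = np.nan
            ok = np.isfinite(u) & np.isfinite(v)
            if ok.sum() < 3 or np.ptp(u[ok]) == 0 or np.ptp(v[ok]) == 0:
                continue
            assert nf.kendall_tau(u, v) == pytest.approx(tau_b_oracle(u, v), abs=1e-12)
            checked += 1


class TestTauMatrixAndIdentify:
    def test_one_subject_matrix(self):
        m = np.array([[1.0, 2.0, 3.0, 2.5]])
        tau = nf.build_tau_matrix(m, m)
        assert tau.shape == (1, 1)
        assert tau[0, 0] == pytest.approx(1.0)

    def test_identical_instances_have_unit_diagonal(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(5, 30))
        tau = nf.build_tau_matrix(maps, maps)
        np.testing.assert_allclose(np.diag(tau), 1.0)

    def test_subject_mismatch_rejected(self):
        mk = lambda sid: nf.NaturalFrequencyMap(
            subject_id=sid, session_id=1,
            freq_hz=np.arange(5.0), selection_t=np.zeros(5),
        )
        with pytest.raises(ValueError, match="different subjects"):
            nf.build_tau_matrix([mk("A")], [mk("B")])

    def test_match_matrix_one_hot_rows(self):
        rng = np.random.default_rng(1)
        match, _ = nf.identify(rng.normal(size=(7, 7)))
        np.testing.assert_array_equal(match.sum(axis=1), 1)

    def test_swapped_pair_gives_one_third(self):
        tau = np.array([[0.9, 0.1, 0.2], [0.1, 0.3, 0.8], [0.2, 0.9, 0.3]])
        match, acc = nf.identify(tau)
        assert acc == pytest.approx(100.0 / 3.0)

    def test_invariant_to_monotone_row_transforms(self):
        rng = np.random.default_rng(2)
        tau = rng.uniform(-1, 1, size=(9, 9))
        m1, a1 = nf.identify(tau)
        transformed = tau.copy()
        transformed[::2] = np.tanh(3 * transformed[::2])  # strictly increasing
        transformed[1::2] = transformed[1::2] ** 3 + 0.2
        m2, a2 = nf.identify(transformed)
        np.testing.assert_array_equal(m1, m2)
        assert a1 == a2

    def test_joint_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        tau = rng.uniform(-1, 1, size=(8, 8))
        perm = rng.permutation(8)
        _, acc = nf.identify(tau)
        _, acc_p = nf.identify(tau[np.ix_(perm, perm)])
        assert acc == pytest.approx(acc_p)
        m = nf.identifiability_metrics(tau)
        m_p = nf.identifiability_metrics(tau[np.ix_(perm, perm)])
        np.testing.assert_allclose(
            m.loc[perm, "I_self"].to_numpy(), m_p["I_self"].to_numpy(), atol=1e-12
        )


def diag_dominant_tau(n, correct, rng, self_val=0.9, spread=0.2):
    """Random tau matrix with exactly `correct` self-matching rows."""
    tau = rng.uniform(0.0, spread, size=(n, n))
    for i in range(n):
        tau[i, i] = self_val
    for i in range(n - correct):
        row = i  # sabotage the first n-correct rows
        other = (row + 1) % n
        tau[row, other] = self_val + 0.05
    return tau


class TestIdentifiabilityMetrics:
    def test_formulas_on_constructed_matrix(self):
        # group-level values: tau_self 0.50, mu_others 0.18 -> I = 0.32
        n = 6
        tau = np.full((n, n), 0.18)
        np.fill_diagonal(tau, 0.50)
        tau[0, 1] = 0.28  # break sigma = 0 for subject 0's pool
        m = nf.identifiability_metrics(tau)
        # subject 0's pool includes the 0.28 entry: mu = (0.28 + 9*0.18)/10
        assert m.loc[0, "I_self"] == pytest.approx(0.50 - (0.28 + 9 * 0.18) / 10)
        # subject 2's pool is all 0.18 (group-level worked values)
        assert m.loc[2, "mu_others"] == pytest.approx(0.18)
        assert m.loc[2, "I_self"] == pytest.approx(0.32)

    def test_differentiability_is_I_over_sigma(self):
        rng = np.random.default_rng(4)
        tau = diag_dominant_tau(8, 8, rng)
        m = nf.identifiability_metrics(tau)
        np.testing.assert_allclose(m.D_self, m.I_self / m.sigma_others)
        # direct formula: I 0.32 and sigma 0.10 -> D = 3.2
        assert 0.32 / 0.10 == pytest.approx(3.2)

    def test_sigma_zero_flagged(self):
        tau = np.full((4, 4), 0.2)
        np.fill_diagonal(tau, 0.6)
        m = nf.identifiability_metrics(tau)
        assert m.sigma_zero.all()
        assert m.D_self.isna().all()

    def test_independent_recomputation_identity(self):
        rng = np.random.default_rng(5)
        tau = rng.uniform(-0.2, 0.8, size=(15, 15))
        m = nf.identifiability_metrics(tau)
        for i in range(15):
            others = [tau[i, j] for j in range(15) if j != i] + [
                tau[j, i] for j in range(15) if j != i
            ]
            mu = sum(others) / len(others)
            var = sum((o - mu) ** 2 for o in others) / (len(others) - 1)
            assert abs(m.loc[i, "I_self"] - (tau[i, i] - mu)) < 1e-12
            assert abs(m.loc[i, "D_self"] - (tau[i, i] - mu) / var**0.5) < 1e-12


class TestBootstrap:
    def test_perfect_diagonal_gives_degenerate_ci(self):
        tau = np.eye(6)
        assert nf.bootstrap_accuracy_ci(tau, n_boot=500, seed=0) == (100.0, 100.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        tau = diag_dominant_tau(10, 8, rng)
        a = nf.bootstrap_accuracy_ci(tau, n_boot=300, seed=42)
        b = nf.bootstrap_accuracy_ci(tau, n_boot=300, seed=42)
        assert a == b

    def test_ci_contains_point_accuracy(self):
        rng = np.random.default_rng(7)
        hits = 0
        for rep in range(50):
            tau = diag_dominant_tau(16, rng.integers(10, 17), rng)
            _, acc = nf.identify(tau)
            lo, hi = nf.bootstrap_accuracy_ci(tau, n_boot=1000, seed=rep)
            hits += lo - 1e-9 <= acc <= hi + 1e-9
        assert hits >= 48  # >= 95% of 50 seeded repeats


class TestPermutationNull:
    def test_two_subjects_all_or_nothing(self):
        tau = np.array([[0.9, 0.1], [0.2, 0.8]])
        null = nf.permutation_null(tau, n_perm=200, seed=0)
        assert set(np.unique(null.accuracies_pct)) <= {0.0, 100.0}
        assert null.max_rate_pct == 100.0  # identity permutation recovers it

    def test_mean_matches_is_one_fixed_point(self):
        rng = np.random.default_rng(8)
        tau = diag_dominant_tau(12, 12, rng)
        null = nf.permutation_null(tau, n_perm=10000, seed=1)
        correct = null.accuracies_pct / 100.0 * 12
        se = correct.std(ddof=1) / np.sqrt(correct.size)
        assert abs(null.mean_matches - 1.0) <= 3 * se

    def test_strong_diagonal_beats_all_permutations(self):
        rng = np.random.default_rng(9)
        tau = diag_dominant_tau(27, 27, rng)
        null = nf.permutation_null(tau, n_perm=10000, seed=2)
        assert null.p_value < 0.001
        assert null.max_rate_pct < 100.0


def make_result(metrics, matched):
    metrics = metrics.copy()
    metrics["matched"] = matched
    n = len(metrics)
    return FingerprintResult(
        subjects=[f"S{i}" for i in range(n)],
        tau=np.eye(n),
        match=np.diag(np.asarray(matched).astype(int)),
        accuracy_pct=100.0 * np.mean(matched),
        metrics=metrics,
        ci95=(0.0, 100.0),
        perm=PermutationNull(0.0, 1.0, np.zeros(1), 1.0),
    )


class TestGroupComparisons:
    def _metrics(self, I, D, tau_self=None, mu=None):
        n = len(I)
        return pd.DataFrame(
            {
                "tau_self": tau_self if tau_self is not None else np.linspace(0.4, 0.6, n),
                "mu_others": mu if mu is not None else np.full(n, 0.2),
                "sigma_others": np.full(n, 0.1),
                "I_self": I,
                "D_self": D,
            }
        )

    def test_identical_groups_welch_t_zero(self):
        I = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        res = make_result(self._metrics(I, I), [True] * 3 + [False] * 3)
        out = nf.group_comparisons(res)
        assert out["I_target_vs_nontarget"]["stat"] == pytest.approx(0.0)
        assert out["I_target_vs_nontarget"]["p"] == pytest.approx(1.0)

    def test_welch_df_matches_hand_formula(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 2, 7)
        res = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / 20, b.var(ddof=1) / 7
        df_hand = (va + vb) ** 2 / (va**2 / 19 + vb**2 / 6)
        assert res.df == pytest.approx(df_hand, abs=1e-10)

    def test_paired_self_vs_others(self):
        rng = np.random.default_rng(11)
        ts = rng.uniform(0.4, 0.6, 10)
        mu = rng.uniform(0.1, 0.2, 10)
        res = make_result(
            self._metrics(ts - mu, (ts - mu) / 0.1, tau_self=ts, mu=mu),
            [True] * 8 + [False] * 2,
        )
        out = nf.group_comparisons(res)
        ref = stats.ttest_rel(ts, mu)
        assert out["self_vs_others"]["stat"] == pytest.approx(ref.statistic)

    def test_constant_elapsed_days_skips_pearson(self, caplog):
        I = np.linspace(0.0, 0.5, 6)
        res = make_result(self._metrics(I, I), [True] * 4 + [False] * 2)
        with caplog.at_level("WARNING"):
            out = nf.group_comparisons(res, elapsed_days=np.full(6, 30.0))
        assert "days_vs_tau_self" not in out
        assert "skipped" in caplog.text

    def test_small_group_comparison_skipped(self, caplog):
        I = np.linspace(0.0, 0.5, 5)
        res = make_result(self._metrics(I, I), [True] * 4 + [False])
        with caplog.at_level("WARNING"):
            out = nf.group_comparisons(res)
        assert "I_target_vs_nontarget" not in out

    def test_ks_normality_reported_per_map(self):
        rng = np.random.default_rng(13)
        I = np.linspace(0.0, 0.5, 6)
        res = make_result(self._metrics(I, I), [True] * 3 + [False] * 3)
        maps = [rng.normal(10, 1, 200) for _ in range(3)]
        maps.append(rng.exponential(2.0, 200) + 8)
        out = nf.group_comparisons(res, maps=maps)
        ps = out["ks_normality"]["p_values"]
        assert len(ps) == 4
        assert ps[0] > 0.01  # gaussian map not rejected
        assert ps[3] < 0.01  # skewed map rejected
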