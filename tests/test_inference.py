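"""Null ensembles, Welch tests, FDR, consistency, cohort expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import eegalign as ea


def _random_matrix(n, seed):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0, 1, (n, n))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0)
    return ea.ConnectivityMatrix(W)


class TestRandomize:
    def test_constant_offdiagonal_fixed_point(self):
        W = ea.ConnectivityMatrix(0.3 * (np.ones((5, 5)) - np.eye(5)))
        R = ea.randomize_connectivity(W, seed=1)
        np.testing.assert_array_equal(R.W, W.W)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_multiset_preserved_exactly(self, seed, n):
        W = _random_matrix(n, seed)
        R = ea.randomize_connectivity(W, seed=seed + 1)
        np.testing.assert_array_equal(
            np.sort(R.pair_values()), np.sort(W.pair_values())
        )
        assert np.allclose(R.W, R.W.T) and np.all(np.diag(R.W) == 0)

    def test_seed_reproducibility(self):
        W = _random_matrix(10, 0)
        a = ea.randomize_connectivity(W, seed=5)
        b = ea.randomize_connectivity(W, seed=5)
        c = ea.randomize_connectivity(W, seed=6)
        np.testing.assert_array_equal(a.W, b.W)
        assert not np.array_equal(a.W, c.W)


class TestNullEnsemble:
    def test_single_subject_three_nulls(self):
        W = _random_matrix(6, 2)
        ens = ea.build_null_ensemble([W], n_null=3, seed=0)
        assert len(ens.matrices) == 3 and len(ens.alignments) == 3
        assert np.all(ens.provenance == 0)

    def test_round_robin_provenance_balance(self):
        group = [_random_matrix(6, s) for s in range(3)]
        ens = ea.build_null_ensemble(group, n_null=10, seed=0)
        counts = np.bincount(ens.provenance, minlength=3)
        assert counts.max() - counts.min() <= 1

    def test_validation(self):
        with pytest.raises(ValueError, match="nonempty"):
            ea.build_null_ensemble([], n_null=5)
        with pytest.raises(ValueError, match="n_null"):
            ea.build_null_ensemble([_random_matrix(5, 0)], n_null=0)

    def test_null_angle_distribution_wider_than_structured(self, planted_3comm):
        """Randomisation destroys community structure, broadening the angle law."""
        W, _ = planted_3comm
        th = ea.eigenvector_alignment(W).pair_values()
        ens = ea.build_null_ensemble([W], n_null=100, seed=3)
        ks = stats.ks_2samp(th, ens.theta_stack().ravel())
        assert ks.statistic > 0 and ks.pvalue < 0.01


class TestWelch:
    def test_identical_samples_t_zero_p_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(90, 5, size=(10, 6))
        sm = ea.pairwise_welch_test(x, x.copy())
        np.testing.assert_allclose(sm.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(sm.p, 1.0)
        assert np.all(sm.direction == "none")

    def test_shifted_sample_strongly_significant_increased(self):
        """Subjects 20 deg below null (sd 2): Welch p < 1e-6, labelled increased."""
        rng = np.random.default_rng(1)
        null = rng.normal(90, 2, size=(1000, 3))
        subj = rng.normal(70, 2, size=(13, 3))
        sm = ea.pairwise_welch_test(subj, null)
        assert np.all(sm.p < 1e-6)
        assert np.all(sm.direction == "increased")
        # cross-check one pair against the closed-form Welch statistic
        a, b = subj[:, 0], null[:, 0]
        t_ref = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 13 + b.var(ddof=1) / 1000)
        assert sm.t[0] == pytest.approx(t_ref)

    def test_degenerate_zero_variance(self):
        a = np.full((4, 3), 10.0)
        b = np.full((6, 3), 10.0)
        b[:, 1] = 20.0
        rng = np.random.default_rng(0)
        a[:, 2] = rng.normal(10, 1, 4)
        b[:, 2] = rng.normal(10, 1, 6)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            sm = ea.pairwise_welch_test(a, b)
        assert sm.p[0] == 1.0 and sm.t[0] == 0.0
        assert sm.p[1] == 0.0 and np.isinf(sm.t[1])
        assert 0 < sm.p[2] <= 1

    def test_128_channels_give_8128_pairs(self):
        rng = np.random.default_rng(2)
        n_pairs = 128 * 127 // 2
        sm = ea.pairwise_welch_test(
            rng.normal(90, 5, (4, n_pairs)), rng.normal(90, 5, (10, n_pairs))
        )
        assert sm.n_pairs == 8128
        assert len(sm.channel_labels) == 128

    def test_undefined_pairs_excluded(self):
        rng = np.random.default_rng(3)
        a = rng.normal(90, 5, (5, 3))
        b = rng.normal(90, 5, (8, 3))
        a[0, 1] = np.nan
        sm = ea.pairwise_welch_test(a, b)
        assert np.isnan(sm.t[1]) and np.isnan(sm.q[1])
        assert sm.direction[1] == "none"
        assert np.all(np.isfinite(sm.q[[0, 2]]))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(ea.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_edge_cases(self):
        np.testing.assert_array_equal(ea.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(ea.bh_fdr([0.37]), [0.37])
        assert ea.bh_fdr([]).size == 0
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ea.bh_fdr([0.5, 1.7])

    def test_q_at_least_p_and_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 200) ** 2
        q = ea.bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        assert set(np.flatnonzero(q < 0.05)) <= set(np.flatnonzero(q < 0.10))


def _make_map(direction, labels=("a", "b", "c")):
    n = len(labels)
    pairs = np.column_stack(np.triu_indices(n, k=1))
    m = pairs.shape[0]
    d = np.asarray(direction, dtype=object)
    q = np.where(d == "none", 0.5, 0.01)
    return ea.SignificanceMap(
        list(labels), pairs, np.zeros(m), q.astype(float), q.astype(float), d, 5, 100
    )


class TestConsistency:
    def test_three_of_four_same_direction(self):
        maps = {
            "delta": _make_map(["increased", "none", "none"]),
            "theta": _make_map(["increased", "none", "decreased"]),
            "alpha": _make_map(["increased", "none", "decreased"]),
            "beta": _make_map(["none", "none", "none"]),
        }
        cs = ea.consistency_filter(maps, min_bands=3)
        assert cs.consistent.tolist() == [True, False, False]
        assert cs.direction[0] == "increased"

    def test_two_bands_insufficient(self):
        maps = {
            b: _make_map(["increased", "none", "none"]) for b in ("delta", "theta")
        } | {b: _make_map(["none", "none", "none"]) for b in ("alpha", "beta")}
        cs = ea.consistency_filter(maps, min_bands=3)
        assert not cs.consistent.any()

    def test_direction_conflict_not_consistent(self):
        maps = {b: _make_map(["increased", "none", "none"]) for b in ("delta", "theta")}
        maps |= {b: _make_map(["decreased", "none", "none"]) for b in ("alpha", "beta")}
        cs = ea.consistency_filter(maps, min_bands=3)
        assert not cs.consistent.any()

    def test_mismatched_labels_error(self):
        maps = {
            "delta": _make_map(["none"] * 3),
            "theta": _make_map(["none"] * 3),
            "alpha": _make_map(["none"] * 3, labels=("a", "b", "z")),
        }
        with pytest.raises(ValueError, match="alpha"):
            ea.consistency_filter(maps, min_bands=3)

    def test_too_few_maps_error(self):
        with pytest.raises(ValueError, match="min_bands"):
            ea.consistency_filter({"delta": _make_map(["none"] * 3)}, min_bands=3)


class TestExpandCohort:
    def test_factor_one_identity(self):
        group = [_random_matrix(5, s) for s in range(3)]
        out = ea.expand_cohort(group, factor=1)
        assert len(out) == 3
        for a, b in zip(group, out):
            np.testing.assert_array_equal(a.W, b.W)
            assert not b.meta.get("artificially_expanded", False)

    def test_duplication_counts_and_flag(self):
        group = [_random_matrix(5, s) for s in range(10)]
        out = ea.expand_cohort(group, factor=2)
        assert len(out) == 20
        for orig in group:
            matches = [m for m in out if np.array_equal(m.W, orig.W)]
            assert len(matches) == 2
        assert all(m.meta["artificially_expanded"] for m in out)

    def test_expansion_inflates_significance(self, small_cohort_matrices):
        """Duplicating subjects doubles n and shrinks p-values on average."""
        group = small_cohort_matrices
        base = ea.NullModelTest(n_null=100, random_state=0).fit(group)
        expanded = ea.NullModelTest(n_null=100, random_state=0).fit(
            ea.expand_cohort(group, factor=2)
        )
        assert expanded.significance_.artificially_expanded
        assert not base.significance_.artificially_expanded
        assert np.nanmean(expanded.significance_.p) < np.nanmean(base.significance_.p)


def test_type_one_error_controlled_under_null_law():
    """Subjects drawn from the randomisation law itself: BH keeps discoveries ~5%."""
    base = _random_matrix(16, 123)
    fractions = []
    for rep in range(20):
        rng_seed = 1000 + rep
        subjects = [ea.randomize_connectivity(base, seed=rng_seed * 100 + i) for i in range(8)]
        fit = ea.NullModelTest(n_null=200, random_state=rng_seed).fit(subjects)
        sig = fit.significance_.significant_pairs().size
        fractions.append(sig / fit.significance_.n_pairs)
    fractions = np.asarray(fractions)
    se = np.sqrt(0.05 * 0.95 / (fractions.size * base.n_pairs))
    assert fractions.mean() <= 0.05 + 3 * se
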