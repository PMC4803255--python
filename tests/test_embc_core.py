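"""Constrained EM: E-step, initialization, delimiters, regions, M-step, fit."""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import embc
from embc import binary
from embc.binary import DelimiterSet, region_membership
from embc.core import (EMbCConfig, MixtureModel, assign_labels, compute_delimiter,
                       compute_delimiters, estep, fit, fit_pooled,
                       init_max_entropy, loglik, mstep_embc)
from embc.features import FeatureMatrix


def model_2x1d(mu_a=-1.0, mu_b=1.0, s_a=1.0, s_b=1.0, pi_a=0.5):
    return MixtureModel(
        mus=np.array([[mu_a], [mu_b]]),
        sigmas=np.array([[[s_a**2]], [[s_b**2]]]),
        pis=np.array([pi_a, 1 - pi_a]),
        active=np.array([True, True]),
        codes=["L", "H"],
    )


def random_model(rng, k=2, m=2):
    mus = rng.normal(size=(k, m))
    sigmas = np.empty((k, m, m))
    for j in range(k):
        A = rng.normal(size=(m, m))
        sigmas[j] = A @ A.T + 0.3 * np.eye(m)
    pis = rng.dirichlet(np.ones(k))
    return MixtureModel(mus=mus, sigmas=sigmas, pis=pis,
                        active=np.ones(k, bool),
                        codes=binary.codes(int(np.log2(k))) if k in (2, 4, 8)
                        else [str(j) for j in range(k)])


class TestEstep:
    def test_identical_components_give_half(self, rng):
        model = model_2x1d(0.0, 0.0)
        W = estep(rng.normal(size=(20, 1)), model)
        np.testing.assert_allclose(W, 0.5)

    def test_extreme_separation(self):
        model = model_2x1d(0.0, 100.0)
        W = estep(np.array([[0.0]]), model)
        assert W[0, 0] > 1 - 1e-10

    def test_matches_direct_density_formula(self, rng):
        model = random_model(rng)
        X = rng.normal(size=(30, 2))
        W = estep(X, model)
        dens = np.column_stack([
            model.pis[j] * multivariate_normal.pdf(X, model.mus[j],
                                                   model.sigmas[j])
            for j in range(2)])
        np.testing.assert_allclose(W, dens / dens.sum(1, keepdims=True),
                                   atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        model = random_model(rng, k=4)
        W = estep(rng.normal(size=(50, 2)), model)
        np.testing.assert_allclose(W.sum(1), 1.0, atol=1e-12)


class TestInitMaxEntropy:
    def test_univariate_delimiter_is_median(self, rng):
        X = rng.normal(size=(31, 1))
        delims, model = init_max_entropy(X, np.array([1e-6]))
        assert delims["."] == pytest.approx(np.median(X))
        assert model.k == 2

    def test_symmetric_tie_breaks_to_first_variable(self, rng):
        # same values in both variables -> equal 1-bit split entropy
        v = rng.normal(size=16)
        X = np.column_stack([v, v[::-1]])
        delims, _ = init_max_entropy(X, np.full(2, 1e-6))
        # variable 1 split first: its delimiter is the global median in
        # both contexts
        assert delims[".L"] == delims[".H"] == pytest.approx(np.median(v))

    def test_matches_exhaustive_order_enumeration(self, rng):
        X = rng.normal(size=(12, 2)) * np.array([1.0, 3.0])
        delims, _ = init_max_entropy(X, np.full(2, 1e-6))

        def entropy(p):
            return 0.0 if p in (0.0, 1.0) else -(p * np.log2(p)
                                                 + (1 - p) * np.log2(1 - p))

        # brute force: try both top-level variables, score total split
        # entropy greedily per node, pick the better order
        best = None
        for first in (0, 1):
            med = np.median(X[:, first])
            h_top = entropy(np.mean(X[:, first] <= med))
            other = 1 - first
            d = {}
            for code, sel in (("L", X[:, first] <= med),
                              ("H", X[:, first] > med)):
                d[code] = np.median(X[sel, other])
            if best is None or h_top > best[0] + 1e-12:
                best = (h_top, first, med, d)
        _, first, med, d = best
        key_top = (".L", ".H") if first == 0 else ("L.", "H.")
        assert delims[key_top[0]] == pytest.approx(med)
        assert delims[key_top[1]] == pytest.approx(med)
        key_low, key_high = ("L.", "H.") if first == 0 else (".L", ".H")
        assert delims[key_low] == pytest.approx(d["L"])
        assert delims[key_high] == pytest.approx(d["H"])

    def test_uniform_prior_and_floor(self, rng):
        X = rng.normal(size=(40, 2))
        floor = np.array([0.5, 0.5])
        _, model = init_max_entropy(X, floor)
        np.testing.assert_allclose(model.pis, 0.25)
        for j in range(4):
            assert np.all(np.diag(model.sigmas[j]) >= floor**2 - 1e-15)


class TestDelimiters:
    def test_symmetric_pair_splits_at_zero(self):
        model = model_2x1d()
        X = np.array([[-1.0], [0.0], [1.0], [-0.5], [0.5]])
        assert compute_delimiter(X, model, 0, 1, 0) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, k=2, m=2)
        X = rng.normal(size=(200, 2)) + model.mus[rng.integers(2, size=200)]
        r = compute_delimiter(X, model, 0, 1, split_var=0)

        mu_a, mu_b = model.mus
        d = mu_b - mu_a
        tgrid = np.linspace(0.0, 1.0, 20001)
        Z = mu_a + tgrid[:, None] * d
        la = np.log(model.pis[0]) + multivariate_normal.logpdf(
            Z, mu_a, model.sigmas[0])
        lb = np.log(model.pis[1]) + multivariate_normal.logpdf(
            Z, mu_b, model.sigmas[1])
        wa = 1.0 / (1.0 + np.exp(lb - la))
        grid_best = Z[np.argmin(np.abs(2 * wa - 1)), 0]
        # within one data-point spacing of the dense-grid optimum
        tproj = (X - mu_a) @ d / (d @ d)
        inside = np.sort(tproj[(tproj >= 0) & (tproj <= 1)])
        spacing = (np.max(np.diff(inside)) if inside.size > 1 else 1.0)
        assert abs(r - grid_best) <= spacing * abs(d[0]) + 1e-9

    def test_unequal_pi_shifts_toward_rare_cluster(self, rng):
        model = model_2x1d(pi_a=0.95)
        X = rng.uniform(-1, 1, size=(2001, 1))
        r = compute_delimiter(X, model, 0, 1, 0)
        assert r > 0.0  # shifted toward mu_b = +1

    def test_count_and_undefined_on_absorption(self, rng):
        model = random_model(rng, k=4, m=2)
        X = rng.normal(size=(50, 2))
        delims = compute_delimiters(X, model)
        assert delims.expected_count == 4
        assert delims.defined_count == 4
        model.active[2] = False
        delims = compute_delimiters(X, model)
        assert delims.defined_count == 2
        assert delims[".L"] is None and delims["H."] is None

    def test_delimiter_counts_scale_as_m_2m1(self):
        for m in range(1, 5):
            assert DelimiterSet(m).expected_count == m * 2 ** (m - 1)
            assert len(DelimiterSet(m)) == m * 2 ** (m - 1)


class TestRegionMembership:
    codes4 = ["LL", "LH", "HL", "HH"]

    def test_aligned_delimiters_partition_exactly(self, rng):
        delims = DelimiterSet(2, {".L": 0.5, ".H": 0.5, "L.": 0.5, "H.": 0.5})
        X = rng.uniform(size=(200, 2))
        memb = region_membership(X, delims, self.codes4, np.ones(4, bool))
        assert np.all(memb.sum(1) == 1)

    def test_overlapping_delimiters_share_middle_with_LL_HH(self):
        delims = DelimiterSet(2, {".L": 0.6, ".H": 0.4, "L.": 0.6, "H.": 0.4})
        X = np.array([[0.5, 0.5]])
        memb = region_membership(X, delims, self.codes4, np.ones(4, bool))
        assert memb[0].tolist() == [True, False, False, True]

    def test_non_overlapping_delimiters_share_middle_with_LH_HL(self):
        delims = DelimiterSet(2, {".L": 0.4, ".H": 0.6, "L.": 0.4, "H.": 0.6})
        X = np.array([[0.5, 0.5]])
        memb = region_membership(X, delims, self.codes4, np.ones(4, bool))
        assert memb[0].tolist() == [False, True, True, False]

    def test_orphan_point_falls_back_to_max_posterior_region(self):
        # gap in variable 1 only: the middle-left point is in no region
        delims = DelimiterSet(2, {".L": 0.4, ".H": 0.6, "L.": 0.5, "H.": 0.5})
        X = np.array([[0.5, 0.2]])
        W = np.array([[0.1, 0.2, 0.6, 0.1]])
        memb = region_membership(X, delims, self.codes4, np.ones(4, bool), W)
        assert memb[0].tolist() == [False, False, True, False]

    def test_undefined_delimiter_skips_constraint(self):
        delims = DelimiterSet(2, {".L": 0.5, "L.": 0.5, "H.": 0.5})
        X = np.array([[0.9, 0.9]])
        memb = region_membership(X, delims, self.codes4, np.ones(4, bool))
        assert memb[0, 3]  # HH accepts despite the missing .H delimiter


def naive_mstep(X, W, U, memb, mus_shape):
    """Independent double-loop evaluation of the weighted update rules."""
    n, m = X.shape
    k = W.shape[1]
    pis = np.array([sum(W[i, j] for i in range(n)) / n for j in range(k)])
    mus = np.zeros((k, m))
    sigs = np.zeros((k, m, m))
    for j in range(k):
        for l in range(m):
            num = den = 0.0
            for i in range(n):
                if memb[i, j]:
                    num += U[i, l] * W[i, j] * X[i, l]
                    den += U[i, l] * W[i, j]
            mus[j, l] = num / den
        for r in range(m):
            for s in range(m):
                num = den = 0.0
                for i in range(n):
                    u = np.sqrt((U[i, r] ** 2 + U[i, s] ** 2) / 2.0)
                    num += u * W[i, j] * (X[i, r] - mus[j, r]) * (X[i, s] - mus[j, s])
                    den += u * W[i, j]
                sigs[j, r, s] = num / den
    return pis, mus, sigs


class TestMStep:
    def test_matches_naive_weighted_sums(self, rng):
        n, m, k = 40, 2, 4
        X = rng.normal(size=(n, m))
        W = rng.dirichlet(np.ones(k), size=n)
        U = rng.uniform(0.2, 1.0, size=(n, m))
        memb = rng.uniform(size=(n, k)) < 0.7
        memb[:, 0] = True  # keep every region populated
        model = random_model(rng, k=k, m=m)
        new = mstep_embc(X, W, U, memb, model, np.full(m, 1e-9))
        pis, mus, sigs = naive_mstep(X, W, U, memb, (k, m))
        np.testing.assert_allclose(new.pis, pis, atol=1e-12)
        np.testing.assert_allclose(new.mus, mus, atol=1e-12)
        np.testing.assert_allclose(new.sigmas, sigs, atol=1e-10)

    def test_one_hot_weights_recover_class_statistics(self, rng):
        X = np.vstack([rng.normal(0, 1, size=(30, 2)),
                       rng.normal(5, 1, size=(50, 2))])
        W = np.zeros((80, 4))
        W[:30, 0] = 1.0
        W[30:, 3] = 1.0
        memb = W > 0
        memb[:, 1] = memb[:, 2] = True  # irrelevant for zero-mass clusters
        model = random_model(rng, k=4, m=2)
        new = mstep_embc(X, W, np.ones((80, 2)), memb, model,
                         np.full(2, 1e-9))
        np.testing.assert_allclose(new.mus[0], X[:30].mean(0), atol=1e-12)
        np.testing.assert_allclose(new.mus[3], X[30:].mean(0), atol=1e-12)
        # zero-mass clusters absorbed, survivors renormalized
        assert not new.active[1] and not new.active[2]
        np.testing.assert_allclose(new.pis[[0, 3]], [30 / 80, 50 / 80])

    def test_mean_clipped_into_region(self, rng):
        X = rng.uniform(size=(50, 2))
        W = np.full((50, 4), 0.25)
        memb = np.ones((50, 4), bool)
        model = random_model(rng, k=4, m=2)
        model.codes = ["LL", "LH", "HL", "HH"]
        delims = DelimiterSet(2, {".L": 0.1, ".H": 0.1, "L.": 0.1, "H.": 0.1})
        new = mstep_embc(X, W, np.ones((50, 2)), memb, model,
                         np.full(2, 1e-9), delimiters=delims)
        lo, hi = delims.bounds("LL")
        assert np.all(new.mus[0] <= hi + 1e-12)
        lo, hi = delims.bounds("HH")
        assert np.all(new.mus[3] >= lo - 1e-12)


class TestLoglik:
    def test_single_component_closed_form(self):
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        model = MixtureModel(mus=np.array([[1.0, -1.0]]),
                             sigmas=sigma[None], pis=np.array([1.0]),
                             active=np.array([True]), codes=["L"])
        expected = -(2 / 2) * np.log(2 * np.pi) - 0.5 * np.log(
            np.linalg.det(sigma))
        assert loglik(model.mus, model) == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_summation(self, rng):
        model = random_model(rng, k=4, m=2)
        X = rng.normal(size=(25, 2))
        naive = np.mean([
            np.log(sum(model.pis[j] * multivariate_normal.pdf(
                x, model.mus[j], model.sigmas[j]) for j in range(4)))
            for x in X])
        assert loglik(X, model) == pytest.approx(naive, abs=1e-12)

    def test_mean_per_point_invariant_to_duplication(self, rng):
        model = random_model(rng, k=2, m=2)
        X = rng.normal(size=(10, 2))
        assert loglik(np.vstack([X, X]), model) == pytest.approx(
            loglik(X, model), abs=1e-12)


class TestFit:
    def test_recovers_separated_blobs(self, blobs):
        X, ref = blobs
        res = fit(FeatureMatrix.from_array(X), EMbCConfig(sigma_min=[1e-3, 1e-3]))
        assert res.n_active == 4
        assert embc.f_score(ref, res.labels) > 0.99
        centers = {"LL": (0.2, 0.2), "LH": (0.2, 0.8),
                   "HL": (0.8, 0.2), "HH": (0.8, 0.8)}
        for j, code in enumerate(res.codes):
            se = 0.03 / np.sqrt(100)
            np.testing.assert_allclose(res.model.mus[j], centers[code],
                                       atol=4 * se)

    def test_single_gaussian_input_absorbs_clusters(self, rng, caplog):
        X = rng.normal(size=(300, 2))
        res = fit(FeatureMatrix.from_array(X), EMbCConfig(sigma_min=[1e-6] * 2))
        assert res.n_active <= 4
        assert np.all([lab in res.codes for lab in res.labels])

    def test_deterministic(self, synth400):
        r1 = fit(synth400.features)
        r2 = fit(synth400.features)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.model.mus, r2.model.mus)
        assert r1.loglik_trace == r2.loglik_trace

    def test_posteriors_and_floors(self, synth400):
        res = fit(synth400.features)
        Wv = res.W[synth400.features.valid]
        np.testing.assert_allclose(
            Wv[:, res.model.active].sum(1), 1.0, atol=1e-12)
        floor = np.array([0.01, 0.087])  # named velocity/turn defaults
        for j in np.flatnonzero(res.model.active):
            assert np.all(np.diag(res.model.sigmas[j]) >= floor**2 - 1e-15)

    def test_means_inside_their_regions(self, synth400):
        res = fit(synth400.features)
        for j, code in enumerate(res.codes):
            if not res.model.active[j]:
                continue
            lo, hi = res.delimiters.bounds(code)
            assert np.all(res.model.mus[j] >= lo - 1e-9)
            assert np.all(res.model.mus[j] <= hi + 1e-9)

    def test_best_loglik_non_decreasing(self, synth400):
        res = fit(synth400.features)
        best = np.maximum.accumulate(res.loglik_trace)
        assert np.all(np.diff(best) >= -1e-12)

    def test_near_ceiling_recovery_on_default_regime(self, synth400):
        # gamma=0.05 caps per-point accuracy near 0.885; the fit should
        # approach that ceiling
        res = fit(synth400.features)
        assert embc.f_score(synth400.state_labels, res.labels,
                            labels=synth400.codes) > 0.75

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit(FeatureMatrix.from_array(np.ones((3, 2)) * np.arange(3)[:, None]))

    def test_identical_points_single_cluster(self):
        res = fit(FeatureMatrix.from_array(np.full((10, 2), 1.0)))
        assert res.n_active == 1
        assert set(res.labels) == {"LL"}

    def test_invalid_rows_backfilled(self, rng):
        X = rng.uniform(size=(50, 2))
        valid = np.ones(50, bool)
        valid[[0, 10, 49]] = False
        fm = FeatureMatrix.from_array(X)
        fm.valid = valid
        res = fit(fm, EMbCConfig(sigma_min=[1e-6] * 2))
        assert res.labels[10] == res.labels[9]
        assert res.labels[49] == res.labels[48]
        assert res.labels[0] == res.labels[1]  # leading row takes first valid


class TestFitPooled:
    def test_duplicate_sets_get_identical_slices(self, synth400):
        res, slices = fit_pooled([synth400.features, synth400.features])
        np.testing.assert_array_equal(slices[0], slices[1])
        assert len(slices[0]) == synth400.features.n

    def test_stack_order_only_matters_through_content(self, synth400, rng):
        other = embc.simulate(embc.SyntheticConfig(n=200, gamma=0.05, seed=9))
        r1, s1 = fit_pooled([synth400.features, other.features])
        r2, s2 = fit_pooled([other.features, synth400.features])
        np.testing.assert_allclose(r1.model.mus, r2.model.mus, atol=1e-8)
        np.testing.assert_array_equal(s1[0], s2[1])

    def test_union_of_individual_labels_is_population_set(self, synth400):
        other = embc.simulate(embc.SyntheticConfig(n=300, gamma=0.05, seed=3))
        res, slices = fit_pooled([synth400.features, other.features])
        union = set().union(*[set(s.tolist()) for s in slices])
        assert union == set(res.labels.tolist())

    def test_rejects_mismatched_variables(self, synth400):
        bad = FeatureMatrix.from_array(np.ones((10, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="mismatched"):
            fit_pooled([synth400.features, bad])
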