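"""AAHC clustering, GEV, consensus templates and canonical ordering."""
from itertools import combinations, permutations

import numpy as np
import pytest

import msdyn as m
from msdyn.clustering import _dominant_eigenvector, _normalize_maps
from msdyn.datatypes import InvalidInputError, UndefinedResultError


class TestSpatialCorrelation:
    def test_identity_and_polarity(self):
        u = np.array([1.0, -2.0, 1.0])
        assert m.spatial_correlation(u, u) == pytest.approx(1.0)
        assert m.spatial_correlation(u, -u) == pytest.approx(1.0)

    def test_hand_value(self):
        assert m.spatial_correlation([1, -1, 0], [1, 0, -1]) == pytest.approx(0.5)

    def test_flat_map_rejected(self):
        with pytest.raises(UndefinedResultError):
            m.spatial_correlation([1.0, 1.0, 1.0], [1.0, -1.0, 0.0])


class TestGEV:
    def test_perfect_fit_is_one(self, planted_templates):
        maps = np.repeat(planted_templates.maps, 5, axis=0) * 3.7
        maps[::2] *= -1  # polarity must not matter
        assignment = np.repeat(np.arange(4), 5)
        g = np.ones(20)
        assert m.gev(maps, g, planted_templates, assignment) == pytest.approx(1.0)

    def test_orthogonal_maps_zero(self):
        ts = m.make_templates(10, 2, seed=0)
        extra = m.make_templates(10, 4, seed=0)  # first 2 rows == ts
        ortho = extra.maps[2:]  # orthogonal to both templates
        val = m.gev(ortho, np.ones(2), ts, np.zeros(2, dtype=int))
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_equal_gfp(self):
        # maps with corr {1, 0.5, 0} to the template, equal GFP
        # -> (1 + 0.25 + 0)/3
        t = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
        ts = m.TemplateSet(t[None, :])
        u = t.copy()
        v = np.array([1.0, 0.0, -1.0, 0.0])   # corr 0.5 with t
        w = np.array([1.0, 1.0, -1.0, -1.0])  # corr 0 with t
        assert m.spatial_correlation(v, t) == pytest.approx(0.5)
        assert m.spatial_correlation(w, t) == pytest.approx(0.0, abs=1e-12)
        val = m.gev(np.vstack([u, v, w]), np.ones(3), ts,
                    np.zeros(3, dtype=int))
        assert val == pytest.approx((1 + 0.25 + 0) / 3)


def _exhaustive_two_partition_gev(maps, g):
    """Best GEV over all 2-block set partitions (oracle for small inputs)."""
    n = maps.shape[0]
    normed, _ = _normalize_maps(maps)
    best = -1.0
    idx = list(range(n))
    for r in range(1, n // 2 + 1):
        for block in combinations(idx, r):
            block = set(block)
            assignment = np.array([0 if i in block else 1 for i in idx])
            tmpl = np.empty((2, maps.shape[1]))
            for c in (0, 1):
                mem = normed[assignment == c]
                tmpl[c] = _dominant_eigenvector(mem.T @ mem)
            ts = m.TemplateSet(tmpl)
            best = max(best, m.gev(maps, g, ts, assignment))
    return best


class TestAAHC:
    def test_noiseless_recovery_corr_one_gev_one(self, planted_templates):
        maps = np.repeat(planted_templates.maps, 25, axis=0)
        sol = m.aahc(maps, np.ones(100), k=4)
        assert sol.gev == pytest.approx(1.0)
        aligned, _ = m.align_templates(sol.templates, planted_templates)
        for i in range(4):
            assert m.spatial_correlation(
                aligned.maps[i], planted_templates.maps[i]) == pytest.approx(1.0)

    def test_returns_exactly_k_templates(self, short_subject):
        rec, _ = short_subject
        filtered = m.bandpass(m.average_reference(rec))
        g = m.smooth_gfp(m.compute_gfp(filtered))
        peaks = m.subsample_peaks(m.find_gfp_peaks(g), 500, seed=0)
        from msdyn.gfp import peak_maps
        maps, gfp_at = peak_maps(filtered, peaks)
        sol = m.aahc(maps, gfp_at, k=4)
        assert sol.templates.k == 4
        assert np.all(sol.assignment >= 0) and np.all(sol.assignment < 4)

    def test_matches_exhaustive_two_partition(self):
        # 8 maps = 2 planted patterns + small perturbation
        rng = np.random.default_rng(3)
        base = m.make_templates(12, 2, seed=3).maps
        maps = np.vstack([base[i % 2] + 0.05 * rng.standard_normal(12)
                          for i in range(8)])
        maps -= maps.mean(axis=1, keepdims=True)
        g = np.abs(rng.normal(1.0, 0.1, size=8))
        sol = m.aahc(maps, g, k=2)
        best = _exhaustive_two_partition_gev(maps, g)
        assert sol.gev >= best - 1e-9

    def test_polarity_invariance(self, planted_templates):
        rng = np.random.default_rng(5)
        maps = np.repeat(planted_templates.maps, 10, axis=0)
        maps = maps + 0.02 * rng.standard_normal(maps.shape)
        g = np.ones(40)
        sol_a = m.aahc(maps, g, k=4)
        flip = rng.random(40) < 0.5
        flipped = maps.copy()
        flipped[flip] *= -1
        sol_b = m.aahc(flipped, g, k=4)
        assert sol_a.gev == pytest.approx(sol_b.gev, abs=1e-9)
        for i in range(4):
            assert m.spatial_correlation(sol_a.templates.maps[i],
                                         sol_b.templates.maps[i]) > 1 - 1e-9

    def test_gev_monotone_in_k(self, short_subject):
        rec, _ = short_subject
        filtered = m.bandpass(m.average_reference(rec))
        g = m.smooth_gfp(m.compute_gfp(filtered))
        peaks = m.subsample_peaks(m.find_gfp_peaks(g), 300, seed=1)
        from msdyn.gfp import peak_maps
        maps, gfp_at = peak_maps(filtered, peaks)
        gevs = [m.aahc(maps, gfp_at, k=k).gev for k in (2, 3, 4, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(gevs[:-1], gevs[1:]))

    def test_too_few_maps_rejected(self):
        with pytest.raises(InvalidInputError):
            m.aahc(np.eye(4), np.ones(4), k=4)


class TestGroupTemplates:
    def test_identity_for_single_subject(self, planted_templates):
        out = m.group_templates([planted_templates])
        np.testing.assert_allclose(out.maps, planted_templates.maps)

    def test_consensus_of_shuffled_signed_copies(self, planted_templates):
        rng = np.random.default_rng(0)
        subjects = []
        for _ in range(6):
            perm = rng.permutation(4)
            signs = rng.choice([-1.0, 1.0], size=4)
            subjects.append(m.TemplateSet(planted_templates.maps[perm]
                                          * signs[:, None]))
        out = m.group_templates(subjects)
        aligned, _ = m.align_templates(out, planted_templates)
        for i in range(4):
            assert m.spatial_correlation(
                aligned.maps[i], planted_templates.maps[i]) == pytest.approx(1.0)

    def test_averaging_beats_individuals(self, planted_templates):
        rng = np.random.default_rng(1)
        total_group, total_indiv = 0.0, 0.0
        for rep in range(20):
            subjects = []
            indiv_corr = []
            for _ in range(10):
                noisy = (planted_templates.maps
                         + 0.12 * rng.standard_normal((4, 31)))
                ts = m.TemplateSet(noisy)
                subjects.append(ts)
                aligned, _ = m.align_templates(ts, planted_templates)
                indiv_corr.append(np.mean([m.spatial_correlation(
                    aligned.maps[i], planted_templates.maps[i])
                    for i in range(4)]))
            out = m.group_templates(subjects)
            aligned, _ = m.align_templates(out, planted_templates)
            total_group += np.mean([m.spatial_correlation(
                aligned.maps[i], planted_templates.maps[i]) for i in range(4)])
            total_indiv += np.mean(indiv_corr)
        assert total_group > total_indiv


class TestCanonicalOrdering:
    def test_already_canonical_identity(self):
        canon = m.load_canonical_templates()
        out = m.order_canonical(canon, canon)
        np.testing.assert_allclose(out.maps, canon.maps)

    def test_reversed_rows_recovered(self):
        canon = m.load_canonical_templates()
        reversed_ts = m.TemplateSet(canon.maps[::-1].copy())
        out = m.order_canonical(reversed_ts, canon)
        np.testing.assert_allclose(np.abs(np.sum(out.maps * canon.maps,
                                                 axis=1)), 1.0, atol=1e-9)

    def test_chosen_permutation_is_optimal(self):
        canon = m.load_canonical_templates()
        ts = m.make_templates(31, 4, seed=9)
        _, perm = m.align_templates(ts, canon)
        corr = np.abs(ts.maps @ canon.maps.T)
        best = max(sum(corr[list(p), range(4)]) for p in
                   permutations(range(4)))
        assert sum(corr[list(perm), range(4)]) == pytest.approx(best)
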