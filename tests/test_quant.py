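"""Curve fitting, goodness maps, bootstrap, mixtures, r_max inversion."""

import numpy as np
import pytest

import ldquant as lq
from ldquant.quant import eq1_log2r, eq2_log2r


def curve_samples(y_fn, n=300, seed=0, modality="1p", noise=0.0, object_id="o",
                  weight=None):
    rng = np.random.default_rng(seed)
    th = rng.uniform(0, 180, n)
    y = y_fn(th) + (rng.normal(0, noise, n) if noise else 0.0)
    w = np.ones(n) if weight is None else weight
    return lq.ThetaSamples(theta_deg=th, log2r=y, weight=w, modality=modality,
                           object_id=object_id)


class TestFit1P:
    def test_exact_recovery_from_generating_curve(self):
        s = curve_samples(lambda t: eq1_log2r(t, 0.0, 0.5, 0.0, 0.0))
        f = lq.fit_1p(s)
        assert f.a1p == pytest.approx(0.0, abs=1e-6)
        assert f.b1p == pytest.approx(0.5, abs=1e-6)
        assert f.phi1_deg % 180 == pytest.approx(0.0, abs=1e-3) or \
            f.phi1_deg % 180 == pytest.approx(180.0, abs=1e-3)
        assert f.log2_rmax == pytest.approx(np.log2(3), abs=1e-6)
        assert f.r2 == pytest.approx(1.0, abs=1e-9)

    def test_flat_data_flagged(self):
        s = curve_samples(lambda t: np.zeros_like(t))
        f = lq.fit_1p(s)
        assert f.b1p == pytest.approx(0.0, abs=1e-6)
        assert f.log2_rmax == pytest.approx(0.0, abs=1e-6)
        assert f.zero_variance and np.isnan(f.r2)

    def test_noise_recovery_calibration(self):
        """b1p recovered within ±0.03 at 95% over repeated noisy draws."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            s = curve_samples(lambda t: eq1_log2r(t, 0.0, 0.5, 10.0, 10.0),
                              n=500, seed=seed, noise=0.05)
            f = lq.fit_1p(s)
            hits += abs(f.b1p - 0.5) <= 0.03
        assert hits >= int(0.85 * n_rep)

    def test_insufficient_span_errors(self):
        th = np.linspace(0, 40, 20)
        s = lq.ThetaSamples(theta_deg=th, log2r=np.zeros(20), weight=np.ones(20))
        with pytest.raises(ValueError, match="span"):
            lq.fit_1p(s)

    def test_phase_split_bounded(self):
        s = curve_samples(lambda t: eq1_log2r(t, 0.1, 0.4, 8.0, -8.0), n=400, seed=3)
        f = lq.fit_1p(s)
        d = abs(f.phi1_deg - f.phi2_deg) % 180
        assert min(d, 180 - d) <= 20.0 + 1e-6


class TestFit2P:
    def test_forward_inverse_roundtrip(self, coarse_table):
        dist = lq.TiltDistribution.single(90.0, 10.0)
        s = curve_samples(lambda t: lq.predict_log2r(dist, t, "2p"), modality="2p")
        fr = lq.fit_2p(s, restricted=True, table=coarse_table)
        assert (fr.alpha0, fr.sigma) == (90.0, 10.0)
        fu = lq.fit_2p(s, restricted=False)
        assert fu.b2p == pytest.approx(fr.b2p, abs=1e-4)
        assert fu.c2p == pytest.approx(fr.c2p, abs=1e-4)

    def test_isotropic_data_gives_zero_params(self):
        s = curve_samples(lambda t: np.zeros_like(t), modality="2p", noise=0.001,
                          seed=1)
        f = lq.fit_2p(s)
        assert abs(f.b2p) < 0.01 and abs(f.c2p) < 0.01

    def test_adversarial_data_stays_finite(self):
        rng = np.random.default_rng(9)
        th = np.linspace(0, 179, 200)
        y = np.where(np.abs(((th + 45) % 180) - 90) < 20, 8.0, -8.0)
        s = lq.ThetaSamples(theta_deg=th, log2r=y, weight=np.ones(200), modality="2p")
        f = lq.fit_2p(s)
        assert np.all(np.isfinite(f.curve(np.arange(0.0, 180.0, 0.5))))
        assert f.r2 < 0.9

    def test_restricted_never_beats_unrestricted(self, coarse_table):
        dist = lq.TiltDistribution.single(40.0, 20.0)
        s = curve_samples(lambda t: lq.predict_log2r(dist, t, "2p"), modality="2p",
                          noise=0.1, seed=4)
        fr = lq.fit_2p(s, restricted=True, table=coarse_table)
        fu = lq.fit_2p(s, restricted=False, table=coarse_table)
        assert fr.r2 <= fu.r2 + 1e-9


class TestGoodnessMap:
    def test_noiseless_2p_argmax_is_truth(self, coarse_table):
        dist = lq.TiltDistribution.single(40.0, 20.0)
        s = curve_samples(lambda t: lq.predict_log2r(dist, t, "2p"), modality="2p")
        m = lq.goodness_map(s, coarse_table)
        assert (m.best_alpha0, m.best_sigma) == (40.0, 20.0)

    def test_noiseless_1p_level_set_degeneracy(self, fine_table):
        """1P data pin one shape parameter: equal-b1p cells score identically."""
        dist = lq.TiltDistribution.single(40.0, 20.0)
        s = curve_samples(lambda t: lq.predict_log2r(dist, t, "1p"), modality="1p")
        m = lq.goodness_map(s, fine_table)
        best = np.nanmax(m.r2)
        # the 1-deg grid samples the level set only approximately, so the
        # "identical score" band is grid-resolution limited
        near = m.r2 >= best - 1e-3
        assert near.sum() > 10
        b_target = fine_table.b1p[m.best_idx]
        b_near = fine_table.b1p[near]
        assert np.max(np.abs(b_near - b_target)) < 2e-2
        # and the degenerate cells span a wide range of alpha0 values
        alphas = fine_table.alpha0[np.nonzero(near)[0]]
        assert alphas.max() - alphas.min() > 20.0

    def test_zero_variance_flagged_rmsd_still_valid(self, coarse_table):
        th = np.linspace(0, 179, 100)
        s = lq.ThetaSamples(theta_deg=th, log2r=np.zeros(100), weight=np.ones(100))
        m = lq.goodness_map(s, coarse_table)
        assert not m.r2_defined
        assert np.all(np.isfinite(m.rmsd))

    def test_best_cell_attains_extrema(self, coarse_table):
        dist = lq.TiltDistribution.single(25.0, 25.0)
        sets = [curve_samples(lambda t: lq.predict_log2r(dist, t, m_), modality=m_,
                              noise=0.05, seed=i)
                for i, m_ in enumerate(("1p", "2p"))]
        m = lq.goodness_map(sets, coarse_table)
        assert m.r2[m.best_idx] == pytest.approx(np.nanmax(m.r2))


class TestPoolAndFit:
    def test_duplicated_object_identical_fit(self, coarse_table):
        dist = lq.TiltDistribution.single(30.0, 15.0)
        s = curve_samples(lambda t: lq.predict_log2r(dist, t, "1p"), noise=0.05,
                          seed=5)
        single = lq.pool_and_fit([s], table=coarse_table)
        doubled = lq.pool_and_fit([s, s], table=coarse_table)
        assert single.fit1p.b1p == pytest.approx(doubled.fit1p.b1p, abs=1e-6)
        assert single.combined_alpha0 == doubled.combined_alpha0

    def test_combined_narrows_1p_degeneracy(self, fine_table):
        dist = lq.TiltDistribution.single(25.0, 25.0)
        s1 = curve_samples(lambda t: lq.predict_log2r(dist, t, "1p"), modality="1p",
                           noise=0.03, seed=6, n=500)
        s2 = curve_samples(lambda t: lq.predict_log2r(dist, t, "2p"), modality="2p",
                           noise=0.03, seed=7, n=500)
        pooled = lq.pool_and_fit([s1, s2], table=fine_table)
        assert abs(pooled.combined_alpha0 - 25.0) <= 2.0
        assert abs(pooled.combined_sigma - 25.0) <= 2.0
        n_1p = pooled.map1p.near_optimal_cells()
        n_comb = pooled.map_combined.near_optimal_cells()
        assert n_1p > 10
        assert n_comb < n_1p
        assert pooled.predicted_1p_from_2p is not None

    def test_conflicting_modalities_lower_combined_r2(self, coarse_table):
        d1 = lq.TiltDistribution.single(10.0, 10.0)
        d2 = lq.TiltDistribution.single(80.0, 10.0)
        s1 = curve_samples(lambda t: lq.predict_log2r(d1, t, "1p"), modality="1p",
                           noise=0.02, seed=8)
        s2 = curve_samples(lambda t: lq.predict_log2r(d2, t, "2p"), modality="2p",
                           noise=0.02, seed=9)
        pooled = lq.pool_and_fit([s1, s2], table=coarse_table)
        r2_comb = np.nanmax(pooled.map_combined.r2)
        assert r2_comb < np.nanmax(pooled.map1p.r2)
        assert r2_comb < np.nanmax(pooled.map2p.r2)

    def test_missing_modality_slot_absent(self, coarse_table):
        dist = lq.TiltDistribution.single(30.0, 15.0)
        s = curve_samples(lambda t: lq.predict_log2r(dist, t, "1p"), noise=0.05)
        pooled = lq.pool_and_fit([s], table=coarse_table)
        assert pooled.fit2p is None and pooled.map2p is None

    def test_combined_r2_never_above_both(self, coarse_table):
        """Tied-distribution fit cannot beat both single-modality fits."""
        dist = lq.TiltDistribution.single(60.0, 20.0)
        s1 = curve_samples(lambda t: lq.predict_log2r(dist, t, "1p"), modality="1p",
                           noise=0.08, seed=10)
        s2 = curve_samples(lambda t: lq.predict_log2r(dist, t, "2p"), modality="2p",
                           noise=0.08, seed=11)
        pooled = lq.pool_and_fit([s1, s2], table=coarse_table)
        r2c = np.nanmax(pooled.map_combined.r2)
        assert r2c <= max(np.nanmax(pooled.map1p.r2), np.nanmax(pooled.map2p.r2)) + 1e-9


class TestBootstrap:
    def make_sets(self, n_obj=20, noise=0.05, seed0=0):
        dist = lq.TiltDistribution.single(90.0, 10.0)
        sets = []
        for o in range(n_obj):
            for k, mod in enumerate(("1p", "2p")):
                sets.append(lq.sample_theta_curve(
                    dist, mod, n=150, noise_sd=noise, seed=seed0 + 2 * o + k,
                    object_id=f"obj{o}"))
        return sets

    def test_truth_inside_mask(self, coarse_table):
        sets = self.make_sets()
        mask, counts, gmap = lq.bootstrap_confidence(sets, coarse_table,
                                                     n_boot=200, seed=1)
        i = int(np.argwhere(gmap.alpha0 == 90)[0, 0])
        j = int(np.argwhere(gmap.sigma == 10)[0, 0])
        assert mask[i, j]
        assert counts.sum() == 200

    def test_identical_objects_collapse_mask(self, coarse_table):
        dist = lq.TiltDistribution.single(90.0, 10.0)
        one = lq.sample_theta_curve(dist, "1p", n=200, noise_sd=0.02, seed=0,
                                    object_id="a")
        two = lq.ThetaSamples(theta_deg=one.theta_deg, log2r=one.log2r,
                              weight=one.weight, modality="1p", object_id="b")
        mask, _, _ = lq.bootstrap_confidence([one, two], coarse_table,
                                             n_boot=100, seed=2)
        assert mask.sum() <= 2

    def test_two_seeds_stable(self, coarse_table):
        sets = self.make_sets(noise=0.1, seed0=50)
        m1, _, _ = lq.bootstrap_confidence(sets, coarse_table, n_boot=200, seed=3)
        m2, _, _ = lq.bootstrap_confidence(sets, coarse_table, n_boot=200, seed=4)
        overlap = (m1 & m2).sum() / max((m1 | m2).sum(), 1)
        assert overlap >= 0.5

    def test_mask_contains_best_cell(self, coarse_table):
        sets = self.make_sets(n_obj=5, noise=0.2, seed0=80)
        mask, _, gmap = lq.bootstrap_confidence(sets, coarse_table, n_boot=100,
                                                seed=5)
        assert mask[gmap.best_idx]

    def test_single_object_rejected(self, coarse_table):
        sets = self.make_sets(n_obj=1)
        with pytest.raises(ValueError, match="objects"):
            lq.bootstrap_confidence(sets, coarse_table)

    def test_mask_shrinks_with_more_objects(self, coarse_table):
        areas = {n: [] for n in (10, 40)}
        for rep in range(5):
            for n in areas:
                sets = self.make_sets(n_obj=n, noise=0.3, seed0=1000 * rep)
                mask, _, _ = lq.bootstrap_confidence(sets, coarse_table,
                                                     n_boot=100, seed=rep)
                areas[n].append(mask.sum())
        assert np.mean(areas[40]) <= np.mean(areas[10])


class TestMixtureSearch:
    def test_single_gaussian_recovered_degenerately(self):
        targets = lq.shape_params(lq.TiltDistribution.single(90.0, 10.0))
        cands = lq.mixture_search(targets)
        top = cands[0]
        assert top.residual < 1e-3
        same_comp = (top.alpha0_a, top.sigma_a) == (top.alpha0_b, top.sigma_b)
        assert top.fraction_a > 0.85 or same_comp

    def test_isotropic_targets_prefer_wide_distributions(self):
        targets = lq.DichroicShapeParams(0.0, 0.0, 0.0)
        cands = lq.mixture_search(targets)
        for c in cands[:5]:
            assert abs(c.b1p) < 0.01 and abs(c.b2p) < 0.01 and abs(c.c2p) < 0.01
        # wide-σ components dominate the isotropy-approaching candidates
        assert max(cands[0].sigma_a, cands[0].sigma_b) >= 40.0
        assert cands[0].entropy_bits > 6.0

    def test_true_mixture_contained_in_candidates(self):
        mix = lq.TiltDistribution.mixture((90.0, 10.0), (20.0, 10.0), 0.5)
        targets = lq.shape_params(mix)
        cands = lq.mixture_search(targets, top_k=20)
        found = False
        for c in cands:
            pairs = sorted([(c.alpha0_a, c.sigma_a), (c.alpha0_b, c.sigma_b)])
            da = abs(pairs[1][0] - 90) <= 10 and abs(pairs[1][1] - 10) <= 10
            db = abs(pairs[0][0] - 20) <= 10 and abs(pairs[0][1] - 10) <= 10
            if da and db and abs(c.fraction_a - 0.5) <= 0.2:
                found = True
        assert found

    def test_nonfinite_targets_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            lq.mixture_search(lq.DichroicShapeParams(0.0, np.nan, 0.0))


class TestRmaxToOrientation:
    def test_zero_1p_value_is_magic_angle_level_set(self, coarse_table):
        m = lq.rmax_to_orientation(log2_rmax_1p=0.0, table=coarse_table,
                                   tolerance=0.05)
        assert len(m.cells) > 0
        assert np.all(np.abs(coarse_table.b1p[m.mask]) < 0.02)
        # the sigma->0 end of the level set sits at the magic angle
        small_sigma = [a for a, s in m.cells if s == 5.0]
        assert any(abs(a - 55.0) <= 5.0 for a in small_sigma)

    def test_combining_modalities_narrows_set(self, coarse_table):
        dist = lq.TiltDistribution.single(25.0, 25.0)
        v1 = lq.predict_log2r(dist, [0.0], "1p")[0]
        from ldquant.quant import _signed_extremum

        v2 = _signed_extremum(lambda t: lq.predict_log2r(dist, t, "2p"))
        only_1p = lq.rmax_to_orientation(log2_rmax_1p=v1, table=coarse_table)
        both = lq.rmax_to_orientation(log2_rmax_1p=v1, log2_rmax_2p=v2,
                                      table=coarse_table)
        assert (25.0, 25.0) in both.cells
        assert len(both.cells) < len(only_1p.cells)

    def test_infeasible_value_reports_range(self, coarse_table):
        m = lq.rmax_to_orientation(log2_rmax_1p=10.0, table=coarse_table)
        assert m.cells == []
        lo, hi = m.achievable["1p"]
        assert lo < 0 < hi < 10


class TestRoundTripRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_noiseless_combined_recovery_exact(self, coarse_table, seed):
        rng = np.random.default_rng(seed)
        i = rng.integers(1, coarse_table.alpha0.size)
        j = rng.integers(0, coarse_table.sigma.size - 4)
        a0, sg = float(coarse_table.alpha0[i]), float(coarse_table.sigma[j])
        dist = lq.TiltDistribution.single(a0, sg)
        sets = [curve_samples(lambda t: lq.predict_log2r(dist, t, m_), modality=m_,
                              seed=seed + 100, n=400)
                for m_ in ("1p", "2p")]
        m = lq.goodness_map(sets, coarse_table)
        assert (m.best_alpha0, m.best_sigma) == (a0, sg)
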