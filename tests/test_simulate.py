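"""Simulator regimes: limiting behaviors, moments, determinism, containment."""

import numpy as np
import pytest
from scipy import stats as sps

import rafttrack as rt
from conftest import make_track


def steps_sq(tracks):
    out = []
    for t in tracks:
        d = np.diff(t.positions, axis=0)
        out.append((d * d).sum(axis=1))
    return np.concatenate(out)


def ensemble_V(tracks):
    v = [s.V for t in tracks for s in rt.segment_stats(t)]
    return np.mean(v), np.std(v) / np.sqrt(len(tracks)), len(v)


class TestFree:
    def test_zero_diffusion_freezes_particle(self):
        p = rt.MembraneModelParams(regime="free", D_free=1e-300, sigma_loc=0.0,
                                   n_frames=50, seed=0)
        (t,) = rt.simulate_free(p, 1)
        assert np.allclose(t.positions, t.positions[0], atol=1e-140)

    def test_step_moment_matches_4Dtau(self, tau):
        D = 0.12
        p = rt.MembraneModelParams(regime="free", D_free=D, sigma_loc=0.0,
                                   n_frames=400, seed=1)
        sq = steps_sq(rt.simulate_free(p, 500))
        se = sq.std() / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * D * tau) < 3 * se

    def test_increment_normality_and_axis_variance(self, tau):
        D = 1.0
        p = rt.MembraneModelParams(regime="free", D_free=D, sigma_loc=0.0,
                                   n_frames=100, seed=2)
        tracks = rt.simulate_free(p, 1000)
        dx = np.concatenate([np.diff(t.x) for t in tracks])
        assert dx.var() == pytest.approx(2 * D * tau, rel=0.02)
        # normality on a subsample (the test is extremely powerful at full n)
        assert sps.normaltest(dx[:5000]).pvalue > 1e-3

    def test_determinism_bit_identical(self):
        p = rt.MembraneModelParams(regime="free", D_free=1.0, seed=42)
        a = rt.simulate(p, 5)
        b = rt.simulate(p, 5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rt.MembraneModelParams(regime="free", D_free=0.0)
        p = rt.MembraneModelParams(regime="free")
        with pytest.raises(ValueError):
            rt.simulate_free(p, 0)

    def test_isotropy_of_mean_R2_under_rotation(self):
        p = rt.MembraneModelParams(regime="free", D_free=0.5, sigma_loc=0.0,
                                   n_frames=100, seed=9)
        tracks = rt.simulate_free(p, 50)
        base = np.mean([rt.msd_series(t).R2.mean() for t in tracks])
        c, s = np.cos(1.1), np.sin(1.1)
        R = np.array([[c, -s], [s, c]])
        rot = [make_track(t.positions @ R.T) for t in tracks]
        rotated = np.mean([rt.msd_series(t).R2.mean() for t in rot])
        assert rotated == pytest.approx(base, rel=1e-12)


class TestLocalizationNoise:
    def test_zero_sigma_is_identity(self):
        p = rt.MembraneModelParams(regime="free", D_free=0.1, seed=3)
        tracks = rt.simulate_free(p, 3)
        noisy = rt.add_localization_noise(tracks, 0.0)
        for a, b in zip(tracks, noisy):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_stationary_emitter_step_energy(self):
        sigma = 0.04
        t = make_track(np.zeros((4000, 2)))
        (noisy,) = rt.add_localization_noise([t], sigma, seed=5)
        sq = (np.diff(noisy.positions, axis=0) ** 2).sum(axis=1)
        se = sq.std() / np.sqrt(len(sq))
        assert abs(sq.mean() - 2 * sigma**2) < 3 * se

    def test_noise_floor_of_mean_R2(self):
        # stationary emitter at the apparatus accuracy: mean R2 in
        # [0.001, 0.004] um^2 (order-of-magnitude check)
        t = make_track(np.zeros((2000, 2)))
        (noisy,) = rt.add_localization_noise([t], 0.04, seed=8)
        m = rt.msd_series(noisy).R2.mean()
        assert 0.001 < m < 0.004

    def test_noise_seed_reproducible_and_input_unmodified(self):
        t = make_track(np.zeros((50, 2)))
        a = rt.add_localization_noise([t], 0.04, seed=1)[0]
        b = rt.add_localization_noise([t], 0.04, seed=1)[0]
        np.testing.assert_array_equal(a.positions, b.positions)
        assert np.all(t.positions == 0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            rt.add_localization_noise([], -0.1)


class TestCorral:
    def test_zero_barrier_matches_free(self):
        p = rt.MembraneModelParams(regime="corral", D_free=0.1,
                                   barrier_height=0.0, sigma_loc=0.0,
                                   n_frames=100, seed=4)
        sq_c = steps_sq(rt.simulate_corral(p, 150))
        sq_f = steps_sq(rt.simulate_free(p.replace(regime="free"), 150))
        assert sps.ks_2samp(sq_c, sq_f).pvalue > 0.01

    def test_containment_at_high_barrier(self):
        # 10 kT walls hold a default-mobility molecule within a few
        # compartments over a 100 s track
        p = rt.MembraneModelParams(regime="corral", corral_radius=0.1,
                                   barrier_height=10.0, sigma_loc=0.0,
                                   n_frames=4000, seed=5)
        tracks = rt.simulate_corral(p, 30)
        d = np.concatenate([np.hypot(t.x, t.y) for t in tracks])
        assert np.percentile(d, 99) < 3 * p.corral_radius

    def test_excursion_suppressed_monotonically_in_barrier_height(self):
        p99 = []
        for H in (0.0, 3.0, 8.0):
            p = rt.MembraneModelParams(regime="corral", barrier_height=H,
                                       D_free=0.1, sigma_loc=0.0,
                                       n_frames=300, seed=6)
            tracks = rt.simulate_corral(p, 60)
            d = np.concatenate([np.hypot(t.x, t.y) for t in tracks])
            p99.append(np.percentile(d, 99))
        assert p99[0] > p99[1] > p99[2]

    def test_corral_V_exceeds_matched_free_V(self):
        D = 0.1
        pc = rt.MembraneModelParams(regime="corral", D_free=D, sigma_loc=0.0,
                                    n_frames=400, seed=7)
        pf = pc.replace(regime="free")
        vc, se_c, _ = ensemble_V(rt.simulate_corral(pc, 300))
        vf, se_f, _ = ensemble_V(rt.simulate_free(pf, 300))
        z = (vc - vf) / np.hypot(se_c, se_f)
        assert z > 2.33  # one-sided 1%

    def test_substep_convergence_of_moments(self):
        # halving the substep count must not move the ensemble moments
        # beyond Monte-Carlo error
        base = dict(regime="corral", D_free=0.03, sigma_loc=0.0, n_frames=300)
        p50 = rt.MembraneModelParams(substeps=50, seed=8, **base)
        p25 = rt.MembraneModelParams(substeps=25, seed=9, **base)
        sq50 = steps_sq(rt.simulate_corral(p50, 150))
        sq25 = steps_sq(rt.simulate_corral(p25, 150))
        se = np.hypot(sq50.std() / np.sqrt(len(sq50) / 2),
                      sq25.std() / np.sqrt(len(sq25) / 2))
        assert abs(sq50.mean() - sq25.mean()) < 3 * se

    def test_invalid_barrier_width_rejected(self):
        with pytest.raises(ValueError):
            rt.MembraneModelParams(regime="corral", barrier_width=0.0)


class TestDomain:
    def test_slow_shell_limit_reduces_to_free(self):
        p = rt.MembraneModelParams(regime="domain",
                                   domain_relaxation_time=1e12,
                                   D_free=0.1, sigma_loc=0.0, n_frames=200,
                                   seed=10)
        sq_d = steps_sq(rt.simulate_domain(p, 200))
        sq_f = steps_sq(rt.simulate_free(p.replace(regime="free"), 200))
        assert sps.ks_2samp(sq_d, sq_f).pvalue > 0.01

    def test_default_domain_has_V_below_2(self):
        p = rt.MembraneModelParams(regime="domain", sigma_loc=0.0, seed=11)
        v, se, _ = ensemble_V(rt.simulate_domain(p, 300))
        assert v + 3 * se < 2.0

    def test_no_cholesterol_recovers_free_V(self):
        p = rt.MembraneModelParams(regime="domain", cholesterol=0.0,
                                   sigma_loc=0.0, seed=12)
        v, se, _ = ensemble_V(rt.simulate_domain(p, 300))
        assert abs(v - 2.0) < 3 * se

    def test_invalid_relaxation_time_rejected(self):
        with pytest.raises(ValueError):
            rt.MembraneModelParams(regime="domain", domain_relaxation_time=0.0)


class TestOrdering:
    def test_V_ordering_corral_free_domain(self):
        """V(corral) > V(free) > V(domain) at matched D and sampling."""
        D = 0.1
        seeds = {"corral": 20, "free": 21, "domain": 22}
        vals = {}
        for regime, seed in seeds.items():
            p = rt.MembraneModelParams(regime=regime, D_free=D, sigma_loc=0.0,
                                       n_frames=400, seed=seed)
            gen = {"corral": rt.simulate_corral, "free": rt.simulate_free,
                   "domain": rt.simulate_domain}[regime]
            vals[regime] = ensemble_V(gen(p, 500))
        for hi, lo in [("corral", "free"), ("free", "domain")]:
            (m1, s1, _), (m2, s2, _) = vals[hi], vals[lo]
            z = (m1 - m2) / np.hypot(s1, s2)
            assert z > 2.33, f"V({hi})={m1:.3f} not above V({lo})={m2:.3f}"


class TestPair:
    def test_decoupled_pair_matches_independent_null(self):
        p = rt.MembraneModelParams(regime="pair", pair_spring_k=0.0,
                                   sigma_loc=0.0, n_frames=200, seed=30)
        pairs = rt.simulate_pair(p, 150)
        cs = [rt.degree_of_correlation(a.positions[:40], b.positions[:40])
              for a, b in pairs]
        null_sd = np.std(cs)
        assert abs(np.mean(cs)) < 3 * null_sd / np.sqrt(len(cs))
        assert np.mean(np.array(cs) > 0.8) < 0.05

    def test_rigid_pair_reaches_full_correlation(self):
        p = rt.MembraneModelParams(regime="pair", pair_spring_k=1e9,
                                   sigma_loc=0.0, n_frames=100, seed=31)
        pairs = rt.simulate_pair(p, 10)
        for a, b in pairs:
            c = rt.degree_of_correlation(a.positions[:40], b.positions[:40])
            assert c == pytest.approx(1.0, abs=1e-6)

    def test_members_share_frames_and_ids_are_distinct(self):
        p = rt.MembraneModelParams(regime="pair", sigma_loc=0.0, n_frames=50,
                                   seed=32)
        pairs = rt.simulate_pair(p, 3)
        ids = [t.track_id for ab in pairs for t in ab]
        assert len(set(ids)) == 6
        for a, b in pairs:
            np.testing.assert_array_equal(a.frames, b.frames)

    def test_invalid_pair_count_rejected(self):
        p = rt.MembraneModelParams(regime="pair")
        with pytest.raises(ValueError):
            rt.simulate_pair(p, 0)
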