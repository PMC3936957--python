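import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from ldsplit import bench, fwdsim
from ldsplit.hapio import HaplotypePanel
from ldsplit.recprofile import (
    EstimatorConfig,
    EstimationError,
    RecombinationProfile,
    average_aligned_profiles,
    detect_hotspots,
    estimate_profile,
    hotspot_strength,
    pac_loglik,
    watterson_theta,
)
from .conftest import make_random_panel


def brute_force_pac(panel, interval_rho, ordering, theta):
    """Independent oracle: sum over all copy paths of each conditional.

    Enumerates every hidden state sequence explicitly (exponential in L,
    usable only for tiny panels).
    """
    haps = panel.alleles[np.asarray(ordering)]
    d = np.diff(panel.positions_kb)
    n, L = haps.shape
    total = 0.0
    for k in range(1, n):
        eps = theta / (2.0 * (k + theta))
        prob = 0.0
        for path in itertools.product(range(k), repeat=L):
            p = 1.0 / k
            for j, s in enumerate(path):
                if j > 0:
                    sw = 1.0 - np.exp(-interval_rho[j - 1] * d[j - 1] / k)
                    trans = (1 - sw) * (path[j - 1] == s) + sw / k
                    p *= trans
                e = 1.0 - eps if haps[s, j] == haps[k, j] else eps
                p *= e
            prob += p
        total += np.log(prob)
    return total


class TestPacLoglik:
    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        L = int(rng.integers(2, 5))
        panel = make_random_panel(rng, n, L)
        rho = rng.uniform(0.01, 5.0, size=L - 1)
        ordering = rng.permutation(n)
        theta = watterson_theta(n)
        got = pac_loglik(panel, rho, ordering, theta)
        want = brute_force_pac(panel, rho, ordering, theta)
        assert got == pytest.approx(want, rel=1e-10)

    def test_two_identical_haplotypes_ignore_rho(self):
        alleles = np.array([[0, 1, 0, 1], [0, 1, 0, 1]], dtype=np.int8)
        panel = HaplotypePanel(alleles, [1.0, 2.0, 3.0, 4.0])
        lls = [
            pac_loglik(panel, np.full(3, r), [0, 1]) for r in (0.0, 0.5, 5.0, 50.0)
        ]
        assert np.ptp(lls) < 1e-12

    def test_invariant_under_global_allele_relabeling(self, rng):
        panel = make_random_panel(rng, 5, 4)
        flipped = HaplotypePanel((1 - panel.alleles).astype(np.int8), panel.positions)
        rho = rng.uniform(0.1, 2.0, size=3)
        ordering = [2, 0, 4, 1, 3]
        assert pac_loglik(panel, rho, ordering) == pytest.approx(
            pac_loglik(flipped, rho, ordering)
        )

    def test_missing_calls_rejected(self, rng):
        panel = make_random_panel(rng, 4, 3, missing_rate=0.3)
        with pytest.raises(EstimationError):
            pac_loglik(panel, np.ones(2), [0, 1, 2, 3])


class TestEstimateProfile:
    def test_bitwise_reproducible(self, rng):
        panel = make_random_panel(rng, 20, 8)
        cfg = EstimatorConfig.desk(seed=7)
        p1 = estimate_profile(panel, cfg)
        p2 = estimate_profile(panel, cfg)
        np.testing.assert_array_equal(p1.interval_rho, p2.interval_rho)

    def test_duplicating_haplotypes_keeps_argmax(self, rng):
        panel = make_random_panel(rng, 12, 6)
        doubled = HaplotypePanel(
            np.vstack([panel.alleles, panel.alleles]),
            panel.positions,
        )
        cfg = EstimatorConfig.desk(seed=3)
        a1 = int(np.argmax(estimate_profile(panel, cfg).interval_rho))
        a2 = int(np.argmax(estimate_profile(doubled, cfg).interval_rho))
        assert abs(a1 - a2) <= 1

    def test_too_few_segregating_sites_errors(self):
        alleles = np.zeros((6, 4), dtype=np.int8)
        alleles[0, 1] = 1
        panel = HaplotypePanel(alleles, [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(EstimationError):
            estimate_profile(panel, EstimatorConfig.desk())

    def test_monomorphic_sites_reexpanded_as_zero_information(self, rng):
        panel = make_random_panel(rng, 15, 6)
        alleles = panel.alleles.copy()
        alleles[:, 0] = 0  # fix the first site
        fixed = HaplotypePanel(alleles, panel.positions)
        prof = estimate_profile(fixed, EstimatorConfig.desk(seed=1))
        assert prof.interval_rho.shape == (5,)
        assert prof.interval_rho[0] == 0.0  # outside the reduced span

    def test_monotone_response_to_simulated_crossover_rate(self):
        """Mean estimated hotspot strength rises with the simulated
        crossover probability."""
        cfg_est = EstimatorConfig.desk(seed=0)
        probs, strengths = [], []
        for p_hot in (0.001, 0.003, 0.01):
            for rep in range(10):
                cfg = fwdsim.SimulationConfig.desk_null(
                    seed=10 * rep + int(p_hot * 1e4),
                    n_subsets=1,
                    p_xover_background=p_hot,
                    p_xover_hot=p_hot,
                )
                pop = fwdsim.initialize_population(cfg)
                fwdsim.evolve(pop, cfg, rng=np.random.default_rng(cfg.seed + 1))
                panel = bench.analysis_window(fwdsim.sample_panels(pop, cfg)[0])
                prof = estimate_profile(panel, cfg_est)
                probs.append(p_hot)
                strengths.append(hotspot_strength(prof, bench.HOTSPOT_INTERVAL_BP))
        rho, _ = spearmanr(probs, strengths)
        assert rho > 0


class TestHotspotStrength:
    def uniform_profile(self):
        return RecombinationProfile(
            interval_rho=np.ones(10), positions=np.arange(11.0), unit="kb"
        )

    def test_rectangle_area(self):
        assert hotspot_strength(self.uniform_profile(), (2000, 4000)) == pytest.approx(2.0)

    def test_single_gap(self):
        prof = RecombinationProfile([0.5, 2.0, 1.0], [0.0, 1.0, 3.0, 4.0])
        assert hotspot_strength(prof, (1000, 3000)) == pytest.approx(2.0 * 2.0)

    def test_additive_over_partition(self, rng):
        prof = RecombinationProfile(
            rng.uniform(0, 3, 9), np.sort(rng.uniform(0, 50, 10))
        )
        lo = prof.positions[0] * 1000 + 10
        hi = prof.positions[-1] * 1000 - 10
        mid = prof.positions[4] * 1000
        whole = hotspot_strength(prof, (lo, hi))
        parts = hotspot_strength(prof, (lo, mid)) + hotspot_strength(prof, (mid, hi))
        assert whole == pytest.approx(parts)

    def test_linear_in_rescaling(self):
        prof = self.uniform_profile()
        scaled = RecombinationProfile(prof.interval_rho * 3, prof.positions)
        assert hotspot_strength(scaled, (500, 9500)) == pytest.approx(
            3 * hotspot_strength(prof, (500, 9500))
        )

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError):
            hotspot_strength(self.uniform_profile(), (50000, 60000))


class TestDetectHotspots:
    def test_flat_profile_has_no_hotspots(self):
        prof = RecombinationProfile(np.ones(20), np.arange(21.0))
        assert detect_hotspots(prof) == []

    def test_all_zero_profile_has_no_hotspots(self):
        prof = RecombinationProfile(np.zeros(5), np.arange(6.0))
        assert detect_hotspots(prof) == []

    def test_single_rectangular_bump(self):
        rho = np.ones(20)
        rho[9:11] = 10.0  # 2 kb bump at 10x background
        prof = RecombinationProfile(rho, np.arange(21.0))
        spots = detect_hotspots(prof, fold=5)
        assert spots == [(9000.0, 11000.0)]

    def test_two_separated_bumps(self):
        rho = np.ones(30)
        rho[5] = 20.0
        rho[20] = 20.0
        prof = RecombinationProfile(rho, np.arange(31.0))
        spots = detect_hotspots(prof, fold=5, merge_gap_bp=1000)
        assert len(spots) == 2


class TestAverageAlignedProfiles:
    def test_single_profile_is_own_regridding(self):
        prof = RecombinationProfile([1.0, 3.0], [0.0, 1.0, 2.0])
        out = average_aligned_profiles([prof], [1000.0], span_bp=1000, bin_bp=500)
        np.testing.assert_allclose(out.mean_rho, [1.0, 1.0, 3.0, 3.0])

    def test_idempotent_over_copies(self):
        prof = RecombinationProfile([1.0, 3.0, 0.5], [0.0, 1.0, 2.0, 3.0])
        one = average_aligned_profiles([prof], [1500.0], 1000, 250)
        many = average_aligned_profiles([prof] * 5, [1500.0] * 5, 1000, 250)
        np.testing.assert_allclose(one.mean_rho, many.mean_rho)

    def test_mirror_profiles_average_symmetric(self):
        a = RecombinationProfile([0.0, 4.0, 1.0, 0.0], [0.0, 1.0, 2.0, 3.0, 4.0])
        b = RecombinationProfile([0.0, 1.0, 4.0, 0.0], [0.0, 1.0, 2.0, 3.0, 4.0])
        out = average_aligned_profiles([a, b], [2000.0, 2000.0], 2000, 500)
        np.testing.assert_allclose(out.mean_rho, out.mean_rho[::-1])

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            average_aligned_profiles([], [], 1000, 100)
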