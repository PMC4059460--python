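"""Mixture estimation, HMM construction, Viterbi decoding, region extraction."""

import itertools

import numpy as np
import pytest

from derseg.segmentation import (
    HMMParams,
    MixtureFit,
    Region,
    build_hmm,
    estimate_pi0,
    extract_regions,
    fit_mixture,
    viterbi_decode,
)

from conftest import make_cov


def simple_mix(mu1=0.0, var1=1.0, mu2=3.0, var2=4.0, pi2=0.2):
    return MixtureFit(
        pi1_star=1 - pi2, pi2_star=pi2, mu1=mu1, var1=var1, mu2=mu2,
        var2=var2, loglik=0.0, n_iter=1, converged=True,
    )


def random_params(rng):
    pi = rng.dirichlet([1, 1, 1])
    retain = rng.uniform(0.5, 0.99)
    mix = simple_mix(
        mu1=rng.normal(0, 0.5),
        var1=rng.uniform(0.5, 2.0),
        mu2=rng.normal(0, 4.0),
        var2=rng.uniform(2.0, 9.0),
        pi2=rng.uniform(0.05, 0.5),
    )
    params = build_hmm(pi[0], mix, delta=rng.uniform(1e-5, 1e-2), retain_prob=retain)
    # replace the scaled priors by the raw dirichlet draw for variety
    params.state_priors = pi
    return params


def brute_force_path(stats, params):
    """Exhaustive argmax over all 3^L state sequences (lexicographic ties)."""
    log_pi = np.log(params.state_priors)
    log_a = np.log(params.transition)
    log_b = np.column_stack(
        [
            -0.5 * (np.log(2 * np.pi * params.variances[d])
                    + (stats - params.means[d]) ** 2 / params.variances[d])
            for d in range(3)
        ]
    )
    best, best_score = None, -np.inf
    for seq in itertools.product(range(3), repeat=len(stats)):
        score = log_pi[seq[0]] + log_b[0, seq[0]]
        for t in range(1, len(stats)):
            score += log_a[seq[t - 1], seq[t]] + log_b[t, seq[t]]
        if score > best_score:
            best, best_score = seq, score
    return np.array(best)


class TestPi0:
    def test_fraction_below_cutoff(self):
        counts = np.array([[0], [1], [2], [10], [10], [10], [10], [10], [10], [0]])
        cov = make_cov(counts)
        assert estimate_pi0(cov, cutoff_c=5.0) == pytest.approx(0.4)

    @pytest.mark.parametrize("fill,expected", [(0, 1.0), (50, 0.0)])
    def test_boundaries(self, fill, expected):
        cov = make_cov(np.full((10, 2), fill))
        assert estimate_pi0(cov, cutoff_c=5.0) == expected


class TestMixture:
    def test_recovers_planted_components(self, rng):
        n = 20_000
        null = rng.random(n) < 0.9
        s = np.where(null, rng.normal(0, 1, n), rng.normal(3, 1.5, n))
        m = fit_mixture(s)
        assert m.pi2_star == pytest.approx(0.1, abs=0.02)
        assert m.mu2 == pytest.approx(3.0, abs=0.15)
        assert m.var2 >= m.var1

    def test_pure_null_drives_alt_weight_to_boundary(self, rng):
        m = fit_mixture(rng.normal(0, 1, 20_000))
        assert m.pi2_star <= 0.05
        assert abs(m.mu1) < 0.1

    def test_symmetric_shoulders_keep_null_centered(self, rng):
        s = np.concatenate(
            [
                rng.normal(0, 1, 4000),
                rng.normal(3, 0.5, 500),
                -rng.normal(3, 0.5, 500),
            ]
        )
        m = fit_mixture(s)
        assert m.mu1 == pytest.approx(0.0, abs=0.15)

    def test_group_specific_track_keeps_null_near_zero(self, rng):
        # every expressed base differential: the null component must not
        # drift onto the signal blob
        s = rng.normal(25, 6, 5000)
        m = fit_mixture(s)
        assert abs(m.mu1) <= 2.0
        assert m.var1 <= 9.0
        assert m.mu2 == pytest.approx(25, abs=2.0)
        assert m.pi2_star > 0.9

    def test_requires_enough_points(self):
        with pytest.raises(ValueError, match="at least 50"):
            fit_mixture(np.zeros(10))


class TestBuildHmm:
    def test_prior_scaling_rule(self):
        params = build_hmm(0.5, simple_mix(pi2=0.2))
        np.testing.assert_allclose(params.state_priors, [0.5, 0.4, 0.1])

    def test_off_diagonal_even_split(self):
        params = build_hmm(0.3, simple_mix(), retain_prob=0.999)
        off = params.transition[0, 1]
        assert off == pytest.approx(0.0005)
        np.testing.assert_allclose(params.transition.sum(axis=1), 1.0)

    @pytest.mark.parametrize("pi0", [0.0, 0.123, 0.97, 1.0])
    def test_priors_sum_to_one(self, pi0):
        params = build_hmm(pi0, simple_mix(pi2=0.31))
        assert params.state_priors.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_hmm(1.5, simple_mix())
        with pytest.raises(ValueError):
            build_hmm(0.5, simple_mix(), retain_prob=1.0)
        with pytest.raises(ValueError):
            build_hmm(0.5, simple_mix(), delta=0.0)


class TestViterbi:
    def test_zero_track_decodes_all_state0(self):
        params = build_hmm(0.4, simple_mix(mu1=0.5, mu2=4.0), delta=1e-4)
        path = viterbi_decode(np.zeros(50), params)
        assert (path == 0).all()

    def test_strong_signal_decodes_all_state2(self):
        params = build_hmm(0.4, simple_mix(mu1=0.0, mu2=8.0, var2=1.0))
        path = viterbi_decode(np.full(50, 8.0), params)
        assert (path == 2).all()

    def test_nonfinite_statistic_names_position(self):
        params = build_hmm(0.4, simple_mix())
        s = np.zeros(10)
        s[7] = np.nan
        with pytest.raises(ValueError, match="index 7"):
            viterbi_decode(s, params)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            L = int(rng.integers(1, 9))
            params = random_params(rng)
            stats = rng.normal(0, 3, L)
            np.testing.assert_array_equal(
                viterbi_decode(stats, params), brute_force_path(stats, params)
            )

    def test_matches_hmmlearn_decoder(self, rng):
        # independent oracle on a longer track
        from hmmlearn.hmm import GaussianHMM

        params = random_params(rng)
        stats = rng.normal(0, 3, 300)
        ours = viterbi_decode(stats, params)
        hm = GaussianHMM(n_components=3, covariance_type="diag", init_params="")
        hm.startprob_ = params.state_priors
        hm.transmat_ = params.transition
        hm.means_ = params.means.reshape(-1, 1)
        hm.covars_ = params.variances.reshape(-1, 1)
        _, theirs = hm.decode(stats.reshape(-1, 1), algorithm="viterbi")
        np.testing.assert_array_equal(ours, theirs)


class TestRegions:
    def test_run_length_extraction(self):
        path = np.array([0, 0, 2, 2, 1, 2])
        positions = np.arange(100, 106)
        stats = np.array([0.0, 0.0, 3.0, 4.0, 1.0, 5.0])
        regs = extract_regions(path, positions, stats)
        assert [(r.start, r.end, r.state) for r in regs] == [
            (100, 102, 0),
            (102, 104, 2),
            (104, 105, 1),
            (105, 106, 2),
        ]
        assert regs[1].mean_stat == pytest.approx(3.5)

    def test_all_one_path_yields_single_region_no_candidates(self):
        regs = extract_regions(np.ones(10, int), np.arange(10), np.zeros(10))
        assert len(regs) == 1
        assert regs[0].state == 1

    def test_mean_and_sum_modes(self):
        path = np.full(3, 2)
        stats = np.array([1.0, 2.0, 3.0])
        mean_reg = extract_regions(path, np.arange(3), stats, stat_mode="mean")[0]
        sum_reg = extract_regions(path, np.arange(3), stats, stat_mode="sum")[0]
        assert mean_reg.mean_stat == pytest.approx(2.0)
        assert sum_reg.mean_stat == pytest.approx(6.0)

    def test_direction_from_sign(self):
        regs = extract_regions(
            np.array([2, 2, 2, 2]), np.arange(4), np.array([2.0, 2, -5, -5])
        )
        assert regs[0].direction == "down"  # mean is -1.5

    def test_partition_invariants_on_random_paths(self, rng):
        for _ in range(20):
            L = int(rng.integers(1, 200))
            path = rng.integers(0, 3, L)
            regs = extract_regions(path, np.arange(L), rng.normal(size=L))
            assert sum(r.length for r in regs) == L
            starts = [r.start for r in regs]
            assert starts == sorted(starts)
            for a, b in zip(regs, regs[1:]):
                assert a.end == b.start
                assert a.state != b.state

    def test_raising_retain_prob_never_fragments_more(self, rng):
        stats = np.concatenate(
            [rng.normal(0, 1, 200), rng.normal(4, 1, 80), rng.normal(0, 1, 200)]
        )
        mix = simple_mix(mu2=4.0, var2=1.5)
        n_regions = []
        for retain in (0.6, 0.9, 0.99, 0.999):
            params = build_hmm(0.2, mix, retain_prob=retain)
            path = viterbi_decode(stats, params)
            n_regions.append(
                len(extract_regions(path, np.arange(stats.size), stats))
            )
        assert all(a >= b for a, b in zip(n_regions, n_regions[1:]))
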