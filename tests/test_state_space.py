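"""Switching dynamics, causal filter, and acausal smoother."""

import numpy as np
import pytest
from scipy.special import erf

from replaystate.likelihoods import LikelihoodMatrix, make_time_bins
from replaystate.state_space import (
    DynamicsModel,
    acausal_smoother,
    build_dynamics_model,
    causal_filter,
    decode,
)
from replaystate.track import linear_track, make_grid_1d


def _tiny_grid(n_bins: int, bin_size: float = 3.0):
    return make_grid_1d(linear_track(n_bins * bin_size), bin_size)


def _lik(ll: np.ndarray) -> LikelihoodMatrix:
    ll = np.asarray(ll, dtype=float)
    return LikelihoodMatrix(log_likelihood=ll, time_bin_edges=make_time_bins(0.002 * ll.shape[0]))


def brute_force_marginals(ll: np.ndarray, dyn: DynamicsModel):
    """Exhaustive path-sum posterior over (dynamic, bin) states.

    Enumerates every joint path, weights it by initial distribution,
    transition kernels, and likelihood, and accumulates the smoothed
    marginal at every time step.  Exponential cost; tiny instances only.
    """
    import itertools

    n_time, n_bins = ll.shape
    n_dyn = dyn.n_dynamics
    lik = np.exp(ll - ll.max())
    states = [(i, x) for i in range(n_dyn) for x in range(n_bins)]
    marg = np.zeros((n_time, n_dyn, n_bins))
    for path in itertools.product(range(len(states)), repeat=n_time):
        i0, x0 = states[path[0]]
        w = dyn.initial_distribution[i0, x0] * lik[0, x0]
        for k in range(1, n_time):
            ip, xp = states[path[k - 1]]
            i, x = states[path[k]]
            w *= (
                dyn.discrete_transition[ip, i]
                * dyn.movement_kernels[ip][i][xp, x]
                * lik[k, x]
            )
        for k, s in enumerate(path):
            i, x = states[s]
            marg[k, i, x] += w
    marg /= marg.sum(axis=(1, 2), keepdims=True)
    return marg


class TestDynamicsModel:
    def test_discrete_transition_and_expected_dwell(self):
        """Stay probability 0.98 gives 0.01 off-diagonals and a geometric
        expected dwell of 100 ms at 2 ms steps."""
        grid = _tiny_grid(4)
        dyn = build_dynamics_model(grid, stay_prob=0.98)
        T = dyn.discrete_transition
        assert np.allclose(np.diag(T), 0.98)
        assert np.allclose(T[~np.eye(3, dtype=bool)], 0.01)
        dwell_ms = 1.0 / (1.0 - 0.98) * 2.0
        assert dwell_ms == pytest.approx(100.0)

    def test_stay_prob_one_never_switches(self):
        grid = _tiny_grid(3)
        dyn = build_dynamics_model(grid, stay_prob=1.0)
        assert np.allclose(dyn.discrete_transition, np.eye(3))

    def test_random_walk_displacement_bound(self):
        """95% of per-step mass lies within 2 SD = 4.90 cm; the mass within
        +-1 bin of the origin matches the Gaussian CDF on the bin edges."""
        sd = np.sqrt(6.0)
        assert 2 * sd == pytest.approx(4.90, abs=0.01)
        grid = _tiny_grid(21)
        dyn = build_dynamics_model(grid, rw_variance=6.0)
        rw = dyn.movement_kernels[1][1]  # continuous -> continuous
        center = 10
        within = rw[center, center - 1 : center + 2].sum()
        # independent midpoint-rule oracle: the kernel evaluates the
        # Gaussian at bin centers and row-normalizes
        offsets = 3.0 * (np.arange(21) - center)
        pdf = np.exp(-0.5 * offsets**2 / 6.0)
        expected = pdf[center - 1 : center + 2].sum() / pdf.sum()
        assert within == pytest.approx(expected, abs=1e-12)
        # and the continuous 2 SD (4.90 cm) bound is respected
        assert within >= erf(4.5 / (sd * np.sqrt(2))) - 0.01

    def test_all_rows_stochastic(self):
        grid = _tiny_grid(7)
        dyn = build_dynamics_model(grid)
        assert np.allclose(dyn.discrete_transition.sum(axis=1), 1.0, atol=1e-10)
        for row in dyn.movement_kernels:
            for k in row:
                assert np.allclose(k.sum(axis=1), 1.0, atol=1e-10)
                assert np.all(k >= 0)

    def test_kernel_assignment_per_dynamic_pair(self):
        grid = _tiny_grid(5)
        dyn = build_dynamics_model(grid)
        n = grid.n_bins
        eye = np.eye(n)
        # stationary column: identity from stationary and continuous
        assert np.allclose(dyn.movement_kernels[0][0], eye)
        assert np.allclose(dyn.movement_kernels[1][0], eye)
        # fragmented rows and column: uniform
        uni = dyn.movement_kernels[2][2]
        assert np.allclose(uni, uni[0][None, :])
        for i in range(3):
            assert np.allclose(dyn.movement_kernels[2][i], uni)
            assert np.allclose(dyn.movement_kernels[i][2], uni)

    @pytest.mark.parametrize("bad", [dict(stay_prob=0.0), dict(stay_prob=1.5), dict(rw_variance=-1.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            build_dynamics_model(_tiny_grid(3), **bad)


class TestFilterSmoother:
    def test_flat_likelihood_keeps_uniform_dynamics(self):
        grid = _tiny_grid(5)
        dyn = build_dynamics_model(grid)
        post = causal_filter(_lik(np.zeros((20, 5))), dyn)
        marg = post.causal.sum(axis=2)
        assert np.allclose(marg, 1.0 / 3.0, atol=1e-12)

    def test_hand_computed_forward_pass(self):
        """2 bins, 2 dynamics, 3 steps with hand-set numbers match a manual
        forward recursion to 1e-12."""
        grid = _tiny_grid(2)
        n = 2
        K = [
            [np.array([[0.9, 0.1], [0.2, 0.8]]), np.array([[0.5, 0.5], [0.5, 0.5]])],
            [np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[0.6, 0.4], [0.3, 0.7]])],
        ]
        T = np.array([[0.95, 0.05], [0.1, 0.9]])
        init = np.array([[0.3, 0.2], [0.25, 0.25]])
        dyn = DynamicsModel(
            dynamics=("stationary", "continuous"),
            discrete_transition=T,
            movement_kernels=K,
            initial_distribution=init,
            stay_prob=0.95,
            rw_variance=6.0,
        )
        ll = np.log(np.array([[0.7, 0.3], [0.4, 0.6], [0.9, 0.1]]))
        post = causal_filter(_lik(ll), dyn)
        # manual recursion
        lik = np.exp(ll)
        p = init * lik[0][None, :]
        p /= p.sum()
        manual = [p]
        for k in (1, 2):
            pred = np.zeros((2, n))
            for i in range(2):
                for ip in range(2):
                    pred[i] += T[ip, i] * (manual[-1][ip] @ K[ip][i])
            cur = pred * lik[k][None, :]
            cur /= cur.sum()
            manual.append(cur)
        for k in range(3):
            assert np.allclose(post.causal[k], manual[k], atol=1e-12)

    def test_smoother_matches_brute_force_path_enumeration(self):
        """Acausal marginals equal the exhaustive path sum (3 bins x 3
        dynamics x 4 steps) to 1e-10."""
        grid = _tiny_grid(3)
        dyn = build_dynamics_model(grid)
        rng = np.random.default_rng(0)
        ll = np.log(rng.uniform(0.1, 1.0, size=(4, 3)))
        post = acausal_smoother(causal_filter(_lik(ll), dyn), dyn)
        expected = brute_force_marginals(ll, dyn)
        assert np.max(np.abs(post.acausal - expected)) < 1e-10

    def test_final_slice_boundary_condition(self):
        grid = _tiny_grid(4)
        dyn = build_dynamics_model(grid)
        rng = np.random.default_rng(1)
        ll = np.log(rng.uniform(0.1, 1.0, size=(6, 4)))
        post = acausal_smoother(causal_filter(_lik(ll), dyn), dyn)
        assert np.allclose(post.acausal[-1], post.causal[-1], atol=1e-14)

    def test_slices_normalized_and_nonnegative(self):
        grid = _tiny_grid(6)
        dyn = build_dynamics_model(grid)
        rng = np.random.default_rng(2)
        ll = rng.normal(size=(15, 6))
        post = acausal_smoother(causal_filter(_lik(ll), dyn), dyn)
        for arr in (post.causal, post.acausal):
            assert np.all(arr >= 0)
            assert np.allclose(arr.sum(axis=(1, 2)), 1.0, atol=1e-8)

    def test_time_reversal_symmetry_of_symmetric_submodel(self):
        """For a reversible joint chain (symmetric kernels per ordered
        pair), decoding the time-reversed likelihood yields the
        time-reversed acausal posterior.  The full model is deliberately
        not reversible: stationary->continuous is a random walk while
        continuous->stationary is the identity."""
        grid = _tiny_grid(5)
        base = build_dynamics_model(grid)
        uni = base.movement_kernels[2][2]
        # circulant Gaussian random walk (periodic boundary): symmetric
        n = 5
        idx = np.arange(n)
        ring = np.minimum(np.abs(idx[:, None] - idx[None, :]), n - np.abs(idx[:, None] - idx[None, :]))
        rw = np.exp(-0.5 * (3.0 * ring) ** 2 / 6.0)
        rw /= rw.sum(axis=1, keepdims=True)
        assert np.allclose(rw, rw.T)
        K = [[rw, rw, uni], [rw, rw, uni], [uni, uni, uni]]
        dyn = DynamicsModel(
            dynamics=base.dynamics,
            discrete_transition=base.discrete_transition,
            movement_kernels=K,
            initial_distribution=base.initial_distribution,
            stay_prob=base.stay_prob,
            rw_variance=base.rw_variance,
        )
        rng = np.random.default_rng(3)
        ll = rng.normal(size=(12, 5))
        fwd = acausal_smoother(causal_filter(_lik(ll), dyn), dyn)
        rev = acausal_smoother(causal_filter(_lik(ll[::-1]), dyn), dyn)
        assert np.allclose(fwd.acausal, rev.acausal[::-1], atol=1e-10)

    def test_continuous_only_reduces_to_plain_hmm(self):
        """One dynamic with stay probability 1 is a textbook HMM; the
        smoothed marginals match an independent forward-backward pass."""
        grid = _tiny_grid(4)
        dyn = build_dynamics_model(grid, stay_prob=1.0, dynamics=("continuous",))
        rng = np.random.default_rng(4)
        ll = np.log(rng.uniform(0.1, 1.0, size=(6, 4)))
        post = acausal_smoother(causal_filter(_lik(ll), dyn), dyn)
        # independent forward-backward
        A = dyn.movement_kernels[0][0]
        B = np.exp(ll)
        pi0 = dyn.initial_distribution[0]
        alpha = np.zeros_like(B)
        alpha[0] = pi0 * B[0]
        for k in range(1, len(B)):
            alpha[k] = (alpha[k - 1] @ A) * B[k]
        beta = np.ones_like(B)
        for k in range(len(B) - 2, -1, -1):
            beta[k] = A @ (B[k + 1] * beta[k + 1])
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        assert np.allclose(post.acausal[:, 0, :], gamma, atol=1e-10)

    def test_single_bin_event_is_prior_times_likelihood(self):
        grid = _tiny_grid(4)
        dyn = build_dynamics_model(grid)
        ll = np.log(np.array([[0.1, 0.5, 0.3, 0.1]]))
        post = acausal_smoother(causal_filter(_lik(ll), dyn), dyn)
        expected = dyn.initial_distribution * np.exp(ll[0])[None, :]
        expected /= expected.sum()
        assert np.allclose(post.acausal[0], expected, atol=1e-12)

    def test_zero_mass_slice_aborts_with_diagnostic(self):
        grid = _tiny_grid(3)
        dyn = build_dynamics_model(grid)
        ll = np.full((3, 3), -np.inf)
        with pytest.raises(FloatingPointError):
            causal_filter(_lik(ll), dyn)


class TestDecode:
    def test_decode_rejects_unknown_encoder(self, grid60):
        with pytest.raises(TypeError):
            decode(None, object(), grid60)

    def test_decode_speed_smoke(self, sim_encoder, bank):
        """A 280 ms event on a 60-bin grid decodes in well under a second."""
        import time

        from replaystate.simulate import make_test_sequence

        encoder, grid, bank_ = sim_encoder
        seq, _ = make_test_sequence(bank_, [("continuous", 280)], seed=0)
        t0 = time.perf_counter()
        post = decode(seq, encoder, grid)
        elapsed = time.perf_counter() - t0
        assert elapsed < 1.0
        assert post.acausal.shape == (140, 3, 60)
        assert post.metadata["stay_prob"] == 0.98
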