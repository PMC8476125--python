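"""Posterior summaries: classification, HPD, MAP, speed, event flags."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replaystate.likelihoods import LikelihoodMatrix, make_time_bins
from replaystate.postprocess import (
    classify,
    dynamics_marginal,
    estimate_speed,
    hpd_region,
    map_position,
    position_marginal,
    segment_mean_speeds,
    summarize_event,
)
from replaystate.state_space import Posterior, acausal_smoother, build_dynamics_model, causal_filter
from replaystate.track import linear_track, make_grid_1d


def _posterior_from(joint: np.ndarray) -> Posterior:
    joint = np.asarray(joint, dtype=float)
    return Posterior(
        causal=joint,
        acausal=joint,
        time_bin_edges=make_time_bins(0.002 * joint.shape[0]),
        dynamics=("stationary", "continuous", "fragmented"),
    )


class TestMarginals:
    def test_degenerate_posterior_gives_unit_dynamic(self):
        joint = np.zeros((1, 3, 4))
        joint[0, 1, 2] = 1.0
        assert np.allclose(dynamics_marginal(_posterior_from(joint)), [[0, 1, 0]])

    def test_marginals_match_dense_summation(self):
        rng = np.random.default_rng(0)
        joint = rng.uniform(size=(7, 3, 12))
        joint /= joint.sum(axis=(1, 2), keepdims=True)
        post = _posterior_from(joint)
        dm = dynamics_marginal(post)
        pm = position_marginal(post)
        assert np.allclose(dm, joint.sum(axis=2), atol=1e-12)
        assert np.allclose(pm, joint.sum(axis=1), atol=1e-12)
        assert np.allclose(dm.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(pm.sum(axis=1), 1.0, atol=1e-12)

    def test_single_dynamic_posterior_marginal_equals_slice(self):
        rng = np.random.default_rng(1)
        joint = np.zeros((4, 3, 6))
        joint[:, 0, :] = rng.uniform(size=(4, 6))
        joint /= joint.sum(axis=(1, 2), keepdims=True)
        pm = position_marginal(_posterior_from(joint))
        assert np.allclose(pm, joint[:, 0, :] / joint[:, 0, :].sum(axis=1, keepdims=True))


class TestClassify:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ((1.0, 0.0, 0.0), "stationary"),
            ((0.85, 0.10, 0.05), "stationary"),
            ((0.6, 0.4, 0.0), "stationary-continuous-mixture"),
            ((0.5, 0.31, 0.19), "stationary-continuous-mixture"),
            ((0.0, 0.5, 0.4), "fragmented-continuous-mixture"),
            ((0.1, 0.5, 0.4), "fragmented-continuous-mixture"),
            ((0.5, 0.3, 0.2), "unclassified"),
            ((0.0, 0.85, 0.15), "continuous"),
            ((0.05, 0.1, 0.85), "fragmented"),
        ],
    )
    def test_five_category_rule(self, probs, expected):
        track = classify(np.array([probs]), 0.80)
        assert track.labels[0] == expected

    def test_individual_beats_mixture(self):
        # stationary 0.85 also clears the mixture sum; individual wins
        track = classify(np.array([[0.85, 0.14, 0.01]]), 0.80)
        assert track.labels[0] == "stationary"

    def test_segments_partition_event(self):
        marg = np.array([[0.9, 0.1, 0.0]] * 3 + [[0.1, 0.9, 0.0]] * 4 + [[0.4, 0.3, 0.3]] * 2)
        track = classify(marg, 0.80)
        assert [c for _, _, c in track.segments] == ["stationary", "continuous", "unclassified"]
        starts = [s for s, _, _ in track.segments]
        ends = [e for _, e, _ in track.segments]
        assert starts[0] == 0.0
        assert ends[-1] == pytest.approx(0.018)
        assert all(a == b for a, b in zip(ends[:-1], starts[1:]))

    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 1.0, allow_nan=False),
                st.floats(0.0, 1.0, allow_nan=False),
                st.floats(0.0, 1.0, allow_nan=False),
            ).filter(lambda p: sum(p) > 1e-6),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_raising_threshold_never_classifies_new_bins(self, rows):
        marg = np.array([np.array(r) / sum(r) for r in rows])
        low = classify(marg, 0.80).labels
        high = classify(marg, 0.95).labels
        # every bin classified at 0.95 is also classified at 0.80
        assert np.all((high == "unclassified") | (low != "unclassified"))

    @pytest.mark.parametrize("threshold", [0.5, 1.2, 0.0])
    def test_invalid_threshold_rejected(self, threshold):
        with pytest.raises(ValueError):
            classify(np.array([[1.0, 0.0, 0.0]]), threshold)


class TestHpd:
    def test_point_mass_has_one_bin_region(self, grid60):
        marg = np.zeros((1, 60))
        marg[0, 17] = 1.0
        member, size = hpd_region(marg, grid60)
        assert member[0].sum() == 1
        assert size[0] == pytest.approx(3.0)

    def test_uniform_region_is_ceil_of_coverage(self, grid60):
        marg = np.full((1, 60), 1.0 / 60)
        _, size = hpd_region(marg, grid60)
        assert size[0] == pytest.approx(57 * 3.0)  # ceil(0.95 * 60) bins

    def test_bimodal_region_matches_exhaustive_threshold_search(self, grid60):
        """Region equals the best exhaustive scan over candidate h values."""
        x = grid60.bin_centers
        density = np.exp(-0.5 * ((x - 45) / 6) ** 2) + 0.7 * np.exp(-0.5 * ((x - 130) / 9) ** 2)
        density /= density.sum()
        member, size = hpd_region(density[None, :], grid60)
        # exhaustive: for every candidate threshold h (taken from the
        # posterior values), the smallest region with mass >= 0.95
        best_size, best_n = np.inf, None
        for h in np.sort(density)[::-1]:
            region = density >= h
            if density[region].sum() >= 0.95:
                s = grid60.bin_widths[region].sum()
                if s < best_size:
                    best_size, best_n = s, region.sum()
                break
        assert size[0] == pytest.approx(best_size)
        assert member[0].sum() == best_n
        # and the region covers both modes
        assert member[0, np.argmin(np.abs(x - 45))]
        assert member[0, np.argmin(np.abs(x - 130))]

    def test_hpd_shrinks_with_concentration(self, grid60):
        """Sharper posteriors have (weakly) smaller HPD regions."""
        x = grid60.bin_centers
        sizes = []
        for sd in (40.0, 20.0, 10.0, 5.0, 2.0):
            d = np.exp(-0.5 * ((x - 90) / sd) ** 2)
            d /= d.sum()
            sizes.append(hpd_region(d[None, :], grid60)[1][0])
        assert np.all(np.diff(sizes) <= 0)


class TestMapAndSpeed:
    def test_map_point_mass_and_tie_break(self, grid60):
        marg = np.zeros((2, 60))
        marg[0, 31] = 1.0
        marg[1, 10] = marg[1, 40] = 0.5  # tie -> lowest index
        idx, cm = map_position(marg, grid60)
        assert idx.tolist() == [31, 10]
        assert cm[0] == grid60.bin_centers[31]

    def test_map_matches_dense_argmax(self, grid60):
        rng = np.random.default_rng(2)
        marg = rng.uniform(size=(20, 60))
        marg /= marg.sum(axis=1, keepdims=True)
        idx, _ = map_position(marg, grid60)
        assert np.array_equal(idx, np.argmax(marg, axis=1))

    def test_constant_track_speed_zero(self):
        assert np.allclose(estimate_speed(np.full(50, 42.0)), 0.0)

    def test_ramp_speed_is_bin_per_step(self):
        """One 3 cm bin per 2 ms step = 1500 cm/s."""
        track = np.arange(50) * 3.0
        speed = estimate_speed(track, dt=0.002)
        assert np.allclose(speed[5:-5], 1500.0, rtol=1e-6)

    def test_short_segments_excluded_from_mean_speeds(self, grid60):
        marg = np.array([[0.9, 0.1, 0.0]] * 5 + [[0.1, 0.9, 0.0]] * 15)
        track = classify(marg, 0.80)
        map_track = np.arange(20) * 3.0
        out = segment_mean_speeds(track, map_track, min_duration=0.020)
        cats = [c for _, _, c, _ in out]
        assert cats == ["continuous"]  # 10 ms stationary segment dropped


class TestSummarize:
    def _uniform_grid(self):
        return make_grid_1d(linear_track(180.0), 3.0)

    def test_all_stationary_local_event(self):
        grid = self._uniform_grid()
        n = 20
        marg_dyn = np.tile([0.9, 0.1, 0.0], (n, 1))
        track = classify(marg_dyn, 0.80)
        marg_pos = np.zeros((n, grid.n_bins))
        marg_pos[:, 5] = 1.0
        animal_xy = grid.centers_xy[5]
        summary = summarize_event(track, marg_pos, grid, animal_xy)
        assert summary.spatially_coherent
        assert not summary.spatially_incoherent
        assert not summary.non_local_stationary
        assert summary.mean_hpd_size == pytest.approx(3.0)
        assert summary.classified_fraction == 1.0

    def test_non_local_stationary_flagged_beyond_30cm(self):
        grid = self._uniform_grid()
        n = 20
        track = classify(np.tile([0.95, 0.05, 0.0], (n, 1)), 0.80)
        marg_pos = np.zeros((n, grid.n_bins))
        marg_pos[:, 20] = 1.0  # decoded at 61.5 cm
        animal_xy = grid.centers_xy[5]  # animal at 16.5 cm -> 45 cm away
        summary = summarize_event(track, marg_pos, grid, animal_xy)
        assert summary.non_local_stationary
        assert summary.mean_distance_from_animal == pytest.approx(45.0)

    def test_mixed_event_bookkeeping(self):
        """Durations per category sum to the event duration and both
        coherence flags can be true at once."""
        grid = self._uniform_grid()
        marg_dyn = np.array([[0.0, 0.9, 0.1]] * 15 + [[0.0, 0.1, 0.9]] * 10)
        track = classify(marg_dyn, 0.80)
        marg_pos = np.full((25, grid.n_bins), 1.0 / grid.n_bins)
        summary = summarize_event(track, marg_pos, grid)
        assert summary.spatially_coherent and summary.spatially_incoherent
        total = sum(summary.duration_by_category.values())
        assert total == pytest.approx(25 * 0.002)
        assert summary.duration_by_category["continuous"] == pytest.approx(0.030)
        assert summary.duration_by_category["fragmented"] == pytest.approx(0.020)


class TestEndToEndSummaries:
    def test_decoded_stationary_event_summary(self, grid60):
        """A posterior built from a stationary likelihood classifies as a
        coherent stationary event with a compact HPD region."""
        dyn = build_dynamics_model(grid60)
        ll = np.zeros((40, 60))
        ll[:, :] = -5.0
        ll[:, 20] = 0.0
        lik = LikelihoodMatrix(log_likelihood=ll, time_bin_edges=make_time_bins(0.08))
        post = acausal_smoother(causal_filter(lik, dyn), dyn)
        dm = dynamics_marginal(post)
        pm = position_marginal(post)
        track = classify(dm, 0.80, post.dynamics, post.time_bin_edges)
        _, hpd = hpd_region(pm, grid60)
        assert "stationary" in set(track.labels)
        assert hpd.mean() < 30.0
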