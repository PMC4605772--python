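"""Estimator correctness against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ash_oracle, cmi_oracle, mi_oracle, si_oracle

from klinfo.assays import Recording
from klinfo.info import (
    ash_joint,
    entropy,
    estimate_joint,
    mi_profile,
    mutual_information,
    specific_information,
    specific_information_all,
    te_profile,
    transfer_entropy,
)

def _discrete_recording(rng, n_trials=200, n_steps=4, levels=3):
    """Recording whose values sit on an integer alphabet (exact binning)."""
    stim = rng.integers(0, levels, n_trials).astype(float)
    traces = rng.integers(0, levels, (n_trials, n_steps, 2)).astype(float)
    # make variable "b" depend on the past of "a" so TE is nonzero
    traces[:, 1:, 1] = traces[:, :-1, 0]
    return Recording(
        stimulus=stim,
        traces=traces,
        dt=0.01,
        variables=("a", "b"),
        meta={"stim_lo": -0.5, "stim_hi": levels - 0.5},
    )


# ---------------------------------------------------------------------- #
# ASH estimation
# ---------------------------------------------------------------------- #


class TestASH:
    def test_matches_brute_force_average_of_shifted_histograms(self):
        rng = np.random.default_rng(7)
        cols = [rng.normal(size=50), rng.uniform(-1, 2, size=50)]
        ranges = [(-4.0, 4.0), (-1.0, 2.0)]  # ranges cover the samples
        ours = ash_joint(cols, ranges, [5, 4], [3, 2])
        oracle = ash_oracle(cols, ranges, [5, 4], [3, 2])
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_matches_brute_force_in_three_dimensions(self):
        rng = np.random.default_rng(11)
        cols = [rng.normal(size=40) for _ in range(3)]
        ranges = [(-3.0, 3.0)] * 3
        ours = ash_joint(cols, ranges, [4, 3, 5], [2, 3, 2])
        oracle = ash_oracle(cols, ranges, [4, 3, 5], [2, 3, 2])
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_single_shift_is_plain_histogram(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 300)
        p = ash_joint([x], [(0.0, 1.0)], [10], [1])
        h, _ = np.histogram(x, bins=np.arange(11) / 10.0)
        np.testing.assert_allclose(p[:10], h / 300.0, atol=1e-12)
        assert p[10] == 0.0

    def test_normalization_and_nonnegativity(self):
        rng = np.random.default_rng(5)
        cols = [rng.normal(size=500), rng.normal(size=500)]
        p = ash_joint(cols, [(-4, 4), (-4, 4)], [50, 50], [12, 12])
        assert abs(p.sum() - 1.0) < 1e-9
        assert (p >= 0).all()

    def test_independent_samples_near_product_form(self):
        rng = np.random.default_rng(9)
        cols = [rng.uniform(0, 1, 20000), rng.uniform(0, 1, 20000)]
        p = ash_joint(cols, [(0, 1), (0, 1)], [5, 5], [2, 2])
        outer = np.outer(p.sum(axis=1), p.sum(axis=0))
        assert np.abs(p - outer).max() < 0.01

    def test_constant_column_collapses_to_single_slot(self):
        x = np.full(100, 3.7)
        p = ash_joint([x], [(3.7, 3.7)], [10], [4])
        assert p[0] == 1.0 and p[1:].sum() == 0.0


# ---------------------------------------------------------------------- #
# mutual information
# ---------------------------------------------------------------------- #


class TestMutualInformation:
    def test_hand_worked_two_by_two_joint(self):
        p = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information(p) == pytest.approx(0.2781, abs=5e-5)

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_identity_channel_reaches_stimulus_entropy(self, k):
        p = np.eye(k) / k
        assert mutual_information(p) == pytest.approx(np.log2(k), abs=1e-12)
        assert mutual_information(p) / entropy(p.sum(axis=1)) == pytest.approx(1.0)

    def test_constant_response_carries_nothing(self):
        p = np.zeros((4, 3))
        p[:, 1] = 0.25
        assert mutual_information(p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_discrete_samples(self):
        rng = np.random.default_rng(21)
        rec = _discrete_recording(rng)
        tv = estimate_joint(rec, "a", time_index=2, bins=3, shifts=1)
        ours = mutual_information(tv.p[0])
        oracle = mi_oracle(rec.stimulus.tolist(), rec.trace("a")[:, 2].tolist())
        assert ours == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------- #
# specific information
# ---------------------------------------------------------------------- #


class TestSpecificInformation:
    def test_matches_enumeration_on_discrete_samples(self):
        rng = np.random.default_rng(33)
        rec = _discrete_recording(rng)
        tv = estimate_joint(rec, "a", time_index=1, bins=3, shifts=1)
        s_vals = rec.stimulus.tolist()
        r_vals = rec.trace("a")[:, 1].tolist()
        for s_slot, s_sym in ((0, 0.0), (1, 1.0), (2, 2.0)):
            ours = specific_information(tv.p[0], s_slot)
            assert ours == pytest.approx(si_oracle(s_vals, r_vals, s_sym), abs=1e-12)

    def test_independent_response_gives_zero_for_every_stimulus(self):
        ps = np.array([0.2, 0.3, 0.5])
        pr = np.array([0.6, 0.4])
        joint = np.outer(ps, pr)
        for i in range(3):
            assert specific_information(joint, i) == pytest.approx(0.0, abs=1e-12)

    def test_zero_probability_stimulus_is_an_error(self):
        joint = np.array([[0.5, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError):
            specific_information(joint, 1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_average_specific_information_is_mutual_information(self, seed):
        """Sum_s p(s) I(S=s;R) = I(S;R) on random joints (exact identity)."""
        rng = np.random.default_rng(seed)
        joint = rng.dirichlet(np.ones(12)).reshape(4, 3)
        ps = joint.sum(axis=1)
        si = specific_information_all(joint)
        avg = np.nansum(np.where(ps > 0, ps * si, 0.0))
        assert avg == pytest.approx(mutual_information(joint), abs=1e-9)

    def test_off_half_of_a_rectified_readout_is_one_bit(self):
        """A sensor reading max(s, 0) under symmetric uniform stimulus gives
        exactly one bit about every stimulus in its silent half (knowing the
        sensor is off rules out the positive half of the stimuli)."""
        bins = 50
        # analytic joint on the discretized stimulus: negative slots -> slot 0
        # of the response; positive slots -> distinct response slots
        p = np.zeros((bins, bins // 2 + 1))
        for i in range(bins):
            if i < bins // 2:
                p[i, 0] = 1.0 / bins
            else:
                p[i, i - bins // 2 + 1] = 1.0 / bins
        for i in range(bins // 2):
            assert specific_information(p, i) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------- #
# transfer entropy
# ---------------------------------------------------------------------- #


class TestTransferEntropy:
    def test_copy_channel_equals_source_entropy(self):
        """X_t = Y_{t-1} with an uninformative own history transfers the
        full (empirical) entropy of the source."""
        rng = np.random.default_rng(4)
        n = 600
        y_prev = rng.integers(0, 4, n).astype(float)
        traces = np.zeros((n, 2, 2))
        traces[:, 0, 0] = 0.0  # constant own history: conditioning is trivial
        traces[:, 1, 0] = y_prev  # X_t copies Y_{t-1}
        traces[:, 0, 1] = y_prev
        traces[:, 1, 1] = rng.integers(0, 4, n)
        rec = Recording(
            stimulus=rng.uniform(-1, 1, n),
            traces=traces,
            dt=0.01,
            variables=("x", "y"),
        )
        te = transfer_entropy(rec, "y", "x", 1, bins=4, shifts=1)
        h_y = entropy(np.bincount(y_prev.astype(int), minlength=4) / n)
        assert te == pytest.approx(h_y, abs=1e-9)

    def test_constant_source_transfers_nothing(self):
        rng = np.random.default_rng(8)
        n = 200
        traces = np.zeros((n, 3, 2))
        traces[:, :, 0] = rng.normal(size=(n, 3))
        traces[:, :, 1] = 1.0
        rec = Recording(
            stimulus=rng.uniform(-1, 1, n),
            traces=traces,
            dt=0.01,
            variables=("x", "y"),
        )
        assert transfer_entropy(rec, "y", "x", 2, bins=5, shifts=1) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_brute_force_conditional_mi(self):
        rng = np.random.default_rng(17)
        rec = _discrete_recording(rng, n_trials=300)
        for ti in (1, 2, 3):
            ours = transfer_entropy(rec, "a", "b", ti, bins=3, shifts=1)
            oracle = cmi_oracle(
                rec.trace("b")[:, ti].tolist(),
                rec.trace("a")[:, ti - 1].tolist(),
                rec.trace("b")[:, ti - 1].tolist(),
            )
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_needs_a_previous_timestep(self):
        rng = np.random.default_rng(2)
        rec = _discrete_recording(rng)
        with pytest.raises(ValueError):
            transfer_entropy(rec, "a", "b", 0)


# ---------------------------------------------------------------------- #
# time-resolved wrappers
# ---------------------------------------------------------------------- #


class TestProfiles:
    def test_unstimulated_variable_profile_is_zero(self):
        rng = np.random.default_rng(6)
        n = 400
        traces = np.zeros((n, 5, 2))
        traces[:, :, 0] = 0.5  # constant, stimulus-independent
        traces[:, :, 1] = rng.normal(size=(n, 1))  # trial-random, constant in t
        rec = Recording(
            stimulus=rng.uniform(-0.01, 0.01, n),
            traces=traces,
            dt=0.01,
            variables=("flat", "noise"),
            meta={"stim_lo": -0.01, "stim_hi": 0.01},
        )
        prof = mi_profile(rec, "flat", bins=20, shifts=4)
        np.testing.assert_allclose(prof.bits, 0.0, atol=1e-12)

    def test_normalized_profile_bounded_by_one(self):
        rng = np.random.default_rng(13)
        n = 500
        stim = rng.uniform(-0.01, 0.01, n)
        traces = np.repeat(stim, 3).reshape(n, 3, 1)  # perfect readout
        rec = Recording(
            stimulus=stim,
            traces=traces,
            dt=0.01,
            variables=("copy",),
            meta={"stim_lo": -0.01, "stim_hi": 0.01},
        )
        prof = mi_profile(rec, "copy", bins=50, shifts=12)
        assert (prof.normalized <= 1.0 + 1e-9).all()
        # high, but deflated below 1 by the cross-shift smoothing leakage of
        # the ASH estimator on deterministic readouts
        assert prof.normalized[0] > 0.7

    def test_constant_stimulus_is_rejected(self):
        rec = Recording(
            stimulus=np.full(10, 0.5),
            traces=np.zeros((10, 2, 1)),
            dt=0.01,
            variables=("x",),
        )
        with pytest.raises(ValueError, match="[Cc]onstant stimulus"):
            mi_profile(rec, "x")

    def test_te_profile_runs_and_is_nonnegative(self):
        rng = np.random.default_rng(19)
        rec = _discrete_recording(rng)
        prof = te_profile(rec, "a", "b", bins=3, shifts=2)
        assert prof.bits.shape == (3,)
        assert (prof.bits >= -1e-12).all()
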