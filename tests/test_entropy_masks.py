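"""Entropy computation and the anomaly/quality masks against loop oracles."""

import numpy as np
import pytest

from entroseg import entropy_masks as em
from entroseg.entropy_masks import InvalidConfigError, InvalidInputError

from conftest import oracle_entropy, oracle_masks, random_prob_map


class TestEntropy:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((0.5, 0.5), np.log(2.0)),
            ((1.0, 0.0), 0.0),
            ((0.8, 0.2), 0.50040),
        ],
    )
    def test_single_voxel_values(self, probs, expected):
        p = np.array(probs).reshape(-1, 1, 1, 1)
        assert em.compute_entropy(p)[0, 0, 0] == pytest.approx(expected, abs=1e-5)

    def test_matches_loop_oracle(self, rng):
        for c in (2, 3, 4):
            p = random_prob_map(rng, c)
            np.testing.assert_allclose(em.compute_entropy(p), oracle_entropy(p),
                                       atol=1e-10)

    def test_bounded_and_maximised_at_uniform(self, rng):
        for c in (2, 3, 4):
            p = random_prob_map(rng, c)
            e = em.compute_entropy(p)
            assert np.all(e >= 0) and np.all(e <= np.log(c) + 1e-12)
            uniform = np.full((c, 1, 1, 1), 1.0 / c)
            assert em.compute_entropy(uniform)[0, 0, 0] == pytest.approx(np.log(c))

    def test_permutation_invariant_over_classes(self, rng):
        p = random_prob_map(rng, 4)
        perm = rng.permutation(4)
        np.testing.assert_allclose(em.compute_entropy(p), em.compute_entropy(p[perm]),
                                   atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            em.compute_entropy(np.ones((1, 2, 2, 2)))

    def test_batched_input_supported(self, rng):
        p = np.stack([random_prob_map(rng, 3) for _ in range(2)])
        e = em.compute_entropy(p)
        assert e.shape == (2, 4, 4, 4)
        np.testing.assert_allclose(e[0], em.compute_entropy(p[0]))


def _random_instance(rng, c):
    pv = random_prob_map(rng, c)
    ph = random_prob_map(rng, c)
    gt = rng.integers(0, c, size=(4, 4, 4))
    ev, eh = em.compute_entropy(pv), em.compute_entropy(ph)
    yv, yh = em.hard_labels(pv), em.hard_labels(ph)
    return ev, eh, yv, yh, gt


class TestMasks:
    def test_all_masks_match_loop_oracle(self, rng):
        tau1, tau2, beta = 0.3, 0.05, 0.2
        for _ in range(60):
            for c in (2, 3, 4):
                ev, eh, yv, yh, gt = _random_instance(rng, c)
                ref = oracle_masks(ev, eh, yv, yh, gt, tau1, tau2, beta)
                m2, m3 = em.mask_entropy_mismatch(ev, eh, yv, yh, gt)
                got = dict(
                    m1=em.mask_consensus_error(yv, yh, gt),
                    m2=m2,
                    m3=m3,
                    m4=em.mask_entropy_divergence(ev, eh, tau1),
                    md_v=em.mask_entropy_difference(ev, eh, beta, tau2),
                    md_h=em.mask_entropy_difference(eh, ev, beta, tau2),
                    mh_v=em.mask_high_quality(ev, beta),
                )
                got["mex"] = em.combine_hard_region(got["m1"], got["m2"],
                                                    got["m3"], got["m4"])
                for name, ref_mask in ref.items():
                    np.testing.assert_array_equal(got[name], ref_mask, err_msg=name)

    def test_strict_comparisons_give_zero_on_ties(self):
        e = np.full((2, 2, 2), 0.3)
        # equal entropies: both mismatch masks empty
        y = np.zeros((2, 2, 2), np.int64)
        m2, m3 = em.mask_entropy_mismatch(e, e, y, 1 - y, y)
        assert not m2.any() and not m3.any()
        # |ΔE| exactly at threshold
        assert not em.mask_entropy_divergence(e, e + 0.3, tau1=0.3).any()
        # E exactly at beta, and E exactly 0
        assert not em.mask_high_quality(np.full((1, 1, 1), 0.2), beta=0.2).any()
        assert not em.mask_high_quality(np.zeros((1, 1, 1)), beta=0.2).any()
        # Md: E_self exactly beta fails the first conjunct
        assert not em.mask_entropy_difference(e - 0.1, e + 0.4, beta=0.2, tau2=0.05).any()

    def test_mismatch_masks_mutually_exclusive(self, rng):
        for _ in range(50):
            ev, eh, yv, yh, gt = _random_instance(rng, 3)
            m2, m3 = em.mask_entropy_mismatch(ev, eh, yv, yh, gt)
            assert not np.any(m2 & m3)

    def test_union_dominates_components(self, rng):
        masks = [rng.integers(0, 2, (4, 4, 4)).astype(np.uint8) for _ in range(4)]
        mex = em.combine_hard_region(*masks)
        for m in masks:
            assert np.all(mex >= m)
        assert not em.combine_hard_region(*[np.zeros((2, 2, 2), np.uint8)] * 4).any()

    def test_outputs_are_binary_and_shape_preserving(self, rng):
        ev, eh, yv, yh, gt = _random_instance(rng, 3)
        for mask in (em.mask_consensus_error(yv, yh, gt),
                     em.mask_entropy_divergence(ev, eh, 0.3),
                     em.mask_entropy_difference(ev, eh, 0.2, 0.05),
                     em.mask_high_quality(ev, 0.2)):
            assert mask.shape == gt.shape
            assert set(np.unique(mask)) <= {0, 1}

    def test_shape_mismatch_rejected(self):
        a, b = np.zeros((2, 2, 2), np.int64), np.zeros((3, 2, 2), np.int64)
        with pytest.raises(InvalidInputError):
            em.mask_consensus_error(a, a, b)

    @pytest.mark.parametrize("bad", [0.0, -0.1])
    def test_nonpositive_thresholds_rejected(self, bad):
        e = np.zeros((2, 2, 2))
        with pytest.raises(InvalidConfigError):
            em.mask_entropy_divergence(e, e, tau1=bad)
        with pytest.raises(InvalidConfigError):
            em.mask_entropy_difference(e, e, beta=bad, tau2=0.05)
        with pytest.raises(InvalidConfigError):
            em.mask_high_quality(e, beta=bad)

    def test_argmax_ties_take_lowest_class(self):
        p = np.full((3, 1, 1, 1), 1 / 3)
        assert em.hard_labels(p)[0, 0, 0] == 0


class TestProbabilityMapContract:
    def test_valid_map_accepted(self, rng):
        em.validate_probability_map(random_prob_map(rng, 3))

    def test_unnormalised_or_out_of_range_rejected(self, rng):
        p = random_prob_map(rng, 2)
        with pytest.raises(InvalidInputError):
            em.validate_probability_map(p * 2.0)
        bad = p.copy()
        bad[0, 0, 0, 0] = -0.2
        bad[1, 0, 0, 0] = 1.2
        with pytest.raises(InvalidInputError):
            em.validate_probability_map(bad)
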