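"""Random-library correction, masking, normalization, ratios, smoothing."""

import numpy as np
import pytest

from fourc import (
    FragmentCounts,
    FragmentStatus,
    NormalizedProfile,
    RandomLibraryTrack,
    correct_by_random_library,
    digest_sequence,
    log2_ratio,
    mask_viewpoint,
    normalize,
    running_mean,
    simulate_viewpoint,
)
from fourc.profiles import running_mean_masked


@pytest.fixture()
def toy_map():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    return digest_sequence(seq, "CATG", "GATC")


def make_profile(fmap, values, status=None):
    status = (
        np.full(fmap.n_fragments, FragmentStatus.OK, dtype=np.int8)
        if status is None
        else status
    )
    return NormalizedProfile(fragment_map=fmap, values=values, status=status)


class TestCorrection:
    def test_flat_in_flat_out(self, toy_map):
        n = toy_map.n_fragments
        raw = FragmentCounts(toy_map, np.full(n, 6.0))
        rnd = RandomLibraryTrack(toy_map, np.full(n, 2.0))
        prof = correct_by_random_library(raw, rnd)
        assert np.allclose(prof.values[prof.ok], 3.0)
        assert prof.ok.all()

    def test_blacklisted_fragment_becomes_aberrant(self, toy_map):
        n = toy_map.n_fragments
        raw = FragmentCounts(toy_map, np.full(n, 6.0))
        rnd = RandomLibraryTrack(toy_map, np.full(n, 2.0))
        s, e = int(toy_map.starts[5]), int(toy_map.ends[5])
        prof = correct_by_random_library(raw, rnd, blacklist=[(toy_map.chrom, s, e)])
        assert prof.status[5] == FragmentStatus.ABERRANT
        norm = normalize(prof)
        # aberrant fragment carries no signal in downstream sums
        assert norm.values[5] == 0.0
        assert np.isclose(norm.ok_total, 1e6, rtol=1e-9)

    def test_zero_random_fragment_is_uncovered(self, toy_map):
        n = toy_map.n_fragments
        rnd_values = np.full(n, 2.0)
        rnd_values[7] = 0.0
        raw = FragmentCounts(toy_map, np.full(n, 6.0))
        prof = correct_by_random_library(raw, RandomLibraryTrack(toy_map, rnd_values))
        assert prof.status[7] == FragmentStatus.UNCOVERED

    def test_all_zero_random_track_rejected(self, toy_map):
        n = toy_map.n_fragments
        raw = FragmentCounts(toy_map, np.full(n, 6.0))
        with pytest.raises(ValueError, match="entirely zero"):
            correct_by_random_library(raw, RandomLibraryTrack(toy_map, np.zeros(n)))

    def test_coverage_interval_restricts_correction(self, toy_map):
        n = toy_map.n_fragments
        raw = FragmentCounts(toy_map, np.full(n, 6.0))
        lo = int(toy_map.starts[2])
        hi = int(toy_map.ends[6])
        rnd = RandomLibraryTrack(toy_map, np.full(n, 2.0), coverage_interval=(lo, hi))
        prof = correct_by_random_library(raw, rnd)
        assert prof.ok[2:7].all()
        assert (prof.status[:2] == FragmentStatus.UNCOVERED).all()
        assert (prof.status[7:] == FragmentStatus.UNCOVERED).all()


class TestMaskViewpoint:
    def test_halfwidth_zero_masks_only_bait(self, toy_map):
        prof = make_profile(toy_map, np.ones(toy_map.n_fragments))
        out = mask_viewpoint(prof, bait_fragment=4, halfwidth_fragments=0)
        assert out.status[4] == FragmentStatus.VIEWPOINT
        assert out.ok.sum() == toy_map.n_fragments - 1

    def test_halfwidth_clipped_at_edge(self, toy_map):
        prof = make_profile(toy_map, np.ones(toy_map.n_fragments))
        out = mask_viewpoint(prof, bait_fragment=0, halfwidth_fragments=2)
        assert (out.status[:3] == FragmentStatus.VIEWPOINT).all()
        assert out.ok[3]

    def test_negative_halfwidth_rejected(self, toy_map):
        prof = make_profile(toy_map, np.ones(toy_map.n_fragments))
        with pytest.raises(ValueError):
            mask_viewpoint(prof, bait_fragment=0, halfwidth_fragments=-1)

    def test_masked_bait_leaves_normalization_sum(self, toy_map):
        values = np.ones(toy_map.n_fragments)
        values[10] = 1000.0  # high-signal bait
        prof = make_profile(toy_map, values)
        before = normalize(prof)
        after = normalize(mask_viewpoint(prof, bait_fragment=10, halfwidth_fragments=1))
        # the constant is restored to 1e6 over the remaining ok fragments
        assert np.isclose(before.ok_total, 1e6, rtol=1e-9)
        assert np.isclose(after.ok_total, 1e6, rtol=1e-9)
        assert after.values[10] == 0.0


class TestNormalize:
    def test_single_ok_fragment(self, toy_map):
        values = np.zeros(toy_map.n_fragments)
        values[0] = 3.0
        status = np.full(toy_map.n_fragments, FragmentStatus.EXCLUDED, dtype=np.int8)
        status[0] = FragmentStatus.OK
        prof = make_profile(toy_map, values, status)
        assert normalize(prof).values[0] == 1e6

    def test_scale_invariance(self, toy_map):
        rng = np.random.default_rng(1)
        values = rng.exponential(1.0, toy_map.n_fragments)
        a = normalize(make_profile(toy_map, values))
        b = normalize(make_profile(toy_map, 37.5 * values))
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_idempotence(self, toy_map):
        rng = np.random.default_rng(2)
        prof = normalize(make_profile(toy_map, rng.exponential(1.0, toy_map.n_fragments)))
        again = normalize(prof)
        assert np.allclose(prof.values, again.values, rtol=1e-12)

    def test_sum_invariant_on_simulated_profile(self, small_model, small_map):
        raw, rnd, _ = simulate_viewpoint(small_model, small_map, seed=5)
        prof = normalize(correct_by_random_library(raw, rnd))
        assert np.isclose(prof.ok_total, 1e6, rtol=1e-9)

    def test_all_zero_signal_rejected(self, toy_map):
        with pytest.raises(ValueError, match="no positive OK signal"):
            normalize(make_profile(toy_map, np.zeros(toy_map.n_fragments)))


class TestLog2Ratio:
    def test_identity_gives_zero(self, toy_map):
        rng = np.random.default_rng(4)
        prof = normalize(make_profile(toy_map, rng.exponential(1.0, toy_map.n_fragments)))
        ratio = log2_ratio(prof, prof)
        assert np.allclose(ratio.values[ratio.ok], 0.0)

    def test_antisymmetry_exact(self, toy_map):
        rng = np.random.default_rng(5)
        a = normalize(make_profile(toy_map, rng.exponential(1.0, toy_map.n_fragments)))
        b = normalize(make_profile(toy_map, rng.exponential(1.0, toy_map.n_fragments)))
        ab = log2_ratio(a, b)
        ba = log2_ratio(b, a)
        assert np.array_equal(ab.values[ab.ok], -ba.values[ba.ok])

    def test_doubling_approaches_one_as_pseudocount_vanishes(self, toy_map):
        values = np.full(toy_map.n_fragments, 8.0)
        a = make_profile(toy_map, 2 * values)
        b = make_profile(toy_map, values)
        r_large = log2_ratio(a, b, pseudocount=8.0).values[0]
        r_small = log2_ratio(a, b, pseudocount=1e-9).values[0]
        assert r_large < r_small
        assert np.isclose(r_small, 1.0, atol=1e-8)

    def test_zero_pseudocount_with_zeros_rejected(self, toy_map):
        values = np.zeros(toy_map.n_fragments)
        values[0] = 1.0
        a = make_profile(toy_map, values)
        with pytest.raises(ValueError, match="pseudocount"):
            log2_ratio(a, a, pseudocount=0.0)


class TestRunningMean:
    def test_window_one_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(running_mean(x, 1), x)

    def test_constant_track_unchanged_including_edges(self):
        x = np.full(50, 3.5)
        assert np.allclose(running_mean(x, 11), 3.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            running_mean(np.arange(10.0), 4)

    def test_interior_matches_slice_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(1.0, 200)
        sm = running_mean(x, 11)
        for i in range(5, 195):
            assert np.isclose(sm[i], x[i - 5 : i + 6].mean(), rtol=1e-12)

    def test_masked_fragments_skipped_not_zero_filled(self):
        x = np.array([1.0, 100.0, 1.0, 1.0, 1.0])
        ok = np.array([True, False, True, True, True])
        sm = running_mean_masked(x, ok, 3)
        # the masked 100.0 never enters any window
        assert np.isnan(sm[1])
        assert sm[0] == 1.0 and sm[2] == 1.0

    def test_mean_preserved_within_one_percent(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(1.0, 400)
        sm = running_mean(x, 11)
        assert abs(sm.mean() - x.mean()) / x.mean() < 0.01

    def test_window_larger_than_ok_support_rejected(self, toy_map):
        prof = make_profile(toy_map, np.ones(toy_map.n_fragments))
        with pytest.raises(ValueError):
            running_mean(prof, 2 * toy_map.n_fragments + 1)


def test_pipeline_invariant_to_raw_scaling(toy_map):
    rng = np.random.default_rng(8)
    n = toy_map.n_fragments
    counts = rng.poisson(50.0, n).astype(float)
    rnd = RandomLibraryTrack(toy_map, rng.poisson(100.0, n) + 1.0)
    a = normalize(correct_by_random_library(FragmentCounts(toy_map, counts), rnd))
    b = normalize(correct_by_random_library(FragmentCounts(toy_map, 13.0 * counts), rnd))
    assert np.allclose(a.values, b.values, rtol=1e-12)
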