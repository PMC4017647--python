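"""Desert tropism, signal partition and viewpoint clustering."""

import numpy as np
import pytest

from fourc import (
    DesertAnnotation,
    FragmentStatus,
    NormalizedProfile,
    cluster_viewpoints,
    cumulative_tropism,
    desert_annotation,
    signal_partition,
    tropism,
)


@pytest.fixture(scope="module")
def setup(small_model_module):
    model, fmap = small_model_module
    return model, fmap, desert_annotation(model, fmap)


@pytest.fixture(scope="module")
def small_model_module():
    from fourc import SimulationModel, simulate_map

    model = SimulationModel(
        n_centromeric=40,
        n_cluster=30,
        n_telomeric=40,
        boundary=15,
        mean_fragment_length=300,
        min_fragment_length=100,
    )
    fmap, _ = simulate_map(model, seed=1)
    return model, fmap


def profile_from(fmap, values):
    status = np.full(fmap.n_fragments, FragmentStatus.OK, dtype=np.int8)
    return NormalizedProfile(fragment_map=fmap, values=np.asarray(values, float), status=status)


class TestTropism:
    def test_all_centromeric_signal(self, setup):
        model, fmap, ann = setup
        values = np.zeros(fmap.n_fragments)
        values[: model.n_centromeric] = 1.0
        t = tropism(profile_from(fmap, values), ann, window=None)
        assert (t.p_cen, t.p_tel) == (1.0, 0.0)

    def test_uniform_signal_matches_fragment_counting(self, setup):
        model, fmap, ann = setup
        t = tropism(profile_from(fmap, np.ones(fmap.n_fragments)), ann, window=None)
        n_cen, n_tel = model.n_centromeric, model.n_telomeric
        assert np.isclose(t.p_cen, n_cen / (n_cen + n_tel), rtol=1e-12)

    def test_invariant_to_global_rescaling(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(20)
        values = rng.exponential(1.0, fmap.n_fragments)
        t1 = tropism(profile_from(fmap, values), ann)
        t2 = tropism(profile_from(fmap, 1000.0 * values), ann)
        assert np.isclose(t1.p_cen, t2.p_cen, rtol=1e-12)

    def test_smoothing_window_changes_tropism_little(self, setup):
        from fourc import contact_mass

        model, fmap, ann = setup
        values = contact_mass(model, model.default_bait())
        prof = profile_from(fmap, values)
        raw = tropism(prof, ann, window=None)
        for window in (5, 11):
            sm = tropism(prof, ann, window=window)
            assert abs(sm.p_cen - raw.p_cen) <= 0.01

    def test_zero_desert_signal_rejected(self, setup):
        model, fmap, ann = setup
        values = np.zeros(fmap.n_fragments)
        c0, c1 = model.cluster_range
        values[c0:c1] = 1.0
        with pytest.raises(ValueError, match="desert"):
            tropism(profile_from(fmap, values), ann, window=None)

    def test_cumulative_mode_sums_to_one_with_cluster(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(22)
        t = cumulative_tropism(
            profile_from(fmap, rng.exponential(1.0, fmap.n_fragments)), ann, window=None
        )
        assert np.isclose(t.p_cen + t.p_tel + t.p_cluster, 1.0, atol=1e-12)


class TestSignalPartition:
    def test_single_category_gets_everything(self, setup):
        model, fmap, ann = setup
        fractions = signal_partition(
            profile_from(fmap, np.ones(fmap.n_fragments)), {"all": fmap.span}
        )
        assert fractions["all"] == 1.0

    def test_equal_split_over_equal_categories(self, setup):
        model, fmap, ann = setup
        n = fmap.n_fragments
        half_end = int(fmap.ends[n // 2 - 1])
        values = np.zeros(n)
        values[: n // 2] = 2.0
        values[n // 2 :] = 2.0
        fractions = signal_partition(
            profile_from(fmap, values),
            {"left": (0, half_end), "right": (half_end, fmap.span[1])},
        )
        left_count = n // 2
        assert np.isclose(fractions["left"], left_count / n, rtol=1e-12)

    def test_fractions_match_accumulation_oracle(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(23)
        values = rng.exponential(1.0, fmap.n_fragments)
        cats = {
            "cen": ann.centromeric,
            "cluster": ann.cluster,
            "tel": ann.telomeric,
        }
        fractions = signal_partition(profile_from(fmap, values), cats)
        assert np.isclose(fractions.sum(), 1.0, atol=1e-12)
        # fragment-by-fragment accumulation oracle
        total = values.sum()
        for name, (lo, hi) in cats.items():
            expected = sum(
                values[f]
                for f in range(fmap.n_fragments)
                if fmap.starts[f] < hi and fmap.ends[f] > lo
            )
            assert np.isclose(fractions[name], expected / total, atol=1e-12)

    def test_overlapping_categories_rejected(self, setup):
        model, fmap, ann = setup
        prof = profile_from(fmap, np.ones(fmap.n_fragments))
        with pytest.raises(ValueError, match="overlap"):
            signal_partition(prof, {"a": (0, 2000), "b": (1000, 4000)})


class TestClusterViewpoints:
    def test_monotone_transforms_merge_first_at_zero_height(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(24)
        base = rng.exponential(1.0, fmap.n_fragments)
        other = rng.exponential(1.0, fmap.n_fragments)
        profiles = {
            "a": profile_from(fmap, base),
            "a_scaled": profile_from(fmap, base**2),  # monotone transform
            "c": profile_from(fmap, other),
        }
        dend = cluster_viewpoints(profiles, ann, window=None)
        assert dend.correlation.loc["a", "a_scaled"] == 1.0
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_duplicates_have_exact_unit_correlation(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(25)
        base = rng.exponential(1.0, fmap.n_fragments)
        profiles = {
            "x": profile_from(fmap, base),
            "y": profile_from(fmap, base.copy()),
            "z": profile_from(fmap, rng.exponential(1.0, fmap.n_fragments)),
        }
        dend = cluster_viewpoints(profiles, ann)
        assert dend.correlation.loc["x", "y"] == 1.0
        assert np.allclose(np.diag(dend.correlation), 1.0)

    def test_fewer_than_three_rejected(self, setup):
        model, fmap, ann = setup
        prof = profile_from(fmap, np.ones(fmap.n_fragments))
        with pytest.raises(ValueError, match="at least 3"):
            cluster_viewpoints({"a": prof, "b": prof}, ann)

    def test_merge_heights_invariant_to_input_order(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(26)
        vals = {k: rng.exponential(1.0, fmap.n_fragments) for k in "abcd"}
        profiles = {k: profile_from(fmap, v) for k, v in vals.items()}
        reordered = {k: profiles[k] for k in ["d", "b", "a", "c"]}
        h1 = cluster_viewpoints(profiles, ann).merge_heights()
        h2 = cluster_viewpoints(reordered, ann).merge_heights()
        assert np.allclose(np.sort(h1), np.sort(h2), rtol=1e-12)

    def test_newick_has_all_leaves(self, setup):
        model, fmap, ann = setup
        rng = np.random.default_rng(27)
        profiles = {
            k: profile_from(fmap, rng.exponential(1.0, fmap.n_fragments))
            for k in ("vp1", "vp2", "vp3")
        }
        newick = cluster_viewpoints(profiles, ann).to_newick()
        assert newick.endswith(";")
        for name in profiles:
            assert name in newick

    def test_tropic_groups_pair_like_with_like(self, setup):
        import dataclasses

        from fourc import (
            correct_by_random_library,
            normalize,
            simulate_biases,
            simulate_viewpoint,
        )

        model, fmap, ann = setup
        bias = simulate_biases(model, seed=9)
        profiles = {}
        specs = [("cen1", 0.15, 5), ("cen2", 0.15, 9), ("tel1", 0.85, 5), ("tel2", 0.85, 9)]
        for i, (name, tau, offset) in enumerate(specs):
            m = dataclasses.replace(model, tau=tau)
            raw, rnd, _ = simulate_viewpoint(
                m, fmap, bait_fragment=model.cluster_range[0] + offset,
                seed=9 + i, biases=bias,
            )
            profiles[name] = normalize(correct_by_random_library(raw, rnd))
        dend = cluster_viewpoints(profiles, ann)
        # the first two merges pair like-tropism viewpoints
        merged = [
            {int(dend.linkage[k][0]), int(dend.linkage[k][1])} for k in range(2)
        ]
        assert {0, 1} in merged and {2, 3} in merged
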