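"""Habitat mapping: median 2-step, Ward 1-step, summaries and brain regions."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from petmr_habitats import (
    BrainSpec,
    Grid,
    HabitatSphere,
    ImageVolume,
    PhantomSpec,
    RoiMask,
    brain_physiologic_regions,
    compute_adc_loglinear,
    generate_brain_sequences,
    generate_phantom,
    habitat_summary,
    one_step_clusters,
    resample_adc,
    two_step_habitats,
)
from petmr_habitats.adc import AdcVolume

from conftest import flat_mask, line_volume


def line_adc(values):
    vol = line_volume(values, "ADC")
    return AdcVolume(vol, np.ones(vol.data.shape, dtype=bool))


class TestTwoStep:
    def test_hand_classification_oracle(self):
        # medians 2.5 / 2.5: anti-monotone metrics -> LH, LH, HL, HL
        hmap = two_step_habitats(
            line_volume([1, 2, 3, 4]), line_adc([4, 3, 2, 1]), flat_mask(4), min_voxels=4
        )
        classes = [hmap.legend[l] for l in hmap.labels[0, 0]]
        assert classes == ["LH", "LH", "HL", "HL"]

    def test_comonotone_metrics_split_hh_ll(self):
        n = 6
        suv = line_volume(np.arange(2 * n, dtype=float))
        adc = line_adc(np.arange(2 * n, dtype=float) * 0.1)
        hmap = two_step_habitats(suv, adc, flat_mask(2 * n))
        classes = [hmap.legend[l] for l in hmap.labels[0, 0]]
        assert classes == ["LL"] * n + ["HH"] * n

    def test_partition_counts_sum_to_lesion(self):
        rng = np.random.default_rng(3)
        n = 101
        hmap = two_step_habitats(
            line_volume(rng.normal(3, 1, n)), line_adc(rng.normal(1.3, 0.3, n)), flat_mask(n)
        )
        labeled = hmap.labels[0, 0]
        assert (labeled > 0).sum() == n
        assert hmap.summary.voxel_count.sum() == n
        assert hmap.summary.volume_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_median_split_balance_even_distinct(self):
        rng = np.random.default_rng(4)
        n = 50
        suv = rng.permutation(np.arange(n, dtype=float))
        hmap = two_step_habitats(line_volume(suv), line_adc(rng.permutation(n).astype(float)), flat_mask(n))
        high_suv = np.isin(hmap.labels[0, 0], [1, 2])  # HH or HL
        assert high_suv.sum() == n // 2

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            two_step_habitats(line_volume([1] * 4), line_adc([1] * 4), flat_mask(4))

    def test_constant_metric_all_low_with_warning(self):
        with pytest.warns(UserWarning, match="constant SUV"):
            hmap = two_step_habitats(
                line_volume([2.0] * 8), line_adc(np.arange(8.0)), flat_mask(8)
            )
        assert set(hmap.legend[l] for l in hmap.labels[0, 0]) == {"LH", "LL"}

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        n = 64
        suv_vals = rng.normal(3, 1, n)
        adc_vals = rng.normal(1.4, 0.4, n)
        a = two_step_habitats(line_volume(suv_vals), line_adc(adc_vals), flat_mask(n))
        b = two_step_habitats(line_volume(np.exp(suv_vals)), line_adc(adc_vals), flat_mask(n))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_invalid_adc_voxels_reported(self):
        valid = np.ones((1, 1, 10), bool)
        valid[0, 0, :2] = False
        adc = AdcVolume(line_volume(np.arange(10.0), "ADC"), valid)
        hmap = two_step_habitats(line_volume(np.arange(10.0)), adc, flat_mask(10))
        assert hmap.invalid_fraction == pytest.approx(0.2)
        assert (hmap.labels[0, 0, :2] == 0).all()


class TestOneStep:
    def test_perfectly_separable_two_clusters(self):
        rng = np.random.default_rng(0)
        n = 60
        suv = np.r_[rng.normal(1, 0.05, n // 2), rng.normal(10, 0.05, n // 2)]
        adc = np.r_[rng.normal(2, 0.02, n // 2), rng.normal(0.5, 0.02, n // 2)]
        res = one_step_clusters(line_volume(suv), line_adc(adc), flat_mask(n), k=2)
        truth = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        assert adjusted_rand_score(truth, res.habitat_map.labels[0, 0]) == 1.0
        # cluster 1 is the high-SUV habitat by the renumbering rule
        assert res.centroids_native[0, 0] > res.centroids_native[1, 0]

    def test_k1_centroid_is_lesion_mean(self):
        rng = np.random.default_rng(1)
        suv = rng.normal(3, 1, 40)
        adc = rng.normal(1.3, 0.2, 40)
        res = one_step_clusters(line_volume(suv), line_adc(adc), flat_mask(40), k=1)
        assert res.centroids_native[0, 0] == pytest.approx(suv.mean())
        assert res.centroids_native[0, 1] == pytest.approx(adc.mean())
        assert (res.habitat_map.labels[0, 0] == 1).all()

    def test_k_exceeding_voxels_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            one_step_clusters(line_volume([1, 2]), line_adc([1, 2]), flat_mask(2), k=3)

    def test_zero_variance_feature_warns_and_proceeds(self):
        suv = np.r_[np.full(10, 1.0), np.full(10, 5.0)]
        with pytest.warns(UserWarning, match="zero-variance ADC"):
            res = one_step_clusters(line_volume(suv), line_adc([1.0] * 20), flat_mask(20), k=2)
        assert adjusted_rand_score(suv, res.habitat_map.labels[0, 0]) == 1.0

    def test_planted_habitats_recovered(self):
        """3 nested habitats, 5-SD per-feature separation: ARI >= 0.95 vs truth."""
        c = (48.0,) * 3
        r = 14.2
        spec = PhantomSpec(
            pet_downsample=1,
            habitats=(
                HabitatSphere("h1", c, r, 2.0, 1.7, suv_noise_sd=0.4, dwi_noise_sd=13.0),
                HabitatSphere("h2", c, r * (2 / 3) ** (1 / 3), 4.0, 1.2, 0.4, 13.0),
                HabitatSphere("h3", c, r * (1 / 3) ** (1 / 3), 6.0, 0.7, 0.4, 13.0),
            ),
            seed=123,
        )
        p = generate_phantom(spec)
        adc = compute_adc_loglinear(p.dwi)
        res = one_step_clusters(p.suv, adc, p.lesion_mask, k=3)
        inside = p.lesion_mask.data
        ari = adjusted_rand_score(p.truth.labels[inside], res.habitat_map.labels[inside])
        assert ari >= 0.95

    def test_label_stability_by_descending_suv(self):
        rng = np.random.default_rng(2)
        suv = np.r_[rng.normal(8, 0.1, 20), rng.normal(4, 0.1, 20), rng.normal(1, 0.1, 20)]
        adc = rng.normal(1.2, 0.05, 60)
        res = one_step_clusters(line_volume(suv), line_adc(adc), flat_mask(60), k=3)
        means = [suv[res.habitat_map.labels[0, 0] == c].mean() for c in (1, 2, 3)]
        assert means[0] > means[1] > means[2]


class TestSummary:
    def test_single_habitat_equals_whole_lesion(self):
        rng = np.random.default_rng(6)
        suv = rng.normal(3, 1, 30)
        adc = rng.normal(1.4, 0.3, 30)
        res = one_step_clusters(line_volume(suv), line_adc(adc), flat_mask(30), k=1)
        row = res.habitat_map.summary.iloc[0]
        assert row.volume_fraction == 1.0
        assert row.mean_suv == pytest.approx(suv.mean())

    def test_fraction_count_oracle(self):
        g = Grid((1, 1, 100), (1.0, 1.0, 1.0))
        labels = np.r_[np.ones(30), np.full(70, 2.0)].reshape(1, 1, 100).astype(int)
        from petmr_habitats.habitats import HabitatMap

        hmap = HabitatMap(labels, g, {1: "a", 2: "b"})
        summary = habitat_summary(hmap, line_volume(np.arange(100.0)), line_adc(np.ones(100)))
        assert summary.volume_fraction.tolist() == [0.30, 0.70]

    def test_weighted_means_recombine_to_whole_lesion(self):
        rng = np.random.default_rng(7)
        n = 80
        suv = rng.normal(3, 1, n)
        adc = rng.normal(1.4, 0.3, n)
        hmap = two_step_habitats(line_volume(suv), line_adc(adc), flat_mask(n))
        s = hmap.summary
        recombined = (s.volume_fraction * s.mean_suv).sum()
        assert recombined == pytest.approx(suv.mean(), abs=1e-9)
        assert (s.volume_fraction * s.mean_adc).sum() == pytest.approx(adc.mean(), abs=1e-9)


class TestBrainRegions:
    def test_no_enhancement_gives_empty_core(self):
        bp = generate_brain_sequences(BrainSpec(enhancement_contrast=0.0))
        regions = brain_physiologic_regions(bp.t1pre, bp.t1post, bp.t2flair, bp.adc, bp.context)
        assert regions.core.sum() == 0

    def test_truth_recovery_on_nested_spheres(self):
        bp = generate_brain_sequences(BrainSpec(seed=8))
        regions = brain_physiologic_regions(bp.t1pre, bp.t1post, bp.t2flair, bp.adc, bp.context)
        np.testing.assert_array_equal(regions.core, bp.truth_core.data)
        np.testing.assert_array_equal(regions.vasogenic_edema, bp.truth_vasogenic.data)
        np.testing.assert_array_equal(regions.restricted_diffusion, bp.truth_restricted.data)

    def test_truth_recovery_with_noise_within_voxelization_error(self):
        bp = generate_brain_sequences(BrainSpec(noise_sd=2.0, adc_noise_sd=0.05, seed=9))
        regions = brain_physiologic_regions(bp.t1pre, bp.t1post, bp.t2flair, bp.adc, bp.context)
        for rec, truth in (
            (regions.core, bp.truth_core.data),
            (regions.restricted_diffusion, bp.truth_restricted.data),
        ):
            mismatch = (rec ^ truth).sum() / truth.sum()
            assert mismatch < 0.05

    def test_partition_disjoint_and_complete(self):
        bp = generate_brain_sequences(BrainSpec(seed=10))
        r = brain_physiologic_regions(bp.t1pre, bp.t1post, bp.t2flair, bp.adc, bp.context)
        parts = [r.core, r.vasogenic_edema, r.restricted_diffusion, r.residual]
        total = np.zeros_like(bp.context.data, dtype=int)
        for p in parts:
            total += p.astype(int)
        assert np.array_equal(total > 0, bp.context.data)
        assert total.max() == 1  # pairwise disjoint
        assert np.all(bp.context.data[r.restricted_diffusion])

    def test_missing_sequence_named_in_error(self):
        bp = generate_brain_sequences(BrainSpec())
        with pytest.raises(ValueError, match="t2flair"):
            brain_physiologic_regions(bp.t1pre, bp.t1post, None, bp.adc, bp.context)
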