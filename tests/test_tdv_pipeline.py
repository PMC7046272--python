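"""Tumour-burden segmentation chain: stages, composition, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdvpipe.dwi_models import computed_dwi, fit_adc
from tdvpipe.synthdata import (Lesion, PhantomSpec, diffuse_spec_for_volume,
                               generate_phantom)
from tdvpipe.tdv_pipeline import (DEFAULT_LOWER_THRESHOLDS, PipelineStageError,
                                  SegmentationConfig, apply_exclusions,
                                  background_mask, compute_tdv,
                                  filter_adc_band, histogram_features,
                                  normalize_intensity, otsu_threshold,
                                  segment_study, threshold_sweep)


def otsu_oracle(values, bins=256):
    """Exhaustive search over candidate bin edges, class moments computed
    directly from the data at each edge; returns (edge, partition)."""
    v = np.asarray(values, float).ravel()
    edges = np.linspace(v.min(), v.max(), bins + 1)[1:-1]
    best = (-np.inf, None, None)
    for e in edges:
        lo = v[v <= e]
        hi = v[v > e]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / v.size
        var_b = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if var_b > best[0]:
            best = (var_b, e, v <= e)
    return best


class TestBackgroundMask:
    def test_all_zero_volume_empty(self):
        assert not background_mask(np.zeros((4, 4, 4)), 97.0).any()

    def test_two_level_volume(self):
        vol = np.zeros((2, 2, 2))
        vol[0] = 50.0
        vol[1] = 150.0
        # already spans 0..150 -> normalized 150 -> 255, 50 -> 85
        mask = background_mask(vol, 97.0)
        assert mask[1].all() and not mask[0].any()

    def test_matches_elementwise_oracle(self, rng):
        vol = rng.uniform(0, 1000, (8, 8, 8))
        mask = background_mask(vol, 97.0)
        norm = (vol - vol.min()) / (vol.max() - vol.min()) * 255.0
        np.testing.assert_array_equal(mask, norm > 97.0)


class TestOtsu:
    def test_two_delta_clusters_split_exactly(self):
        v = np.array([0.0] * 100 + [255.0] * 100)
        level = otsu_threshold(v)
        assert (v[v <= level] == 0).all() and (v[v > level] == 255).all()

    def test_two_gaussian_clusters_separated(self, rng):
        # the between-class variance of two balanced clusters is nearly
        # flat across the gap; the argmax (like skimage's) sits near the
        # upper edge of the lower cluster, and the induced partition must
        # split the clusters almost perfectly and match exhaustive search
        v = np.concatenate([rng.normal(50, 5, 500), rng.normal(200, 5, 500)])
        level = otsu_threshold(v)
        _, oracle_level, part = otsu_oracle(v)
        np.testing.assert_array_equal(v <= level, part)
        low, high = v[:500], v[500:]
        assert np.mean(low <= level) > 0.99
        assert np.mean(high > level) == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(10, 3.0))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:
            v = rng.uniform(0, 255, 200)
        elif kind == 1:
            v = np.concatenate([rng.normal(60, 20, 150),
                                rng.normal(190, 15, 80)])
        else:
            v = rng.integers(0, 12, 300).astype(float)
        if np.ptp(v) == 0:
            return
        level = otsu_threshold(v)
        var_best, _, part = otsu_oracle(v)
        # the chosen level induces the oracle's optimal partition
        np.testing.assert_array_equal(v <= level, part)


class TestMaskStages:
    def test_exclusion_covers_everything(self):
        m = np.ones((3, 3, 3), bool)
        assert not apply_exclusions(m, m).any()

    def test_empty_exclusion_is_identity(self, rng):
        m = rng.uniform(size=(3, 3, 3)) > 0.5
        np.testing.assert_array_equal(
            apply_exclusions(m, np.zeros_like(m)), m)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_exclusions(np.ones((3, 3, 3), bool), np.ones((2, 3, 3), bool))

    def test_band_keeps_lesions_drops_organs(self):
        mask = np.ones((2, 2, 1), bool)
        adc = np.array([[[1.0e-3], [2.5e-3]], [[0.5e-3], [np.nan]]])
        out = filter_adc_band(mask, adc, 0.55e-3, 2.0e-3)
        assert out[0, 0, 0]          # in band
        assert not out[0, 1, 0]      # shine-through, above upper cut
        assert not out[1, 0, 0]      # below lower cut
        assert not out[1, 1, 0]      # invalid ADC
        # boundary semantics: strict lower, inclusive upper
        assert filter_adc_band(mask, np.full((2, 2, 1), 2.0e-3),
                               0.55e-3, 2.0e-3).all()
        assert not filter_adc_band(mask, np.full((2, 2, 1), 0.55e-3),
                                   0.55e-3, 2.0e-3).any()

    def test_band_matches_elementwise_oracle(self, rng):
        mask = rng.uniform(size=(6, 6, 6)) > 0.3
        adc = rng.uniform(0, 3e-3, (6, 6, 6))
        out = filter_adc_band(mask, adc, 0.55e-3, 2.0e-3)
        oracle = mask & (adc > 0.55e-3) & (adc <= 2.0e-3)
        np.testing.assert_array_equal(out, oracle)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            filter_adc_band(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2)),
                            2.0e-3, 0.55e-3)


class TestTdvAndFeatures:
    def test_empty_mask_zero_ml(self):
        assert compute_tdv(np.zeros((4, 4, 4), bool), (2, 2, 2)) == 0.0

    def test_thousand_voxels_at_2mm_is_8ml(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        assert compute_tdv(mask, (2.0, 2.0, 2.0)) == pytest.approx(8.0)

    def test_additive_over_disjoint_masks(self, rng):
        a = rng.uniform(size=(5, 5, 5)) > 0.6
        b = ~a & (rng.uniform(size=(5, 5, 5)) > 0.6)
        sp = (1.5, 2.0, 2.5)
        assert compute_tdv(a | b, sp) == pytest.approx(
            compute_tdv(a, sp) + compute_tdv(b, sp))

    def test_hand_computed_symmetric_sample(self):
        feats = histogram_features(np.array([1.0, 2.0, 3.0]) * 1e-3)
        assert feats.mean == pytest.approx(2.0e-3)
        assert feats.p25 == pytest.approx(1.5e-3)
        assert feats.p75 == pytest.approx(2.5e-3)
        # n < 4: shape moments flagged
        assert not feats.moments_defined

    def test_symmetric_four_sample_skewness_zero(self):
        feats = histogram_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert feats.moments_defined
        assert feats.skewness == pytest.approx(0.0, abs=1e-12)

    def test_constant_values_flagged(self):
        feats = histogram_features(np.full(10, 1.0e-3))
        assert not feats.moments_defined
        assert np.isnan(feats.skewness) and np.isnan(feats.kurtosis)

    def test_gaussian_limit_zero_skew_and_excess_kurtosis(self, rng):
        v = rng.normal(1.0, 0.1, 200_000)
        feats = histogram_features(v)
        assert feats.skewness == pytest.approx(0.0, abs=0.03)
        assert feats.kurtosis == pytest.approx(0.0, abs=0.06)


class TestSegmentStudy:
    def test_combined_phantom_recovered_exactly(self, combined_study):
        res = segment_study(combined_study)
        truth = combined_study.truth_lesion_mask
        np.testing.assert_array_equal(res.disease_mask, truth)
        assert res.tdv_ml == pytest.approx(combined_study.truth_tdv_ml)
        # no excluded voxels survive
        assert not (res.disease_mask
                    & combined_study.truth_exclusion_mask).any()

    def test_normal_phantom_yields_zero_tdv(self, normal_study):
        assert segment_study(normal_study).tdv_ml == 0.0

    def test_equals_manual_stage_composition(self, combined_study):
        """segment_study is exactly the composition of its public stages."""
        cfg = SegmentationConfig()
        series = combined_study.dwi
        cdwi = computed_dwi(series, cfg.computed_b)
        adc = fit_adc(series)
        norm = normalize_intensity(cdwi, cfg.intensity_scale)
        bg = norm > cfg.background_threshold
        level = otsu_threshold(norm[bg], cfg.otsu_bins)
        disease = bg & (norm > level)
        disease = apply_exclusions(disease,
                                   combined_study.truth_exclusion_mask)
        disease = filter_adc_band(disease, adc, cfg.adc_lower, cfg.adc_upper)
        manual_tdv = compute_tdv(disease, series.voxel_spacing)

        res = segment_study(combined_study, cfg)
        np.testing.assert_array_equal(res.disease_mask, disease)
        assert res.tdv_ml == manual_tdv

    def test_tdv_invariant_to_global_intensity_rescale(self, combined_study):
        from tdvpipe.dwi_models import DwiSeries

        series = combined_study.dwi
        scaled = DwiSeries(b_values=series.b_values,
                           volumes=series.volumes * 37.5,
                           voxel_spacing=series.voxel_spacing)
        a = segment_study(combined_study)
        b = segment_study(scaled,
                          exclusion_mask=combined_study.truth_exclusion_mask)
        assert a.tdv_ml == pytest.approx(b.tdv_ml)

    def test_followup_shrinkage_tracks_configured_change(self):
        base = generate_phantom(diffuse_spec_for_volume(201.0))
        fup = generate_phantom(diffuse_spec_for_volume(21.0))
        t0 = segment_study(base).tdv_ml
        t1 = segment_study(fup).tdv_ml
        assert 100 * (t1 - t0) / t0 == pytest.approx(
            100 * (21.0 - 201.0) / 201.0, abs=0.5)

    def test_stage_failure_carries_stage_name(self):
        from tdvpipe.dwi_models import DwiSeries

        # uniform tissue: nothing exceeds the background threshold
        vols = np.full((2, 4, 4, 4), 500.0)
        vols[1] *= 0.7
        series = DwiSeries([0.0, 1000.0], vols, (2, 2, 2))
        with pytest.raises(PipelineStageError) as err:
            segment_study(series)
        assert err.value.stage in ("background_mask", "otsu_threshold")

    def test_mip_variant_runs(self, combined_study):
        res = segment_study(combined_study,
                            SegmentationConfig(otsu_on_mip=True))
        assert res.tdv_ml > 0


class TestThresholdSweep:
    def test_defaults_are_the_three_candidate_cuts(self):
        np.testing.assert_allclose(DEFAULT_LOWER_THRESHOLDS,
                                   (0.45e-3, 0.55e-3, 0.65e-3))

    def test_single_adc_lesions_identical_across_cuts(self, combined_study):
        table = threshold_sweep([combined_study])
        assert table.tdv_ml.nunique() == 1

    def test_tdv_strictly_decreasing_when_lesion_adcs_straddle_cuts(self):
        # lesions at ADC 0.5/0.6/0.7e-3; s0 adjusted so all are equally
        # bright on the computed b=999 image
        lesions = [
            Lesion(center=(32, 32, 25), adc=0.5e-3,
                   s0=1000.0 * np.exp(-(1.0e-3 - 0.5e-3) * 999)),
            Lesion(center=(32, 32, 60), adc=0.6e-3,
                   s0=1000.0 * np.exp(-(1.0e-3 - 0.6e-3) * 999)),
            Lesion(center=(32, 32, 95), adc=0.7e-3,
                   s0=1000.0 * np.exp(-(1.0e-3 - 0.7e-3) * 999)),
        ]
        study = generate_phantom(PhantomSpec(lesions=lesions))
        table = threshold_sweep([study])
        tdvs = table.sort_values("adc_lower").tdv_ml.to_numpy()
        assert np.all(np.diff(tdvs) < 0)

    def test_raising_lower_cut_never_increases_tdv(self, combined_study):
        table = threshold_sweep([combined_study],
                                lower_list=np.linspace(0.3e-3, 1.5e-3, 7))
        tdvs = table.sort_values("adc_lower").tdv_ml.to_numpy()
        assert np.all(np.diff(tdvs) <= 0)

    def test_empty_threshold_list_rejected(self, combined_study):
        with pytest.raises(ValueError):
            threshold_sweep([combined_study], lower_list=[])

    def test_auc_column_with_labels(self, combined_study, normal_study):
        table = threshold_sweep([combined_study, normal_study],
                                labels=[1, 0])
        assert (table.auc == 1.0).all()
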