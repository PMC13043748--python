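"""FRAP analysis: regions, drift, double normalization, mobile fraction, stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omdiff import frap as fr
from omdiff import synthetic as syn
from omdiff.errors import (
    DriftError,
    NormalizationError,
    ParameterError,
    SegmentationError,
)


def _blob_sequence(n_frames=4, shape=(60, 80), dim_after=None):
    """A bright rectangular blob on dark background; optionally a corner of
    the blob dims in post-bleach frames (a crude bleach)."""
    frames = np.full((n_frames,) + shape, 10.0)
    for i in range(n_frames):
        frames[i, 20:40, 30:60] = 100.0
        if dim_after is not None and i >= dim_after:
            frames[i, 20:30, 30:40] = 25.0
    t = np.arange(n_frames, dtype=float) - 0.5
    phase = np.where(t <= 0, "pre", "post").astype(object)
    return fr.FrapSequence(frames=frames, t=t, phase=phase)


class TestIdentifyRegions:
    def test_recovers_generator_masks(self, default_frap):
        seq, truth = default_frap
        regions = fr.identify_regions(seq)

        def jaccard(a, b):
            return (a & b).sum() / (a | b).sum()

        assert jaccard(regions.cell, truth["cell_mask"]) >= 0.8
        assert jaccard(regions.bleach, truth["bleach_mask"]) >= 0.8

    def test_no_bleach_event_is_segmentation_error(self):
        seq = _blob_sequence(dim_after=None)  # pre == post
        with pytest.raises(SegmentationError, match="bleach"):
            fr.identify_regions(seq)

    def test_two_cells_returns_the_bleached_one(self):
        seq = _blob_sequence(dim_after=1)
        # paste a second, larger, unbleached cell
        seq.frames[:, 45:58, 5:75] = 100.0
        regions = fr.identify_regions(seq)
        assert np.all(regions.cell[regions.bleach])        # containment
        assert not regions.cell[50, 40]                    # not the bystander

    def test_masks_are_disjoint_and_nonempty(self, default_frap):
        seq, _ = default_frap
        regions = fr.identify_regions(seq)
        assert regions.bleach.any() and regions.background.any()
        assert not np.any(regions.background & regions.cell)


class TestCorrectDrift:
    def test_recovers_injected_shift(self):
        seq = _blob_sequence(n_frames=5, dim_after=2)
        seq.frames[3] = np.roll(seq.frames[3], 3, axis=1)   # +3 px in x
        seq.frames[4] = np.roll(seq.frames[4], 3, axis=1)
        out = fr.correct_drift(seq)
        assert out.meta["drift_shifts"][3] == (0, -3)
        assert out.meta["drift_shifts"][4] == (0, -3)

    def test_identical_frames_zero_shift(self):
        seq = _blob_sequence(dim_after=None)
        out = fr.correct_drift(seq)
        assert all(s == (0, 0) for s in out.meta["drift_shifts"])

    def test_half_field_shift_is_drift_error(self):
        seq = _blob_sequence(n_frames=4, dim_after=2)
        seq.frames[3] = np.roll(seq.frames[3], 40, axis=1)  # half the width
        with pytest.raises(DriftError):
            fr.correct_drift(seq)


class TestExtractTraces:
    def test_uniform_frame_gives_equal_traces(self):
        frames = np.full((3, 4, 4), 7.0)
        seq = fr.FrapSequence(
            frames=frames, t=np.array([-1.0, 1.0, 2.0]),
            phase=np.array(["pre", "post", "post"], dtype=object),
        )
        m = np.zeros((4, 4), bool)
        cell = m.copy(); cell[1:3, 1:3] = True
        bleach = m.copy(); bleach[1, 1] = True
        bg = m.copy(); bg[3, 3] = True
        traces = fr.extract_traces(seq, fr.RegionSet(bleach=bleach, cell=cell, background=bg))
        assert np.all(traces.B == 7.0) and np.all(traces.T == 7.0) and np.all(traces.BG == 7.0)

    def test_hand_built_region_means(self):
        frames = np.zeros((2, 4, 4))
        frames[0, 0, :2] = [2.0, 4.0]      # bleach pixels, mean 3
        frames[0, 1, :2] = [6.0, 8.0]      # rest of cell
        frames[0, 3, 3] = 1.0              # background
        frames[1] = frames[0] * 2.0
        seq = fr.FrapSequence(
            frames=np.concatenate([frames, frames[1:]]),
            t=np.array([-1.0, 1.0, 2.0]),
            phase=np.array(["pre", "post", "post"], dtype=object),
        )
        bleach = np.zeros((4, 4), bool); bleach[0, :2] = True
        cell = bleach.copy(); cell[1, :2] = True
        bg = np.zeros((4, 4), bool); bg[3, 3] = True
        tr = fr.extract_traces(seq, fr.RegionSet(bleach=bleach, cell=cell, background=bg))
        assert tr.B[0] == 3.0 and tr.T[0] == 5.0 and tr.BG[0] == 1.0
        assert tr.B[1] == 6.0 and tr.T[1] == 10.0 and tr.BG[1] == 2.0

    def test_single_pixel_mask_returns_pixel_series(self):
        frames = np.arange(3 * 4 * 4, dtype=float).reshape(3, 4, 4)
        seq = fr.FrapSequence(
            frames=frames, t=np.array([-1.0, 1.0, 2.0]),
            phase=np.array(["pre", "post", "post"], dtype=object),
        )
        bleach = np.zeros((4, 4), bool); bleach[2, 2] = True
        cell = bleach
        bg = np.zeros((4, 4), bool); bg[0, 0] = True
        tr = fr.extract_traces(seq, fr.RegionSet(bleach=bleach, cell=cell, background=bg))
        assert np.array_equal(tr.B, frames[:, 2, 2])


def _traces(B, T, BG, t=None):
    B = np.asarray(B, float)
    n = len(B)
    t = np.asarray(t, float) if t is not None else np.arange(n) - 0.5
    phase = np.where(t <= 0, "pre", "post").astype(object)
    return fr.RegionTraces(t=t, phase=phase, B=B, T=np.asarray(T, float), BG=np.asarray(BG, float))


class TestDoubleNormalize:
    def test_worked_example_to_4dp(self):
        tr = _traces([100, 20, 40], [200, 180, 190], [10, 10, 10], t=[-1, 1, 300])
        curve = fr.double_normalize(tr, reference_index=0)
        assert curve.i_hat == pytest.approx([1.0, 0.1242, 0.3519], abs=5e-5)

    def test_reduces_to_simple_ratio_without_background(self):
        tr = _traces([50, 10, 30], [80, 80, 80], [0, 0, 0], t=[-1, 1, 300])
        curve = fr.double_normalize(tr)
        assert curve.i_hat == pytest.approx([1.0, 10 / 50, 30 / 50])

    def test_equal_traces_give_unity(self):
        tr = _traces([50, 40, 45], [50, 40, 45], [5, 5, 5], t=[-1, 1, 300])
        assert fr.double_normalize(tr).i_hat == pytest.approx([1.0, 1.0, 1.0])

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_global_rescaling(self, scale):
        tr = _traces([100, 20, 40], [200, 180, 190], [10, 10, 10], t=[-1, 1, 300])
        scaled = _traces(
            np.array([100, 20, 40.0]) * scale,
            np.array([200, 180, 190.0]) * scale,
            np.array([10, 10, 10.0]) * scale,
            t=[-1, 1, 300],
        )
        a = fr.double_normalize(tr).i_hat
        b = fr.double_normalize(scaled).i_hat
        assert np.allclose(a, b, rtol=1e-9)

    def test_acquisition_decay_cancels_exactly(self):
        lam = 0.95
        base = _traces([100, 20, 40], [200, 180, 190], [0, 0, 0], t=[-1, 1, 300])
        decayed = _traces(
            [100 * lam**0, 20 * lam**1, 40 * lam**2],
            [200 * lam**0, 180 * lam**1, 190 * lam**2],
            [0, 0, 0],
            t=[-1, 1, 300],
        )
        a = fr.double_normalize(base).i_hat
        b = fr.double_normalize(decayed).i_hat
        assert np.max(np.abs(a - b)) < 1e-12

    def test_nonpositive_reference_raises(self):
        tr = _traces([10, 20, 40], [200, 180, 190], [10, 10, 10], t=[-1, 1, 300])
        with pytest.raises(NormalizationError):
            fr.double_normalize(tr)

    def test_nonpositive_whole_cell_names_frame(self):
        tr = _traces([100, 20, 40], [200, 5, 190], [10, 10, 10], t=[-1, 1, 300])
        with pytest.raises(NormalizationError, match="frame 1"):
            fr.double_normalize(tr)

    def test_reference_defaults_to_last_prebleach(self):
        tr = _traces([90, 100, 20, 40], [190, 200, 180, 190], [10] * 4, t=[-2, -1, 1, 300])
        curve = fr.double_normalize(tr)
        assert curve.reference_index == 1
        assert curve.i_hat[1] == pytest.approx(1.0)


class TestMobileFraction:
    def test_worked_example(self):
        tr = _traces([100, 20, 40], [200, 180, 190], [10, 10, 10], t=[-1, 1, 300])
        res = fr.mobile_fraction(fr.double_normalize(tr))
        assert res.mobile_fraction == pytest.approx(0.2600, abs=5e-5)
        assert res.mobile_fraction + res.immobile_fraction == 1.0

    def test_no_recovery_gives_zero(self):
        tr = _traces([100, 20, 20], [200, 200, 200], [0, 0, 0], t=[-1, 1, 300])
        assert fr.mobile_fraction(fr.double_normalize(tr)).mobile_fraction == pytest.approx(0.0)

    def test_full_recovery_gives_one(self):
        tr = _traces([100, 20, 100], [200, 200, 200], [0, 0, 0], t=[-1, 1, 300])
        assert fr.mobile_fraction(fr.double_normalize(tr)).mobile_fraction == pytest.approx(1.0)

    def test_monotone_in_i_end_and_i_postbleach(self):
        def mf(i_post, i_end):
            return (i_end - i_post) / (1 - i_post)

        grid = np.linspace(0.05, 0.9, 12)
        for i_post in grid[:-1]:
            vals = [mf(i_post, e) for e in np.linspace(i_post, 1.0, 8)]
            assert np.all(np.diff(vals) >= 0)
        for i_end in grid:
            vals = [mf(p, i_end) for p in np.linspace(0.01, min(i_end, 0.95) - 1e-6, 8)]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_no_photobleach_raises(self):
        tr = _traces([100, 110, 120], [200, 200, 200], [0, 0, 0], t=[-1, 1, 300])
        with pytest.raises(ParameterError, match="photobleach"):
            fr.mobile_fraction(fr.double_normalize(tr))

    def test_missing_300s_frame_is_flagged(self):
        tr = _traces([100, 20, 40], [200, 180, 190], [10, 10, 10], t=[-1, 1, 5])
        res = fr.mobile_fraction(fr.double_normalize(tr))
        assert any("i_end" in f for f in res.flags)


class TestCompareMobileFractions:
    def test_identical_samples(self):
        res = fr.compare_mobile_fractions([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(9 / 2)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_fully_separated_small_samples_exact(self):
        # enumeration over all C(6,3)=20 rank arrangements: two-sided P = 2/20
        res = fr.compare_mobile_fractions([1, 2, 3], [10, 11, 12])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_power_at_study_sample_sizes(self):
        # distributions emulating untreated vs chelator-treated mobile
        # fractions (medians 0.09 vs 0.21), n = 49 per group
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            a = rng.normal(0.09, 0.06, 49)
            b = rng.normal(0.21, 0.06, 49)
            hits += fr.compare_mobile_fractions(a, b).p_value < 0.05
        assert hits >= 0.95 * n_rep

    def test_empty_group_raises(self):
        with pytest.raises(ParameterError):
            fr.compare_mobile_fractions([], [1.0, 2.0])

    def test_quartiles_and_outlier_flags(self):
        a = [0.1, 0.11, 0.12, 0.13, 5.0]
        res = fr.compare_mobile_fractions(a, [0.2, 0.21, 0.22, 0.23])
        assert res.outliers_a[-1]
        assert not res.outliers_b.any()


class TestEndToEndRecovery:
    def test_single_cell_pipeline_close_to_truth(self, default_frap):
        seq, truth = default_frap
        _, res = fr.analyze_sequence(seq)
        assert res.mobile_fraction == pytest.approx(truth["mobile_fraction"], abs=0.1)

    def test_user_supplied_masks_are_respected(self, default_frap):
        seq, truth = default_frap
        bg = ~(truth["cell_mask"])
        bg[:, : bg.shape[1] // 2] = False  # any clean off-cell region
        import scipy.ndimage as ndi

        bg &= ~ndi.binary_dilation(truth["cell_mask"], iterations=10)
        regions = fr.RegionSet(
            bleach=truth["bleach_mask"], cell=truth["cell_mask"], background=bg
        )
        _, res = fr.analyze_sequence(seq, regions, drift_correction=False)
        assert res.mobile_fraction == pytest.approx(truth["mobile_fraction"], abs=0.1)
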