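"""Background, per-vesicle partition statistics, and crosstalk correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvpart.detection import AngularProfile, VesicleContour, detect_vesicles, extract_angular_profile
from guvpart.errors import BackgroundError, CrosstalkError, ZeroSignalError
from guvpart.pipeline import quantify_frame
from guvpart.quantify import (
    CrosstalkMatrix,
    apply_crosstalk_correction,
    compute_partition,
    correct_background,
    estimate_background,
    estimate_crosstalk,
)
from guvpart.segmentation import segment_phases
from guvpart.synthetic import ImagingParams, render_frame

from conftest import make_vesicle

from test_segmentation import profile_from_means, two_level


def simple_record(I_Lo, I_Ld, n=36, bg=0.0):
    """Build a profile whose Lo arc (bins 20-35) and Ld arc carry the
    requested construct means, then run segmentation + quantification."""
    lipid = two_level(n)
    construct = np.full(n, I_Ld + bg, dtype=float)
    construct[20:] = I_Lo + bg
    prof = profile_from_means(lipid, construct)
    seg = segment_phases(prof)
    return compute_partition(prof, seg, (bg, bg), construct_channel=1)


class TestComputePartition:
    def test_defining_formula(self):
        rec = simple_record(60.0, 40.0)
        assert rec.f_p_Lo == pytest.approx(0.6)
        assert rec.I_Lo == pytest.approx(60.0)
        assert rec.I_Ld == pytest.approx(40.0)
        assert rec.f_p_Lo + rec.f_p_Ld == pytest.approx(1.0)

    def test_symmetric_signal(self):
        assert simple_record(55.0, 55.0).f_p_Lo == pytest.approx(0.5)

    def test_background_subtracted(self):
        rec = simple_record(60.0, 40.0, bg=25.0)
        assert rec.f_p_Lo == pytest.approx(0.6)

    def test_negative_clamped_and_flagged(self):
        rec = simple_record(30.0, -5.0)  # Ld arc below background
        assert rec.I_Ld == 0.0
        assert rec.f_p_Lo == 1.0
        assert any(f.startswith("clamped") for f in rec.flags)

    def test_zero_signal_error(self):
        with pytest.raises(ZeroSignalError):
            simple_record(0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_gain_invariance(self, gain):
        # f is a ratio: rescaling the construct channel cannot move it
        lipid = two_level()
        construct = np.full(36, 40.0)
        construct[20:] = 60.0
        prof = profile_from_means(lipid, construct * gain)
        seg = segment_phases(prof)
        rec = compute_partition(prof, seg, (0.0, 0.0), construct_channel=1)
        assert rec.f_p_Lo == pytest.approx(0.6, abs=1e-12)

    def test_pipeline_recovers_known_dG(self, default_imaging):
        # mean f over 20 shot-noise vesicles within +/-0.03 of the logistic value
        from guvpart.synthetic import PopulationParams, simulate_population

        pop = PopulationParams(n_vesicles=1, dG_true=-1.4)
        frames = simulate_population(pop, default_imaging, 20, seed=21)
        fs = []
        for frame, _ in frames:
            recs, _ = quantify_frame(frame)
            fs += [r.f_p_Lo for r in recs]
        assert len(fs) >= 19
        assert np.mean(fs) == pytest.approx(1 / (1 + math.exp(-1.4)), abs=0.03)


class TestBackground:
    def test_exact_noise_free(self):
        im = ImagingParams(frame_size=(160, 160), noise_model="none",
                           background=(50.0, 50.0))
        frame, _ = render_frame([make_vesicle(radius=35, center=(80, 80))], im)
        contours = detect_vesicles(frame)
        bg = estimate_background(frame, contours)
        np.testing.assert_allclose(bg, [50.0, 50.0])

    def test_poisson_median_close(self):
        im = ImagingParams(frame_size=(256, 256), background=(50.0, 50.0), seed=3)
        frame, _ = render_frame([make_vesicle(radius=35, center=(128, 128))], im)
        contours = detect_vesicles(frame)
        bg = estimate_background(frame, contours)
        assert np.all(np.abs(bg - 50.0) <= 1.0)

    def test_fully_covered_frame_errors(self):
        im = ImagingParams(frame_size=(128, 128), noise_model="none")
        frame, _ = render_frame([make_vesicle(radius=30, center=(64, 64))], im)
        giant = VesicleContour((64.0, 64.0), 80.0, 60.0, 1.0)
        with pytest.raises(BackgroundError):
            estimate_background(frame, [giant])


class TestCrosstalk:
    def test_identity_leaves_profile_unchanged(self):
        prof = profile_from_means(two_level(), np.linspace(10, 90, 36))
        out = apply_crosstalk_correction(prof, CrosstalkMatrix.identity())
        np.testing.assert_allclose(out.mean_intensity, prof.mean_intensity)

    def test_mix_then_correct_round_trip(self):
        prof = profile_from_means(two_level(), np.linspace(10, 90, 36))
        M = CrosstalkMatrix(((1.0, 0.08), (0.12, 1.0)))
        mixed = AngularProfile(
            bin_edges=prof.bin_edges,
            mean_intensity=M.as_array() @ prof.mean_intensity,
            pixel_count=prof.pixel_count,
        )
        restored = apply_crosstalk_correction(mixed, M)
        np.testing.assert_allclose(
            restored.mean_intensity, prof.mean_intensity, atol=1e-9
        )

    def test_ill_conditioned_rejected(self):
        M = CrosstalkMatrix(((1.0, 0.999999), (0.999999, 1.0)),
                            condition_limit=1e3)
        with pytest.raises(CrosstalkError):
            M.inverse()

    def test_estimate_from_clean_controls(self):
        # generator leakage rows scaled so off/on = 5% exactly
        im = ImagingParams(frame_size=(160, 160), noise_model="none",
                           crosstalk=((0.95, 0.0475), (0.0475, 0.95)))
        v = make_vesicle(radius=35, center=(80, 80))
        c0, _ = render_frame([v], im, active_channels=(True, False))
        c1, _ = render_frame([v], im, active_channels=(False, True))
        M = estimate_crosstalk({0: c0, 1: c1}).as_array()
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert M[1, 0] == pytest.approx(0.05, abs=1e-6)
        assert M[0, 1] == pytest.approx(0.05, abs=1e-6)

    def test_estimate_under_shot_noise(self):
        im = ImagingParams(frame_size=(160, 160), seed=8,
                           crosstalk=((0.95, 0.0475), (0.0475, 0.95)))
        v = make_vesicle(radius=35, center=(80, 80), amplitude=1000.0)
        c0, _ = render_frame([v], im, active_channels=(True, False))
        c1, _ = render_frame([v], im, active_channels=(False, True))
        M = estimate_crosstalk({0: c0, 1: c1}).as_array()
        assert M[1, 0] == pytest.approx(0.05, abs=0.005)
        assert M[0, 1] == pytest.approx(0.05, abs=0.005)

    def test_zero_leakage_gives_identity(self):
        im = ImagingParams(frame_size=(160, 160), noise_model="none")
        v = make_vesicle(radius=35, center=(80, 80))
        c0, _ = render_frame([v], im, active_channels=(True, False))
        c1, _ = render_frame([v], im, active_channels=(False, True))
        np.testing.assert_allclose(
            estimate_crosstalk({0: c0, 1: c1}).as_array(), np.eye(2), atol=1e-9
        )

    def test_bias_toward_half_and_correction(self):
        # 10% bleed-through pulls f toward 0.5; unmixing restores it
        from guvpart.synthetic import PopulationParams, simulate_population

        true_f = 1 / (1 + math.exp(1.9))
        pop = PopulationParams(n_vesicles=1, dG_true=1.9)
        im = ImagingParams(frame_size=(192, 192),
                           crosstalk=((0.9, 0.09), (0.09, 0.9)))
        frames = simulate_population(pop, im, 12, seed=77)
        M = CrosstalkMatrix(((1.0, 0.1), (0.1, 1.0)))
        f_raw, f_corr = [], []
        for frame, _ in frames:
            recs, _ = quantify_frame(frame)
            f_raw += [r.f_p_Lo for r in recs]
            recs, _ = quantify_frame(frame, crosstalk=M)
            f_corr += [r.f_p_Lo for r in recs]
        assert np.mean(f_raw) > true_f + 0.01  # biased toward 0.5
        assert np.mean(f_corr) == pytest.approx(true_f, abs=0.03)

    def test_correct_background_through_matrix(self):
        M = CrosstalkMatrix(((1.0, 0.1), (0.1, 1.0)))
        bg = correct_background((110.0, 110.0), M)
        np.testing.assert_allclose(M.as_array() @ bg, [110.0, 110.0])
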