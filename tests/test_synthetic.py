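"""Synthetic Janus-GUV generator: ground truth, placement, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvpart.errors import PlacementError, ValidationError
from guvpart.synthetic import (
    GroundTruthVesicle,
    ImagingParams,
    PopulationParams,
    intensity_ratio_from_dG,
    render_frame,
    sample_population,
    simulate_population,
    true_fraction,
)

from conftest import arc_mean, make_vesicle


class TestIntensityRatio:
    def test_no_partitioning(self):
        assert intensity_ratio_from_dG(0.0) == 1.0

    def test_closed_forms(self):
        assert intensity_ratio_from_dG(-1.4) == pytest.approx(4.0552, abs=1e-4)
        assert intensity_ratio_from_dG(1.9) == pytest.approx(0.149569, abs=1e-6)

    def test_strictly_decreasing(self):
        dgs = np.linspace(-3, 3, 50)
        ratios = [intensity_ratio_from_dG(d) for d in dgs]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            intensity_ratio_from_dG(float("inf"))


@settings(derandomize=True, max_examples=100)
@given(st.floats(min_value=-5, max_value=5))
def test_true_fraction_logistic_antisymmetry(dG):
    f = true_fraction(dG)
    assert f == pytest.approx(1.0 / (1.0 + math.exp(dG)), abs=1e-12)
    assert true_fraction(-dG) == pytest.approx(1.0 - f, abs=1e-12)


class TestSamplePopulation:
    def test_degenerate_distribution(self):
        params = PopulationParams(n_vesicles=1, radius_median=40.0, radius_shape=0.0)
        (v,) = sample_population(params, seed=3)
        assert v.radius == pytest.approx(40.0)

    def test_determinism(self):
        params = PopulationParams(n_vesicles=5)
        a = sample_population(params, seed=11)
        b = sample_population(params, seed=11)
        assert a == b

    def test_radius_median_recovered(self):
        # resample oracle: empirical median of the log-normal at larger n
        params = PopulationParams(n_vesicles=30, radius_median=35.0, radius_shape=0.3,
                                  membrane_amplitude=1500.0)
        vs = sample_population(params, seed=7, frame_size=(2000, 2000))
        med = np.median([v.radius for v in vs])
        assert abs(med - 35.0) / 35.0 < 0.15

    def test_no_overlap_and_in_frame(self):
        params = PopulationParams(n_vesicles=4, radius_median=30, radius_shape=0.1)
        vs = sample_population(params, seed=2, frame_size=(300, 300))
        for i, a in enumerate(vs):
            assert a.radius < a.center[0] < 300 - a.radius
            for b in vs[i + 1:]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                assert d > a.radius + b.radius

    def test_placement_failure_names_count(self):
        params = PopulationParams(n_vesicles=50, radius_median=40, radius_shape=0.0)
        with pytest.raises(PlacementError) as exc:
            sample_population(params, seed=0, frame_size=(256, 256), max_tries=500)
        assert exc.value.achieved < exc.value.requested == 50


class TestRenderFrame:
    def test_symmetric_channel_at_zero_dG(self, clean_imaging):
        v = make_vesicle(dG=0.0, lo_frac=0.5)
        frame, _ = render_frame([v], clean_imaging)
        lo = arc_mean(frame, v, channel=1, lo=True)
        ld = arc_mean(frame, v, channel=1, lo=False)
        assert lo == pytest.approx(ld, rel=1e-6)

    def test_lipid_contrast_ratio(self, clean_imaging):
        v = make_vesicle(contrast=5.0)
        frame, _ = render_frame([v], clean_imaging)
        ld = arc_mean(frame, v, channel=0, lo=False)
        lo = arc_mean(frame, v, channel=0, lo=True)
        assert ld / lo == pytest.approx(5.0, rel=0.01)

    def test_construct_ratio_matches_boltzmann(self, clean_imaging):
        v = make_vesicle(dG=-1.4)
        frame, _ = render_frame([v], clean_imaging)
        lo = arc_mean(frame, v, channel=1, lo=True)
        ld = arc_mean(frame, v, channel=1, lo=False)
        assert lo / ld == pytest.approx(math.exp(1.4), rel=0.01)

    def test_deterministic_with_seed(self):
        im = ImagingParams(frame_size=(128, 128), seed=9)
        v = make_vesicle(radius=30, center=(64, 64))
        a, _ = render_frame([v], im)
        b, _ = render_frame([v], im)
        np.testing.assert_array_equal(a.data, b.data)

    def test_ground_truth_table_f_true(self, clean_imaging):
        v = make_vesicle(dG=1.9, radius=30, center=(64, 64))
        _, truth = render_frame([v], ImagingParams(frame_size=(128, 128),
                                                   noise_model="none"))
        assert truth.loc[0, "f_true"] == pytest.approx(1 / (1 + math.exp(1.9)))

    def test_vesicle_outside_frame_rejected(self, clean_imaging):
        v = make_vesicle(radius=120)
        with pytest.raises(ValidationError):
            render_frame([v], clean_imaging)

    def test_crosstalk_conserves_total_counts(self):
        # row-stochastic mixing: photons move between channels, none lost
        v = make_vesicle(dG=-0.8, contrast=4.0)
        base = ImagingParams(frame_size=(192, 192), noise_model="none",
                             background=(0.0, 0.0))
        mixed = ImagingParams(frame_size=(192, 192), noise_model="none",
                              background=(0.0, 0.0),
                              crosstalk=((0.9, 0.1), (0.2, 0.8)))
        f0, _ = render_frame([v], base)
        f1, _ = render_frame([v], mixed)
        assert f1.data.sum() == pytest.approx(f0.data.sum(), rel=1e-9)

    def test_invalid_crosstalk_rejected(self):
        with pytest.raises(ValidationError):
            ImagingParams(crosstalk=((1.0, 0.05), (0.0, 1.0)))  # row sum > 1
        with pytest.raises(ValidationError):
            ImagingParams(crosstalk=((0.0, 0.5), (0.5, 0.5)))  # zero diagonal


class TestGroundTruthInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"radius": -1.0},
            {"lo_frac": 0.0},
            {"lo_frac": 1.0},
            {"contrast": 0.5},
            {"dG": float("nan")},
        ],
    )
    def test_invalid_vesicles_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_vesicle(**kwargs)


def test_simulate_population_deterministic_streams():
    params = PopulationParams(n_vesicles=1, radius_median=30, radius_shape=0.1)
    im = ImagingParams(frame_size=(160, 160))
    a = simulate_population(params, im, n_frames=2, seed=13)
    b = simulate_population(params, im, n_frames=2, seed=13)
    for (fa, ta), (fb, tb) in zip(a, b):
        np.testing.assert_array_equal(fa.data, fb.data)
    # frames within a run use independent noise streams
    assert not np.array_equal(a[0][0].data, a[1][0].data)
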