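import math

import numpy as np
import pytest

from guvpart.synthetic import GroundTruthVesicle, ImageFrame, ImagingParams, render_frame


@pytest.fixture
def clean_imaging():
    """Noise-free, crosstalk-free, background-free imaging settings."""
    return ImagingParams(
        frame_size=(192, 192), noise_model="none", background=(0.0, 0.0)
    )


@pytest.fixture
def default_imaging():
    """Default study conditions: shot noise, 100-count background."""
    return ImagingParams(frame_size=(192, 192), seed=42)


def make_vesicle(dG=0.0, radius=40.0, center=(96.0, 96.0), lo_frac=0.5,
                 lo_start=0.0, contrast=3.0, amplitude=1500.0):
    return GroundTruthVesicle(
        center=center,
        radius=radius,
        lo_arc_fraction=lo_frac,
        lo_arc_start=lo_start,
        construct_dG=dG,
        lipid_contrast=contrast,
        membrane_amplitude=amplitude,
    )


def flat_ring_frame(shape=(128, 128), center=(63.5, 63.5), radius=40.0,
                    half_width=4.0, level_fn=None, n_channels=2):
    """A flat-top annulus phantom: constant intensity inside the ring band.

    ``level_fn(theta) -> per-channel values``; defaults to 100 counts in
    both channels everywhere on the ring.
    """
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    d = np.hypot(xx - center[0], yy - center[1])
    theta = np.mod(np.arctan2(yy - center[1], xx - center[0]), 2 * math.pi)
    on = np.abs(d - radius) <= half_width
    data = np.zeros((n_channels, H, W))
    if level_fn is None:
        level_fn = lambda th: (100.0,) * n_channels  # noqa: E731
    levels = np.array([level_fn(t) for t in theta[on]])
    for ch in range(n_channels):
        data[ch][on] = levels[:, ch]
    return ImageFrame(data)


def arc_mean(frame, vesicle, channel, lo=True, interior=0.8):
    """Oracle: mean intensity over the central `interior` of one arc's band."""
    H, W = frame.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cx, cy = vesicle.center
    d = np.hypot(xx - cx, yy - cy)
    theta = np.mod(np.arctan2(yy - cy, xx - cx) - vesicle.lo_arc_start, 2 * math.pi)
    span = 2 * math.pi * vesicle.lo_arc_fraction
    if lo:
        pad = span * (1 - interior) / 2
        sel_arc = (theta > pad) & (theta < span - pad)
    else:
        rest = 2 * math.pi - span
        pad = rest * (1 - interior) / 2
        sel_arc = (theta > span + pad) & (theta < 2 * math.pi - pad)
    band = np.abs(d - vesicle.radius) < 1.0
    return float(frame.data[channel][band & sel_arc].mean())
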