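"""Synthetic two-channel equatorial sections of phase-separated GUVs.

An equatorial confocal slice through a Janus (two-domain) giant unilamellar
vesicle is a bright ring split into two contiguous arcs: a liquid-disordered
(Ld) arc, enriched in the lipid dye, and a liquid-ordered (Lo) arc.  The
generator renders that geometry with known ground truth so every downstream
stage — ring detection, arc segmentation, partition quantification — can be
validated without microscopy data.

Image model, per vesicle and channel::

    I(x, y) = A(theta) * exp(-(d - R)^2 / (2 * ring_sigma^2))

where ``d`` is the distance of pixel centre from the vesicle centre, ``R``
the radius, and ``A(theta)`` a two-level arc amplitude (sharp boundary).
The lipid channel (index 0) is brighter on the Ld arc by ``lipid_contrast``;
the construct channel (index 1) carries an Lo:Ld amplitude ratio of
``exp(-dG)``, the Boltzmann concentration ratio implied by the ground-truth
partitioning free energy.  Rendering then applies, in order: Gaussian PSF
blur, linear inter-channel cross-talk mixing, constant background, and shot
(or Gaussian) noise.

Conventions (used throughout the package): pixel coordinates are 0-based
with x = column and y = row; angles are radians, counter-clockwise from the
+x axis; default pixel pitch is 0.2 um, so a radius of 35 px corresponds to
a 7 um GUV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import PlacementError, ValidationError

__all__ = [
    "GroundTruthVesicle",
    "ImagingParams",
    "PopulationParams",
    "ImageFrame",
    "intensity_ratio_from_dG",
    "true_fraction",
    "sample_population",
    "render_frame",
    "simulate_population",
]

LIPID_CHANNEL = 0
CONSTRUCT_CHANNEL = 1


@dataclass(frozen=True)
class GroundTruthVesicle:
    """Ground-truth parameters of one synthetic Janus GUV.

    ``construct_dG`` is the partitioning free energy (kBT) of the labelled
    construct, Lo relative to Ld; ``lipid_contrast`` is the Ld:Lo intensity
    ratio of the lipid dye (>= 1, the dye enriches Ld).
    """

    center: tuple[float, float]  # (x, y), px
    radius: float  # px
    lo_arc_fraction: float  # fraction of circumference in Lo
    lo_arc_start: float  # radians, ccw from +x
    construct_dG: float  # kBT
    lipid_contrast: float = 3.0
    membrane_amplitude: float = 1500.0  # peak ring counts per channel

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"radius must be > 0, got {self.radius}")
        if not 0.0 < self.lo_arc_fraction < 1.0:
            raise ValidationError(
                f"lo_arc_fraction must be in (0, 1), got {self.lo_arc_fraction}"
            )
        if self.lipid_contrast < 1.0:
            raise ValidationError(
                f"lipid_contrast must be >= 1, got {self.lipid_contrast}"
            )
        if not math.isfinite(self.construct_dG):
            raise ValidationError("construct_dG must be finite")
        if self.membrane_amplitude <= 0:
            raise ValidationError("membrane_amplitude must be > 0")

    @property
    def true_f(self) -> float:
        """Implied true fractional Lo intensity, 1 / (1 + exp(dG))."""
        return true_fraction(self.construct_dG)


@dataclass(frozen=True)
class ImagingParams:
    """Optics, detector and noise settings for rendering.

    ``crosstalk`` is a row-stochastic 2x2 leakage matrix: row ``i`` says
    where true channel ``i``'s photons are recorded (diagonal in (0, 1],
    off-diagonal in [0, 1), rows summing to <= 1, so photons are conserved
    when a row sums to exactly 1).
    """

    frame_size: tuple[int, int] = (256, 256)  # (height, width) px
    psf_sigma: float = 2.0  # px
    background: tuple[float, float] = (100.0, 100.0)  # counts per channel
    noise_model: Literal["poisson", "gaussian", "none"] = "poisson"
    gaussian_sigma: float = 10.0  # counts; used when noise_model == "gaussian"
    crosstalk: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 0.0),
        (0.0, 1.0),
    )
    ring_sigma: float = 2.0  # px, radial 1/e half-width of the membrane
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma < 0:
            raise ValidationError("psf_sigma must be >= 0")
        if self.ring_sigma <= 0:
            raise ValidationError("ring_sigma must be > 0")
        M = np.asarray(self.crosstalk, dtype=float)
        if M.shape != (2, 2):
            raise ValidationError("crosstalk must be a 2x2 matrix")
        d = np.diag(M)
        off = M[~np.eye(2, dtype=bool)]
        if np.any(d <= 0) or np.any(d > 1):
            raise ValidationError("crosstalk diagonal must be in (0, 1]")
        if np.any(off < 0) or np.any(off >= 1):
            raise ValidationError("crosstalk off-diagonal must be in [0, 1)")
        if np.any(M.sum(axis=1) > 1 + 1e-12):
            raise ValidationError("each crosstalk row must sum to <= 1")
        if any(b < 0 for b in self.background):
            raise ValidationError("background must be >= 0")

    @property
    def crosstalk_matrix(self) -> np.ndarray:
        return np.asarray(self.crosstalk, dtype=float)


@dataclass(frozen=True)
class PopulationParams:
    """Describes a population of vesicles to sample for one condition."""

    n_vesicles: int = 20
    radius_median: float = 35.0  # px (log-normal median)
    radius_shape: float = 0.3  # log-normal shape (sigma of log)
    dG_true: float = 0.0  # kBT, population mean
    dG_jitter_sd: float = 0.15  # kBT, per-vesicle biological variability
    lo_arc_fraction_range: tuple[float, float] = (0.3, 0.7)
    lipid_contrast: float = 3.0
    membrane_amplitude: float = 1500.0
    min_radius: float = 15.0  # px, smallest detectable ring
    dna_to_lipid_ratio: float = 4e-4  # bookkeeping label for density sweeps

    def __post_init__(self) -> None:
        if self.n_vesicles < 1:
            raise ValidationError("n_vesicles must be >= 1")
        lo, hi = self.lo_arc_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("lo_arc_fraction_range must lie inside (0, 1)")
        if self.radius_median <= 0 or self.radius_shape < 0:
            raise ValidationError("invalid radius distribution")
        if self.min_radius <= 0:
            raise ValidationError("min_radius must be > 0")
        if self.dG_jitter_sd < 0:
            raise ValidationError("dG_jitter_sd must be >= 0")


@dataclass
class ImageFrame:
    """A two-channel 2D intensity image with pixel-size metadata.

    ``data`` has shape (2, H, W); channel 0 is the lipid-phase marker
    (Ld-bright), channel 1 the construct label.
    """

    data: np.ndarray
    pixel_size_um: float = 0.2
    lipid_channel: int = LIPID_CHANNEL
    construct_channel: int = CONSTRUCT_CHANNEL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValidationError(
                f"frame data must be (n_channels>=2, H, W), got {self.data.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def intensity_ratio_from_dG(dG: float) -> float:
    """Lo:Ld construct concentration ratio implied by a free energy (kBT).

    The Boltzmann ratio ``exp(-dG)``: strictly decreasing in dG, 1 at dG=0.
    """
    dG = float(dG)
    if not math.isfinite(dG):
        raise ValidationError(f"dG must be finite, got {dG}")
    return math.exp(-dG)


def true_fraction(dG: float) -> float:
    """Ground-truth fractional Lo intensity, ``1 / (1 + exp(dG))``."""
    r = intensity_ratio_from_dG(dG)
    return r / (1.0 + r)


def sample_population(
    params: PopulationParams,
    seed: int,
    frame_size: tuple[int, int] = (256, 256),
    placement_margin: float = 12.0,
    max_tries: int = 10_000,
) -> list[GroundTruthVesicle]:
    """Draw a population of ground-truth vesicles placed without overlap.

    Radii are log-normal (median ``radius_median``, shape ``radius_shape``),
    truncated below at ``min_radius``; Lo-arc fraction and start angle are
    uniform; per-vesicle free energies are Gaussian about ``dG_true`` with
    SD ``dG_jitter_sd`` (vesicle-to-vesicle compositional variability, the
    scatter a box-scatter plot of a real population shows).  Centres are
    rejection-sampled so rings (dilated by
    ``placement_margin``) neither overlap each other nor touch the border.

    Raises
    ------
    PlacementError
        If fewer than ``n_vesicles`` non-overlapping placements are found
        within ``max_tries`` attempts (names the achieved count).
    """
    rng = np.random.default_rng(seed)
    H, W = frame_size
    placed: list[GroundTruthVesicle] = []
    tries = 0
    while len(placed) < params.n_vesicles and tries < max_tries:
        tries += 1
        r = params.radius_median * math.exp(params.radius_shape * rng.standard_normal())
        if r < params.min_radius:
            continue
        lim = r + placement_margin
        if 2 * lim >= min(H, W):
            continue
        x = rng.uniform(lim, W - 1 - lim)
        y = rng.uniform(lim, H - 1 - lim)
        if any(
            math.hypot(x - v.center[0], y - v.center[1])
            < r + v.radius + placement_margin
            for v in placed
        ):
            continue
        lo_frac = rng.uniform(*params.lo_arc_fraction_range)
        lo_start = rng.uniform(0.0, 2.0 * math.pi)
        dg = params.dG_true + params.dG_jitter_sd * rng.standard_normal()
        placed.append(
            GroundTruthVesicle(
                center=(x, y),
                radius=r,
                lo_arc_fraction=lo_frac,
                lo_arc_start=lo_start,
                construct_dG=dg,
                lipid_contrast=params.lipid_contrast,
                membrane_amplitude=params.membrane_amplitude,
            )
        )
    if len(placed) < params.n_vesicles:
        raise PlacementError(params.n_vesicles, len(placed))
    return placed


def _arc_amplitudes(v: GroundTruthVesicle) -> np.ndarray:
    """Per-channel (lipid, construct) x (Lo, Ld) arc amplitudes."""
    A = v.membrane_amplitude
    ratio = intensity_ratio_from_dG(v.construct_dG)  # Lo : Ld
    return np.array(
        [
            [A, A * v.lipid_contrast],  # lipid channel: Ld bright
            # construct channel: Lo/Ld = ratio, Lo+Ld amplitude held at 2A
            [A * 2.0 * ratio / (1.0 + ratio), A * 2.0 / (1.0 + ratio)],
        ]
    )


def _in_lo_arc(theta: np.ndarray, v: GroundTruthVesicle) -> np.ndarray:
    span = 2.0 * math.pi * v.lo_arc_fraction
    rel = np.mod(theta - v.lo_arc_start, 2.0 * math.pi)
    return rel < span


def render_frame(
    vesicles: Sequence[GroundTruthVesicle],
    imaging: ImagingParams,
    active_channels: tuple[bool, bool] = (True, True),
) -> tuple[ImageFrame, pd.DataFrame]:
    """Render vesicles into a two-channel frame plus a ground-truth table.

    ``active_channels`` zeroes a channel's pre-mixing signal; this is how
    single-fluorophore cross-talk control frames are produced.

    Returns the frame (float counts) and a DataFrame with one row per
    vesicle: id, x, y, radius_px, lo_arc_start_rad, lo_arc_fraction,
    dG_true, f_true.
    """
    H, W = imaging.frame_size
    margin = 4.0 * imaging.ring_sigma
    for v in vesicles:
        x, y = v.center
        if (
            x - v.radius < margin
            or y - v.radius < margin
            or x + v.radius > W - 1 - margin
            or y + v.radius > H - 1 - margin
        ):
            raise ValidationError(
                f"vesicle at {v.center} r={v.radius:.1f} does not fit the "
                f"{H}x{W} frame with margin {margin:.1f}"
            )

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    signal = np.zeros((2, H, W), dtype=float)
    inv2s2 = 1.0 / (2.0 * imaging.ring_sigma**2)
    for v in vesicles:
        dx, dy = xx - v.center[0], yy - v.center[1]
        d = np.hypot(dx, dy)
        # only a band around the ring contributes meaningfully
        band = np.abs(d - v.radius) < 5.0 * imaging.ring_sigma
        if not band.any():
            continue
        radial = np.exp(-((d[band] - v.radius) ** 2) * inv2s2)
        theta = np.arctan2(dy[band], dx[band])
        lo = _in_lo_arc(theta, v)
        amps = _arc_amplitudes(v)
        for ch in range(2):
            if not active_channels[ch]:
                continue
            a = np.where(lo, amps[ch, 0], amps[ch, 1])
            signal[ch][band] += a * radial

    if imaging.psf_sigma > 0:
        for ch in range(2):
            signal[ch] = gaussian_filter(signal[ch], imaging.psf_sigma)

    M = imaging.crosstalk_matrix
    observed = np.einsum("ji,jhw->ihw", M, signal)
    observed += np.asarray(imaging.background, dtype=float)[:, None, None]

    rng = np.random.default_rng(imaging.seed)
    if imaging.noise_model == "poisson":
        observed = rng.poisson(np.clip(observed, 0, None)).astype(float)
    elif imaging.noise_model == "gaussian":
        observed = observed + rng.normal(0.0, imaging.gaussian_sigma, observed.shape)
    elif imaging.noise_model != "none":
        raise ValidationError(f"unknown noise model {imaging.noise_model!r}")

    truth = pd.DataFrame(
        {
            "vesicle_id": np.arange(len(vesicles)),
            "x": [v.center[0] for v in vesicles],
            "y": [v.center[1] for v in vesicles],
            "radius_px": [v.radius for v in vesicles],
            "lo_arc_start_rad": [v.lo_arc_start for v in vesicles],
            "lo_arc_fraction": [v.lo_arc_fraction for v in vesicles],
            "dG_true": [v.construct_dG for v in vesicles],
            "f_true": [v.true_f for v in vesicles],
        }
    )
    return ImageFrame(observed), truth


def simulate_population(
    params: PopulationParams,
    imaging: ImagingParams,
    n_frames: int,
    seed: int,
    vesicles_per_frame: int | None = None,
) -> list[tuple[ImageFrame, pd.DataFrame]]:
    """Render a multi-frame population with deterministic per-frame streams.

    One master ``seed`` spawns independent child seeds for each frame's
    placement and noise, so populations are reproducible and frames are
    statistically independent.  ``params.n_vesicles`` applies per frame
    unless ``vesicles_per_frame`` overrides it.
    """
    n_per = vesicles_per_frame or params.n_vesicles
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_frames)
    out = []
    for i in range(n_frames):
        place_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        noise_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        frame_params = replace(params, n_vesicles=n_per)
        vesicles = sample_population(
            frame_params, place_seed, frame_size=imaging.frame_size
        )
        frame, truth = render_frame(vesicles, replace(imaging, seed=noise_seed))
        truth["frame"] = i
        truth["dna_to_lipid_ratio"] = params.dna_to_lipid_ratio
        out.append((frame, truth))
    return out
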