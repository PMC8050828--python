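"""Per-vesicle partition quantification.

Turns a segmented angular profile into the per-vesicle statistic of the
study: background-corrected mean construct-channel intensities over each
phase arc (I_Lo, I_Ld) and the fractional Lo intensity

    f_p_Lo = I_Lo / (I_Lo + I_Ld)

Phase means are pixel-count weighted over the retained bins, which equals
the direct per-pixel mean over the arc and is robust to unequal bin
occupancy.  Negative background-subtracted means are clamped to zero and
flagged so f stays in [0, 1].

Spectral bleed-through between the two detection channels is modelled as a
linear mixing matrix: single-fluorophore control frames yield the leakage
fractions (observed off-channel over on-channel membrane signal, diagonal
normalised to 1), and profiles are corrected by applying the matrix
inverse per bin before background subtraction (the background vector is
corrected through the same matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detection import AngularProfile, VesicleContour, detect_vesicles, extract_angular_profile
from .errors import BackgroundError, CrosstalkError, ValidationError, ZeroSignalError
from .segmentation import LD, LO, PhaseSegmentation
from .synthetic import ImageFrame

__all__ = [
    "PartitionRecord",
    "CrosstalkMatrix",
    "estimate_background",
    "compute_partition",
    "estimate_crosstalk",
    "apply_crosstalk_correction",
    "correct_background",
]


@dataclass(frozen=True)
class PartitionRecord:
    """One vesicle's partitioning measurement — the atom of all statistics."""

    vesicle_id: int
    I_Lo: float
    I_Ld: float
    f_p_Lo: float
    radius: float
    separation_score: float
    population_label: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def f_p_Ld(self) -> float:
        return 1.0 - self.f_p_Lo


@dataclass(frozen=True)
class CrosstalkMatrix:
    """2x2 linear map from true channel signals to observed channels.

    Column j holds where fluorophore j's signal is recorded; the diagonal
    is normalised to 1 so off-diagonal entries are leakage fractions.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]]
    condition_limit: float = 1e6

    def __post_init__(self) -> None:
        M = self.as_array()
        if M.shape != (2, 2):
            raise ValidationError("crosstalk matrix must be 2x2")
        if np.any(np.diag(M) <= 0):
            raise ValidationError("crosstalk diagonal must be positive")
        off = M[~np.eye(2, dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValidationError("leakage fractions must be in [0, 1)")
        if abs(np.linalg.det(M)) < 1e-12:
            raise CrosstalkError("crosstalk matrix is singular")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def inverse(self) -> np.ndarray:
        M = self.as_array()
        if np.linalg.cond(M) > self.condition_limit:
            raise CrosstalkError(
                f"crosstalk matrix condition number exceeds {self.condition_limit:g}"
            )
        return np.linalg.inv(M)

    @classmethod
    def identity(cls) -> "CrosstalkMatrix":
        return cls(((1.0, 0.0), (0.0, 1.0)))


def estimate_background(
    frame: ImageFrame,
    contours: Sequence[VesicleContour],
    margin: float = 4.0,
) -> np.ndarray:
    """Median per-channel intensity outside all vesicles.

    Pixels inside any vesicle disk dilated by ``ring_width/2 + margin``
    (annulus plus interior) are excluded.  Raises
    :class:`BackgroundError` if nothing remains.
    """
    H, W = frame.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    mask = np.ones((H, W), dtype=bool)
    for c in contours:
        d = np.hypot(xx - c.center[0], yy - c.center[1])
        mask &= d > c.radius + c.ring_width / 2.0 + margin
    if not mask.any():
        raise BackgroundError("no background pixels outside the vesicles")
    return np.median(frame.data[:, mask].astype(float), axis=1)


def compute_partition(
    profile: AngularProfile,
    seg: PhaseSegmentation,
    background: Sequence[float] | np.ndarray,
    construct_channel: int = 1,
    vesicle_id: int = 0,
    radius: float = float("nan"),
    population_label: str = "",
) -> PartitionRecord:
    """Compute I_Lo, I_Ld and f_p_Lo for one segmented vesicle.

    ``I_phase`` is the pixel-count-weighted mean of (bin mean − background)
    over the phase's non-excluded bins; negatives clamp to 0 with a flag.

    Raises
    ------
    ZeroSignalError
        If I_Lo + I_Ld <= 0 (no construct signal above background).
    """
    if construct_channel >= profile.mean_intensity.shape[0]:
        raise ValidationError(f"profile has no channel {construct_channel}")
    if seg.n_bins != profile.n_bins:
        raise ValidationError("segmentation and profile bin counts differ")
    bg = float(np.asarray(background, dtype=float)[construct_channel])

    flags: list[str] = []

    def _phase_mean(label: str) -> float:
        bins = seg.bins_of(label)
        w = profile.pixel_count[bins].astype(float)
        m = profile.mean_intensity[construct_channel, bins]
        val = float((w * m).sum() / w.sum()) - bg
        if val < 0:
            flags.append(f"clamped_{label}")
            val = 0.0
        return val

    I_Lo = _phase_mean(LO)
    I_Ld = _phase_mean(LD)
    total = I_Lo + I_Ld
    if total <= 0:
        raise ZeroSignalError(
            f"vesicle {vesicle_id}: no construct signal above background"
        )
    return PartitionRecord(
        vesicle_id=vesicle_id,
        I_Lo=I_Lo,
        I_Ld=I_Ld,
        f_p_Lo=I_Lo / total,
        radius=radius,
        separation_score=seg.separation_score,
        population_label=population_label,
        flags=tuple(flags),
    )


def _membrane_signal(frame: ImageFrame) -> np.ndarray:
    """Per-channel background-subtracted mean membrane signal of a frame."""
    contours = detect_vesicles(frame)
    if not contours:
        raise BackgroundError("no vesicle detected in control frame")
    bg = estimate_background(frame, contours)
    sums = np.zeros(frame.n_channels)
    count = 0
    for c in contours:
        prof = extract_angular_profile(frame, c)
        w = prof.pixel_count.astype(float)
        sums += (prof.mean_intensity * w).sum(axis=1)
        count += int(w.sum())
    return sums / count - bg


def estimate_crosstalk(
    control_frames: Mapping[int, ImageFrame],
) -> CrosstalkMatrix:
    """Estimate the leakage matrix from single-fluorophore control frames.

    ``control_frames`` maps fluorophore (true-channel) index -> a frame in
    which only that fluorophore is present.  For control j, column j's
    off-diagonal entry is the observed off-channel membrane signal divided
    by the on-channel signal; diagonals are normalised to 1.

    Raises
    ------
    BackgroundError
        If a control's on-channel membrane signal is at or below background.
    """
    M = np.eye(2)
    for j in (0, 1):
        if j not in control_frames:
            raise ValidationError(f"missing control frame for channel {j}")
        sig = _membrane_signal(control_frames[j])
        if sig[j] <= 0:
            raise BackgroundError(
                f"control for channel {j}: on-channel signal not above background"
            )
        i = 1 - j
        M[i, j] = max(float(sig[i] / sig[j]), 0.0)
    return CrosstalkMatrix(((M[0, 0], M[0, 1]), (M[1, 0], M[1, 1])))


def apply_crosstalk_correction(
    profile: AngularProfile, M: CrosstalkMatrix
) -> AngularProfile:
    """Unmix an angular profile: per-bin channel vectors times M inverse.

    Corrected intensities may be marginally negative at low signal; they
    are left untouched here (background subtraction and clamping happen in
    :func:`compute_partition`).
    """
    inv = M.inverse()
    corrected = inv @ profile.mean_intensity
    return AngularProfile(
        bin_edges=profile.bin_edges,
        mean_intensity=corrected,
        pixel_count=profile.pixel_count,
    )


def correct_background(
    background: Sequence[float] | np.ndarray, M: CrosstalkMatrix
) -> np.ndarray:
    """Map an observed background vector into unmixed channel space."""
    return M.inverse() @ np.asarray(background, dtype=float)
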