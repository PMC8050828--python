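"""Thermodynamics of membrane-phase partitioning.

A membrane-anchored construct distributed between coexisting liquid-ordered
(Lo) and liquid-disordered (Ld) lipid phases is characterised by its
fractional Lo intensity ``f = I_Lo / (I_Lo + I_Ld)``.  Assuming fluorescence
is proportional to concentration, the free energy of moving one construct
from Ld to Lo is

    dG = -ln(f / (1 - f))        [units of kBT, natural log]

so ``f = 1/2`` means no preference (dG = 0) and negative dG means Lo
enrichment.  For a construct carrying several independent hydrophobic
anchors, at low surface density and absent co-operativity, the total
partitioning free energy is modelled as the sum of per-anchor
contributions (the additivity rule); deviations from that sum quantify
anchor co-operativity (nonadditivity).

All energies in this module are dimensionless (kBT units); no temperature
parameter is exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ValidationError

__all__ = [
    "DEFAULT_ANCHOR_LIBRARY",
    "ConstructDesign",
    "fraction_to_dG",
    "dG_to_fraction",
    "predict_additive",
    "nonadditivity",
    "load_anchor_library",
    "save_anchor_library",
]

#: Default per-anchor partitioning free energies (kBT), measured on ternary
#: DOPC/DPPC/cholestanol membranes:
#:
#: ==========  =======  =====================================================
#: tag         dG/kBT   anchor
#: ==========  =======  =====================================================
#: sC          -0.4     single cholesteryl-TEG (weak Lo preference)
#: dC          -0.8     double cholesteryl-TEG duplex
#: sT           1.9     single alpha-tocopherol (strong Ld preference)
#: sT+dC        1.0     measured tocopherol + double-cholesterol coupling
#: ==========  =======  =====================================================
#:
#: ``sT+dC`` is the *measured* value for the coupled construct, kept in the
#: library because the responsive-device model can be configured to use the
#: measured rather than the additive bridged-state energy.  Override per run
#: via :func:`load_anchor_library`.
DEFAULT_ANCHOR_LIBRARY: dict[str, float] = {
    "sC": -0.4,
    "dC": -0.8,
    "sT": 1.9,
    "sT+dC": 1.0,
}


@dataclass(frozen=True)
class FreeEnergy:
    """A partitioning free energy in kBT units (negative = Lo preference)."""

    dG: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dG):
            raise ValidationError(f"free energy must be finite, got {self.dG}")

    def __float__(self) -> float:
        return self.dG


@dataclass(frozen=True)
class ConstructDesign:
    """A multi-anchor construct: ordered anchor tags with dG contributions.

    Parameters
    ----------
    name
        Condition tag, e.g. ``"dC"`` or ``"sC+sT"``.
    anchors
        Sequence of ``(tag, dG_kBT)`` pairs, one per hydrophobic anchor.
    """

    name: str
    anchors: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.anchors) == 0:
            raise ValidationError(f"construct {self.name!r} has no anchors")
        for tag, dg in self.anchors:
            if not math.isfinite(dg):
                raise ValidationError(f"anchor {tag!r} has non-finite dG {dg}")

    @classmethod
    def from_library(
        cls, name: str, tags: Iterable[str], library: Mapping[str, float] | None = None
    ) -> "ConstructDesign":
        lib = DEFAULT_ANCHOR_LIBRARY if library is None else library
        missing = [t for t in tags if t not in lib]
        if missing:
            raise ValidationError(f"anchors {missing} not in library {sorted(lib)}")
        return cls(name, tuple((t, float(lib[t])) for t in tags))


def fraction_to_dG(f: float) -> float:
    """Partitioning free energy (kBT) from a fractional Lo intensity.

    ``dG = -ln(f / (1 - f))``; strictly decreasing in ``f`` and antisymmetric:
    ``fraction_to_dG(1 - f) == -fraction_to_dG(f)``.

    Raises
    ------
    ValidationError
        If ``f`` is outside ``[0, 1]``, not finite, or exactly 0 or 1
        (the free energy is unbounded there).
    """
    f = float(f)
    if not math.isfinite(f) or f < 0.0 or f > 1.0:
        raise ValidationError(f"fractional intensity must be in [0, 1], got {f}")
    if f == 0.0 or f == 1.0:
        raise ValidationError(
            f"fractional intensity {f} implies an unbounded free energy"
        )
    return -math.log(f / (1.0 - f))


def dG_to_fraction(dG: float) -> float:
    """Fractional Lo intensity from a partitioning free energy (kBT).

    The inverse logistic map ``f = 1 / (1 + exp(dG))``; round-trips with
    :func:`fraction_to_dG` to ~1e-12.
    """
    dG = float(dG)
    if not math.isfinite(dG):
        raise ValidationError(f"free energy must be finite, got {dG}")
    # exp-safe for large |dG|
    if dG >= 0:
        return math.exp(-dG) / (1.0 + math.exp(-dG))
    return 1.0 / (1.0 + math.exp(dG))


def predict_additive(design: ConstructDesign | Iterable[float]) -> float:
    """Additive multi-anchor prediction: the sum of per-anchor dG (kBT).

    Accepts a :class:`ConstructDesign` or a bare iterable of per-anchor
    free energies.  Permutation-invariant in anchor order.
    """
    if isinstance(design, ConstructDesign):
        contributions = [dg for _, dg in design.anchors]
    else:
        contributions = [float(x) for x in design]
        if not contributions:
            raise ValidationError("empty anchor list")
        for dg in contributions:
            if not math.isfinite(dg):
                raise ValidationError(f"non-finite anchor contribution {dg}")
    return float(math.fsum(contributions))


def nonadditivity(measured: float, predicted: float) -> float:
    """Deviation (kBT) of a measured free energy from the additive prediction.

    ``delta = measured - predicted``.  Negative values mean the construct
    prefers Lo more strongly than the per-anchor sum predicts.
    """
    measured, predicted = float(measured), float(predicted)
    if not (math.isfinite(measured) and math.isfinite(predicted)):
        raise ValidationError("measured and predicted free energies must be finite")
    return measured - predicted


def load_anchor_library(path: str | Path) -> dict[str, float]:
    """Read an anchor library from a tab-separated table: tag, dG, [note]."""
    lib: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"malformed anchor-library line: {line!r}")
        lib[parts[0]] = float(parts[1])
    if not lib:
        raise ValidationError(f"anchor library {path} is empty")
    return lib


def save_anchor_library(
    library: Mapping[str, float], path: str | Path, notes: Mapping[str, str] | None = None
) -> None:
    """Write an anchor library as a tab-separated table (tag, dG, note)."""
    notes = notes or {}
    lines = ["# anchor\tdG_kBT\tnote"]
    for tag, dg in library.items():
        lines.append(f"{tag}\t{dg:g}\t{notes.get(tag, '')}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")
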