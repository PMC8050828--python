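"""Population-level statistics over per-vesicle partition records.

Aggregates :class:`~guvpart.quantify.PartitionRecord` collections into the
outputs a partitioning study reports: per-condition summaries (mean, SD,
quartiles of f and of the per-vesicle free energy), nonparametric
two-sample comparisons (Mann-Whitney), the radius-independence check
(Spearman rank correlation of f against vesicle radius), and surface
density sweeps (mean f per DNA-to-lipid ratio with a flatness statistic).

Free energies are computed per vesicle and then averaged, rather than from
the pooled mean f; vesicles at f exactly 0 or 1 (unbounded energy) are
excluded from the energy average and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .quantify import PartitionRecord
from .thermo import fraction_to_dG

__all__ = [
    "PopulationSummary",
    "summarize",
    "compare_populations",
    "radius_independence",
    "density_sweep",
]


@dataclass(frozen=True)
class PopulationSummary:
    population_label: str
    n: int
    mean_f: float
    sd_f: float
    median_f: float
    q1_f: float
    q3_f: float
    mean_dG: float
    sd_dG: float
    n_excluded_dG: int  # vesicles at f in {0, 1}, excluded from dG stats
    flags: tuple[str, ...] = ()


def _f_values(records: Sequence[PartitionRecord] | Sequence[float]) -> np.ndarray:
    vals = [r.f_p_Lo if isinstance(r, PartitionRecord) else float(r) for r in records]
    return np.asarray(vals, dtype=float)


def summarize(
    records: Sequence[PartitionRecord] | Sequence[float], label: str = ""
) -> PopulationSummary:
    """Summarise one population's fractional intensities and free energies."""
    f = _f_values(records)
    if len(f) == 0:
        raise ValidationError(
            f"population {label!r}: no records after quality gates"
        )
    flags: list[str] = []
    if len(f) == 1:
        flags.append("n=1")
    interior = f[(f > 0.0) & (f < 1.0)]
    dgs = np.array([fraction_to_dG(x) for x in interior])
    q1, med, q3 = np.percentile(f, [25, 50, 75])
    return PopulationSummary(
        population_label=label,
        n=len(f),
        mean_f=float(f.mean()),
        sd_f=float(f.std(ddof=1)) if len(f) > 1 else 0.0,
        median_f=float(med),
        q1_f=float(q1),
        q3_f=float(q3),
        mean_dG=float(dgs.mean()) if len(dgs) else float("nan"),
        sd_dG=float(dgs.std(ddof=1)) if len(dgs) > 1 else 0.0,
        n_excluded_dG=int(len(f) - len(interior)),
        flags=tuple(flags),
    )


def compare_populations(
    a: Sequence[PartitionRecord] | Sequence[float],
    b: Sequence[PartitionRecord] | Sequence[float],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of two populations' f.

    Uses exact enumeration when the smaller sample has <= 8 values and the
    data are tie-free, and the tie-corrected normal approximation
    otherwise.  Symmetric in its arguments.  Returns ``(U, p)``.

    Degenerate input (every value identical in both samples) returns
    ``p = 1.0`` with a warning rather than an error.
    """
    x, y = _f_values(a), _f_values(b)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("each sample needs n >= 3")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate comparison: all values identical", stacklevel=2)
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def radius_independence(
    records: Sequence[PartitionRecord],
) -> tuple[float, float]:
    """Spearman rank correlation of f against vesicle radius.

    Verifies that partitioning is a property of the construct, not of
    vesicle size.  Returns ``(rho, p)``; raises on zero radius variance or
    fewer than 5 records.
    """
    if len(records) < 5:
        raise ValidationError("radius independence needs n >= 5")
    f = np.array([r.f_p_Lo for r in records])
    radius = np.array([r.radius for r in records])
    if np.ptp(radius) == 0:
        raise ValidationError("zero radius variance")
    if np.ptp(f) == 0:
        return 0.0, 1.0  # constant f: no association by construction
    rho, p = sps.spearmanr(f, radius)
    return float(rho), float(p)


def density_sweep(
    groups: Mapping[float, Sequence[PartitionRecord] | Sequence[float]],
    stationary_range: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-ratio summaries for a DNA-to-lipid surface-density sweep.

    Returns a table (ratio, n, mean_f, sd_f) sorted ascending by ratio,
    plus a flatness statistic: the maximum |mean_f − grand mean| over the
    groups inside ``stationary_range`` (all groups when ``None``).  At
    saturating densities mean f drifts toward 0.5 — the flatness statistic
    is meant to be computed over the pre-saturation plateau.
    """
    if len(groups) < 2:
        raise ValidationError("density sweep needs >= 2 ratio groups")
    rows = []
    for ratio in sorted(groups):
        f = _f_values(groups[ratio])
        if len(f) == 0:
            raise ValidationError(f"ratio group {ratio} is empty")
        rows.append(
            {
                "dna_to_lipid_ratio": float(ratio),
                "n": len(f),
                "mean_f": float(f.mean()),
                "sd_f": float(f.std(ddof=1)) if len(f) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    if stationary_range is None:
        sel = table
    else:
        lo, hi = stationary_range
        sel = table[(table.dna_to_lipid_ratio >= lo) & (table.dna_to_lipid_ratio <= hi)]
        if sel.empty:
            raise ValidationError("stationary range contains no groups")
    grand = sel.mean_f.mean()
    flatness = float((sel.mean_f - grand).abs().max())
    return table, flatness
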