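"""qPCR standard curves, dilution-consistency quantification, abundances.

A qPCR standard curve is an ordinary least-squares fit of quantification
cycle Cq on log10 template copies over a tenfold dilution series (typically
10^1–10^8 copies per reaction, triplicate).  The slope gives the per-cycle
amplification efficiency

    E = (10^(-1/slope) - 1) * 100  [%],

100% meaning perfect doubling (slope -1/log10(2) = -3.3219).  Curves with
r^2 < 0.98 are flagged against the usual acceptance rule.

Environmental extracts are quantified at several template dilutions (10x to
10,000x) to dodge PCR inhibition by co-extracted substances; the two highest
dilutions whose back-scaled estimates agree within a log10 tolerance are
averaged geometrically to give the final copy number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "QuantResult",
    "AbundanceProfile",
    "fit_standard_curve",
    "quantify",
    "relative_abundance",
    "efficiency_from_slope",
    "slope_from_efficiency",
]

R2_ACCEPTANCE = 0.98


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope."""
    if slope >= 0:
        raise ValueError("amplifying assays require slope < 0")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_fraction: float) -> float:
    """Inverse mapping: slope = -1/log10(1+E) with E as a fraction."""
    if efficiency_fraction <= 0:
        raise ValueError("efficiency must be > 0")
    return -1.0 / math.log10(1.0 + efficiency_fraction)


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Cq on log10(copies) with derived efficiency."""

    points: tuple[tuple[float, float], ...]  # (log10_copies, Cq), replicates kept
    slope: float
    intercept: float
    r2: float

    @property
    def efficiency_percent(self) -> float:
        return efficiency_from_slope(self.slope)

    @property
    def passes_r2(self) -> bool:
        return self.r2 >= R2_ACCEPTANCE

    def copies_from_cq(self, cq: float) -> float:
        """Invert the curve: copies in the reaction producing this Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
) -> StandardCurve:
    """Fit a standard curve from (log10_copies, Cq) replicate points.

    Requires >= 3 distinct dilution levels and finite Cq values; slope must be
    negative (more template, earlier quantification cycle).
    """
    pts = [(float(x), float(y)) for x, y in points]
    if any(not (math.isfinite(x) and math.isfinite(y)) for x, y in pts):
        raise ValueError("non-finite log10_copies or Cq")
    levels = {round(x, 9) for x, _ in pts}
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct dilution levels, got {len(levels)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError(f"non-negative slope {res.slope:.4g}: not an amplifying assay")
    return StandardCurve(tuple(pts), float(res.slope), float(res.intercept),
                         float(res.rvalue**2))


@dataclass(frozen=True)
class QuantResult:
    """Dilution-consistency quantification of one sample x assay."""

    copies_per_dilution: Mapping[float, float]  # dilution factor -> scaled copies
    consistent_pair: tuple[float, float] | None  # the two dilution factors used
    final_copies: float | None  # geometric mean over the pair; None if inconclusive
    tolerance_log10: float

    @property
    def inconclusive(self) -> bool:
        return self.final_copies is None


def quantify(
    cq_by_dilution: Mapping[float, Sequence[float] | float],
    curve: StandardCurve,
    tolerance_log10: float = 0.3,
) -> QuantResult:
    """Quantify an unknown from Cq values measured at several dilutions.

    Per dilution factor d, the extract-level estimate is
    ``10^((Cq - intercept)/slope) * d`` (replicates combined by geometric
    mean).  The pair of highest dilution factors whose estimates agree within
    ``tolerance_log10`` (default 0.3, about twofold) is selected — higher
    dilutions are trusted because PCR inhibition fades with dilution — and the
    final value is the geometric mean of the pair.  A single measured dilution degenerates to
    its own estimate (no pair to cross-check); otherwise no agreeing pair
    flags the result inconclusive rather than raising.
    """
    if tolerance_log10 <= 0:
        raise ValueError("tolerance_log10 must be > 0")
    est: dict[float, float] = {}
    for d, cqs in cq_by_dilution.items():
        vals = [cqs] if isinstance(cqs, (int, float)) else list(cqs)
        if not vals:
            raise ValueError(f"no Cq values for dilution {d}")
        logs = [math.log10(curve.copies_from_cq(c) * d) for c in vals]
        est[float(d)] = 10.0 ** (sum(logs) / len(logs))
    dils = sorted(est, reverse=True)  # highest dilution factor first
    if len(dils) == 1:
        return QuantResult(est, None, est[dils[0]], tolerance_log10)
    pair = None
    for i in range(len(dils)):
        for j in range(i + 1, len(dils)):
            hi, lo = dils[i], dils[j]
            if abs(math.log10(est[hi]) - math.log10(est[lo])) <= tolerance_log10:
                pair = (hi, lo)
                break
        if pair:
            break
    if pair is None:
        return QuantResult(est, None, None, tolerance_log10)
    gm = math.sqrt(est[pair[0]] * est[pair[1]])
    return QuantResult(est, pair, gm, tolerance_log10)


@dataclass(frozen=True)
class AbundanceProfile:
    """Copy numbers and fractions of summed total amoA across assays."""

    copies: Mapping[str, float]
    fractions: Mapping[str, float] | None  # None when the total is 0

    @property
    def defined(self) -> bool:
        return self.fractions is not None


def relative_abundance(copies_by_group: Mapping[str, float]) -> AbundanceProfile:
    """Per-group fraction of the summed copy number (e.g. clade A vs AOA vs AOB).

    Fractions sum to 1 over assayed groups; an all-zero input yields a flagged
    undefined profile instead of dividing by zero.
    """
    if not copies_by_group:
        raise ValueError("no groups")
    if any(v < 0 for v in copies_by_group.values()):
        raise ValueError("negative copy numbers")
    total = sum(copies_by_group.values())
    if total == 0:
        return AbundanceProfile(dict(copies_by_group), None)
    fr = {g: v / total for g, v in copies_by_group.items()}
    return AbundanceProfile(dict(copies_by_group), fr)
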