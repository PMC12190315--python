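"""Ethanol intake from bottle masses, and blood-ethanol accumulation slopes.

Intake in g ethanol per kg body mass is the standard drinking-in-the-dark
conversion: the mass of solution removed from the bottle is converted to a
volume through the solution density, the ethanol volume fraction and ethanol
density give grams of ethanol, and the result is normalised to body mass:

    intake = (m_pre - m_post) / rho_solution * f_ethanol * rho_ethanol
             / (body_mass / 1000)

with rho_ethanol = 0.789 g/mL and rho_solution defaulting to 0.97 g/mL for
20% v/v ethanol (standard ethanol-water density tables); both are
configurable.

The accumulation relation — blood ethanol concentration at session end as a
function of intake — is fit per group by ordinary least squares (intercept
included by default, through-origin available).  Its group slope ratio is
the unit-free pharmacokinetic contrast of interest; a bootstrap percentile
interval over animals accompanies it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as sps

from .errors import ValidationError
from .event_io import SessionRecord

_log = logging.getLogger(__name__)

ETHANOL_DENSITY = 0.789  # g/mL


@dataclass(frozen=True)
class FluidSpec:
    """Composition of the bottle fluid for intake conversion."""

    ethanol_vol_fraction: float = 0.20
    ethanol_density: float = ETHANOL_DENSITY
    solution_density: float = 0.97  # g/mL, 20% v/v ethanol in water
    additive: str = "none"  # none | saccharin03 | saccharin01

    def __post_init__(self):
        if not (0 <= self.ethanol_vol_fraction <= 1):
            raise ValidationError("ethanol_vol_fraction must be in [0, 1]")
        if self.ethanol_density <= 0 or self.solution_density <= 0:
            raise ValidationError("densities must be > 0")
        if self.additive not in ("none", "saccharin03", "saccharin01"):
            raise ValidationError(f"unknown additive {self.additive!r}")


WATER_SPEC = FluidSpec(ethanol_vol_fraction=0.0, solution_density=1.0)

#: FluidSpec presets keyed by the manifest fluid enum.
FLUID_SPECS: dict[str, FluidSpec] = {
    "ethanol20": FluidSpec(),
    "ethanol20_saccharin03": FluidSpec(additive="saccharin03"),
    "saccharin01": FluidSpec(
        ethanol_vol_fraction=0.0, solution_density=1.0, additive="saccharin01"
    ),
    "water": WATER_SPEC,
}


@dataclass
class AccumulationFit:
    group: str
    slope: float      # concentration per (g/kg)
    intercept: float  # concentration
    r_squared: float
    n: int


@dataclass
class SlopeRatio:
    ratio: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0


def compute_intake(session: SessionRecord, fluid: FluidSpec = FluidSpec()) -> float:
    """Ethanol intake for one session, g ethanol per kg body mass."""
    if session.body_mass <= 0:
        raise ValidationError("body mass must be > 0")
    mass_diff = session.bottle_mass_pre - session.bottle_mass_post
    volume_ml = mass_diff / fluid.solution_density
    grams_ethanol = volume_ml * fluid.ethanol_vol_fraction * fluid.ethanol_density
    return grams_ethanol / (session.body_mass / 1000.0)


def _ols(x: np.ndarray, y: np.ndarray, include_intercept: bool) -> tuple[float, float, float]:
    if include_intercept:
        res = sps.linregress(x, y)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)
    slope = float(np.dot(x, y) / np.dot(x, x))
    resid = y - slope * x
    ss_tot = float(np.dot(y, y))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else np.nan
    return slope, 0.0, r2


def fit_accumulation(
    intake: Sequence[float],
    bec: Sequence[float],
    groups: Sequence[str],
    include_intercept: bool = True,
) -> dict[str, AccumulationFit]:
    """Per-group OLS of blood ethanol concentration on intake (g/kg).

    Requires at least 3 points and non-degenerate intake variance per group.
    """
    intake = np.asarray(intake, dtype=float)
    bec = np.asarray(bec, dtype=float)
    groups = np.asarray(groups)
    if not (intake.size == bec.size == groups.size):
        raise ValidationError("intake, bec and groups must have equal length")
    fits: dict[str, AccumulationFit] = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        mask = groups == g
        x, y = intake[mask], bec[mask]
        if x.size < 3:
            raise ValidationError(
                f"group {g!r} has {x.size} points; >= 3 required for a fit"
            )
        if np.ptp(x) == 0:
            raise ValidationError(f"group {g!r} has zero intake variance")
        slope, intercept, r2 = _ols(x, y, include_intercept)
        fits[str(g)] = AccumulationFit(str(g), slope, intercept, r2, int(x.size))
    return fits


def slope_ratio(
    fit_a: AccumulationFit,
    fit_b: AccumulationFit,
    points_a: tuple[Sequence[float], Sequence[float]] | None = None,
    points_b: tuple[Sequence[float], Sequence[float]] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    include_intercept: bool = True,
) -> SlopeRatio:
    """Ratio of accumulation slopes, b over a.

    When the underlying (intake, bec) points are supplied, a seeded bootstrap
    over animals (pairs resampled with replacement within each group,
    ``n_boot`` replicates) gives a 95% percentile interval; degenerate
    resamples are skipped.
    """
    if fit_a.slope == 0:
        raise ValidationError("denominator slope is zero")
    ratio = fit_b.slope / fit_a.slope
    if points_a is None or points_b is None:
        return SlopeRatio(ratio)
    rng = np.random.default_rng(seed)
    xa, ya = (np.asarray(v, dtype=float) for v in points_a)
    xb, yb = (np.asarray(v, dtype=float) for v in points_b)
    ratios = []
    for _ in range(n_boot):
        ia = rng.integers(0, xa.size, xa.size)
        ib = rng.integers(0, xb.size, xb.size)
        if np.ptp(xa[ia]) == 0 or np.ptp(xb[ib]) == 0:
            continue
        sa, _, _ = _ols(xa[ia], ya[ia], include_intercept)
        sb, _, _ = _ols(xb[ib], yb[ib], include_intercept)
        if sa != 0:
            ratios.append(sb / sa)
    if not ratios:
        return SlopeRatio(ratio)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return SlopeRatio(ratio, float(lo), float(hi), len(ratios))
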