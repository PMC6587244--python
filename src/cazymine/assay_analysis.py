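"""Enzyme-assay analytics: standard curves, activity calls, units.

Colorimetric assays (DNS reducing-sugar at 540 nm for endoglucanase on
CMC; p-nitrophenol at 405 nm for exoglucanase/β-glucosidase on
pNPC/pNPG) are quantified against a linear standard curve. One enzyme
unit (U) is 1 µmol of product released per minute; specific activity is
U per mg protein.

A crude extract is called active on a substrate when its mean
absorbance-derived product exceeds 1.5 × (negative-control mean +
control standard deviation); the alternative reading of that rule,
control mean + 1.5 × control SD, is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Mapping, Sequence

from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration: absorbance = intercept + slope × concentration."""

    analyte: str
    slope: float
    intercept: float
    r2: float

    def concentration(self, absorbance: float) -> float:
        """Invert the curve (product concentration in the curve's units)."""
        return (absorbance - self.intercept) / self.slope


@dataclass(frozen=True)
class ActivityCall:
    clone_id: str
    substrate: str
    sample_mean: float
    control_mean: float
    control_sd: float
    threshold: float
    positive: bool


@dataclass(frozen=True)
class OptimumProfile:
    optimum: float
    relative: dict[float, float]  # condition -> % of max
    tied: bool


def fit_standard_curve(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    analyte: str = "glucose",
) -> StandardCurve:
    """Ordinary-least-squares line through the standard wells.

    Requires ≥ 3 distinct concentrations and a positive slope (a
    non-increasing calibration is rejected rather than silently
    inverted downstream).
    """
    if len(concentrations) != len(absorbances):
        raise ValueError("concentrations and absorbances differ in length")
    if len(set(concentrations)) < 3:
        raise ValueError("need at least 3 distinct standard concentrations")
    fit = stats.linregress(concentrations, absorbances)
    if not math.isfinite(fit.slope) or fit.slope <= 0:
        raise ValueError(f"standard curve slope {fit.slope} is not positive")
    return StandardCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def call_activity(
    sample_wells: Sequence[float],
    control_wells: Sequence[float],
    clone_id: str = "",
    substrate: str = "",
    factor: float = 1.5,
    alternative_rule: bool = False,
) -> ActivityCall:
    """Positive iff mean(sample) strictly exceeds the control threshold.

    Primary rule: threshold = factor × (control mean + control SD);
    ``alternative_rule`` uses control mean + factor × control SD
    instead. The SD is the n−1 sample standard deviation, so at least
    two control wells are required; duplicates suffice.
    """
    if len(control_wells) < 2:
        raise ValueError("need ≥ 2 control wells to estimate their SD")
    if not sample_wells:
        raise ValueError("need ≥ 1 sample well")
    c_mean = mean(control_wells)
    c_sd = stdev(control_wells)
    s_mean = mean(sample_wells)
    if alternative_rule:
        threshold = c_mean + factor * c_sd
    else:
        threshold = factor * (c_mean + c_sd)
    return ActivityCall(
        clone_id=clone_id,
        substrate=substrate,
        sample_mean=s_mean,
        control_mean=c_mean,
        control_sd=c_sd,
        threshold=threshold,
        positive=s_mean > threshold,
    )


def specific_activity(
    delta_absorbance: float,
    curve: StandardCurve,
    reaction_minutes: float,
    reaction_volume_ml: float,
    protein_mg: float,
) -> float:
    """Specific activity in U/mg from a blanked absorbance change.

    µmol product = concentration(delta_absorbance) × reaction volume;
    U = µmol/min; result = U / mg protein. The reaction volume and time
    are assay-dependent and must be supplied explicitly.
    """
    if reaction_minutes <= 0 or reaction_volume_ml <= 0:
        raise ValueError("reaction time and volume must be positive")
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    umol = curve.concentration(delta_absorbance) * reaction_volume_ml
    units = umol / reaction_minutes
    return units / protein_mg


def profile_optimum(activities: Mapping[float, float]) -> OptimumProfile:
    """Optimum condition (temperature or pH) and relative-activity curve.

    The optimum is the argmax; ties are resolved to the lower condition
    value and flagged. Relative activity is 100 × activity / max.
    """
    if len(activities) < 3:
        raise ValueError("need ≥ 3 conditions to profile an optimum")
    peak = max(activities.values())
    if peak <= 0:
        raise ValueError("all activities are zero; no optimum defined")
    winners = sorted(c for c, a in activities.items() if a == peak)
    relative = {c: 100.0 * a / peak for c, a in sorted(activities.items())}
    return OptimumProfile(optimum=winners[0], relative=relative, tied=len(winners) > 1)


def residual_activity(
    timecourse: Mapping[float, float],
    baseline: float,
    monotone_tol: float = 1e-9,
) -> tuple[dict[float, float], bool]:
    """Percent of original activity retained per timepoint.

    Returns (residual %, monotone-decay flag); the flag is True when
    the chronologically ordered residuals never increase by more than
    ``monotone_tol``.
    """
    if baseline <= 0:
        raise ValueError("baseline activity must be positive")
    if not timecourse:
        raise ValueError("empty timecourse")
    items = sorted(timecourse.items())
    residuals = {t: 100.0 * a / baseline for t, a in items}
    vals = [residuals[t] for t, _ in items]
    monotone = all(b <= a + monotone_tol for a, b in zip(vals, vals[1:]))
    return residuals, monotone


__all__ = [
    "StandardCurve", "ActivityCall", "OptimumProfile",
    "fit_standard_curve", "call_activity", "specific_activity",
    "profile_optimum", "residual_activity",
]
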