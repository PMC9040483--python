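"""Stomatal-density traits: FOV counts → densities, per-sample medians,
automatic-vs-manual validation, and between-season plasticity.

One field of view covers 0.64 mm² of abaxial leaf surface (800 × 800 µm),
so stomatal density SD = count / 0.64 in mm⁻².  A sample contributes 4–6
FOV; its trait value is the median FOV density.  Plasticity between two
growing seasons is expressed as a percent change with the wetter-year
value as the reference, oriented so that the typical response (SLA up,
SD down in the second season) comes out positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FOV_AREA_MM2",
    "SDRecord",
    "ValidationFit",
    "stomatal_density",
    "sample_median_sd",
    "validate_counts",
    "percent_change_sla",
    "percent_change_sd",
    "pearson_correlation",
]

#: Area of one 800 × 800 µm field of view.
DEFAULT_FOV_AREA_MM2 = 0.64


@dataclass
class SDRecord:
    sample_id: str
    fov_densities: list[float]
    median_density: float
    n_fov: int


@dataclass
class ValidationFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    direction: str


def stomatal_density(count: int, fov_area_mm2: float = DEFAULT_FOV_AREA_MM2) -> float:
    """Stomata per mm²: count divided by the imaged area."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if fov_area_mm2 <= 0:
        raise ValueError("fov_area_mm2 must be positive")
    return count / fov_area_mm2


def sample_median_sd(fov_densities: list[float], sample_id: str = "sample") -> SDRecord:
    """Median of the per-FOV densities; warns when n is outside 4–6."""
    densities = [float(d) for d in fov_densities]
    if not densities:
        raise ValueError("at least one FOV density required")
    if any(d < 0 for d in densities):
        raise ValueError("densities must be non-negative")
    n = len(densities)
    if not (4 <= n <= 6):
        logger.warning("sample %s has %d FOV (expected 4-6)", sample_id, n)
    return SDRecord(
        sample_id=sample_id,
        fov_densities=densities,
        median_density=float(np.median(densities)),
        n_fov=n,
    )


def validate_counts(
    auto: list[float], manual: list[float], direction: str = "auto_on_manual"
) -> ValidationFit:
    """OLS validation of automatic against manual counts.

    ``auto_on_manual`` regresses automatic on manual (y = auto); the
    reverse direction is available; R² is identical either way in simple
    regression.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be 1-D and equal length")
    if len(auto) < 3:
        raise ValueError("need at least 3 paired counts")
    if direction == "auto_on_manual":
        x, y = manual, auto
    elif direction == "manual_on_auto":
        x, y = auto, manual
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor")
    fit = stats.linregress(x, y)
    return ValidationFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(auto),
        direction=direction,
    )


def percent_change_sla(sla_2016: float, sla_2017: float) -> float:
    """(SLA₂₀₁₇ − SLA₂₀₁₆) / SLA₂₀₁₇ × 100 — positive when SLA rises."""
    if sla_2017 <= 0:
        raise ValueError("reference-year SLA must be positive")
    return (sla_2017 - sla_2016) / sla_2017 * 100.0


def percent_change_sd(sd_2016: float, sd_2017: float) -> float:
    """(SD₂₀₁₆ − SD₂₀₁₇) / SD₂₀₁₆ × 100 — positive when density drops."""
    if sd_2016 <= 0:
        raise ValueError("reference-year SD must be positive")
    return (sd_2016 - sd_2017) / sd_2016 * 100.0


def pearson_correlation(x: list[float], y: list[float]) -> tuple[float, float]:
    """Pearson r and two-sided p between two trait vectors."""
    r, p = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p)
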