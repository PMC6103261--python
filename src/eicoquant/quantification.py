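"""Calibration and concentration calculation.

Standard curves are weighted linear regressions of response (peak area, or
analyte/IS area ratio) on nominal concentration; the customary weighting for
bioanalytical dilution series spanning two or more decades is 1/x, which
keeps the low standards from being swamped by the variance of the high ones.
The LLOQ is the lowest calibration level at which the median S/N is >= 10
and the replicate CV of back-calculated concentrations is <= 20%.

Sample concentrations are computed from the analyte/IS area ratio times the
known IS concentration (stable-isotope dilution), then normalized to the
sample basis (volume, tissue mass, cell count, or protein/DNA content).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateDesignError, UnquantifiableError, WeightingError
from .signal_extraction import PeakResult

__all__ = [
    "CalibrationCurve",
    "BackCalculation",
    "LloqDecision",
    "QuantResult",
    "fit_calibration",
    "back_calculate",
    "determine_lloq",
    "quantify",
    "normalize",
    "WEIGHTINGS",
    "DEFAULT_EXTRACT_VOLUME_UL",
]

WEIGHTINGS = ("none", "1/x", "1/x^2")
_BASIS_KINDS = ("volume", "tissue_mass", "cell_count", "protein")

#: Final reconstitution volume of the extraction protocol, µL.
DEFAULT_EXTRACT_VOLUME_UL = 50.0


@dataclass(frozen=True)
class CalibrationCurve:
    analyte_id: str
    slope: float
    intercept: float
    r_squared: float
    weighting: str
    response_mode: str
    points: tuple[tuple[float, float, int], ...]
    lloq_ng_ml: float | None = None

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(sorted({p[0] for p in self.points}))


@dataclass(frozen=True)
class BackCalculation:
    concentration_ng_ml: float
    below_lloq: bool
    above_range: bool


@dataclass(frozen=True)
class LevelDiagnostic:
    level_ng_ml: float
    median_snr: float
    cv_percent: float
    snr_pass: bool
    cv_pass: bool


@dataclass(frozen=True)
class LloqDecision:
    lloq_ng_ml: float | None
    diagnostics: tuple[LevelDiagnostic, ...]


@dataclass(frozen=True)
class QuantResult:
    analyte_id: str
    area_ratio: float
    concentration_ng_ml: float
    normalized_value: float | None = None
    basis: str | None = None


def _weights(x: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(x)
    if weighting in {"1/x", "1/x^2"}:
        if np.any(x <= 0):
            raise WeightingError(f"{weighting} weighting requires all concentrations > 0")
        return 1.0 / x if weighting == "1/x" else 1.0 / x**2
    raise WeightingError(f"unknown weighting {weighting!r}; choose from {WEIGHTINGS}")


def fit_calibration(
    points: Sequence[tuple],
    weighting: str = "1/x",
    response_mode: str = "area",
    analyte_id: str = "",
) -> CalibrationCurve:
    """Weighted least-squares line through (nominal concentration, response).

    ``points`` are ``(nominal_ng_ml, response)`` or
    ``(nominal_ng_ml, response, replicate_index)`` tuples. Minimizes
    Σ wᵢ (yᵢ − a − b·xᵢ)² with wᵢ ∈ {1, 1/xᵢ, 1/xᵢ²}; the coefficients come
    from the closed-form weighted normal equations, and r² is the weighted
    coefficient of determination (consistent with the fit's objective).
    """
    norm_points: list[tuple[float, float, int]] = []
    for i, p in enumerate(points):
        if len(p) == 2:
            norm_points.append((float(p[0]), float(p[1]), i))
        else:
            norm_points.append((float(p[0]), float(p[1]), int(p[2])))
    x = np.array([p[0] for p in norm_points])
    y = np.array([p[1] for p in norm_points])
    if np.unique(x).size < 2:
        raise DegenerateDesignError(
            "calibration requires at least 2 distinct concentration levels"
        )
    w = _weights(x, weighting)
    sw = w.sum()
    swx = (w * x).sum()
    swy = (w * y).sum()
    swxx = (w * x * x).sum()
    swxy = (w * x * y).sum()
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    fitted = intercept + slope * x
    ybar_w = swy / sw
    ss_res = (w * (y - fitted) ** 2).sum()
    ss_tot = (w * (y - ybar_w) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(
        analyte_id=analyte_id,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        weighting=weighting,
        response_mode=response_mode,
        points=tuple(norm_points),
    )


def back_calculate(curve: CalibrationCurve, response: float) -> BackCalculation:
    """Invert the curve: concentration = (response − intercept) / slope.

    Values at or below zero, or below the curve's LLOQ when one is set, are
    flagged ``below_lloq``; values above the top calibration level are
    flagged ``above_range`` (reported, not extrapolated away).
    """
    if curve.slope == 0:
        raise UnquantifiableError(f"{curve.analyte_id}: zero slope")
    conc = (response - curve.intercept) / curve.slope
    below = conc <= 0.0 or (curve.lloq_ng_ml is not None and conc < curve.lloq_ng_ml)
    above = conc > max(curve.levels)
    return BackCalculation(float(conc), below, above)


def determine_lloq(
    back_calculated: Mapping[float, Sequence[float]],
    snr_by_level: Mapping[float, float | Sequence[float]],
    cv_threshold: float = 20.0,
    snr_threshold: float = 10.0,
) -> LloqDecision:
    """Lowest calibration level passing both the S/N and the CV criterion.

    ``back_calculated`` maps each nominal level to its replicate
    back-calculated concentrations; ``snr_by_level`` to a scalar or replicate
    S/N values (the median is used). A level passes when median S/N >=
    ``snr_threshold`` AND the replicate CV <= ``cv_threshold``; when no level
    passes, ``lloq_ng_ml`` is None and the diagnostics list every failure.
    """
    diagnostics: list[LevelDiagnostic] = []
    lloq: float | None = None
    for level in sorted(back_calculated):
        values = np.asarray(back_calculated[level], dtype=float)
        snr_values = np.atleast_1d(np.asarray(snr_by_level[level], dtype=float))
        med_snr = float(np.median(snr_values))
        mean = values.mean()
        if values.size < 2 or mean == 0:
            cv = float("inf")
        else:
            cv = float(values.std(ddof=1) / mean * 100.0)
        snr_ok = med_snr >= snr_threshold
        cv_ok = cv <= cv_threshold
        diagnostics.append(LevelDiagnostic(level, med_snr, cv, snr_ok, cv_ok))
        if lloq is None and snr_ok and cv_ok:
            lloq = level
    return LloqDecision(lloq, tuple(diagnostics))


def quantify(
    analyte_peak: PeakResult,
    is_peak: PeakResult,
    is_concentration_ng_ml: float,
    analyte_id: str = "",
) -> QuantResult:
    """Stable-isotope-dilution quantification.

    concentration = (analyte area / IS area) × IS concentration. A missing
    or zero-area IS peak makes the whole sample unquantifiable.
    """
    if not is_peak.found or is_peak.area <= 0:
        raise UnquantifiableError(
            f"{analyte_id or 'sample'}: internal-standard peak missing or empty"
        )
    if not analyte_peak.found:
        raise UnquantifiableError(f"{analyte_id or 'analyte'}: peak not found")
    ratio = analyte_peak.area / is_peak.area
    return QuantResult(
        analyte_id=analyte_id,
        area_ratio=float(ratio),
        concentration_ng_ml=float(ratio * is_concentration_ng_ml),
    )


def normalize(
    result: QuantResult,
    basis_value: float,
    basis_kind: str,
    extract_volume_ul: float = DEFAULT_EXTRACT_VOLUME_UL,
) -> QuantResult:
    """Normalize an extract concentration to the original sample basis.

    The analyte amount in the final extract is ``concentration ×
    extract_volume``. Basis units: ``volume`` in µL (result: ng/mL of the
    original fluid), ``tissue_mass`` in mg (ng/mg), ``cell_count`` in cells
    (ng/cell), ``protein`` in µg (ng/µg).
    """
    if basis_kind not in _BASIS_KINDS:
        raise ValueError(f"unknown basis kind {basis_kind!r}; choose from {_BASIS_KINDS}")
    if basis_value <= 0:
        raise ValueError("basis_value must be > 0")
    if extract_volume_ul <= 0:
        raise ValueError("extract_volume_ul must be > 0")
    if basis_kind == "volume":
        value = result.concentration_ng_ml * extract_volume_ul / basis_value
    else:
        amount_ng = result.concentration_ng_ml * extract_volume_ul / 1000.0
        value = amount_ng / basis_value
    return replace(result, normalized_value=float(value), basis=basis_kind)
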