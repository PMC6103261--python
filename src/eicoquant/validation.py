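"""Bioanalytical method-validation statistics and acceptance gates.

Accuracy is the relative error RE = (Cex − Cav)/Cex × 100 between the
expected (nominal) concentration Cex and the measured mean Cav; precision
is the relative standard deviation RSD = SD/Cav × 100 over replicates
(sample SD, n−1 denominator). Extraction recovery compares pre-extraction-
spiked samples with unextracted neat standards; the matrix effect compares
post-extraction spikes with the same neat standards (>100% = ionization
enhancement, <100% = suppression). The acceptance gates follow FDA
bioanalytical guidance: RSD <= 15% and |RE| <= 15% (20% at the LLOQ level),
mean accuracy within 80–120%, and replicate CV <= 15% for recovery and
matrix-effect determinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationStats",
    "MatrixAssessment",
    "RecoveryResult",
    "GateThresholds",
    "relative_error",
    "relative_standard_deviation",
    "summarize_qc",
    "recovery",
    "matrix_effect",
    "fda_gate",
]


def relative_error(expected: float, measured_mean: float) -> float:
    """Signed accuracy error, percent: (Cex − Cav)/Cex × 100."""
    if expected <= 0:
        raise ValueError("expected concentration must be > 0")
    return (expected - measured_mean) / expected * 100.0


def relative_standard_deviation(values: Sequence[float]) -> float:
    """Precision, percent: sample SD (n−1) over the mean × 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero-mean replicates")
    return float(arr.std(ddof=1) / mean * 100.0)


@dataclass(frozen=True)
class ValidationStats:
    """Precision/accuracy summary for one (analyte, level) cell."""

    analyte_id: str
    level_label: str
    scope: str  # "intraday" or "interday"
    expected_ng_ml: float
    mean_ng_ml: float
    sd_ng_ml: float
    rsd_percent: float
    re_percent: float
    n: int
    day: int | None = None
    flagged: bool = False  # insufficient replicates


@dataclass(frozen=True)
class RecoveryResult:
    is_id: str
    matrix: str
    level_label: str
    recovery_percent: float
    sd_percent: float
    n: int


@dataclass(frozen=True)
class MatrixAssessment:
    is_id: str
    matrix: str
    level_label: str
    matrix_effect_percent: float
    sd_percent: float
    n: int
    classification: str  # "suppression" | "enhancement" | "none"


def summarize_qc(
    quant: pd.DataFrame,
    scope: str,
    min_replicates: int = 2,
) -> list[ValidationStats]:
    """Per-(analyte, level) precision and accuracy from replicate QC results.

    ``quant`` needs columns analyte_id, level_label, day, replicate,
    concentration_ng_ml, expected_ng_ml. ``scope="intraday"`` pools within
    each day (one row per analyte/level/day); ``scope="interday"`` pools all
    replicates across days. Cells with fewer than ``min_replicates`` values
    are flagged rather than silently dropped.
    """
    if scope not in {"intraday", "interday"}:
        raise ValueError("scope must be 'intraday' or 'interday'")
    keys = ["analyte_id", "level_label"] + (["day"] if scope == "intraday" else [])
    out: list[ValidationStats] = []
    for key, group in quant.groupby(keys, sort=True):
        values = group["concentration_ng_ml"].to_numpy(dtype=float)
        expected = float(group["expected_ng_ml"].iloc[0])
        analyte, level = key[0], key[1]
        day = int(key[2]) if scope == "intraday" else None
        n = values.size
        if n < min_replicates:
            out.append(
                ValidationStats(analyte, level, scope, expected, float(values.mean()) if n else float("nan"),
                                float("nan"), float("nan"), float("nan"), n, day, flagged=True)
            )
            continue
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        out.append(
            ValidationStats(
                analyte_id=analyte,
                level_label=level,
                scope=scope,
                expected_ng_ml=expected,
                mean_ng_ml=mean,
                sd_ng_ml=sd,
                rsd_percent=relative_standard_deviation(values),
                re_percent=relative_error(expected, mean),
                n=n,
                day=day,
            )
        )
    return out


def _ratio_stats(numerator: Sequence[float], denominator: Sequence[float]) -> tuple[float, float, int]:
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.size == 0 or den.size == 0:
        raise ValueError("both replicate groups must be non-empty")
    den_mean = den.mean()
    if den_mean == 0:
        raise ValueError("neat-standard mean area is zero")
    ratios = num / den_mean * 100.0
    percent = float(num.mean() / den_mean * 100.0)
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return percent, sd, int(num.size)


def recovery(
    pre_spike_areas: Sequence[float],
    neat_areas: Sequence[float],
    is_id: str = "",
    matrix: str = "",
    level_label: str = "",
) -> RecoveryResult:
    """Extraction recovery: mean pre-extraction-spiked area over mean neat
    area × 100, with SD taken over the replicate ratios."""
    percent, sd, n = _ratio_stats(pre_spike_areas, neat_areas)
    return RecoveryResult(is_id, matrix, level_label, percent, sd, n)


def matrix_effect(
    post_spike_areas: Sequence[float],
    neat_areas: Sequence[float],
    is_id: str = "",
    matrix: str = "",
    level_label: str = "",
) -> MatrixAssessment:
    """Matrix effect: mean post-extraction-spiked area over mean neat area
    × 100; <100% is ionization suppression, >100% enhancement."""
    percent, sd, n = _ratio_stats(post_spike_areas, neat_areas)
    if np.isclose(percent, 100.0, rtol=0, atol=1e-9):
        cls = "none"
    elif percent < 100.0:
        cls = "suppression"
    else:
        cls = "enhancement"
    return MatrixAssessment(is_id, matrix, level_label, percent, sd, n, cls)


@dataclass(frozen=True)
class GateThresholds:
    """FDA-style acceptance thresholds (all in percent)."""

    rsd_limit: float = 15.0
    rsd_limit_lloq: float = 20.0
    re_limit: float = 15.0
    re_limit_lloq: float = 20.0
    accuracy_low: float = 80.0
    accuracy_high: float = 120.0
    replicate_cv_limit: float = 15.0


def fda_gate(
    stats: Sequence[ValidationStats],
    assessments: Sequence[RecoveryResult | MatrixAssessment] = (),
    thresholds: GateThresholds = GateThresholds(),
    lloq_levels: frozenset[str] | set[str] = frozenset(),
) -> pd.DataFrame:
    """Apply the acceptance gates and return a per-cell pass/fail table.

    Precision passes when RSD <= 15% (20% at a level named in
    ``lloq_levels``); accuracy passes when |RE| is within the same limits
    AND the mean accuracy Cav/Cex × 100 lies in [80, 120]. Recovery and
    matrix-effect rows pass when their replicate CV (SD over mean × 100)
    is <= 15%. Gates are monotone: tightening any threshold never turns a
    fail into a pass.
    """
    rows: list[dict] = []
    for s in stats:
        at_lloq = s.level_label in lloq_levels
        rsd_lim = thresholds.rsd_limit_lloq if at_lloq else thresholds.rsd_limit
        re_lim = thresholds.re_limit_lloq if at_lloq else thresholds.re_limit
        if s.flagged or not np.isfinite(s.rsd_percent):
            precision_pass = accuracy_pass = False
            accuracy_pct = float("nan")
        else:
            accuracy_pct = s.mean_ng_ml / s.expected_ng_ml * 100.0
            precision_pass = s.rsd_percent <= rsd_lim
            accuracy_pass = (
                abs(s.re_percent) <= re_lim
                and thresholds.accuracy_low <= accuracy_pct <= thresholds.accuracy_high
            )
        rows.append(
            {
                "kind": "qc",
                "analyte_id": s.analyte_id,
                "matrix": "",
                "level_label": s.level_label,
                "scope": s.scope,
                "day": s.day,
                "n": s.n,
                "rsd_percent": _round2(s.rsd_percent),
                "re_percent": _round2(s.re_percent),
                "accuracy_percent": _round2(accuracy_pct),
                "value_percent": float("nan"),
                "sd_percent": float("nan"),
                "replicate_cv_percent": float("nan"),
                "precision_pass": precision_pass,
                "accuracy_pass": accuracy_pass,
                "cv_pass": pd.NA,
                "overall_pass": precision_pass and accuracy_pass,
            }
        )
    for a in assessments:
        if isinstance(a, RecoveryResult):
            kind, value = "recovery", a.recovery_percent
        else:
            kind, value = "matrix_effect", a.matrix_effect_percent
        cv = a.sd_percent / value * 100.0 if value else float("inf")
        cv_pass = cv <= thresholds.replicate_cv_limit
        rows.append(
            {
                "kind": kind,
                "analyte_id": a.is_id,
                "matrix": a.matrix,
                "level_label": a.level_label,
                "scope": "",
                "day": None,
                "n": a.n,
                "rsd_percent": float("nan"),
                "re_percent": float("nan"),
                "accuracy_percent": float("nan"),
                "value_percent": _round2(value),
                "sd_percent": _round2(a.sd_percent),
                "replicate_cv_percent": _round2(cv),
                "precision_pass": pd.NA,
                "accuracy_pass": pd.NA,
                "cv_pass": cv_pass,
                "overall_pass": cv_pass,
            }
        )
    return pd.DataFrame(rows)


def _round2(x: float) -> float:
    """Two decimals, round-half-even, matching report precision."""
    if not np.isfinite(x):
        return x
    return float(round(x, 2))
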