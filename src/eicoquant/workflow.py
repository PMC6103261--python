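"""Pipeline orchestration: from scans (or recipes) to validation reports.

Ties the stages together the way the assay is actually run: extract every
scheduled channel, align retention times on the internal standards,
integrate, quantify by stable-isotope dilution, fit weighted calibration
curves from the standard series, and roll replicate results up into the
precision/accuracy/recovery/matrix-effect report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .method_library import RtTable, Transition
from .mzml_io import Run
from .quantification import (
    CalibrationCurve,
    LloqDecision,
    back_calculate,
    determine_lloq,
    fit_calibration,
)
from .signal_extraction import (
    DEFAULT_PRECURSOR_TOL_DA,
    align_by_internal_standards,
    detect_peak,
    estimate_snr,
    extract_channel,
)
from .synthetic import (
    GroundTruth,
    RunRecipe,
    simulate_run,
    simulate_validation_campaign,
)
from .validation import (
    GateThresholds,
    MatrixAssessment,
    RecoveryResult,
    ValidationStats,
    fda_gate,
    matrix_effect,
    recovery,
    summarize_qc,
)

__all__ = [
    "ExtractionParams",
    "quantify_run",
    "CampaignResult",
    "process_campaign",
    "build_calibration",
    "lloq_by_analyte",
    "qc_concentrations",
    "matrix_study_tables",
    "StudyResult",
    "run_validation_study",
    "isomer_assignment_study",
    "ISOBARIC_PAIRS",
]

#: Isobaric/isomeric pairs sharing indistinguishable channels, resolved by RT.
ISOBARIC_PAIRS = (
    ("PGE2", "PGD2"),
    ("LTB4", "6-trans-LTB4"),
    ("LTD4", "11-trans-LTD4"),
)


@dataclass(frozen=True)
class ExtractionParams:
    precursor_tol_da: float = DEFAULT_PRECURSOR_TOL_DA
    rt_tolerance_min: float = 0.5
    align: bool = True


def quantify_run(
    run: Run,
    library: Sequence[Transition],
    rt_table: RtTable,
    transition_ids: Sequence[str] | None = None,
    params: ExtractionParams = ExtractionParams(),
) -> pd.DataFrame:
    """Extract, align and integrate every requested channel of one run.

    Returns one row per transition with the apex RT, area, height, S/N
    (NaN when inestimable) and the IS-alignment offset applied.
    """
    index = {t.analyte_id: t for t in library}
    ids = list(transition_ids) if transition_ids is not None else [t.analyte_id for t in library]
    targets = [index[i] for i in ids]
    offset, align_ok = 0.0, True
    if params.align:
        is_ids = [t.analyte_id for t in targets if t.is_internal_standard]
        alignment = align_by_internal_standards(
            run,
            library,
            rt_table,
            is_ids=is_ids or None,
            precursor_tol_da=params.precursor_tol_da,
            rt_tolerance_min=params.rt_tolerance_min,
        )
        offset, align_ok = alignment.offset_min, alignment.ok
    rows = []
    for t in targets:
        expected = rt_table.entries.get(t.analyte_id)
        chrom = extract_channel(run, t, params.precursor_tol_da)
        if expected is None or len(chrom) == 0:
            peak = None
        else:
            peak = detect_peak(chrom, expected + offset, params.rt_tolerance_min)
        if peak is not None and peak.found:
            try:
                snr = estimate_snr(chrom, peak)
            except InsufficientDataError:
                snr = float("nan")
            rows.append(
                {
                    "run_id": run.run_id,
                    "analyte_id": t.analyte_id,
                    "is_internal_standard": t.is_internal_standard,
                    "paired_is_id": t.internal_standard_id or "",
                    "found": True,
                    "apex_rt_min": peak.apex_rt_min,
                    "left_rt_min": peak.left_rt_min,
                    "right_rt_min": peak.right_rt_min,
                    "area": peak.area,
                    "height": peak.height,
                    "snr": snr,
                    "rt_offset_min": offset,
                    "alignment_ok": align_ok,
                }
            )
        else:
            rows.append(
                {
                    "run_id": run.run_id,
                    "analyte_id": t.analyte_id,
                    "is_internal_standard": t.is_internal_standard,
                    "paired_is_id": t.internal_standard_id or "",
                    "found": False,
                    "apex_rt_min": float("nan"),
                    "left_rt_min": float("nan"),
                    "right_rt_min": float("nan"),
                    "area": 0.0,
                    "height": 0.0,
                    "snr": float("nan"),
                    "rt_offset_min": offset,
                    "alignment_ok": align_ok,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CampaignResult:
    """Per-transition peak table and ground truth for a simulated campaign."""

    peaks: pd.DataFrame
    truth: pd.DataFrame


_MANIFEST_COLS = ("sample_kind", "level_label", "matrix", "day", "replicate")


def process_campaign(
    recipes: Sequence[RunRecipe],
    library: Sequence[Transition],
    rt_table: RtTable,
    *,
    spectral_library=None,
    params: ExtractionParams = ExtractionParams(),
) -> CampaignResult:
    """Simulate and quantify every recipe, streaming one run at a time."""
    from .method_library import default_spectral_library

    if spectral_library is None:
        spectral_library = default_spectral_library(library)
    peak_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    for recipe in recipes:
        run, truth = simulate_run(
            recipe, library, rt_table, spectral_library=spectral_library
        )
        ids = sorted(set(recipe.analyte_concentrations) | set(recipe.is_concentrations))
        frame = quantify_run(run, library, rt_table, transition_ids=ids, params=params)
        for col, val in zip(
            _MANIFEST_COLS,
            (recipe.sample_kind, recipe.level_label, recipe.matrix, recipe.day, recipe.replicate),
        ):
            frame[col] = val
        frame["expected_ng_ml"] = [recipe.concentration_of(i) for i in frame["analyte_id"]]
        frame["is_spike_ng_ml"] = [
            recipe.is_concentrations.get(pid, float("nan")) for pid in frame["paired_is_id"]
        ]
        peak_frames.append(frame)
        for tid, tt in truth.per_transition.items():
            truth_rows.append(
                {
                    "run_id": recipe.run_id,
                    "analyte_id": tid,
                    "true_concentration_ng_ml": tt.true_concentration,
                    "true_area": tt.true_area,
                    "expected_area_after_factors": tt.expected_area_after_factors,
                    "rt_shift_min": truth.rt_shift_min,
                    "recovery_factor": truth.recovery_factor,
                    "matrix_factor": truth.matrix_factor,
                }
            )
    return CampaignResult(
        peaks=pd.concat(peak_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
    )


def build_calibration(
    peaks: pd.DataFrame,
    weighting: str = "1/x",
    response_mode: str = "area",
) -> tuple[dict[str, CalibrationCurve], pd.DataFrame]:
    """Fit per-analyte curves from the calibration runs of a peak table.

    ``response_mode="area"`` regresses the standard's peak area on nominal
    concentration; ``"area_ratio"`` uses the analyte/IS area ratio. Returns
    the curves and a back-calculation table (one row per standard
    injection) carrying replicate S/N for LLOQ determination.
    """
    cal = peaks[(peaks["sample_kind"] == "calibration") & (~peaks["is_internal_standard"])]
    is_areas = _is_area_lookup(peaks)
    curves: dict[str, CalibrationCurve] = {}
    back_rows: list[dict] = []
    for analyte, group in cal.groupby("analyte_id", sort=True):
        found = group[group["found"]]
        pts = []
        for _, row in found.iterrows():
            response = row["area"]
            if response_mode == "area_ratio":
                response = response / is_areas[(row["run_id"], row["paired_is_id"])]
            pts.append((row["expected_ng_ml"], response, row["replicate"]))
        if len({p[0] for p in pts}) < 2:
            continue
        curve = fit_calibration(pts, weighting, response_mode, analyte_id=analyte)
        curves[analyte] = curve
        for (level, response, rep), (_, row) in zip(pts, found.iterrows()):
            bc = back_calculate(curve, response)
            back_rows.append(
                {
                    "analyte_id": analyte,
                    "nominal_ng_ml": level,
                    "replicate": rep,
                    "back_calculated_ng_ml": bc.concentration_ng_ml,
                    "snr": row["snr"],
                }
            )
    return curves, pd.DataFrame(back_rows)


def lloq_by_analyte(
    backcalc: pd.DataFrame,
    cv_threshold: float = 20.0,
    snr_threshold: float = 10.0,
) -> dict[str, LloqDecision]:
    """LLOQ per analyte from replicate back-calculations and S/N."""
    out: dict[str, LloqDecision] = {}
    for analyte, group in backcalc.groupby("analyte_id", sort=True):
        levels: dict[float, list[float]] = {}
        snrs: dict[float, list[float]] = {}
        for _, row in group.iterrows():
            levels.setdefault(row["nominal_ng_ml"], []).append(row["back_calculated_ng_ml"])
            snr = row["snr"]
            snrs.setdefault(row["nominal_ng_ml"], []).append(
                1e12 if np.isinf(snr) else (0.0 if np.isnan(snr) else snr)
            )
        out[analyte] = determine_lloq(levels, snrs, cv_threshold, snr_threshold)
    return out


def _is_area_lookup(peaks: pd.DataFrame) -> dict[tuple[str, str], float]:
    is_rows = peaks[peaks["is_internal_standard"] & peaks["found"]]
    return {
        (row["run_id"], row["analyte_id"]): row["area"] for _, row in is_rows.iterrows()
    }


def qc_concentrations(peaks: pd.DataFrame) -> pd.DataFrame:
    """Isotope-dilution concentrations for the QC runs of a peak table.

    concentration = (analyte area / paired-IS area in the same run) × IS
    spike concentration. Analytes whose IS peak is missing are emitted with
    NaN concentration and ``quantifiable=False``.
    """
    qc = peaks[(peaks["sample_kind"] == "qc") & (~peaks["is_internal_standard"])]
    is_areas = _is_area_lookup(peaks)
    rows = []
    for _, row in qc.iterrows():
        key = (row["run_id"], row["paired_is_id"])
        is_area = is_areas.get(key, 0.0)
        ok = bool(row["found"]) and is_area > 0
        conc = (
            row["area"] / is_area * row["is_spike_ng_ml"] if ok else float("nan")
        )
        rows.append(
            {
                "run_id": row["run_id"],
                "analyte_id": row["analyte_id"],
                "level_label": row["level_label"],
                "day": row["day"],
                "replicate": row["replicate"],
                "expected_ng_ml": row["expected_ng_ml"],
                "concentration_ng_ml": conc,
                "quantifiable": ok,
            }
        )
    return pd.DataFrame(rows)


def matrix_study_tables(
    peaks: pd.DataFrame,
) -> tuple[list[RecoveryResult], list[MatrixAssessment]]:
    """Recovery and matrix-effect summaries from the spike-pair runs."""
    spikes = peaks[
        peaks["sample_kind"].isin(["matrix_pre_spike", "matrix_post_spike", "neat_standard"])
        & peaks["is_internal_standard"]
        & peaks["found"]
    ]
    recoveries: list[RecoveryResult] = []
    assessments: list[MatrixAssessment] = []
    neat = spikes[spikes["sample_kind"] == "neat_standard"]
    in_matrix = spikes[spikes["sample_kind"] != "neat_standard"]
    for (matrix, level, is_id), group in in_matrix.groupby(
        ["matrix", "level_label", "analyte_id"], sort=True
    ):
        neat_areas = neat[
            (neat["level_label"] == level) & (neat["analyte_id"] == is_id)
        ]["area"].to_numpy()
        if neat_areas.size == 0:
            continue
        pre = group[group["sample_kind"] == "matrix_pre_spike"]["area"].to_numpy()
        post = group[group["sample_kind"] == "matrix_post_spike"]["area"].to_numpy()
        if pre.size:
            recoveries.append(recovery(pre, neat_areas, is_id, matrix, level))
        if post.size:
            assessments.append(matrix_effect(post, neat_areas, is_id, matrix, level))
    return recoveries, assessments


@dataclass
class StudyResult:
    """Everything the validation campaign produces."""

    curves: dict[str, CalibrationCurve]
    backcalc: pd.DataFrame
    lloq: dict[str, LloqDecision]
    qc: pd.DataFrame
    intraday: list[ValidationStats]
    interday: list[ValidationStats]
    recoveries: list[RecoveryResult]
    matrix_effects: list[MatrixAssessment]
    gate_report: pd.DataFrame
    campaign: CampaignResult = field(repr=False, default=None)


def run_validation_study(
    seed: int,
    library: Sequence[Transition] | None = None,
    rt_table: RtTable | None = None,
    thresholds: GateThresholds = GateThresholds(),
    **campaign_kwargs,
) -> StudyResult:
    """Simulate the full validation campaign and compute every statistic.

    Keyword arguments are forwarded to
    :func:`eicoquant.synthetic.simulate_validation_campaign`, whose defaults
    are the study design (10-level curve × 5, QC 3 × 5 × 3 days,
    recovery/matrix-effect pairs n=6 per matrix, 5% injection noise).
    """
    from .method_library import load_bundled_rt_table, load_bundled_transitions

    if library is None:
        library = load_bundled_transitions()
    if rt_table is None:
        rt_table = load_bundled_rt_table()
    recipes = simulate_validation_campaign(library, rt_table, seed=seed, **campaign_kwargs)
    campaign = process_campaign(recipes, library, rt_table)
    curves, backcalc = build_calibration(campaign.peaks)
    lloq = lloq_by_analyte(backcalc)
    qc = qc_concentrations(campaign.peaks)
    quantifiable = qc[qc["quantifiable"]]
    intraday = summarize_qc(quantifiable, "intraday")
    interday = summarize_qc(quantifiable, "interday")
    recoveries, assessments = matrix_study_tables(campaign.peaks)
    gate_report = fda_gate(intraday + interday, recoveries + assessments, thresholds)
    return StudyResult(
        curves=curves,
        backcalc=backcalc,
        lloq=lloq,
        qc=qc,
        intraday=intraday,
        interday=interday,
        recoveries=recoveries,
        matrix_effects=assessments,
        gate_report=gate_report,
        campaign=campaign,
    )


def isomer_assignment_study(
    seed: int,
    library: Sequence[Transition] | None = None,
    rt_table: RtTable | None = None,
    n_replicates: int = 3,
    concentration_ratio: tuple[float, float] = (10.0, 5.0),
) -> pd.DataFrame:
    """Noiseless runs containing both members of each isobaric pair.

    The pair members share precursor and fragment windows, so their
    channels are identical and only retention time separates them; the
    assignment is correct when each channel's detected apex lies within
    0.15 min of its own member's (shift-corrected) true RT. Returns one
    row per (pair, replicate, member) with a ``correct`` flag.
    """
    from .method_library import load_bundled_rt_table, load_bundled_transitions

    if library is None:
        library = load_bundled_transitions()
    if rt_table is None:
        rt_table = load_bundled_rt_table()
    index = {t.analyte_id: t for t in library}
    seeds = np.random.SeedSequence(seed).generate_state(
        len(ISOBARIC_PAIRS) * n_replicates
    ) % (2**31)
    rows = []
    k = 0
    for first, second in ISOBARIC_PAIRS:
        is_ids = sorted(
            {index[first].internal_standard_id, index[second].internal_standard_id}
        )
        for rep in range(1, n_replicates + 1):
            recipe = RunRecipe(
                run_id=f"isomer_{first}_r{rep}",
                sample_kind="qc",
                level_label="isomer",
                analyte_concentrations={
                    first: concentration_ratio[0],
                    second: concentration_ratio[1],
                },
                is_concentrations={i: 148.1 for i in is_ids},
                noise_sd=0.0,
                area_cv=0.0,
                seed=int(seeds[k]),
                replicate=rep,
            )
            k += 1
            run, truth = simulate_run(recipe, library, rt_table)
            frame = quantify_run(
                run,
                library,
                rt_table,
                transition_ids=[first, second] + is_ids,
            )
            for member in (first, second):
                row = frame[frame["analyte_id"] == member].iloc[0]
                true_rt = rt_table.rt_for(member) + truth.rt_shift_min
                correct = bool(row["found"]) and abs(row["apex_rt_min"] - true_rt) <= 0.15
                rows.append(
                    {
                        "pair": f"{first}/{second}",
                        "replicate": rep,
                        "analyte_id": member,
                        "true_rt_min": true_rt,
                        "apex_rt_min": row["apex_rt_min"],
                        "correct": correct,
                    }
                )
    return pd.DataFrame(rows)
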