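"""Synthetic scheduled MRM-HR acquisitions with known ground truth.

The generator emulates the validation study's designs so every downstream
stage is testable without instrument data:

* a 10-level calibration dilution series (2.3 … 500 ng/mL) injected in
  replicate;
* quality-control samples at 0.15 / 1.5 / 5 ng/mL (LQC/MQC/HQC) across days;
* recovery and matrix-effect pairs, in which deuterated internal standards
  are spiked into a biological matrix either before extraction (recovery ×
  matrix factor applied) or after (matrix factor only) and compared with
  neat solvent standards.

Chromatographic peaks are exponentially modified Gaussians placed at the
expected retention times of the bundled panel; a per-run retention-time
shift (uniform, ±0.1 min by default) exercises IS-based alignment.
Scheduling follows the acquisition geometry of a product-ion experiment:
each transition is monitored inside a window around its expected RT, one
scan per active transition per cycle, with a 10 ms dwell per channel. Each
scan carries the quantifier fragment, the spectral-library qualifier
fragments at their relative intensities, optional additive detector noise
(floored at zero) over a flat chemical background, and Poisson-count
spurious centroids at random m/z within the 50–700 acquisition range.

Every stochastic operation is driven by an explicit integer seed; a
campaign derives per-run seeds from the master seed, so identical seeds
give identical scans, ground truth and mzML bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import SchedulingError, UnknownAnalyteError
from .method_library import (
    RtTable,
    SpectralLibraryEntry,
    Transition,
    default_spectral_library,
)
from .mzml_io import Run, Scan

__all__ = [
    "PeakModel",
    "RunRecipe",
    "TransitionTruth",
    "GroundTruth",
    "make_calibration_design",
    "make_qc_design",
    "make_is_levels",
    "simulate_run",
    "simulate_validation_campaign",
    "campaign_manifest",
    "MATRIX_FACTOR_DESIGN",
    "DEFAULT_CAMPAIGN_ANALYTES",
    "DEFAULT_RESPONSE_FACTOR",
    "DEFAULT_IS_SPIKE_NG_ML",
    "DWELL_MS",
]

#: Per-channel dwell time of the scheduled product-ion experiment, ms.
DWELL_MS = 10.0
#: Default detector response, intensity·min per ng/mL. Shared between an
#: analyte and its deuterated IS, as for co-eluting isotopologues.
DEFAULT_RESPONSE_FACTOR = 1000.0
#: IS concentration spiked into calibration/QC samples, ng/mL.
DEFAULT_IS_SPIKE_NG_ML = 148.1

#: Acquisition m/z range for spurious noise centroids.
_MZ_RANGE = (50.0, 700.0)

#: Compact analyte panel used for simulated campaigns: covers two of the
#: isobaric pairs that must be resolved chromatographically (PGE2/PGD2 share
#: a channel; LTB4 pairs with 6-trans-LTB4) plus early/late eluters.
DEFAULT_CAMPAIGN_ANALYTES = ("TXB2", "PGE2", "PGD2", "LTD4", "LTB4", "5-HETE")

#: Per-matrix, per-level (recovery %, matrix-effect %) pairs measured for the
#: PGE2-d4 internal standard; these are the generator's default spiking
#: conditions. Recovery as printed is the pre-spike vs neat response ratio,
#: i.e. extraction efficiency × matrix factor, so the injected
#: extraction-efficiency factor is recovery/ME and the ionization factor ME/100.
MATRIX_FACTOR_DESIGN: dict[str, dict[str, tuple[float, float]]] = {
    "plasma": {"HQC": (74.7, 88.5), "MQC": (91.7, 100.1), "LQC": (94.6, 93.7)},
    "lung": {"HQC": (53.9, 77.1), "MQC": (64.6, 105.0), "LQC": (60.5, 95.8)},
    "culture_medium": {"HQC": (56.6, 64.2), "MQC": (78.8, 94.3), "LQC": (71.5, 80.1)},
}


def make_calibration_design() -> list[float]:
    """The 10 calibration levels of the dilution series, ng/mL, ascending."""
    return [2.3, 4.6, 9.2, 18.5, 37.0, 74.0, 148.1, 222.2, 333.3, 500.0]


def make_qc_design() -> dict[str, float]:
    """Quality-control concentrations, ng/mL, by level label."""
    return {"LQC": 0.15, "MQC": 1.5, "HQC": 5.0}


def make_is_levels() -> dict[str, float]:
    """IS spiking solutions for recovery/matrix-effect studies, ng/mL."""
    return {"LQC": 18.5, "MQC": 148.1, "HQC": 500.0}


@dataclass(frozen=True)
class PeakModel:
    """Exponentially modified Gaussian chromatographic peak.

    ``asymmetry`` is the exponential tailing constant expressed in units of
    ``sigma_min`` (0 → symmetric Gaussian). ``true_area`` is the area of the
    quantifier-channel profile in intensity·min.
    """

    apex_rt_min: float
    sigma_min: float
    true_area: float
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be > 0")
        if self.true_area < 0:
            raise ValueError("true_area must be >= 0")
        if self.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Intensity at times ``t`` (minutes); integrates to ``true_area``."""
        t = np.asarray(t, dtype=float)
        if self.true_area == 0.0:
            return np.zeros_like(t)
        if self.asymmetry < 1e-9:
            pdf = stats.norm.pdf(t, loc=self.apex_rt_min, scale=self.sigma_min)
        else:
            pdf = stats.exponnorm.pdf(
                t, self.asymmetry, loc=self.apex_rt_min, scale=self.sigma_min
            )
        return self.true_area * pdf


_SAMPLE_KINDS = {
    "calibration",
    "qc",
    "matrix_pre_spike",
    "matrix_post_spike",
    "neat_standard",
    "blank",
}
_MATRICES = {"plasma", "lung", "culture_medium", "none"}


@dataclass(frozen=True)
class RunRecipe:
    """Complete description of one simulated injection.

    ``recovery_factor`` (extraction efficiency, fraction) applies only to
    pre-extraction spikes; ``matrix_factor`` (ionization suppression < 1,
    enhancement > 1) applies to both pre- and post-extraction spikes but not
    to neat standards. ``area_cv`` is a per-peak multiplicative noise
    fraction (injection-to-injection variability); ``noise_sd`` is additive
    per-centroid detector noise over a flat ``baseline_level`` background.
    """

    run_id: str
    sample_kind: str
    level_label: str
    analyte_concentrations: Mapping[str, float] = field(default_factory=dict)
    is_concentrations: Mapping[str, float] = field(default_factory=dict)
    matrix: str = "none"
    recovery_factor: float = 1.0
    matrix_factor: float = 1.0
    noise_sd: float = 0.0
    baseline_level: float = 0.0
    area_cv: float = 0.0
    noise_peak_rate: float = 3.0
    response_factor: float = DEFAULT_RESPONSE_FACTOR
    peak_sigma_min: float = 0.05
    peak_asymmetry: float = 0.0
    rt_shift_range_min: float = 0.1
    seed: int = 0
    day: int = 1
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.sample_kind not in _SAMPLE_KINDS:
            raise ValueError(f"unknown sample_kind {self.sample_kind!r}")
        if self.matrix not in _MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        for cmap in (self.analyte_concentrations, self.is_concentrations):
            for k, v in cmap.items():
                if v < 0:
                    raise ValueError(f"negative concentration for {k}")
        if not (0.0 < self.recovery_factor <= 1.5):
            raise ValueError("recovery_factor must be in (0, 1.5]")
        if self.matrix_factor <= 0:
            raise ValueError("matrix_factor must be > 0")

    @property
    def applied_recovery_factor(self) -> float:
        return self.recovery_factor if self.sample_kind == "matrix_pre_spike" else 1.0

    @property
    def applied_matrix_factor(self) -> float:
        in_matrix = self.sample_kind in {"matrix_pre_spike", "matrix_post_spike"}
        return self.matrix_factor if in_matrix else 1.0

    def concentration_of(self, transition_id: str) -> float:
        if transition_id in self.analyte_concentrations:
            return self.analyte_concentrations[transition_id]
        return self.is_concentrations.get(transition_id, 0.0)


@dataclass(frozen=True)
class TransitionTruth:
    analyte_id: str
    true_concentration: float
    true_area: float
    expected_area_after_factors: float


@dataclass(frozen=True)
class GroundTruth:
    """What actually went into a simulated run."""

    run_id: str
    rt_shift_min: float
    recovery_factor: float
    matrix_factor: float
    per_transition: Mapping[str, TransitionTruth]


def _scheduled_times(
    windows: dict[str, tuple[float, float]], dwell_min: float
) -> dict[str, np.ndarray]:
    """Scan times per transition: one scan per active transition per cycle,
    cycle time = dwell × number of concurrently scheduled transitions."""
    ids = sorted(windows)
    events = sorted({edge for w in windows.values() for edge in w})
    chunks: dict[str, list[np.ndarray]] = {i: [] for i in ids}
    for a, b in zip(events, events[1:]):
        mid = 0.5 * (a + b)
        active = [i for i in ids if windows[i][0] <= mid <= windows[i][1]]
        if not active:
            continue
        cycle = dwell_min * len(active)
        n_cycles = int(np.floor((b - a) / cycle))
        if n_cycles <= 0:
            continue
        starts = a + np.arange(n_cycles) * cycle
        for k, tid in enumerate(active):
            chunks[tid].append(starts + k * dwell_min)
    return {
        i: (np.concatenate(c) if c else np.empty(0, dtype=float))
        for i, c in chunks.items()
    }


def simulate_run(
    recipe: RunRecipe,
    library: Sequence[Transition],
    rt_table: RtTable,
    *,
    spectral_library: Mapping[str, SpectralLibraryEntry] | None = None,
    schedule_window_min: float = 0.5,
    dwell_ms: float = DWELL_MS,
    co_isolation_tol_da: float = 0.7,
) -> tuple[Run, GroundTruth]:
    """Simulate one scheduled MRM-HR injection.

    Returns the scan sequence and the ground truth (true areas,
    concentrations and the factors actually applied). Identical recipes
    (including seed) produce identical output.

    Raises
    ------
    UnknownAnalyteError
        If a recipe analyte is not in the library.
    SchedulingError
        If a scheduled transition has no retention time in ``rt_table``.
    """
    index = {t.analyte_id: t for t in library}
    ids = sorted(set(recipe.analyte_concentrations) | set(recipe.is_concentrations))
    for tid in ids:
        if tid not in index:
            raise UnknownAnalyteError(tid)
        try:
            rt_table.rt_for(tid)
        except UnknownAnalyteError as exc:
            raise SchedulingError(f"no expected RT for {tid}: {exc}") from None
    if spectral_library is None:
        spectral_library = default_spectral_library(library)

    rng = np.random.default_rng(recipe.seed)
    rt_shift = float(rng.uniform(-recipe.rt_shift_range_min, recipe.rt_shift_range_min))

    dwell_min = dwell_ms / 60000.0
    windows = {}
    for tid in ids:
        mu = rt_table.rt_for(tid) + rt_shift
        windows[tid] = (mu - schedule_window_min, mu + schedule_window_min)
    times_by_id = _scheduled_times(windows, dwell_min)

    rec_f = recipe.applied_recovery_factor
    mat_f = recipe.applied_matrix_factor
    truth: dict[str, TransitionTruth] = {}
    peaks: dict[str, PeakModel] = {}
    frag_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tid in ids:
        conc = recipe.concentration_of(tid)
        true_area = recipe.response_factor * conc
        expected_area = true_area * rec_f * mat_f
        truth[tid] = TransitionTruth(tid, conc, true_area, expected_area)
        area_scale = 1.0
        if recipe.area_cv > 0:
            area_scale = max(float(rng.normal(1.0, recipe.area_cv)), 0.0)
        peaks[tid] = PeakModel(
            apex_rt_min=rt_table.rt_for(tid) + rt_shift,
            sigma_min=recipe.peak_sigma_min,
            asymmetry=recipe.peak_asymmetry,
            true_area=expected_area * area_scale,
        )
        entry = spectral_library.get(tid)
        if entry is not None:
            frag_arrays[tid] = (
                np.array([f.mz for f in entry.fragments]),
                np.array([f.relative_intensity for f in entry.fragments]),
            )
        else:
            frag_arrays[tid] = (np.array([index[tid].product_mz]), np.array([1.0]))

    scans: list[Scan] = []
    for tid in ids:
        t = index[tid]
        times = times_by_id[tid]
        if times.size == 0:
            continue
        # every analyte co-isolated with this precursor is co-fragmented and
        # contributes its fragments to each scan of this channel
        members = [
            j for j in ids
            if abs(index[j].precursor_mz - t.precursor_mz) <= co_isolation_tol_da
        ]
        frag_mz = np.concatenate([frag_arrays[j][0] for j in members])
        blocks = [
            peaks[j].profile(times)[:, None] * frag_arrays[j][1][None, :]
            for j in members
        ]
        intensities = np.hstack(blocks) + recipe.baseline_level
        if recipe.noise_sd > 0:
            intensities = intensities + rng.normal(0.0, recipe.noise_sd, intensities.shape)
        np.maximum(intensities, 0.0, out=intensities)

        n_scans = times.size
        if recipe.noise_sd > 0 and recipe.noise_peak_rate > 0:
            counts = rng.poisson(recipe.noise_peak_rate, n_scans)
            total = int(counts.sum())
            spur_mz = rng.uniform(*_MZ_RANGE, total)
            spur_int = np.abs(rng.normal(0.0, recipe.noise_sd, total))
            splits = np.cumsum(counts)[:-1]
            spur_mz_per = np.split(spur_mz, splits)
            spur_int_per = np.split(spur_int, splits)
        else:
            spur_mz_per = spur_int_per = None

        for j in range(n_scans):
            keep = intensities[j] > 0.0
            mzs = frag_mz[keep]
            ints = intensities[j][keep]
            if spur_mz_per is not None and spur_mz_per[j].size:
                mzs = np.concatenate([mzs, spur_mz_per[j]])
                ints = np.concatenate([ints, spur_int_per[j]])
            order = np.argsort(mzs, kind="stable")
            scans.append(
                Scan(
                    rt_min=float(times[j]),
                    precursor_mz=t.precursor_mz,
                    mz=mzs[order],
                    intensity=ints[order],
                )
            )

    scans.sort(key=lambda s: (s.rt_min, s.precursor_mz))
    run = Run(run_id=recipe.run_id, scans=scans)
    return run, GroundTruth(
        run_id=recipe.run_id,
        rt_shift_min=rt_shift,
        recovery_factor=rec_f,
        matrix_factor=mat_f,
        per_transition=truth,
    )


# ---------------------------------------------------------------------------
# campaign design


def _paired_is(
    analytes: Sequence[str], library: Sequence[Transition]
) -> list[str]:
    index = {t.analyte_id: t for t in library}
    out: list[str] = []
    for a in analytes:
        is_id = index[a].internal_standard_id
        if is_id and is_id not in out:
            out.append(is_id)
    return out


def simulate_validation_campaign(
    library: Sequence[Transition],
    rt_table: RtTable,
    *,
    analytes: Sequence[str] = DEFAULT_CAMPAIGN_ANALYTES,
    n_calibration_replicates: int = 5,
    n_qc_replicates: int = 5,
    days: int = 3,
    n_recovery_replicates: int = 6,
    matrices: Sequence[str] = ("plasma", "lung", "culture_medium"),
    recovery_is_ids: Sequence[str] = ("PGE2-d4",),
    area_cv: float = 0.05,
    noise_sd: float = 12.0,
    baseline_level: float = 60.0,
    is_spike_ng_ml: float = DEFAULT_IS_SPIKE_NG_ML,
    seed: int = 0,
) -> list[RunRecipe]:
    """Build the full validation-campaign manifest as a list of recipes.

    The design mirrors the validation study: a 10-level calibration series ×
    ``n_calibration_replicates``; QC at LQC/MQC/HQC × ``n_qc_replicates`` ×
    ``days``; and per matrix, recovery (pre-extraction spike) and matrix
    effect (post-extraction spike) against neat standards at the three IS
    levels × ``n_recovery_replicates``. Per-run seeds are spawned
    deterministically from ``seed``.
    """
    if n_recovery_replicates < 2:
        raise ValueError("n_recovery_replicates must be >= 2")
    is_ids = _paired_is(analytes, library)
    recipes: list[RunRecipe] = []

    def add(**kwargs) -> None:
        recipes.append(RunRecipe(area_cv=area_cv, noise_sd=noise_sd,
                                 baseline_level=baseline_level, seed=0, **kwargs))

    for li, level in enumerate(make_calibration_design(), start=1):
        for rep in range(1, n_calibration_replicates + 1):
            add(
                run_id=f"cal_L{li:02d}_r{rep}",
                sample_kind="calibration",
                level_label=f"L{li:02d}",
                analyte_concentrations={a: level for a in analytes},
                is_concentrations={i: is_spike_ng_ml for i in is_ids},
                replicate=rep,
            )
    for day in range(1, days + 1):
        for label, conc in make_qc_design().items():
            for rep in range(1, n_qc_replicates + 1):
                add(
                    run_id=f"qc_{label}_d{day}_r{rep}",
                    sample_kind="qc",
                    level_label=label,
                    analyte_concentrations={a: conc for a in analytes},
                    is_concentrations={i: is_spike_ng_ml for i in is_ids},
                    day=day,
                    replicate=rep,
                )
    is_levels = make_is_levels()
    for matrix in matrices:
        for label, conc in is_levels.items():
            rec_pct, me_pct = MATRIX_FACTOR_DESIGN[matrix][label]
            extraction_eff = rec_pct / me_pct
            ion_factor = me_pct / 100.0
            for rep in range(1, n_recovery_replicates + 1):
                common = dict(
                    level_label=label,
                    is_concentrations={i: conc for i in recovery_is_ids},
                    replicate=rep,
                )
                add(
                    run_id=f"rec_{matrix}_{label}_pre_r{rep}",
                    sample_kind="matrix_pre_spike",
                    matrix=matrix,
                    recovery_factor=extraction_eff,
                    matrix_factor=ion_factor,
                    **common,
                )
                add(
                    run_id=f"rec_{matrix}_{label}_post_r{rep}",
                    sample_kind="matrix_post_spike",
                    matrix=matrix,
                    recovery_factor=extraction_eff,
                    matrix_factor=ion_factor,
                    **common,
                )
                add(
                    run_id=f"rec_{matrix}_{label}_neat_r{rep}",
                    sample_kind="neat_standard",
                    **common,
                )

    seeds = np.random.SeedSequence(seed).generate_state(len(recipes)) % (2**31)
    from dataclasses import replace

    return [replace(r, seed=int(s)) for r, s in zip(recipes, seeds)]


def campaign_manifest(recipes: Sequence[RunRecipe]):
    """Tabular manifest (one row per run) linking files to their recipes."""
    import pandas as pd

    rows = []
    for r in recipes:
        rows.append(
            {
                "run_id": r.run_id,
                "sample_kind": r.sample_kind,
                "level_label": r.level_label,
                "matrix": r.matrix,
                "day": r.day,
                "replicate": r.replicate,
                "recovery_factor": r.recovery_factor,
                "matrix_factor": r.matrix_factor,
                "noise_sd": r.noise_sd,
                "area_cv": r.area_cv,
                "seed": r.seed,
                "analyte_concentrations_ng_ml": ";".join(
                    f"{k}={v:g}" for k, v in sorted(r.analyte_concentrations.items())
                ),
                "is_concentrations_ng_ml": ";".join(
                    f"{k}={v:g}" for k, v in sorted(r.is_concentrations.items())
                ),
            }
        )
    return pd.DataFrame(rows)
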