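"""Post-acquisition MRM-HR channel extraction and peak integration.

An MRM-HR channel is built after acquisition by selecting the MS2 scans
whose quadrupole isolation target matches a transition's precursor and
summing centroid intensity inside a narrow window around the quantifier
fragment (0.05 Da full width by default). Peaks are located near their
expected retention time, integrated above a linear baseline, and scored
with a robust (MAD-based) signal-to-noise ratio. Retention-time drift
between runs is corrected from the internal-standard channels: the deuterated
standards co-elute with their natural forms, so the median apex displacement
over the IS channels estimates a per-run RT offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError
from .method_library import RtTable, Transition, window_bounds
from .mzml_io import Run, Scan

__all__ = [
    "Chromatogram",
    "PeakResult",
    "AlignmentResult",
    "extract_channel",
    "detect_peak",
    "estimate_snr",
    "align_by_internal_standards",
    "DEFAULT_PRECURSOR_TOL_DA",
]

#: Quadrupole isolation match tolerance (unit-resolution isolation), Da.
DEFAULT_PRECURSOR_TOL_DA = 0.7

#: Integration stops when the trace falls to this fraction of the
#: baseline-corrected apex height (noise permitting); chosen so that a pure
#: Gaussian integrates to within 0.1% of its analytic area h·sigma·sqrt(2*pi).
_BOUNDARY_FRACTION = 1e-4

_MAD_SCALE = 1.4826


@dataclass
class Chromatogram:
    """One extracted transition channel: intensity vs retention time."""

    transition_ref: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities differ in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PeakResult:
    """An integrated chromatographic peak.

    ``snr`` is ``math.inf`` for noiseless traces. ``found`` is False when no
    point in the search window rises above the noise gate; the numeric
    fields are then zero.
    """

    found: bool
    apex_rt_min: float = 0.0
    left_rt_min: float = 0.0
    right_rt_min: float = 0.0
    area: float = 0.0
    height: float = 0.0
    snr: float = 0.0

    @classmethod
    def not_found(cls) -> "PeakResult":
        return cls(found=False)


def extract_channel(
    run: Run | Iterable[Scan],
    transition: Transition,
    precursor_tol_da: float = DEFAULT_PRECURSOR_TOL_DA,
) -> Chromatogram:
    """Extract the fragment chromatogram for one transition.

    Every MS2 scan whose isolation m/z lies within ``±precursor_tol_da`` of
    the transition's precursor contributes one point: the sum of centroid
    intensities inside the fragment extraction window. Scans of other
    precursors contribute nothing; an empty chromatogram is a valid result.
    """
    lo, hi = window_bounds(transition)
    prec = transition.precursor_mz
    scans = run.scans if isinstance(run, Run) else list(run)
    times: list[float] = []
    values: list[float] = []
    for scan in scans:
        if abs(scan.precursor_mz - prec) > precursor_tol_da:
            continue
        times.append(scan.rt_min)
        mz = scan.mz
        if mz.size:
            inside = (mz >= lo) & (mz <= hi)
            values.append(float(scan.intensity[inside].sum()))
        else:
            values.append(0.0)
    t = np.asarray(times)
    v = np.asarray(values)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if t.size > 1:
        # merge coincident scan times (same channel acquired twice in a cycle)
        uniq, inverse = np.unique(t, return_inverse=True)
        if uniq.size != t.size:
            sums = np.bincount(inverse, weights=v)
            counts = np.bincount(inverse)
            t, v = uniq, sums / counts
    return Chromatogram(transition.analyte_id, t, v)


def _robust_noise(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return float(_MAD_SCALE * np.median(np.abs(values - med)))


def _diff_noise(values: np.ndarray) -> float:
    """Point-to-point noise from first differences (insensitive to smooth
    peaks, unlike a plain MAD when peaks cover much of the trace)."""
    if values.size < 3:
        return 0.0
    diffs = np.diff(values)
    return float(_MAD_SCALE * np.median(np.abs(diffs)) / math.sqrt(2.0))


def _baseline_estimate(values: np.ndarray, noise: float) -> float:
    """Median of the trace with signal regions masked out."""
    if values.size == 0:
        return 0.0
    rough = float(np.percentile(values, 25))
    if noise > 0:
        quiet = values[values <= rough + 3.0 * noise]
        if quiet.size >= max(8, values.size // 20):
            return float(np.median(quiet))
    return rough


def detect_peak(
    chromatogram: Chromatogram,
    expected_rt_min: float,
    rt_tolerance_min: float = 0.5,
) -> PeakResult:
    """Locate and integrate the peak nearest the expected retention time.

    Candidate apexes are local maxima inside ``expected_rt ± tolerance``
    rising above the noise gate; among them the one closest to the expected
    RT wins (tie → higher, then earlier), so a co-monitored isobaric isomer
    with a taller peak elsewhere in the window is not picked by mistake.
    Integration bounds extend down each flank until the trace reaches the
    local baseline (or a valley, for partially resolved isomer pairs); the
    area is the trapezoidal integral above a linear baseline between the
    bounds. ``found`` is False when nothing in the window exceeds three
    times the robust noise.
    """
    t, y = chromatogram.times, chromatogram.intensities
    if t.size == 0:
        return PeakResult.not_found()
    in_window = np.abs(t - expected_rt_min) <= rt_tolerance_min
    if not np.any(in_window):
        return PeakResult.not_found()

    noise = _diff_noise(y)
    baseline_est = _baseline_estimate(y, noise)

    all_candidates, _ = find_peaks(y, prominence=max(5.0 * noise, 0.0) or None)
    candidates = (
        all_candidates[in_window[all_candidates]] if all_candidates.size else all_candidates
    )
    if candidates.size:
        dist = np.abs(t[candidates] - expected_rt_min)
        # nearest expected RT; ties broken by height, then by earlier RT
        order = np.lexsort((t[candidates], -y[candidates], np.round(dist, 9)))
        apex = int(candidates[order[0]])
    else:
        window_idx = np.flatnonzero(in_window)
        apex = int(window_idx[np.argmax(y[window_idx])])

    apex_height = y[apex] - baseline_est
    if y[apex] <= 0 or apex_height <= 3.0 * noise:
        return PeakResult.not_found()

    # extend the bounds down to ~1 noise-sd above baseline: stopping at the
    # 3-sigma gate instead would clip 2-3% of the area of an S/N~100 peak
    stop = baseline_est + max(1.0 * noise, _BOUNDARY_FRACTION * apex_height)

    # bounds may not cross a genuine valley towards a neighbouring peak:
    # genuine means the trace descends essentially to baseline there
    # (noise bumps riding on the peak flank do not create valleys)
    valley_ceiling = baseline_est + max(3.0 * noise, 0.05 * apex_height)
    lower = all_candidates[all_candidates < apex]
    upper = all_candidates[all_candidates > apex]
    left_limit = 0
    if lower.size:
        nb = int(lower.max())
        vi = nb + int(np.argmin(y[nb : apex + 1]))
        if y[vi] < valley_ceiling:
            left_limit = vi
    right_limit = y.size - 1
    if upper.size:
        nb = int(upper.min())
        vi = apex + int(np.argmin(y[apex : nb + 1]))
        if y[vi] < valley_ceiling:
            right_limit = vi

    left = apex
    while left > left_limit and y[left - 1] > stop:
        left -= 1
    right = apex
    while right < right_limit and y[right + 1] > stop:
        right += 1
    if left == right:
        return PeakResult.not_found()

    # baseline endpoints from the out-of-peak flanks; capped by the global
    # trace median so a co-monitored isomer peak sitting in one flank cannot
    # drag the baseline up
    out_left = y[:left]
    out_right = y[right + 1 :]
    y_left = min(float(np.median(out_left)), baseline_est) if out_left.size >= 4 else baseline_est
    y_right = min(float(np.median(out_right)), baseline_est) if out_right.size >= 4 else baseline_est
    seg_t = t[left : right + 1]
    seg_y = y[left : right + 1]
    if seg_t[-1] > seg_t[0]:
        slope = (y_right - y_left) / (seg_t[-1] - seg_t[0])
    else:
        slope = 0.0
    baseline_line = y_left + slope * (seg_t - seg_t[0])
    area = float(np.trapezoid(seg_y - baseline_line, seg_t))
    height = float(y[apex] - (y_left + slope * (t[apex] - seg_t[0])))
    return PeakResult(
        found=True,
        apex_rt_min=float(t[apex]),
        left_rt_min=float(t[left]),
        right_rt_min=float(t[right]),
        area=max(area, 0.0),
        height=max(height, 0.0),
        snr=0.0,
    )


def estimate_snr(chromatogram: Chromatogram, peak: PeakResult) -> float:
    """Signal-to-noise of a found peak.

    Noise is the scaled median absolute deviation (1.4826 × MAD) of the
    intensities outside the integration bounds — robust to neighbouring
    peaks; S/N is the baseline-corrected height over that noise. Returns
    ``math.inf`` when the out-of-peak trace is exactly constant.

    Raises
    ------
    ValueError
        If the peak was not found.
    InsufficientDataError
        If fewer than 8 points lie outside the integration bounds.
    """
    if not peak.found:
        raise ValueError("cannot estimate S/N for a peak that was not found")
    t, y = chromatogram.times, chromatogram.intensities
    outside = (t < peak.left_rt_min) | (t > peak.right_rt_min)
    n_out = int(outside.sum())
    if n_out < 8:
        raise InsufficientDataError(
            f"only {n_out} points outside the integration bounds (need >= 8)"
        )
    noise = _robust_noise(y[outside])
    if noise == 0.0:
        return math.inf
    return peak.height / noise


@dataclass(frozen=True)
class AlignmentResult:
    """Per-run retention-time offset estimated from the IS channels."""

    offset_min: float
    n_is_used: int
    ok: bool
    per_is_offset: Mapping[str, float]

    def shifted_rt(self, expected_rt_min: float) -> float:
        return expected_rt_min + self.offset_min


def align_by_internal_standards(
    run: Run | Iterable[Scan],
    library: Sequence[Transition],
    rt_table: RtTable,
    *,
    is_ids: Sequence[str] | None = None,
    precursor_tol_da: float = DEFAULT_PRECURSOR_TOL_DA,
    rt_tolerance_min: float = 0.5,
) -> AlignmentResult:
    """Estimate the run's RT offset as the median apex displacement of the
    internal-standard channels relative to their expected retention times.

    Runs in which no IS peak is found get an alignment-failure flag
    (``ok=False``) and a zero offset.
    """
    scans = run.scans if isinstance(run, Run) else list(run)
    index = {t.analyte_id: t for t in library}
    if is_ids is None:
        targets = [t for t in library if t.is_internal_standard]
    else:
        targets = [index[i] for i in is_ids]
    offsets: dict[str, float] = {}
    for t in targets:
        expected = rt_table.entries.get(t.analyte_id)
        if expected is None:
            continue
        chrom = extract_channel(scans, t, precursor_tol_da)
        peak = detect_peak(chrom, expected, rt_tolerance_min)
        if peak.found:
            offsets[t.analyte_id] = peak.apex_rt_min - expected
    if not offsets:
        return AlignmentResult(0.0, 0, False, {})
    return AlignmentResult(
        offset_min=float(np.median(list(offsets.values()))),
        n_is_used=len(offsets),
        ok=True,
        per_is_offset=offsets,
    )
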