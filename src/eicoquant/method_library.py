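"""Method library for the eicosanoid MRM-HR panel.

The method is described by *transitions*: one precursor/product ion pair per
analyte, acquired in negative mode on a quadrupole-TOF, with the quantifier
channel extracted post-acquisition from the high-resolution product-ion
spectra inside a narrow m/z window (0.05 Da full width by default). Each
endogenous analyte is paired with a deuterated internal standard (IS) that
co-elutes with its natural form.

The module bundles the reference panel (58 channels, including the IS
channels), the expected retention times at mobile-phase pH 5.8 together with
each analyte's calibration r^2 and on-column LLOQ, an alias map resolving
the naming variants used across the source tables, and a high-resolution
spectral-library entry for 5-HETE.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    LibraryIntegrityError,
    NoInternalStandardError,
    TransitionFormatError,
    UnknownAnalyteError,
)

__all__ = [
    "Transition",
    "SpectralFragment",
    "SpectralLibraryEntry",
    "SpectrumMatch",
    "RtTable",
    "load_transition_table",
    "write_transition_table",
    "internal_standard_for",
    "window_bounds",
    "match_spectrum",
    "load_rt_table",
    "load_aliases",
    "resolve_alias",
    "load_bundled_transitions",
    "load_bundled_rt_table",
    "load_bundled_aliases",
    "load_spectral_library",
    "save_spectral_library",
    "default_spectral_library",
    "RUN_LENGTH_MIN",
    "DEFAULT_RT_TOLERANCE_MIN",
    "DEFAULT_WINDOW_DA",
]

#: Total chromatographic run length (gradient + re-equilibration), minutes.
RUN_LENGTH_MIN = 25.0
#: Default half-window used when locating a peak around its expected RT.
DEFAULT_RT_TOLERANCE_MIN = 0.5
#: Default full width of the fragment extraction window, Da.
DEFAULT_WINDOW_DA = 0.05

_TRANSITION_COLUMNS = (
    "analyte_id",
    "common_name",
    "is_internal_standard",
    "internal_standard_id",
    "precursor_mz",
    "product_mz",
    "dp_volts",
    "ce_volts",
    "window_da",
    "expected_rt_min",
)


@dataclass(frozen=True)
class Transition:
    """One MRM-HR channel.

    Parameters
    ----------
    analyte_id : str
        Unique key; distinct even when ``common_name`` repeats.
    precursor_mz, product_mz : float
        Quadrupole isolation target and quantifier fragment m/z (Th).
    declustering_potential, collision_energy : float
        Source/collision settings in volts (negative in negative-ion mode).
    window_da : float
        Full width of the fragment extraction window in Da.
    internal_standard_id : str or None
        The paired deuterated IS channel; ``None`` for IS channels themselves.
    expected_rt_min : float or None
        Expected apex retention time under the active chromatography.
    rt_tolerance_min : float
        Half-window for peak location around ``expected_rt_min``.
    """

    analyte_id: str
    common_name: str
    precursor_mz: float
    product_mz: float
    declustering_potential: float
    collision_energy: float
    window_da: float = DEFAULT_WINDOW_DA
    is_internal_standard: bool = False
    internal_standard_id: str | None = None
    expected_rt_min: float | None = None
    rt_tolerance_min: float = DEFAULT_RT_TOLERANCE_MIN

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError(
                f"{self.analyte_id}: m/z values must be positive "
                f"(precursor {self.precursor_mz}, product {self.product_mz})"
            )
        if self.window_da <= 0:
            raise ValueError(f"{self.analyte_id}: window_da must be > 0")


@dataclass(frozen=True)
class SpectralFragment:
    mz: float
    relative_intensity: float
    annotation: str = ""
    quantifier: bool = False


@dataclass(frozen=True)
class SpectralLibraryEntry:
    """High-resolution product-ion spectrum for one analyte."""

    analyte_id: str
    precursor_mz: float
    fragments: tuple[SpectralFragment, ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"{self.analyte_id}: fragment list is empty")
        for f in self.fragments:
            if not (0.0 < f.relative_intensity <= 1.0):
                raise ValueError(
                    f"{self.analyte_id}: relative intensity {f.relative_intensity} "
                    "outside (0, 1]"
                )
        if sum(f.quantifier for f in self.fragments) != 1:
            raise ValueError(f"{self.analyte_id}: exactly one quantifier fragment required")


@dataclass(frozen=True)
class SpectrumMatch:
    """Result of matching an observed spectrum against a library entry."""

    n_matched: int
    matched_annotations: tuple[str, ...]
    confirmed: bool


@dataclass(frozen=True)
class RtTable:
    """Expected retention times for one mobile-phase pH.

    ``entries`` maps analyte_id to the expected apex RT in minutes, or to
    ``None`` for analytes not detected under that chromatography.
    """

    ph_label: str
    entries: Mapping[str, float | None]
    r_squared: Mapping[str, float] = field(default_factory=dict)
    lloq_pg: Mapping[str, float] = field(default_factory=dict)

    def rt_for(self, analyte_id: str) -> float:
        try:
            rt = self.entries[analyte_id]
        except KeyError:
            raise UnknownAnalyteError(analyte_id) from None
        if rt is None:
            raise UnknownAnalyteError(f"{analyte_id} not detected at pH {self.ph_label}")
        return rt


# ---------------------------------------------------------------------------
# transition table I/O


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no", ""}:
        return False
    raise TransitionFormatError(f"unparseable boolean {text!r}")


def load_transition_table(path: str | Path) -> list[Transition]:
    """Read a transition panel from a comma-separated UTF-8 file.

    The header row is mandatory; lines starting with ``#`` are comments.
    Duplicate or missing analyte_ids are disambiguated with an ordinal
    suffix derived from the common name, so panels that list the same
    compound twice load without silent overwrite.

    Raises
    ------
    TransitionFormatError
        If a required column is absent or a field does not parse.
    LibraryIntegrityError
        If a non-IS row references an internal standard that is not in
        the table.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(_strip_comments(fh)))
    if rows:
        missing = [c for c in _TRANSITION_COLUMNS if c not in rows[0]]
        if missing:
            raise TransitionFormatError(
                f"{path.name}: missing required column(s): {', '.join(missing)}"
            )
    transitions: list[Transition] = []
    seen: dict[str, int] = {}
    for row in rows:
        tid = (row["analyte_id"] or "").strip() or row["common_name"].strip()
        if tid in seen:
            seen[tid] += 1
            tid = f"{tid}-{seen[tid]}"
        seen.setdefault(tid, 1)
        try:
            rt_text = (row["expected_rt_min"] or "").strip()
            transitions.append(
                Transition(
                    analyte_id=tid,
                    common_name=row["common_name"].strip(),
                    is_internal_standard=_parse_bool(row["is_internal_standard"]),
                    internal_standard_id=(row["internal_standard_id"] or "").strip() or None,
                    precursor_mz=float(row["precursor_mz"]),
                    product_mz=float(row["product_mz"]),
                    declustering_potential=float(row["dp_volts"]),
                    collision_energy=float(row["ce_volts"]),
                    window_da=float(row["window_da"]),
                    expected_rt_min=float(rt_text) if rt_text else None,
                )
            )
        except (ValueError, KeyError) as exc:
            if isinstance(exc, TransitionFormatError):
                raise
            raise TransitionFormatError(f"{path.name}: bad row {row!r}: {exc}") from exc
    _check_is_references(transitions)
    return transitions


def _strip_comments(lines: Iterable[str]) -> Iterable[str]:
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line


def _check_is_references(transitions: Sequence[Transition]) -> None:
    ids = {t.analyte_id for t in transitions}
    dangling = [
        t.analyte_id
        for t in transitions
        if not t.is_internal_standard
        and t.internal_standard_id is not None
        and t.internal_standard_id not in ids
    ]
    if dangling:
        raise LibraryIntegrityError(
            "dangling internal-standard reference(s) for: " + ", ".join(sorted(dangling))
        )


def _fmt(x: float) -> str:
    return format(x, ".10g")


def write_transition_table(transitions: Sequence[Transition], path: str | Path) -> None:
    """Write transitions as CSV; ``load_transition_table`` round-trips it."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRANSITION_COLUMNS)
        for t in transitions:
            writer.writerow(
                [
                    t.analyte_id,
                    t.common_name,
                    "true" if t.is_internal_standard else "false",
                    t.internal_standard_id or "",
                    _fmt(t.precursor_mz),
                    _fmt(t.product_mz),
                    _fmt(t.declustering_potential),
                    _fmt(t.collision_energy),
                    _fmt(t.window_da),
                    _fmt(t.expected_rt_min) if t.expected_rt_min is not None else "",
                ]
            )


# ---------------------------------------------------------------------------
# lookups


def _index(library: Sequence[Transition]) -> dict[str, Transition]:
    return {t.analyte_id: t for t in library}


def internal_standard_for(analyte_id: str, library: Sequence[Transition]) -> Transition:
    """Return the internal-standard transition paired with ``analyte_id``.

    Raises :class:`NoInternalStandardError` if the analyte is itself an IS
    and :class:`UnknownAnalyteError` for ids absent from the library.
    """
    idx = _index(library)
    try:
        t = idx[analyte_id]
    except KeyError:
        raise UnknownAnalyteError(analyte_id) from None
    if t.is_internal_standard or t.internal_standard_id is None:
        raise NoInternalStandardError(f"{analyte_id} is an internal standard")
    try:
        return idx[t.internal_standard_id]
    except KeyError:  # load_transition_table guards this; direct lists may not
        raise LibraryIntegrityError(
            f"{analyte_id} references unknown IS {t.internal_standard_id!r}"
        ) from None


def window_bounds(t: Transition) -> tuple[float, float]:
    """Fragment extraction window ``(product_mz - w/2, product_mz + w/2)``."""
    half = t.window_da / 2.0
    return (t.product_mz - half, t.product_mz + half)


def match_spectrum(
    spectrum: Sequence[tuple[float, float]],
    entry: SpectralLibraryEntry,
    tol_da: float = 0.01,
) -> SpectrumMatch:
    """Match an observed centroid spectrum against a library entry.

    Pairs library fragments with observed peaks by ascending m/z distance,
    each observed peak satisfying at most one fragment. Identity is
    *confirmed* when at least two fragments match — the standard practice of
    requiring two or more transitions per precursor.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be > 0")
    pairs = [
        (abs(peak_mz - frag.mz), fi, pi)
        for fi, frag in enumerate(entry.fragments)
        for pi, (peak_mz, _inten) in enumerate(spectrum)
        if abs(peak_mz - frag.mz) <= tol_da
    ]
    pairs.sort()
    used_frags: set[int] = set()
    used_peaks: set[int] = set()
    matched: list[str] = []
    for _dist, fi, pi in pairs:
        if fi in used_frags or pi in used_peaks:
            continue
        used_frags.add(fi)
        used_peaks.add(pi)
        matched.append(entry.fragments[fi].annotation)
    return SpectrumMatch(
        n_matched=len(used_frags),
        matched_annotations=tuple(matched),
        confirmed=len(used_frags) >= 2,
    )


# ---------------------------------------------------------------------------
# retention-time tables and aliases


def load_aliases(path: str | Path) -> dict[str, str]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return {
            row["alias"]: row["canonical"]
            for row in csv.DictReader(_strip_comments(fh))
        }


def resolve_alias(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a table synonym onto the canonical panel analyte_id."""
    if aliases is None:
        aliases = load_bundled_aliases()
    return aliases.get(name, name)


def load_rt_table(path: str | Path, ph_label: str, aliases: Mapping[str, str] | None = None) -> RtTable:
    """Read an RT reference (columns common_name, rt_min[, r_squared, lloq_pg]).

    An ``rt_min`` of ``*`` or empty marks an analyte not detected at that pH.
    Names are passed through the alias map onto canonical analyte_ids.
    """
    entries: dict[str, float | None] = {}
    r2: dict[str, float] = {}
    lloq: dict[str, float] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(_strip_comments(fh)):
            aid = resolve_alias(row["common_name"].strip(), aliases)
            rt_text = (row.get("rt_min") or "").strip()
            entries[aid] = None if rt_text in {"", "*"} else float(rt_text)
            if (row.get("r_squared") or "").strip():
                r2[aid] = float(row["r_squared"])
            if (row.get("lloq_pg") or "").strip():
                lloq[aid] = float(row["lloq_pg"])
    return RtTable(ph_label=ph_label, entries=entries, r_squared=r2, lloq_pg=lloq)


# ---------------------------------------------------------------------------
# bundled data


def _data_path(name: str):
    return resources.files("eicoquant.data").joinpath(name)


def load_bundled_aliases() -> dict[str, str]:
    with resources.as_file(_data_path("aliases.csv")) as p:
        return load_aliases(p)


def load_bundled_transitions() -> list[Transition]:
    """The bundled 58-channel eicosanoid panel with pH 5.8 retention times."""
    with resources.as_file(_data_path("transitions_ph58.csv")) as p:
        return load_transition_table(p)


def load_bundled_rt_table(ph_label: str = "5.8") -> RtTable:
    """Bundled RT/r^2/LLOQ reference. Only pH 5.8 ships with the package;
    alternative-pH tables load through :func:`load_rt_table`."""
    if ph_label != "5.8":
        raise ValueError(f"no bundled RT table for pH {ph_label}; load one with load_rt_table()")
    aliases = load_bundled_aliases()
    with resources.as_file(_data_path("rt_ph58.csv")) as p:
        table = load_rt_table(p, ph_label, aliases)
    # IS channels co-elute exactly with their natural forms.
    rts = dict(table.entries)
    for t in load_bundled_transitions():
        if t.analyte_id not in rts and t.expected_rt_min is not None:
            rts[t.analyte_id] = t.expected_rt_min
    return replace(table, entries=rts)


# ---------------------------------------------------------------------------
# spectral library


def load_spectral_library(path: str | Path) -> dict[str, SpectralLibraryEntry]:
    with Path(path).open(encoding="utf-8") as fh:
        doc = json.load(fh)
    out: dict[str, SpectralLibraryEntry] = {}
    for raw in doc["entries"]:
        frags = tuple(
            SpectralFragment(
                mz=f["mz"],
                relative_intensity=f["relative_intensity"],
                annotation=f.get("annotation", ""),
                quantifier=bool(f.get("quantifier", False)),
            )
            for f in raw["fragments"]
        )
        entry = SpectralLibraryEntry(raw["analyte_id"], raw["precursor_mz"], frags)
        out[entry.analyte_id] = entry
    return out


def save_spectral_library(entries: Mapping[str, SpectralLibraryEntry], path: str | Path) -> None:
    doc = {
        "entries": [
            {
                "analyte_id": e.analyte_id,
                "precursor_mz": e.precursor_mz,
                "fragments": [
                    {
                        "mz": f.mz,
                        "relative_intensity": f.relative_intensity,
                        "annotation": f.annotation,
                        "quantifier": f.quantifier,
                    }
                    for f in e.fragments
                ],
            }
            for e in entries.values()
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1, ensure_ascii=False), encoding="utf-8")


_H2O = 18.0106
_CO2 = 43.9898


def default_spectral_library(
    library: Sequence[Transition] | None = None,
) -> dict[str, SpectralLibraryEntry]:
    """Spectral-library entries for the whole panel.

    5-HETE uses its published fragment m/z values; every other analyte gets a
    constructed entry (synthetic): the quantifier fragment from its transition
    plus one neutral-loss qualifier (water loss, or CO2 loss when the water
    loss would collide with the quantifier window).
    """
    if library is None:
        library = load_bundled_transitions()
    with resources.as_file(_data_path("spectral_library_5hete.json")) as p:
        entries = load_spectral_library(p)
    for t in library:
        if t.analyte_id in entries:
            continue
        qual_mz = t.precursor_mz - _H2O
        if abs(qual_mz - t.product_mz) < 0.1:
            qual_mz = t.precursor_mz - _CO2
        frags = [SpectralFragment(t.product_mz, 1.0, "quantifier", True)]
        if qual_mz > 50.0 and abs(qual_mz - t.product_mz) >= 0.1:
            frags.append(SpectralFragment(qual_mz, 0.4, "neutral-loss qualifier (synthetic)"))
        entries[t.analyte_id] = SpectralLibraryEntry(
            t.analyte_id, t.precursor_mz, tuple(frags)
        )
    return entries
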