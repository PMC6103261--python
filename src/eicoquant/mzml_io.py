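"""Minimal mzML I/O for centroided MS2 (product-ion) acquisitions.

Covers exactly what an MRM-HR workflow needs: time-ordered MS2 scans, each
carrying a scan start time, the quadrupole isolation target m/z, and
centroided m/z / intensity arrays. The writer emits standards-conformant
indexed mzML (64-bit float arrays, no compression, deterministic output for
identical input); the reader parses any centroided-MS2 mzML via lxml and
converts scan times to minutes.
"""

from __future__ import annotations

import base64
import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

__all__ = ["Scan", "Run", "write_mzml", "read_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"


@dataclass
class Scan:
    """One centroided MS2 scan."""

    rt_min: float
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")


@dataclass
class Run:
    """A time-ordered sequence of MS2 scans from one injection."""

    run_id: str
    scans: list[Scan] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)


def _b64(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _cv(acc: str, name: str, value=None, unit: tuple[str, str, str] | None = None) -> str:
    s = f'<cvParam cvRef="MS" accession="{acc}" name="{name}"'
    s += f' value="{value}"' if value is not None else ' value=""'
    if unit:
        s += f' unitCvRef="{unit[0]}" unitAccession="{unit[1]}" unitName="{unit[2]}"'
    return s + "/>"


_MINUTE = ("UO", "UO:0000031", "minute")
_MZ_UNIT = ("MS", "MS:1000040", "m/z")
_COUNTS = ("MS", "MS:1000131", "number of detector counts")

_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml"'
    ' xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance"'
    ' xsi:schemaLocation="http://psi.hupo.org/ms/mzml'
    ' http://psidev.info/files/ms/mzML/xsd/mzML1.1.2_idx.xsd">\n'
)


def write_mzml(run: Run, path: str | Path) -> Path:
    """Serialize a run as indexed mzML.

    Scan times are written in minutes; m/z and intensity arrays as
    uncompressed base64 little-endian 64-bit floats, so the module's own
    reader round-trips them losslessly. Byte content depends only on the
    run's data (no timestamps), keeping seeded simulations reproducible
    at the file level.
    """
    if not run.scans:
        raise ValueError("refusing to write an mzML file with no scans")
    path = Path(path)
    parts: list[bytes] = []
    pos = 0

    def w(text: str) -> None:
        nonlocal pos
        b = text.encode("utf-8")
        parts.append(b)
        pos += len(b)

    w(_HEADER)
    w(f'<mzML xmlns="http://psi.hupo.org/ms/mzml" id="{run.run_id}" version="1.1.0">\n')
    w(
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' version="4.1.0" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" version="releases/2020-03-10"'
        ' URI="http://ontologies.berkeleybop.org/uo.obo"/></cvList>\n'
    )
    w(
        "<fileDescription><fileContent>"
        + _cv("MS:1000580", "MSn spectrum")
        + _cv("MS:1000127", "centroid spectrum")
        + "</fileContent></fileDescription>\n"
    )
    w(
        '<softwareList count="1"><software id="eicoquant" version="0.1.0">'
        + _cv("MS:1000799", "custom unreleased software tool", "eicoquant")
        + "</software></softwareList>\n"
    )
    w(
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1">'
        + _cv("MS:1000031", "instrument model")
        + "</instrumentConfiguration></instrumentConfigurationList>\n"
    )
    w(
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="eicoquant">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>\n"
    )
    w(f'<run id="{run.run_id}" defaultInstrumentConfigurationRef="IC1">\n')
    w(f'<spectrumList count="{len(run.scans)}" defaultDataProcessingRef="DP1">\n')
    offsets: list[tuple[str, int]] = []
    for i, scan in enumerate(run.scans):
        sid = f"scan={i + 1}"
        offsets.append((sid, pos))
        n = len(scan.mz)
        w(f'<spectrum index="{i}" id="{sid}" defaultArrayLength="{n}">')
        w(
            _cv("MS:1000580", "MSn spectrum")
            + _cv("MS:1000511", "ms level", 2)
            + _cv("MS:1000127", "centroid spectrum")
        )
        w(
            '<scanList count="1">'
            + _cv("MS:1000795", "no combination")
            + "<scan>"
            + _cv("MS:1000016", "scan start time", repr(float(scan.rt_min)), _MINUTE)
            + "</scan></scanList>"
        )
        prec = repr(float(scan.precursor_mz))
        w(
            '<precursorList count="1"><precursor><isolationWindow>'
            + _cv("MS:1000827", "isolation window target m/z", prec, _MZ_UNIT)
            + _cv("MS:1000828", "isolation window lower offset", "0.35", _MZ_UNIT)
            + _cv("MS:1000829", "isolation window upper offset", "0.35", _MZ_UNIT)
            + '</isolationWindow><selectedIonList count="1"><selectedIon>'
            + _cv("MS:1000744", "selected ion m/z", prec, _MZ_UNIT)
            + "</selectedIon></selectedIonList><activation>"
            + _cv("MS:1000133", "collision-induced dissociation")
            + "</activation></precursor></precursorList>"
        )
        mzb, inb = _b64(scan.mz), _b64(scan.intensity)
        w('<binaryDataArrayList count="2">')
        w(
            f'<binaryDataArray encodedLength="{len(mzb)}">'
            + _cv("MS:1000523", "64-bit float")
            + _cv("MS:1000576", "no compression")
            + _cv("MS:1000514", "m/z array", "", _MZ_UNIT)
            + f"<binary>{mzb}</binary></binaryDataArray>"
        )
        w(
            f'<binaryDataArray encodedLength="{len(inb)}">'
            + _cv("MS:1000523", "64-bit float")
            + _cv("MS:1000576", "no compression")
            + _cv("MS:1000515", "intensity array", "", _COUNTS)
            + f"<binary>{inb}</binary></binaryDataArray>"
        )
        w("</binaryDataArrayList></spectrum>\n")
    w("</spectrumList></run></mzML>\n")
    index_offset = pos
    w('<indexList count="1"><index name="spectrum">')
    for sid, off in offsets:
        w(f'<offset idRef="{sid}">{off}</offset>')
    w("</index></indexList>\n")
    w(f"<indexListOffset>{index_offset}</indexListOffset>\n")
    digest = hashlib.sha1(b"".join(parts) + b"<fileChecksum>").hexdigest()
    w(f"<fileChecksum>{digest}</fileChecksum></indexedmzML>\n")
    path.write_bytes(b"".join(parts))
    return path


def _decode_array(bda: etree._Element) -> tuple[np.ndarray, bool]:
    accessions = {c.get("accession") for c in bda.iter(_NS + "cvParam")}
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(base64.b64decode(bda.findtext(_NS + "binary") or ""))
    else:
        raw = base64.b64decode(bda.findtext(_NS + "binary") or "")
    if "MS:1000521" in accessions:  # 32-bit float
        values = np.frombuffer(raw, dtype="<f4").astype(float)
    else:
        values = np.frombuffer(raw, dtype="<f8").astype(float)
    return values, "MS:1000514" in accessions


def read_mzml(path: str | Path) -> Run:
    """Parse centroided MS2 scans from an mzML file.

    Scan start times are converted to minutes (mzML files written in
    seconds are divided by 60, keyed off the unit name). MS1 or other
    non-MS2 spectra are skipped.
    """
    path = Path(path)
    scans: list[Scan] = []
    for _event, el in etree.iterparse(str(path), events=("end",), tag=_NS + "spectrum"):
        params = {
            c.get("accession"): c
            for c in el.iter(_NS + "cvParam")
            if c.getparent().tag != _NS + "binaryDataArray"
        }
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in {"2", "2.0"}:
            el.clear()
            continue
        rt_param = params.get("MS:1000016")
        rt = float(rt_param.get("value"))
        if (rt_param.get("unitName") or "").startswith("second"):
            rt /= 60.0
        prec_param = params.get("MS:1000827")
        if prec_param is None:
            prec_param = params.get("MS:1000744")
        if prec_param is None:
            el.clear()
            continue
        precursor = float(prec_param.get("value"))
        mz = np.empty(0)
        inten = np.empty(0)
        for bda in el.iter(_NS + "binaryDataArray"):
            values, is_mz = _decode_array(bda)
            if is_mz:
                mz = values
            else:
                inten = values
        scans.append(Scan(rt_min=rt, precursor_mz=precursor, mz=mz, intensity=inten))
        el.clear()
    run_id = _read_run_id(path)
    scans.sort(key=lambda s: s.rt_min)
    return Run(run_id=run_id, scans=scans)


def _read_run_id(path: Path) -> str:
    for _event, el in etree.iterparse(str(path), events=("start",), tag=_NS + "run"):
        rid = el.get("id") or path.stem
        el.clear()
        return rid
    return path.stem
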