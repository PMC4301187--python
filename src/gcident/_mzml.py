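"""Minimal mzML 1.1 read/write for centroided MS1 chromatograms.

Covers the subset of mzML the pipeline consumes: a flat spectrum list with a
scan start time and uncompressed or zlib-compressed 32/64-bit float m/z and
intensity arrays.  Scan start times are normalized to seconds.
"""

from __future__ import annotations

import base64
import zlib
import xml.etree.ElementTree as ET
from typing import Iterator, Sequence

import numpy as np

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_SCAN_START = "MS:1000016"


class MzmlError(ValueError):
    """Raised for mzML content this reader does not understand."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(bda: ET.Element) -> tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values) with kind mz|intensity."""
    dtype = np.dtype("<f8")
    compressed = False
    kind = None
    text = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.dtype("<f4")
            elif acc == _ACC_F64:
                dtype = np.dtype("<f8")
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_NOCOMP:
                compressed = False
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif name == "binary":
            text = child.text or ""
    if kind is None:
        return "other", np.empty(0)
    raw = base64.b64decode(text) if text.strip() else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _scan_time_s(spectrum: ET.Element) -> float:
    for cv in spectrum.iter(f"{_NS}cvParam"):
        if cv.get("accession") == _ACC_SCAN_START:
            value = float(cv.get("value"))
            unit = (cv.get("unitName") or "").lower()
            if unit.startswith("minute"):
                return value * 60.0
            if unit in ("", "second", "seconds"):
                return value
            raise MzmlError(f"unsupported scan start time unit {unit!r}")
    raise MzmlError("spectrum without a scan start time")


def iter_spectra(path) -> Iterator[tuple[float, np.ndarray, np.ndarray]]:
    """Yield (scan_time_s, mz_array, intensity_array) per spectrum, in file order."""
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            time_s = _scan_time_s(elem)
            mzs = np.empty(0)
            ints = np.empty(0)
            for bda in elem.iter(f"{_NS}binaryDataArray"):
                kind, values = _decode_array(bda)
                if kind == "mz":
                    mzs = values
                elif kind == "intensity":
                    ints = values
            if len(mzs) != len(ints):
                raise MzmlError(
                    f"m/z and intensity arrays disagree in length ({len(mzs)} vs {len(ints)})"
                )
            yield time_s, mzs, ints
            elem.clear()
    except ET.ParseError as exc:
        raise MzmlError(f"not a well-formed mzML file: {exc}") from exc


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(
    path,
    scan_times_s: Sequence[float],
    scans: Sequence[tuple[Sequence[float], Sequence[float]]],
    run_id: str = "run",
) -> None:
    """Write centroided MS1 spectra as uncompressed 64-bit mzML."""
    if len(scan_times_s) != len(scans):
        raise ValueError("scan_times_s and scans must have the same length")
    out = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'  <run id="{run_id}">',
        f'    <spectrumList count="{len(scans)}">',
    ]
    for i, (t, (mzs, ints)) in enumerate(zip(scan_times_s, scans)):
        n = len(mzs)
        out.append(f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">')
        out.append('        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>')
        out.append('        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
        out.append('        <scanList count="1"><scan>')
        out.append(
            f'          <cvParam cvRef="MS" accession="{_ACC_SCAN_START}" name="scan start time" '
            f'value="{float(t)!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
        )
        out.append("        </scan></scanList>")
        out.append('        <binaryDataArrayList count="2">')
        for acc, name, arr in (
            (_ACC_MZ_ARRAY, "m/z array", mzs),
            (_ACC_INT_ARRAY, "intensity array", ints),
        ):
            b = _b64(np.asarray(arr, dtype=float))
            out.append(f'          <binaryDataArray encodedLength="{len(b)}">')
            out.append(f'            <cvParam cvRef="MS" accession="{_ACC_F64}" name="64-bit float" value=""/>')
            out.append(f'            <cvParam cvRef="MS" accession="{_ACC_NOCOMP}" name="no compression" value=""/>')
            out.append(f'            <cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>')
            out.append(f"            <binary>{b}</binary>")
            out.append("          </binaryDataArray>")
        out.append("        </binaryDataArrayList>")
        out.append("      </spectrum>")
    out += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out))
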