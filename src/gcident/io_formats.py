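"""Readers and writers for the pipeline's external formats.

* NIST-style ``msp`` spectral libraries with structured entry names
  (``Metabolite_(Derivatization)_Product_RI:<value>_Database``),
* peak lists in the ChromaTOF CSV export layout (ten required columns),
* raw chromatograms in ANDI-MS netCDF or mzML,
* quantification-mass override files (TSV).
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _mzml
from .spectra import MassSpectrum

__all__ = [
    "LibraryEntry",
    "PeakRecord",
    "RawChromatogram",
    "QuantMassOverride",
    "MspFormatError",
    "PeaklistSchemaError",
    "RawDataError",
    "REQUIRED_PEAKLIST_COLUMNS",
    "read_msp_library",
    "write_msp_library",
    "read_peaklist",
    "read_raw",
    "read_quant_mass_file",
    "parse_entry_name",
]

#: Exact header strings a peak list must contain.
REQUIRED_PEAKLIST_COLUMNS = (
    "Name",
    "Retention Index",
    "Area",
    "UniqueMass",
    "Quant Masses",
    "R.T. (s)",
    "S/N",
    "Integration Begin",
    "Integration End",
    "Full Width at Half Height",
)

#: Nominal instrument bin range; masses outside are retained but flagged.
MASS_RANGE = (70, 600)


class MspFormatError(ValueError):
    """Malformed msp content (record structure, naming convention, duplicates)."""


class PeaklistSchemaError(ValueError):
    """Peak-list file missing required columns or containing unparseable cells."""


class RawDataError(ValueError):
    """Raw chromatogram file unreadable or violating basic invariants."""


# ---------------------------------------------------------------------------
# library entries


@dataclass
class LibraryEntry:
    """One msp record with its parsed five-element name.

    ``quant_masses`` is empty until resolved (override file or default rule).
    """

    raw_name: str
    metabolite: str
    derivatization: str
    product: str
    reference_ri: float
    source_db: str
    spectrum: MassSpectrum
    quant_masses: list[int] = field(default_factory=list)

    @property
    def valid_for_search(self) -> bool:
        return not self.spectrum.is_empty


def parse_entry_name(name: str) -> tuple[str, str, str, float, str]:
    """Split a library entry name into its five underscore-separated elements.

    The fourth element must be ``RI:<number>`` with a finite, non-negative
    value, e.g. ``Phenylalanine_(1TMS)_BP_RI:1551_pubDB``.
    """
    parts = name.split("_")
    if len(parts) != 5:
        raise MspFormatError(
            f"entry name {name!r} does not have the five underscore-separated "
            f"elements metabolite_derivatization_product_RI:<value>_database "
            f"(got {len(parts)})"
        )
    metabolite, derivatization, product, ri_part, source_db = parts
    if not ri_part.startswith("RI:"):
        raise MspFormatError(f"entry name {name!r}: fourth element {ri_part!r} must start with 'RI:'")
    try:
        ri = float(ri_part[3:])
    except ValueError:
        raise MspFormatError(f"entry name {name!r}: cannot parse retention index from {ri_part!r}") from None
    if not math.isfinite(ri) or ri < 0:
        raise MspFormatError(f"entry name {name!r}: retention index {ri} must be finite and non-negative")
    return metabolite, derivatization, product, ri, source_db


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_msp_library(path) -> list[LibraryEntry]:
    """Parse an msp library file into a list of :class:`LibraryEntry`.

    Records are blocks starting with a ``Name:`` line and carrying a
    ``Num Peaks:`` count followed by the peak list (``mz intensity`` pairs,
    whitespace- or ``;``-delimited, possibly several per line).  Spectra are
    binned to integer m/z.  Entries are returned in file order.
    """
    path = Path(path)
    text = _read_text(path)
    entries: list[LibraryEntry] = []
    seen: set[str] = set()

    record_lines: list[tuple[int, str]] = []

    def flush(record_index: int):
        if not record_lines:
            return
        name = None
        num_peaks = None
        pair_tokens: list[str] = []
        in_peaks = False
        for lineno, line in record_lines:
            stripped = line.strip()
            if not in_peaks:
                low = stripped.lower()
                if low.startswith("name:"):
                    name = stripped[5:].strip()
                elif low.startswith("num peaks:"):
                    try:
                        num_peaks = int(stripped.split(":", 1)[1].strip())
                    except ValueError:
                        raise MspFormatError(
                            f"record {record_index} (line {lineno}): unparseable Num Peaks in {stripped!r}"
                        ) from None
                    in_peaks = True
                # other metadata lines (Formula:, CAS#:, Comments: ...) ignored
            else:
                pair_tokens.extend(t for t in stripped.replace(";", " ").replace(",", " ").split() if t)
        first_line = record_lines[0][0]
        if name is None:
            raise MspFormatError(f"record {record_index} (line {first_line}): missing Name line")
        if num_peaks is None:
            raise MspFormatError(f"record {record_index} ({name!r}, line {first_line}): missing Num Peaks line")
        if len(pair_tokens) != 2 * num_peaks:
            raise MspFormatError(
                f"record {record_index} ({name!r}, line {first_line}): declared {num_peaks} peaks "
                f"but found {len(pair_tokens) // 2} value pairs"
            )
        try:
            values = [float(t) for t in pair_tokens]
        except ValueError as exc:
            raise MspFormatError(f"record {record_index} ({name!r}): bad peak value: {exc}") from None
        mzs = values[0::2]
        intens = values[1::2]
        if name in seen:
            raise MspFormatError(f"record {record_index}: duplicate entry name {name!r}")
        seen.add(name)
        metabolite, deriv, product, ri, source = parse_entry_name(name)
        entries.append(
            LibraryEntry(
                raw_name=name,
                metabolite=metabolite,
                derivatization=deriv,
                product=product,
                reference_ri=ri,
                source_db=source,
                spectrum=MassSpectrum.from_pairs(mzs, intens),
            )
        )

    record_index = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip().lower().startswith("name:") and record_lines:
            flush(record_index)
            record_index += 1
            record_lines = []
        if line.strip():
            record_lines.append((lineno, line))
    flush(record_index)
    return entries


def write_msp_library(entries: Sequence[LibraryEntry], path) -> Path:
    """Write entries as msp; round-trips names, reference RIs, and spectra."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for entry in entries:
            mzs, intens = entry.spectrum.to_arrays()
            fh.write(f"Name: {entry.raw_name}\n")
            fh.write(f"Num Peaks: {len(mzs)}\n")
            for mz, inten in zip(mzs, intens):
                fh.write(f"{int(mz)} {inten:.6g};\n")
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# peak lists


@dataclass
class PeakRecord:
    """One row of a ChromaTOF-style peak list."""

    name: str
    reported_ri: float | None
    reported_area: float
    unique_mass: int
    reported_quant_masses: str
    rt_s: float
    snr: float
    integ_begin_s: float
    integ_end_s: float
    fwhh_s: float

    def __post_init__(self):
        if not (self.integ_begin_s <= self.rt_s <= self.integ_end_s):
            raise PeaklistSchemaError(
                f"peak {self.name!r}: integration bounds [{self.integ_begin_s}, {self.integ_end_s}] "
                f"do not contain the apex RT {self.rt_s}"
            )
        if self.snr < 0:
            raise PeaklistSchemaError(f"peak {self.name!r}: negative S/N {self.snr}")
        if self.fwhh_s < 0:
            raise PeaklistSchemaError(f"peak {self.name!r}: negative FWHH {self.fwhh_s}")


def _sniff_delimiter(header_line: str) -> str:
    try:
        return csv.Sniffer().sniff(header_line, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_peaklist(path) -> list[PeakRecord]:
    """Read a peak-list CSV/TSV; rows are returned sorted by retention time.

    The header must contain all ten required column names (exact strings, any
    column order); the delimiter is sniffed from the header line, and quoted
    fields are honored.
    """
    path = Path(path)
    text = _read_text(path)
    header_line = text.splitlines()[0] if text.strip() else ""
    delim = _sniff_delimiter(header_line)
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_PEAKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise PeaklistSchemaError(f"peak list {path.name} is missing required column(s): {missing}")

    def num(row_ix: int, col: str, *, optional: bool = False) -> float | None:
        cell = str(df.at[row_ix, col]).strip()
        if cell == "":
            if optional:
                return None
            raise PeaklistSchemaError(f"{path.name} row {row_ix + 2}: empty required cell {col!r}")
        try:
            return float(cell)
        except ValueError:
            raise PeaklistSchemaError(
                f"{path.name} row {row_ix + 2}: cannot parse {col!r} value {cell!r} as a number"
            ) from None

    records: list[PeakRecord] = []
    for ix in df.index:
        try:
            records.append(
                PeakRecord(
                    name=str(df.at[ix, "Name"]),
                    reported_ri=num(ix, "Retention Index", optional=True),
                    reported_area=num(ix, "Area"),
                    unique_mass=int(num(ix, "UniqueMass")),
                    reported_quant_masses=str(df.at[ix, "Quant Masses"]),
                    rt_s=num(ix, "R.T. (s)"),
                    snr=num(ix, "S/N"),
                    integ_begin_s=num(ix, "Integration Begin"),
                    integ_end_s=num(ix, "Integration End"),
                    fwhh_s=num(ix, "Full Width at Half Height"),
                )
            )
        except PeaklistSchemaError:
            raise
    records.sort(key=lambda r: r.rt_s)
    return records


# ---------------------------------------------------------------------------
# raw chromatograms


@dataclass
class RawChromatogram:
    """A full-scan chromatogram: one unit-binned spectrum per scan."""

    sample_id: str
    scan_times_s: np.ndarray
    scans: list[MassSpectrum]

    def __post_init__(self):
        self.scan_times_s = np.asarray(self.scan_times_s, dtype=float)
        if len(self.scan_times_s) != len(self.scans):
            raise RawDataError(
                f"{self.sample_id}: {len(self.scan_times_s)} scan times for {len(self.scans)} scans"
            )
        if len(self.scan_times_s) > 1 and not np.all(np.diff(self.scan_times_s) > 0):
            raise RawDataError(f"{self.sample_id}: scan times are not strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def nearest_scan(self, time_s: float) -> int:
        """Index of the scan whose acquisition time is closest to ``time_s``."""
        if self.n_scans == 0:
            raise RawDataError(f"{self.sample_id}: chromatogram has no scans")
        return int(np.argmin(np.abs(self.scan_times_s - time_s)))

    def scan_range(self, begin_s: float, end_s: float) -> tuple[int, int]:
        """Integration bounds to inclusive scan indices.

        start = first scan at or after ``begin_s``; end = last scan at or
        before ``end_s``.
        """
        if begin_s > end_s:
            raise ValueError(f"begin {begin_s} > end {end_s}")
        start = int(np.searchsorted(self.scan_times_s, begin_s, side="left"))
        end = int(np.searchsorted(self.scan_times_s, end_s, side="right")) - 1
        if start >= self.n_scans or end < 0 or start > end:
            raise RawDataError(
                f"{self.sample_id}: integration window [{begin_s}, {end_s}] s contains no scans"
            )
        return start, end


def _read_raw_netcdf(path: Path, sample_id: str) -> RawChromatogram:
    from scipy.io import netcdf_file

    try:
        nc = netcdf_file(str(path), "r", mmap=False)
    except Exception as exc:
        raise RawDataError(f"{path.name}: not a readable netCDF file ({exc})") from exc
    with nc:
        try:
            times = np.array(nc.variables["scan_acquisition_time"][:], dtype=float)
            counts = np.array(nc.variables["point_count"][:], dtype=int)
            masses = np.array(nc.variables["mass_values"][:], dtype=float)
            intens = np.array(nc.variables["intensity_values"][:], dtype=float)
        except KeyError as exc:
            raise RawDataError(f"{path.name}: missing ANDI-MS variable {exc}") from None
    scans = []
    offset = 0
    for count in counts:
        scans.append(MassSpectrum.from_pairs(masses[offset : offset + count], intens[offset : offset + count]))
        offset += count
    return _finish_raw(sample_id, times, scans, masses)


def _read_raw_mzml(path: Path, sample_id: str) -> RawChromatogram:
    times = []
    scans = []
    all_masses = []
    for t, mzs, ints in _mzml.iter_spectra(path):
        times.append(t)
        scans.append(MassSpectrum.from_pairs(mzs, ints))
        all_masses.append(mzs)
    masses = np.concatenate(all_masses) if all_masses else np.empty(0)
    return _finish_raw(sample_id, np.array(times, dtype=float), scans, masses)


def _finish_raw(sample_id: str, times: np.ndarray, scans: list[MassSpectrum], masses: np.ndarray) -> RawChromatogram:
    if masses.size:
        lo, hi = MASS_RANGE
        n_out = int(np.count_nonzero((masses < lo - 0.5) | (masses >= hi + 0.5)))
        if n_out:
            warnings.warn(
                f"{sample_id}: {n_out} raw data points outside the nominal m/z range "
                f"[{lo}, {hi}] (retained)",
                stacklevel=3,
            )
    return RawChromatogram(sample_id=sample_id, scan_times_s=times, scans=scans)


def read_raw(path, sample_id: str | None = None) -> RawChromatogram:
    """Read a raw chromatogram from ANDI-MS netCDF or mzML.

    Dispatch is by extension (``.cdf``/``.nc`` vs ``.mzml``) with a content
    sniff as fallback; both formats yield identical chromatograms for
    equivalent content (spectra unit-binned, times in seconds).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    suffix = path.suffix.lower()
    if suffix in (".cdf", ".nc"):
        return _read_raw_netcdf(path, sample_id)
    if suffix == ".mzml":
        return _read_raw_mzml(path, sample_id)
    head = path.read_bytes()[:64]
    if head.startswith(b"CDF"):
        return _read_raw_netcdf(path, sample_id)
    if head.lstrip().startswith(b"<?xml") or b"<mzML" in head:
        return _read_raw_mzml(path, sample_id)
    raise RawDataError(f"{path.name}: unsupported raw format (expected ANDI-MS netCDF or mzML)")


# ---------------------------------------------------------------------------
# quantification-mass overrides


@dataclass(frozen=True)
class QuantMassOverride:
    """User-specified quantification masses for one library entry."""

    entry_name: str
    masses: tuple[int, ...]


def read_quant_mass_file(path, library: Sequence[LibraryEntry]) -> list[QuantMassOverride]:
    """Read the TSV of entry name ↦ semicolon-separated quantification masses.

    Names not present in the library are skipped with a warning.  A named
    entry with an empty mass list is a row error.
    """
    path = Path(path)
    known = {e.raw_name for e in library}
    overrides: list[QuantMassOverride] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_read_text(path).splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise PeaklistSchemaError(
                f"{path.name} line {lineno}: expected two tab-separated columns, got {len(parts)}"
            )
        name, mass_field = parts[0].strip(), parts[1].strip()
        tokens = [t for t in mass_field.split(";") if t.strip()]
        if not tokens:
            raise PeaklistSchemaError(f"{path.name} line {lineno}: empty mass list for {name!r}")
        try:
            masses = tuple(int(float(t)) for t in tokens)
        except ValueError:
            raise PeaklistSchemaError(
                f"{path.name} line {lineno}: cannot parse masses from {mass_field!r}"
            ) from None
        if name in seen:
            raise PeaklistSchemaError(f"{path.name} line {lineno}: duplicate entry name {name!r}")
        seen.add(name)
        if name not in known:
            warnings.warn(
                f"quant-mass file {path.name} line {lineno}: {name!r} is not in the library; skipped",
                stacklevel=2,
            )
            continue
        overrides.append(QuantMassOverride(entry_name=name, masses=masses))
    return overrides
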