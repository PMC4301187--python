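"""Quant-mass quantification and data-matrix export.

An accepted assignment is quantified by returning to the baseline-corrected
raw data: for each of the entry's quantification masses, the intensities of
that mass are summed over all scans between the peak's integration begin and
end times, and the per-mass sums are summed into the total peak area.

Export produces two CSV matrices of identical shape (metabolites × samples):
``rawAreaMatrix.csv`` holds the peak caller's own Area values and
``AreaMatrix.csv`` the quant-mass areas computed here.  Slots without an
assignment export as empty cells, distinguishable from a true zero.  A
long-format ``areasByMass.csv`` with the per-mass areas is written alongside.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .io_formats import RawChromatogram
from .reverse_search import Assignment, PeakGroup

__all__ = [
    "QuantResult",
    "quantify_assignment",
    "quantify_project",
    "export_matrices",
]


@dataclass
class QuantResult:
    """Quantification of one entry in one sample."""

    entry_name: str
    sample_id: str
    per_mass_area: dict[int, float]
    total_area: float
    raw_area: float


def quantify_assignment(
    assignment: Assignment,
    raw: RawChromatogram,
    quant_masses: Sequence[int],
) -> QuantResult:
    """Sum each quantification mass over the peak's integration scan range."""
    if not quant_masses:
        raise ValueError(f"{assignment.entry_name}: empty quantification mass list")
    peak = assignment.peak
    start, end = raw.scan_range(peak.integ_begin_s, peak.integ_end_s)
    per_mass: dict[int, float] = {}
    for mass in quant_masses:
        area = 0.0
        for scan_ix in range(start, end + 1):
            area += raw.scans[scan_ix].intensity_at(mass)
        if area == 0.0:
            warnings.warn(
                f"{assignment.entry_name} in {assignment.sample_id}: quantification mass "
                f"{mass} has zero intensity over scans [{start}, {end}]",
                stacklevel=2,
            )
        per_mass[int(mass)] = area
    return QuantResult(
        entry_name=assignment.entry_name,
        sample_id=assignment.sample_id,
        per_mass_area=per_mass,
        total_area=sum(per_mass.values()),
        raw_area=peak.reported_area,
    )


def quantify_project(
    groups: Sequence[PeakGroup],
    raws: Mapping[str, RawChromatogram],
) -> list[QuantResult]:
    """Quantify every assignment of every locked group.

    Only locked (validated) groups are quantified; unassigned sample slots
    are simply absent from the result and export as empty cells.
    """
    results: list[QuantResult] = []
    for group in groups:
        if not group.locked:
            continue
        if not group.entry.quant_masses:
            raise ValueError(f"{group.entry.raw_name!r}: quantification masses not resolved")
        for sample_id, assignment in group.assignments.items():
            if sample_id not in raws:
                raise KeyError(f"no raw chromatogram for sample {sample_id!r}")
            results.append(quantify_assignment(assignment, raws[sample_id], group.entry.quant_masses))
    return results


def export_matrices(
    results: Sequence[QuantResult],
    groups: Sequence[PeakGroup],
    out_dir,
    sample_ids: Sequence[str],
    treatments: Mapping[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write ``rawAreaMatrix.csv`` and ``AreaMatrix.csv`` (plus per-mass areas).

    Rows are the locked groups in library order; columns follow
    ``sample_ids``.  The first header row carries the sample ids, the second
    the treatment labels.  Both matrices share shape, row names, and column
    order; missing assignments are empty cells.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    treatments = treatments or {}
    locked = [g for g in groups if g.locked]
    by_cell = {(r.entry_name, r.sample_id): r for r in results}

    def write_matrix(path: Path, value_of) -> Path:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Metabolite"] + list(sample_ids))
            writer.writerow(["Treatment"] + [treatments.get(s, "") for s in sample_ids])
            for group in locked:
                row = [group.entry.raw_name]
                for sample_id in sample_ids:
                    res = by_cell.get((group.entry.raw_name, sample_id))
                    row.append("" if res is None else repr(value_of(res)))
                writer.writerow(row)
        return path

    raw_path = write_matrix(out_dir / "rawAreaMatrix.csv", lambda r: r.raw_area)
    area_path = write_matrix(out_dir / "AreaMatrix.csv", lambda r: r.total_area)

    with open(out_dir / "areasByMass.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Metabolite", "Sample", "QuantMass", "Area"])
        for res in results:
            for mass in sorted(res.per_mass_area):
                writer.writerow([res.entry_name, res.sample_id, mass, repr(res.per_mass_area[mass])])
    return raw_path, area_path
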