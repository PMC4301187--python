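"""Headless curation operations on peaks and peak groups.

These are the scriptable equivalents of the interactive curation actions:
fusing wrongly deconvoluted split peaks, duplicating peaks that hold two
co-eluting metabolites, manually adding/removing assignments, accepting a
peak (which drops the RI penalty from its score), and locking a validated
group for export.  Every operation can be recorded in an append-only edit
log and replayed deterministically from a script.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, MutableSequence, Sequence

from .io_formats import LibraryEntry
from .reverse_search import (
    Assignment,
    LockError,
    Peak,
    PeakGroup,
    PeakState,
)
from .spectra import ScoringConfig, cosine_score

__all__ = [
    "PeakGroup",
    "LockError",
    "EditLog",
    "fuse",
    "fuse_region",
    "duplicate",
    "set_found",
    "set_not_found",
    "set_all_found",
    "set_all_not_found",
    "accept_peak",
    "accept_group",
    "enable_edit",
    "apply_edit_script",
]


@dataclass
class EditLog:
    """Append-only record of curation operations, serializable as JSON lines."""

    records: list[dict] = field(default_factory=list)

    def append(self, op: str, **params):
        self.records.append({"op": op, **params})

    def dump(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")
        return path


def _log(log: EditLog | None, op: str, **params):
    if log is not None:
        log.append(op, **params)


def fuse(
    sample_peaks: MutableSequence[Peak],
    left: Peak,
    right: Peak,
    log: EditLog | None = None,
) -> Peak:
    """Fuse two adjacent peaks of one sample into one.

    The fused peak takes the mean RI of the two, the union of their scan
    ranges and integration bounds, and the per-bin sum of their apex spectra.
    The originals are removed from the sample peak list and the fused peak
    inserted in RT order.
    """
    if left is right:
        raise ValueError("cannot fuse a peak with itself")
    if left.sample_id != right.sample_id:
        raise ValueError(f"cannot fuse peaks of different samples ({left.sample_id!r} vs {right.sample_id!r})")
    left.require_unlocked()
    right.require_unlocked()
    if left.rt_s > right.rt_s:
        left, right = right, left
    if left.ri is not None and right.ri is not None:
        ri = (left.ri + right.ri) / 2.0
    else:
        ri = None
    scans = [s for s in (left.start_scan, right.start_scan) if s is not None]
    ends = [s for s in (left.end_scan, right.end_scan) if s is not None]
    dominant = left if left.apex_spectrum.total_intensity() >= right.apex_spectrum.total_intensity() else right
    fused = Peak(
        sample_id=left.sample_id,
        rt_s=(left.rt_s + right.rt_s) / 2.0,
        apex_spectrum=left.apex_spectrum + right.apex_spectrum,
        integ_begin_s=min(left.integ_begin_s, right.integ_begin_s),
        integ_end_s=max(left.integ_end_s, right.integ_end_s),
        unique_mass=dominant.unique_mass,
        snr=max(left.snr, right.snr),
        reported_area=left.reported_area + right.reported_area,
        fwhh_s=max(left.fwhh_s, right.fwhh_s),
        ri=ri,
        start_scan=min(scans) if scans else None,
        end_scan=max(ends) if ends else None,
        provenance_name=f"fused({left.provenance_name}|{right.provenance_name})",
    )
    for p in (left, right):
        sample_peaks.remove(p)
    sample_peaks.append(fused)
    try:
        sample_peaks.sort(key=lambda p: p.rt_s)  # type: ignore[attr-defined]
    except AttributeError:
        pass
    _log(log, "fuse", sample=left.sample_id, rt_left=left.rt_s, rt_right=right.rt_s)
    return fused


def fuse_region(
    samples: Mapping[str, MutableSequence[Peak]],
    ri_lo: float,
    ri_hi: float,
    log: EditLog | None = None,
) -> dict[str, int]:
    """Fuse, per sample, all unlocked peaks whose RI falls in [ri_lo, ri_hi].

    Peaks are fused pairwise left to right into a single peak per sample.
    A sample whose window touches a locked peak is skipped with a warning.
    Returns the number of fusions performed per sample.
    """
    if not (ri_lo < ri_hi):
        raise ValueError(f"invalid RI window [{ri_lo}, {ri_hi}]")
    report: dict[str, int] = {}
    for sample_id, peaks in samples.items():
        in_window = [p for p in peaks if p.ri is not None and ri_lo <= p.ri <= ri_hi]
        if any(p.locked for p in in_window):
            warnings.warn(f"{sample_id}: fuse region [{ri_lo}, {ri_hi}] overlaps a locked peak; skipped", stacklevel=2)
            report[sample_id] = 0
            continue
        in_window.sort(key=lambda p: p.rt_s)
        count = 0
        while len(in_window) > 1:
            fused = fuse(peaks, in_window[0], in_window[1], log=None)
            in_window = [fused] + in_window[2:]
            count += 1
        report[sample_id] = count
    _log(log, "fuse_region", ri_lo=ri_lo, ri_hi=ri_hi, report=dict(report))
    return report


def duplicate(
    sample_peaks: MutableSequence[Peak],
    peaks: Sequence[Peak],
    source_entry: LibraryEntry | None = None,
    target_entry: LibraryEntry | None = None,
    log: EditLog | None = None,
) -> list[Peak]:
    """Copy peaks so a second co-eluting metabolite can be assigned to them.

    The copies keep RT, RI, scan bounds, and spectrum, but start unassigned.
    When both the currently assigned entry and the intended second entry are
    given, a warning names any quantification masses they share (duplication
    is only valid for disjoint quant masses).
    """
    copies: list[Peak] = []
    for peak in peaks:
        peak.require_unlocked()
        copy = Peak(
            sample_id=peak.sample_id,
            rt_s=peak.rt_s,
            apex_spectrum=peak.apex_spectrum,
            integ_begin_s=peak.integ_begin_s,
            integ_end_s=peak.integ_end_s,
            unique_mass=peak.unique_mass,
            snr=peak.snr,
            reported_area=peak.reported_area,
            fwhh_s=peak.fwhh_s,
            ri=peak.ri,
            ri_extrapolated=peak.ri_extrapolated,
            start_scan=peak.start_scan,
            end_scan=peak.end_scan,
            provenance_name=f"duplicate({peak.provenance_name})",
        )
        sample_peaks.append(copy)
        copies.append(copy)
        _log(log, "duplicate", sample=peak.sample_id, rt=peak.rt_s)
    try:
        sample_peaks.sort(key=lambda p: p.rt_s)  # type: ignore[attr-defined]
    except AttributeError:
        pass
    if source_entry is not None and target_entry is not None:
        shared = sorted(set(source_entry.quant_masses) & set(target_entry.quant_masses))
        if shared:
            warnings.warn(
                f"duplicate: {source_entry.raw_name!r} and {target_entry.raw_name!r} share "
                f"quantification mass(es) {shared}; their quantifications will not be independent",
                stacklevel=2,
            )
    return copies


def set_found(group: PeakGroup, peak: Peak, log: EditLog | None = None) -> Assignment:
    """Manually assign a peak to the group's entry, bypassing the threshold.

    The recorded score is the unpenalized cosine between entry and peak.
    Idempotent when the peak is already the group's assignment.
    """
    group.require_unlocked()
    peak.require_unlocked()
    entry = group.entry
    existing = group.assignments.get(peak.sample_id)
    if existing is not None and existing.peak is peak:
        return existing
    if existing is not None:
        existing.peak.clear_assignment()
    if peak.ri is None:
        raise ValueError(f"peak at {peak.rt_s} s has no RI; calibrate before assigning")
    raw = cosine_score(entry.spectrum, peak.apex_spectrum)
    assignment = Assignment(
        entry_name=entry.raw_name,
        sample_id=peak.sample_id,
        peak=peak,
        raw_cosine=raw,
        ri_difference=abs(peak.ri - entry.reference_ri),
        penalized=raw,
        manual=True,
    )
    peak.state = PeakState.PUTATIVE
    peak.assigned_entry = entry.raw_name
    peak.assigned_score = raw
    group.assignments[peak.sample_id] = assignment
    _log(log, "set_found", entry=entry.raw_name, sample=peak.sample_id, rt=peak.rt_s)
    return assignment


def set_not_found(group: PeakGroup, sample_id: str, log: EditLog | None = None) -> None:
    """Remove the group's assignment in one sample (no-op if none)."""
    group.require_unlocked()
    assignment = group.assignments.pop(sample_id, None)
    if assignment is not None:
        assignment.peak.clear_assignment()
    _log(log, "set_not_found", entry=group.entry.raw_name, sample=sample_id)


def set_all_found(
    group: PeakGroup,
    samples: Mapping[str, Sequence[Peak]],
    config: ScoringConfig | None = None,
    log: EditLog | None = None,
) -> dict[str, bool]:
    """Assign, per sample, the best in-window peak by plain cosine, no threshold.

    Intended for entries the reverse search missed for want of peak quality
    or intensity.  Samples without an in-window unlocked peak are skipped
    with a warning.  Returns per-sample success flags.
    """
    group.require_unlocked()
    config = config or ScoringConfig()
    entry = group.entry
    report: dict[str, bool] = {}
    for sample_id, peaks in samples.items():
        candidates = [
            p
            for p in peaks
            if not p.locked and p.ri is not None and abs(p.ri - entry.reference_ri) <= config.ri_window
        ]
        if not candidates:
            warnings.warn(
                f"set_all_found({entry.raw_name}): no unlocked peak within ±{config.ri_window} RI "
                f"units in sample {sample_id}",
                stacklevel=2,
            )
            report[sample_id] = False
            continue
        best = max(
            candidates,
            key=lambda p: (
                cosine_score(entry.spectrum, p.apex_spectrum, config.score_scale),
                -abs(p.ri - entry.reference_ri),
                -p.rt_s,
            ),
        )
        set_found(group, best, log=None)
        report[sample_id] = True
    _log(log, "set_all_found", entry=entry.raw_name, report=dict(report))
    return report


def set_all_not_found(group: PeakGroup, log: EditLog | None = None) -> None:
    """Remove the group's assignments in every sample."""
    group.require_unlocked()
    for sample_id in list(group.assignments):
        set_not_found(group, sample_id, log=None)
    _log(log, "set_all_not_found", entry=group.entry.raw_name)


def accept_peak(group: PeakGroup, sample_id: str, log: EditLog | None = None) -> Assignment:
    """Confirm one assignment: re-score without the RI penalty and accept.

    The stored score becomes the plain cosine similarity; the peak moves to
    the accepted state.  Idempotent.
    """
    group.require_unlocked()
    assignment = group.assignments.get(sample_id)
    if assignment is None:
        raise ValueError(f"{group.entry.raw_name!r} has no assignment in sample {sample_id!r}")
    peak = assignment.peak
    peak.require_unlocked()
    peak.assigned_score = assignment.raw_cosine
    assignment.penalized = assignment.raw_cosine
    peak.state = PeakState.ACCEPTED
    _log(log, "accept_peak", entry=group.entry.raw_name, sample=sample_id)
    return assignment


def accept_group(group: PeakGroup, log: EditLog | None = None) -> PeakGroup:
    """Lock the group: members are validated, immutable, and exportable."""
    for assignment in group.assignments.values():
        assignment.peak.state = PeakState.LOCKED
    group.locked = True
    _log(log, "accept_group", entry=group.entry.raw_name)
    return group


def enable_edit(group: PeakGroup, log: EditLog | None = None) -> PeakGroup:
    """Remove the lock; members return to the accepted (editable) state."""
    group.locked = False
    for assignment in group.assignments.values():
        assignment.peak.state = PeakState.ACCEPTED
    _log(log, "enable_edit", entry=group.entry.raw_name)
    return group


# ---------------------------------------------------------------------------
# edit scripts


def _find_peak(peaks: Sequence[Peak], rt: float, tol: float = 0.51) -> Peak:
    best = min(peaks, key=lambda p: abs(p.rt_s - rt))
    if abs(best.rt_s - rt) > tol:
        raise ValueError(f"no peak within {tol} s of RT {rt} s")
    return best


def apply_edit_script(
    groups: Sequence[PeakGroup],
    samples: Mapping[str, MutableSequence[Peak]],
    script,
    config: ScoringConfig | None = None,
    log: EditLog | None = None,
) -> None:
    """Replay an edit script (JSON-lines file, path, or iterable of records).

    Supported operations: ``fuse`` (sample, rt_left, rt_right),
    ``fuse_region`` (ri_lo, ri_hi), ``duplicate`` (sample, rt),
    ``set_found`` (entry, sample, rt), ``set_not_found`` (entry, sample),
    ``set_all_found`` / ``set_all_not_found`` (entry), ``accept_peak``
    (entry, sample), ``accept_group`` / ``enable_edit`` (entry).
    """
    config = config or ScoringConfig()
    if isinstance(script, (str, Path)):
        with open(script, encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    else:
        records = [dict(r) for r in script]
    by_entry = {g.entry.raw_name: g for g in groups}

    def group_of(rec) -> PeakGroup:
        name = rec["entry"]
        if name not in by_entry:
            raise ValueError(f"edit script names unknown library entry {name!r}")
        return by_entry[name]

    for rec in records:
        op = rec.get("op")
        if op == "fuse":
            peaks = samples[rec["sample"]]
            left = _find_peak(peaks, float(rec["rt_left"]))
            right = _find_peak(peaks, float(rec["rt_right"]))
            fused = fuse(peaks, left, right, log=log)
            _scrub_dangling(groups, peaks)
            del fused
        elif op == "fuse_region":
            fuse_region(samples, float(rec["ri_lo"]), float(rec["ri_hi"]), log=log)
            for peaks in samples.values():
                _scrub_dangling(groups, peaks)
        elif op == "duplicate":
            peaks = samples[rec["sample"]]
            duplicate(peaks, [_find_peak(peaks, float(rec["rt"]))], log=log)
        elif op == "set_found":
            peaks = samples[rec["sample"]]
            set_found(group_of(rec), _find_peak(peaks, float(rec["rt"])), log=log)
        elif op == "set_not_found":
            set_not_found(group_of(rec), rec["sample"], log=log)
        elif op == "set_all_found":
            set_all_found(group_of(rec), samples, config, log=log)
        elif op == "set_all_not_found":
            set_all_not_found(group_of(rec), log=log)
        elif op == "accept_peak":
            accept_peak(group_of(rec), rec["sample"], log=log)
        elif op == "accept_group":
            accept_group(group_of(rec), log=log)
        elif op == "enable_edit":
            enable_edit(group_of(rec), log=log)
        else:
            raise ValueError(f"unknown edit operation {op!r}")


def _scrub_dangling(groups: Sequence[PeakGroup], peaks: Sequence[Peak]):
    """Drop group assignments whose peak was removed (e.g. by fusion)."""
    alive = {id(p) for p in peaks}
    for group in groups:
        for sample_id, assignment in list(group.assignments.items()):
            if assignment.sample_id == (peaks[0].sample_id if peaks else None) and id(assignment.peak) not in alive:
                del group.assignments[sample_id]
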