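"""Reverse library search: per library entry, find the best sample peak.

Instead of assigning every peak a library identity (forward search), the
search asks, for each library entry and each sample, which peak within
±13 RI units of the entry's reference RI best matches the entry's spectrum.
Candidates are ranked by the cosine score penalized for RI deviation; the
winner is putatively assigned only if its penalized score is strictly above
the threshold (800 by default).  At most one peak per entry per sample is
ever assigned.

Cross-entry conflicts (two entries winning the same peak) are resolved in
favor of the higher penalized score; the losing entry falls back to its next
best above-threshold candidate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .io_formats import LibraryEntry, PeakRecord, RawChromatogram
from .spectra import MassSpectrum, ScoringConfig, cosine_score, penalized_score

__all__ = [
    "PeakState",
    "Peak",
    "Assignment",
    "PeakGroup",
    "LockError",
    "build_peaks",
    "reverse_search_entry",
    "reverse_search_all",
]


class LockError(RuntimeError):
    """Raised when an operation would mutate a locked peak or group."""


class PeakState(enum.Enum):
    UNKNOWN = "unknown"
    PUTATIVE = "putative"
    ACCEPTED = "accepted"
    LOCKED = "locked"


@dataclass
class Peak:
    """One detected chromatographic feature in one sample."""

    sample_id: str
    rt_s: float
    apex_spectrum: MassSpectrum
    integ_begin_s: float
    integ_end_s: float
    unique_mass: int = 0
    snr: float = 0.0
    reported_area: float = 0.0
    fwhh_s: float = 0.0
    ri: float | None = None
    ri_extrapolated: bool = False
    start_scan: int | None = None
    end_scan: int | None = None
    state: PeakState = PeakState.UNKNOWN
    assigned_entry: str | None = None
    assigned_score: float | None = None
    is_alkane_anchor: bool = False
    provenance_name: str = ""

    def __post_init__(self):
        if self.integ_begin_s > self.integ_end_s:
            raise ValueError(f"peak at {self.rt_s} s: integration begin after end")
        if self.start_scan is not None and self.end_scan is not None and self.start_scan > self.end_scan:
            raise ValueError(f"peak at {self.rt_s} s: start_scan after end_scan")

    @property
    def locked(self) -> bool:
        return self.state is PeakState.LOCKED

    def require_unlocked(self):
        if self.locked:
            raise LockError(f"peak at RT {self.rt_s} s in sample {self.sample_id} is locked")

    def clear_assignment(self):
        self.require_unlocked()
        self.assigned_entry = None
        self.assigned_score = None
        self.state = PeakState.UNKNOWN


@dataclass
class Assignment:
    """The outcome of matching one library entry to one peak in one sample."""

    entry_name: str
    sample_id: str
    peak: Peak
    raw_cosine: float
    ri_difference: float
    penalized: float
    manual: bool = False


@dataclass
class PeakGroup:
    """One library entry plus its (at most one) assigned peak per sample."""

    entry: LibraryEntry
    assignments: dict[str, Assignment] = field(default_factory=dict)
    locked: bool = False

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    def require_unlocked(self):
        if self.locked:
            raise LockError(f"peak group {self.entry.raw_name!r} is locked (Accept Group); Enable Edit first")


def build_peaks(records: Sequence[PeakRecord], raw: RawChromatogram) -> list[Peak]:
    """Materialize peaks from peak-list rows against their raw chromatogram.

    The apex spectrum is the raw scan nearest the reported retention time;
    scan bounds come from the integration begin/end times.
    """
    peaks: list[Peak] = []
    for rec in records:
        apex = raw.scans[raw.nearest_scan(rec.rt_s)]
        start, end = raw.scan_range(rec.integ_begin_s, rec.integ_end_s)
        peaks.append(
            Peak(
                sample_id=raw.sample_id,
                rt_s=rec.rt_s,
                apex_spectrum=apex,
                integ_begin_s=rec.integ_begin_s,
                integ_end_s=rec.integ_end_s,
                unique_mass=rec.unique_mass,
                snr=rec.snr,
                reported_area=rec.reported_area,
                fwhh_s=rec.fwhh_s,
                start_scan=start,
                end_scan=end,
                provenance_name=rec.name,
            )
        )
    peaks.sort(key=lambda p: p.rt_s)
    return peaks


def _candidate_assignments(
    entry: LibraryEntry,
    sample_peaks: Sequence[Peak],
    config: ScoringConfig,
) -> list[Assignment]:
    """All above-threshold candidates for an entry in one sample, best first.

    Candidates are unlocked/unaccepted peaks within the RI window (inclusive
    at exactly the window edge).  Ordered by penalized score descending, then
    smaller |ΔRI|, then earlier RT.
    """
    if not entry.valid_for_search:
        raise ValueError(f"library entry {entry.raw_name!r} has an empty spectrum and cannot be searched")
    out: list[Assignment] = []
    for peak in sample_peaks:
        if peak.ri is None:
            raise ValueError(
                f"sample {peak.sample_id!r} has peaks without retention indices; calibrate first"
            )
        if peak.state in (PeakState.ACCEPTED, PeakState.LOCKED):
            continue
        d_ri = abs(peak.ri - entry.reference_ri)
        if d_ri > config.ri_window:
            continue
        raw = cosine_score(entry.spectrum, peak.apex_spectrum, scale=config.score_scale)
        pen = penalized_score(raw, d_ri, config.penalty_table)
        if pen > config.score_threshold:
            out.append(
                Assignment(
                    entry_name=entry.raw_name,
                    sample_id=peak.sample_id,
                    peak=peak,
                    raw_cosine=raw,
                    ri_difference=d_ri,
                    penalized=pen,
                )
            )
    out.sort(key=lambda a: (-a.penalized, a.ri_difference, a.peak.rt_s))
    return out


def _mark_putative(assignment: Assignment):
    peak = assignment.peak
    peak.state = PeakState.PUTATIVE
    peak.assigned_entry = assignment.entry_name
    peak.assigned_score = assignment.penalized


def reverse_search_entry(
    entry: LibraryEntry,
    sample_peaks: Sequence[Peak],
    config: ScoringConfig | None = None,
) -> Assignment | None:
    """Search one entry in one sample; assign the best peak, if any qualifies.

    Returns ``None`` when no in-window peak scores strictly above the
    threshold — the entry simply appears absent from the sample.
    """
    config = config or ScoringConfig()
    candidates = _candidate_assignments(entry, sample_peaks, config)
    if not candidates:
        return None
    winner = candidates[0]
    _mark_putative(winner)
    return winner


def reverse_search_all(
    library: Sequence[LibraryEntry],
    samples: Mapping[str, Sequence[Peak]],
    config: ScoringConfig | None = None,
) -> list[PeakGroup]:
    """Run the reverse search for every entry across every sample.

    Returns one :class:`PeakGroup` per library entry (library order), each
    holding the per-sample assignments.  Within a sample, a peak carries at
    most one identity: if two entries win the same peak, the higher penalized
    score keeps it and the other entry falls back to its next-best candidate
    above threshold (iterated to a fixpoint).
    """
    config = config or ScoringConfig()
    groups = [PeakGroup(entry=entry) for entry in library]
    by_name = {g.entry.raw_name: g for g in groups}
    if len(by_name) != len(groups):
        raise ValueError("library contains duplicate entry names")

    for sample_id, peaks in samples.items():
        # ranked candidate lists per entry, then greedy by descending score:
        # at each step the globally best remaining (entry, free peak) pair is
        # fixed, so no later entry can displace an earlier winner.
        ranked = {
            entry.raw_name: _candidate_assignments(entry, peaks, config)
            for entry in library
            if entry.valid_for_search
        }
        taken: set[int] = set()
        unassigned = set(ranked)
        while True:
            best: Assignment | None = None
            best_key = None
            for name in unassigned:
                for cand in ranked[name]:
                    if id(cand.peak) in taken:
                        continue
                    key = (-cand.penalized, cand.ri_difference, cand.peak.rt_s, cand.entry_name)
                    if best_key is None or key < best_key:
                        best, best_key = cand, key
                    break  # lists are sorted; first free candidate is the entry's best
            if best is None:
                break
            taken.add(id(best.peak))
            unassigned.discard(best.entry_name)
            _mark_putative(best)
            by_name[best.entry_name].assignments[sample_id] = best
    return groups


def brute_force_reverse_search(
    library: Sequence[LibraryEntry],
    samples: Mapping[str, Sequence[Peak]],
    config: ScoringConfig | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Independent oracle: score every entry/peak pair, then filter and argmax.

    No windowing shortcut — every pair in a sample is scored, the RI window
    and threshold are applied afterwards, and cross-entry conflicts are
    resolved by exhaustively re-ranking after each removal.  Returns
    ``(entry_name, sample_id) -> (penalized_score, peak_rt_s)`` for the
    assignments it makes.  Used only for testing the production search.
    """
    config = config or ScoringConfig()
    result: dict[tuple[str, str], tuple[float, float]] = {}
    for sample_id, peaks in samples.items():
        scored: list[tuple[float, float, float, str, Peak]] = []
        for entry in library:
            if not entry.valid_for_search:
                continue
            for peak in peaks:
                if peak.state in (PeakState.ACCEPTED, PeakState.LOCKED):
                    continue
                d = abs(peak.ri - entry.reference_ri)
                pen = penalized_score(
                    cosine_score(entry.spectrum, peak.apex_spectrum, config.score_scale),
                    d,
                    config.penalty_table,
                )
                if d <= config.ri_window and pen > config.score_threshold:
                    scored.append((pen, d, peak.rt_s, entry.raw_name, peak))
        assigned_entries: set[str] = set()
        taken_peaks: set[int] = set()
        while True:
            pool = [s for s in scored if s[3] not in assigned_entries and id(s[4]) not in taken_peaks]
            if not pool:
                break
            pool.sort(key=lambda s: (-s[0], s[1], s[2], s[3]))
            pen, d, rt, name, peak = pool[0]
            assigned_entries.add(name)
            taken_peaks.add(id(peak))
            result[(name, sample_id)] = (pen, rt)
    return result
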