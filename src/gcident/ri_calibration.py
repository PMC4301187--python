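"""Retention-index calibration against an n-alkane ladder.

A wash run containing only the alkane mixture anchors the RI scale: the
alkane with *n* carbons defines RI = 100·n.  Alkane peaks are found in the
wash by their diagnostic electron-ionization fragments (m/z 71, 85, 99 by
default), matched to user-supplied approximate retention times, and collected
into a wash database of spectra and retention times.  Each sample is then
searched for the alkanes within ±15 s of the wash retention times by cosine
similarity to the wash spectra, and every peak's RI follows by piecewise
linear interpolation in retention time between the bracketing alkane anchors
(the temperature-programmed, van den Dool & Kratz form):

    RI(t) = 100·c_k + 100·(c_{k+1} − c_k) · (t − t_k) / (t_{k+1} − t_k)

Outside the anchor range the terminal segment's line is extended and the peak
is flagged as extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reverse_search import Peak
from .spectra import MassSpectrum, cosine_score

__all__ = [
    "AlkaneConfig",
    "WashAnchor",
    "WashDatabase",
    "CalibrationAnchor",
    "AlkaneCalibration",
    "CalibrationError",
    "detect_wash_alkanes",
    "locate_alkanes_in_sample",
    "assign_retention_indices",
]

DEFAULT_DIAGNOSTIC_MASSES = (71, 85, 99)


class CalibrationError(ValueError):
    """Alkane detection or RI calibration cannot proceed."""


@dataclass(frozen=True)
class AlkaneConfig:
    """User-provided description of the alkane ladder.

    ``approx_wash_rts_s`` are the approximate alkane retention times in the
    wash run; ``sample_search_window_s`` is the half-width of the targeted
    per-sample search (±15 s); ``wash_match_tolerance_s`` bounds how far an
    observed wash candidate may sit from its stated approximate RT.
    """

    carbon_numbers: tuple[int, ...]
    approx_wash_rts_s: tuple[float, ...]
    diagnostic_masses: tuple[int, ...] = DEFAULT_DIAGNOSTIC_MASSES
    sample_search_window_s: float = 15.0
    wash_match_tolerance_s: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "carbon_numbers", tuple(int(c) for c in self.carbon_numbers))
        object.__setattr__(self, "approx_wash_rts_s", tuple(float(t) for t in self.approx_wash_rts_s))
        object.__setattr__(self, "diagnostic_masses", tuple(int(m) for m in self.diagnostic_masses))
        if len(self.carbon_numbers) != len(self.approx_wash_rts_s):
            raise CalibrationError("carbon_numbers and approx_wash_rts_s must have equal length")
        if len(self.carbon_numbers) < 2:
            raise CalibrationError("at least two alkanes are required for interpolation")
        if any(b <= a for a, b in zip(self.carbon_numbers, self.carbon_numbers[1:])):
            raise CalibrationError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(self.approx_wash_rts_s, self.approx_wash_rts_s[1:])):
            raise CalibrationError("approximate wash RTs must be strictly increasing")
        if self.sample_search_window_s <= 0:
            raise CalibrationError("sample_search_window_s must be positive")

    @property
    def n_alkanes(self) -> int:
        return len(self.carbon_numbers)


@dataclass(frozen=True)
class WashAnchor:
    name: str
    carbon_number: int
    wash_rt_s: float
    spectrum: MassSpectrum


@dataclass(frozen=True)
class WashDatabase:
    """Spectra and retention times of the alkanes identified in the wash run."""

    anchors: tuple[WashAnchor, ...]

    def __post_init__(self):
        rts = [a.wash_rt_s for a in self.anchors]
        carbons = [a.carbon_number for a in self.anchors]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise CalibrationError("wash anchors must be in strictly increasing carbon order")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise CalibrationError("wash anchor RTs must increase with carbon number")


@dataclass
class CalibrationAnchor:
    carbon_number: int
    rt_s: float | None
    confirmed: bool

    @property
    def nominal_ri(self) -> float:
        return 100.0 * self.carbon_number


@dataclass
class AlkaneCalibration:
    """Per-sample alkane anchor positions used for RI interpolation."""

    sample_id: str
    anchors: list[CalibrationAnchor] = field(default_factory=list)

    @property
    def confirmed_anchors(self) -> list[CalibrationAnchor]:
        return [a for a in self.anchors if a.confirmed]


def _diagnostic_intensity(peak: Peak, masses: Sequence[int]) -> float:
    return sum(peak.apex_spectrum.intensity_at(m) for m in masses)


def detect_wash_alkanes(wash_peaks: Sequence[Peak], config: AlkaneConfig) -> WashDatabase:
    """Identify the alkane peaks in the wash run.

    Candidates are the peaks with the highest summed intensity over the
    diagnostic masses (one candidate slot per configured alkane); each alkane
    is then matched to the candidate with the minimal distance to its
    approximate retention time.  A candidate may serve at most one alkane.
    """
    if not wash_peaks:
        raise CalibrationError("wash peak list is empty")
    ranked = sorted(
        (p for p in wash_peaks if _diagnostic_intensity(p, config.diagnostic_masses) > 0),
        key=lambda p: (-_diagnostic_intensity(p, config.diagnostic_masses), p.rt_s),
    )
    candidates = ranked[: config.n_alkanes]
    if len(candidates) < config.n_alkanes:
        raise CalibrationError(
            f"wash contains only {len(candidates)} peaks with diagnostic-mass signal "
            f"({config.n_alkanes} alkanes configured)"
        )
    claimed: dict[int, int] = {}  # candidate index -> alkane position
    anchors: list[WashAnchor] = []
    for pos, (carbon, approx_rt) in enumerate(zip(config.carbon_numbers, config.approx_wash_rts_s)):
        dists = [abs(c.rt_s - approx_rt) for c in candidates]
        best_ix = int(np.argmin(dists))
        if dists[best_ix] > config.wash_match_tolerance_s:
            raise CalibrationError(
                f"no wash candidate within {config.wash_match_tolerance_s} s of the approximate RT "
                f"{approx_rt} s for alkane C{carbon}"
            )
        if best_ix in claimed:
            other = config.carbon_numbers[claimed[best_ix]]
            raise CalibrationError(
                f"alkanes C{other} and C{carbon} both match the wash peak at "
                f"{candidates[best_ix].rt_s} s; check the approximate retention times"
            )
        claimed[best_ix] = pos
        cand = candidates[best_ix]
        anchors.append(
            WashAnchor(
                name=f"C{carbon}",
                carbon_number=carbon,
                wash_rt_s=cand.rt_s,
                spectrum=cand.apex_spectrum,
            )
        )
    anchors.sort(key=lambda a: a.carbon_number)
    return WashDatabase(anchors=tuple(anchors))


def locate_alkanes_in_sample(
    sample_peaks: Sequence[Peak],
    wash: WashDatabase,
    config: AlkaneConfig,
) -> AlkaneCalibration:
    """Targeted search for every wash alkane in one sample.

    For each anchor, peaks within ±``sample_search_window_s`` of the wash RT
    are scored by cosine similarity against the wash spectrum; the best
    scorer becomes the anchor (ties: smaller |ΔRT|, then earlier RT).
    Anchors with no in-window candidate, or breaking RT monotonicity, are
    left unconfirmed; at least two confirmed anchors are required.
    """
    if not sample_peaks:
        raise CalibrationError("sample peak list is empty")
    sample_id = sample_peaks[0].sample_id
    anchors: list[CalibrationAnchor] = []
    for wa in wash.anchors:
        in_window = [p for p in sample_peaks if abs(p.rt_s - wa.wash_rt_s) <= config.sample_search_window_s]
        if not in_window:
            warnings.warn(
                f"{sample_id}: no peak within ±{config.sample_search_window_s} s of the "
                f"wash RT for C{wa.carbon_number}; anchor unconfirmed",
                stacklevel=2,
            )
            anchors.append(CalibrationAnchor(wa.carbon_number, None, confirmed=False))
            continue
        best = min(
            in_window,
            key=lambda p: (
                -cosine_score(wa.spectrum, p.apex_spectrum),
                abs(p.rt_s - wa.wash_rt_s),
                p.rt_s,
            ),
        )
        best.is_alkane_anchor = True
        anchors.append(CalibrationAnchor(wa.carbon_number, best.rt_s, confirmed=True))
    # anchors violating RT monotonicity are demoted to unconfirmed
    last_rt = -np.inf
    for anchor in anchors:
        if not anchor.confirmed:
            continue
        if anchor.rt_s <= last_rt:
            warnings.warn(
                f"{sample_id}: C{anchor.carbon_number} anchor at {anchor.rt_s} s breaks RT "
                f"monotonicity; anchor unconfirmed",
                stacklevel=2,
            )
            anchor.confirmed = False
        else:
            last_rt = anchor.rt_s
    calib = AlkaneCalibration(sample_id=sample_id, anchors=anchors)
    if len(calib.confirmed_anchors) < 2:
        raise CalibrationError(
            f"{sample_id}: only {len(calib.confirmed_anchors)} confirmed alkane anchors; "
            f"at least two are needed for interpolation"
        )
    return calib


def _interpolator(calib: AlkaneCalibration):
    anchors = calib.confirmed_anchors
    rts = np.array([a.rt_s for a in anchors], dtype=float)
    ris = np.array([a.nominal_ri for a in anchors], dtype=float)
    if np.any(np.diff(rts) <= 0):
        raise CalibrationError(f"{calib.sample_id}: coincident or non-increasing anchor RTs")

    def ri_of(t: float) -> tuple[float, bool]:
        k = int(np.clip(np.searchsorted(rts, t, side="right") - 1, 0, len(rts) - 2))
        slope = (ris[k + 1] - ris[k]) / (rts[k + 1] - rts[k])
        return float(ris[k] + slope * (t - rts[k])), bool(t < rts[0] or t > rts[-1])

    return ri_of


def assign_retention_indices(sample_peaks: Sequence[Peak], calib: AlkaneCalibration) -> list[Peak]:
    """Set every peak's RI by linear interpolation between confirmed anchors.

    Peaks outside the anchor RT range take the extended terminal segment and
    are flagged ``ri_extrapolated``.  Returns the same peak objects.
    """
    if len(calib.confirmed_anchors) < 2:
        raise CalibrationError(f"{calib.sample_id}: need at least two confirmed anchors")
    ri_of = _interpolator(calib)
    for peak in sample_peaks:
        peak.ri, peak.ri_extrapolated = ri_of(peak.rt_s)
    return list(sample_peaks)
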