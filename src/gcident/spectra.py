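"""Mass spectra, the scaled cosine similarity score, and the RI-difference penalty.

Spectra are sparse maps from integer m/z bins to non-negative intensities.
Two spectra are compared by the cosine of the angle between their intensity
vectors, scaled to [0, 1000]:

    score(A, B) = 1000 * sum_i(A_i * B_i) / sqrt(sum_i(A_i^2) * sum_i(B_i^2))

where the sum runs over the union of occupied bins (an absent bin contributes
zero).  A match found by the reverse search is additionally penalized for the
retention-index deviation between peak and library entry, via a stepwise
penalty table.

This module also implements the default quantification-mass rule: the five
most intense library-spectrum masses at or above m/z 85, excluding the
trimethylsilyl-derived fragments at m/z 147 and 148, which are not metabolite
specific.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "PenaltyTable",
    "ScoringConfig",
    "DEFAULT_PENALTY_TABLE",
    "QUANT_MIN_MASS",
    "QUANT_EXCLUDED_MASSES",
    "cosine_score",
    "ri_penalty",
    "penalized_score",
    "default_quant_masses",
    "resolve_quant_masses",
]

#: Quantification masses below this m/z are never chosen by the default rule.
QUANT_MIN_MASS = 85
#: TMS-derivatization fragments, excluded from default quantification masses.
QUANT_EXCLUDED_MASSES = frozenset({147, 148})


def bin_mz(mz: float) -> int:
    """Nearest-integer m/z bin: ``floor(mz + 0.5)``."""
    return int(math.floor(mz + 0.5))


class MassSpectrum:
    """A centroided mass spectrum on a unit-m/z grid.

    Parameters
    ----------
    intensities:
        Mapping from integer m/z bin to intensity.  Intensities must be
        non-negative; zero-intensity bins are dropped.
    """

    __slots__ = ("_data", "_norm")

    def __init__(self, intensities: Mapping[int, float] | None = None):
        data: dict[int, float] = {}
        if intensities:
            for mz, inten in intensities.items():
                inten = float(inten)
                if inten < 0:
                    raise ValueError(f"negative intensity {inten} at m/z {mz}")
                if inten > 0:
                    data[int(mz)] = data.get(int(mz), 0.0) + inten
        self._data = data
        self._norm: float | None = None

    @classmethod
    def from_pairs(cls, mzs: Iterable[float], intensities: Iterable[float]) -> "MassSpectrum":
        """Build a spectrum from parallel m/z / intensity sequences.

        Fractional m/z values are binned to the nearest integer; intensities
        falling into the same bin are summed.
        """
        data: dict[int, float] = {}
        for mz, inten in zip(mzs, intensities):
            inten = float(inten)
            if inten < 0:
                raise ValueError(f"negative intensity {inten} at m/z {mz}")
            if inten > 0:
                b = bin_mz(float(mz))
                data[b] = data.get(b, 0.0) + inten
        return cls(data)

    @property
    def intensities(self) -> dict[int, float]:
        return dict(self._data)

    @property
    def is_empty(self) -> bool:
        return not self._data

    @property
    def norm(self) -> float:
        """Euclidean norm of the intensity vector."""
        if self._norm is None:
            self._norm = math.sqrt(sum(v * v for v in self._data.values()))
        return self._norm

    def intensity_at(self, mz: int) -> float:
        return self._data.get(int(mz), 0.0)

    def total_intensity(self) -> float:
        return sum(self._data.values())

    def mzs(self) -> list[int]:
        return sorted(self._data)

    def scaled(self, factor: float) -> "MassSpectrum":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return MassSpectrum({mz: v * factor for mz, v in self._data.items()})

    def __add__(self, other: "MassSpectrum") -> "MassSpectrum":
        data = dict(self._data)
        for mz, v in other._data.items():
            data[mz] = data.get(mz, 0.0) + v
        return MassSpectrum(data)

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        return f"MassSpectrum({len(self._data)} bins, base peak {max(self._data, key=self._data.get) if self._data else None})"

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (m/z, intensity) arrays."""
        mzs = np.array(sorted(self._data), dtype=np.int64)
        return mzs, np.array([self._data[m] for m in mzs], dtype=float)


@dataclass(frozen=True)
class PenaltyTable:
    """Stepwise score penalty as a function of |RI difference|.

    ``bins`` is an ordered list of ``(upper_bound, penalty_percent)``; the
    penalty of a difference *d* is that of the first bin whose upper bound is
    >= *d* (bins are closed at the upper bound, so a difference exactly on a
    boundary takes the milder penalty).  The last bound is +inf.
    """

    bins: tuple[tuple[float, float], ...] = (
        (1.5, 0.0),
        (3.0, 3.0),
        (4.0, 5.0),
        (5.0, 7.0),
        (math.inf, 15.0),
    )

    def __post_init__(self):
        bounds = [b for b, _ in self.bins]
        pens = [p for _, p in self.bins]
        if not bounds or bounds[-1] != math.inf:
            raise ValueError("last penalty bin must have an infinite upper bound")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("penalty bin bounds must be strictly increasing")
        if any(p2 < p1 for p1, p2 in zip(pens, pens[1:])):
            raise ValueError("penalties must be non-decreasing")
        if any(not (0 <= p <= 100) for p in pens):
            raise ValueError("penalties must be percentages in [0, 100]")

    def penalty(self, ri_difference: float) -> float:
        if ri_difference < 0:
            raise ValueError("RI difference must be non-negative")
        for bound, pen in self.bins:
            if ri_difference <= bound:
                return pen
        raise AssertionError("unreachable: last bound is infinite")


DEFAULT_PENALTY_TABLE = PenaltyTable()


@dataclass(frozen=True)
class ScoringConfig:
    """Scoring constants of the reverse search.

    score_scale:
        Cosine similarity is multiplied by this factor (1000).
    score_threshold:
        A candidate is assigned only if its penalized score is strictly
        greater than this threshold (800).
    ri_window:
        Half-width of the retention-index search window around a library
        entry's reference RI (13 RI units, inclusive).
    """

    score_scale: float = 1000.0
    score_threshold: float = 800.0
    ri_window: float = 13.0
    penalty_table: PenaltyTable = field(default_factory=PenaltyTable)

    def __post_init__(self):
        if not (0 < self.score_threshold <= self.score_scale):
            raise ValueError("require 0 < score_threshold <= score_scale")
        if self.ri_window <= 0:
            raise ValueError("ri_window must be positive")


def cosine_score(a: MassSpectrum, b: MassSpectrum, scale: float = 1000.0) -> float:
    """Scaled cosine similarity between two spectra.

    Returns ``scale * <A,B> / (|A| |B|)`` over the union of occupied bins.
    Either spectrum empty (or all-zero) yields 0.
    """
    if a.is_empty or b.is_empty:
        return 0.0
    # iterate the smaller spectrum's bins: only shared bins contribute
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    dot = 0.0
    ldata = large._data
    for mz, v in small._data.items():
        w = ldata.get(mz)
        if w is not None:
            dot += v * w
    # guard against fp excess just above the scale (e.g. self-similarity)
    return min(scale, scale * dot / (a.norm * b.norm))


def ri_penalty(ri_difference: float, table: PenaltyTable = DEFAULT_PENALTY_TABLE) -> float:
    """Penalty percent for an absolute RI difference (stepwise table lookup)."""
    return table.penalty(ri_difference)


def penalized_score(
    raw_score: float,
    ri_difference: float,
    table: PenaltyTable = DEFAULT_PENALTY_TABLE,
) -> float:
    """Apply the RI-deviation penalty: ``raw_score * (1 - penalty/100)``."""
    if not (-1e-9 <= raw_score <= 1000 + 1e-9):
        raise ValueError(f"raw score {raw_score} outside [0, 1000]")
    return raw_score * (1.0 - ri_penalty(ri_difference, table) / 100.0)


def default_quant_masses(entry) -> list[int]:
    """Default quantification masses for a library entry.

    The five most intense masses of the library spectrum, restricted to
    m/z >= 85 and excluding 147/148.  Intensity ties break toward the lower
    m/z.  Fewer than five eligible masses yields all of them with a warning;
    none at all is an error (the entry cannot be quantified).
    """
    spectrum: MassSpectrum = entry.spectrum
    if spectrum.is_empty:
        raise ValueError(f"library entry {entry.raw_name!r} has an empty spectrum")
    eligible = [
        (mz, inten)
        for mz, inten in spectrum.intensities.items()
        if mz >= QUANT_MIN_MASS and mz not in QUANT_EXCLUDED_MASSES
    ]
    if not eligible:
        raise ValueError(
            f"no eligible quantification mass for {entry.raw_name!r}: "
            f"all masses are below {QUANT_MIN_MASS} or in {sorted(QUANT_EXCLUDED_MASSES)}"
        )
    eligible.sort(key=lambda t: (-t[1], t[0]))
    chosen = [mz for mz, _ in eligible[:5]]
    if len(chosen) < 5:
        warnings.warn(
            f"{entry.raw_name}: only {len(chosen)} eligible quantification masses (default rule asks for 5)",
            stacklevel=2,
        )
    return chosen


def resolve_quant_masses(library: Sequence, overrides: Sequence = ()) -> None:
    """Populate ``quant_masses`` on every library entry, in place.

    Entries named in ``overrides`` take the override masses verbatim (user
    choices are not filtered by the >=85 / 147 / 148 rule); every other entry
    gets :func:`default_quant_masses`.
    """
    by_name = {ov.entry_name: list(ov.masses) for ov in overrides}
    for entry in library:
        if entry.raw_name in by_name:
            entry.quant_masses = [int(m) for m in by_name[entry.raw_name]]
        else:
            entry.quant_masses = default_quant_masses(entry)
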