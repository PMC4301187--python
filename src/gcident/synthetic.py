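"""Ground-truthed synthetic GC–MS projects for testing every pipeline stage.

The generator emulates a small targeted metabolomics batch: an alkane wash
run, a set of sample runs carrying the alkane ladder under a per-sample
affine retention-time drift, a handful of planted metabolites at known
nominal retention indices, and decoy peaks whose spectra are rejection-
sampled to stay dissimilar (cosine < 600) to every library entry and to the
alkanes.  Chromatographic peaks are Gaussians on a unit-m/z grid; baselines
are exactly zero, since the pipeline's inputs are defined as
baseline-corrected.  Ion counts optionally carry Poisson counting noise.

Everything the pipeline reads is written out: raw chromatograms in both
ANDI-MS netCDF and mzML, ChromaTOF-layout peak lists, an msp library, a
quantification-mass override file, and a ready-to-run project config.  The
returned :class:`GroundTruth` records the planted retention times, indices,
and the exact (post-discretization, post-noise) quant-mass areas, so tests
can check recovery instead of plausibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import _mzml
from .io_formats import LibraryEntry, write_msp_library
from .reverse_search import Peak
from .spectra import MassSpectrum, cosine_score, default_quant_masses

__all__ = [
    "ProjectSpec",
    "GroundTruth",
    "ProjectPaths",
    "generate_project",
    "generate_library",
    "generate_split_peak",
    "generate_coelution",
    "SplitPeakFixture",
    "CoelutionFixture",
    "write_raw_netcdf",
    "write_raw_mzml",
]

_GAUSS_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHH = 2.3548 sigma

# nominal RIs keep >= 15 RI units from every alkane anchor (multiples of 100)
# and from each other, so synthetic peaks never overlap chromatographically
_METABOLITE_NAMES = (
    "Alanine_(2TMS)_BP_RI:1115_synthDB",
    "Valine_(2TMS)_BP_RI:1220_synthDB",
    "Proline_(2TMS)_BP_RI:1285_synthDB",
    "Succinate_(2TMS)_BP_RI:1340_synthDB",
    "Fumarate_(2TMS)_BP_RI:1455_synthDB",
    "Malate_(3TMS)_BP_RI:1520_synthDB",
    "Phenylalanine_(1TMS)_BP_RI:1665_synthDB",
    "Citrate_(4TMS)_BP_RI:1740_synthDB",
    "Glucose_(5TMS)_MP_RI:1855_synthDB",
)

_ALKANE_BASE_SPECTRUM = {71: 1000.0, 85: 820.0, 99: 600.0, 113: 350.0, 127: 180.0, 141: 90.0}


@dataclass(frozen=True)
class ProjectSpec:
    """Generator parameters; the defaults are the conditions used throughout."""

    n_metabolites: int = 9
    n_samples: int = 9
    n_alkanes: int = 10
    decoys_per_sample: int = 20
    scan_interval_s: float = 0.5
    alkane_rt0_s: float = 60.0
    alkane_spacing_s: float = 60.0
    first_carbon: int = 10
    fwhh_s: float = 2.0
    noise: bool = True
    #: per-sample affine RT drift t -> a*t + b; combined |drift| stays <= 10 s
    drift_slope_range: tuple[float, float] = (0.995, 1.005)
    drift_offset_range_s: tuple[float, float] = (-7.0, 7.0)
    n_override_entries: int = 2
    treatments: tuple[str, ...] = ("baseline", "stress", "control")
    min_peak_separation_s: float = 8.0
    approx_rt_error_s: float = 3.0

    def __post_init__(self):
        if self.n_alkanes < 2:
            raise ValueError("need at least two alkanes")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        if self.alkane_spacing_s <= self.min_peak_separation_s:
            raise ValueError("alkane spacing must exceed the minimum peak separation (alkanes would overlap)")

    @property
    def carbon_numbers(self) -> tuple[int, ...]:
        return tuple(range(self.first_carbon, self.first_carbon + self.n_alkanes))

    @property
    def wash_alkane_rts_s(self) -> tuple[float, ...]:
        return tuple(self.alkane_rt0_s + self.alkane_spacing_s * i for i in range(self.n_alkanes))

    @property
    def run_length_s(self) -> float:
        return self.wash_alkane_rts_s[-1] + self.alkane_spacing_s

    def rt_of_ri_wash(self, ri: float) -> float:
        """Wash retention time of a nominal RI (the ladder is uniform in RT)."""
        return self.alkane_rt0_s + self.alkane_spacing_s * (ri / 100.0 - self.first_carbon)


@dataclass
class PlantedPeak:
    """Truth for one planted metabolite in one sample."""

    entry_name: str
    sample_id: str
    nominal_ri: float
    rt_s: float
    integ_begin_s: float
    integ_end_s: float
    quant_area: float = 0.0  # filled after raw discretization
    per_mass_area: dict[int, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    seed: int
    spec: ProjectSpec
    sample_ids: list[str]
    treatments: dict[str, str]
    drift: dict[str, tuple[float, float]]  # sample -> (slope, offset)
    alkane_rts: dict[str, list[float]]  # sample -> drifted alkane RTs
    planted: list[PlantedPeak]
    decoy_rts: dict[str, list[float]]
    quant_masses: dict[str, list[int]]
    override_entries: list[str]

    def planted_for(self, sample_id: str) -> list[PlantedPeak]:
        return [p for p in self.planted if p.sample_id == sample_id]


@dataclass
class ProjectPaths:
    root: Path
    config: Path
    library: Path
    quant_mass_file: Path
    wash_raw: Path
    wash_peaklist: Path
    sample_raw: dict[str, Path]
    sample_raw_mzml: dict[str, Path]
    sample_peaklist: dict[str, Path]


# ---------------------------------------------------------------------------
# spectra


def _random_metabolite_spectrum(rng: np.random.Generator) -> MassSpectrum:
    """A synthetic EI spectrum: ~18 fragments, several quantifiable ones.

    Includes the ubiquitous TMS fragment at m/z 73 and guarantees at least
    eight eligible quantification masses (>= 85, not 147/148).
    """
    low = rng.choice(np.arange(70, 85), size=4, replace=False)
    eligible_pool = np.array([m for m in range(85, 451) if m not in (147, 148)])
    high = rng.choice(eligible_pool, size=12, replace=False)
    data: dict[int, float] = {73: float(rng.uniform(400, 999))}
    for m in low:
        data[int(m)] = float(rng.uniform(20, 400))
    intens = np.sort(rng.uniform(30, 999, size=12))[::-1]
    for m, i in zip(high, intens):
        data[int(m)] = float(i)
    return MassSpectrum(data)


def _alkane_spectrum(carbon: int) -> MassSpectrum:
    data = dict(_ALKANE_BASE_SPECTRUM)
    mol = 142 + 14 * (carbon - 10)
    if 70 <= mol <= 600:
        data[mol] = data.get(mol, 0.0) + 120.0
    return MassSpectrum(data)


def _random_decoy_spectrum(
    rng: np.random.Generator, avoid: Sequence[MassSpectrum], max_cosine: float = 600.0
) -> MassSpectrum:
    """Rejection-sample a spectrum scoring below ``max_cosine`` vs every target."""
    for _ in range(500):
        masses = rng.choice(np.arange(70, 451), size=int(rng.integers(10, 18)), replace=False)
        cand = MassSpectrum({int(m): float(v) for m, v in zip(masses, rng.uniform(20, 999, size=len(masses)))})
        if all(cosine_score(cand, s) < max_cosine for s in avoid):
            return cand
    raise RuntimeError("could not sample a decoy spectrum dissimilar to the library")


def generate_library(seed: int, n_entries: int = 9) -> list[LibraryEntry]:
    """A deterministic synthetic msp-style library with structured names."""
    if n_entries > len(_METABOLITE_NAMES):
        raise ValueError(f"at most {len(_METABOLITE_NAMES)} synthetic library entries are available")
    rng = np.random.default_rng(seed)
    entries = []
    from .io_formats import parse_entry_name

    for name in _METABOLITE_NAMES[:n_entries]:
        metabolite, deriv, product, ri, source = parse_entry_name(name)
        entries.append(
            LibraryEntry(
                raw_name=name,
                metabolite=metabolite,
                derivatization=deriv,
                product=product,
                reference_ri=ri,
                source_db=source,
                spectrum=_random_metabolite_spectrum(rng),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# raw data assembly


class _SparseRun:
    """Accumulates Gaussian peak contributions on a scan × m/z grid."""

    def __init__(self, scan_times_s: np.ndarray):
        self.times = scan_times_s
        self.data: list[dict[int, float]] = [dict() for _ in scan_times_s]

    def add_peak(self, rt_s: float, spectrum: MassSpectrum, amount: float, fwhh_s: float):
        """Add one peak; ``amount`` scales the base-peak apex height."""
        sigma = fwhh_s / _GAUSS_TO_SIGMA
        base = max(spectrum.intensities.values())
        lo = np.searchsorted(self.times, rt_s - 4 * sigma)
        hi = np.searchsorted(self.times, rt_s + 4 * sigma, side="right")
        for ix in range(lo, hi):
            g = math.exp(-((self.times[ix] - rt_s) ** 2) / (2 * sigma**2))
            row = self.data[ix]
            for mz, inten in spectrum.intensities.items():
                row[mz] = row.get(mz, 0.0) + amount * (inten / base) * g

    def apply_noise(self, rng: np.random.Generator):
        for row in self.data:
            for mz in list(row):
                row[mz] = float(rng.poisson(row[mz]))
                if row[mz] == 0.0:
                    del row[mz]

    def arrays(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for row in self.data:
            mzs = np.array(sorted(row), dtype=float)
            out.append((mzs, np.array([row[int(m)] for m in mzs], dtype=float)))
        return out

    def area(self, begin_s: float, end_s: float, masses: Sequence[int]) -> dict[int, float]:
        """Per-mass sums over scans with begin_s <= t <= end_s (the pipeline's rule)."""
        start = int(np.searchsorted(self.times, begin_s, side="left"))
        end = int(np.searchsorted(self.times, end_s, side="right")) - 1
        return {
            int(m): float(sum(self.data[ix].get(int(m), 0.0) for ix in range(start, end + 1)))
            for m in masses
        }


def write_raw_netcdf(path, scan_times_s: Sequence[float], scans: Sequence[tuple[np.ndarray, np.ndarray]]):
    """Write scans as an ANDI-MS style netCDF (classic NetCDF3) file."""
    from scipy.io import netcdf_file

    counts = np.array([len(m) for m, _ in scans], dtype="i4")
    index = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype("i4") if len(counts) else np.empty(0, "i4")
    masses = np.concatenate([m for m, _ in scans]) if len(scans) else np.empty(0)
    intens = np.concatenate([i for _, i in scans]) if len(scans) else np.empty(0)
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", len(scans))
        nc.createDimension("point_number", max(len(masses), 1))
        if len(masses) == 0:
            masses = np.zeros(1)
            intens = np.zeros(1)
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = np.asarray(scan_times_s, dtype=float)
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = index
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = counts
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = masses
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = intens


def write_raw_mzml(path, scan_times_s: Sequence[float], scans: Sequence[tuple[np.ndarray, np.ndarray]]):
    """Write the same content as uncompressed 64-bit mzML."""
    _mzml.write_mzml(path, scan_times_s, scans)


# ---------------------------------------------------------------------------
# peak lists


_PEAKLIST_HEADER = (
    "Name,Retention Index,Area,UniqueMass,Quant Masses,R.T. (s),S/N,"
    "Integration Begin,Integration End,Full Width at Half Height"
)


def _peaklist_row(
    name: str,
    ri: float | None,
    area: float,
    unique_mass: int,
    quant_masses: Sequence[int],
    rt: float,
    snr: float,
    begin: float,
    end: float,
    fwhh: float,
) -> str:
    ri_cell = "" if ri is None else f"{ri:.1f}"
    qm = ";".join(str(m) for m in quant_masses)
    return f'"{name}",{ri_cell},{area!r},{unique_mass},{qm},{rt!r},{snr:.1f},{begin!r},{end!r},{fwhh!r}'


# ---------------------------------------------------------------------------
# project generation


def generate_project(
    out_dir, seed: int, spec: ProjectSpec | None = None
) -> tuple[ProjectPaths, GroundTruth]:
    """Write a complete synthetic project and return its paths and truth.

    Deterministic for a given (seed, spec): running twice produces
    byte-identical files.
    """
    spec = spec or ProjectSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    library = generate_library(int(rng.integers(2**31)), spec.n_metabolites)
    ri_span = (100.0 * spec.carbon_numbers[0], 100.0 * spec.carbon_numbers[-1])
    for entry in library:
        if not (ri_span[0] + 20 <= entry.reference_ri <= ri_span[1] - 20):
            raise ValueError(
                f"entry {entry.raw_name}: reference RI {entry.reference_ri} falls outside the "
                f"alkane ladder {ri_span}; extend the ladder"
            )
    alkane_spectra = {c: _alkane_spectrum(c) for c in spec.carbon_numbers}

    # quantification masses: a few explicit overrides, defaults elsewhere
    override_entries = [e.raw_name for e in library[: spec.n_override_entries]]
    quant_masses: dict[str, list[int]] = {}
    for entry in library:
        defaults = default_quant_masses(entry)
        if entry.raw_name in override_entries:
            quant_masses[entry.raw_name] = sorted(defaults[:3])  # an explicit user choice
        else:
            quant_masses[entry.raw_name] = defaults

    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    treatments = {
        s: spec.treatments[i * len(spec.treatments) // spec.n_samples]
        for i, s in enumerate(sample_ids)
    }
    fold = {
        (e.raw_name, t): (1.0 if t == spec.treatments[0] else float(rng.uniform(0.5, 2.0)))
        for e in library
        for t in spec.treatments
    }
    base_amount = {e.raw_name: float(rng.uniform(2e4, 2e5)) for e in library}

    n_scans = int(round(spec.run_length_s / spec.scan_interval_s)) + 1
    scan_times = np.arange(n_scans) * spec.scan_interval_s

    decoy_spectra_targets = [e.spectrum for e in library] + list(alkane_spectra.values())

    truth = GroundTruth(
        seed=seed,
        spec=spec,
        sample_ids=sample_ids,
        treatments=treatments,
        drift={},
        alkane_rts={},
        planted=[],
        decoy_rts={},
        quant_masses=quant_masses,
        override_entries=override_entries,
    )

    # --- wash run (alkanes only, no drift)
    wash_run = _SparseRun(scan_times)
    wash_rows = []
    half_width = 3.0 * spec.fwhh_s / _GAUSS_TO_SIGMA
    for carbon, rt in zip(spec.carbon_numbers, spec.wash_alkane_rts_s):
        amount = float(rng.uniform(5e4, 1e5))
        wash_run.add_peak(rt, alkane_spectra[carbon], amount, spec.fwhh_s)
        area = sum(wash_run.area(rt - half_width, rt + half_width, alkane_spectra[carbon].mzs()).values())
        wash_rows.append(
            _peaklist_row(
                f"C{carbon}", 100.0 * carbon, area, 71, (71, 85, 99), rt, 500.0,
                rt - half_width, rt + half_width, spec.fwhh_s,
            )
        )
    if spec.noise:
        wash_run.apply_noise(np.random.default_rng(int(rng.integers(2**31))))

    wash_raw = out_dir / "wash.cdf"
    write_raw_netcdf(wash_raw, scan_times, wash_run.arrays())
    write_raw_mzml(out_dir / "wash.mzml", scan_times, wash_run.arrays())
    wash_peaklist = out_dir / "wash_peaklist.csv"
    wash_peaklist.write_text(_PEAKLIST_HEADER + "\n" + "\n".join(wash_rows) + "\n", encoding="utf-8")

    # --- sample runs
    sample_raw: dict[str, Path] = {}
    sample_raw_mzml: dict[str, Path] = {}
    sample_peaklist: dict[str, Path] = {}
    for sample_id in sample_ids:
        slope = float(rng.uniform(*spec.drift_slope_range))
        offset = float(rng.uniform(*spec.drift_offset_range_s))
        truth.drift[sample_id] = (slope, offset)
        drift = lambda t: slope * t + offset  # noqa: E731

        run = _SparseRun(scan_times)
        placed_rts: list[float] = []
        rows: list[tuple[float, str]] = []

        alk_rts = []
        for carbon, rt_wash in zip(spec.carbon_numbers, spec.wash_alkane_rts_s):
            rt = drift(rt_wash)
            alk_rts.append(rt)
            placed_rts.append(rt)
            amount = float(rng.uniform(5e4, 1e5))
            run.add_peak(rt, alkane_spectra[carbon], amount, spec.fwhh_s)
            rows.append(
                (
                    rt,
                    _peaklist_row(
                        f"alkane-C{carbon}", None, 0.0, 71, (), rt, 500.0,
                        rt - half_width, rt + half_width, spec.fwhh_s,
                    ),
                )
            )
        truth.alkane_rts[sample_id] = alk_rts

        planted_here: list[PlantedPeak] = []
        for entry in library:
            rt = drift(spec.rt_of_ri_wash(entry.reference_ri))
            placed_rts.append(rt)
            amount = base_amount[entry.raw_name] * fold[(entry.raw_name, treatments[sample_id])]
            amount *= float(rng.uniform(0.9, 1.1))  # biological scatter
            run.add_peak(rt, entry.spectrum, amount, spec.fwhh_s)
            planted_here.append(
                PlantedPeak(
                    entry_name=entry.raw_name,
                    sample_id=sample_id,
                    nominal_ri=entry.reference_ri,
                    rt_s=rt,
                    integ_begin_s=rt - half_width,
                    integ_end_s=rt + half_width,
                )
            )

        decoys = []
        lo_rt = spec.alkane_rt0_s - 20.0
        hi_rt = spec.run_length_s - 10.0
        for _ in range(spec.decoys_per_sample):
            for _attempt in range(200):
                rt = float(rng.uniform(lo_rt, hi_rt))
                if all(abs(rt - other) >= spec.min_peak_separation_s for other in placed_rts):
                    break
            else:
                raise RuntimeError("could not place a decoy peak without overlap; lower decoys_per_sample")
            spectrum = _random_decoy_spectrum(rng, decoy_spectra_targets)
            amount = float(rng.uniform(1e4, 1e5))
            run.add_peak(rt, spectrum, amount, spec.fwhh_s)
            placed_rts.append(rt)
            decoys.append((rt, spectrum))
        truth.decoy_rts[sample_id] = sorted(rt for rt, _ in decoys)

        if spec.noise:
            run.apply_noise(np.random.default_rng(int(rng.integers(2**31))))

        # areas measured from the final (discretized, noisy) run, so the
        # peak-list Area agrees exactly with what quantification will see
        for planted in planted_here:
            entry_masses = quant_masses[planted.entry_name]
            planted.per_mass_area = run.area(planted.integ_begin_s, planted.integ_end_s, entry_masses)
            planted.quant_area = float(sum(planted.per_mass_area.values()))
            rows.append(
                (
                    planted.rt_s,
                    _peaklist_row(
                        "Analyte", planted.nominal_ri, planted.quant_area,
                        entry_masses[0], entry_masses, planted.rt_s, 100.0,
                        planted.integ_begin_s, planted.integ_end_s, spec.fwhh_s,
                    ),
                )
            )
            truth.planted.append(planted)
        for rt, spectrum in decoys:
            area = sum(run.area(rt - half_width, rt + half_width, spectrum.mzs()).values())
            rows.append(
                (
                    rt,
                    _peaklist_row(
                        "Unknown", None, area, spectrum.mzs()[0], (), rt, 60.0,
                        rt - half_width, rt + half_width, spec.fwhh_s,
                    ),
                )
            )

        rows.sort(key=lambda t: t[0])
        raw_path = out_dir / f"{sample_id}.cdf"
        write_raw_netcdf(raw_path, scan_times, run.arrays())
        mzml_path = out_dir / f"{sample_id}.mzml"
        write_raw_mzml(mzml_path, scan_times, run.arrays())
        pl_path = out_dir / f"{sample_id}_peaklist.csv"
        pl_path.write_text(_PEAKLIST_HEADER + "\n" + "\n".join(r for _, r in rows) + "\n", encoding="utf-8")
        sample_raw[sample_id] = raw_path
        sample_raw_mzml[sample_id] = mzml_path
        sample_peaklist[sample_id] = pl_path

    # --- library, quant-mass file, project config
    library_path = write_msp_library(library, out_dir / "library.msp")
    quant_path = out_dir / "quant_masses.tsv"
    with open(quant_path, "w", encoding="utf-8") as fh:
        for name in override_entries:
            fh.write(f"{name}\t{';'.join(str(m) for m in quant_masses[name])}\n")

    approx_rts = [
        rt + float(e) for rt, e in zip(
            spec.wash_alkane_rts_s,
            np.random.default_rng(int(rng.integers(2**31))).uniform(
                -spec.approx_rt_error_s, spec.approx_rt_error_s, size=spec.n_alkanes
            ),
        )
    ]
    config = {
        "library": "library.msp",
        "quant_mass_file": "quant_masses.tsv",
        "wash": {"raw": "wash.cdf", "peaklist": "wash_peaklist.csv"},
        "samples": [
            {
                "id": s,
                "raw": f"{s}.cdf",
                "peaklist": f"{s}_peaklist.csv",
                "treatment": treatments[s],
            }
            for s in sample_ids
        ],
        "alkanes": {
            "carbon_numbers": list(spec.carbon_numbers),
            "approx_wash_rts_s": [round(t, 3) for t in approx_rts],
            "diagnostic_masses": [71, 85, 99],
            "sample_search_window_s": 15.0,
        },
        "scoring": {"score_scale": 1000.0, "score_threshold": 800.0, "ri_window": 13.0},
        "output_dir": "output",
        "auto_accept_threshold": 800.0,
    }
    config_path = out_dir / "project.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False), encoding="utf-8")

    paths = ProjectPaths(
        root=out_dir,
        config=config_path,
        library=library_path,
        quant_mass_file=quant_path,
        wash_raw=wash_raw,
        wash_peaklist=wash_peaklist,
        sample_raw=sample_raw,
        sample_raw_mzml=sample_raw_mzml,
        sample_peaklist=sample_peaklist,
    )
    return paths, truth


# ---------------------------------------------------------------------------
# curation fixtures


@dataclass
class SplitPeakFixture:
    """A planted peak whose masses were split into two peak-list rows."""

    entry: LibraryEntry
    left: Peak
    right: Peak
    sample_peaks: list[Peak]


def generate_split_peak(seed: int) -> SplitPeakFixture:
    """Emulate a deconvolution split: one peak's masses reported as two peaks.

    The entry's spectrum is built with near-uniform squared intensities so a
    balanced bisection leaves each half scoring well below the assignment
    threshold against the full library spectrum, while their per-bin sum
    restores it exactly.
    """
    rng = np.random.default_rng(seed)
    masses = rng.choice(np.arange(85, 400), size=16, replace=False)
    intens = rng.uniform(600, 999, size=16)
    spectrum = MassSpectrum({int(m): float(v) for m, v in zip(masses, intens)})
    entry = LibraryEntry(
        raw_name="SplitCase_(2TMS)_BP_RI:1400_synthDB",
        metabolite="SplitCase",
        derivatization="(2TMS)",
        product="BP",
        reference_ri=1400.0,
        source_db="synthDB",
        spectrum=spectrum,
    )
    # greedy balance on squared intensity -> both halves near 50% of |S|^2
    items = sorted(spectrum.intensities.items(), key=lambda t: -t[1])
    half_a: dict[int, float] = {}
    half_b: dict[int, float] = {}
    sq_a = sq_b = 0.0
    for mz, inten in items:
        if sq_a <= sq_b:
            half_a[mz] = inten
            sq_a += inten * inten
        else:
            half_b[mz] = inten
            sq_b += inten * inten
    rt = 500.0
    left = Peak(
        sample_id="split", rt_s=rt - 0.8, apex_spectrum=MassSpectrum(half_a),
        integ_begin_s=rt - 4.0, integ_end_s=rt - 0.2, ri=1400.0 - 0.5,
        start_scan=100, end_scan=104,
    )
    right = Peak(
        sample_id="split", rt_s=rt + 0.8, apex_spectrum=MassSpectrum(half_b),
        integ_begin_s=rt - 0.2, integ_end_s=rt + 4.0, ri=1400.0 + 0.5,
        start_scan=104, end_scan=108,
    )
    return SplitPeakFixture(entry=entry, left=left, right=right, sample_peaks=[left, right])


@dataclass
class CoelutionFixture:
    """Two metabolites under one peak, quantifiable on disjoint mass sets."""

    entry_a: LibraryEntry
    entry_b: LibraryEntry
    peak: Peak
    raw: "object"
    truth_per_mass: dict[str, dict[int, float]]  # entry name -> mass -> area
    shared_quant_mass: bool


def generate_coelution(seed: int, shared_quant_mass: bool = False) -> CoelutionFixture:
    """One peak carrying the summed spectra of two co-eluting metabolites.

    The two entries' spectral supports above m/z 85 are disjoint (they share
    only the unquantified TMS fragment at 73), so duplicating the peak and
    quantifying each entry on its own masses partitions the planted ion
    counts exactly.  With ``shared_quant_mass`` the entries are made to share
    one quantification mass, for testing the validity warning.
    """
    from .io_formats import RawChromatogram

    rng = np.random.default_rng(seed)
    pool = [m for m in range(85, 300) if m not in (147, 148)]
    picks = rng.choice(np.array(pool), size=12, replace=False)
    masses_a, masses_b = [int(m) for m in picks[:6]], [int(m) for m in picks[6:]]
    spec_a = MassSpectrum({**{m: float(rng.uniform(200, 999)) for m in masses_a}, 73: 500.0})
    spec_b = MassSpectrum({**{m: float(rng.uniform(200, 999)) for m in masses_b}, 73: 500.0})
    if shared_quant_mass:
        # make one mass dominate both spectra so it enters both top-5 sets
        shared = masses_a[0]
        spec_a = spec_a + MassSpectrum({shared: 1500.0})
        spec_b = spec_b + MassSpectrum({shared: 1500.0})

    def mk(name, ri, spectrum):
        e = LibraryEntry(
            raw_name=name, metabolite=name.split("_")[0], derivatization="(2TMS)",
            product="BP", reference_ri=ri, source_db="synthDB", spectrum=spectrum,
        )
        e.quant_masses = default_quant_masses(e)
        return e

    entry_a = mk("CoeluterA_(2TMS)_BP_RI:1500_synthDB", 1500.0, spec_a)
    entry_b = mk("CoeluterB_(2TMS)_BP_RI:1502_synthDB", 1502.0, spec_b)

    rt, fwhh = 100.0, 2.0
    times = np.arange(80.0, 120.0, 0.5)
    run = _SparseRun(times)
    amount_a, amount_b = 5e4, 8e4
    run.add_peak(rt, spec_a, amount_a, fwhh)
    run.add_peak(rt, spec_b, amount_b, fwhh)
    begin, end = rt - 4.0, rt + 4.0
    truth = {
        entry_a.raw_name: run.area(begin, end, entry_a.quant_masses),
        entry_b.raw_name: run.area(begin, end, entry_b.quant_masses),
    }
    scans = [MassSpectrum.from_pairs(m, i) for m, i in run.arrays()]
    raw = RawChromatogram(sample_id="coelution", scan_times_s=times, scans=scans)
    peak = Peak(
        sample_id="coelution", rt_s=rt, apex_spectrum=scans[raw.nearest_scan(rt)],
        integ_begin_s=begin, integ_end_s=end, ri=1501.0,
        start_scan=raw.scan_range(begin, end)[0], end_scan=raw.scan_range(begin, end)[1],
    )
    return CoelutionFixture(
        entry_a=entry_a, entry_b=entry_b, peak=peak, raw=raw,
        truth_per_mass=truth, shared_quant_mass=shared_quant_mass,
    )
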