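# Methods

This note documents the models, defaults, and design choices behind
`gcident`, and what the synthetic-data tests do and do not demonstrate.

## Scope and data model

The pipeline starts *after* vendor preprocessing: inputs are baseline-
corrected raw chromatograms (ANDI-MS netCDF or mzML, centroided and binned
to unit m/z, nominal range 70–600), one peak list per sample in the
ChromaTOF CSV export layout (ten required columns: Name, Retention Index,
Area, UniqueMass, Quant Masses, R.T. (s), S/N, Integration Begin,
Integration End, Full Width at Half Height), an msp spectral library, and an
optional quantification-mass override TSV. Baseline correction, smoothing,
and peak detection are upstream concerns and out of scope, as are vendor
binary formats and writing raw formats (the synthetic generator has its own
writers for fixture purposes).

Library entry names carry five underscore-separated elements —
`Metabolite_(Derivatization)_Product_RI:<value>_Database` — and must be
unique; the embedded value is the entry's reference retention index.

A peak's identity is re-derived by the search; the peak list's own Name and
Quant Masses columns are parsed and retained as provenance but not consumed.

## Scoring

The cosine score is computed over the union of occupied integer m/z bins and
scaled by 1000; this is numerically identical to a dense 70–600 vector
comparison and faster. The score is clamped at 1000 to absorb floating-point
excess in self-comparisons.

The RI-deviation penalty is a step function of |ΔRI|. The printed bin labels
leave the exact boundary values open; bins here are closed at the upper
bound (d ≤ 1.5 → 0 %, ≤ 3 → 3 %, ≤ 4 → 5 %, ≤ 5 → 7 %, > 5 → 15 %), which
favors the milder penalty at a boundary. The table is configurable
(`scoring.penalty_bins` in the project config) for anyone wanting the other
convention.

Assignment requires the penalized score to be *strictly* greater than the
threshold (default 800 on the 0–1000 scale); the RI window comparison is
inclusive (a peak at exactly 13.0 RI units is a candidate).

## Retention-index calibration

Wash alkane detection ranks peaks by their summed apex intensity over the
diagnostic masses (default 71/85/99), keeps one candidate slot per
configured alkane, and matches each alkane to the candidate nearest its
approximate retention time. Two alkanes claiming one peak is an error rather
than a silent reassignment. A candidate farther than `wash_match_tolerance_s`
(default 30 s — roughly twice the per-sample search window; the matching
step needs *some* sanity bound and the original procedure does not quantify
one) from the stated approximate RT raises a missing-alkane error.

The per-sample targeted search scores every peak within ±15 s of the wash RT
by cosine against the wash spectrum; ties break by smaller |ΔRT|, then
earlier RT, for determinism. Anchors without an in-window candidate, or
breaking RT monotonicity, are left unconfirmed and excluded from
interpolation (fail soft, warn loudly); fewer than two confirmed anchors is
a calibration failure.

Interpolation is linear in retention *time* per anchor segment — the
temperature-programmed (van den Dool & Kratz) form rather than the
isothermal logarithmic Kovats form, since the method targets
temperature-programmed GC. Outside the anchor range the terminal segment's
line is extended and the peak flagged `ri_extrapolated` rather than dropped.

## Reverse search

Per entry and sample, candidates are unlocked peaks inside the RI window;
each is scored `penalized(cosine)`; the best above-threshold candidate wins.
Candidate ties break by smaller ΔRI, then earlier RT. Cross-entry conflicts
(two entries winning the same peak — possible since windows may overlap) are
resolved greedily by descending penalized score: the higher score keeps the
peak, the loser falls back to its next-best above-threshold candidate. The
greedy order makes the fixpoint deterministic and preserves the
one-identity-per-peak data model. The search is verified in tests against a
brute-force oracle that scores every entry × peak pair without windowing and
applies window, threshold, and argmax afterwards.

## Curation semantics

- **fuse**: mean RI, min/max of scan bounds and integration times, per-bin
  *sum* of the apex spectra. Only the RI and scan-bound updates are forced
  by the peak model; summing the spectra is this package's choice — it is
  the inverse of the deconvolution-split failure mode the operation exists
  to repair. The fused RT is the midpoint, consistent with the mean RI under
  piecewise-linear RI(t).
- **duplicate**: copies keep coordinates and spectrum, start unassigned; a
  warning names any quantification masses shared between the original's and
  the copy's intended entries (shared masses make the two quantifications
  non-independent).
- **set_found / set_all_found**: manual overrides bypass the threshold; the
  recorded score is the unpenalized cosine. The batch form picks the best
  in-window peak by plain cosine with no threshold (its purpose is exactly
  the case where the search failed on peak quality; no selection rule is
  prescribed, so best-cosine is the natural one).
- **accept_peak** re-scores without the RI penalty; **accept_group** locks
  every member peak; any mutating operation on a locked peak or group raises
  `LockError`. Only locked groups are quantified and exported.
- Every operation can append to a JSON-lines edit log; `apply_edit_script`
  replays such a log deterministically, which substitutes for interactive
  undo and makes curation reviewable.

## Quantification and export

Integration bounds map to scans as: first scan at or after Integration
Begin, last scan at or before Integration End (inclusive, 0-based). Per
quantification mass, intensities are summed over that scan range from the
raw data; the total area is the grand sum over masses (a single number per
cell rather than per-mass columns; per-mass values are exported separately
in `areasByMass.csv`). Default quantification masses are the five most
intense library masses ≥ 85 excluding 147/148 (TMS-derived, not metabolite
specific); ties break toward lower m/z; fewer than five eligible masses
yields all of them with a warning, none is an error. Override-file masses
are taken verbatim — explicit user choices are not second-guessed by the
≥ 85 filter.

Missing assignments export as empty cells, distinguishable from a true zero.
Normalization to an internal standard is deliberately not applied — the
standard is just another library entry, and normalization happens downstream
of export.

## The synthetic generator

The generator emulates a small batch: 9 metabolites × 9 samples ×
10 alkanes (C10–C19, 60 s apart from 60 s), 20 decoy peaks per sample,
scan interval 0.5 s, Gaussian peaks with FWHH 2 s, zero baseline, Poisson
counting noise, and per-sample affine RT drift t → a·t + b with
a ∈ [0.995, 1.005] and b ∈ [−7, 7] s (combined drift within ±10 s, inside
the ±15 s alkane search window). These sizes mirror a small validation batch
(three treatment groups of three samples, a nine-metabolite target library)
while keeping a full run generating and processing in seconds. Planted
metabolite RTs are derived from their nominal RIs through the drifted
ladder, so calibration recovers the nominal RI exactly by construction —
recovery tests check machine-precision agreement against a 1-RI-unit bound.
Decoy spectra are rejection-sampled to score below 600 against every library
entry and alkane spectrum, which makes search outcomes attributable: any
decoy assignment is a bug, not bad luck.

Peak-list Area values are measured from the final (discretized, noisy) raw
arrays over the integration bounds and the entry's quantification masses, so
`rawAreaMatrix` and `AreaMatrix` agree exactly on synthetic projects — a
self-consistency property, deliberately so: it isolates the quantification
path from the generator.

What the fixtures do *not* emulate: realistic EI fragmentation (spectra are
random), chromatographic tailing, mass-accuracy drift, co-elution beyond
the dedicated fixture, detector saturation, and baseline residue. Passing
tests therefore demonstrate the correctness of the computational pipeline,
not identification performance on real chromatograms.

## Numerical and interface choices

- m/z binning: nearest integer, `floor(mz + 0.5)`; masses outside [70, 600]
  are retained with a warning rather than dropped.
- Peak-list delimiter is sniffed from the header line (comma/tab/semicolon);
  quoted fields are honored; the ten required columns may appear in any
  order. msp files are read as UTF-8 with Latin-1 fallback.
- mzML support covers centroided MS1 spectra with 32/64-bit float arrays,
  uncompressed or zlib; scan start times are normalized to seconds. netCDF
  and mzML encodings of the same run parse to identical chromatograms.
- The CLI exposes `make-fixtures` and `run` (import → calibrate → search →
  optional edit script → auto-accept → quantify → export). The intermediate
  stages are library functions; they are not separate subcommands because
  the package deliberately has no on-disk project database — a run is cheap
  and deterministic, and re-running beats state management. The headless
  auto-accept policy locks every group whose assignments all reach an
  unpenalized cosine of ≥ 800 (mirroring the search threshold) and with at
  least one assignment; anything else stays unlocked for scripted curation.

## Known limitations

- Only two raw formats, read-only; no vendor binaries.
- Calibration is piecewise linear; no spline/nonlinear RT warping, no
  FAME-based ladders.
- One spectrum per peak (the apex scan); the search does not re-integrate
  or deconvolve.
- Conflict resolution among entries is greedy; a global optimal matching
  (e.g. Hungarian) could differ in contrived ties but not above-threshold
  clear cases.
- The quantification trusts the peak caller's integration bounds; no curve
  fitting or bound refinement.
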