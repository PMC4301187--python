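# gcident

Targeted identification and quantification of metabolites in GC–MS
metabolomics batches: retention-index calibration from an n-alkane wash run,
a reverse spectral-library search scored by RI-penalized cosine similarity,
scriptable peak curation, quantification-mass peak integration, and export of
the final metabolite × sample data matrices.

## Who this is for

GC–MS (typically GC–TOF–MS with electron ionization and TMS derivatization)
produces, after vendor-side preprocessing, a peak list and a baseline-
corrected raw chromatogram per sample. Turning those into a validated data
matrix — which peak in each sample is which metabolite, and how much of it is
there — is the labor-intensive step. `gcident` implements that step as a
headless, reproducible library + CLI: given peak lists (ChromaTOF CSV
layout), raw data (ANDI-MS netCDF or mzML), and an msp spectral library with
reference retention indices, it produces putative identifications, curation
hooks, and quantified matrices.

## The method

**Retention-index calibration.** A wash run containing only the n-alkane
mixture anchors the RI scale (the alkane with *n* carbons defines
RI = 100·n). Alkane peaks are found in the wash by their diagnostic EI
fragments (m/z 71, 85, 99) and matched to user-supplied approximate retention
times. Each sample is then searched for every alkane within ±15 s of its wash
retention time by spectral similarity, and peak RIs follow by piecewise
linear interpolation in retention time between bracketing anchors
(van den Dool & Kratz):

    RI(t) = 100·c_k + 100·(c_{k+1} − c_k) · (t − t_k) / (t_{k+1} − t_k)

**Spectral similarity.** Two spectra *A*, *B* (unit-m/z binned intensity
vectors) are compared by the cosine score, scaled to [0, 1000]:

    score(A, B) = 1000 · Σᵢ AᵢBᵢ / √(ΣᵢAᵢ² · ΣᵢBᵢ²)

**Reverse search.** Instead of looking every peak up in the library (forward
search, which can hand one metabolite name to several peaks), the search runs
per library entry: all sample peaks within ±13 RI units of the entry's
reference RI are scored, the score is reduced by a stepwise penalty for the
RI deviation (0 / 3 / 5 / 7 / 15 % for |ΔRI| ≤ 1.5 / ≤ 3 / ≤ 4 / ≤ 5 / > 5),
and the best candidate is putatively assigned only if its penalized score
exceeds 800 — so each entry gets at most one peak per sample.

**Curation.** The interactive validation step is reproduced as scriptable
operations: `fuse` (repair deconvolution splits; mean RI, union scan range,
summed spectra), `duplicate` (co-eluting metabolites; valid only for disjoint
quantification masses), `set_found` / `set_not_found` (manual overrides,
bypassing the threshold), `accept_peak` (re-score without the RI penalty),
and `accept_group` / `enable_edit` (lock a validated group for export). All
edits land in a replayable JSON-lines log.

**Quantification.** Each entry is quantified on its quantification masses —
user-specified via a TSV override file, or by default the five most intense
library-spectrum masses at or above m/z 85 excluding the TMS fragments
147/148. Per mass, intensities are summed over all raw scans between the
peak's integration bounds; the per-mass sums add up to the peak area. Export
writes `rawAreaMatrix.csv` (the peak caller's own Area values) and
`AreaMatrix.csv` (the quant-mass areas computed here) with identical shape,
plus per-mass areas in `areasByMass.csv`.

## Worked example

The package ships a ground-truthed synthetic project generator (Gaussian
peaks on a unit-m/z grid, per-sample affine RT drift, decoy peaks kept
dissimilar to the library by construction):

```
$ gcident make-fixtures --out demo --seed 11 --samples 3 --metabolites 4 --decoys 10
wrote project for 3 samples under demo (config: demo/project.yaml)
$ gcident run demo/project.yaml --out demo_out
exported 12 quantifications for 4 locked groups -> demo_out/AreaMatrix.csv
$ head -4 demo_out/AreaMatrix.csv
Metabolite,S01,S02,S03
Treatment,baseline,stress,control
Alanine_(2TMS)_BP_RI:1115_synthDB,1508150.0,1947048.0,2295551.0
Valine_(2TMS)_BP_RI:1220_synthDB,1066371.0,599305.0,722501.0
```

All 4 library entries were found in all 3 samples (12 quantifications), every
group passed the auto-accept threshold, and each matrix cell is the summed
quant-mass ion count of that metabolite's peak in that sample. The run report
(`demo_out/report.json`) lists the per-sample alkane anchor table and
per-entry assignment counts; `demo_out/editLog.jsonl` records the accept
operations.

The same pieces are available as a library:

```python
>>> from gcident import MassSpectrum, cosine_score, ri_penalty, penalized_score
>>> cosine_score(MassSpectrum({100: 3, 200: 4}), MassSpectrum({100: 4, 200: 3}))
960.0
>>> ri_penalty(3.5)
5.0
>>> penalized_score(900, 3.5)
855.0
```

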