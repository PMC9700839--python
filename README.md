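# scpriq

**Reporter-ion quantification for multiplexed single-cell proteomics on
fast TOF-class instruments.**

Multiplexed single-cell proteomics labels the peptides of each cell (plus a
method blank and a many-fold bulk *carrier* channel) with isobaric TMT/TMTPro
reagents and reads per-cell abundance from low-m/z reporter ions in each MS2
spectrum. On trapped-ion-mobility TOF instruments this is fast but the mass
accuracy is looser than on Orbitraps, and single-cell signal is tiny, so the
processing stack has to work hard: recalibrate masses post-acquisition,
filter spectra that carry no single-cell evidence, correct isotopic
impurities, and verify quantitative accuracy on standard designs before any
biology is read off the matrix.

`scpriq` implements that stack as a tested Python library plus CLI:

- **spectra** — MGF read/write (1/k0 ion-mobility annotation included),
  top-N noise filtering, and merging of redundant MS2 scans
  (RT ≤ 5 s, 1/k0 ≤ 0.1, precursor ≤ 0.05 Da).
- **reporters** — TMT11/TMTPro channel definitions from elemental
  composition (monoisotopic cation mass − 1 e⁻), reporter extraction in a
  0.005 Da (or ppm) window, NNLS isotopic-impurity correction, the
  interference-free index IFI = 1 − mean(knockout)/mean(parent), and
  diagnostic-ion detection (acetyl-lysine immonium-derived ion at
  126.0913 Th, 0.0364 Th below the 126 reporter).
- **calibration** — per-file constant-ppm offset estimated as the median
  relative mass error over reporter anchors; lets a ~50 ppm extraction
  window be tightened to 20 ppm with no loss of quantified reporters.
- **qc** — DIDAR-style filtering (keep MS2 scans with ≥1 single-cell
  reporter in 127N–131N), rejection of runs whose cell-channel evidence is
  not >3× the 126 blank's, and 12-per-100-Da peak binning.
- **quant** — feature×channel matrices (missing ≠ zero), minimum-average
  intensity 10 filter, channel exclusion, total-sum normalization,
  pairwise-peptide ratio roll-up with a 100-fold cap, PTM-to-protein ratio
  normalization, and long-form 3-D export.
- **cellcycle** — per-cell stage scoring from a curated marker panel
  (row min-max scaling → stage mean → argmax) and condition-level stage
  composition.
- **evaluation** — dilution-series linearity (R², slope on log10 scales),
  missing-value profiles, two-proteome 1:5:10 spike-ratio accuracy, and
  carrier-effect curves.
- **simulate** — synthetic TIMS-TOF-like spectra and single-cell matrices
  with full ground truth (Poisson reporter counts, ppm mass error, impurity
  leakage, carrier, ion-budget compression, planted cell-cycle stages and
  treatment effects), so the whole stack is testable without raw data.

## Worked example

```python
from scpriq import (SimParams, simulate_run, estimate_offset,
                    apply_calibration, two_proteome_9plex)

design = two_proteome_9plex()          # 9-plex, E. coli spikes at 1:5:10
params = SimParams(n_spectra=1000, systematic_offset_ppm=30.0, seed=1)
records, truth = simulate_run(params)

model = estimate_offset(records, design, search_tol_ppm=50.0)
print(f"offset {model.offset_ppm:.2f} ppm from {model.n_anchors} anchors")
corrected = [apply_calibration(r, model) for r in records]
print(f"residual {estimate_offset(corrected, design).offset_ppm:.3f} ppm")
```

prints

```
offset 30.03 ppm from 9000 anchors
residual -0.000 ppm
```

i.e. the injected 30 ppm systematic TOF drift is recovered from the
reporter-ion ensemble (9 channels × 1000 spectra) and removed, after which
reporter extraction can run at a 20 ppm tolerance without losing matches.

The same pipeline runs from the shell:

```bash
scpriq simulate run --n-spectra 1000 --offset-ppm 30 --seed 1 --out raw.mgf
scpriq calibrate --in raw.mgf --out cal.mgf --auto --range 120:140
scpriq didar --in cal.mgf --required 127N,128N,129N,130N,131N --tol 0.005
scpriq run-all --config pipeline.toml   # config-driven, writes a manifest
```

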