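# resiglyco

Quantitative analysis of cell-surface glycan organization from multiplexed
DNA-PAINT / RESI localization microscopy data.

Metabolically labelled sugars (e.g. sialic acids via Ac₄ManNAz, LacNAc via
Ac₄GalNAz) carry one of six orthogonal DNA barcodes and are imaged in six
sequential DNA-PAINT rounds. Each sugar site is sampled by many transient
imager-binding events, leaving a clump of K localizations of precision
σ_SMLM ≈ 3 nm. Averaging these improves the precision to

    σ_RESI = σ_SMLM / √K

reaching the ångström range for K ~ 100 — enough to resolve individual
sugars within single glycans. `resiglyco` implements the downstream
computational pipeline for this kind of experiment, together with a
synthetic-data generator that emulates the acquisition, so every step is
testable against a known ground truth.

## What the pipeline computes

1. **RESI site detection** (`resiglyco.resi_core`). Per-channel density
   clustering of localizations with radius r = 7.15 nm (≈ 2.35 σ_SMLM) and
   a minimum of n_min = 10 localizations (the `n_mean − n_std` rule), time-
   trace filtering that removes short-lived nonspecific binding, centre
   averaging (σ_RESI = s/√K), translation alignment of channels from gold-
   nanoparticle fiducials, and merging of all six channels into one table
   of super-resolved sugar positions.
2. **Spatial statistics** (`resiglyco.spatial_stats`). DBSCAN clustering of
   sugar positions (ε = 10 nm, minPts = 2), N = 40 analysis areas of
   0.5 µm², matched-count complete-spatial-randomness (CSR) references per
   area, the clusterization excess

       Δ clustered = (f_data − f̄_CSR) / f̄_CSR

   (f = fraction of sugars in clusters of ≥ 2) with one-sided one-sample
   and two-sided Welch t-tests, and 1st–4th nearest-neighbour distance
   (NND) distributions against the closed-form 2-D Poisson law
   F_k(d) = 1 − exp(−λπd²) Σ_{j<k} (λπd²)^j / j!.
3. **Synthetic scenes** (`resiglyco.synthetic_data`). CSR or
   glycan-structured ground truth (proteins → glycans → labelled tips at
   0.9–10 nm spacings), barcode assignment, DNA-PAINT blinking kinetics
   over 40,000 frames, ~3 nm localization noise and sparse nonspecific
   events, plus the single-round resolvability model
   1 − exp(−(ρ/6)·πd²).

## Worked example

Write `config.yaml`:

```yaml
fov_width: 3000
fov_height: 3000
seed: 11
simulate:
  mode: glycan          # proteins carrying multi-antennary glycans
  protein_density: 220  # per um^2
areas:
  n_areas: 12
csr:
  n_reps: 25
```

and run the full pipeline (simulate → resi → stats → report):

```sh
resiglyco run -c config.yaml -w run/
```

`run/report.txt` then begins:

```
RESI spatial-statistics report
==================================
areas analysed:      12
mean density:        506.7 sites/um^2
CSR mean 1st NND:    22.21 nm
Delta clustered:     +5.1559 +- 0.1256 (s.e.m., n=12)
one-sided t vs 0:    t=41.064, dof=11, p=1.09e-13 -> significant (p < 0.05)
```

Reading: the detected sugar density is ~507 µm⁻²; under CSR at that density
the mean first-NND would be 22.2 nm; the fraction of sugars in DBSCAN
clusters is 6.2× its CSR expectation (Δ = +5.16), overwhelmingly
significant — as it must be, since the scene placed sugars in
multi-antennary glycan clusters. Re-running with `simulate.mode: csr`
produces a report whose one-sided test is NS. Full per-area numbers are in
`run/delta_clustered.csv`, cluster-size histograms in
`run/cluster_sizes.csv`, NND samples in `run/nnd_k{1..4}.csv`, per-channel
QC in `run/qc.json`, and a reproducibility manifest (resolved config,
per-stage seeds, output digests) in `run/manifest.json`.

Each stage is also available separately (`resiglyco simulate|resi|stats|
report`) and as plain library calls.

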