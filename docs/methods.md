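# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `resiglyco`. Coordinates are in nm with the origin at the
lower-left corner of the field of view (FOV), y increasing upward; barcode
channels are integers 0–5 (input labels R1–R6 are mapped to 0–5). All
random procedures are pure functions of their inputs and a seed; the
pipeline derives one seed per stage from `(config.seed, stage)` so stages
can be rerun independently.

## RESI site detection

**Per-channel clustering.** Each sugar site, repeatedly sampled by imager
binding, leaves a clump of localizations of width σ_SMLM ≈ 3 nm. The
clustering algorithm is seeded density clustering, fixed as follows so that
it is deterministic and testable against a brute-force re-implementation:

1. for every localization, count neighbours within radius r (circle,
   distance ≤ r, the point itself included);
2. a localization is a *seed* when its count is a strict local maximum over
   its r-neighbourhood; ties are broken by higher count, then lower frame,
   then lower x, then lower y;
3. every localization joins the nearest seed within r, otherwise it is
   noise;
4. clusters with fewer than n_min members are discarded.

Defaults r = 7.15 nm and n_min = 10: the radius is ~2.35× the localization
precision (the FWHM of the localization spread), which captures a site's
localizations while keeping the chance of nonspecific pile-ups small, and
n_min = 10 implements the `round(mean − std)` rule on per-cluster
localization counts (`suggest_nmin`, floored at 2; `suggest_radius` returns
2.35 × median precision). One (r, n_min) pair is shared by all channels;
the configuration accepts overrides.

**Time-trace filter.** A genuine docking site is revisited throughout the
40,000-frame acquisition, whereas nonspecific sticking is one short burst.
Member frames are merged into binding events by closing gaps of up to
`gap_frames` (default 5) frames; clusters with fewer than `min_events`
(default 3) events or a first-to-last-frame span below `min_span_fraction`
(default 0.1) of the acquisition are removed. The criterion (all three
knobs exposed) is this package's concretization, calibrated on synthetic
data: at default kinetics it removes essentially all 1–3-localization
nonspecific events (which n_min already rejects) while retaining >99% of
genuine sites.

**Centres.** The site position is the arithmetic mean of the K member
localizations; its precision is reported as s/√K with s the sample standard
deviation pooled over x and y, s = √((s_x² + s_y²)/2). Using the empirical
s rather than the nominal precision makes the 1/√K law an emergent,
testable property. K = 1 clusters (possible only with n_min = 1) fall back
to the localization's own precision and are flagged.

**Alignment and merging.** Channels are registered by translation only:
fiducial localizations are collapsed to per-fiducial centres (link-radius
connected components, 50 nm default), matched mutual-nearest-neighbour to
the reference channel within 100 nm (warning when two fiducials sit within
twice that), and the shift is the mean matched displacement, with the RMS
residual reported. No rotation or magnification terms are fitted. Merging
translates each channel's centres and concatenates; distinct barcodes are
distinct molecules, so there is no cross-channel deduplication. The
pipeline's simulate stage generates drift-free, pre-aligned channels, so
the orchestrated runs use zero shifts; `align_channels` is the entry point
for real acquisitions.

## Spatial statistics

**DBSCAN.** ε = 10 nm, minPts = 2 by default, with minPts counting the
point itself, so minPts = 2 means "at least one neighbour within ε" and
clusters are exactly the connected components of the ε-neighbourhood graph
(implementations differ on this; it is stated explicitly). Labels are
deterministic: components numbered by lowest member index. The
implementation builds the ε-graph with a KD-tree and takes sparse connected
components; for minPts > 2, core points (≥ minPts within ε) form clusters
and border points join their lowest-index core neighbour. Writing the graph
route in-package (rather than delegating to scikit-learn) is what allows
toroidal geometry in the null simulations; scikit-learn's DBSCAN serves as
an independent cross-check in the tests, as does a brute-force
connected-components oracle.

**Areas.** Statistics are taken over N = 40 squares of 0.5 µm²
(side 707.1 nm) tiling the FOV, keeping squares whose record density lies
within 0.5–1.5× the median candidate density ("apparently homogeneous") and
sampling the requested number without overlap, seeded; an explicit ROI list
bypasses selection. DBSCAN runs once on the full merged table and per-area
quantities are then restricted to each square, so neighbourhood information
at square boundaries is not lost (picks are interior to the FOV).

**CSR reference and Δ clustered.** Each area gets its own null: replicates
of exactly the observed record count placed uniformly on the square
(conditioning on the count removes count noise from the null — "same
density" without Poisson number fluctuations), analysed with toroidal
distances (edge-free, mirroring the interior-area treatment of the data).
Default 100 replicates per area (pipeline-scale runs in this repository use
25; the null mean's contribution to the per-area Δ noise is negligible at
either setting). Δ = (f_data − f̄_CSR)/f̄_CSR per area, where f is the
fraction of records in clusters of size ≥ 2; the absolute difference is
kept alongside. Against the null, a one-sample one-sided t-test (H₁:
mean > 0); between conditions, a two-sided Welch t-test (the
unequal-variance form is this package's choice). Zero-variance samples are
handled degenerately and flagged.

**NND.** Distances from each sugar to its 1st–4th nearest neighbours
(KD-tree; monotone in k by construction), computed on the full table and
restricted to areas, without edge correction; the CSR reference curve is
the closed-form 2-D Poisson law F_k(d) = 1 − e^(−m) Σ_{j<k} m^j/j! with
m = λπd², equivalently the regularized incomplete gamma P(k, m), with mean
first-NND 1/(2√λ). Histograms use 0.5 nm bins by default.

## Synthetic data generator

The generator emulates the acquisition the pipeline is designed for:

* **Scenes.** CSR mode: Poisson site count at the target density (defaults
  bracket the observed 750–1,100 sugars/µm²), uniform positions. Glycan
  mode: Poisson protein centres; each protein carries a fixed or
  zero-truncated-Poisson number of glycan anchors, jittered by a 2-nm
  Gaussian (membrane proteins are ~5 nm across); each glycan draws a
  template from a weighted mixture and places its 1–5 labelled tips under a
  uniform random rotation. The built-in template library spans mono- to
  penta-antennary layouts with pairwise tip spacings from 0.9 to 6 nm
  (including a 9 Å pair). Tips are wrapped toroidally into the scene so the
  marginal density is position-independent. Protein/glycan lineage ids are
  recorded for recovery tests.
* **Barcodes** are i.i.d. uniform over the six channels (the labelling
  chemistry gives no stated bias).
* **Kinetics.** Per site, a Poisson number of binding events (mean 20) at
  uniform start frames, geometric event durations (mean 5 frames), one
  localization per bright frame — ~100 localizations per site over 40,000
  frames, consistent with n_min = 10 and ångström-scale averaged precision;
  the event statistics are this package's model, set once, not measured
  values. Localization noise is isotropic Gaussian with σ_SMLM = 3 nm; the
  stored per-localization precision is σ_SMLM jittered ±10%.
* **Background.** Nonspecific events are uniform in space and time, 500
  events/µm² per channel over the acquisition, 1–3 localizations each —
  exactly the signature the n_min and time-trace filters are designed to
  remove (<10% of localizations at the default densities).
* **Resolvability.** `fraction_nonresolvable` gives the probability that a
  molecule has a same-barcode neighbour within the single-round resolution
  distance d: analytically 1 − exp(−(ρ/n_ch)πd²), or by toroidal
  Monte-Carlo. At 1,100 µm⁻² over 6 channels and d = 10 nm this is ≈ 5.6%.

What the generator does *not* emulate: camera frames and PSF fitting (it
produces localization tables directly), drift (scenes are drift-free, so
pipeline runs skip alignment), 3-D structure, photophysics beyond the
event/duration model, imager-concentration effects, and any barcode-
assignment bias. Tests passing on synthetic data therefore validate the
analysis chain, not upstream reconstruction.

## Problem sizes in the test suite

The repository's own calibration runs use desk-scale sizes, chosen once:
null calibration uses 20 seeded end-to-end runs on a 4.95 × 4.24 µm FOV at
750 sugars/µm² (the lower of the two bracketed study densities) with 40
areas and 25 CSR replicates per area; structure recovery uses one
end-to-end glycan run at 220 proteins/µm² (tetra-antennary, ~880 sugars/µm²)
analysed at ε = 8, 10, 12 nm, plus 30 grid-construction scenes for the
cluster-size cap; precision scaling uses 400–1,000 sites per K. The
acceptance script evaluates ~2.2 × 10⁶ molecules (t1) and 1,000 sites (t2).

## Known limitations

* **Single-round non-resolvability deflects Δ on dense CSR patterns.**
  Same-barcode sites closer than roughly the clustering radius scale
  (~10–14 nm; the count field of two σ = 3 nm clumps under a 7.15-nm disc
  has a single maximum below ~2r) merge into one cluster during per-channel
  clustering — the "non-resolvable within a round" fraction that
  `fraction_nonresolvable` quantifies. Detection therefore suppresses
  same-barcode close pairs (1/6 of close pairs at six barcodes), while the
  ideal-CSR reference retains them, so the end-to-end null on dense CSR
  scenes sits measurably *below* zero rather than at it (the null-
  calibration check in the acceptance tests computes this directly; the
  statistics stage alone, fed ground-truth positions, is unbiased). The
  practical consequences: Δ > 0 findings are conservative, and Δ values
  from data processed by detection should not be compared against an exact
  zero null at high density.
* **Two-site separation estimation.** The Euclidean distance between two
  recovered centres is Rice-biased upward when the true separation is
  comparable to the centre error (at 0.9 nm truth and K = 100 the scalar
  mean distance is ≈ 1.07 nm); parameter recovery of a known-pair
  separation uses the norm of the mean displacement vector across
  replicates (records ordered by barcode), which is unbiased.
* The detected-site accuracy distribution has a tail from the
  compound-Poisson spread of K (~100 ± 30 at default kinetics): typical
  (median) centre errors are ~0.4 nm, but a few per cent of sites exceed
  1 nm.
* Channel alignment is translation-only; rotation/magnification errors are
  not corrected. Area selection assumes the FOV is homogeneous enough that
  a density band around the median identifies usable squares. All analysis
  is 2-D. Multiple-testing correction across conditions is out of scope
  (at most two tests are reported per comparison).
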