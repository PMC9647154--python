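# Methods

`cbctsc` implements a prior-CT-guided, hybrid-domain scatter correction for
cone-beam CT (CBCT) together with everything needed to exercise it without
any external data: a digital pelvis phantom, a cone-beam projection/
reconstruction chain, image-quality metrics, and a dosimetric evaluation
layer for brachytherapy-style dose distributions. This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic benchmark does and does not demonstrate.

## The correction model

Photon scatter adds a smooth, strictly positive signal S to each detector
view. Measured intensities are therefore I = I0·exp(−p) + S, and the
reconstructed attenuation is biased low ("cupping"), by several hundred HU
in a bowtie-less pelvis scan. The correction assumes a high-quality planning
CT of the same (rigid) anatomy is available and runs in six steps:

1. **Reference attenuation coefficients.** For each tissue class — air,
   adipose, muscle, bone, windowed at [−1024, −500], [−125, −60], [15, 85]
   and > 190 HU — the histogram mode of the planning CT inside the window
   (1 HU bins) is converted to a linear attenuation coefficient (LAC)
   through the water anchor `mu = HU/1000 · mu_w + mu_w` (default
   `mu_w = 0.020 /mm`). Ties break toward the window centre; negative
   results clamp to zero.
2. **Uniform projection-domain correction.** A single constant `s_bar` per
   scan — the intensity that 90% of object pixels (pooled over views,
   object = pixels below 0.9·I0) exceed, nearest-rank convention — is
   subtracted in the intensity domain with a C¹ soft cut that preserves
   positivity: plain subtraction where `I − s_bar ≥ eps·I` (eps = 0.05),
   and `eps·I·exp((I − s_bar − eps·I)/(eps·I))` below. A first-pass volume
   CBCT_c is reconstructed with FDK. Two guards bound the tail behaviour:
   `s_bar` is capped at `(1 − eps)·min(object I)` so no object pixel enters
   the exponential branch (without the cap the percentile rule pushes ~10%
   of pixels into a near-zero collapse that reconstructs as a sharp
   high-HU blob no smooth ratio can repair), and the log conversion floors
   intensities at `1e-4·I0` (a 16-bit-panel dynamic-range scale, capping
   implied attenuation at p ≈ 9.2).
3. **Segmentation and template.** The four-class windowing is applied to
   the planning CT and the labels transferred rigidly to the CBCT grid (the
   phantom is rigid; an alternative mode thresholds CBCT_c directly).
   Values between windows ("gap" voxels — e.g. muscle-equivalent plastics
   at ~130 HU) are labelled air but flagged unclassified. The template
   CBCT_t fills each class with its reference LAC; voxels above 1000 HU in
   CBCT_c are treated as applicator and filled with the applicator's
   nominal LAC.
4. **Scatter ratio and sampling mask.** `r = CBCT_t / max(CBCT_c, 1e-4)`.
   A binary mask f keeps trustworthy samples: f = 0 where `|r|` exceeds
   `r_max` or the in-plane central-difference gradient magnitude exceeds
   `G_max` — each the nearest-rank 80th percentile of its field over the
   candidate set (confidently classified voxels inside the body) — and
   additionally at unclassified voxels, outside the body, and inside the
   applicator. Ties at the threshold are kept. The percentile population
   matters: gap-class voxels carry the air template value, so their ratio
   ≈ 0 would dominate any whole-body percentile and invert the outlier
   rejection; exterior air would likewise flood the statistics. The body
   mask is "labelled non-air or unclassified".
5. **Local filtration.** Per axial slice, masked normalised convolution
   `r_f = (r·f) ∗∗ w / (f ∗∗ w)` with a 2D Gaussian `w` (σ = 12 mm,
   truncated at 3σ, zero-padded borders — the normalisation cancels the
   padding exactly). Where the local weight sum falls below 1e-6 the
   fallback fills in the global mean of the sampled ratio (an identity
   fallback is also available). The ratio may optionally be computed
   against a pre-smoothed first pass (`ratio_presmooth_mm`); the corrected
   volume always multiplies the unsmoothed CBCT_c.
6. **Apply and substitute.** `CBCT_fc = CBCT_c · r_f`, converted to HU for
   reporting. Finally the applicator footprint (thresholded at 1000 HU) is
   replaced by a rigid applicator model, registered by centroid +
   principal-axes alignment of the two thresholded point clouds (or a
   supplied/identity transform); residual blooming voxels outside the
   transformed model are filled with the median HU of a thin ring around
   the footprint.

The correction is anchored to the prior wherever a class is confidently
sampled; in unsampled regions it interpolates the ratio field. That
distinction drives the accuracy structure seen in the benchmark (below).

## Synthetic study design

**Phantom.** An elliptical body, 340 mm × 200 mm in cross-section, on a
256 × 192 × 96 grid at 1.5 mm isotropic voxels (axes ordered z, y, x).
Structures are analytic ellipsoids/cylinders painted in priority order:
an adipose shell (−112 ± 10 HU) around a muscle-equivalent background
(130 ± 9 HU — deliberately *between* the muscle and bone windows, as
muscle-equivalent plastics are), intestine (30 ± 9, inside the muscle
window), bladder (191 ± 10), uterus (196 ± 15) and rectum (199 ± 10) —
organ-equivalent materials just above the bone threshold — and bilateral
bone stand-ins (PMMA-like cortical 120 ± 12, gap-class; POM-like
cancellous 340 ± 12). Texture is seeded Gaussian noise per structure.
A titanium-like tandem applicator (radius 3 mm, 2500 HU) runs along the
z axis through the uterus. Analytic shapes give exact volumes for DVH
checks; there is no anatomical deformation. The ROI catalog mirrors the
phantom-study census: six muscle ROIs spread through the background plus
adipose, bladder, uterus and rectum, each strictly inside its structure
(the catalog builder rejects impure ROIs).

**Prior.** Ground truth plus i.i.d. Gaussian noise (std 10 HU) — an
idealised planning CT on the same grid (identity registration; the rigid
transfer machinery is exercised separately).

**Geometry.** Circular full scan, SAD 1000 mm, SDD 1500 mm, 360 views at
1°, flat detector of 384 × 192 pixels at 1.552 mm pitch. The 192 detector
rows are the minimum power-of-two-friendly height whose cone covers the
144 mm-tall phantom at maximum magnification; the projector refuses
truncated geometries outright.

**Scatter.** Per view, `S = spr·[(1 − c)·G_sigma(I) + c·mean(I)]` with the
plateau mean taken over the whole stack: a broad blurred component
(σ = 150 mm at the detector) plus a scan-level plateau (c = 0.9). Real
flat-panel scatter kernels combine a wide PSF with a nearly flat plateau,
and a scan-level plateau is precisely the regime in which a single
empirical constant per scan removes the bulk of the scatter — the premise
of step 2. Amplitude `spr = 0.06` and the photon budget `1e6` photons per
unattenuated pixel were calibrated once against the published raw-CBCT
severity of the phantom experiment this benchmark emulates — raw RMSE
≈ 490–520 HU (printed: 510), raw muscle SNU ≈ 80–95 (printed: 107),
within-ROI std ≈ 10–25 HU raw and ≈ 20–45 HU corrected (printed: 2–15 and
24–41) — and then frozen. The generator does **not** model beam hardening,
bowtie filtration, detector lag/glare, polychromatic spectra, or
object-generated scatter physics; its scatter is additive, smooth and
constant-preserving by construction.

**Benchmark loop.** Phantom → forward projection (Joseph-style ray
marching, step = half the smallest voxel) → Beer–Lambert → scatter →
Poisson noise → (a) raw FDK, (b) the six-step correction → ROI statistics,
RMSE/SNU/CNR → toy dose on ground-truth vs corrected LAC with a ten-dwell
plan (5 mm steps, 30 s dwells) → 3D local gamma at (1%,1mm), (2%,1mm),
(2%,2mm) with 3/6/9/12 Gy thresholds → D90 (uterus) and D2cc (bladder,
rectum, intestine). All randomness flows from the single run seed. A full
run takes ≈ 4–5 minutes on one CPU core.

## Reconstruction numerics

FDK with cosine weighting for a flat detector, a band-limited spatial-
domain Ram-Lak kernel evaluated on the isocenter-rescaled pitch and applied
in the frequency domain with zero-padding to the next power of two (the
discrete kernel, h[0] = 1/(4·ds²), h[odd n] = −1/(π n ds)², avoids the DC
bias of a naive |ω| ramp), optional Hann apodisation, and distance-weighted
voxel-driven backprojection with per-view angular increments. On an
analytic water cylinder the interior mean reconstructs to 0.020 /mm within
0.2% (tests assert 5%); the central-ray line integral of a 100 mm chord is
exact to 0.003%. The benchmark reconstructs with Hann: at the calibrated
photon budget Ram-Lak noise roughly doubles the spread of the ratio field
that the step-4 percentiles see. HU↔LAC conversions are exact affine
inverses.

## Dosimetry numerics

The toy dose engine is `D(x) = Σ_j S·t_j / max(d_j², d_min²) ·
exp(−∫ mu dl)` — inverse square and primary attenuation only, no scatter
buildup, no TG-43 anisotropy. `d_min` is half the dose-voxel diagonal;
`S = 7.5 Gy·mm²/s` corresponds roughly to a fresh ~10 Ci Ir-192 source
(≈ 2.3 Gy per 30 s dwell at 10 mm in water). The dose grid default is
2.5 × 2.5 × 1 mm. It exists to propagate HU errors into dose, not to
predict clinical dose.

Gamma uses local normalisation (the reference voxel's own dose), a search
radius of 3·DTA and a DTA/10 interpolation subgrid with offsets sorted by
distance and early termination (exactly equivalent to exhaustive search
within the radius; verified against a brute-force oracle on 9³ grids to
1e-3). DVH: D90 is the 10th percentile of in-structure dose; D2cc
interpolates linearly on the sorted doses at exactly 2 cm³ and is undefined
below 2 cm³. ROI statistics use the sample (n−1) standard deviation;
spherical ROIs by default, with a single-slice disc mode for replicating
2D-drawn tables.

## Accuracy structure and known limitations

Where a tissue class is confidently sampled near a region, the corrected
HU error is small: on the default benchmark the organ ROIs (bladder,
rectum) and the adipose shell land within ≈ ±15 HU of ground truth, the
corrected RMSE is ≈ 4–7× better than the first pass and ≈ 7× better than
raw, and the dosimetric agreement between ground-truth and corrected-CBCT
dose is high (3D local gamma at (2%, 2 mm), 3 Gy threshold ≥ 99.8%; D2cc
deviations ~1%).

The method's structural limit shows in regions that are *not* sampled:
the gap-class muscle background (whose 130 HU material falls between the
muscle and bone windows, so its ratio is never sampled) and the deep
centre. After a single uniform subtraction the residual first-pass error
still varies by ~±150 HU across the body — unavoidable, since the central
primary signal is only ~e⁻⁷·I0 and any scatter non-uniformity beyond a
fraction of that leaves a large log-domain residual. The ratio field is
multiplicative, so an additive residual δ needs class-specific ratios
(`mu/(mu+δ)` differs between adipose, muscle and organ LACs); interpolating
across classes into the unsampled background leaves systematic errors of
roughly δ·(Δmu/mu) — measured at −80…−100 HU for the mid-body muscle ROIs
and the central uterus ROI at the frozen study conditions. Mid-body ROIs
adjacent to sampled organs do far better (muscle_5: −9 HU). The published
experiment this emulates reports < 15 HU for all ROIs; reproducing that
within this framework would require either near-perfectly uniform scatter
(non-uniformity ≲ 0.1% of I0) or ROIs placed within the filtration radius
of correctly-templated structures. This is documented rather than patched:
the corresponding acceptance check is expected to fail at roughly
100 HU and the failure mechanism is the honest behaviour of the published
pipeline under these conditions.

Other known limitations: no short-scan (Parker) weighting and no
truncation handling in FDK; rigid-only applicator registration with
principal-axis sign disambiguation suited to small rotations; the bone
template inherits the organ-material mode when organ-equivalent materials
occupy the bone window (as in the emulated phantom), so bone HU accuracy is
sacrificed — consistent with the method's stated scope; CNR of the
corrected image can exceed the planning CT's when noise amplification is
outweighed by restored contrast, so CNR checks are property-based, not
value-exact.

## Open design choices made here

- Uniform subtraction happens in the intensity domain (positivity via the
  soft cut is only meaningful pre-log).
- One global `s_bar` per scan; percentiles use the nearest-rank convention;
  `r_max` and `G_max` are computed separately at the 80th percentile.
- Eq.-style 2D operations (gradient, filtration) act per axial slice —
  scatter cupping is in-plane; the slice axis is configurable.
- Filtration σ = 12 mm: sweeps from 4–30 mm moved individual ROI errors by
  ±30 HU without a uniformly better setting; the default is the midpoint of
  the flat region of that trade-off.
- Segmentation defaults to prior-transfer (mirroring the planning-CT
  workflow); direct CBCT thresholding is available as `segmentation_source
  = "cbct"`.
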