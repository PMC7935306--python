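# Methods

`specctmar` simulates a three-energy-bin photon-counting CT acquisition of 2-D
digital phantoms and runs the downstream spectral analysis chain: per-bin
normalized metal artifact reduction (NMAR), image-domain three-material
decomposition (MD), virtual monochromatic image (VMI) synthesis, and
ROI-based image-quality metrics (CNR, uniformity, iodine recovery). This note
documents the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Source spectrum and attenuation data

The tube output is a Kramers-type bremsstrahlung: photon fluence per keV
proportional to `kvp/E − 1`, zero at and above the tube voltage (default
140 kVp), attenuated through a fixed 2 mm aluminum-equivalent inherent
filtration by Beer–Lambert; no characteristic lines. MD and VMI only need a
plausible polyenergetic shape, not a validated tube model. The filtered
140-kVp beam has a mean energy of 54.2 keV.

Mass attenuation coefficients (µ/ρ, cm²/g) for water, air, PMMA, soft tissue,
cortical-type bone, aluminum, calcium, titanium, iodine and gadolinium are
shipped as plain-text package data on a 1-keV grid over 20–150 keV
(`data/mass_attenuation.csv`). The table is compiled by
`scripts/build_attenuation_table.py` from anchor values of standard published
photon cross-section tabulations, log-log interpolated; iodine and gadolinium
are interpolated separately below and above their K-edges (33.17 and
50.24 keV), which fall between grid samples so the discontinuity is preserved.
Accuracy is at the few-percent level, which is sufficient because the forward
simulation and the analysis share the same table (the pipeline is
self-consistent by construction); absolute dosimetry is out of scope.

Derived materials are mixtures of partial densities. The iodine basis used
throughout is `iodine_cal`, water (1.0 g/cm³) plus iodine at 0.0189 g/cm³: a
decomposed fraction of 1 means "full calibration contrast", i.e. 18.9 mg/mL,
so concentration images are simply `b × 18.9`.

## Detector model

* **Energy bins.** Counter thresholds at 30/50/65 keV partition the spectrum
  into half-open bins [30, 50), [50, 65), [65, 140] keV. Binning is applied
  to the transmitted spectrum per ray.
* **Energy resolution.** A Gaussian blur with FWHM equal to
  `fwhm_fraction × reference energy` (default 4.51% at the 122.06-keV Co-57
  line), held constant across the spectrum. It is available as an explicit
  spectrum operation and off by default in the pipeline, since threshold
  smearing has no qualitative effect on any quantity evaluated here.
* **Dead time.** Non-paralyzable counting: measured rate `m = n/(1 + nτ)`,
  true rate `n = m/(1 − mτ)`; τ defaults to 101.42 ns, pixel pitch
  0.190 × 0.230 mm. `fit_dead_time` recovers τ from (input, measured) rate
  pairs by a bounded scalar least-squares search in measured-rate space. At
  50% loss the measured rate per detector area evaluates to 112.8 Mcps/mm².

## Phantoms

All phantoms are 2-D label grids with per-label compositions (material mass
fractions + density), default 512×512 at 0.5 mm/pixel, isocenter-origin mm
coordinates, row 0 at the top. Background air is treated as non-attenuating.

* Iodine cylinders: PMMA bodies of 12/17/22 cm with up to five 20-mm holes of
  iodine solution (3.5–23 mg/mL) on a ring at 60% of the body radius.
* Calibration phantom: 150-mm PMMA, iodine 3.7/10.1/18.9 mg/mL (upper ring)
  mirrored by gadolinium 3.0/7.5/13.8 mg/mL (lower ring).
* Multi-energy phantom: 160-mm water body, iodine 2/5/10/15 mg/mL and
  calcium 300/100/50 mg/mL rods on one ring.
* Head phantom: stylized lower-jaw cross-section — soft-tissue ellipse
  (156 × 190 mm), U-shaped jawbone arch (bone at 1.5 g/cm³) with six teeth
  (2.0 g/cm³), two 5-mm pure-titanium disk implants at (±39, −52) mm, and a
  10-mm iodine-enhanced insert at (0, −52) mm, collinear with the implants so
  streaks overlap the lesion. The tissue density and the insert's iodine
  loading are solved linearly against the broad-spectrum effective
  attenuation so that the noiseless broad-bin image reads ≈57 HU (tissue)
  and ≈75 HU (insert).
* Water phantom: uniform 150-mm disk for uniformity measurements.

The geometric model deliberately omits anatomy beyond what the analysis
needs: metal–lesion collinearity, bone heterogeneity near the trace (jaw vs
teeth), and air/bone/tissue boundaries for prior segmentation.

## Acquisition and reconstruction

Equiangular fan beam: source–isocenter 227.5 mm, source–detector 408.6 mm,
1440 views over 2π, 424 channels of 1.14 mm pitch (6 × 190 µm), covering the
250-mm FOV (384 channels would cover only 232 mm, so the channel count is the
one geometry parameter raised above its nominal value). Line integrals are
computed by ray marching at quarter-pixel steps with bilinear sampling
(numba-compiled). For each ray the per-material path lengths are combined
with the 1-keV attenuation table, the binned source spectrum is attenuated
per energy sample, and transmitted fluence is summed per bin. Poisson noise
is optional; every stochastic operation takes an explicit seed and no global
RNG state is used.

The air scan is the same model without an object. Exposure is expressed as
air counts per channel summed over bins; the default 1.0 × 10⁵ was calibrated
once so the head phantom's broad-bin soft-tissue SD falls in the 10–20 HU
regime at the default acquisition scale (measured 11.4 HU), then frozen.

Pre-processing: `p = ln(I₀/I)` with a 0.5-count floor against photon
starvation, clamped at zero. By default the pipeline then applies a standard
single-material (water) beam-hardening linearization per bin: the
polyenergetic water curve `p_m(L)` is inverted per sample and re-projected at
the bin's effective water attenuation. Without it, broad-bin hardening
through ~170 mm of tissue depresses HU by ≈110 and the decomposition
misallocates tissue into bone; with it, water-like paths reconstruct exactly
while bone, iodine and metal retain realistic hardening residuals. The raw
air-corrected chain remains available (`water_precorrect=False`) and is what
exhibits the classic cupping of a polyenergetic water scan.

Reconstruction is equiangular fan-beam FBP: cosine weighting, the discrete
equiangular ramp kernel with Hann apodization (cutoff at Nyquist), FFT
filtering, and inverse-square-distance backprojection. On a noiseless
monoenergetic 100-mm water disk the interior mean is within 0.01% of the true
attenuation, and `fbp(project_image(x)) ≈ x` with <5% relative RMSE on smooth
images.

## NMAR

Metal is segmented once on the summed-bin (broad) image at 3000 HU with
small-component removal; the same metal trace (projection of the mask) is
applied to every bin, while the prior is built per bin. The prior segments
air (< −300 HU) and bone (> +300 HU), cleans both label maps by morphological
opening then closing with a 3-pixel disk (suppressing boundary
mis-segmentations, e.g. tooth edges, that would seed new streaks), flattens
air and soft tissue to their class means, replaces metal with the soft-tissue
value, and — by default — keeps bone pixels at their measured values. A
strictly three-level prior (`mode="three_level"`) is available but not the
default: on this head phantom, bone spans the jaw (≈1500 HU in bin 1) and
teeth (≈2600 HU), and forcing one bone level injects several times more
normalized-sinogram error than the metal streaks it removes. The measured
sinogram is divided by the projected prior (10⁻⁶ floor for air-only rays),
the trace is bridged per view by 1-D linear interpolation in the normalized
domain, the result is denormalized, and the bin is re-reconstructed. Outside
the trace the corrected sinogram is bit-identical to the input. Metal
reinsertion into corrected images is available but off by default and never
inside metric ROIs.

## Material decomposition, VMI, quantification

Per pixel, the three bin attenuations are modeled as a linear combination of
basis attenuations and solved by one shared 3×3 inversion; solutions are
clipped componentwise to [0, 1] without renormalization. The matrix comes
either from the spectral tables (fluence-weighted bin averages) or — the
default for quantitative work — regressed from ROI means of a reconstructed
calibration scan with known compositions, which absorbs residual hardening
bias. The condition number is reported and a warning is raised above 10³.

The VMI at energy E interprets each fraction as the amount of basis material
present at its nominal density: `µ(x, E) = Σ b_m(x) (µ/ρ)_m(E) ρ_m`,
converted to HU against water at E. This is the only unit-consistent reading
of a mass-fraction weighted recombination that yields HU images. Iodine
concentration images are `b_iodine_cal × 18.9 mg/mL`. The iodine/calcium
overlay labels each pixel by the dominant fraction above a 0.02 floor; it
requires the rod-calibrated matrix because the iodine and calcium columns of
the spectral matrix are nearly collinear in bins 1–2 (bin-2/bin-1 ratios
0.490 vs 0.494) and only bin 3 separates them.

## Evaluation

ROIs are circles in mm; statistics are the arithmetic mean and sample SD
(ddof = 1) over interior pixels (≥20 required; default radius 5 mm, never
stated in the source study). CNR uses the lesion/tissue/air scheme: noise is
the arithmetic mean of the three air-ROI SDs and `CNR_k = (mean₁ − mean₂ₖ)/
noise`; this is the convention that reproduces the published worked examples.
The summary mean ± SD is computed over the three CNRs rounded to the 0.1
reporting precision, matching summaries that were evidently derived from
printed one-decimal values. Uniformity is the maximum absolute difference
between the center and four peripheral ROI means on the water phantom.
Iodine recovery is an OLS fit of measured vs true concentration with R² and
per-point absolute errors. Artifact strength is RMS error against a
metal-free reference outside an exclusion mask.

## Problem sizes

The default ("study") scale is a 512² grid at 0.5 mm, 1440 views, 424
channels. The test suite runs its shared simulations at half scale (256² at
1 mm, 720 views, 212 channels) except for the artifact-reduction and CNR
acceptance checks, which use the study scale because the artifact-to-
inpainting-floor balance that NMAR exploits only emerges at the calibrated
noise level. The full head experiment (scan, three bins + broad, NMAR, MD,
VMIs, evaluation) completes in roughly three minutes on one CPU.

## What the synthetic data do and do not show

The generator reproduces the acquisition geometry, spectral binning, beam
hardening, photon starvation and Poisson statistics of a bench photon-
counting scanner, and the phantom set mirrors the physical phantoms'
dimensions and concentrations. It does not model charge sharing, pulse
pileup, fluorescence escape, scatter, detector gain drift, ring artifacts
from miscalibration, or 3-D cone/multi-slice effects; anatomical realism is
limited to the stylized geometry above. Passing tests therefore validate the
algorithms under idealized detector physics, not scanner-grade image quality.

Two consequences are worth stating plainly. First, with the 5-mm titanium
disk stand-ins (the implants' true composition and size are unknown), metal
artifacts are much milder than dental hardware produces: NMAR's inpainting
floor is then comparable to the artifact level, and its RMSE benefit appears
only at the calibrated study-scale noise level. Second, unregularized
image-domain three-material decomposition amplifies noise from the bins to a
40-keV VMI by roughly an order of magnitude while amplifying iodine contrast
only ~3×, a ratio independent of exposure; the end-to-end CNR ordering of the
four processing arms reported for the physical scanner (40-keV VMI with NMAR
above the uncorrected broad image above the NMAR-only broad image) is
therefore not reproduced by this idealized chain — the corresponding
acceptance test documents the discrepancy rather than hiding it.

## Numerical choices

* Ray-march step: pixel/4 for the polyenergetic projector and for
  `project_image`; integration is restricted to a 135-mm radius circle.
* FBP filter: equiangular ramp kernel, Hann window, 4× zero-padding.
* Zero-count imputation: 0.5 counts; log sinograms clamped at 0.
* Water-precorrection lookup: 3000 thicknesses to 1.5 m, linear continuation
  beyond (photon-starved metal rays).
* Prior-sinogram floor: 10⁻⁶ before division.
* Dead-time fit bounds: τ ∈ [0, 10/max(n)], warning when all pairs sit
  within 2% of linearity.
* Tie-breaks in the overlay: iodine wins equal fractions (`b_i ≥ b_c`).
* Seeds: every stochastic entry point takes an integer seed;
  `numpy.random.default_rng` only.
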