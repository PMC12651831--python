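# Methods

## Digital phantom

`build_phantom` voxelises spheres on an isotropic grid (1 mm default) with
voxel-centre containment: a voxel belongs to a sphere when its centre lies
inside the continuous sphere. Targets carry `background × TBR` kBq/mL on a
uniform 5 kBq/mL background. The study grid is 90³ voxels — large enough
that the biggest sphere's tracking zone, shell and aperture kernel stay well
inside the volume. The reference experiment crosses diameters
{8, 9, 11, 13, 16, 20} mm with TBR {5, 10, 15, 20}:1, one sphere per
simulated image (screening statistics are local to one target, so
co-locating all six spheres would only risk shell cross-talk).

## Imaging chains

`simulate_scan` models a chain as PSF convolution followed by multiplicative
Gaussian noise (cv 0.05 by default) on the reconstructed image, clipped at
zero. Reconstruction-domain noise is a deliberate simplification: the
screening statistics only ever see reconstructed images, and sinogram-level
physics (scatter, randoms, TOF) is out of scope.

* **Diagnostic chain** — isotropic Gaussian PSF, FWHM 4.5 mm (the 4–5 mm
  resolution class of modern PET-CT). SUVmax and the PET-avid volume are
  measured here. The SUV scale is 0.2 SUV per kBq/mL, so the background sits
  at SUV 1 and a TBR 20:1 target at true SUV 20; measured small-sphere
  SUVmax then lands in the mid-teens, the clinically reported regime.
* **Tracking (X1) chain** — a uniform spherical-aperture kernel whose
  *diameter* is the chain's single calibration scalar (default 24.5 mm).

The aperture choice is load-bearing and deserves its justification. The
published deliverability pattern requires the 16 mm sphere to pass at
TBR 5:1 (contrast 20 kBq/mL) while the 9 mm sphere fails at TBR 20:1
(contrast 95 kBq/mL); the hot-core recovery ratio between the two sizes must
therefore exceed 95/20 = 4.75. For a Gaussian PSF the ratio of hot-core
recoveries of 16 mm vs 9 mm balls peaks near 4.6 at the operating point —
at *no* width does a Gaussian chain produce the pattern (at the widths where
the ratio would suffice, all signal magnitudes are far below the floor). A
hard spherical aperture that contains both spheres responds with
total signal / aperture volume, so the ratio becomes the volume ratio
(16/9)³ = 5.6, comfortably above 4.75 — and total signal ∝ concentration ×
volume is exactly the physics that motivates the Volume × SUVmax criterion
in the first place. The aperture is a deliberately simple effective model of
a tracking chain that aggregates counts over a finite acceptance region; it
is not a claim about the vendor's reconstruction.

`calibrate_x1_aperture` scans candidate diameters and accepts those whose
mean anchor statistics (16/20 mm pass at TBR 5:1, 8/9 mm fail at TBR 20:1,
averaged over a few noise realisations at the operating cv) fall on the
correct side of the floor, returning the midpoint of the feasible interval.
Calibration runs under noise because the hot-core statistic carries a small
positive noise-selection bias that noise-free calibration would miss.

## Structures and screening statistics

PTV = GTV + 5 mm, BTZ = GTV + 10 mm (Euclidean dilation via distance
transform). The background shell is the annulus between BTZ + 3 mm and
BTZ + 8 mm: close enough to represent local background, with the gap
excluding most spill-out. Both gap and thickness are configurable; the
vendor's exact shell is not public.

AC is read as the *hot-core contrast*: the mean of BTZ voxels at or above
80% of the BTZ maximum, minus the shell mean. Alternative readings of the
"top 80% of voxels" phrase (hottest 80% by count) average mostly background
— the BTZ dwarfs the target — and could never reach the tens of kBq/mL that
screened targets exhibit; the hot-core reading also reproduces the exact
no-blur limit AC = background × (TBR − 1). NTS divides AC by the shell
standard deviation; it is undefined (by construction and by convention) on
noise-free images, and is not reported when AC fails the floor. With white
reconstruction noise of cv 0.05 the shell sd is ≈ 0.25 kBq/mL, which makes
NTS numerically ≈ 4 × AC; NTS *thresholds* (2.7 planning / 2.0
pre-treatment) are honoured throughout, but NTS magnitudes are a property of
the noise model and are not calibrated against measured values.

## Segmentation

`fraction_of_max` implements the classic adaptive threshold
`bg + f·(max − bg)` with f = 0.41, on an image first denoised with a 2 mm
Gaussian (the analogue of a diagnostic post-reconstruction filter — without
it the single-voxel maximum is noise-inflated and volumes shrink
systematically).

`gradient` casts 256 radial rays from the half-maximum centroid, takes the
per-ray steepest-descent radius and uses the median. The raw
steepest-descent radius of a blurred sphere is systematically *inside* the
physical edge (for a 13 mm sphere at the diagnostic resolution the bias is
≈ −0.5 mm, i.e. −20% in volume), so when the chain PSF is known the
apparent radius is inverted through a lookup calibrated on antialiased
digital spheres passed through the same blur — a model-based edge recovery
in the spirit of commercial gradient tools, which are validated to recover
physical sphere volumes. The phantom study uses this method; recovered
volumes match nominal sphere volumes to a few percent.

## Eligibility analysis

Scores are strict inequalities (`> 11`, `> 5 kBq/mL`). The positive class is
"planning succeeded", so sensitivity is the fraction of deliverable lesions
retained by screening. Threshold optimisation scans 100 linearly spaced
candidates on [4, 35] (inclusive); ties are resolved to the lowest candidate
by default (maximising clinical utility) or uniformly at random. The
bootstrap draws 1000 resamples with replacement at cohort size and reports
the empirical 2.5/97.5 percentile interval of per-sample optima.

The two tie rules answer different questions. The lowest rule is the
clinical convention but is *not* a calibrated estimator of the generative
boundary: on cleanly separable cohorts every threshold across the empirical
gap ties at accuracy 1 and the rule always returns the bottom of the gap, so
its bootstrap CI sits systematically low. Parameter-recovery checks
(does the CI cover the true boundary?) therefore use the random rule, whose
tie handling is unbiased across the gap.

The synthetic cohort generator draws volume and SUVmax log-uniformly from
the clinical ranges (1.2–7.4 cc, 3.6–37.3) and sets the latent
AC = (5/11)·volume·SUVmax + N(0, 1 kBq/mL), placing the deliverability
boundary exactly at product 11. An outlier mechanism (probability 1/18,
AC × 0.5) emulates elevated-background-shell failures, where a lesion with a
healthy product nevertheless fails the AC floor. What the generator does
*not* emulate: irregular lesion shapes, inter-institution contouring
variability, heterogeneous uptake, and respiratory motion — passing tests
demonstrate correct machinery and internal consistency, not clinical
performance.

## Treatment windows and sequencing

`treatment_window` is the closed-form decay time
`(T½/ln 2)·ln(AC₀/5)` with the F-18 half-life 109.8 min. The window table
evaluates a per-size linear AC-vs-SUVmax fit (from the study's 24
measurements) at bin midpoints and floors each window to 0.5 h — a delivery
slot must fit entirely inside the window. The linear response is trusted up
to 1.3 × the largest SUVmax measured for that size and withheld beyond; the
sub-centimetre columns stay empty because within their measured domain AC
never reaches the floor. Cell-exact agreement with published tables is not
claimed (the underlying regressions are not public); the structure — row
and column monotonicity, empty sub-centimetre columns — is. Sequencing is
earliest-deadline-first with optional per-target setup overhead;
EDF is feasibility-optimal, which the tests verify against exhaustive
permutation search.

## Gamma comparator

Reference and evaluated grids must coincide (resampling is out of scope in
this version). Candidate displacements live on a lattice of step dta/10
capped at radius 3 × dta; the evaluated dose is linearly interpolated at
sub-voxel candidates; candidates outside the evaluated grid are skipped.
The pass-rate denominator is the set of *reference* points at or above the
low-dose cut (10% of the reference maximum), the common convention, and is
declared in the CLI output. The optimised search visits offsets in
increasing distance order with an exact early-termination bound and is
tested to 10⁻⁶ against an independent per-point exhaustive implementation.

## Numerical choices and problem sizes

All randomness flows from per-run seeds through `numpy` `SeedSequence`
spawning, making every artifact reproducible byte-for-byte from
(config, seed). The study uses 90³ images (≈ 0.6 s per configuration
including both chains and structure construction; the full grid runs in
≈ 15 s). Oracle-equivalence tests use 64³ images and 31×31 dose grids;
coverage simulations use 200 cohorts × 1000 bootstrap resamples. Degenerate
inputs are rejected with messages (empty masks, zero shell variance,
non-positive scores, overlapping spheres) except where the domain defines a
result (flat image → "no avid lesion"; AC at the floor → screening fail).

## Known limitations

* The aperture kernel and the hot-core reading are effective models of a
  proprietary chain; their *pattern* is validated, their cell values are not
  vendor-exact (measured AC magnitudes agree with published planning values
  to roughly ±30%).
* One configuration — 11 mm at TBR 15:1 — is intrinsically borderline for
  the product criterion: its true product is 0.70 × 15 = 10.5, and only the
  (real, systematic) noise inflation of single-voxel SUVmax lifts the
  measured product above 11. Under some noise seeds the measured product
  lands just below 11 and the criterion disagrees with deliverability on
  that single cell (23/24 instead of 24/24). This mirrors the boundary role
  the 11 mm target plays in defining the threshold.
* No respiratory motion, no anisotropic voxels, no DICOM-RT I/O.
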