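# Methods

## The measurement model

A nucleus is a grey-scale image (staining density in arbitrary units) with
physical calibration: pixel size (nm) and optical resolution (nm, the PSF
full-width half-maximum), a boolean nucleus mask, and optional nucleolus
masks.  Nucleolus interiors are excluded from every statistic — they serve
ribosomal RNA transcription and assembly, not the chromatin
compartmentation being measured — while their surfaces count as boundary,
because perinucleolar heterochromatin plays the same structural role as the
peripheral layer.

### Binary metrics

Binarization thresholds only within-nucleus, non-nucleolar grey values;
darker-than-threshold pixels are heterochromatin (OsO4 polarity; a flag
inverts it).  The default method is Otsu — the standard parameter-free
bimodal split — with quantile and manual overrides for sensitivity
analysis.  A constant region raises an error under Otsu rather than
returning an arbitrary cut.

*Heterochromatin percentage* is 100 × (heterochromatin pixels)/(valid
pixels).  *Run length* scans every row and every column; a run is a maximal
stretch of consecutive heterochromatin pixels terminated by euchromatin, a
nucleolus, the mask boundary or the image edge, and all runs from both
directions enter one pooled mean (so the pooled mean equals 2·N_het/n_runs).
Connectivity is strictly 1-D along the scan direction — no diagonal
merging.  Whether nucleolus-interrupted or border-truncated runs should
count is not decidable from first principles; the defaults (split at
nucleoli, keep truncated runs) are exposed as flags
(`nucleolus_runs`, `border_runs`).  With no heterochromatin the mean is
reported as missing (NaN), never 0.

*Peripheral profile*: the exact Euclidean distance transform of the valid
region (image padded by one background pixel, so the frame also acts as
boundary) gives each pixel its distance to the nearest envelope or
nucleolar surface.  Ribbon k collects pixels with distance in
[k·w, (k+1)·w) — the half-open interval is the deterministic tie-break —
and the per-ribbon share of total heterochromatin sums to 100% by
construction.  An area-normalized variant (share divided by the ribbon's
area fraction) reads as an enrichment factor, 1 = spatially uniform.
Ribbon-width convention: 37.5 nm at ≈7.8 nm pixels, 16.4 nm at ≈8.2 nm
pixels (the two acquisition setups this analysis is designed around),
otherwise 2 × pixel size; always overridable.

### Grey-scale correlation

The fluctuation field subtracts the within-nucleus mean (not the
whole-image mean, which would mix in background) and zeroes invalid
pixels.  The autocorrelation uses the masked Wiener–Khinchine estimator:

    numerator   = IFFT( |FFT(values · mask)|² )   # sum of products per lag
    denominator = IFFT( |FFT(mask)|² )            # pair count per lag
    B(lag)      = numerator / denominator         where count ≥ 16

with zero-padding to at least twice the linear size, which removes periodic
wrap-around and makes the estimator *exactly* equal to the direct sum over
in-mask pixel pairs (verified against an O(N²) brute-force oracle to 1e−9).
The minimum pair count of 16 suppresses the high-variance rim of the lag
domain.  Rotational averaging bins lags into one-pixel-wide annuli with
pair-count weights, reporting r at bin centers.

Normalization divides by B interpolated at r_min = the optical resolution
(interpolated, never snapped to a bin center, to avoid bin-center bias
between datasets with different pixel sizes); truncation takes r_max as the
linearly interpolated first crossing of 0.02.  The returned curve carries
the interpolated endpoints, so B(r_min) = 1 and B(r_max) = 0.02 hold
exactly and the operation is idempotent.  A curve that never decays to the
cutoff raises `CurveTruncationError` and the nucleus is skipped (counted,
and the pipeline fails if the skip rate exceeds a configurable threshold).

The Whittle–Matérn family A (r/l_c)^ν K_ν(r/l_c) with ν = (D−3)/2 is
evaluated through `scipy.special.kv` (stable over r/l_c ∈ [1e−6, 50]; at
D = 4 it reduces to A√(π/2)·e^(−r/l_c), at D = 3 to A·K₀).  The fit is a
grid search: D ∈ [2, 6] in steps of 0.05 (differences of interest are
0.2–1, so 0.05 resolves them with margin), l_c at 60 evenly spaced points
in [0.66·r_max, r_max].  The amplitude is not free: the normalization
constraint B(r_min) = 1 pins A = 1/[(r_min/l_c)^ν K_ν(r_min/l_c)] per grid
point (an unconstrained-A mode exists behind a flag).  Goodness of fit is
plain r² = 1 − SS_res/SS_tot over the truncated samples, unweighted; ties
break toward smaller D, then smaller l_c; optional bounded local refinement
inside the winning cell is off by default.  Classification from D: < 3
power-law (fractal), [3, 4) stretched exponential, 4 ± half a grid step
exponential (an exact-equality class is measure-zero on a grid), > 4
Gaussian-like.

### Group statistics

The statistical unit is the nucleus image; standard errors are between
images.  Welch's two-sample t-test is the default (robust to unequal group
sizes; Mann–Whitney available), two-sided.  Profiles are compared pointwise
per length scale with no multiplicity correction by default — each scale is
shaded at its own p < α, matching how per-length-scale significance bands
are usually drawn — with Benjamini–Hochberg behind a flag.  Zero-variance
degenerate inputs are defined explicitly: equal constant groups give p = 1.

## The synthetic generator

The generator emulates what the measurements see, not chromatin biophysics:

* **Density field** — a stationary Gaussian random field with prescribed
  Whittle–Matérn correlation, by spectral synthesis: build the periodic 2-D
  correlation image from the radial target, FFT to a power spectrum, clip
  truncation-induced negative spectral values to zero (standard fix;
  negligible bias for smooth targets), filter complex white noise by the
  square-root spectrum, inverse-transform, restandardize.  For D ≤ 3 the
  family diverges at r = 0, so the target is floored at half a pixel —
  sub-pixel structure is unobservable anyway.
* **Geometry** — elliptical nuclei (defaults ~4–6 µm across at TEM pixel
  sizes), pixel-center membership, optional circular nucleoli validated to
  lie inside the ellipse.
* **Binary texture** — thresholding the field at its within-mask quantile
  pins the realized area fraction to the target up to ties (within
  1/(mask pixels) for a tie-free field).  Peripheral enrichment subtracts
  `bias` × (boundary distance normalized to [0, 1]) from the field before
  re-solving the quantile, so positive bias moves heterochromatin outward
  without changing the global fraction.  Clump size (run length) is
  controlled by the field's correlation length.
* **Rendering** — 8-bit, dark = dense: a bimodal compartment contrast
  (heterochromatin ≈ level 106, euchromatin ≈ 168) plus a weaker continuous
  modulation by the field (±9 per unit field) within compartments, Gaussian
  PSF blur to the stated resolution, additive Gaussian grey noise (sd 4)
  before quantization.  The bimodality is deliberate: stained TEM contrast
  is compartment-dominated, and it is what makes a parameter-free threshold
  (Otsu) recover the generating fraction.
* **Cohorts** — per-nucleus seeds spawned deterministically from one master
  seed (bit-exact reproducibility); nuisance jitter of ellipse axes (±10%)
  and orientation; and a small per-nucleus jitter of the heterochromatin
  fraction (sd 0.02) — without it the quantile construction would pin every
  nucleus to the target almost exactly, giving unrealistically small
  between-image standard errors.

Default two-group parameters target the measured ranges of colonic TEM
cohorts: heterochromatin fractions 0.30–0.55, run lengths ~140–310 nm,
D spanning the fractal → stretched-exponential transition (control
D = 2.5 with peripheral enrichment; case D = 3.5, larger l_c, enrichment
lost).

What the generator does **not** emulate: staining chemistry, sectioning,
patient-level clustering of nuclei, instrument drift, non-Gaussian density
statistics, or any physical mechanism for the loss of peripheral
heterochromatin (distance-biased thresholding is a surrogate for the
measured profile shape only).  Passing tests therefore validate the
*measurement chain*, not biological claims about real tissue.

## Identifiability of the shape parameter

A structural property of the procedure, established numerically and worth
knowing when reading fitted D values: once the curve is normalized at
r_min and truncated at 0.02, the decay length of a Whittle–Matérn curve
with l_c far below the field size sits well under the grid's lower bound
0.66·r_max (the analytic ratio l_c/r_max is ≈0.52 at D = 2.5, ≈0.30 at
D = 3.5, ≈0.20 at D = 5 as r_min → 0).  The grid then compensates with a
smaller D.  Recovery is accurate in the regime the analysis is designed
for — correlation length comparable to the analysis range, where finite-
field mean subtraction brings the curve to the cutoff early: on 512²
full-frame fields with l_c = 200 px, ten-seed mean fitted D is ≈2.5 for
D_true = 2.5 and ≈3.4 for D_true = 3.5.  For D_true = 5 the fitted value
saturates near 3.9 regardless of l_c: the Gaussian-like regime is not
identifiable under this normalization/truncation/grid combination, and
fitted D should be read as ordinal beyond ≈4.  On small masked elliptical
nuclei with compartment-dominated contrast (the demo cohort) absolute D is
additionally biased low, while group contrasts preserve the generating
difference and its significance.

## Problem sizes

Tests and the demo run at reduced scale chosen to exercise every code path
with comfortable statistics: demo cohorts of 12 + 12 nuclei at 256² px
(15 nm pixels), recovery experiments on ten 512² fields per condition,
null calibration over 50 replicates of 6 + 6 nuclei at 96² px.  All sizes
are parameters; the defaults of the generator itself are full TEM scale
(1024² at 7.8 nm pixels).
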