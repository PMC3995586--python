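# chromatex

Quantification of nanoscale chromatin organization in transmission electron
microscopy (TEM) images of cell nuclei, for researchers studying early
(microscopically undetectable) structural changes of the nucleus — e.g. in
the field of colorectal cancer.

Chromatin texture is measured at two levels of detail:

**Binary metrics.** Under OsO4 staining, dense heterochromatin is dark and
open euchromatin light, so a grey-level threshold (Otsu by default)
separates the two compartments.  From the binary map the package computes

* the **heterochromatin percentage** of nuclear area,
* the **run length** — the pooled mean length of maximal consecutive
  heterochromatin pixel runs along horizontal and vertical scan lines, a
  measure of clump size,
* the **peripheral profile** — the share of total heterochromatin in
  ribbons of equal distance from the nuclear envelope (and nucleolar
  surfaces), computed from an exact Euclidean distance transform.

**Grey-scale spatial correlation.** The fluctuation field
ρ<sub>Δ</sub> (grey levels minus the within-nucleus mean) is summarized by
its autocorrelation via the Wiener–Khinchine relation,

&nbsp;&nbsp;&nbsp;&nbsp;B<sub>ρ</sub>(x,y) = F⁻¹[ |F[ρ<sub>Δ</sub>]|² ],

estimated with a masked, pair-count-normalized FFT estimator so irregular
nucleus shapes do not bias the result.  After rotational averaging, the
curve B<sub>ρ</sub>(r) is normalized to 1 at r<sub>min</sub> (the optical
resolution) and truncated at r<sub>max</sub> where it decays to 0.02, then
fitted to the three-parameter Whittle–Matérn correlation family

&nbsp;&nbsp;&nbsp;&nbsp;B<sub>ρ</sub>(r) = A<sub>ρ</sub> (r/l<sub>c</sub>)<sup>(D−3)/2</sup> K<sub>(D−3)/2</sub>(r/l<sub>c</sub>)

by a grid search over D ∈ [2, 6] and l<sub>c</sub> ∈ [0.66·r<sub>max</sub>,
r<sub>max</sub>].  The shape parameter D classifies the correlation type:
power law (mass fractal) for D &lt; 3, stretched exponential for
3 &lt; D &lt; 4, pure exponential at D = 4, Gaussian-like beyond.

Because suitable TEM data are rarely shareable, the package includes a
**synthetic nucleus generator** (Gaussian random fields with prescribed
Whittle–Matérn correlation, elliptical nuclei, optional nucleoli,
quantile-thresholded binary textures with controllable area fraction and
peripheral enrichment) so the whole chain is testable against known ground
truth, plus Welch-based **two-group statistics** with per-length-scale
significance.

## Worked example

The demo analysis (`analysis/01_simulate_cohort.py` … `04_group_comparison.py`,
or equivalently `chromatex run --config configs/demo.yaml`) simulates
12 control + 12 case nuclei (256² px, 15 nm pixels, 30 nm resolution):
controls have fractal chromatin (D = 2.5), 34.2% heterochromatin in small
clumps and a peripheral heterochromatin border; cases have
stretched-exponential chromatin (D = 3.5), 42.9% heterochromatin in larger
clumps with the border lost.  Running the drivers prints:

```
        hetero_percent       run_length_nm
                  mean   sem          mean   sem
case             43.62  0.38        149.30  1.84
control          34.41  0.58         77.39  1.01

             D        r_squared
          mean    sem      mean    sem
case     2.804  0.033     0.980  0.002
control  2.117  0.042     0.992  0.002

ribbon significant ranges (nm): [(15.0, 315.0), (495.0, 1185.0)]
curve significant ranges (nm): [(37.5, 277.5)]
```

All four hallmark directions of early neoplastic transformation are
recovered from the images alone: heterochromatin percentage up
(34.4 → 43.6%, Welch p ≈ 5·10⁻¹¹), run length up (77 → 149 nm),
heterochromatin interiorized (the near-periphery ribbons, 15–315 nm,
differ significantly with control excess), and the correlation shape
parameter D up (2.12 → 2.80, p ≈ 3·10⁻¹¹).  Absolute fitted D on small
masked nuclei is biased low (see `docs/methods.md`), but the group contrast
mirrors the generating difference.  Tables and figures land in `results/`.

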