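"""Synthetic nucleus generator with known ground-truth texture parameters.

Real TEM micrographs of colonic nuclei are not redistributable at will, so
every downstream stage is exercised on synthetic nuclei whose texture
parameters are known exactly:

* the chromatin density field is a stationary Gaussian random field with a
  prescribed Whittle–Matérn spatial correlation (shape parameter D,
  correlation length l_c), produced by spectral synthesis;
* the nucleus is an ellipse (a few µm across at TEM pixel sizes), optionally
  with circular nucleoli;
* the binary heterochromatin texture is carved out of the density field by
  quantile thresholding, which pins the realized area fraction to the target
  almost exactly; a signed ``peripheral_bias`` tilts the threshold with
  distance from the boundary to emulate the peripheral heterochromatin
  border of normal nuclei (positive bias = peripheral enrichment);
* the grey image is an 8-bit rendering with bimodal compartment contrast
  (dark heterochromatin, light euchromatin, matching OsO4 staining
  polarity) plus a weaker continuous modulation by the density field,
  after Gaussian PSF blur to the stated optical resolution, with additive
  grey-level noise before quantization.

Defaults mirror the measured ranges of colonic TEM data: heterochromatin
fractions ~0.30–0.55, clump run lengths ~140–310 nm, D spanning the
fractal (D < 3) to stretched-exponential (3 < D < 4) transition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .binary import BinaryChromatinMap, distance_to_boundary
from .correlation import whittle_matern
from .io import Micrograph, NucleusMask, save_nucleus

__all__ = [
    "SyntheticNucleusSpec",
    "SyntheticNucleus",
    "wm_target",
    "synthesize_correlated_field",
    "make_nucleus_mask",
    "make_binary_texture",
    "synthesize_nucleus",
    "generate_cohort",
    "human_control_spec",
    "human_case_spec",
]


@dataclass(frozen=True)
class SyntheticNucleusSpec:
    """Ground-truth parameters of one synthetic nucleus.

    ``d_true`` and ``lc_true_nm`` are the Whittle–Matérn shape parameter and
    correlation length of the underlying density field;
    ``hetero_fraction_true`` the target heterochromatin area fraction;
    ``peripheral_bias`` ≥ 0 enriches heterochromatin toward the periphery
    (0 = spatially uniform); ``noise_sd`` is additive grey-level noise on
    the 0–255 scale.
    """

    image_size: int = 1024
    pixel_size_nm: float = 7.8
    ellipse_axes_nm: tuple[float, float] = (3000.0, 2200.0)
    nucleoli: tuple[tuple[tuple[float, float], float], ...] = ()
    d_true: float = 2.5
    lc_true_nm: float = 250.0
    hetero_fraction_true: float = 0.34
    peripheral_bias: float = 0.0
    noise_sd: float = 4.0
    resolution_nm: float = 39.0
    rotation_deg: float = 0.0
    seed: int = 0
    group: str = "control"

    def __post_init__(self) -> None:
        if not (2.0 < self.d_true <= 6.0):
            raise ValueError(f"d_true must lie in (2, 6], got {self.d_true}")
        if self.lc_true_nm <= 0:
            raise ValueError("lc_true_nm must be positive")
        if not (0.0 < self.hetero_fraction_true < 1.0):
            raise ValueError("hetero_fraction_true must lie in (0, 1)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        a, b = self.ellipse_axes_nm
        if a <= 0 or b <= 0:
            raise ValueError(f"degenerate ellipse axes {self.ellipse_axes_nm}")
        half_nm = self.image_size * self.pixel_size_nm / 2.0
        if max(a, b) > half_nm:
            raise ValueError(
                f"ellipse semi-axis {max(a, b)} nm exceeds image half-size {half_nm} nm"
            )
        for (cx, cy), radius in self.nucleoli:
            if radius <= 0:
                raise ValueError("nucleolus radius must be positive")
            # require the whole nucleolus disk inside the (unrotated) ellipse:
            # scaled center distance plus scaled radius below 1
            margin = radius / min(a, b)
            if np.hypot(cx / a, cy / b) + margin > 1.0:
                raise ValueError(f"nucleolus at ({cx}, {cy}) nm not inside the ellipse")


@dataclass
class SyntheticNucleus:
    """One generated nucleus: grey image, masks, and realized ground truth."""

    micrograph: Micrograph
    mask: NucleusMask
    spec: SyntheticNucleusSpec
    true_binary: BinaryChromatinMap
    realized_fraction: float
    field: np.ndarray = dataclasses.field(repr=False, default=None)

    @property
    def truth(self) -> dict:
        return {
            "d_true": self.spec.d_true,
            "lc_true_nm": self.spec.lc_true_nm,
            "hetero_fraction_true": self.spec.hetero_fraction_true,
            "peripheral_bias": self.spec.peripheral_bias,
            "realized_fraction": self.realized_fraction,
        }


def wm_target(
    d: float, lc_px: float, r_floor_px: float = 0.5
) -> Callable[[np.ndarray], np.ndarray]:
    """Isotropic correlation target: Whittle–Matérn in pixel units,
    normalized to 1 at lag 0.

    For D ≤ 3 the family diverges at r → 0, so radii are floored at
    ``r_floor_px`` (half a pixel by default) — physically, structure below
    the pixel is unobservable anyway.
    """
    b0 = float(whittle_matern(np.array([r_floor_px]), d, lc_px)[0])

    def target(r: np.ndarray) -> np.ndarray:
        r = np.maximum(np.asarray(r, dtype=np.float64), r_floor_px)
        return whittle_matern(r, d, lc_px) / b0

    return target


def synthesize_correlated_field(
    size: int,
    target_curve: Callable[[np.ndarray], np.ndarray],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Stationary Gaussian field with a prescribed isotropic correlation.

    Spectral synthesis: the 2-D correlation image built from the radial
    target (with periodic wrapped distances) is Fourier-transformed to a
    power spectrum; truncation-induced negative spectral values are clipped
    to zero; complex white noise is filtered by the spectrum's square root
    and inverse-transformed.  The real part is restandardized to zero mean
    and unit variance, so the empirical rotationally averaged
    autocorrelation converges to the target as ``size`` grows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.arange(size)
    wrapped = np.minimum(idx, size - idx)  # periodic lag distance
    r = np.hypot(wrapped[:, None], wrapped[None, :])
    corr = np.asarray(target_curve(r), dtype=np.float64)
    if not np.all(np.isfinite(corr)):
        raise ValueError("target correlation produced non-finite values")

    spectrum = sfft.fft2(corr).real
    np.clip(spectrum, 0.0, None, out=spectrum)
    if not spectrum.any():
        raise ValueError("all-zero power spectrum: target correlation is degenerate")

    white = rng.standard_normal((size, size))
    field = sfft.ifft2(np.sqrt(spectrum) * sfft.fft2(white)).real
    sd = field.std()
    if sd == 0:
        raise ValueError("degenerate synthesized field (zero variance)")
    return (field - field.mean()) / sd


def make_nucleus_mask(spec: SyntheticNucleusSpec) -> NucleusMask:
    """Filled-ellipse nucleus mask plus disk nucleolus submasks.

    Pixel membership is decided by the pixel center lying inside the
    (optionally rotated) ellipse.  Nucleoli are returned as separate
    submasks, not holes.
    """
    n = spec.image_size
    # pixel-center coordinates in nm relative to the image center
    coords = (np.arange(n) + 0.5 - n / 2.0) * spec.pixel_size_nm
    y, x = np.meshgrid(coords, coords, indexing="ij")
    theta = np.deg2rad(spec.rotation_deg)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    a, b = spec.ellipse_axes_nm
    nucleus = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    nucleoli = []
    for (cx, cy), radius in spec.nucleoli:
        # nucleolus centers are specified in the ellipse frame
        nucleoli.append((xr - cx) ** 2 + (yr - cy) ** 2 <= radius**2)
    return NucleusMask(nucleus=nucleus, nucleoli=nucleoli)


def make_binary_texture(
    mask: NucleusMask,
    field: np.ndarray,
    fraction: float,
    peripheral_bias: float,
    distances_nm: np.ndarray,
) -> BinaryChromatinMap:
    """Carve a binary heterochromatin texture with an exact area fraction.

    The density field is thresholded at its within-mask quantile so exactly
    ``fraction`` of analyzable pixels are heterochromatin (up to grey-value
    ties).  A nonzero ``peripheral_bias`` subtracts bias·(distance to
    boundary, normalized to [0, 1]) from the field before thresholding, and
    the quantile is re-solved on the biased field, so peripheral enrichment
    never changes the global fraction.  Clump size is controlled upstream by
    the field's correlation length.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    valid = mask.valid
    if field.shape != valid.shape:
        raise ValueError("field and mask dimensions differ")

    score = np.asarray(field, dtype=np.float64)
    if peripheral_bias != 0.0:
        d = np.where(valid, distances_nm, 0.0)
        dmax = d[valid].max()
        if dmax > 0:
            score = score - peripheral_bias * (d / dmax)
    thr = float(np.quantile(score[valid], 1.0 - fraction))
    hetero = valid & (score >= thr)
    return BinaryChromatinMap(
        hetero=hetero, valid=valid, threshold_used=thr, method="synthetic-quantile"
    )


def synthesize_nucleus(spec: SyntheticNucleusSpec, id: str = "nucleus") -> SyntheticNucleus:
    """Generate one nucleus end-to-end from its spec.

    The density field is blurred with a Gaussian PSF to the stated optical
    resolution (FWHM) when that exceeds the pixel size; the binary ground
    truth is carved from the blurred field (what a measurement could see);
    the grey image renders the field to 8-bit (dark = dense) with additive
    noise before quantization.
    """
    rng = np.random.default_rng(spec.seed)
    mask = make_nucleus_mask(spec)

    lc_px = spec.lc_true_nm / spec.pixel_size_nm
    target = wm_target(spec.d_true, lc_px)
    field = synthesize_correlated_field(spec.image_size, target, rng)

    if spec.resolution_nm > spec.pixel_size_nm * 1.001:
        sigma_px = (spec.resolution_nm / spec.pixel_size_nm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        field = ndimage.gaussian_filter(field, sigma_px, mode="wrap")
        field = (field - field.mean()) / field.std()

    distances = distance_to_boundary(mask, spec.pixel_size_nm)
    binary = make_binary_texture(
        mask, field, spec.hetero_fraction_true, spec.peripheral_bias, distances
    )
    realized = float(binary.hetero.sum()) / float(mask.valid.sum())

    # 8-bit rendering, dark = dense: a bimodal compartment contrast (heavily
    # stained heterochromatin vs lightly stained euchromatin) plus a weaker
    # continuous modulation by the density field within each compartment
    grey = 168.0 - 62.0 * binary.hetero - 9.0 * field
    grey[~mask.nucleus] = 230.0
    grey = grey + rng.normal(0.0, spec.noise_sd, grey.shape)
    grey = np.clip(np.rint(grey), 0, 255).astype(np.uint8)

    micro = Micrograph(
        pixels=grey,
        pixel_size_nm=spec.pixel_size_nm,
        resolution_nm=spec.resolution_nm,
        id=id,
        group=spec.group,
    )
    return SyntheticNucleus(
        micrograph=micro,
        mask=mask,
        spec=spec,
        true_binary=binary,
        realized_fraction=realized,
        field=field,
    )


def generate_cohort(
    n_control: int,
    n_case: int,
    control_spec: SyntheticNucleusSpec,
    case_spec: SyntheticNucleusSpec,
    seed: int,
    jitter: float = 0.1,
    fraction_jitter_sd: float = 0.02,
    out_dir: str | Path | None = None,
) -> list[SyntheticNucleus]:
    """Generate a two-group cohort with per-nucleus nuisance jitter.

    Per-nucleus seeds are derived deterministically from the master seed
    (``numpy`` SeedSequence spawning), so a fixed master seed reproduces the
    cohort bit-exactly.  Ellipse axes are jittered by ±``jitter`` (relative)
    and orientation uniformly, emulating section-to-section variability; the
    per-nucleus heterochromatin fraction is jittered by a Gaussian of sd
    ``fraction_jitter_sd`` so between-image variance resembles real cohorts
    (the quantile construction would otherwise pin every nucleus to the
    target fraction almost exactly).  With ``out_dir`` set, images, masks
    and truth sidecars are persisted.
    """
    if n_control < 1 or n_case < 1:
        raise ValueError("need at least one nucleus per group")
    seed_seq = np.random.SeedSequence(int(seed))
    children = seed_seq.spawn(n_control + n_case)

    nuclei: list[SyntheticNucleus] = []
    plan = [("control", control_spec)] * n_control + [("case", case_spec)] * n_case
    for i, ((group, base), child) in enumerate(zip(plan, children)):
        child_rng = np.random.default_rng(child)
        nucleus_seed = int(child_rng.integers(0, 2**31 - 1))
        a, b = base.ellipse_axes_nm
        scale_a = 1.0 + jitter * (2.0 * child_rng.random() - 1.0)
        scale_b = 1.0 + jitter * (2.0 * child_rng.random() - 1.0)
        frac = base.hetero_fraction_true
        if fraction_jitter_sd > 0:
            frac = float(np.clip(child_rng.normal(frac, fraction_jitter_sd), 0.05, 0.95))
        spec = dataclasses.replace(
            base,
            ellipse_axes_nm=(a * scale_a, b * scale_b),
            hetero_fraction_true=frac,
            rotation_deg=float(child_rng.uniform(0.0, 180.0)),
            seed=nucleus_seed,
            group=group,
        )
        nid = f"{group}_{i:03d}"
        nuc = synthesize_nucleus(spec, id=nid)
        nuclei.append(nuc)
        if out_dir is not None:
            save_nucleus(nuc.micrograph, nuc.mask, out_dir, truth=nuc.truth)
    return nuclei


def human_control_spec(**overrides) -> SyntheticNucleusSpec:
    """Human-like control nucleus: fractal chromatin (D = 2.5), ~34%
    heterochromatin, peripheral enrichment, 7.8 nm pixels, 39 nm resolution."""
    spec = dict(
        image_size=1024,
        pixel_size_nm=7.8,
        ellipse_axes_nm=(3000.0, 2200.0),
        d_true=2.5,
        lc_true_nm=250.0,
        hetero_fraction_true=0.342,
        peripheral_bias=1.5,
        resolution_nm=39.0,
    )
    spec.update(overrides)
    return SyntheticNucleusSpec(group="control", **spec)


def human_case_spec(**overrides) -> SyntheticNucleusSpec:
    """Human-like pre-neoplastic nucleus: stretched-exponential chromatin
    (D = 3.5), ~43% heterochromatin, larger clumps, peripheral border lost."""
    spec = dict(
        image_size=1024,
        pixel_size_nm=7.8,
        ellipse_axes_nm=(3000.0, 2200.0),
        d_true=3.5,
        lc_true_nm=330.0,
        hetero_fraction_true=0.429,
        peripheral_bias=0.0,
        resolution_nm=39.0,
    )
    spec.update(overrides)
    return SyntheticNucleusSpec(group="case", **spec)
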