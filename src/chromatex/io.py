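"""Reading and writing micrographs, masks, calibration sidecars and result tables.

A nucleus on disk is three things: a grey-scale image (TIFF or PNG), a binary
nucleus mask of identical shape, and a JSON sidecar holding the physical
calibration (pixel size in nm, optical resolution in nm as the PSF FWHM) and
the group label.  Nucleoli are separate binary mask files listed in the
sidecar; keeping every mask strictly binary makes them auditable.  Calibration
deliberately lives in the sidecar rather than in TIFF tags, whose conventions
vary by microscope vendor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: column order of the per-nucleus results table
RESULT_COLUMNS = [
    "id",
    "group",
    "hetero_percent",
    "run_length_nm",
    "D",
    "lc_nm",
    "r_squared",
    "correlation_class",
]


@dataclass
class Micrograph:
    """A single-nucleus grey-scale TEM image with physical calibration.

    Parameters
    ----------
    pixels
        2-D grey values (staining density, arbitrary units).  Dark means
        dense under OsO4 staining.
    pixel_size_nm
        Physical edge length of one pixel, nm.
    resolution_nm
        Optical resolution as PSF full-width half-maximum, nm.  Never below
        the pixel size.
    id, group
        Identifier and cohort label (e.g. ``"control"`` / ``"case"``).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    resolution_nm: float
    id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")
        if self.resolution_nm < self.pixel_size_nm:
            raise ValueError(
                "resolution_nm must be at least pixel_size_nm "
                f"({self.resolution_nm} < {self.pixel_size_nm})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NucleusMask:
    """Boolean nucleus region plus optional nucleolus subregions.

    ``nucleus`` marks every pixel inside the nuclear envelope; each entry of
    ``nucleoli`` marks one nucleolus and must lie entirely inside the nucleus.
    Analyses exclude nucleolus interiors (they serve ribosomal RNA assembly,
    not the chromatin compartmentation being quantified) but treat their
    surfaces as boundary, like the nuclear envelope.
    """

    nucleus: np.ndarray
    nucleoli: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        if self.nucleus.ndim != 2:
            raise ValueError("nucleus mask must be 2-D")
        if not self.nucleus.any():
            raise ValueError("nucleus mask is empty")
        self.nucleoli = [np.asarray(n, dtype=bool) for n in self.nucleoli]
        for i, n in enumerate(self.nucleoli):
            if n.shape != self.nucleus.shape:
                raise ValueError(f"nucleolus mask {i} shape {n.shape} != nucleus {self.nucleus.shape}")
            if np.any(n & ~self.nucleus):
                raise ValueError(f"nucleolus mask {i} extends outside the nucleus")

    @property
    def valid(self) -> np.ndarray:
        """Analyzable pixels: nucleus minus all nucleolus interiors."""
        v = self.nucleus.copy()
        for n in self.nucleoli:
            v &= ~n
        return v


def _read_image(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def load_nucleus(
    image_path: str | Path,
    mask_path: str | Path,
    sidecar_path: str | Path,
) -> tuple[Micrograph, NucleusMask]:
    """Load one nucleus: image + mask + JSON calibration sidecar.

    Grey values are read exactly as stored (no rescaling).  A missing
    ``resolution_nm`` in the sidecar falls back to the pixel size with a
    logged warning — appropriate for well-focused acquisitions where the PSF
    is not characterized.
    """
    pixels = _read_image(Path(image_path))
    if pixels.ndim == 3:  # greyscale stored with a trailing channel axis
        pixels = pixels[..., 0]
    mask_arr = _read_image(Path(mask_path)) > 0

    with open(sidecar_path) as fh:
        meta = json.load(fh)

    pixel_size = float(meta["pixel_size_nm"])
    if pixel_size <= 0:
        raise ValueError(f"non-positive pixel_size_nm in sidecar: {pixel_size}")
    resolution = meta.get("resolution_nm")
    if resolution is None:
        logger.warning(
            "sidecar %s has no resolution_nm; defaulting to pixel size %.3g nm",
            sidecar_path,
            pixel_size,
        )
        resolution = pixel_size
    resolution = float(resolution)

    if mask_arr.shape != pixels.shape:
        raise ValueError(f"mask shape {mask_arr.shape} does not match image shape {pixels.shape}")

    nucleoli = []
    base = Path(sidecar_path).parent
    for rel in meta.get("nucleolus_masks", []):
        n = _read_image(base / rel) > 0
        if n.shape != pixels.shape:
            raise ValueError(f"nucleolus mask {rel} shape mismatch")
        nucleoli.append(n)

    micro = Micrograph(
        pixels=pixels,
        pixel_size_nm=pixel_size,
        resolution_nm=resolution,
        id=str(meta.get("id", Path(image_path).stem)),
        group=str(meta.get("group", "")),
    )
    return micro, NucleusMask(nucleus=mask_arr, nucleoli=nucleoli)


def save_nucleus(
    micrograph: Micrograph,
    mask: NucleusMask,
    out_dir: str | Path,
    truth: dict | None = None,
    image_format: str = "tiff",
) -> dict[str, Path]:
    """Write image, masks and sidecar for one nucleus; returns written paths.

    The sidecar records calibration, group, nucleolus-mask filenames and —
    for synthetic nuclei — the ground-truth generation parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nid = micrograph.id or "nucleus"
    ext = ".tif" if image_format in ("tif", "tiff") else ".png"

    img_path = out_dir / f"{nid}{ext}"
    mask_path = out_dir / f"{nid}_mask{ext}"
    pix = micrograph.pixels
    if pix.dtype.kind == "f":
        pix = pix.astype(np.float32)
    if ext == ".tif":
        tifffile.imwrite(img_path, pix)
        tifffile.imwrite(mask_path, mask.nucleus.astype(np.uint8) * 255)
    else:
        iio.imwrite(img_path, np.asarray(pix, dtype=np.uint8))
        iio.imwrite(mask_path, mask.nucleus.astype(np.uint8) * 255)

    nucleolus_files = []
    for k, n in enumerate(mask.nucleoli):
        npath = out_dir / f"{nid}_nucleolus{k}{ext}"
        if ext == ".tif":
            tifffile.imwrite(npath, n.astype(np.uint8) * 255)
        else:
            iio.imwrite(npath, n.astype(np.uint8) * 255)
        nucleolus_files.append(npath.name)

    sidecar = {
        "id": nid,
        "group": micrograph.group,
        "pixel_size_nm": micrograph.pixel_size_nm,
        "resolution_nm": micrograph.resolution_nm,
        "nucleolus_masks": nucleolus_files,
    }
    if truth is not None:
        sidecar["truth"] = truth
    sidecar_path = out_dir / f"{nid}.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)

    return {"image": img_path, "mask": mask_path, "sidecar": sidecar_path}


def write_results(records: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-nucleus metrics table as CSV (one row per nucleus).

    An empty record list produces a header-only file.  Floats are written at
    full precision so a round-trip read reproduces them to at least 12
    significant digits.
    """
    if len(records) == 0:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    else:
        df = pd.DataFrame(list(records))
        lead = [c for c in RESULT_COLUMNS if c in df.columns]
        rest = [c for c in df.columns if c not in lead]
        df = df[lead + rest]
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def write_long_profiles(profiles: Sequence[dict], path: str | Path) -> pd.DataFrame:
    """Write per-nucleus profiles (ribbon shares or correlation curves) in
    long format: one row per (nucleus, x) sample."""
    rows = []
    for p in profiles:
        nid, group = p["id"], p.get("group", "")
        for x, y in zip(p["x"], p["y"]):
            rows.append({"id": nid, "group": group, p["x_name"]: x, p["y_name"]: y})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")
    return df
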