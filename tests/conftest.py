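"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from chromatex.correlation import FluctuationField


def direct_autocorrelation(values: np.ndarray, valid: np.ndarray):
    """O(N^2) direct pair summation over all in-mask pixel pairs.

    Independent oracle for the FFT-based masked estimator: for each lag
    (dy, dx) sums values[p]·values[p+lag] over pairs with both pixels in the
    mask, and divides by the pair count.
    """
    n0, n1 = values.shape
    dys = np.arange(-(n0 - 1), n0)
    dxs = np.arange(-(n1 - 1), n1)
    B = np.full((dys.size, dxs.size), np.nan)
    counts = np.zeros((dys.size, dxs.size), dtype=int)
    for i, dy in enumerate(dys):
        for j, dx in enumerate(dxs):
            s = 0.0
            c = 0
            for y in range(n0):
                y2 = y + dy
                if not (0 <= y2 < n0):
                    continue
                for x in range(n1):
                    x2 = x + dx
                    if 0 <= x2 < n1 and valid[y, x] and valid[y2, x2]:
                        s += values[y, x] * values[y2, x2]
                        c += 1
            counts[i, j] = c
            if c:
                B[i, j] = s / c
    return B, counts


def brute_force_boundary_distance(valid: np.ndarray, pixel_size_nm: float) -> np.ndarray:
    """Nearest-boundary distance by exhaustive scan over all non-valid pixel
    centers (image padded by one background ring, so edges count)."""
    padded = np.pad(valid, 1, constant_values=False)
    bg = np.argwhere(~padded)  # background pixel centers, padded coords
    out = np.full(valid.shape, np.nan)
    for y, x in np.argwhere(valid):
        d2 = (bg[:, 0] - (y + 1)) ** 2 + (bg[:, 1] - (x + 1)) ** 2
        out[y, x] = np.sqrt(d2.min()) * pixel_size_nm
    return out


def enumerate_runs(hetero: np.ndarray) -> list[int]:
    """All maximal horizontal+vertical consecutive-True runs, by plain
    python scanning (oracle for the vectorized implementation)."""
    runs = []
    for arr in (hetero, hetero.T):
        for row in arr:
            length = 0
            for v in list(row) + [False]:
                if v:
                    length += 1
                elif length:
                    runs.append(length)
                    length = 0
    return runs


@pytest.fixture
def toy_map():
    """The 4x4 worked example: 8 hetero pixels, pooled mean run 16/11 px."""
    return np.array(
        [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 1, 1]], dtype=bool
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def masked_fluctuation(values: np.ndarray, valid: np.ndarray) -> FluctuationField:
    mu = values[valid].mean()
    return FluctuationField(values=np.where(valid, values - mu, 0.0), valid=valid)
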