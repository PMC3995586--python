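"""Two-group comparisons of per-nucleus chromatin metrics.

The statistical unit is the nucleus image (standard errors are between
images).  Scalar metrics (heterochromatin %, run length, fitted D) are
compared with Welch's two-sample t-test by default — robust to the unequal
group sizes typical of micrograph cohorts — with Mann–Whitney as a
distribution-free alternative.  Profile metrics (ribbon shares, normalized
correlation curves) are compared pointwise at each length scale; by default
no multiple-testing correction is applied across length scales (each scale
is reported at its own p < alpha), with Benjamini–Hochberg available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = ["GroupComparison", "ProfileComparison", "compare_scalar", "compare_profiles"]


@dataclass
class GroupComparison:
    """Group means, between-image standard errors and a two-sided p-value."""

    metric: str
    mean_control: float
    mean_case: float
    se_control: float
    se_case: float
    p_value: float
    n_control: int
    n_case: int
    test: str = "welch"

    @property
    def difference(self) -> float:
        return self.mean_case - self.mean_control


@dataclass
class ProfileComparison:
    """Pointwise group comparison along a length-scale axis.

    ``significant_ranges`` lists maximal contiguous x-intervals where
    p < alpha (the shaded bands of a profile figure).
    """

    x: np.ndarray
    comparisons: list[GroupComparison]
    alpha: float
    significant_ranges: list[tuple[float, float]] = field(default_factory=list)

    @property
    def p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.comparisons])


def compare_scalar(
    control: Sequence[float],
    case: Sequence[float],
    test: str = "welch",
    metric: str = "",
) -> GroupComparison:
    """Compare one scalar metric between groups.

    ``test`` is ``"welch"`` (default) or ``"mannwhitney"``.  Degenerate
    zero-variance inputs are handled explicitly: equal constant groups give
    p = 1, distinct constant groups p = 0.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    control = control[np.isfinite(control)]
    case = case[np.isfinite(case)]
    if control.size < 2 or case.size < 2:
        raise ValueError("need at least 2 finite values per group")

    if control.std(ddof=1) == 0 and case.std(ddof=1) == 0:
        p = 1.0 if control.mean() == case.mean() else 0.0
    elif test == "welch":
        p = float(sstats.ttest_ind(control, case, equal_var=False).pvalue)
    elif test == "mannwhitney":
        p = float(sstats.mannwhitneyu(control, case, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        metric=metric,
        mean_control=float(control.mean()),
        mean_case=float(case.mean()),
        se_control=float(control.std(ddof=1) / np.sqrt(control.size)),
        se_case=float(case.std(ddof=1) / np.sqrt(case.size)),
        p_value=p,
        n_control=int(control.size),
        n_case=int(case.size),
        test=test,
    )


def _resample(profiles: Sequence[tuple[np.ndarray, np.ndarray]], x: np.ndarray) -> np.ndarray:
    rows = []
    for px, py in profiles:
        px = np.asarray(px, float)
        py = np.asarray(py, float)
        rows.append(np.interp(x, px, py))
    return np.vstack(rows)


def compare_profiles(
    control: Sequence[tuple[np.ndarray, np.ndarray]],
    case: Sequence[tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    test: str = "welch",
    adjust: str | None = None,
    metric: str = "",
) -> ProfileComparison:
    """Pointwise two-group comparison of per-nucleus profiles.

    Each profile is an ``(x, y)`` pair; profiles are resampled by linear
    interpolation onto the common grid of the overlapping x-range (the grid
    of the first control profile, restricted to the overlap).  ``adjust``
    may be ``"bh"`` for Benjamini–Hochberg across length scales.
    """
    if len(control) == 0 or len(case) == 0:
        raise ValueError("both groups must be non-empty")
    lo = max(np.min(np.asarray(p[0], float)) for p in list(control) + list(case))
    hi = min(np.max(np.asarray(p[0], float)) for p in list(control) + list(case))
    if lo > hi:
        raise ValueError("profiles have disjoint x ranges")
    base_x = np.asarray(control[0][0], dtype=float)
    x = base_x[(base_x >= lo) & (base_x <= hi)]
    if x.size == 0:
        x = np.array([lo, hi]) if hi > lo else np.array([lo])

    ctrl = _resample(control, x)
    cs = _resample(case, x)

    comparisons = [
        compare_scalar(ctrl[:, j], cs[:, j], test=test, metric=f"{metric}@{x[j]:g}")
        for j in range(x.size)
    ]
    p = np.array([c.p_value for c in comparisons])
    if adjust == "bh":
        p = sstats.false_discovery_control(p, method="bh")
        for c, pj in zip(comparisons, p):
            c.p_value = float(pj)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    sig = p < alpha
    ranges: list[tuple[float, float]] = []
    j = 0
    while j < sig.size:
        if sig[j]:
            k = j
            while k + 1 < sig.size and sig[k + 1]:
                k += 1
            ranges.append((float(x[j]), float(x[k])))
            j = k + 1
        else:
            j += 1

    return ProfileComparison(x=x, comparisons=comparisons, alpha=alpha, significant_ranges=ranges)
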