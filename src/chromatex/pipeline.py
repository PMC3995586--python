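"""End-to-end cohort pipeline: simulate/load → binarize → metrics → fit → stats.

One YAML/JSON config drives the whole analysis.  Outputs mirror the figures
a chromatin-texture study reports: per-nucleus metric table, group
comparison table with per-length-scale significance, ribbon-profile and
correlation-curve long tables, a JSON summary, and optional figures
(heterochromatin % and run-length bars, peripheral profile with shaded
significant ranges, group-mean correlation curves, D boxplots).

Example config::

    seed: 1
    output_dir: results/demo
    simulate:
      n_control: 12
      n_case: 12
      image_size: 256
      pixel_size_nm: 20.0
      resolution_nm: 40.0
      control: {d_true: 2.5, lc_true_nm: 260, hetero_fraction_true: 0.342,
                peripheral_bias: 0.8}
      case:    {d_true: 3.5, lc_true_nm: 330, hetero_fraction_true: 0.429,
                peripheral_bias: 0.0}
    analysis:
      threshold: otsu
      ribbon_width_nm: 37.5
      cutoff: 0.02
      d_step: 0.05
      alpha: 0.05
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binary, correlation, stats, synthetic
from .io import Micrograph, NucleusMask, load_nucleus, write_results

logger = logging.getLogger(__name__)

__all__ = ["analyze_nucleus", "run_pipeline", "load_config"]


def analyze_nucleus(
    micrograph: Micrograph,
    mask: NucleusMask,
    threshold: str = "otsu",
    quantile: float | None = None,
    manual_threshold: float | None = None,
    ribbon_width_nm: float | None = None,
    cutoff: float = correlation.DEFAULT_CUTOFF,
    d_step: float = correlation.DEFAULT_D_STEP,
    n_lc: int = correlation.DEFAULT_N_LC,
    min_pair_count: int = correlation.DEFAULT_MIN_PAIR_COUNT,
) -> dict:
    """All per-nucleus metrics as one record.

    Returns the scalar record plus the peripheral profile and normalized
    correlation curve under ``"profile"`` and ``"curve"`` keys.  A curve
    that never decays to the cutoff marks the nucleus ``skipped`` for the
    correlation part; binary metrics are still reported.
    """
    bmap = binary.binarize_chromatin(
        micrograph, mask, method=threshold, quantile=quantile, manual_threshold=manual_threshold
    )
    pct = binary.heterochromatin_percentage(bmap)
    runs = binary.run_length(bmap, micrograph.pixel_size_nm, nucleolus_masks=mask.nucleoli)
    distances = binary.distance_to_boundary(mask, micrograph.pixel_size_nm)
    width = ribbon_width_nm or binary.default_ribbon_width_nm(micrograph.pixel_size_nm)
    profile = binary.peripheral_profile(bmap, distances, width)

    record = {
        "id": micrograph.id,
        "group": micrograph.group,
        "hetero_percent": pct,
        "run_length_nm": runs.mean_run_nm,
        "run_length_px": runs.mean_run_px,
        "n_runs": runs.n_runs,
        "threshold_used": bmap.threshold_used,
    }
    try:
        curve, fit = correlation.analyze_correlation(
            micrograph,
            mask,
            cutoff=cutoff,
            min_pair_count=min_pair_count,
            d_step=d_step,
            n_lc=n_lc,
        )
        record.update(
            D=fit.D,
            lc_nm=fit.lc_nm,
            A_rho=fit.A_rho,
            r_squared=fit.r_squared,
            correlation_class=fit.correlation_class,
            r_min_nm=curve.r_min_nm,
            r_max_nm=curve.r_max_nm,
            skipped=False,
        )
    except correlation.CurveTruncationError as exc:
        logger.warning("nucleus %s skipped for correlation analysis: %s", micrograph.id, exc)
        record.update(
            D=np.nan,
            lc_nm=np.nan,
            A_rho=np.nan,
            r_squared=np.nan,
            correlation_class="",
            r_min_nm=np.nan,
            r_max_nm=np.nan,
            skipped=True,
        )
        curve = None
    record["profile"] = profile
    record["curve"] = curve
    return record


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def _cohort_from_config(cfg: dict, seed: int) -> list:
    sim = cfg["simulate"]
    shared = {
        k: sim[k]
        for k in ("image_size", "pixel_size_nm", "resolution_nm", "noise_sd", "ellipse_axes_nm")
        if k in sim
    }
    if "ellipse_axes_nm" in shared:
        shared["ellipse_axes_nm"] = tuple(shared["ellipse_axes_nm"])
    control = synthetic.human_control_spec(**shared, **sim.get("control", {}))
    case = synthetic.human_case_spec(**shared, **sim.get("case", {}))
    return synthetic.generate_cohort(
        n_control=int(sim["n_control"]),
        n_case=int(sim["n_case"]),
        control_spec=control,
        case_spec=case,
        seed=seed,
        jitter=float(sim.get("jitter", 0.1)),
        fraction_jitter_sd=float(sim.get("fraction_jitter_sd", 0.02)),
        out_dir=sim.get("persist_dir"),
    )


def _load_cohort(input_dir: str | Path) -> list[tuple[Micrograph, NucleusMask]]:
    input_dir = Path(input_dir)
    pairs = []
    for sidecar in sorted(input_dir.glob("*.json")):
        nid = sidecar.stem
        img = next((p for p in (sidecar.with_suffix(".tif"), sidecar.with_suffix(".png")) if p.exists()), None)
        if img is None:
            continue
        mask = img.with_name(f"{nid}_mask{img.suffix}")
        pairs.append(load_nucleus(img, mask, sidecar))
    if not pairs:
        raise ValueError(f"no nuclei found in {input_dir}")
    return pairs


def run_pipeline(config: dict | str | Path, seed: int | None = None) -> dict:
    """Run the full analysis from a config; returns the summary dict.

    Writes into ``output_dir``: ``per_nucleus.csv``, ``comparisons.csv``,
    ``ribbon_profiles.csv``, ``correlation_curves.csv``, ``summary.json``
    and (unless ``figures: false``) PNG figures.  Raises if the fraction of
    nuclei skipped by the correlation stage exceeds ``max_skip_fraction``
    (default 0.5).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out_dir = Path(config.get("output_dir", "results/pipeline"))
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = dict(config.get("analysis", {}))
    alpha = float(analysis.pop("alpha", 0.05))
    test = analysis.pop("test", "welch")
    adjust = analysis.pop("adjust", None)
    max_skip = float(config.get("max_skip_fraction", 0.5))

    if "simulate" in config:
        cohort = _cohort_from_config(config, seed)
        units = [(n.micrograph, n.mask) for n in cohort]
    elif "input_dir" in config:
        units = _load_cohort(config["input_dir"])
    else:
        raise ValueError("config needs a 'simulate' block or an 'input_dir'")

    records = [analyze_nucleus(m, mk, **analysis) for m, mk in units]
    n_skipped = sum(r["skipped"] for r in records)
    if n_skipped / len(records) > max_skip:
        raise RuntimeError(
            f"{n_skipped}/{len(records)} nuclei skipped by the correlation stage "
            f"(limit {max_skip:.0%})"
        )

    profiles = [r.pop("profile") for r in records]
    curves = [r.pop("curve") for r in records]
    write_results(records, out_dir / "per_nucleus.csv")

    prof_rows = []
    for r, p in zip(records, profiles):
        for d, s, a_n in zip(p.distances_nm, p.hetero_share_percent, p.area_normalized):
            prof_rows.append(
                {"id": r["id"], "group": r["group"], "distance_nm": d,
                 "hetero_share_percent": s, "area_normalized": a_n}
            )
    pd.DataFrame(prof_rows).to_csv(out_dir / "ribbon_profiles.csv", index=False,
                                   float_format="%.17g")

    curve_rows = []
    for r, c in zip(records, curves):
        if c is None:
            continue
        for rr, bb in zip(c.r_nm, c.B):
            curve_rows.append({"id": r["id"], "group": r["group"], "r_nm": rr, "B": bb})
    pd.DataFrame(curve_rows).to_csv(out_dir / "correlation_curves.csv", index=False,
                                    float_format="%.17g")

    df = pd.DataFrame(records)
    is_ctrl = df["group"] == "control"
    scalar_comparisons = {}
    for metric in ("hetero_percent", "run_length_nm", "D"):
        vals_c = df.loc[is_ctrl, metric].to_numpy()
        vals_x = df.loc[~is_ctrl, metric].to_numpy()
        scalar_comparisons[metric] = stats.compare_scalar(vals_c, vals_x, test=test, metric=metric)

    def _profile_pairs(sel):
        return [
            (p.distances_nm, p.hetero_share_percent)
            for p, keep in zip(profiles, sel)
            if keep
        ]

    ribbon_cmp = stats.compare_profiles(
        _profile_pairs(is_ctrl.to_numpy()), _profile_pairs((~is_ctrl).to_numpy()),
        alpha=alpha, test=test, adjust=adjust, metric="ribbon_share",
    )

    curve_pairs_c = [(c.r_nm, c.B) for c, keep in zip(curves, is_ctrl) if keep and c is not None]
    curve_pairs_x = [(c.r_nm, c.B) for c, keep in zip(curves, ~is_ctrl) if keep and c is not None]
    curve_cmp = None
    if len(curve_pairs_c) >= 2 and len(curve_pairs_x) >= 2:
        curve_cmp = stats.compare_profiles(
            curve_pairs_c, curve_pairs_x, alpha=alpha, test=test, adjust=adjust, metric="B",
        )

    cmp_rows = [dataclasses.asdict(c) for c in scalar_comparisons.values()]
    cmp_rows += [dataclasses.asdict(c) for c in ribbon_cmp.comparisons]
    if curve_cmp is not None:
        cmp_rows += [dataclasses.asdict(c) for c in curve_cmp.comparisons]
    pd.DataFrame(cmp_rows).to_csv(out_dir / "comparisons.csv", index=False,
                                  float_format="%.17g")

    summary = {
        "seed": seed,
        "n_control": int(is_ctrl.sum()),
        "n_case": int((~is_ctrl).sum()),
        "n_skipped": int(n_skipped),
        "scalar": {
            m: {
                "mean_control": c.mean_control,
                "mean_case": c.mean_case,
                "se_control": c.se_control,
                "se_case": c.se_case,
                "p_value": c.p_value,
            }
            for m, c in scalar_comparisons.items()
        },
        "ribbon_significant_ranges_nm": ribbon_cmp.significant_ranges,
        "curve_significant_ranges_nm": (curve_cmp.significant_ranges if curve_cmp else None),
        "parameters": {"alpha": alpha, "test": test, "adjust": adjust, **analysis},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)

    if config.get("figures", True):
        _write_figures(out_dir, df, profiles, curves, ribbon_cmp, curve_cmp, alpha)
    return summary


def _write_figures(out_dir, df, profiles, curves, ribbon_cmp, curve_cmp, alpha):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    is_ctrl = (df["group"] == "control").to_numpy()

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, metric, label in zip(
        axes, ("hetero_percent", "run_length_nm", "D"),
        ("heterochromatin (%)", "run length (nm)", "shape parameter D"),
    ):
        if metric == "D":
            data = [df.loc[is_ctrl, "D"].dropna(), df.loc[~is_ctrl, "D"].dropna()]
            ax.boxplot(data, tick_labels=["control", "case"])
        else:
            for i, sel in enumerate((is_ctrl, ~is_ctrl)):
                v = df.loc[sel, metric]
                ax.bar(i, v.mean(), yerr=v.sem(), width=0.6,
                       color=["#7799cc", "#cc7777"][i])
            ax.set_xticks([0, 1], ["control", "case"])
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(out_dir / "group_metrics.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for sel, color, label in ((is_ctrl, "#7799cc", "control"), (~is_ctrl, "#cc7777", "case")):
        grp = [(p.distances_nm, p.hetero_share_percent) for p, k in zip(profiles, sel) if k]
        x = ribbon_cmp.x
        ys = np.vstack([np.interp(x, px, py) for px, py in grp])
        m, se = ys.mean(axis=0), ys.std(axis=0, ddof=1) / np.sqrt(len(grp))
        ax.errorbar(x, m, yerr=se, color=color, label=label)
    for lo, hi in ribbon_cmp.significant_ranges:
        ax.axvspan(lo, hi, color="0.85", zorder=0)
    ax.set_xlabel("distance from periphery (nm)")
    ax.set_ylabel("heterochromatin share (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "peripheral_profile.png", dpi=150)
    plt.close(fig)

    if curve_cmp is not None:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for sel, color, label in ((is_ctrl, "#7799cc", "control"), (~is_ctrl, "#cc7777", "case")):
            grp = [(c.r_nm, c.B) for c, k in zip(curves, sel) if k and c is not None]
            x = curve_cmp.x
            ys = np.vstack([np.interp(x, px, py) for px, py in grp])
            m, se = ys.mean(axis=0), ys.std(axis=0, ddof=1) / np.sqrt(len(grp))
            ax.errorbar(x, m, yerr=se, color=color, label=label)
        for lo, hi in curve_cmp.significant_ranges:
            ax.axvspan(lo, hi, color="0.85", zorder=0)
        ax.set_xlabel("separation r (nm)")
        ax.set_ylabel("normalized B(r)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "correlation_curves.png", dpi=150)
        plt.close(fig)
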