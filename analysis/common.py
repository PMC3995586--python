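"""Shared configuration for the demo analysis: a scaled-down two-group
cohort (control vs pre-neoplastic) with the measured contrasts built in —
more heterochromatin, larger clumps, lost peripheral enrichment, larger
correlation shape parameter D in the case group."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH_COHORT = ROOT / "scratch" / "demo_cohort"
RESULTS = ROOT / "results"

DEMO_CONFIG = {
    "seed": 7,
    "output_dir": str(RESULTS / "demo"),
    "simulate": {
        "n_control": 12,
        "n_case": 12,
        "image_size": 256,
        "pixel_size_nm": 15.0,
        "resolution_nm": 30.0,
        "ellipse_axes_nm": [1700, 1300],
        "control": {
            "d_true": 2.5,
            "lc_true_nm": 120.0,
            "hetero_fraction_true": 0.342,
            "peripheral_bias": 1.5,
        },
        "case": {
            "d_true": 3.5,
            "lc_true_nm": 200.0,
            "hetero_fraction_true": 0.429,
            "peripheral_bias": 0.0,
        },
    },
    "analysis": {"ribbon_width_nm": 30.0},
}


def build_cohort(persist: bool = False):
    """Deterministically (re)build the demo cohort from DEMO_CONFIG."""
    from chromatex.pipeline import _cohort_from_config

    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEMO_CONFIG.items()}
    if persist:
        SCRATCH_COHORT.mkdir(parents=True, exist_ok=True)
        cfg["simulate"]["persist_dir"] = str(SCRATCH_COHORT)
    return _cohort_from_config(cfg, seed=DEMO_CONFIG["seed"])
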