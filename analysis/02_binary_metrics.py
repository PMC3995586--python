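"""Binary chromatin metrics per nucleus: Otsu binarization, heterochromatin
percentage, pooled run length, peripheral ribbon profile.

Reads the persisted cohort if 01_simulate_cohort.py has run, otherwise
regenerates it in memory.  Writes results/binary_metrics.csv and
results/ribbon_profiles.csv, and prints the group means.
"""

import pandas as pd

from common import DEMO_CONFIG, RESULTS, SCRATCH_COHORT, build_cohort

from chromatex.binary import (
    binarize_chromatin,
    distance_to_boundary,
    heterochromatin_percentage,
    peripheral_profile,
    run_length,
)
from chromatex.pipeline import _load_cohort

def load_units():
    if SCRATCH_COHORT.exists() and any(SCRATCH_COHORT.glob("*.json")):
        return _load_cohort(SCRATCH_COHORT)
    return [(n.micrograph, n.mask) for n in build_cohort()]

def main():
    width = DEMO_CONFIG["analysis"]["ribbon_width_nm"]
    rows, prof_rows = [], []
    for micro, mask in load_units():
        bmap = binarize_chromatin(micro, mask)
        runs = run_length(bmap, micro.pixel_size_nm, nucleolus_masks=mask.nucleoli)
        d = distance_to_boundary(mask, micro.pixel_size_nm)
        prof = peripheral_profile(bmap, d, width)
        rows.append(
            {"id": micro.id, "group": micro.group,
             "hetero_percent": heterochromatin_percentage(bmap),
             "run_length_nm": runs.mean_run_nm, "n_runs": runs.n_runs}
        )
        for dist, share in zip(prof.distances_nm, prof.hetero_share_percent):
            prof_rows.append({"id": micro.id, "group": micro.group,
                              "distance_nm": dist, "hetero_share_percent": share})

    RESULTS.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "binary_metrics.csv", index=False)
    pd.DataFrame(prof_rows).to_csv(RESULTS / "ribbon_profiles.csv", index=False)
    print(df.groupby("group")[["hetero_percent", "run_length_nm"]].agg(["mean", "sem"]).round(2))

if __name__ == "__main__":
    main()
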