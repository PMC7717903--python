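"""Resampled-median comparisons between cohorts.

From the fitted loss curves of 02, derives survival-time distributions and
compares groups the way the imaging study does: medians of 10 random
samples at the observed cohort sizes, exact Mann-Whitney U test.  Runs the
SP+ vs SP- contrast within each scenario and the denervation contrast
within each SP state.
"""

import json
import sys
from pathlib import Path

from spinesurvival import compare_groups, derive_survival_times
from spinesurvival.models import model_from_dict

SEED = 20260920
RESULTS = Path(__file__).resolve().parent.parent / "results"
# day-0 cohort sizes used for resampling, per scenario and SP state
COHORT_SIZES = {
    ("control", "sp_pos"): 31,
    ("control", "sp_neg"): 392,
    ("denervated", "sp_pos"): 35,
    ("denervated", "sp_neg"): 302,
}
CONTRASTS = [
    (("control", "sp_pos"), ("control", "sp_neg")),
    (("denervated", "sp_pos"), ("denervated", "sp_neg")),
    (("denervated", "sp_pos"), ("control", "sp_pos")),
    (("denervated", "sp_neg"), ("control", "sp_neg")),
]


def main() -> int:
    fits_path = RESULTS / "decay_fits.json"
    if not fits_path.exists():
        print(f"missing {fits_path}; run analysis/02_fit_decay_models.py first")
        return 1
    fits = json.loads(fits_path.read_text())

    dists = {
        key: derive_survival_times(
            model_from_dict(fits[key[0]][key[1]]),
            n_time_points=10**6,
            n_fraction_bins=10**4,
        )
        for key in COHORT_SIZES
    }

    out = []
    for i, (a, b) in enumerate(CONTRASTS):
        result = compare_groups(
            dists[a], COHORT_SIZES[a], dists[b], COHORT_SIZES[b],
            seed=SEED + i, labels=("_".join(a), "_".join(b)),
        )
        out.append(result.to_dict())
        med_a = float(sorted(result.sample_medians[0])[len(result.sample_medians[0]) // 2])
        med_b = float(sorted(result.sample_medians[1])[len(result.sample_medians[1]) // 2])
        print(
            f"{'_'.join(a)} (median of sample medians {med_a:.1f} d) vs "
            f"{'_'.join(b)} ({med_b:.1f} d): U = {result.u_statistic:.0f}, "
            f"p = {result.p_value:.2e}"
        )

    (RESULTS / "group_comparisons.json").write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {RESULTS / 'group_comparisons.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
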