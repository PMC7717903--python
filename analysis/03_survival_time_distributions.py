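"""Derive survival-time distributions from the fitted decay curves.

Reads the fits from 02, inverts each loss curve numerically (10^7 time
points over 30·tau_max, 10^5 fractional-survival bins — the full-resolution
procedure) and writes the equal-mass survival times' percentiles plus the
relative-frequency histograms under results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from spinesurvival import derive_survival_times
from spinesurvival.models import model_from_dict

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    fits_path = RESULTS / "decay_fits.json"
    if not fits_path.exists():
        print(f"missing {fits_path}; run analysis/02_fit_decay_models.py first")
        return 1
    fits = json.loads(fits_path.read_text())

    summary = {}
    for scenario, cohorts in fits.items():
        for cohort, fit in cohorts.items():
            model = model_from_dict(fit)
            dist = derive_survival_times(model)
            key = f"{scenario}_{cohort}"
            summary[key] = {"percentiles_days": dist.percentiles}
            edges, freqs = dist.histogram
            pd.DataFrame(
                {"bin_left_days": edges[:-1], "bin_right_days": edges[1:],
                 "relative_frequency": freqs}
            ).to_csv(RESULTS / f"histogram_{key}.csv", index=False)
            p = dist.percentiles
            print(
                f"{key}: median {p[50]:.1f} d "
                f"(IQR {p[25]:.1f}-{p[75]:.1f}, 10-90% {p[10]:.1f}-{p[90]:.1f})"
            )

    (RESULTS / "survival_time_percentiles.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"wrote {RESULTS / 'survival_time_percentiles.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
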