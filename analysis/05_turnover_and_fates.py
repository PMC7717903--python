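"""Turnover metrics, size classes, size matching and fate trajectories.

Computes the bookkeeping metrics on the simulated control table from 01:
turnover/formation/loss ratios over days -1..12, the day-0 SP+ fraction and
size-class breakdown, SP+/SP- size-matched pairs, the one-day interval loss
(day -1 to 0), and per-spine fate labels for the day-0 cohort.
"""

import json
import sys
from pathlib import Path

from spinesurvival import (
    classify_fates,
    fraction_sp_positive,
    interval_loss,
    match_pairs_by_size,
    read_longitudinal_csv,
    turnover_metrics,
)
from spinesurvival.metrics import size_class_counts

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    path = RESULTS / "table_control.csv"
    if not path.exists():
        print(f"missing {path}; run analysis/01_simulate_cohorts.py first")
        return 1
    table = read_longitudinal_csv(path)

    tm = turnover_metrics(table, -1, 12)
    print(
        f"turnover {tm.turnover_ratio:.3f} = (formation {tm.formation_ratio:.3f} "
        f"+ loss {tm.loss_ratio:.3f})/2  "
        f"[N_initial={tm.n_initial}, N_final={tm.n_final}, N_total={tm.n_total}]"
    )

    frac, n_pos, n_present = fraction_sp_positive(table, 0)
    print(f"day 0: {n_pos}/{n_present} spines SP+ ({frac:.1f}%)")

    pct, n_lost, n_from = interval_loss(table, -1, 0)
    print(f"day -1 -> 0: {n_lost}/{n_from} spines lost ({pct:.2f}%)")

    day0 = table[(table["day"] == 0) & table["present"]]
    sizes = size_class_counts(day0["head_area"].to_numpy())
    print("day-0 size classes:", ", ".join(f"{k}={v}" for k, v in sizes.items()))

    pos = day0[day0["sp_positive"].astype(bool)]
    neg = day0[~day0["sp_positive"].astype(bool)]
    pairs = match_pairs_by_size(
        list(zip(pos["spine_id"], pos["head_area"])),
        list(zip(neg["spine_id"], neg["head_area"])),
    )
    print(
        f"size-matched SP+/SP- pairs: {len(pairs)} "
        f"(mean areas {pairs['area_a'].mean():.3f} vs {pairs['area_b'].mean():.3f} um^2)"
    )

    fates = classify_fates(table)
    counts = {"survived": 0, "pruned_via_sp_neg": 0, "pruned_direct": 0}
    undulating = 0
    for f in fates.values():
        counts[f.outcome] += 1
        undulating += int(f.undulating)
    pruned = counts["pruned_via_sp_neg"] + counts["pruned_direct"]
    via_pct = 100.0 * counts["pruned_via_sp_neg"] / pruned if pruned else float("nan")
    print(
        f"fates of {len(fates)} day-0 spines: {counts}; "
        f"{via_pct:.0f}% of pruned spines went through the SP- state; "
        f"{undulating} undulating"
    )

    report = {
        "turnover": tm.to_dict(),
        "fraction_sp_positive_percent": frac,
        "interval_loss_percent": pct,
        "size_class_counts": sizes,
        "n_matched_pairs": len(pairs),
        "fate_counts": counts,
        "n_undulating": undulating,
    }
    (RESULTS / "spine_metrics.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {RESULTS / 'spine_metrics.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
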