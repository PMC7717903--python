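"""Turnover ratios, size classes, size matching and spine-fate trajectories.

Turnover bookkeeping follows the standard longitudinal-imaging formulas:
``turnover = (N_gained + N_lost) / (2·N_total)``,
``formation = (N_total − N_initial)/N_total``,
``loss = (N_total − N_final)/N_total``, where ``N_total`` counts spines
observed at one or more imaging days, so the identity
``turnover = (formation + loss)/2`` holds on every table.

Head areas are classified into the four conventional size bins (µm²):
very small [0, 0.3), small [0.3, 0.55), medium [0.55, 0.8), large [0.8, ∞);
boundary areas go to the upper class.

Fate classification records, per day-0 spine, whether it survived the
observation period or was pruned, and whether a pruned spine was SP⁻ at its
last observed day (pruned via the SP⁻ state) or still SP⁺ (apparent direct
loss, typically a missed intermediate given sparse imaging).  Spines with two
or more SP-state changes are additionally flagged as undulating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TurnoverMetrics",
    "FateLabel",
    "SIZE_CLASS_BOUNDS",
    "turnover_metrics",
    "classify_size",
    "size_class_counts",
    "match_pairs_by_size",
    "classify_fates",
    "fraction_sp_positive",
    "interval_loss",
]

#: Half-open head-area intervals [lo, hi) per size class, µm².
SIZE_CLASS_BOUNDS = {
    "very_small": (0.0, 0.3),
    "small": (0.3, 0.55),
    "medium": (0.55, 0.8),
    "large": (0.8, np.inf),
}
_SIZE_EDGES = np.array([0.3, 0.55, 0.8])
_SIZE_LABELS = np.array(["very_small", "small", "medium", "large"])


@dataclass(frozen=True)
class TurnoverMetrics:
    n_gained: int
    n_lost: int
    n_total: int
    n_initial: int
    n_final: int
    turnover_ratio: float
    formation_ratio: float
    loss_ratio: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class FateLabel:
    """Fate of one day-0 spine over the observation period."""

    outcome: str  # 'survived' | 'pruned_via_sp_neg' | 'pruned_direct'
    undulating: bool
    transitions: Tuple[int, ...]  # days at which the SP state changed


def turnover_metrics(
    table: pd.DataFrame, first_day: int, last_day: int
) -> TurnoverMetrics:
    """Turnover/formation/loss ratios between ``first_day`` and ``last_day``."""
    days = set(table["day"].unique())
    if first_day not in days or last_day not in days:
        raise ValueError(f"days {first_day} and {last_day} must both be observed")
    window = table[(table["day"] >= first_day) & (table["day"] <= last_day)]
    present = window[window["present"]]
    n_total = present["spine_id"].nunique()
    n_initial = present.loc[present["day"] == first_day, "spine_id"].nunique()
    n_final = present.loc[present["day"] == last_day, "spine_id"].nunique()
    n_gained = n_total - n_initial
    n_lost = n_total - n_final
    if n_total == 0:
        raise ValueError("no spines present in the requested window")
    return TurnoverMetrics(
        n_gained=n_gained,
        n_lost=n_lost,
        n_total=n_total,
        n_initial=n_initial,
        n_final=n_final,
        turnover_ratio=(n_gained + n_lost) / (2.0 * n_total),
        formation_ratio=n_gained / n_total,
        loss_ratio=n_lost / n_total,
    )


def classify_size(head_area):
    """Size class of one or more head areas (µm²); boundaries go upward."""
    arr = np.asarray(head_area, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("head areas must be positive")
    labels = _SIZE_LABELS[np.searchsorted(_SIZE_EDGES, arr, side="right")]
    return str(labels) if arr.ndim == 0 else labels


def size_class_counts(head_areas) -> Dict[str, int]:
    """Counts per size class, in canonical order."""
    labels = classify_size(np.atleast_1d(head_areas))
    return {lbl: int(np.sum(labels == lbl)) for lbl in _SIZE_LABELS}


def match_pairs_by_size(
    group_a: Sequence[Tuple[str, float]],
    group_b: Sequence[Tuple[str, float]],
    caliper: float = 0.10,
) -> pd.DataFrame:
    """Greedily pair spines of near-equal head size across two groups.

    Iterates ``group_a`` in ascending area order; each spine is paired with
    the unmatched ``group_b`` spine of minimal absolute area difference, and
    the pair is kept only if ``|Δarea| <= caliper·area_a`` (default 10%
    relative caliper).  Returns a frame with columns
    ``id_a,id_b,area_a,area_b,diff`` (signed ``area_a − area_b``), suitable
    for a matched-pairs zero-difference (Wilcoxon–Pratt) test.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    a_sorted = sorted(group_a, key=lambda r: r[1])
    b_ids = [r[0] for r in group_b]
    b_areas = np.array([r[1] for r in group_b], dtype=float)
    unmatched = np.ones(len(group_b), dtype=bool)
    rows = []
    for id_a, area_a in a_sorted:
        if not unmatched.any():
            break
        cand = np.flatnonzero(unmatched)
        j = cand[np.argmin(np.abs(b_areas[cand] - area_a))]
        if abs(b_areas[j] - area_a) <= caliper * area_a:
            unmatched[j] = False
            rows.append((id_a, b_ids[j], area_a, float(b_areas[j]),
                         area_a - float(b_areas[j])))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "area_a", "area_b", "diff"])


def classify_fates(
    table: pd.DataFrame, cohort_day: int = 0
) -> Dict[str, FateLabel]:
    """Fate label for every spine present at ``cohort_day``.

    A spine is 'survived' if present at the last observation day (or at any
    day after its last absence — reappearance counts as detection miss);
    otherwise it is pruned, and labeled by its SP state on the last day it
    was seen.  Spines with >= 2 SP-state changes are flagged undulating.
    """
    if cohort_day not in set(table["day"].unique()):
        raise ValueError(f"cohort day {cohort_day} not observed")
    days = np.sort(table["day"].unique())
    fates: Dict[str, FateLabel] = {}
    for spine_id, sub in table.sort_values("day").groupby("spine_id", sort=False):
        at_day0 = sub[sub["day"] == cohort_day]
        if at_day0.empty or not bool(at_day0["present"].iloc[0]):
            continue
        present = sub["present"].to_numpy(dtype=bool)
        sp = sub["sp_positive"].to_numpy()
        sub_days = sub["day"].to_numpy()
        if pd.isna(sp[present]).any():
            raise ValueError(f"spine {spine_id}: present row with missing SP state")
        sp_seq = sp[present].astype(bool)
        seen_days = sub_days[present]
        change = sp_seq[1:] != sp_seq[:-1]
        transitions = tuple(int(d) for d in seen_days[1:][change])
        survived = bool(present[-1])
        if survived:
            outcome = "survived"
        else:
            outcome = "pruned_via_sp_neg" if not sp_seq[-1] else "pruned_direct"
        fates[spine_id] = FateLabel(
            outcome=outcome,
            undulating=len(transitions) >= 2,
            transitions=transitions,
        )
    if not fates:
        raise ValueError("no spines present at the cohort day")
    return fates


def fraction_sp_positive(table: pd.DataFrame, day: int) -> Tuple[float, int, int]:
    """Percent of present spines that are SP⁺ at ``day``; returns (%, n_pos, n_present)."""
    at_day = table[(table["day"] == day) & table["present"]]
    n_present = len(at_day)
    if n_present == 0:
        raise ValueError(f"no spines present at day {day}")
    if at_day["sp_positive"].isna().any():
        raise ValueError("present rows with missing SP state")
    n_pos = int(at_day["sp_positive"].sum())
    return 100.0 * n_pos / n_present, n_pos, n_present


def interval_loss(
    table: pd.DataFrame, day_from: int, day_to: int
) -> Tuple[float, int, int]:
    """Percent of spines present at ``day_from`` that are absent at ``day_to``.

    Returns ``(percent_lost, n_lost, n_at_from)``.  The companion counter for
    one-interval loss analyses (e.g. the single 1-day interval of the default
    schedule, day −1 → day 0).
    """
    days = set(table["day"].unique())
    if day_from not in days or day_to not in days:
        raise ValueError("both days must be observed")
    at_from = table[(table["day"] == day_from) & table["present"]]
    if at_from.empty:
        raise ValueError(f"no spines present at day {day_from}")
    ids = at_from["spine_id"]
    at_to = table[(table["day"] == day_to) & table["spine_id"].isin(ids)]
    lost = ~at_to.set_index("spine_id")["present"].reindex(ids).fillna(False).astype(bool)
    n_lost = int(lost.sum())
    n_from = len(ids)
    return 100.0 * n_lost / n_from, n_lost, n_from
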