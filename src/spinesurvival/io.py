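"""CSV/JSON/YAML I/O, validation and the end-to-end pipeline.

The interchange format for longitudinal tables is CSV with header
``spine_id,segment_id,group,day,present,sp_positive,head_area``; booleans are
0/1 and missing values are empty fields.  :func:`run_pipeline` strings the
stages together for one simulated or loaded dataset: survival tables, decay
fits (single-phase for the SP⁻ cohort, two-stage with τ_spine pinned to the
SP⁻ fit for the SP⁺ cohort), survival-time distributions, the resampled-
median comparison, and turnover/size/fate metrics.  Reports carry the seed
and a config hash so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import metrics as _metrics
from .comparison import compare_groups
from .distribution import derive_survival_times
from .fitting import build_survival_table, fit_single_phase, fit_two_stage
from .simulate import SimulationConfig, simulate_population

__all__ = [
    "SCHEMA_COLUMNS",
    "SchemaError",
    "read_longitudinal_csv",
    "write_longitudinal_csv",
    "validate_table",
    "PipelineConfig",
    "load_pipeline_config",
    "run_pipeline",
]

SCHEMA_COLUMNS = (
    "spine_id",
    "segment_id",
    "group",
    "day",
    "present",
    "sp_positive",
    "head_area",
)


class SchemaError(ValueError):
    """A longitudinal table violates the schema or its invariants."""


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; returns the table with canonical dtypes.

    Checks: required columns; (spine_id, day) uniqueness; absent rows carry
    no SP state or head area; every spine has a row for every observation day
    of its segment.  Error messages name the offending rows.
    """
    missing = [c for c in SCHEMA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    t = table.loc[:, list(SCHEMA_COLUMNS)].copy()
    t["spine_id"] = t["spine_id"].astype(str)
    t["segment_id"] = t["segment_id"].astype(str)
    t["group"] = t["group"].astype(str)
    try:
        t["day"] = t["day"].astype("int64")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"column 'day' must be integer: {exc}") from None
    t["present"] = _parse_bool(t["present"], "present", allow_na=False).astype(bool)
    t["sp_positive"] = _parse_bool(t["sp_positive"], "sp_positive", allow_na=True)
    t["head_area"] = pd.to_numeric(t["head_area"], errors="coerce")

    dup = t.duplicated(subset=["spine_id", "day"])
    if dup.any():
        rows = t.loc[dup, ["spine_id", "day"]].head(3).to_dict("records")
        raise SchemaError(f"duplicate (spine_id, day) rows, e.g. {rows}")

    absent = ~t["present"]
    bad = absent & (t["sp_positive"].notna() | t["head_area"].notna())
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        r = t.iloc[i]
        raise SchemaError(
            f"row {i} (spine {r['spine_id']}, day {r['day']}): absent spine "
            "must have empty sp_positive and head_area"
        )
    present_bad = t["present"] & t["sp_positive"].isna()
    if present_bad.any():
        i = int(np.flatnonzero(present_bad.to_numpy())[0])
        r = t.iloc[i]
        raise SchemaError(
            f"row {i} (spine {r['spine_id']}, day {r['day']}): present spine "
            "lacks an SP state"
        )
    if (t["head_area"].dropna() <= 0).any():
        raise SchemaError("head_area values must be positive where present")

    for seg, sub in t.groupby("segment_id"):
        seg_days = set(sub["day"].unique())
        counts = sub.groupby("spine_id")["day"].nunique()
        short = counts[counts != len(seg_days)]
        if not short.empty:
            raise SchemaError(
                f"segment {seg}: spines missing observation-day rows: "
                f"{list(short.index[:3])}"
            )
    return t


def _parse_bool(col: pd.Series, name: str, allow_na: bool) -> pd.Series:
    col = col.mask(col.astype(object).eq(""), pd.NA)
    mapped = col.map(
        {
            True: True, False: False, 1: True, 0: False,
            "1": True, "0": False, "True": True, "False": False,
        }
    ).astype("boolean")
    unknown = mapped.isna() & col.notna()
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise SchemaError(f"row {i}: column {name!r} has non-boolean value {col.iloc[i]!r}")
    if not allow_na and mapped.isna().any():
        i = int(np.flatnonzero(mapped.isna().to_numpy())[0])
        raise SchemaError(f"row {i}: column {name!r} must not be empty")
    return mapped


def read_longitudinal_csv(path) -> pd.DataFrame:
    """Read and validate a longitudinal spine table from CSV."""
    raw = pd.read_csv(path, dtype={"spine_id": str, "segment_id": str, "group": str})
    return validate_table(raw)


def write_longitudinal_csv(table: pd.DataFrame, path) -> None:
    """Write a longitudinal table as CSV (booleans 0/1, missing empty)."""
    out = table.copy()
    out["present"] = out["present"].astype(int)
    out["sp_positive"] = out["sp_positive"].astype("Int64")
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end pipeline run."""

    input_csv: Optional[str] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    cohort_day: int = 0
    distribution_points: int = 10**6
    distribution_bins: int = 10**4
    n_samples: int = 10
    caliper: float = 0.10
    out_dir: Optional[str] = None


def load_pipeline_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    sim = SimulationConfig(**data.pop("simulation", {}))
    if "observation_days" in dataclasses.asdict(sim):
        sim = dataclasses.replace(sim, observation_days=tuple(sim.observation_days))
    return PipelineConfig(simulation=sim, **data)


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # output location is not part of the analysis
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis for one dataset and return the report dict.

    If ``config.out_dir`` is set, writes ``report.json``, per-cohort survival
    CSVs and the matched-pairs CSV there.
    """
    if config.input_csv is not None:
        table = read_longitudinal_csv(config.input_csv)
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        table = simulate_population(sim)

    st_neg = build_survival_table(table, "sp_neg", cohort_day=config.cohort_day)
    st_pos = build_survival_table(table, "sp_pos", cohort_day=config.cohort_day)

    fit_neg = fit_single_phase(st_neg)
    fit_pos = fit_two_stage(st_pos, tau_spine_fixed=fit_neg.model.tau_spine)

    dist_kwargs = dict(
        n_time_points=config.distribution_points,
        n_fraction_bins=config.distribution_bins,
    )
    dist_neg = derive_survival_times(fit_neg.model, **dist_kwargs)
    dist_pos = derive_survival_times(fit_pos.model, **dist_kwargs)

    comparison = compare_groups(
        dist_pos,
        st_pos.n_initial,
        dist_neg,
        st_neg.n_initial,
        n_samples=config.n_samples,
        seed=config.seed,
        labels=("sp_pos", "sp_neg"),
    )

    days = np.sort(table["day"].unique())
    turnover = _metrics.turnover_metrics(table, int(days[0]), int(days[-1]))
    frac_pos, n_pos, n_present = _metrics.fraction_sp_positive(
        table, config.cohort_day
    )
    fates = _metrics.classify_fates(table, cohort_day=config.cohort_day)
    fate_counts: dict = {"survived": 0, "pruned_via_sp_neg": 0, "pruned_direct": 0}
    n_undulating = 0
    for f in fates.values():
        fate_counts[f.outcome] += 1
        n_undulating += int(f.undulating)

    day0 = table[(table["day"] == config.cohort_day) & table["present"]]
    sizes = _metrics.size_class_counts(day0["head_area"].to_numpy())
    pos_rows = day0[day0["sp_positive"].astype(bool)]
    neg_rows = day0[~day0["sp_positive"].astype(bool)]
    pairs = _metrics.match_pairs_by_size(
        list(zip(pos_rows["spine_id"], pos_rows["head_area"])),
        list(zip(neg_rows["spine_id"], neg_rows["head_area"])),
        caliper=config.caliper,
    )

    report = {
        "provenance": {
            "seed": config.seed,
            "config_hash": _config_hash(config),
        },
        "cohorts": {
            "sp_neg": {
                "n_initial": st_neg.n_initial,
                "fit": fit_neg.to_dict(),
                "median_survival_days": dist_neg.median,
                "percentiles_days": dist_neg.percentiles,
            },
            "sp_pos": {
                "n_initial": st_pos.n_initial,
                "fit": fit_pos.to_dict(),
                "median_survival_days": dist_pos.median,
                "percentiles_days": dist_pos.percentiles,
            },
        },
        "comparison": comparison.to_dict(),
        "metrics": {
            "turnover": turnover.to_dict(),
            "fraction_sp_positive_percent": frac_pos,
            "n_sp_positive": n_pos,
            "n_present": n_present,
            "size_class_counts": sizes,
            "fate_counts": fate_counts,
            "n_undulating": n_undulating,
            "n_matched_pairs": int(len(pairs)),
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        st_neg.to_csv(out / "survival_sp_neg.csv")
        st_pos.to_csv(out / "survival_sp_pos.csv")
        pairs.to_csv(out / "matched_pairs.csv", index=False)
    return report
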