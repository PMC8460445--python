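"""Cohort eligibility rules and left-truncated risk-interval construction.

Subjects enter the risk set one year after the first breast cancer (BC1);
time is measured in years since BC1.  A contralateral breast cancer (CBC)
within one year of BC1 counts as synchronous and excludes the subject.
Follow-up is censored at the earliest of baseline ascertainment age,
risk-reducing contralateral mastectomy and death (optionally also distant
relapse, as a sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_DEFINITIONS",
    "apply_eligibility",
    "build_risk_intervals",
    "birth_cohort_quartiles",
]

EVENT_DEFINITIONS = ("all_cbc", "invasive_only", "er_positive", "er_negative")

ENTRY_YEARS = 1.0  # delayed entry: one year after BC1
SYNCHRONOUS_WINDOW = 1.0  # CBC within a year of BC1 is synchronous


def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into eligible subjects and an exclusion log.

    Exclusions, applied in order with one reason per subject:

    * ``missing_baseline_age`` — no baseline ascertainment age;
    * ``baseline_within_entry`` — BC1 less than one year before baseline,
      so the subject never reaches the delayed-entry point;
    * ``synchronous_cbc`` — CBC within one year of BC1;
    * ``metastatic_bc1`` — known metastatic first tumour.  Subjects with
      unknown metastatic status are retained (assumed non-metastatic).
    """
    if (records["age_cbc"] < records["age_bc1"]).any():
        bad = records.loc[records["age_cbc"] < records["age_bc1"], "subject_id"]
        raise ValueError(f"age_cbc precedes age_bc1 for subjects {list(bad)[:5]}")

    reasons = pd.Series(pd.NA, index=records.index, dtype="string")
    baseline_missing = records["age_baseline"].isna()
    reasons[baseline_missing] = "missing_baseline_age"

    too_recent = (
        records["age_baseline"] - records["age_bc1"] < ENTRY_YEARS
    ) & reasons.isna()
    reasons[too_recent] = "baseline_within_entry"

    synchronous = (
        (records["age_cbc"] - records["age_bc1"] < SYNCHRONOUS_WINDOW)
        & records["age_cbc"].notna()
        & reasons.isna()
    )
    reasons[synchronous] = "synchronous_cbc"

    metastatic = (records.get("metastatic_bc1", "unknown") == "yes") & reasons.isna()
    reasons[metastatic] = "metastatic_bc1"

    excluded = reasons.notna()
    log = pd.DataFrame(
        {
            "subject_id": records.loc[excluded, "subject_id"],
            "reason": reasons[excluded],
        }
    )
    return records.loc[~excluded].copy(), log.reset_index(drop=True)


def birth_cohort_quartiles(birth_year: pd.Series) -> pd.Series:
    """Quartile labels of the observed birth-year distribution.

    Quartile edges use linear-interpolation quantiles of the analysis cohort
    itself (recorded in ``.attrs['edges']``), matching adjustment for birth
    cohort by quartiles of the observed distribution.
    """
    edges = np.quantile(birth_year.dropna(), [0.25, 0.5, 0.75])
    labels = pd.Series(
        np.searchsorted(edges, birth_year, side="right"), index=birth_year.index
    ).map(lambda q: f"Q{q + 1}")
    labels.attrs["edges"] = list(edges)
    return labels


@dataclass
class IntervalBuildResult:
    intervals: pd.DataFrame
    dropped: pd.DataFrame  # subjects without positive time at risk, with reason


def build_risk_intervals(
    records: pd.DataFrame,
    event_definition: str = "all_cbc",
    sensitivity: str = "none",
) -> IntervalBuildResult:
    """Construct left-truncated risk intervals for one event definition.

    * ``all_cbc`` — any metachronous CBC, invasive or in situ, is an event.
    * ``invasive_only`` — in situ CBC censors at its diagnosis age.
    * ``er_positive`` / ``er_negative`` — CBC of the other (or unknown) ER
      status censors at the CBC age.

    ``sensitivity='censor_distant_relapse'`` additionally censors at distant
    relapse; subjects whose relapse precedes the entry point are excluded.
    """
    if event_definition not in EVENT_DEFINITIONS:
        raise ValueError(f"unknown event definition {event_definition!r}")
    if sensitivity not in {"none", "censor_distant_relapse"}:
        raise ValueError(f"unknown sensitivity {sensitivity!r}")

    rec = records.reset_index(drop=True)
    age_bc1 = rec["age_bc1"].to_numpy(dtype=float)

    censor_age = np.fmin(
        rec["age_baseline"].to_numpy(dtype=float),
        np.fmin(
            rec.get("age_rrm", pd.Series(np.nan, index=rec.index)).to_numpy(dtype=float),
            rec.get("age_death", pd.Series(np.nan, index=rec.index)).to_numpy(dtype=float),
        ),
    )
    if sensitivity == "censor_distant_relapse":
        relapse = rec.get(
            "age_distant_relapse", pd.Series(np.nan, index=rec.index)
        ).to_numpy(dtype=float)
        censor_age = np.fmin(censor_age, relapse)

    age_cbc = rec["age_cbc"].to_numpy(dtype=float)
    has_cbc = np.isfinite(age_cbc) & (age_cbc < censor_age)

    invasive = (
        rec.get("cbc_invasive", pd.Series(pd.NA, index=rec.index))
        .astype("boolean")
        .fillna(False)
        .to_numpy(dtype=bool)
    )
    er = rec.get("cbc_er_status", pd.Series("unknown", index=rec.index)).astype(str)

    if event_definition == "all_cbc":
        is_event = has_cbc
    elif event_definition == "invasive_only":
        is_event = has_cbc & invasive
    elif event_definition == "er_positive":
        is_event = has_cbc & (er == "positive").to_numpy()
    else:
        is_event = has_cbc & (er == "negative").to_numpy()

    # non-qualifying CBC censors at its diagnosis age
    exit_age = np.where(has_cbc, age_cbc, censor_age)
    exit_t = exit_age - age_bc1
    event = is_event.astype(int)

    out = pd.DataFrame(
        {
            "subject_id": rec["subject_id"],
            "entry": ENTRY_YEARS,
            "exit": exit_t,
            "event": event,
            "event_definition": event_definition,
            "stratum": rec["country"],
            "cluster": rec["family_id"],
            "z": rec["z"],
            "age_bc1": age_bc1,
            "birth_year": rec["birth_year"],
        }
    )
    for col in ("variant_class",):
        if col in rec.columns:
            out[col] = rec[col].to_numpy()

    ok = out["exit"] > out["entry"]
    dropped = pd.DataFrame(
        {
            "subject_id": out.loc[~ok, "subject_id"],
            "reason": "no_time_at_risk",
        }
    ).reset_index(drop=True)
    intervals = out.loc[ok].reset_index(drop=True)
    if len(intervals):
        quartiles = birth_cohort_quartiles(intervals["birth_year"])
        intervals["birth_cohort_q"] = quartiles
        intervals.attrs["birth_cohort_edges"] = quartiles.attrs["edges"]
    else:
        intervals["birth_cohort_q"] = pd.Series(dtype="string")
    return IntervalBuildResult(intervals=intervals, dropped=dropped)
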