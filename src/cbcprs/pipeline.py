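"""End-to-end orchestration: score -> eligibility -> intervals -> fits -> curves.

A run is described by a YAML config holding input paths, the PRS flavour and
reference SD, the event definition and sensitivity flags, the model list,
imputation settings and a master seed.  Every output bundle carries a
manifest (config hash, package version, seeds, subject/event counts per
stage) so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eligibility import apply_eligibility, build_risk_intervals
from .impute import mice_impute, pool_estimates
from .riskcurves import (
    IncidenceSchedule,
    constrain_baseline,
    effective_beta,
    marginal_conservation_check,
    normal_percentile_nodes,
    percentile_risk_curves,
    risk_curve_table,
)
from .scoring import (
    StandardizationSpec,
    compute_prs,
    read_dosage_csv,
    read_weight_panel,
    standardize_prs,
)
from .survival import (
    compute_percentile_bands,
    fit_age_group_models,
    fit_cox_categorical,
    fit_cox_continuous,
    fit_interaction,
    fit_variant_class_models,
    harrell_c,
    rcs_linearity_check,
    schoenfeld_ph_test,
)

__all__ = ["RunConfig", "run_association", "run_risk_curves"]

VALID_MODELS = {
    "continuous",
    "categorical",
    "interaction",
    "age-groups",
    "variant-class",
    "diagnostics",
}


@dataclass
class RunConfig:
    weights: str
    genotypes: str
    phenotypes: str
    reference_sd: float
    prs_flavor: str = "overall"
    event_definition: str = "all_cbc"
    sensitivity: str = "none"
    models: list[str] = field(default_factory=lambda: ["continuous"])
    m_imputations: int = 0  # 0 disables imputation
    schedule: str | None = None
    percentiles: list[float] = field(default_factory=lambda: [5, 25, 50, 75, 95])
    ages: list[float] = field(default_factory=lambda: [35.0, 45.0, 55.0])
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        for attr in ("weights", "genotypes", "phenotypes"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} path does not exist: {p}")
        unknown = set(self.models) - VALID_MODELS
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.reference_sd <= 0:
            raise ValueError("reference_sd must be positive")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest(config: RunConfig, stages: dict) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.digest(),
        "config": config.__dict__,
        "stages": stages,
    }


def run_association(config: RunConfig, write: bool = True) -> dict:
    """Execute the full association pipeline and return the results bundle."""
    config.validate()
    stages: dict = {}

    panel = read_weight_panel(config.weights)
    dosages = read_dosage_csv(config.genotypes)
    scores = compute_prs(dosages, panel, flavor=config.prs_flavor)
    z, spec = standardize_prs(
        scores["raw_score"], StandardizationSpec(scale=config.reference_sd)
    )
    scores = scores.assign(z=z)
    stages["scoring"] = {
        "n_scored": len(scores),
        "center": spec.center,
        "scale": spec.scale,
    }

    records = pd.read_csv(config.phenotypes)
    # any PRS column already present is superseded by the freshly computed one
    records = records.drop(columns=["z"], errors="ignore").merge(
        scores[["z"]], left_on="subject_id", right_index=True, how="inner"
    )
    eligible, exclusions = apply_eligibility(records)
    stages["eligibility"] = {
        "n_input": len(records),
        "n_eligible": len(eligible),
        "exclusions": exclusions["reason"].value_counts().to_dict(),
    }

    build = build_risk_intervals(
        eligible, config.event_definition, sensitivity=config.sensitivity
    )
    intervals = build.intervals
    stages["intervals"] = {
        "n_intervals": len(intervals),
        "n_events": int(intervals["event"].sum()),
        "n_dropped": len(build.dropped),
    }

    results: dict = {}
    if config.m_imputations >= 2:
        followup = intervals.set_index("subject_id")
        aug = eligible.assign(
            event_flag=followup.reindex(eligible["subject_id"])["event"]
            .fillna(0)
            .to_numpy(),
            log_followup=np.log(
                followup.reindex(eligible["subject_id"])["exit"].fillna(1.0).to_numpy()
            ),
        )
        imp = mice_impute(aug, m=config.m_imputations, seed=config.seed)
        stages["imputation"] = {"m": imp.m, "visit_order": imp.visit_order}
        # ER status is imputed per completed dataset, alternative-ER censoring
        # is applied inside each dataset before fitting, then estimates pooled
        per_imp = []
        for completed in imp.completed:
            cdf = completed.drop(columns=["event_flag", "log_followup"])
            b = build_risk_intervals(
                cdf, config.event_definition, sensitivity=config.sensitivity
            )
            per_imp.append(fit_cox_continuous(b.intervals))
        results["pooled_continuous"] = pool_estimates(per_imp).to_dict()

    if "continuous" in config.models:
        results["continuous"] = fit_cox_continuous(intervals).to_dict()
    if "categorical" in config.models:
        ubc_z = intervals.loc[intervals["event"] == 0, "z"].to_numpy()
        bands = compute_percentile_bands(ubc_z)
        results["categorical"] = fit_cox_categorical(intervals, bands).to_dict()
    if "interaction" in config.models:
        results["interaction"] = fit_interaction(intervals).to_dict()
    if "age-groups" in config.models:
        results["age_groups"] = {
            g: f.to_dict() for g, f in fit_age_group_models(intervals).items()
        }
    if "variant-class" in config.models and "variant_class" in intervals.columns:
        results["variant_class"] = {
            c: f.to_dict() for c, f in fit_variant_class_models(intervals).items()
        }
    if "diagnostics" in config.models:
        cont = fit_cox_continuous(intervals)
        cidx = harrell_c(intervals, n_bootstrap=0)
        results["diagnostics"] = {
            "schoenfeld_p": schoenfeld_ph_test(cont, intervals),
            "rcs_nonlinearity_p": rcs_linearity_check(intervals),
            "harrell_c": cidx.c,
        }

    bundle = {
        "results": results,
        "manifest": _manifest(config, stages),
    }
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "results.json").write_text(json.dumps(bundle, indent=2, default=str))
        exclusions.to_csv(outdir / "exclusions.csv", index=False)
        intervals.to_csv(outdir / "intervals.csv", index=False)
        _table2_csv(results, outdir / "association_table.csv")
    return bundle


def _table2_csv(results: dict, path: Path) -> None:
    """Flat per-term export of every fitted model."""
    rows = []

    def emit(model: str, fit: dict) -> None:
        for term, coef in fit["coefficients"].items():
            rows.append(
                (
                    model,
                    term,
                    fit["hr"][term],
                    fit["ci95_low"][term],
                    fit["ci95_high"][term],
                    fit["p"][term],
                    fit["n_subjects"],
                    fit["n_events"],
                )
            )

    for model, fit in results.items():
        if model in {"age_groups", "variant_class"}:
            for sub, f in fit.items():
                emit(f"{model}:{sub}", f)
        elif model != "diagnostics":
            emit(model, fit)
    pd.DataFrame(
        rows, columns=["model", "term", "hr", "ci_low", "ci_high", "p", "n", "events"]
    ).to_csv(path, index=False)


def run_risk_curves(
    schedule_path: str | Path,
    beta: float,
    gamma: float = 0.0,
    ages: list[float] | None = None,
    percentiles: list[float] | None = None,
    dt: float = 0.1,
    n_nodes: int = 99,
    outdir: str | Path | None = None,
) -> dict:
    """Constrained-incidence risk curves for each age-group schedule.

    ``beta``/``gamma`` may come from a fitted interaction model or be given
    explicitly; the two routes are equivalent when the values match.
    """
    schedules = IncidenceSchedule.from_csv(schedule_path)
    ages = ages or [35.0, 45.0, 55.0]
    percentiles = percentiles or [5, 25, 50, 75, 95]
    if len(ages) != len(schedules):
        # pair schedules with evaluation ages positionally when counts match,
        # else evaluate every schedule at every age
        pairs = [(g, a) for g in sorted(schedules) for a in ages]
    else:
        pairs = list(zip(sorted(schedules), ages))

    nodes = normal_percentile_nodes(n_nodes)
    curves_by_group: dict[str, list] = {}
    conservation: dict[str, float] = {}
    for group, age in pairs:
        sched = schedules[group].refine(dt)
        beff = effective_beta(beta, gamma, age)
        baseline = constrain_baseline(sched, beff, nodes)
        key = group if len(pairs) == len(schedules) else f"{group}@age{age:g}"
        curves_by_group[key] = percentile_risk_curves(baseline, percentiles)
        conservation[key] = marginal_conservation_check(baseline, sched)

    table = risk_curve_table(curves_by_group)
    out = {"curves": table, "conservation_max_abs_deviation": conservation}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "risk_curves.csv", index=False)
        (outdir / "conservation.json").write_text(json.dumps(conservation, indent=2))
    return out
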