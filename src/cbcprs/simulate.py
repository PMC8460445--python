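"""Synthetic cohorts with family-structured genotypes and known generative truth.

The generator emulates a clinic-based retrospective cohort of BRCA1/2
pathogenic-variant carriers followed for contralateral breast cancer (CBC):
left-truncated time at risk starting one year after the first breast cancer,
censoring at baseline ascertainment / risk-reducing mastectomy / death,
country strata, family clusters, and covariate missingness of the magnitude
seen in large consortium data.  Every downstream stage (scoring, eligibility,
survival modelling, imputation, absolute risk) can therefore be tested
against parameters that are known by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SimulationConfig",
    "generate_variant_panel",
    "generate_families_genotypes",
    "generate_cohort",
    "simulate_cbc_events",
    "inject_missingness",
    "simulate_study",
    "write_study",
]

#: covariate -> missing fraction, patterned on the "unknown" rows of a large
#: carrier cohort (ER of the first tumour unknown in over half of subjects).
DEFAULT_MISSINGNESS = {
    "family_history": 0.45,
    "er_bc1": 0.56,
    "node_status": 0.55,
    "tumor_size": 0.59,
    "chemo": 0.67,
    "hormone_therapy": 0.68,
    "trastuzumab": 0.76,
    "radiotherapy": 0.69,
    "cbc_er_status": 0.61,
}


@dataclass
class SimulationConfig:
    """Generative truth for one synthetic study.

    Time for the event process is measured in years since the first breast
    cancer (BC1), with delayed entry fixed at 1.0 year.  The CBC hazard for a
    subject with standardized PRS ``z`` and age at first cancer ``a`` is

        lambda(t | z, a) = lambda_b(t) * exp((beta_true + gamma_true * a) * z)

    with ``lambda_b`` piecewise constant.  When ``calibrate_events`` is set,
    the baseline is rescaled so the expected event fraction matches
    ``target_event_fraction`` under the drawn censoring times.
    """

    n_subjects: int = 6591
    n_variants: int = 313
    target_event_fraction: float = 1402 / 6591
    beta_true: float = math.log(1.12)
    gamma_true: float = 0.0
    #: piecewise-constant baseline hazard: breakpoints (years since BC1,
    #: starting at entry) and one rate per interval, per year.
    hazard_breakpoints: tuple[float, ...] = (1.0,)
    hazard_rates: tuple[float, ...] = (0.032,)
    age_bc1_mean: float = 41.8
    age_bc1_sd: float = 10.0
    age_bc1_bounds: tuple[float, float] = (18.0, 85.0)
    n_countries: int = 5
    #: probabilities of family sizes 1, 2, 3 (mostly singletons, as in
    #: consortium family data where <10% of clusters have >1 member)
    family_size_probs: tuple[float, float, float] = (0.90, 0.08, 0.02)
    #: lag from BC1 to baseline ascertainment: lognormal(mu, sigma) + 1 year
    baseline_lag_logmu: float = math.log(6.0)
    baseline_lag_logsd: float = 0.8
    rrm_fraction: float = 0.03
    rrm_mean_delay: float = 5.0
    death_fraction: float = 0.008
    death_mean_delay: float = 8.0
    insitu_fraction: float = 0.10
    cbc_er_positive_fraction: float = 0.20
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    calibrate_events: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_event_fraction < 1:
            raise ValueError("target_event_fraction must lie in (0, 1)")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if any(r <= 0 for r in self.hazard_rates):
            raise ValueError("hazard rates must be positive")
        if len(self.hazard_breakpoints) != len(self.hazard_rates):
            raise ValueError("need one rate per breakpoint interval")
        for name, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {name!r} outside [0, 1]")
        if abs(sum(self.family_size_probs) - 1.0) > 1e-9:
            raise ValueError("family_size_probs must sum to 1")

    def child_seed(self, stage: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))


# ---------------------------------------------------------------------------
# variant panel and genotypes
# ---------------------------------------------------------------------------

_NUCS = np.array(list("ACGT"))


def generate_variant_panel(
    n_variants: int,
    seed: int | np.random.SeedSequence = 0,
    variance_target: float = 1.0,
) -> pd.DataFrame:
    """Draw a synthetic variant weight panel.

    Effect-allele frequencies are uniform on (0.01, 0.5); per-allele weights
    are drawn normal and rescaled so the raw-score variance under
    linkage equilibrium, ``sum_i 2 p_i (1 - p_i) w_i**2``, equals
    ``variance_target`` exactly.  The ER-positive and ER-negative flavours
    are correlated perturbations of the overall weights, mimicking
    subtype-reweighted panels.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.01, 0.5, size=n_variants)
    w = rng.normal(0.0, 1.0, size=n_variants)

    def _rescale(wts: np.ndarray) -> np.ndarray:
        var = np.sum(2.0 * p * (1.0 - p) * wts**2)
        return wts * math.sqrt(variance_target / var)

    w = _rescale(w)
    w_pos = _rescale(0.9 * w + 0.1 * rng.normal(0.0, np.abs(w).mean(), n_variants))
    w_neg = _rescale(0.9 * w + 0.1 * rng.normal(0.0, np.abs(w).mean(), n_variants))

    eff_idx = rng.integers(0, 4, size=n_variants)
    oth_idx = (eff_idx + rng.integers(1, 4, size=n_variants)) % 4
    return pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + i}" for i in range(n_variants)],
            "chrom": [str(1 + i % 22) for i in range(n_variants)],
            "pos": np.arange(1, n_variants + 1) * 10_000 + 123,
            "effect_allele": _NUCS[eff_idx],
            "other_allele": _NUCS[oth_idx],
            "eaf": p,
            "weight_overall": w,
            "weight_erpos": w_pos,
            "weight_erneg": w_neg,
        }
    )


def _sample_family_sizes(
    n_subjects: int, probs: tuple[float, ...], rng: np.random.Generator
) -> np.ndarray:
    sizes = []
    total = 0
    while total < n_subjects:
        s = int(rng.choice([1, 2, 3], p=probs))
        s = min(s, n_subjects - total)
        sizes.append(s)
        total += s
    return np.asarray(sizes)


def generate_families_genotypes(
    panel: pd.DataFrame,
    n_subjects: int,
    family_size_probs: tuple[float, float, float] = (0.90, 0.08, 0.02),
    seed: int | np.random.SeedSequence = 0,
    fractional_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate genotype dosages with genuine family structure.

    Singleton subjects are Hardy–Weinberg founders at the panel frequencies.
    Families of size 2 or 3 are full sibships: two unobserved parental
    genotypes are drawn under HWE and each child receives one allele
    transmitted at random from each parent, giving the Mendelian sib-sib
    genotype correlation of one half.

    Returns the dosage matrix (subjects x variants) and a family-id Series
    aligned to its index.  ``fractional_noise_sd`` adds truncated Gaussian
    noise to mimic imputed expected allele counts.
    """
    if len(panel) == 0:
        raise ValueError("empty variant panel")
    rng = np.random.default_rng(seed)
    p = panel["eaf"].to_numpy()
    m = len(p)

    sizes = _sample_family_sizes(n_subjects, family_size_probs, rng)
    dosages = np.empty((n_subjects, m), dtype=float)
    family_ids = np.empty(n_subjects, dtype=object)

    row = 0
    for fam_idx, size in enumerate(sizes):
        fid = f"F{fam_idx:06d}"
        if size == 1:
            dosages[row] = rng.binomial(2, p)
        else:
            # parental haplotype pairs; each child draws one allele per parent
            mother = rng.random((2, m)) < p
            father = rng.random((2, m)) < p
            for k in range(size):
                pick_m = rng.integers(0, 2, size=m)
                pick_f = rng.integers(0, 2, size=m)
                dosages[row + k] = (
                    mother[pick_m, np.arange(m)].astype(float)
                    + father[pick_f, np.arange(m)]
                )
        family_ids[row : row + size] = fid
        row += size

    if fractional_noise_sd > 0:
        dosages = np.clip(
            dosages + rng.normal(0.0, fractional_noise_sd, dosages.shape), 0.0, 2.0
        )

    subject_ids = [f"S{i:06d}" for i in range(n_subjects)]
    geno = pd.DataFrame(dosages, index=subject_ids, columns=panel["variant_id"])
    geno.index.name = "subject_id"
    return geno, pd.Series(family_ids, index=geno.index, name="family_id")


# ---------------------------------------------------------------------------
# cohort phenotypes
# ---------------------------------------------------------------------------

def _truncnorm(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: SimulationConfig,
    z: np.ndarray,
    family_ids: pd.Series | None = None,
) -> pd.DataFrame:
    """Build subject records around a vector of standardized PRS values.

    Draws age at first breast cancer (truncated normal), country, birth year,
    baseline ascertainment age and competing censoring ages, then attaches
    CBC event times via :func:`simulate_cbc_events`.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    n = len(z)
    rng = np.random.default_rng(config.child_seed(1))

    age_bc1 = _truncnorm(
        config.age_bc1_mean, config.age_bc1_sd, *config.age_bc1_bounds, size=n, rng=rng
    )
    country_probs = np.full(config.n_countries, 1.0 / config.n_countries)
    country = rng.choice(
        [f"C{i:02d}" for i in range(config.n_countries)], size=n, p=country_probs
    )

    lag = 1.0 + rng.lognormal(config.baseline_lag_logmu, config.baseline_lag_logsd, n)
    age_baseline = age_bc1 + lag
    ascert_year = rng.uniform(1995, 2015, n)
    birth_year = np.round(ascert_year - age_baseline).astype(int)

    age_rrm = np.where(
        rng.random(n) < config.rrm_fraction,
        age_bc1 + 1.0 + rng.exponential(config.rrm_mean_delay, n),
        np.nan,
    )
    age_death = np.where(
        rng.random(n) < config.death_fraction,
        age_bc1 + 1.0 + rng.exponential(config.death_mean_delay, n),
        np.nan,
    )

    if family_ids is None:
        fam = pd.Series([f"F{i:06d}" for i in range(n)])
    else:
        fam = pd.Series(np.asarray(family_ids), name="family_id")

    records = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "family_id": fam.to_numpy(),
            "country": country,
            "birth_year": birth_year,
            "age_bc1": age_bc1,
            "age_baseline": age_baseline,
            "age_rrm": age_rrm,
            "age_death": age_death,
            "age_distant_relapse": np.nan,
            "metastatic_bc1": "no",
            "z": z,
        }
    )
    records = simulate_cbc_events(records, z, config)
    records = _attach_covariates(records, rng)
    return records


def simulate_cbc_events(
    records: pd.DataFrame, z: np.ndarray, config: SimulationConfig
) -> pd.DataFrame:
    """Attach CBC event times by inverting the piecewise-exponential model.

    The censoring age is min(baseline, mastectomy, death).  Event times are
    generated on the delayed-entry window (from one year after BC1) and kept
    only when they precede censoring.  With ``calibrate_events`` the baseline
    hazard is rescaled so the expected event fraction, conditional on the
    drawn censoring times and linear predictors, equals the target.
    """
    records = records.copy()
    z = np.asarray(z, dtype=float)
    rng = np.random.default_rng(config.child_seed(2))
    n = len(records)

    eta = (config.beta_true + config.gamma_true * records["age_bc1"].to_numpy()) * z
    if np.any(np.abs(eta) > 50):
        raise OverflowError("linear predictor too large; hazard would overflow")
    rel_hazard = np.exp(eta)

    censor_age = np.fmin(
        records["age_baseline"].to_numpy(),
        np.fmin(records["age_rrm"].to_numpy(), records["age_death"].to_numpy()),
    )
    censor_t = censor_age - records["age_bc1"].to_numpy()  # years since BC1

    breaks = np.asarray(config.hazard_breakpoints)
    rates = np.asarray(config.hazard_rates, dtype=float)

    def cumhaz(t: np.ndarray, scale: float) -> np.ndarray:
        """Baseline cumulative hazard from entry (breaks[0]) to t."""
        total = np.zeros_like(t, dtype=float)
        for j, rate in enumerate(rates):
            lo = breaks[j]
            hi = breaks[j + 1] if j + 1 < len(breaks) else np.inf
            total += scale * rate * np.clip(t - lo, 0.0, hi - lo)
        return total

    scale = 1.0
    if config.calibrate_events:
        exposure = np.clip(censor_t, breaks[0], None)

        def expected_fraction(s: float) -> float:
            prob = 1.0 - np.exp(-cumhaz(exposure, s) * rel_hazard)
            return float(prob.mean()) - config.target_event_fraction

        scale = optimize.brentq(expected_fraction, 1e-8, 1e4, xtol=1e-10)

    # inversion for piecewise-constant hazard: walk the intervals
    u = rng.exponential(1.0, n)  # target cumulative hazard (incl. rel hazard)
    target = u / rel_hazard / scale
    event_t = np.full(n, np.inf)
    acc = np.zeros(n)
    for j, rate in enumerate(rates):
        lo = breaks[j]
        hi = breaks[j + 1] if j + 1 < len(breaks) else np.inf
        width = hi - lo
        within = (target - acc) / rate
        hit = (event_t == np.inf) & (within <= width)
        event_t[hit] = lo + within[hit]
        acc += rate * width

    is_event = event_t < censor_t
    age_cbc = np.where(is_event, records["age_bc1"].to_numpy() + event_t, np.nan)

    records["age_cbc"] = age_cbc
    records["cbc_invasive"] = pd.array(
        np.where(is_event, rng.random(n) >= config.insitu_fraction, pd.NA),
        dtype="boolean",
    )
    er_pos = rng.random(n) < config.cbc_er_positive_fraction
    records["cbc_er_status"] = np.where(
        is_event, np.where(er_pos, "positive", "negative"), "none"
    )
    return records


_COVARIATE_LEVELS = {
    "family_history": (["0", "1", "2+"], [0.21, 0.33, 0.46]),
    "er_bc1": (["negative", "positive"], [0.75, 0.25]),
    "node_status": (["negative", "positive"], [0.66, 0.34]),
    "tumor_size": (["T1", "T2", "T3", "T4"], [0.60, 0.36, 0.03, 0.01]),
    "chemo": (["no", "yes"], [0.34, 0.66]),
    "hormone_therapy": (["no", "yes"], [0.69, 0.31]),
    "trastuzumab": (["no", "yes"], [0.98, 0.02]),
    "radiotherapy": (["no", "yes"], [0.33, 0.67]),
    "variant_class": (["I", "II", "III"], [0.65, 0.26, 0.09]),
}


def _attach_covariates(records: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    records = records.copy()
    n = len(records)
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        records[name] = rng.choice(levels, size=n, p=probs)
    return records


def inject_missingness(
    records: pd.DataFrame,
    missingness_rates: dict[str, float],
    mechanism: str = "MCAR",
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank covariate entries at the configured rates.

    Under ``MCAR`` every entry is blanked independently; under
    ``MAR-on-country`` the per-subject blanking probability is tilted by
    country (same marginal rate on average) so the imputer can be stressed
    with a mechanism that is missing-at-random given an observed covariate.

    Returns ``(records_with_missing, truth)`` where ``truth`` holds the
    original values of the masked columns for recovery checks.
    """
    if mechanism not in {"MCAR", "MAR-on-country"}:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    for name, rate in missingness_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    truth = records[list(missingness_rates)].copy()

    if mechanism == "MAR-on-country":
        countries = np.unique(records["country"])
        tilt = {
            c: t for c, t in zip(countries, np.linspace(0.5, 1.5, len(countries)))
        }
        weight = records["country"].map(tilt).to_numpy()
    else:
        weight = np.ones(len(records))

    for name, rate in missingness_rates.items():
        prob = np.clip(rate * weight, 0.0, 1.0)
        # cbc ER status can only be missing where a CBC occurred
        mask = rng.random(len(out)) < prob
        if name == "cbc_er_status":
            mask &= out[name].to_numpy() != "none"
        out.loc[mask, name] = (
            "unknown" if out[name].dtype == object else np.nan
        )
    return out, truth


# ---------------------------------------------------------------------------
# full study + file emission
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig, with_genotypes: bool = True) -> dict:
    """Run the whole generator: panel -> genotypes -> PRS -> cohort -> missingness.

    When ``with_genotypes`` is false, z is drawn directly standard normal
    (useful for survival-layer studies that do not exercise scoring).
    Returns a dict with keys ``panel, genotypes, family_ids, records, truth,
    records_complete``.
    """
    out: dict = {"config": config}
    if with_genotypes:
        panel = generate_variant_panel(config.n_variants, config.child_seed(0))
        geno, fam = generate_families_genotypes(
            panel, config.n_subjects, config.family_size_probs, config.child_seed(3)
        )
        raw = geno.to_numpy() @ panel["weight_erneg"].to_numpy()
        z = (raw - raw.mean()) / 1.0  # reference SD 1 by panel construction
        out.update(panel=panel, genotypes=geno, family_ids=fam)
        records = generate_cohort(config, z, family_ids=fam)
    else:
        rng = np.random.default_rng(config.child_seed(4))
        z = rng.standard_normal(config.n_subjects)
        sizes = _sample_family_sizes(
            config.n_subjects, config.family_size_probs, rng
        )
        fam = pd.Series(np.repeat([f"F{i:06d}" for i in range(len(sizes))], sizes))
        records = generate_cohort(config, z, family_ids=fam)
    out["records_complete"] = records
    masked, truth = inject_missingness(
        records, config.missingness_rates, seed=config.child_seed(5)
    )
    out["records"] = masked
    out["truth"] = truth
    return out


def write_study(study: dict, outdir: str | Path, vcf: bool = False) -> None:
    """Emit weight TSV, dosage CSV, phenotype CSV and truth JSON (optionally VCF)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: SimulationConfig = study["config"]
    if "panel" in study:
        study["panel"].to_csv(outdir / "weights.tsv", sep="\t", index=False)
        study["genotypes"].to_csv(outdir / "dosages.csv")
        if vcf:
            _write_dosage_vcf(study["panel"], study["genotypes"], outdir / "dosages.vcf")
    study["records"].to_csv(outdir / "phenotypes.csv", index=False)
    truth = {
        "beta_true": config.beta_true,
        "gamma_true": config.gamma_true,
        "hazard_breakpoints": list(config.hazard_breakpoints),
        "hazard_rates": list(config.hazard_rates),
        "seed": config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    (outdir / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str)
    )


def _write_dosage_vcf(panel: pd.DataFrame, geno: pd.DataFrame, path: Path) -> None:
    """Minimal VCF with a per-sample DS (dosage) FORMAT field."""
    samples = list(geno.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Expected effect (ALT) allele dosage">\n'
        )
        for chrom in panel["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        mat = geno.to_numpy().T  # variants x subjects
        for i, row in enumerate(panel.itertuples(index=False)):
            ds = "\t".join(f"{d:g}" for d in mat[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\tPASS\t.\tDS\t{ds}\n"
            )
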