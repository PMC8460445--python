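"""Stratified, cluster-robust Cox models and diagnostics for CBC risk.

All fits use delayed entry (time at risk begins one year after the first
breast cancer), stratification by country, adjustment for birth-cohort
quartiles, and a cluster sandwich variance over family identifiers so that
related subjects do not deflate standard errors.  Ties are handled by the
Efron approximation (lifelines' default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "CoxFit",
    "PercentileBands",
    "CIndexResult",
    "fit_cox_continuous",
    "compute_percentile_bands",
    "assign_bands",
    "fit_cox_categorical",
    "predict_band_hrs",
    "fit_interaction",
    "fit_age_group_models",
    "fit_variant_class_models",
    "schoenfeld_ph_test",
    "rcs_basis",
    "rcs_linearity_check",
    "harrell_c",
    "km_cumulative_risk",
]

DEFAULT_BAND_PERCENTILES = (5, 10, 20, 40, 60, 80, 90, 95)
AGE_GROUPS = (("<40", -np.inf, 40.0), ("40-50", 40.0, 50.0), (">=50", 50.0, np.inf))


@dataclass
class CoxFit:
    """Summary of one Cox partial-likelihood fit."""

    coefficients: dict[str, float]
    robust_se: dict[str, float]
    naive_se: dict[str, float]
    hr: dict[str, float]
    ci95_low: dict[str, float]
    ci95_high: dict[str, float]
    p: dict[str, float]
    n_subjects: int
    n_events: int
    log_likelihood: float
    strata_var: str = "stratum"
    cluster_var: str = "cluster"
    ties_method: str = "efron"
    covariate_names: list[str] = field(default_factory=list)
    naive_variance: np.ndarray | None = field(default=None, repr=False)
    model: CoxPHFitter | None = field(default=None, repr=False)

    @classmethod
    def from_lifelines(cls, cph: CoxPHFitter, df: pd.DataFrame) -> "CoxFit":
        summ = cph.summary
        naive_var = np.asarray(cph.variance_matrix_)
        return cls(
            coefficients=summ["coef"].to_dict(),
            robust_se=summ["se(coef)"].to_dict(),
            naive_se=dict(zip(summ.index, np.sqrt(np.diag(naive_var)))),
            hr=summ["exp(coef)"].to_dict(),
            ci95_low=summ["exp(coef) lower 95%"].to_dict(),
            ci95_high=summ["exp(coef) upper 95%"].to_dict(),
            p=summ["p"].to_dict(),
            n_subjects=len(df),
            n_events=int(df["event"].sum()),
            log_likelihood=float(cph.log_likelihood_),
            covariate_names=list(summ.index),
            naive_variance=naive_var,
            model=cph,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "robust_se": self.robust_se,
            "hr": self.hr,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p": self.p,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
        }


def _fit(
    df: pd.DataFrame,
    covariates: list[str],
    robust: bool = True,
) -> CoxFit:
    """Fit on pre-encoded numeric covariate columns (keeps the design
    matrix recoverable as df[covariates] for residual computations)."""
    if df["event"].sum() == 0:
        raise ValueError("no events in any stratum; cannot fit")
    if not np.all(np.isfinite(df["z"])):
        raise ValueError("non-finite PRS values")
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="exit",
        event_col="event",
        entry_col="entry",
        strata=["stratum"],
        cluster_col="cluster" if robust else None,
        formula=" + ".join(covariates),
        robust=robust,
    )
    fit = CoxFit.from_lifelines(cph, df)
    fit.covariate_names = covariates
    return fit


def _adjustment_terms(df: pd.DataFrame, adjust_birth_cohort: bool) -> list[str]:
    """Dummy-encode birth-cohort quartiles in place; return added columns."""
    terms: list[str] = []
    if adjust_birth_cohort and "birth_cohort_q" in df.columns:
        levels = sorted(df["birth_cohort_q"].dropna().unique())
        for level in levels[1:]:
            col = f"bcq_{level}"
            df[col] = (df["birth_cohort_q"] == level).astype(float)
            terms.append(col)
    return terms


def fit_cox_continuous(
    intervals: pd.DataFrame,
    adjust_birth_cohort: bool = True,
    robust: bool = True,
) -> CoxFit:
    """Continuous per-SD PRS model: country strata, family clusters."""
    df = intervals.copy()
    terms = ["z"] + _adjustment_terms(df, adjust_birth_cohort)
    return _fit(df, terms, robust=robust)


# ---------------------------------------------------------------------------
# percentile-band (categorical) analysis
# ---------------------------------------------------------------------------

@dataclass
class PercentileBands:
    """PRS category edges from the unilateral-case score distribution."""

    edges: np.ndarray  # interior percentile cut points, strictly increasing
    percentiles: tuple[float, ...] = DEFAULT_BAND_PERCENTILES
    reference_label: str = "40-60"

    @property
    def labels(self) -> list[str]:
        pct = [0, *self.percentiles, 100]
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(pct[:-1], pct[1:])]


def compute_percentile_bands(
    z_unilateral: np.ndarray, percentiles: tuple[float, ...] = DEFAULT_BAND_PERCENTILES
) -> PercentileBands:
    """Band edges at the stated quantiles of the unilateral-case PRS.

    Uses linear-interpolation quantiles; edges must be strictly increasing,
    which fails only for nearly-degenerate score distributions.
    """
    z = np.asarray(z_unilateral, dtype=float)
    if len(z) < 100:
        raise ValueError("need at least 100 unilateral cases to set band edges")
    edges = np.quantile(z, np.asarray(percentiles) / 100.0)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("too few unique PRS values to form distinct bands")
    return PercentileBands(edges=edges, percentiles=tuple(percentiles))


def assign_bands(z: np.ndarray, bands: PercentileBands) -> pd.Categorical:
    """Map each score to its half-open band [lower, upper)."""
    idx = np.searchsorted(bands.edges, np.asarray(z, dtype=float), side="right")
    labels = bands.labels
    return pd.Categorical([labels[i] for i in idx], categories=labels)


def fit_cox_categorical(intervals: pd.DataFrame, bands: PercentileBands) -> CoxFit:
    """Indicator-coded band model, reference band omitted.

    Empty bands yield undefined (absent) hazard ratios; the fit proceeds on
    the remaining indicators.
    """
    df = intervals.copy()
    band_labels = assign_bands(df["z"].to_numpy(), bands)
    terms = []
    for label in bands.labels:
        if label == bands.reference_label:
            continue
        col = f"band_{label.replace('-', '_')}"
        df[col] = (band_labels == label).astype(float)
        if df[col].sum() > 0:
            terms.append(col)
    terms += _adjustment_terms(df, True)
    fit = _fit(df, terms)
    fit.model.band_labels = band_labels  # type: ignore[union-attr]
    return fit


def predict_band_hrs(beta: float, bands: PercentileBands) -> dict[str, float]:
    """Expected band hazard ratios implied by a continuous per-SD log HR.

    Assuming z is standard normal, the expected relative hazard within a band
    B = (a, b) is E[e^{beta z} | z in B] = e^{beta^2/2}
    (Phi(b - beta) - Phi(a - beta)) / (Phi(b) - Phi(a)); each band's HR is
    that expectation relative to the reference band.  This is the smooth
    curve a categorical fit should track when the continuous model holds.
    """
    pct = np.array([0.0, *bands.percentiles, 100.0]) / 100.0
    qs = stats.norm.ppf(pct)  # -inf .. +inf

    def band_mean(a: float, b: float) -> float:
        num = stats.norm.cdf(b - beta) - stats.norm.cdf(a - beta)
        den = stats.norm.cdf(b) - stats.norm.cdf(a)
        return math.exp(beta**2 / 2.0) * num / den

    means = {
        label: band_mean(qs[i], qs[i + 1]) for i, label in enumerate(bands.labels)
    }
    ref = means[bands.reference_label]
    return {label: m / ref for label, m in means.items()}


# ---------------------------------------------------------------------------
# interaction and subgroup fits
# ---------------------------------------------------------------------------

def fit_interaction(intervals: pd.DataFrame) -> CoxFit:
    """Main PRS effect plus PRS x (uncentred) age-at-first-cancer interaction.

    The main-effect coefficient is then the log HR per SD extrapolated to age
    zero, and the interaction coefficient the change in log HR per year of
    age at first diagnosis.
    """
    if intervals["age_bc1"].isna().any():
        raise ValueError("age_bc1 required for all subjects")
    df = intervals.copy()
    df["z_age"] = df["z"] * df["age_bc1"]
    terms = ["z", "z_age"] + _adjustment_terms(df, True)
    return _fit(df, terms)


def fit_age_group_models(intervals: pd.DataFrame) -> dict[str, CoxFit]:
    """Refit the continuous model within age-at-first-cancer groups.

    Boundaries: <40, [40, 50), [50, inf) — age exactly 40 belongs to the
    middle group and exactly 50 to the oldest.
    """
    fits: dict[str, CoxFit] = {}
    for label, lo, hi in AGE_GROUPS:
        sub = intervals[(intervals["age_bc1"] >= lo) & (intervals["age_bc1"] < hi)]
        if len(sub) == 0 or sub["event"].sum() == 0:
            continue  # empty group skipped
        fits[label] = fit_cox_continuous(sub)
    return fits


def fit_variant_class_models(intervals: pd.DataFrame) -> dict[str, CoxFit]:
    """Continuous-model refits within pathogenic-variant classes I and II."""
    fits: dict[str, CoxFit] = {}
    for cls in ("I", "II"):
        sub = intervals[intervals["variant_class"] == cls]
        if len(sub) and sub["event"].sum() > 0:
            fits[cls] = fit_cox_continuous(sub)
    return fits


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _ensure_design(df: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Recreate encoded covariate columns (dummies, interaction) on a copy."""
    df = df.copy()
    for name in names:
        if name in df.columns:
            continue
        if name.startswith("bcq_"):
            df[name] = (df["birth_cohort_q"] == name[4:]).astype(float)
        elif name == "z_age":
            df[name] = df["z"] * df["age_bc1"]
        else:
            raise KeyError(f"cannot reconstruct covariate column {name!r}")
    return df


def schoenfeld_residuals(fit: CoxFit, intervals: pd.DataFrame) -> pd.DataFrame:
    """Schoenfeld residuals honouring delayed entry and country strata.

    For each event, the residual is the subject's covariate vector minus the
    risk-weighted covariate mean over the stratum risk set
    {entry < t <= exit} at the event time.  Returns one row per event with
    the event time in column ``_time``.
    """
    df = _ensure_design(intervals, fit.covariate_names).reset_index(drop=True)
    covs = fit.covariate_names
    beta = np.array([fit.coefficients[c] for c in covs])
    rows = []
    for _, sub in df.groupby("stratum", observed=True):
        x = sub[covs].to_numpy(dtype=float)
        entry = sub["entry"].to_numpy(dtype=float)
        exit_ = sub["exit"].to_numpy(dtype=float)
        event = sub["event"].to_numpy(dtype=int)
        w = np.exp(x @ beta)
        for i in np.flatnonzero(event == 1):
            t = exit_[i]
            at_risk = (entry < t) & (exit_ >= t)
            wr = w[at_risk]
            xbar = (wr[:, None] * x[at_risk]).sum(axis=0) / wr.sum()
            rows.append((t, *(x[i] - xbar)))
    out = pd.DataFrame(rows, columns=["_time", *covs]).sort_values("_time")
    return out.reset_index(drop=True)


def schoenfeld_ph_test(
    fit: CoxFit, intervals: pd.DataFrame, term: str = "z"
) -> float:
    """Proportional-hazards check: scaled Schoenfeld residuals vs KM time.

    The score statistic correlates the scaled Schoenfeld residuals of the
    term with Kaplan–Meier-transformed event time (the left-truncated KM
    estimate of the event distribution), referred to chi-squared with one
    degree of freedom — the Grambsch–Therneau test with the survival-function
    time transform.
    """
    if fit.n_events < 10:
        raise ValueError("too few events for a meaningful PH test")
    resid = schoenfeld_residuals(fit, intervals)
    covs = fit.covariate_names
    d = len(resid)
    scaled = d * resid[covs].to_numpy() @ np.asarray(fit.naive_variance)

    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=intervals["exit"],
        event_observed=intervals["event"],
        entry=intervals["entry"],
    )
    g = 1.0 - kmf.predict(resid["_time"].to_numpy()).to_numpy()
    g_c = g - g.mean()

    k = covs.index(term)
    se_k = fit.naive_se[term]
    stat = (g_c @ scaled[:, k]) ** 2 / (d * se_k**2 * (g_c**2).sum())
    return float(stats.chi2.sf(stat, df=1))


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterisation).

    For k knots returns k-2 nonlinear columns (the linear term is supplied
    separately); the curve is linear beyond the boundary knots and has
    continuous second derivatives at each knot.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def plus3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    cols = []
    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def rcs_linearity_check(intervals: pd.DataFrame) -> float:
    """Likelihood-ratio test of nonlinearity in the PRS effect.

    Adds restricted-cubic-spline terms (3 knots at the 10th/50th/90th
    percentiles of z) on top of the linear term and compares partial
    log-likelihoods; the null is a linear log-hazard in z.
    """
    z = intervals["z"].to_numpy()
    knots = np.quantile(z, [0.10, 0.50, 0.90])
    if len(np.unique(knots)) < 3:
        raise ValueError("degenerate PRS distribution; cannot place knots")
    df = intervals.copy()
    spline = rcs_basis(z, knots)
    spline_terms = []
    for j in range(spline.shape[1]):
        df[f"z_rcs{j}"] = spline[:, j]
        spline_terms.append(f"z_rcs{j}")
    adj = _adjustment_terms(df, True)
    # naive (non-robust) likelihoods are the correct objects for an LR test
    full = _fit(df, ["z", *spline_terms, *adj], robust=False)
    reduced = _fit(df, ["z", *adj], robust=False)
    lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    return float(stats.chi2.sf(max(lr, 0.0), df=len(spline_terms)))


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class CIndexResult:
    c: float
    ci95: tuple[float, float] | None
    n_comparable_pairs: float
    stratified_by: str = "stratum"


class _Fenwick:
    __slots__ = ("n", "tree")

    def __init__(self, n: int) -> None:
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def update(self, i: int, delta: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += delta
            i += i & (-i)

    def prefix(self, i: int) -> int:
        # count of items with rank <= i
        s = 0
        i += 1
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def _stratum_concordance(
    entry: np.ndarray, exit_: np.ndarray, event: np.ndarray, score: np.ndarray
) -> tuple[float, float]:
    """Concordant (ties counted half) and comparable pair counts, honouring
    delayed entry: a pair is comparable only if the non-failing member is in
    the risk set at the failure time (entry < t <= exit)."""
    n = len(exit_)
    ranks = stats.rankdata(score, method="dense").astype(int) - 1
    n_ranks = int(ranks.max()) + 1

    order_entry = np.argsort(entry, kind="stable")
    order_exit = np.argsort(exit_, kind="stable")
    event_idx = np.flatnonzero(event == 1)
    event_times = exit_[event_idx]
    order_events = event_idx[np.argsort(event_times, kind="stable")]

    tree = _Fenwick(n_ranks)
    active = np.zeros(n, dtype=bool)
    pe = px = 0
    concordant = 0.0
    comparable = 0.0

    i = 0
    m = len(order_events)
    while i < m:
        t = exit_[order_events[i]]
        group = [order_events[i]]
        while i + 1 < m and exit_[order_events[i + 1]] == t:
            i += 1
            group.append(order_events[i])
        # activate entry < t, deactivate exit < t
        while pe < n and entry[order_entry[pe]] < t:
            j = order_entry[pe]
            tree.update(ranks[j], 1)
            active[j] = True
            pe += 1
        while px < n and exit_[order_exit[px]] < t:
            j = order_exit[px]
            if active[j]:
                tree.update(ranks[j], -1)
                active[j] = False
            px += 1
        n_active = tree.prefix(n_ranks - 1)
        group_ranks = ranks[group]
        for idx in group:
            if not active[idx]:  # entered exactly at t; not at risk
                continue
            r = ranks[idx]
            less = tree.prefix(r - 1) if r > 0 else 0
            eq = tree.prefix(r) - less
            # exclude self and other tied events at t from the risk set
            less -= int(np.sum(group_ranks < r))
            eq -= int(np.sum(group_ranks == r))  # includes self
            comp = n_active - len(group)
            if comp <= 0:
                continue
            comparable += comp
            concordant += less + 0.5 * eq
        i += 1
    return concordant, comparable


def harrell_c(
    intervals: pd.DataFrame,
    score_col: str = "z",
    n_bootstrap: int = 0,
    seed: int = 0,
) -> CIndexResult:
    """Harrell's C for a risk score, stratified by country.

    Pairs are counted within strata only, and only where the risk sets
    overlap under delayed entry.  A higher score failing earlier is
    concordant; score ties count one half.  The optional confidence interval
    is a cluster bootstrap over families (resampling whole clusters).
    """

    def _c(df: pd.DataFrame) -> tuple[float, float]:
        conc = comp = 0.0
        for _, sub in df.groupby("stratum", observed=True):
            if sub["event"].sum() == 0:
                continue
            c1, c2 = _stratum_concordance(
                sub["entry"].to_numpy(dtype=float),
                sub["exit"].to_numpy(dtype=float),
                sub["event"].to_numpy(dtype=int),
                sub[score_col].to_numpy(dtype=float),
            )
            conc += c1
            comp += c2
        return conc, comp

    conc, comp = _c(intervals)
    if comp == 0:
        raise ValueError("no comparable pairs")
    c = conc / comp

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        families = intervals["cluster"].unique()
        grouped = dict(tuple(intervals.groupby("cluster", observed=True)))
        cs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.choice(families, size=len(families), replace=True)
            boot = pd.concat([grouped[f] for f in pick], ignore_index=True)
            bc, bp = _c(boot)
            cs[b] = bc / bp if bp > 0 else np.nan
        lo, hi = np.nanpercentile(cs, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return CIndexResult(c=float(c), ci95=ci, n_comparable_pairs=float(comp))


# ---------------------------------------------------------------------------
# Kaplan–Meier cumulative risk
# ---------------------------------------------------------------------------

def km_cumulative_risk(
    intervals: pd.DataFrame, horizon: float
) -> tuple[float, tuple[float, float]]:
    """Cumulative CBC risk 1 - S(horizon) with delayed entry.

    Uses the product-limit estimator with left truncation and lifelines'
    Greenwood-based confidence band, evaluated at the horizon (years since
    first breast cancer).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=intervals["exit"],
        event_observed=intervals["event"],
        entry=intervals["entry"],
    )
    s = float(kmf.predict(horizon))
    ci_df = kmf.confidence_interval_survival_function_
    idx = ci_df.index.searchsorted(horizon, side="right") - 1
    if idx < 0:
        return 0.0, (0.0, 0.0)
    lo_s, hi_s = ci_df.iloc[idx]
    return 1.0 - s, (1.0 - float(hi_s), 1.0 - float(lo_s))
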