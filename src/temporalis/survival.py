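"""CSA-stratified survival analysis.

The clinical question: is a larger temporalis muscle cross-sectional area
(CSA), a sarcopenia surrogate, associated with longer overall or
progression-free survival?  The analysis pipeline is the standard one for
a continuous biomarker dichotomised at the cohort median:

1. :func:`dichotomize_by_median` — split each cohort at its own CSA median
   (never pooled across cohorts).
2. :func:`km_logrank` — Kaplan–Meier product-limit curves per group with a
   two-sided log-rank test.
3. :func:`cox_fit` — Cox proportional-hazards models (Efron tie handling),
   univariate for the group effect or adjusted for age and sex.
4. :func:`cohort_characteristics` — Pearson CSA-vs-age correlation and a
   Welch t-test of CSA by sex.

Codings: group high = 1 / low = 0; sex male = 1 / female = 0.  The
median-tie rule defaults to "csa >= median goes high" and is configurable,
since reasonable cohorts have been split under either convention.
Model fitting delegates to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class PatientRecord:
    """One subject entering the survival analysis."""

    id: str
    csa_mm2: float
    age: float
    sex: str  # "male" | "female"
    time_months: float
    event: int  # 1 = event observed, 0 = censored
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(f"{self.id}: time_months must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.id}: event must be 0 or 1")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.id}: sex must be 'male' or 'female'")


@dataclass
class DichotomyResult:
    median_csa_mm2: float
    group: dict[str, str]  # patient id -> "low" | "high"
    n_low: int
    n_high: int
    flags: list[str] = field(default_factory=list)


@dataclass
class KMGroup:
    times: np.ndarray
    survival: np.ndarray
    median_months: float  # inf if not reached
    q25_months: float
    q75_months: float
    n: int
    n_events: int


@dataclass
class KMResult:
    groups: dict[str, KMGroup]
    logrank_chi2: float
    logrank_p: float


@dataclass
class CovariateEffect:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


@dataclass
class CoxResult:
    effects: dict[str, CovariateEffect]
    model_type: str  # "univariate" | "multivariate"
    n: int
    n_events: int


def dichotomize_by_median(
    cohort: list[PatientRecord], high_if_equal: bool = True
) -> DichotomyResult:
    """Split a cohort at its CSA median.

    For even n the median is the midpoint of the two central values.  A
    patient whose CSA equals the median goes to the high group under the
    default rule (``high_if_equal=True``); the opposite convention is
    available because published cohorts have used both.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients to dichotomize")
    csa = np.array([p.csa_mm2 for p in cohort])
    med = float(np.median(csa))
    if high_if_equal:
        is_high = csa >= med
    else:
        is_high = csa > med
    group = {p.id: ("high" if h else "low") for p, h in zip(cohort, is_high)}
    flags = []
    if is_high.all() or not is_high.any():
        flags.append("degenerate_split")
    return DichotomyResult(
        median_csa_mm2=med,
        group=group,
        n_low=int((~is_high).sum()),
        n_high=int(is_high.sum()),
        flags=flags,
    )


def _km_quantile(kmf: KaplanMeierFitter, q: float) -> float:
    """First time at which S(t) <= q; inf when never reached."""
    sf = kmf.survival_function_.iloc[:, 0]
    hit = sf[sf <= q]
    return float(hit.index[0]) if len(hit) else math.inf


def km_logrank(cohort: list[PatientRecord], groups: DichotomyResult) -> KMResult:
    """Kaplan–Meier curves per CSA group and the two-sided log-rank test.

    Median survival per group is the first time the product-limit estimate
    drops to 0.5 or below; quartile times are reported the same way.
    """
    by_group: dict[str, list[PatientRecord]] = {"low": [], "high": []}
    for p in cohort:
        by_group[groups.group[p.id]].append(p)
    for name, members in by_group.items():
        if not members:
            raise ValueError(f"group {name!r} has zero subjects")

    fitted: dict[str, KMGroup] = {}
    for name, members in by_group.items():
        t = np.array([p.time_months for p in members])
        e = np.array([p.event for p in members])
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        sf = kmf.survival_function_
        fitted[name] = KMGroup(
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            median_months=_km_quantile(kmf, 0.5),
            q25_months=_km_quantile(kmf, 0.75),
            q75_months=_km_quantile(kmf, 0.25),
            n=len(members),
            n_events=int(e.sum()),
        )

    lo, hi = by_group["low"], by_group["high"]
    res = logrank_test(
        [p.time_months for p in lo],
        [p.time_months for p in hi],
        event_observed_A=[p.event for p in lo],
        event_observed_B=[p.event for p in hi],
    )
    return KMResult(
        groups=fitted,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def _cohort_frame(cohort: list[PatientRecord], groups: DichotomyResult | None) -> pd.DataFrame:
    rows = {
        "time": [p.time_months for p in cohort],
        "event": [p.event for p in cohort],
        "age": [p.age for p in cohort],
        "sex": [1 if p.sex == "male" else 0 for p in cohort],
        "csa": [p.csa_mm2 for p in cohort],
    }
    if groups is not None:
        rows["group"] = [1 if groups.group[p.id] == "high" else 0 for p in cohort]
    return pd.DataFrame(rows)


def cox_fit(
    cohort: list[PatientRecord],
    covariates: tuple[str, ...] = ("group",),
    groups: DichotomyResult | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``covariates`` is a subset of {"group", "age", "sex"}; "group" requires
    a :class:`DichotomyResult`.  Hazard ratios are exp(coef) with Wald 95%
    CIs exp(coef ± 1.96·SE) and two-sided Wald p-values.
    """
    allowed = {"group", "age", "sex"}
    bad = set(covariates) - allowed
    if bad:
        raise ValueError(f"unknown covariates {sorted(bad)}; allowed: {sorted(allowed)}")
    if "group" in covariates and groups is None:
        raise ValueError("covariate 'group' requires a DichotomyResult")
    df = _cohort_frame(cohort, groups)
    n_events = int(df["event"].sum())
    if n_events < 1:
        raise ValueError("Cox model requires at least one observed event")
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant; model is degenerate")

    cols = ["time", "event", *covariates]
    cph = CoxPHFitter()
    try:
        cph.fit(df[cols], duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    effects = {}
    summ = cph.summary
    for cov in covariates:
        row = summ.loc[cov]
        effects[cov] = CovariateEffect(
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            coef=float(row["coef"]),
            se=float(row["se(coef)"]),
        )
    return CoxResult(
        effects=effects,
        model_type="univariate" if len(covariates) == 1 else "multivariate",
        n=len(cohort),
        n_events=n_events,
    )


@dataclass
class CohortCharacteristics:
    pearson_r_csa_age: float
    pearson_p_csa_age: float
    csa_mean_male: float
    csa_sd_male: float
    csa_mean_female: float
    csa_sd_female: float
    ttest_t: float
    ttest_p: float
    notices: list[str] = field(default_factory=list)


def cohort_characteristics(cohort: list[PatientRecord]) -> CohortCharacteristics:
    """CSA-vs-age Pearson correlation and Welch t-test of CSA by sex."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 patients")
    csa = np.array([p.csa_mm2 for p in cohort])
    age = np.array([p.age for p in cohort])
    notices: list[str] = []
    if csa.std() == 0 or age.std() == 0:
        r = p_r = math.nan
        notices.append("pearson_undefined_zero_variance")
    else:
        r, p_r = stats.pearsonr(csa, age)

    male = np.array([p.sex == "male" for p in cohort])
    csa_m, csa_f = csa[male], csa[~male]
    if len(csa_m) == 0 or len(csa_f) == 0:
        t = p_t = math.nan
        notices.append("ttest_skipped_single_sex")
    else:
        t, p_t = stats.ttest_ind(csa_m, csa_f, equal_var=False)

    def _ms(a: np.ndarray) -> tuple[float, float]:
        if len(a) == 0:
            return math.nan, math.nan
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    mm, ms = _ms(csa_m)
    fm, fs = _ms(csa_f)
    return CohortCharacteristics(
        pearson_r_csa_age=float(r),
        pearson_p_csa_age=float(p_r),
        csa_mean_male=mm,
        csa_sd_male=ms,
        csa_mean_female=fm,
        csa_sd_female=fs,
        ttest_t=float(t),
        ttest_p=float(p_t),
        notices=notices,
    )


def load_cohort_csv(path, endpoint: str = "OS") -> list[PatientRecord]:
    """Read `id,sex,age,csa_mm2,time_months,event` CSV into records."""
    df = pd.read_csv(path)
    required = {"id", "sex", "age", "csa_mm2", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PatientRecord(
            id=str(r.id), csa_mm2=float(r.csa_mm2), age=float(r.age), sex=str(r.sex),
            time_months=float(r.time_months), event=int(r.event), endpoint=endpoint,
        )
        for r in df.itertuples()
    ]
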