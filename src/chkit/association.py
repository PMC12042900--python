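"""Endpoint harmonization and cohort association / survival models.

All p-values are two sided. Exclusions (prevalent-malignancy and
complete-case covariate filtering) are logged row by row so that the ``n``
carried on every estimate equals the input n minus the logged exclusions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class EffectEstimate:
    """An OR or HR with Wald CI and two-sided p."""

    exposure: str
    outcome: str
    measure: str  # "OR" | "HR"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model_spec: dict = field(default_factory=dict)
    flagged: bool = False
    exclusions: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# Endpoint harmonization
# ---------------------------------------------------------------------------

def harmonize_endpoints(
    events: pd.DataFrame,
    sampling_dates: pd.Series,
    code_map: Mapping[str, Iterable[str]],
    inclusive_boundary: bool = True,
) -> pd.DataFrame:
    """Derive prevalent/incident status per participant per endpoint.

    Parameters
    ----------
    events
        Long-format table with columns ``sample_id``, ``code``, ``date``.
    sampling_dates
        Series indexed by sample_id giving the DNA sampling date.
    code_map
        Endpoint name -> collection of registry codes.
    inclusive_boundary
        When True (default) an event dated exactly on the sampling date
        counts as prevalent; set False for a strict "before" rule.

    Returns one row per (sample_id, endpoint) with columns ``prevalent``,
    ``incident``, ``first_event_date`` and ``time_to_event_years`` (from
    sampling to first post-sampling event; NaN otherwise).
    """
    events = events.copy()
    if events["date"].isna().any():
        bad = events[events["date"].isna()]
        raise ValueError(
            f"{len(bad)} event row(s) have no date; first offender: "
            f"sample {bad.iloc[0]['sample_id']} code {bad.iloc[0]['code']}"
        )
    events["date"] = pd.to_datetime(events["date"])
    sampling_dates = pd.to_datetime(sampling_dates)
    rows = []
    for endpoint, codes in code_map.items():
        codes = set(codes)
        sub = events[events["code"].isin(codes)]
        first = sub.groupby("sample_id")["date"].min()
        for sample_id, sampling in sampling_dates.items():
            fd = first.get(sample_id, pd.NaT)
            if pd.isna(fd):
                rows.append((sample_id, endpoint, False, False, pd.NaT, np.nan))
                continue
            if inclusive_boundary:
                prevalent = fd <= sampling
            else:
                prevalent = fd < sampling
            incident = not prevalent
            tte = (fd - sampling).days / DAYS_PER_YEAR if incident else np.nan
            rows.append((sample_id, endpoint, prevalent, incident, fd, tte))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "endpoint", "prevalent", "incident",
            "first_event_date", "time_to_event_years",
        ],
    )


def ra_serotype(
    events: pd.DataFrame,
    seropositive_codes: Iterable[str],
    seronegative_codes: Iterable[str],
) -> pd.Series:
    """Serotype per participant with seropositive dominance.

    A participant is ``seronegative`` only if they carry no seropositive
    code anywhere in the record; any seropositive code wins; participants
    with neither are ``none``.
    """
    pos, neg = set(seropositive_codes), set(seronegative_codes)
    out = {}
    for sample_id, grp in events.groupby("sample_id"):
        codes = set(grp["code"])
        if codes & pos:
            out[sample_id] = "seropositive"
        elif codes & neg:
            out[sample_id] = "seronegative"
        else:
            out[sample_id] = "none"
    return pd.Series(out, name="serotype")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _complete_case(
    df: pd.DataFrame, needed: Sequence[str], exclude_flag: Optional[str]
) -> tuple:
    """Apply exclusion flag then complete-case filtering, logging reasons."""
    logs = []
    work = df
    if exclude_flag is not None:
        flagged = work[work[exclude_flag].fillna(False).astype(bool)]
        for sid in flagged.get("sample_id", flagged.index):
            logs.append((sid, f"excluded:{exclude_flag}"))
        work = work[~work[exclude_flag].fillna(False).astype(bool)]
    missing = work[needed].isna().any(axis=1)
    dropped = work[missing]
    for sid in dropped.get("sample_id", dropped.index):
        logs.append((sid, "missing_covariate"))
    work = work[~missing]
    return work, pd.DataFrame(logs, columns=["sample_id", "reason"])


def _encode(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Coerce model columns to float, mapping sex labels and booleans."""
    out = pd.DataFrame(index=df.index)
    for c in cols:
        col = df[c]
        if col.dtype == object:
            col = col.map(
                lambda v: {"male": 1.0, "female": 0.0, True: 1.0, False: 0.0}.get(v, v)
            )
        out[c] = col.astype(float)
    return out


def prevalent_logistic(
    df: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] = (),
    exclude_flag: Optional[str] = None,
) -> EffectEstimate:
    """Covariate-adjusted logistic model for a prevalent endpoint.

    Rows flagged by ``exclude_flag`` (e.g. prevalent hematologic malignancy)
    are dropped first, then rows missing any model variable (complete-case).
    Returns the exposure OR with 95% Wald CI and two-sided p. Perfect
    separation or non-convergence yields a flagged estimate, not a crash.
    """
    needed = [exposure, outcome, *covariates]
    work, exclusions = _complete_case(df, needed, exclude_flag)
    n = len(work)
    spec = {
        "covariates": list(covariates),
        "exclude_flag": exclude_flag,
        "n_input": len(df),
        "n_excluded": len(exclusions),
    }
    X = sm.add_constant(_encode(work, [exposure, *covariates]), has_constant="add")
    y = _encode(work, [outcome])[outcome]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = float(res.params[exposure]), float(res.bse[exposure])
        if not (np.isfinite(beta) and np.isfinite(se)) or se > 1e3:
            raise ValueError("unstable fit (possible separation)")
        est = float(np.exp(beta))
        ci = (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)))
        p = float(res.pvalues[exposure])
        return EffectEstimate(exposure, outcome, "OR", est, ci[0], ci[1], p, n, spec, False, exclusions)
    except Exception as exc:  # separation / singular design
        spec["diagnostic"] = str(exc)
        return EffectEstimate(
            exposure, outcome, "OR", float("nan"), float("nan"), float("nan"),
            float("nan"), n, spec, True, exclusions,
        )


def build_survival_columns(
    df: pd.DataFrame,
    sampling_date: str = "sampling_date",
    death_date: str = "death_date",
    censor_date: str = "censor_date",
    hem_malignancy_date: Optional[str] = None,
) -> pd.DataFrame:
    """Derive (duration_years, event) from dated columns.

    Time origin is the sampling date. Follow-up ends at the earliest of
    death, administrative censoring, or (when given) an incident hematologic
    malignancy; only death at that earliest date counts as an event, so a
    malignancy occurring before death converts the death to a censoring.
    """
    out = df.copy()
    sampling = pd.to_datetime(out[sampling_date])
    death = pd.to_datetime(out[death_date])
    censor = pd.to_datetime(out[censor_date])
    end = death.fillna(censor)
    event = death.notna()
    if hem_malignancy_date is not None:
        hem = pd.to_datetime(out[hem_malignancy_date])
        hem_first = hem.notna() & (hem > sampling) & (hem < end)
        end = end.where(~hem_first, hem)
        event = event & ~hem_first
    out["duration_years"] = (end - sampling).dt.days / DAYS_PER_YEAR
    out["event"] = event.astype(int)
    if (out["duration_years"] < 0).any():
        raise ValueError("negative follow-up time: event dated before sampling")
    return out


def survival_cox(
    df: pd.DataFrame,
    exposure: str,
    duration_col: str = "duration_years",
    event_col: str = "event",
    covariates: Sequence[str] = (),
    exclude_flag: Optional[str] = None,
) -> EffectEstimate:
    """Cox proportional-hazards fit; exposure HR with 95% CI, two-sided p."""
    needed = [exposure, duration_col, event_col, *covariates]
    work, exclusions = _complete_case(df, needed, exclude_flag)
    n = len(work)
    spec = {
        "covariates": list(covariates),
        "exclude_flag": exclude_flag,
        "n_input": len(df),
        "n_excluded": len(exclusions),
        "n_events": int(work[event_col].sum()),
    }
    if work[event_col].sum() == 0:
        spec["diagnostic"] = "no events in stratum"
        return EffectEstimate(
            exposure, "survival", "HR", float("nan"), float("nan"), float("nan"),
            float("nan"), n, spec, True, exclusions,
        )
    model_df = _encode(work, [exposure, *covariates])
    model_df[duration_col] = work[duration_col].astype(float)
    model_df[event_col] = work[event_col].astype(int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(model_df, duration_col=duration_col, event_col=event_col)
        beta = float(cph.params_[exposure])
        se = float(cph.standard_errors_[exposure])
        est = float(np.exp(beta))
        ci = (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)))
        p = float(cph.summary.loc[exposure, "p"])
        return EffectEstimate(exposure, "survival", "HR", est, ci[0], ci[1], p, n, spec, False, exclusions)
    except Exception as exc:
        spec["diagnostic"] = str(exc)
        return EffectEstimate(
            exposure, "survival", "HR", float("nan"), float("nan"), float("nan"),
            float("nan"), n, spec, True, exclusions,
        )


@dataclass(frozen=True)
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    p: Optional[float]
    survival_at_horizon: dict


def km_logrank(
    durations: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
    horizon: Optional[float] = None,
) -> KMResult:
    """Kaplan-Meier curves per group with a two-sided log-rank p.

    With a single group the p-value is absent. ``horizon`` additionally
    reports the KM survival estimate at that time per group.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    curves, at_horizon = {}, {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(durations[mask], events[mask])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        if horizon is not None:
            at_horizon[g] = float(kmf.predict(horizon))
    p = None
    if len(curves) > 1:
        res = multivariate_logrank_test(durations, groups, events)
        p = float(res.p_value)
    return KMResult(curves, p, at_horizon)


def cumulative_incidence(
    durations: Sequence[float], events: Sequence[int]
) -> pd.DataFrame:
    """1 - KM estimate (death treated as censoring; no competing risks)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(durations, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(), "cumulative_incidence": 1.0 - sf.iloc[:, 0].to_numpy()}
    )


# ---------------------------------------------------------------------------
# Group tests and summaries
# ---------------------------------------------------------------------------

def kruskal_wallis(values: Sequence[float], groups: Sequence) -> float:
    """Kruskal-Wallis p across groups; degenerate all-tied input gives 1.0."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if len(np.unique(values)) == 1:
        return 1.0
    return float(stats.kruskal(*samples).pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def chi2_test(table) -> float:
    """Pearson chi-squared p (no continuity correction) for an RxC table."""
    return float(stats.chi2_contingency(np.asarray(table), correction=False)[1])


def das28_auc(series: Sequence[tuple], horizon: float = 24.0) -> float:
    """Trapezoidal area under a DAS28 time series (score x months).

    ``series`` is a time-sorted list of ``(months, das28)`` starting at
    month 0; at least two points are required. The series is truncated at
    ``horizon`` with linear interpolation; if follow-up ends earlier the
    integral runs to the last observation.
    """
    if len(series) < 2:
        raise ValueError("need at least two DAS28 observations")
    t = np.asarray([p[0] for p in series], dtype=float)
    v = np.asarray([p[1] for p in series], dtype=float)
    if t[0] != 0:
        raise ValueError("series must start at month 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("series must be sorted by time")
    if t[-1] > horizon:
        v_h = float(np.interp(horizon, t, v))
        keep = t < horizon
        t = np.append(t[keep], horizon)
        v = np.append(v[keep], v_h)
    return float(np.trapezoid(v, t))


def prevalence_by_age(
    carrier: Sequence[bool],
    ages: Sequence[float],
    bin_edges: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-age-bin carrier prevalence with Wilson score 95% CI.

    Default bins are decades spanning the observed age range. Bins
    partition the cohort; the returned counts sum to the input size.
    """
    carrier = np.asarray(carrier, dtype=bool)
    ages = np.asarray(ages, dtype=float)
    if bin_edges is None:
        lo = int(np.floor(ages.min() / 10) * 10)
        hi = int(np.ceil((ages.max() + 1e-9) / 10) * 10)
        bin_edges = list(range(lo, hi + 10, 10))
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.searchsorted(bin_edges, ages, side="right") - 1, 0, len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        k = int(carrier[mask].sum())
        if n:
            lo_ci, hi_ci = proportion_confint(k, n, alpha=0.05, method="wilson")
        else:
            lo_ci = hi_ci = np.nan
        rows.append(
            (f"[{bin_edges[b]:g},{bin_edges[b+1]:g})", n, k,
             k / n if n else np.nan, lo_ci, hi_ci)
        )
    return pd.DataFrame(
        rows, columns=["age_bin", "n", "carriers", "prevalence", "ci_low", "ci_high"]
    )


def ratio_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """A count ratio as a rounded percentage, the way cohort tables print it."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)
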