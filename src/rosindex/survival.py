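"""Prognostic screening: univariate Cox, log-rank, Kaplan-Meier, HR display.

Cox fits use the partial likelihood with Efron tie handling (via lifelines).
Hazard ratios below 1 are displayed as -1/HR so that protective and risk
effects are symmetric around +/-1 in reports.  Screens apply
Benjamini-Hochberg FDR across all fitted (unit, cancer type) pairs;
significance stars follow the raw p-value (0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LifelinesConvergence
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .scoring import IndexTable

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """The Cox partial-likelihood maximization failed to converge."""


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit summary for one covariate."""

    covariate: str
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int

    @property
    def display_hr(self) -> float:
        return display_hr(self.hr)


@dataclass
class ScreenResult:
    """A prognostic screen over (unit, cancer type) pairs."""

    table: pd.DataFrame
    fdr_threshold: float = 0.05
    skipped: list = field(default_factory=list)

    def summary(self) -> dict:
        """Headline counts: units/types with at least one significant fit."""
        t = self.table
        sig_q = t[t["q"] < self.fdr_threshold]
        sig_p = t[t["p"] < self.fdr_threshold]
        n_units = t["unit"].nunique()
        n_types = t["cancer_type"].nunique()
        return {
            "n_units": n_units,
            "n_types": n_types,
            "units_significant_ge1_type_q": sig_q["unit"].nunique(),
            "frac_units_significant_ge1_type_q": sig_q["unit"].nunique() / n_units,
            "types_with_ge1_unit_q": sig_q["cancer_type"].nunique(),
            "units_significant_ge1_type_p": sig_p["unit"].nunique(),
            "frac_units_significant_ge1_type_p": sig_p["unit"].nunique() / n_units,
            "types_with_ge1_unit_p": sig_p["cancer_type"].nunique(),
        }


def display_hr(hr: float) -> float:
    """Signed display transform: HR if HR >= 1, else -1/HR.

    Encodes protective factors (HR < 1) as negative magnitudes so risk and
    protection are symmetric; odd-symmetric around 1:
    display_hr(h) = -display_hr(1/h) for h != 1.
    """
    if not np.isfinite(hr) or hr <= 0:
        raise ValidationError(f"hazard ratio must be finite and > 0, got {hr}")
    return float(hr) if hr >= 1 else float(-1.0 / hr)


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cox_univariate(
    values,
    time,
    event,
    name: str | None = None,
    alpha: float = 0.05,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald inference)."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if name is None:
        name = getattr(values, "name", None) or "covariate"
    if len(x) != len(t) or len(x) != len(e):
        raise ValidationError("covariate, time and event lengths differ")
    if len(x) < 2:
        raise ValidationError("need at least 2 observations")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite covariate values")
    if e.sum() < 1:
        raise ValidationError("no events observed")
    if np.ptp(x) == 0:
        raise ValidationError(f"covariate {name!r} has zero variance")

    df = pd.DataFrame({"x": x, "time": t, "event": e})
    cph = CoxPHFitter(penalizer=0.0, alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (_LifelinesConvergence, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit for {name!r} did not converge: {exc}")
    s = cph.summary.loc["x"]
    return CoxResult(
        covariate=name,
        beta=float(s["coef"]),
        se=float(s["se(coef)"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        n=len(df),
        n_events=int(e.sum()),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p: float


def logrank(groups, time, event) -> LogrankResult:
    """k-group log-rank test (chi-square with k-1 degrees of freedom)."""
    g = pd.Series(groups).reset_index(drop=True)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    k = g.nunique()
    if k < 2:
        raise ValidationError("log-rank requires at least 2 groups")
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return LogrankResult(
        statistic=float(res.test_statistic), df=k - 1, p=float(res.p_value)
    )


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier step table: time, at-risk, events, survival."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table.copy()
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    return out


def prognostic_screen(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    stratify_by: str | None = "cancer_type",
    fdr_threshold: float = 0.05,
    min_samples: int = 10,
    min_events: int = 3,
    method: str = "fdr_bh",
) -> ScreenResult:
    """Univariate Cox screen of every unit (row of ``scores``) per stratum.

    ``scores`` is units x samples; ``clinical`` is indexed by sample with
    ``time``/``event`` (and ``stratify_by``) columns.  q-values are BH
    across all fitted pairs (``method='bonferroni'`` switches the
    correction).  Pairs failing preconditions (too few samples/events,
    constant covariate, non-convergence) are recorded in ``skipped``.
    """
    common = scores.columns.intersection(clinical.index)
    if len(common) < min_samples:
        raise ValidationError("too few samples shared by scores and clinical")
    scores = scores[common]
    clinical = clinical.loc[common]
    if stratify_by is None:
        strata = {"all": common}
    else:
        strata = {
            str(level): idx.index
            for level, idx in clinical.groupby(stratify_by)
        }

    rows, skipped = [], []
    for stratum, samples in sorted(strata.items()):
        sub = clinical.loc[samples]
        if len(samples) < min_samples or sub["event"].sum() < min_events:
            skipped.append((stratum, "*", "too few samples or events"))
            continue
        for unit in scores.index:
            x = scores.loc[unit, samples]
            try:
                res = cox_univariate(x, sub["time"], sub["event"], name=str(unit))
            except (ValidationError, ConvergenceError) as exc:
                skipped.append((stratum, unit, str(exc)))
                continue
            rows.append(
                {
                    "unit": unit,
                    "cancer_type": stratum,
                    "beta": res.beta,
                    "se": res.se,
                    "hr": res.hr,
                    "display_hr": res.display_hr,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": res.n,
                    "events": res.n_events,
                }
            )
    if not rows:
        raise ValidationError("no (unit, stratum) pair could be fitted")
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method=method)[1]
    table["stars"] = table["p"].map(stars)
    return ScreenResult(table=table, fdr_threshold=fdr_threshold, skipped=skipped)


def cluster_logrank(assignment, clinical: pd.DataFrame) -> LogrankResult:
    """Log-rank comparison of survival across ROS clusters."""
    labels = assignment.labels if hasattr(assignment, "labels") else pd.Series(assignment)
    common = labels.index.intersection(clinical.index)
    sub = clinical.loc[common]
    return logrank(labels.loc[common], sub["time"], sub["event"])
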