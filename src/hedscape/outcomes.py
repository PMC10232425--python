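"""Time-to-event machinery: Kaplan-Meier, log-rank, Aalen-Johansen cumulative
incidence under competing risks, and cause-specific Cox regression.

The data model is one record per subject with a single terminal state: relapse,
death without prior relapse (the competing event), or censoring. Relapse
incidence is estimated with the Aalen-Johansen estimator (death competes);
regression on a cause treats competing events as censored at their time — the
cause-specific hazard convention.

Cox partial-likelihood fitting (Efron tie handling) and the log-rank test are
delegated to lifelines behind this module's interface; the Kaplan-Meier and
Aalen-Johansen step curves are computed here in a single shared risk-set sweep
so that the cause-specific incidences and the event-free probability are exact
complements at every step time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "EVENT_STATES",
    "RELAPSE",
    "DEATH",
    "CENSORED",
    "SubjectOutcome",
    "StepCurve",
    "CoxTerm",
    "CoxFit",
    "CoxConvergenceError",
    "outcomes_to_frame",
    "frame_to_outcomes",
    "build_design",
    "km_estimate",
    "logrank_test",
    "cif_aalen_johansen",
    "cox_cause_specific",
]

RELAPSE = "relapse"
DEATH = "death_without_relapse"
CENSORED = "censored"
EVENT_STATES: tuple[str, ...] = (RELAPSE, DEATH, CENSORED)

#: Default definition of "event" for all-cause (event-free survival) curves.
ANY_EVENT: frozenset[str] = frozenset({RELAPSE, DEATH})


@dataclass(frozen=True)
class SubjectOutcome:
    """One subject's follow-up: positive time (months), terminal state, covariates."""

    subject_id: str
    time: float
    event: str
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(
                f"subject {self.subject_id}: time must be finite and > 0, got {self.time}"
            )
        if self.event not in EVENT_STATES:
            raise ValueError(
                f"subject {self.subject_id}: unknown event state {self.event!r}; "
                f"expected one of {EVENT_STATES}"
            )


def outcomes_to_frame(outcomes: Iterable[SubjectOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        row = {"subject_id": o.subject_id, "time": o.time, "event": o.event}
        row.update(o.covariates)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def frame_to_outcomes(df: pd.DataFrame) -> list[SubjectOutcome]:
    """Inverse of :func:`outcomes_to_frame` (index or column ``subject_id``)."""
    work = df.reset_index() if df.index.name == "subject_id" else df.copy()
    covar_cols = [c for c in work.columns if c not in ("subject_id", "time", "event")]
    return [
        SubjectOutcome(
            subject_id=str(r["subject_id"]),
            time=float(r["time"]),
            event=str(r["event"]),
            covariates={c: r[c] for c in covar_cols},
        )
        for _, r in work.iterrows()
    ]


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function on [0, inf): times ascending, one value
    and one pointwise variance per time. Survival curves start at 1 before the
    first time; incidence curves start at 0."""

    times: np.ndarray
    values: np.ndarray
    variance: np.ndarray
    kind: str = "survival"  # "survival" | "incidence"

    def at(self, t: float) -> float:
        """Value of the step function at time t."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        if i < 0:
            return 1.0 if self.kind == "survival" else 0.0
        return float(self.values[i])


def _risk_table(
    outcomes: Sequence[SubjectOutcome],
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Unique observed times with risk-set size, per-cause event counts.

    Censorings tied with events are handled events-first: a subject censored at
    t is still at risk for events at t.
    """
    if not outcomes:
        raise ValueError("no outcome records supplied")
    times = np.array([o.time for o in outcomes], dtype=float)
    states = np.array([o.event for o in outcomes], dtype=object)
    uniq = np.unique(times)
    n_at_risk = np.array([(times >= t).sum() for t in uniq], dtype=float)
    deaths_by_cause = {
        cause: np.array([((times == t) & (states == cause)).sum() for t in uniq], dtype=float)
        for cause in (RELAPSE, DEATH)
    }
    censored = np.array([((times == t) & (states == CENSORED)).sum() for t in uniq], dtype=float)
    return uniq, n_at_risk, deaths_by_cause, censored


def km_estimate(
    outcomes: Sequence[SubjectOutcome],
    event_def: Iterable[str] = ANY_EVENT,
) -> StepCurve:
    """Product-limit survival estimate with Greenwood variance.

    ``event_def`` names the states counted as events; every other non-censored
    state is treated as censoring at its time (cause-specific convention).
    """
    event_set = frozenset(event_def)
    bad = event_set - set(EVENT_STATES)
    if bad:
        raise ValueError(f"unknown event states in event_def: {sorted(bad)}")
    uniq, n, by_cause, _ = _risk_table(outcomes)
    d = np.zeros_like(n)
    for cause in event_set & set(by_cause):
        d += by_cause[cause]
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var = S(t)^2 * sum_{ti<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n - d > 0, d / (n * (n - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return StepCurve(times=uniq, values=surv, variance=var, kind="survival")


def logrank_test(
    outcomes: Sequence[SubjectOutcome],
    group_label: str,
    event_def: Iterable[str] = ANY_EVENT,
) -> tuple[float, float]:
    """k-sample log-rank test across the levels of a grouping covariate.

    Returns (chi-square statistic, p-value) with k-1 degrees of freedom.
    """
    event_set = frozenset(event_def)
    groups = [o.covariates.get(group_label) for o in outcomes]
    if len(set(groups)) < 2:
        raise ValueError(
            f"log-rank needs >= 2 groups; covariate {group_label!r} has "
            f"levels {sorted(map(str, set(groups)))}"
        )
    durations = [o.time for o in outcomes]
    observed = [1 if o.event in event_set else 0 for o in outcomes]
    res = multivariate_logrank_test(durations, groups, observed)
    return float(res.test_statistic), float(res.p_value)


def cif_aalen_johansen(
    outcomes: Sequence[SubjectOutcome],
    cause: str = RELAPSE,
) -> StepCurve:
    """Aalen-Johansen cumulative incidence of one cause under competing risks.

    CIF_c(t) = sum over event times t_i <= t of S(t_i-) * d_ci / n_i, where
    S is the all-cause Kaplan-Meier. With no competing events this reduces
    exactly to 1 - KM of the cause. The pointwise variance is the standard
    delta-method estimator (as in R's cmprsk).
    """
    if cause not in (RELAPSE, DEATH):
        raise ValueError(f"cause must be one of {(RELAPSE, DEATH)}, got {cause!r}")
    uniq, n, by_cause, _ = _risk_table(outcomes)
    d_all = by_cause[RELAPSE] + by_cause[DEATH]
    d_c = by_cause[cause]
    s_all = np.cumprod(1.0 - d_all / n)
    s_prev = np.concatenate([[1.0], s_all[:-1]])
    cif = np.cumsum(s_prev * d_c / n)

    # Delta-method variance (Aalen 1978; Marubini & Valsecchi form).
    k = len(uniq)
    var = np.zeros(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        va = np.where(n - d_all > 0, d_all / (n * (n - d_all)), 0.0)
    for j in range(k):
        diff = cif[j] - cif[: j + 1]
        term1 = np.sum(diff**2 * va[: j + 1])
        term2 = np.sum(
            s_prev[: j + 1] ** 2
            * (n[: j + 1] - d_c[: j + 1])
            / n[: j + 1]
            * d_c[: j + 1]
            / n[: j + 1] ** 2
        )
        term3 = -2.0 * np.sum(diff * s_prev[: j + 1] * d_c[: j + 1] / n[: j + 1] ** 2)
        var[j] = term1 + term2 + term3
    return StepCurve(times=uniq, values=cif, variance=np.maximum(var, 0.0), kind="incidence")


@dataclass(frozen=True)
class CoxTerm:
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class CoxFit:
    """Per-term estimates plus the maximized log partial likelihood."""

    terms: Mapping[str, CoxTerm]
    log_likelihood: float
    ties: str = "efron"
    n: int = 0
    n_events: int = 0

    def hazard_ratio(self, term: str) -> float:
        return self.terms[term].hr

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": {k: t.coef for k, t in self.terms.items()},
                "se": {k: t.se for k, t in self.terms.items()},
                "hr": {k: t.hr for k, t in self.terms.items()},
                "ci_low": {k: t.ci_low for k, t in self.terms.items()},
                "ci_high": {k: t.ci_high for k, t in self.terms.items()},
                "p": {k: t.p for k, t in self.terms.items()},
            }
        )


class CoxConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (includes monotone likelihood /
    complete separation, for which penalization is out of scope here)."""


def build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Reference-coded numeric design matrix.

    Numeric covariates pass through unchanged. A covariate is treated as
    categorical when its column is non-numeric or when it appears in
    ``reference_levels``; its declared level order (first level = reference)
    produces indicator columns named ``name=level`` for non-reference levels.
    """
    reference_levels = reference_levels or {}
    cols: dict[str, np.ndarray] = {}
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not present in data")
        col = df[name]
        categorical = name in reference_levels or not pd.api.types.is_numeric_dtype(col)
        if not categorical:
            cols[name] = col.to_numpy(dtype=float)
            continue
        values = col.astype(str)
        levels = [str(l) for l in reference_levels.get(name, sorted(values.unique()))]
        unknown = set(values.unique()) - set(levels)
        if unknown:
            raise ValueError(
                f"covariate {name!r}: observed levels {sorted(unknown)} missing "
                f"from declared order {levels}"
            )
        for level in levels[1:]:
            cols[f"{name}={level}"] = (values == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def cox_cause_specific(
    outcomes: Sequence[SubjectOutcome] | pd.DataFrame,
    cause: str | Iterable[str],
    covariates: Sequence[str],
    *,
    reference_levels: Mapping[str, Sequence[str]] | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Cause-specific Cox proportional-hazards fit.

    Events of the named cause(s) count as events; competing events are censored
    at their time. Ties are handled with the Efron approximation; Wald 95%
    intervals use exp(coef +/- 1.96 se).
    """
    if ties != "efron":
        raise NotImplementedError(
            "only the Efron tie approximation is supported (the default here)"
        )
    cause_set = frozenset([cause] if isinstance(cause, str) else cause)
    bad = cause_set - (set(EVENT_STATES) - {CENSORED})
    if bad:
        raise ValueError(f"invalid cause(s): {sorted(bad)}")
    df = outcomes if isinstance(outcomes, pd.DataFrame) else outcomes_to_frame(outcomes)
    design = build_design(df, covariates, reference_levels)
    fit_df = design.copy()
    fit_df["duration"] = df["time"].to_numpy(dtype=float)
    fit_df["observed"] = df["event"].isin(cause_set).to_numpy(dtype=float)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(fit_df, duration_col="duration", event_col="observed")
    except (ConvergenceError, ConvergenceWarning) as exc:
        raise CoxConvergenceError(
            f"cause-specific Cox fit for {sorted(cause_set)} did not converge "
            f"cleanly: {exc}"
        ) from exc

    terms = {}
    for name in design.columns:
        coef = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        terms[name] = CoxTerm(
            coef=coef,
            se=se,
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.96 * se)),
            ci_high=float(np.exp(coef + 1.96 * se)),
            p=float(cph.summary.loc[name, "p"]),
        )
    return CoxFit(
        terms=terms,
        log_likelihood=float(cph.log_likelihood_),
        ties="efron",
        n=int(len(fit_df)),
        n_events=int(fit_df["observed"].sum()),
    )
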