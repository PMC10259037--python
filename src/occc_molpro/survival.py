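"""Cohort statistics: association tests, mutual exclusivity, endpoints,
Kaplan-Meier / log-rank, and Cox proportional hazards with backward
elimination.

Endpoint definitions: recurrence-free survival (RFS) runs from diagnosis to
recurrence or death of disease; overall survival (OS) runs from diagnosis to
any recorded death, regardless of cause.  Samples without follow-up status
are excluded with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .types import ClinicalRecord, SurvivalStatus

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


class SurvivalError(Exception):
    pass


# ---------------------------------------------------------------------------
# endpoints
# ---------------------------------------------------------------------------

def build_endpoints(clinical: list[ClinicalRecord]) -> pd.DataFrame:
    """Construct RFS and OS endpoint columns from clinical records.

    RFS event: recurrence, or death of disease (DOD); time is the recurrence
    date when recorded, else follow-up end.  OS event: any recorded death
    (DOD, DTC, DUC, DOC); non-disease deaths censor RFS at the death date.
    Returns a DataFrame indexed by sample with rfs_time/rfs_event,
    os_time/os_event and an ``evaluable`` flag; NA-status or missing
    follow-up records are marked not evaluable.
    """
    rows = []
    n_excluded = 0
    for r in clinical:
        if r.survival_status is SurvivalStatus.NA or r.followup_months is None:
            n_excluded += 1
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "evaluable": False,
                    "rfs_time": np.nan,
                    "rfs_event": False,
                    "os_time": np.nan,
                    "os_event": False,
                }
            )
            continue
        os_event = r.survival_status.is_death
        os_time = r.followup_months
        rfs_event = bool(r.recurrence) or r.survival_status is SurvivalStatus.DOD
        if r.recurrence and r.recurrence_months is not None:
            rfs_time = r.recurrence_months
        else:
            rfs_time = r.followup_months
        rows.append(
            {
                "sample_id": r.sample_id,
                "evaluable": True,
                "rfs_time": rfs_time,
                "rfs_event": rfs_event,
                "os_time": os_time,
                "os_event": os_event,
            }
        )
    if n_excluded:
        logger.info("endpoints: %d record(s) without follow-up excluded", n_excluded)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# categorical association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    p_value: float
    method: str  # "fisher" or "chi2"
    statistic: float | None = None


def association_test(table: np.ndarray | list[list[int]]) -> AssociationResult:
    """Two-sided association test on a 2-way contingency table.

    Fisher's exact test when any expected cell count is 5 or less (the
    boundary case counts as small), otherwise Pearson's chi-squared without
    continuity correction.  Degenerate tables (a zero margin) are not
    evaluable.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise SurvivalError("contingency table must hold non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise SurvivalError("degenerate table: zero row or column margin")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 5).any():
        if table.shape != (2, 2):
            raise SurvivalError("Fisher branch implemented for 2x2 tables only")
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return AssociationResult(p_value=float(p), method="fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(p_value=float(p), method="chi2", statistic=float(chi2))


@dataclass
class MutualExclusivityResult:
    gene_a: str
    gene_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    fisher_p: float
    direction: str  # "exclusive", "co_occurring", or "none"


def mutual_exclusivity(status: pd.DataFrame, gene_a: str, gene_b: str) -> MutualExclusivityResult:
    """Co-occurrence screen for two genes of a boolean status matrix.

    Reports the overlap count and the two-sided Fisher p on the 2x2 table of
    statuses; the direction is read off the odds-ratio sign.
    """
    for g in (gene_a, gene_b):
        if g not in status.columns:
            raise SurvivalError(f"gene {g!r} absent from status matrix")
    a = status[gene_a].astype(bool)
    b = status[gene_b].astype(bool)
    n_both = int((a & b).sum())
    n_a = int((a & ~b).sum())
    n_b = int((~a & b).sum())
    n_none = int((~a & ~b).sum())
    table = np.array([[n_both, n_a], [n_b, n_none]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if n_both == 0 or (np.isfinite(odds) and odds < 1):
        direction = "exclusive"
    elif odds > 1:
        direction = "co_occurring"
    else:
        direction = "none"
    return MutualExclusivityResult(gene_a, gene_b, n_both, n_a, n_b, n_none, float(p), direction)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> survival function table
    logrank_p: float | None
    logrank_statistic: float | None
    lr_p: float | None  # likelihood-ratio p from a one-term Cox fit
    dropped_groups: list[str] = field(default_factory=list)


def km_logrank(
    endpoints: pd.DataFrame,
    groups: pd.Series,
    time_col: str = "rfs_time",
    event_col: str = "rfs_event",
) -> KMResult:
    """Kaplan-Meier curves per group with log-rank and LR comparisons.

    Empty groups are dropped with a warning.  With a single remaining group
    the comparison p-values are ``None``.
    """
    df = endpoints.loc[endpoints["evaluable"]].copy()
    groups = groups.reindex(df.index)
    df = df[groups.notna()]
    groups = groups.loc[df.index]

    curves: dict[str, pd.DataFrame] = {}
    kept = []
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            logger.warning("km_logrank: dropping empty group %r", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, time_col], event_observed=df.loc[mask, event_col], label=str(g))
        tab = kmf.survival_function_.copy()
        tab["at_risk"] = kmf.event_table["at_risk"].reindex(tab.index)
        curves[str(g)] = tab
        kept.append(g)

    logrank_p = logrank_stat = lr_p = None
    if len(kept) >= 2:
        res = multivariate_logrank_test(
            df[time_col], groups, df[event_col]
        )
        logrank_p = float(res.p_value)
        logrank_stat = float(res.test_statistic)
        try:
            cox_df = pd.DataFrame(
                {
                    "time": df[time_col],
                    "event": df[event_col].astype(int),
                    "group": pd.Categorical(groups).codes,
                }
            )
            cph = CoxPHFitter()
            cph.fit(cox_df, duration_col="time", event_col="event")
            lr_p = float(cph.log_likelihood_ratio_test().p_value)
        except Exception as exc:  # monotone likelihood etc.
            logger.warning("LR test unavailable: %s", exc)
            lr_p = None
    dropped = [str(g) for g in pd.unique(groups) if g not in kept]
    return KMResult(curves, logrank_p, logrank_stat, lr_p, dropped)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """One Cox PH fit: per-term estimates plus the elimination trace."""

    terms: list[str]
    summary: pd.DataFrame  # beta, HR, CI bounds, Wald p per term
    log_likelihood: float
    strategy: str
    elimination_trace: list[dict] = field(default_factory=list)
    separation_flags: list[str] = field(default_factory=list)
    evaluable: bool = True
    note: str = ""


def _detect_separation(df: pd.DataFrame, covariates: list[str], event_col: str) -> list[str]:
    """Monotone-likelihood screen: binary covariate levels with zero events."""
    flags = []
    for c in covariates:
        values = df[c].dropna().unique()
        if len(values) <= 5:  # treat few-level covariates as categorical
            for v in values:
                sub = df[df[c] == v]
                if len(sub) > 0 and sub[event_col].sum() == 0:
                    flags.append(c)
                    break
    return flags


def _fit_once(df: pd.DataFrame, covariates: list[str], time_col: str, event_col: str) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(
        df[[time_col, event_col] + covariates],
        duration_col=time_col,
        event_col=event_col,
    )
    return cph


def _summary_frame(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "beta": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
        }
    )
    return out


def cox_model(
    endpoints: pd.DataFrame,
    covariates: pd.DataFrame,
    strategy: str = "univariable",
    time_col: str = "rfs_time",
    event_col: str = "rfs_event",
    alpha: float = SIGNIFICANCE_LEVEL,
) -> CoxFit | dict[str, CoxFit]:
    """Cox PH modeling (Efron tie handling via lifelines).

    ``univariable``: one single-term fit per covariate column, returned as a
    dict.  ``multivariable_backward``: covariates significant in the
    univariable screen (Wald p < alpha) enter a full model; the highest-p term
    is removed iteratively until every remaining term has p < alpha, with the
    trace recorded.  Monotone likelihood (a covariate level with zero events)
    is detected and flagged, never silently reported as converged.
    """
    if strategy not in ("univariable", "multivariable_backward"):
        raise SurvivalError(f"unknown strategy {strategy!r}")
    df = endpoints.loc[endpoints["evaluable"], [time_col, event_col]].join(
        covariates, how="inner"
    )
    df = df.dropna()
    df[event_col] = df[event_col].astype(int)
    if df[event_col].sum() == 0:
        return CoxFit(
            terms=[], summary=pd.DataFrame(), log_likelihood=np.nan,
            strategy=strategy, evaluable=False, note="zero events",
        )
    cov_names = list(covariates.columns)

    def fit_terms(terms: list[str], strat: str) -> CoxFit:
        flags = _detect_separation(df, terms, event_col)
        try:
            cph = _fit_once(df, terms, time_col, event_col)
            return CoxFit(
                terms=terms,
                summary=_summary_frame(cph),
                log_likelihood=float(cph.log_likelihood_),
                strategy=strat,
                separation_flags=flags,
                note="monotone likelihood suspected" if flags else "",
            )
        except Exception as exc:
            return CoxFit(
                terms=terms, summary=pd.DataFrame(), log_likelihood=np.nan,
                strategy=strat, separation_flags=flags or terms,
                evaluable=False, note=f"fit failed: {exc}",
            )

    if strategy == "univariable":
        return {c: fit_terms([c], "univariable") for c in cov_names}

    uni = {c: fit_terms([c], "univariable") for c in cov_names}
    selected = [
        c
        for c, f in uni.items()
        if f.evaluable and not f.summary.empty and float(f.summary["wald_p"].iloc[0]) < alpha
    ]
    trace: list[dict] = [{"step": 0, "terms": list(selected), "action": "univariable screen"}]
    if not selected:
        return CoxFit(
            terms=[], summary=pd.DataFrame(), log_likelihood=np.nan,
            strategy=strategy, elimination_trace=trace, evaluable=False,
            note="no covariate passed the univariable screen",
        )
    step = 0
    current = list(selected)
    fit = fit_terms(current, strategy)
    while len(current) > 1 and fit.evaluable and not fit.summary.empty:
        worst = fit.summary["wald_p"].idxmax()
        if float(fit.summary.loc[worst, "wald_p"]) < alpha:
            break
        step += 1
        current = [c for c in current if c != worst]
        trace.append({"step": step, "terms": list(current), "action": f"removed {worst}"})
        fit = fit_terms(current, strategy)
    fit.elimination_trace = trace
    return fit


def plot_km(km: KMResult, path, title: str = "") -> None:
    """Step-function survival plot with censoring implied by the tables."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for label, tab in km.curves.items():
        ax.step(tab.index, tab.iloc[:, 0], where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if km.logrank_p is not None:
        ax.set_title(f"{title} (log-rank p = {km.logrank_p:.3g})")
    elif title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
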