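"""Endpoint construction, association tests against exact enumeration,
Kaplan-Meier limits, and Cox parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from occc_molpro.survival import (
    SurvivalError,
    association_test,
    build_endpoints,
    cox_model,
    km_logrank,
    mutual_exclusivity,
)
from occc_molpro.types import ClinicalRecord, SurvivalStatus


def record(sample_id="S001", **kw):
    defaults = dict(sample_id=sample_id, survival_status=SurvivalStatus.NED, followup_months=52.0)
    defaults.update(kw)
    return ClinicalRecord(**defaults)


def test_endpoint_censoring_and_events():
    eps = build_endpoints(
        [
            record("A"),  # NED at 52: censored
            record("B", survival_status=SurvivalStatus.DOD, followup_months=25.0),
            record("C", survival_status=SurvivalStatus.DOC, followup_months=28.0),
            record("D", survival_status=SurvivalStatus.AWD, followup_months=40.0,
                   recurrence=True, recurrence_months=18.0),
            record("E", survival_status=SurvivalStatus.NA, followup_months=None),
        ]
    )
    a, b, c, d, e = (eps.loc[s] for s in "ABCDE")
    assert not a["rfs_event"] and a["rfs_time"] == 52.0 and not a["os_event"]
    # death of disease without a recurrence date is an RFS event at death
    assert b["rfs_event"] and b["rfs_time"] == 25.0 and b["os_event"]
    # death of other cause: OS event, RFS censored at death
    assert c["os_event"] and not c["rfs_event"] and c["rfs_time"] == 28.0
    assert d["rfs_event"] and d["rfs_time"] == 18.0 and not d["os_event"]
    assert not e["evaluable"]


def test_chi_squared_branch_textbook_statistic():
    """[[30,20],[20,30]] has expected cells 25 and chi-squared 4.0."""
    res = association_test([[30, 20], [20, 30]])
    assert res.method == "chi2"
    assert res.statistic == pytest.approx(4.0)


def test_fisher_branch_on_low_expected_cells():
    res = association_test([[10, 0], [0, 10]])
    assert res.method == "fisher"
    assert res.p_value < 0.01


def test_balanced_table_fisher_p_is_one():
    res = association_test([[2, 2], [2, 2]])
    assert res.method == "fisher"
    assert res.p_value == pytest.approx(1.0)


def test_degenerate_table_not_evaluable():
    with pytest.raises(SurvivalError):
        association_test([[0, 0], [3, 4]])


def fisher_exact_enumeration(a, b, c, d):
    """Two-sided Fisher p by brute-force hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_p(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def test_fisher_matches_enumeration_for_small_margins():
    """Implementation p equals exact hypergeometric enumeration on all 2x2
    tables with margins <= 15."""
    from scipy.stats import fisher_exact

    checked = 0
    for a in range(0, 8):
        for b in range(0, 8):
            for c in range(0, 8):
                for d in range(0, 8):
                    if 0 < a + b + c + d and a + b <= 15 and c + d <= 15 and min(a + b, c + d) > 0 and min(a + c, b + d) > 0:
                        p_impl = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
                        p_enum = fisher_exact_enumeration(a, b, c, d)
                        assert p_impl == pytest.approx(p_enum, abs=1e-9), (a, b, c, d)
                        checked += 1
    assert checked > 1000


def test_mutual_exclusivity_planted_disjoint(default_bundle, kb):
    """KRAS and TP53 statuses are planted disjoint: overlap 0, direction
    exclusive."""
    from occc_molpro.interpret import build_gene_status_matrix

    matrix = build_gene_status_matrix(
        default_bundle.variants, default_bundle.kb, sample_ids=default_bundle.dna_samples
    )
    res = mutual_exclusivity(matrix.status, "KRAS", "TP53")
    assert res.n_both == 0
    assert res.direction == "exclusive"
    assert res.n_a_only == 18 and res.n_b_only == 12


def test_mutual_exclusivity_same_gene_is_perfect_cooccurrence():
    status = pd.DataFrame({"KRAS": [True, True, False, False]})
    status["KRAS2"] = status["KRAS"]
    res = mutual_exclusivity(status, "KRAS", "KRAS2")
    assert res.n_both == 2 and res.direction == "co_occurring"


def test_independent_statuses_expected_overlap():
    """Independent 18%/13% statuses at n=100: mean overlap near 2.3 and Fisher
    p rarely small (simulation)."""
    rng = np.random.default_rng(44)
    overlaps, small_p = [], 0
    reps = 200
    for _ in range(reps):
        a = rng.random(100) < 0.18
        b = rng.random(100) < 0.13
        status = pd.DataFrame({"A": a, "B": b})
        res = mutual_exclusivity(status, "A", "B")
        overlaps.append(res.n_both)
        if res.fisher_p < 0.05:
            small_p += 1
    assert np.mean(overlaps) == pytest.approx(2.34, abs=0.6)
    assert small_p / reps < 0.15


def test_km_equals_empirical_survival_without_censoring():
    """With every subject an event, KM is 1 minus the empirical CDF."""
    times = [5.0, 10.0, 10.0, 20.0, 30.0]
    eps = pd.DataFrame(
        {
            "evaluable": True,
            "rfs_time": times,
            "rfs_event": True,
            "os_time": times,
            "os_event": True,
        },
        index=[f"S{i}" for i in range(5)],
    )
    groups = pd.Series("all", index=eps.index)
    res = km_logrank(eps, groups)
    curve = res.curves["all"].iloc[:, 0]
    for t in [5.0, 10.0, 20.0, 30.0]:
        empirical = np.mean([x > t for x in times])
        assert curve.loc[t] == pytest.approx(empirical)
    assert (curve.diff().dropna() <= 1e-12).all()
    assert ((curve >= 0) & (curve <= 1)).all()


def test_logrank_zero_for_identical_groups():
    rng = np.random.default_rng(8)
    times = rng.exponential(20, size=30).round(1)
    events = rng.random(30) < 0.7
    eps = pd.DataFrame(
        {
            "evaluable": True,
            "rfs_time": np.concatenate([times, times]),
            "rfs_event": np.concatenate([events, events]),
            "os_time": 1.0,
            "os_event": False,
        },
        index=[f"S{i}" for i in range(60)],
    )
    groups = pd.Series(["g1"] * 30 + ["g2"] * 30, index=eps.index)
    res = km_logrank(eps, groups)
    assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)
    assert res.logrank_p == pytest.approx(1.0)


def test_protected_group_curve_constant(default_bundle, pipeline_result):
    """The planted POLEmut/MSI-High group has zero RFS events: its KM curve
    stays at 1.0."""
    eps = pipeline_result.tables["endpoints"]
    truth = default_bundle.truth["samples"]
    protected = truth.index[truth["pole_mut"] | truth["msi_high"]]
    groups = pd.Series(
        ["protected" if s in set(protected) else "other" for s in eps.index],
        index=eps.index,
    )
    res = km_logrank(eps, groups)
    assert (res.curves["protected"].iloc[:, 0] == 1.0).all()


def test_cox_null_covariate():
    """Identical survival in both arms: beta near 0, HR near 1."""
    rng = np.random.default_rng(10)
    times = rng.exponential(20, size=200)
    eps = pd.DataFrame(
        {
            "evaluable": True,
            "rfs_time": np.concatenate([times, times]),
            "rfs_event": True,
            "os_time": 1.0,
            "os_event": False,
        },
        index=[f"S{i}" for i in range(400)],
    )
    covs = pd.DataFrame({"arm": [0] * 200 + [1] * 200}, index=eps.index)
    fits = cox_model(eps, covs, strategy="univariable")
    s = fits["arm"].summary
    assert abs(s["beta"].iloc[0]) < 0.05
    assert s["hazard_ratio"].iloc[0] == pytest.approx(1.0, abs=0.06)


def test_cox_recovers_true_hazard_ratio():
    """Exponential survival with true HR 2.0 between arms at n = 500: the
    estimate's 95% CI covers 2.0 and the point estimate is close."""
    rng = np.random.default_rng(123)
    n = 500
    arm = rng.integers(0, 2, size=n)
    base_hazard = 0.05
    times = rng.exponential(1.0 / (base_hazard * np.exp(np.log(2.0) * arm)))
    censor = rng.exponential(60, size=n)
    observed = np.minimum(times, censor)
    event = times <= censor
    eps = pd.DataFrame(
        {
            "evaluable": True,
            "rfs_time": observed,
            "rfs_event": event,
            "os_time": 1.0,
            "os_event": False,
        },
        index=[f"S{i}" for i in range(n)],
    )
    covs = pd.DataFrame({"arm": arm}, index=eps.index)
    fit = cox_model(eps, covs, strategy="univariable")["arm"]
    hr = fit.summary["hazard_ratio"].iloc[0]
    lo, hi = fit.summary["ci_lower"].iloc[0], fit.summary["ci_upper"].iloc[0]
    assert lo < 2.0 < hi
    assert hr == pytest.approx(2.0, rel=0.20)


def test_cox_separation_flagged(default_bundle, pipeline_result):
    """A covariate level with zero events (the planted POLEmut/MSI-High group)
    raises the monotone-likelihood flag instead of a silent 'converged'."""
    eps = pipeline_result.tables["endpoints"]
    truth = default_bundle.truth["samples"]
    protected = (truth["pole_mut"] | truth["msi_high"]).astype(int)
    covs = pd.DataFrame({"protected": protected.reindex(eps.index)})
    fit = cox_model(eps, covs, strategy="univariable")["protected"]
    assert "protected" in fit.separation_flags
    assert fit.note != ""


def test_backward_elimination_trace():
    """Backward elimination drops noise terms and keeps the real effect."""
    rng = np.random.default_rng(77)
    n = 400
    effect = rng.integers(0, 2, size=n)
    noise = rng.normal(size=n)
    times = rng.exponential(1.0 / (0.05 * np.exp(1.0 * effect)))
    eps = pd.DataFrame(
        {
            "evaluable": True,
            "rfs_time": times,
            "rfs_event": True,
            "os_time": 1.0,
            "os_event": False,
        },
        index=[f"S{i}" for i in range(n)],
    )
    covs = pd.DataFrame({"effect": effect, "noise": noise}, index=eps.index)
    fit = cox_model(eps, covs, strategy="multivariable_backward")
    assert "effect" in fit.terms
    assert (fit.summary["wald_p"] < 0.05).all()
    assert fit.elimination_trace[0]["action"] == "univariable screen"


def test_zero_events_not_evaluable():
    eps = pd.DataFrame(
        {
            "evaluable": True,
            "rfs_time": [10.0, 20.0],
            "rfs_event": False,
            "os_time": 1.0,
            "os_event": False,
        },
        index=["A", "B"],
    )
    covs = pd.DataFrame({"x": [0, 1]}, index=eps.index)
    fit = cox_model(eps, covs, strategy="multivariable_backward")
    assert not fit.evaluable and fit.note == "zero events"
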