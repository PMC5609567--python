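"""Logistic fitting, relative-activity statistics and normalisations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rampkit import pharm_stats as ps

GRID = np.logspace(-12, -6, 8)


def make_experiment(basal, emax, pec50, sigma=0.0, rng=None, n_rep=3):
    x = np.log10(GRID)
    mean = ps.three_parameter_logistic(x, basal, emax, pec50)
    if sigma > 0:
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=(len(GRID), n_rep))
        return ps.Experiment(GRID, mean[:, None] * noise)
    return ps.Experiment(GRID, np.repeat(mean[:, None], n_rep, axis=1))


# ---------------------------------------------------------------------------
# three-parameter logistic fit
# ---------------------------------------------------------------------------

def test_noiseless_fit_recovers_truth_exactly():
    fit = ps.fit_three_parameter_logistic(make_experiment(0.0, 30.0, 9.0))
    assert fit.converged
    assert abs(fit.basal - 0.0) < 1e-6 * 30
    assert abs(fit.emax - 30.0) / 30.0 < 1e-6
    assert abs(fit.pec50 - 9.0) / 9.0 < 1e-6


def _grid_search_fit(x, y):
    """Independent oracle: exhaustive least squares on a parameter lattice."""
    basals = np.linspace(y.min() - 2, y.min() + 2, 9)
    emaxes = np.linspace(0.5 * y.max(), 1.5 * y.max(), 41)
    pec50s = np.linspace(6.0, 12.0, 121)
    best, best_sse = None, np.inf
    for b in basals:
        for e in emaxes:
            pred = b + (e - b) / (1.0 + 10.0 ** (-(x[None, :] + pec50s[:, None])))
            sse = np.sum((pred - y[None, :]) ** 2, axis=1)
            k = int(np.argmin(sse))
            if sse[k] < best_sse:
                best_sse, best = sse[k], (b, e, pec50s[k])
    return best


def test_noisy_pec50_recovery_matches_grid_oracle():
    """Median pEC50 error stays below 0.1 at assay-like noise, and the
    optimiser agrees with an exhaustive grid-search oracle."""
    rng = np.random.default_rng(42)
    errors, disagreements = [], []
    for i in range(300):
        exp = make_experiment(1.0, 30.0, 9.0, sigma=0.15, rng=rng)
        fit = ps.fit_three_parameter_logistic(exp)
        assert fit.converged
        errors.append(abs(fit.pec50 - 9.0))
        if i < 40:  # the oracle is slow; spot-check a subset
            x, y = exp.points()
            gb, ge, gp = _grid_search_fit(x, y)
            disagreements.append(abs(fit.pec50 - gp))
    assert np.median(errors) <= 0.1
    assert np.median(disagreements) <= 0.05  # grid resolution


def test_flat_responses_are_flagged_unidentifiable():
    exp = ps.Experiment(GRID, np.full((8, 3), 12.0))
    fit = ps.fit_three_parameter_logistic(exp)
    assert (not fit.converged) or abs(fit.emax - fit.basal) < 1e-6 or fit.no_curve


def test_weak_span_flagged_as_no_curve():
    rng = np.random.default_rng(0)
    # span comparable to the noise floor
    exp = make_experiment(10.0, 10.5, 9.0, sigma=0.15, rng=rng)
    fit = ps.fit_three_parameter_logistic(exp)
    if fit.converged:
        assert fit.no_curve


@pytest.mark.parametrize("bad", [
    dict(concentrations=[1e-9, 1e-8, 1e-7], responses=[1, 2, 3]),
    dict(concentrations=[-1e-9, 1e-8, 1e-7, 1e-6], responses=[1, 2, 3, 4]),
    dict(concentrations=[1e-9, 1e-8, 1e-7, 1e-6], responses=[1, 2, np.inf, 4]),
])
def test_invalid_experiments_rejected(bad):
    with pytest.raises(ValueError):
        ps.Experiment(np.asarray(bad["concentrations"], dtype=float),
                      np.asarray(bad["responses"], dtype=float))


def test_dataset_frame_round_trip():
    rng = np.random.default_rng(3)
    ds = ps.ConcentrationResponseDataset(
        "WT", "CGRP", [make_experiment(1, 30, 9, 0.1, rng) for _ in range(3)])
    df = ps.dataset_to_frame(ds)
    back = ps.dataset_from_frame(df)
    assert back.n_experiments == 3
    for a, b in zip(ds.experiments, back.experiments):
        np.testing.assert_allclose(np.sort(a.responses, axis=1),
                                   np.sort(b.responses, axis=1))


# ---------------------------------------------------------------------------
# Δlog(RA)
# ---------------------------------------------------------------------------

def test_delta_log_ra_reproduces_published_loss_of_function():
    """N305A with RAMP1/CGRP: strong loss of function near 2.7 log units."""
    res = ps.delta_log_ra_from_summary(10.08, 31.16, 7.60, 19.35, 95.5)
    assert res.delta_log_ra == pytest.approx(2.667, abs=0.005)


def test_delta_log_ra_reproduces_published_moderate_effect():
    res = ps.delta_log_ra_from_summary(10.10, 36.34, 9.23, 32.99, 99.2)
    assert res.delta_log_ra == pytest.approx(0.91, abs=0.01)


def test_error_propagation_quadrature():
    """Quadrature of the five SEM components; frozen oracle value from
    direct arithmetic: sqrt(0.06² + 0.12² + (8.65/(31.16·ln10))²
    + (5.94/(19.35·ln10))² + ((4.42/95.5)/ln10)²) = 0.225194..."""
    res = ps.delta_log_ra_from_summary(
        10.08, 31.16, 7.60, 19.35, 95.5,
        se_wt_pec50=0.06, se_wt_emax=8.65,
        se_mut_pec50=0.12, se_mut_emax=5.94, se_expression=4.42)
    assert res.se_delta == pytest.approx(0.2251943, abs=1e-6)
    assert res.significant  # CI well clear of zero


def test_delta_log_ra_identity_is_zero():
    res = ps.delta_log_ra_from_summary(9.0, 30.0, 9.0, 30.0, 100.0)
    assert res.delta_log_ra == 0.0
    assert res.se_delta == 0.0
    assert not res.significant


def test_noiseless_delta_matches_constructed_truth():
    wt = ps.fit_three_parameter_logistic(make_experiment(0.0, 35.0, 9.9))
    mut = ps.fit_three_parameter_logistic(make_experiment(0.0, 20.0, 8.2))
    expr = ps.ExpressionSummary(80.0, 0.0, 3)
    res = ps.delta_log_ra(wt, mut, expr)
    truth = (math.log10(35.0) + 9.9) - (math.log10(20.0) + 8.2
                                        - math.log10(0.8))
    assert res.delta_log_ra == pytest.approx(truth, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(wt_pec50=st.floats(7, 11), mut_pec50=st.floats(7, 11),
       wt_emax=st.floats(10, 50), mut_emax=st.floats(10, 50),
       expr=st.floats(30, 200), k=st.floats(0.1, 10))
def test_delta_log_ra_symmetries(wt_pec50, mut_pec50, wt_emax, mut_emax,
                                 expr, k):
    """Antisymmetry under WT/mutant swap, SE exchange invariance, and the
    exact +log10(k) shift under expression rescaling."""
    fwd = ps.delta_log_ra_from_summary(wt_pec50, wt_emax, mut_pec50, mut_emax,
                                       expr, 0.1, 2.0, 0.2, 3.0, 5.0)
    rev = ps.delta_log_ra_from_summary(mut_pec50, mut_emax, wt_pec50, wt_emax,
                                       100.0 * 100.0 / expr, 0.2, 3.0,
                                       0.1, 2.0, 5.0 * 100 * 100 / expr ** 2)
    assert rev.delta_log_ra == pytest.approx(-fwd.delta_log_ra, abs=1e-9)
    swapped_se = ps.delta_log_ra_from_summary(
        mut_pec50, mut_emax, wt_pec50, wt_emax, expr, 0.2, 3.0, 0.1, 2.0, 5.0)
    assert swapped_se.se_delta == pytest.approx(fwd.se_delta, abs=1e-12)
    scaled = ps.delta_log_ra_from_summary(wt_pec50, wt_emax, mut_pec50,
                                          mut_emax, expr * k, 0.1, 2.0,
                                          0.2, 3.0, 5.0)
    assert scaled.delta_log_ra - fwd.delta_log_ra == pytest.approx(
        math.log10(k), abs=1e-9)


def test_delta_log_ra_rejects_bad_expression_and_unconverged():
    wt = ps.LogisticFitResult(0, 30, 9, 0, 0, 0, converged=True)
    bad = ps.LogisticFitResult(0, 30, 9, 0, 0, 0, converged=False)
    with pytest.raises(ValueError):
        ps.delta_log_ra(wt, wt, ps.ExpressionSummary(-5.0, 0.0, 1))
    res = ps.delta_log_ra(wt, bad, ps.ExpressionSummary(100.0, 0.0, 1))
    assert not res.available


# ---------------------------------------------------------------------------
# fold potency
# ---------------------------------------------------------------------------

def test_fold_potency_examples_and_reciprocity():
    assert ps.fold_potency_change(8.43, 10.44) == pytest.approx(102.3, rel=0.01)
    assert ps.fold_potency_change(9.0, 9.0) == 1.0
    assert ps.fold_potency_change(9.0, 10.0) == pytest.approx(10.0)
    f = ps.fold_potency_change(8.1, 9.7)
    assert f * ps.fold_potency_change(9.7, 8.1) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ELISA normalisation
# ---------------------------------------------------------------------------

def _plate(rows):
    return pd.DataFrame(rows, columns=["experiment_id", "role", "a490",
                                       "a650", "a595"])


def _wells(exp, role, ratio, n=3):
    return [(exp, role, ratio + 0.1, 0.1, 1.0) for _ in range(n)]


def test_elisa_identity_and_null():
    plate = _plate(_wells(0, "wt", 0.5) + _wells(0, "mut", 0.5)
                   + _wells(0, "background", 0.1))
    assert ps.normalize_elisa(plate).percent_of_wt == pytest.approx(100.0)
    plate = _plate(_wells(0, "wt", 0.5) + _wells(0, "mut", 0.1)
                   + _wells(0, "background", 0.1))
    assert ps.normalize_elisa(plate).percent_of_wt == pytest.approx(0.0)


def test_elisa_hand_arithmetic_across_experiments():
    """Raw ratios WT 0.50, mutant 0.40, background 0.10 in three
    experiments give (0.40−0.10)/(0.50−0.10) = 75% with zero SEM."""
    rows = []
    for e in range(3):
        rows += _wells(e, "wt", 0.5) + _wells(e, "mut", 0.4) \
            + _wells(e, "background", 0.1)
    summary = ps.normalize_elisa(_plate(rows))
    assert summary.percent_of_wt == pytest.approx(75.0)
    assert summary.se_percent == pytest.approx(0.0, abs=1e-9)
    assert summary.n_experiments == 3


def test_elisa_negative_signal_allowed_but_flagged():
    plate = _plate(_wells(0, "wt", 0.5) + _wells(0, "mut", 0.05)
                   + _wells(0, "background", 0.1))
    summary = ps.normalize_elisa(plate)
    assert summary.percent_of_wt < 0
    assert summary.negative_flagged


def test_elisa_rejects_nonpositive_a595():
    plate = _plate([(0, "wt", 0.6, 0.1, 0.0)] + _wells(0, "mut", 0.4)
                   + _wells(0, "background", 0.1))
    with pytest.raises(ValueError):
        ps.normalize_elisa(plate)


# ---------------------------------------------------------------------------
# radioligand binding
# ---------------------------------------------------------------------------

def _binding_table(top, bottom, pic50, sigma_frac=0.0, rng=None, n_rep=3):
    conc = np.logspace(-12, -6, 8)
    x = np.log10(conc)
    mean = bottom + (top - bottom) / (1.0 + 10.0 ** (x + pic50))
    rows = []
    for c, m in zip(conc, mean):
        for _ in range(n_rep):
            v = m + (rng.normal(0, sigma_frac * m) if sigma_frac else 0.0)
            rows.append({"concentration_M": c, "counts": v})
    return pd.DataFrame(rows)


def test_binding_identity_and_constructed_half_span():
    wt = _binding_table(2000, 200, 9.0)
    res = ps.relative_binding(wt, wt.copy())
    assert res.percent_bound_vs_wt == pytest.approx(100.0, abs=1e-6)
    assert res.ci95[0] <= 100.0 <= res.ci95[1]
    half = _binding_table(1100, 200, 9.0)  # span 900 = half of 1800
    res = ps.relative_binding(wt, half)
    assert res.percent_bound_vs_wt == pytest.approx(50.0, abs=1e-6)


def test_binding_ci_coverage_monte_carlo():
    """Delta-method 95% CI on the span ratio covers the true ratio at a
    rate consistent with its nominal level (5% counting noise, 500 sims)."""
    rng = np.random.default_rng(1234)
    true_ratio = 100.0 * 900.0 / 1800.0
    hits = 0
    for _ in range(500):
        wt = _binding_table(2000, 200, 9.0, 0.05, rng)
        mut = _binding_table(1100, 200, 8.7, 0.05, rng)
        res = ps.relative_binding(wt, mut)
        hits += int(res.ci95[0] <= true_ratio <= res.ci95[1])
    assert 0.93 <= hits / 500 <= 0.97


def test_binding_zero_wt_span_rejected():
    flat = _binding_table(500, 500, 9.0)
    mut = _binding_table(1000, 200, 9.0)
    with pytest.raises(ValueError):
        ps.relative_binding(flat, mut)
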