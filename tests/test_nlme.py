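"""Mixed-effects objective, fitting, empirical-Bayes etas and diagnostics.

The approximate marginal likelihood is checked against two independent
oracles: the exact pooled Gaussian likelihood when the random-effect
variance is zero, and adaptive Gauss-Hermite quadrature over eta otherwise.
"""

import dataclasses

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import logsumexp

from civipop.covariates import CovariateTerm
from civipop.dataset import ConcentrationRecord, DoseEvent, StudyDataset
from civipop.nlme import (
    ModelSpec,
    fit_model,
    foce_objective,
    gof_table,
    posthoc_etas,
    variance_to_cv_percent,
)
from civipop.structural import PKParameters, predict_concentrations
from conftest import make_patient, make_simple_dataset


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def pooled_neg2ll(model, dataset):
    """Exact -2 log-likelihood at eta = 0 (valid when omega2 = 0)."""
    total = 0.0
    for p in dataset.patients:
        params = PKParameters(cl=model.typical_cl(p), v=model.v)
        doses = dataset.doses_of(p.patient_id)
        obs = [o for o in dataset.included_observations() if o.patient_id == p.patient_id]
        f = predict_concentrations(params, doses, [o.time for o in obs])
        y = np.array([o.concentration for o in obs])
        sd = np.sqrt(model.sigma2_normal) * f
        total += -2.0 * np.sum(stats.norm.logpdf(y, loc=f, scale=sd))
    return total


def quadrature_neg2ll(model, dataset, n_nodes=96):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for p in dataset.patients:
        doses = dataset.doses_of(p.patient_id)
        obs = [o for o in dataset.included_observations() if o.patient_id == p.patient_id]
        times = [o.time for o in obs]
        y = np.array([o.concentration for o in obs])
        tvcl = model.typical_cl(p)

        def neg2_joint(eta):
            f = predict_concentrations(PKParameters(cl=tvcl * np.exp(eta), v=model.v), doses, times)
            var = model.sigma2_normal * f * f
            obs_term = np.sum(np.log(2 * np.pi * var) + (y - f) ** 2 / var)
            return obs_term + np.log(2 * np.pi * model.omega2) + eta * eta / model.omega2

        mode = optimize.minimize_scalar(neg2_joint, bounds=(-4, 4), method="bounded",
                                        options=dict(xatol=1e-12)).x
        h = 1e-4
        d2 = (neg2_joint(mode + h) - 2 * neg2_joint(mode) + neg2_joint(mode - h)) / h**2
        scale = np.sqrt(2.0 / max(d2, 1e-8))
        eta_k = mode + np.sqrt(2.0) * scale * nodes
        log_terms = np.array(
            [np.log(weights[k]) + nodes[k] ** 2 - 0.5 * neg2_joint(eta_k[k])
             for k in range(n_nodes)]
        )
        log_lik = logsumexp(log_terms) + np.log(np.sqrt(2.0) * scale)
        total += -2.0 * log_lik
    return total


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def test_zero_iiv_matches_exact_pooled_likelihood():
    ds = make_simple_dataset(n_patients=3, sigma_cv=0.2, seed=1)
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.0, sigma2_normal=0.04)
    assert foce_objective(model, ds) == pytest.approx(pooled_neg2ll(model, ds), abs=1e-8)


def test_matches_quadrature_for_single_patient():
    ds = make_simple_dataset(n_patients=1, sigma_cv=0.25, omega2=0.04, seed=2,
                             obs_times=(24.0, 168.0))
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.04, sigma2_normal=0.06)
    assert foce_objective(model, ds) == pytest.approx(
        quadrature_neg2ll(model, ds), abs=0.1
    )


def test_laplace_gap_shrinks_with_iiv():
    ds = make_simple_dataset(n_patients=2, sigma_cv=0.2, omega2=0.05, seed=3)
    gaps = []
    for omega2 in (0.1, 0.01, 0.001):
        model = ModelSpec(cl=42.1, v=319.0, omega2=omega2, sigma2_normal=0.05)
        gaps.append(abs(foce_objective(model, ds) - quadrature_neg2ll(model, ds)))
    assert gaps[-1] < gaps[0]
    assert gaps[-1] < 1e-3


def test_null_covariate_term_leaves_ofv_unchanged():
    ds = make_simple_dataset(n_patients=3, sigma_cv=0.2, omega2=0.04, seed=4)
    base = ModelSpec(cl=42.1, v=319.0, omega2=0.04, sigma2_normal=0.05)
    with_null_power = dataclasses.replace(
        base, covariate_terms=(CovariateTerm("CLCR", "power", 0.0, reference=79.22),)
    )
    with_null_ratio = dataclasses.replace(
        base, covariate_terms=(CovariateTerm("MM", "ratio", 1.0),)
    )
    ofv = foce_objective(base, ds)
    assert foce_objective(with_null_power, ds) == pytest.approx(ofv, abs=1e-9)
    assert foce_objective(with_null_ratio, ds) == pytest.approx(ofv, abs=1e-9)


def test_ofv_invariant_to_patient_order():
    ds = make_simple_dataset(n_patients=4, sigma_cv=0.2, omega2=0.05, seed=5)
    model = ModelSpec(cl=40.0, v=300.0, omega2=0.05, sigma2_normal=0.05)
    reversed_ds = StudyDataset(
        list(reversed(ds.patients)), list(reversed(ds.doses)),
        list(reversed(ds.observations)),
    )
    assert foce_objective(model, reversed_ds) == pytest.approx(
        foce_objective(model, ds), abs=1e-9
    )


def test_ofv_invariant_to_time_unit_rescaling():
    """Hours vs days with consistent rate/CL/V rescaling give identical OFV."""
    ds = make_simple_dataset(n_patients=2, sigma_cv=0.2, omega2=0.04, seed=6)
    model_h = ModelSpec(cl=42.1, v=319.0, omega2=0.04, sigma2_normal=0.05)
    scaled = StudyDataset(
        [dataclasses.replace(p) for p in ds.patients],
        [DoseEvent(d.patient_id, d.start_time / 24.0, d.duration / 24.0, d.amount)
         for d in ds.doses],
        [dataclasses.replace(o, time=o.time / 24.0) for o in ds.observations],
    )
    model_d = dataclasses.replace(model_h, cl=42.1 * 24.0)  # L/day, V unchanged
    assert foce_objective(model_d, scaled) == pytest.approx(
        foce_objective(model_h, ds), abs=1e-8
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_recovers_truth_at_vanishing_noise():
    ds = make_simple_dataset(n_patients=8, sigma_cv=0.01, omega2=0.0, seed=7)
    start = ModelSpec(cl=30.0, v=200.0, omega2=0.01, sigma2_normal=0.01)
    fit = fit_model(start, ds, compute_se=False)
    assert fit.converged
    assert fit.model.cl == pytest.approx(42.1, rel=0.02)
    assert fit.model.v == pytest.approx(319.0, rel=0.02)


def test_multistart_reaches_same_optimum():
    ds = make_simple_dataset(n_patients=6, sigma_cv=0.05, omega2=0.02, seed=8)
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.02, sigma2_normal=0.01)
    fits = []
    for factor in (1.0, 2.0, 0.5):
        start = dataclasses.replace(
            model, cl=model.cl * factor, v=model.v * factor,
            omega2=model.omega2, sigma2_normal=model.sigma2_normal,
        )
        fits.append(fit_model(model, ds, inits=start, compute_se=False))
    for fit in fits[1:]:
        assert fit.ofv == pytest.approx(fits[0].ofv, abs=0.05)
        assert fit.model.cl == pytest.approx(fits[0].model.cl, rel=1e-3)


def test_nested_models_never_fit_worse(clean_study):
    dataset, truth = clean_study
    base = ModelSpec(cl=42.0, v=320.0, omega2=0.08, sigma2_normal=0.09)
    base_fit = fit_model(base, dataset, compute_se=False)
    full = dataclasses.replace(
        base_fit.model,
        covariate_terms=(CovariateTerm("CLCR", "power", 0.0, reference=79.22),),
    )
    full_fit = fit_model(full, dataset, compute_se=False)
    assert full_fit.ofv <= base_fit.ofv + 1e-3


def test_variance_to_cv_percent_values():
    assert variance_to_cv_percent(0.0385) == pytest.approx(19.6, abs=0.05)
    assert variance_to_cv_percent(0.0838) == pytest.approx(28.9, abs=0.05)


# ---------------------------------------------------------------------------
# post-hoc etas
# ---------------------------------------------------------------------------


def test_eta_zero_when_observations_match_population_prediction():
    # small residual variance so the interaction term (the eta-dependence of
    # the residual variance) cannot shift the conditional mode measurably
    ds = make_simple_dataset(n_patients=1, sigma_cv=0.0)
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.05, sigma2_normal=1e-8)
    etas = posthoc_etas(model, ds)
    assert abs(etas[0].eta_cl) < 1e-6
    assert etas[0].individual_cl == pytest.approx(42.1, rel=1e-5)


def test_eta_minus_log2_when_concentrations_double_at_plateau():
    # at plateau C = R/CL, so doubling C corresponds to halving CL
    ds = make_simple_dataset(n_patients=1, obs_times=(120.0, 140.0, 160.0, 168.0))
    for o in ds.observations:
        o.concentration *= 2.0
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.1, sigma2_normal=1e-8)
    etas = posthoc_etas(model, ds)
    # tolerance allows for the slight shape change of the rising branch when
    # CL halves (the late sampling times are close to but not at plateau)
    assert etas[0].eta_cl == pytest.approx(-np.log(2.0), abs=1e-3)


def test_patient_without_observations_gets_zero_eta():
    ds = make_simple_dataset(n_patients=2, sigma_cv=0.1, seed=9)
    for o in ds.observations:
        if o.patient_id == "P2":
            o.blq = True
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.05, sigma2_normal=0.05)
    etas = {e.patient_id: e for e in posthoc_etas(model, ds)}
    assert etas["P2"].eta_cl == 0.0
    assert etas["P2"].n_obs == 0
    assert etas["P1"].n_obs > 0


def test_eta_distribution_centred_at_zero(clean_study, clean_study_base_fit):
    dataset, _ = clean_study
    etas = np.array([e.eta_cl for e in clean_study_base_fit.etas if e.n_obs > 0])
    se = etas.std(ddof=1) / np.sqrt(len(etas))
    assert abs(etas.mean()) < 3.0 * se + 1e-3


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def _fixed_fit(model, ds):
    from civipop.nlme import FitResult

    return FitResult(
        model=model, ofv=foce_objective(model, ds), standard_errors={},
        etas=posthoc_etas(model, ds), converged=True, n_function_evals=0,
    )


def test_wres_zero_for_noise_free_data():
    ds = make_simple_dataset(n_patients=3, sigma_cv=0.0)
    model = ModelSpec(cl=42.1, v=319.0, omega2=0.02, sigma2_normal=0.04)
    gof = gof_table(_fixed_fit(model, ds), ds)
    assert np.all(np.abs(gof["wres"]) < 1e-6)
    assert np.all(gof["pred"] >= 0) and np.all(gof["ipred"] >= 0)


def test_wres_calibrated_under_true_model(clean_study, final_truth):
    dataset, _ = clean_study
    fit = fit_model(final_truth, dataset, compute_se=False)
    gof = gof_table(fit, dataset)
    wres = gof["wres"].to_numpy()
    assert abs(wres.mean()) < 0.1
    assert np.mean((wres > -2) & (wres < 2)) > 0.90


def test_misspecified_volume_leaves_time_trend(clean_study, final_truth):
    """Fixing V at 10x truth must produce a systematic WRES-vs-time pattern
    in the post-infusion window, detected by a sign test."""
    dataset, _ = clean_study
    bad = dataclasses.replace(final_truth, v=final_truth.v * 10.0)
    gof = gof_table(_fixed_fit(bad, dataset), dataset)
    post = gof[(gof["time"] > 168.0) & (gof["time"] < 200.0)]
    # with V too large the predicted post-infusion decay is far too slow,
    # so late residuals are predominantly one-signed
    frac_neg = np.mean(post["wres"] < 0)
    assert frac_neg > 0.8 or frac_neg < 0.2
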