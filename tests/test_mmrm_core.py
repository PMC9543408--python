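"""MMRM design construction, REML engine, contrasts."""

import numpy as np
import pytest

import estimandtools as et
from estimandtools.mmrm_core import (
    MmrmSpec,
    _neg_restricted_loglik,
    _pack_chol,
    _pattern_stats,
    build_design,
    contrast,
    reml_fit_design,
)
from estimandtools.trial_data import PatternLabel

from conftest import monotone_dropout_config, no_dropout_config


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def test_design_column_counts(small_trial):
    ds, _ = small_trial
    d = build_design(ds, MmrmSpec())
    # intercept + treatment + 5 visit + 5 interaction + baseline
    assert d.X.shape[1] == 13
    assert d.names[0] == "const"
    assert d.names[-1] == "baseline"


def test_design_pattern_columns():
    # all three patterns present in both arms -> 2 pattern + 2 interaction
    rng = np.random.default_rng(5)
    subs = []
    for arm in ("placebo", "active"):
        for k in range(4):
            full = rng.uniform(10, 30, 6)
            subs.append(et.SubjectRecord(f"{arm}cq{k}", arm, rng.uniform(20, 40), full))
            late = rng.uniform(10, 30, 6)
            late[4:] = np.nan
            subs.append(et.SubjectRecord(f"{arm}lt{k}", arm, rng.uniform(20, 40),
                                         late, "LoE", 4))
            early = rng.uniform(10, 30, 6)
            early[2:] = np.nan
            subs.append(et.SubjectRecord(f"{arm}er{k}", arm, rng.uniform(20, 40),
                                         early, "AE", 2))
    ds = et.TrialDataset(et.VisitSchedule(6), subs, "placebo")
    d = build_design(ds, MmrmSpec(include_pattern_terms=True))
    assert d.X.shape[1] == 17
    assert "pattern_late_dropout" in d.names
    assert "treat_active:pattern_early_dropout" in d.names


def test_design_rows_are_observed_cells_only(tiny_dataset):
    d = build_design(tiny_dataset, MmrmSpec())
    masks = [s.mask.sum() for s in tiny_dataset.subjects]
    assert len(d.y) == sum(masks)
    # subject a2 observed at visits {1, 3} only -> exactly 2 rows
    rows_a2 = (np.array(d.subject_ids)[d.subject] == "a2").sum()
    assert rows_a2 == 2


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------


def test_gradient_matches_finite_differences(small_trial):
    ds, _ = small_trial
    d = build_design(ds, MmrmSpec())
    stats = _pattern_stats(d)
    V, q, N = d.n_visits, d.X.shape[1], len(d.y)
    rng = np.random.default_rng(1)
    theta = _pack_chol(np.diag(rng.uniform(20, 40, V)))
    f, g = _neg_restricted_loglik(theta, stats, V, q, N)
    eps = 1e-6
    for i in range(0, len(theta), 5):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fp, _ = _neg_restricted_loglik(tp, stats, V, q, N)
        fm, _ = _neg_restricted_loglik(tm, stats, V, q, N)
        assert g[i] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4, abs=1e-5)


def test_complete_balanced_fit_equals_cell_means():
    # with complete data, gamma = 0 and a saturated mean, GLS reproduces
    # the per-arm-per-visit sample means under the cell-mean reparameterization
    cfg = no_dropout_config(150, baseline_coef=0.0)
    ds, _ = et.simulate_trial(cfg, 19)
    fit = et.reml_fit(ds)
    Y = ds.outcome_matrix()
    arm = np.array([s.arm for s in ds.subjects])
    # model-implied cell means vs sample cell means
    bl = ds.baseline_vector().mean()
    for j in range(1, 7):
        mu_p = fit.coef("const") + (fit.coef(f"visit_{j}") if j > 1 else 0.0) \
            + fit.coef("baseline") * bl
        mu_a = mu_p + fit.coef("treat_active") \
            + (fit.coef(f"treat_active:visit_{j}") if j > 1 else 0.0)
        # baseline column enters per-subject; with complete balanced data the
        # GLS solution matches OLS cell means up to the baseline adjustment
        samp_p = Y[arm == "placebo", j - 1].mean()
        samp_a = Y[arm == "active", j - 1].mean()
        assert mu_a - mu_p == pytest.approx(
            samp_a - samp_p
            - fit.coef("baseline")
            * (ds.baseline_vector()[arm == "active"].mean()
               - ds.baseline_vector()[arm == "placebo"].mean()),
            abs=1e-6,
        )


def test_duplicating_subjects_keeps_beta_halves_covariance(tiny_dataset):
    cfg = monotone_dropout_config(15)
    ds, _ = et.simulate_trial(cfg, 23)
    doubled = ds.copy()
    for s in ds.subjects:
        doubled.subjects.append(
            et.SubjectRecord(s.subject_id + "_dup", s.arm, s.baseline,
                             s.outcomes.copy(), s.disc_reason, s.disc_visit)
        )
    doubled.validate()
    f1 = et.reml_fit(ds)
    f2 = et.reml_fit(doubled)
    # beta is exactly GLS-invariant at fixed Sigma; the REML Sigma-hat moves
    # slightly because the restricted-likelihood penalty does not double
    np.testing.assert_allclose(f1.beta, f2.beta, atol=2e-2)
    np.testing.assert_allclose(
        np.diag(f1.beta_cov) / np.diag(f2.beta_cov), 2.0, rtol=0.1
    )


def test_fit_invariant_to_subject_and_row_order(small_trial):
    ds, _ = small_trial
    f1 = et.reml_fit(ds)
    shuffled = et.TrialDataset(
        ds.schedule, list(reversed(ds.subjects)), ds.reference_arm
    )
    f2 = et.reml_fit(shuffled)
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)
    np.testing.assert_allclose(f1.sigma, f2.sigma, atol=1e-5)
    assert f1.reml_loglik == pytest.approx(f2.reml_loglik, abs=1e-6)


def test_sigma_positive_definite_and_fit_metadata(small_trial):
    ds, _ = small_trial
    fit = et.reml_fit(ds)
    assert fit.converged
    w = np.linalg.eigvalsh(fit.sigma)
    assert w.min() > 0
    assert np.linalg.eigvalsh(fit.beta_cov).min() > -1e-12
    assert fit.n_obs == int(sum(s.mask.sum() for s in ds.subjects))
    assert len(fit.coef_frame()) == len(fit.beta)
    assert fit.sigma_frame().shape == (6, 6)


def test_too_few_observations_raises():
    cfg = no_dropout_config(2)
    ds, _ = et.simulate_trial(cfg, 2)
    with pytest.raises(et.MmrmError, match="too few"):
        et.reml_fit(ds)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


def _toy_fit(beta_names, beta, cov):
    from estimandtools.mmrm_core import MmrmFit

    return MmrmFit(
        beta=np.asarray(beta, dtype=float),
        beta_names=list(beta_names),
        beta_cov=np.asarray(cov, dtype=float),
        sigma=np.eye(6),
        reml_loglik=0.0,
        n_subjects_used=0,
        n_obs=0,
        converged=True,
        n_visits=6,
        arms=["placebo", "active"],
    )


def test_delta6_is_sum_of_main_effect_and_interaction():
    names = ["const", "treat_active"] + [f"visit_{j}" for j in range(2, 7)] \
        + [f"treat_active:visit_{j}" for j in range(2, 7)] + ["baseline"]
    beta = np.zeros(13)
    beta[names.index("treat_active")] = 2.0
    beta[names.index("treat_active:visit_6")] = -3.0
    fit = _toy_fit(names, beta, np.eye(13))
    res = et.treatment_effect_at_visit(fit, 6)
    assert res.estimate == pytest.approx(-1.0)
    assert res.se == pytest.approx(np.sqrt(2.0))
    # visit 1: delta1 = beta1, se = sqrt(Omega_11)
    res1 = et.treatment_effect_at_visit(fit, 1)
    assert res1.estimate == pytest.approx(2.0)
    assert res1.se == pytest.approx(1.0)
    assert res1.ci_low == pytest.approx(2.0 - 1.959963984540054)


def test_contrast_errors():
    names = ["const", "treat_active"] + [f"visit_{j}" for j in range(2, 7)] \
        + [f"treat_active:visit_{j}" for j in range(2, 7)] + ["baseline"]
    fit = _toy_fit(names, np.zeros(13), np.eye(13))
    with pytest.raises(ValueError, match="visit"):
        et.treatment_effect_at_visit(fit, 7)
    with pytest.raises(ValueError):
        et.treatment_effect_at_visit(fit, 3, arm="placebo")


def test_generic_contrast_ci_ordering(small_trial):
    ds, _ = small_trial
    fit = et.reml_fit(ds)
    c = np.zeros(len(fit.beta))
    c[1] = 1.0
    r = contrast(fit, c)
    assert r.ci_low <= r.estimate <= r.ci_high
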