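"""The eight treatment-effect analysis methods as uniform operations.

Every operation returns an :class:`EffectEstimate` for the last scheduled
visit V: a method-labelled, estimand-labelled contrast (points MADRS10,
negative favours the experimental arm) with SE and 95% CI.  The methods:

ANCOVA_CC, ANCOVA_LOCF, ANCOVA_MI - endpoint ANCOVA on complete cases, after
LOCF, and after predictive-mean-matching MI with Rubin pooling;
MMRM, MMRM_LOCF, MMRM_J2R - direct-likelihood MMRM, MMRM after LOCF, and
MMRM after jump-to-reference MI with Rubin pooling;
PMMM - pattern-mixture mixed model (pattern-specific effects averaged with
sample-frequency weights);
PRINCIPAL_STRATUM - propensity-score-selected stratum of subjects predicted
not to experience the intercurrent event, analysed by MMRM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .imputation import (
    ImputationSet,
    j2r_multiple_impute,
    locf_impute,
    pmm_multiple_impute,
    rubin_pool,
)
from .mmrm_core import (
    MmrmError,
    MmrmSpec,
    Z975,
    contrast,
    reml_fit,
    treatment_effect_at_visit,
)
from .trial_data import PatternLabel, TrialDataset, classify_pattern

METHODS = (
    "ANCOVA_CC",
    "ANCOVA_LOCF",
    "ANCOVA_MI",
    "MMRM",
    "MMRM_LOCF",
    "MMRM_J2R",
    "PMMM",
    "PRINCIPAL_STRATUM",
)


@dataclass
class EffectEstimate:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    visit: int
    estimand_labels: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PrincipalStratumConfig:
    """Propensity-model settings for the principal-stratum analysis."""

    covariates: tuple[str, ...] = ("baseline",)  # of {"baseline", "arm"}
    cutoff: float | str = "AUTO"
    ie_definition: tuple[str, ...] | str = "ANY"

    def __post_init__(self) -> None:
        if not isinstance(self.cutoff, str) and not 0.0 < float(self.cutoff) <= 1.0:
            raise ValueError("cutoff must lie in (0, 1] or be 'AUTO'")


def _last_visit(dataset: TrialDataset) -> int:
    return dataset.schedule.last_visit


def _target_arm(dataset: TrialDataset, arm: str | None) -> str:
    nonref = [a for a in dataset.arms if a != dataset.reference_arm]
    if arm is None:
        return nonref[0]
    if arm not in nonref:
        raise ValueError(f"arm {arm!r} is not a non-reference arm")
    return arm


# ---------------------------------------------------------------------------
# ANCOVA family
# ---------------------------------------------------------------------------


def ancova_fit(
    dataset: TrialDataset,
    subjects: list[int] | None = None,
    arm: str | None = None,
) -> EffectEstimate:
    """OLS of the last-visit outcome on treatment + baseline; delta = b1."""
    arm = _target_arm(dataset, arm)
    V = _last_visit(dataset)
    idx = range(dataset.n_subjects) if subjects is None else subjects
    rows = [
        dataset.subjects[i]
        for i in idx
        if not np.isnan(dataset.subjects[i].outcomes[V - 1])
    ]
    arms = dataset.arms
    for a in arms:
        if sum(1 for s in rows if s.arm == a) < 3:
            raise MmrmError(f"ANCOVA needs >= 3 subjects per arm (arm {a!r})")
    y = np.array([s.outcomes[V - 1] for s in rows])
    bl = np.array([s.baseline for s in rows])
    X = np.column_stack(
        [np.ones(len(rows))]
        + [np.array([float(s.arm == a) for s in rows]) for a in arms[1:]]
        + [bl]
    )
    res = sm.OLS(y, X).fit()
    k = 1 + arms[1:].index(arm)
    est = float(res.params[k])
    se = float(res.bse[k])
    return EffectEstimate(
        method="ANCOVA_CC",
        estimate=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        visit=V,
        diagnostics={"n_used": len(rows), "arm": arm},
    )


def ancova_complete_cases(dataset: TrialDataset, arm: str | None = None) -> EffectEstimate:
    """ANCOVA on subjects with observed baseline and last-visit outcome
    (intermediate visits are irrelevant)."""
    out = ancova_fit(dataset, arm=arm)
    out.method = "ANCOVA_CC"
    out.estimand_labels = ("E1", "completer-contrast")
    return out


def ancova_locf(dataset: TrialDataset, arm: str | None = None) -> EffectEstimate:
    """ANCOVA after LOCF (while-on-treatment / treatment-policy-under-LOCF)."""
    imp = locf_impute(dataset)
    out = ancova_fit(imp.datasets[0], arm=arm)
    out.method = "ANCOVA_LOCF"
    out.estimand_labels = ("E2", "E3")
    out.diagnostics["n_imputed_cells"] = len(imp.imputed_cells)
    return out


def ancova_mi(
    dataset: TrialDataset, m: int = 10, seed: int = 0, arm: str | None = None
) -> EffectEstimate:
    """ANCOVA on each PMM-imputed dataset, pooled by Rubin's rules."""
    arm = _target_arm(dataset, arm)
    imp = pmm_multiple_impute(dataset, m=m, seed=seed)
    if not imp.imputed_cells:
        out = ancova_fit(dataset, arm=arm)
        out.method = "ANCOVA_MI"
        out.estimand_labels = ("E1", "E3")
        out.diagnostics.update({"m": m, "B": 0.0})
        return out
    fits = [ancova_fit(d, arm=arm) for d in imp.datasets]
    pooled = rubin_pool([f.estimate for f in fits], [f.se for f in fits])
    return EffectEstimate(
        method="ANCOVA_MI",
        estimate=pooled.qbar,
        se=pooled.se,
        ci_low=pooled.ci_low,
        ci_high=pooled.ci_high,
        visit=_last_visit(dataset),
        estimand_labels=("E1", "E3"),
        diagnostics={"m": m, "B": pooled.B, "df": pooled.df, "arm": arm,
                     "n_imputed_cells": len(imp.imputed_cells)},
    )


# ---------------------------------------------------------------------------
# MMRM family
# ---------------------------------------------------------------------------


def mmrm_plain(dataset: TrialDataset, arm: str | None = None) -> EffectEstimate:
    """Direct-likelihood MMRM; delta_V from the saturated fit."""
    arm = _target_arm(dataset, arm)
    fit = reml_fit(dataset)
    V = _last_visit(dataset)
    c = treatment_effect_at_visit(fit, V, arm=arm)
    return EffectEstimate(
        method="MMRM",
        estimate=c.estimate,
        se=c.se,
        ci_low=c.ci_low,
        ci_high=c.ci_high,
        visit=V,
        estimand_labels=("E1", "E3"),
        diagnostics={"n_used": fit.n_subjects_used, "converged": fit.converged,
                     "reml_loglik": fit.reml_loglik, "arm": arm},
    )


def mmrm_locf(dataset: TrialDataset, arm: str | None = None) -> EffectEstimate:
    imp = locf_impute(dataset)
    out = mmrm_plain(imp.datasets[0], arm=arm)
    out.method = "MMRM_LOCF"
    out.estimand_labels = ("E3",)
    out.diagnostics["n_imputed_cells"] = len(imp.imputed_cells)
    return out


def mmrm_j2r(
    dataset: TrialDataset,
    m: int = 10,
    seed: int = 0,
    arm: str | None = None,
    draws: str = "marginal",
) -> EffectEstimate:
    """MMRM after jump-to-reference MI, pooled by Rubin's rules."""
    arm = _target_arm(dataset, arm)
    imp = j2r_multiple_impute(dataset, m=m, seed=seed, draws=draws)
    if not imp.imputed_cells:
        out = mmrm_plain(dataset, arm=arm)
        out.method = "MMRM_J2R"
        out.estimand_labels = ("E4", "E3")
        out.diagnostics.update({"m": m, "B": 0.0})
        return out
    ests, ses = [], []
    for d in imp.datasets:
        c = treatment_effect_at_visit(reml_fit(d), _last_visit(d), arm=arm)
        ests.append(c.estimate)
        ses.append(c.se)
    pooled = rubin_pool(ests, ses)
    return EffectEstimate(
        method="MMRM_J2R",
        estimate=pooled.qbar,
        se=pooled.se,
        ci_low=pooled.ci_low,
        ci_high=pooled.ci_high,
        visit=_last_visit(dataset),
        estimand_labels=("E4", "E3"),
        diagnostics={"m": m, "B": pooled.B, "df": pooled.df, "arm": arm,
                     "n_imputed_cells": len(imp.imputed_cells)},
    )


# ---------------------------------------------------------------------------
# Pattern-mixture mixed model
# ---------------------------------------------------------------------------

_MERGE_CHAIN = {
    PatternLabel.EARLY_DROPOUT: PatternLabel.LATE_DROPOUT,
    PatternLabel.LATE_DROPOUT: PatternLabel.COMPLETER_QUASI,
}


def merge_sparse_patterns(
    dataset: TrialDataset,
    labels: list[PatternLabel],
    min_per_cell: int = 2,
) -> tuple[list[PatternLabel], list[str]]:
    """Merge any pattern with < min_per_cell subjects in some arm into the
    adjacent pattern (EARLY -> LATE -> COMPLETER_QUASI)."""
    labels = list(labels)
    log: list[str] = []
    arms = dataset.arms
    for pat in (PatternLabel.EARLY_DROPOUT, PatternLabel.LATE_DROPOUT):
        while pat in labels:
            counts = {
                a: sum(
                    1
                    for s, p in zip(dataset.subjects, labels)
                    if p == pat and s.arm == a
                )
                for a in arms
            }
            if min(counts.values()) >= min_per_cell:
                break
            target = _MERGE_CHAIN[pat]
            labels = [target if p == pat else p for p in labels]
            log.append(f"merged {pat.value} into {target.value} (counts {counts})")
    return labels, log


def pmmm(dataset: TrialDataset, arm: str | None = None) -> EffectEstimate:
    """Pattern-mixture mixed model.

    delta_VP = b1 + b3V + b6P per dropout pattern; the reported effect is the
    average of the pattern-specific effects weighted by the pattern relative
    frequencies in the analyzed sample (weights treated as fixed), with
    SE = sqrt(w' C w) from the model coefficient covariance.
    """
    arm = _target_arm(dataset, arm)
    V = _last_visit(dataset)
    labels = [classify_pattern(s.mask) for s in dataset.subjects]
    labels, merge_log = merge_sparse_patterns(dataset, labels)
    usable = [p for p in labels if p != PatternLabel.UNCLASSIFIABLE]
    present = [p for p in (PatternLabel.COMPLETER_QUASI, PatternLabel.LATE_DROPOUT,
                           PatternLabel.EARLY_DROPOUT) if p in usable]

    if len(present) <= 1:
        out = mmrm_plain(dataset, arm=arm)
        out.method = "PMMM"
        out.estimand_labels = ("E5", "E3")
        out.diagnostics["patterns"] = [p.value for p in present]
        out.diagnostics["merge_log"] = merge_log
        return out

    spec = MmrmSpec(include_pattern_terms=True)
    fit = reml_fit(dataset, spec, pattern_labels=labels)
    # weights: relative pattern frequencies among analyzed subjects
    counts = {p: usable.count(p) for p in present}
    total = sum(counts.values())
    w = np.array([counts[p] / total for p in present])
    cvecs = [
        treatment_effect_at_visit(fit, V, arm=arm, pattern=p).contrast_vector
        for p in present
    ]
    deltas = np.array([c @ fit.beta for c in cvecs])
    Cmat = np.array([[ci @ fit.beta_cov @ cj for cj in cvecs] for ci in cvecs])
    est = float(w @ deltas)
    se = float(np.sqrt(max(w @ Cmat @ w, 0.0)))
    return EffectEstimate(
        method="PMMM",
        estimate=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        visit=V,
        estimand_labels=("E5", "E3"),
        diagnostics={
            "patterns": [p.value for p in present],
            "weights": w.tolist(),
            "pattern_deltas": deltas.tolist(),
            "merge_log": merge_log,
            "n_used": fit.n_subjects_used,
            "arm": arm,
        },
    )


# ---------------------------------------------------------------------------
# Principal stratum
# ---------------------------------------------------------------------------


def principal_stratum(
    dataset: TrialDataset,
    config: PrincipalStratumConfig = PrincipalStratumConfig(),
    seed: int = 0,
    arm: str | None = None,
) -> EffectEstimate:
    """MMRM on the propensity-selected stratum predicted free of the
    intercurrent event.

    A logistic regression of the IE indicator on the configured covariates
    (all subjects pooled across arms) yields per-subject propensities; the
    stratum keeps subjects below the cutoff.  AUTO cutoff = the empirical
    propensity quantile equal to the observed no-IE fraction, i.e. the
    stratum size matches the observed number of IE-free subjects.
    """
    arm = _target_arm(dataset, arm)
    if config.ie_definition == "ANY":
        has_ie = np.array([s.disc_visit is not None for s in dataset.subjects])
    else:
        wanted = set(config.ie_definition)
        has_ie = np.array(
            [s.disc_visit is not None and s.disc_reason in wanted
             for s in dataset.subjects]
        )

    if not has_ie.any():
        out = mmrm_plain(dataset, arm=arm)
        out.method = "PRINCIPAL_STRATUM"
        out.estimand_labels = ("E6",)
        out.diagnostics["note"] = "no intercurrent events; stratum = everyone"
        return out
    if has_ie.all():
        raise MmrmError("every subject experienced the intercurrent event")

    cols = [np.ones(dataset.n_subjects)]
    if "baseline" in config.covariates:
        cols.append(dataset.baseline_vector())
    if "arm" in config.covariates:
        codes = dataset.arm_codes()
        for a in range(1, codes.max() + 1):
            cols.append((codes == a).astype(float))
    X = np.column_stack(cols)
    probs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(has_ie.astype(float), X).fit(disp=0, maxiter=200)
            if np.isfinite(res.params).all() and np.abs(res.params).max() < 1e3:
                probs = np.asarray(res.predict(X))
        except Exception:
            probs = None
    if probs is None:
        # separation or non-convergence: ridge-penalized fallback; the
        # propensity ranking is all the selection needs
        warnings.warn(
            "logistic propensity fit failed or separated; using penalized fit",
            stacklevel=2,
        )
        res = sm.Logit(has_ie.astype(float), X).fit_regularized(
            alpha=1e-2, disp=0, maxiter=500
        )
        probs = np.asarray(sm.Logit(has_ie.astype(float), X).predict(res.params))

    n = dataset.n_subjects
    if config.cutoff == "AUTO":
        k = int((~has_ie).sum())  # stratum size = observed no-IE count
        order = np.argsort(probs, kind="stable")
        stratum = np.zeros(n, dtype=bool)
        stratum[order[:k]] = True
        cutoff_used = float(probs[order[k - 1]]) if k else 0.0
    else:
        cutoff_used = float(config.cutoff)
        if cutoff_used >= 1.0:
            stratum = np.ones(n, dtype=bool)
        else:
            stratum = probs < cutoff_used

    for a in dataset.arms:
        if sum(1 for i in np.nonzero(stratum)[0] if dataset.subjects[i].arm == a) < 3:
            raise MmrmError(f"principal stratum smaller than 3 subjects in arm {a!r}")

    sub = TrialDataset(
        dataset.schedule,
        [dataset.subjects[i] for i in np.nonzero(stratum)[0]],
        dataset.reference_arm,
    )
    out = mmrm_plain(sub, arm=arm)
    out.method = "PRINCIPAL_STRATUM"
    out.estimand_labels = ("E6",)
    out.diagnostics.update(
        {"stratum_size": int(stratum.sum()), "cutoff": cutoff_used,
         "n_ie": int(has_ie.sum())}
    )
    return out
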