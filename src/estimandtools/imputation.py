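"""Single and multiple imputation for monotone/intermittent missing outcomes.

Three fill-in strategies feed the downstream estimators:

* LOCF - deterministic last-observation-carried-forward (baseline is carried
  into leading missing cells);
* PMM_MI - chained-equations multiple imputation with type-1 predictive mean
  matching (predictors: treatment, baseline, all other visits);
* J2R_MI - jump-to-reference multiple imputation: a reference-arm MMRM
  (intercept + visit + baseline, unstructured covariance) predicts the fixed
  part of each experimental-arm post-discontinuation cell, and a random
  error drawn from the reference covariance enables multiple imputation.
  Control-arm missing cells and experimental-arm intermittent cells are
  considered MAR and left to the downstream direct-likelihood fit.

Rubin's rules pool the per-imputation (estimate, SE) pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .mmrm_core import Design, MmrmError, reml_fit_design, Z975
from .trial_data import SubjectRecord, TrialDataset, analyzable_subjects, write_trial_csv


def _imp_rng(seed: int, i: int) -> np.random.Generator:
    # imputation i uses substream (seed, i)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 1000 + i))))


@dataclass
class ImputationSet:
    """m completed datasets plus provenance.

    ``imputed_cells`` lists (subject_id, visit) pairs that were filled;
    completed datasets drop ``disc_visit`` annotations (the monotone tail no
    longer exists once filled) but keep the discontinuation reason.
    """

    method: str  # LOCF | PMM_MI | J2R_MI
    m: int
    datasets: list[TrialDataset]
    seed: int | None = None
    imputed_cells: list[tuple[str, int]] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def write_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, d in enumerate(self.datasets, start=1):
            write_trial_csv(d, path / f"imputation_{i:02d}.csv")
        manifest = {
            "method": self.method,
            "m": self.m,
            "seed": self.seed,
            "imputed_cells": [[sid, int(v)] for sid, v in self.imputed_cells],
            "notes": self.notes,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass
class RubinPooled:
    qbar: float
    W: float          # within-imputation variance
    B: float          # between-imputation variance
    T: float          # total variance = W + (1 + 1/m) B
    df: float         # Rubin degrees of freedom (inf when B = 0)
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))


def _completed_subject(s: SubjectRecord, outcomes: np.ndarray) -> SubjectRecord:
    return SubjectRecord(s.subject_id, s.arm, s.baseline, outcomes,
                         s.disc_reason, None)


# ---------------------------------------------------------------------------
# LOCF
# ---------------------------------------------------------------------------


def locf_impute(dataset: TrialDataset) -> ImputationSet:
    """Last observation carried forward (m = 1, deterministic, idempotent).

    Each missing cell receives the most recent previously observed
    post-baseline value; cells before the first observed post-baseline value
    are filled from baseline (counted separately in the notes).
    """
    subs = []
    cells: list[tuple[str, int]] = []
    n_baseline_carried = 0
    for s in dataset.subjects:
        out = s.outcomes.copy()
        last = s.baseline
        from_baseline = True
        for j0 in range(len(out)):
            if np.isnan(out[j0]):
                out[j0] = last
                cells.append((s.subject_id, j0 + 1))
                if from_baseline:
                    n_baseline_carried += 1
            else:
                last = out[j0]
                from_baseline = False
        subs.append(_completed_subject(s, out))
    completed = TrialDataset(dataset.schedule, subs, dataset.reference_arm)
    return ImputationSet(
        method="LOCF",
        m=1,
        datasets=[completed],
        imputed_cells=cells,
        notes={"n_baseline_carried": n_baseline_carried},
    )


# ---------------------------------------------------------------------------
# Predictive mean matching MI
# ---------------------------------------------------------------------------


def _bayes_lm_draw(Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator):
    """Posterior draw from a normal linear model with a noninformative prior.

    Returns (beta_hat, beta_star): the least-squares estimate and one draw
    beta* ~ N(beta_hat, sigma*^2 (X'X)^-1) with sigma*^2 = SSE / chi2_{n-q}.
    """
    n, q = Xo.shape
    XtX = Xo.T @ Xo
    XtX_reg = XtX + 1e-8 * np.trace(XtX) / q * np.eye(q)
    beta_hat = np.linalg.solve(XtX_reg, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - q, 1)
    sse = float(resid @ resid)
    sigma2_star = sse / max(rng.chisquare(dof), 1e-12) if sse > 0 else 0.0
    cov = sigma2_star * np.linalg.inv(XtX_reg)
    cov = (cov + cov.T) / 2.0
    w, Vc = np.linalg.eigh(cov)
    root = Vc * np.sqrt(np.maximum(w, 0.0))
    beta_star = beta_hat + root @ rng.standard_normal(q)
    return beta_hat, beta_star


def pmm_multiple_impute(
    dataset: TrialDataset,
    m: int = 10,
    seed: int = 0,
    donors: int = 5,
    sweeps: int = 10,
) -> ImputationSet:
    """Chained-equations MI with type-1 predictive mean matching.

    For each visit in increasing order, the observed scores at that visit are
    regressed on treatment, baseline and the current values of every other
    visit; regression parameters are drawn from their approximate posterior;
    each missing cell copies the observed value of one of the ``donors``
    closest cases by predicted mean (uniform tie-breaking within the
    imputation substream).  Every imputed value is therefore an observed
    value of the same visit.
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2")
    V = dataset.schedule.n_visits
    Y0 = dataset.outcome_matrix()
    miss = np.isnan(Y0)
    cells = [
        (dataset.subjects[i].subject_id, j + 1)
        for i, j in zip(*np.nonzero(miss))
    ]
    if not miss.any():
        datasets = [dataset.copy() for _ in range(m)]
        return ImputationSet("PMM_MI", m, datasets, seed, [], {"no_missing": True})
    for j in range(V):
        if miss[:, j].all():
            raise MmrmError(f"visit {j + 1} has no observed values; cannot impute")

    bl = dataset.baseline_vector()
    arm_codes = dataset.arm_codes()
    n_arms = int(arm_codes.max()) + 1
    treat = np.zeros((len(bl), n_arms - 1))
    for a in range(1, n_arms):
        treat[:, a - 1] = arm_codes == a

    completed: list[TrialDataset] = []
    for i_imp in range(m):
        rng = _imp_rng(seed, i_imp)
        Y = Y0.copy()
        # initial fill: random observed value of the same visit
        for j in range(V):
            obs_vals = Y0[~miss[:, j], j]
            k = int(miss[:, j].sum())
            if k:
                Y[miss[:, j], j] = rng.choice(obs_vals, size=k, replace=True)
        for _ in range(sweeps):
            for j in range(V):
                mis_rows = np.nonzero(miss[:, j])[0]
                if mis_rows.size == 0:
                    continue
                obs_rows = np.nonzero(~miss[:, j])[0]
                others = [k for k in range(V) if k != j]
                Xfull = np.column_stack(
                    [np.ones(len(bl)), treat, bl, Y[:, others]]
                )
                ndon = donors
                if len(obs_rows) < donors + 2:
                    ndon = max(1, len(obs_rows) - 1)
                    warnings.warn(
                        f"visit {j + 1}: only {len(obs_rows)} observed values; "
                        f"donor pool reduced to {ndon}",
                        stacklevel=2,
                    )
                beta_hat, beta_star = _bayes_lm_draw(
                    Xfull[obs_rows], Y0[obs_rows, j], rng
                )
                pred_obs = Xfull[obs_rows] @ beta_hat
                pred_mis = Xfull[mis_rows] @ beta_star
                for r, row in enumerate(mis_rows):
                    dist = np.abs(pred_obs - pred_mis[r])
                    pool = np.argsort(dist, kind="stable")[:ndon]
                    Y[row, j] = Y0[obs_rows[rng.choice(pool)], j]
        subs = [
            _completed_subject(s, Y[i].copy())
            for i, s in enumerate(dataset.subjects)
        ]
        completed.append(TrialDataset(dataset.schedule, subs, dataset.reference_arm))
    return ImputationSet(
        "PMM_MI", m, completed, seed, cells, {"donors": donors, "sweeps": sweeps}
    )


# ---------------------------------------------------------------------------
# Jump-to-reference MI
# ---------------------------------------------------------------------------


def fit_reference_mmrm(dataset: TrialDataset):
    """MMRM on reference-arm subjects only: intercept + visit + baseline,
    unstructured covariance.  Returns the fit (used for J2R prediction)."""
    ref = dataset.reference_arm
    keep = [
        i
        for i in analyzable_subjects(dataset)
        if dataset.subjects[i].arm == ref
    ]
    if not keep:
        raise MmrmError("reference arm has no analyzable subjects")
    V = dataset.schedule.n_visits
    names = ["const"] + [f"visit_{F}" for F in range(2, V + 1)] + ["baseline"]
    q = len(names)
    ys, xs, ss, vs, sids = [], [], [], [], []
    for si, i in enumerate(keep):
        s = dataset.subjects[i]
        sids.append(s.subject_id)
        for j0 in np.nonzero(s.mask)[0]:
            x = np.zeros(q)
            x[0] = 1.0
            if j0 + 1 >= 2:
                x[names.index(f"visit_{j0 + 1}")] = 1.0
            x[q - 1] = s.baseline
            xs.append(x)
            ys.append(s.outcomes[j0])
            ss.append(si)
            vs.append(j0)
    design = Design(
        y=np.asarray(ys, dtype=float),
        X=np.vstack(xs),
        subject=np.asarray(ss, dtype=int),
        visit0=np.asarray(vs, dtype=int),
        names=names,
        subject_ids=sids,
        n_visits=V,
        arms=[ref],
    )
    return reml_fit_design(design)


def _j2r_fixed_prediction(fit, visit: int, baseline: float) -> float:
    pred = fit.coef("const") + fit.coef("baseline") * baseline
    if visit >= 2:
        pred += fit.coef(f"visit_{visit}")
    return pred


def j2r_multiple_impute(
    dataset: TrialDataset,
    m: int = 10,
    seed: int = 0,
    draws: str = "marginal",
) -> ImputationSet:
    """Jump-to-reference multiple imputation of experimental-arm
    post-discontinuation cells.

    The reference-arm MMRM's fixed part (baseline and visit only) predicts
    each missing post-discontinuation value; a random error is added per
    imputation.  ``draws="marginal"`` (default) draws independent per-visit
    errors N(0, Sigma_ref[j,j]); ``draws="joint"`` draws each subject's
    missing block jointly from MVN(0, Sigma_ref[block, block]).  Imputed
    values are neither rounded nor clipped.  Reference-arm cells are never
    imputed; experimental-arm intermittent (pre-discontinuation) cells are
    left missing (MAR, handled by the downstream likelihood).
    """
    if m < 2:
        raise ValueError("multiple imputation needs m >= 2")
    if draws not in ("marginal", "joint"):
        raise ValueError("draws must be 'marginal' or 'joint'")
    V = dataset.schedule.n_visits
    ref = dataset.reference_arm

    targets: list[tuple[int, np.ndarray]] = []  # (subject index, 0-based visits)
    for i, s in enumerate(dataset.subjects):
        if s.arm == ref or s.disc_visit is None:
            continue
        post = np.arange(int(s.disc_visit), V)
        post = post[np.isnan(s.outcomes[post])]
        if post.size:
            targets.append((i, post))
    cells = [
        (dataset.subjects[i].subject_id, int(j) + 1)
        for i, post in targets
        for j in post
    ]
    if not targets:
        datasets = [dataset.copy() for _ in range(m)]
        return ImputationSet("J2R_MI", m, datasets, seed, [], {"no_missing": True})

    ref_fit = fit_reference_mmrm(dataset)
    sigma = ref_fit.sigma

    completed: list[TrialDataset] = []
    for i_imp in range(m):
        rng = _imp_rng(seed, i_imp)
        d = dataset.copy()
        d.allow_out_of_range = True  # J2R values are neither rounded nor clipped
        for i, post in targets:
            s = d.subjects[i]
            fixed = np.array(
                [_j2r_fixed_prediction(ref_fit, int(j) + 1, s.baseline) for j in post]
            )
            if draws == "marginal":
                err = rng.standard_normal(post.size) * np.sqrt(
                    np.maximum(np.diag(sigma)[post], 0.0)
                )
            else:
                block = sigma[np.ix_(post, post)]
                err = rng.multivariate_normal(
                    np.zeros(post.size), block, method="eigh"
                )
            s.outcomes[post] = fixed + err
            s.disc_visit = None  # tail is filled; reason kept
        d.validate()
        completed.append(d)
    return ImputationSet(
        "J2R_MI", m, completed, seed, cells,
        {"draws": draws, "reference_loglik": ref_fit.reml_loglik},
    )


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


def rubin_pool(estimates, ses) -> RubinPooled:
    """Combine m (estimate, SE) pairs by Rubin's rules.

    qbar = mean(estimates); W = mean(se^2); B = sample variance of estimates;
    T = W + (1 + 1/m) B; df = (m-1)(1 + W / ((1+1/m)B))^2 when B > 0,
    infinite otherwise (normal quantile used for the CI).
    """
    q = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    qbar = float(q.mean())
    W = float((s**2).mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        tq = float(sps.t.ppf(0.975, df))
    else:
        df = float("inf")
        tq = Z975
    half = tq * float(np.sqrt(T))
    return RubinPooled(qbar, W, B, T, df, qbar - half, qbar + half, m)
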