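"""Mixed model for repeated measures (MMRM) estimated by REML.

The model for post-baseline MADRS10 outcomes is saturated in visit-specific
treatment effects:

    Y_ij = b0 + b1 * Treat_i + b2F * Time_ijF + b3F * Time_ijF * Treat_i
           + b4 * Baseline_i + eps_ij,       F = 2..V,

with eps_i ~ MVN(0, Sigma) and Sigma an unstructured V x V within-subject
covariance.  A random-intercept-plus-unstructured-serial decomposition is not
jointly identified when the serial part is unrestricted, so the single
unstructured total covariance spans the same marginal model; the subject
random intercept is represented through Sigma.

Estimation maximizes the restricted likelihood over Sigma (log-Cholesky
parameterization) with the fixed effects profiled out by GLS; each subject
contributes through the sub-matrix of Sigma at their observed visits
(direct-likelihood handling of intermittent and monotone missingness, valid
under MAR).  Inference uses the normal approximation (z intervals).

The optional pattern-mixture extension appends dropout-pattern main effects
and pattern-by-treatment interactions to the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .trial_data import (
    PatternLabel,
    TrialDataset,
    analyzable_subjects,
    classify_pattern,
)

Z975 = 1.959963984540054  # normal 97.5% quantile

# fixed dummy-coding order for non-reference patterns
PATTERN_ORDER = (
    PatternLabel.COMPLETER_QUASI,
    PatternLabel.LATE_DROPOUT,
    PatternLabel.EARLY_DROPOUT,
)


class MmrmError(RuntimeError):
    """Raised on design or convergence failures."""


@dataclass(frozen=True)
class MmrmSpec:
    """MMRM variant: plain, or pattern-mixture (PMMM) when pattern terms on."""

    include_pattern_terms: bool = False
    reference_arm: str | None = None  # default: the dataset's reference arm
    reference_pattern: PatternLabel = PatternLabel.COMPLETER_QUASI


@dataclass
class Design:
    y: np.ndarray            # (N,) observed outcomes
    X: np.ndarray            # (N, q) fixed-effects design
    subject: np.ndarray      # (N,) subject index into `subject_ids`
    visit0: np.ndarray       # (N,) 0-based visit index
    names: list[str]
    subject_ids: list[str]
    n_visits: int
    arms: list[str]          # reference first
    pattern_levels: list[PatternLabel] = field(default_factory=list)


@dataclass
class MmrmFit:
    beta: np.ndarray
    beta_names: list[str]
    beta_cov: np.ndarray     # (X' V^-1 X)^-1 at the REML optimum
    sigma: np.ndarray        # V x V estimated within-subject covariance
    reml_loglik: float
    n_subjects_used: int
    n_obs: int
    converged: bool
    n_visits: int
    arms: list[str]
    pattern_levels: list[PatternLabel] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def coef_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.beta_cov))
        return pd.DataFrame(
            {"coef": self.beta_names, "estimate": self.beta, "se": se}
        )

    def sigma_frame(self) -> pd.DataFrame:
        cols = [f"visit_{j}" for j in range(1, self.n_visits + 1)]
        return pd.DataFrame(self.sigma, index=cols, columns=cols)


@dataclass
class ContrastResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    visit: int
    contrast_vector: np.ndarray


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def build_design(
    dataset: TrialDataset,
    spec: MmrmSpec = MmrmSpec(),
    pattern_labels: list[PatternLabel] | None = None,
) -> Design:
    """Long-format design matrix over observed subject-visit cells.

    Columns: intercept; one treatment indicator per non-reference arm; visit
    indicators for F = 2..V (visit 1 is the reference level, so the intercept
    is the reference-arm mean at visit 1); arm-by-visit interactions;
    baseline (uncentred); and, when pattern terms are enabled, non-reference
    pattern indicators plus pattern-by-treatment interactions.
    """
    ref = spec.reference_arm or dataset.reference_arm
    arms = dataset.arms
    if ref != arms[0]:
        if ref not in arms:
            raise MmrmError(f"reference arm {ref!r} not in data")
        arms = [ref] + [a for a in arms if a != ref]
    V = dataset.schedule.n_visits
    keep = analyzable_subjects(dataset)
    if not keep:
        raise MmrmError("no subjects with observed post-baseline outcomes")
    for a in arms:
        if not any(dataset.subjects[i].arm == a for i in keep):
            raise MmrmError(f"arm {a!r} has no analyzable subjects")

    nonref = arms[1:]
    names = ["const"]
    names += [f"treat_{a}" for a in nonref]
    names += [f"visit_{F}" for F in range(2, V + 1)]
    names += [f"treat_{a}:visit_{F}" for a in nonref for F in range(2, V + 1)]
    names += ["baseline"]

    levels: list[PatternLabel] = []
    subj_pattern: list[PatternLabel] = []
    if spec.include_pattern_terms:
        if pattern_labels is None:
            pattern_labels = [classify_pattern(dataset.subjects[i].mask) for i in keep]
        else:
            pattern_labels = [pattern_labels[i] for i in keep]
        present = set(pattern_labels)
        levels = [p for p in PATTERN_ORDER if p in present and p != spec.reference_pattern]
        names += [f"pattern_{p.value}" for p in levels]
        names += [f"treat_{a}:pattern_{p.value}" for a in nonref for p in levels]
        subj_pattern = pattern_labels

    q = len(names)
    col = {nm: k for k, nm in enumerate(names)}

    rows_y, rows_x, rows_s, rows_v = [], [], [], []
    subject_ids = []
    for si, i in enumerate(keep):
        s = dataset.subjects[i]
        subject_ids.append(s.subject_id)
        obs = np.nonzero(s.mask)[0]
        x_base = np.zeros(q)
        x_base[col["const"]] = 1.0
        if s.arm != arms[0]:
            x_base[col[f"treat_{s.arm}"]] = 1.0
        x_base[col["baseline"]] = s.baseline
        if spec.include_pattern_terms:
            p = subj_pattern[si]
            if p != spec.reference_pattern and p in levels:
                x_base[col[f"pattern_{p.value}"]] = 1.0
                if s.arm != arms[0]:
                    x_base[col[f"treat_{s.arm}:pattern_{p.value}"]] = 1.0
        for j0 in obs:
            x = x_base.copy()
            F = j0 + 1
            if F >= 2:
                x[col[f"visit_{F}"]] = 1.0
                if s.arm != arms[0]:
                    x[col[f"treat_{s.arm}:visit_{F}"]] = 1.0
            rows_x.append(x)
            rows_y.append(s.outcomes[j0])
            rows_s.append(si)
            rows_v.append(j0)

    X = np.vstack(rows_x)
    if np.linalg.matrix_rank(X) < q:
        raise MmrmError(
            "singular design (e.g. an empty pattern-by-arm cell); "
            "merge sparse patterns before fitting"
        )
    return Design(
        y=np.asarray(rows_y, dtype=float),
        X=X,
        subject=np.asarray(rows_s, dtype=int),
        visit0=np.asarray(rows_v, dtype=int),
        names=names,
        subject_ids=subject_ids,
        n_visits=V,
        arms=list(arms),
        pattern_levels=levels,
    )


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------


def _pattern_stats(design: Design):
    """Sufficient statistics per observed-visit pattern.

    Subjects sharing an observed-visit set share the Sigma sub-matrix, so the
    restricted likelihood and its gradient reduce to per-pattern tensors:
    G[j,l,:,:] = sum_s x_sj x_sl', U[j,l,:] = sum_s x_sj y_sl,
    yy[j,l] = sum_s y_sj y_sl.
    """
    by_subject: dict[int, list[int]] = {}
    for r, s in enumerate(design.subject):
        by_subject.setdefault(int(s), []).append(r)
    groups: dict[tuple, list[list[int]]] = {}
    for s, rows in by_subject.items():
        rows = sorted(rows, key=lambda r: design.visit0[r])
        key = tuple(int(design.visit0[r]) for r in rows)
        groups.setdefault(key, []).append(rows)
    stats = []
    for key, members in groups.items():
        Xs = np.stack([design.X[rows] for rows in members])  # (ns, k, q)
        ys = np.stack([design.y[rows] for rows in members])  # (ns, k)
        G = np.einsum("sja,slb->jlab", Xs, Xs)
        U = np.einsum("sja,sl->jla", Xs, ys)
        yy = np.einsum("sj,sl->jl", ys, ys)
        stats.append(
            {
                "idx": np.asarray(key, dtype=int),
                "n": len(members),
                "G": G,
                "U": U,
                "yy": yy,
            }
        )
    return stats


def _unpack_chol(theta: np.ndarray, V: int) -> np.ndarray:
    L = np.zeros((V, V))
    il, jl = np.tril_indices(V)
    L[il, jl] = theta
    d = np.arange(V)
    L[d, d] = np.exp(np.clip(np.diag(L), -20.0, 20.0))
    return L


def _pack_chol(sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(sigma)
    M = L.copy()
    d = np.arange(L.shape[0])
    M[d, d] = np.log(np.diag(L))
    il, jl = np.tril_indices(L.shape[0])
    return M[il, jl]


def _neg_restricted_loglik(theta, stats, V, q, N, want_grad=True):
    L = _unpack_chol(theta, V)
    sigma = L @ L.T
    kk_cache = []
    M = np.zeros((q, q))
    h = np.zeros(q)
    qyy = 0.0
    ld = 0.0
    for st in stats:
        idx = st["idx"]
        k = len(idx)
        Sp = sigma[np.ix_(idx, idx)]
        try:
            C = np.linalg.cholesky(Sp)
        except np.linalg.LinAlgError:
            return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
        A = np.linalg.inv(C.T) @ np.linalg.inv(C)
        logdet = 2.0 * np.log(np.diag(C)).sum()
        Gf = st["G"].reshape(k * k, q, q)
        Uf = st["U"].reshape(k * k, q)
        M += np.tensordot(A.ravel(), Gf, axes=1)
        h += A.ravel() @ Uf
        qyy += float((A * st["yy"]).sum())
        ld += st["n"] * logdet
        kk_cache.append(A)
    cM, low = None, None
    try:
        cM = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    beta = np.linalg.solve(M, h)
    logdetM = 2.0 * np.log(np.diag(cM)).sum()
    Q = qyy - h @ beta
    neg2l = (N - q) * np.log(2.0 * np.pi) + ld + logdetM + Q
    f = 0.5 * neg2l
    if not want_grad:
        return f, beta, M, sigma
    Minv = np.linalg.inv(M)
    E = np.zeros((V, V))
    for st, A in zip(stats, kk_cache):
        idx = st["idx"]
        k = len(idx)
        Gf = st["G"].reshape(k * k, q, q)
        Ttil = np.tensordot(Gf, Minv, axes=([1, 2], [0, 1])).reshape(k, k)
        W = st["U"] @ beta                      # (k, k): W[j,l] = sum x_sj.b y_sl
        Gb = np.tensordot(st["G"], beta, axes=([3], [0]))  # (k,k,q)
        Bq = Gb @ beta                          # (k, k)
        R = st["yy"] - W - W.T + Bq
        Ep = 0.5 * (st["n"] * A - A @ (Ttil + R) @ A)
        E[np.ix_(idx, idx)] += Ep
    GL = 2.0 * E @ L
    d = np.arange(V)
    GL[d, d] *= np.diag(L)
    il, jl = np.tril_indices(V)
    return f, GL[il, jl]


def _start_sigma(design: Design) -> np.ndarray:
    """OLS-residual pairwise covariance, floored to positive definiteness."""
    V = design.n_visits
    beta0, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta0
    n_subj = len(design.subject_ids)
    R = np.full((n_subj, V), np.nan)
    R[design.subject, design.visit0] = resid
    cov = pd.DataFrame(R).cov(min_periods=2).to_numpy()
    var0 = np.nanmean(np.diag(cov)) if np.isfinite(np.diag(cov)).any() else 1.0
    if not np.isfinite(var0) or var0 <= 0:
        var0 = 1.0
    cov = np.where(np.isfinite(cov), cov, 0.0)
    np.fill_diagonal(cov, np.where(np.isfinite(np.diag(cov)) & (np.diag(cov) > 0),
                                   np.diag(cov), var0))
    w, Vc = np.linalg.eigh((cov + cov.T) / 2.0)
    w = np.maximum(w, 1e-2 * var0)
    return (Vc * w) @ Vc.T


def reml_fit_design(
    design: Design, maxiter: int = 200, rel_tol: float = 1e-8
) -> MmrmFit:
    """REML fit on an already-built design (used directly by the J2R
    reference-arm model, which has no treatment term)."""
    V = design.n_visits
    q = design.X.shape[1]
    N = len(design.y)
    n_cov = V * (V + 1) // 2
    if N <= q + n_cov:
        raise MmrmError(
            f"too few observed cells ({N}) for {q} coefficients "
            f"+ {n_cov} covariance parameters"
        )
    stats = _pattern_stats(design)
    theta0 = _pack_chol(_start_sigma(design))

    best = None
    converged = False
    rng = np.random.default_rng(0)
    for attempt in range(2):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, theta0.shape)
        res = optimize.minimize(
            _neg_restricted_loglik,
            t0,
            args=(stats, V, q, N),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": rel_tol * 1e-4, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success or res.status == 0:
            converged = True
            break
    if best is None or not np.isfinite(best.fun):
        raise MmrmError("REML optimization failed to produce a finite objective")
    if not converged:
        gnorm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
        if gnorm < 1e-3:
            converged = True
        else:
            warnings.warn(
                f"REML optimizer did not report convergence (|grad|={gnorm:.2e}); "
                "returning best iterate",
                stacklevel=2,
            )

    f, beta, M, sigma = _neg_restricted_loglik(
        best.x, stats, V, q, N, want_grad=False
    )
    return MmrmFit(
        beta=beta,
        beta_names=list(design.names),
        beta_cov=np.linalg.inv(M),
        sigma=sigma,
        reml_loglik=-f,
        n_subjects_used=len(design.subject_ids),
        n_obs=N,
        converged=converged,
        n_visits=V,
        arms=list(design.arms),
        pattern_levels=list(design.pattern_levels),
    )


def reml_fit(
    dataset: TrialDataset,
    spec: MmrmSpec = MmrmSpec(),
    pattern_labels: list[PatternLabel] | None = None,
) -> MmrmFit:
    """Fit the MMRM (or its pattern-mixture extension) by REML."""
    design = build_design(dataset, spec, pattern_labels)
    return reml_fit_design(design)


def restricted_loglik(fit_or_design, sigma: np.ndarray) -> float:
    """Restricted log-likelihood of a given Sigma on a design (diagnostic)."""
    design = fit_or_design
    stats = _pattern_stats(design)
    q = design.X.shape[1]
    f, *_ = _neg_restricted_loglik(
        _pack_chol(sigma), stats, design.n_visits, q, len(design.y), want_grad=False
    )
    return -f


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------


def treatment_effect_at_visit(
    fit: MmrmFit,
    visit: int,
    arm: str | None = None,
    pattern: PatternLabel | None = None,
) -> ContrastResult:
    """Visit-specific treatment effect delta_F = b1 (+ b3F) (+ b6P).

    The contrast selects the arm's main effect, plus its interaction with
    visit F when F >= 2, plus its interaction with the dropout pattern when a
    non-reference pattern is given.  SE = sqrt(c' Omega c); 95% normal CI.
    """
    if not 1 <= visit <= fit.n_visits:
        raise ValueError(f"visit {visit} outside 1..{fit.n_visits}")
    nonref = fit.arms[1:]
    if arm is None:
        arm = nonref[0]
    if arm not in nonref:
        raise ValueError(f"arm {arm!r} is not a non-reference arm of this fit")
    c = np.zeros(len(fit.beta))
    c[fit.beta_names.index(f"treat_{arm}")] = 1.0
    if visit >= 2:
        c[fit.beta_names.index(f"treat_{arm}:visit_{visit}")] = 1.0
    if pattern is not None:
        if pattern not in PATTERN_ORDER:
            raise ValueError(f"unknown pattern {pattern!r}")
        nm = f"treat_{arm}:pattern_{pattern.value}"
        if nm in fit.beta_names:  # reference pattern has no b6 term
            c[fit.beta_names.index(nm)] = 1.0
    est = float(c @ fit.beta)
    se = float(np.sqrt(max(c @ fit.beta_cov @ c, 0.0)))
    return ContrastResult(
        estimate=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        visit=visit,
        contrast_vector=c,
    )


def contrast(fit: MmrmFit, c: np.ndarray, visit: int = 0) -> ContrastResult:
    """Generic linear contrast c'beta with normal-approximation CI."""
    c = np.asarray(c, dtype=float)
    est = float(c @ fit.beta)
    se = float(np.sqrt(max(c @ fit.beta_cov @ c, 0.0)))
    return ContrastResult(est, se, est - Z975 * se, est + Z975 * se, visit, c)
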