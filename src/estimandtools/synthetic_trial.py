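"""Synthetic short-term depression trials with intercurrent events.

Generates trials with the statistical structure the downstream analyses
assume: longitudinal MADRS10 outcomes from a mixed model (arm-by-visit mean
profile, baseline covariate, subject random intercept, serially correlated
visit errors), discrete-time reason-specific discontinuation hazards that
produce monotone missing tails, and independent intermittent (MCAR)
missingness.  Alongside the observed dataset the generator emits a
:class:`TruthRecord` holding the complete potential-outcome matrices in the
hypothetical world (no intercurrent events) and in the treatment-policy world
(under a configurable post-event mechanism), so the true value of every
estimand is computable.

Default parameters emulate a 2-arm, 6-visit mirtazapine-era trial: baseline
MADRS10 around 30 points, placebo improving to ~19 by week 6, an active arm
4 points lower at end of trial, and ~20-25%% of subjects discontinuing
(mostly for lack of efficacy, with an early adverse-event window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from .trial_data import (
    SubjectRecord,
    TrialDataset,
    VisitSchedule,
)

ESTIMAND_WORLDS = (
    "HYPOTHETICAL",
    "TREATMENT_POLICY",
    "WHILE_ON_TREATMENT",
    "PRINCIPAL_STRATUM",
)

POST_IE_MECHANISMS = ("MAR_CONTINUATION", "J2R_SWITCH", "RETAINED_SLOPE")

# named substreams spawned from the master seed; toggling one mechanism
# leaves the draws of the others unchanged
_STREAMS = {"baseline": 0, "random_effects": 1, "residuals": 2,
            "dropout": 3, "intermittent": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, _STREAMS[stream]))))


def ar1_cov(sds: Sequence[float] | float, rho: float, n: int | None = None) -> np.ndarray:
    """AR(1) covariance: Cov[j,l] = sd_j * sd_l * rho^|j-l|."""
    if np.isscalar(sds):
        if n is None:
            raise ValueError("n required with scalar sd")
        sds = np.full(n, float(sds))
    s = np.asarray(sds, dtype=float)
    V = len(s)
    idx = np.arange(V)
    return np.outer(s, s) * rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class ReasonHazard:
    """Discrete-time logistic hazard for one discontinuation reason.

    At visit j the hazard is expit(intercept_arm + score_coef * score_ij),
    evaluated only inside ``visit_range`` (inclusive, 1-based).  Per-arm
    intercepts fall back to the ``"*"`` key.
    """

    intercepts: dict[str, float]
    score_coef: float = 0.0
    visit_range: tuple[int, int] | None = None

    def intercept_for(self, arm: str) -> float:
        if arm in self.intercepts:
            return self.intercepts[arm]
        return self.intercepts["*"]

    def active_at(self, visit: int) -> bool:
        if self.visit_range is None:
            return True
        lo, hi = self.visit_range
        return lo <= visit <= hi


def _default_dropout() -> dict[str, ReasonHazard]:
    # calibrated once so that at the default outcome profile the trial-level
    # missing fraction lands near the middle of the emulated 10-46% range,
    # with LoE dominating (score-dependent, hence heavier in placebo) and AEs
    # confined to an early window, slightly heavier on active treatment
    return {
        "LoE": ReasonHazard(intercepts={"*": -4.9}, score_coef=0.08),
        "AE": ReasonHazard(intercepts={"placebo": -4.6, "*": -3.8},
                           visit_range=(1, 2)),
        "drug_unrelated": ReasonHazard(intercepts={"*": -4.8}),
        "unknown": ReasonHazard(intercepts={"*": -5.3}),
    }


@dataclass
class SimConfig:
    """Generator parameters; the defaults define the emulated study conditions."""

    n_per_arm: int = 60
    arms: tuple[str, ...] = ("placebo", "active")
    reference_arm: str = "placebo"
    n_visits: int = 6
    week_of_visit: dict[int, int] | None = None
    baseline_mean: float = 30.0
    baseline_sd: float = 5.0
    baseline_trunc: tuple[float, float] = (10.0, 60.0)
    baseline_coef: float = 0.5
    arm_visit_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "placebo": (26.0, 24.0, 22.0, 21.0, 20.0, 19.0),
            "active": (24.0, 21.0, 19.0, 17.0, 16.0, 15.0),
        }
    )
    sigma_b: float = 5.0
    serial_sd: float | tuple[float, ...] = 5.0
    serial_rho: float = 0.6
    serial_cov: np.ndarray | None = None  # overrides (serial_sd, serial_rho)
    dropout_model: dict[str, ReasonHazard] = field(default_factory=_default_dropout)
    intermittent_prob: float = 0.03
    post_ie_mechanism: str = "MAR_CONTINUATION"
    integer_scores: bool = False
    cross_world_stratum: bool = False  # experimental shared-uniform cross-world IE
    master_seed: int = 0

    def schedule(self) -> VisitSchedule:
        return VisitSchedule(self.n_visits, dict(self.week_of_visit or {}))

    def resolved_serial_cov(self) -> np.ndarray:
        if self.serial_cov is not None:
            S = np.asarray(self.serial_cov, dtype=float)
        else:
            S = ar1_cov(self.serial_sd, self.serial_rho, self.n_visits)
        if S.shape != (self.n_visits, self.n_visits):
            raise ValueError("serial covariance must be V x V")
        if not np.allclose(S, S.T):
            raise ValueError("serial covariance must be symmetric")
        if S.any():
            eig = np.linalg.eigvalsh(S)
            if eig.min() < -1e-10 * max(1.0, eig.max()):
                raise ValueError("serial covariance must be positive semi-definite")
        return S

    def mean_matrix(self) -> np.ndarray:
        """(n_arms, V) arm-by-visit mean profile, rows ordered as self.arm_order()."""
        return np.vstack([np.asarray(self.arm_visit_means[a], dtype=float)
                          for a in self.arm_order()])

    def arm_order(self) -> list[str]:
        order = [self.reference_arm]
        order += [a for a in self.arms if a != self.reference_arm]
        return order

    def validate(self) -> None:
        if self.reference_arm not in self.arms:
            raise ValueError("reference arm must be one of the configured arms")
        if not 0.0 <= self.intermittent_prob <= 1.0:
            raise ValueError("intermittent_prob must lie in [0, 1]")
        if self.post_ie_mechanism not in POST_IE_MECHANISMS:
            raise ValueError(f"unknown post-IE mechanism {self.post_ie_mechanism!r}")
        M = self.mean_matrix()
        if not np.isfinite(M).all():
            raise ValueError("arm_visit_means must be finite")
        for a in self.arms:
            if len(self.arm_visit_means[a]) != self.n_visits:
                raise ValueError(f"arm {a!r}: need {self.n_visits} visit means")
        self.resolved_serial_cov()

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dropout_model"] = {
            r: {"intercepts": h.intercepts, "score_coef": h.score_coef,
                "visit_range": list(h.visit_range) if h.visit_range else None}
            for r, h in self.dropout_model.items()
        }
        if self.serial_cov is not None:
            d["serial_cov"] = np.asarray(self.serial_cov).tolist()
        d["arms"] = list(self.arms)
        d["arm_visit_means"] = {a: list(v) for a, v in self.arm_visit_means.items()}
        d["baseline_trunc"] = list(self.baseline_trunc)
        if isinstance(self.serial_sd, tuple):
            d["serial_sd"] = list(self.serial_sd)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "dropout_model" in d:
            d["dropout_model"] = {
                r: ReasonHazard(
                    intercepts=dict(h["intercepts"]),
                    score_coef=float(h.get("score_coef", 0.0)),
                    visit_range=tuple(h["visit_range"]) if h.get("visit_range") else None,
                )
                for r, h in d["dropout_model"].items()
            }
        if d.get("serial_cov") is not None:
            d["serial_cov"] = np.asarray(d["serial_cov"], dtype=float)
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        if "arm_visit_means" in d:
            d["arm_visit_means"] = {a: tuple(v) for a, v in d["arm_visit_means"].items()}
        if "baseline_trunc" in d:
            d["baseline_trunc"] = tuple(d["baseline_trunc"])
        if isinstance(d.get("serial_sd"), list):
            d["serial_sd"] = tuple(d["serial_sd"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated trial.

    ``hypothetical`` and ``policy`` are (n, V) potential-outcome matrices on
    the reported (clipped/rounded) scale; ``latent`` is the unclipped linear
    predictor + noise used by the dropout hazards.  ``ie_visit`` is -1 for
    subjects without an intercurrent event.
    """

    subject_ids: list[str]
    arm_labels: list[str]
    baseline: np.ndarray
    hypothetical: np.ndarray
    policy: np.ndarray
    latent: np.ndarray
    random_intercepts: np.ndarray
    residuals: np.ndarray
    ie_visit: np.ndarray
    ie_reason: list[str]
    no_ie_own: np.ndarray  # bool: no IE under own assignment
    no_ie_cross: np.ndarray | None  # bool: no IE under either assignment (optional)
    reference_arm: str
    arm_order: list[str]

    def arm_mask(self, arm: str) -> np.ndarray:
        return np.array([a == arm for a in self.arm_labels])

    def to_frame(self):
        import pandas as pd

        n, V = self.hypothetical.shape
        rows = []
        for i in range(n):
            for j in range(V):
                rows.append(
                    {
                        "subject_id": self.subject_ids[i],
                        "arm": self.arm_labels[i],
                        "visit": j + 1,
                        "hypothetical": self.hypothetical[i, j],
                        "policy": self.policy[i, j],
                        "ie_visit": int(self.ie_visit[i]),
                        "ie_reason": self.ie_reason[i],
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    todo = np.ones(size, dtype=bool)
    while todo.any():
        draw = rng.normal(mean, sd, size=int(todo.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.nonzero(todo)[0]
        out[idx[ok]] = draw[ok]
        todo[idx[ok]] = False
    return out


def _emit_scale(values: np.ndarray, config: SimConfig) -> np.ndarray:
    v = np.clip(values, 0.0, 60.0)
    if config.integer_scores:
        v = np.round(v)
    return v


def simulate_complete(config: SimConfig, seed: int | None = None):
    """Simulate the no-intercurrent-event (hypothetical) world.

    Y_ij = mu[arm, j] + gamma * (baseline_i - baseline_mean) + b_i + e_ij with
    b_i ~ N(0, sigma_b^2) and e_i ~ MVN(0, serial_cov); baseline is a
    truncated normal.  Returns ``(dataset, truth)`` where the dataset has no
    missing cells and ``truth`` is partial (policy world filled in by
    :func:`apply_intercurrent_events`).
    """
    config.validate()
    if seed is None:
        seed = config.master_seed
    V = config.n_visits
    arm_order = config.arm_order()
    M = config.mean_matrix()
    n = config.n_per_arm * len(arm_order)

    arm_labels = [a for a in arm_order for _ in range(config.n_per_arm)]
    arm_idx = np.repeat(np.arange(len(arm_order)), config.n_per_arm)

    lo, hi = config.baseline_trunc
    baseline = _truncated_normal(
        _rng(seed, "baseline"), config.baseline_mean, config.baseline_sd, lo, hi, n
    )
    b = _rng(seed, "random_effects").normal(0.0, config.sigma_b, size=n)
    S = config.resolved_serial_cov()
    if S.any():
        e = _rng(seed, "residuals").multivariate_normal(
            np.zeros(V), S, size=n, method="cholesky"
        )
    else:
        e = np.zeros((n, V))

    latent = (
        M[arm_idx]
        + config.baseline_coef * (baseline - config.baseline_mean)[:, None]
        + b[:, None]
        + e
    )
    hyp = _emit_scale(latent, config)

    sids = [f"S{i + 1:04d}" for i in range(n)]
    subjects = [
        SubjectRecord(sids[i], arm_labels[i], float(baseline[i]), hyp[i].copy())
        for i in range(n)
    ]
    dataset = TrialDataset(config.schedule(), subjects, config.reference_arm)
    truth = TruthRecord(
        subject_ids=sids,
        arm_labels=arm_labels,
        baseline=baseline,
        hypothetical=hyp,
        policy=hyp.copy(),
        latent=latent,
        random_intercepts=b,
        residuals=e,
        ie_visit=np.full(n, -1, dtype=int),
        ie_reason=["none"] * n,
        no_ie_own=np.ones(n, dtype=bool),
        no_ie_cross=None,
        reference_arm=config.reference_arm,
        arm_order=arm_order,
    )
    return dataset, truth


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_ie(latent, arm_labels, config, uniforms, reasons):
    """First-passage discontinuation times from per-reason logistic hazards.

    ``uniforms`` has shape (n, V-1, n_reasons); the first reason triggered in
    enumeration order at the earliest visit wins.
    """
    n, V = latent.shape
    ie_visit = np.full(n, -1, dtype=int)
    ie_reason = ["none"] * n
    for i in range(n):
        arm = arm_labels[i]
        for j in range(1, V):  # hazard opportunities at visits 1..V-1
            hit = False
            for r, reason in enumerate(reasons):
                hz = config.dropout_model[reason]
                if not hz.active_at(j):
                    continue
                eta = hz.intercept_for(arm) + hz.score_coef * latent[i, j - 1]
                if uniforms[i, j - 1, r] < _expit(eta):
                    ie_visit[i] = j
                    ie_reason[i] = reason
                    hit = True
                    break
            if hit:
                break
    return ie_visit, ie_reason


def apply_intercurrent_events(
    complete: TrialDataset,
    config: SimConfig,
    seed: int | None = None,
    truth: TruthRecord | None = None,
):
    """Impose discontinuation and intermittent missingness on complete data.

    Discontinuation at visit d blanks visits d+1..V (monotone tail) and sets
    the subject's reason; independent MCAR blanking at ``intermittent_prob``
    is applied to the remaining observed cells (never the baseline).  The
    treatment-policy potential outcomes after the event follow
    ``config.post_ie_mechanism``:

    * MAR_CONTINUATION - the hypothetical-world values stand;
    * J2R_SWITCH - the fixed part jumps to the reference arm's mean profile,
      keeping the subject's own baseline effect, random intercept and
      residual draws;
    * RETAINED_SLOPE - the deviation from the arm profile observed at the
      discontinuation visit is carried to later visits.

    Returns ``(dataset_with_missing, truth)``.
    """
    config.validate()
    if seed is None:
        seed = config.master_seed
    V = config.n_visits
    n = complete.n_subjects
    if truth is None:
        _, truth = simulate_complete(config, seed)
        # fall back to the dataset's own values as the latent scores
        truth.latent = complete.outcome_matrix()
        truth.hypothetical = complete.outcome_matrix()

    reasons = list(config.dropout_model)
    u = _rng(seed, "dropout").random((n, V - 1, len(reasons)))
    ie_visit, ie_reason = _draw_ie(truth.latent, truth.arm_labels, config, u, reasons)

    # treatment-policy potential outcomes after the event
    M = config.mean_matrix()
    arm_pos = {a: k for k, a in enumerate(truth.arm_order)}
    ref_row = M[arm_pos[truth.reference_arm]]
    policy_latent = truth.latent.copy()
    for i in range(n):
        d = ie_visit[i]
        if d < 0 or d >= V:
            continue
        own_row = M[arm_pos[truth.arm_labels[i]]]
        if config.post_ie_mechanism == "J2R_SWITCH":
            policy_latent[i, d:] = (
                ref_row[d:]
                + config.baseline_coef * (truth.baseline[i] - config.baseline_mean)
                + truth.random_intercepts[i]
                + truth.residuals[i, d:]
            )
        elif config.post_ie_mechanism == "RETAINED_SLOPE":
            dev = truth.latent[i, d - 1] - own_row[d - 1]
            policy_latent[i, d:] = own_row[d:] + dev
        # MAR_CONTINUATION: hypothetical values stand
    policy = _emit_scale(policy_latent, config)

    # observed data: policy values, blanked after the IE and intermittently
    obs = policy.copy()
    for i in range(n):
        d = ie_visit[i]
        if 0 <= d < V:
            obs[i, d:] = np.nan
    if config.intermittent_prob > 0:
        drop = _rng(seed, "intermittent").random((n, V)) < config.intermittent_prob
        obs[drop] = np.nan

    no_ie_own = ie_visit < 0
    no_ie_cross = None
    if config.cross_world_stratum:
        # experimental: shared-uniform counterfactual IE status.  The
        # counterfactual latent trajectory swaps the arm mean profile; the
        # same uniforms decide discontinuation in both worlds.
        cf_latent = truth.latent.copy()
        cf_labels = []
        nonref = [a for a in truth.arm_order if a != truth.reference_arm]
        for i in range(n):
            own = truth.arm_labels[i]
            cf = truth.reference_arm if own != truth.reference_arm else nonref[0]
            cf_labels.append(cf)
            cf_latent[i] += M[arm_pos[cf]] - M[arm_pos[own]]
        cf_visit, _ = _draw_ie(cf_latent, cf_labels, config, u, reasons)
        no_ie_cross = no_ie_own & (cf_visit < 0)

    subjects = []
    for i, s in enumerate(complete.subjects):
        d = int(ie_visit[i])
        subjects.append(
            SubjectRecord(
                s.subject_id,
                s.arm,
                s.baseline,
                obs[i],
                ie_reason[i] if d >= 0 else "none",
                d if d >= 0 else None,
            )
        )
    dataset = TrialDataset(complete.schedule, subjects, complete.reference_arm)

    truth.policy = policy
    truth.ie_visit = ie_visit
    truth.ie_reason = list(ie_reason)
    truth.no_ie_own = no_ie_own
    truth.no_ie_cross = no_ie_cross
    return dataset, truth


def simulate_trial(config: SimConfig, seed: int | None = None):
    """Convenience wrapper: complete world + intercurrent events in one call."""
    complete, truth = simulate_complete(config, seed)
    return apply_intercurrent_events(complete, config, seed, truth)


# ---------------------------------------------------------------------------
# True estimand values
# ---------------------------------------------------------------------------


def true_estimand_value(
    truth: TruthRecord, estimand: str, arm: str | None = None
) -> float:
    """Finite-sample true contrast (arm minus reference) at the last visit.

    * HYPOTHETICAL - mean contrast of the no-IE potential outcomes;
    * TREATMENT_POLICY - mean contrast of the policy-world potential
      outcomes under the configured post-event mechanism;
    * WHILE_ON_TREATMENT - contrast of each subject's last on-treatment
      value (value at the discontinuation visit, or the last visit if none);
    * PRINCIPAL_STRATUM - last-visit hypothetical contrast among subjects
      without an intercurrent event (cross-world stratum when simulated,
      else the own-assignment approximation).
    """
    if estimand not in ESTIMAND_WORLDS:
        raise ValueError(f"unknown estimand label {estimand!r}")
    nonref = [a for a in truth.arm_order if a != truth.reference_arm]
    if arm is None:
        arm = nonref[0]
    a_mask = truth.arm_mask(arm)
    r_mask = truth.arm_mask(truth.reference_arm)
    V = truth.hypothetical.shape[1]

    if estimand == "HYPOTHETICAL":
        vals = truth.hypothetical[:, V - 1]
    elif estimand == "TREATMENT_POLICY":
        vals = truth.policy[:, V - 1]
    elif estimand == "WHILE_ON_TREATMENT":
        last = np.where(truth.ie_visit >= 1, truth.ie_visit, V)
        vals = truth.hypothetical[np.arange(len(last)), last - 1]
    else:  # PRINCIPAL_STRATUM
        stratum = truth.no_ie_cross if truth.no_ie_cross is not None else truth.no_ie_own
        a_mask = a_mask & stratum
        r_mask = r_mask & stratum
        vals = truth.hypothetical[:, V - 1]
    return float(vals[a_mask].mean() - vals[r_mask].mean())
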