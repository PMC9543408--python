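"""Data model and I/O for long-format repeated-measures depression trials.

The unit of analysis is a subject observed at baseline and at V post-baseline
visits on the MADRS10 scale (0-60 points, lower = less severe depression).
Subjects may discontinue the study ("intercurrent event"); all outcomes after
the discontinuation visit are missing (a monotone tail).  Additional isolated
visits may be missing intermittently.

Visits are indexed 1..V post-baseline; baseline is a separate field and is
never part of the outcomes vector.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("estimandtools")

#: canonical discontinuation reason codes (free-text combinations are allowed)
REASON_CODES = (
    "AE",
    "LoE",
    "AE+LoE",
    "drug_unrelated",
    "unknown",
    "efficacy",
    "insufficient_compliance",
    "none",
)

SCORE_MIN = 0.0
SCORE_MAX = 60.0

CSV_COLUMNS = [
    "subject_id",
    "arm",
    "baseline",
    "visit",
    "score",
    "disc_reason",
    "disc_visit",
]


class TrialValidationError(ValueError):
    """Raised when a trial table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Visit schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VisitSchedule:
    """Planned post-baseline visit schedule.

    Parameters
    ----------
    n_visits
        Number of post-baseline visits V (at least 2; the trials emulated
        here use 3 or 6).
    week_of_visit
        Mapping visit index (1..V) -> week number, strictly increasing.
        Defaults to week = visit index.
    """

    n_visits: int
    week_of_visit: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_visits < 2:
            raise TrialValidationError("a schedule needs at least 2 post-baseline visits")
        if not self.week_of_visit:
            object.__setattr__(
                self, "week_of_visit", {j: j for j in range(1, self.n_visits + 1)}
            )
        if sorted(self.week_of_visit) != list(range(1, self.n_visits + 1)):
            raise TrialValidationError("visit indices must be contiguous 1..V")
        weeks = [self.week_of_visit[j] for j in range(1, self.n_visits + 1)]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise TrialValidationError("week numbers must be strictly increasing")

    @property
    def last_visit(self) -> int:
        return self.n_visits

    @property
    def visits(self) -> range:
        return range(1, self.n_visits + 1)


# ---------------------------------------------------------------------------
# Subjects and datasets
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """One randomized subject.

    ``outcomes`` has length V with ``nan`` marking missing scores; if
    ``disc_visit`` = d, every outcome at visits d+1..V is missing.
    """

    subject_id: str
    arm: str
    baseline: float
    outcomes: np.ndarray
    disc_reason: str = "none"
    disc_visit: int | None = None

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed-indicator over visits 1..V."""
        return ~np.isnan(self.outcomes)

    def validate(self, n_visits: int, check_bounds: bool = True) -> None:
        if len(self.outcomes) != n_visits:
            raise TrialValidationError(
                f"subject {self.subject_id}: expected {n_visits} outcomes, "
                f"got {len(self.outcomes)}"
            )
        if np.isnan(self.baseline):
            raise TrialValidationError(f"subject {self.subject_id}: missing baseline")
        if check_bounds:
            obs = self.outcomes[self.mask]
            bad = obs[(obs < SCORE_MIN) | (obs > SCORE_MAX)]
            if bad.size:
                raise TrialValidationError(
                    f"subject {self.subject_id}: score {bad[0]} outside "
                    f"[{SCORE_MIN:g}, {SCORE_MAX:g}]"
                )
            if not (SCORE_MIN <= self.baseline <= SCORE_MAX):
                raise TrialValidationError(
                    f"subject {self.subject_id}: baseline {self.baseline} outside "
                    f"[{SCORE_MIN:g}, {SCORE_MAX:g}]"
                )
        if self.disc_visit is not None:
            d = int(self.disc_visit)
            if not 1 <= d <= n_visits:
                raise TrialValidationError(
                    f"subject {self.subject_id}: disc_visit {d} outside 1..{n_visits}"
                )
            if self.mask[d:].any():
                j = d + 1 + int(np.nonzero(self.mask[d:])[0][0])
                raise TrialValidationError(
                    f"subject {self.subject_id}: outcome observed at visit {j} "
                    f"after discontinuation visit {d} (monotone-tail violation)"
                )


@dataclass
class TrialDataset:
    """A validated trial: schedule, subjects, and the designated reference arm.

    ``allow_out_of_range`` relaxes the [0, 60] score bound; imputation
    methods that deliberately do not clip (jump-to-reference) mark their
    completed datasets with it.
    """

    schedule: VisitSchedule
    subjects: list[SubjectRecord]
    reference_arm: str
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        arms = self.arms
        if self.subjects:
            if len(arms) < 2:
                raise TrialValidationError("a trial needs at least 2 arms")
            if self.reference_arm not in arms:
                raise TrialValidationError(
                    f"reference arm {self.reference_arm!r} not present in data"
                )
        for s in self.subjects:
            s.validate(self.schedule.n_visits, check_bounds=not self.allow_out_of_range)

    @property
    def arms(self) -> list[str]:
        """Arm labels, reference first, others in order of first appearance."""
        seen: list[str] = []
        for s in self.subjects:
            if s.arm not in seen:
                seen.append(s.arm)
        if self.reference_arm in seen:
            seen.remove(self.reference_arm)
            seen.insert(0, self.reference_arm)
        return seen

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    # -- array views -------------------------------------------------------

    def outcome_matrix(self) -> np.ndarray:
        """(n_subjects, V) outcome matrix with nan for missing cells."""
        if not self.subjects:
            return np.empty((0, self.schedule.n_visits))
        return np.vstack([s.outcomes for s in self.subjects])

    def baseline_vector(self) -> np.ndarray:
        return np.array([s.baseline for s in self.subjects], dtype=float)

    def arm_codes(self) -> np.ndarray:
        """Integer arm codes: 0 = reference arm, 1.. = others."""
        order = {a: i for i, a in enumerate(self.arms)}
        return np.array([order[s.arm] for s in self.subjects], dtype=int)

    def copy(self) -> "TrialDataset":
        subs = [
            SubjectRecord(
                s.subject_id, s.arm, s.baseline, s.outcomes.copy(),
                s.disc_reason, s.disc_visit,
            )
            for s in self.subjects
        ]
        return TrialDataset(self.schedule, subs, self.reference_arm,
                            self.allow_out_of_range)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per subject-visit."""
        rows = []
        for s in self.subjects:
            for j in self.schedule.visits:
                y = s.outcomes[j - 1]
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "arm": s.arm,
                        "baseline": s.baseline,
                        "visit": j,
                        "score": y,
                        "disc_reason": s.disc_reason,
                        "disc_visit": s.disc_visit,
                    }
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _format_score(v: float) -> str:
    if np.isnan(v):
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))  # repr round-trips exactly


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write a dataset in the long CSV dialect (UTF-8, '' = missing).

    ``read_trial_csv(write_trial_csv(d))`` reproduces ``d`` bit-exactly.
    """
    lines = [",".join(CSV_COLUMNS)]
    for s in dataset.subjects:
        dv = "" if s.disc_visit is None else str(int(s.disc_visit))
        for j in dataset.schedule.visits:
            lines.append(
                ",".join(
                    [
                        str(s.subject_id),
                        str(s.arm),
                        _format_score(s.baseline),
                        str(j),
                        _format_score(s.outcomes[j - 1]),
                        s.disc_reason,
                        dv,
                    ]
                )
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trial_csv(path, reference_arm: str) -> TrialDataset:
    """Read and validate a long-format trial CSV.

    Expected columns: subject_id, arm, baseline, visit, score, disc_reason,
    disc_visit; one row per subject-visit; an empty score marks a missing
    outcome.  All structural invariants (score bounds, monotone tail after
    discontinuation, complete visit coverage) are enforced; violations raise
    :class:`TrialValidationError` naming the offending subject.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "arm": str, "disc_reason": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialValidationError(f"missing required column(s): {missing_cols}")

    if df.empty:
        return TrialDataset(VisitSchedule(2), [], reference_arm)

    visits = sorted(int(v) for v in df["visit"].unique())
    n_visits = max(visits)
    if visits != list(range(1, n_visits + 1)):
        raise TrialValidationError(f"visit indices not contiguous 1..V: {visits}")
    schedule = VisitSchedule(n_visits)

    subjects: list[SubjectRecord] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("visit")
        if list(grp["visit"]) != list(range(1, n_visits + 1)):
            raise TrialValidationError(
                f"subject {sid}: rows must cover all scheduled visits exactly once"
            )
        outcomes = grp["score"].to_numpy(dtype=float)
        dv = grp["disc_visit"].iloc[0]
        disc_visit = None if pd.isna(dv) else int(dv)
        reason = grp["disc_reason"].iloc[0] or "none"
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                arm=str(grp["arm"].iloc[0]),
                baseline=float(grp["baseline"].iloc[0]),
                outcomes=outcomes,
                disc_reason=reason,
                disc_visit=disc_visit,
            )
        )
    return TrialDataset(schedule, subjects, reference_arm)


# ---------------------------------------------------------------------------
# Missingness-pattern classification
# ---------------------------------------------------------------------------


class PatternLabel(enum.Enum):
    """Dropout pattern, defined on the shape of the observed-data mask."""

    COMPLETER_QUASI = "completer_quasi"
    LATE_DROPOUT = "late_dropout"
    EARLY_DROPOUT = "early_dropout"
    UNCLASSIFIABLE = "unclassifiable"


def trailing_missing_run(mask: Sequence[bool] | np.ndarray) -> int:
    """Length of the maximal trailing run of missing (False) entries."""
    m = np.asarray(mask, dtype=bool)
    t = 0
    for obs in m[::-1]:
        if obs:
            break
        t += 1
    return t


def classify_pattern(mask: Sequence[bool] | np.ndarray) -> PatternLabel:
    """Classify a subject's observed-visit mask into a dropout pattern.

    Classification depends only on the trailing run of missing visits t:

    * t <= 1  -> COMPLETER_QUASI (last visit observed, or only it missing;
      earlier visits may be intermittently missing),
    * t == 2  -> LATE_DROPOUT (exactly the last two visits monotone missing),
    * 3 <= t <= V-1 -> EARLY_DROPOUT (monotone tail starting at visit 2..V-2;
      for V=6 that is weeks 2, 3 or 4),
    * t == V  -> UNCLASSIFIABLE (no post-baseline data at all).
    """
    m = np.asarray(mask, dtype=bool)
    t = trailing_missing_run(m)
    if t == len(m):
        return PatternLabel.UNCLASSIFIABLE
    if t <= 1:
        return PatternLabel.COMPLETER_QUASI
    if t == 2:
        return PatternLabel.LATE_DROPOUT
    return PatternLabel.EARLY_DROPOUT


def classify_subjects(dataset: TrialDataset) -> list[PatternLabel]:
    return [classify_pattern(s.mask) for s in dataset.subjects]


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


@dataclass
class MissingnessSummary:
    """Observed/missing bookkeeping for a trial (the heatmap content)."""

    mask_matrix: np.ndarray  # subjects x visits, True = observed
    per_arm_visit: pd.DataFrame  # arm, visit, n_observed, n_missing
    missing_fraction: float


def missingness_summary(dataset: TrialDataset) -> MissingnessSummary:
    """Per-arm-per-visit observed/missing counts and the trial-level fraction."""
    V = dataset.schedule.n_visits
    mask = (
        np.vstack([s.mask for s in dataset.subjects])
        if dataset.subjects
        else np.empty((0, V), dtype=bool)
    )
    rows = []
    for arm in dataset.arms:
        idx = [i for i, s in enumerate(dataset.subjects) if s.arm == arm]
        sub = mask[idx]
        for j in range(1, V + 1):
            n_obs = int(sub[:, j - 1].sum())
            rows.append(
                {
                    "arm": arm,
                    "visit": j,
                    "n_observed": n_obs,
                    "n_missing": len(idx) - n_obs,
                }
            )
    per_arm_visit = pd.DataFrame(rows, columns=["arm", "visit", "n_observed", "n_missing"])
    total = mask.size
    frac = float((~mask).sum() / total) if total else 0.0
    return MissingnessSummary(mask, per_arm_visit, frac)


def ie_table(dataset: TrialDataset, reasons: Iterable[str] | None = None) -> pd.DataFrame:
    """Intercurrent-event tabulation: counts and percentages by arm x reason.

    Percentages are taken against the randomized N of the whole trial, and
    reasons with zero count are retained as structural zeros.
    """
    if reasons is None:
        reasons = [r for r in REASON_CODES if r != "none"]
        extra = sorted(
            {s.disc_reason for s in dataset.subjects}
            - set(reasons) - {"none"}
        )
        reasons = list(reasons) + extra
    else:
        reasons = list(reasons)
    n_total = dataset.n_subjects
    rows = []
    for arm in dataset.arms:
        subs = [s for s in dataset.subjects if s.arm == arm]
        for reason in reasons:
            n = sum(1 for s in subs if s.disc_visit is not None and s.disc_reason == reason)
            pct = 100.0 * n / n_total if n_total else 0.0
            rows.append(
                {"arm": arm, "reason": reason, "n": n, "pct_of_trial_n": round(pct, 1)}
            )
    return pd.DataFrame(rows, columns=["arm", "reason", "n", "pct_of_trial_n"])


def analyzable_subjects(dataset: TrialDataset) -> list[int]:
    """Indices of subjects with >=1 observed post-baseline outcome.

    Subjects with an all-missing outcome vector contribute nothing to any
    likelihood and are excluded from model fits (with a warning); they still
    count in intercurrent-event denominators.
    """
    keep = []
    for i, s in enumerate(dataset.subjects):
        if s.mask.any():
            keep.append(i)
        else:
            warnings.warn(
                f"subject {s.subject_id} has no observed post-baseline outcomes; "
                "excluded from model fitting",
                stacklevel=2,
            )
    return keep
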