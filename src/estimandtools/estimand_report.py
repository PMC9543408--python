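"""Estimand catalog, batch analysis runner, and forest-plot-ready tables.

The catalog encodes the analysis-to-estimand mapping for the eight methods
under the ICH E9(R1) attributes (treatment, population, variable,
population-level summary, intercurrent-event strategy).  Six estimands
cover the mapping; the same analysis can correspond to more than one
estimand and the same estimand to several analyses, which is exactly what
makes some method pairs usable as sensitivity analyses for each other.
"""

from __future__ import annotations

import time
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import EffectEstimate, METHODS, PrincipalStratumConfig
from .synthetic_trial import TruthRecord, true_estimand_value
from .trial_data import TrialDataset

logger = logging.getLogger("estimandtools")

#: fixed reporting order (the order the methods are usually listed in)
METHOD_ORDER = list(METHODS)


@dataclass(frozen=True)
class EstimandDescriptor:
    id: str
    ie_strategy: str
    population: str
    variable: str
    population_level_summary: str
    required_assumptions: str
    methods: tuple[str, ...]
    clinically_meaningful: bool = True
    prose_alias: str | None = None  # conflicting running-text numbering


_TREATMENT = (
    "experimental anti-depressant vs control, administered as the only "
    "depression medication for the trial duration"
)
_POP = "adults suffering from depression"
_SUMMARY = "difference in mean MADRS10 at end of trial (last scheduled visit)"


def estimand_catalog() -> list[EstimandDescriptor]:
    """The six estimands and their bipartite mapping to the eight methods."""
    return [
        EstimandDescriptor(
            id="E1",
            ie_strategy="hypothetical",
            population=_POP,
            variable="MADRS10 at end of trial",
            population_level_summary=_SUMMARY,
            required_assumptions=(
                "treatment effect had discontinuation not occurred; MCAR for "
                "the complete-case analysis, MAR for MI and direct-likelihood "
                "MMRM"
            ),
            methods=("ANCOVA_CC", "ANCOVA_MI", "MMRM"),
        ),
        EstimandDescriptor(
            id="E2",
            ie_strategy="while_on_treatment",
            population=_POP,
            variable="last on-treatment MADRS10",
            population_level_summary=(
                "difference in mean MADRS10 prior to treatment "
                "discontinuation, within a maximum of the trial duration"
            ),
            required_assumptions=(
                "no missing-data assumption: values after discontinuation are "
                "not of interest and the contrast has no fixed timepoint"
            ),
            methods=("ANCOVA_LOCF",),
        ),
        EstimandDescriptor(
            id="E3",
            ie_strategy="treatment_policy",
            population=_POP,
            variable="MADRS10 at end of trial",
            population_level_summary=_SUMMARY,
            required_assumptions=(
                "effect regardless of any treatment stopping; each estimator "
                "imposes its own post-discontinuation model (unchanged course "
                "for LOCF, MAR for MI/MMRM, jump-to-reference MNAR for J2R, "
                "pattern-dependent MNAR for the pattern-mixture model)"
            ),
            methods=(
                "ANCOVA_LOCF",
                "MMRM_LOCF",
                "ANCOVA_MI",
                "MMRM",
                "MMRM_J2R",
                "PMMM",
            ),
        ),
        EstimandDescriptor(
            id="E4",
            ie_strategy="composite",
            population=_POP,
            variable=(
                "composite MADRS10: measured values before discontinuation, "
                "reference-arm-like assigned values after"
            ),
            population_level_summary=_SUMMARY,
            required_assumptions=(
                "post-discontinuation outcomes behave as in the reference arm "
                "(MAR in the reference arm itself)"
            ),
            methods=("MMRM_J2R",),
            clinically_meaningful=False,
            prose_alias="estimand 5 in running-text numbering",
        ),
        EstimandDescriptor(
            id="E5",
            ie_strategy="composite",
            population=_POP,
            variable=(
                "composite MADRS10: measured values before discontinuation, "
                "values extrapolated from the pre-discontinuation course "
                "(differently for early vs late dropout) after"
            ),
            population_level_summary=_SUMMARY,
            required_assumptions=(
                "disease course after discontinuation continues as observed "
                "within the subject's dropout pattern; MAR for intermittent "
                "missingness"
            ),
            methods=("PMMM",),
            clinically_meaningful=False,
            prose_alias="estimand 6 in running-text numbering",
        ),
        EstimandDescriptor(
            id="E6",
            ie_strategy="principal_stratum",
            population=(
                "adults suffering from depression who would not discontinue "
                "treatment (would not experience the intercurrent event)"
            ),
            variable="MADRS10 at end of trial",
            population_level_summary=_SUMMARY,
            required_assumptions=(
                "the propensity model identifies the latent stratum; "
                "missingness in the stratum is MNAR overall, MAR within the "
                "selected subjects"
            ),
            methods=("PRINCIPAL_STRATUM",),
        ),
    ]


def methods_for(catalog: list[EstimandDescriptor], estimand_id: str) -> tuple[str, ...]:
    for d in catalog:
        if d.id == estimand_id:
            return d.methods
    raise KeyError(estimand_id)


def labels_for_method(catalog: list[EstimandDescriptor], method: str) -> tuple[str, ...]:
    return tuple(d.id for d in catalog if method in d.methods)


def catalog_frame(catalog: list[EstimandDescriptor] | None = None) -> pd.DataFrame:
    catalog = catalog or estimand_catalog()
    rows = []
    for d in catalog:
        r = asdict(d)
        r["methods"] = ";".join(d.methods)
        rows.append(r)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Batch runner
# ---------------------------------------------------------------------------


@dataclass
class AnalysisRun:
    estimates: dict[str, EffectEstimate]
    failures: dict[str, str]
    seed: int
    options: dict
    truths: dict[str, float] = field(default_factory=dict)


def run_all(
    dataset: TrialDataset,
    m: int = 10,
    seed: int = 0,
    arm: str | None = None,
    ps_config: PrincipalStratumConfig | None = None,
    truth: TruthRecord | None = None,
) -> AnalysisRun:
    """Run all eight methods; per-method failures are captured, not raised."""
    ps_config = ps_config or PrincipalStratumConfig()
    calls = {
        "ANCOVA_CC": lambda: est.ancova_complete_cases(dataset, arm=arm),
        "ANCOVA_LOCF": lambda: est.ancova_locf(dataset, arm=arm),
        "ANCOVA_MI": lambda: est.ancova_mi(dataset, m=m, seed=seed, arm=arm),
        "MMRM": lambda: est.mmrm_plain(dataset, arm=arm),
        "MMRM_LOCF": lambda: est.mmrm_locf(dataset, arm=arm),
        "MMRM_J2R": lambda: est.mmrm_j2r(dataset, m=m, seed=seed, arm=arm),
        "PMMM": lambda: est.pmmm(dataset, arm=arm),
        "PRINCIPAL_STRATUM": lambda: est.principal_stratum(
            dataset, ps_config, seed=seed, arm=arm
        ),
    }
    catalog = estimand_catalog()
    estimates: dict[str, EffectEstimate] = {}
    failures: dict[str, str] = {}
    for method in METHOD_ORDER:
        t0 = time.perf_counter()
        try:
            out = calls[method]()
            out.estimand_labels = labels_for_method(catalog, method)
            estimates[method] = out
        except Exception as exc:  # capture, keep running
            failures[method] = f"{type(exc).__name__}: {exc}"
        logger.info("%s: %.2fs", method, time.perf_counter() - t0)

    truths: dict[str, float] = {}
    if truth is not None:
        for world in ("HYPOTHETICAL", "TREATMENT_POLICY",
                      "WHILE_ON_TREATMENT", "PRINCIPAL_STRATUM"):
            truths[world] = true_estimand_value(truth, world, arm=arm)
    return AnalysisRun(
        estimates=estimates,
        failures=failures,
        seed=seed,
        options={"m": m, "arm": arm},
        truths=truths,
    )


def forest_table(run: AnalysisRun) -> pd.DataFrame:
    """Ordered forest-plot content: method, estimand labels, estimate, CI."""
    truth_map = {
        "ANCOVA_CC": "HYPOTHETICAL",
        "ANCOVA_LOCF": "WHILE_ON_TREATMENT",
        "ANCOVA_MI": "HYPOTHETICAL",
        "MMRM": "HYPOTHETICAL",
        "MMRM_LOCF": "TREATMENT_POLICY",
        "MMRM_J2R": "TREATMENT_POLICY",
        "PMMM": "TREATMENT_POLICY",
        "PRINCIPAL_STRATUM": "PRINCIPAL_STRATUM",
    }
    rows = []
    for method in METHOD_ORDER:
        if method not in run.estimates:
            continue
        e = run.estimates[method]
        row = {
            "method": method,
            "estimands": ";".join(e.estimand_labels),
            "estimate": e.estimate,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n_used": e.diagnostics.get("n_used", np.nan),
        }
        if run.truths:
            row["truth"] = run.truths.get(truth_map[method], np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_pairs(
    catalog: list[EstimandDescriptor] | None = None,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Unordered method pairs sharing at least one estimand.

    Methods that share an estimand (same attributes) but rest on different
    assumptions can serve as sensitivity analyses for each other; pairs with
    no shared estimand cannot.
    """
    catalog = catalog or estimand_catalog()
    methods = methods or METHOD_ORDER
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            shared = tuple(
                d.id for d in catalog if a in d.methods and b in d.methods
            )
            if not shared:
                continue
            texts = [
                d.required_assumptions for d in catalog if d.id in shared
            ]
            rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "shared_estimands": ";".join(shared),
                    "differing_assumptions": " | ".join(texts),
                }
            )
    return pd.DataFrame(
        rows, columns=["method_a", "method_b", "shared_estimands",
                       "differing_assumptions"]
    )
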