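"""Orchestration of the full GBV validation battery.

Given a cohort and a marker panel, :func:`run_validation` reproduces the
validation battery end to end: phenotype cross-tabulations and the CHD-CED
association, GBV/GBV(S) computation with its standardization constants,
group medians and rank tests, the univariable GBV logistic model with its
AUC, the full additive+dominance model, stepwise marker selection for CHD
and for severe CHD, and heterozygote relative risks for dominance-flagged
markers.  Every sub-analysis failure is captured in its report section
without aborting the rest, and the whole report serializes losslessly to
JSON (two runs on identical inputs are byte-identical).

CED, which is not linked to the panel markers, runs through identical code
paths as a negative control.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from .cohort_io import (
    Cohort,
    contingency_2x2,
    cross_tabulate,
    dichotomize,
    dosage_matrix,
)
from .gbv_scoring import score_cohort
from .marker_panel import MarkerPanel
from .stats_core import (
    EffectEstimate,
    LogisticFit,
    StepwiseTrace,
    auc_rank,
    fit_logistic,
    kruskal_wallis,
    odds_ratio,
    relative_risk,
    stepwise_select,
)

__all__ = [
    "ValidationConfig",
    "ValidationReport",
    "build_design_matrix",
    "summarize_gbv_by_group",
    "run_validation",
    "plot_gbv_by_class",
]

_QUANTILE_METHODS = {
    # numpy names for the two supported conventions: linear interpolation
    # between order statistics, and the empirical CDF with averaging
    "linear": "linear",
    "empirical_cdf_averaging": "averaged_inverted_cdf",
}


@dataclass(frozen=True)
class ValidationConfig:
    """Analysis settings; defaults mirror the published battery."""

    missing_policy: str = "exclude"
    slentry: float = 0.05
    slstay: float = 0.05
    conf_level: float = 0.95
    quantile_convention: str = "linear"
    include_ced: bool = True

    def __post_init__(self) -> None:
        if self.quantile_convention not in _QUANTILE_METHODS:
            raise ValueError(
                f"quantile_convention must be one of {sorted(_QUANTILE_METHODS)}"
            )


@dataclass
class ValidationReport:
    """Structured results of one validation run, JSON round-trippable."""

    sections: dict[str, Any] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"sections": self.sections, "log": self.log},
            indent=2,
            sort_keys=True,
            allow_nan=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        payload = json.loads(text)
        return cls(sections=payload["sections"], log=payload["log"])


def build_design_matrix(
    cohort: Cohort, panel: MarkerPanel | None = None, effects: str = "both"
) -> pd.DataFrame:
    """Additive/dominance design columns for every marker.

    Per marker: ``<id>_add`` is the CHD-associated allele dosage (0, 1, 2)
    and ``<id>_dom`` the heterozygosity indicator (1 for heterozygotes,
    0 for either homozygote).  Missing genotypes yield NaN; callers decide
    the complete-case policy.  ``effects`` selects "additive", "dominance"
    or "both" column sets.
    """
    if effects not in ("additive", "dominance", "both"):
        raise ValueError(f"unknown effects spec {effects!r}")
    dosages = dosage_matrix(cohort, panel or cohort.panel).astype(float)
    cols = {}
    for marker_id in dosages.columns:
        d = dosages[marker_id]
        if effects in ("additive", "both"):
            cols[f"{marker_id}_add"] = d
        if effects in ("dominance", "both"):
            cols[f"{marker_id}_dom"] = (d == 1).astype(float).where(d.notna())
    return pd.DataFrame(cols, index=dosages.index)


def summarize_gbv_by_group(
    gbvs: pd.Series,
    groups: pd.Series,
    quantile_convention: str = "linear",
) -> pd.DataFrame:
    """Median and inter-quartile range (Q3 - Q1) of GBV per group.

    ``quantile_convention`` chooses how quartiles interpolate: "linear"
    (interpolation between order statistics) or "empirical_cdf_averaging".
    Animals missing GBV or group label are dropped; an empty group is an
    error.
    """
    method = _QUANTILE_METHODS[quantile_convention]
    df = pd.DataFrame({"gbv": gbvs, "group": groups}).dropna()
    rows = {}
    for label, sub in df.groupby("group", sort=True):
        vals = sub["gbv"].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method=method)
        rows[label] = {"n": len(vals), "median": med, "q1": q1, "q3": q3, "iqr": q3 - q1}
    if not rows:
        raise ValueError("no animals with both GBV and group label")
    return pd.DataFrame.from_dict(rows, orient="index")


# --------------------------------------------------------------------------
# serialization helpers


def _effect_dict(e: EffectEstimate) -> dict[str, Any]:
    return asdict(e)


def _fit_dict(fit: LogisticFit) -> dict[str, Any]:
    se = np.sqrt(np.diag(fit.covariance))
    return {
        "terms": {
            name: {"coef": float(b), "se": float(s)}
            for name, b, s in zip(fit.term_names, fit.coefficients, se)
        },
        "converged": bool(fit.converged),
        "n_iterations": fit.n_iterations,
        "log_likelihood": fit.log_likelihood,
        "n": int(len(fit.outcome)),
    }


def _trace_dict(trace: StepwiseTrace) -> dict[str, Any]:
    return {
        "steps": [asdict(s) for s in trace.steps],
        "final_terms": list(trace.final_terms),
        "cycled": trace.cycled,
    }


# --------------------------------------------------------------------------
# the battery


def run_validation(
    cohort: Cohort,
    panel: MarkerPanel | None = None,
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """Run the complete validation battery on a cohort.

    Deterministic given its inputs; every section that fails records an
    ``{"error": ...}`` entry instead of aborting the run.
    """
    panel = panel or cohort.panel
    config = config or ValidationConfig()
    report = ValidationReport()
    report.sections["config"] = asdict(config)
    report.log.append(f"cohort: {cohort.n_animals} animals, {len(panel)} markers")

    def section(name: str, fn: Callable[[], Any]) -> Any:
        try:
            result = fn()
            report.sections[name] = result
            return result
        except Exception as exc:  # noqa: BLE001 - per-section isolation
            report.sections[name] = {"error": f"{type(exc).__name__}: {exc}"}
            report.log.append(f"section {name} failed: {exc}")
            return None

    chd = cohort.phenotypes["chd_class"]
    ced = cohort.phenotypes["ced_class"]
    chd_aff = dichotomize(chd, "affected")
    chd_sev = dichotomize(chd, "severe")

    # -- phenotype distributions and CHD x CED association
    def class_distributions() -> dict[str, Any]:
        out = {}
        for disease in ("chd", "ced"):
            table, excluded = cross_tabulate(cohort, disease)
            counts = {str(c): int(table.loc[disease].get(c, 0)) for c in range(1, 6)}
            out[disease] = {
                "counts": counts,
                "n": int(sum(counts.values())),
                "excluded": int(excluded),
            }
        return out

    section("class_distributions", class_distributions)

    def chd_ced_association() -> dict[str, Any]:
        table, excluded = cross_tabulate(cohort, "ced:affected", "chd:affected")
        t = contingency_2x2(table)
        return {
            "both": t.a,
            "ced_only": t.b,
            "chd_only": t.c,
            "neither": t.d,
            "n": t.total,
            "excluded": excluded,
            "odds_ratio": _effect_dict(odds_ratio(t, config.conf_level)),
        }

    section("chd_ced_association", chd_ced_association)

    # -- GBV scores
    scores, constants = score_cohort(cohort, panel, config.missing_policy)
    gbv = scores["gbv"]
    report.sections["standardization_constants"] = constants
    report.sections["gbv_s_range"] = {
        "min": float(scores["gbv_s"].min()),
        "max": float(scores["gbv_s"].max()),
    }
    n_undef = int(gbv.isna().sum())
    if n_undef:
        report.log.append(
            f"{n_undef} animals without GBV under policy {config.missing_policy!r}"
        )

    # -- group summaries and rank tests
    def gbv_summaries() -> dict[str, Any]:
        out: dict[str, Any] = {"quantile_convention": config.quantile_convention}
        status = chd_aff.map({0: "unaffected", 1: "affected"})
        out["chd_status"] = summarize_gbv_by_group(
            gbv, status, config.quantile_convention
        ).to_dict(orient="index")
        bins = chd.map(lambda k: {1: "1", 2: "2-4", 3: "2-4", 4: "2-4", 5: "5"}.get(k))
        out["chd_class_bins"] = summarize_gbv_by_group(
            gbv, bins, config.quantile_convention
        ).to_dict(orient="index")
        if config.include_ced:
            ced_status = dichotomize(ced, "affected").map(
                {0: "unaffected", 1: "affected"}
            )
            out["ced_status"] = summarize_gbv_by_group(
                gbv, ced_status, config.quantile_convention
            ).to_dict(orient="index")
        return out

    section("gbv_summaries", gbv_summaries)

    def kw_tests() -> dict[str, Any]:
        out = {}
        pairs = [("chd", chd_aff)]
        if config.include_ced:
            pairs.append(("ced", dichotomize(ced, "affected")))
        for name, status in pairs:
            df = pd.DataFrame({"gbv": gbv, "g": status}).dropna()
            res = kruskal_wallis(df["gbv"].to_numpy(), df["g"].to_numpy())
            out[name] = {
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "n": len(df),
            }
        return out

    section("kw_tests", kw_tests)

    # -- univariable GBV logistic model
    def gbv_model() -> dict[str, Any]:
        df = pd.DataFrame({"gbv": gbv, "y": chd_aff}).dropna()
        design = np.column_stack([np.ones(len(df)), df["gbv"].to_numpy()])
        fit = fit_logistic(design, df["y"].to_numpy(float), ["(intercept)", "gbv"])
        return {
            "fit": _fit_dict(fit),
            "or_per_unit_gbv": _effect_dict(fit.wald_or("gbv", config.conf_level)),
            "auc": auc_rank(fit.fitted_probabilities, df["y"].to_numpy(int)),
        }

    section("gbv_model", gbv_model)

    # -- inverted raw GBV as a 'test' for severe CHD
    def inverted_gbv_severe() -> dict[str, Any]:
        df = pd.DataFrame({"gbv": gbv, "y": chd_sev}).dropna()
        return {
            "auc": auc_rank(-df["gbv"].to_numpy(), df["y"].to_numpy(int)),
            "n": len(df),
        }

    section("inverted_gbv_severe", inverted_gbv_severe)

    # -- marker models
    design_all = build_design_matrix(cohort, panel, "both")

    def full_model() -> dict[str, Any]:
        df = pd.concat([design_all, chd_aff.rename("y")], axis=1).dropna()
        x = np.column_stack([np.ones(len(df)), df[design_all.columns].to_numpy(float)])
        fit = fit_logistic(
            x, df["y"].to_numpy(float), ["(intercept)", *design_all.columns]
        )
        return {
            "fit": _fit_dict(fit),
            "n_columns": len(design_all.columns),
            "auc": auc_rank(fit.fitted_probabilities, df["y"].to_numpy(int)),
        }

    section("full_model", full_model)

    def stepwise(outcome: pd.Series) -> dict[str, Any]:
        df = pd.concat([design_all, outcome.rename("y")], axis=1).dropna()
        trace, fit = stepwise_select(
            df[design_all.columns],
            df["y"].to_numpy(float),
            slentry=config.slentry,
            slstay=config.slstay,
        )
        effects = {
            term: _effect_dict(fit.wald_or(term, config.conf_level))
            for term in trace.final_terms
        }
        return {
            "trace": _trace_dict(trace),
            "candidates": list(design_all.columns),
            "effects": effects,
            "fit": _fit_dict(fit),
            "auc": auc_rank(fit.fitted_probabilities, df["y"].to_numpy(int)),
        }

    stepwise_chd = section("stepwise_chd", lambda: stepwise(chd_aff))
    stepwise_severe = section("stepwise_severe", lambda: stepwise(chd_sev))

    # -- heterozygote (dominance) relative risks for severe CHD
    def dominance_risks() -> dict[str, Any]:
        flagged = []
        if stepwise_severe and "trace" in stepwise_severe:
            flagged = [
                t[: -len("_dom")]
                for t in stepwise_severe["trace"]["final_terms"]
                if t.endswith("_dom")
            ]
        dosages = dosage_matrix(cohort, panel)
        out = {}
        for marker_id in flagged:
            df = pd.DataFrame({"d": dosages[marker_id], "y": chd_sev}).dropna()
            het = df["d"] == 1
            exposed = (int(df.loc[het, "y"].sum()), int(het.sum()))
            unexposed = (int(df.loc[~het, "y"].sum()), int((~het).sum()))
            try:
                rr = _effect_dict(
                    relative_risk(exposed, unexposed, config.conf_level)
                )
            except Exception as exc:  # noqa: BLE001 - boundary tables
                rr = {"error": f"{type(exc).__name__}: {exc}"}
            out[marker_id] = {
                "heterozygous": {"events": exposed[0], "n": exposed[1]},
                "homozygous": {"events": unexposed[0], "n": unexposed[1]},
                "relative_risk": rr,
            }
        return out

    section("dominance_risks", dominance_risks)

    return report


def plot_gbv_by_class(
    gbvs: pd.Series, classes: pd.Series, path: str, title: str = "GBV by phenotypic class"
) -> None:
    """Box plot of GBV against the 1-5 phenotypic class (report figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame({"gbv": gbvs, "cls": classes}).dropna()
    groups = [df.loc[df["cls"] == k, "gbv"].to_numpy() for k in sorted(df["cls"].unique())]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(groups, tick_labels=[str(int(k)) for k in sorted(df["cls"].unique())])
    ax.set_xlabel("phenotypic class")
    ax.set_ylabel("GBV")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
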