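"""Synthetic cohorts with the statistical structure the validation assumes.

The generator draws 17 biallelic autosomal markers in Hardy-Weinberg
proportions (dosage probabilities ((1-q)^2, 2q(1-q), q^2) per marker, linkage
equilibrium between markers), assigns a 5-class ordinal hip phenotype whose
class-1 (unaffected) prevalence is ~70%, and optionally plants additive and/or
dominance log-odds effects of chosen markers on affection — or, in
``effect_target="severe"`` mode, on severe disease (class 5), mimicking the
heterozygote-risk pattern seen for TiHo12/TiHo18.  Elbow phenotypes are drawn
with a configurable CHD-CED log-odds association (default ln 1.73) and serve
as the negative control.  The all-null model (every effect zero) is the
default.

Default class margins and the TiHo12 allele frequency (0.842) are frozen from
the study's printed tables; other allele frequencies are fixed synthetic
choices in 0.08-0.55.  Identical config and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort_io import Cohort, write_cohort
from .marker_panel import MarkerPanel, bundled_panel

__all__ = [
    "SimulationError",
    "MarkerSim",
    "SimulationConfig",
    "default_config",
    "simulate_genotypes",
    "mask_missing",
    "simulate_phenotypes",
    "simulate_cohort",
]

# study-margin calibration constants (printed cross-tabulation)
CHD_CLASS_COUNTS = (657, 179, 53, 21, 25)   # n = 935
CED_CLASS_COUNTS = (714, 70, 39, 68, 37)    # n = 928
DEFAULT_CHD_CED_OR = 1.73

_DEFAULT_Q = {
    "TiHo1": 0.35, "TiHo2": 0.10, "TiHo4": 0.22, "TiHo6": 0.45, "TiHo9": 0.30,
    "TiHo12": 0.842, "TiHo14": 0.15, "TiHo16": 0.50, "TiHo18": 0.27,
    "TiHo19": 0.40, "TiHo21": 0.08, "TiHo25": 0.38, "TiHo26": 0.33,
    "TiHo29": 0.20, "TiHo31": 0.55, "TiHo35": 0.25, "TiHo37": 0.12,
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class MarkerSim:
    """Simulation settings for one marker: allele frequency and planted effects."""

    marker_id: str
    q: float                  # mutant (CHD-associated) allele frequency
    beta_add: float = 0.0     # per-dosage log-odds effect
    beta_dom: float = 0.0     # heterozygote log-odds deviation

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise SimulationError(f"{self.marker_id}: q={self.q} outside [0, 1]")


def _norm_probs(counts: Sequence[float]) -> tuple[float, ...]:
    total = float(sum(counts))
    return tuple(c / total for c in counts)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one synthetic cohort draw."""

    n_animals: int = 935
    seed: int = 0
    markers: tuple[MarkerSim, ...] = ()
    baseline_class_probs: tuple[float, ...] = _norm_probs(CHD_CLASS_COUNTS)
    ced_class_probs: tuple[float, ...] = _norm_probs(CED_CLASS_COUNTS)
    chd_ced_log_or: float = float(np.log(DEFAULT_CHD_CED_OR))
    missing_rate: float = 0.0
    effect_target: str = "affected"   # "affected" | "severe"

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise SimulationError("n_animals must be >= 2")
        for name in ("baseline_class_probs", "ced_class_probs"):
            probs = getattr(self, name)
            if len(probs) != 5 or any(p < 0 for p in probs):
                raise SimulationError(f"{name} must be 5 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-8:
                raise SimulationError(f"{name} must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must be in [0, 1)")
        if self.effect_target not in ("affected", "severe"):
            raise SimulationError(f"unknown effect_target {self.effect_target!r}")
        if not self.markers:
            raise SimulationError("config needs at least one marker")

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["markers"] = [asdict(m) for m in self.markers]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["markers"] = tuple(MarkerSim(**m) for m in payload["markers"])
        for key in ("baseline_class_probs", "ced_class_probs"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def default_config(
    seed: int = 0,
    n_animals: int = 935,
    effects: dict[str, tuple[float, float]] | None = None,
    **overrides,
) -> SimulationConfig:
    """Study-shaped configuration over the bundled panel (all-null by default).

    ``effects`` plants ``marker_id -> (beta_add, beta_dom)`` log-odds effects;
    any other :class:`SimulationConfig` field can be overridden by keyword.
    """
    effects = effects or {}
    unknown = set(effects) - set(_DEFAULT_Q)
    if unknown:
        raise SimulationError(f"effects for unknown markers: {sorted(unknown)}")
    markers = tuple(
        MarkerSim(mid, q, *effects.get(mid, (0.0, 0.0)))
        for mid, q in _DEFAULT_Q.items()
    )
    return SimulationConfig(
        n_animals=n_animals, seed=seed, markers=markers, **overrides
    )


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Complete (unmasked) dosage table under Hardy-Weinberg proportions.

    Returns an animals x markers DataFrame of dosages in {0,1,2}, indexed by
    generated animal ids.  Reproducible: a fresh generator is seeded from
    ``config.seed`` unless one is passed in.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_animals
    data = {}
    for m in config.markers:
        hwe = np.array([(1 - m.q) ** 2, 2 * m.q * (1 - m.q), m.q**2])
        data[m.marker_id] = rng.choice(3, size=n, p=hwe)
    index = pd.Index([f"dog{i + 1:05d}" for i in range(n)], name="animal_id")
    return pd.DataFrame(data, index=index)


def mask_missing(
    dosages: pd.DataFrame, missing_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Mask each call independently with probability ``missing_rate``."""
    if missing_rate == 0.0:
        return dosages.astype("Int64")
    mask = rng.random(dosages.shape) < missing_rate
    return dosages.astype("Int64").mask(mask)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept making mean(expit(alpha + eta)) equal the target prevalence."""
    if target <= 0.0:
        return -np.inf  # degenerate margin: nobody affected
    if target >= 1.0:
        return np.inf
    f = lambda a: expit(a + eta).mean() - target  # noqa: E731
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise SimulationError("intercept solver failed: target unreachable")
    return float(brentq(f, lo, hi, xtol=1e-12))


def simulate_phenotypes(
    dosages: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """CHD and CED classes 1-5 from complete genotypes.

    The genetic linear predictor sum(beta_add * dosage + beta_dom * het) acts
    on affection (classes 2-5) or, in "severe" mode, on class 5 membership;
    the intercept is solved so the realized-cohort expected prevalence matches
    the configured class margins.  Severity among the remaining classes is
    assigned independently of genotype.  CED affection is drawn with the
    configured CHD-CED log-odds ratio while preserving the CED margin, and is
    otherwise independent of the markers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    by_id = {m.marker_id: m for m in config.markers}
    missing_markers = set(dosages.columns) - set(by_id)
    if missing_markers:
        raise SimulationError(f"no simulation settings for {sorted(missing_markers)}")
    if dosages.isna().any().any():
        raise SimulationError("phenotype simulation needs complete genotypes")
    d = dosages.to_numpy(dtype=float)
    beta_add = np.array([by_id[c].beta_add for c in dosages.columns])
    beta_dom = np.array([by_id[c].beta_dom for c in dosages.columns])
    eta = d @ beta_add + (d == 1) @ beta_dom

    probs = np.asarray(config.baseline_class_probs)
    n = len(dosages)
    chd = np.empty(n, dtype=int)
    if config.effect_target == "affected":
        p_target = 1.0 - probs[0]
        alpha = _solve_intercept(eta, p_target)
        affected = rng.random(n) < expit(alpha + eta)
        chd[~affected] = 1
        if affected.any():
            cond = probs[1:] / probs[1:].sum()
            chd[affected] = rng.choice(
                np.arange(2, 6), size=int(affected.sum()), p=cond
            )
    else:  # severe
        alpha = _solve_intercept(eta, probs[4])
        severe = rng.random(n) < expit(alpha + eta)
        chd[severe] = 5
        if (~severe).any():
            cond = probs[:4] / probs[:4].sum()
            chd[~severe] = rng.choice(
                np.arange(1, 5), size=int((~severe).sum()), p=cond
            )

    # CED: margin-preserving association with CHD affection
    ced_probs = np.asarray(config.ced_class_probs)
    p_ced = 1.0 - ced_probs[0]
    chd_aff = (chd >= 2).astype(float)
    lor = config.chd_ced_log_or
    t0 = _solve_intercept(lor * chd_aff, p_ced)
    ced_aff = rng.random(n) < expit(t0 + lor * chd_aff)
    ced = np.ones(n, dtype=int)
    if ced_aff.any():
        cond_ced = ced_probs[1:] / ced_probs[1:].sum()
        ced[ced_aff] = rng.choice(
            np.arange(2, 6), size=int(ced_aff.sum()), p=cond_ced
        )

    return pd.DataFrame(
        {"chd_class": chd, "ced_class": ced}, index=dosages.index
    ).astype("Int64")


def _dosage_to_calls(dosages: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    out = {}
    for marker_id in dosages.columns:
        m = panel[marker_id]
        calls = {
            0: f"{m.wild_allele}/{m.wild_allele}",
            1: f"{m.wild_allele}/{m.mutant_allele}",
            2: f"{m.mutant_allele}/{m.mutant_allele}",
        }
        out[marker_id] = dosages[marker_id].map(lambda d: calls.get(d, np.nan))
    return pd.DataFrame(out, index=dosages.index)


def simulate_cohort(
    config: SimulationConfig,
    panel: MarkerPanel | None = None,
    out_path: str | Path | None = None,
) -> Cohort:
    """Draw a full cohort (genotypes + phenotypes) and optionally write it.

    Effects are computed on the complete genotypes; missing-call masking is
    applied afterwards.  The written CSV follows the canonical cohort schema
    (round-trips through ``read_cohort``) and echoes the seed in its header.
    """
    panel = panel or bundled_panel()
    rng = np.random.default_rng(config.seed)
    dosages = simulate_genotypes(config, rng)
    phenotypes = simulate_phenotypes(dosages, config, rng)
    masked = mask_missing(dosages, config.missing_rate, rng)
    cohort = Cohort(_dosage_to_calls(masked, panel), phenotypes, panel)
    if out_path is not None:
        write_cohort(
            cohort,
            out_path,
            header_comment=(
                f"synthetic cohort | seed={config.seed} n={config.n_animals} "
                f"missing_rate={config.missing_rate} effect_target={config.effect_target}"
            ),
        )
    return cohort
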