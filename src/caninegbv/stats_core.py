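"""Statistical machinery for the validation battery.

Implements, with the semantics of the procedures the original study ran:

* tie-corrected Kruskal-Wallis rank test (NPAR1WAY-style H with the
  ``1 - sum(t^3 - t)/(N^3 - N)`` correction);
* maximum-likelihood logistic regression via iteratively reweighted least
  squares (IRLS/Newton-Raphson), with honest convergence and separation
  diagnostics;
* Rao score tests for candidate terms and SAS-style stepwise selection
  (score-chi-square entry, Wald-chi-square stay);
* rank-based (Mann-Whitney) AUC with tie handling, equal to the trapezoidal
  area under the empirical ROC curve;
* 2x2 odds ratios and relative risks with Woolf/Katz log-scale confidence
  intervals.

These are the quantities under scrutiny in a diagnostic-test validation, so
they are implemented from the definitions rather than delegated; scipy
supplies only ranking and reference distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit

from .cohort_io import Contingency2x2

__all__ = [
    "StatsError",
    "SeparationError",
    "CollinearityError",
    "RankTestResult",
    "LogisticFit",
    "StepwiseStep",
    "StepwiseTrace",
    "EffectEstimate",
    "kruskal_wallis",
    "fit_logistic",
    "score_test",
    "wald_test",
    "stepwise_select",
    "auc_rank",
    "odds_ratio",
    "relative_risk",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


class SeparationError(StatsError):
    """The logistic likelihood is monotone (complete/quasi-complete separation)."""


class CollinearityError(StatsError):
    """A design column is collinear with the current model terms."""


# --------------------------------------------------------------------------
# rank tests


@dataclass(frozen=True)
class RankTestResult:
    """Tie-corrected Kruskal-Wallis statistic with its chi-square p-value."""

    statistic: float
    df: int
    p_value: float


def kruskal_wallis(values: Sequence[float], groups: Sequence[object]) -> RankTestResult:
    """Kruskal-Wallis H test across >= 2 groups with midrank tie correction.

    H is divided by ``1 - sum(t^3 - t) / (N^3 - N)`` over tie groups of size t;
    the p-value comes from the chi-square distribution with k-1 df.  All
    observations identical (correction factor 0) is an error, as is a single
    group or an empty group.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise StatsError("values and groups must have equal length")
    if np.isnan(x).any():
        raise StatsError("missing values must be removed before testing")
    labels, inverse = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise StatsError("need at least two groups")
    n = len(x)
    ranks = sps.rankdata(x)  # midranks
    h = 0.0
    for j in range(k):
        rj = ranks[inverse == j]
        if len(rj) == 0:
            raise StatsError(f"group {labels[j]!r} is empty")
        h += rj.sum() ** 2 / len(rj)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(x, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction <= 0:
        raise StatsError("all observations identical; H is undefined")
    h /= correction
    df = k - 1
    return RankTestResult(statistic=float(h), df=df, p_value=float(sps.chi2.sf(h, df)))


# --------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    ``coefficients`` has the intercept first, in ``term_names`` order.
    ``covariance`` is the inverse observed Fisher information at the MLE.
    The design and outcome are retained so score tests for candidate terms
    can be evaluated at this restricted fit.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float
    fitted_probabilities: np.ndarray
    term_names: list[str]
    design: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)

    def wald_or(self, term: str, level: float = 0.95) -> "EffectEstimate":
        """exp(coefficient) for one term with a Wald confidence interval."""
        j = self.term_names.index(term)
        beta = self.coefficients[j]
        se = float(np.sqrt(self.covariance[j, j]))
        z = sps.norm.ppf(1 - (1 - level) / 2)
        return EffectEstimate(
            kind="OR",
            point=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            level=level,
        )


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    term_names: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> LogisticFit:
    """Logistic MLE by IRLS with honest failure modes.

    ``design`` must carry an explicit intercept column.  Convergence is a
    relative log-likelihood change below ``tol``.  Separation (a monotone
    likelihood) is flagged when any standardized coefficient ``|beta_j| * sd_j``
    exceeds 15 — the estimate is then diverging, not converging — and raises
    :class:`SeparationError` rather than returning garbage.  A singular
    information matrix raises :class:`CollinearityError`.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise StatsError("design must be 2-D and conformable with outcome")
    n, p = x.shape
    if n < p:
        raise StatsError(f"n={n} observations for p={p} columns")
    if not np.isin(y, (0.0, 1.0)).all():
        raise StatsError("outcome must be 0/1")
    if y.min() == y.max():
        raise SeparationError("outcome is constant (all 0 or all 1)")
    names = list(term_names) if term_names is not None else [
        f"x{j}" for j in range(p)
    ]
    if len(names) != p:
        raise StatsError("term_names length must match design columns")

    sd = x.std(axis=0)
    sd_check = np.where(sd > 0, sd, 0.0)  # intercept/constants exempt
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    info = None
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu)
        info = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(
                "singular information matrix (collinear design columns)"
            ) from exc
        beta = beta + step
        if np.abs(beta * sd_check).max() > 15.0:
            raise SeparationError(
                "coefficients diverging (|beta|*sd > 15): complete or "
                "quasi-complete separation"
            )
        ll = _log_likelihood(x @ beta, y)
        if abs(ll - ll_old) < tol * (abs(ll) + tol):
            converged = True
            break
        ll_old = ll

    eta = x @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = x.T @ (x * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("singular information matrix at the MLE") from exc
    return LogisticFit(
        coefficients=beta,
        covariance=cov,
        converged=converged,
        n_iterations=it,
        log_likelihood=_log_likelihood(eta, y),
        fitted_probabilities=mu,
        term_names=names,
        design=x,
        outcome=y,
    )


def score_test(fit: LogisticFit, candidate: np.ndarray) -> tuple[float, float]:
    """Rao score test (1 df) for adding one column to a fitted model.

    Evaluated at the restricted MLE: with z the candidate, U = z'(y - p) and
    V = z'Wz - z'WX (X'WX)^-1 X'Wz; the statistic is U^2/V.  A candidate
    collinear with the current terms (V ~ 0) raises
    :class:`CollinearityError`.
    """
    z = np.asarray(candidate, dtype=float)
    if z.shape != fit.outcome.shape:
        raise StatsError("candidate length must match the fitted data")
    if np.ptp(z) == 0.0:
        # a constant carries no information beyond the intercept
        return 0.0, 1.0
    x = fit.design
    mu = fit.fitted_probabilities
    w = mu * (1.0 - mu)
    u = float(z @ (fit.outcome - mu))
    wz = w * z
    xtwz = x.T @ wz
    v = float(z @ wz - xtwz @ np.linalg.solve(x.T @ (x * w[:, None]), xtwz))
    scale = float(z @ wz) if float(z @ wz) > 0 else 1.0
    if v <= 1e-10 * scale:
        raise CollinearityError("candidate is collinear with the current model")
    chi2 = u * u / v
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def wald_test(fit: LogisticFit, term: str) -> tuple[float, float]:
    """Wald chi-square (1 df) for one fitted term."""
    j = fit.term_names.index(term)
    beta = fit.coefficients[j]
    var = fit.covariance[j, j]
    chi2 = beta * beta / var
    return float(chi2), float(sps.chi2.sf(chi2, 1))


# --------------------------------------------------------------------------
# stepwise selection


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    term: str
    statistic: float  # score chi2 for enter, Wald chi2 for remove
    p_value: float


@dataclass
class StepwiseTrace:
    """Ordered record of every stepwise action plus the final term set."""

    steps: list[StepwiseStep]
    final_terms: list[str]
    cycled: bool = False


def stepwise_select(
    candidates: "object",
    outcome: np.ndarray,
    slentry: float = 0.05,
    slstay: float = 0.05,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[StepwiseTrace, LogisticFit]:
    """SAS-style stepwise logistic selection over named candidate columns.

    ``candidates`` is a pandas DataFrame (column names = term names).  At each
    step the out-of-model candidate with the smallest score-test p-value
    enters if p <= ``slentry``; then in-model terms with Wald p > ``slstay``
    are removed (worst first).  Candidates whose score test cannot be
    evaluated (collinear, separated fit) are passed over.  Revisiting a
    previously seen model flags the trace as cycled and stops.  Returns the
    trace and the final fitted model (intercept-only when nothing enters).
    """
    import pandas as pd  # local import keeps module load cheap

    if not isinstance(candidates, pd.DataFrame):
        raise StatsError("candidates must be a named-column DataFrame")
    if candidates.shape[1] < 1:
        raise StatsError("need at least one candidate")
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if len(candidates) != n:
        raise StatsError("candidates and outcome must have equal length")
    cols = {c: candidates[c].to_numpy(dtype=float) for c in candidates.columns}

    def refit(terms: list[str]) -> LogisticFit:
        mat = np.column_stack([np.ones(n)] + [cols[t] for t in terms])
        return fit_logistic(
            mat, y, ["(intercept)"] + terms, tol=tol, max_iter=max_iter
        )

    in_terms: list[str] = []
    steps: list[StepwiseStep] = []
    seen = {frozenset()}
    cycled = False
    fit = refit(in_terms)

    while True:
        # entry phase
        best: tuple[float, float, str] | None = None
        for name in candidates.columns:
            if name in in_terms:
                continue
            try:
                chi2, p = score_test(fit, cols[name])
            except StatsError:
                continue
            if best is None or p < best[1] or (p == best[1] and chi2 > best[0]):
                best = (chi2, p, name)
        if best is None or best[1] > slentry:
            break
        chi2, p, name = best
        in_terms.append(name)
        steps.append(StepwiseStep("enter", name, chi2, p))
        try:
            fit = refit(in_terms)
        except StatsError:
            # entering this term broke the fit; back it out and stop
            in_terms.pop()
            steps.append(StepwiseStep("remove", name, float("nan"), float("nan")))
            fit = refit(in_terms)
            break

        # removal phase
        while in_terms:
            walds = [(t, *wald_test(fit, t)) for t in in_terms]
            worst = max(walds, key=lambda w: w[2])
            if worst[2] <= slstay:
                break
            in_terms.remove(worst[0])
            steps.append(StepwiseStep("remove", worst[0], worst[1], worst[2]))
            fit = refit(in_terms)

        state = frozenset(in_terms)
        if state in seen:
            cycled = True
            break
        seen.add(state)

    return StepwiseTrace(steps=steps, final_terms=list(in_terms), cycled=cycled), fit


# --------------------------------------------------------------------------
# ROC / AUC


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 1/2 P(tie).

    Computed from midranks in O(n log n); identical to the trapezoidal area
    under the empirical ROC curve.  Requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise StatsError("scores and labels must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise StatsError("labels must be 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise StatsError("both label classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# --------------------------------------------------------------------------
# 2x2 effect measures


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio or relative risk with a log-scale confidence interval."""

    kind: str  # "OR" | "RR"
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point <= self.ci_high):
            raise StatsError(
                f"{self.kind} point {self.point} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def odds_ratio(t: Contingency2x2, level: float = 0.95) -> EffectEstimate:
    """Sample odds ratio ad/bc with the Woolf log-method interval.

    CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).  A zero cell is an
    error (no silent continuity correction).
    """
    cells = {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
    zeros = [k for k, v in cells.items() if v == 0]
    if zeros:
        raise StatsError(f"zero cell(s) {zeros} in 2x2 table; OR undefined")
    point = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return EffectEstimate(
        kind="OR",
        point=float(point),
        ci_low=float(np.exp(np.log(point) - z * se)),
        ci_high=float(np.exp(np.log(point) + z * se)),
        level=level,
    )


def relative_risk(
    exposed: tuple[int, int],
    unexposed: tuple[int, int],
    level: float = 0.95,
) -> EffectEstimate:
    """Risk ratio (e1/n1)/(e0/n0) with the Katz log-method interval.

    CI = exp(ln RR +/- z * sqrt(1/e1 - 1/n1 + 1/e0 - 1/n0)).  Zero events in
    the unexposed group (infinite estimate) or in the exposed group (zero
    estimate, log CI undefined) are errors.
    """
    e1, n1 = exposed
    e0, n0 = unexposed
    if n1 <= 0 or n0 <= 0:
        raise StatsError("group totals must be positive")
    if e0 == 0:
        raise StatsError("zero events in the unexposed group; RR infinite")
    if e1 == 0:
        raise StatsError("zero events in the exposed group; log-scale CI undefined")
    if e1 > n1 or e0 > n0:
        raise StatsError("events exceed group total")
    point = (e1 / n1) / (e0 / n0)
    se = np.sqrt(1 / e1 - 1 / n1 + 1 / e0 - 1 / n0)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return EffectEstimate(
        kind="RR",
        point=float(point),
        ci_low=float(np.exp(np.log(point) - z * se)),
        ci_high=float(np.exp(np.log(point) + z * se)),
        level=level,
    )
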