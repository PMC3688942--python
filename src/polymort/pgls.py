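"""Phylogenetic generalized least squares with ML Pagel's λ, AICc and weights.

The regression model is y = Xβ + ε with ε ~ N(0, σ²·V(λ)), where V(λ) is the
Brownian among-species covariance with off-diagonals multiplied by λ.  β and
σ² have closed-form ML solutions conditional on λ; λ itself is profiled out
by bounded scalar optimization on [0, 1].

Model selection follows small-sample information-theoretic practice:
AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting all estimated
quantities (coefficients, σ², λ), Akaike weights w_i ∝ exp(−Δ_i/2), and a
parsimony rule that retains the simplest model within 2 AICc units of the
best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phylo import CovarianceMatrix, lambda_transform

__all__ = [
    "ModelSpec",
    "GlsResult",
    "PglsFit",
    "ModelComparison",
    "gls_fit",
    "profile_lambda",
    "aicc",
    "akaike_weights",
    "compare_models",
    "select_model",
    "adjusted_r2",
    "check_normality",
]

#: absolute tolerance of the λ optimizer
LAMBDA_TOL = 1e-6
#: parsimony window for model selection (AICc units)
AICC_THRESHOLD = 2.0
#: extra parameters beyond the regression coefficients: σ² and λ
EXTRA_PARAMS = 2


class SingularModelError(np.linalg.LinAlgError):
    """Raised when XᵀV⁻¹X is singular (collinear design columns)."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression: response ~ main effects (+ interactions).

    Interactions are products of two predictors; by construction both members
    also enter as main effects.
    """

    response: str
    terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(
            self, "interactions", tuple(tuple(p) for p in self.interactions)
        )
        for a, b in self.interactions:
            if a not in self.terms or b not in self.terms:
                raise ValueError(
                    f"interaction {a}x{b} requires both main effects in terms"
                )
        if not self.label:
            object.__setattr__(self, "label", self.format_label())

    def format_label(self) -> str:
        parts = [t for t in self.terms]
        parts += [f"{a}*{b}" for a, b in self.interactions]
        return " + ".join(parts) if parts else "Constant"

    @property
    def n_coef(self) -> int:
        return 1 + len(self.terms) + len(self.interactions)

    @property
    def k(self) -> int:
        """AICc parameter count: coefficients + residual variance + λ."""
        return self.n_coef + EXTRA_PARAMS

    def design_matrix(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(data))]
        names = ["Intercept"]
        for t in self.terms:
            cols.append(data[t].to_numpy(dtype=float))
            names.append(t)
        for a, b in self.interactions:
            cols.append(
                data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
            )
            names.append(f"{a}:{b}")
        return np.column_stack(cols), names


@dataclass(frozen=True)
class GlsResult:
    """Closed-form GLS solution at a fixed covariance matrix."""

    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    sigma2: float
    logLik: float
    n: int
    p: int
    rss_whitened: float
    zero_residuals: bool = False


@dataclass(frozen=True)
class PglsFit:
    """A fitted PGLS model at the ML λ, with its information-criterion bookkeeping."""

    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    sigma2: float
    lambda_hat: float
    logLik: float
    k: int
    n: int
    aicc: float
    r2_adj: float
    term_names: tuple[str, ...] = ()
    spec: ModelSpec | None = None

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.term_names),
                "estimate": self.beta,
                "se": self.se,
                "t": self.t_stat,
                "p": self.p_value,
            }
        )


@dataclass
class ModelComparison:
    """Ranked candidate set with ΔAICc, Akaike weights and the retained model."""

    table: pd.DataFrame
    fits: list[PglsFit] = field(repr=False, default_factory=list)
    selected: int = 0

    @property
    def selected_fit(self) -> PglsFit:
        return self.fits[self.selected]


# ---------------------------------------------------------------------------
# GLS core
# ---------------------------------------------------------------------------


def gls_fit(y: np.ndarray, X: np.ndarray, V: CovarianceMatrix | np.ndarray) -> GlsResult:
    """ML generalized least squares at a fixed covariance matrix.

    β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y and σ̂² = rᵀV⁻¹r/n (the ML estimator, used in the
    likelihood); standard errors use the (n−p)-denominator variance so t
    statistics follow the usual t distribution with n−p df.
    """
    Vm = V.V if isinstance(V, CovarianceMatrix) else np.asarray(V, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n or Vm.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and V")
    try:
        L = np.linalg.cholesky(Vm)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("V is not positive definite") from exc
    # whiten: L⁻¹y, L⁻¹X
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        bad = _collinear_columns(Xw)
        raise SingularModelError(f"singular design (collinear columns: {bad})")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2_ml = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    zero = rss <= 1e-12 * max(float(yw @ yw), 1.0)
    if zero:
        logLik = math.inf
        se = np.zeros(p)
        t = np.full(p, np.inf)
        pv = np.zeros(p)
    else:
        logLik = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdetV + n)
        sigma2_unb = rss / (n - p) if n > p else math.nan
        cov_beta = sigma2_unb * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        pv = 2.0 * stats.t.sf(np.abs(t), df=max(n - p, 1))
    return GlsResult(
        beta=beta,
        se=se,
        t_stat=t,
        p_value=pv,
        sigma2=sigma2_ml,
        logLik=logLik,
        n=n,
        p=p,
        rss_whitened=rss,
        zero_residuals=zero,
    )


def _collinear_columns(Xw: np.ndarray) -> list[int]:
    """Identify columns not adding rank, by incremental QR."""
    bad = []
    rank = 0
    for j in range(Xw.shape[1]):
        r = np.linalg.matrix_rank(Xw[:, : j + 1])
        if r == rank:
            bad.append(j)
        rank = r
    return bad


def profile_lambda(
    y: np.ndarray,
    X: np.ndarray,
    V0: CovarianceMatrix,
    tol: float = LAMBDA_TOL,
    spec: ModelSpec | None = None,
    term_names: Sequence[str] | None = None,
) -> PglsFit:
    """Fit PGLS maximising the profile likelihood over Pagel's λ ∈ [0, 1].

    Bounded Brent search in the interior plus explicit endpoint evaluation;
    a tie between an interior optimum and an endpoint resolves to the
    endpoint (so phylogeny-free data report λ̂ = 0 rather than an arbitrary
    interior value — on a star tree every λ is equivalent and 0 is returned).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))

    def negll(lam: float) -> float:
        res = gls_fit(y, X, lambda_transform(V0, lam))
        return -res.logLik

    opt = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol}
    )
    candidates = [(0.0, negll(0.0)), (1.0, negll(1.0)), (float(opt.x), float(opt.fun))]
    best_val = min(v for _, v in candidates)
    tie = 10 * tol
    for lam, v in candidates:  # endpoints first: ties resolve to 0, then 1
        if v <= best_val + tie:
            lam_hat = lam
            break
    res = gls_fit(y, X, lambda_transform(V0, lam_hat))
    k = res.p + EXTRA_PARAMS
    n = res.n
    fit_aicc = aicc(res.logLik, k, n) if n > k + 1 else math.inf
    names = tuple(term_names) if term_names is not None else tuple(
        f"x{i}" for i in range(res.p)
    )
    fit = PglsFit(
        beta=res.beta,
        se=res.se,
        t_stat=res.t_stat,
        p_value=res.p_value,
        sigma2=res.sigma2,
        lambda_hat=lam_hat,
        logLik=res.logLik,
        k=k,
        n=n,
        aicc=fit_aicc,
        r2_adj=math.nan,
        term_names=names,
        spec=spec,
    )
    null = gls_fit(y, np.ones((n, 1)), lambda_transform(V0, lam_hat))
    return _with_r2(fit, null)


def _with_r2(fit: PglsFit, null_res: GlsResult) -> PglsFit:
    from dataclasses import replace

    return replace(fit, r2_adj=_adjusted_r2(fit, null_res))


# ---------------------------------------------------------------------------
# information criteria and selection
# ---------------------------------------------------------------------------


def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logLik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta_aicc: Sequence[float]) -> np.ndarray:
    """Normalized relative likelihoods w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2)."""
    d = np.asarray(delta_aicc, dtype=float)
    if d.size == 0:
        raise ValueError("empty ΔAICc list")
    if np.any(d < 0) or not np.isclose(d.min(), 0.0):
        raise ValueError("ΔAICc values must be >= 0 with at least one 0")
    rel = np.exp(-d / 2.0)
    return rel / rel.sum()


def compare_models(fits: Sequence[PglsFit], threshold: float = AICC_THRESHOLD) -> ModelComparison:
    """Assemble the ranked comparison table and apply the parsimony rule."""
    if not fits:
        raise ValueError("no fitted models to compare")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    weights = akaike_weights(delta)
    table = pd.DataFrame(
        {
            "label": [f.spec.label if f.spec else "?" for f in fits],
            "k": [f.k for f in fits],
            "lambda": [f.lambda_hat for f in fits],
            "r2_adj": [f.r2_adj for f in fits],
            "deviance": [-2.0 * f.logLik for f in fits],
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": weights,
        }
    )
    cmp = ModelComparison(table=table, fits=list(fits))
    cmp.selected = select_model(cmp, threshold=threshold)
    cmp.table["selected"] = ""
    cmp.table.loc[cmp.selected, "selected"] = "*"
    return cmp


def select_model(cmp: ModelComparison, threshold: float = AICC_THRESHOLD) -> int:
    """Parsimony rule: among models within ``threshold`` AICc units of the
    best, retain the one with the fewest parameters (ties: smaller AICc,
    then listing order)."""
    t = cmp.table
    window = t.index[t["delta_aicc"] <= threshold]
    if len(window) == 0:
        raise ValueError("comparison has no model at ΔAICc = 0")
    rows = t.loc[window]
    order = rows.sort_values(["k", "aicc"], kind="stable")
    return int(order.index[0])


def adjusted_r2(fit: GlsResult | PglsFit, null_fit: GlsResult) -> float:
    """Adjusted R² in the V(λ̂)-whitened space, against the intercept-only fit."""
    return _adjusted_r2(fit, null_fit)


def _adjusted_r2(fit, null_fit) -> float:
    rss = fit.rss_whitened if hasattr(fit, "rss_whitened") else fit.sigma2 * fit.n
    tss = null_fit.rss_whitened
    n = fit.n
    p = fit.p if hasattr(fit, "p") else len(fit.beta)
    if p == 1:
        return 0.0
    if tss <= 0:
        return 0.0
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


# ---------------------------------------------------------------------------
# normality screening
# ---------------------------------------------------------------------------


def check_normality(values: Sequence[float], alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro–Wilk test; the flag recommends a log transform when p < alpha."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: normality test undefined")
    p = float(stats.shapiro(v).pvalue)
    return p, p < alpha
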