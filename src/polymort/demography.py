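"""Life-table demography: survivorship, median lifespan, onset of senescence, aging rate.

A species' mortality schedule enters the comparative analysis through two
scalar metrics derived from its life table:

* **median lifespan** — the age at which half of a cohort initialised at age 1
  is still alive (juvenile survival between birth and age 1 is too variable
  across studies to compare, so cohorts start at 1 year);
* **aging rate** — the slope of the ordinary least-squares regression of
  annual survival on age from the onset of senescence onward, where the onset
  is located on a smoothed (spline/GAM-style) survival trajectory as the age
  at which survival starts to decline.

All functions operate on :class:`LifeTable` objects, which can be built from
either cohort counts ``n(x)`` (converted to annual survival
``s(x) = n(x+1)/n(x)``) or directly supplied annual survival probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "LifeTable",
    "SurvivalCurve",
    "DemographicMetrics",
    "read_life_table",
    "read_life_tables",
    "survivorship",
    "median_lifespan",
    "fit_survival_smooth",
    "onset_of_senescence",
    "aging_rate",
    "species_metrics",
    "metrics_table",
]

#: default effective degrees of freedom of the survival smoother; ``None``
#: selects the smoothing level by generalized cross-validation
DEFAULT_SMOOTH_DF: float | None = None
#: grid resolution (years) at which the smoothed survival curve is evaluated
GRID_STEP = 0.1


class LifeTableError(ValueError):
    """Raised when a life table violates its structural invariants."""


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual survival probabilities for one species.

    ``ages[i]`` carries the annual survival probability ``survival[i]`` =
    P(alive at ages[i]+1 | alive at ages[i]).  When built from cohort counts
    the last observed age drops out (no following count to form a ratio).
    """

    species: str
    ages: np.ndarray
    survival: np.ndarray
    n_alive: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "survival", surv)
        if ages.ndim != 1 or surv.shape != ages.shape:
            raise LifeTableError("ages and survival must be 1-D and congruent")
        if len(ages) < 3:
            raise LifeTableError(
                f"{self.species}: need at least 3 age classes, got {len(ages)}"
            )
        if np.any(np.diff(ages) <= 0):
            raise LifeTableError(f"{self.species}: ages must be strictly increasing")
        if np.any((surv < 0) | (surv > 1)):
            raise LifeTableError(f"{self.species}: survival values must lie in [0, 1]")

    @property
    def n_ages(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class SurvivalCurve:
    """Smoothed annual-survival trajectory on a dense age grid."""

    grid: np.ndarray
    fitted: np.ndarray
    effective_df: float
    #: fitted values at the observed ages (used by the aging-rate regression
    #: when it is configured to run on smoothed rather than raw survival)
    fitted_at_ages: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("fitted survival curve contains non-finite values")


@dataclass(frozen=True)
class DemographicMetrics:
    """Per-species mortality metrics consumed by the comparative pipeline.

    ``median_lifespan`` is ``None`` when cohort survivorship never drops to
    0.5 within the observed ages; such species stay in aging-rate analyses
    but are excluded from lifespan analyses.  ``aging_rate`` is the signed
    slope (non-positive for senescing species); ``abs_aging_rate`` is its
    magnitude, the quantity that is log-transformed downstream.
    """

    species: str
    onset_age: float
    aging_rate: float
    abs_aging_rate: float
    median_lifespan: float | None
    n_ages: int


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "species": "species",
    "age": "age",
    "n_alive": "n_alive",
    "survival": "survival",
}


def read_life_table(
    path: str | Path | pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    species: str | None = None,
) -> LifeTable:
    """Read a single-species life-table CSV.

    The file must carry an age column plus either a cohort-count column
    (``n_alive``) or an annual-survival column (``survival``).  Counts are
    converted to annual survival ``s(x) = n(x+1)/n(x)``; non-increasing
    counts are enforced.
    """
    tables = read_life_tables(path, schema=schema)
    if species is not None:
        for lt in tables:
            if lt.species == species:
                return lt
        raise LifeTableError(f"species {species!r} not found in {path}")
    if len(tables) != 1:
        raise LifeTableError(
            f"expected a single species in {path}, found {len(tables)}"
        )
    return tables[0]


def read_life_tables(
    path: str | Path | pd.DataFrame, schema: Mapping[str, str] | None = None
) -> list[LifeTable]:
    """Read a (possibly long-format, multi-species) life-table CSV."""
    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    source = "" if isinstance(path, pd.DataFrame) else str(path)

    if cols["age"] not in df.columns:
        raise LifeTableError(f"missing age column {cols['age']!r}")
    has_counts = cols["n_alive"] in df.columns
    has_surv = cols["survival"] in df.columns
    if not (has_counts or has_surv):
        raise LifeTableError(
            f"need a {cols['n_alive']!r} or {cols['survival']!r} column"
        )

    if cols["species"] in df.columns:
        groups = [(str(sp), g) for sp, g in df.groupby(cols["species"], sort=True)]
    else:
        groups = [("unknown", df)]

    tables = []
    for sp, g in groups:
        g = g.sort_values(cols["age"])
        ages = g[cols["age"]].to_numpy(dtype=float)
        if has_counts and not g[cols["n_alive"]].isna().all():
            n = g[cols["n_alive"]].to_numpy(dtype=float)
            tables.append(life_table_from_counts(sp, ages, n, source=source))
        else:
            s = g[cols["survival"]].to_numpy(dtype=float)
            tables.append(LifeTable(sp, ages, s, source=source))
    return tables


def life_table_from_counts(
    species: str, ages: Sequence[float], n_alive: Sequence[float], source: str = ""
) -> LifeTable:
    """Build a :class:`LifeTable` from cohort counts, s(x) = n(x+1)/n(x)."""
    ages = np.asarray(ages, dtype=float)
    n = np.asarray(n_alive, dtype=float)
    if np.any(n < 0):
        raise LifeTableError(f"{species}: negative cohort counts")
    inc = np.nonzero(np.diff(n) > 0)[0]
    if inc.size:
        bad_age = ages[inc[0] + 1]
        raise LifeTableError(f"{species}: counts increase at age {bad_age:g}")
    # drop trailing extinct classes: survival after extinction is undefined
    alive = np.nonzero(n > 0)[0]
    last = alive[-1] if alive.size else -1
    ages, n = ages[: last + 1], n[: last + 1]
    if len(n) < 4:
        raise LifeTableError(
            f"{species}: need at least 3 age classes of survival "
            f"(4 cohort counts), got {len(n)} counts"
        )
    s = n[1:] / n[:-1]
    return LifeTable(species, ages[:-1], s, n_alive=n, source=source)


# ---------------------------------------------------------------------------
# survivorship and median lifespan
# ---------------------------------------------------------------------------


def survivorship(lt: LifeTable, from_age: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative survivorship l(x) with l(from_age) = 1.

    Returns ``(ages, l)`` where ages runs from ``from_age`` through one past
    the last survival age: ``l(x+1) = l(x) * s(x)``.
    """
    idx = np.searchsorted(lt.ages, from_age)
    if idx >= len(lt.ages) or lt.ages[idx] != from_age:
        if from_age < lt.ages[0] or from_age > lt.ages[-1]:
            raise LifeTableError(
                f"{lt.species}: from_age {from_age:g} outside table ages "
                f"[{lt.ages[0]:g}, {lt.ages[-1]:g}]"
            )
        raise LifeTableError(f"{lt.species}: from_age {from_age:g} not an age class")
    s = lt.survival[idx:]
    ages = np.concatenate([lt.ages[idx:], [lt.ages[-1] + (lt.ages[-1] - lt.ages[-2])]])
    l = np.concatenate([[1.0], np.cumprod(s)])
    return ages, l


def median_lifespan(lt: LifeTable, from_age: float = 1.0) -> float | None:
    """Age at which survivorship of a cohort initialised at ``from_age`` hits 0.5.

    Linearly interpolated between the bracketing age classes; ``None`` when
    survivorship never reaches 0.5 within the observed ages (the species is
    then dropped from lifespan analyses, mirroring how sparse field life
    tables preclude a reliable median).
    """
    ages, l = survivorship(lt, from_age=from_age)
    below = np.nonzero(l <= 0.5)[0]
    if below.size == 0:
        return None
    j = below[0]
    if l[j] == 0.5 or j == 0:
        return float(ages[j])
    a0, a1 = ages[j - 1], ages[j]
    l0, l1 = l[j - 1], l[j]
    return float(a0 + (l0 - 0.5) / (l0 - l1) * (a1 - a0))


# ---------------------------------------------------------------------------
# smoothed survival trajectory and onset of senescence
# ---------------------------------------------------------------------------


def _roughness_matrix(x: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline roughness penalty K = Dᵀ W⁻¹ D (Green & Silverman).

    The penalised criterion Σ(y−f)² + lam·∫f''² has solution
    f̂ = (I + lam·K)⁻¹ y at the knots, so trace((I + lam·K)⁻¹) is the
    smoother's effective degrees of freedom.
    """
    n = len(x)
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def _edf(K: np.ndarray, lam: float) -> float:
    n = K.shape[0]
    return float(np.trace(np.linalg.inv(np.eye(n) + lam * K)))


def _lambda_for_df(K: np.ndarray, df: float) -> float:
    """Bisect on log-lambda for the penalty weight giving the target edf."""
    lo, hi = -18.0, 18.0
    # edf is decreasing in lam: edf(lo) ~ n, edf(hi) ~ 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _edf(K, math.exp(mid)) > df:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def _penalized_spline(x: np.ndarray, y: np.ndarray, lam: float):
    """Smoothing-spline fit via the penalty matrices directly (any n >= 3).

    The solution of the penalized criterion is a natural cubic spline through
    its own fitted values at the knots, so evaluating it anywhere reduces to
    natural-cubic interpolation of (x, f̂).
    """
    from scipy.interpolate import CubicSpline

    if lam > 0:
        K = _roughness_matrix(x)
        fitted = np.linalg.solve(np.eye(len(x)) + lam * K, y)
    else:
        fitted = y
    return CubicSpline(x, fitted, bc_type="natural")


def _gcv_lambda(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Grid GCV for the penalty weight: minimize n·RSS / (n − edf)²."""
    K = _roughness_matrix(x)
    n = len(x)
    best = (0.0, float(n), -np.inf)
    for loglam in np.linspace(-18, 18, 73):
        lam = math.exp(loglam)
        A = np.linalg.inv(np.eye(n) + lam * K)
        f = A @ y
        edf = float(np.trace(A))
        rss = float(np.sum((y - f) ** 2))
        score = n * rss / max(n - edf, 1e-9) ** 2
        if best[2] == -np.inf or score < best[2]:
            best = (lam, edf, score)
    return best[0], best[1]


def _edf_from_fit(K: np.ndarray, x: np.ndarray, y: np.ndarray, fitted: np.ndarray) -> float:
    """Effective df implied by a smoothing fit, matched through its RSS."""
    rss = float(np.sum((y - fitted) ** 2))
    if rss <= 1e-14:
        return float(len(x))
    lo, hi = -18.0, 18.0  # RSS is increasing in lam
    n = len(x)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = np.linalg.solve(np.eye(n) + math.exp(mid) * K, y)
        if float(np.sum((y - f) ** 2)) < rss:
            lo = mid
        else:
            hi = mid
    return _edf(K, math.exp(0.5 * (lo + hi)))


def fit_survival_smooth(
    lt: LifeTable, df: float | None = DEFAULT_SMOOTH_DF, grid_step: float = GRID_STEP
) -> SurvivalCurve:
    """Cubic smoothing-spline fit of annual survival on age.

    With ``df=None`` (default) the smoothing level is chosen by generalized
    cross-validation, so precise life tables (large cohorts) are tracked
    closely while noisy ones are smoothed hard.  An explicit ``df``
    calibrates the smoothing parameter so the smoother matrix has that
    effective degrees of freedom (the classical GAM convention).  ``df`` is
    capped at ``n_ages``; at the cap the spline interpolates the data, and
    as ``df`` → 2 it collapses to the least-squares line.
    """
    x, y = lt.ages, lt.survival
    n = len(x)
    if df is None:
        if n >= 5:
            spline = make_smoothing_spline(x, y)  # GCV
            df_eff = _edf_from_fit(_roughness_matrix(x), x, y, spline(x))
        else:
            lam, df_eff = _gcv_lambda(x, y)
            spline = _penalized_spline(x, y, lam)
    else:
        if df < 1:
            raise ValueError(f"df must be >= 1, got {df}")
        df_eff = min(float(df), float(n))
        if df_eff >= n - 1e-9:
            lam = 0.0
        else:
            K = _roughness_matrix(x)
            lam = _lambda_for_df(K, max(df_eff, 2.0))
        spline = (
            make_smoothing_spline(x, y, lam=lam) if n >= 5 else _penalized_spline(x, y, lam)
        )
    grid = np.arange(x[0], x[-1] + grid_step / 2, grid_step)
    grid[-1] = min(grid[-1], x[-1])
    return SurvivalCurve(
        grid=grid,
        fitted=spline(grid),
        effective_df=df_eff,
        fitted_at_ages=spline(x),
    )


def onset_of_senescence(curve: SurvivalCurve, persist: float = 0.5) -> float:
    """Age at which the smoothed survival trajectory starts to decline.

    Detected as the earliest grid age at which the fitted curve enters a
    *sustained* decline: its derivative stays below half the curve's mean
    decline rate (range / age span) for at least ``persist`` years.  For a
    strictly declining curve this is the first observed age; for a curve
    rising to a peak it is the peak (up to the shoulder of the smoother);
    for a flat plateau followed by decline it is the end of the plateau.
    A relative-rate threshold rather than the bare fitted maximum is used
    because smoothing tilts flat plateaus slightly downward, which would
    otherwise pin the maximum to the first age, and because sparse terminal
    age classes can throw noisy bumps late in the curve.

    Falls back to the earliest age of the fitted maximum when no sustained
    decline exists (flat or rising curves).
    """
    grid, fitted = curve.grid, curve.fitted
    rng = float(fitted.max() - fitted.min())
    peak_first = float(grid[int(np.nonzero(fitted >= fitted.max() - 1e-9)[0][0])])
    span = float(grid[-1] - grid[0])
    if rng <= 1e-6 or span <= 0:
        return float(grid[0])
    thresh = -0.5 * rng / span
    d = np.gradient(fitted, grid)
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    w = max(1, int(round(persist / step)))
    below = d <= thresh
    for i in range(len(grid)):
        j = i + w
        if j <= len(grid) and below[i:j].all():
            return float(grid[i])
        if j > len(grid) and below[i:].all() and below[i:].size:
            return float(grid[i])
    return peak_first


def aging_rate(lt: LifeTable, onset: float, use_fitted: SurvivalCurve | None = None) -> float:
    """OLS slope of annual survival on age from the onset of senescence onward.

    Raw observed survival is regressed by default; pass the fitted curve via
    ``use_fitted`` to regress the smoothed values instead.  Consumers take
    ``log|slope|`` downstream, so a zero slope is legal here but flagged at
    assembly time.
    """
    mask = lt.ages >= onset - 1e-9
    if mask.sum() < 2:
        raise LifeTableError(
            f"{lt.species}: fewer than 2 age classes at or after onset {onset:g}"
        )
    x = lt.ages[mask]
    y = (use_fitted.fitted_at_ages if use_fitted is not None else lt.survival)[mask]
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# per-species and batch drivers
# ---------------------------------------------------------------------------


def species_metrics(
    lt: LifeTable,
    df: float | None = DEFAULT_SMOOTH_DF,
    rate_on_fitted: bool = False,
) -> DemographicMetrics:
    """Full metric extraction for one species: smooth → onset → rate → median."""
    curve = fit_survival_smooth(lt, df=df)
    onset = onset_of_senescence(curve)
    # the regression needs >= 2 points; pull the onset back if the maximum
    # sits on the last age class
    if (lt.ages >= onset - 1e-9).sum() < 2:
        onset = float(lt.ages[-2])
    rate = aging_rate(lt, onset, use_fitted=curve if rate_on_fitted else None)
    med = median_lifespan(lt)
    return DemographicMetrics(
        species=lt.species,
        onset_age=onset,
        aging_rate=rate,
        abs_aging_rate=abs(rate),
        median_lifespan=med,
        n_ages=lt.n_ages,
    )


def metrics_table(
    tables: Sequence[LifeTable],
    df: float | None = DEFAULT_SMOOTH_DF,
    rate_on_fitted: bool = False,
) -> pd.DataFrame:
    """Batch driver: one row of mortality metrics per species."""
    rows = []
    for lt in tables:
        m = species_metrics(lt, df=df, rate_on_fitted=rate_on_fitted)
        rows.append(
            {
                "species": m.species,
                "onset_age": m.onset_age,
                "aging_rate": m.aging_rate,
                "abs_aging_rate": m.abs_aging_rate,
                "median_lifespan": np.nan if m.median_lifespan is None else m.median_lifespan,
                "n_ages": m.n_ages,
            }
        )
    return pd.DataFrame(rows)
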