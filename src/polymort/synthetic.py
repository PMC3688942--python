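"""Synthetic trees, trait tables and life tables with known ground truth.

The comparative analysis rests on three inputs — per-species life tables, a
trait table (testes mass, body mass, age at first reproduction, multiple
paternity, litter size), and a dated phylogeny.  This module generates all
three under the statistical model the analysis assumes, so every stage can
be tested for parameter recovery:

* trees are Yule (pure-birth), rescaled to unit root-to-tip depth;
* continuous predictors evolve as Brownian motion on the tree; responses are
  linear in log-predictors with multivariate-normal residuals whose
  correlation follows the λ-scaled phylogenetic covariance;
* life tables realise a plateau-then-linear-decline annual-survival schedule
  with binomial demographic noise, so small cohorts show realistic
  irregularity.

The default study fixture ties both mortality metrics to the pace of life
(age at first reproduction) with NO testes-mass effect — the null that the
comparative analysis is designed to detect or reject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import LifeTable, life_table_from_counts
from .phylo import CovarianceMatrix, Phylogeny, lambda_transform, parse_newick, vcv

__all__ = [
    "TraitTruth",
    "LifeTableTruth",
    "simulate_tree",
    "simulate_brownian",
    "simulate_traits",
    "simulate_life_table",
    "make_study_fixture",
    "StudyFixture",
]

# default fixture calibration: effect sizes near the published comparative
# estimates so qualitative reproduction (pace-of-life signal, polyandry null)
# is the expected outcome
FIXTURE_SLOPE_LIFESPAN_AFR = 1.0
FIXTURE_SLOPE_LOGAGING_AFR = -1.2
FIXTURE_RESID_SD = 0.35
# residual phylogenetic correlation of the mortality metrics after the
# pace-of-life effect: zero, i.e. all tree signal in the mortality metrics is
# inherited through the pace of life; fitted lambdas of retained
# pace-of-life models in this literature are near zero
FIXTURE_LAMBDA = 0.0
FIXTURE_COHORT = 200_000


@dataclass(frozen=True)
class TraitTruth:
    """Generative truth for a simulated trait regression."""

    beta: tuple[float, ...]  # slope per predictor (intercept excluded)
    lambda_true: float
    sigma2: float
    n_tips: int
    seed: int
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")


@dataclass(frozen=True)
class LifeTableTruth:
    """Generative truth for a plateau-then-decline survival schedule."""

    s0: float  # plateau annual survival
    onset_true: float  # age (yr) at which survival starts to decline
    slope_true: float  # per-year decline in annual survival (<= 0; 0 = no senescence)
    max_age: float
    cohort0: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.s0 <= 1.0:
            raise ValueError("s0 must be in (0, 1]")
        if self.slope_true > 0:
            raise ValueError("slope_true cannot be positive")
        if self.s0 + self.slope_true * (self.max_age - self.onset_true) < -1e-9:
            raise ValueError("survival schedule goes negative before max_age")

    def survival_at(self, age: np.ndarray) -> np.ndarray:
        """Noise-free annual survival schedule p(x)."""
        age = np.asarray(age, dtype=float)
        p = np.where(
            age < self.onset_true,
            self.s0,
            self.s0 + self.slope_true * (age - self.onset_true),
        )
        return np.clip(p, 0.0, 1.0)

    def analytic_median(self) -> float:
        """Exact age at which true survivorship from age 1 crosses 0.5."""
        ages = np.arange(1.0, self.max_age + 1)
        p = self.survival_at(ages)
        l = np.concatenate([[1.0], np.cumprod(p)])
        grid = np.concatenate([ages, [self.max_age + 1]])
        below = np.nonzero(l <= 0.5)[0]
        if below.size == 0:
            raise ValueError("true survivorship never reaches 0.5")
        j = below[0]
        if l[j] == 0.5 or j == 0:
            return float(grid[j])
        return float(grid[j - 1] + (l[j - 1] - 0.5) / (l[j - 1] - l[j]))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Yule (pure-birth) tree with unit root-to-tip depth, tips sp_1..sp_n.

    Lineages split at unit rate; waiting times are exponential with rate
    equal to the current lineage count and the splitting lineage is chosen
    uniformly.  The tree is ultrametric by construction and rescaled so
    every tip sits at depth 1.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    # crown tree: start at the root split with two lineages at time 0
    def leaf() -> dict:
        return {"children": [], "t_split": None, "born": None}

    root = {"children": [leaf(), leaf()], "t_split": 0.0, "born": 0.0}
    for k in root["children"]:
        k["born"] = 0.0
    tips = list(root["children"])
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(int(rng.integers(len(tips))))
        node["t_split"] = t
        node["children"] = [leaf(), leaf()]
        for k in node["children"]:
            k["born"] = t
        tips.extend(node["children"])
    t_end = t + rng.exponential(1.0 / len(tips))

    labels = iter(f"sp_{i}" for i in range(1, n_tips + 1))

    def newick(node: dict) -> str:
        if not node["children"]:
            return f"{next(labels)}:{(t_end - node['born']) / t_end:.10f}"
        inner = ",".join(newick(k) for k in node["children"])
        return f"({inner}):{(node['t_split'] - node['born']) / t_end:.10f}"

    s = f"({','.join(newick(k) for k in root['children'])});"
    return parse_newick(s)


def simulate_brownian(
    phy: Phylogeny, rng: np.random.Generator, rate: float = 1.0, root_value: float = 0.0
) -> pd.Series:
    """One Brownian-motion trait realised at the tips (variance = rate·depth)."""
    values: dict[int, float] = {}
    tree = phy.tree
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            values[id(node)] = root_value
        else:
            parent = values[id(node.parent_node)]
            bl = node.edge.length or 0.0
            values[id(node)] = parent + rng.normal(0.0, np.sqrt(rate * bl))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="bm")


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_traits(
    phy: Phylogeny,
    truth: TraitTruth,
    predictor_names: tuple[str, ...] | None = None,
    response_name: str = "y",
) -> pd.DataFrame:
    """Simulate predictors (Brownian) and a response y = Xβ + ε on the tree.

    ε ~ N(0, σ²·V(λ_true)) with V the Brownian covariance of the tree.  The
    returned columns are exponentiated, so taking logs downstream recovers
    the linear model exactly.
    """
    if truth.n_tips != phy.n_tips:
        raise ValueError("truth.n_tips must equal the tree's tip count")
    rng = np.random.default_rng(truth.seed)
    names = predictor_names or tuple(f"x{i + 1}" for i in range(len(truth.beta)))
    if len(names) != len(truth.beta):
        raise ValueError("one predictor name per slope")
    preds = {nm: simulate_brownian(phy, rng) for nm in names}
    taxa = list(preds[names[0]].index) if names else [
        lf.taxon.label for lf in phy.tree.leaf_node_iter()
    ]
    X = np.column_stack([preds[nm].loc[taxa].to_numpy() for nm in names]) if names else np.zeros((len(taxa), 0))
    cov = lambda_transform(vcv(phy).reorder(taxa), truth.lambda_true)
    L = np.linalg.cholesky(cov.V + 1e-12 * np.eye(len(taxa)))
    eps = np.sqrt(truth.sigma2) * (L @ rng.standard_normal(len(taxa)))
    y = truth.intercept + X @ np.asarray(truth.beta) + eps
    out = pd.DataFrame({"species": taxa})
    for j, nm in enumerate(names):
        out[nm] = np.exp(X[:, j])
    out[response_name] = np.exp(y)
    return out


# ---------------------------------------------------------------------------
# life tables
# ---------------------------------------------------------------------------


def simulate_life_table(
    truth: LifeTableTruth, species: str = "synthetic", min_count: int = 2
) -> LifeTable:
    """Realise cohort counts n(x+1) ~ Binomial(n(x), p(x)) from n(1) = cohort0.

    The table ends once fewer than ``min_count`` individuals remain (an age
    class followed by a single survivor yields an annual-survival ratio of
    exactly 0 or 1 — pure noise — and published life tables likewise stop
    when the cohort is effectively exhausted).  Trailing extinct classes are
    truncated in any case.
    """
    rng = np.random.default_rng(truth.seed)
    ages = np.arange(1.0, np.floor(truth.max_age) + 1)
    p = truth.survival_at(ages)
    counts = [truth.cohort0]
    for px in p[:-1]:
        nxt = int(rng.binomial(counts[-1], px))
        if nxt < min_count:
            break
        counts.append(nxt)
    n = np.array(counts, dtype=float)
    return life_table_from_counts(species, ages[: len(n)], n, source="synthetic")


# ---------------------------------------------------------------------------
# the full study fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyFixture:
    """One complete synthetic comparative study with its generative truth."""

    tree: Phylogeny
    traits: pd.DataFrame
    life_tables: list[LifeTable]
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "traits": out / "traits.csv",
            "life_tables": out / "life_tables.csv",
        }
        self.tree.write_newick(paths["tree"])
        self.traits.to_csv(paths["traits"], index=False)
        rows = []
        for lt in self.life_tables:
            assert lt.n_alive is not None
            n_ages = np.concatenate([lt.ages, [lt.ages[-1] + 1]])
            for a, n in zip(n_ages, lt.n_alive):
                rows.append({"species": lt.species, "age": a, "n_alive": int(n)})
        pd.DataFrame(rows).to_csv(paths["life_tables"], index=False)
        return paths


def make_study_fixture(
    n_species: int = 51,
    seed: int = 42,
    slope_lifespan_afr: float = FIXTURE_SLOPE_LIFESPAN_AFR,
    slope_logaging_afr: float = FIXTURE_SLOPE_LOGAGING_AFR,
    resid_sd: float = FIXTURE_RESID_SD,
    lambda_true: float = FIXTURE_LAMBDA,
    cohort0: int = FIXTURE_COHORT,
) -> StudyFixture:
    """Generate a full synthetic comparative study.

    Age at first reproduction (AFR), body mass and testes mass evolve on a
    Yule tree; testes mass tracks body mass allometrically (slope ~0.7 on
    the log scale) but is independent of AFR, so the fixture satisfies the
    collinearity precondition of the analysis.  True log median lifespan and
    log |aging rate| are linear in log AFR with phylogenetically correlated
    residuals and NO testes-mass effect; each species' life table is then
    constructed so its analytic metrics match those truths, and realised
    with binomial noise.
    """
    if n_species < 10:
        raise ValueError("fixture needs at least 10 species")
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, seed=int(rng.integers(2**31 - 1)))
    taxa = [lf.taxon.label for lf in tree.tree.leaf_node_iter()]
    n = len(taxa)

    cov = vcv(tree).reorder(taxa)
    Llam = np.linalg.cholesky(
        lambda_transform(cov, lambda_true).V + 1e-12 * np.eye(n)
    )

    def phylo_noise(sd: float) -> np.ndarray:
        return sd * (Llam @ rng.standard_normal(n))

    # log-scale traits: AFR around ~2.5 yr, body mass around ~50 kg (log-g),
    # testes mass allometric on body mass with independent deviation
    log_afr = 1.0 + 0.45 * simulate_brownian(tree, rng).loc[taxa].to_numpy()
    log_bm = 10.8 + 1.6 * simulate_brownian(tree, rng).loc[taxa].to_numpy()
    log_tm = -4.6 + 0.7 * log_bm + phylo_noise(0.5)

    log_median = 1.1 + slope_lifespan_afr * log_afr + phylo_noise(resid_sd)
    log_absrate = -2.3 + slope_logaging_afr * log_afr + phylo_noise(resid_sd)
    # multiple paternity and litter size: independent of the mortality truths
    mp = np.clip(rng.uniform(5, 95, size=n), 0.5, 100.0)
    litter = np.clip(np.round(np.exp(0.5 + 0.4 * rng.standard_normal(n))), 1, 12)

    # feasibility floors/caps only (onset >= 2 needs median >= ~2.1; annual
    # survival cannot decline faster than it starts); they should almost
    # never bind so the log-linear generative relations stay exact
    median_target = np.clip(np.exp(log_median), 1.9, None)
    rate_target = -np.clip(np.exp(log_absrate), 4e-3, 0.25)

    orders = np.where(
        np.arange(n) % 3 == 0, "Artiodactyla", np.where(np.arange(n) % 3 == 1, "Carnivora", "Primates")
    )

    life_tables = []
    truths = []
    for i, sp in enumerate(taxa):
        truth = _life_truth_for_targets(
            median=float(median_target[i]),
            slope=float(rate_target[i]),
            cohort0=cohort0,
            seed=int(rng.integers(2**31 - 1)),
        )
        truths.append(truth)
        life_tables.append(simulate_life_table(truth, species=sp))

    traits = pd.DataFrame(
        {
            "species": taxa,
            "testes_mass_g": np.exp(log_tm),
            "body_mass_g": np.exp(log_bm),
            "afr_yr": np.exp(log_afr),
            "mp_percent": mp,
            "litter_size": litter,
            "order": orders,
        }
    )
    truth = {
        "slope_lifespan_afr": slope_lifespan_afr,
        "slope_logaging_afr": slope_logaging_afr,
        "lambda_true": lambda_true,
        "resid_sd": resid_sd,
        "median_target": median_target,
        "rate_target": rate_target,
        "life_table_truths": truths,
        "seed": seed,
    }
    return StudyFixture(tree=tree, traits=traits, life_tables=life_tables, truth=truth)


def _life_truth_for_targets(
    median: float, slope: float, cohort0: int, seed: int
) -> LifeTableTruth:
    """Build a plateau-then-decline schedule whose analytic median lifespan
    equals ``median`` and whose post-onset slope equals ``slope``.

    The onset is placed at roughly 60% of the target median (senescence
    starts before half the cohort is gone) and the plateau survival s0 is
    solved by bisection.
    """
    onset = max(2.0, round(0.6 * median))
    median = max(median, 1.9)

    def solve_s0(slope_: float) -> float:
        # the analytic median is increasing in s0; bisect
        lo, hi = 0.45, 0.999

        def median_for(s0: float) -> float:
            t = LifeTableTruth(
                s0=s0, onset_true=onset, slope_true=slope_,
                max_age=onset + s0 / (-slope_), cohort0=cohort0, seed=seed,
            )
            try:
                return t.analytic_median()
            except ValueError:
                return np.inf

        if median_for(lo) > median:
            return lo
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if median_for(mid) < median:
                lo = mid
            else:
                hi = mid
        return min(0.5 * (lo + hi), 0.999)

    s0 = solve_s0(slope)
    # the decline must span at least ~3 age classes or the realised table is
    # too short to regress; cap the decline rate and re-solve the plateau
    if s0 / (-slope) < 3.0:
        slope = -s0 / 3.0
        s0 = solve_s0(slope)
    max_age = float(np.floor(onset + s0 / (-slope)))
    return LifeTableTruth(
        s0=s0, onset_true=onset, slope_true=slope,
        max_age=max_age, cohort0=cohort0, seed=seed,
    )
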