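"""Comparative-analysis pipeline: dataset assembly, candidate model sets,
block-wise model selection and headline regressions.

The analysis asks whether two sperm-competition proxies — relative testes
mass (always accompanied by male body mass as a covariate, never as a
residual) and the percentage of multiply-sired litters — predict female
mortality metrics (median lifespan, aging rate) across mammals once the
pace of life (age at first reproduction) is controlled for.  Candidate
model sets are compared by AICc within taxonomic blocks, and a handful of
headline bivariate regressions summarise the signal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import pgls
from .demography import metrics_table
from .pgls import ModelComparison, ModelSpec, PglsFit, profile_lambda
from .phylo import Phylogeny, covariance_for, normalize_label, prune

__all__ = [
    "ComparativeDataset",
    "AnalysisReport",
    "assemble",
    "table2_models",
    "table4_models",
    "run_block",
    "collinearity_check",
    "headline_fits",
    "full_report",
    "sensitivity_rerun",
]

log = logging.getLogger("polymort")

# canonical analysis-variable names (log scale throughout; natural logs)
RESPONSES = ("log_median_lifespan", "log_abs_aging_rate")
AFR, TM, BM, MP, LS = ("log_afr", "log_testes_mass", "log_body_mass", "log_mp", "log_litter_size")

_TRAIT_COLUMNS = {
    "testes_mass_g": TM,
    "body_mass_g": BM,
    "afr_yr": AFR,
    "mp_percent": MP,
    "litter_size": LS,
}


@dataclass(frozen=True)
class ComparativeDataset:
    """Merged per-species analysis table, log-transformed, tree-matched.

    ``data`` has one row per species with the log-scale modelling variables;
    ``log_median_lifespan`` is NaN for species whose life table never drops
    to half the cohort (they stay in aging-rate analyses only), and species
    with an exactly zero aging rate are excluded from log analyses and
    listed in ``flagged``.
    """

    data: pd.DataFrame
    tree: Phylogeny
    flagged: tuple[str, ...] = ()
    dropped: tuple[str, ...] = ()

    @property
    def n_species(self) -> int:
        return len(self.data)

    def subset(self, order: str | None) -> pd.DataFrame:
        if order is None or order == "all":
            return self.data
        return self.data[self.data["order"] == order]


@dataclass
class AnalysisReport:
    """Model comparisons per (response, subset) block plus headline fits."""

    comparisons: dict[tuple[str, str], ModelComparison] = field(default_factory=dict)
    headline: dict[str, PglsFit] = field(default_factory=dict)
    n_by_block: dict[tuple[str, str], int] = field(default_factory=dict)

    def selected_labels(self) -> dict[tuple[str, str], str]:
        return {
            key: cmp.table.loc[cmp.selected, "label"]
            for key, cmp in self.comparisons.items()
        }


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble(
    metrics: pd.DataFrame,
    traits: pd.DataFrame | str | Path,
    tree: Phylogeny,
) -> ComparativeDataset:
    """Inner-join mortality metrics with the trait table, log-transform,
    and prune the tree to the joined species set.

    Natural logs throughout; the aging rate enters as log|slope|.  Species
    present in only one input are dropped with a log message; an empty join
    is an error.
    """
    if not isinstance(traits, pd.DataFrame):
        traits = pd.read_csv(traits)
    m = metrics.copy()
    t = traits.copy()
    m["_key"] = m["species"].map(normalize_label)
    t["_key"] = t["species"].map(normalize_label)
    tree_keys = {normalize_label(l) for l in tree.tip_labels}

    merged = m.merge(t.drop(columns=["species"]), on="_key", how="inner")
    names_by_key = dict(zip(m["_key"], m["species"]))
    names_by_key.update(zip(t["_key"], t["species"]))
    only_m = sorted(names_by_key[k] for k in set(m["_key"]) - set(t["_key"]))
    only_t = sorted(names_by_key[k] for k in set(t["_key"]) - set(m["_key"]))
    no_tree = sorted(names_by_key[k] for k in set(merged["_key"]) - tree_keys)
    for key, where in ((only_m, "trait table"), (only_t, "metrics"), (no_tree, "tree")):
        if key:
            log.info("dropping species missing from %s: %s", where, key)
    merged = merged[merged["_key"].isin(tree_keys)]
    if merged.empty:
        raise ValueError("no species shared between metrics, traits and tree")

    flagged = tuple(merged.loc[merged["abs_aging_rate"] <= 0, "species"])
    if flagged:
        log.warning("zero aging rate, excluded from log analyses: %s", flagged)
    merged = merged[merged["abs_aging_rate"] > 0]

    for raw, name in _TRAIT_COLUMNS.items():
        if raw in merged.columns:
            vals = merged[raw].to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError(f"{raw} must be positive to log-transform")
            merged[name] = np.log(vals)
    merged["log_abs_aging_rate"] = np.log(merged["abs_aging_rate"].to_numpy(dtype=float))
    med = merged["median_lifespan"].to_numpy(dtype=float)
    merged["log_median_lifespan"] = np.where(med > 0, np.log(np.where(med > 0, med, 1)), np.nan)

    keep_cols = ["species", "order"] if "order" in merged.columns else ["species"]
    keep_cols += [c for c in merged.columns if c.startswith("log_")]
    data = merged[keep_cols].sort_values("species").reset_index(drop=True)
    pruned = prune(tree, data["species"])
    return ComparativeDataset(
        data=data,
        tree=pruned,
        flagged=flagged,
        dropped=tuple(only_m + only_t + no_tree),
    )


# ---------------------------------------------------------------------------
# candidate model sets
# ---------------------------------------------------------------------------


def table2_models(response: str) -> list[ModelSpec]:
    """Testes-mass candidate set (six models; body mass accompanies testes
    mass in every model that includes it):

    Constant; AFR; BM; TM+BM; AFR+TM+BM; AFR×TM+BM.
    """
    return [
        ModelSpec(response, (), label="Constant"),
        ModelSpec(response, (AFR,), label="Age at first reproduction"),
        ModelSpec(response, (BM,), label="Body mass"),
        ModelSpec(response, (TM, BM), label="Testes mass+Body mass"),
        ModelSpec(
            response, (AFR, TM, BM), label="Age at first reproduction+Testes mass+Body mass"
        ),
        ModelSpec(
            response,
            (AFR, TM, BM),
            interactions=((AFR, TM),),
            label="Age at first reproduction*Testes mass+Body mass",
        ),
    ]


def table4_models(response: str) -> list[ModelSpec]:
    """Multiple-paternity candidate set (nine models; litter size enters as
    a detectability covariate but the set follows the published layout, so
    MP also appears alone):

    Constant; AFR; MP; LS; MP+LS; MP×LS; AFR+MP; AFR+MP+LS; AFR+MP×LS.
    """
    return [
        ModelSpec(response, (), label="Constant"),
        ModelSpec(response, (AFR,), label="Age at first reproduction"),
        ModelSpec(response, (MP,), label="MP"),
        ModelSpec(response, (LS,), label="LS"),
        ModelSpec(response, (MP, LS), label="MP+LS"),
        ModelSpec(response, (MP, LS), interactions=((MP, LS),), label="MP*LS"),
        ModelSpec(response, (AFR, MP), label="Age at first reproduction+MP"),
        ModelSpec(response, (AFR, MP, LS), label="Age at first reproduction+MP+LS"),
        ModelSpec(
            response,
            (AFR, MP, LS),
            interactions=((MP, LS),),
            label="Age at first reproduction+MP*LS",
        ),
    ]


# ---------------------------------------------------------------------------
# model fitting blocks
# ---------------------------------------------------------------------------


def _fit_spec(
    df: pd.DataFrame, tree: Phylogeny, spec: ModelSpec
) -> PglsFit:
    needed = [spec.response, *spec.terms]
    sub = df.dropna(subset=needed)
    cov = covariance_for(tree, list(sub["species"]))
    y = sub[spec.response].to_numpy(dtype=float)
    X, names = spec.design_matrix(sub)
    return profile_lambda(y, X, cov, spec=spec, term_names=names)


def run_block(
    ds: ComparativeDataset,
    response: str,
    models: Sequence[ModelSpec],
    subset: str | None = None,
    threshold: float = pgls.AICC_THRESHOLD,
) -> ModelComparison | None:
    """Fit one candidate set on one taxonomic subset and rank by AICc.

    Every model in the block is fitted on the same species (rows complete
    for the union of the block's variables), so the AICc values are
    comparable.  Returns ``None`` with a warning when the subset is too
    small for the largest model.
    """
    df = ds.subset(subset)
    all_vars = {response} | {t for m in models for t in m.terms}
    df = df.dropna(subset=sorted(all_vars))
    max_k = max(m.k for m in models)
    if len(df) <= max_k + 1:
        warnings.warn(
            f"subset {subset or 'all'!r} has n={len(df)} <= max k+1={max_k + 1}; "
            "block skipped"
        )
        return None
    fits = [_fit_spec(df, ds.tree, m) for m in models]
    return pgls.compare_models(fits, threshold=threshold)


def collinearity_check(ds: ComparativeDataset) -> dict[str, PglsFit]:
    """Pace-of-life vs polyandry-proxy screens run before the main models:
    AFR ~ TM + BM (relative testes mass) and AFR ~ MP."""
    out = {
        "afr~tm+bm": _fit_spec(
            ds.data, ds.tree, ModelSpec(AFR, (TM, BM), label="AFR ~ Testes mass+Body mass")
        )
    }
    if MP in ds.data.columns and ds.data[MP].notna().sum() >= 5:
        out["afr~mp"] = _fit_spec(
            ds.data, ds.tree, ModelSpec(AFR, (MP,), label="AFR ~ MP")
        )
    return out


def headline_fits(ds: ComparativeDataset, allometry_pgls: bool = True) -> dict[str, PglsFit]:
    """The bivariate summary regressions reported alongside the model sets:
    lifespan ~ AFR, log|aging| ~ AFR, lifespan ~ aging, the testes–body
    allometry, and the collinearity screens."""
    d = ds.data
    fits = {
        "lifespan~afr": _fit_spec(d, ds.tree, ModelSpec(RESPONSES[0], (AFR,))),
        "aging~afr": _fit_spec(d, ds.tree, ModelSpec(RESPONSES[1], (AFR,))),
        "lifespan~aging": _fit_spec(d, ds.tree, ModelSpec(RESPONSES[0], (RESPONSES[1],))),
    }
    allo_spec = ModelSpec(TM, (BM,), label="Testes mass ~ Body mass")
    if allometry_pgls:
        fits["testes~body"] = _fit_spec(d, ds.tree, allo_spec)
    else:
        sub = d.dropna(subset=[TM, BM])
        y = sub[TM].to_numpy(float)
        X, names = allo_spec.design_matrix(sub)
        from .phylo import CovarianceMatrix

        eye = CovarianceMatrix(tuple(sub["species"]), np.eye(len(sub)))
        res = pgls.gls_fit(y, X, eye)
        fits["testes~body"] = PglsFit(
            beta=res.beta, se=res.se, t_stat=res.t_stat, p_value=res.p_value,
            sigma2=res.sigma2, lambda_hat=0.0, logLik=res.logLik,
            k=res.p + pgls.EXTRA_PARAMS, n=res.n,
            aicc=pgls.aicc(res.logLik, res.p + pgls.EXTRA_PARAMS, res.n),
            r2_adj=math.nan, term_names=tuple(names), spec=allo_spec,
        )
    fits.update(collinearity_check(ds))
    return fits


def full_report(
    ds: ComparativeDataset,
    subsets: Sequence[str | None] = (None, "Artiodactyla", "Carnivora"),
    threshold: float = pgls.AICC_THRESHOLD,
    with_mp_block: bool = True,
) -> AnalysisReport:
    """Run every (response × subset) testes-mass block, the multiple-
    paternity blocks on the species with MP data, and the headline fits."""
    report = AnalysisReport()
    for response in RESPONSES:
        for subset in subsets:
            key = (response, subset or "all")
            cmp = run_block(ds, response, table2_models(response), subset=subset, threshold=threshold)
            if cmp is not None:
                report.comparisons[key] = cmp
                report.n_by_block[key] = int(cmp.fits[0].n)
        if with_mp_block and MP in ds.data.columns:
            cmp = run_block(ds, response, table4_models(response), subset=None, threshold=threshold)
            if cmp is not None:
                report.comparisons[(response, "mp")] = cmp
                report.n_by_block[(response, "mp")] = int(cmp.fits[0].n)
    report.headline = headline_fits(ds)
    return report


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------


def sensitivity_rerun(
    ds: ComparativeDataset,
    drop: Sequence[str] = (),
    substitute: Sequence[tuple[str, str, float]] = (),
    subsets: Sequence[str | None] = (None,),
) -> tuple[AnalysisReport, pd.DataFrame]:
    """Re-run the report after dropping species and/or substituting trait
    values, and diff the selected models and headline slopes.

    ``substitute`` entries are (species, log-scale column, new raw value);
    the value is logged before insertion.  Unknown species are an error.
    """
    data = ds.data.copy()
    keys = {normalize_label(s): i for s, i in zip(data["species"], data.index)}
    for sp in drop:
        if normalize_label(sp) not in keys:
            raise KeyError(f"unknown species {sp!r}")
    for sp, col, _ in substitute:
        if normalize_label(sp) not in keys:
            raise KeyError(f"unknown species {sp!r}")
        if col not in data.columns:
            raise KeyError(f"unknown column {col!r}")
    drop_idx = [keys[normalize_label(sp)] for sp in drop]
    data = data.drop(index=drop_idx)
    for sp, col, value in substitute:
        data.loc[keys[normalize_label(sp)], col] = (
            np.log(value) if col.startswith("log_") else value
        )
    mod = ComparativeDataset(
        data=data.reset_index(drop=True),
        tree=prune(ds.tree, data["species"]),
        flagged=ds.flagged,
        dropped=ds.dropped,
    )
    base = full_report(ds, subsets=subsets)
    new = full_report(mod, subsets=subsets)
    rows = []
    for key in base.comparisons:
        if key not in new.comparisons:
            continue
        b, n_ = base.comparisons[key], new.comparisons[key]
        rows.append(
            {
                "block": f"{key[0]}|{key[1]}",
                "selected_before": b.table.loc[b.selected, "label"],
                "selected_after": n_.table.loc[n_.selected, "label"],
                "changed": b.selected != n_.selected,
            }
        )
    for name in base.headline:
        if name not in new.headline:
            continue
        rows.append(
            {
                "block": f"headline:{name}",
                "selected_before": f"slope={base.headline[name].beta[-1]:.3f}",
                "selected_after": f"slope={new.headline[name].beta[-1]:.3f}",
                "changed": not np.isclose(
                    base.headline[name].beta[-1], new.headline[name].beta[-1]
                ),
            }
        )
    return new, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """One TSV per comparison block plus a headline-fit summary TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (response, subset), cmp in report.comparisons.items():
        name = f"comparison_{response}_{subset}.tsv".replace("|", "_")
        cmp.table.to_csv(out / name, sep="\t", index=False, float_format="%.4f")
    rows = []
    for name, fit in report.headline.items():
        rows.append(
            {
                "fit": name,
                "n": fit.n,
                "lambda": fit.lambda_hat,
                "r2_adj": fit.r2_adj,
                **{
                    f"{t}": f"{b:.4f}±{s:.4f} (t={tv:.2f}, p={pv:.4f})"
                    for t, b, s, tv, pv in zip(
                        fit.term_names, fit.beta, fit.se, fit.t_stat, fit.p_value
                    )
                    if t != "Intercept"
                },
            }
        )
    pd.DataFrame(rows).to_csv(out / "headline_fits.tsv", sep="\t", index=False)


def run_metrics(
    life_tables_path: str | Path, df: float | None = None
) -> pd.DataFrame:
    """Life-table file(s) → per-species metrics table (batch CLI entry)."""
    from .demography import read_life_tables

    p = Path(life_tables_path)
    tables = []
    if p.is_dir():
        for f in sorted(p.glob("*.csv")):
            tables.extend(read_life_tables(f))
    else:
        tables.extend(read_life_tables(p))
    return metrics_table(tables, df=df)
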