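"""End-to-end orchestration: inventory tables in, run report out.

Stages run in dependency order — biomass, diversity, block PCA, the path
model, random-forest importance, and the bivariate layer — and every
stage's table is written as CSV next to a JSON report carrying the seed,
config hash and headline numbers, so a run is regenerable bit-identically
from the same inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, diversity, importance, ordination, pathmodel, stats
from .config import RunConfig, run_metadata
from .io import (
    SOIL_COLUMNS,
    TRAIT_COLUMNS,
    CommunityDataset,
    validate_dataset,
    write_table,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunReport:
    """Everything a run produced, plus where it was written."""

    metadata: dict
    outputs: dict[str, str]
    headline: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": REPORT_SCHEMA_VERSION,
                "metadata": self.metadata,
                "outputs": self.outputs,
                "headline": self.headline,
            },
            indent=2,
            default=float,
        )


def assemble_model_table(
    dataset: CommunityDataset,
    cfg: RunConfig,
    biomass: pd.DataFrame,
    div: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, ordination.PCAResult, ordination.PCAResult]:
    """Plot x (soil, FD, SR, CWM, AGB) table for the path model.

    Soil chemistry and the 15 CWM traits are each compressed to their
    first principal component (parallel analysis logged via ``retained``).
    """
    soil_pca = ordination.compress_block(
        dataset.soil[SOIL_COLUMNS],
        n_sim=cfg.parallel_n_sim,
        criterion=cfg.parallel_criterion,
        rng=rng,
        scale=cfg.pca_scale,
    )
    cwm_cols = [f"cwm_{t}" for t in TRAIT_COLUMNS]
    cwm_pca = ordination.compress_block(
        div[cwm_cols],
        n_sim=cfg.parallel_n_sim,
        criterion=cfg.parallel_criterion,
        rng=rng,
        scale=cfg.pca_scale,
    )
    table = pd.DataFrame(
        {
            "soil": soil_pca.scores["PC1"],
            "FD": div["fdis"],
            "SR": div["richness"].astype(float),
            "CWM": cwm_pca.scores["PC1"],
            "AGB": biomass["agb_per_area"],
        }
    )
    return table, soil_pca, cwm_pca


def run_pipeline(
    dataset: CommunityDataset,
    allometric_params: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
) -> RunReport:
    """Run every stage on a validated dataset and write all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    outputs: dict[str, str] = {}

    biomass = allometry.plot_agb_table(dataset.inventory, allometric_params, cfg)
    write_table(biomass, out / "biomass.csv", index=True)
    outputs["biomass"] = str(out / "biomass.csv")

    div = diversity.diversity_table(dataset, cfg)
    write_table(div, out / "diversity.csv", index=True)
    outputs["diversity"] = str(out / "diversity.csv")

    table, soil_pca, cwm_pca = assemble_model_table(
        dataset, cfg, biomass, div, rng
    )
    write_table(table, out / "model_table.csv", index=True)
    outputs["model_table"] = str(out / "model_table.csv")
    for name, block in (("soil", soil_pca), ("cwm", cwm_pca)):
        summary = block.loadings.copy()
        summary.loc["explained_pct"] = block.explained_pct
        write_table(summary, out / f"pca_{name}.csv", index=True)
        outputs[f"pca_{name}"] = str(out / f"pca_{name}.csv")

    spec = pathmodel.PathModelSpec.from_strings(cfg.sem_paths)
    fit = pathmodel.fit(spec, table, standardized=True)
    coef = fit.coefficient_table()
    write_table(coef, out / "sem_paths.csv")
    outputs["sem_paths"] = str(out / "sem_paths.csv")
    effects = pathmodel.decompose_fit(fit)
    write_table(effects, out / "sem_effects.csv")
    outputs["sem_effects"] = str(out / "sem_effects.csv")

    rf_settings = importance.ForestSettings(
        n_trees=cfg.rf_n_trees,
        mtry=cfg.rf_mtry,
        min_leaf=cfg.rf_min_leaf,
        n_perm=cfg.rf_n_perm,
    )
    cwm_cols = [f"cwm_{t}" for t in TRAIT_COLUMNS]
    rf = importance.permutation_significance(
        div[cwm_cols].rename(columns=lambda c: c.removeprefix("cwm_")),
        biomass["agb_per_area"],
        rf_settings,
        rng,
    )
    rf_table = rf.table()
    write_table(rf_table, out / "rf_importance.csv", index=True)
    outputs["rf_importance"] = str(out / "rf_importance.csv")

    bivariate = []
    for predictor in ("FD", "SR", "CWM", "soil"):
        reg = stats.ols(table[predictor], table["AGB"])
        bivariate.append(
            {
                "response": "AGB",
                "predictor": predictor,
                "slope": reg.slope,
                "r2": reg.r2,
                "f_stat": reg.f_stat,
                "p_value": reg.p_value,
                "n": reg.n,
            }
        )
    bivariate = pd.DataFrame(bivariate)
    write_table(bivariate, out / "bivariate.csv")
    outputs["bivariate"] = str(out / "bivariate.csv")

    rounding = cfg.rounding
    headline = {
        "path_coefficients": {
            f"{s}->{t}": round(fit.beta[(s, t)], rounding) for s, t in spec.paths
        },
        "fit_indices": {
            "chi2": round(fit.chi2, 3),
            "df": fit.df,
            "p": round(fit.p_value, 3),
            "gfi": round(fit.gfi, 3),
            "cfi": round(fit.cfi, 3),
            "srmr": round(fit.srmr, 3),
            "aic_chi2": round(fit.aic_chi2, 2),
            "aic_loglik": round(fit.aic_loglik, 2),
        },
        "r2": {k: round(v, rounding) for k, v in fit.r2.items()},
        "soil_pc1_pct": round(float(soil_pca.explained_pct[0]), 1),
        "soil_axes_retained": soil_pca.retained,
        "cwm_pc1_pct": round(float(cwm_pca.explained_pct[0]), 1),
        "cwm_axes_retained": cwm_pca.retained,
        "rf_top_traits": rf_table.head(5).index.tolist(),
        "rf_variance_explained": round(float(rf.variance_explained), 3),
    }
    report = RunReport(
        metadata=run_metadata(cfg), outputs=outputs, headline=headline
    )
    (out / "report.json").write_text(report.to_json())
    return report


def pipeline_from_tables(
    inventory: pd.DataFrame,
    traits: pd.DataFrame,
    soil: pd.DataFrame,
    allometric_params: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
) -> RunReport:
    """Validate raw tables, then run the full pipeline."""
    dataset = validate_dataset(inventory, traits, soil, cfg)
    return run_pipeline(dataset, allometric_params, cfg, out_dir)
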