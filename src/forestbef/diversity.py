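"""Community-weighted means and functional dispersion.

Three per-plot quantities link community composition to function:

* **CWM** — the abundance-weighted mean of a trait, ``sum(p_i * T_i)``;
  the mass-ratio proxy.
* **single-trait dispersion** — ``sum(p_i * |T_i - CWM|) / sum(|T_i - CWM|)``,
  a bounded [0, 1] spread of one trait around its community mean. For equal
  abundances it equals 1/n regardless of the trait values. When every
  present species shares the trait value (or only one species is present)
  the 0/0 case is defined as 0.
* **FDis** — multi-trait functional dispersion: the abundance-weighted mean
  Euclidean distance of species to the abundance-weighted centroid in
  (optionally z-scored) trait space. Traits are standardised across the
  species pool by default because the 15 traits carry incommensurable
  units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ValidationError
from .io import TRAIT_COLUMNS, CommunityDataset


@dataclass
class DiversityResult:
    """Per-plot diversity summary: CWMs, single-trait dispersion, FDis."""

    plot_id: str
    cwm: pd.Series          # one value per trait
    fd_single: pd.Series    # one value per trait, in [0, 1]
    fdis: float
    centroid: np.ndarray    # weighted centroid in (standardised) trait space
    z: pd.Series            # per-species distance to centroid
    richness: int


def cwm(p: np.ndarray, trait: np.ndarray) -> float:
    """Abundance-weighted mean trait value; lies in [min T, max T]."""
    p = np.asarray(p, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if np.isnan(trait[p > 0]).any():
        raise ValidationError("trait missing for a species present in community")
    return float(p @ trait)


def fd_single(p: np.ndarray, trait: np.ndarray) -> float:
    """Single-trait dispersion in [0, 1]; 0 when all present traits coincide."""
    p = np.asarray(p, dtype=float)
    trait = np.asarray(trait, dtype=float)
    m = cwm(p, trait)
    dev = np.abs(trait - m)
    denom = dev.sum()
    if denom == 0.0:
        return 0.0
    return float((p @ dev) / denom)


def fdis(
    abundance: np.ndarray, traits: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Functional dispersion of one community.

    Parameters
    ----------
    abundance:
        Raw (or relative — FDis is scale-invariant in abundance) species
        abundances ``A_j >= 0`` with a positive total.
    traits:
        Species x trait matrix, already standardised if desired.

    Returns
    -------
    (fdis, centroid, z) where ``centroid = sum(A_j x_j) / sum(A_j)``,
    ``z_j`` is the Euclidean distance of species j to the centroid and
    ``fdis = sum(A_j z_j) / sum(A_j)``.
    """
    a = np.asarray(abundance, dtype=float)
    x = np.atleast_2d(np.asarray(traits, dtype=float))
    if x.shape[0] != a.shape[0]:
        x = x.T
    total = a.sum()
    if total <= 0:
        raise ValidationError("zero total abundance")
    c = (a @ x) / total
    z = np.linalg.norm(x - c, axis=1)
    return float((a @ z) / total), c, z


def standardize_traits(
    traits: pd.DataFrame, pool_index: pd.Index | None = None
) -> pd.DataFrame:
    """z-score trait columns over the species pool (ddof=0).

    Constant columns are left centred (sd treated as 1) rather than
    producing NaNs.
    """
    pool = traits if pool_index is None else traits.loc[pool_index]
    mu = pool.mean(axis=0)
    sd = pool.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (traits - mu) / sd


def plot_diversity(
    dataset: CommunityDataset, plot_id: str, cfg: RunConfig
) -> DiversityResult:
    """CWM vector, per-trait dispersion and FDis for one plot."""
    rel = dataset.abundance.loc[plot_id]
    present = rel.index[rel > 0]
    p = rel.loc[present].to_numpy()
    raw = dataset.raw_abundance.loc[plot_id, present].to_numpy()
    traits = dataset.traits.loc[present, TRAIT_COLUMNS]

    cwms = pd.Series(
        {t: cwm(p, traits[t].to_numpy()) for t in TRAIT_COLUMNS}, name=plot_id
    )
    fds = pd.Series(
        {t: fd_single(p, traits[t].to_numpy()) for t in TRAIT_COLUMNS},
        name=plot_id,
    )

    if cfg.trait_standardize:
        if cfg.standardize_pool == "plantation":
            plantation = dataset.plot_meta.loc[plot_id, "plantation"]
            plots = dataset.plot_meta.index[
                dataset.plot_meta["plantation"] == plantation
            ]
            pool = dataset.abundance.loc[plots].sum(axis=0)
            pool_index = pool.index[pool > 0]
        else:
            pool_index = dataset.traits.index
        space = standardize_traits(dataset.traits, pool_index).loc[present]
    else:
        space = traits
    fdis_val, c, z = fdis(raw, space.to_numpy())
    return DiversityResult(
        plot_id=plot_id,
        cwm=cwms,
        fd_single=fds,
        fdis=fdis_val,
        centroid=c,
        z=pd.Series(z, index=present),
        richness=len(present),
    )


def diversity_table(dataset: CommunityDataset, cfg: RunConfig) -> pd.DataFrame:
    """Per-plot table: 15 CWM columns, 15 dispersion columns, FDis, richness."""
    rows = []
    for plot_id in dataset.plots:
        r = plot_diversity(dataset, plot_id, cfg)
        row = {"plot_id": plot_id, "fdis": r.fdis, "richness": r.richness}
        row.update({f"cwm_{t}": r.cwm[t] for t in TRAIT_COLUMNS})
        row.update({f"fd_{t}": r.fd_single[t] for t in TRAIT_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot_id").sort_index()
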