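"""Allometric aboveground biomass from stem diameter and height.

Stem biomass follows the power law

    AGB = a * (DBH^2 * H)^b

with DBH in cm, height H in m, and species- (or plantation-) specific
parameters ``a > 0`` and ``b``. The output mass unit is whatever the
supplied parameterisation implies; the package treats it as opaque and
comparisons are only valid within one parameter table. Stems measured at
mid-height (total height below 1.50 m) use the same functional form with
their recorded diameter and are counted in ``n_mid_height``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ConfigurationError


@dataclass(frozen=True)
class AllometricParams:
    """Power-law parameters for one species or plantation."""

    a: float
    b: float
    applies_to: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("allometric scale parameter a must be > 0")
        if not np.isfinite(self.b):
            raise ValueError("allometric exponent b must be finite")


@dataclass
class PlotBiomass:
    """Total and per-area aboveground biomass of one plot."""

    plot_id: str
    agb_total: float
    agb_per_area: float
    n_stems: int
    n_mid_height: int


def stem_agb(dbh, height, params: AllometricParams):
    """Aboveground biomass of a single stem (vectorised over dbh/height).

    Strictly increasing in both dbh and height whenever ``b > 0``.
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if (dbh <= 0).any() or (height <= 0).any():
        raise ValueError("dbh and height must be strictly positive")
    return params.a * (dbh**2 * height) ** params.b


def resolve_params(
    species: str, plantation: str, table: pd.DataFrame
) -> AllometricParams:
    """Species-level parameters with a plantation-level fallback."""
    for key in (species, plantation):
        if key in table.index:
            row = table.loc[key]
            return AllometricParams(float(row["a"]), float(row["b"]), key)
    raise ConfigurationError(
        f"no allometric parameters for species {species!r} "
        f"(no plantation fallback {plantation!r} either)"
    )


def plot_agb(
    stems: pd.DataFrame, params: pd.DataFrame, cfg: RunConfig
) -> PlotBiomass:
    """Sum stem biomass over the stems of one plot.

    ``stems`` is an inventory slice for a single plot; ``params`` the
    allometric parameter table indexed by ``applies_to``.
    """
    plot_ids = stems["plot_id"].unique()
    if len(plot_ids) > 1:
        raise ValueError(f"stems span multiple plots: {sorted(plot_ids)}")
    total = 0.0
    n_mid = 0
    for _, stem in stems.iterrows():
        p = resolve_params(stem["species"], stem["plantation"], params)
        total += float(stem_agb(stem["dbh"], stem["height"], p))
        if stem["dbh_basis"] == "mid_height":
            n_mid += 1
    plot_id = plot_ids[0] if len(plot_ids) else ""
    return PlotBiomass(
        plot_id=plot_id,
        agb_total=total,
        agb_per_area=total / cfg.plot_area_m2,
        n_stems=len(stems),
        n_mid_height=n_mid,
    )


def plot_agb_table(
    inventory: pd.DataFrame, params: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Per-plot biomass table for a whole inventory, indexed by plot."""
    records = []
    for plot_id, stems in inventory.groupby("plot_id"):
        pb = plot_agb(stems, params, cfg)
        records.append(
            {
                "plot_id": plot_id,
                "agb_total": pb.agb_total,
                "agb_per_area": pb.agb_per_area,
                "n_stems": pb.n_stems,
                "n_mid_height": pb.n_mid_height,
            }
        )
    return pd.DataFrame(records).set_index("plot_id").sort_index()
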