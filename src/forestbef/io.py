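"""Reading, validating and writing the tabular inputs.

All tables are comma-separated UTF-8 text with a header row and ``.`` as
the decimal mark. Four tables drive the pipeline:

* **inventory** — one row per stem: plot, plantation type, slope position,
  species, DBH (cm) and height (m). Stems shorter than 1.50 m are measured
  at mid-height rather than breast height and carry ``dbh_basis =
  "mid_height"``.
* **traits** — one row per species, 15 trait columns spanning the leaf and
  root economic spectra plus maximum height.
* **soil** — one row per plot: SOC, TN, TP, TK concentrations.
* **allometric parameters** — ``applies_to`` (species or plantation), ``a``,
  ``b`` for the biomass power law.

``validate_dataset`` cross-references the tables into a
:class:`CommunityDataset` whose per-plot relative abundances (stem-count or
basal-area basis) sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import CrossReferenceError, SchemaError, ValidationError

#: Canonical order of the 15 functional trait columns.
TRAIT_COLUMNS = [
    "height_max",  # maximum plant height, m
    "SLA",    # specific leaf area
    "LDMC",   # leaf dry matter content
    "VD",     # leaf vein density
    "LC",     # leaf carbon
    "LN",     # leaf nitrogen
    "LP",     # leaf phosphorus
    "RD",     # root diameter
    "SRL",    # specific root length
    "RDMC",   # root dry matter content
    "RTD",    # root tissue density
    "RBI",    # root branching intensity
    "RC",     # root carbon
    "RN",     # root nitrogen
    "RP",     # root phosphorus
]

PLANTATIONS = ("AM", "EE", "MC", "NS")
SLOPES = ("upper", "middle", "lower")
SOIL_COLUMNS = ["soc", "tn", "tp", "tk"]

_INVENTORY_REQUIRED = ["plot_id", "plantation", "slope", "species", "dbh", "height"]
#: Height (m) below which diameter is taken at mid-height, not breast height.
BREAST_HEIGHT_MIN_M = 1.50


@dataclass
class CommunityDataset:
    """Cross-referenced bundle of inventory, traits, soil and abundances.

    ``abundance`` holds per-plot *relative* abundances (rows sum to 1) on
    the configured basis; ``raw_abundance`` the unnormalised values
    (stem counts or summed basal areas, cm^2).
    """

    inventory: pd.DataFrame
    traits: pd.DataFrame        # species x 15 traits
    soil: pd.DataFrame          # plot x (soc, tn, tp, tk)
    abundance: pd.DataFrame     # plot x species, rows sum to 1
    raw_abundance: pd.DataFrame
    plot_meta: pd.DataFrame     # plot x (plantation, slope)
    basis: str

    @property
    def plots(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns {missing}")


def read_inventory(path: str | Path) -> pd.DataFrame:
    """Read and validate a stem inventory.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming the offending 1-based data row) for
    non-positive DBH/height or an inconsistent ``dbh_basis``.
    """
    df = pd.read_csv(path)
    _require_columns(df, _INVENTORY_REQUIRED, "inventory")
    if "dbh_basis" not in df.columns:
        df["dbh_basis"] = np.where(
            df["height"] < BREAST_HEIGHT_MIN_M, "mid_height", "breast_height"
        )
    return validate_inventory(df)


def validate_inventory(df: pd.DataFrame) -> pd.DataFrame:
    """Check stem-record invariants on an in-memory inventory frame."""
    _require_columns(df, _INVENTORY_REQUIRED + ["dbh_basis"], "inventory")
    for col in ("dbh", "height"):
        bad = df.index[~(pd.to_numeric(df[col], errors="coerce") > 0)]
        if len(bad):
            rows = ", ".join(str(i + 1) for i in bad[:5])
            raise ValidationError(
                f"non-positive or non-numeric {col} in inventory row(s) {rows}"
            )
    bad_basis = df.index[~df["dbh_basis"].isin(["breast_height", "mid_height"])]
    if len(bad_basis):
        raise ValidationError(
            f"unknown dbh_basis in inventory row(s) "
            f"{', '.join(str(i + 1) for i in bad_basis[:5])}"
        )
    # mid-height measurement is only for stems below breast height
    inconsistent = df.index[
        (df["dbh_basis"] == "mid_height") & (df["height"] >= BREAST_HEIGHT_MIN_M)
    ]
    if len(inconsistent):
        raise ValidationError(
            f"dbh_basis=mid_height requires height < {BREAST_HEIGHT_MIN_M} m; "
            f"violated in row(s) {', '.join(str(i + 1) for i in inconsistent[:5])}"
        )
    return df.reset_index(drop=True)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a species x trait table indexed by species.

    All 15 canonical trait columns must be present, finite and complete.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["species"] + TRAIT_COLUMNS, "trait")
    df = df.set_index("species")[TRAIT_COLUMNS]
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing trait cells for species {bad}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError("non-finite trait values")
    return df


def read_soil(path: str | Path) -> pd.DataFrame:
    """Read a plot x soil-chemistry table (SOC, TN, TP, TK)."""
    df = pd.read_csv(path)
    _require_columns(df, ["plot_id"] + SOIL_COLUMNS, "soil")
    if df["plot_id"].duplicated().any():
        dupes = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValidationError(f"duplicate plot_id rows in soil table: {dupes}")
    df = df.set_index("plot_id")[SOIL_COLUMNS]
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative soil concentration values")
    return df


def read_allometric_params(path: str | Path) -> pd.DataFrame:
    """Read the allometric parameter table (applies_to, a, b)."""
    df = pd.read_csv(path)
    _require_columns(df, ["applies_to", "a", "b"], "allometric parameter")
    if (df["a"] <= 0).any():
        raise ValidationError("allometric scale parameter a must be > 0")
    if not np.isfinite(df["b"]).all():
        raise ValidationError("allometric exponent b must be finite")
    return df.set_index("applies_to")[["a", "b"]]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a table in the package's one CSV dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


def abundance_matrix(
    inventory: pd.DataFrame, basis: str = "stem_count"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot raw and relative abundance matrices on the given basis.

    ``basal_area`` weights each stem by pi * dbh^2 / 4 (cm^2).
    """
    inv = inventory.copy()
    if basis == "stem_count":
        inv["w"] = 1.0
    elif basis == "basal_area":
        inv["w"] = np.pi * inv["dbh"] ** 2 / 4.0
    else:
        raise ValueError(f"unknown abundance basis {basis!r}")
    raw = (
        inv.pivot_table(index="plot_id", columns="species", values="w",
                        aggfunc="sum", fill_value=0.0)
        .sort_index()
    )
    raw.columns.name = None
    rel = raw.div(raw.sum(axis=1), axis=0)
    return raw, rel


def validate_dataset(
    inventory: pd.DataFrame,
    traits: pd.DataFrame,
    soil: pd.DataFrame,
    cfg: RunConfig,
) -> CommunityDataset:
    """Cross-reference the tables into a :class:`CommunityDataset`.

    Every species in the inventory must have a trait row and every plot a
    soil row; offenders are listed in the :class:`CrossReferenceError`.
    """
    inventory = validate_inventory(inventory)
    orphan_species = sorted(set(inventory["species"]) - set(traits.index))
    if orphan_species:
        raise CrossReferenceError(
            f"species in inventory but not in trait table: {orphan_species}"
        )
    orphan_plots = sorted(set(inventory["plot_id"]) - set(soil.index))
    if orphan_plots:
        raise CrossReferenceError(
            f"plots in inventory but not in soil table: {orphan_plots}"
        )
    raw, rel = abundance_matrix(inventory, cfg.abundance_basis)
    plot_meta = (
        inventory.groupby("plot_id")[["plantation", "slope"]].first().sort_index()
    )
    return CommunityDataset(
        inventory=inventory,
        traits=traits,
        soil=soil.loc[rel.index],
        abundance=rel,
        raw_abundance=raw,
        plot_meta=plot_meta,
        basis=cfg.abundance_basis,
    )
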