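"""Synthetic study data: structural-level draws and full community datasets.

Two generators stand in for the undeposited field data.

**Structural generator** — draws (soil, FD, SR, CWM, AGB) rows directly
from a standardised recursive path model. Exogenous variables are
standard normal; each endogenous variable is the coefficient-weighted sum
of its parents plus a Gaussian residual whose variance is set so the
variable has unit population variance. The residual variance is derived
from the DAG-implied covariance of the parents (upstream paths induce
parent correlations), so the generated R^2 matches the model-implied
value. Default coefficients encode the study-scale effect sizes: soil
fertility promotes functional dispersion strongly, functional dispersion
and species richness promote biomass, community-mean traits add a smaller
direct contribution.

**Community generator** — emulates the inventory design: 4 plantation
types x 3 slope positions x 3 plots = 36 plots, a pool of 20 dominant
species with correlated leaf/root economic-spectrum traits, per-plot soil
chemistry driven by a latent fertility, Dirichlet abundances, log-normal
stem sizes, and a growth signal that makes richer, more functionally
dispersed plots carry more biomass — so the downstream diversity-biomass
relationships are positive by construction. The distributions are
explicit fixtures, not claims about any real site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import PLANTATIONS, SLOPES, SOIL_COLUMNS, TRAIT_COLUMNS
from .pathmodel import Edge, PathModelSpec

#: Standardised path coefficients of the default structural model.
DEFAULT_PATHS: dict[Edge, float] = {
    ("soil", "FD"): 0.52,
    ("soil", "SR"): -0.18,
    ("soil", "CWM"): 0.17,
    ("soil", "AGB"): 0.20,
    ("FD", "AGB"): 0.49,
    ("SR", "AGB"): 0.40,
    ("CWM", "AGB"): 0.26,
}

DEFAULT_VARIABLES = ("soil", "FD", "SR", "CWM", "AGB")


@dataclass
class StructuralGenSpec:
    """Coefficients and size for the structural-level generator."""

    coefficients: dict[Edge, float] = field(
        default_factory=lambda: dict(DEFAULT_PATHS)
    )
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    n: int = 5000

    def model_spec(self) -> PathModelSpec:
        return PathModelSpec(self.variables, tuple(self.coefficients))


def implied_covariance(spec: StructuralGenSpec) -> pd.DataFrame:
    """Closed-form population covariance of the standardised DAG.

    Built recursively in topological order: cov(new, z) = b' cov(parents, z)
    and var(new) = b' cov(parents) b + psi with psi chosen for unit
    variance. Raises :class:`ValidationError` if any implied R^2 >= 1.
    """
    model = spec.model_spec()
    order = model.topological_order()
    cov = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    for var in order:
        parents = model.parents(var)
        if not parents:
            cov.loc[var, var] = 1.0
            for prev in order[: order.index(var)]:
                # independent exogenous variables
                cov.loc[var, prev] = cov.loc[prev, var] = 0.0
            continue
        b = np.array([spec.coefficients[(p, var)] for p in parents])
        Cp = cov.loc[parents, parents].to_numpy()
        explained = float(b @ Cp @ b)
        if explained >= 1.0:
            raise ValidationError(
                f"coefficients imply R^2 >= 1 for {var} ({explained:.3f})"
            )
        cov.loc[var, var] = 1.0
        for prev in order[: order.index(var)]:
            c = float(b @ cov.loc[parents, prev].to_numpy())
            cov.loc[var, prev] = cov.loc[prev, var] = c
    return cov.loc[list(spec.variables), list(spec.variables)]


def residual_variances(spec: StructuralGenSpec) -> dict[str, float]:
    """Unit-variance residual variances implied by the coefficients."""
    model = spec.model_spec()
    cov = implied_covariance(spec)
    out = {}
    for var in model.endogenous:
        parents = model.parents(var)
        b = np.array([spec.coefficients[(p, var)] for p in parents])
        Cp = cov.loc[parents, parents].to_numpy()
        out[var] = 1.0 - float(b @ Cp @ b)
    return out


def gen_structural(
    spec: StructuralGenSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample ``spec.n`` rows from the standardised structural model."""
    model = spec.model_spec()
    psi = residual_variances(spec)
    data: dict[str, np.ndarray] = {}
    for var in model.topological_order():
        parents = model.parents(var)
        if not parents:
            data[var] = rng.standard_normal(spec.n)
        else:
            mean = sum(
                spec.coefficients[(p, var)] * data[p] for p in parents
            )
            data[var] = mean + rng.normal(0.0, np.sqrt(psi[var]), spec.n)
    return pd.DataFrame({v: data[v] for v in spec.variables})


# ---------------------------------------------------------------------------
# Community-level generator
# ---------------------------------------------------------------------------

#: Acquisitive-economics loading of each trait on the species' strategy
#: axis (positive = fast/acquisitive), and log-scale baselines. Values are
#: fixture choices shaped like published leaf/root economics patterns.
_TRAIT_GEN = {
    # trait: (log-mean, loading on economics axis, residual sd, positive?)
    "height_max": (2.3, 0.10, 0.45, True),   # ~10 m canopy, own stature axis
    "SLA": (2.7, 0.55, 0.25, True),          # cm2/g-ish scale
    "LDMC": (-1.1, -0.40, 0.20, True),       # g/g
    "VD": (1.6, 0.15, 0.30, True),
    "LC": (6.1, -0.10, 0.05, True),          # mg/g
    "LN": (2.9, 0.50, 0.20, True),
    "LP": (0.3, 0.45, 0.25, True),
    "RD": (-0.7, -0.35, 0.30, True),         # mm
    "SRL": (3.0, 0.55, 0.30, True),          # m/g
    "RDMC": (-1.2, -0.40, 0.20, True),
    "RTD": (-0.9, -0.45, 0.25, True),
    "RBI": (1.1, 0.20, 0.35, True),
    "RC": (6.0, -0.10, 0.06, True),
    "RN": (2.2, 0.50, 0.25, True),
    "RP": (-0.2, 0.45, 0.25, True),
}

#: Per-plantation mean of the latent soil-fertility axis.
_PLANTATION_FERTILITY = {"AM": 0.8, "EE": 0.3, "MC": -0.2, "NS": -0.9}
#: Slope-position adjustment (nutrients accumulate downslope).
_SLOPE_FERTILITY = {"upper": -0.35, "middle": 0.0, "lower": 0.35}
#: Soil variables: (log-scale intercept, fertility loading, noise sd).
_SOIL_GEN = {
    "soc": (2.6, 0.40, 0.18),
    "tn": (0.4, 0.38, 0.18),
    "tp": (-0.8, 0.25, 0.22),
    "tk": (2.2, 0.20, 0.25),
}


@dataclass
class CommunityGenSpec:
    """Design and effect sizes for the community-level generator."""

    plantations: tuple[str, ...] = PLANTATIONS
    slopes: tuple[str, ...] = SLOPES
    plots_per_slope: int = 3
    n_species: int = 20
    mean_richness: float = 9.0
    richness_fertility_effect: float = 3.0
    stems_per_plot: float = 28.0
    fertility_sd: float = 0.45            # plot-level noise on the latent axis
    growth_fertility_effect: float = 0.15  # log-DBH response to fertility
    growth_fd_effect: float = 0.30         # log-DBH response to trait dispersion
    growth_richness_effect: float = 0.12   # log-DBH response to richness
    dbh_log_mean: float = 1.85             # ~6.4 cm median DBH
    dbh_log_sd: float = 0.45
    abundance_concentration: float = 1.2   # Dirichlet alpha at fertility 0
    evenness_fertility_effect: float = 0.6  # log-alpha response to fertility
    allometric_a: float = 0.06
    allometric_b: float = 0.88

    @property
    def n_plots(self) -> int:
        return len(self.plantations) * len(self.slopes) * self.plots_per_slope


@dataclass
class CommunityData:
    """In-memory bundle of the four generated tables."""

    inventory: pd.DataFrame
    traits: pd.DataFrame
    soil: pd.DataFrame
    allometric_params: pd.DataFrame


def _gen_species_pool(
    spec: CommunityGenSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Species trait table plus each species' economics-axis position."""
    ids = [f"sp{k + 1:02d}" for k in range(spec.n_species)]
    econ = rng.standard_normal(spec.n_species)
    cols = {}
    for trait, (mu, load, sd, positive) in _TRAIT_GEN.items():
        vals = mu + load * econ + rng.normal(0.0, sd, spec.n_species)
        cols[trait] = np.exp(vals) if positive else vals
    traits = pd.DataFrame(cols, index=pd.Index(ids, name="species"))
    return traits[TRAIT_COLUMNS], econ


def gen_community(
    spec: CommunityGenSpec, rng: np.random.Generator
) -> CommunityData:
    """Generate a full community dataset with the 36-plot design."""
    traits, econ = _gen_species_pool(spec, rng)
    species_ids = np.array(traits.index)
    # z-scored pool trait space: the same space the pipeline measures
    # dispersion in, so the growth signal targets the measured FDis
    z_traits = (
        (traits - traits.mean()) / traits.std(ddof=0).replace(0.0, 1.0)
    ).to_numpy()

    params = pd.DataFrame(
        {
            "applies_to": species_ids,
            "a": np.exp(
                np.log(spec.allometric_a) + rng.normal(0.0, 0.15, spec.n_species)
            ),
            "b": rng.normal(spec.allometric_b, 0.02, spec.n_species),
        }
    )

    inventory_rows = []
    soil_rows = []
    for plantation in spec.plantations:
        for slope in spec.slopes:
            for rep in range(spec.plots_per_slope):
                plot_id = f"{plantation}-{slope}-{rep + 1}"
                fert = (
                    _PLANTATION_FERTILITY[plantation]
                    + _SLOPE_FERTILITY[slope]
                    + rng.normal(0.0, spec.fertility_sd)
                )
                soil_row = {"plot_id": plot_id}
                for col, (mu, load, sd) in _SOIL_GEN.items():
                    soil_row[col] = float(
                        np.exp(mu + load * fert + rng.normal(0.0, sd))
                    )
                soil_rows.append(soil_row)

                richness = int(
                    np.clip(
                        round(
                            spec.mean_richness
                            + spec.richness_fertility_effect * fert
                            + rng.normal(0.0, 1.5)
                        ),
                        1,
                        spec.n_species,
                    )
                )
                member_idx = rng.choice(
                    spec.n_species, size=richness, replace=False
                )
                members = species_ids[member_idx]
                # fertile plots are more even (higher Dirichlet alpha),
                # which raises the measured dispersion
                alpha = spec.abundance_concentration * float(
                    np.exp(spec.evenness_fertility_effect * fert)
                )
                probs = rng.dirichlet(np.full(richness, alpha))
                n_stems = max(richness, rng.poisson(spec.stems_per_plot))
                counts = rng.multinomial(n_stems - richness, probs) + 1

                # abundance-weighted mean distance to the abundance-weighted
                # centroid in the z-scored trait space (the plot's FDis,
                # before stem-level noise)
                w = counts / counts.sum()
                member_z = z_traits[member_idx]
                centroid = w @ member_z
                dispersion = float(
                    w @ np.linalg.norm(member_z - centroid, axis=1)
                )

                growth = (
                    spec.growth_fertility_effect * fert
                    + spec.growth_fd_effect * (dispersion - 3.2)
                    + spec.growth_richness_effect
                    * (richness - spec.mean_richness)
                    / 3.0
                )
                for sp, count in zip(members, counts):
                    ln_dbh = rng.normal(
                        spec.dbh_log_mean + growth, spec.dbh_log_sd, count
                    )
                    dbh = np.exp(ln_dbh)
                    height = np.exp(
                        0.45 + 0.55 * ln_dbh + rng.normal(0.0, 0.12, count)
                    )
                    for d, h in zip(dbh, height):
                        inventory_rows.append(
                            {
                                "plot_id": plot_id,
                                "plantation": plantation,
                                "slope": slope,
                                "species": sp,
                                "dbh": float(d),
                                "height": float(h),
                                "dbh_basis": (
                                    "mid_height" if h < 1.50 else "breast_height"
                                ),
                            }
                        )

    inventory = pd.DataFrame(inventory_rows)
    soil = pd.DataFrame(soil_rows).set_index("plot_id")[SOIL_COLUMNS]
    return CommunityData(
        inventory=inventory,
        traits=traits,
        soil=soil,
        allometric_params=params.set_index("applies_to"),
    )


def write_community(data: CommunityData, out_dir) -> dict[str, str]:
    """Write the four tables as CSV; returns the file map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "inventory": out / "inventory.csv",
        "traits": out / "traits.csv",
        "soil": out / "soil.csv",
        "allometric_params": out / "allometric_params.csv",
    }
    data.inventory.to_csv(paths["inventory"], index=False)
    data.traits.reset_index().to_csv(paths["traits"], index=False)
    data.soil.reset_index().to_csv(paths["soil"], index=False)
    data.allometric_params.reset_index().to_csv(
        paths["allometric_params"], index=False
    )
    return {k: str(v) for k, v in paths.items()}
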