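"""Run configuration: one object that carries every tunable of the pipeline.

The configuration is a plain dataclass readable from a TOML file. All
randomness in the package flows from ``RunConfig.seed`` through explicit
``numpy.random.Generator`` objects handed to operations; nothing seeds
global state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

#: Abundance bases accepted for community vectors.
ABUNDANCE_BASES = ("stem_count", "basal_area")


@dataclass
class RunConfig:
    """Pipeline settings.

    Parameters
    ----------
    abundance_basis:
        How relative abundance is computed per plot: ``"stem_count"``
        (number of stems, the minimal-information default) or
        ``"basal_area"`` (sum of pi * dbh^2 / 4 per species).
    plot_area_m2:
        Plot area used for per-area biomass; default 100 (10 m x 10 m plots).
    trait_standardize:
        Whether traits are z-scored across the species pool before
        multi-trait dispersion.
    standardize_pool:
        Pool for the z-scoring: ``"global"`` (all species) or
        ``"plantation"``.
    pca_scale:
        ``"correlation"`` (default; blocks mix units) or ``"covariance"``.
    parallel_n_sim / parallel_criterion:
        Horn parallel-analysis settings (simulations; ``"mean"`` or
        ``"p95"`` retention criterion).
    rf_n_trees, rf_mtry, rf_min_leaf, rf_n_perm:
        Regression-forest settings; ``rf_mtry=None`` means ceil(p / 3).
    seed:
        Master seed; recorded in every output sidecar.
    rounding:
        Decimal places for reported coefficients.
    """

    abundance_basis: str = "stem_count"
    plot_area_m2: float = 100.0
    trait_standardize: bool = True
    standardize_pool: str = "global"
    pca_scale: str = "correlation"
    parallel_n_sim: int = 1000
    parallel_criterion: str = "mean"
    rf_n_trees: int = 5000
    rf_mtry: int | None = None
    rf_min_leaf: int = 5
    rf_n_perm: int = 500
    seed: int = 0
    rounding: int = 2
    sem_paths: list[str] = field(
        default_factory=lambda: [
            "soil -> FD",
            "soil -> SR",
            "soil -> CWM",
            "soil -> AGB",
            "FD -> AGB",
            "SR -> AGB",
            "CWM -> AGB",
        ]
    )

    def __post_init__(self) -> None:
        if self.abundance_basis not in ABUNDANCE_BASES:
            raise ConfigurationError(
                f"abundance_basis must be one of {ABUNDANCE_BASES}, "
                f"got {self.abundance_basis!r}"
            )
        if self.pca_scale not in ("correlation", "covariance"):
            raise ConfigurationError(f"unknown pca_scale {self.pca_scale!r}")
        if self.parallel_criterion not in ("mean", "p95"):
            raise ConfigurationError(
                f"unknown parallel_criterion {self.parallel_criterion!r}"
            )
        if self.plot_area_m2 <= 0:
            raise ConfigurationError("plot_area_m2 must be positive")

    def rng(self) -> np.random.Generator:
        """A fresh generator seeded from ``seed``."""
        return np.random.default_rng(self.seed)

    def hash(self) -> str:
        """Stable hash of the configuration for run metadata."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a TOML file.

    Unknown keys raise :class:`ConfigurationError` rather than being
    silently dropped.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def run_metadata(cfg: RunConfig) -> dict:
    """JSON-serialisable sidecar: seed, config hash, package version."""
    from . import __version__

    return {
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
    }
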