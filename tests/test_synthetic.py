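import numpy as np
import pandas as pd
import pytest

from forestbef import allometry, diversity, pathmodel, synthetic
from forestbef.config import RunConfig
from forestbef.errors import ValidationError
from forestbef.io import validate_dataset
from forestbef.pipeline import assemble_model_table
from forestbef.synthetic import CommunityGenSpec, StructuralGenSpec


class TestStructuralGenerator:
    def test_null_model_gives_independent_standard_normals(self):
        spec = StructuralGenSpec(
            coefficients={k: 0.0 for k in synthetic.DEFAULT_PATHS}, n=5000
        )
        data = synthetic.gen_structural(spec, np.random.default_rng(0))
        corr = data.corr().to_numpy()
        off_diag = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off_diag).max() < 0.05
        assert np.allclose(data.var(ddof=1), 1.0, atol=0.07)

    def test_default_spec_population_moments(self):
        spec = StructuralGenSpec(n=5000)
        data = synthetic.gen_structural(spec, np.random.default_rng(1))
        # population correlation soil-FD equals the path coefficient
        assert data["soil"].corr(data["FD"]) == pytest.approx(0.52, abs=0.03)
        assert data["AGB"].var(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_sample_covariance_matches_closed_form(self):
        spec = StructuralGenSpec(n=5000)
        implied = synthetic.implied_covariance(spec)
        data = synthetic.gen_structural(spec, np.random.default_rng(2))
        sample = data.cov()
        np.testing.assert_allclose(
            sample.to_numpy(), implied.to_numpy(), atol=0.06
        )

    def test_unit_variance_residual_construction(self):
        spec = StructuralGenSpec()
        psi = synthetic.residual_variances(spec)
        implied = synthetic.implied_covariance(spec)
        for var, value in psi.items():
            assert 0 < value < 1
            assert implied.loc[var, var] == pytest.approx(1.0, abs=1e-12)

    def test_coefficients_implying_r2_above_one_rejected(self):
        bad = dict(synthetic.DEFAULT_PATHS)
        bad[("FD", "AGB")] = 0.9
        bad[("SR", "AGB")] = 0.9
        spec = StructuralGenSpec(coefficients=bad)
        with pytest.raises(ValidationError, match="R\\^2"):
            synthetic.gen_structural(spec, np.random.default_rng(0))


class TestCommunityGenerator:
    def test_study_design_dimensions(self, community):
        inv = community.inventory
        assert inv["plot_id"].nunique() == 36
        assert inv["plantation"].nunique() == 4
        per_plantation = inv.groupby("plantation")["plot_id"].nunique()
        assert (per_plantation == 9).all()
        assert set(inv["slope"]) == {"upper", "middle", "lower"}
        assert community.traits.shape == (20, 15)

    def test_every_plot_has_at_least_one_species(self, community):
        richness = community.inventory.groupby("plot_id")["species"].nunique()
        assert (richness >= 1).all()
        assert len(richness) == 36

    def test_generated_dataset_validates(self, community):
        cfg = RunConfig()
        ds = validate_dataset(
            community.inventory, community.traits, community.soil, cfg
        )
        assert len(ds.plots) == 36

    def test_deterministic_under_seed(self):
        spec = CommunityGenSpec()
        a = synthetic.gen_community(spec, np.random.default_rng(5))
        b = synthetic.gen_community(spec, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a.inventory, b.inventory)
        pd.testing.assert_frame_equal(a.traits, b.traits)

    def test_acquisitive_traits_positively_correlated(self, community):
        # the economics axis couples SLA, LN, LP, SRL, RN, RP (log scale)
        logt = np.log(community.traits[["SLA", "LN", "LP", "SRL", "RN", "RP"]])
        corr = logt.corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert off.mean() > 0.2

    def test_fitted_fd_agb_path_positive_across_replicates(self):
        """The generator is built so functional dispersion raises biomass;
        the fitted FD->AGB path should be positive in >= 95% of replicates."""
        cfg = RunConfig(parallel_n_sim=150)
        spec_model = pathmodel.PathModelSpec.from_strings(cfg.sem_paths)
        positive = 0
        reps = 20
        for seed in range(reps):
            data = synthetic.gen_community(
                CommunityGenSpec(), np.random.default_rng(seed)
            )
            ds = validate_dataset(data.inventory, data.traits, data.soil, cfg)
            bio = allometry.plot_agb_table(
                ds.inventory, data.allometric_params, cfg
            )
            div = diversity.diversity_table(ds, cfg)
            table, _, _ = assemble_model_table(
                ds, cfg, bio, div, np.random.default_rng(seed)
            )
            fit = pathmodel.fit(spec_model, table)
            if fit.beta[("FD", "AGB")] > 0:
                positive += 1
        assert positive >= 19
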