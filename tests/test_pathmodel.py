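import itertools

import numpy as np
import pandas as pd
import pytest

from forestbef import pathmodel, synthetic
from forestbef.errors import ModelError
from forestbef.pathmodel import PathModelSpec, chi2_pvalue, decompose_effects, model_df

FIG_MODEL = PathModelSpec.from_strings(
    [
        "soil -> FD",
        "soil -> SR",
        "soil -> CWM",
        "soil -> AGB",
        "FD -> AGB",
        "SR -> AGB",
        "CWM -> AGB",
    ]
)

STUDY_BETAS = {
    ("soil", "FD"): 0.52,
    ("soil", "SR"): -0.18,
    ("soil", "CWM"): 0.17,
    ("soil", "AGB"): 0.20,
    ("FD", "AGB"): 0.49,
    ("SR", "AGB"): 0.40,
    ("CWM", "AGB"): 0.26,
}


class TestModelDf:
    def test_five_variable_seven_path_model(self):
        assert model_df(FIG_MODEL) == 3

    def test_saturated_three_variable_model(self):
        spec = PathModelSpec.from_strings(["a -> b", "a -> c", "b -> c"])
        assert model_df(spec) == 0

    def test_dropping_a_path_adds_a_df(self):
        spec = PathModelSpec(
            FIG_MODEL.variables, tuple(p for p in FIG_MODEL.paths if p != ("soil", "AGB"))
        )
        assert model_df(spec) == 4

    def test_cyclic_spec_rejected(self):
        with pytest.raises(ModelError, match="cycle"):
            PathModelSpec.from_strings(["a -> b", "b -> c", "c -> a"])


class TestChi2Pvalue:
    def test_upper_tail_probability(self):
        assert chi2_pvalue(2.555, 3) == pytest.approx(0.465, abs=5e-4)

    def test_zero_statistic_gives_one(self):
        for k in (1, 3, 10):
            assert chi2_pvalue(0.0, k) == 1.0

    def test_monotone_decreasing_to_zero(self):
        ps = [chi2_pvalue(c, 1) for c in (1.0, 5.0, 20.0, 80.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-15

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-1.0, 3)
        with pytest.raises(ValueError):
            chi2_pvalue(1.0, 0)


class TestFit:
    def test_saturated_model_reproduces_sample_covariance(self, rng):
        spec = PathModelSpec.from_strings(["a -> b", "a -> c", "b -> c"])
        data = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        fit = pathmodel.fit(spec, data)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.gfi == pytest.approx(1.0, abs=1e-8)
        assert fit.srmr == pytest.approx(0.0, abs=1e-8)
        pd.testing.assert_frame_equal(fit.sigma_theta, fit.S, atol=1e-10)

    def test_parameter_recovery_within_three_se(self):
        gen = synthetic.StructuralGenSpec(n=5000)
        data = synthetic.gen_structural(gen, np.random.default_rng(42))
        fit = pathmodel.fit(FIG_MODEL, data)
        for edge, true_beta in STUDY_BETAS.items():
            assert abs(fit.beta[edge] - true_beta) < 3 * fit.se[edge]

    def test_cfi_near_one_for_true_model(self):
        gen = synthetic.StructuralGenSpec(n=2000)
        data = synthetic.gen_structural(gen, np.random.default_rng(3))
        fit = pathmodel.fit(FIG_MODEL, data)
        assert fit.cfi > 0.99
        assert fit.gfi > 0.99

    def test_r2_equals_one_minus_residual_variance(self, rng):
        gen = synthetic.StructuralGenSpec(n=800)
        data = synthetic.gen_structural(gen, rng)
        fit = pathmodel.fit(FIG_MODEL, data)
        for var in FIG_MODEL.endogenous:
            # standardized: sample variance 1, so R^2 = 1 - psi (both ddof=1)
            assert fit.r2[var] == pytest.approx(
                1.0 - fit.residual_var[var], abs=1e-10
            )

    def test_missing_variable_raises(self, rng):
        data = pd.DataFrame(rng.normal(size=(50, 2)), columns=["soil", "FD"])
        with pytest.raises(ModelError):
            pathmodel.fit(FIG_MODEL, data)


def _random_dag(rng, n_nodes):
    """Random DAG over <= 6 nodes with coefficients in [-0.4, 0.4]."""
    names = [f"v{i}" for i in range(n_nodes)]
    paths = []
    betas = {}
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < 0.5:
            paths.append((names[i], names[j]))
            betas[(names[i], names[j])] = float(rng.uniform(-0.4, 0.4))
    if not paths:
        paths = [(names[0], names[1])]
        betas[(names[0], names[1])] = 0.3
    return PathModelSpec(tuple(names), tuple(paths)), betas


def _reduced_form_totals(spec, betas):
    """(I - B)^-1 - I : total effects by matrix inversion (the oracle)."""
    names = list(spec.variables)
    v = len(names)
    B = np.zeros((v, v))
    for (s, t), b in betas.items():
        B[names.index(t), names.index(s)] = b
    T = np.linalg.inv(np.eye(v) - B) - np.eye(v)
    return {
        (names[j], names[i]): T[i, j]
        for i in range(v)
        for j in range(v)
        if abs(T[i, j]) > 0
    }


class TestEffectDecomposition:
    def test_study_coefficients_reproduce_reported_decomposition(self):
        table = decompose_effects(FIG_MODEL, STUDY_BETAS)
        soil_agb = table[(table.source == "soil") & (table.target == "AGB")]
        effects = dict(zip(soil_agb.pathway, soil_agb.effect))
        assert effects["via FD"] == pytest.approx(0.25, abs=0.005)
        assert effects["via SR"] == pytest.approx(-0.07, abs=0.005)
        assert effects["via CWM"] == pytest.approx(0.04, abs=0.005)
        assert effects["total"] == pytest.approx(0.43, abs=0.005)

    def test_direct_only_pair_total_equals_direct(self):
        table = decompose_effects(FIG_MODEL, STUDY_BETAS)
        fd_agb = table[(table.source == "FD") & (table.target == "AGB")]
        effects = dict(zip(fd_agb.pathway, fd_agb.effect))
        assert effects == {"direct": 0.49, "total": 0.49}

    def test_total_is_direct_plus_indirects(self):
        table = decompose_effects(FIG_MODEL, STUDY_BETAS)
        for (_, _), grp in table.groupby(["source", "target"]):
            eff = dict(zip(grp.pathway, grp.effect))
            total = eff.pop("total")
            assert total == pytest.approx(sum(eff.values()), abs=1e-12)

    def test_chain_enumeration_matches_reduced_form_on_random_dags(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            spec, betas = _random_dag(rng, int(rng.integers(3, 7)))
            table = decompose_effects(spec, betas)
            totals = {
                (r.source, r.target): r.effect
                for r in table.itertuples()
                if r.pathway == "total"
            }
            oracle = _reduced_form_totals(spec, betas)
            for pair, expected in oracle.items():
                assert totals[pair] == pytest.approx(expected, abs=1e-10)

    def test_delta_method_p_values_present_for_fitted_model(self):
        gen = synthetic.StructuralGenSpec(n=1000)
        data = synthetic.gen_structural(gen, np.random.default_rng(8))
        fit = pathmodel.fit(FIG_MODEL, data)
        table = pathmodel.decompose_fit(fit)
        strong = table[
            (table.source == "soil")
            & (table.target == "AGB")
            & (table.pathway == "via FD")
        ]
        assert float(strong.p_value.iloc[0]) < 0.01
        assert table.se.notna().all()
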