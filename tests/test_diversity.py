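import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestbef import diversity
from forestbef.config import RunConfig
from forestbef.errors import ValidationError
from forestbef.io import TRAIT_COLUMNS


@pytest.mark.parametrize(
    "p,traits,expected",
    [
        ([1.0, 0.0], [5.0, 9.0], 5.0),
        ([0.5, 0.5], [2.0, 4.0], 3.0),
        ([0.2, 0.3, 0.5], [10.0, 20.0, 30.0], 23.0),
    ],
)
def test_cwm_values(p, traits, expected):
    assert diversity.cwm(np.array(p), np.array(traits)) == pytest.approx(expected)


def test_cwm_bounded_by_trait_range(rng):
    for _ in range(20):
        p = rng.dirichlet(np.ones(6))
        t = rng.normal(size=6)
        m = diversity.cwm(p, t)
        assert t.min() - 1e-12 <= m <= t.max() + 1e-12


def test_fd_single_hand_case():
    # p=(0.9,0.1), T=(0,10): CWM=1 -> (0.9*1 + 0.1*9) / (1 + 9) = 0.18
    assert diversity.fd_single(
        np.array([0.9, 0.1]), np.array([0.0, 10.0])
    ) == pytest.approx(0.18)


def test_fd_single_degenerate_cases():
    assert diversity.fd_single(np.array([1.0]), np.array([4.2])) == 0.0
    assert diversity.fd_single(np.array([0.6, 0.4]), np.array([3.0, 3.0])) == 0.0


@settings(max_examples=100, deadline=None)
@given(
    n=st.integers(2, 10),
    seed=st.integers(0, 2**31 - 1),
)
def test_fd_single_equal_abundance_identity(n, seed):
    """With equal abundances the numerator is denominator/n, so FD = 1/n."""
    t = np.random.default_rng(seed).normal(size=n)
    if np.unique(t).size < 2:
        return
    p = np.full(n, 1.0 / n)
    assert diversity.fd_single(p, t) == pytest.approx(1.0 / n, abs=1e-12)


@pytest.mark.parametrize(
    "abund,traits,expected_fdis,expected_c",
    [
        ([1.0, 1.0], [[0.0], [2.0]], 1.0, [1.0]),
        ([3.0, 1.0], [[0.0], [4.0]], 1.5, [1.0]),  # z = (1, 3): (3+3)/4
        ([2.0, 5.0], [[1.5, -2.0], [1.5, -2.0]], 0.0, [1.5, -2.0]),
    ],
)
def test_fdis_hand_cases(abund, traits, expected_fdis, expected_c):
    fdis_val, c, _ = diversity.fdis(np.array(abund), np.array(traits))
    assert fdis_val == pytest.approx(expected_fdis)
    np.testing.assert_allclose(c, expected_c)


def test_fdis_zero_abundance_error():
    with pytest.raises(ValidationError):
        diversity.fdis(np.array([0.0, 0.0]), np.array([[1.0], [2.0]]))


def _fdis_brute_force(a, x):
    """Direct loops over species: the independent oracle."""
    total = sum(a)
    c = [sum(a[j] * x[j][k] for j in range(len(a))) / total for k in range(len(x[0]))]
    out = 0.0
    z = []
    for j in range(len(a)):
        d = sum((x[j][k] - c[k]) ** 2 for k in range(len(c))) ** 0.5
        z.append(d)
        out += a[j] * d
    return out / total


def test_fdis_matches_brute_force_on_random_communities(rng):
    for _ in range(50):
        n = int(rng.integers(2, 11))
        k = int(rng.integers(1, 16))
        a = rng.uniform(0.1, 5.0, n)
        x = rng.normal(size=(n, k))
        fast, _, _ = diversity.fdis(a, x)
        slow = _fdis_brute_force(list(a), [list(row) for row in x])
        assert fast == pytest.approx(slow, abs=1e-12)


def test_fdis_invariant_to_splitting_a_species(rng):
    a = np.array([2.0, 3.0, 1.0])
    x = rng.normal(size=(3, 4))
    base, _, _ = diversity.fdis(a, x)
    # duplicate species 0, splitting its abundance 2 -> 0.5 + 1.5
    a2 = np.array([0.5, 1.5, 3.0, 1.0])
    x2 = np.vstack([x[0], x[0], x[1], x[2]])
    split, _, _ = diversity.fdis(a2, x2)
    assert split == pytest.approx(base, abs=1e-12)


def test_fdis_scales_linearly_with_traits(rng):
    a = rng.uniform(0.5, 2.0, 5)
    x = rng.normal(size=(5, 3))
    base, _, _ = diversity.fdis(a, x)
    scaled, _, _ = diversity.fdis(a, 7.5 * x)
    assert scaled == pytest.approx(7.5 * base, rel=1e-12)


def test_plot_diversity_single_species_plot(tiny_dataset):
    cfg = RunConfig()
    result = diversity.plot_diversity(tiny_dataset, "p2", cfg)
    assert result.richness == 2
    r1 = diversity.plot_diversity(tiny_dataset, "p1", cfg)
    # p1: oak 3 stems, pine 1 -> CWM pulled 3/4 toward oak
    for t in TRAIT_COLUMNS:
        oak, pine = (
            tiny_dataset.traits.loc["oak", t],
            tiny_dataset.traits.loc["pine", t],
        )
        assert r1.cwm[t] == pytest.approx(0.75 * oak + 0.25 * pine)


def test_diversity_table_shape_and_bounds(community):
    from forestbef.io import validate_dataset

    cfg = RunConfig()
    ds = validate_dataset(community.inventory, community.traits, community.soil, cfg)
    table = diversity.diversity_table(ds, cfg)
    assert len(table) == 36
    fd_cols = [f"fd_{t}" for t in TRAIT_COLUMNS]
    assert ((table[fd_cols] >= 0) & (table[fd_cols] <= 1)).all().all()
    assert (table["fdis"] >= 0).all()
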