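"""Correspondence analysis, Bray-Curtis, PERMANOVA and dispersion tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from fruitniche import (
    ValidationError,
    bray_curtis,
    build_contingency,
    correspondence_analysis,
    dispersion_homogeneity,
    permanova,
)


# ----------------------------------------------------------- contingency


def test_build_contingency_single_cell():
    plots = pd.DataFrame(
        [("P1", "SW", "A", 10)], columns=["plot_id", "habitat", "taxon", "stems"]
    )
    assignment = pd.DataFrame({"trait": ["Fallback apes"]}, index=["A"])
    table, n_excl = build_contingency(plots, assignment, by="trait")
    assert table.loc["SW", "Fallback apes"] == 10
    assert n_excl == 0


def test_build_contingency_drops_and_counts_empty_plots():
    plots = pd.DataFrame(
        [("P1", "SW", "A", 10), ("P2", "MF", "B", 4), ("P3", "MF", "Z", 7)],
        columns=["plot_id", "habitat", "taxon", "stems"],
    )
    assignment = pd.DataFrame(
        {"trait": ["Fallback apes", "Preferred apes", "none"]},
        index=["A", "B", "Z"],
    )
    table, n_excl = build_contingency(plots, assignment, by="trait")
    assert n_excl == 1            # P3 holds only a "none" taxon
    assert table.to_numpy().sum() == 14


# --------------------------------------------------------------------- CA


def test_ca_independence_zero_inertia():
    r = np.array([0.5, 0.3, 0.2])
    c = np.array([0.4, 0.6])
    table = pd.DataFrame(1000 * np.outer(r, c))
    ca = correspondence_analysis(table)
    assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)
    assert len(ca.singular_values) == 0


def test_ca_2x2_diagonal_full_inertia():
    ca = correspondence_analysis(pd.DataFrame([[10, 0], [0, 10]]))
    assert ca.total_inertia == pytest.approx(1.0, abs=1e-12)
    assert len(ca.singular_values) == 1
    assert ca.inertia_pct[0] == pytest.approx(100.0)


def test_ca_matches_pearson_chi_square_on_random_tables():
    rng = np.random.default_rng(99)
    for _ in range(300):
        shape = rng.integers(2, 7, size=2)
        X = rng.integers(1, 40, size=shape)
        ca = correspondence_analysis(pd.DataFrame(X))
        chi2 = chi2_contingency(X, correction=False).statistic
        assert ca.total_inertia == pytest.approx(chi2 / X.sum(), abs=1e-10)
        # deviation margins vanish; axis count <= min(rows, cols) - 1
        assert abs(ca.deviations.sum(axis=0).sum()) < 1e-8
        assert abs(ca.deviations.sum(axis=1).sum()) < 1e-8
        assert len(ca.singular_values) <= min(shape) - 1


def test_ca_row_scores_centered():
    """Mass-weighted mean of principal coordinates is zero on every axis."""
    rng = np.random.default_rng(5)
    X = rng.integers(1, 30, size=(5, 4))
    table = pd.DataFrame(X)
    ca = correspondence_analysis(table)
    r = X.sum(axis=1) / X.sum()
    c = X.sum(axis=0) / X.sum()
    np.testing.assert_allclose(r @ ca.row_coords.to_numpy(), 0.0, atol=1e-10)
    np.testing.assert_allclose(c @ ca.col_coords.to_numpy(), 0.0, atol=1e-10)


def test_ca_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        correspondence_analysis(pd.DataFrame([[1, 2]]))
    with pytest.raises(ValidationError):
        correspondence_analysis(pd.DataFrame([[1, 0], [2, 0]]))


# ------------------------------------------------------------ Bray-Curtis


def test_bray_curtis_hand_values():
    d = bray_curtis(pd.DataFrame([[1.0, 2.0], [2.0, 1.0], [0.0, 0.0]]))
    assert d.iloc[0, 1] == pytest.approx(2.0 / 6.0)
    assert d.iloc[0, 2] == pytest.approx(1.0)     # vs zero row: maximal
    assert d.iloc[0, 0] == 0.0


def test_bray_curtis_zero_pair_warns():
    with pytest.warns(UserWarning, match="zero-sum"):
        d = bray_curtis(pd.DataFrame([[0.0, 0.0], [0.0, 0.0]]))
    assert d.iloc[0, 1] == 0.0


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.integers(2, 6), st.integers(1, 5),
    st.integers(0, 2**31 - 1),
)
def test_bray_curtis_metric_properties(n, p, seed):
    """Symmetry, zero diagonal and [0,1] bounds on random nonnegative data."""
    X = np.random.default_rng(seed).uniform(0.01, 5.0, size=(n, p))
    d = bray_curtis(pd.DataFrame(X)).to_numpy()
    np.testing.assert_allclose(d, d.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()


# -------------------------------------------------------------- PERMANOVA


def _brute_force_permanova(d: np.ndarray, sizes: tuple[int, int]):
    """Independent exact test: enumerate all group-membership choices."""
    n = d.shape[0]
    idx = set(range(n))

    def f_stat(g1):
        g2 = sorted(idx - set(g1))
        groups = [list(g1), g2]
        N, a = n, 2
        sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / N
        ssw = 0.0
        for g in groups:
            ssw += sum(
                d[i, j] ** 2 for ii, i in enumerate(g) for j in g[ii + 1:]
            ) / len(g)
        ssb = sst - ssw
        return (ssb / (a - 1)) / (ssw / (N - a))

    obs = f_stat(tuple(range(sizes[0])))
    stats = [
        f_stat(g1) for g1 in itertools.combinations(range(n), sizes[0])
    ]
    # assignments to group labels: choosing members of group 1 enumerates
    # every distinct labelling (group sizes fixed)
    return obs, sum(s >= obs - 1e-12 for s in stats) / len(stats)


@pytest.mark.parametrize("sizes", [(2, 2), (2, 3), (3, 3), (2, 4), (3, 4), (4, 4)])
def test_permanova_exact_matches_brute_force(sizes):
    rng = np.random.default_rng(sum(sizes))
    n = sum(sizes)
    X = rng.uniform(0.1, 4.0, size=(n, 4))
    d = bray_curtis(pd.DataFrame(X))
    groups = ["a"] * sizes[0] + ["b"] * sizes[1]
    res = permanova(d, groups, method="exact")
    f_obs, p_exact = _brute_force_permanova(d.to_numpy(), sizes)
    assert res.statistic == pytest.approx(f_obs, rel=1e-10)
    assert res.p_value == pytest.approx(p_exact, abs=1e-12)


def test_permanova_matches_reference_implementation():
    """Pseudo-F agrees exactly with scikit-bio's PERMANOVA."""
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(21)
    X = rng.uniform(0.1, 3.0, size=(12, 5))
    d = bray_curtis(pd.DataFrame(X))
    groups = ["a", "b", "c", "d"] * 3
    mine = permanova(d, groups, n_perm=999, seed=3)
    np.random.seed(0)   # the reference implementation permutes via global state
    ref = skbio_distance.permanova(
        skbio_distance.DistanceMatrix(d.to_numpy()), groups, permutations=999
    )
    assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-12)
    assert mine.p_value == pytest.approx(ref["p-value"], abs=0.05)


def test_permanova_duplicated_points_f_zero():
    X = np.tile(np.random.default_rng(4).uniform(1, 2, size=(3, 4)), (2, 1))
    d = bray_curtis(pd.DataFrame(X))
    res = permanova(d, ["a", "a", "a", "b", "b", "b"], n_perm=99, seed=0)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value > 0.5


def test_permanova_rejects_singleton_group():
    d = bray_curtis(pd.DataFrame(np.eye(3)))
    with pytest.raises(ValidationError):
        permanova(d, ["a", "a", "b"], n_perm=9)


# ------------------------------------------------------------- dispersion


def test_dispersion_equal_spread_null():
    """Two point clouds with identical spread: high p."""
    rng = np.random.default_rng(8)
    A = rng.uniform(1, 2, size=(10, 4))
    B = rng.uniform(1, 2, size=(10, 4))
    d = bray_curtis(pd.DataFrame(np.vstack([A, B])))
    res = dispersion_homogeneity(d, ["a"] * 10 + ["b"] * 10, n_perm=499, seed=1)
    assert res.p_value > 0.05


def test_dispersion_detects_scaled_spread():
    """One group a 3x-spread copy of the other: small p."""
    rng = np.random.default_rng(9)
    center = np.full(4, 3.0)
    A = center + rng.normal(0, 0.05, size=(10, 4))
    B = center + rng.normal(0, 0.6, size=(10, 4))
    X = np.abs(np.vstack([A, B]))
    d = bray_curtis(pd.DataFrame(X))
    res = dispersion_homogeneity(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
    assert res.statistic > 10
    assert res.p_value < 0.01


def test_dispersion_degenerate_distances():
    """All within-group distances equal: F = 0, p = 1."""
    # 4 points forming two congruent pairs
    d = np.array(
        [[0, 0.4, 0.9, 0.9],
         [0.4, 0, 0.9, 0.9],
         [0.9, 0.9, 0, 0.4],
         [0.9, 0.9, 0.4, 0]]
    )
    res = dispersion_homogeneity(pd.DataFrame(d), ["a", "a", "b", "b"], n_perm=99)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value == 1.0


def test_distance_tests_match_vegan_frozen_values():
    """Pseudo-F and centroid distances equal R vegan's adonis2/betadisper
    (type='centroid') outputs, computed once externally and frozen here."""
    from fruitniche.ordination import centroid_distances

    rng = np.random.default_rng(314)
    X = rng.uniform(0.1, 3.0, size=(12, 5)).round(4)
    d = bray_curtis(pd.DataFrame(X))
    groups = ["a", "b", "c", "d"] * 3
    assert permanova(d, groups, n_perm=9, seed=0).statistic == pytest.approx(
        0.9793739, abs=1e-7
    )
    res = dispersion_homogeneity(d, groups, n_perm=9, seed=0)
    assert res.statistic == pytest.approx(1.092102687, abs=1e-8)
    z_vegan = [0.106497, 0.100928, 0.159615, 0.138035, 0.196978, 0.174521,
               0.275554, 0.245199, 0.178449, 0.167271, 0.205132, 0.205389]
    np.testing.assert_allclose(centroid_distances(d, groups), z_vegan, atol=1e-6)


def test_permanova_null_uniform_p(toy):
    """Exchangeable rows: p-values spread over (0,1], no excess rejection."""
    rng = np.random.default_rng(77)
    groups = ["a", "b", "c", "d"] * 3
    ps = []
    for rep in range(200):
        X = rng.uniform(size=(12, 6))
        d = bray_curtis(pd.DataFrame(X))
        ps.append(permanova(d, groups, n_perm=199, seed=rep).p_value)
    assert np.mean(np.array(ps) <= 0.05) == pytest.approx(0.05, abs=0.04)
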