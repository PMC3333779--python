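"""Group tests, correlations, partial correlations, tree distances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from codonbias import (
    bias_distance_correlation,
    chi_square_independence,
    compare_trait_groups,
    kruskal_wallis,
    mann_whitney,
    pairwise_tree_distance,
    partial_correlation,
    pearson_correlation,
    random_tree,
    read_newick,
    select_remote_subset,
)

SEED = 11


# ------------------------------------------------------------ Mann-Whitney

def test_mann_whitney_identical_samples_p_one():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.p_value == pytest.approx(1.0)


def test_mann_whitney_disjoint_small_samples_exact():
    # U = 0; two-sided p = 2/20 over all C(6,3) labelings
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_exact_matches_scipy_on_tiefree_data():
    rng = np.random.default_rng(SEED)
    for n1, n2 in [(4, 5), (6, 6), (7, 3)]:
        a = rng.normal(size=n1)
        b = rng.normal(0.5, size=n2)
        ours = mann_whitney(a, b).p_value
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_mann_whitney_invariant_under_monotone_transform():
    rng = np.random.default_rng(SEED)
    a = rng.normal(size=15)
    b = rng.normal(0.8, size=12)
    base = mann_whitney(a, b)
    trans = mann_whitney(np.exp(a), np.exp(b))
    assert trans.p_value == pytest.approx(base.p_value)
    assert trans.statistic == pytest.approx(base.statistic)


def test_mann_whitney_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1, 2])


def test_mann_whitney_type_one_error_calibrated():
    """Null rejection rate at alpha = 0.05 over 1,000 replicates."""
    rng = np.random.default_rng(SEED)
    rejections = sum(
        mann_whitney(rng.normal(size=20), rng.normal(size=20)).p_value < 0.05
        for _ in range(1000))
    assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------- Kruskal-Wallis

def test_kruskal_wallis_constant_groups_h_zero():
    res = kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_wallis_two_groups_matches_mann_whitney_normal():
    """At k = 2 the H test is the square of the Mann-Whitney z (no
    continuity correction), so the p-values coincide."""
    rng = np.random.default_rng(SEED)
    a = rng.normal(size=25)
    b = rng.normal(0.6, size=30)
    kw = kruskal_wallis([a, b])
    mw = mann_whitney(a, b, use_continuity=False)
    assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)


def test_kruskal_wallis_needs_two_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])


def test_kruskal_wallis_type_one_error_calibrated():
    rng = np.random.default_rng(SEED + 1)
    rejections = sum(
        kruskal_wallis([rng.normal(size=15) for _ in range(4)]).p_value < 0.05
        for _ in range(1000))
    assert 0.03 <= rejections / 1000 <= 0.07


# ------------------------------------------------------------- chi-square

def test_chi_square_hand_value():
    # 2x2 table [[10,20],[20,10]]: all expected 15, chi2 = 4*25/15 = 20/3
    a = ["x"] * 30 + ["y"] * 30
    b = ["p"] * 10 + ["q"] * 20 + ["p"] * 20 + ["q"] * 10
    chi2, p, dof, _ = chi_square_independence(a, b)
    assert chi2 == pytest.approx(20 / 3)
    assert dof == 1


def test_chi_square_independent_table_zero():
    # counts exactly proportional to the margins
    a = (["x"] * 30 + ["y"] * 60)
    b = (["p"] * 10 + ["q"] * 20) + (["p"] * 20 + ["q"] * 40)
    chi2, p, _, _ = chi_square_independence(a, b)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_single_category_errors():
    with pytest.raises(ValueError):
        chi_square_independence(["x"] * 10, ["p"] * 5 + ["q"] * 5)


# ------------------------------------------------------------ correlations

def test_pearson_perfect_linear():
    x = np.arange(10.0)
    assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson_correlation(x, -x).r == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula():
    rng = np.random.default_rng(SEED)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    expected = (np.mean((x - x.mean()) * (y - y.mean()))
                / (x.std() * y.std()))
    assert pearson_correlation(x, y).r == pytest.approx(expected)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValueError, match="zero variance"):
        pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])


def test_partial_correlation_reduces_when_z_uncorrelated():
    # exact algebraic case: r_xz = r_yz = 0 -> r_xy.z = r_xy
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    z = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to both, mean 0
    r_plain = pearson_correlation(x, y).r
    res = partial_correlation(x, y, z)
    assert res.r == pytest.approx(r_plain)


def test_partial_correlation_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(SEED)
    z = rng.normal(size=200)
    x = z + rng.normal(size=200)
    y = 0.5 * z + rng.normal(size=200)
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
    res = partial_correlation(x, y, z)
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                        rel=1e-6)


def test_partial_correlation_removes_confounder():
    """x and y independent given z: plain r is large, partial r ~ 0."""
    rng = np.random.default_rng(SEED)
    n = 2000
    z = rng.normal(size=n)
    x = z + 0.8 * rng.normal(size=n)
    y = z + 0.8 * rng.normal(size=n)
    assert abs(pearson_correlation(x, y).r) > 0.3
    assert abs(partial_correlation(x, y, z).r) < 0.05


def test_partial_correlation_approaches_plain_with_noise_control():
    rng = np.random.default_rng(SEED)
    n = 5000
    x = rng.normal(size=n)
    y = 0.4 * x + rng.normal(size=n)
    z = rng.normal(size=n)  # pure noise control
    plain = pearson_correlation(x, y).r
    part = partial_correlation(x, y, z).r
    assert abs(plain - part) < 0.01


def test_partial_correlation_collinear_control_errors():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(ValueError, match="collinear"):
        partial_correlation(x, x.copy(), x.copy())


# ----------------------------------------------------------- tree distance

def test_pairwise_tree_distance_hand_values():
    tree = read_newick("((A:1,B:2):3,C:4);")
    assert pairwise_tree_distance(tree, "A", "B") == pytest.approx(3.0)
    assert pairwise_tree_distance(tree, "A", "C") == pytest.approx(8.0)
    assert pairwise_tree_distance(tree, "C", "C") == 0.0
    with pytest.raises(KeyError):
        pairwise_tree_distance(tree, "A", "Z")


def test_tree_distance_is_a_metric_on_random_trees():
    rng = np.random.default_rng(SEED)
    for _ in range(3):
        tree = random_tree([f"L{i}" for i in range(8)], rng)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        labels = sorted(taxa)
        d = {(a, b): pdm.patristic_distance(taxa[a], taxa[b])
             for a in labels for b in labels}
        for a, b, c in itertools.permutations(labels, 3):
            assert d[a, b] == pytest.approx(d[b, a])
            assert d[a, c] <= d[a, b] + d[b, c] + 1e-9
        for a in labels:
            assert d[a, a] == 0.0


def test_bias_distance_pair_counts_and_null():
    rng = np.random.default_rng(SEED)
    ids = [f"org{i}" for i in range(4)]
    tree = random_tree(ids, rng)
    prof = pd.DataFrame({"organism_id": ids,
                         "cai_ave": [0.4, 0.5, 0.6, 0.7]})
    result, pairs = bias_distance_correlation(prof, tree)
    assert len(pairs) == 6  # C(4, 2)


def test_bias_distance_degenerate_measure_errors():
    rng = np.random.default_rng(SEED)
    ids = [f"org{i}" for i in range(5)]
    tree = random_tree(ids, rng)
    prof = pd.DataFrame({"organism_id": ids, "cai_ave": [0.5] * 5})
    with pytest.raises(ValueError, match="zero variance"):
        bias_distance_correlation(prof, tree)


def test_bias_distance_needs_three_shared():
    rng = np.random.default_rng(SEED)
    tree = random_tree(["a", "b", "c", "d"], rng)
    prof = pd.DataFrame({"organism_id": ["a", "b"], "cai_ave": [0.4, 0.6]})
    with pytest.raises(ValueError, match=">= 3"):
        bias_distance_correlation(prof, tree)


# ------------------------------------------------------------ group joins

def _profiles_and_annotations():
    rng = np.random.default_rng(SEED)
    ids = [f"org{i}" for i in range(24)]
    prof = pd.DataFrame({
        "organism_id": ids,
        "cai_ave": np.r_[rng.normal(0.4, 0.02, 12),
                         rng.normal(0.8, 0.02, 12)]})
    annot = pd.DataFrame({
        "organism_id": ids,
        "habitat": ["specialized"] * 12 + ["multiple"] * 12,
        "oxygen": (["aerobic"] * 6 + ["anaerobic"] * 6
                   + ["facultative"] * 6 + ["microaerophilic"] * 6)})
    return prof, annot


def test_compare_trait_groups_two_group_dispatch():
    prof, annot = _profiles_and_annotations()
    res = compare_trait_groups(prof, annot, "habitat")
    assert res.test.startswith("mann-whitney")
    assert res.p_value < 0.01
    assert res.group_medians["specialized"] < res.group_medians["multiple"]


def test_compare_trait_groups_multi_group_dispatch():
    prof, annot = _profiles_and_annotations()
    res = compare_trait_groups(prof, annot, "oxygen")
    assert res.test == "kruskal-wallis"
    assert len(res.group_sizes) == 4


def test_compare_trait_groups_all_missing_errors():
    prof, annot = _profiles_and_annotations()
    annot["habitat"] = pd.NA
    with pytest.raises(ValueError, match="fewer than 2 groups"):
        compare_trait_groups(prof, annot, "habitat")


def test_compare_trait_groups_unknown_trait_errors():
    prof, annot = _profiles_and_annotations()
    with pytest.raises(KeyError, match="salinity"):
        compare_trait_groups(prof, annot, "salinity")


# ---------------------------------------------------------- remote subset

def test_select_remote_subset_greedy_maximin():
    tree = read_newick("(((A:0.1,B:0.1):0.1,C:5):1,(D:5,E:0.1):1);")
    picked = select_remote_subset(tree, 3, seed=SEED)
    assert len(picked) == 3
    assert len(set(picked)) == 3
    # the two long-branch leaves must be among any 3 remote picks
    assert {"C", "D"} <= set(picked)
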