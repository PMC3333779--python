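"""Comparative statistics for organism-scale codon bias.

Phenotype-group contrasts use rank-based tests (Mann-Whitney for two
groups, Kruskal-Wallis for more); trait interdependence a Pearson
chi-square; growth-rate/habitat/bias relations plain Pearson and
first-order partial correlations; and the phylogeny analysis relates
pairwise patristic distances to differences in CAI_ave.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import profiles_frame

#: largest per-group size at which Mann-Whitney is computed by exact
#: enumeration of all labelings
EXACT_ENUMERATION_MAX = 8


@dataclass
class GroupComparisonResult:
    trait: str
    test: str  # "mann-whitney" or "kruskal-wallis"
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    group_means: dict[str, float]


@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    r: float
    p_value: float
    n: int
    controlled: str | None = None


def _rank_sum_u(ranks: np.ndarray, idx, n1: int) -> float:
    return float(ranks[list(idx)].sum()) - n1 * (n1 + 1) / 2.0


def mann_whitney(a, b, *, use_continuity: bool = True,
                 trait: str = "", labels=("a", "b")) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test.

    For groups of at most 8 each the two-sided p-value is obtained by
    exhaustive enumeration of all C(n, n1) group labelings of the
    pooled sample (doubled smaller tail, capped at 1), which is exact
    even under ties.  Larger samples use the tie-corrected normal
    approximation, with continuity correction by default.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n2 = a.size, b.size
    u1 = _rank_sum_u(ranks, range(n1), n1)

    if n1 <= EXACT_ENUMERATION_MAX and n2 <= EXACT_ENUMERATION_MAX:
        us = np.array([
            _rank_sum_u(ranks, idx, n1)
            for idx in itertools.combinations(range(n1 + n2), n1)])
        p_lo = np.mean(us <= u1 + 1e-12)
        p_hi = np.mean(us >= u1 - 1e-12)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        test = "mann-whitney-exact"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic",
                                use_continuity=use_continuity)
        p = float(p)
        test = "mann-whitney"

    return GroupComparisonResult(
        trait=trait, test=test, statistic=u1, p_value=p,
        group_sizes={labels[0]: n1, labels[1]: n2},
        group_medians={labels[0]: float(np.median(a)),
                       labels[1]: float(np.median(b))},
        group_means={labels[0]: float(np.mean(a)),
                     labels[1]: float(np.mean(b))},
    )


def kruskal_wallis(groups, *, trait: str = "",
                   labels=None) -> GroupComparisonResult:
    """Kruskal-Wallis H test with tie correction, chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    labels = labels or [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # no variation at all: trivially null
    else:
        h, p = sps.kruskal(*groups)
    return GroupComparisonResult(
        trait=trait, test="kruskal-wallis", statistic=float(h),
        p_value=float(p),
        group_sizes={l: g.size for l, g in zip(labels, groups)},
        group_medians={l: float(np.median(g))
                       for l, g in zip(labels, groups)},
        group_means={l: float(np.mean(g)) for l, g in zip(labels, groups)},
    )


def chi_square_independence(trait_a, trait_b):
    """Pearson chi-square test of independence of two paired traits.

    Returns (statistic, p_value, dof, contingency table).  Expected
    cell counts below 5 trigger a warning; a trait with a single
    observed category is an error.
    """
    table = pd.crosstab(pd.Series(trait_a), pd.Series(trait_b))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("each trait needs >= 2 observed categories")
    chi2, p, dof, expected = sps.chi2_contingency(table.values,
                                                  correction=False)
    if (expected < 5).any():
        warnings.warn("expected cell counts < 5; chi-square p-value "
                      "approximate")
    return float(chi2), float(p), int(dof), table


def pearson_correlation(x, y, *, variables=("x", "y")) -> CorrelationResult:
    """Sample Pearson correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(variables=variables, r=float(r),
                             p_value=float(p), n=int(x.size))


def partial_correlation(x, y, z, *,
                        variables=("x", "y"),
                        controlled: str = "z") -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    Significance from t = r sqrt((n-3)/(1-r^2)) with n-3 df.  Binary
    variables (e.g. the 0/1 habitat code) enter as numerics, giving
    the point-biserial form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for a first-order partial correlation")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("control variable collinear with an input; "
                         "partial correlation undefined")
    r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(variables=variables, r=r, p_value=float(p),
                             n=n, controlled=controlled)


def _distance_matrix(tree: dendropy.Tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return pdm, taxa


def pairwise_tree_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Patristic distance: path length between two leaves via the MRCA."""
    pdm, taxa = _distance_matrix(tree)
    for leaf in (a, b):
        if leaf not in taxa:
            raise KeyError(f"leaf {leaf!r} not in tree")
    return float(pdm.patristic_distance(taxa[a], taxa[b]))


def bias_distance_correlation(profiles, tree: dendropy.Tree,
                              measure: str = "cai_ave"):
    """Correlate pairwise |Δmeasure| with patristic distance.

    Emits one row per unordered organism pair shared between the
    profile table and the tree, and the Pearson correlation over the
    pairs.  Returns (CorrelationResult, pair DataFrame).
    """
    prof = profiles_frame(profiles).set_index("organism_id")
    pdm, taxa = _distance_matrix(tree)
    shared = sorted(set(prof.index) & set(taxa))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} organisms shared between profiles and "
            "tree; need >= 3")
    rows = [
        {"organism_a": a, "organism_b": b,
         "delta_measure": abs(prof.loc[a, measure] - prof.loc[b, measure]),
         "tree_distance": float(pdm.patristic_distance(taxa[a], taxa[b]))}
        for a, b in itertools.combinations(shared, 2)]
    pairs = pd.DataFrame(rows)
    result = pearson_correlation(
        pairs["delta_measure"], pairs["tree_distance"],
        variables=(f"|delta {measure}|", "patristic distance"))
    return result, pairs


def compare_trait_groups(profiles, annotations: pd.DataFrame, trait: str,
                         measure: str = "cai_ave", *,
                         min_group: int = 3,
                         use_continuity: bool = True) -> GroupComparisonResult:
    """Compare a bias measure between phenotype groups.

    Joins profiles to annotations on organism_id, drops organisms with
    a missing trait and groups smaller than ``min_group``, then
    dispatches to Mann-Whitney (two groups) or Kruskal-Wallis (more).
    """
    prof = profiles_frame(profiles)
    if trait not in annotations.columns:
        raise KeyError(
            f"trait {trait!r} not in annotation columns "
            f"{sorted(annotations.columns)}")
    merged = prof.merge(annotations[["organism_id", trait]], on="organism_id")
    merged = merged.dropna(subset=[trait, measure])
    groups = {label: sub[measure].to_numpy()
              for label, sub in merged.groupby(trait, observed=True)
              if len(sub) >= min_group}
    if len(groups) < 2:
        raise ValueError(
            f"fewer than 2 groups with >= {min_group} members for "
            f"trait {trait!r}")
    labels = sorted(groups)
    if len(labels) == 2:
        res = mann_whitney(groups[labels[0]], groups[labels[1]],
                           use_continuity=use_continuity, trait=trait,
                           labels=labels)
    else:
        res = kruskal_wallis([groups[l] for l in labels], trait=trait,
                             labels=labels)
    return res


def select_remote_subset(tree: dendropy.Tree, k: int, *,
                         min_distance: float = 0.0,
                         seed: int = 0) -> list[str]:
    """Greedy maximin selection of phylogenetically remote leaves.

    Starting from a seeded random leaf, repeatedly adds the leaf whose
    minimum patristic distance to the already-selected set is largest,
    stopping at ``k`` leaves or when that minimum falls below
    ``min_distance``.
    """
    pdm, taxa = _distance_matrix(tree)
    labels = sorted(taxa)
    if k < 1 or k > len(labels):
        raise ValueError("k out of range")
    rng = np.random.default_rng(seed)
    selected = [labels[rng.integers(len(labels))]]
    remaining = [l for l in labels if l != selected[0]]
    while remaining and len(selected) < k:
        dists = {
            l: min(float(pdm.patristic_distance(taxa[l], taxa[s]))
                   for s in selected)
            for l in remaining}
        best = max(sorted(dists), key=dists.get)
        if dists[best] < min_distance:
            break
        selected.append(best)
        remaining.remove(best)
    return selected
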