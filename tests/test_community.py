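import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy import stats as sstats
from scipy.spatial.distance import pdist, squareform

import isobiome as ib


# ---------------------------------------------------------------------------
# Shannon


def test_shannon_single_taxon_zero():
    assert ib.shannon_diversity([7, 0, 0]) == pytest.approx(0.0)


def test_shannon_equal_taxa_log2():
    assert ib.shannon_diversity([5, 5, 5, 5]) == pytest.approx(2.0)


def test_shannon_hand_value():
    # -(1/2 log2 1/2 + 2 * 1/4 log2 1/4) = 1.5 bits
    assert ib.shannon_diversity([2, 1, 1]) == pytest.approx(1.5)


def test_shannon_all_zero_errors():
    with pytest.raises(ValueError):
        ib.shannon_diversity([0, 0])


# ---------------------------------------------------------------------------
# Faith's PD


def test_faith_pd_hand_paths(toy_tree):
    assert ib.faith_pd({"A"}, toy_tree) == pytest.approx(2.0)
    assert ib.faith_pd({"A", "B"}, toy_tree) == pytest.approx(3.0)
    assert ib.faith_pd({"A", "B", "C", "D"}, toy_tree) == pytest.approx(6.0)


def test_faith_pd_empty_sample_warns_zero(toy_tree, caplog):
    with caplog.at_level("WARNING", logger="isobiome"):
        assert ib.faith_pd(set(), toy_tree) == 0.0


def test_faith_pd_monotone_under_addition():
    rng = np.random.default_rng(21)
    tree = ib.simulate_tree(15, rng)
    leaves = [t.name for t in tree.tips()]
    obs: set = set()
    prev = 0.0
    for leaf in rng.permutation(leaves):
        obs.add(leaf)
        pd_now = ib.faith_pd(obs, tree)
        assert pd_now >= prev - 1e-12
        prev = pd_now


@pytest.mark.parametrize("seed", range(5))
def test_faith_pd_matches_skbio(seed):
    from skbio.diversity.alpha import faith_pd as sk_faith

    rng = np.random.default_rng(seed)
    tree = ib.simulate_tree(20, rng)
    fids = [t.name for t in tree.tips()]
    counts = rng.integers(0, 5, size=20)
    counts[0] = 1
    mine = ib.faith_pd(np.asarray(fids)[counts > 0], tree)
    assert mine == pytest.approx(sk_faith(counts, fids, tree), abs=1e-10)


# ---------------------------------------------------------------------------
# UniFrac


def test_unweighted_unifrac_hand_values(toy_tree):
    counts = pd.DataFrame(
        [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
        index=["ab", "cd", "ac"], columns=list("ABCD"),
    )
    table = ib.FeatureTable(counts)
    assert ib.unweighted_unifrac("ab", "ab", table, toy_tree) == pytest.approx(0.0)
    assert ib.unweighted_unifrac("ab", "cd", table, toy_tree) == pytest.approx(1.0)
    # unique branches B, C, int2 (3 of 5 observed) -> 0.6
    assert ib.unweighted_unifrac("ab", "ac", table, toy_tree) == pytest.approx(0.6)


def test_weighted_unifrac_hand_values(toy_tree):
    counts = pd.DataFrame(
        [[4, 0, 0, 0], [0, 6, 0, 0], [0, 0, 3, 0]],
        index=["a", "b", "c"], columns=list("ABCD"),
    )
    table = ib.FeatureTable(counts)
    assert ib.weighted_unifrac("a", "a", table, toy_tree) == pytest.approx(0.0)
    # A and B share the internal branch: normalized distance 0.5
    assert ib.weighted_unifrac("a", "b", table, toy_tree) == pytest.approx(0.5)
    # disjoint subtrees carry fully disjoint mass: 1.0
    assert ib.weighted_unifrac("a", "c", table, toy_tree) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(8))
def test_unifrac_matches_enumeration_oracle(seed):
    """Both variants equal skbio's independent per-branch enumeration."""
    from skbio.diversity import beta_diversity

    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(5, 20))
    tree = ib.simulate_tree(n_leaves, rng)
    fids = [t.name for t in tree.tips()]
    counts = rng.integers(0, 25, size=(5, n_leaves))
    counts[:, 0] += 1  # no empty samples
    ids = [f"s{i}" for i in range(5)]
    table = ib.FeatureTable(pd.DataFrame(counts, index=ids, columns=fids))
    uu = ib.unweighted_unifrac_matrix(table, tree)
    wu = ib.weighted_unifrac_matrix(table, tree)
    uu_ref = beta_diversity("unweighted_unifrac", counts, ids=ids, taxa=fids, tree=tree)
    wu_ref = beta_diversity(
        "weighted_unifrac", counts, ids=ids, taxa=fids, tree=tree, normalized=True
    )
    assert np.abs(uu.data - uu_ref.data).max() < 1e-10
    assert np.abs(wu.data - wu_ref.data).max() < 1e-10
    assert uu.data.max() <= 1.0 + 1e-12 and uu.data.min() >= 0.0
    assert np.allclose(uu.data, uu.data.T) and np.allclose(np.diag(uu.data), 0.0)


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_recovers_points_on_a_line():
    x = np.array([0.0, 1.0, 3.0, 6.0])
    d = np.abs(x[:, None] - x[None, :])
    ordn = ib.pcoa(skbio.DistanceMatrix(d, ids=list("wxyz")))
    axis1 = ordn.samples[:, 0]
    gaps = np.abs(np.diff(axis1))
    assert gaps == pytest.approx([1.0, 2.0, 3.0], abs=1e-8)


def test_pcoa_equilateral_has_two_equal_eigenvalues():
    d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    ordn = ib.pcoa(skbio.DistanceMatrix(d, ids=list("abc")))
    pos = ordn.eigenvalues[ordn.eigenvalues > 1e-10]
    assert len(pos) == 2
    assert pos[0] == pytest.approx(pos[1])


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(9, 4))
    d = squareform(pdist(pts))
    ordn = ib.pcoa(skbio.DistanceMatrix(d, ids=[f"p{i}" for i in range(9)]))
    rec = squareform(pdist(ordn.samples))
    assert np.abs(rec - d).max() < 1e-8


def test_pcoa_rejects_asymmetric():
    import isobiome.community as comm

    class Fake:
        data = np.array([[0, 1.0], [2.0, 0]])
        ids = ("a", "b")

    with pytest.raises(ValueError, match="symmetric"):
        comm.pcoa(Fake())


def test_biplot_loadings_rank_features(toy_tree):
    counts = pd.DataFrame(
        [[10, 0, 0, 1], [9, 1, 0, 1], [0, 0, 10, 1], [0, 1, 9, 1]],
        index=["s1", "s2", "s3", "s4"], columns=list("ABCD"),
    )
    table = ib.FeatureTable(counts)
    dm = ib.weighted_unifrac_matrix(table, toy_tree)
    ordn = ib.pcoa(dm)
    top = ib.biplot_loadings(ordn, table, n_top=2)
    assert set(top.index) <= {"A", "C"}  # the axis-driving features


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP


def _two_cloud_dm(rng, n_per=5, sep=4.0):
    pts = np.vstack(
        [rng.normal(0, 1, size=(n_per, 3)), rng.normal(sep, 1, size=(n_per, 3))]
    )
    ids = [f"s{i}" for i in range(2 * n_per)]
    return skbio.DistanceMatrix(squareform(pdist(pts)), ids=ids), ["a"] * n_per + ["b"] * n_per


def test_permanova_statistic_matches_skbio():
    rng = np.random.default_rng(12)
    dm, groups = _two_cloud_dm(rng)
    mine = ib.permanova(dm, groups, n_perm=99, seed=0)
    ref = skbio.stats.distance.permanova(dm, groups, permutations=99)
    assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-10)
    assert mine.p_value <= 0.05
    assert 0 < mine.effect_size < 1


def test_permanova_exact_enumeration_on_4_samples():
    """Sampled permutation p converges to the exact all-permutation null."""
    d = np.array(
        [
            [0.0, 0.3, 2.0, 2.2],
            [0.3, 0.0, 2.1, 2.4],
            [2.0, 2.1, 0.0, 0.4],
            [2.2, 2.4, 0.0 + 0.4, 0.0],
        ]
    )
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    dm = skbio.DistanceMatrix(d, ids=list("wxyz"))
    groups = ["a", "a", "b", "b"]
    import isobiome.community as comm

    f_obs, _ = comm._permanova_f(d**2, comm._group_indices(groups))
    stats_all = []
    for perm in itertools.permutations(groups):
        f, _ = comm._permanova_f(d**2, comm._group_indices(list(perm)))
        stats_all.append(f)
    exact = np.mean([f >= f_obs for f in stats_all])
    mine = ib.permanova(dm, groups, n_perm=4999, seed=7)
    assert abs(mine.p_value - exact) < 0.02


def test_permanova_degenerate_groupings_rejected():
    d = skbio.DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]), ids=list("abc"))
    with pytest.raises(ValueError):
        ib.permanova(d, ["g", "g", "g"])  # single group
    with pytest.raises(ValueError):
        ib.permanova(d, ["g", "g", "h"])  # group of size 1


def test_permanova_seeded_reproducibility():
    rng = np.random.default_rng(3)
    dm, groups = _two_cloud_dm(rng, sep=0.5)
    p1 = ib.permanova(dm, groups, n_perm=199, seed=42).p_value
    p2 = ib.permanova(dm, groups, n_perm=199, seed=42).p_value
    assert p1 == p2


def test_permdisp_translation_invariance():
    """Identical clouds translated apart: location differs, dispersion equal."""
    rng = np.random.default_rng(9)
    cloud = rng.normal(0, 1, size=(6, 3))
    pts = np.vstack([cloud, cloud + 10.0])
    dm = skbio.DistanceMatrix(
        squareform(pdist(pts)), ids=[f"s{i}" for i in range(12)]
    )
    groups = ["a"] * 6 + ["b"] * 6
    res = ib.permdisp(dm, groups, n_perm=199, seed=1)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value > 0.5


def test_permdisp_detects_spread_difference():
    rng = np.random.default_rng(10)
    pts = np.vstack(
        [rng.normal(0, 0.2, size=(8, 3)), rng.normal(0, 3.0, size=(8, 3))]
    )
    dm = skbio.DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(16)])
    groups = ["tight"] * 8 + ["spread"] * 8
    res = ib.permdisp(dm, groups, n_perm=999, seed=2)
    assert res.statistic > 10
    assert res.p_value <= 0.05


@pytest.mark.parametrize("seed", range(5))
def test_permdisp_f_matches_reference(seed):
    rng = np.random.default_rng(seed)
    dm, groups = _two_cloud_dm(rng, n_per=6, sep=1.0)
    mine = ib.permdisp(dm, groups, n_perm=49, seed=0)
    ref = skbio.stats.distance.permdisp(
        dm, groups, test="centroid", permutations=49, dimensions=12
    )
    assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-6)


# ---------------------------------------------------------------------------
# Rank / t tests


def test_identical_groups_t_zero_p_one():
    res = ib.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_mann_whitney_hand_enumerated_u():
    res = ib.mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(0.0)


@pytest.mark.parametrize("seed", range(5))
def test_rank_tests_match_reference_routines(seed):
    rng = np.random.default_rng(seed)
    x = np.round(rng.normal(size=12), 1)  # rounding induces ties
    y = np.round(rng.normal(0.5, 1, size=15), 1)
    z = np.round(rng.normal(1.0, 1, size=10), 1)

    kw = ib.kruskal_wallis(
        np.concatenate([x, y, z]), ["x"] * 12 + ["y"] * 15 + ["z"] * 10
    )
    ref = sstats.kruskal(x, y, z)
    assert kw.statistic == pytest.approx(ref.statistic, abs=1e-8)
    assert kw.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    mw = ib.mann_whitney(x, y)
    ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert mw.statistic == pytest.approx(ref.statistic, abs=1e-8)
    assert mw.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    tt = ib.student_t(x, y)
    ref = sstats.ttest_ind(x, y, equal_var=True)
    assert tt.statistic == pytest.approx(ref.statistic, abs=1e-8)
    assert tt.p_value == pytest.approx(ref.pvalue, abs=1e-8)

def test_wilcoxon_matches_reference():
    rng = np.random.default_rng(17)
    a = rng.normal(size=20)
    b = a + rng.normal(0.4, 0.5, size=20)
    mine = ib.wilcoxon_signed_rank(a, b)
    ref = sstats.wilcoxon(a, b, method="approx", correction=False)
    # scipy reports min(W+, W-); ours is W+; p-values must agree
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)


def test_all_tied_rank_test_warns_p_one(caplog):
    with caplog.at_level("WARNING", logger="isobiome"):
        res = ib.kruskal_wallis([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
    assert res.p_value == 1.0


def test_rank_and_t_dispatch():
    res = ib.rank_and_t_tests([1, 2, 3, 4], ["a", "a", "b", "b"], test="student_t")
    assert res.test == "student_t"
    with pytest.raises(ValueError, match="unknown test"):
        ib.rank_and_t_tests([1, 2], ["a", "b"], test="anova")
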