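"""Phylogenetic diversity, UniFrac distances, PCoA, and group tests.

Everything here is computed directly from first principles — branch
traversals for Faith's PD and UniFrac, double-centering for PCoA,
Anderson's partition for PERMANOVA, centroid dispersions for PERMDISP, and
tie-corrected classical rank/t statistics — with established library
implementations used only as independent cross-checks in the test-suite.

Conventions: Shannon in bits (base 2) by default; Faith's PD includes the
branch into the root's child subtrees (the path union from the root);
weighted UniFrac normalized by default; PERMANOVA/PERMDISP permute raw
labels with a one-sided upper-tail p and +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.stats import rankdata

from .io import FeatureTable, logger


# ---------------------------------------------------------------------------
# Alpha diversity


def shannon_diversity(counts, base: float = 2.0) -> float:
    """Shannon entropy of one sample's count vector (bits when base 2)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero sample has undefined Shannon diversity")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _node_index(tree: skbio.TreeNode):
    """Postorder non-root nodes, their lengths, and leaf-membership masks."""
    leaves = [t.name for t in tree.tips()]
    leaf_pos = {name: i for i, name in enumerate(leaves)}
    nodes, lengths, masks = [], [], []
    for node in tree.postorder(include_self=False):
        mask = np.zeros(len(leaves), dtype=bool)
        if node.is_tip():
            mask[leaf_pos[node.name]] = True
        else:
            for t in node.tips():
                mask[leaf_pos[t.name]] = True
        nodes.append(node)
        lengths.append(node.length or 0.0)
        masks.append(mask)
    return leaves, np.asarray(lengths), np.vstack(masks)


def faith_pd(observed_features, tree: skbio.TreeNode) -> float:
    """Faith's phylogenetic diversity: total branch length spanning a sample.

    Sums branch lengths over the union of root-to-leaf paths of the observed
    features.  Features absent from the tree are dropped with a warning; an
    empty sample yields 0 with a warning.
    """
    leaves, lengths, masks = _node_index(tree)
    obs = set(observed_features)
    missing = obs - set(leaves)
    if missing:
        logger.warning("features absent from tree ignored by faith_pd: %s", sorted(missing))
        obs -= missing
    if not obs:
        logger.warning("empty sample: Faith's PD = 0")
        return 0.0
    present = np.isin(np.asarray(leaves), sorted(obs))
    on_path = (masks & present).any(axis=1)
    return float(lengths[on_path].sum())


# ---------------------------------------------------------------------------
# UniFrac


def _branch_masses(table: FeatureTable, tree: skbio.TreeNode):
    leaves, lengths, masks = _node_index(tree)
    missing = set(table.feature_ids) - set(leaves)
    if missing:
        raise ValueError(f"features absent from tree: {sorted(missing)}")
    counts = (
        table.counts.reindex(columns=leaves, fill_value=0).to_numpy(dtype=float)
    )
    depths = counts.sum(axis=1)
    if np.any(depths == 0):
        empty = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"samples with no observed features: {empty}")
    props = counts / depths[:, None]
    # samples x branches: proportion (or presence) of each sample under each branch
    mass = props @ masks.T.astype(float)
    presence = (counts > 0) @ masks.T.astype(float) > 0
    return lengths, mass, presence


def unweighted_unifrac_matrix(table: FeatureTable, tree: skbio.TreeNode) -> skbio.DistanceMatrix:
    """Pairwise unweighted UniFrac: unique over observed branch length."""
    lengths, _, presence = _branch_masses(table, tree)
    n = presence.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = presence[i], presence[j]
            union = (a | b) @ lengths
            uniq = (a ^ b) @ lengths
            d[i, j] = d[j, i] = uniq / union if union > 0 else 0.0
    return skbio.DistanceMatrix(d, ids=table.sample_ids)


def weighted_unifrac_matrix(
    table: FeatureTable, tree: skbio.TreeNode, normalized: bool = True
) -> skbio.DistanceMatrix:
    """Pairwise weighted UniFrac over branch abundance masses.

    Raw form: Σ_b l_b |p_ib − p_jb|; normalized divides by
    Σ_b l_b (p_ib + p_jb).
    """
    lengths, mass, _ = _branch_masses(table, tree)
    n = mass.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = lengths @ np.abs(mass[i] - mass[j])
            if normalized:
                den = lengths @ (mass[i] + mass[j])
                d[i, j] = d[j, i] = num / den if den > 0 else 0.0
            else:
                d[i, j] = d[j, i] = num
    return skbio.DistanceMatrix(d, ids=table.sample_ids)


def unweighted_unifrac(sample_i, sample_j, table: FeatureTable, tree) -> float:
    """Unweighted UniFrac between two named samples."""
    if sample_i == sample_j:
        return 0.0
    sub = FeatureTable(table.counts.loc[[sample_i, sample_j]])
    return float(unweighted_unifrac_matrix(sub, tree)[sample_i, sample_j])


def weighted_unifrac(sample_i, sample_j, table: FeatureTable, tree, normalized=True) -> float:
    """Weighted UniFrac between two named samples."""
    if sample_i == sample_j:
        return 0.0
    sub = FeatureTable(table.counts.loc[[sample_i, sample_j]])
    return float(weighted_unifrac_matrix(sub, tree, normalized)[sample_i, sample_j])


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a distance matrix.

    ``samples`` holds coordinates on the positive-eigenvalue axes, ordered
    by descending eigenvalue; all eigenvalues (including negative ones) are
    reported.  ``negative_coords`` are the coordinates on |negative| axes,
    used for the imaginary-axis correction in PERMDISP.
    """

    sample_ids: list
    samples: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_coords: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.samples.shape[1])]
        return pd.DataFrame(self.samples, index=self.sample_ids, columns=cols)


def pcoa(dm: skbio.DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates by double-centering + eigendecomposition.

    Negative eigenvalues are retained and reported; coordinates are built
    from positive axes only.  Proportion explained is relative to the sum
    of positive eigenvalues.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    neg = evals < -tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    neg_coords = evecs[:, neg] * np.sqrt(-evals[neg])
    prop = np.zeros_like(evals)
    pos_sum = evals[pos].sum()
    if pos_sum > 0:
        prop[pos] = evals[pos] / pos_sum
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return OrdinationResult(
        sample_ids=list(dm.ids),
        samples=coords,
        eigenvalues=evals,
        proportion_explained=prop,
        negative_coords=neg_coords,
    )


def biplot_loadings(
    ordination: OrdinationResult, table: FeatureTable, n_top: int = 5, n_axes: int = 2
) -> pd.DataFrame:
    """Feature loadings: relative-abundance-weighted mean sample coordinates.

    Features are ranked by loading-vector magnitude; the top ``n_top`` are
    the biplot arrows.
    """
    rel = table.relative_abundance().loc[ordination.sample_ids]
    weights = rel / rel.sum(axis=0)
    coords = ordination.samples[:, :n_axes]
    load = weights.T.to_numpy() @ coords
    out = pd.DataFrame(
        load, index=rel.columns, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    out["magnitude"] = np.linalg.norm(load, axis=1)
    return out.sort_values("magnitude", ascending=False).head(n_top)


# ---------------------------------------------------------------------------
# Group tests


@dataclass
class GroupTestResult:
    """Outcome of one group-comparison test."""

    test: str
    statistic: float
    p_value: float
    effect_size: float = np.nan  # R^2 for PERMANOVA
    n_permutations: int = 0
    seed: int | None = None


def _group_indices(grouping) -> list[np.ndarray]:
    g = np.asarray(grouping)
    return [np.flatnonzero(g == lev) for lev in pd.unique(g)]


def _permanova_f(d2: np.ndarray, groups: list[np.ndarray]):
    n = d2.shape[0]
    a = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in groups:
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dm: skbio.DistanceMatrix, grouping, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Permutational MANOVA (Anderson's pseudo-F partition of squared distances).

    Raw labels are permuted; p is one-sided upper-tail with +1 correction.
    """
    g = np.asarray(grouping)
    if len(g) != len(dm.ids):
        raise ValueError("grouping length must match the distance matrix")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = levels[counts < 2].tolist()
        raise ValueError(f"groups of size 1 are not allowed: {small}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _permanova_f(d2, _group_indices(g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(g)
        f_perm, _ = _permanova_f(d2, _group_indices(perm))
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return GroupTestResult(
        test="permanova", statistic=float(f_obs), p_value=float(p),
        effect_size=float(r2), n_permutations=n_perm, seed=seed,
    )


def _dispersion_distances(dm: skbio.DistanceMatrix, grouping) -> np.ndarray:
    """Per-sample distance to its group centroid in corrected PCoA space.

    Squared real-axis distance minus squared imaginary-axis distance
    (Anderson's correction for non-Euclidean distance matrices); negative
    corrected values are truncated at 0.
    """
    ord_ = pcoa(dm)
    g = np.asarray(grouping)
    z2 = np.zeros(len(g))
    for idx in _group_indices(g):
        for coords, sign in ((ord_.samples, +1), (ord_.negative_coords, -1)):
            if coords.shape[1] == 0:
                continue
            centroid = coords[idx].mean(axis=0)
            z2[idx] += sign * ((coords[idx] - centroid) ** 2).sum(axis=1)
    return np.sqrt(np.maximum(z2, 0.0))


def _anova_f(values: np.ndarray, groups: list[np.ndarray]) -> float:
    grand = values.mean()
    a = len(groups)
    n = len(values)
    ssb = sum(len(i) * (values[i].mean() - grand) ** 2 for i in groups)
    ssw = sum(((values[i] - values[i].mean()) ** 2).sum() for i in groups)
    return (ssb / (a - 1)) / (ssw / (n - a))


def permdisp(
    dm: skbio.DistanceMatrix, grouping, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Homogeneity of multivariate dispersions (centroid variant).

    One-way ANOVA F on distances to group centroids in corrected PCoA
    space; permutation p on F by permuting those distances among samples.
    """
    g = np.asarray(grouping)
    if len(g) != len(dm.ids):
        raise ValueError("grouping length must match the distance matrix")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    dists = _dispersion_distances(dm, g)
    groups = _group_indices(g)
    f_obs = _anova_f(dists, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_groups = _group_indices(rng.permutation(g))
        if _anova_f(dists, perm_groups) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return GroupTestResult(
        test="permdisp", statistic=float(f_obs), p_value=float(p),
        n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Classical rank / t tests (tie-corrected, two-sided)


def kruskal_wallis(values, grouping) -> GroupTestResult:
    v = np.asarray(values, dtype=float)
    groups = _group_indices(grouping)
    if len(groups) < 2 or any(len(i) < 2 for i in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = len(v)
    ranks = rankdata(v)
    h = 12.0 / (n * (n + 1)) * sum(ranks[i].sum() ** 2 / len(i) for i in groups) - 3 * (n + 1)
    _, tie_counts = np.unique(v, return_counts=True)
    correction = 1 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:
        logger.warning("all values tied; Kruskal-Wallis p set to 1")
        return GroupTestResult("kruskal_wallis", 0.0, 1.0)
    h /= correction
    p = float(stats.chi2.sf(h, df=len(groups) - 1))
    return GroupTestResult("kruskal_wallis", float(h), p)


def mann_whitney(x, y) -> GroupTestResult:
    """Mann–Whitney U (statistic = U of the first group), normal approximation
    with midranks, tie-corrected variance, and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        logger.warning("all values tied; Mann-Whitney p set to 1")
        return GroupTestResult("mann_whitney", float(u1), 1.0)
    z = (np.abs(u1 - mu) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))
    return GroupTestResult("mann_whitney", float(u1), p)


def student_t(x, y) -> GroupTestResult:
    """Classical two-sample pooled-variance t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return GroupTestResult("student_t", 0.0, 1.0)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * stats.t.sf(abs(t), df=n1 + n2 - 2))
    return GroupTestResult("student_t", float(t), p)


def wilcoxon_signed_rank(x, y=None) -> GroupTestResult:
    """Paired Wilcoxon signed-rank (statistic = W+, sum of positive ranks).

    Normal approximation with tie-corrected variance, no continuity
    correction; zero differences are dropped.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if len(d) < 1:
        logger.warning("no nonzero pair differences; Wilcoxon p set to 1")
        return GroupTestResult("wilcoxon_signed_rank", 0.0, 1.0)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var == 0:
        return GroupTestResult("wilcoxon_signed_rank", float(w_plus), 1.0)
    z = (w_plus - mu) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return GroupTestResult("wilcoxon_signed_rank", float(w_plus), p)


def rank_and_t_tests(values, grouping=None, paired=None, test: str = "kruskal_wallis") -> GroupTestResult:
    """Dispatch to the classical test named by ``test``.

    Two-group tests expect ``grouping`` with exactly two levels;
    ``wilcoxon_signed_rank`` expects ``paired`` (the second series).
    """
    if test == "kruskal_wallis":
        return kruskal_wallis(values, grouping)
    if test in ("mann_whitney", "student_t"):
        idx = _group_indices(grouping)
        if len(idx) != 2:
            raise ValueError(f"{test} needs exactly 2 groups")
        v = np.asarray(values, dtype=float)
        fn = mann_whitney if test == "mann_whitney" else student_t
        return fn(v[idx[0]], v[idx[1]])
    if test == "wilcoxon_signed_rank":
        return wilcoxon_signed_rank(values, paired)
    raise ValueError(f"unknown test {test!r}")
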