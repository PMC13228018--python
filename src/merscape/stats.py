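"""Multivariate and rank statistics for gene-content comparisons.

Bray–Curtis dissimilarity, PERMANOVA (pseudo-F with free label permutation,
exact enumeration when feasible), homogeneity of multivariate dispersion
(PCoA-embedded distance-to-centroid, permutation F), Kruskal–Wallis with
Bonferroni-corrected Dunn post hoc, the dual Pearson/Spearman reporting rule
(an association is reported only when significant under both), and PCA/PCoA
ordination are implemented here directly on numpy arrays; scipy supplies
only the generic ingredients (rank transforms, chi-square/normal/F tails,
hierarchical-clustering linkage).

All permutation procedures take an integer seed and are bit-reproducible.
p-values from sampled permutations use the (b+1)/(m+1) convention; exhaustive
enumeration yields exact p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

_EPS = 1e-10


# ---------------------------------------------------------------------------
# dissimilarity


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def bray_curtis(counts: pd.DataFrame | np.ndarray) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis dissimilarity between non-negative count rows.

    ``d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk)``; a pair of all-zero
    rows has dissimilarity 0 by convention.  Values lie in [0, 1].
    """
    if isinstance(counts, pd.DataFrame):
        labels = [str(i) for i in counts.index]
        x = counts.to_numpy(dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
        labels = [str(i) for i in range(x.shape[0])]
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if (x < 0).any():
        raise ValueError("Bray–Curtis requires non-negative entries")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(labels=labels, d=d)


def hcluster(D: DissimilarityMatrix, linkage: str = "average") -> str:
    """Hierarchical clustering of a dissimilarity matrix as a Newick string.

    Each merge sits at half its merge height (the UPGMA convention), so on
    ultrametric input the leaf-to-leaf path lengths reproduce the input
    distances.  scipy's deterministic agglomeration order makes the output
    reproducible.
    """
    from scipy.cluster.hierarchy import linkage as _linkage, to_tree
    from scipy.spatial.distance import squareform

    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    z = _linkage(squareform(D.d, checks=False), method=linkage)
    root = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist / 2.0
        if node.is_leaf():
            return f"{D.labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist / 2.0)
        right = render(node.right, node.dist / 2.0)
        return f"({left},{right}):{length:.10g}"

    if root.is_leaf():
        return f"{D.labels[root.id]}:0;"
    left = render(root.left, root.dist / 2.0)
    right = render(root.right, root.dist / 2.0)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None = None


def _multiset_permutations(items: list):
    """Distinct permutations of a multiset, lexicographic order."""
    items = sorted(items)
    n = len(items)
    counts: dict = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    keys = sorted(counts)
    out: list = [None] * n

    def rec(depth: int):
        if depth == n:
            yield tuple(out)
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                out[depth] = k
                yield from rec(depth + 1)
                counts[k] += 1

    yield from rec(0)


def _count_arrangements(labels: np.ndarray) -> int:
    _, cnt = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in cnt:
        total //= math.factorial(int(c))
    return total


def _permanova_stats(
    d2: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, float, float]:
    """(SS_total, SS_within, pseudo_F) for one labelling (codes 0..g-1)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        if ng > 1:
            sub = d2[np.ix_(mask, mask)]
            ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= _EPS * max(ss_total, 1.0):
        f = math.inf if ss_between > _EPS * max(ss_total, 1.0) else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    return ss_total, ss_within, f


def _batch_pseudo_f(d2: np.ndarray, code_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """pseudo-F for many labellings at once (rows of ``code_matrix``)."""
    m, n = code_matrix.shape
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = np.zeros(m)
    for g in range(n_groups):
        mask = (code_matrix == g).astype(float)  # m x n
        ng = mask[0].sum()  # group sizes are permutation-invariant
        quad = np.einsum("mi,ij,mj->m", mask, d2, mask) / 2.0
        ss_within += quad / ng
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f[ss_within <= _EPS * max(ss_total, 1.0)] = np.inf
    return f


def permanova(
    D: DissimilarityMatrix,
    labels,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 10_000,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    ``SS_total = (1/n) Σ_{i<j} d_ij²``; within-group sums analogously per
    group; ``pseudo_F = (SS_b/(g-1)) / (SS_w/(n-g))``.  The p-value permutes
    raw labels freely.  When the number of distinct label arrangements is at
    most ``exhaustive_limit`` they are all enumerated and p is exact;
    otherwise ``n_perm`` random permutations are drawn and
    ``p = (b+1)/(m+1)``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(D.labels):
        raise ValueError("labels length does not match matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.any(np.bincount(codes) == len(labels)):
        raise ValueError("one group contains all samples")
    d2 = D.d**2
    ss_total, ss_within, f_obs = _permanova_stats(d2, codes, g)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    n_arr = _count_arrangements(codes)
    if n_arr <= exhaustive_limit:
        perms = np.array(list(_multiset_permutations(list(codes))), dtype=int)
        f_perm = _batch_pseudo_f(d2, perms, g)
        b = int(np.sum(f_perm >= f_obs - _EPS))
        return PermanovaResult(
            pseudo_F=f_obs,
            R2=r2,
            p_value=b / n_arr,
            n_permutations=n_arr,
            exhaustive=True,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    f_perm = _batch_pseudo_f(d2, perms, g)
    b = int(np.sum(f_perm >= f_obs - _EPS))
    return PermanovaResult(
        pseudo_F=f_obs,
        R2=r2,
        p_value=(b + 1) / (n_perm + 1),
        n_permutations=n_perm,
        exhaustive=False,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dispersion homogeneity


@dataclass
class DispersionResult:
    group_dispersions: dict[str, float]
    F_stat: float
    p_value: float
    n_permutations: int
    degenerate: bool = False
    seed: int | None = None


def _pcoa_embed(D: DissimilarityMatrix, tol: float = 1e-9):
    """Real and imaginary-axis coordinates from classical scaling."""
    n = D.d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (D.d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals).max(), 1.0)
    pos = evals > tol * scale
    neg = evals < -tol * scale
    x_pos = evecs[:, pos] * np.sqrt(evals[pos])
    x_neg = evecs[:, neg] * np.sqrt(-evals[neg])
    return x_pos, x_neg, evals


def _anova_f(values: np.ndarray, codes: np.ndarray, g: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for k in range(g):
        grp = values[codes == k]
        ss_b += len(grp) * (grp.mean() - grand) ** 2
        ss_w += ((grp - grp.mean()) ** 2).sum()
    if ss_w <= _EPS * max(ss_b + ss_w, 1.0):
        return math.inf if ss_b > _EPS else 0.0
    return (ss_b / (g - 1)) / (ss_w / (n - g))


def betadisper(
    D: DissimilarityMatrix, labels, n_perm: int = 999, seed: int = 0
) -> DispersionResult:
    """Homogeneity of multivariate dispersions around group centroids.

    Samples are embedded by PCoA; each sample's squared distance to its
    group centroid is the positive-axis squared distance minus the
    imaginary-axis squared distance (floored at 0).  The F statistic is a
    one-way ANOVA on those distances; the p-value permutes group labels
    over the fixed distances.
    """
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    x_pos, x_neg, _ = _pcoa_embed(D)
    n = len(labels)
    z2 = np.zeros(n)
    for k in range(g):
        mask = codes == k
        c_pos = x_pos[mask].mean(axis=0) if x_pos.size else np.zeros(0)
        c_neg = x_neg[mask].mean(axis=0) if x_neg.size else np.zeros(0)
        d_pos = ((x_pos[mask] - c_pos) ** 2).sum(axis=1) if x_pos.size else 0.0
        d_neg = ((x_neg[mask] - c_neg) ** 2).sum(axis=1) if x_neg.size else 0.0
        z2[mask] = np.maximum(d_pos - d_neg, 0.0)
    z = np.sqrt(z2)
    disp = {str(uniq[k]): float(z[codes == k].mean()) for k in range(g)}
    if np.allclose(z, z[0], atol=1e-12):
        return DispersionResult(
            group_dispersions=disp,
            F_stat=0.0,
            p_value=1.0,
            n_permutations=0,
            degenerate=True,
            seed=seed,
        )
    f_obs = _anova_f(z, codes, g)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        b += _anova_f(z, rng.permutation(codes), g) >= f_obs - _EPS
    return DispersionResult(
        group_dispersions=disp,
        F_stat=f_obs,
        p_value=(b + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank tests


@dataclass
class RankTestResult:
    H: float
    p_value: float
    pairwise: list[tuple[tuple[str, str], float, float, float]] = field(
        default_factory=list
    )  # ((group_a, group_b), dunn_z, raw_p, adjusted_p)


def kruskal_dunn(values, labels, alpha: float = 0.05) -> RankTestResult:
    """Kruskal–Wallis (tie-corrected) with Bonferroni-Dunn pairwise post hoc.

    Dunn z uses pooled mid-ranks with tie correction; two-sided normal
    p-values are multiplied by the number of pairs (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 groups")
    groups = [values[labels == u] for u in uniq]
    if any(len(grp) == 0 for grp in groups):
        raise ValueError("empty group")
    if np.allclose(values, values[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    n = len(values)
    ranks = sps.rankdata(values)
    # tie correction for Dunn's variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    mean_ranks = {u: ranks[labels == u].mean() for u in uniq}
    sizes = {u: int((labels == u).sum()) for u in uniq}
    n_pairs = g * (g - 1) // 2
    pairwise = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = uniq[i], uniq[j]
            se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            raw = 2.0 * sps.norm.sf(abs(z))
            pairwise.append(
                ((str(a), str(b)), float(z), float(raw), min(1.0, raw * n_pairs))
            )
    return RankTestResult(H=float(h), p_value=float(p), pairwise=pairwise)


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    reported: bool
    degenerate: bool = False
    alpha: float = 0.05


def dual_correlation(
    x, y, alpha: float = 0.05, exact: bool = False
) -> CorrelationReport:
    """Pearson + Spearman with the dual-significance reporting rule.

    An association is ``reported`` only when both tests are individually
    significant at ``alpha``.  With ``exact=True`` and n <= 10, p-values are
    computed by full permutation enumeration instead of the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationReport(
            pearson_r=math.nan,
            pearson_p=1.0,
            spearman_rho=math.nan,
            spearman_p=1.0,
            reported=False,
            degenerate=True,
            alpha=alpha,
        )
    if exact and len(x) <= 10:
        import itertools

        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        r_obs = float(sps.pearsonr(x, y).statistic)
        rho_obs = float(sps.pearsonr(rx, ry).statistic)
        count_r = count_rho = total = 0
        for perm in itertools.permutations(range(len(x))):
            yp = y[list(perm)]
            count_r += abs(sps.pearsonr(x, yp).statistic) >= abs(r_obs) - _EPS
            count_rho += (
                abs(sps.pearsonr(rx, ry[list(perm)]).statistic)
                >= abs(rho_obs) - _EPS
            )
            total += 1
        p_r, p_rho = count_r / total, count_rho / total
        return CorrelationReport(
            pearson_r=r_obs,
            pearson_p=p_r,
            spearman_rho=rho_obs,
            spearman_p=p_rho,
            reported=(p_r < alpha and p_rho < alpha),
            alpha=alpha,
        )
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    reported = bool(pr.pvalue < alpha and sr.pvalue < alpha)
    return CorrelationReport(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        reported=reported,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ordination


@dataclass
class Ordination:
    coordinates: np.ndarray  # items x axes
    explained: np.ndarray  # fraction of variance per axis, non-increasing
    method: str  # "PCA" | "PCoA"
    labels: list[str] = field(default_factory=list)
    negative_eigenvalue_mass: float = 0.0
    dropped_columns: list[str] = field(default_factory=list)


def pca(X: pd.DataFrame | np.ndarray) -> Ordination:
    """PCA on the correlation structure (columns centered, unit sample SD).

    Constant columns are dropped with a warning.  Axis signs are fixed so
    each axis's largest-magnitude loading is positive.
    """
    import logging

    if isinstance(X, pd.DataFrame):
        labels = [str(i) for i in X.index]
        colnames = [str(c) for c in X.columns]
        x = X.to_numpy(dtype=float)
    else:
        x = np.asarray(X, dtype=float)
        labels = [str(i) for i in range(x.shape[0])]
        colnames = [str(j) for j in range(x.shape[1])]
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least a 2x2 matrix")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(colnames, keep) if not k]
    if dropped:
        logging.getLogger(__name__).warning(
            "PCA: dropping constant columns %s", dropped
        )
    x = x[:, keep]
    if x.shape[1] < 1:
        raise ValueError("all columns constant")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = (z.T @ z) / (z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for k in range(evecs.shape[1]):
        pivot = np.argmax(np.abs(evecs[:, k]))
        if evecs[pivot, k] < 0:
            evecs[:, k] = -evecs[:, k]
    coords = z @ evecs
    explained = evals / evals.sum() if evals.sum() > 0 else evals
    return Ordination(
        coordinates=coords,
        explained=explained,
        method="PCA",
        labels=labels,
        dropped_columns=dropped,
    )


def pcoa(D: DissimilarityMatrix) -> Ordination:
    """Principal coordinate analysis (classical MDS) of a dissimilarity matrix.

    Coordinates are returned on positive-eigenvalue axes; the relative mass
    of negative eigenvalues (non-Euclidean distances such as Bray–Curtis)
    is reported, never hidden.
    """
    x_pos, _x_neg, evals = _pcoa_embed(D)
    pos = evals[evals > 0]
    neg_mass = float(abs(evals[evals < 0]).sum() / abs(evals).sum()) if abs(
        evals
    ).sum() > 0 else 0.0
    coords = x_pos.copy()
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] = -coords[:, k]
    explained = pos[: coords.shape[1]] / pos.sum() if pos.sum() > 0 else pos
    return Ordination(
        coordinates=coords,
        explained=np.asarray(explained),
        method="PCoA",
        labels=list(D.labels),
        negative_eigenvalue_mass=neg_mass,
    )
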