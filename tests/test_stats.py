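"""First-principles statistics layer, cross-checked against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from merscape.stats import (
    DissimilarityMatrix,
    betadisper,
    bray_curtis,
    dual_correlation,
    hcluster,
    kruskal_dunn,
    pca,
    pcoa,
    permanova,
)


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_values():
    d = bray_curtis(np.array([[6.0, 0, 2], [2, 2, 2], [6, 0, 2]])).d
    assert d[0, 1] == pytest.approx(6 / 14)
    assert d[0, 2] == 0.0


def test_bray_curtis_disjoint_supports_and_zero_rows():
    d = bray_curtis(np.array([[2.0, 0], [0, 2], [0, 0], [0, 0]])).d
    assert d[0, 1] == 1.0
    assert d[2, 3] == 0.0  # convention for two all-zero rows


def test_bray_curtis_rejects_negative():
    with pytest.raises(ValueError):
        bray_curtis(np.array([[1.0, -1], [0, 1]]))


def test_bray_curtis_matches_scipy(rng):
    from scipy.spatial.distance import braycurtis

    x = rng.poisson(5, size=(6, 4)).astype(float)
    d = bray_curtis(x).d
    for i, j in itertools.combinations(range(6), 2):
        assert d[i, j] == pytest.approx(braycurtis(x[i], x[j]), abs=1e-12)


def test_bray_curtis_bounded_symmetric(rng):
    x = rng.poisson(3, size=(8, 5)).astype(float)
    D = bray_curtis(x)
    assert ((D.d >= 0) & (D.d <= 1)).all()
    assert np.allclose(D.d, D.d.T)


# ---------------------------------------------------------------------------
# hierarchical clustering


def test_hcluster_two_items():
    # single join at height d_12 = 0.4; leaf edges of 0.2 reproduce it
    D = DissimilarityMatrix(labels=["A", "B"], d=np.array([[0, 0.4], [0.4, 0]]))
    assert hcluster(D) == "(A:0.2,B:0.2);"


def test_hcluster_nearest_pair_joined_first():
    d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
    nwk = hcluster(DissimilarityMatrix(labels=["A", "B", "C"], d=d))
    assert "(A:0.05,B:0.05)" in nwk


def test_hcluster_ultrametric_heights_exact():
    # ultrametric: (A,B) at 0.2, C joins at 0.6
    d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
    nwk = hcluster(DissimilarityMatrix(labels=["A", "B", "C"], d=d))
    assert nwk == "(C:0.3,(A:0.1,B:0.1):0.2);"


# ---------------------------------------------------------------------------
# PERMANOVA


def _brute_force_permanova(d, labels):
    """Independent oracle: McArdle-Anderson trace formulation + full enumeration."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    j = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * j @ (d**2) @ j

    def f_stat(lab):
        lab = np.asarray(lab)
        uniq = sorted(set(lab))
        X = np.column_stack([(lab == u).astype(float) for u in uniq])
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        g = len(uniq)
        ss_b = np.trace(H @ G @ H)
        ss_w = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H))
        return (ss_b / (g - 1)) / (ss_w / (n - g))

    f_obs = f_stat(labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        count += f_stat(perm) >= f_obs - 1e-10
    return f_obs, count / total


def test_permanova_exhaustive_matches_brute_force(rng):
    x = rng.poisson(8, size=(7, 4)).astype(float)
    labels = ["a", "a", "a", "b", "b", "c", "c"]
    D = bray_curtis(x)
    res = permanova(D, labels, seed=0)
    assert res.exhaustive
    f_ref, p_ref = _brute_force_permanova(D.d, labels)
    assert res.pseudo_F == pytest.approx(f_ref, rel=1e-9)
    assert res.p_value == pytest.approx(p_ref, abs=1e-12)


def test_permanova_ss_decomposition_closes():
    """Distance-form sums of squares equal coordinate-form sums (Euclidean)."""
    from merscape.stats import _permanova_stats

    rng = np.random.default_rng(7)
    x = rng.normal(size=(10, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    codes = np.array([0] * 5 + [1] * 5)
    ss_total, ss_within, _ = _permanova_stats(d**2, codes, 2)
    ss_total_coord = ((x - x.mean(axis=0)) ** 2).sum()
    ss_within_coord = sum(
        ((x[codes == k] - x[codes == k].mean(axis=0)) ** 2).sum() for k in (0, 1)
    )
    assert ss_total == pytest.approx(ss_total_coord, rel=1e-9)
    assert ss_within == pytest.approx(ss_within_coord, rel=1e-9)
    assert (ss_total - ss_within) + ss_within == pytest.approx(ss_total, rel=1e-12)


def test_permanova_matches_skbio_f():
    import skbio

    rng = np.random.default_rng(3)
    x = rng.poisson(10, size=(12, 5)).astype(float)
    labels = ["a"] * 6 + ["b"] * 6
    D = bray_curtis(x)
    ours = permanova(D, labels, seed=0)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(D.d, ids=D.labels), grouping=labels, permutations=99
    )
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_permanova_separated_clusters_attain_minimum_p():
    x = np.array(
        [[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1], [5, 5], [5.1, 5], [5, 5.1], [5.1, 5.1]]
    )
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    labels = ["a"] * 4 + ["b"] * 4
    res = permanova(DissimilarityMatrix(labels=[str(i) for i in range(8)], d=d), labels)
    assert res.exhaustive
    # the observed split is the unique maximum among C(8,4)=70 arrangements,
    # counted twice (label swap)
    assert res.p_value == pytest.approx(2 / 70)


def test_permanova_equal_distances_degenerate():
    d = np.ones((6, 6)) - np.eye(6)
    D = DissimilarityMatrix(labels=[str(i) for i in range(6)], d=d)
    res = permanova(D, ["a", "a", "a", "b", "b", "b"], seed=0)
    assert res.p_value == 1.0


def test_permanova_rejects_single_group():
    d = np.ones((4, 4)) - np.eye(4)
    D = DissimilarityMatrix(labels=list("abcd"), d=d)
    with pytest.raises(ValueError):
        permanova(D, ["x", "x", "x", "x"])


def test_permanova_seed_reproducible(rng):
    x = rng.poisson(6, size=(14, 4)).astype(float)
    labels = ["a"] * 7 + ["b"] * 7  # 3432 arrangements > limit below
    D = bray_curtis(x)
    r1 = permanova(D, labels, n_perm=500, seed=42, exhaustive_limit=10)
    r2 = permanova(D, labels, n_perm=500, seed=42, exhaustive_limit=10)
    assert not r1.exhaustive
    assert r1.p_value == r2.p_value


def test_permanova_r2_in_unit_interval(rng):
    for _ in range(5):
        x = rng.poisson(5, size=(9, 3)).astype(float) + 1
        labels = rng.choice(["a", "b", "c"], size=9).tolist()
        if len(set(labels)) < 2:
            continue
        res = permanova(bray_curtis(x), labels, exhaustive_limit=1, n_perm=30, seed=0)
        assert 0.0 <= res.R2 <= 1.0


# ---------------------------------------------------------------------------
# betadisper


def test_betadisper_unequal_spread_detected():
    rng = np.random.default_rng(0)
    tight = rng.normal(scale=0.01, size=(8, 2))
    loose = rng.normal(scale=5.0, size=(8, 2))
    x = np.vstack([tight, loose])
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    D = DissimilarityMatrix(labels=[str(i) for i in range(16)], d=d)
    res = betadisper(D, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=1)
    assert res.p_value < 0.01
    assert res.group_dispersions["b"] > res.group_dispersions["a"]


def test_betadisper_identical_points_degenerate():
    d = np.zeros((6, 6))
    D = DissimilarityMatrix(labels=[str(i) for i in range(6)], d=d)
    res = betadisper(D, ["a"] * 3 + ["b"] * 3, seed=0)
    assert res.degenerate and res.p_value == 1.0
    assert all(v == 0.0 for v in res.group_dispersions.values())


def test_betadisper_null_rejection_rate():
    """Equal-spread groups: rejection rate near alpha."""
    rng = np.random.default_rng(10)
    rejections = 0
    n_sims = 400
    for _ in range(n_sims):
        x = rng.normal(size=(12, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
        D = DissimilarityMatrix(labels=[str(i) for i in range(12)], d=d)
        res = betadisper(D, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= 0.05
    rate = rejections / n_sims
    assert 0.01 <= rate <= 0.10  # ~binomial 99.9% band around 0.05 at n=400


# ---------------------------------------------------------------------------
# rank tests


def test_kruskal_hand_value():
    res = kruskal_dunn([1, 2, 3, 4], ["a", "a", "b", "b"])
    assert res.H == pytest.approx(2.4)


def test_kruskal_identical_groups():
    res = kruskal_dunn([5, 5, 5, 5], ["a", "a", "b", "b"])
    assert res.H == 0.0 and res.p_value == 1.0


def test_dunn_three_groups_bonferroni():
    values = [1, 2, 3, 10, 11, 12, 20, 21, 22]
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    res = kruskal_dunn(values, labels)
    assert len(res.pairwise) == 3
    for _, _, raw, adj in res.pairwise:
        assert adj == pytest.approx(min(1.0, raw * 3))
        assert adj >= raw


def test_kruskal_invariant_under_monotone_transform(rng):
    values = rng.normal(size=12)
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    h1 = kruskal_dunn(values, labels).H
    h2 = kruskal_dunn(np.exp(values), labels).H
    h3 = kruskal_dunn(values**3, labels).H
    assert h1 == pytest.approx(h2) == pytest.approx(h3)


def test_kruskal_empty_group_rejected():
    with pytest.raises(ValueError):
        kruskal_dunn([1.0], ["a"])


# ---------------------------------------------------------------------------
# dual correlation


def test_dual_correlation_identity():
    rep = dual_correlation(np.arange(10.0), np.arange(10.0))
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.spearman_rho == pytest.approx(1.0)
    assert rep.reported


def test_dual_correlation_monotone_nonlinear():
    x = np.linspace(0, 1, 50)
    y = np.exp(5 * x)
    rep = dual_correlation(x, y)
    assert rep.spearman_rho == pytest.approx(1.0)
    assert rep.pearson_r < 1.0


def test_dual_correlation_zero_variance_flagged():
    rep = dual_correlation(np.ones(6), np.arange(6.0))
    assert rep.degenerate and not rep.reported


def test_dual_correlation_exact_small_n():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    rep = dual_correlation(x, x**2, exact=True)
    # |rho| = 1 is attained only by the identity and the full reversal
    assert rep.spearman_p == pytest.approx(2 / math.factorial(6), abs=1e-12)
    assert rep.pearson_p <= 0.05


# ---------------------------------------------------------------------------
# ordination


def test_pca_collinear_points_single_axis():
    x = np.outer(np.arange(5.0), [1.0, 2.0])
    ord_ = pca(x + 0.0)
    assert ord_.explained[0] == pytest.approx(1.0)


def test_pca_drops_constant_column():
    x = np.column_stack([np.arange(6.0), np.full(6, 3.0), np.arange(6.0) ** 2])
    ord_ = pca(x)
    assert ord_.dropped_columns == ["1"]


def test_pcoa_recovers_euclidean_configuration(rng):
    x = rng.normal(size=(7, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    D = DissimilarityMatrix(labels=[str(i) for i in range(7)], d=d)
    ord_ = pcoa(D)
    c = ord_.coordinates
    d2 = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    assert np.allclose(d2, d, atol=1e-8)
    assert ord_.negative_eigenvalue_mass == pytest.approx(0.0, abs=1e-9)


def test_pcoa_matches_skbio_proportions(rng):
    import warnings

    import skbio
    import skbio.stats.ordination as sko

    x = rng.poisson(10, size=(9, 5)).astype(float)
    D = bray_curtis(x)
    ours = pcoa(D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theirs = sko.pcoa(skbio.DistanceMatrix(D.d, ids=D.labels))
    assert np.allclose(
        ours.explained[:3], theirs.proportion_explained.values[:3], atol=1e-9
    )


def test_pcoa_bray_curtis_reports_negative_mass(rng):
    x = rng.poisson(4, size=(10, 4)).astype(float)
    ord_ = pcoa(bray_curtis(x))
    assert ord_.negative_eigenvalue_mass >= 0
    assert (np.diff(ord_.explained) <= 1e-12).all()
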