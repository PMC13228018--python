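"""NJ/JC phylogeny: closed forms, consistency on additive matrices, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from merscape import simulate as sim
from merscape.phylo import (
    DistanceMatrix,
    NewickParseError,
    ProteinAlignment,
    bootstrap_support,
    concatenate,
    jc_correct,
    jc_protein_distance,
    neighbor_joining,
    read_newick,
    root_with_outgroup,
    write_newick,
)


def _aln(seqs: dict) -> ProteinAlignment:
    return ProteinAlignment(names=list(seqs), rows=list(seqs.values()))


# ---------------------------------------------------------------------------
# concatenation


def test_concatenate_pads_missing_taxa(caplog):
    a = _aln({"A": "ACDE", "B": "ACDF"})
    b = _aln({"A": "KL"})
    concat = concatenate({"MerR": a, "MerT": b}, order=("MerR", "MerT"))
    assert concat.n_sites == 6
    row_b = concat.rows[concat.names.index("B")]
    assert row_b.endswith("--")


def test_concatenate_single_protein_is_identity():
    a = _aln({"A": "ACDE", "B": "ACDF"})
    concat = concatenate({"MerA": a})
    assert concat.rows == a.rows and concat.names == a.names


def test_concatenate_disjoint_taxa_is_error():
    with pytest.raises(ValueError, match="shared"):
        concatenate({"MerR": _aln({"A": "AC"}), "MerT": _aln({"B": "AC"})})


# ---------------------------------------------------------------------------
# JC distances


def test_jc_identical_and_closed_form():
    dm = jc_protein_distance(_aln({"A": "ACDEFGHIKLMNPQRSTVWY", "B": "ACDEFGHIKLMNPQRSTVWY"}))
    assert dm.d[0, 1] == 0.0
    # p = 0.05 closed form
    assert jc_correct(0.05) == pytest.approx(-(19 / 20) * math.log(1 - 1 / 19), abs=1e-12)
    seq_a = "A" * 20
    seq_b = "C" + "A" * 19  # one difference in 20 sites
    dm = jc_protein_distance(_aln({"A": seq_a, "B": seq_b}))
    assert dm.d[0, 1] == pytest.approx(jc_correct(0.05), abs=1e-12)


def test_jc_saturation_hits_ceiling():
    dm = jc_protein_distance(_aln({"A": "A" * 20, "B": "C" * 20}))
    assert dm.d[0, 1] == 5.0
    assert dm.saturated_pairs == [("A", "B")]


def test_jc_pairwise_deletion_and_incomparable_pair():
    dm = jc_protein_distance(_aln({"A": "AC-E", "B": "ACD-", "C": "AC-E"}))
    assert dm.d[0, 2] == 0.0  # compared over non-gap columns only
    with pytest.raises(ValueError, match="comparable"):
        jc_protein_distance(_aln({"A": "--AC", "B": "AC--"}))


def test_jc_monotone_in_p():
    ps = np.linspace(0, 0.94, 50)
    ds = [jc_correct(p) for p in ps]
    assert all(b > a for a, b in zip(ds, ds[1:]))


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_point_closed_form():
    dm = DistanceMatrix(
        labels=["A", "B", "C"],
        d=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
    )
    t = neighbor_joining(dm)
    lengths = {
        lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()
    }
    assert lengths["A"] == pytest.approx(0.05, abs=1e-12)
    assert lengths["B"] == pytest.approx(0.15, abs=1e-12)
    assert lengths["C"] == pytest.approx(0.25, abs=1e-12)


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1], [1, 0]])))


def _random_additive(rng, n):
    """Random binary tree over n taxa; returns (patristic matrix, bipartitions)."""
    import dendropy

    labels = [f"t{i:02d}" for i in range(n)]
    nodes = [(label, None) for label in labels]
    newick_parts = {label: label for label in labels}
    lengths = {}
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        la, lb = rng.uniform(0.05, 0.4, size=2)
        merged = f"({newick_parts[a]}:{la:.6f},{newick_parts[b]}:{lb:.6f})"
        key = f"[{a}|{b}]"
        newick_parts[key] = merged
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [key]
    newick = newick_parts[parts[0]] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    ref = min(labels)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= n - 2:
            bips.add(frozenset(side))
    del nodes, lengths
    return labels, d, bips


def test_nj_consistent_on_additive_matrices():
    rng = np.random.default_rng(77)
    for _ in range(40):
        n = int(rng.integers(4, 13))
        labels, d, true_bips = _random_additive(rng, n)
        t = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        assert t.bipartitions() == true_bips
        assert t.negative_branches_clipped == 0


def test_nj_tie_break_deterministic():
    d = np.array(
        [[0, 2.0, 2, 2], [2, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]]
    )
    t1 = neighbor_joining(DistanceMatrix(labels=list("ABCD"), d=d.copy()))
    t2 = neighbor_joining(DistanceMatrix(labels=list("ABCD"), d=d.copy()))
    assert t1.newick() == t2.newick()
    assert t1.bipartitions() == {frozenset({"C", "D"})}  # lexicographic join of (A,B)


def test_nj_matches_skbio_topology(rng):
    import dendropy
    import skbio
    from dendropy.calculate import treecompare

    n = 7
    m = rng.random((n, n))
    m = (m + m.T) / 2 + 1
    np.fill_diagonal(m, 0)
    labels = [f"t{i}" for i in range(n)]
    ours = neighbor_joining(DistanceMatrix(labels=labels, d=m))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
    tns = dendropy.TaxonNamespace(labels)
    a = dendropy.Tree.get(data=ours.newick(), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=str(theirs), schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    assert treecompare.symmetric_difference(a, b) == 0


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_single_replicate_degenerate():
    tree = "((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5);"
    alns, _ = sim.generate_alignment(tree, {"MerA": 300}, 1.0, seed=2)
    t = bootstrap_support(alns["MerA"], n_reps=1, seed=3)
    assert set(t.supports.values()) <= {0.0, 100.0}


def test_bootstrap_strong_signal_support():
    tree = "((A:0.05,B:0.05):0.6,(C:0.05,D:0.05):0.6);"
    alns, _ = sim.generate_alignment(
        tree, {"MerR": 144, "MerT": 116, "MerP": 91, "MerA": 561}, 1.0, seed=5
    )
    concat = concatenate(alns)
    t = bootstrap_support(concat, n_reps=300, seed=6)
    assert t.supports[frozenset({"C", "D"})] >= 95.0


def test_bootstrap_star_data_no_dominant_support():
    tree = "((A:0.3,B:0.3):0.0,(C:0.3,D:0.3):0.0);"
    alns, _ = sim.generate_alignment(tree, {"MerA": 200}, 1.0, seed=8)
    t = bootstrap_support(alns["MerA"], n_reps=300, seed=9)
    for val in t.supports.values():
        assert val <= 90.0


def test_bootstrap_seed_reproducible_and_taxon_order_invariant():
    tree = "((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);"
    alns, _ = sim.generate_alignment(tree, {"MerA": 200}, 1.0, seed=4)
    aln = alns["MerA"]
    t1 = bootstrap_support(aln, n_reps=50, seed=11)
    t2 = bootstrap_support(aln, n_reps=50, seed=11)
    assert t1.supports == t2.supports


# ---------------------------------------------------------------------------
# Newick I/O and rooting


def test_newick_three_taxon_star():
    dm = DistanceMatrix(
        labels=["A", "B", "C"],
        d=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
    )
    nwk = neighbor_joining(dm).newick()
    assert nwk.replace(" ", "") == "(A:0.05,B:0.15,C:0.25);"


def test_newick_round_trip(tmp_path):
    tree = "((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5);"
    alns, _ = sim.generate_alignment(tree, {"MerA": 300}, 1.0, seed=12)
    t = bootstrap_support(alns["MerA"], n_reps=20, seed=13)
    path = tmp_path / "t.nwk"
    write_newick(t, path)
    t2 = read_newick(path)
    assert t2.bipartitions() == t.bipartitions()
    assert t2.supports == {k: float(int(round(v))) for k, v in t.supports.items()}
    lengths1 = sorted(
        e.length for e in t.tree.preorder_edge_iter() if e.length is not None
    )
    lengths2 = sorted(
        e.length for e in t2.tree.preorder_edge_iter() if e.length is not None
    )
    assert np.allclose(lengths1, lengths2, atol=1e-9)


def test_malformed_newick_raises():
    with pytest.raises(NewickParseError):
        read_newick("((A:0.1,B:0.2;")


def test_outgroup_rooting_preserves_bipartitions():
    tree = "((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3);"
    alns, _ = sim.generate_alignment(tree, {"MerA": 250}, 1.0, seed=14)
    t = bootstrap_support(alns["MerA"], n_reps=20, seed=15)
    rooted = root_with_outgroup(t, "A")
    assert rooted.bipartitions() == t.bipartitions()
    assert rooted.tree.is_rooted
    with pytest.raises(KeyError):
        root_with_outgroup(t, "ZZZ")


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 9))
def test_nj_additive_property(seed, n):
    """NJ reconstructs the generating topology from any additive matrix."""
    rng = np.random.default_rng(seed)
    labels, d, true_bips = _random_additive(rng, n)
    t = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    assert t.bipartitions() == true_bips
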