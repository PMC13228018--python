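"""Neighbor-joining phylogeny of concatenated Mer proteins.

Distances between aligned amino-acid sequences are Jukes–Cantor-corrected
20-state protein distances, ``d = -(19/20) ln(1 - 20p/19)`` where ``p`` is
the proportion of differing sites over pairwise-comparable columns (neither
row gapped or 'X').  Saturated pairs (p >= 19/20) are set to a configurable
ceiling and flagged.  Trees are built with classical neighbor joining
(Q-criterion, standard split branch lengths, negatives clipped to 0,
lexicographic tie-break) and supports come from non-parametric bootstrap
resampling of alignment columns, attached to the full-data tree's
bipartitions.  dendropy handles Newick serialisation and rooting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

log = logging.getLogger(__name__)

PROTEIN_ORDER = ("MerR", "MerT", "MerP", "MerA")
AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}
JC_CEILING = 5.0


class NewickParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alignments


@dataclass
class ProteinAlignment:
    """Equal-length aligned amino-acid rows with named taxa."""

    names: list[str]
    rows: list[str]
    source_proteins: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        if not self.source_proteins and self.rows:
            self.source_proteins = [("protein", 0, len(self.rows[0]))]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encode(self) -> np.ndarray:
        """Rows as an int matrix: amino acid index, or -1 for gap/X/unknown."""
        out = np.full((len(self.rows), self.n_sites), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row.upper()):
                out[i, j] = _AA_INDEX.get(ch, -1)
        return out


def read_alignment(path: str | Path) -> ProteinAlignment:
    from Bio import SeqIO

    names, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        names.append(record.id)
        rows.append(str(record.seq))
    return ProteinAlignment(names=names, rows=rows)


def write_alignment(aln: ProteinAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


def concatenate(
    alignments: dict[str, ProteinAlignment],
    order: tuple[str, ...] = PROTEIN_ORDER,
) -> ProteinAlignment:
    """Concatenate per-protein alignments in fixed order.

    Taxa missing from a protein are padded with gaps (logged); the taxon
    sets must share at least one name.
    """
    present = [p for p in order if p in alignments]
    present += [p for p in alignments if p not in order]
    if not present:
        raise ValueError("no alignments given")
    taxa_sets = [set(alignments[p].names) for p in present]
    shared = set.intersection(*taxa_sets)
    if not shared:
        raise ValueError("no taxa shared across proteins")
    all_taxa = sorted(set.union(*taxa_sets))
    rows = {t: [] for t in all_taxa}
    spans = []
    offset = 0
    for p in present:
        aln = alignments[p]
        width = aln.n_sites
        lookup = dict(zip(aln.names, aln.rows))
        for t in all_taxa:
            if t in lookup:
                rows[t].append(lookup[t])
            else:
                log.warning("taxon %s missing from %s; padded with gaps", t, p)
                rows[t].append("-" * width)
        spans.append((p, offset, offset + width))
        offset += width
    return ProteinAlignment(
        names=all_taxa,
        rows=["".join(rows[t]) for t in all_taxa],
        source_proteins=spans,
    )


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str = "JC-protein"
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")


def jc_correct(p: float) -> float:
    """Jukes–Cantor 20-state correction of a raw proportion of differences."""
    return -(19.0 / 20.0) * math.log(1.0 - 20.0 * p / 19.0)


def _jc_from_encoded(
    enc: np.ndarray, ceiling: float
) -> tuple[np.ndarray, list[tuple[int, int]], list[tuple[int, int]]]:
    """(distance matrix, saturated index pairs, incomparable index pairs)."""
    n = enc.shape[0]
    d = np.zeros((n, n))
    saturated: list[tuple[int, int]] = []
    incomparable: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            valid = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(valid.sum())
            if m == 0:
                incomparable.append((i, j))
                continue
            p = float((enc[i][valid] != enc[j][valid]).sum()) / m
            if p >= 19.0 / 20.0:
                d[i, j] = d[j, i] = ceiling
                saturated.append((i, j))
            else:
                d[i, j] = d[j, i] = jc_correct(p)
    return d, saturated, incomparable


def jc_protein_distance(
    aln: ProteinAlignment, ceiling: float = JC_CEILING
) -> DistanceMatrix:
    """Pairwise JC-corrected protein distances with pairwise gap deletion."""
    if len(aln.names) < 2:
        raise ValueError("need at least 2 taxa")
    d, saturated, incomparable = _jc_from_encoded(aln.encode(), ceiling)
    if incomparable:
        i, j = incomparable[0]
        raise ValueError(
            f"no comparable columns between {aln.names[i]!r} "
            f"and {aln.names[j]!r}"
        )
    return DistanceMatrix(
        labels=list(aln.names),
        d=d,
        model="JC-protein",
        saturated_pairs=[(aln.names[i], aln.names[j]) for i, j in saturated],
    )


# ---------------------------------------------------------------------------
# trees


@dataclass
class Tree:
    """An unrooted NJ tree with optional bootstrap supports (percent)."""

    tree: dendropy.Tree
    negative_branches_clipped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
        return s

    def bipartitions(self) -> set[frozenset]:
        """Internal bipartitions, each as the side not containing the
        lexicographically smallest taxon."""
        all_taxa = set(self.taxa)
        ref = min(all_taxa)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = {lf.taxon.label for lf in node.leaf_iter()}
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(frozenset(side))
        return out

    def annotate_supports(self) -> None:
        """Write supports onto internal node labels (integer percent)."""
        all_taxa = set(self.taxa)
        ref = min(all_taxa)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = {lf.taxon.label for lf in node.leaf_iter()}
            if ref in side:
                side = all_taxa - side
            key = frozenset(side)
            if key in self.supports:
                node.label = str(int(round(self.supports[key])))


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Classical neighbor joining.

    Joins the pair minimising ``Q_ij = (n-2) d_ij - r_i - r_j``; ties are
    broken by the lexicographically smallest pair of subtree labels (each
    subtree keyed by its smallest leaf).  Negative branch lengths are
    clipped to 0 and counted.
    """
    n0 = len(D.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(D.labels)
    nodes = []
    for label in D.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node._minleaf = label
        nodes.append(node)
    dist = {
        (i, j): float(D.d[i, j]) for i in range(n0) for j in range(n0) if i != j
    }
    active = list(range(n0))
    next_id = n0
    clipped = 0

    def d(a: int, b: int) -> float:
        return 0.0 if a == b else dist[(a, b)]

    node_of = dict(enumerate(nodes))
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key_pair = tuple(
                    sorted((node_of[a]._minleaf, node_of[b]._minleaf))
                )
                cand = (q, key_pair, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = d(a, b) - la
        if la < 0:
            clipped += 1
            la = 0.0
        if lb < 0:
            clipped += 1
            lb = 0.0
        parent = dendropy.Node()
        parent._minleaf = min(node_of[a]._minleaf, node_of[b]._minleaf)
        node_of[a].edge.length = la
        node_of[b].edge.length = lb
        parent.add_child(node_of[a])
        parent.add_child(node_of[b])
        u = next_id
        next_id += 1
        node_of[u] = parent
        for c in active:
            if c not in (a, b):
                dist[(u, c)] = dist[(c, u)] = 0.5 * (
                    d(a, c) + d(b, c) - d(a, b)
                )
        active = [c for c in active if c not in (a, b)] + [u]
    a, b, c = active
    root = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
        if lx < 0:
            clipped += 1
            lx = 0.0
        node_of[x].edge.length = lx
        root.add_child(node_of[x])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return Tree(tree=tree, negative_branches_clipped=clipped)


def bootstrap_support(
    aln: ProteinAlignment,
    n_reps: int = 10_000,
    seed: int = 0,
    ceiling: float = JC_CEILING,
) -> Tree:
    """Full-data NJ tree with bootstrap supports on its bipartitions.

    Columns are resampled with replacement per replicate; replicates whose
    distance matrix has a saturated or incomparable pair are skipped and
    counted (warned when >1% are skipped).
    """
    full_dm = jc_protein_distance(aln, ceiling=ceiling)
    full_tree = neighbor_joining(full_dm)
    target = full_tree.bipartitions()
    counts = dict.fromkeys(target, 0)
    rng = np.random.default_rng(seed)
    enc = aln.encode()
    L = aln.n_sites
    skipped = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        d, saturated, incomparable = _jc_from_encoded(enc[:, cols], ceiling)
        if saturated or incomparable:
            skipped += 1
            continue
        dm = DistanceMatrix(labels=list(aln.names), d=d, model="JC-protein")
        used += 1
        for bp in neighbor_joining(dm).bipartitions():
            if bp in counts:
                counts[bp] += 1
    if n_reps and skipped > 0.01 * n_reps:
        log.warning("bootstrap: skipped %d of %d replicates", skipped, n_reps)
    denom = max(used, 1)
    full_tree.supports = {bp: 100.0 * c / denom for bp, c in counts.items()}
    full_tree.annotate_supports()
    return full_tree


def root_with_outgroup(t: Tree, outgroup: str) -> Tree:
    """Rooted view of the tree with the named outgroup; bipartitions unchanged."""
    clone = dendropy.Tree(t.tree)
    node = clone.find_node_with_taxon_label(outgroup)
    if node is None:
        raise KeyError(outgroup)
    length = node.edge.length or 0.0
    clone.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    clone.is_rooted = True
    return Tree(
        tree=clone,
        negative_branches_clipped=t.negative_branches_clipped,
        supports=dict(t.supports),
    )


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_newick(path_or_text: str | Path) -> Tree:
    """Parse Newick (file path or literal string) into a Tree."""
    text = str(path_or_text)
    if "(" not in text:
        p = Path(text)
        if not p.exists():
            raise NewickParseError(f"no such file and not Newick text: {text!r}")
        text = p.read_text()
    elif Path(text).exists():  # pragma: no cover - pathological overlap
        text = Path(text).read_text()
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    t = Tree(tree=dt)
    # recover integer supports from internal labels
    all_taxa = set(t.taxa)
    if all_taxa:
        ref = min(all_taxa)
        for node in dt.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or not node.label:
                continue
            try:
                val = float(node.label)
            except ValueError:
                continue
            side = {lf.taxon.label for lf in node.leaf_iter()}
            if ref in side:
                side = all_taxa - side
            t.supports[frozenset(side)] = val
    return t
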