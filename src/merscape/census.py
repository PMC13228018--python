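"""Lexicon-based resistance/mobility gene categorisation and genome censuses.

Genes are assigned hierarchical category tags (``ARG``, ``MRG:<metal>``,
``MGE:<element>``) by case-insensitive substring matching of a keyword
lexicon against the annotated gene name and product string.  Within a
top-level group (ARG / MRG / MGE) a feature receives at most one category —
the highest-priority match — so a "phage integrase" counts once as
MGE:phage, never twice.  Groups are independent: a gene may legitimately be
both an MRG and an ARG if distinct keywords match.

The census aggregates tags into a genome x category count matrix, the raw
material for the multivariate statistics layer, plus z-score profiles
(per-category standardisation, clipped to +/-4) and per-replicon CDS
proportions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from merscape.model import Cohort, Genome

DEFAULT_CLIP = 4.0


@dataclass
class CategoryLexicon:
    """One category with its matching keywords and intra-group priority."""

    category: str
    keywords: list[str]
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"lexicon {self.category!r} has no keywords")
        self.keywords = [k.lower() for k in self.keywords]

    @property
    def group(self) -> str:
        return self.category.split(":", 1)[0]


def load_lexicons(path: str | Path | None = None) -> list[CategoryLexicon]:
    """Load a category lexicon TSV (category, keyword, priority).

    With no argument, the packaged default lexicon is returned.
    """
    if path is None:
        source = resources.files("merscape.data") / "category_lexicon.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table = pd.read_csv(pd.io.common.StringIO(text), sep="\t", dtype=str)
    lexicons: dict[str, CategoryLexicon] = {}
    for _, row in table.iterrows():
        cat = row["category"]
        if cat not in lexicons:
            lexicons[cat] = CategoryLexicon(
                category=cat, keywords=[row["keyword"]], priority=int(row["priority"])
            )
        else:
            lexicons[cat].keywords.append(row["keyword"].lower())
    return list(lexicons.values())


def lexicon_checksum(lexicons: list[CategoryLexicon]) -> str:
    text = "\n".join(
        f"{lx.category}\t{lx.priority}\t{','.join(sorted(lx.keywords))}"
        for lx in sorted(lexicons, key=lambda l: l.category)
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def categorize(gene_name: str, product: str, lexicons: list[CategoryLexicon]) -> set[str]:
    """Category tags for one annotation, one winner per top-level group."""
    haystack = f"{gene_name} {product}".lower()
    best: dict[str, tuple[int, str]] = {}
    for lx in lexicons:
        if any(kw in haystack for kw in lx.keywords):
            current = best.get(lx.group)
            # higher priority wins; ties broken by category name for determinism
            key = (lx.priority, lx.category)
            if current is None or key > current:
                best[lx.group] = key
    return {cat for _, cat in best.values()}


def assign_categories(
    genome: Genome, lexicons: list[CategoryLexicon] | None = None
) -> Genome:
    """Fill ``feature.categories`` in place for every CDS; returns the genome."""
    if lexicons is None:
        lexicons = load_lexicons()
    if not lexicons:
        raise ValueError("empty lexicon set")
    for f in genome.features:
        f.categories = categorize(f.gene_name, f.product, lexicons)
    genome.categories_assigned = True
    return genome


@dataclass
class GeneCensus:
    """Genome x category count matrix with per-genome CDS totals."""

    matrix: pd.DataFrame  # genomes x categories, non-negative ints
    totals: pd.Series  # CDS count per genome
    provenance: str = ""

    def cohort_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def group_totals(self) -> pd.Series:
        """Counts aggregated to top-level groups (ARG / MRG / MGE)."""
        groups = self.matrix.columns.str.split(":").str[0]
        return self.matrix.T.groupby(groups).sum().T.sum(axis=0)


def census(
    cohort: Cohort, lexicons: list[CategoryLexicon] | None = None
) -> GeneCensus:
    """Count categorized CDSs per genome.

    Categories are assigned on the fly when any genome still lacks them.
    """
    if lexicons is None:
        lexicons = load_lexicons()
    categories = sorted(lx.category for lx in lexicons)
    rows = {}
    totals = {}
    for genome in cohort:
        if all(not f.categories for f in genome.features) and genome.features:
            assign_categories(genome, lexicons)
        counts = dict.fromkeys(categories, 0)
        for f in genome.features:
            for cat in f.categories:
                if cat in counts:
                    counts[cat] += 1
        rows[genome.genome_id] = counts
        totals[genome.genome_id] = len(genome.features)
    matrix = pd.DataFrame.from_dict(rows, orient="index")[categories].astype(int)
    return GeneCensus(
        matrix=matrix,
        totals=pd.Series(totals, name="total_cds"),
        provenance=lexicon_checksum(lexicons),
    )


@dataclass
class ZScoreProfile:
    matrix: pd.DataFrame
    clip: float = DEFAULT_CLIP
    clipped_entries: int = field(default=0)


def zscore_standardize(gc: GeneCensus, clip: float = DEFAULT_CLIP) -> ZScoreProfile:
    """Per-category z-scores (ddof=1), clipped to ``[-clip, +clip]``.

    Zero-variance categories map to all-zero columns.  Requires >= 2 genomes.
    """
    if len(gc.matrix) < 2:
        raise ValueError("z-score standardisation needs at least 2 genomes")
    x = gc.matrix.astype(float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    z = (x - mean).div(sd.replace(0.0, np.inf), axis=1)
    clipped = int((z.abs() > clip).to_numpy().sum())
    return ZScoreProfile(matrix=z.clip(-clip, clip), clip=clip, clipped_entries=clipped)


def replicon_proportions(genome: Genome) -> pd.DataFrame:
    """Category abundance as percent of each replicon's CDSs.

    Returns a replicon x category table with an extra ``genome`` row
    aggregating over all replicons.  Replicons with zero CDSs report 0%
    (with a warning); they carry no signal.
    """
    import logging

    categories = sorted({cat for f in genome.features for cat in f.categories})
    index = [r.replicon_id for r in genome.replicons]
    counts = pd.DataFrame(0, index=index, columns=categories, dtype=float)
    cds = pd.Series(0, index=index, dtype=float)
    for f in genome.features:
        cds[f.replicon_id] += 1
        for cat in f.categories:
            counts.loc[f.replicon_id, cat] += 1
    out = pd.DataFrame(0.0, index=index, columns=categories)
    for rid in index:
        if cds[rid] == 0:
            logging.getLogger(__name__).warning(
                "replicon %s of %s has no CDSs; proportions reported as 0",
                rid,
                genome.genome_id,
            )
            continue
        out.loc[rid] = 100.0 * counts.loc[rid] / cds[rid]
    total_cds = cds.sum()
    if total_cds > 0:
        out.loc["genome"] = 100.0 * counts.sum(axis=0) / total_cds
    else:
        out.loc["genome"] = 0.0
    return out
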