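"""Shared data model: genomes, replicons, gene features, cohorts.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based inclusive external convention.  Only CDS features are modelled:
every screen in the pipeline operates on annotated protein-coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRANDS = ("+", "-")
TOPOLOGIES = ("circular", "linear")
REPLICON_KINDS = ("chromosome", "plasmid", "unknown")
ISOLATION_SOURCES = (
    "human",
    "food",
    "soil_sediment",
    "water",
    "insect",
    "other",
    "unknown",
)


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


@dataclass
class GeneFeature:
    """A positioned, stranded CDS with free-text annotation.

    ``start``/``end`` are 0-based half-open on the replicon.  ``categories``
    is filled by :func:`merscape.census.assign_categories` and is empty on
    freshly parsed genomes.
    """

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    gene_name: str = ""
    product: str = ""
    family_id: str | None = None
    categories: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"feature {self.feature_id!r}: unknown strand {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"feature {self.feature_id!r}: invalid span "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def copy(self) -> "GeneFeature":
        return replace(self, categories=set(self.categories))


@dataclass
class Replicon:
    replicon_id: str
    length: int
    topology: str = "linear"
    kind: str = "unknown"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(
                f"replicon {self.replicon_id!r}: non-positive length {self.length}"
            )
        if self.topology not in TOPOLOGIES:
            raise ValidationError(
                f"replicon {self.replicon_id!r}: unknown topology {self.topology!r}"
            )
        if self.kind not in REPLICON_KINDS:
            raise ValidationError(
                f"replicon {self.replicon_id!r}: unknown kind {self.kind!r}"
            )


@dataclass
class Genome:
    """An annotated multi-replicon genome with cohort metadata."""

    genome_id: str
    species_label: str = ""
    isolation_source: str = "unknown"
    lifestyle_label: str | None = None
    replicons: list[Replicon] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.isolation_source not in ISOLATION_SOURCES:
            self.isolation_source = "unknown"
        self.validate()

    def validate(self) -> None:
        rep_ids = [r.replicon_id for r in self.replicons]
        if len(rep_ids) != len(set(rep_ids)):
            raise ValidationError(
                f"genome {self.genome_id!r}: duplicate replicon ids"
            )
        lengths = {r.replicon_id: r.length for r in self.replicons}
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValidationError(
                    f"genome {self.genome_id!r}: duplicate feature id "
                    f"{f.feature_id!r}"
                )
            seen.add(f.feature_id)
            if f.replicon_id not in lengths:
                raise ValidationError(
                    f"genome {self.genome_id!r}: feature {f.feature_id!r} "
                    f"references unknown replicon {f.replicon_id!r}"
                )
            if f.end > lengths[f.replicon_id]:
                raise ValidationError(
                    f"genome {self.genome_id!r}: feature {f.feature_id!r} "
                    f"extends beyond replicon {f.replicon_id!r} "
                    f"({f.end} > {lengths[f.replicon_id]})"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def feature(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def features_on(self, replicon_id: str) -> list[GeneFeature]:
        """Features on one replicon, sorted by (start, end)."""
        return sorted(
            (f for f in self.features if f.replicon_id == replicon_id),
            key=lambda f: (f.start, f.end, f.feature_id),
        )

    def copy(self) -> "Genome":
        return Genome(
            genome_id=self.genome_id,
            species_label=self.species_label,
            isolation_source=self.isolation_source,
            lifestyle_label=self.lifestyle_label,
            replicons=[replace(r) for r in self.replicons],
            features=[f.copy() for f in self.features],
        )


@dataclass
class Cohort:
    genomes: list[Genome]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValidationError("cohort is empty")
        ids = [g.genome_id for g in self.genomes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate genome ids in cohort: {dupes}")

    def genome(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)
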