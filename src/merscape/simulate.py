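"""Synthetic annotated cohorts with machine-readable ground truth.

The generator emulates the inputs of the comparative screen: multi-replicon
bacterial genomes (GFF3-serialisable) carrying planted *mer* operons of
configurable architecture, flanking mobile-element cassettes (e.g. the
tniA/B/Q transposition module), co-localised metal-resistance loci (czc,
copper, ...), scattered ARG/MRG/MGE genes at Poisson rates, and neutral
background genes whose product strings are guaranteed to miss every default
lexicon keyword — so census ground truth is exact by construction.

It also simulates gap-free Mer-protein alignments along a given true tree
(Poisson substitution counts per site, uniform replacement over the other
19 amino acids, matching the Jukes–Cantor assumption downstream) and
lifestyle-structured gene-family presence/absence matrices.

Randomness: one global seed; the per-genome stream is
``np.random.default_rng(SeedSequence((seed, genome_index)))``, so outputs
are independent of generation order and bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from merscape.census import categorize, load_lexicons
from merscape.model import ISOLATION_SOURCES, Cohort, GeneFeature, Genome, Replicon
from merscape.phylo import AA, ProteinAlignment

# typical CDS lengths (bp) of mer genes; fixed for reproducibility
MER_GENE_LENGTHS = {
    "merR": 435,
    "merT": 351,
    "merP": 273,
    "merC": 420,
    "merF": 243,
    "merA": 1695,
    "merB": 639,
    "merD": 366,
    "merE": 237,
    "merG": 624,
    "hyp": 300,
}

MER_PRODUCTS = {
    "merR": ("merR", "mercuric resistance operon regulatory protein MerR"),
    "merT": ("merT", "mercuric transport protein MerT"),
    "merP": ("merP", "periplasmic mercuric ion-binding protein MerP"),
    "merC": ("merC", "mercuric transport protein MerC"),
    "merF": ("merF", "mercuric transport protein MerF"),
    "merA": ("merA", "mercuric reductase"),
    "merB": ("merB", "organomercurial lyase"),
    "merD": ("merD", "mercuric resistance co-regulator MerD"),
    "merE": ("merE", "broad-spectrum mercury transporter MerE"),
    "merG": ("merG", "phenylmercury resistance protein MerG"),
    "hyp": ("", "hypothetical protein"),
}

CATEGORY_PRODUCTS = {
    "ARG": [
        "class A beta-lactamase",
        "aminoglycoside O-phosphotransferase",
        "fluoroquinolone resistance pentapeptide protein QnrB",
        "phosphomycin resistance kinase FomA",
    ],
    "MRG:mercury": ["mercury resistance system protein"],
    "MRG:copper": [
        "copper resistance protein CopA",
        "copper-translocating P-type ATPase",
    ],
    "MRG:czc": [
        "cobalt-zinc-cadmium resistance protein CzcA",
        "cobalt-zinc-cadmium resistance protein CzcB",
        "cobalt-zinc-cadmium resistance protein CzcC",
    ],
    "MRG:chromate": ["chromate transport protein ChrA"],
    "MRG:silver": ["silver resistance protein SilE"],
    "MRG:arsenic": ["arsenate reductase ArsC"],
    "MGE:phage": [
        "phage tail fiber protein",
        "phage capsid protein",
        "phage terminase large subunit",
        "phage portal protein",
    ],
    "MGE:insertion": [
        "IS5 family transposase",
        "tyrosine recombinase",
        "transposition helper protein",
    ],
    "MGE:plasmid": [
        "plasmid replication initiator protein RepA",
        "conjugative transfer protein TraG",
        "plasmid stabilization protein ParE",
    ],
}

# neutral products: none contains any default lexicon keyword
BACKGROUND_PRODUCTS = [
    "hypothetical protein",
    "ABC transporter permease",
    "DNA gyrase subunit B",
    "50S ribosomal protein L2",
    "30S ribosomal protein S4",
    "translation elongation factor Tu",
    "chaperone protein DnaK",
    "cell division protein FtsZ",
    "NADH-quinone oxidoreductase subunit C",
    "citrate synthase",
    "enolase",
    "histidine kinase sensor protein",
    "outer membrane porin",
    "acyl carrier protein",
    "glutamine synthetase",
    "sugar kinase",
]

DEFAULT_CATEGORY_RATES = {
    "ARG": 8.0,
    "MRG:mercury": 1.0,
    "MRG:copper": 4.0,
    "MRG:czc": 3.0,
    "MRG:chromate": 2.0,
    "MRG:silver": 1.0,
    "MRG:arsenic": 1.0,
    "MGE:phage": 12.0,
    "MGE:insertion": 10.0,
    "MGE:plasmid": 6.0,
}


class SpecError(ValueError):
    pass


@dataclass
class OperonTemplate:
    """A plantable operon: ordered mer genes 5'->3' plus flanking context."""

    name: str
    ordered_genes: list[str]
    strand: str = "+"
    intergenic_gaps: list[int] | None = None
    flank_upstream: list[tuple[str, str]] = field(default_factory=list)
    flank_downstream: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ordered_genes:
            raise SpecError(f"template {self.name!r} has no genes")
        unknown = set(self.ordered_genes) - set(MER_GENE_LENGTHS)
        if unknown:
            raise SpecError(f"template {self.name!r}: unknown genes {unknown}")
        if self.intergenic_gaps is not None:
            if len(self.intergenic_gaps) != len(self.ordered_genes) - 1:
                raise SpecError(
                    f"template {self.name!r}: gap list length must be genes-1"
                )
            if any(g < 0 for g in self.intergenic_gaps):
                raise SpecError(f"template {self.name!r}: negative gap")

    @property
    def architecture(self) -> str:
        return "-".join(self.ordered_genes)

    @property
    def complete(self) -> bool:
        genes = set(self.ordered_genes)
        return (
            "merR" in genes
            and "merA" in genes
            and bool(genes & {"merT", "merP", "merC", "merF"})
        )

    @property
    def spectrum(self) -> str:
        return "broad" if "merB" in self.ordered_genes else "narrow"


def default_templates() -> dict[str, OperonTemplate]:
    """The template families exercised by the standard validation cohort."""
    czc = [
        ("MRG:czc", "cobalt-zinc-cadmium resistance protein CzcC"),
        ("MRG:czc", "cobalt-zinc-cadmium resistance protein CzcB"),
        ("MRG:czc", "cobalt-zinc-cadmium resistance protein CzcA"),
    ]
    tni = [
        ("MGE:insertion", "transposition protein TniA"),
        ("MGE:insertion", "transposition protein TniB"),
        ("MGE:insertion", "transposition protein TniQ"),
    ]
    return {
        "TPCAB_broad": OperonTemplate(
            "TPCAB_broad", ["merR", "merT", "merP", "merC", "merA", "merB"]
        ),
        "TPCABDE_broad": OperonTemplate(
            "TPCABDE_broad",
            ["merR", "merT", "merP", "merC", "merA", "merB", "merD", "merE"],
        ),
        "F_substituted": OperonTemplate(
            "F_substituted", ["merR", "merT", "merP", "merF", "merA"]
        ),
        "isolated_merA": OperonTemplate("isolated_merA", ["merA"]),
        "tni_flanked": OperonTemplate(
            "tni_flanked",
            ["merR", "merT", "merP", "merC", "merA"],
            flank_upstream=tni,
        ),
        "czc_adjacent": OperonTemplate(
            "czc_adjacent",
            ["merR", "merT", "merP", "merC", "merA", "merE"],
            flank_downstream=czc,
        ),
    }


@dataclass
class CohortSpec:
    """Generator conditions for one synthetic cohort."""

    n_genomes: int = 30
    seed: int = 0
    templates: dict[str, OperonTemplate] = field(default_factory=default_templates)
    # genome index -> list of (template name, replicon kind, position fraction)
    operon_plan: dict[int, list[tuple[str, str, float]]] = field(default_factory=dict)
    category_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_RATES)
    )
    chromosome_length: int = 250_000
    plasmid_length: int = 60_000
    background_genes: int = 120
    # lifestyle -> {"genomes": int, "families": {family: prevalence}}
    lifestyle_plan: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise SpecError("n_genomes must be >= 1")
        if any(r < 0 for r in self.category_rates.values()):
            raise SpecError("category rates must be non-negative")


@dataclass
class PlantedOperon:
    genome_id: str
    replicon_id: str
    span: tuple[int, int]
    template: str
    architecture: str
    complete: bool
    spectrum: str
    strand: str


@dataclass
class GroundTruth:
    planted_operons: list[PlantedOperon]
    planted_category_counts: pd.DataFrame  # genome x category
    family_matrix: pd.DataFrame | None = None
    lifestyle_labels: dict[str, str] = field(default_factory=dict)
    true_tree: str | None = None

    def to_json(self) -> str:
        payload = {
            "planted_operons": [
                {
                    "genome_id": p.genome_id,
                    "replicon_id": p.replicon_id,
                    "span": list(p.span),
                    "template": p.template,
                    "architecture": p.architecture,
                    "complete": p.complete,
                    "spectrum": p.spectrum,
                    "strand": p.strand,
                }
                for p in self.planted_operons
            ],
            "planted_category_counts": {
                g: {k: int(v) for k, v in row.items()}
                for g, row in self.planted_category_counts.to_dict("index").items()
            },
            "lifestyle_labels": self.lifestyle_labels,
            "true_tree": self.true_tree,
        }
        if self.family_matrix is not None:
            payload["family_matrix"] = {
                g: {k: int(v) for k, v in row.items()}
                for g, row in self.family_matrix.to_dict("index").items()
            }
        return json.dumps(payload, indent=1, sort_keys=True)


def _place(rng, occupied: list[tuple[int, int]], length: int, rep_len: int) -> int:
    """Random non-overlapping start (20 bp margin); raises after 200 tries."""
    if length + 40 >= rep_len:
        raise SpecError("feature longer than replicon")
    for _ in range(200):
        start = int(rng.integers(20, rep_len - length - 20))
        if all(start >= e + 20 or start + length <= s - 20 for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise SpecError("could not place feature without overlap")


def _plant_operon(
    rng,
    template: OperonTemplate,
    replicon: Replicon,
    frac: float,
    occupied: list[tuple[int, int]],
    new_feature,
) -> tuple[int, int]:
    genes = template.ordered_genes
    gaps = template.intergenic_gaps or [
        int(rng.integers(10, 151)) for _ in range(len(genes) - 1)
    ]
    lengths = [MER_GENE_LENGTHS[g] for g in genes]
    span_len = sum(lengths) + sum(gaps)
    margin = 12_000  # leave room for flanks inside the replicon
    lo = max(margin, 20)
    hi = replicon.length - span_len - margin
    if hi <= lo:
        raise SpecError(
            f"operon {template.name!r} does not fit replicon {replicon.replicon_id!r}"
        )
    start = int(lo + frac * (hi - lo))
    if any(start < e + 500 and start + span_len > s - 500 for s, e in occupied):
        raise SpecError("planted operon spans overlap")
    occupied.append((start, start + span_len))
    # genomic order: template order on '+', reversed on '-'
    genomic_genes = genes if template.strand == "+" else genes[::-1]
    genomic_lengths = [MER_GENE_LENGTHS[g] for g in genomic_genes]
    genomic_gaps = gaps if template.strand == "+" else gaps[::-1]
    pos = start
    for k, gene in enumerate(genomic_genes):
        name, product = MER_PRODUCTS[gene]
        new_feature(
            replicon.replicon_id,
            pos,
            pos + genomic_lengths[k],
            template.strand,
            name,
            product,
        )
        pos += genomic_lengths[k]
        if k < len(genomic_gaps):
            pos += genomic_gaps[k]
    end = start + span_len

    def plant_flank(entries: list[tuple[str, str]], left: bool) -> None:
        gap0 = int(rng.integers(200, 2001))
        cursor = (start - gap0) if left else (end + gap0)
        ordered = entries[::-1] if left else entries
        for category, product in ordered:
            length = 600
            fstart = (cursor - length) if left else cursor
            if fstart < 20 or fstart + length > replicon.length - 20:
                raise SpecError("flank gene outside replicon")
            occupied.append((fstart, fstart + length))
            new_feature(
                replicon.replicon_id,
                fstart,
                fstart + length,
                template.strand,
                "",
                product,
            )
            step = length + int(rng.integers(100, 401))
            cursor = (cursor - step) if left else (cursor + step)
            del category

    # upstream = 5' side on the operon strand
    up_left = template.strand == "+"
    if template.flank_upstream:
        plant_flank(template.flank_upstream, left=up_left)
    if template.flank_downstream:
        plant_flank(template.flank_downstream, left=not up_left)
    return start, end


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, GroundTruth]:
    """Generate an annotated cohort plus exact ground truth.

    Deterministic for a fixed spec+seed.  Planted features carry product
    strings the default lexicon maps to the intended category; background
    genes never match any keyword.
    """
    lexicons = load_lexicons()
    categories = sorted(lx.category for lx in lexicons)
    genomes = []
    planted: list[PlantedOperon] = []
    count_rows = {}
    lifestyle_labels: dict[str, str] = {}
    lifestyle_seq: list[str] = []
    if spec.lifestyle_plan:
        for name, plan in spec.lifestyle_plan.items():
            lifestyle_seq += [name] * int(plan.get("genomes", 0))
    sources = [s for s in ISOLATION_SOURCES if s != "unknown"]

    for gi in range(spec.n_genomes):
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, gi)))
        genome_id = f"SYN{gi:03d}"
        plan = spec.operon_plan.get(gi, [])
        needs_plasmid = any(kind == "plasmid" for _, kind, _ in plan)
        replicons = [
            Replicon(f"{genome_id}_chr1", spec.chromosome_length, "circular", "chromosome")
        ]
        if needs_plasmid:
            replicons.append(
                Replicon(f"{genome_id}_p1", spec.plasmid_length, "circular", "plasmid")
            )
        occupied = {r.replicon_id: [] for r in replicons}
        features: list[GeneFeature] = []
        counter = [0]

        def new_feature(rid, start, end, strand, name, product):
            counter[0] += 1
            features.append(
                GeneFeature(
                    feature_id=f"{genome_id}_{counter[0]:05d}",
                    replicon_id=rid,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_name=name,
                    product=product,
                )
            )

        for template_name, kind, frac in plan:
            template = spec.templates[template_name]
            rep = next((r for r in replicons if r.kind == kind), replicons[0])
            span = _plant_operon(
                rng, template, rep, frac, occupied[rep.replicon_id], new_feature
            )
            planted.append(
                PlantedOperon(
                    genome_id=genome_id,
                    replicon_id=rep.replicon_id,
                    span=span,
                    template=template.name,
                    architecture=template.architecture,
                    complete=template.complete,
                    spectrum=template.spectrum,
                    strand=template.strand,
                )
            )
        # scattered categorized genes at Poisson rates (chromosome only, away
        # from operons by the placement margin)
        chrom = replicons[0]
        for category in sorted(spec.category_rates):
            rate = spec.category_rates[category]
            k = int(rng.poisson(rate))
            products = CATEGORY_PRODUCTS[category]
            for _ in range(k):
                length = int(rng.integers(400, 1400))
                start = _place(rng, occupied[chrom.replicon_id], length, chrom.length)
                new_feature(
                    chrom.replicon_id,
                    start,
                    start + length,
                    "+" if rng.random() < 0.5 else "-",
                    "",
                    products[int(rng.integers(len(products)))],
                )
        # neutral background genes across all replicons
        for rep in replicons:
            share = max(
                1, int(spec.background_genes * rep.length / spec.chromosome_length)
            )
            for _ in range(share):
                length = int(rng.integers(300, 1500))
                try:
                    start = _place(rng, occupied[rep.replicon_id], length, rep.length)
                except SpecError:
                    break
                new_feature(
                    rep.replicon_id,
                    start,
                    start + length,
                    "+" if rng.random() < 0.5 else "-",
                    "",
                    BACKGROUND_PRODUCTS[int(rng.integers(len(BACKGROUND_PRODUCTS)))],
                )
        lifestyle = lifestyle_seq[gi] if gi < len(lifestyle_seq) else None
        genome = Genome(
            genome_id=genome_id,
            species_label="Synthetica merophila",
            isolation_source=sources[gi % len(sources)],
            lifestyle_label=lifestyle,
            replicons=replicons,
            features=features,
        )
        genomes.append(genome)
        if lifestyle:
            lifestyle_labels[genome_id] = lifestyle
        # exact recount of planted features under the default lexicon
        counts = dict.fromkeys(categories, 0)
        for f in features:
            for cat in categorize(f.gene_name, f.product, lexicons):
                counts[cat] += 1
        count_rows[genome_id] = counts

    truth = GroundTruth(
        planted_operons=planted,
        planted_category_counts=pd.DataFrame.from_dict(count_rows, orient="index")[
            categories
        ].astype(int),
        lifestyle_labels=lifestyle_labels,
    )
    cohort = Cohort(genomes=genomes, provenance=f"synthetic seed={spec.seed}")
    if spec.lifestyle_plan:
        fam, labels = generate_family_matrix(
            spec.lifestyle_plan,
            seed=spec.seed,
            genome_ids=[g.genome_id for g in genomes],
        )
        truth.family_matrix = fam
        truth.lifestyle_labels = labels
        for g in genomes:
            g.lifestyle_label = labels.get(g.genome_id, g.lifestyle_label)
    return cohort, truth


def standard_validation_spec(seed: int = 0, n_genomes: int = 30) -> CohortSpec:
    """The 30-genome / 20-operon cohort spanning every default template family.

    Genomes 0–17 carry one operon each (templates cycled); genome 18 carries
    two operons on different replicons; the remainder are negative controls.
    """
    names = list(default_templates())
    plan: dict[int, list[tuple[str, str, float]]] = {}
    fracs = [0.15, 0.35, 0.55, 0.75, 0.85, 0.25]
    for i in range(min(18, n_genomes)):
        kind = "plasmid" if names[i % 6] in ("tni_flanked", "czc_adjacent") else "chromosome"
        plan[i] = [(names[i % 6], kind, fracs[i % 6])]
    if n_genomes > 18:
        plan[18] = [
            ("TPCAB_broad", "chromosome", 0.2),
            ("F_substituted", "plasmid", 0.5),
        ]
    return CohortSpec(n_genomes=n_genomes, seed=seed, operon_plan=plan)


def generate_alignment(
    true_tree: str,
    n_sites_per_protein: dict[str, int],
    substitution_rate: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, ProteinAlignment], str]:
    """Simulate gap-free protein alignments along a Newick tree.

    Substitution counts per site are Poisson(rate x branch length); each
    substitution replaces the residue with one of the other 19 amino acids
    uniformly (the Jukes–Cantor assumption).  Returns the per-protein
    alignments and the tree string used.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(data=true_tree, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("tree needs at least 3 leaves")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11)))
    alignments: dict[str, ProteinAlignment] = {}
    for protein in sorted(n_sites_per_protein):
        L = int(n_sites_per_protein[protein])
        seqs: dict[int, np.ndarray] = {}
        root = tree.seed_node
        seqs[id(root)] = rng.integers(0, 20, size=L)
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            parent_seq = seqs[id(node.parent_node)]
            bl = max(node.edge.length or 0.0, 0.0)
            seq = parent_seq.copy()
            n_subs = rng.poisson(substitution_rate * bl, size=L)
            for site in np.nonzero(n_subs)[0]:
                state = seq[site]
                for _ in range(int(n_subs[site])):
                    state = (state + 1 + int(rng.integers(19))) % 20
                seq[site] = state
            seqs[id(node)] = seq
        names, rows = [], []
        for lf in tree.leaf_node_iter():
            names.append(lf.taxon.label)
            rows.append("".join(AA[i] for i in seqs[id(lf)]))
        alignments[protein] = ProteinAlignment(
            names=names, rows=rows, source_proteins=[(protein, 0, L)]
        )
    return alignments, true_tree


def generate_family_matrix(
    lifestyle_plan: dict[str, dict],
    seed: int = 0,
    genome_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Binary genome x family matrix with lifestyle-structured prevalences.

    Each family is drawn independently per genome with its lifestyle's
    prevalence (families a lifestyle does not mention have prevalence 0).
    """
    for name, plan in lifestyle_plan.items():
        if int(plan.get("genomes", 0)) < 1:
            raise SpecError(f"lifestyle {name!r} has no genomes")
        for fam, p in plan.get("families", {}).items():
            if not 0.0 <= float(p) <= 1.0:
                raise SpecError(f"prevalence of {fam!r} outside [0, 1]")
    families = sorted(
        {f for plan in lifestyle_plan.values() for f in plan.get("families", {})}
    )
    labels: dict[str, str] = {}
    rows = {}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFA_1)))
    idx = 0
    for name in lifestyle_plan:
        plan = lifestyle_plan[name]
        prev = plan.get("families", {})
        for _ in range(int(plan["genomes"])):
            gid = (
                genome_ids[idx]
                if genome_ids is not None and idx < len(genome_ids)
                else f"SYN{idx:03d}"
            )
            labels[gid] = name
            rows[gid] = {
                fam: int(rng.random() < float(prev.get(fam, 0.0)))
                for fam in families
            }
            idx += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index")[families].astype(int)
    return matrix, labels


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")
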