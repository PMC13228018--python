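"""merA-anchored *mer* operon detection and genomic-context annotation.

The screen follows the classical neighborhood strategy: find every CDS
annotated as a mercuric reductase (*merA*), examine the surrounding ~10 kb
for accessory *mer* genes (*merR/T/P/C/F/B/D/E/G*), and grow a contiguous
operon from the anchor.  Contiguity is operationalised by three knobs —
maximum intergenic gap (default 500 bp), at most one embedded non-mer CDS,
and same-strand membership (with divergently transcribed *merR* immediately
upstream admitted as a special case, its usual arrangement).

An operon call records its members 5'->3' on the operon strand as a
hyphen-joined architecture string, a completeness flag (regulator *merR* +
reductase *merA* + at least one transport gene of *merT/P/C/F*), and its
resistance spectrum: broad when the organomercurial lyase *merB* is present
(organic + inorganic mercury), narrow otherwise.

Context annotation lists mobile-genetic-element genes (phage, insertion
sequence/transposon, plasmid) and co-resident metal-resistance loci (czc,
copper, chromate, silver, arsenic) within the window but outside the
operon, with side (upstream/downstream on the operon strand) and distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from merscape.census import assign_categories, load_lexicons
from merscape.model import Cohort, GeneFeature, Genome

MER_SYMBOLS = (
    "merR",
    "merT",
    "merP",
    "merC",
    "merF",
    "merA",
    "merB",
    "merD",
    "merE",
    "merG",
)
TRANSPORT_GENES = {"merT", "merP", "merC", "merF"}

# MRG subtypes reported as co-resident context; mercury itself is the operon.
_CONTEXT_MRG = {
    "MRG:czc": "czc",
    "MRG:copper": "copper",
    "MRG:chromate": "chromate",
    "MRG:silver": "silver",
    "MRG:arsenic": "arsenic",
}
_CONTEXT_MGE = {
    "MGE:phage": "phage",
    "MGE:insertion": "insertion",
    "MGE:plasmid": "plasmid",
}


def load_mer_lexicon(path: str | Path | None = None) -> dict[str, list[str]]:
    """Symbol -> product-keyword list (case-insensitive substrings)."""
    if path is None:
        text = (resources.files("merscape.data") / "mer_lexicon.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = pd.read_csv(pd.io.common.StringIO(text), sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        out.setdefault(row["symbol"], []).append(row["keyword"].lower())
    return out


@dataclass
class DetectorParams:
    """Tunable knobs of the neighborhood screen."""

    window_bp: int = 10_000
    max_intergenic_gap_bp: int = 500
    max_embedded_nonmer: int = 1
    require_same_strand: bool = True
    allow_divergent_merR: bool = True
    anchor_lexicon: list[str] = field(default_factory=list)
    accessory_lexicon: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.max_intergenic_gap_bp < 0:
            raise ValueError("max_intergenic_gap_bp must be non-negative")
        if not self.accessory_lexicon:
            self.accessory_lexicon = load_mer_lexicon()
        if not self.anchor_lexicon:
            self.anchor_lexicon = list(self.accessory_lexicon.get("merA", []))

    def match_symbol(self, feature: GeneFeature) -> str | None:
        """The mer gene symbol a feature's annotation maps to, if any."""
        name = feature.gene_name.strip().lower()
        for symbol in MER_SYMBOLS:
            if name == symbol.lower():
                return symbol
        haystack = f"{feature.gene_name} {feature.product}".lower()
        for symbol in MER_SYMBOLS:
            for kw in self.accessory_lexicon.get(symbol, []):
                if kw in haystack:
                    return symbol
        return None

    def is_anchor(self, feature: GeneFeature) -> bool:
        name = feature.gene_name.strip().lower()
        if name == "mera":
            return True
        haystack = f"{feature.gene_name} {feature.product}".lower()
        return any(kw in haystack for kw in self.anchor_lexicon)


@dataclass
class MerOperonCall:
    """One detected operon: members, architecture, completeness, spectrum."""

    genome_id: str
    replicon_id: str
    span: tuple[int, int]
    strand: str
    ordered_members: list[tuple[str, str]]  # (symbol or "hyp", feature_id), 5'->3'
    architecture: str
    complete: bool
    spectrum: str  # "broad" | "narrow"
    anchor_feature_id: str

    @property
    def member_ids(self) -> set[str]:
        return {fid for _, fid in self.ordered_members}

    @property
    def symbols(self) -> set[str]:
        return {sym for sym, _ in self.ordered_members if sym != "hyp"}


@dataclass
class ContextAnnotation:
    """MGE and MRG genes flanking / co-resident with one operon call."""

    call: MerOperonCall
    flank_mges: list[tuple[str, str, str, int]]  # (feature_id, subtype, side, distance)
    coresident_mrgs: list[tuple[str, str, int]]  # (feature_id, subtype, distance)


def find_mer_anchors(genome: Genome, params: DetectorParams | None = None) -> list[str]:
    """All merA-annotated CDS ids, sorted by (replicon_id, start)."""
    params = params or DetectorParams()
    hits = [f for f in genome.features if params.is_anchor(f)]
    hits.sort(key=lambda f: (f.replicon_id, f.start))
    return [f.feature_id for f in hits]


def _finalize_call(
    genome: Genome,
    feats: list[GeneFeature],
    included: list[int],
    symbols: dict[int, str | None],
    strand: str,
    anchor_id: str,
) -> MerOperonCall:
    included = sorted(included)
    members = [feats[i] for i in included]
    ordered = [(symbols[i] or "hyp", feats[i].feature_id) for i in included]
    if strand == "-":
        ordered = ordered[::-1]  # 5'->3' on the operon strand
    present = {sym for sym, _ in ordered if sym != "hyp"}
    complete = (
        "merR" in present
        and "merA" in present
        and bool(present & TRANSPORT_GENES)
    )
    return MerOperonCall(
        genome_id=genome.genome_id,
        replicon_id=members[0].replicon_id,
        span=(min(f.start for f in members), max(f.end for f in members)),
        strand=strand,
        ordered_members=ordered,
        architecture="-".join(sym for sym, _ in ordered),
        complete=complete,
        spectrum="broad" if "merB" in present else "narrow",
        anchor_feature_id=anchor_id,
    )


def call_operon(
    genome: Genome, anchor: str, params: DetectorParams | None = None
) -> MerOperonCall:
    """Grow an operon from one merA anchor by bidirectional extension.

    Extension along the sorted CDS list stops when the gap between directly
    adjacent genes exceeds ``max_intergenic_gap_bp``, when a mer gene lies on
    the wrong strand (divergent merR at the 5' end excepted), when more than
    ``max_embedded_nonmer`` consecutive non-mer CDSs would have to be
    skipped, or at the edge of the ±``window_bp`` neighborhood.
    """
    params = params or DetectorParams()
    anchor_feat = genome.feature(anchor)
    if not params.is_anchor(anchor_feat):
        raise ValueError(f"{anchor!r} is not a merA anchor")
    feats = genome.features_on(anchor_feat.replicon_id)
    idx = next(i for i, f in enumerate(feats) if f.feature_id == anchor)
    strand = anchor_feat.strand
    lo = anchor_feat.start - params.window_bp
    hi = anchor_feat.end + params.window_bp
    symbols: dict[int, str | None] = {idx: "merA"}

    def admit(i: int, sym: str, direction: int) -> bool:
        f = feats[i]
        if not params.require_same_strand or f.strand == strand:
            return True
        # divergent merR immediately upstream (5' side on the operon strand)
        upstream = -1 if strand == "+" else +1
        return (
            params.allow_divergent_merR and sym == "merR" and direction == upstream
        )

    included = [idx]
    for direction in (+1, -1):
        pending: list[int] = []
        j = idx + direction
        edge = idx
        while 0 <= j < len(feats):
            f = feats[j]
            if f.end <= lo or f.start >= hi:
                break
            prev = feats[j - direction]
            gap = (f.start - prev.end) if direction == +1 else (prev.start - f.end)
            if max(gap, 0) > params.max_intergenic_gap_bp:
                break
            sym = params.match_symbol(f)
            if sym is not None:
                if not admit(j, sym, direction):
                    break
                symbols[j] = sym
                for k in pending:
                    symbols[k] = None
                included.extend(pending)
                included.append(j)
                pending = []
                edge = j
            else:
                pending.append(j)
                if len(pending) > params.max_embedded_nonmer:
                    break
            j += direction
        del edge
    return _finalize_call(genome, feats, included, symbols, strand, anchor)


def merge_calls(genome: Genome, calls: list[MerOperonCall]) -> list[MerOperonCall]:
    """Merge calls with intersecting member sets (shared operons, two anchors)."""
    if not calls:
        return []
    groups: list[list[MerOperonCall]] = []
    for call in sorted(calls, key=lambda c: (c.replicon_id, c.span)):
        for group in groups:
            if any(call.member_ids & other.member_ids for other in group):
                group.append(call)
                break
        else:
            groups.append([call])
    merged = []
    for group in groups:
        if len(group) == 1:
            merged.append(group[0])
            continue
        feats = genome.features_on(group[0].replicon_id)
        index = {f.feature_id: i for i, f in enumerate(feats)}
        symbols: dict[int, str | None] = {}
        included: set[int] = set()
        for call in group:
            order = call.ordered_members
            if call.strand == "-":
                order = order[::-1]
            for sym, fid in order:
                i = index[fid]
                included.add(i)
                symbols[i] = None if sym == "hyp" else sym
        anchor = min(
            (c.anchor_feature_id for c in group), key=lambda fid: index[fid]
        )
        merged.append(
            _finalize_call(
                genome, feats, sorted(included), symbols, group[0].strand, anchor
            )
        )
    merged.sort(key=lambda c: (c.replicon_id, c.span))
    return merged


def annotate_context(
    genome: Genome, call: MerOperonCall, params: DetectorParams | None = None
) -> ContextAnnotation:
    """MGE/MRG genes within the window around a call, excluding its members."""
    params = params or DetectorParams()
    if not getattr(genome, "categories_assigned", False):
        raise RuntimeError(
            "feature categories not assigned; run merscape.census."
            "assign_categories on the genome first"
        )
    lo, hi = call.span
    members = call.member_ids
    mges: list[tuple[str, str, str, int]] = []
    mrgs: list[tuple[str, str, int]] = []
    for f in genome.features_on(call.replicon_id):
        if f.feature_id in members:
            continue
        if f.end <= lo - params.window_bp or f.start >= hi + params.window_bp:
            continue
        if f.start >= hi:
            distance = f.start - hi
            left_side = False
        elif f.end <= lo:
            distance = lo - f.end
            left_side = True
        else:  # overlaps the span without being a member
            distance = 0
            left_side = f.start < lo
        side = (
            "upstream"
            if (left_side == (call.strand == "+"))
            else "downstream"
        )
        for cat in sorted(f.categories):
            if cat in _CONTEXT_MGE:
                mges.append((f.feature_id, _CONTEXT_MGE[cat], side, distance))
            elif cat in _CONTEXT_MRG:
                mrgs.append((f.feature_id, _CONTEXT_MRG[cat], distance))
            elif cat.startswith("MRG:") and cat != "MRG:mercury":
                mrgs.append((f.feature_id, "other-metal", distance))
    return ContextAnnotation(call=call, flank_mges=mges, coresident_mrgs=mrgs)


@dataclass
class DetectionResult:
    calls: list[tuple[MerOperonCall, ContextAnnotation]]
    summary: dict

    def calls_table(self) -> pd.DataFrame:
        rows = [
            {
                "genome_id": c.genome_id,
                "replicon_id": c.replicon_id,
                "start": c.span[0],
                "end": c.span[1],
                "strand": c.strand,
                "architecture": c.architecture,
                "complete": c.complete,
                "spectrum": c.spectrum,
                "anchor": c.anchor_feature_id,
            }
            for c, _ in self.calls
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "genome_id",
                "replicon_id",
                "start",
                "end",
                "strand",
                "architecture",
                "complete",
                "spectrum",
                "anchor",
            ],
        )

    def context_table(self) -> pd.DataFrame:
        rows = []
        for call, ctx in self.calls:
            for fid, subtype, side, dist in ctx.flank_mges:
                rows.append(
                    {
                        "genome_id": call.genome_id,
                        "anchor": call.anchor_feature_id,
                        "kind": "MGE",
                        "feature_id": fid,
                        "subtype": subtype,
                        "side": side,
                        "distance_bp": dist,
                    }
                )
            for fid, subtype, dist in ctx.coresident_mrgs:
                rows.append(
                    {
                        "genome_id": call.genome_id,
                        "anchor": call.anchor_feature_id,
                        "kind": "MRG",
                        "feature_id": fid,
                        "subtype": subtype,
                        "side": "",
                        "distance_bp": dist,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "genome_id",
                "anchor",
                "kind",
                "feature_id",
                "subtype",
                "side",
                "distance_bp",
            ],
        )


def detect_all(cohort: Cohort, params: DetectorParams | None = None) -> DetectionResult:
    """Per-genome anchor screen + merge + context, with a cohort summary.

    The summary reports the fraction of genomes carrying at least one
    complete operon and the fraction carrying *merB* (broad spectrum).
    """
    params = params or DetectorParams()
    results: list[tuple[MerOperonCall, ContextAnnotation]] = []
    n_complete = 0
    n_merb = 0
    for genome in cohort:
        if not getattr(genome, "categories_assigned", False):
            assign_categories(genome, load_lexicons())
        anchors = find_mer_anchors(genome, params)
        calls = merge_calls(
            genome, [call_operon(genome, a, params) for a in anchors]
        )
        if any(c.complete for c in calls):
            n_complete += 1
        if any("merB" in c.symbols for c in calls):
            n_merb += 1
        for call in calls:
            results.append((call, annotate_context(genome, call, params)))
    n = len(cohort)
    return DetectionResult(
        calls=results,
        summary={
            "n_genomes": n,
            "n_calls": len(results),
            "fraction_complete": n_complete / n,
            "fraction_merB": n_merb / n,
        },
    )
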