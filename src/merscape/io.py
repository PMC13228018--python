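"""Reading and writing annotated genomes and cohort metadata.

Two on-disk dialects are supported:

* ``gff3`` — generic GFF3 with CDS rows and ``##sequence-region`` pragmas.
  Replicon kind/topology and genome metadata that GFF3 has no column for are
  carried in ``#!merscape`` pragma comments, which other GFF3 consumers
  ignore.  External coordinates are 1-based inclusive; internally everything
  is 0-based half-open.
* ``feature_tsv`` — a flat tab-separated table (internal coordinates) with
  the same pragma header, convenient for spreadsheets and hand-built tests.

Cohort metadata is a TSV with columns ``genome_id``, ``species_label``,
``isolation_source``, ``annotation_file`` and optional ``lifestyle_label``.
"""

from __future__ import annotations

import logging
import urllib.parse
from pathlib import Path

import pandas as pd

from merscape.model import (
    ISOLATION_SOURCES,
    Cohort,
    GeneFeature,
    Genome,
    Replicon,
    ValidationError,
)

log = logging.getLogger(__name__)

_TSV_COLUMNS = [
    "feature_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "gene_name",
    "product",
    "family_id",
]


class ParseError(ValueError):
    """A file could not be parsed under the named dialect."""


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = urllib.parse.unquote(value.strip())
    return out


def _format_attributes(feature: GeneFeature) -> str:
    parts = [f"ID={urllib.parse.quote(feature.feature_id, safe='')}"]
    if feature.gene_name:
        parts.append(f"gene={urllib.parse.quote(feature.gene_name, safe='')}")
    if feature.product:
        parts.append(f"product={urllib.parse.quote(feature.product, safe=' ')}")
    if feature.family_id:
        parts.append(f"family={urllib.parse.quote(feature.family_id, safe='')}")
    return ";".join(parts)


def read_genome(
    annotation_path: str | Path,
    sequence_path: str | Path | None = None,
    format: str = "gff3",
) -> Genome:
    """Read one annotated genome.

    Parameters
    ----------
    annotation_path
        GFF3 or feature-TSV file.
    sequence_path
        Optional FASTA whose record lengths supply replicon lengths when the
        annotation lacks ``##sequence-region`` pragmas.
    format
        ``"gff3"`` or ``"feature_tsv"``.

    Returns
    -------
    Genome
        Validated genome with internal 0-based half-open coordinates.  Only
        CDS rows are retained; other feature types are counted and logged.
    """
    annotation_path = Path(annotation_path)
    if format == "gff3":
        genome = _read_gff3(annotation_path)
    elif format == "feature_tsv":
        genome = _read_feature_tsv(annotation_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if sequence_path is not None:
        from Bio import SeqIO

        known = {r.replicon_id for r in genome.replicons}
        for record in SeqIO.parse(str(sequence_path), "fasta"):
            if record.id not in known:
                genome.replicons.append(Replicon(record.id, len(record.seq)))
                known.add(record.id)
    genome.validate()
    return genome


def _read_pragmas(line: str, meta: dict, replicon_meta: dict) -> None:
    fields = line.split("\t")[1:]  # keep empty fields (e.g. blank species)
    if not fields:
        return
    if fields[0] == "genome" and len(fields) >= 2:
        meta["genome_id"] = fields[1]
        if len(fields) >= 3:
            meta["species_label"] = fields[2]
        if len(fields) >= 4:
            meta["isolation_source"] = fields[3]
        if len(fields) >= 5 and fields[4] != ".":
            meta["lifestyle_label"] = fields[4]
    elif fields[0] == "replicon" and len(fields) >= 4:
        replicon_meta[fields[1]] = (fields[2], fields[3])


def _read_gff3(path: Path) -> Genome:
    meta: dict = {}
    replicon_meta: dict[str, tuple[str, str]] = {}
    replicons: list[Replicon] = []
    features: list[GeneFeature] = []
    skipped = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#!merscape"):
                _read_pragmas(line, meta, replicon_meta)
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: malformed ##sequence-region pragma"
                    )
                try:
                    end = int(parts[3])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer sequence-region bound"
                    ) from exc
                replicons.append(Replicon(parts[1], end))
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                skipped += 1
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"{path}:{lineno}: invalid 1-based span {start1}..{end1}"
                )
            attributes = _parse_attributes(attrs)
            feature_id = attributes.get("ID", f"{seqid}_{lineno}")
            try:
                features.append(
                    GeneFeature(
                        feature_id=feature_id,
                        replicon_id=seqid,
                        start=start1 - 1,  # 1-based inclusive -> 0-based half-open
                        end=end1,
                        strand=strand,
                        gene_name=attributes.get("gene", ""),
                        product=attributes.get("product", ""),
                        family_id=attributes.get("family"),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if skipped:
        log.info("%s: ignored %d non-CDS feature rows", path, skipped)
    for rep in replicons:
        if rep.replicon_id in replicon_meta:
            kind, topology = replicon_meta[rep.replicon_id]
            rep.kind = kind
            rep.topology = topology
    return Genome(
        genome_id=meta.get("genome_id", path.stem),
        species_label=meta.get("species_label", ""),
        isolation_source=meta.get("isolation_source", "unknown"),
        lifestyle_label=meta.get("lifestyle_label"),
        replicons=replicons,
        features=features,
    )


def _read_feature_tsv(path: Path) -> Genome:
    meta: dict = {}
    replicon_meta: dict[str, tuple[str, str]] = {}
    replicons: list[Replicon] = []
    features: list[GeneFeature] = []
    header: list[str] | None = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#!merscape"):
                _read_pragmas(line, meta, replicon_meta)
                continue
            if line.startswith("#!length"):
                _, rid, length_s = line.split("\t")
                replicons.append(Replicon(rid, int(length_s)))
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                if header != _TSV_COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: unexpected feature_tsv header"
                    )
                continue
            if len(cols) != len(_TSV_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns"
                )
            row = dict(zip(_TSV_COLUMNS, cols))
            try:
                features.append(
                    GeneFeature(
                        feature_id=row["feature_id"],
                        replicon_id=row["replicon_id"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=row["strand"],
                        gene_name=row["gene_name"],
                        product=row["product"],
                        family_id=row["family_id"] or None,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    for rep in replicons:
        if rep.replicon_id in replicon_meta:
            kind, topology = replicon_meta[rep.replicon_id]
            rep.kind = kind
            rep.topology = topology
    return Genome(
        genome_id=meta.get("genome_id", path.stem),
        species_label=meta.get("species_label", ""),
        isolation_source=meta.get("isolation_source", "unknown"),
        lifestyle_label=meta.get("lifestyle_label"),
        replicons=replicons,
        features=features,
    )


def _pragma_block(genome: Genome) -> list[str]:
    lines = [
        "#!merscape\tgenome\t{}\t{}\t{}\t{}".format(
            genome.genome_id,
            genome.species_label,
            genome.isolation_source,
            genome.lifestyle_label if genome.lifestyle_label else ".",
        )
    ]
    for rep in genome.replicons:
        lines.append(
            f"#!merscape\treplicon\t{rep.replicon_id}\t{rep.kind}\t{rep.topology}"
        )
    return lines


def write_genome(genome: Genome, path: str | Path, format: str = "gff3") -> None:
    """Write a genome as GFF3 (1-based inclusive) or feature TSV (internal).

    ``read_genome(write_genome(g))`` is the identity on the data model
    (feature ``categories`` excepted: they are derived, not serialized).
    """
    genome.validate()
    path = Path(path)
    lines: list[str]
    if format == "gff3":
        lines = ["##gff-version 3"]
        lines += _pragma_block(genome)
        for rep in genome.replicons:
            lines.append(f"##sequence-region {rep.replicon_id} 1 {rep.length}")
        for f in genome.features:
            lines.append(
                "\t".join(
                    [
                        f.replicon_id,
                        "merscape",
                        "CDS",
                        str(f.start + 1),  # back to 1-based inclusive
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        _format_attributes(f),
                    ]
                )
            )
    elif format == "feature_tsv":
        lines = _pragma_block(genome)
        for rep in genome.replicons:
            lines.append(f"#!length\t{rep.replicon_id}\t{rep.length}")
        lines.append("\t".join(_TSV_COLUMNS))
        for f in genome.features:
            lines.append(
                "\t".join(
                    [
                        f.feature_id,
                        f.replicon_id,
                        str(f.start),
                        str(f.end),
                        f.strand,
                        f.gene_name,
                        f.product,
                        f.family_id or "",
                    ]
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_cohort(metadata_path: str | Path, genome_dir: str | Path) -> Cohort:
    """Load a cohort from a metadata TSV plus one annotation file per row."""
    metadata_path = Path(metadata_path)
    genome_dir = Path(genome_dir)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "species_label", "isolation_source", "annotation_file"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"{metadata_path}: missing columns {sorted(missing)}")
    if meta["genome_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["genome_id"].duplicated(), "genome_id"])
        raise ValidationError(f"duplicate genome ids in metadata: {dupes}")
    genomes = []
    for _, row in meta.iterrows():
        ann = genome_dir / row["annotation_file"]
        if not ann.exists():
            raise FileNotFoundError(
                f"genome {row['genome_id']!r}: annotation file {ann} not found"
            )
        fmt = "feature_tsv" if ann.suffix == ".tsv" else "gff3"
        genome = read_genome(ann, format=fmt)
        genome.genome_id = row["genome_id"]
        genome.species_label = row["species_label"] or genome.species_label
        source = row["isolation_source"]
        genome.isolation_source = (
            source if source in ISOLATION_SOURCES else "unknown"
        )
        if "lifestyle_label" in meta.columns and row["lifestyle_label"]:
            genome.lifestyle_label = row["lifestyle_label"]
        genomes.append(genome)
    return Cohort(genomes=genomes, provenance=str(metadata_path))


def write_cohort(cohort: Cohort, out_dir: str | Path, format: str = "gff3") -> Path:
    """Write one annotation file per genome plus a metadata TSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".gff3" if format == "gff3" else ".tsv"
    rows = []
    for genome in cohort:
        fname = f"{genome.genome_id}{suffix}"
        write_genome(genome, out_dir / fname, format=format)
        rows.append(
            {
                "genome_id": genome.genome_id,
                "species_label": genome.species_label,
                "isolation_source": genome.isolation_source,
                "lifestyle_label": genome.lifestyle_label or "",
                "annotation_file": fname,
            }
        )
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    return meta_path
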