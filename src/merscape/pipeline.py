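"""End-to-end orchestration: simulate -> detect -> census -> stats -> phylo -> lags.

A run is configured by a single YAML-compatible mapping (see
:class:`RunConfig`), executed stage by stage in dependency order, and
produces a report bundle: per-stage output files plus a manifest recording
the config checksum, the seed, every output file with its SHA-256, and any
warnings.  Outputs contain no timestamps, so two runs with the same config
and seed are byte-identical.

The derived factor ``mer_operon_presence`` (does a genome carry at least
one complete operon?) is computed from detection and fed to the
multivariate tests alongside ``isolation_source`` and, when available,
``lifestyle``.  Pairwise post hoc results are emitted only when the global
test is significant at ``alpha``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from merscape import census as census_mod
from merscape import detect as detect_mod
from merscape import lags as lags_mod
from merscape import phylo as phylo_mod
from merscape import simulate as sim_mod
from merscape import stats as stats_mod
from merscape.io import read_cohort, write_cohort
from merscape.model import Cohort

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "merscape_run"
    seed: int = 0
    # input: either a metadata TSV + genome dir, or a simulation request
    metadata: str | None = None
    genome_dir: str | None = None
    simulate: bool = True
    n_genomes: int = 30
    window_bp: int = 10_000
    max_intergenic_gap_bp: int = 500
    alpha: float = 0.05
    permutations: int = 10_000
    bootstrap_reps: int = 500
    factors: tuple[str, ...] = ("isolation_source", "mer_operon_presence")
    lexicon: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "factors" in data:
            data["factors"] = tuple(data["factors"])
        return cls(**data)

    def checksum(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict

    def checksums(self) -> dict[str, str]:
        return dict(self.manifest["files"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")


def _result_to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            out[f.name] = v
        return out
    return dict(obj)


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> ReportBundle:
    """Execute all stages; returns the bundle with a validated manifest.

    Stage failures mark the bundle partial (recorded in the manifest)
    rather than discarding completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_checksum": config.checksum(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "files": {},
    }
    files: list[Path] = []

    def record(path: Path) -> None:
        files.append(path)

    truth = None
    try:
        if cohort is None:
            if config.simulate:
                spec = sim_mod.standard_validation_spec(
                    seed=config.seed, n_genomes=config.n_genomes
                )
                spec.lifestyle_plan = _default_lifestyle_plan(config.n_genomes)
                cohort, truth = sim_mod.generate_cohort(spec)
                meta = write_cohort(cohort, out / "cohort")
                record(meta)
                for g in cohort:
                    record(out / "cohort" / f"{g.genome_id}.gff3")
                truth_path = out / "ground_truth.json"
                sim_mod.write_ground_truth(truth, truth_path)
                record(truth_path)
            else:
                if not config.metadata or not config.genome_dir:
                    raise ValueError("metadata and genome_dir required")
                cohort = read_cohort(config.metadata, config.genome_dir)
        manifest["stages"]["input"] = "ok"
    except Exception as exc:  # pragma: no cover - config errors surface early
        manifest["stages"]["input"] = f"failed: {exc}"
        manifest["partial"] = True
        _finalize(out, manifest, files)
        raise

    lexicons = census_mod.load_lexicons(config.lexicon)
    for genome in cohort:
        census_mod.assign_categories(genome, lexicons)

    # --- detection ---------------------------------------------------------
    params = detect_mod.DetectorParams(
        window_bp=config.window_bp,
        max_intergenic_gap_bp=config.max_intergenic_gap_bp,
    )
    detection = detect_mod.detect_all(cohort, params)
    calls_path = out / "operon_calls.tsv"
    detection.calls_table().to_csv(calls_path, sep="\t", index=False)
    context_path = out / "operon_context.tsv"
    detection.context_table().to_csv(context_path, sep="\t", index=False)
    summary_path = out / "detection_summary.json"
    _json_dump(detection.summary, summary_path)
    record(calls_path)
    record(context_path)
    record(summary_path)
    manifest["stages"]["detect"] = "ok"

    # --- census ------------------------------------------------------------
    gc = census_mod.census(cohort, lexicons)
    census_path = out / "census.tsv"
    gc.matrix.to_csv(census_path, sep="\t")
    record(census_path)
    if len(cohort) >= 2:
        zp = census_mod.zscore_standardize(gc)
        z_path = out / "zscores.tsv"
        zp.matrix.to_csv(z_path, sep="\t", float_format="%.6g")
        record(z_path)
        if zp.clipped_entries:
            manifest["warnings"].append(
                f"z-scores: {zp.clipped_entries} entries clipped to ±{zp.clip:g}"
            )
    manifest["stages"]["census"] = "ok"

    # --- statistics --------------------------------------------------------
    mer_positive = {
        g.genome_id: "mer_positive" for g in cohort
    }
    complete_by_genome = {g.genome_id: False for g in cohort}
    for call, _ctx in detection.calls:
        if call.complete:
            complete_by_genome[call.genome_id] = True
    for gid, has in complete_by_genome.items():
        mer_positive[gid] = "mer_positive" if has else "mer_negative"

    factor_values = {
        "isolation_source": {g.genome_id: g.isolation_source for g in cohort},
        "mer_operon_presence": mer_positive,
        "lifestyle": {
            g.genome_id: g.lifestyle_label
            for g in cohort
            if g.lifestyle_label is not None
        },
    }
    D = stats_mod.bray_curtis(gc.matrix)
    dist_path = out / "bray_curtis.tsv"
    D.to_frame().to_csv(dist_path, sep="\t", float_format="%.10g")
    record(dist_path)
    newick = stats_mod.hcluster(D)
    dendro_path = out / "census_dendrogram.nwk"
    dendro_path.write_text(newick + "\n")
    record(dendro_path)

    stats_report: dict = {}
    for factor in config.factors:
        values = factor_values.get(factor, {})
        labels = [values.get(g.genome_id) for g in cohort]
        if any(v is None for v in labels) or len(set(labels)) < 2:
            stats_report[factor] = {"skipped": "factor unavailable or constant"}
            continue
        perm = stats_mod.permanova(
            D, labels, n_perm=config.permutations, seed=config.seed
        )
        disp = stats_mod.betadisper(
            D, labels, n_perm=min(config.permutations, 999), seed=config.seed
        )
        entry = {
            "permanova": _result_to_dict(perm),
            "betadisper": _result_to_dict(disp),
            "rank_tests": {},
        }
        group_counts = {
            "ARG": gc.matrix.filter(like="ARG").sum(axis=1),
            "MRG": gc.matrix.filter(like="MRG").sum(axis=1),
            "MGE": gc.matrix.filter(like="MGE").sum(axis=1),
        }
        for group, counts in group_counts.items():
            rt = stats_mod.kruskal_dunn(
                counts.to_numpy(), np.asarray(labels), alpha=config.alpha
            )
            row = {"H": rt.H, "p_value": rt.p_value}
            # post hoc gated on a significant global test
            if rt.p_value < config.alpha:
                row["pairwise"] = [
                    {
                        "groups": list(pair),
                        "z": z,
                        "p_raw": p_raw,
                        "p_bonferroni": p_adj,
                    }
                    for pair, z, p_raw, p_adj in rt.pairwise
                ]
            entry["rank_tests"][group] = row
        stats_report[factor] = entry

    mrg_total = gc.matrix.filter(like="MRG").sum(axis=1).to_numpy(dtype=float)
    correlations = {}
    for partner in ("MGE:phage", "MGE:insertion", "MGE:plasmid", "ARG"):
        if partner not in gc.matrix.columns:
            continue
        y = gc.matrix[partner].to_numpy(dtype=float)
        rep = stats_mod.dual_correlation(mrg_total, y, alpha=config.alpha)
        correlations[f"MRG_vs_{partner}"] = _result_to_dict(rep)
    stats_report["dual_correlations"] = correlations

    if len(cohort) >= 3:
        ord_pca = stats_mod.pca(gc.matrix.loc[:, gc.matrix.std(axis=0) > 0])
        ord_pcoa = stats_mod.pcoa(D)
        stats_report["ordination"] = {
            "pca_explained": [float(v) for v in ord_pca.explained[:5]],
            "pcoa_explained": [float(v) for v in ord_pcoa.explained[:5]],
            "pcoa_negative_eigenvalue_mass": ord_pcoa.negative_eigenvalue_mass,
        }
    stats_path = out / "statistics.json"
    _json_dump(stats_report, stats_path)
    record(stats_path)
    manifest["stages"]["stats"] = "ok"

    # --- phylogeny ---------------------------------------------------------
    mer_pos_ids = sorted(
        gid for gid, has in complete_by_genome.items() if has
    )[:10]
    if len(mer_pos_ids) >= 4:
        tree_str = _random_true_tree(mer_pos_ids, seed=config.seed)
        alignments, _ = sim_mod.generate_alignment(
            tree_str,
            {"MerR": 144, "MerT": 116, "MerP": 91, "MerA": 561},
            substitution_rate=1.0,
            seed=config.seed,
        )
        concat = phylo_mod.concatenate(alignments)
        tree = phylo_mod.bootstrap_support(
            concat, n_reps=config.bootstrap_reps, seed=config.seed
        )
        tree_path = out / "mer_protein_tree.nwk"
        phylo_mod.write_newick(tree, tree_path)
        record(tree_path)
        manifest["stages"]["phylo"] = "ok"
    else:
        manifest["stages"]["phylo"] = "skipped: <4 mer-positive genomes"

    # --- LAGs --------------------------------------------------------------
    if truth is not None and truth.family_matrix is not None:
        labels = truth.lifestyle_labels
        prev = lags_mod.prevalence(truth.family_matrix, labels)
        table = lags_mod.classify_lags(prev)
        lag_path = out / "lag_table.tsv"
        table.to_frame().to_csv(lag_path, sep="\t", index=False)
        record(lag_path)
        focal = truth.family_matrix.index[0]
        summary = lags_mod.lag_summary(table, truth.family_matrix, focal)
        lag_sum_path = out / "lag_summary.json"
        _json_dump(summary, lag_sum_path)
        record(lag_sum_path)
        manifest["stages"]["lags"] = "ok"
    else:
        manifest["stages"]["lags"] = "skipped: no presence-absence matrix"

    _finalize(out, manifest, files)
    return ReportBundle(out_dir=out, manifest=manifest)


def _finalize(out: Path, manifest: dict, files: list[Path]) -> None:
    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))
    }
    _json_dump(manifest, out / "manifest.json")


def _default_lifestyle_plan(n_genomes: int) -> dict[str, dict]:
    """Three lifestyles with distinct high-prevalence family blocks."""
    third = max(n_genomes // 3, 1)
    fams = lambda prefix, lo, hi: {f"{prefix}{i:03d}": hi for i in range(10)}
    plan = {
        "soil_free_living": {
            "genomes": third,
            "families": {f"soilFam{i:03d}": 0.9 for i in range(10)},
        },
        "human_opportunistic": {
            "genomes": third,
            "families": {f"humFam{i:03d}": 0.9 for i in range(10)},
        },
        "plant_associated": {
            "genomes": n_genomes - 2 * third,
            "families": {f"plantFam{i:03d}": 0.9 for i in range(10)},
        },
    }
    del fams
    return plan


def _random_true_tree(names: list[str], seed: int) -> str:
    """A random binary Newick tree over the given taxa (coalescent-like)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7EE)))
    nodes = [(n, 0.1 + 0.2 * float(rng.random())) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, la), (nb, lb) = nodes[i], nodes[j]
        merged = (f"({na}:{la:.4f},{nb}:{lb:.4f})", 0.1 + 0.2 * float(rng.random()))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0][0] + ";"


def validate_manifest(out_dir: str | Path) -> bool:
    """Every file listed in the manifest exists and hashes match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    for rel, digest in manifest["files"].items():
        p = out / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
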