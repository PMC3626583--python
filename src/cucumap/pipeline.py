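"""End-to-end pipeline orchestration and artifact management.

Stages run in dependency order (simulate -> map -> integrate -> annotate ->
anchor -> report); every artifact is a plain-text file (TSV/FASTA/Newick/BED)
under the output directory, and the manifest records each file's SHA-256
together with the configuration and seeds, so a re-run with the same
configuration reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from . import report as crep
from .anchoring import anchor_genes, anchor_scaffolds, assign_markers, colinearity_check
from .genotypes import GenotypeMatrix
from .integration import IntegrationConfig, detect_marker_clusters, integrate_maps
from .linkage import KOSAMBI, MapParams, build_component_map, relabel_linkage_groups
from .rgh import RghGene, detect_clusters, est_support, nb_domain_set, nj_tree
from .synthetic_data import (
    ConfigError,
    CrossDesign,
    EstParams,
    PrimerParams,
    TruthConfig,
    simulate_population,
    simulate_sequences,
    simulate_truth,
)

log = logging.getLogger("cucumap")

STAGES = ("simulate", "map", "integrate", "annotate", "anchor", "report")


@dataclass
class PopulationSpec:
    name: str
    kind: str
    n_individuals: int
    apply_suppression: bool = False
    missing_rate: float = 0.03
    genotyping_error_rate: float = 0.005


def default_populations() -> list[PopulationSpec]:
    # the three component-map designs being emulated
    return [
        PopulationSpec("CSS-F2", "F2", 92, apply_suppression=False),
        PopulationSpec("CSS-RIL", "RIL", 148, apply_suppression=False),
        PopulationSpec("CSH-RIL", "RIL", 77, apply_suppression=True),
    ]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "cucumap_out"
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    bp_scale: float = 1.0 / 25.0  # physical profile for sequence-bearing stages
    truth: dict = field(default_factory=dict)  # TruthConfig overrides
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    map_function: str = KOSAMBI
    lod_threshold: float = 6.0
    rf_threshold: float = 0.30
    bin_width: float = 1.0
    reference_map: str = "CSS-F2"
    n_bootstrap: int = 1000
    max_product: int = 2000

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if not self.populations:
            raise ConfigError("at least one population required")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "populations" in data:
            data["populations"] = [
                p if isinstance(p, PopulationSpec) else PopulationSpec(**p)
                for p in data["populations"]
            ]
        if "stages" in data:
            stages = {s: True for s in STAGES}
            stages.update(data["stages"])
            data["stages"] = stages
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stages = config.stages

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        log.info("wrote %s", path)

    truth_cfg = TruthConfig(**{**config.truth, "seed": config.seed}).scaled(config.bp_scale) \
        if config.bp_scale != 1.0 else TruthConfig(**{**config.truth, "seed": config.seed})
    truth = simulate_truth(truth_cfg)
    bundle = None
    matrices: dict[str, GenotypeMatrix] = {}

    if stages.get("simulate", True):
        log.info("simulate: truth genome + %d populations", len(config.populations))
        bundle = simulate_sequences(truth, EstParams(), PrimerParams(), seed=config.seed)
        for k, spec in enumerate(config.populations):
            design = CrossDesign(spec.kind, spec.n_individuals,
                                 missing_rate=spec.missing_rate,
                                 genotyping_error_rate=spec.genotyping_error_rate,
                                 seed=config.seed * 1000 + k + 1,
                                 apply_suppression=spec.apply_suppression, name=spec.name)
            matrices[spec.name] = simulate_population(truth, design)
        save("truth_markers.tsv", lambda p: pd.DataFrame(
            [{"marker": m.id, "LG": m.chromosome, "cM": round(m.true_cm, 4),
              "scaffold": m.scaffold_id, "offset_bp": m.scaffold_offset_bp}
             for m in truth.markers]).to_csv(p, sep="\t", index=False))
        save("scaffolds.fasta", lambda p: cio.write_fasta(bundle.scaffold_sequences, p))
        save("rgh_peptides.fasta", lambda p: cio.write_fasta(bundle.peptides, p))
        save("ests.fasta", lambda p: cio.write_fasta(
            {e.id: e.sequence for e in bundle.ests}, p))
        save("primers.tsv", lambda p: cio.write_primers(bundle.primers, p))
        save("annotations.tsv", lambda p: cio.write_annotations(truth.rgh_genes, p))
        for name, matrix in matrices.items():
            save(f"genotypes_{name}.tsv", matrix.write)

    component_maps = {}
    rf_tables = {}
    missing_counts: dict[str, int] = {}
    if stages.get("map", True):
        log.info("map: building %d component maps", len(matrices))
        params = MapParams(config.map_function, config.lod_threshold, config.rf_threshold)
        marker_lg = {m.id: m.chromosome for m in truth.markers}
        for name, matrix in matrices.items():
            res = build_component_map(matrix, params, name=name)
            cmap = relabel_linkage_groups(res.component_map, marker_lg)
            cmap.name = name
            component_maps[name] = cmap
            rf_tables[name] = res.rf_table
            missing_counts.update(res.cleaned_matrix.missing_counts())
            save(f"map_{name}.tsv", lambda p, c=cmap: cio.write_map(c, p))

    consensus = None
    integration_result = None
    if stages.get("integrate", True) and len(component_maps) >= 2:
        log.info("integrate: %d component maps", len(component_maps))
        exclusions = []
        suppressed = {s.name for s in config.populations if s.apply_suppression}
        for name in suppressed & set(component_maps):
            exclusions += detect_marker_clusters(component_maps[name])
        icfg = IntegrationConfig(config.bin_width, config.map_function,
                                 config.reference_map if config.reference_map in component_maps else None,
                                 exclusions, seed=config.seed)
        integration_result = integrate_maps(list(component_maps.values()), rf_tables,
                                            truth.marker_scaffolds(), missing_counts, icfg)
        consensus = integration_result.consensus
        save("consensus_map.tsv", lambda p: cio.write_tsv(consensus.to_frame(), p))
        save("bins.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"map": b.map_name, "LG": b.lg, "start_cM": round(b.start_cm, 3),
              "end_cM": round(b.end_cm, 3), "n_members": len(b.members),
              "representatives": ",".join(b.representative_ids)}
             for b in integration_result.bins]), p))
        save("conflicts.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"marker": c.marker_id, "scaffold": c.scaffold_id or "",
              "resolution": c.resolution or "dropped", "rule": c.rule_applied,
              "assignments": ";".join(f"{m}:{g}:{cm:.2f}" for m, g, cm in c.assignments)}
             for c in integration_result.conflicts]), p))
        conc_rows = []
        for (a, b), per_lg in integration_result.concordance.items():
            for lg, (r, n) in per_lg.items():
                conc_rows.append({"map_x": a, "map_y": b, "LG": lg,
                                  "spearman_r": None if r is None else round(r, 4),
                                  "n_shared": n})
        save("concordance.tsv", lambda p: cio.write_tsv(pd.DataFrame(conc_rows), p))

    genes = [RghGene(g.id, g.scaffold_id, g.start_bp, g.end_bp, g.domain_architecture,
                     g.chromosome, g.peptide, g.nb_span) for g in truth.rgh_genes]
    clusters = []
    if stages.get("annotate", True):
        log.info("annotate: %d genes", len(genes))
        clusters = detect_clusters(genes, max_span_bp=truth_cfg.cluster_rule_bp)
        save("rgh_classes.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"gene": g.id, "scaffold": g.scaffold_id, "chromosome": g.chromosome,
              "domains": ",".join(g.domains), "class": g.rgh_class} for g in genes]), p))
        save("rgh_clusters.bed", lambda p: cio.write_clusters_bed(clusters, p))
        nb = nb_domain_set(truth.rgh_genes)
        if len(nb) >= 3:
            tree = nj_tree(nb, n_bootstrap=config.n_bootstrap, seed=config.seed)
            save("nb_tree.nwk", lambda p: Path(p).write_text(tree.newick() + "\n"))
        if bundle is not None:
            est_by_gene: dict[str, list] = {}
            for e in bundle.ests:
                est_by_gene.setdefault(e.gene_id, []).append((e.id, e.sequence, e.tissue))
            rows = []
            for g in truth.rgh_genes:
                supported, hits, per_tissue = est_support(
                    bundle.gene_cds[g.id], est_by_gene.get(g.id, []))
                rows.append({"gene": g.id, "supported": supported, "hits": hits,
                             "tissues": ",".join(f"{t}:{c}" for t, c in sorted(per_tissue.items()))})
            save("est_support.tsv", lambda p: cio.write_tsv(pd.DataFrame(rows), p))

    anchor_report = None
    if stages.get("anchor", True) and bundle is not None and consensus is not None:
        log.info("anchor: in silico PCR of %d primer pairs", len(bundle.primers))
        assignments = assign_markers(bundle.primers, bundle.scaffold_sequences,
                                     config.max_product)
        save("amplicons.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"marker": m, "label": label, "scaffold": a.scaffold_id,
              "start": a.start_bp, "end": a.end_bp, "strand": a.strand}
             for m, (amps, label) in sorted(assignments.items()) for a in amps] or
            [{"marker": "", "label": "", "scaffold": "", "start": 0, "end": 0, "strand": ""}]), p))
        marker_scaffolds = {m: amps[0].scaffold_id
                            for m, (amps, label) in assignments.items() if label == "unique"}
        marker_offsets = {m: amps[0].start_bp
                          for m, (amps, label) in assignments.items() if label == "unique"}
        positions = consensus.positions()
        scaffold_lengths = {s.id: s.length_bp for s in truth.scaffolds}
        genome_bp = sum(c.length_bp for c in truth.chromosomes)
        anchor_report = anchor_scaffolds(positions, marker_scaffolds, scaffold_lengths,
                                         genome_bp, marker_offsets)
        save("anchor_report.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"scaffold": a.scaffold_id, "LG": a.lg or "", "anchored": a.anchored,
              "orientation": a.orientation, "markers": ",".join(a.supporting_markers)}
             for a in anchor_report.scaffolds]), p))
        col = colinearity_check(positions, {m: (marker_scaffolds[m], marker_offsets[m])
                                            for m in marker_scaffolds}, anchor_report)
        save("colinearity.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"LG": lg, "spearman_r": None if r is None else round(r, 4), "n": n}
             for lg, (r, n) in col.items()]), p))
        delimited = anchor_genes(truth.rgh_genes, marker_scaffolds, positions)
        save("rgh_anchoring.tsv", lambda p: cio.write_tsv(pd.DataFrame(
            [{"gene": g, "delimited": v} for g, v in sorted(delimited.items())]), p))

    if stages.get("report", True):
        log.info("report: summary tables")
        save("report_classes.tsv", lambda p: cio.write_tsv(crep.summarize_classes(genes), p))
        if clusters:
            save("report_clusters.tsv", lambda p: cio.write_tsv(
                crep.summarize_clusters(clusters, len(genes)), p))
        if consensus is not None:
            rows = crep.consensus_map_rows(consensus, anchor_report)
            save("report_map.tsv", lambda p: cio.write_tsv(crep.summarize_map_table(rows), p))

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "truth_config_hash": truth_cfg.config_hash(),
        "truth_hash": truth.content_hash(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
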