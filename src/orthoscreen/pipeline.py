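"""End-to-end orthology screen: configuration, orchestration, reports.

A run either consumes real inputs (per-species protein FASTA, GO TSV,
stage TSV, optionally precomputed hits) or simulates them with the
built-in generator, then executes: redundancy screen -> all-vs-all
similarity -> orthology graph -> Markov clustering -> membership
partition -> absence-verification panel -> GO enrichment of the
dorylaim-specific cluster class -> phylotypic-stage refinement.  Every
output is deterministic given the configuration, and the manifest
records the seed and a content hash of every input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as osio
from .absence import VerificationParams, shared_loss, verify_panel
from .align import SimilarityParams, all_vs_all, redundancy_filter
from .enrichment import EnrichmentParams, enrich_terms
from .graph import build_graph
from .mcl import ClusteringParams, mcl
from .partition import member_proteins, partition_counts, select_clusters
from .simulate import (ConfigurationError, SimulationParams, simulate_study)
from .stages import StageParams, refine_phylotypic
from .tree import SPECIES

logger = logging.getLogger("orthoscreen")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-serializable."""

    output_dir: str = "orthoscreen_out"
    rng_seed: int = 42
    simulate: bool = True
    # input paths (run mode)
    fasta_paths: dict[str, str] = field(default_factory=dict)
    go_path: str | None = None
    stage_path: str | None = None
    hits_path: str | None = None  # precomputed outfmt-6-like TSV
    verify_queries: list[str] = field(default_factory=list)
    verify_targets: list[str] = field(default_factory=lambda: ["rc", "ts"])
    redundancy_threshold: float = 0.99
    run_stages: bool = True
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    verification: VerificationParams = field(default_factory=VerificationParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    stage_params: StageParams = field(default_factory=StageParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self):
        # keep the single seed authoritative for the generator
        self.simulation.rng_seed = self.rng_seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, typ in (("similarity", SimilarityParams),
                         ("clustering", ClusteringParams),
                         ("verification", VerificationParams),
                         ("enrichment", EnrichmentParams),
                         ("stage_params", StageParams),
                         ("simulation", SimulationParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for tup_field in ("seq_length_range", "phylotypic_range"):
                    if tup_field in sub and isinstance(sub[tup_field], list):
                        sub[tup_field] = tuple(sub[tup_field])
                kwargs[key] = typ(**sub)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Hash of the scientific configuration (not the output location)."""
        payload = self.to_dict()
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()

    def validate(self) -> None:
        if not self.simulate:
            missing = [sp for sp in SPECIES if sp not in self.fasta_paths]
            if missing:
                raise ConfigurationError(
                    f"run mode needs a FASTA path per species; missing {missing}")
            for label, p in [*self.fasta_paths.items(),
                             ("go", self.go_path),
                             ("stage", self.stage_path)]:
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"input path for {label!r} "
                                             f"does not exist: {p}")
            if self.run_stages and self.stage_path is None:
                raise ConfigurationError(
                    "stage analysis enabled but no stage TSV configured")


@dataclass
class RunReport:
    partition: dict
    absence_panel: list[dict]
    shared_loss: list[dict]
    enrichment: list[dict]
    phylotypic: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "partition": self.partition,
            "absence_panel": self.absence_panel,
            "shared_loss": self.shared_loss,
            "enrichment": self.enrichment,
            "phylotypic": self.phylotypic,
            "provenance": self.provenance,
        }


def _default_sim_queries(study) -> list[str]:
    """Default verification panel for simulated runs.

    C. elegans members of families truly absent from both dorylaims
    (candidate rhabditid-restricted genes) plus members of the
    extreme-divergence families (the hard cases for the decision tree).
    """
    queries: list[str] = []
    for fam in study.truth:
        if not fam.members.get("ce"):
            continue
        present = fam.present_species
        if ("rc" not in present and "ts" not in present) or fam.divergent:
            queries.extend(fam.members["ce"])
    return sorted(queries)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True):
    """Execute the full screen; returns ``(report, artifacts)``.

    ``artifacts`` carries the in-memory objects (study, hits, graph,
    clusters, panel, ...) for programmatic use.
    """
    config.validate()
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    input_hashes: dict[str, str] = {}
    study = None
    if config.simulate:
        logger.info("simulating study (seed %d)", config.rng_seed)
        study = simulate_study(config.simulation)
        proteomes = study.proteomes
        annotations = study.annotations
        stage_table = study.stage_table
        if write_outputs:
            for sp in SPECIES:
                p = outdir / f"{sp}.fasta"
                osio.write_fasta(proteomes[sp], p)
                input_hashes[p.name] = osio.sha256_of(p)
            osio.write_truth_tsv(study.truth, outdir / "truth.tsv")
            osio.write_go_tsv(annotations, outdir / "go.tsv")
            osio.write_stage_tsv(stage_table, outdir / "stages.tsv")
            for name in ("truth.tsv", "go.tsv", "stages.tsv"):
                input_hashes[name] = osio.sha256_of(outdir / name)
    else:
        proteomes = {sp: osio.read_fasta(p)
                     for sp, p in sorted(config.fasta_paths.items())}
        for sp, p in sorted(config.fasta_paths.items()):
            input_hashes[Path(p).name] = osio.sha256_of(p)
        annotations = osio.read_go_tsv(config.go_path) if config.go_path else None
        if config.go_path:
            input_hashes[Path(config.go_path).name] = osio.sha256_of(config.go_path)
        stage_table = (osio.read_stage_tsv(config.stage_path)
                       if config.stage_path else None)
        if config.stage_path:
            input_hashes[Path(config.stage_path).name] = \
                osio.sha256_of(config.stage_path)

    # redundancy screen
    filtered: dict[str, dict[str, str]] = {}
    removal_rows: list[dict] = []
    for sp in SPECIES:
        filtered[sp], log = redundancy_filter(
            proteomes[sp], config.redundancy_threshold, config.similarity)
        removal_rows.extend(
            {"species": sp, "removed": rm, "retained": kept,
             "identity": ident} for rm, kept, ident in log)

    # similarity
    if config.hits_path:
        logger.info("importing precomputed hits from %s", config.hits_path)
        species_of = {pid: sp for sp, prot in filtered.items() for pid in prot}
        hits = osio.read_hits_tsv(config.hits_path, species_of)
        input_hashes[Path(config.hits_path).name] = osio.sha256_of(config.hits_path)
    else:
        logger.info("computing all-vs-all similarity")
        hits = all_vs_all(filtered, config.similarity)

    # graph + clustering
    graph = build_graph(hits, config.similarity)
    clusters = mcl(graph, config.clustering)
    species_of = hits.species_of

    # membership partition
    part = partition_counts(clusters, species_of)
    partition_block = {
        "pattern_counts": {r["pattern"]: r["count"] for r in part.to_rows()},
        "n_clusters": part.n_clusters,
        "n_singletons": part.n_singletons,
        "conserved_nematode_core": part.conserved_nematode_core,
        "conserved_ecdysozoan_core": part.conserved_ecdysozoan_core,
    }

    # absence panel
    queries = list(config.verify_queries)
    if not queries and study is not None:
        queries = _default_sim_queries(study)
    panel = verify_panel(queries, config.verify_targets, clusters, hits,
                         config.verification)
    panel_rows = panel.to_rows()
    shared_rows: list[dict] = []
    if {"rc", "ts"} <= set(config.verify_targets):
        calls_rc = {q: panel.call(q, "rc") for q in panel.queries}
        calls_ts = {q: panel.call(q, "ts") for q in panel.queries}
        shared_rows = [
            {"protein": c.query_id, "shared_loss": int(c.shared_loss),
             "caveat": int(c.caveat)}
            for c in shared_loss(calls_rc, calls_ts).values()
        ]

    # enrichment of the dorylaim-specific class (rc+ts, no ce)
    enrichment_rows: list[dict] = []
    if annotations is not None:
        selection = select_clusters(clusters, species_of,
                                    require={"rc", "ts"}, forbid={"ce"})
        study_proteins = sorted(
            set(member_proteins(selection, "rc", species_of))
            | set(member_proteins(selection, "ts", species_of)))
        reference = sorted(pid for pid, sp in species_of.items()
                           if sp in ("rc", "ts"))
        if study_proteins:
            results = enrich_terms(study_proteins, reference, annotations,
                                   config.enrichment)
            enrichment_rows = [
                {"term": r.term_id, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                 "p": r.p_value, "significant": int(r.significant)}
                for r in results
            ]

    # phylotypic-stage analysis
    phylo_block = None
    if config.run_stages and stage_table is not None:
        report = refine_phylotypic(stage_table, clusters, species_of, hits,
                                   config.verification, config.stage_params)
        phylo_block = report.to_dict()

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.rng_seed,
        "package_version": __version__,
        "input_hashes": dict(sorted(input_hashes.items())),
    }
    report = RunReport(
        partition=partition_block, absence_panel=panel_rows,
        shared_loss=shared_rows, enrichment=enrichment_rows,
        phylotypic=phylo_block, provenance=provenance,
    )

    if write_outputs:
        osio.write_hits_tsv(hits, outdir / "hits.tsv")
        osio.write_groups(clusters, outdir / "groups.txt")
        edge_rows = [
            {"node1": e.u, "node2": e.v, "class": e.edge_class,
             "raw_weight": e.raw_weight,
             "normalized_weight": e.normalized_weight}
            for (_u, _v), e in sorted(graph.edges.items())
        ]
        osio.write_tsv_rows(edge_rows,
                            ["node1", "node2", "class", "raw_weight",
                             "normalized_weight"], outdir / "graph.tsv")
        osio.write_tsv_rows(part.to_rows(), ["pattern", "count"],
                            outdir / "partition.tsv")
        if removal_rows:
            osio.write_tsv_rows(removal_rows,
                                ["species", "removed", "retained", "identity"],
                                outdir / "redundancy_removed.tsv")
        if panel_rows:
            cols = ["protein"]
            for t in panel.target_species:
                cols += [t, f"{t}_status"]
            osio.write_tsv_rows(panel_rows, cols, outdir / "absence_panel.tsv")
            osio.write_json([panel.call(q, t).evidence()
                             for q in panel.queries
                             for t in panel.target_species],
                            outdir / "absence_evidence.json")
        if shared_rows:
            osio.write_tsv_rows(shared_rows,
                                ["protein", "shared_loss", "caveat"],
                                outdir / "shared_loss.tsv")
        if enrichment_rows:
            osio.write_tsv_rows(enrichment_rows,
                                ["term", "k", "n", "K", "N", "p", "significant"],
                                outdir / "enrichment.tsv")
        if phylo_block is not None:
            osio.write_json(phylo_block, outdir / "phylotypic.json")
            prop_rows = [
                {"stage": s,
                 "restricted_proportion":
                     "" if v is None else v}
                for s, v in sorted(
                    (int(k), v) for k, v in
                    phylo_block["per_stage_restricted_proportion"].items())
            ]
            osio.write_tsv_rows(prop_rows, ["stage", "restricted_proportion"],
                                outdir / "stage_proportions.tsv")
        osio.write_json(report.to_dict(), outdir / "report.json")
        osio.write_json(provenance, outdir / "manifest.json")

    artifacts = {
        "study": study, "proteomes": filtered, "hits": hits, "graph": graph,
        "clusters": clusters, "partition": part, "panel": panel,
        "annotations": annotations, "stage_table": stage_table,
    }
    return report, artifacts
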