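"""End-to-end orchestration: reads (real or simulated) to profiles.

``run_pipeline`` wires the stages together — input, quality filtering,
curation (UMI consensus or cluster dedup), annotation, clonotyping, GSSP
and GSNP construction, optional signature searches — and records every
stage's parameters and input/output counts in a machine-readable manifest.
Reruns with an identical config and inputs are byte-identical: every
stochastic step (only the simulator) consumes the single configured seed,
and no timestamps enter any artifact.

Raw reads are deduplicated before per-sequence annotation: annotation is a
deterministic function of the sequence, so annotating the curated unique
set gives the same annotations as annotating every raw read at a fraction
of the alignment cost.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from . import annotate as ann
from . import clonotype, curate, glyco, io, numbering, prevalence, sim
from .model import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    chain: str = "heavy"
    germline_path: Optional[str] = None  # None -> toy germline from seed
    input_fastq: Optional[str] = None  # None -> simulate
    simulate: dict[str, Any] = field(default_factory=dict)
    curation_mode: str = "cluster"  # umi | cluster
    qc: dict[str, Any] = field(default_factory=dict)
    curation: dict[str, Any] = field(default_factory=dict)
    clone_identity: float = clonotype.CLONE_CDR3_IDENTITY
    gssp_min_clones: int = clonotype.MIN_GSSP_CLONES
    gsnp_min_shm_pct: float = 1.0
    searches: list[dict[str, Any]] = field(default_factory=list)
    repertoire_id: str = "rep1"
    donor_id: str = "donor1"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.curation_mode not in ("umi", "cluster"):
            raise ConfigurationError(f"bad curation_mode {cfg.curation_mode!r}")
        if cfg.input_fastq and not os.path.exists(cfg.input_fastq):
            raise ConfigurationError(f"input_fastq {cfg.input_fastq!r} not found")
        if cfg.germline_path and not os.path.exists(cfg.germline_path):
            raise ConfigurationError(f"germline_path {cfg.germline_path!r} not found")
        return cfg


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str) -> dict[str, Any]:
    """Run all stages; artifacts and manifest land in ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest: dict[str, Any] = {"stages": [], "seed": config.seed}

    # --- germline reference -------------------------------------------------
    if config.germline_path:
        germline = io.load_germline_fasta(config.germline_path)
        germline_src = config.germline_path
    else:
        germline = sim.make_toy_germline(config.seed)
        germline_src = os.path.join(outdir, "germline.fasta")
        io.write_germline_fasta(germline, germline_src)
    numbering.register_toy_tables(germline)
    manifest["germline"] = {
        # relative for generated references so identical runs in different
        # directories produce identical manifests
        "path": (config.germline_path if config.germline_path
                 else os.path.relpath(germline_src, outdir)),
        "n_segments": len(germline),
        "sha256": _sha256_file(germline_src),
    }

    # --- input reads --------------------------------------------------------
    truth = None
    if config.input_fastq:
        reads = list(io.read_fastq(config.input_fastq))
        manifest["stages"].append({"stage": "input", "source": config.input_fastq,
                                   "n_reads": len(reads)})
    else:
        sim_cfg = sim.SimulationConfig(
            seed=config.seed, germline=germline, chain=config.chain,
            repertoire_id=config.repertoire_id, donor_id=config.donor_id,
            **config.simulate,
        )
        reads, truth = sim.simulate_repertoire(sim_cfg)
        io.write_fastq(reads, os.path.join(outdir, "reads.fastq"))
        sim.write_truth_tsv(truth, os.path.join(outdir, "truth.tsv"))
        manifest["stages"].append({
            "stage": "simulate", "n_reads": len(reads),
            "n_cells": sim_cfg.n_cells,
            "n_true_unique": len(truth.unique_transcripts),
        })

    # --- quality filter -----------------------------------------------------
    thresholds = ann.QCThresholds(**config.qc)
    kept, rejected = ann.qc_filter(reads, thresholds)
    with open(os.path.join(outdir, "qc_drops.tsv"), "w") as fh:
        fh.write("read_id\treason\n")
        for rec, reason in rejected:
            fh.write(f"{rec.read_id}\t{reason}\n")
    manifest["stages"].append({
        "stage": "qc_filter", "params": dataclasses.asdict(thresholds),
        "n_in": len(reads), "n_kept": len(kept), "n_rejected": len(rejected),
    })

    # --- curation -----------------------------------------------------------
    params = curate.CurationParams(**config.curation)
    if config.curation_mode == "umi":
        unique, drops = curate.umi_consensus(kept, params)
    else:
        unique, drops = curate.cluster_dedup_no_umi(kept, params)
    with open(os.path.join(outdir, "curation_drops.tsv"), "w") as fh:
        fh.write("read_id\treason\n")
        for rid, reason in drops:
            fh.write(f"{rid}\t{reason}\n")
    repertoire_ok = curate.repertoire_filter(unique, params)
    manifest["stages"].append({
        "stage": "curate", "mode": config.curation_mode,
        "params": dataclasses.asdict(params),
        "n_in": len(kept), "n_unique": len(unique), "n_dropped": len(drops),
        "repertoire_kept": repertoire_ok,
    })
    if truth is not None:
        manifest["stages"][-1]["n_true_unique"] = len(truth.unique_transcripts)
    if not repertoire_ok:
        log.warning("repertoire %s dropped: %d unique transcripts < %d",
                    config.repertoire_id, len(unique),
                    params.min_repertoire_unique)

    # --- annotation of the unique set --------------------------------------
    transcripts = []
    for rec in unique:
        t = ann.annotate_record(
            rec, germline, chain=config.chain, thresholds=thresholds,
            schemes=("IMGT", "Kabat", "Chothia"),
            repertoire_id=config.repertoire_id, donor_id=config.donor_id,
        )
        if t is not None:
            transcripts.append(t)
    productive = [t for t in transcripts if t.productive]
    io.write_annotated_fasta(transcripts, os.path.join(outdir, "unique.fasta"))
    manifest["stages"].append({
        "stage": "annotate", "n_unique": len(unique),
        "n_assigned": len(transcripts), "n_productive": len(productive),
    })

    # --- clonotyping and profiles ------------------------------------------
    clones, excluded = clonotype.cluster_clones(productive, config.clone_identity)
    reps = [c.representative for c in clones]
    gssp_db: dict[str, clonotype.GSSP] = {}
    for gene in sorted({c.v_gene for c in clones}):
        gssp = clonotype.build_gssp(reps, gene, min_clones=config.gssp_min_clones)
        if gssp is not None:
            gssp_db[gene] = gssp
            clonotype.write_gssp_tsv(
                gssp, os.path.join(outdir, f"gssp_{gene.replace('*', '_')}.tsv"))
    gsnps = glyco.build_gsnp(productive, germline,
                             min_shm_pct=config.gsnp_min_shm_pct)
    glyco.write_gsnp_tsv(gsnps, os.path.join(outdir, "gsnp.tsv"))
    manifest["stages"].append({
        "stage": "profiles", "n_clones": len(clones),
        "n_excluded_transcripts": len(excluded),
        "gssp_genes": sorted(gssp_db), "gsnp_genes": sorted(gsnps),
    })

    # --- signature searches -------------------------------------------------
    search_rows = []
    for spec_dict in config.searches:
        query = prevalence.SignatureQuery(**{k: v for k, v in spec_dict.items()
                                             if k != "denominator"})
        row = prevalence.signature_frequency(
            query, productive, repertoire_id=config.repertoire_id,
            denominator=spec_dict.get(
                "denominator",
                "gene" if query.gene_constraint else "all"),
        )
        search_rows.append(dataclasses.asdict(row) | {"query": spec_dict})
    if search_rows:
        with open(os.path.join(outdir, "search.json"), "w") as fh:
            json.dump(search_rows, fh, indent=1)
            fh.write("\n")
        manifest["stages"].append({"stage": "search", "n_queries": len(search_rows)})

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
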