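"""End-to-end orchestration: simulate -> ends -> regseq -> de -> enrich ->
cluster, with a manifest recording parameters and output checksums."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_fasta, read_gff3_genes, read_bedgraph
from .simulate import SimConfig, make_genome_annotation, simulate_termseq, simulate_omics, write_dataset
from .ends import cpm_normalize, call_consensus_ends, classify_ends, utr3_lengths
from .motifs import (
    pwm_from_consensus, classify_promoter, classify_polyU,
    nucleotide_enrichment, intergenic_intervals, sequence_composition,
    PROMOTER_WINDOW, STRENGTH_WINDOW, TERMINATOR_WINDOW,
)
from .simulate import PROMOTER_CONSENSUS
from .de import de_table
from .enrich import arcog_enrichment
from .cluster import zscore_rows, cluster_genes, cluster_profiles

log = logging.getLogger("thermomics")

STAGES = ["simulate", "ends", "regseq", "de", "enrich", "cluster"]


@dataclass
class PipelineConfig:
    outdir: str = "thermomics_run"
    seed: int = 7
    simulate: dict = field(default_factory=dict)   # SimConfig overrides
    ends: dict = field(default_factory=dict)       # min_replicates, min_cpm, merge_window, window
    regseq: dict = field(default_factory=dict)     # alpha, u_window, min_u, n_background
    de: dict = field(default_factory=dict)         # contrasts
    enrich: dict = field(default_factory=dict)     # alpha
    cluster: dict = field(default_factory=dict)    # k_min, k_max, k, max_missing
    inputs: dict = field(default_factory=dict)     # paths when not simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {key!r}: no such file {p}")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    current = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulate)
        sim_dir = outdir / "simulate"
        paths = write_dataset(sim_cfg, sim_dir)
        genome, genes, truth = make_genome_annotation(sim_cfg)
        tracks = simulate_termseq(sim_cfg, truth, genome)
        rna, protein = simulate_omics(sim_cfg, truth)
        manifest["stages"]["simulate"] = {
            "params": {k: v for k, v in asdict(sim_cfg).items() if k != "templates"},
            "outputs": {k: str(p) for k, p in paths.items()},
            "checksums": {k: _checksum(p) for k, p in paths.items()},
        }
        log.info("simulate: %d genes, %d replicates", sim_cfg.n_genes, sim_cfg.n_replicates)

        # --- ends ---------------------------------------------------------
        current = "ends"
        ends_par = {"min_replicates": 3, "min_cpm": 5.0, "merge_window": 3,
                    "downstream_window": 300, **cfg.ends}
        calls = []
        for strand in "+-":
            cpm_tracks = [cpm_normalize(rep[strand]) for rep in tracks]
            consensus = call_consensus_ends(
                cpm_tracks,
                min_replicates=ends_par["min_replicates"],
                min_cpm=ends_par["min_cpm"],
                merge_window=ends_par["merge_window"],
            )
            calls.extend(c for _pk, c in consensus)
        classified = classify_ends(calls, genes, ends_par["downstream_window"])
        ends_frame = pd.DataFrame(
            [{"contig": c.contig, "strand": c.strand, "position": c.position,
              "height_cpm": c.height, "n_supporting": c.n_supporting,
              "gene_id": c.gene_id, "end_class": c.end_class} for c in classified]
        )
        utr3 = utr3_lengths(classified, genes)
        ends_dir = outdir / "ends"
        ends_dir.mkdir(exist_ok=True)
        p_calls = ends_dir / "end_calls.tsv"
        ends_frame.to_csv(p_calls, sep="\t", index=False)
        p_utr3 = ends_dir / "utr3_lengths.tsv"
        utr3.to_frame().to_csv(p_utr3, sep="\t")
        manifest["stages"]["ends"] = {
            "params": ends_par,
            "outputs": {"end_calls": str(p_calls), "utr3_lengths": str(p_utr3)},
            "checksums": {"end_calls": _checksum(p_calls), "utr3_lengths": _checksum(p_utr3)},
        }
        log.info("ends: %d consensus calls", len(ends_frame))

        # --- regseq -------------------------------------------------------
        current = "regseq"
        reg_par = {"alpha": 1e-3, "u_window": 8, "min_u": 6,
                   "n_background": 100_000, **cfg.regseq}
        pwm = pwm_from_consensus(PROMOTER_CONSENSUS)
        prom = classify_promoter(genes, genome, pwm, alpha=reg_par["alpha"])
        primaries = [c for c in classified if c.end_class == "primary"]
        polyu = classify_polyU(primaries, genome,
                               u_window=reg_par["u_window"], min_u=reg_par["min_u"])
        inter = intergenic_intervals(genome, genes)
        seqs = []
        from .io import extract_window
        for c in primaries:
            s = extract_window(genome, c.contig, c.position,
                               TERMINATOR_WINDOW[0], TERMINATOR_WINDOW[1], strand=c.strand)
            if s is not None:
                seqs.append(s)
        enr = nucleotide_enrichment(seqs, genome, inter,
                                    n_background=reg_par["n_background"], seed=cfg.seed)
        reg_dir = outdir / "regseq"
        reg_dir.mkdir(exist_ok=True)
        p_prom = reg_dir / "promoters.tsv"
        prom.to_csv(p_prom, sep="\t")
        p_polyu = reg_dir / "polyU.tsv"
        polyu.to_csv(p_polyu, sep="\t", index=False)
        p_enr = reg_dir / "nt_enrichment.tsv"
        enr.to_csv(p_enr, sep="\t", index=False)
        manifest["stages"]["regseq"] = {
            "params": reg_par,
            "outputs": {"promoters": str(p_prom), "polyU": str(p_polyu),
                        "nt_enrichment": str(p_enr)},
            "checksums": {"promoters": _checksum(p_prom), "polyU": _checksum(p_polyu),
                          "nt_enrichment": _checksum(p_enr)},
        }

        # --- de -----------------------------------------------------------
        current = "de"
        contrasts = cfg.de.get("contrasts")
        rna_de = de_table(rna, contrasts)
        prot_de = de_table(protein, contrasts)
        de_dir = outdir / "de"
        de_dir.mkdir(exist_ok=True)
        p_rna = de_dir / "rna_de.tsv"
        rna_de.to_csv(p_rna, sep="\t", index=False)
        p_prot = de_dir / "protein_de.tsv"
        prot_de.to_csv(p_prot, sep="\t", index=False)
        manifest["stages"]["de"] = {
            "params": {"contrasts": contrasts or "all vs Ctrl"},
            "outputs": {"rna": str(p_rna), "protein": str(p_prot)},
            "checksums": {"rna": _checksum(p_rna), "protein": _checksum(p_prot)},
        }

        # --- enrich -------------------------------------------------------
        current = "enrich"
        alpha = cfg.enrich.get("alpha", 0.05)
        cats = truth.genes.set_index("gene_id")["arcog"]
        lengths = rna.lengths
        enr_frames = []
        for contrast in rna_de["contrast"].unique():
            sub = rna_de[rna_de["contrast"] == contrast].set_index("gene_id")
            for direction in ("up", "down"):
                try:
                    res = arcog_enrichment(sub["group"], cats.reindex(sub.index),
                                           lengths.reindex(sub.index), direction, alpha)
                except ValueError:
                    continue
                res.insert(0, "contrast", contrast)
                enr_frames.append(res)
        enr_all = pd.concat(enr_frames, ignore_index=True) if enr_frames else pd.DataFrame()
        enr_dir = outdir / "enrich"
        enr_dir.mkdir(exist_ok=True)
        p_enrich = enr_dir / "arcog_enrichment.tsv"
        enr_all.to_csv(p_enrich, sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "params": {"alpha": alpha},
            "outputs": {"enrichment": str(p_enrich)},
            "checksums": {"enrichment": _checksum(p_enrich)},
        }

        # --- cluster ------------------------------------------------------
        current = "cluster"
        clu_par = {"k_min": 2, "k_max": 8, "k": None, "max_missing": 0.5, **cfg.cluster}
        fc = _foldchange_matrix(rna_de, prot_de)
        z, _dropped = zscore_rows(fc)
        n_genes_z = len(z)
        k_max = min(clu_par["k_max"], max(n_genes_z - 2, 2))
        assignment = cluster_genes(
            z, range(clu_par["k_min"], k_max + 1),
            max_missing=clu_par["max_missing"], k_override=clu_par["k"],
        )
        profiles = cluster_profiles(assignment, z)
        clu_dir = outdir / "cluster"
        clu_dir.mkdir(exist_ok=True)
        p_assign = clu_dir / "assignments.tsv"
        assignment.labels.to_frame().to_csv(p_assign, sep="\t")
        p_curve = clu_dir / "elbow_curve.tsv"
        assignment.wss_curve.rename("wss").to_frame().to_csv(p_curve, sep="\t")
        p_prof = clu_dir / "profiles.tsv"
        profiles.to_csv(p_prof, sep="\t", index=False)
        manifest["stages"]["cluster"] = {
            "params": {**clu_par, "k_selected": assignment.k, "n_pcs": assignment.n_pcs},
            "outputs": {"assignments": str(p_assign), "elbow": str(p_curve),
                        "profiles": str(p_prof)},
            "checksums": {"assignments": _checksum(p_assign), "elbow": _checksum(p_curve),
                          "profiles": _checksum(p_prof)},
        }
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _foldchange_matrix(rna_de: pd.DataFrame, prot_de: pd.DataFrame) -> pd.DataFrame:
    """Genes x (condition, layer) log2FC frame from stacked DE tables."""
    rna_piv = rna_de.pivot(index="gene_id", columns="contrast", values="log2FC")
    prot_piv = prot_de.pivot(index="gene_id", columns="contrast", values="log2FC")
    rna_piv.columns = pd.MultiIndex.from_product(
        [rna_piv.columns, ["rna"]], names=["condition", "layer"])
    prot_piv.columns = pd.MultiIndex.from_product(
        [prot_piv.columns, ["protein"]], names=["condition", "layer"])
    return rna_piv.join(prot_piv, how="left")
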