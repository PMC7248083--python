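"""End-to-end pipeline orchestration.

Composes the stages over whatever inputs are present:

  genomes:  quality filter (completeness > 50%, contamination < 5%)
            -> sketch -> pairwise Mash distances -> average-linkage SGBs
            -> source classification -> food/human overlap summary
  profiles: LAB filter -> prevalence gate -> stratified prevalence
  genes:    completeness filter -> prevalence-band filter -> Fisher enrichment

Every run writes its artifacts plus a JSON manifest recording the config,
seed, and SHA-256 checksums of the inputs, so a run can be replayed.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import io as lio
from .catalog import Genome, as_catalogue, quality_filter
from .clustering import average_linkage_cluster, classify_sgbs, classical_mds, overlap_summary
from .config import PipelineConfig
from .enrichment import filter_genes_by_band, filter_genomes_by_completeness, gene_enrichment
from .prevalence import filter_lab_species, prevalence_by_stratum, prevalence_gate
from .sketching import pairwise_distances
from .synthetic import GeneMatrix

logger = logging.getLogger("labgut")

__all__ = ["run_pipeline"]


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _checksum_genomes(genomes: list[Genome]) -> str:
    h = hashlib.sha256()
    for g in sorted(genomes, key=lambda g: g.id):
        h.update(g.id.encode())
        for seq in (g.sequences or []):
            h.update(seq.encode())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir,
                 genomes: list[Genome] | None = None,
                 profile_table: pd.DataFrame | None = None,
                 metadata: pd.DataFrame | None = None,
                 gene_matrix: GeneMatrix | None = None,
                 prevalence_groupings: tuple[str, ...] = ("age_category",),
                 ) -> dict:
    """Run every stage whose input is present and write all artifacts.

    Returns the report bundle: a dict with the in-memory results per stage
    plus the path of each written artifact.
    """
    if genomes is None and profile_table is None and gene_matrix is None:
        raise ValueError("at least one of genomes / profile_table / gene_matrix "
                         "must be provided")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"artifacts": {}}
    manifest: dict = {"config": config.to_dict(), "inputs": {}, "stages": []}

    def _write(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        report["artifacts"][name] = str(path)

    if genomes is not None:
        manifest["inputs"]["genomes_sha256"] = _checksum_genomes(genomes)
        kept = quality_filter(genomes, config.completeness_min_cluster,
                              config.contamination_max)
        logger.info("quality filter kept %d of %d genomes", len(kept), len(genomes))
        if len(kept) < 2:
            raise ValueError("fewer than 2 genomes survive the quality filter")
        catalogue = as_catalogue(kept)
        dmat = pairwise_distances({g.id: g.sequences for g in kept},
                                  k=config.k, s=config.sketch_size,
                                  hash_seed=config.hash_seed)
        sgbs, tree = average_linkage_cluster(dmat, config.sgb_threshold)
        classify_sgbs(sgbs, catalogue,
                      ksgb_requires_reference=config.ksgb_requires_reference)
        summary = overlap_summary(sgbs, catalogue)
        mds = classical_mds(dmat, dims=2)
        report.update({"distances": dmat, "sgbs": sgbs, "merge_tree": tree,
                       "overlap_summary": summary, "mds": mds,
                       "n_genomes_kept": len(kept)})
        manifest["stages"].append("genomes")
        _write("distances.tsv", lio.write_distance_matrix, dmat)
        _write("sgb_partition.tsv", lio.write_partition, sgbs)
        _write("merge_tree.nwk", lio.write_newick, tree.to_newick())
        _write("overlap_summary.tsv",
               lambda df, p: df.to_csv(p, sep="\t"), summary)
        _write("mds_coordinates.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index_label="genome_id"), mds)
        _write("genome_catalogue.tsv", lio.write_genome_catalogue, kept)

    if profile_table is not None:
        if metadata is None:
            raise ValueError("profile analysis needs sample metadata")
        manifest["inputs"]["profile_sha256"] = _sha256_bytes(
            profile_table.to_csv().encode())
        lab = filter_lab_species(profile_table)
        gated = prevalence_gate(lab, metadata,
                                min_prevalence=config.prevalence_gate,
                                detection_threshold=config.detection_threshold)
        lab = lab.loc[gated]
        prev_frames = []
        for grouping in prevalence_groupings:
            pf = prevalence_by_stratum(lab, metadata, grouping,
                                       detection_threshold=config.detection_threshold)
            pf.insert(0, "grouping", grouping)
            prev_frames.append(pf)
        prev = pd.concat(prev_frames, ignore_index=True) if prev_frames else pd.DataFrame()
        report.update({"lab_species": gated, "prevalence": prev})
        manifest["stages"].append("profiles")
        _write("prevalence.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index=False, na_rep="NA"), prev)

    if gene_matrix is not None:
        manifest["inputs"]["gene_matrix_sha256"] = _sha256_bytes(
            gene_matrix.presence.to_csv().encode())
        gm = gene_matrix
        if genomes is not None:
            catalogue = as_catalogue(genomes)
            if any(gid in catalogue for gid in gm.genome_ids):
                gm = filter_genomes_by_completeness(
                    gm, catalogue, config.completeness_min_enrichment)
            else:
                logger.info("gene matrix genomes not in catalogue; "
                            "completeness filter skipped")
        gm = filter_genes_by_band(gm, config.gene_band_lower, config.gene_band_upper)
        enr = gene_enrichment(gm)
        report["enrichment"] = enr
        manifest["stages"].append("genes")
        _write("enrichment.tsv",
               lambda df, p: df.to_csv(p, sep="\t", index=False, na_rep="NA"), enr)

    lio.write_json(manifest, outdir / "manifest.json")
    report["artifacts"]["manifest.json"] = str(outdir / "manifest.json")
    report["manifest"] = manifest
    return report
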