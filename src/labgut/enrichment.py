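"""Pangenome gene-enrichment testing between genome source groups.

Operates on a genome x gene boolean presence/absence matrix (Roary-style
output is consumed, never recomputed).  Before testing, genomes with
completeness <= 80% are dropped to avoid biases from highly incomplete
genomes, and genes outside the [5%, 95%) overall-prevalence band (i.e. core
or near-absent genes, uninformative for a prevalence contrast) are removed.
Each retained gene is tested with the two-sided Fisher exact test on the
(present, absent) x (group A, group B) table, with BH FDR across genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .catalog import Genome
from .prevalence import bh_fdr, fisher_exact_2x2
from .synthetic import GeneMatrix

__all__ = [
    "filter_genomes_by_completeness",
    "filter_genes_by_band",
    "gene_enrichment",
]


def filter_genomes_by_completeness(matrix: GeneMatrix,
                                   catalogue: dict[str, Genome],
                                   min_completeness: float = 80.0) -> GeneMatrix:
    """Retain genomes with completeness strictly > ``min_completeness``.

    Genomes missing from the catalogue or lacking a completeness value are
    excluded with a warning.
    """
    keep = []
    for gid in matrix.genome_ids:
        g = catalogue.get(gid)
        if g is None or g.completeness is None:
            warnings.warn(f"genome {gid!r} has no completeness value; excluded")
            continue
        if g.completeness > min_completeness:
            keep.append(gid)
    return GeneMatrix(presence=matrix.presence.loc[keep],
                      groups=matrix.groups.loc[keep])


def filter_genes_by_band(matrix: GeneMatrix, lower: float = 0.05,
                         upper: float = 0.95) -> GeneMatrix:
    """Retain genes with overall prevalence in [lower, upper).

    The lower bound is inclusive ("present in at least 5%") and the upper
    bound exclusive ("< 95% of the genomes").
    """
    if matrix.presence.empty:
        raise ValueError("gene matrix is empty")
    if not (0.0 <= lower <= upper <= 1.0):
        raise ValueError(f"invalid prevalence band [{lower}, {upper})")
    prev = matrix.presence.mean(axis=0)
    keep = prev.index[(prev >= lower) & (prev < upper)]
    return GeneMatrix(presence=matrix.presence[keep], groups=matrix.groups)


def gene_enrichment(matrix: GeneMatrix, group_a: str = "food",
                    group_b: str = "human") -> pd.DataFrame:
    """Differential gene-prevalence test between two source groups.

    Returns one row per gene: per-group prevalences, odds ratio, two-sided
    Fisher p, BH q (across all tested genes), and ``enriched_in`` (the group
    with the higher prevalence; NA on exact ties).
    """
    in_a = matrix.groups == group_a
    in_b = matrix.groups == group_b
    na, nb = int(in_a.sum()), int(in_b.sum())
    if na == 0 or nb == 0:
        raise ValueError(f"empty group in contrast {group_a!r} vs {group_b!r}")
    pa_mat = matrix.presence.loc[in_a.index[in_a]]
    pb_mat = matrix.presence.loc[in_b.index[in_b]]
    rows = []
    for gene in matrix.gene_ids:
        a = int(pa_mat[gene].sum())
        c = int(pb_mat[gene].sum())
        odds, p = fisher_exact_2x2(a, na - a, c, nb - c)
        prev_a, prev_b = a / na, c / nb
        if prev_a > prev_b:
            direction = group_a
        elif prev_b > prev_a:
            direction = group_b
        else:
            direction = "NA"
        rows.append({"gene_id": gene,
                     f"prevalence_{group_a}": prev_a,
                     f"prevalence_{group_b}": prev_b,
                     "odds_ratio": odds, "p": p, "enriched_in": direction})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"]) if len(out) else np.array([])
    return out
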