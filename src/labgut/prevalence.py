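"""Stratified prevalence and abundance profiling of taxonomic tables.

Works on MetaPhlAn-style species x sample relative-abundance tables (percent
units, lineage strings with k__|p__|...|s__ prefixes as row index) plus a
sample-metadata table.  A species is "present" in a sample when its relative
abundance is strictly greater than the detection threshold (default 0.01%);
prevalence is the fraction of present samples within a stratum, and average
abundance is computed on positive samples only.

Also houses the shared significance machinery: a two-sided Fisher exact test
(minimum-likelihood rule) and Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LAB_GENERA",
    "LAB_EXTRA_SPECIES",
    "parse_genus",
    "parse_species",
    "apply_species_aliases",
    "detect",
    "filter_lab_species",
    "prevalence_gate",
    "prevalence_by_stratum",
    "fisher_exact_2x2",
    "bh_fdr",
    "compare_strata",
]

#: Genera defining the lactic acid bacteria (LAB) group.
LAB_GENERA = frozenset({"Lactobacillus", "Lactococcus", "Leuconostoc", "Weissella"})
#: Species outside those genera that are counted as LAB.
LAB_EXTRA_SPECIES = frozenset({"Streptococcus_thermophilus"})


def parse_species(lineage: str) -> str | None:
    """Species name from a lineage string (the s__ component), else None."""
    for part in str(lineage).split("|")[::-1]:
        if part.startswith("s__"):
            return part[3:]
    return None


def parse_genus(lineage: str) -> str | None:
    """Genus from the g__ component, falling back to the first token of the
    species name; None when neither parses."""
    genus = None
    for part in str(lineage).split("|"):
        if part.startswith("g__") and len(part) > 3:
            genus = part[3:]
    if genus:
        return genus
    sp = parse_species(lineage)
    if sp:
        return sp.split("_")[0]
    return None


def apply_species_aliases(table: pd.DataFrame,
                          alias_map: Mapping[str, str]) -> pd.DataFrame:
    """Merge taxa according to an alias map (e.g. Lactobacillus_casei and
    Lactobacillus_paracasei -> Lactobacillus_casei_paracasei).

    Keys and values are species names; rows mapping to the same target are
    summed.  Applied before any prevalence computation.
    """
    if not alias_map:
        return table
    new_index = []
    for lineage in table.index:
        sp = parse_species(lineage)
        if sp in alias_map:
            lineage = str(lineage).replace(f"s__{sp}", f"s__{alias_map[sp]}")
        new_index.append(lineage)
    out = table.copy()
    out.index = pd.Index(new_index, name=table.index.name)
    return out.groupby(level=0, sort=False).sum()


def detect(table: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Boolean species x sample presence: abundance strictly > threshold (%)."""
    if threshold < 0:
        raise ValueError(f"detection threshold must be >= 0, got {threshold}")
    return table > threshold


def filter_lab_species(table: pd.DataFrame,
                       genera: Iterable[str] | None = None,
                       extra_species: Iterable[str] | None = None) -> pd.DataFrame:
    """Restrict a profile table to lactic acid bacteria.

    Retains species whose genus is in ``genera`` (default: Lactobacillus,
    Lactococcus, Leuconostoc, Weissella) or whose species name is in
    ``extra_species`` (default: Streptococcus_thermophilus).  Rows whose
    lineage cannot be parsed to a genus are skipped with a warning.
    """
    genera = frozenset(genera) if genera is not None else LAB_GENERA
    extra = frozenset(extra_species) if extra_species is not None else LAB_EXTRA_SPECIES
    keep = []
    for lineage in table.index:
        sp = parse_species(lineage)
        genus = parse_genus(lineage)
        if sp is None and genus is None:
            warnings.warn(f"unparseable lineage skipped: {lineage!r}")
            continue
        if (genus in genera) or (sp in extra):
            keep.append(lineage)
    return table.loc[keep]


def _stratum_samples(metadata: pd.DataFrame, field: str, value: str) -> list[str]:
    if field not in metadata.columns:
        raise KeyError(f"unknown metadata field {field!r}")
    col = metadata[field].astype(str)
    return list(metadata.index[(col == value) & (col != "NA")])


def prevalence_gate(table: pd.DataFrame, metadata: pd.DataFrame,
                    min_prevalence: float = 0.001,
                    body_site: str = "stool",
                    detection_threshold: float = 0.01) -> list[str]:
    """Species whose prevalence in one body site strictly exceeds the gate.

    Mirrors the study design of restricting analysis to species with
    prevalence > 0.1% in the human gut (stool samples).
    """
    samples = [s for s in _stratum_samples(metadata, "body_site", body_site)
               if s in table.columns]
    if not samples:
        raise ValueError(f"no samples in body site {body_site!r}")
    pres = detect(table[samples], detection_threshold)
    prev = pres.sum(axis=1) / len(samples)
    return [lin for lin, p in prev.items() if p > min_prevalence]


def prevalence_by_stratum(table: pd.DataFrame, metadata: pd.DataFrame,
                          grouping: str,
                          detection_threshold: float = 0.01) -> pd.DataFrame:
    """Per-(species, stratum) prevalence and mean abundance on positives.

    Samples whose ``grouping`` value is NA are excluded from that grouping's
    denominators.  Returns a tidy frame with columns species, stratum,
    n_total, n_positive, prevalence, mean_abundance_positive (NaN when no
    positive sample exists).
    """
    if grouping not in metadata.columns:
        raise KeyError(f"unknown metadata field {grouping!r}")
    shared = [s for s in table.columns if s in metadata.index]
    rows = []
    values = metadata.loc[shared, grouping].astype(str)
    for stratum in sorted(v for v in values.unique() if v != "NA"):
        samples = [s for s in shared if values[s] == stratum]
        sub = table[samples]
        pres = detect(sub, detection_threshold)
        n_total = len(samples)
        for lineage in table.index:
            mask = pres.loc[lineage]
            n_pos = int(mask.sum())
            mean_pos = float(sub.loc[lineage][mask].mean()) if n_pos else float("nan")
            rows.append({"species": lineage, "stratum": stratum,
                         "n_total": n_total, "n_positive": n_pos,
                         "prevalence": n_pos / n_total,
                         "mean_abundance_positive": mean_pos})
    return pd.DataFrame(rows)


_FISHER_RELTOL = 1.0 + 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 contingency table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities of all tables with the same
    margins whose probability is <= that of the observed table (with a 1e-7
    relative tolerance on the comparison).  The odds ratio is ad/bc, with
    inf when bc = 0 and ad > 0 and NaN for 0/0.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        p = 1.0
    else:
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, n, r1, c1)
        p_obs = pmf[a - lo]
        p = float(min(1.0, pmf[pmf <= p_obs * _FISHER_RELTOL].sum()))
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return odds, p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_strata(table: pd.DataFrame, metadata: pd.DataFrame, grouping: str,
                   group_a: str, group_b: str,
                   species: Iterable[str] | None = None,
                   detection_threshold: float = 0.01) -> pd.DataFrame:
    """Per-species prevalence contrast between two strata.

    Builds the 2x2 table of (positive, negative) x (group_a, group_b) at the
    detection rule, computes the two-sided Fisher p, and applies BH FDR
    across the species tested in this contrast.
    """
    samples_a = [s for s in _stratum_samples(metadata, grouping, group_a)
                 if s in table.columns]
    samples_b = [s for s in _stratum_samples(metadata, grouping, group_b)
                 if s in table.columns]
    if not samples_a or not samples_b:
        raise ValueError(
            f"empty stratum in contrast {group_a!r} vs {group_b!r} on {grouping!r}")
    rows_index = list(species) if species is not None else list(table.index)
    pres = detect(table, detection_threshold)
    rows = []
    for lineage in rows_index:
        pa = pres.loc[lineage, samples_a]
        pb = pres.loc[lineage, samples_b]
        a = int(pa.sum())
        b = len(samples_a) - a
        c = int(pb.sum())
        d = len(samples_b) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append({"species": lineage,
                     "n_positive_a": a, "n_negative_a": b,
                     "n_positive_b": c, "n_negative_b": d,
                     "prevalence_a": a / len(samples_a),
                     "prevalence_b": c / len(samples_b),
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out
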