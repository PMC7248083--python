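"""Synthetic genomes, abundance tables, and gene matrices with known truth.

Every downstream stage (sketching/distances, SGB clustering, prevalence
profiling, gene enrichment) is testable against ground truth planted here,
with no external data.

The genome simulator plants an ANI structure: each species draws a centroid
sequence, centroids of distinct species diverge from a shared ancestor at a
"between" per-site substitution rate (or are fully independent in
"unrelated" mode), and each strain is its centroid with i.i.d. substitutions
at a "within" rate.  With the defaults (within 0.01, between 0.2) pairwise
within-species divergence sits near 2% and between-species divergence well
above 10%, bracketing the 5% SGB threshold from both sides.

The alphabet is A/C/G/T only and substitutions draw uniformly from the three
alternative bases, so expected identity is exactly 1 - rate.  One global
seed fans out to per-component substreams via numpy SeedSequence spawning;
identical arguments and seed reproduce identical output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Genome

__all__ = [
    "SpeciesTruth",
    "ProfileTruth",
    "GeneTruth",
    "GeneMatrix",
    "random_sequence",
    "mutate_sequence",
    "generate_diverged_pair",
    "generate_species_genomes",
    "degrade_genome",
    "default_profile_truth",
    "generate_abundance_table",
    "generate_gene_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {0: "A", 1: "C", 2: "G", 3: "T"}


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return codes


@dataclass
class SpeciesTruth:
    """Planted truth for one simulated species."""

    species_id: str
    centroid_length: int
    within_divergence: float
    member_genome_ids: list[str]
    centroid: str = field(repr=False, default="")


@dataclass
class ProfileTruth:
    """Per (species, stratum) presence probability and lognormal
    abundance-on-presence parameters (natural-log location/scale of percent
    abundance)."""

    table: pd.DataFrame  # columns: species, stratum, presence_probability, log_mean, log_sigma

    def __post_init__(self) -> None:
        required = {"species", "stratum", "presence_probability", "log_mean", "log_sigma"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ProfileTruth table missing columns: {sorted(missing)}")
        p = self.table["presence_probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("presence probabilities must lie in [0, 1]")

    def lookup(self, species: str, stratum: str) -> tuple[float, float, float]:
        t = self.table
        row = t[(t["species"] == species) & (t["stratum"] == stratum)]
        if row.empty:
            raise KeyError(f"no truth entry for ({species!r}, {stratum!r})")
        r = row.iloc[0]
        return float(r["presence_probability"]), float(r["log_mean"]), float(r["log_sigma"])


@dataclass
class GeneTruth:
    """Planted differential genes and per-(gene, group) presence probabilities."""

    planted_differential_genes: set[str]
    presence_probability: pd.DataFrame  # index gene, columns group labels


@dataclass
class GeneMatrix:
    """Genome x gene boolean presence/absence matrix with group labels."""

    presence: pd.DataFrame  # index genome ids, columns gene ids, bool
    groups: pd.Series  # genome id -> group label in {food, human, other, NA}

    def __post_init__(self) -> None:
        if self.presence.index.has_duplicates:
            raise ValueError("duplicate genome ids in gene matrix")
        bad = set(self.groups.unique()) - {"food", "human", "other", "NA"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not self.presence.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.presence.index)
            if self.groups.isna().any():
                raise ValueError("every genome needs a group label")
        self.presence = self.presence.astype(bool)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.presence.columns)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _codes_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-site rate; each substituted
    site draws uniformly from the three alternative bases."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"substitution rate must be in [0, 1], got {rate}")
    codes = _str_to_codes(seq).copy()
    mask = rng.random(codes.size) < rate
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    codes[mask] = (codes[mask] + shifts) % 4
    return _codes_to_str(codes)


def generate_diverged_pair(length: int, rate: float, seed: int) -> tuple[str, str]:
    """A random sequence and a copy diverged from it at exactly the per-site
    substitution rate ``rate`` (in expectation).  Used to probe the
    distance-divergence agreement of the Mash estimator."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    a = random_sequence(length, rng)
    b = mutate_sequence(a, rate, rng)
    return a, b


def _species_label(i: int, n: int) -> str:
    width = max(2, len(str(n)))
    return f"SP{i + 1:0{width}d}"


def generate_species_genomes(n_species: int, strains_per_species: int,
                             centroid_length: int = 100_000,
                             within_rate: float = 0.01,
                             between_rate: float | str = 0.2,
                             seed: int = 0,
                             kmer_length: int = 21
                             ) -> tuple[list[Genome], list[SpeciesTruth]]:
    """Simulate ``n_species`` species with ``strains_per_species`` strains each.

    Centroids diverge from a shared ancestor at ``between_rate`` per site, or
    are drawn independently when ``between_rate="unrelated"``; each strain is
    its centroid with substitutions at ``within_rate``.  Genomes are labelled
    food MAGs by default (metadata is freely editable afterwards).
    """
    unrelated = isinstance(between_rate, str)
    if unrelated and between_rate != "unrelated":
        raise ValueError(f"between_rate must be a rate or 'unrelated', got {between_rate!r}")
    if not unrelated:
        if not (0.0 <= within_rate < between_rate <= 0.75):
            raise ValueError(
                f"need 0 <= within_rate < between_rate <= 0.75, "
                f"got within={within_rate}, between={between_rate}")
    elif not (0.0 <= within_rate <= 0.75):
        raise ValueError(f"within_rate must be in [0, 0.75], got {within_rate}")
    if n_species < 1 or strains_per_species < 1:
        raise ValueError("n_species and strains_per_species must be >= 1")
    if centroid_length < 10 * kmer_length:
        raise ValueError(
            f"centroid_length must be >= 10 x k-mer length "
            f"({10 * kmer_length}), got {centroid_length}")
    root = np.random.SeedSequence(seed)
    ss_ancestor, ss_species = root.spawn(2)
    ancestor = (None if unrelated
                else random_sequence(centroid_length,
                                     np.random.default_rng(ss_ancestor)))
    genomes: list[Genome] = []
    truths: list[SpeciesTruth] = []
    for si, ss in enumerate(ss_species.spawn(n_species)):
        rng = np.random.default_rng(ss)
        sp = _species_label(si, n_species)
        if unrelated:
            centroid = random_sequence(centroid_length, rng)
        else:
            centroid = mutate_sequence(ancestor, float(between_rate), rng)
        member_ids = []
        for gi in range(strains_per_species):
            gid = f"{sp}_G{gi + 1:02d}"
            strain = mutate_sequence(centroid, within_rate, rng)
            genomes.append(Genome(id=gid, source_category="food", origin="MAG",
                                  site="synthetic", completeness=100.0,
                                  contamination=0.0, sequences=[strain]))
            member_ids.append(gid)
        truths.append(SpeciesTruth(species_id=sp, centroid_length=centroid_length,
                                   within_divergence=within_rate,
                                   member_genome_ids=member_ids,
                                   centroid=centroid))
    return genomes, truths


def degrade_genome(genome: Genome, keep_fraction: float,
                   fragment_length: int = 5000, seed: int = 0) -> Genome:
    """Emulate MAG incompleteness by contig dropout.

    Each contig is cut into fragments of ~``fragment_length`` and a random
    ``keep_fraction`` of all fragments is retained (kept fragments preserve
    genome order).  The recorded completeness becomes 100 * keep_fraction;
    contamination is unchanged.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    if genome.sequences is None:
        raise ValueError(f"genome {genome.id!r} has no in-memory sequences")
    if keep_fraction == 1.0:
        fragments = list(genome.sequences)
        kept = fragments
    else:
        fragments = []
        for seq in genome.sequences:
            for start in range(0, len(seq), fragment_length):
                fragments.append(seq[start:start + fragment_length])
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n_keep = max(1, round(keep_fraction * len(fragments)))
        idx = np.sort(rng.choice(len(fragments), size=n_keep, replace=False))
        kept = [fragments[i] for i in idx]
    return Genome(id=genome.id, source_category=genome.source_category,
                  origin=genome.origin, site=genome.site,
                  completeness=100.0 * keep_fraction,
                  contamination=genome.contamination,
                  sequence_path=genome.sequence_path, sequences=kept)


_LINEAGE_TEMPLATE = ("k__Bacteria|p__Firmicutes|c__Bacilli|o__Lactobacillales"
                     "|f__{family}|g__{genus}|s__{species}")


_FAMILY_BY_GENUS = {
    "Lactobacillus": "Lactobacillaceae",
    "Lactococcus": "Streptococcaceae",
    "Streptococcus": "Streptococcaceae",
    "Leuconostoc": "Leuconostocaceae",
    "Weissella": "Leuconostocaceae",
}


def species_lineage(species: str, family: str | None = None) -> str:
    """MetaPhlAn-style lineage for a species name like
    'Lactobacillus_rhamnosus' (genus = first underscore-separated token)."""
    genus = species.split("_")[0]
    if family is None:
        family = _FAMILY_BY_GENUS.get(genus, f"{genus}aceae")
    return _LINEAGE_TEMPLATE.format(family=family, genus=genus, species=species)


def default_profile_truth(species: Iterable[str], strata: Iterable[str],
                          seed: int = 0,
                          presence_range: tuple[float, float] = (0.05, 0.6),
                          log_mean_range: tuple[float, float] = (-2.0, 0.0),
                          log_sigma: float = 1.0) -> ProfileTruth:
    """Random per-(species, stratum) profile truth.

    Presence probabilities are uniform on ``presence_range``; log-abundance
    locations uniform on ``log_mean_range`` (natural log of percent, i.e.
    median abundances between ~0.14% and 1%), a scale well clear of the
    0.01% detection floor.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for sp in species:
        for st in strata:
            rows.append({
                "species": sp, "stratum": st,
                "presence_probability": float(rng.uniform(*presence_range)),
                "log_mean": float(rng.uniform(*log_mean_range)),
                "log_sigma": log_sigma,
            })
    return ProfileTruth(pd.DataFrame(rows))


def generate_abundance_table(species_list: Sequence[str],
                             strata_design: Mapping[str, int],
                             truth: ProfileTruth,
                             detection_floor: float = 0.01,
                             seed: int = 0,
                             stratum_field: str = "age_category",
                             body_site: str = "stool"
                             ) -> tuple[pd.DataFrame, pd.DataFrame, ProfileTruth]:
    """Draw a species x sample percent-abundance table plus sample metadata.

    For each sample and species: present with the stratum's presence
    probability; if present the abundance is lognormal(log_mean, log_sigma)
    in percent; if absent (or the draw falls below ``detection_floor``) the
    abundance is 0.  Strata map onto ``stratum_field`` of the metadata.
    """
    if detection_floor < 0:
        raise ValueError("detection_floor must be >= 0")
    known = set(truth.table["stratum"].unique())
    for st, n in strata_design.items():
        if n < 1:
            raise ValueError(f"stratum {st!r}: sample count must be >= 1")
        if st not in known:
            raise KeyError(f"stratum {st!r} not present in the profile truth")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lineages = [species_lineage(sp) for sp in species_list]
    sample_ids: list[str] = []
    meta_rows = []
    columns = {}
    counter = 0
    for st, n in strata_design.items():
        params = [truth.lookup(sp, st) for sp in species_list]
        for _ in range(n):
            counter += 1
            sid = f"SMP{counter:05d}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "body_site": body_site,
                              "age_category": "NA", "westernized": "NA",
                              "country": "NA", "geography_group": "NA",
                              stratum_field: st})
            vals = np.zeros(len(species_list))
            for i, (p, mu, sig) in enumerate(params):
                if rng.random() < p:
                    a = float(np.exp(rng.normal(mu, sig))) if sig > 0 else float(np.exp(mu))
                    vals[i] = a if a >= detection_floor else 0.0
            columns[sid] = vals
    table = pd.DataFrame(columns, index=pd.Index(lineages, name="clade_name"))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, metadata, truth


def generate_gene_matrix(n_genomes_per_group: int, n_genes: int,
                         n_differential: int, prev_in: float = 0.8,
                         prev_out: float = 0.2, background_prev: float = 0.5,
                         seed: int = 0,
                         groups: tuple[str, str] = ("food", "human")
                         ) -> tuple[GeneMatrix, GeneTruth]:
    """Planted differential gene presence/absence matrix.

    The first ``n_differential`` genes are present with probability
    ``prev_in`` in ``groups[0]`` and ``prev_out`` in ``groups[1]``; the
    remaining genes share ``background_prev`` across both groups.
    """
    for name, p in (("prev_in", prev_in), ("prev_out", prev_out),
                    ("background_prev", background_prev)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    if n_differential > n_genes:
        raise ValueError("n_differential cannot exceed n_genes")
    if n_genomes_per_group < 1 or n_genes < 1:
        raise ValueError("n_genomes_per_group and n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    width = len(str(n_genes))
    gene_ids = [f"gene_{i + 1:0{width}d}" for i in range(n_genes)]
    planted = set(gene_ids[:n_differential])
    genome_ids, labels, blocks = [], [], []
    for gi, group in enumerate(groups):
        p_vec = np.full(n_genes, background_prev)
        p_vec[:n_differential] = prev_in if gi == 0 else prev_out
        block = rng.random((n_genomes_per_group, n_genes)) < p_vec
        blocks.append(block)
        genome_ids += [f"{group}_{i + 1:03d}" for i in range(n_genomes_per_group)]
        labels += [group] * n_genomes_per_group
    presence = pd.DataFrame(np.vstack(blocks), index=genome_ids, columns=gene_ids)
    gm = GeneMatrix(presence=presence,
                    groups=pd.Series(labels, index=genome_ids, name="group"))
    prob = pd.DataFrame(
        {groups[0]: np.where([g in planted for g in gene_ids], prev_in, background_prev),
         groups[1]: np.where([g in planted for g in gene_ids], prev_out, background_prev)},
        index=gene_ids)
    return gm, GeneTruth(planted_differential_genes=planted,
                         presence_probability=prob)
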