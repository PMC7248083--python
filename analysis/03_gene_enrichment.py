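"""Differential gene prevalence between food and human genomes.

Simulates a Roary-style presence/absence matrix for 50 food + 50 human
genomes with 500 genes of which 20 are planted as differentially prevalent
(80% in food vs 20% in human), applies the prevalence-band filter
([5%, 95%) of genomes), and tests every retained gene with Fisher + BH.

Writes results/enrichment/: the enrichment table and the planted truth.
The simulated gene matrix itself goes under scratch/ (regenerable from the
seed).
"""

from pathlib import Path

from labgut import generate_gene_matrix
from labgut import io as lio
from labgut.enrichment import filter_genes_by_band, gene_enrichment

OUT = Path(__file__).resolve().parents[1] / "results" / "enrichment"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "enrichment"


def main() -> None:
    gm, truth = generate_gene_matrix(50, 500, 20, prev_in=0.8, prev_out=0.2,
                                     seed=3)
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    lio.write_gene_matrix(gm, SCRATCH / "gene_matrix.tsv")
    lio.write_json({"planted_differential_genes":
                    sorted(truth.planted_differential_genes)},
                   OUT / "gene_truth.json")

    banded = filter_genes_by_band(gm)
    print(f"prevalence band [5%, 95%) kept {len(banded.gene_ids)} of "
          f"{len(gm.gene_ids)} genes")
    res = gene_enrichment(banded)
    res.to_csv(OUT / "enrichment.tsv", sep="\t", index=False, na_rep="NA")

    sig_q = res[res["q"] < 0.05]
    sig_p = res[res["p"] < 0.05]
    planted = truth.planted_differential_genes
    hits = set(sig_q["gene_id"]) & planted
    print(f"{len(sig_p)} genes at p<0.05, {len(sig_q)} at q<0.05")
    print(f"planted genes recovered at q<0.05: {len(hits)}/{len(planted)}")
    fp = set(sig_q["gene_id"]) - planted
    print(f"false positives at q<0.05: {len(fp)}")
    print(f"\nartifacts in {OUT}")


if __name__ == "__main__":
    main()
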