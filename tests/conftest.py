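import numpy as np
import pandas as pd
import pytest

from labgut import generate_species_genomes, pairwise_distances


@pytest.fixture(scope="session")
def small_species_run():
    """3 species x 3 strains of short genomes, with their distance matrix."""
    genomes, truths = generate_species_genomes(
        3, 3, centroid_length=5000, within_rate=0.01, between_rate=0.2, seed=11)
    d = pairwise_distances({g.id: g.sequences for g in genomes}, k=21, s=10000)
    return genomes, truths, d


@pytest.fixture()
def toy_profile():
    """Hand-sized profile table (percent) + metadata over two age strata."""
    lineages = [
        "k__Bacteria|p__Firmicutes|c__Bacilli|o__Lactobacillales"
        "|f__Streptococcaceae|g__Streptococcus|s__Streptococcus_thermophilus",
        "k__Bacteria|p__Firmicutes|c__Bacilli|o__Lactobacillales"
        "|f__Lactobacillaceae|g__Lactobacillus|s__Lactobacillus_rhamnosus",
        "k__Bacteria|p__Actinobacteria|c__Actinobacteria|o__Bifidobacteriales"
        "|f__Bifidobacteriaceae|g__Bifidobacterium|s__Bifidobacterium_longum",
    ]
    samples = [f"S{i}" for i in range(1, 7)]
    values = np.array([
        [0.50, 0.009, 0.02, 0.00, 1.20, 0.30],   # S. thermophilus
        [0.00, 0.015, 0.00, 0.01, 0.00, 0.05],   # Lb. rhamnosus
        [3.00, 2.000, 1.00, 4.00, 2.00, 1.00],   # B. longum (non-LAB)
    ])
    table = pd.DataFrame(values, index=pd.Index(lineages, name="clade_name"),
                         columns=samples)
    metadata = pd.DataFrame({
        "sample_id": samples,
        "body_site": ["stool"] * 6,
        "age_category": ["newborn", "newborn", "newborn", "adult", "adult", "NA"],
        "westernized": ["yes", "yes", "no", "yes", "no", "yes"],
        "country": ["USA"] * 6,
        "geography_group": ["NorthAmerica"] * 6,
    }).set_index("sample_id")
    return table, metadata


def random_distance_matrix(n: int, rng: np.random.Generator):
    """Random symmetric distance matrix with zero diagonal, entries in (0,1)."""
    v = rng.uniform(0.01, 0.99, size=(n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return v
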