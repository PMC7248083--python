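"""Genome catalogue records and quality filtering.

Each genome carries a source category (where the organism came from), an
origin (cultured reference genome vs metagenome-assembled genome), and the
CheckM-style quality estimates (completeness and contamination, percent)
that drive the medium-quality filter applied before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SOURCE_CATEGORIES = ("human", "food", "other", "NA")
ORIGINS = ("reference", "MAG")


@dataclass
class Genome:
    """One assembly with its curated metadata.

    Sequence content may live on disk (``sequence_path``) or in memory
    (``sequences``, a list of contig strings); synthetic genomes use the
    latter.
    """

    id: str
    source_category: str = "NA"
    origin: str = "MAG"
    site: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    sequence_path: str | None = None
    sequences: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.source_category not in SOURCE_CATEGORIES:
            raise ValueError(
                f"genome {self.id!r}: source_category {self.source_category!r} "
                f"not in {SOURCE_CATEGORIES}")
        if self.origin not in ORIGINS:
            raise ValueError(
                f"genome {self.id!r}: origin {self.origin!r} not in {ORIGINS}")
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"genome {self.id!r}: {name} must be in [0, 100], got {v}")

    @property
    def is_food_mag(self) -> bool:
        return self.source_category == "food" and self.origin == "MAG"

    @property
    def is_human_mag(self) -> bool:
        return self.source_category == "human" and self.origin == "MAG"

    @property
    def is_reference(self) -> bool:
        return self.origin == "reference"

    @property
    def total_length(self) -> int:
        if self.sequences is None:
            raise ValueError(f"genome {self.id!r} has no in-memory sequences")
        return sum(len(s) for s in self.sequences)


def quality_filter(genomes: list[Genome], min_completeness: float = 50.0,
                   max_contamination: float = 5.0) -> list[Genome]:
    """Medium-quality MAG filter: completeness > 50% and contamination < 5%.

    Both bounds are strict, mirroring the usual CheckM screening convention.
    Reference genomes pass through the same filter (their completeness is
    conventionally 100).
    """
    return [g for g in genomes
            if g.completeness > min_completeness
            and g.contamination < max_contamination]


def as_catalogue(genomes: list[Genome]) -> dict[str, Genome]:
    cat: dict[str, Genome] = {}
    for g in genomes:
        if g.id in cat:
            raise ValueError(f"duplicate genome id {g.id!r} in catalogue")
        cat[g.id] = g
    return cat
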