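"""Genome coordinate plumbing shared by the simulator and the callers.

Two coordinate dialects are used throughout the package and are never mixed
silently: BED-like intervals (0-based, half-open) for mosaics, blocks and
coverage; GFF-like gene models (1-based, inclusive) for gene annotation.
Genetic positions (Morgans) are obtained from physical positions by linear
interpolation between chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeMap",
    "GeneCopy",
    "DuplicatedGeneSpec",
    "GeneModel",
]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the simulated genome."""

    id: str
    length_bp: int
    genetic_length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.id}: length_bp must be positive")
        if self.genetic_length_morgans < 0:
            raise ValueError(
                f"chromosome {self.id}: genetic length must be non-negative"
            )


@dataclass
class GenomeMap:
    """Chromosome sizes plus marker positions.

    Parameters
    ----------
    chromosomes
        Ordered chromosomes.
    markers
        Mapping chromosome id -> strictly increasing marker positions (bp,
        0-based).
    """

    chromosomes: Sequence[Chromosome]
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("GenomeMap needs at least one chromosome")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")
        self.markers = {k: np.asarray(v, dtype=np.int64) for k, v in self.markers.items()}
        for chrom_id, pos in self.markers.items():
            if chrom_id not in ids:
                raise ValueError(f"markers given for unknown chromosome {chrom_id}")
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions on {chrom_id} not strictly increasing")
            chrom = self.chromosome(chrom_id)
            if pos.size and (pos[0] < 0 or pos[-1] >= chrom.length_bp):
                raise ValueError(f"marker positions on {chrom_id} out of range")

    def chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def bp_to_morgans(self, chrom_id: str, bp: float) -> float:
        c = self.chromosome(chrom_id)
        return (bp / c.length_bp) * c.genetic_length_morgans

    def morgans_to_bp(self, chrom_id: str, m: float) -> float:
        c = self.chromosome(chrom_id)
        if c.genetic_length_morgans == 0:
            raise ValueError(f"chromosome {chrom_id} has zero genetic length")
        return (m / c.genetic_length_morgans) * c.length_bp

    def marker_morgans(self, chrom_id: str) -> np.ndarray:
        """Genetic positions (Morgans) of the markers on one chromosome."""
        pos = self.markers.get(chrom_id)
        if pos is None:
            raise KeyError(chrom_id)
        c = self.chromosome(chrom_id)
        return pos / c.length_bp * c.genetic_length_morgans


@dataclass(frozen=True)
class GeneCopy:
    """One copy of a duplicated gene family (1-based inclusive coordinates)."""

    copy_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    tss_bp: int | None = None
    tes_bp: int | None = None

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError(f"{self.copy_id}: start_bp must be < end_bp")
        if self.strand not in "+-":
            raise ValueError(f"{self.copy_id}: strand must be '+' or '-'")

    @property
    def midpoint_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2


# The functional states a gene copy can be in, in one haplotype.
COPY_STATES = ("functional", "lof", "silenced", "absent")


@dataclass
class DuplicatedGeneSpec:
    """A duplicated gene family: copies, per-founder functional states,
    and whether the family is essential (zero functional copies lethal).

    ``founder_states[founder][copy_id]`` is one of :data:`COPY_STATES`.
    ``penetrance`` is the probability that a genotype with zero functional
    copies over the whole family dies.
    """

    family_id: str
    copies: Sequence[GeneCopy]
    founder_states: dict[str, dict[str, str]]
    essential: bool = False
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        copy_ids = [c.copy_id for c in self.copies]
        if len(set(copy_ids)) != len(copy_ids):
            raise ValueError("duplicate copy ids")
        for founder, states in self.founder_states.items():
            for cid in copy_ids:
                if cid not in states:
                    raise ValueError(
                        f"founder {founder} missing state for copy {cid}"
                    )
                if states[cid] not in COPY_STATES:
                    raise ValueError(
                        f"invalid state {states[cid]!r} for {founder}/{cid}"
                    )

    def copy(self, copy_id: str) -> GeneCopy:
        for c in self.copies:
            if c.copy_id == copy_id:
                return c
        raise KeyError(copy_id)

    def is_functional(self, founder: str, copy_id: str) -> bool:
        return self.founder_states[founder][copy_id] == "functional"

    def functional_copy_count(self, homolog_founders: dict[str, tuple[str, str]]) -> int:
        """Count functional copies in a diplotype.

        ``homolog_founders[copy_id]`` gives the founder carried at that copy's
        locus on each of the two homologs.
        """
        n = 0
        for c in self.copies:
            for founder in homolog_founders[c.copy_id]:
                if self.is_functional(founder, c.copy_id):
                    n += 1
        return n

    def interchromosomal(self) -> bool:
        return len({c.chromosome for c in self.copies}) >= 2


@dataclass
class GeneModel:
    """Gene model used by the variant-effect classifier and the methylation
    profiler (1-based inclusive coordinates; ``cds_segments`` ordered by
    genomic position).

    ``sequence`` is the genomic sequence of ``[start_bp, end_bp]`` on the
    forward strand; it is required for effect classification of point
    variants (premature stop detection needs the codons).
    """

    gene_id: str
    chromosome: str
    strand: str
    tss_bp: int
    tes_bp: int
    cds_segments: Sequence[tuple[int, int]]
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for s, e in self.cds_segments:
            if s > e:
                raise ValueError("CDS segment with start > end")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError("overlapping CDS segments")
        if sum(e - s + 1 for s, e in self.cds_segments) <= 0:
            raise ValueError("total CDS length must be positive")

    @property
    def start_bp(self) -> int:
        return min(self.tss_bp, self.tes_bp)

    @property
    def end_bp(self) -> int:
        return max(self.tss_bp, self.tes_bp)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)
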