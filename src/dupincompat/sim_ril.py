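"""Forward simulation of multiparent RIL subpopulations.

The crossing design mirrors an eight-founder diallel intercross: each
subpopulation starts from two F1* hybrids (each a cross of two inbred
founders), which are crossed to produce F1 individuals, and every line is
then advanced by single-seed-descent selfing to a target generation (F4 or
F6). Meiosis uses a Poisson crossover count per chromosome (no
interference), crossover positions uniform in genetic distance, and linear
bp<->Morgan interpolation.

Lethal incompatibilities act at selection time in every generation: an
embryo whose total functional-copy count over an essential duplicated-gene
family is zero dies with probability ``penetrance`` and is replaced by
redrawing a sibling from the same parents (bounded retries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import DuplicatedGeneSpec, GenomeMap

__all__ = [
    "CrossDesign",
    "Haplotype",
    "SimulatedIndividual",
    "founder_at",
    "sample_gamete",
    "sample_founder_alleles",
    "simulate_subpopulation",
    "simulate_gene_pair_genotypes",
]

# A haplotype: chromosome id -> list of (start, end, founder) segments,
# 0-based half-open, tiling the chromosome without gaps or overlaps.
Haplotype = dict[str, list[tuple[int, int, str]]]

MISSING = -1  # observed-genotype missing code


@dataclass(frozen=True)
class CrossDesign:
    """One subpopulation of the diallel intercross.

    ``founders`` is the ordered quadruple (p1, p2, p3, p4); the two F1*
    hybrids are p1 x p2 and p3 x p4. ``selfing_generations`` is the F-number
    of the final generation (6 means five rounds of selfing after the
    hybrid x hybrid F1).
    """

    label: str
    founders: tuple[str, str, str, str]
    selfing_generations: int = 6
    target_n: int = 90

    def __post_init__(self) -> None:
        if len(set(self.founders)) != 4:
            raise ValueError("design requires exactly four distinct founders")
        if self.selfing_generations < 2:
            raise ValueError("selfing_generations must be >= 2")
        if self.target_n <= 0:
            raise ValueError("target_n must be positive")


@dataclass
class SimulatedIndividual:
    """A simulated RIL: truth mosaic, observed markers, viability flag."""

    mosaic: tuple[Haplotype, Haplotype]
    observed: dict[str, np.ndarray] = field(default_factory=dict)
    viable: bool = True


def _founder_haplotype(founder: str, genome: GenomeMap) -> Haplotype:
    return {c.id: [(0, c.length_bp, founder)] for c in genome.chromosomes}


def founder_at(segments: list[tuple[int, int, str]], pos: int) -> str:
    """Founder label of the segment containing ``pos`` (0-based)."""
    ends = np.fromiter((e for _, e, _ in segments), dtype=np.int64)
    i = int(np.searchsorted(ends, pos, side="right"))
    if i >= len(segments) or pos < segments[i][0]:
        raise ValueError(f"position {pos} not covered by segments")
    return segments[i][2]


def _founders_at_markers(
    segments: list[tuple[int, int, str]], positions: np.ndarray
) -> np.ndarray:
    ends = np.fromiter((e for _, e, _ in segments), dtype=np.int64)
    idx = np.searchsorted(ends, positions, side="right")
    return np.array([segments[i][2] for i in idx])


def _recombine(
    hap_a: list[tuple[int, int, str]],
    hap_b: list[tuple[int, int, str]],
    breakpoints_bp: Sequence[int],
    start_on_a: bool,
) -> list[tuple[int, int, str]]:
    """Splice two homologs at the given breakpoints (0-based bp)."""
    length = hap_a[-1][1]
    cuts = [0, *sorted(breakpoints_bp), length]
    out: list[tuple[int, int, str]] = []
    use_a = start_on_a
    for lo, hi in zip(cuts, cuts[1:]):
        if lo >= hi:
            use_a = not use_a
            continue
        src = hap_a if use_a else hap_b
        for s, e, f in src:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                if out and out[-1][2] == f and out[-1][1] == a:
                    out[-1] = (out[-1][0], b, f)
                else:
                    out.append((a, b, f))
        use_a = not use_a
    return out


def sample_gamete(
    diplotype: tuple[Haplotype, Haplotype],
    genome: GenomeMap,
    rng: np.random.Generator,
) -> Haplotype:
    """Draw one recombinant gamete from a diplotype.

    Per chromosome the crossover count is Poisson with mean equal to the
    genetic length (Morgans), crossover positions are uniform in genetic
    distance (mapped to bp by linear interpolation), and the starting
    homolog is chosen with probability 1/2.
    """
    if not genome.chromosomes:
        raise ValueError("empty genome map")
    hap_a, hap_b = diplotype
    gamete: Haplotype = {}
    for chrom in genome.chromosomes:
        n_xo = rng.poisson(chrom.genetic_length_morgans)
        if chrom.genetic_length_morgans > 0 and n_xo > 0:
            pos_m = rng.uniform(0.0, chrom.genetic_length_morgans, size=n_xo)
            bps = sorted(
                int(round(genome.morgans_to_bp(chrom.id, m))) for m in pos_m
            )
            # drop degenerate cuts at the chromosome ends
            bps = [b for b in bps if 0 < b < chrom.length_bp]
        else:
            bps = []
        start_on_a = bool(rng.integers(2))
        gamete[chrom.id] = _recombine(
            hap_a[chrom.id], hap_b[chrom.id], bps, start_on_a
        )
    return gamete


def sample_founder_alleles(
    genome: GenomeMap,
    founders: Sequence[str],
    rng: np.random.Generator,
    p_alt: float = 0.5,
) -> dict[str, dict[str, np.ndarray]]:
    """Assign biallelic marker alleles (0/1) to each founder.

    Each founder independently carries the alternate allele with probability
    ``p_alt`` at each marker; markers where all founders agree are retained
    (they are simply uninformative for haplotype reconstruction, as in real
    marker panels restricted per subpopulation).
    """
    return {
        f: {
            chrom: rng.integers(0, 2, size=len(pos)).astype(np.int8)
            for chrom, pos in genome.markers.items()
        }
        for f in founders
    }


def _observe(
    mosaic: tuple[Haplotype, Haplotype],
    genome: GenomeMap,
    founder_alleles: dict[str, dict[str, np.ndarray]],
    rng: np.random.Generator,
    error_rate: float,
    missing_rate: float,
) -> dict[str, np.ndarray]:
    obs: dict[str, np.ndarray] = {}
    for chrom, positions in genome.markers.items():
        dosage = np.zeros(len(positions), dtype=np.int8)
        for hap in mosaic:
            labels = _founders_at_markers(hap[chrom], positions)
            alleles = np.empty(len(positions), dtype=np.int8)
            for f in np.unique(labels):
                mask = labels == f
                alleles[mask] = founder_alleles[f][chrom][mask]
            if error_rate > 0:
                flip = rng.random(len(positions)) < error_rate
                alleles = np.where(flip, 1 - alleles, alleles)
            dosage += alleles
        if missing_rate > 0:
            miss = rng.random(len(positions)) < missing_rate
            dosage = np.where(miss, MISSING, dosage).astype(np.int8)
        obs[chrom] = dosage
    return obs


def _functional_count(
    mosaic: tuple[Haplotype, Haplotype], gene: DuplicatedGeneSpec
) -> int:
    homolog_founders = {}
    for copy in gene.copies:
        pos = copy.midpoint_bp - 1  # 1-based midpoint -> 0-based
        homolog_founders[copy.copy_id] = (
            founder_at(mosaic[0][copy.chromosome], pos),
            founder_at(mosaic[1][copy.chromosome], pos),
        )
    return gene.functional_copy_count(homolog_founders)


def _is_viable(
    mosaic: tuple[Haplotype, Haplotype],
    genes: Sequence[DuplicatedGeneSpec],
    rng: np.random.Generator,
) -> bool:
    for gene in genes:
        if not gene.essential:
            continue
        if _functional_count(mosaic, gene) == 0:
            if rng.random() < gene.penetrance:
                return False
    return True


def _viable_offspring(
    mother: tuple[Haplotype, Haplotype],
    father: tuple[Haplotype, Haplotype],
    genes: Sequence[DuplicatedGeneSpec],
    genome: GenomeMap,
    rng: np.random.Generator,
    max_retries: int,
) -> tuple[Haplotype, Haplotype]:
    for _ in range(max_retries):
        child = (
            sample_gamete(mother, genome, rng),
            sample_gamete(father, genome, rng),
        )
        if _is_viable(child, genes, rng):
            return child
    raise RuntimeError(
        f"no viable offspring after {max_retries} attempts "
        "(all allele combinations may be lethal)"
    )


def simulate_subpopulation(
    design: CrossDesign,
    founder_alleles: dict[str, dict[str, np.ndarray]],
    genes: Sequence[DuplicatedGeneSpec],
    genome: GenomeMap,
    rng: np.random.Generator,
    error_rate: float = 0.005,
    missing_rate: float = 0.10,
    max_retries: int = 200,
) -> list[SimulatedIndividual]:
    """Simulate one RIL subpopulation under the diallel crossing design.

    Returns ``design.target_n`` viable lines, each with its truth mosaic and
    an observed marker-genotype vector per chromosome (dosage 0/1/2 with
    allele-flip errors and missing codes).
    """
    for gene in genes:
        for f in design.founders:
            if f not in gene.founder_states:
                raise ValueError(
                    f"gene {gene.family_id}: no founder state for {f}"
                )
    p1, p2, p3, p4 = design.founders
    hybrid1 = (_founder_haplotype(p1, genome), _founder_haplotype(p2, genome))
    hybrid2 = (_founder_haplotype(p3, genome), _founder_haplotype(p4, genome))
    lines: list[SimulatedIndividual] = []
    for _ in range(design.target_n):
        individual = _viable_offspring(
            hybrid1, hybrid2, genes, genome, rng, max_retries
        )
        for _gen in range(design.selfing_generations - 1):
            individual = _viable_offspring(
                individual, individual, genes, genome, rng, max_retries
            )
        obs = _observe(
            individual, genome, founder_alleles, rng, error_rate, missing_rate
        )
        lines.append(SimulatedIndividual(mosaic=individual, observed=obs))
    return lines


# ---------------------------------------------------------------------------
# Fast exact pedigree simulation at a single unlinked gene pair.
#
# Two loci on different chromosomes segregate independently through every
# meiosis, so the full chromosome machinery can be bypassed: a gamete simply
# inherits one of the two parental alleles at each locus, independently.
# This is exact (not an approximation) for interchromosomal pairs and is the
# workhorse of the distortion scan's calibration and power analyses.
# ---------------------------------------------------------------------------


def _pair_gamete(ind, rng: np.random.Generator):
    (a1, a2), (b1, b2) = ind
    return (
        a1 if rng.integers(2) == 0 else a2,
        b1 if rng.integers(2) == 0 else b2,
    )


def _pair_functional_count(ind, gene: DuplicatedGeneSpec) -> int:
    copy1, copy2 = gene.copies[0].copy_id, gene.copies[1].copy_id
    (a1, a2), (b1, b2) = ind
    n = 0
    for f in (a1, a2):
        n += gene.is_functional(f, copy1)
    for f in (b1, b2):
        n += gene.is_functional(f, copy2)
    return n


def _pair_viable(ind, gene, rng) -> bool:
    if gene is None or not gene.essential:
        return True
    if _pair_functional_count(ind, gene) == 0:
        return rng.random() >= gene.penetrance
    return True


def _pair_offspring(mother, father, gene, rng, max_retries: int):
    for _ in range(max_retries):
        g_m = _pair_gamete(mother, rng)
        g_f = _pair_gamete(father, rng)
        child = ((g_m[0], g_f[0]), (g_m[1], g_f[1]))
        if _pair_viable(child, gene, rng):
            return child
    raise RuntimeError(f"no viable offspring after {max_retries} attempts")


def simulate_f1_cross(
    parent1,
    parent2,
    gene: DuplicatedGeneSpec | None,
    n_offspring: int,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """F1 offspring of two fixed diplotypes at an unlinked locus pair.

    Parents are ``((l1a, l1b), (l2a, l2b))`` allele-label diplotypes;
    lethality selection applies as in the RIL pedigree. Used for
    complementation-cross fixtures (e.g., a heterozygous knockout line
    crossed to a line heterozygous for a naturally nonfunctional allele).
    """
    out = []
    for _ in range(n_offspring):
        ind = _pair_offspring(parent1, parent2, gene, rng, max_retries)
        (a1, a2), (b1, b2) = ind
        out.append((tuple(sorted((a1, a2))), tuple(sorted((b1, b2)))))
    return out


def simulate_gene_pair_genotypes(
    design: CrossDesign,
    gene: DuplicatedGeneSpec | None,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Simulate founder genotypes at one unlinked duplicated gene pair.

    ``gene`` (two copies on different chromosomes) supplies founder states
    and penetrance for viability selection; ``None`` simulates a neutral
    pair. Returns, per individual, the unordered founder pair at each locus
    (each sorted canonically).
    """
    if gene is not None and len(gene.copies) != 2:
        raise ValueError("gene pair simulation requires exactly two copies")
    p1, p2, p3, p4 = design.founders
    hybrid1 = ((p1, p2), (p1, p2))
    hybrid2 = ((p3, p4), (p3, p4))
    out = []
    for _ in range(design.target_n):
        ind = _pair_offspring(hybrid1, hybrid2, gene, rng, max_retries)
        for _gen in range(design.selfing_generations - 1):
            ind = _pair_offspring(ind, ind, gene, rng, max_retries)
        (a1, a2), (b1, b2) = ind
        out.append((tuple(sorted((a1, a2))), tuple(sorted((b1, b2)))))
    return out
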