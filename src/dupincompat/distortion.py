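"""Segregation-distortion scan over unlinked duplicated gene pairs.

A genetic incompatibility between reciprocally pseudofunctionalized copies
of a duplicated gene removes (or depletes) the double-homozygous
nonfunctional allele-pair class from a RIL population. The scan counts
founder allele-pair combinations at each interchromosomal gene pair and
tests the counts against their expectation with a chi-square statistic,
per subpopulation, in merged same-founder subpopulations, and
population-wide (where per-subpopulation observed and expected tables are
summed cell-wise over the union of all founders before forming the
statistic). Candidate pairs must additionally show a nonfunctional allele
in *both* copies somewhere among the founders — otherwise the distortion is
better explained by linkage to an incompatibility elsewhere.

Counting convention: a double homozygote ``aabb`` adds 2 to o[a,b]; a
genotype with heterozygosity pairs the k-th allele of locus 1 with the k-th
allele of locus 2 after sorting each locus's alleles canonically, adding 1
to each resulting combination (``abbc`` -> o[a,b] += 1, o[b,c] += 1). Each
individual therefore contributes exactly two counts; because the two counts
of a double homozygote are identical, the raw chi-square is inflated under
the null. ``chisq_distortion`` computes the statistic exactly as defined,
and optionally applies a first-order clustered-counts (Rao-Scott style)
correction, dividing the statistic by the design effect
``1 + (duplicate contributions) / n`` before the p-value; the screen uses
that correction by default so its p-values are calibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import DuplicatedGeneSpec

__all__ = [
    "GenePairLocus",
    "AllelePairCountTable",
    "DistortionResult",
    "genotype_at_locus",
    "count_allele_pairs",
    "expected_pairs",
    "chisq_distortion",
    "chisq_whole_population",
    "benjamini_hochberg",
    "screen_gene_pairs",
    "confirm_lof_in_founders",
]

log = logging.getLogger(__name__)

GenotypePair = tuple[tuple[str, str], tuple[str, str]]


@dataclass(frozen=True)
class GenePairLocus:
    """Anchors of a duplicated gene pair: for reference copies the gene
    midpoint, for non-reference copies the midpoint between the two closest
    flanking syntenic regions."""

    family_id: str
    locus1: tuple[str, int]  # (chromosome, midpoint_bp, 1-based)
    locus2: tuple[str, int]

    def __post_init__(self) -> None:
        if self.locus1[0] == self.locus2[0]:
            raise ValueError(
                f"{self.family_id}: loci must lie on different chromosomes"
            )


@dataclass
class AllelePairCountTable:
    """Observed allele-pair counts o[i, j] (locus-1 founder i, locus-2
    founder j), plus the bookkeeping the clustered-counts correction needs."""

    counts: pd.DataFrame
    n_individuals: int
    n_duplicate: int  # individuals whose two contributed pairs are identical

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    @property
    def design_effect(self) -> float:
        if self.n_individuals == 0:
            return 1.0
        return 1.0 + self.n_duplicate / self.n_individuals


@dataclass
class DistortionResult:
    statistic: float  # the raw chi-square, sum (o-e)^2 / e
    df: int
    pvalue: float
    design_effect: float = 1.0  # 1.0 means no correction applied
    qvalue: float | None = None
    population: str | None = None


def genotype_at_locus(
    blocks: pd.DataFrame, anchor: tuple[str, int]
) -> tuple[str, str] | None:
    """Founder pair of the haplotype block containing the anchor.

    ``blocks`` is a block table (chrom, start, end, state) in BED
    convention; the anchor midpoint is 1-based. An anchor falling exactly on
    a block boundary is assigned to the left (lower-coordinate) block. An
    anchor outside every block returns ``None`` (the individual is excluded
    from counting).
    """
    chrom, midpoint_bp = anchor
    pos = midpoint_bp - 1  # 0-based
    sub = blocks[blocks["chrom"] == chrom]
    if sub.empty:
        return None
    ends = sub["end"].to_numpy()
    starts = sub["start"].to_numpy()
    i = int(np.searchsorted(ends, pos, side="left"))
    if i >= len(sub) or pos < starts[i]:
        return None
    state = sub["state"].iloc[i]
    a, b = state.split("|")
    return tuple(sorted((a, b)))


def _pair_contributions(g1: tuple[str, str], g2: tuple[str, str]):
    """The two (i, j) combinations one individual contributes."""
    x1, x2 = sorted(g1)
    y1, y2 = sorted(g2)
    return (x1, y1), (x2, y2)


def count_allele_pairs(
    genotype_pairs: Sequence[GenotypePair | None],
    founders1: Sequence[str] | None = None,
    founders2: Sequence[str] | None = None,
) -> AllelePairCountTable:
    """Tally allele-pair combinations across a population.

    ``None`` entries (unknown genotype at either locus) are skipped. The
    table axes default to the sorted set of alleles observed at each locus;
    pass ``founders1``/``founders2`` to fix them.
    """
    used = [g for g in genotype_pairs if g is not None]
    n_skipped = len(genotype_pairs) - len(used)
    if n_skipped:
        log.info("count_allele_pairs: skipped %d individuals with unknown genotype", n_skipped)
    if founders1 is None:
        founders1 = sorted({a for g1, _ in used for a in g1})
    if founders2 is None:
        founders2 = sorted({a for _, g2 in used for a in g2})
    counts = pd.DataFrame(
        0.0, index=list(founders1), columns=list(founders2)
    )
    n_dup = 0
    for g1, g2 in used:
        c1, c2 = _pair_contributions(g1, g2)
        counts.loc[c1] += 1
        counts.loc[c2] += 1
        if c1 == c2:
            n_dup += 1
    return AllelePairCountTable(counts=counts, n_individuals=len(used), n_duplicate=n_dup)


def expected_pairs(o: AllelePairCountTable, method: str = "marginal") -> pd.DataFrame:
    """Expected allele-pair counts.

    ``design``: uniform over all cells (the crossing-design expectation,
    1/16 of the total for a 4x4 subpopulation table) — exact for a neutral
    unlinked pair under the balanced intercross, and sensitive to the full
    incompatibility deficit including its marginal component. ``marginal``:
    product of the observed marginals — robust when a locus shows
    single-locus segregation distortion of independent origin, at the cost
    of power against the two-locus deficit.
    """
    c = o.counts.to_numpy(dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero grand total")
    if method == "marginal":
        e = np.outer(c.sum(axis=1), c.sum(axis=0)) / total
    elif method == "design":
        e = np.full_like(c, total / c.size)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(e, index=o.counts.index, columns=o.counts.columns)


def _chisq(o: np.ndarray, e: np.ndarray) -> float:
    if np.any((e == 0) & (o > 0)):
        raise ValueError("observed count in a cell with zero expectation")
    mask = e > 0
    return float(((o[mask] - e[mask]) ** 2 / e[mask]).sum())


def chisq_distortion(
    o: AllelePairCountTable,
    e: pd.DataFrame,
    method: str = "marginal",
    correction: str | None = None,
) -> DistortionResult:
    """Per-population distortion test on one observed/expected table pair.

    Degrees of freedom: ``marginal`` -> (r-1)(c-1) over the nonzero marginal
    classes; ``design`` -> (included cells) - 1. ``correction="clustered"``
    divides the statistic by the table's design effect before the p-value
    (see module docstring); the reported ``statistic`` stays uncorrected.
    """
    obs = o.counts.to_numpy(dtype=float)
    exp = e.to_numpy(dtype=float)
    stat = _chisq(obs, exp)
    if method == "marginal":
        r = int((obs.sum(axis=1) > 0).sum())
        c = int((obs.sum(axis=0) > 0).sum())
        df = max((r - 1) * (c - 1), 1)
    elif method == "design":
        df = max(int((exp > 0).sum()) - 1, 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    deff = 1.0
    if correction == "clustered":
        deff = o.design_effect
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    p = float(stats.chi2.sf(stat / deff, df))
    return DistortionResult(statistic=stat, df=df, pvalue=p, design_effect=deff)


def chisq_whole_population(
    tables: Sequence[tuple[AllelePairCountTable, pd.DataFrame]],
    correction: str | None = None,
) -> DistortionResult:
    """Population-wide test: sum observed and expected tables cell-wise over
    the union of all founders, then form the chi-square over cells with
    positive summed expectation (df = such cells - 1)."""
    if not tables:
        raise ValueError("empty table list")
    rows = sorted({i for o, _ in tables for i in o.counts.index})
    cols = sorted({j for o, _ in tables for j in o.counts.columns})
    o_sum = pd.DataFrame(0.0, index=rows, columns=cols)
    e_sum = pd.DataFrame(0.0, index=rows, columns=cols)
    n_ind = n_dup = 0
    for o, e in tables:
        o_sum = o_sum.add(o.counts, fill_value=0.0)
        e_sum = e_sum.add(e, fill_value=0.0)
        n_ind += o.n_individuals
        n_dup += o.n_duplicate
    stat = _chisq(o_sum.to_numpy(), e_sum.to_numpy())
    df = max(int((e_sum.to_numpy() > 0).sum()) - 1, 1)
    deff = 1.0
    if correction == "clustered":
        deff = 1.0 + (n_dup / n_ind if n_ind else 0.0)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    p = float(stats.chi2.sf(stat / deff, df))
    return DistortionResult(statistic=stat, df=df, pvalue=p, design_effect=deff)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(ranked, 1.0)
    return q


def screen_gene_pairs(
    pair_genotypes: Mapping[str, Mapping[str, Sequence[GenotypePair | None]]],
    merge_groups: Mapping[str, Sequence[str]] | None = None,
    alpha: float = 0.05,
    method: str = "design",
    correction: str | None = "clustered",
) -> pd.DataFrame:
    """Run the distortion scan over many gene pairs and populations.

    Parameters
    ----------
    pair_genotypes
        family_id -> subpopulation label -> per-individual genotype pairs.
    merge_groups
        merged-population label -> subpopulation labels sharing the same
        founder quadruple (their genotypes are pooled and retested).
    alpha
        FDR level; Benjamini-Hochberg is applied within each population's
        scan family.

    Returns a tidy table (family_id, population, chi2, df, p, q, retained);
    a family is retained when any of its q-values is below ``alpha``. Pairs
    with no genotyped individuals in a population are excluded from that
    population's scan with a logged reason.
    """
    merge_groups = dict(merge_groups or {})
    records = []
    per_pair_tables: dict[str, list[tuple[AllelePairCountTable, pd.DataFrame]]] = {}
    for family_id, by_pop in pair_genotypes.items():
        per_pair_tables[family_id] = []
        populations: dict[str, list] = {k: list(v) for k, v in by_pop.items()}
        for label, members in merge_groups.items():
            pooled: list = []
            for m in members:
                pooled.extend(by_pop.get(m, []))
            populations[label] = pooled
        for pop, genos in populations.items():
            used = [g for g in genos if g is not None]
            if not used:
                log.warning(
                    "screen: pair %s has no genotyped individuals in %s; excluded",
                    family_id,
                    pop,
                )
                continue
            o = count_allele_pairs(genos)
            e = expected_pairs(o, method=method)
            if pop in by_pop:
                per_pair_tables[family_id].append((o, e))
            res = chisq_distortion(o, e, method=method, correction=correction)
            records.append(
                {
                    "family_id": family_id,
                    "population": pop,
                    "chi2": res.statistic,
                    "df": res.df,
                    "p": res.pvalue,
                }
            )
        if per_pair_tables[family_id]:
            res = chisq_whole_population(
                per_pair_tables[family_id], correction=correction
            )
            records.append(
                {
                    "family_id": family_id,
                    "population": "whole",
                    "chi2": res.statistic,
                    "df": res.df,
                    "p": res.pvalue,
                }
            )
    table = pd.DataFrame(records)
    if table.empty:
        return table.assign(q=[], retained=[])
    table["q"] = np.nan
    for pop, idx in table.groupby("population").groups.items():
        table.loc[idx, "q"] = benjamini_hochberg(table.loc[idx, "p"].to_numpy())
    retained_families = set(table.loc[table["q"] < alpha, "family_id"])
    table["retained"] = table["family_id"].isin(retained_families)
    return table


def confirm_lof_in_founders(
    screened_families: Sequence[str],
    genes: Mapping[str, DuplicatedGeneSpec],
) -> list[str]:
    """Second filter step: keep a distorted pair only if some founder is
    nonfunctional at copy 1 and some founder (possibly another) is
    nonfunctional at copy 2 — i.e., a cross could actually produce a
    zero-functional genotype."""
    kept = []
    for family_id in screened_families:
        gene = genes.get(family_id)
        if gene is None or len(gene.copies) < 2:
            # no founder functional annotation -> cannot be confirmed
            continue
        c1, c2 = gene.copies[0].copy_id, gene.copies[1].copy_id
        nonfunc1 = any(
            states[c1] != "functional" for states in gene.founder_states.values()
        )
        nonfunc2 = any(
            states[c2] != "functional" for states in gene.founder_states.values()
        )
        if nonfunc1 and nonfunc2:
            kept.append(family_id)
    return kept
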