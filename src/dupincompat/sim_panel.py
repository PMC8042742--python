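"""Synthetic accession panels for the downstream callers.

The generator emulates the structure of a large inbred-accession panel the
way the GWA and functional-calling stages consume it: per-accession
functional states of each gene copy (functional / lof / silenced / absent)
drawn from configurable haplotype frequencies, loss-of-function variant
evidence in DNA and RNA (with the RNA signal vanishing for variants on a
silenced copy — the pseudoheterozygous contrast), bimodal promoter
methylation reports, copy-number-scaled coverage tracks against a
single-copy reference, and a structured genome-wide marker matrix
(discrete subpopulations diverged by a Balding-Nichols drift parameter)
for kinship estimation.

Accessions are treated as fully inbred: one haplotype per copy, dosages in
{0, 2}. An accession with zero functional copies among the reference-family
copies is viable only because of a rescuing modifier copy, so such
accessions are always modifier carriers; other accessions carry the
modifier with the configured background frequency. Modifier carriers share
a local haplotype at a dedicated marker window (the mappable signal) and an
increased total copy number (the coverage signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .copynum import CoverageTrack
from .genome import COPY_STATES, DuplicatedGeneSpec, GeneModel

__all__ = [
    "AccessionPanelConfig",
    "PanelBundle",
    "synthetic_gene_model",
    "simulate_accession_panel",
]

BASES = np.array(list("ACGT"))


def synthetic_gene_model(
    gene_id: str,
    chromosome: str,
    rng: np.random.Generator,
    tss_bp: int = 1001,
    n_exons: int = 2,
    exon_bp: int = 300,
    intron_bp: int = 120,
    strand: str = "+",
) -> GeneModel:
    """A small random gene model with a valid ORF-bearing sequence."""
    segs = []
    pos = tss_bp
    for _ in range(n_exons):
        segs.append((pos, pos + exon_bp - 1))
        pos += exon_bp + intron_bp
    tes = segs[-1][1]
    start, end = tss_bp, tes
    seq = rng.choice(BASES, size=end - start + 1)
    # plant a clean ORF: ATG at the CDS start, no internal stops, TAA at end
    cds_pos = [p for s, e in segs for p in range(s, e + 1)]
    codons = ["ATG"]
    sense = ["GCT", "GGT", "CCA", "ACT", "GAA", "TGG", "TTC", "AAG"]
    n_codons = len(cds_pos) // 3
    for _ in range(n_codons - 2):
        codons.append(sense[rng.integers(len(sense))])
    codons.append("TAA")
    coding = "".join(codons)
    for p, base in zip(cds_pos, coding):
        seq[p - start] = base
    # trim CDS to a multiple of 3
    extra = len(cds_pos) - 3 * n_codons
    if extra:
        s, e = segs[-1]
        segs[-1] = (s, e - extra)
        tes = segs[-1][1]
    return GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        strand=strand,
        tss_bp=tss_bp,
        tes_bp=tes,
        cds_segments=segs,
        sequence="".join(seq[: tes - start + 1]),
    )


@dataclass
class AccessionPanelConfig:
    """Study conditions for one synthetic accession panel.

    copy_state_freqs maps copy_id -> {state: frequency}; states omitted
    default to the remaining mass on ``functional``. Frequencies must not
    exceed 1 per copy.
    """

    n_accessions: int = 300
    n_subpopulations: int = 3
    divergence: float = 0.1  # Balding-Nichols F between subpopulations
    n_markers: int = 5000
    copy_state_freqs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    modifier_frequency: float = 0.10
    modifier_extra_copies: int = 1
    # marker index window tagging the modifier locus; None = a 20-marker
    # window at the centre of the panel
    modifier_region: tuple[int, int] | None = None
    modifier_marker_noise: float = 0.02
    meth_mean_high: float = 0.8
    meth_mean_low: float = 0.05
    meth_concentration: float = 50.0  # Beta concentration; higher = tighter
    reads_per_window: int = 20
    dna_error: float = 0.0
    rna_error: float = 0.0
    depth_mean: float = 30.0
    region_bp: int = 2000
    generate_methylation: bool = True
    generate_coverage: bool = True

    def validate(self, gene: DuplicatedGeneSpec) -> None:
        if self.n_accessions <= 0 or self.n_markers <= 0:
            raise ValueError("n_accessions and n_markers must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        lo, hi = self.resolved_modifier_region()
        if not (0 <= lo < hi <= self.n_markers):
            raise ValueError("modifier_region must be a valid marker window")
        for copy in gene.copies:
            freqs = self.copy_state_freqs.get(copy.copy_id, {})
            for state, f in freqs.items():
                if state not in COPY_STATES:
                    raise ValueError(f"unknown state {state!r}")
                if not 0.0 <= f <= 1.0:
                    raise ValueError("frequencies must be in [0, 1]")
            if sum(freqs.values()) > 1.0 + 1e-9:
                raise ValueError(
                    f"state frequencies for {copy.copy_id} sum above 1"
                )

    def resolved_modifier_region(self) -> tuple[int, int]:
        if self.modifier_region is not None:
            return self.modifier_region
        width = min(20, max(1, self.n_markers // 10))
        lo = max(0, self.n_markers // 2 - width // 2)
        return lo, min(self.n_markers, lo + width)


@dataclass
class PanelBundle:
    """Everything the downstream stages consume, plus truth labels."""

    truth: pd.DataFrame  # accessions x copies, state strings
    modifier: pd.Series  # bool per accession
    groups: pd.Series  # subpopulation label per accession
    markers: pd.DataFrame  # accessions x markers, dosage 0/2
    models: dict[str, GeneModel]
    variants: pd.DataFrame  # variant_id -> copy_id (the copy it sits on)
    dna_presence: pd.DataFrame  # accessions x variants, bool
    rna_presence: pd.DataFrame  # accessions x variants, bool
    methylation_reports: dict[str, dict[str, pd.DataFrame]]  # copy -> acc -> report
    coverage_tracks: dict[str, CoverageTrack]  # accession -> family-region track


def _sample_states(
    copy_id: str, config: AccessionPanelConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    freqs = dict(config.copy_state_freqs.get(copy_id, {}))
    freqs.setdefault("functional", max(0.0, 1.0 - sum(freqs.values())))
    states = list(freqs)
    p = np.array([freqs[s] for s in states], dtype=float)
    p = p / p.sum()
    return rng.choice(states, size=n, p=p)


def _methylation_report(
    model: GeneModel,
    hypermethylated: bool,
    config: AccessionPanelConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One accession's cytosine report over a gene's window span: one pooled
    record per 100-bp window and context."""
    from .functional import PROMOTER_UPSTREAM, WINDOW_BP, window_grid

    n_win = window_grid(model)
    mean = config.meth_mean_high if hypermethylated else config.meth_mean_low
    k = config.meth_concentration
    rows = []
    origin = (
        model.tss_bp - PROMOTER_UPSTREAM
        if model.strand == "+"
        else model.tss_bp + PROMOTER_UPSTREAM
    )
    step = WINDOW_BP if model.strand == "+" else -WINDOW_BP
    for w in range(n_win):
        pos = origin + w * step + step // 2
        for ctx in ("CG", "CHG", "CHH"):
            frac = rng.beta(mean * k, (1 - mean) * k)
            total = config.reads_per_window
            meth = int(rng.binomial(total, frac))
            rows.append(
                {
                    "chrom": model.chromosome,
                    "pos": int(pos),
                    "strand": model.strand,
                    "context": ctx,
                    "count_methylated": meth,
                    "count_total": total,
                }
            )
    return pd.DataFrame(rows)


def _structured_markers(
    config: AccessionPanelConfig,
    groups: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inbred dosages (0/2) with Balding-Nichols subpopulation structure."""
    f = config.divergence
    base = rng.uniform(0.05, 0.95, size=config.n_markers)
    dosage = np.zeros((config.n_accessions, config.n_markers), dtype=np.int8)
    for g in np.unique(groups):
        mask = groups == g
        if f > 0:
            a = base * (1 - f) / f
            b = (1 - base) * (1 - f) / f
            pg = rng.beta(a, b)
        else:
            pg = base
        draws = rng.random((mask.sum(), config.n_markers)) < pg
        dosage[mask] = 2 * draws.astype(np.int8)
    return dosage


def simulate_accession_panel(
    config: AccessionPanelConfig,
    gene: DuplicatedGeneSpec,
    rng: np.random.Generator,
) -> PanelBundle:
    """Generate one accession panel for a duplicated gene family.

    ``gene`` supplies the family's copies (their ids and coordinates); the
    per-copy state frequencies come from the config. Gene models and
    per-copy tag LoF variants are synthesized internally.
    """
    config.validate(gene)
    n = config.n_accessions
    accessions = [f"acc{i:04d}" for i in range(n)]
    copy_ids = [c.copy_id for c in gene.copies]

    truth = pd.DataFrame(
        {cid: _sample_states(cid, config, n, rng) for cid in copy_ids},
        index=accessions,
    )

    # viability: zero functional copies over the family forces a modifier
    functional_any = (truth == "functional").any(axis=1)
    modifier = pd.Series(
        rng.random(n) < config.modifier_frequency, index=accessions
    )
    modifier[~functional_any] = True

    groups = pd.Series(
        [f"pop{g}" for g in rng.integers(config.n_subpopulations, size=n)],
        index=accessions,
    )
    dosage = _structured_markers(config, groups.to_numpy(), rng)
    lo, hi = config.resolved_modifier_region()
    carrier = modifier.to_numpy()
    region = np.repeat(2 * carrier.astype(np.int8)[:, None], hi - lo, axis=1)
    flip = rng.random(region.shape) < config.modifier_marker_noise
    region = np.where(flip, 2 - region, region)
    dosage[:, lo:hi] = region
    markers = pd.DataFrame(
        dosage,
        index=accessions,
        columns=[f"m{j:05d}" for j in range(config.n_markers)],
    )

    models = {
        c.copy_id: synthetic_gene_model(
            c.copy_id, c.chromosome, rng, tss_bp=c.tss_bp or 1001, strand=c.strand
        )
        for c in gene.copies
    }

    # one characteristic LoF tag variant per copy; carried in DNA by
    # accessions whose copy state is 'lof', and by half of the 'silenced'
    # carriers (silenced copies accumulate variants that never show in RNA)
    variants = pd.DataFrame(
        {"copy_id": copy_ids}, index=[f"LoF-{cid}" for cid in copy_ids]
    )
    dna = pd.DataFrame(False, index=accessions, columns=variants.index)
    rna = pd.DataFrame(False, index=accessions, columns=variants.index)
    for vid, copy_id in variants["copy_id"].items():
        state = truth[copy_id]
        on_lof = (state == "lof").to_numpy()
        on_sil = (state == "silenced").to_numpy() & (rng.random(n) < 0.5)
        dna_present = on_lof | on_sil
        rna_present = on_lof  # lof copies are expressed; silenced are not
        if config.dna_error > 0:
            dna_present ^= rng.random(n) < config.dna_error
        if config.rna_error > 0:
            rna_present ^= rng.random(n) < config.rna_error
        dna[vid] = dna_present
        rna[vid] = rna_present & dna[vid].to_numpy()

    meth_reports: dict[str, dict[str, pd.DataFrame]] = {}
    if config.generate_methylation:
        for cid in copy_ids:
            meth_reports[cid] = {
                acc: _methylation_report(
                    models[cid], truth.loc[acc, cid] == "silenced", config, rng
                )
                for acc in accessions
            }

    # coverage over a single-copy reference region: depth scales with the
    # accession's total family copy number
    tracks: dict[str, CoverageTrack] = {}
    if config.generate_coverage:
        present = (truth != "absent").sum(axis=1)
        total_copies = present + config.modifier_extra_copies * modifier.astype(int)
        for acc in accessions:
            depth = rng.poisson(
                config.depth_mean * int(total_copies[acc]), size=config.region_bp
            )
            tracks[acc] = CoverageTrack(
                chrom="ref_region",
                start=0,
                end=config.region_bp,
                depths=depth.astype(float),
                genome_mean_depth=config.depth_mean,
            )

    return PanelBundle(
        truth=truth,
        modifier=modifier,
        groups=groups,
        markers=markers,
        models=models,
        variants=variants,
        dna_presence=dna,
        rna_presence=rna,
        methylation_reports=meth_reports,
        coverage_tracks=tracks,
    )
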