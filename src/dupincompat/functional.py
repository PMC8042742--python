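"""Functional-allele calling for duplicated gene copies in accession panels.

A gene copy in an accession is called ``functional``, ``lof`` (disrupted by
a loss-of-function variant), ``silenced`` (hypermethylated promoter),
``absent`` (deleted by coverage evidence) or ``unknown`` (conflicting
evidence). The binary GWAS phenotype is derived from this matrix: presence
(1) or absence (0) of any functional copy, or of the designated reference
copy for families with a single reference-genome copy.

Variant effects use a minimal loss-of-function taxonomy over single-gene
models: start/stop codon loss, premature stop gain, splice-site damage
(+-2 bp of an intron boundary), frameshift indels, and whole-CDS-segment
loss. Promoter/gene-body methylation profiles (percent methylated cytosines
per 100-bp window and per CG/CHG/CHH context, from 500 bp upstream of the
TSS to 300 bp downstream of the TES, strand-aware) are Ward-clustered into
two groups per cohort; the group with the higher mean promoter CG
methylation is labelled hypermethylated.

Pseudoheterozygous variants — apparent heterozygous calls created by reads
from two near-identical copies piling onto one locus — are disambiguated
with an expression contrast: a variant present in DNA but absent in RNA is
assigned to the (single) silenced copy; one present in both is assigned to
the expressed copy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.cluster.hierarchy import fcluster, linkage

from .genome import GeneModel

__all__ = [
    "Variant",
    "EFFECTS",
    "classify_variant_effect",
    "window_grid",
    "profile_methylation",
    "methylation_profile_matrix",
    "impute_profile_matrix",
    "cluster_methylation_profiles",
    "assign_pseudohet_variant",
    "build_functional_matrix",
    "phenotype_from_matrix",
]

EFFECTS = (
    "start_lost",
    "stop_lost",
    "stop_gained",
    "splice_damage",
    "frameshift",
    "cds_loss",
    "none",
)

WINDOW_BP = 100
PROMOTER_UPSTREAM = 500
DOWNSTREAM = 300


@dataclass(frozen=True)
class Variant:
    """A homozygous small variant (1-based position, VCF-style ref/alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def end(self) -> int:
        """Last reference base touched (1-based inclusive)."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _coding_positions(model: GeneModel) -> list[int]:
    """Genomic positions of coding bases in translation order."""
    segs = sorted(model.cds_segments)
    pos = [p for s, e in segs for p in range(s, e + 1)]
    return pos[::-1] if model.strand == "-" else pos


def _cds_sequence(model: GeneModel) -> str:
    if model.sequence is None:
        raise ValueError(f"{model.gene_id}: sequence required for codon analysis")
    offset = model.start_bp
    bases = [model.sequence[p - offset] for p in sorted(
        p for s, e in sorted(model.cds_segments) for p in range(s, e + 1)
    )]
    seq = "".join(bases)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _intron_edges(model: GeneModel) -> list[int]:
    """Genomic positions within 2 bp of an intron boundary (donor/acceptor)."""
    segs = sorted(model.cds_segments)
    edges: list[int] = []
    for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
        intron_start, intron_end = e1 + 1, s2 - 1
        if intron_start > intron_end:
            continue
        edges.extend(
            p
            for p in range(intron_start, min(intron_start + 2, intron_end + 1))
        )
        edges.extend(
            p for p in range(max(intron_end - 1, intron_start), intron_end + 1)
        )
    return edges


def _mutated_spliced_cds(model: GeneModel, variant: Variant) -> str:
    """Spliced coding sequence after applying the variant, mapping the CDS
    segment coordinates through any indel shift (VCF anchor convention:
    the first ref base is unchanged for indels)."""
    if model.sequence is None:
        raise ValueError(f"{model.gene_id}: sequence required for codon analysis")
    offset = model.start_bp
    seq = list(model.sequence)
    i = variant.pos - offset
    seq[i : i + len(variant.ref)] = list(variant.alt)
    shift = len(variant.alt) - len(variant.ref)
    parts = []
    for s, e in sorted(model.cds_segments):
        a, b = s - offset, e - offset
        if shift >= 0:
            a2 = a if a <= i else a + shift
            b2 = b if b < i else b + shift
        else:
            def removed_before(x: int) -> int:
                return min(max(x - i, 0), -shift)

            a2 = a - removed_before(a)
            b2 = b - removed_before(b)
        parts.append("".join(seq[a2 : b2 + 1]))
    out = "".join(parts)
    if model.strand == "-":
        out = str(Seq(out).reverse_complement())
    return out


def classify_variant_effect(variant: Variant, model: GeneModel) -> str:
    """Classify a variant's loss-of-function effect on one gene model.

    Returns one of :data:`EFFECTS`; a variant outside the gene span is
    ``none`` (not an error). Precedence: start_lost, stop_lost, cds_loss
    (a deletion spanning a whole CDS segment), splice_damage, frameshift
    (CDS length change not divisible by 3), stop_gained (a premature stop
    in the spliced, mutated coding sequence), else none.
    """
    if variant.chrom != model.chromosome:
        return "none"
    if variant.end < model.start_bp or variant.pos > model.end_bp:
        return "none"

    coding = _coding_positions(model)
    var_span = set(range(variant.pos, variant.end + 1))
    if var_span & set(coding[:3]):
        return "start_lost"
    if var_span & set(coding[-3:]):
        return "stop_lost"
    if len(variant.ref) > len(variant.alt):
        for s, e in model.cds_segments:
            if variant.pos <= s and variant.end >= e:
                return "cds_loss"
    if var_span & set(_intron_edges(model)):
        return "splice_damage"

    coding_set = set(coding)
    if not var_span & coding_set:
        return "none"

    original = _cds_sequence(model)
    mutated = _mutated_spliced_cds(model, variant)
    if len(mutated) % 3 != len(original) % 3:
        return "frameshift"
    prot = str(Seq(mutated[: len(mutated) // 3 * 3]).translate())
    if "*" in prot[:-1]:
        return "stop_gained"
    return "none"


# ---------------------------------------------------------------------------
# Methylation profiles
# ---------------------------------------------------------------------------


def window_grid(model: GeneModel) -> int:
    """Number of 100-bp windows from TSS-500 to TES+300 (transcription
    direction)."""
    span = abs(model.tes_bp - model.tss_bp) + 1 + PROMOTER_UPSTREAM + DOWNSTREAM
    return int(np.ceil(span / WINDOW_BP))


def _window_offset(model: GeneModel, pos: np.ndarray) -> np.ndarray:
    """Transcription-direction offset of genomic positions from TSS-500."""
    if model.strand == "+":
        return pos - (model.tss_bp - PROMOTER_UPSTREAM)
    return (model.tss_bp + PROMOTER_UPSTREAM) - pos


def profile_methylation(report: pd.DataFrame, model: GeneModel) -> pd.Series:
    """Window x context percent-methylation profile for one accession.

    ``report`` columns: chrom, pos (1-based), strand, context (CG/CHG/CHH),
    count_methylated, count_total. Windows with no covered cytosine are
    NaN (imputed later, before clustering). The result is indexed by
    (window, context).
    """
    if model.tss_bp is None or model.tes_bp is None:
        raise ValueError("gene model lacks TSS/TES")
    n_win = window_grid(model)
    contexts = ("CG", "CHG", "CHH")
    idx = pd.MultiIndex.from_product(
        [range(n_win), contexts], names=["window", "context"]
    )
    out = pd.Series(np.nan, index=idx, dtype=float)
    sub = report[report["chrom"] == model.chromosome]
    if sub.empty:
        return out
    offset = _window_offset(model, sub["pos"].to_numpy())
    span = n_win * WINDOW_BP
    keep = (offset >= 0) & (offset < span)
    sub = sub.loc[keep].assign(window=offset[keep] // WINDOW_BP)
    grouped = sub.groupby(["window", "context"])[["count_methylated", "count_total"]].sum()
    covered = grouped["count_total"] > 0
    pct = 100.0 * grouped.loc[covered, "count_methylated"] / grouped.loc[covered, "count_total"]
    out.loc[pct.index] = pct.to_numpy()
    return out


def methylation_profile_matrix(
    reports: Mapping[str, pd.DataFrame], model: GeneModel
) -> pd.DataFrame:
    """Stack per-accession profiles into an accessions x (window, context)
    matrix with a window grid identical across accessions."""
    rows = {acc: profile_methylation(rep, model) for acc, rep in reports.items()}
    return pd.DataFrame(rows).T


def impute_profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Fill missing windows with the accession-wise context mean (falling
    back to 0 when an accession has no covered window in a context)."""
    out = profiles.copy()
    contexts = out.columns.get_level_values("context")
    for ctx in pd.unique(contexts):
        cols = out.columns[contexts == ctx]
        block = out[cols]
        means = block.mean(axis=1)
        out[cols] = block.apply(lambda col: col.fillna(means))
    return out.fillna(0.0)


def _promoter_cg_columns(profiles: pd.DataFrame) -> pd.Index:
    n_prom = PROMOTER_UPSTREAM // WINDOW_BP
    win = profiles.columns.get_level_values("window")
    ctx = profiles.columns.get_level_values("context")
    return profiles.columns[(win < n_prom) & (ctx == "CG")]


def cluster_methylation_profiles(
    profiles: pd.DataFrame,
    cohorts: pd.Series | None = None,
) -> pd.Series:
    """Two-group Ward clustering of methylation profiles.

    Pairwise Euclidean distances over the concatenated window x context
    vectors; Ward linkage; tree cut at two groups; the group with higher
    mean promoter-region CG methylation is labelled ``hypermethylated``.
    Cohorts from different processing pipelines are clustered separately.
    All-identical profiles yield a single group, all ``unmethylated``, with
    a warning.
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs at least two accessions")
    filled = impute_profile_matrix(profiles)
    labels = pd.Series(index=profiles.index, dtype=object)
    if cohorts is None:
        cohorts = pd.Series("all", index=profiles.index)
    for _, members in cohorts.groupby(cohorts).groups.items():
        block = filled.loc[members]
        x = block.to_numpy()
        if len(block) < 2 or np.allclose(x, x[0]):
            warnings.warn(
                "all profiles identical; single group labelled unmethylated"
            )
            labels.loc[members] = "unmethylated"
            continue
        z = linkage(x, method="ward")
        groups = fcluster(z, t=2, criterion="maxclust")
        prom_cols = _promoter_cg_columns(filled)
        means = {
            g: block.loc[groups == g, prom_cols].to_numpy().mean()
            for g in np.unique(groups)
        }
        hyper = max(means, key=means.get)
        labels.loc[members] = np.where(
            groups == hyper, "hypermethylated", "unmethylated"
        )
    return labels


# ---------------------------------------------------------------------------
# Pseudoheterozygous variant assignment and the functional matrix
# ---------------------------------------------------------------------------


def assign_pseudohet_variant(
    in_dna: bool,
    in_rna: bool,
    copy_methylation: Mapping[str, str],
) -> str | None:
    """Assign a pseudoheterozygous variant to one of two candidate copies.

    Present in DNA, absent in RNA, exactly one copy silenced -> the silenced
    copy (its transcript is missing, so its private variant vanishes from
    RNA). Present in DNA and RNA with one copy silenced -> the expressed
    copy. Otherwise unassigned (``None``).
    """
    if len(copy_methylation) != 2:
        raise ValueError("exactly two candidate copies required")
    if not in_dna:
        raise ValueError("not a pseudoheterozygous candidate (absent in DNA)")
    silenced = [c for c, m in copy_methylation.items() if m == "hypermethylated"]
    expressed = [c for c, m in copy_methylation.items() if m != "hypermethylated"]
    if len(silenced) != 1:
        return None  # no expression contrast
    return expressed[0] if in_rna else silenced[0]


def build_functional_matrix(
    lof: pd.DataFrame,
    methylation_labels: pd.DataFrame | None = None,
    present_by_coverage: pd.DataFrame | None = None,
    rna_expressed: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine evidence into an accessions x copies functional-state matrix.

    Evidence precedence per cell: ``absent`` (missing by coverage; demoted
    to ``unknown`` when RNA nevertheless shows expression), else ``lof``
    (an assigned LoF effect), else ``silenced`` (hypermethylated promoter),
    else ``functional``. Accessions lacking methylation data are assumed
    expressed. Returns (matrix, provenance).
    """
    accessions, copies = lof.index, lof.columns
    matrix = pd.DataFrame("functional", index=accessions, columns=copies)
    prov = pd.DataFrame("default", index=accessions, columns=copies)
    for acc in accessions:
        for copy in copies:
            present = (
                bool(present_by_coverage.loc[acc, copy])
                if present_by_coverage is not None
                else True
            )
            if not present:
                expressed = (
                    rna_expressed is not None
                    and bool(rna_expressed.loc[acc, copy])
                )
                if expressed:
                    matrix.loc[acc, copy] = "unknown"
                    prov.loc[acc, copy] = "conflict:absent_but_expressed"
                else:
                    matrix.loc[acc, copy] = "absent"
                    prov.loc[acc, copy] = "coverage"
                continue
            if bool(lof.loc[acc, copy]):
                matrix.loc[acc, copy] = "lof"
                prov.loc[acc, copy] = "lof_variant"
                continue
            label = (
                methylation_labels.loc[acc, copy]
                if methylation_labels is not None
                and acc in methylation_labels.index
                else None
            )
            if isinstance(label, str) and label == "hypermethylated":
                matrix.loc[acc, copy] = "silenced"
                prov.loc[acc, copy] = "methylation"
    return matrix, prov


def phenotype_from_matrix(
    matrix: pd.DataFrame,
    mode: str = "any_copy",
    reference_copy: str | None = None,
) -> pd.Series:
    """Binary phenotype (presence of function = 1) from the matrix.

    ``any_copy``: 1 iff at least one copy is functional among the known
    (non-``unknown``) copies. ``reference_copy``: 1 iff the designated
    reference copy is functional.
    """
    if mode == "any_copy":
        return (matrix == "functional").any(axis=1).astype(int)
    if mode == "reference_copy":
        if reference_copy is None:
            raise ValueError("reference_copy mode requires a copy id")
        return (matrix[reference_copy] == "functional").astype(int)
    raise ValueError(f"unknown mode {mode!r}")
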