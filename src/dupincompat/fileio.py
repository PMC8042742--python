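"""Readers and writers for the pipeline's on-disk formats.

Coordinate dialects, fixed package-wide:

* BED / BEDGRAPH (mosaics, blocks, coverage): 0-based, half-open.
* GFF3 (gene models) and VCF (variants): 1-based, inclusive.
* Marker matrices: TSV, rows = individuals, columns = ``chrom:pos`` with a
  1-based display position; dosage 0/1/2, ``NA`` for missing.
* Methylation reports: TSV with columns chrom, pos (1-based), strand,
  context (CG/CHG/CHH), count_methylated, count_total; zero-total rows are
  preserved on round trip and flagged with a log message.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import GeneModel, GenomeMap
from .sim_ril import MISSING, SimulatedIndividual

log = logging.getLogger(__name__)

__all__ = [
    "write_marker_matrix",
    "read_marker_matrix",
    "write_founder_alleles",
    "read_founder_alleles",
    "write_mosaic_bed",
    "write_blocks",
    "read_blocks",
    "write_minimal_vcf",
    "read_minimal_vcf",
    "write_methylation_report",
    "read_methylation_report",
    "write_bedgraph",
    "read_bedgraph",
    "write_gene_models_gff3",
    "read_gene_models_gff3",
]


def _marker_columns(genome: GenomeMap) -> list[str]:
    return [
        f"{chrom}:{pos + 1}"
        for chrom, positions in genome.markers.items()
        for pos in positions
    ]


def write_marker_matrix(
    path: str | Path,
    individuals: list[SimulatedIndividual],
    genome: GenomeMap,
    ids: list[str] | None = None,
) -> None:
    cols = _marker_columns(genome)
    rows = []
    for ind in individuals:
        vals = np.concatenate([ind.observed[c] for c in genome.markers])
        rows.append(vals)
    ids = ids or [f"RIL{i:04d}" for i in range(len(individuals))]
    df = pd.DataFrame(rows, index=ids, columns=cols).astype(float)
    df = df.replace(MISSING, np.nan)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="individual")


def read_marker_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="individual", na_values="NA")
    return df


def write_founder_alleles(
    path: str | Path,
    founder_alleles: dict[str, dict[str, np.ndarray]],
    genome: GenomeMap,
) -> None:
    cols = _marker_columns(genome)
    rows = {
        f: np.concatenate([alleles[c] for c in genome.markers])
        for f, alleles in founder_alleles.items()
    }
    pd.DataFrame(rows, index=cols).T.to_csv(
        path, sep="\t", index_label="founder", header=True
    )


def read_founder_alleles(
    path: str | Path,
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """Returns (founder -> chrom -> allele vector, chrom -> positions)."""
    df = pd.read_csv(path, sep="\t", index_col="founder")
    chroms: dict[str, list[int]] = {}
    for col in df.columns:
        chrom, pos = col.rsplit(":", 1)
        chroms.setdefault(chrom, []).append(int(pos) - 1)
    positions = {c: np.asarray(p, dtype=np.int64) for c, p in chroms.items()}
    out: dict[str, dict[str, np.ndarray]] = {}
    for founder in df.index:
        out[founder] = {}
        i = 0
        for chrom, pos in positions.items():
            out[founder][chrom] = df.loc[founder].to_numpy()[i : i + len(pos)].astype(np.int8)
            i += len(pos)
    return out, positions


def write_mosaic_bed(
    path: str | Path, individuals: list[SimulatedIndividual], ids: list[str] | None = None
) -> None:
    """Truth mosaics as BED: chrom, start, end, founder, individual, homolog."""
    ids = ids or [f"RIL{i:04d}" for i in range(len(individuals))]
    rows = []
    for name, ind in zip(ids, individuals):
        for h, hap in enumerate(ind.mosaic):
            for chrom, segments in hap.items():
                for start, end, founder in segments:
                    rows.append((chrom, start, end, founder, name, h))
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "founder", "individual", "homolog"]
    ).to_csv(path, sep="\t", index=False)


def write_blocks(path: str | Path, blocks: pd.DataFrame) -> None:
    blocks.to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"block file missing columns {required - set(df.columns)}")
    return df


def write_minimal_vcf(path: str | Path, records: pd.DataFrame, contigs: dict[str, int]) -> None:
    """Minimal VCF v4.2. ``records`` columns: chrom, pos (1-based), id, ref,
    alt; optional info (string)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contigs.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in records.iterrows():
            info = r.get("info", ".") if "info" in records.columns else "."
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t{r.get('id', '.')}\t"
                f"{r['ref']}\t{r['alt']}\t.\t.\t{info or '.'}\n"
            )


def read_minimal_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "id": rec.id or ".",
                    "ref": rec.ref,
                    "alt": ",".join(rec.alts or ()),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])


METHYLATION_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_total"]


def write_methylation_report(path: str | Path, report: pd.DataFrame) -> None:
    report[METHYLATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_methylation_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METHYLATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"methylation report missing columns {missing}")
    bad_ctx = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad_ctx.any():
        line = int(df.index[bad_ctx][0]) + 2  # header + 1-based
        raise ValueError(f"invalid methylation context at line {line}")
    n_zero = int((df["count_total"] == 0).sum())
    if n_zero:
        log.warning("methylation report has %d zero-total rows (kept)", n_zero)
    return df


def write_bedgraph(path: str | Path, chrom: str, start: int, depths: np.ndarray) -> None:
    """Per-base coverage as BEDGRAPH with runs of equal depth merged."""
    depths = np.asarray(depths)
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(depths) + 1):
            if i == len(depths) or depths[i] != depths[run_start]:
                fh.write(
                    f"{chrom}\t{start + run_start}\t{start + i}\t{depths[run_start]:g}\n"
                )
                run_start = i


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "depth"], comment="#"
    )
    if (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0] + 1
        raise ValueError(f"malformed interval at line {bad}")
    return df


def write_gene_models_gff3(path: str | Path, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chromosome}\t.\tgene\t{m.start_bp}\t{m.end_bp}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(m.cds_segments)):
                fh.write(
                    f"{m.chromosome}\t.\tCDS\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}\n"
                )


def read_gene_models_gff3(
    path: str | Path, sequences: dict[str, str] | None = None
) -> list[GeneModel]:
    """Parse gene + CDS features back into gene models; ``sequences`` maps
    gene id -> genomic span sequence (GFF3 itself carries no sequence)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        cds = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="CDS")
        )
        if not cds:
            raise ValueError(f"gene {gene.id} has no CDS features")
        tss = gene.start if gene.strand == "+" else gene.end
        tes = gene.end if gene.strand == "+" else gene.start
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                tss_bp=tss,
                tes_bp=tes,
                cds_segments=cds,
                sequence=(sequences or {}).get(gene.id),
            )
        )
    return models
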