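"""End-to-end pipeline driver.

Chains the stages on simulated data: simulate RIL subpopulations with a
planted duplicated-gene incompatibility -> reconstruct founder mosaics with
the HMM -> distortion scan over the planted pair plus neutral pairs ->
founder-evidence filter -> simulate an accession panel -> call functional
copies -> kinship-corrected GWA of the binary phenotype -> read-depth copy
number. Every artifact is written under the output directory and listed in
a manifest with its SHA-256 checksum, the seed and the parameters, so a
rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import copynum, distortion, fileio, functional, gwas, hmm, sim_panel, sim_ril
from .genome import Chromosome, DuplicatedGeneSpec, GeneCopy, GenomeMap

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "genotype", "distort", "callfunc", "gwas", "cnv")


@dataclass
class RunConfig:
    """Parameters for every stage of the demo pipeline."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # RIL simulation
    founders: tuple[str, str, str, str] = ("An-1", "Col-0", "Cvi-0", "Kyo")
    n_subpopulations: int = 2  # same founder quadruple, merged in the scan
    target_n: int = 90
    selfing_generations: int = 6
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    genetic_length_m: float = 1.0
    markers_per_chromosome: int = 200
    error_rate: float = 0.005
    missing_rate: float = 0.10
    penetrance: float = 1.0
    n_neutral_pairs: int = 5
    # HMM
    hmm_error_rate: float = 0.005
    min_posterior: float = 0.0
    min_markers: int = 2
    # distortion scan
    method: str = "design"
    alpha: float = 0.05
    correction: str | None = "clustered"
    # accession panel + GWA
    n_accessions: int = 200
    n_markers: int = 2000
    phenotype_mode: str | None = "any_copy"
    maf_min: float = 0.05
    miss_max: float = 0.1
    # copy number
    baseline_copies: int = 1
    min_mean_depth: float = 5.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "callfunc" in self.stages and self.phenotype_mode is None:
            raise ValueError("missing required field: phenotype_mode")
        if self.phenotype_mode not in (None, "any_copy", "reference_copy"):
            raise ValueError(f"invalid phenotype_mode {self.phenotype_mode!r}")


def _default_gene(config: RunConfig) -> DuplicatedGeneSpec:
    """A two-copy essential family with reciprocal pseudofunctionalization:
    every founder but the last carries a functional copy 1 and a LoF copy 2;
    the last founder lacks copy 1 and carries a functional copy 2."""
    f = config.founders
    mid = config.chrom_length_bp // 2
    copies = [
        GeneCopy("copy1", "chr1", mid - 1000, mid + 1000, tss_bp=mid - 900),
        GeneCopy("copy2", "chr2", mid - 1000, mid + 1000, tss_bp=mid - 900),
    ]
    states = {
        founder: {"copy1": "functional", "copy2": "lof"} for founder in f[:-1]
    }
    states[f[-1]] = {"copy1": "absent", "copy2": "functional"}
    return DuplicatedGeneSpec(
        family_id="planted",
        copies=copies,
        founder_states=states,
        essential=True,
        penetrance=config.penetrance,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages and return the output manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    artifacts: dict[str, Path] = {}
    state: dict = {}

    def stage(name):
        return name in config.stages

    def require(key: str, stage_name: str):
        if key not in state:
            raise RuntimeError(
                f"stage {stage_name!r} requires output of an earlier stage "
                f"({key}) that was skipped"
            )
        return state[key]

    try:
        if stage("simulate"):
            _run_simulate(config, rng, outdir, artifacts, state)
        if stage("genotype"):
            _run_genotype(config, outdir, artifacts, state, require)
        if stage("distort"):
            _run_distort(config, rng, outdir, artifacts, state, require)
        if stage("callfunc") or stage("gwas") or stage("cnv"):
            state["panel"] = sim_panel.simulate_accession_panel(
                sim_panel.AccessionPanelConfig(
                    n_accessions=config.n_accessions,
                    n_markers=config.n_markers,
                    copy_state_freqs={
                        "copy1": {"lof": 0.4, "silenced": 0.1, "absent": 0.05},
                        "copy2": {"lof": 0.3, "silenced": 0.2},
                    },
                ),
                state.get("gene") or _default_gene(config),
                rng,
            )
        if stage("callfunc"):
            _run_callfunc(config, outdir, artifacts, state, require)
        if stage("gwas"):
            _run_gwas(config, outdir, artifacts, state, require)
        if stage("cnv"):
            _run_cnv(config, outdir, artifacts, state, require)
    except Exception as err:
        log.error("pipeline aborted: %s", err)
        raise

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_simulate(config, rng, outdir, artifacts, state):
    chroms = [
        Chromosome(f"chr{i + 1}", config.chrom_length_bp, config.genetic_length_m)
        for i in range(config.n_chromosomes)
    ]
    markers = {
        c.id: np.linspace(
            0, c.length_bp - 1, config.markers_per_chromosome, dtype=np.int64
        )
        for c in chroms
    }
    genome = GenomeMap(chroms, markers)
    founder_alleles = sim_ril.sample_founder_alleles(genome, config.founders, rng)
    gene = _default_gene(config)
    subpops = {}
    for i in range(config.n_subpopulations):
        label = f"SP{i + 1}"
        design = sim_ril.CrossDesign(
            label,
            config.founders,
            selfing_generations=config.selfing_generations,
            target_n=config.target_n,
        )
        subpops[label] = sim_ril.simulate_subpopulation(
            design,
            founder_alleles,
            [gene],
            genome,
            rng,
            error_rate=config.error_rate,
            missing_rate=config.missing_rate,
        )
        path = outdir / f"markers_{label}.tsv"
        fileio.write_marker_matrix(path, subpops[label], genome)
        artifacts[f"markers_{label}"] = path
        path = outdir / f"mosaic_{label}.bed"
        fileio.write_mosaic_bed(path, subpops[label])
        artifacts[f"mosaic_{label}"] = path
    path = outdir / "founder_alleles.tsv"
    fileio.write_founder_alleles(path, founder_alleles, genome)
    artifacts["founder_alleles"] = path
    state.update(
        genome=genome, founder_alleles=founder_alleles, gene=gene, subpops=subpops
    )


def _run_genotype(config, outdir, artifacts, state, require):
    genome = require("genome", "genotype")
    founder_alleles = require("founder_alleles", "genotype")
    params = hmm.HmmParams(error_rate=config.hmm_error_rate)
    blocks_by_pop = {}
    for label, individuals in state["subpops"].items():
        frames = []
        for i, ind in enumerate(individuals):
            b = hmm.decode_individual(
                ind,
                genome,
                founder_alleles,
                config.founders,
                params,
                min_posterior=config.min_posterior,
                min_markers=config.min_markers,
            )
            b.insert(0, "individual", f"RIL{i:04d}")
            frames.append(b)
        blocks_by_pop[label] = pd.concat(frames, ignore_index=True)
        path = outdir / f"blocks_{label}.tsv"
        fileio.write_blocks(path, blocks_by_pop[label])
        artifacts[f"blocks_{label}"] = path
    state["blocks"] = blocks_by_pop


def _neutral_anchors(config, rng):
    anchors = []
    for i in range(config.n_neutral_pairs):
        pos1 = int(rng.integers(10_000, config.chrom_length_bp - 10_000))
        pos2 = int(rng.integers(10_000, config.chrom_length_bp - 10_000))
        anchors.append(
            distortion.GenePairLocus(f"neutral{i}", ("chr1", pos1), ("chr2", pos2))
        )
    return anchors


def _run_distort(config, rng, outdir, artifacts, state, require):
    blocks_by_pop = require("blocks", "distort")
    gene = state["gene"]
    pairs = [
        distortion.GenePairLocus(
            gene.family_id,
            (gene.copies[0].chromosome, gene.copies[0].midpoint_bp),
            (gene.copies[1].chromosome, gene.copies[1].midpoint_bp),
        )
    ] + _neutral_anchors(config, rng)
    pair_genotypes = {
        p.family_id: {
            label: [
                (
                    distortion.genotype_at_locus(ind_blocks, p.locus1),
                    distortion.genotype_at_locus(ind_blocks, p.locus2),
                )
                for _, ind_blocks in blocks.groupby("individual")
            ]
            for label, blocks in blocks_by_pop.items()
        }
        for p in pairs
    }
    # a genotype pair is unusable if either side is unknown
    for fam, by_pop in pair_genotypes.items():
        for label, genos in by_pop.items():
            by_pop[label] = [
                None if (g1 is None or g2 is None) else (g1, g2)
                for g1, g2 in genos
            ]
    merge = (
        {"merged": list(blocks_by_pop)} if len(blocks_by_pop) > 1 else None
    )
    table = distortion.screen_gene_pairs(
        pair_genotypes,
        merge_groups=merge,
        alpha=config.alpha,
        method=config.method,
        correction=config.correction,
    )
    retained = sorted(set(table.loc[table["retained"], "family_id"]))
    confirmed = distortion.confirm_lof_in_founders(
        retained, {gene.family_id: gene}
    )
    table["confirmed_candidate"] = table["family_id"].isin(confirmed)
    path = outdir / "distortion_scan.tsv"
    table.to_csv(path, sep="\t", index=False)
    artifacts["distortion_scan"] = path
    state["scan"] = table


def _run_callfunc(config, outdir, artifacts, state, require):
    panel = require("panel", "callfunc")
    copy_ids = list(panel.truth.columns)
    labels = {}
    for cid in copy_ids:
        profiles = functional.methylation_profile_matrix(
            panel.methylation_reports[cid], panel.models[cid]
        )
        labels[cid] = functional.cluster_methylation_profiles(profiles)
    meth = pd.DataFrame(labels)
    lof = pd.DataFrame(False, index=panel.truth.index, columns=copy_ids)
    for vid, cid in panel.variants["copy_id"].items():
        in_dna = panel.dna_presence[vid]
        in_rna = panel.rna_presence[vid]
        for acc in panel.truth.index:
            if not in_dna[acc]:
                continue
            assigned = functional.assign_pseudohet_variant(
                True, bool(in_rna[acc]), {c: meth.loc[acc, c] for c in copy_ids}
            )
            if assigned is not None:
                lof.loc[acc, assigned] = True
    present = pd.DataFrame(
        panel.truth != "absent", index=panel.truth.index, columns=copy_ids
    )
    matrix, provenance = functional.build_functional_matrix(
        lof, methylation_labels=meth, present_by_coverage=present
    )
    phenotype = functional.phenotype_from_matrix(
        matrix, mode=config.phenotype_mode, reference_copy=copy_ids[0]
    )
    for name, df in [
        ("functional_matrix", matrix),
        ("functional_provenance", provenance),
        ("phenotype", phenotype.to_frame("phenotype")),
    ]:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index_label="accession")
        artifacts[name] = path
    state["phenotype"] = phenotype


def _run_gwas(config, outdir, artifacts, state, require):
    panel = require("panel", "gwas")
    phenotype = state.get("phenotype")
    if phenotype is None:
        matrix = panel.truth.apply(lambda col: col == "functional")
        phenotype = matrix.any(axis=1).astype(int)
    filtered = gwas.filter_and_impute(
        panel.markers, maf_min=config.maf_min, miss_max=config.miss_max
    )
    k = gwas.compute_kinship(filtered)
    null = gwas.fit_null_mlm(phenotype.to_numpy(), k)
    assoc = gwas.association_scan(
        filtered, phenotype.to_numpy(), null=null, alpha=config.alpha
    )
    path = outdir / "association.tsv"
    assoc.to_csv(path, sep="\t", index=False)
    artifacts["association"] = path
    vc = pd.DataFrame(
        {
            "sigma_g2": [null.sigma_g2],
            "sigma_e2": [null.sigma_e2],
            "threshold_neglog10p": [assoc.attrs["threshold"]],
        }
    )
    path = outdir / "variance_components.tsv"
    vc.to_csv(path, sep="\t", index=False)
    artifacts["variance_components"] = path
    state["assoc"] = assoc


def _run_cnv(config, outdir, artifacts, state, require):
    panel = require("panel", "cnv")
    table = copynum.copy_number_table(
        panel.coverage_tracks,
        baseline_copies_in_reference=config.baseline_copies,
        min_mean_depth=config.min_mean_depth,
    )
    path = outdir / "copy_number.tsv"
    table.to_csv(path, sep="\t")
    artifacts["copy_number"] = path
    state["cnv"] = table
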