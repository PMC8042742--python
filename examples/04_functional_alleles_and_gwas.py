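"""Call functional gene copies in an accession panel and map the modifier.

Simulates a 300-accession panel for a two-copy gene family: loss-of-function
variants, hypermethylated (silenced) promoters, pseudoheterozygous DNA/RNA
evidence, and a rescuing modifier copy tagged by a local marker haplotype.
Clusters the methylation profiles, assigns pseudoheterozygous variants,
builds the functional matrix, derives the binary phenotype, and runs the
kinship-corrected mixed-model association scan.
"""

import numpy as np
import pandas as pd

from dupincompat import (
    AccessionPanelConfig,
    DuplicatedGeneSpec,
    GeneCopy,
    assign_pseudohet_variant,
    association_scan,
    build_functional_matrix,
    cluster_methylation_profiles,
    compute_kinship,
    filter_and_impute,
    phenotype_from_matrix,
    simulate_accession_panel,
)
from dupincompat.functional import methylation_profile_matrix


def main():
    gene = DuplicatedGeneSpec(
        "fam",
        [
            GeneCopy("copy1", "chr1", 1000, 3000, tss_bp=1101),
            GeneCopy("copy2", "chr2", 1000, 3000, tss_bp=1101),
        ],
        {"ref": {"copy1": "functional", "copy2": "functional"}},
    )
    config = AccessionPanelConfig(
        n_accessions=300,
        n_markers=3000,
        generate_coverage=False,
        copy_state_freqs={
            "copy1": {"lof": 0.4, "absent": 0.05},
            "copy2": {"lof": 0.3, "silenced": 0.15},
        },
    )
    rng = np.random.default_rng(3)
    panel = simulate_accession_panel(config, gene, rng)

    # methylation clustering per copy
    meth = pd.DataFrame(
        {
            cid: cluster_methylation_profiles(
                methylation_profile_matrix(
                    panel.methylation_reports[cid], panel.models[cid]
                )
            )
            for cid in panel.truth.columns
        }
    )

    # pseudoheterozygous variant assignment
    lof = pd.DataFrame(False, index=panel.truth.index, columns=panel.truth.columns)
    for vid, cid in panel.variants["copy_id"].items():
        for acc in panel.truth.index:
            if not panel.dna_presence.loc[acc, vid]:
                continue
            assigned = assign_pseudohet_variant(
                True,
                bool(panel.rna_presence.loc[acc, vid]),
                {c: meth.loc[acc, c] for c in panel.truth.columns},
            )
            if assigned is not None:
                lof.loc[acc, assigned] = True

    present = panel.truth != "absent"
    matrix, _ = build_functional_matrix(lof, meth, present)
    phenotype = phenotype_from_matrix(matrix, mode="any_copy")
    print("functional-state matrix (head):")
    print(matrix.head().to_string())
    print(f"\nphenotype: {int(phenotype.sum())} of {len(phenotype)} accessions "
          "retain a functional reference copy (phenotype 1)")

    g = filter_and_impute(panel.markers.astype(float))
    k = compute_kinship(g)
    assoc = association_scan(g, phenotype.to_numpy(), kinship=k)
    top = assoc.nsmallest(5, "p")[["marker", "beta", "p", "neglog10p"]]
    lo, hi = config.resolved_modifier_region()
    print(f"\ntop associated markers (modifier planted at m{lo:05d}-m{hi - 1:05d}):")
    print(top.to_string(index=False))
    print(f"Bonferroni threshold: -log10 p = {assoc.attrs['threshold']:.2f}")
    print(
        "\nPhenotype-0 accessions survive only through the modifier copy, so\n"
        "the strongest association falls inside the planted modifier window."
    )


if __name__ == "__main__":
    main()
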