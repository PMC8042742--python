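# dupincompat

Detection of duplicated-gene genetic incompatibilities and mapping of the
gene copies that rescue them.

When both copies of a duplicated essential gene are independently
pseudofunctionalized in different genotypes — by a loss-of-function (LoF)
mutation, a hypermethylated (silenced) promoter, or outright deletion —
their hybrid offspring can inherit zero functional copies. This is a
Bateson–Dobzhansky–Muller incompatibility between duplicate gene copies:
each parent is healthy, the wrong allele combination is lethal. The package
implements the full computational workflow for finding such
incompatibilities and their modifiers, for geneticists working with
multiparent recombinant inbred line (RIL) populations and resequenced
accession panels:

* **`sim_ril` / `sim_panel`** — forward simulation of diallel multiparent
  RIL subpopulations (F1\* hybrids crossed, single-seed descent to F4/F6,
  embryo-lethality selection with configurable penetrance) and of accession
  panels with structured relatedness, LoF/methylation/expression evidence
  and copy-number-scaled coverage.
* **`hmm`** — founder-haplotype (identity-by-descent) reconstruction from
  noisy biallelic markers with a 10-state forward–backward HMM, including
  residual heterozygous regions, block calling and breakpoints.
* **`distortion`** — the two-step screen: allele-pair counting at unlinked
  duplicated gene pairs (a double homozygote `aabb` contributes 2 to
  o[a,b]; a heterozygous genotype `abbc` contributes 1 each to o[a,b] and
  o[b,c]), per-subpopulation and population-wide χ² tests

      χ² = Σ_{i,j} (o_ij − e_ij)² / e_ij

  with Benjamini–Hochberg FDR, then confirmation that some founder is
  nonfunctional at *both* copies.
* **`functional`** — functional-allele calling per accession × copy from a
  minimal LoF effect classifier (start/stop loss, premature stop,
  splice damage, frameshift, CDS loss), two-group Ward clustering of
  promoter methylation profiles (100-bp windows, CG/CHG/CHH, TSS−500 to
  TES+300), pseudoheterozygous variant assignment by DNA/RNA expression
  contrast, and the binary presence-of-function phenotype.
* **`gwas`** — kinship-corrected association: VanRaden kinship, REML
  variance components by spectral decomposition, EMMAX-style per-marker
  generalized least squares, Bonferroni threshold −log10(α/m).
* **`copynum`** — copy number from normalized coverage ratios (regional
  mean depth / genome-wide mean) and inclusive ≥5× carrier calls.
* **`pipeline` / CLI** — an end-to-end driver (`dupincompat run`) chaining
  simulate → genotype → distort → callfunc → gwas → cnv with a seeded,
  checksummed manifest.

## Worked example

`examples/` contains one short script per capability. The distortion scan
(`examples/02_distortion_scan.py`) simulates two same-founder F6
subpopulations of 90 RILs with one planted fully penetrant incompatibility
and four neutral gene pairs, and prints:

```
family_id population     chi2  df      p      q  retained
  planted        SP1  83.2889  15 0.0001 0.0005      True
  planted        SP2  72.8000  15 0.0009 0.0044      True
  planted     merged 122.7556  15 0.0000 0.0000      True
  planted      whole 122.7556  15 0.0000 0.0000      True
 neutral0        SP1  40.6222  15 0.1403 0.3508     False
 ...
retained at FDR < 0.05: ['planted']
confirmed (nonfunctional allele in both copies): ['planted']
```

The planted pair is flagged in every population (χ² against the
crossing-design expectation, clustered-counts correction, FDR within each
scan family) and survives the founder-evidence filter; neutral pairs do
not. The modifier-mapping example (`examples/04_functional_alleles_and_gwas.py`)
continues the workflow on a 300-accession panel: it clusters methylation
profiles, assigns pseudoheterozygous LoF variants, derives the binary
phenotype (213 of 300 accessions retain a functional reference copy), and
the top associated markers (`m01506`, p = 2.8e-05, …) fall inside the
planted modifier window — the accessions lacking any functional reference
copy all survive through the modifier haplotype.

The Bonferroni threshold for a 238,166-marker panel at α = 0.05 is
−log10(0.05/238166) = 6.68, which `bonferroni_threshold` reproduces.

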