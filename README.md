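# famvarkit

Family-based rare-variant prioritization for multiplex disease pedigrees:
segregation-aware variant-filter cascades, exact nonparametric linkage
(NPL), rare-variant burden tests with permutation nulls, and a
Mendelian-consistent synthetic-study generator to exercise the whole
pipeline end to end.

The package is aimed at statistical geneticists analysing a sequenced
multiplex family — for example a consanguineous pedigree with several
affected relatives — who need to narrow thousands of called variants
down to a handful of credible candidates and then test those candidates
in a case–control cohort.

## What it computes

**Pedigree machinery.** Malécot kinship φ(i,j) and inbreeding F(i) by the
standard recursion (first cousins: φ = 1/16; their child: F = 1/16),
Mendelian-consistency checking of genotype calls, and affected/unaffected
partitions restricted to sequenced members. Consanguinity loops are
represented exactly, not broken.

**Filter cascades.** The coding cascade keeps variants that (a) affect
the protein (HIGH/MODERATE impact), (b) are carried by every sequenced
affected relative and never homozygous-alternate in an unaffected one,
(c) are novel or have reference-panel MAF < 0.01, (d) fall inside the
linkage region, (e) have GERP++ > 3, and (f) PolyPhen2 > 0.8. All
inequalities are strict and a missing annotation fails its stage. The
regulatory cascade instead requires a promoter/strong-enhancer chromatin
state (union over cell lines), the linkage region, segregation under a
dominant *or* recessive model, proximity (±500 kb) to known
disease-associated loci, and the same frequency rule. Each run produces
a per-stage report (n_in → n_out) and the first failing stage per variant.

**Nonparametric linkage.** Inheritance vectors (one bit per meiosis) are
enumerated exactly up to a configurable 20-bit limit. Allele-sharing is
scored with the Whittemore–Halpern statistics
S_pairs (pairwise IBD counts over affected pairs) and
S_all = 2^(−a) Σ_h Π_i b_i(h)!, standardized against their exact
enumeration null. Multipoint inference is a hidden Markov model over
inheritance vectors with Haldane-map transitions
θ = (1 − e^(−2d/100))/2 and founder-allele-frequency emissions.
Standardized scores Z become LODs through the Kong–Cox one-parameter
models: linear, max_δ Σ_f log(1 + δZ_f), and exponential,
max_δ Σ_f [δZ_f − κ_f(δ)] with κ_f the cumulant-generating function of
the family's null statistic; LOD = ℓ(δ̂)/ln 10, δ̂ ≥ 0. Marker QC
(Mendelian errors, MAF < 0.4, founder HWE p < 1e-5, missingness > 5%),
5-per-cM thinning and r² > 0.15 adjacent-LD pruning are included.

**Burden tests.** C-alpha,
T = Σ_i [(y_i − n_i p₀)² − n_i p₀(1−p₀)], and an adaptive sum test that
flips the sign of variants significantly enriched in controls (one-sided
Fisher p < 0.1) before summing per-individual burdens. Both take
significance from phenotype-label permutations with the add-one
estimator p = (1 + #{T* ≥ T}) / (n_perm + 1); the flip selection is
re-run inside every permutation. Allele-count/proportion accounting, an
exact two-sided Fisher test for 2×k tables, and the 2^−ΔΔCt qPCR fold
change round out the module.

**Synthetic studies.** `famvarkit.simulate` generates a complete study
under one seed: the consanguineous template pedigree (first-cousin
founders, nine generation-II siblings with three affected, twelve
generation-III offspring with one affected proband, 4 + 4 sequenced), a
planted causal variant (homozygous-alternate in the affected
generation-II members, heterozygous in the proband), one decoy per
cascade stage that fails exactly that stage, chromatin/locus tracks, a
null marker panel, and a truth table. Every bundle passes Mendelian
checking by construction.

## Worked example

```
$ famvarkit simulate --seed 7 --out-dir demo/sim
wrote 9 files to demo/sim

$ famvarkit filter-coding --vcf demo/sim/coding.vcf --ped demo/sim/family.ped \
      --regions demo/sim/linkage_regions.tsv --out-dir demo/flt
impact: 8 -> 7
segregation: 7 -> 6
frequency: 6 -> 4
linkage_region: 4 -> 3
conservation: 3 -> 2
pathogenicity: 2 -> 1
survivors: 1
```

The simulated study contains eight coding variants: the planted causal
variant and seven decoys. Each stage removes exactly the decoys built to
fail it — two at the frequency stage, because one decoy carries a panel
MAF of 0.06 and a second of 0.03 — and the single survivor is the
planted variant (`demo/flt/coding_variants.tsv` lists the first failing
stage per variant). Re-running with `--maf 0.05` still yields one
survivor: the 0.03-MAF decoy then fails conservation instead. The
regulatory cascade on the same bundle ends at zero survivors, mirroring
a study in which no regulatory candidate withstands all filters:

```
$ famvarkit filter-regulatory --vcf demo/sim/regulatory.vcf --ped demo/sim/family.ped \
      --regions demo/sim/linkage_regions.tsv --bed-chromatin demo/sim/chromatin.bed \
      --bed-loci demo/sim/loci.bed --out-dir demo/reg
regulatory_state: 5 -> 4
linkage_region: 4 -> 3
segregation_AD_or_AR: 3 -> 2
loci_proximity: 2 -> 1
frequency: 1 -> 0
survivors: 0
```

A qPCR fold change, for completeness:

```
$ famvarkit qpcr --ct-target-sample 26.1 --ct-ref-sample 18.4 \
      --ct-target-calibrator 24.9 --ct-ref-calibrator 18.2
{"fold_change": 0.4999999999999988}
```

ΔΔCt = (26.1 − 18.4) − (24.9 − 18.2) = 1.0, so expression is halved.

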