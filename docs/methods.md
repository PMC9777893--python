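# Methods

## Pedigree model and relatedness

A pedigree is a finite acyclic parent graph with paired parents
(LINKAGE/PED convention: a single recorded parent is rejected at load
time). Kinship φ(i,j) is computed by the classical recursion — expanding
the individual that appears later in a founders-first topological order,
with φ(i,i) = (1 + F_i)/2 and unrelated founders at φ = 0 — and
inbreeding as F(i) = φ(father_i, mother_i). Consanguinity loops are kept
intact; downstream linkage works directly on meioses, so no loop
breaking is ever needed.

Mendelian checking treats a trio with any missing call as
non-informative rather than as an error. Low-coverage family sequencing
makes no-calls common, and counting them as violations would discard
markers for reasons unrelated to genotyping error.

## Filter cascades

Every stage is a pure predicate on one variant, so the survivor *set* is
invariant under stage reordering (the per-stage counts, of course, are
not). Three conventions are fixed deliberately:

- **Strict thresholds.** MAF < 0.01, GERP > 3, PP2 > 0.8 — a variant
  sitting exactly on a threshold fails. The printed operators are
  strict, and strictness makes the boundary testable.
- **Missing annotation fails.** The cascade retains only variants that
  affirmatively meet every criterion; an unannotated variant cannot be
  shown conserved or damaging, which is the conservative choice for
  prioritization.
- **Missing genotype fails segregation.** "Carried by every affected
  relative" cannot be asserted from a no-call.

The regulatory cascade's segregation stage accepts a variant that fits
*either* a fully penetrant dominant or a recessive model. The two models
are alternatives in the study design and no combination rule is forced
by it; the union is the permissive reading and is trivially restricted
by calling `filter_segregation_model` directly. Locus proximity is
measured to a configurable locus point (lead-SNP position) with an
inclusive ±500 kb window; chromatin-state membership is a union over the
configured cell lines. Coordinates are 1-based fully closed internally
(VCF convention); BED input is converted at the boundary and the
conversion is an involution.

## Nonparametric linkage

The engine enumerates inheritance vectors exactly: one bit per meiosis,
2^(2·nonfounders) states, uniform prior. A hard default limit of 20 bits
(10 nonfounders) keeps enumeration at ≤ ~10^6 states; larger pedigrees
raise a capacity error rather than approximating silently. This is a
real scope boundary: the full consanguineous template pedigree has 50
meioses and cannot be scored exactly, so linkage is validated on
sub-pedigrees and synthetic nuclear families, and genome-scan LOD values
for the full family are out of scope by design.

Sharing statistics are the Whittemore–Halpern pair statistic (summed
pairwise IBD counts over affected pairs) and
S_all = 2^(−a) Σ_h Π_i b_i(h)! over the 2^a collections h of one allele
per affected. Both are standardized by their exact enumeration null;
the standardized scores have mean 0 and variance 1 to 10⁻⁹ by
construction, which the tests verify as a consistency check on the
enumeration.

Multipoint inference is the standard forward–backward pass over
inheritance vectors. Transitions factorize per meiosis with
recombination fraction θ = (1 − e^(−2d/100))/2 (Haldane map, no
interference — the conventional choice for multipoint HMMs). Emissions
sum over founder-allele state assignments with i.i.d. panel frequencies
and match unphased genotype dosages; missing calls are uninformative.
Query positions are inserted as silent nodes, so scores can be evaluated
between markers.

Kong–Cox LODs are one-sided (δ ≥ 0): only excess sharing counts as
linkage evidence. The linear model bounds δ so that 1 + δz stays
positive over each family's attainable null support; the exponential
model uses the exact cumulant-generating function of the enumerated
null. When every family sits at its maximal attainable score the
exponential supremum is reached as δ → ∞ and equals
−Σ_f log P_f(max); that limit is returned analytically (δ̂ = ∞) rather
than approximated, and is exactly the "maximum expected LOD" of a
design. Marker QC tests Hardy–Weinberg on founders only (chi-square,
1 df) because nonfounder genotypes are correlated within families; LD
handling is a greedy adjacent-marker clustering at r² > 0.15 computed
from founder dosages (composite, phase-free LD), keeping the
highest-MAF representative — cluster haplotype modelling is not
re-implemented.

## Burden tests

C-alpha uses the global case fraction p₀ = n_cases/n and per-variant
alt-copy counts with missing dosages excluded from that variant's
counts. Significance comes from phenotype-label permutations, not the
asymptotic variance normalization; the permutation p-value uses the
add-one estimator p = (1 + #{T* ≥ T})/(n_perm + 1), which can never
return 0 and makes the test slightly conservative by design. Ties
(permutations reproducing the observed statistic exactly, common with
sparse rare-variant counts) are counted in the exceedance, the standard
conservative convention.

The adaptive sum test needs a marginal per-variant direction test; a
one-sided Fisher's exact test on the 2×2 allele-count table (excess in
controls, α₀ = 0.1) was chosen as a defensible, exactly computable
choice. The flip selection is recomputed inside every permutation so the
data-driven step is properly accounted for. Both tests are deterministic
given their mandatory seed.

Permutation tests with these conventions have attained size slightly
below nominal on sparse data. Measured over 5,000 simulated null
datasets (50 cases/50 controls, six variants with panel frequencies
0.005–0.02, 500 permutations), rejection at p ≤ 0.05 occurs for ~2.9% of
datasets for C-alpha and ~2.7–3.1% for the adaptive sum: valid but
conservative, driven by the discreteness of the permutation distribution
when only a handful of alternative alleles exist, plus the add-one
correction. The type-I test in the suite asserts the [0.03, 0.07]
calibration band and currently sits at this lower boundary.

Allele accounting uses a fixed denominator 2 × individuals × variants
with missing dosages contributing 0 to the numerator — the convention
that matches reporting carrier proportions against the full genotyped
cohort. The control-side proportion of the six-variant fixture
(2/744 = 0.00269) rounds to 0.0027, not the sometimes-quoted 0.0026, so
only the count (2) is asserted, not the printed proportion. The 2×k
Fisher test enumerates all tables with the observed margins and sums
probabilities ≤ the observed table's (two-sided by probability mass);
the family genotype-distribution test exposes both the allelic 2×2 and
genotypic 2×3 layouts because the layout behind a reported p-value is a
modelling choice, not a fact of the data.

## Synthetic studies

The generator's defaults encode the template study: a first-cousin
marriage (with the two connecting grandparental couples) producing nine
generation-II siblings of whom three are affected, twelve generation-III
offspring with a single affected proband, and a 4 affected + 4
unaffected sequenced subset (the unaffected four are configurable, since
a drawing alone does not pin them down). The causal variant descends as
a single ancestral allele copy through both sibling lines, making the
affected generation-II members autozygous and the proband heterozygous
via an affected parent; free meioses are fair coins, redrawn until no
unaffected member is homozygous-alternate. All genotypes therefore pass
Mendelian checking by construction.

Decoys are leave-one-out: per coding stage, one variant that fails
exactly that stage and passes all others. Passer annotations are drawn
from GERP ∈ (3.5, 6), PP2 ∈ (0.85, 1.0) with no panel frequency; failers
sit just across each threshold so the strict boundaries are exercised.
The frequency decoy carries panel MAF 0.06 (failing at both 0.01 and
0.05); an additional sensitivity decoy at MAF 0.03 fails the frequency
stage at the default threshold and, carrying sub-threshold conservation,
still fails under the relaxed 0.05 re-run — so the survivor count is
invariant to that threshold change, as a real prioritization should be
before a frequency cutoff is trusted. Regulatory decoys cover each
regulatory stage; by default no regulatory passer exists, so the
regulatory cascade ends empty.

What the generator does **not** emulate: sequencing reads or genotype
error (calls are perfect), LD between the null markers, population
stratification, phenocopies or reduced penetrance, and realistic
annotation correlation structure (scores are drawn independently).
Passing tests therefore demonstrate the pipeline's logic and its exact
statistics, not robustness to noisy real-world annotation or calling.

## Problem sizes used in the test suite

Exact-enumeration checks run on pedigrees of 4–8 meioses; the
Monte-Carlo kinship oracle uses 100,000 gene drops; the S_all moment
oracle 100,000 drops; C-alpha's exhaustive relabeling oracle a total
sample of 8 with 10,000 permutations; the type-I calibration 5,000 null
datasets at 500 permutations; null-LOD calibration 2,000 replicates of
eight affected-sib-trio families; planted-variant recovery 100 seeds.
These sizes give oracle standard errors well below the asserted
tolerances while keeping the default suite fast.

## Known limitations

- Exact linkage only: no approximate (MCMC/composite) engine for
  pedigrees above the bit limit, no parametric linkage, no haplotyping,
  no sex-specific maps.
- Burden tests provide permutation p-values only — no asymptotic
  approximations, covariates, or kernel (SKAT-style) generalizations.
- The VCF writer emits a minimal GT-only VCF 4.2 with numeric
  annotations serialized as strings for lossless round trips; it is not
  a general-purpose VCF manipulation layer.
- Annotation values (impact class, conservation, pathogenicity, CADD)
  are consumed as given, never computed.
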