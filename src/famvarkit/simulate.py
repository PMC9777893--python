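"""Mendelian-consistent synthetic family sequencing studies.

Generates, under a single seed, the full input bundle of a family-based
rare-variant prioritization study: a multiplex pedigree descended from
a first-cousin marriage (the ``paper_family`` template: 9 generation-II
siblings of whom 3 affected, 12 generation-III offspring of whom 1 — the
proband — affected, with 4 affected + 4 unaffected sequenced members), a
planted causal variant (homozygous-alt in the affected gen-II members,
heterozygous in the affected gen-III proband, never homozygous-alt in
an unaffected), decoy variants engineered to fail specific cascade
stages, chromatin-state and disease-locus tracks for the regulatory
cascade, and a null marker panel for linkage machinery.

All genotypes are produced by constrained gene dropping, so every
bundle passes Mendelian checking by construction; the truth table
records which variant is causal and which stage each decoy fails.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .burden import GenotypeMatrix
from .errors import ConfigurationError, DomainError
from .pedigree import (
    AFFECTED,
    FEMALE,
    HET,
    HOM_ALT,
    HOM_REF,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
    write_ped,
)
from .linkage import Marker, write_marker_files
from .variants import (
    ChromatinSegment,
    GenomicInterval,
    VariantRecord,
    write_bed,
    write_vcf,
)

#: the multipoint linkage region used as the default prioritization window
DEFAULT_LINKAGE_REGION = GenomicInterval("chr11", 120_285_603, 127_792_982)

CODING_STAGES = (
    "impact",
    "segregation",
    "frequency",
    "linkage_region",
    "conservation",
    "pathogenicity",
)
REGULATORY_STAGES = (
    "regulatory_state",
    "linkage_region",
    "segregation_AD_or_AR",
    "loci_proximity",
    "frequency",
)


# -- pedigree templates ------------------------------------------------------


def paper_family_pedigree(
    sequenced_unaffected: Sequence[str] = ("II-4", "II-13", "III-1", "III-12"),
) -> Pedigree:
    """The consanguineous multiplex template.

    Two founding great-grandparents have two children who marry in;
    their offspring I-1 and I-2 are first cousins whose marriage
    produces nine generation-II siblings (II-6, II-11, II-15 affected).
    Twelve generation-III offspring follow; only III-5 (the proband) is
    affected.  Sequenced members: the four affected plus four
    configurable unaffected relatives.
    """
    inds: list[Individual] = []

    def add(iid, sex, father=None, mother=None, affection=UNAFFECTED, label=None):
        inds.append(
            Individual(
                id=iid,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affection=affection,
                sequenced=False,
                generation_label=label or iid,
            )
        )

    # founding couple and the two sibling lines creating the cousin marriage
    add("A0", MALE)
    add("B0", FEMALE)
    add("S1", MALE, "A0", "B0")
    add("S2", FEMALE, "A0", "B0")
    add("S1w", FEMALE)
    add("S2h", MALE)
    add("I-1", MALE, "S1", "S1w")
    add("I-2", FEMALE, "S2h", "S2")

    gen2_sibs = [
        ("II-2", FEMALE, UNAFFECTED),
        ("II-4", FEMALE, UNAFFECTED),
        ("II-6", FEMALE, AFFECTED),
        ("II-8", MALE, UNAFFECTED),
        ("II-11", MALE, AFFECTED),
        ("II-13", FEMALE, UNAFFECTED),
        ("II-15", FEMALE, AFFECTED),
        ("II-16", MALE, UNAFFECTED),
        ("II-18", FEMALE, UNAFFECTED),
    ]
    for iid, sex, aff in gen2_sibs:
        add(iid, sex, "I-1", "I-2", aff)
    # married-in spouses of the gen-II sibs with offspring
    add("II-1", MALE)
    add("II-5", MALE)
    add("II-7", MALE)
    add("II-12", FEMALE)
    add("II-14", MALE)

    gen3 = [
        ("III-1", MALE, "II-1", "II-2", UNAFFECTED),
        ("III-2", FEMALE, "II-1", "II-2", UNAFFECTED),
        ("III-3", MALE, "II-1", "II-2", UNAFFECTED),
        ("III-4", FEMALE, "II-5", "II-4", UNAFFECTED),
        ("III-5", MALE, "II-7", "II-6", AFFECTED),
        ("III-6", FEMALE, "II-7", "II-6", UNAFFECTED),
        ("III-7", MALE, "II-11", "II-12", UNAFFECTED),
        ("III-8", FEMALE, "II-11", "II-12", UNAFFECTED),
        ("III-9", MALE, "II-14", "II-13", UNAFFECTED),
        ("III-10", FEMALE, "II-14", "II-13", UNAFFECTED),
        ("III-11", MALE, "II-14", "II-13", UNAFFECTED),
        ("III-12", FEMALE, "II-14", "II-13", UNAFFECTED),
    ]
    for iid, sex, father, mother, aff in gen3:
        add(iid, sex, father, mother, aff)

    sequenced = set(sequenced_unaffected) | {"II-6", "II-11", "II-15", "III-5"}
    out = []
    for ind in inds:
        if ind.id in sequenced:
            if ind.id in sequenced_unaffected and ind.affection != UNAFFECTED:
                raise ConfigurationError(
                    f"{ind.id!r} is not unaffected; cannot designate as sequenced control"
                )
            out.append(
                Individual(
                    id=ind.id,
                    father_id=ind.father_id,
                    mother_id=ind.mother_id,
                    sex=ind.sex,
                    affection=ind.affection,
                    sequenced=True,
                    generation_label=ind.generation_label,
                )
            )
        else:
            out.append(ind)
    return Pedigree(out)


def sib_trio_pedigree(n_affected: int = 3, n_sibs: int = 3) -> Pedigree:
    """Nuclear family with ``n_sibs`` sequenced children, first ``n_affected`` affected."""
    if n_affected > n_sibs:
        raise ConfigurationError("n_affected cannot exceed n_sibs")
    inds = [
        Individual(id="F", sex=MALE),
        Individual(id="M", sex=FEMALE),
    ]
    for k in range(n_sibs):
        inds.append(
            Individual(
                id=f"C{k + 1}",
                father_id="F",
                mother_id="M",
                sex=MALE if k % 2 == 0 else FEMALE,
                affection=AFFECTED if k < n_affected else UNAFFECTED,
                sequenced=True,
            )
        )
    return Pedigree(inds)


def sib_pair_pedigree() -> Pedigree:
    """Affected sib pair with unaffected parents."""
    return sib_trio_pedigree(n_affected=2, n_sibs=2)


# -- gene dropping -----------------------------------------------------------


def drop_descent(
    ped: Pedigree, seed: int, n_drops: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gene dropping of founder-allele labels.

    Returns (pat, mat) integer arrays of shape (n_drops, n_members) in
    ``ped.members`` order; founder f carries labels (2f, 2f+1).
    """
    rng = np.random.default_rng(seed)
    members = ped.members
    idx = {m: i for i, m in enumerate(members)}
    founder_index = {f: k for k, f in enumerate(ped.founders)}
    pat = np.empty((n_drops, len(members)), dtype=np.int32)
    mat = np.empty((n_drops, len(members)), dtype=np.int32)
    for m in members:
        i = idx[m]
        ind = ped.individuals[m]
        if ind.is_founder:
            f = founder_index[m]
            pat[:, i] = 2 * f
            mat[:, i] = 2 * f + 1
        else:
            fi, mi = idx[ind.father_id], idx[ind.mother_id]
            pick_p = rng.integers(0, 2, n_drops)
            pick_m = rng.integers(0, 2, n_drops)
            pat[:, i] = np.where(pick_p == 0, pat[:, fi], mat[:, fi])
            mat[:, i] = np.where(pick_m == 0, pat[:, mi], mat[:, mi])
    return pat, mat


def gene_drop(ped: Pedigree, founder_freq: float, seed: int) -> dict[str, str]:
    """Drop one biallelic variant through the pedigree.

    Founder alleles are drawn i.i.d. alt with probability
    ``founder_freq``; each meiosis transmits one of the parent's two
    alleles by fair coin.  Deterministic under the seed.
    """
    if not (0 < founder_freq < 1):
        raise DomainError("founder_freq must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pat, mat = drop_descent(ped, seed=int(rng.integers(2**31)), n_drops=1)
    n_founder_alleles = 2 * len(ped.founders)
    states = rng.random(n_founder_alleles) < founder_freq
    out = {}
    for i, m in enumerate(ped.members):
        dose = int(states[pat[0, i]]) + int(states[mat[0, i]])
        out[m] = (HOM_REF, HET, HOM_ALT)[dose]
    return out


# -- constrained genotype planting -------------------------------------------


def _genotypes_from_transmissions(
    ped: Pedigree,
    forced: dict[tuple[str, str], int],
    rng: np.random.Generator,
) -> dict[str, tuple[int, int]]:
    """One descent realization honouring forced meiosis choices.

    ``forced`` maps (child, parent) to 0 (parent's paternal allele) or
    1 (maternal); unconstrained meioses are fair coin flips.
    """
    labels: dict[str, tuple[int, int]] = {}
    founder_index = {f: k for k, f in enumerate(ped.founders)}
    for m in ped.members:
        ind = ped.individuals[m]
        if ind.is_founder:
            f = founder_index[m]
            labels[m] = (2 * f, 2 * f + 1)
        else:
            pa = labels[ind.father_id]
            mo = labels[ind.mother_id]
            cp = forced.get((m, ind.father_id), int(rng.integers(0, 2)))
            cm = forced.get((m, ind.mother_id), int(rng.integers(0, 2)))
            labels[m] = (pa[cp], mo[cm])
    return labels


def _labels_to_genotypes(
    ped: Pedigree, labels: dict[str, tuple[int, int]], alt_labels: set[int]
) -> dict[str, str]:
    out = {}
    for m in ped.members:
        dose = sum(1 for lab in labels[m] if lab in alt_labels)
        out[m] = (HOM_REF, HET, HOM_ALT)[dose]
    return out


def _plant_paper_family(
    ped: Pedigree,
    rng: np.random.Generator,
    forbid_unaffected_carriers: bool = False,
    max_retries: int = 1000,
) -> dict[str, str]:
    """Causal-pattern genotypes on the paper_family template.

    The alt allele is a single ancestral copy in founder A0 (paternal
    allele, label 0), forced down both sibling lines so the first-cousin
    parents I-1/I-2 are both carriers; the three affected gen-II members
    receive it from both parents (autozygous hom-alt) and the affected
    proband III-5 inherits one copy from affected parent II-6.  Free
    meioses are redrawn until no unaffected member is hom-alt (and, when
    ``forbid_unaffected_carriers``, until no sequenced unaffected member
    carries any copy — the dominant-compatible pattern used for
    regulatory variants).
    """
    alt_labels = {0}  # A0's paternal allele
    # each forced entry picks the parent slot (0 paternal / 1 maternal)
    # that carries the ancestral alt copy along the descent path
    forced: dict[tuple[str, str], int] = {
        ("S1", "A0"): 0,  # alt lands on S1's paternal slot
        ("S2", "A0"): 0,  # alt lands on S2's paternal slot
        ("I-1", "S1"): 0,  # alt on I-1's paternal slot (from his father)
        ("I-2", "S2"): 0,  # alt on I-2's maternal slot (from her mother)
    }
    for aff in ("II-6", "II-11", "II-15"):
        forced[(aff, "I-1")] = 0  # I-1's alt sits on his paternal slot
        forced[(aff, "I-2")] = 1  # I-2's alt sits on her maternal slot
    forced[("III-5", "II-6")] = 0  # either slot of a hom-alt parent carries alt

    sequenced_unaffected = {
        i
        for i in ped.members
        if ped.individuals[i].sequenced and ped.individuals[i].affection == UNAFFECTED
    }
    for _ in range(max_retries):
        labels = _genotypes_from_transmissions(ped, forced, rng)
        geno = _labels_to_genotypes(ped, labels, alt_labels)
        bad = any(
            geno[i] == HOM_ALT
            for i in ped.members
            if ped.individuals[i].affection == UNAFFECTED
        )
        if forbid_unaffected_carriers:
            bad = bad or any(geno[i] != HOM_REF for i in sequenced_unaffected)
        if not bad:
            return geno
    raise DomainError("could not realize the planted genotype pattern")


def _plant_sib_trio(
    ped: Pedigree, rng: np.random.Generator, model: str, max_retries: int = 1000
) -> dict[str, str]:
    affected, unaffected = ped.affected_partition()
    for _ in range(max_retries):
        if model == "AR":
            geno = {"F": HET, "M": HET}
        else:
            geno = {"F": HET, "M": HOM_REF}
        ok = True
        for c in affected + unaffected:
            if c in geno:
                continue
            doses = []
            for parent in ("F", "M"):
                alleles = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}[geno[parent]]
                doses.append(alleles[rng.integers(0, 2)])
            geno[c] = (HOM_REF, HET, HOM_ALT)[sum(doses)]
        for c in affected:
            want = HOM_ALT if model == "AR" else HET
            if geno[c] != want:
                ok = False
        for c in unaffected:
            if model == "AR" and geno[c] == HOM_ALT:
                ok = False
            if model == "AD" and geno[c] != HOM_REF:
                ok = False
        if ok:
            return geno
    raise DomainError("could not realize the planted genotype pattern")


def _segregation_decoy_genotypes(
    ped: Pedigree, rng: np.random.Generator, max_retries: int = 1000
) -> dict[str, str]:
    """A rare allele entering through one married-in line: Mendelian-
    consistent but never shared by all affected members, so the
    shared/AD/AR segregation stages all reject it."""
    descendants: dict[str, set[str]] = {i: set() for i in ped.members}
    for i in ped.members:
        ind = ped.individuals[i]
        if not ind.is_founder:
            for anc in (ind.father_id, ind.mother_id):
                stack = [anc]
                while stack:
                    a = stack.pop()
                    if i not in descendants[a]:
                        descendants[a].add(i)
                        aind = ped.individuals[a]
                        if not aind.is_founder:
                            stack.extend([aind.father_id, aind.mother_id])
    affected = {
        i for i in ped.members if ped.individuals[i].affection == AFFECTED
    }
    # a founder whose descent lines miss at least one affected member can
    # never satisfy the "shared by all affected" rule
    safe = [f for f in ped.founders if not affected <= descendants[f]]
    founder_index = {f: k for k, f in enumerate(ped.founders)}
    for attempt in range(max_retries):
        spouse = safe[0] if safe else ped.founders[attempt % len(ped.founders)]
        alt_labels = {2 * founder_index[spouse]}
        labels = _genotypes_from_transmissions(ped, {}, rng)
        geno = _labels_to_genotypes(ped, labels, alt_labels)
        carried_by_all = all(
            geno[i] in (HET, HOM_ALT)
            for i in affected
            if ped.individuals[i].sequenced
        )
        hom_in_unaffected = any(
            geno[i] == HOM_ALT
            for i in ped.members
            if ped.individuals[i].sequenced
            and ped.individuals[i].affection == UNAFFECTED
        )
        if not carried_by_all and not hom_in_unaffected:
            return geno
    raise DomainError("could not realize a segregation-failing decoy")


# -- study bundle ------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study (defaults reproduce the template design)."""

    seed: int = 0
    pedigree_template: Literal["paper_family", "sib_trio", "custom"] = "paper_family"
    custom_pedigree: Pedigree | None = None
    causal_model: Literal["AR", "AD"] = "AR"
    penetrance: tuple[float, float, float] = (0.0, 0.0, 1.0)
    n_decoys_per_stage: int = 1
    include_sensitivity_decoy: bool = True
    include_regulatory_decoys: bool = True
    include_regulatory_passer: bool = False
    n_markers: int = 12
    marker_maf_range: tuple[float, float] = (0.4, 0.5)
    marker_spacing_cm: float = 1.0
    passer_gerp_range: tuple[float, float] = (3.5, 6.0)
    passer_pp2_range: tuple[float, float] = (0.85, 1.0)
    failer_gerp_range: tuple[float, float] = (1.0, 2.9)
    failer_pp2_range: tuple[float, float] = (0.3, 0.79)
    failer_af: float = 0.06
    sensitivity_af: float = 0.03

    def __post_init__(self) -> None:
        if not all(0 <= p <= 1 for p in self.penetrance):
            raise ConfigurationError("penetrance entries must be probabilities")
        if self.n_decoys_per_stage < 0:
            raise ConfigurationError("n_decoys_per_stage must be >= 0")


@dataclass
class StudyBundle:
    """Everything one synthetic study run produces."""

    pedigree: Pedigree
    variants: list[VariantRecord]
    regulatory_variants: list[VariantRecord]
    markers: list[Marker]
    chromatin: list[ChromatinSegment]
    loci: list[GenomicInterval]
    linkage_region: GenomicInterval
    truth: dict[tuple, dict]  # variant key -> {"role", "fails_stage", ...}
    config: SimulationConfig


def _rand_in(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(lo + (hi - lo) * rng.random())


def simulate_family_study(cfg: SimulationConfig) -> StudyBundle:
    """Generate a complete, internally consistent study bundle.

    The coding variant set contains one planted causal variant passing
    every stage of the coding cascade and, per stage, ``n_decoys_per_stage``
    decoys failing exactly that stage; optionally one extra
    frequency-sensitivity decoy (panel AF between the default and
    relaxed thresholds, with sub-threshold conservation so it cannot
    survive the relaxed re-run either).  The regulatory set contains
    stage-specific decoys and, optionally, one full passer.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.pedigree_template == "paper_family":
        ped = paper_family_pedigree()
    elif cfg.pedigree_template == "sib_trio":
        ped = sib_trio_pedigree()
    elif cfg.pedigree_template == "custom":
        if cfg.custom_pedigree is None:
            raise ConfigurationError("custom template requires custom_pedigree")
        ped = cfg.custom_pedigree
    else:
        raise ConfigurationError(f"unknown template {cfg.pedigree_template!r}")

    region = DEFAULT_LINKAGE_REGION
    chrom = region.chrom
    locus_point = GenomicInterval(chrom, 123_400_000, 123_400_000)

    def causal_pattern(forbid_carriers: bool = False) -> dict[str, str]:
        if cfg.pedigree_template == "paper_family":
            return _plant_paper_family(ped, rng, forbid_carriers)
        return _plant_sib_trio(ped, rng, cfg.causal_model)

    pos_counter = [123_485_455]

    def next_pos(offset: int | None = None) -> int:
        if offset is None:
            pos_counter[0] += 1117
            return pos_counter[0]
        return offset

    def passing_annotations() -> dict:
        return dict(
            impact="MODERATE",
            ref_panel_af=None,
            gerp=_rand_in(rng, *cfg.passer_gerp_range),
            pp2=_rand_in(rng, *cfg.passer_pp2_range),
            sift=round(_rand_in(rng, 0.0, 0.04), 3),
            cadd=round(_rand_in(rng, 20.0, 30.0), 2),
        )

    variants: list[VariantRecord] = []
    truth: dict[tuple, dict] = {}

    def add_variant(vid, pos_chrom, pos, genotypes, role, fails=None, note="", **anno):
        base = passing_annotations()
        base.update(anno)
        v = VariantRecord(
            chrom=pos_chrom, pos=pos, ref="T", alt="C", genotypes=genotypes, id=vid, **base
        )
        variants.append(v)
        truth[v.key] = {"id": vid, "role": role, "fails_stage": fails, "note": note}
        return v

    # the planted causal variant
    add_variant("causal", chrom, next_pos(123_485_455), causal_pattern(), "causal")

    for rep in range(cfg.n_decoys_per_stage):
        tag = "" if cfg.n_decoys_per_stage == 1 else f"_{rep + 1}"
        add_variant(
            f"decoy_impact{tag}", chrom, next_pos(), causal_pattern(),
            "decoy", "impact", impact="LOW",
        )
        add_variant(
            f"decoy_segregation{tag}", chrom, next_pos(),
            _segregation_decoy_genotypes(ped, rng), "decoy", "segregation",
        )
        add_variant(
            f"decoy_frequency{tag}", chrom, next_pos(), causal_pattern(),
            "decoy", "frequency", ref_panel_af=cfg.failer_af,
        )
        add_variant(
            f"decoy_region{tag}", "chr2", 50_000_000 + rep, causal_pattern(),
            "decoy", "linkage_region",
        )
        add_variant(
            f"decoy_conservation{tag}", chrom, next_pos(), causal_pattern(),
            "decoy", "conservation", gerp=_rand_in(rng, *cfg.failer_gerp_range),
        )
        add_variant(
            f"decoy_pathogenicity{tag}", chrom, next_pos(), causal_pattern(),
            "decoy", "pathogenicity", pp2=_rand_in(rng, *cfg.failer_pp2_range),
        )
    if cfg.include_sensitivity_decoy:
        add_variant(
            "decoy_sensitivity", chrom, next_pos(), causal_pattern(),
            "decoy", "frequency",
            ref_panel_af=cfg.sensitivity_af,
            gerp=_rand_in(rng, *cfg.failer_gerp_range),
            note="panel AF between the default and relaxed thresholds; "
            "fails conservation under the relaxed re-run",
        )

    # regulatory set: positions, chromatin segments and loci built together
    reg_variants: list[VariantRecord] = []
    chromatin: list[ChromatinSegment] = []
    loci = [locus_point]

    def reg_add(vid, pos_chrom, pos, genotypes, fails, state=None, cell="Gm12878", **anno):
        base = dict(
            impact="MODIFIER", ref_panel_af=None, gerp=None, pp2=None,
            sift=None, cadd=round(_rand_in(rng, 5.0, 15.0), 2),
        )
        base.update(anno)
        v = VariantRecord(
            chrom=pos_chrom, pos=pos, ref="G", alt="A", genotypes=genotypes, id=vid, **base
        )
        reg_variants.append(v)
        if state is not None:
            chromatin.append(
                ChromatinSegment(
                    GenomicInterval(pos_chrom, pos - 200, pos + 200), state, cell
                )
            )
        role = "regulatory_passer" if fails is None else "regulatory_decoy"
        truth[v.key] = {"id": vid, "role": role, "fails_stage": fails, "note": ""}
        return v

    if cfg.include_regulatory_decoys:
        near = locus_point.start
        reg_add(
            "reg_decoy_state", chrom, near + 1_000,
            causal_pattern(forbid_carriers=True), "regulatory_state",
            state="Heterochrom",
        )
        reg_add(
            "reg_decoy_region", "chr2", 60_000_000,
            causal_pattern(forbid_carriers=True), "linkage_region",
            state="Strong Enhancer", cell="K562",
        )
        loci.append(GenomicInterval("chr2", 60_000_100, 60_000_100))
        reg_add(
            "reg_decoy_segregation", chrom, near + 3_000,
            _segregation_decoy_genotypes(ped, rng), "segregation_AD_or_AR",
            state="Active Promoter",
        )
        reg_add(
            "reg_decoy_loci", chrom, near + 2_600_000,
            causal_pattern(forbid_carriers=True), "loci_proximity",
            state="Strong Enhancer",
        )
        reg_add(
            "reg_decoy_frequency", chrom, near + 5_000,
            causal_pattern(forbid_carriers=True), "frequency",
            state="Strong Enhancer", ref_panel_af=cfg.failer_af,
        )
    if cfg.include_regulatory_passer:
        reg_add(
            "reg_passer", chrom, locus_point.start + 7_000,
            causal_pattern(forbid_carriers=True), None,
            state="Strong Enhancer",
        )

    # null marker panel spanning the region (no linked disease locus)
    markers: list[Marker] = []
    lo_maf, hi_maf = cfg.marker_maf_range
    for k in range(cfg.n_markers):
        q = _rand_in(rng, lo_maf, hi_maf)
        geno = gene_drop(ped, q, seed=int(rng.integers(2**31)))
        bp = region.start + int(
            (region.end - region.start) * (k + 1) / (cfg.n_markers + 1)
        )
        markers.append(
            Marker(
                id=f"M{k + 1:03d}",
                chrom=chrom,
                genetic_pos=k * cfg.marker_spacing_cm,
                physical_pos=bp,
                allele_freqs=(1 - q, q),
                genotypes=geno,
            )
        )

    chromatin.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return StudyBundle(
        pedigree=ped,
        variants=variants,
        regulatory_variants=reg_variants,
        markers=markers,
        chromatin=chromatin,
        loci=loci,
        linkage_region=region,
        truth=truth,
        config=cfg,
    )


def write_bundle(bundle: StudyBundle, outdir: str) -> dict[str, str]:
    """Write the bundle as plain-text study files; returns name->path."""
    os.makedirs(outdir, exist_ok=True)
    ped = bundle.pedigree
    sequenced = [i for i in ped.members if ped.individuals[i].sequenced]
    samples = sequenced or ped.members
    paths = {
        "vcf": os.path.join(outdir, "coding.vcf"),
        "regulatory_vcf": os.path.join(outdir, "regulatory.vcf"),
        "ped": os.path.join(outdir, "family.ped"),
        "marker_ped": os.path.join(outdir, "markers.ped"),
        "marker_map": os.path.join(outdir, "markers.map"),
        "chromatin_bed": os.path.join(outdir, "chromatin.bed"),
        "loci_bed": os.path.join(outdir, "loci.bed"),
        "regions": os.path.join(outdir, "linkage_regions.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_vcf(bundle.variants, paths["vcf"], samples)
    write_vcf(bundle.regulatory_variants, paths["regulatory_vcf"], samples)
    write_ped(ped, paths["ped"])
    write_marker_files(bundle.markers, ped, paths["marker_ped"], paths["marker_map"])
    write_bed(bundle.chromatin, paths["chromatin_bed"])
    with open(paths["loci_bed"], "w") as fh:
        for l in bundle.loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\tlocus\n")
    with open(paths["regions"], "w") as fh:
        r = bundle.linkage_region
        fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("id\tchrom\tpos\trole\tfails_stage\tnote\n")
        for key, info in bundle.truth.items():
            fh.write(
                f"{info['id']}\t{key[0]}\t{key[1]}\t{info['role']}\t"
                f"{info['fails_stage'] or '.'}\t{info['note'] or '.'}\n"
            )
    return paths


# -- fixed fixtures ----------------------------------------------------------


def make_paper_burden_fixture() -> GenotypeMatrix:
    """The six-variant case-control burden configuration.

    92 familial cases vs 62 whole-exome controls.  Case alt-dosage
    column sums are (3, 1, 1, 1, 1, 0): variant 1 has one homozygous and
    one heterozygous case carrier, variants 2-5 one heterozygous case
    carrier each, variant 6 none; control column sums are
    (0, 0, 0, 0, 0, 2): variant 6 is heterozygous in two controls.
    """
    n_cases, n_controls, n_var = 92, 62, 6
    dosages = np.zeros((n_cases + n_controls, n_var))
    dosages[0, 0] = 2.0  # homozygous case carrier, variant 1
    dosages[1, 0] = 1.0
    for k in range(1, 5):
        dosages[1 + k, k] = 1.0
    dosages[n_cases, 5] = 1.0  # two heterozygous control carriers, variant 6
    dosages[n_cases + 1, 5] = 1.0
    is_case = np.zeros(n_cases + n_controls, dtype=bool)
    is_case[:n_cases] = True
    return GenotypeMatrix(
        dosages=dosages,
        is_case=is_case,
        sample_ids=[f"CASE{k + 1:03d}" for k in range(n_cases)]
        + [f"CTRL{k + 1:03d}" for k in range(n_controls)],
        variant_ids=[f"V{k + 1}" for k in range(n_var)],
    )


def make_target_sequencing_fixture() -> GenotypeMatrix:
    """Target-sequencing carrier configuration for the c.866C>G variant:
    one heterozygous carrier (the family-B proband) among 91 unrelated
    familial probands."""
    dosages = np.zeros((91, 1))
    dosages[0, 0] = 1.0
    return GenotypeMatrix(
        dosages=dosages,
        is_case=np.ones(91, dtype=bool),
        sample_ids=[f"PROBAND{k + 1:03d}" for k in range(91)],
        variant_ids=["c.866C>G"],
    )
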