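"""Coding and regulatory variant-filter cascades with per-stage accounting.

Each stage is a pure predicate over a :class:`~famvarkit.variants.VariantRecord`
(given the pedigree and track context), so the survivor set is
independent of stage order; the per-stage counts in the report reflect
the configured order.  All thresholds are strict inequalities
(MAF < threshold, GERP > threshold, PP2 > threshold): a variant sitting
exactly on a threshold fails, and a missing annotation fails the stage
that needs it — the cascade retains only variants affirmatively meeting
every criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .errors import ConfigurationError
from .pedigree import HET, HOM_ALT, MISSING, Pedigree
from .variants import ChromatinSegment, GenomicInterval, VariantRecord

SEGREGATION_MODELS = ("shared", "AD", "AR")


@dataclass
class FilterConfig:
    """Thresholds and context for both cascades (defaults as printed sources use)."""

    maf_threshold: float = 0.01
    alt_maf_threshold: float = 0.05  # sensitivity re-run
    gerp_threshold: float = 3.0
    pp2_threshold: float = 0.8
    impact_keep: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    linkage_regions: list[GenomicInterval] = field(default_factory=list)
    regulatory_states: frozenset[str] = frozenset({"Active Promoter", "Strong Enhancer"})
    loci_window: int = 500_000
    segregation_model: str = "shared"

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "alt_maf_threshold", "gerp_threshold", "pp2_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.loci_window < 0:
            raise ConfigurationError("loci_window must be >= 0")
        if self.segregation_model not in SEGREGATION_MODELS:
            raise ConfigurationError(
                f"segregation_model must be one of {SEGREGATION_MODELS}"
            )
        self.impact_keep = frozenset(self.impact_keep)
        self.regulatory_states = frozenset(self.regulatory_states)


@dataclass
class FilterReport:
    """Per-stage accounting of one cascade run."""

    stages: list[tuple[str, int, int]]  # (name, n_in, n_out)
    first_failing: dict[tuple, str]  # variant key -> name of first failed stage
    survivors: list[VariantRecord]

    def stage_counts(self) -> dict[str, tuple[int, int]]:
        return {name: (n_in, n_out) for name, n_in, n_out in self.stages}

    def to_rows(self) -> list[dict]:
        return [
            {"stage": name, "n_in": n_in, "n_out": n_out}
            for name, n_in, n_out in self.stages
        ]


# -- individual stages (list -> list form) ---------------------------------


def filter_impact(vs: Sequence[VariantRecord], cfg: FilterConfig) -> list[VariantRecord]:
    """Keep protein-affecting classes (HIGH/MODERATE by default)."""
    return [v for v in vs if v.impact in cfg.impact_keep]


def _check_samples(vs: Sequence[VariantRecord], ped: Pedigree) -> None:
    for v in vs:
        unknown = set(v.genotypes) - set(ped.individuals)
        if unknown:
            raise ConfigurationError(
                f"variant {v.chrom}:{v.pos} has genotypes for samples not in "
                f"the pedigree: {sorted(unknown)}"
            )


def _passes_shared(v: VariantRecord, affected: list[str], unaffected: list[str]) -> bool:
    # every sequenced affected carries >=1 alt copy (missing fails);
    # no sequenced unaffected is hom_alt (het carriers allowed)
    for i in affected:
        if v.genotypes.get(i, MISSING) not in (HET, HOM_ALT):
            return False
    return all(v.genotypes.get(i, MISSING) != HOM_ALT for i in unaffected)


def _passes_model(
    v: VariantRecord, affected: list[str], unaffected: list[str], model: str
) -> bool:
    if model == "AD":
        # fully penetrant dominant: affected carry, unaffected carry nothing
        return all(
            v.genotypes.get(i, MISSING) in (HET, HOM_ALT) for i in affected
        ) and all(
            v.genotypes.get(i, MISSING) not in (HET, HOM_ALT) for i in unaffected
        )
    if model == "AR":
        # recessive: affected homozygous alt, unaffected never homozygous alt
        return all(v.genotypes.get(i, MISSING) == HOM_ALT for i in affected) and all(
            v.genotypes.get(i, MISSING) != HOM_ALT for i in unaffected
        )
    raise ConfigurationError(f"unknown segregation model {model!r}")


def filter_segregation_shared(
    vs: Sequence[VariantRecord], ped: Pedigree
) -> list[VariantRecord]:
    """Keep variants shared by all sequenced affecteds and never hom-alt in unaffecteds."""
    _check_samples(vs, ped)
    affected, unaffected = ped.affected_partition(sequenced_only=True)
    return [v for v in vs if _passes_shared(v, affected, unaffected)]


def filter_segregation_model(
    vs: Sequence[VariantRecord], ped: Pedigree, model: str
) -> list[VariantRecord]:
    """Keep variants segregating under a fully penetrant AD or AR model."""
    if model not in ("AD", "AR"):
        raise ConfigurationError(f"unknown segregation model {model!r}")
    _check_samples(vs, ped)
    affected, unaffected = ped.affected_partition(sequenced_only=True)
    return [v for v in vs if _passes_model(v, affected, unaffected, model)]


def filter_frequency(
    vs: Sequence[VariantRecord], cfg: FilterConfig, threshold: float | None = None
) -> list[VariantRecord]:
    """Keep novel variants (no panel frequency) or panel MAF strictly below threshold."""
    thr = cfg.maf_threshold if threshold is None else threshold
    return [v for v in vs if v.ref_panel_af is None or v.ref_panel_af < thr]


def filter_linkage_region(
    vs: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Keep variants inside any configured linkage region (bounds inclusive)."""
    if not cfg.linkage_regions:
        raise ConfigurationError("no linkage regions configured")
    return [
        v for v in vs if any(r.contains(v.chrom, v.pos) for r in cfg.linkage_regions)
    ]


def filter_conservation(
    vs: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Keep variants with GERP strictly above threshold (absent score fails)."""
    return [v for v in vs if v.gerp is not None and v.gerp > cfg.gerp_threshold]


def filter_pathogenicity(
    vs: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Keep variants with PolyPhen2 strictly above threshold (absent score fails)."""
    return [v for v in vs if v.pp2 is not None and v.pp2 > cfg.pp2_threshold]


def filter_loci_proximity(
    vs: Sequence[VariantRecord],
    loci: Sequence[GenomicInterval],
    cfg: FilterConfig,
) -> list[VariantRecord]:
    """Keep variants within ``loci_window`` bp (inclusive) of a locus on the same chromosome."""
    return [
        v
        for v in vs
        if any(l.distance_to(v.chrom, v.pos) <= cfg.loci_window for l in loci)
    ]


def filter_regulatory_state(
    vs: Sequence[VariantRecord],
    segments: Sequence[ChromatinSegment],
    cfg: FilterConfig,
) -> list[VariantRecord]:
    """Keep variants inside a configured regulatory state in any cell line (union rule)."""
    keep = []
    for v in vs:
        for s in segments:
            if s.state in cfg.regulatory_states and s.interval.contains(v.chrom, v.pos):
                keep.append(v)
                break
    return keep


# -- cascades --------------------------------------------------------------


def _run_cascade(
    vs: Sequence[VariantRecord],
    stages: list[tuple[str, Callable[[list[VariantRecord]], list[VariantRecord]]]],
) -> FilterReport:
    current = list(vs)
    report_stages: list[tuple[str, int, int]] = []
    first_failing: dict[tuple, str] = {}
    for name, fn in stages:
        n_in = len(current)
        survivors = fn(current)
        kept_keys = {v.key for v in survivors}
        for v in current:
            if v.key not in kept_keys:
                first_failing.setdefault(v.key, name)
        report_stages.append((name, n_in, len(survivors)))
        current = survivors
    return FilterReport(stages=report_stages, first_failing=first_failing, survivors=current)


def run_coding_cascade(
    vs: Sequence[VariantRecord],
    ped: Pedigree,
    cfg: FilterConfig,
    maf_threshold: float | None = None,
) -> FilterReport:
    """Run the coding cascade: impact, segregation (shared), frequency,
    linkage region, conservation, pathogenicity — in that order.

    ``maf_threshold`` overrides the configured frequency threshold for
    sensitivity re-runs.
    """
    stages = [
        ("impact", lambda c: filter_impact(c, cfg)),
        ("segregation", lambda c: filter_segregation_shared(c, ped)),
        ("frequency", lambda c: filter_frequency(c, cfg, maf_threshold)),
        ("linkage_region", lambda c: filter_linkage_region(c, cfg)),
        ("conservation", lambda c: filter_conservation(c, cfg)),
        ("pathogenicity", lambda c: filter_pathogenicity(c, cfg)),
    ]
    return _run_cascade(vs, stages)


def run_regulatory_cascade(
    vs: Sequence[VariantRecord],
    ped: Pedigree,
    segments: Sequence[ChromatinSegment],
    loci: Sequence[GenomicInterval],
    cfg: FilterConfig,
) -> FilterReport:
    """Run the regulatory cascade: chromatin state, linkage region,
    segregation (AD or AR — union), locus proximity, frequency.

    The segregation stage keeps a variant if it segregates under either
    a fully penetrant dominant or a recessive model; the two models are
    listed as alternatives by the study design, and the union is the
    permissive reading.
    """

    def seg_union(c: list[VariantRecord]) -> list[VariantRecord]:
        ad = {v.key for v in filter_segregation_model(c, ped, "AD")}
        ar = {v.key for v in filter_segregation_model(c, ped, "AR")}
        return [v for v in c if v.key in ad or v.key in ar]

    stages = [
        ("regulatory_state", lambda c: filter_regulatory_state(c, segments, cfg)),
        ("linkage_region", lambda c: filter_linkage_region(c, cfg)),
        ("segregation_AD_or_AR", seg_union),
        ("loci_proximity", lambda c: filter_loci_proximity(c, loci, cfg)),
        ("frequency", lambda c: filter_frequency(c, cfg)),
    ]
    return _run_cascade(vs, stages)
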