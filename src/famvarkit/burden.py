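"""Rare-variant burden tests with permutation nulls and small accounting
statistics.

Two region-level case-control tests over a genotype (dosage) matrix:

* C-alpha — a variance-component test sensitive to overdispersion of
  alt-allele counts between cases and controls, regardless of direction
  of effect.
* adaptive sum — a directional score test in which variants showing a
  (nominally significant) excess of alternative alleles in controls
  have their dosage sign flipped before summation, so protective and
  risk variants do not cancel.

Both take significance from phenotype-label permutations with the
add-one estimator p = (1 + #{T_perm >= T_obs}) / (n_perm + 1), which
never returns zero.  Also here: alt-allele accounting (counts and
proportions), an exact two-sided Fisher test for 2xk tables, and the
2^-ddCt relative-expression fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DomainError

CASE = "case"
CONTROL = "control"


@dataclass
class GenotypeMatrix:
    """Individuals x variants alt-dosage matrix with case/control labels.

    ``dosages`` holds values in {0, 1, 2} with ``nan`` for missing;
    ``is_case`` is a boolean vector over rows.
    """

    dosages: np.ndarray
    is_case: np.ndarray
    sample_ids: list[str] | None = None
    variant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.dosages.ndim != 2:
            raise ConfigurationError("dosages must be 2-dimensional")
        if self.is_case.shape != (self.dosages.shape[0],):
            raise ConfigurationError("is_case must have one entry per row")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ConfigurationError("dosages must be 0, 1, 2 or missing (nan)")

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class BurdenResult:
    """Outcome of one permutation burden test."""

    statistic: float
    p_perm: float
    n_perm: int
    seed: int
    flip_mask: np.ndarray | None = None  # adaptive sum only


def _require_testable(gm: GenotypeMatrix) -> None:
    if gm.n_cases < 1 or gm.n_controls < 1:
        raise DomainError("need at least one case and one control")
    if np.nansum(gm.dosages) == 0:
        raise DomainError("no alternative alleles in the genotype matrix")


def _c_alpha_stat(dosages: np.ndarray, is_case: np.ndarray) -> float:
    """T = sum_i [(y_i - n_i p0)^2 - n_i p0 (1 - p0)] over variants,
    with p0 the overall case fraction and n_i/y_i counting alt copies
    in rows non-missing at variant i."""
    present = ~np.isnan(dosages)
    d = np.where(present, dosages, 0.0)
    n_i = d.sum(axis=0)
    y_i = (d * is_case[:, None]).sum(axis=0)
    p0 = is_case.mean()
    return float(np.sum((y_i - n_i * p0) ** 2 - n_i * p0 * (1 - p0)))


def c_alpha(gm: GenotypeMatrix, n_perm: int = 1000, seed: int = 0) -> BurdenResult:
    """C-alpha variance-component test with one-sided permutation p.

    The observed statistic compares, per variant, the alt-allele count
    in cases against its binomial expectation under no association and
    aggregates the excess dispersion; large positive T indicates
    case/control differentiation in either direction.  Missing dosages
    are excluded from that variant's counts.
    """
    _require_testable(gm)
    rng = np.random.default_rng(seed)
    observed = _c_alpha_stat(gm.dosages, gm.is_case)
    present = ~np.isnan(gm.dosages)
    d = np.where(present, gm.dosages, 0.0)
    n_i = d.sum(axis=0)
    p0 = gm.is_case.mean()
    labels = rng.permuted(
        np.tile(gm.is_case.astype(float), (n_perm, 1)), axis=1
    )  # (n_perm, n_samples)
    y = labels @ d  # (n_perm, n_variants)
    stats_perm = ((y - n_i * p0) ** 2 - n_i * p0 * (1 - p0)).sum(axis=1)
    count = int((stats_perm >= observed - 1e-12).sum())
    return BurdenResult(
        statistic=observed,
        p_perm=(1 + count) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


def _control_excess_pvalues(dosages: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """One-sided Fisher (hypergeometric) p for excess alt alleles in
    controls, per variant, on the 2x2 allele-count table."""
    present = ~np.isnan(dosages)
    d = np.where(present, dosages, 0.0)
    alt_total = d.sum(axis=0)
    alt_control = (d * (~is_case)[:, None]).sum(axis=0)
    alleles_control = 2 * (present & ~is_case[:, None]).sum(axis=0)
    alleles_total = 2 * present.sum(axis=0)
    # P(X >= alt_control) for X ~ Hypergeom(alleles_total, alt_total, alleles_control)
    return stats.hypergeom.sf(
        alt_control - 1, alleles_total, alt_total, alleles_control
    )


def _asum_stat(
    dosages: np.ndarray, is_case: np.ndarray, alpha0: float
) -> tuple[float, np.ndarray]:
    p_ctrl = _control_excess_pvalues(dosages, is_case)
    flip = np.where(p_ctrl < alpha0, -1.0, 1.0)
    d = np.where(np.isnan(dosages), 0.0, dosages)
    burden = d @ flip
    y = is_case.astype(float)
    u = float(np.dot(y - y.mean(), burden))
    return u, flip


def adaptive_sum(
    gm: GenotypeMatrix, alpha0: float = 0.1, n_perm: int = 1000, seed: int = 0
) -> BurdenResult:
    """Adaptive sum test: data-driven sign flips, then a score statistic.

    Stage 1 flips the sign of any variant whose alt alleles are
    significantly (one-sided Fisher p < ``alpha0``) enriched in
    controls; stage 2 sums signed dosages per individual and scores the
    case-control contrast.  The flip selection is repeated inside every
    permutation so the data-driven step is properly accounted for; the
    p-value is one-sided on the score.
    """
    _require_testable(gm)
    rng = np.random.default_rng(seed)
    observed, flip = _asum_stat(gm.dosages, gm.is_case, alpha0)
    present = ~np.isnan(gm.dosages)
    d = np.where(present, gm.dosages, 0.0)
    alt_total = d.sum(axis=0)
    alleles_total = 2 * present.sum(axis=0)
    labels = rng.permuted(
        np.tile(gm.is_case, (n_perm, 1)), axis=1
    )  # (n_perm, n_samples) booleans
    # stage 1 per permutation, vectorized hypergeometric tails
    ctrl = ~labels
    alt_control = ctrl.astype(float) @ d  # (n_perm, n_variants)
    alleles_control = 2 * (ctrl.astype(float) @ present.astype(float))
    p_ctrl = stats.hypergeom.sf(
        alt_control - 1, alleles_total[None, :], alt_total[None, :], alleles_control
    )
    flips = np.where(p_ctrl < alpha0, -1.0, 1.0)  # (n_perm, n_variants)
    burden_perm = d @ flips.T  # (n_samples, n_perm)
    y = labels.astype(float)
    centered = y - y.mean(axis=1, keepdims=True)
    stats_perm = np.einsum("ps,sp->p", centered, burden_perm)
    count = int((stats_perm >= observed - 1e-12).sum())
    return BurdenResult(
        statistic=observed,
        p_perm=(1 + count) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        flip_mask=flip,
    )


def exhaustive_case_relabelings(n_total: int, n_cases: int):
    """Yield every case-label assignment (boolean vectors) — the exact
    permutation null for small samples."""
    for case_rows in combinations(range(n_total), n_cases):
        labels = np.zeros(n_total, dtype=bool)
        labels[list(case_rows)] = True
        yield labels


def allele_accounting(
    gm: GenotypeMatrix,
    rows: Sequence[int] | np.ndarray | None = None,
    variants: Sequence[int] | None = None,
) -> tuple[int, float]:
    """Alt-allele count and proportion over a selection of the matrix.

    proportion = alt_count / (2 * n_individuals * n_variants); missing
    dosages count 0 toward the numerator but keep their place in the
    denominator (the fixed-denominator convention used for reporting
    carrier proportions).
    """
    d = gm.dosages
    if rows is not None:
        d = d[np.asarray(rows, dtype=int)]
    if variants is not None:
        d = d[:, np.asarray(variants, dtype=int)]
    if d.size == 0:
        raise DomainError("empty selection for allele accounting")
    alt = int(np.nansum(d))
    return alt, alt / (2 * d.shape[0] * d.shape[1])


def fisher_exact_2xk(table: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p for a 2xk table (k = 2 or 3).

    Enumerates all tables with the observed margins and sums the
    (multivariate) hypergeometric probabilities of tables no more
    probable than the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ConfigurationError("table must be 2x2 or 2x3")
    if (t < 0).any():
        raise ConfigurationError("table entries must be non-negative")
    grand = int(t.sum())
    if grand == 0:
        raise DomainError("zero grand total")
    row1 = int(t[0].sum())
    cols = t.sum(axis=0)

    def log_prob(top: tuple[int, ...]) -> float:
        # P(table | margins) = prod_j C(col_j, top_j) / C(N, row1)
        lp = -_log_comb(grand, row1)
        for cj, tj in zip(cols, top):
            lp += _log_comb(int(cj), tj)
        return lp

    observed_lp = log_prob(tuple(int(x) for x in t[0]))
    total = 0.0
    k = t.shape[1]

    def rec(j: int, remaining: int, top: list[int]) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                lp = log_prob(tuple(top + [remaining]))
                if lp <= observed_lp + 1e-12:
                    total += math.exp(lp)
            return
        for x in range(0, min(int(cols[j]), remaining) + 1):
            rec(j + 1, remaining - x, top + [x])

    rec(0, row1, [])
    return min(total, 1.0)


def family_genotype_tables(
    affected_genotypes: Sequence[str], unaffected_genotypes: Sequence[str]
) -> dict[str, list[list[int]]]:
    """Both contingency layouts for a family genotype-distribution test.

    ``allelic``: 2x2 alt/ref allele counts by affection status;
    ``genotypic``: 2x3 genotype-class counts (hom_ref, het, hom_alt).
    Missing calls are dropped.  Feed either to :func:`fisher_exact_2xk`;
    which layout underlies a reported p-value is a modelling choice the
    caller makes explicitly.
    """
    from .pedigree import DOSAGE, MISSING

    def rows(genos):
        called = [g for g in genos if g != MISSING]
        alt = sum(DOSAGE[g] for g in called)
        allelic = [alt, 2 * len(called) - alt]
        genotypic = [
            sum(1 for g in called if g == code)
            for code in ("hom_ref", "het", "hom_alt")
        ]
        return allelic, genotypic

    aff_allelic, aff_genotypic = rows(affected_genotypes)
    un_allelic, un_genotypic = rows(unaffected_genotypes)
    return {
        "allelic": [aff_allelic, un_allelic],
        "genotypic": [aff_genotypic, un_genotypic],
    }


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator;
    a one-cycle lower ddCt doubles the fold change.
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(v):
            raise DomainError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)
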