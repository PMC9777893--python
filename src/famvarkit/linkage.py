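"""Marker QC/pruning and exact nonparametric multipoint linkage.

The engine enumerates inheritance vectors exactly (one bit per meiosis:
0 = grand-paternal allele transmitted, 1 = grand-maternal) and computes
the Whittemore-Halpern allele-sharing statistics S_pairs and S_all over
them.  Multipoint inference is a hidden-Markov forward-backward over
inheritance vectors with Haldane-map transition probabilities and
founder-allele-frequency emissions; standardized sharing scores are
converted to LOD scores with the Kong-Cox one-parameter linear and
exponential likelihood tilts.

Exact enumeration is capped at a configurable number of meioses
(default 20 bits); larger pedigrees raise :class:`CapacityError` and
must be analysed as sub-pedigrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .errors import (
    CapacityError,
    ConfigurationError,
    DomainError,
    LdUndefinedError,
    ParseError,
)
from .pedigree import (
    DOSAGE,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Pedigree,
    mendelian_check,
)

DEFAULT_BIT_LIMIT = 20

Statistic = Literal["s_pairs", "s_all"]
Model = Literal["linear", "exponential"]


@dataclass
class Marker:
    """A biallelic marker with genetic/physical positions and genotype calls.

    Genotypes use the package-wide codes (hom_ref/het/hom_alt/missing)
    with "alt" meaning the second allele; ``allele_freqs`` are the
    population frequencies of (allele1, allele2).
    """

    id: str
    chrom: str
    genetic_pos: float  # centimorgans
    physical_pos: int  # bp
    allele_freqs: tuple[float, float]
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p, q = self.allele_freqs
        if not (0 < p < 1 and 0 < q < 1) or abs(p + q - 1) > 1e-9:
            raise ConfigurationError(
                f"marker {self.id!r}: allele_freqs must lie in (0,1) and sum to 1"
            )

    def sample_maf(self) -> float:
        """Minor-allele frequency estimated from non-missing genotype calls."""
        doses = [DOSAGE[g] for g in self.genotypes.values() if g != MISSING]
        if not doses:
            return math.nan
        f = sum(doses) / (2 * len(doses))
        return min(f, 1 - f)

    def missing_rate(self) -> float:
        if not self.genotypes:
            return 1.0
        n_miss = sum(1 for g in self.genotypes.values() if g == MISSING)
        return n_miss / len(self.genotypes)


@dataclass
class QcThresholds:
    """Marker-QC cutoffs: remove MAF < maf, HWE p < hwe_p, missingness > max_missing."""

    maf: float = 0.4
    hwe_p: float = 1e-5
    max_missing: float = 0.05


@dataclass
class NplResult:
    """Per-position nonparametric linkage summary."""

    position: float  # cM
    s_pairs: float
    s_all: float
    z_pairs: float
    z_all: float
    delta_hat: float
    lod_linear: float
    lod_exponential: float


# -- marker QC and pruning ---------------------------------------------------


def hwe_pvalue(marker: Marker, ped: Pedigree) -> float:
    """Chi-square (1 df) Hardy-Weinberg test on founder genotypes only.

    Founders are the only mutually independent genotypes in a pedigree.
    Monomorphic or empty founder sets return p = 1 (untestable).
    """
    counts = {HOM_REF: 0, HET: 0, HOM_ALT: 0}
    for i in ped.founders:
        g = marker.genotypes.get(i, MISSING)
        if g != MISSING:
            counts[g] += 1
    n = sum(counts.values())
    if n == 0:
        return 1.0
    p = (2 * counts[HOM_REF] + counts[HET]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([counts[HOM_REF], counts[HET], counts[HOM_ALT]])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_markers(
    markers: Sequence[Marker],
    ped: Pedigree,
    thresholds: QcThresholds | None = None,
) -> list[Marker]:
    """Remove markers with Mendelian errors, low sample MAF, HWE
    disequilibrium (founders only) or excess missingness."""
    thr = thresholds or QcThresholds()
    kept = []
    for m in markers:
        if mendelian_check(ped, m.genotypes):
            continue
        maf = m.sample_maf()
        if math.isnan(maf) or maf < thr.maf:
            continue
        if hwe_pvalue(m, ped) < thr.hwe_p:
            continue
        if m.missing_rate() > thr.max_missing:
            continue
        kept.append(m)
    return kept


def thin_markers(markers: Sequence[Marker], density: int = 5) -> list[Marker]:
    """Thin to at most ``density`` markers per 1-cM bin.

    Bins are half-open and anchored at each chromosome's first marker
    position; within a bin the ``density`` markers with highest sample
    MAF are kept, ties broken toward lower genetic position.
    """
    by_chrom: dict[str, list[Marker]] = {}
    for m in sorted(markers, key=lambda m: (m.chrom, m.genetic_pos, m.id)):
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[Marker] = []
    for chrom in sorted(by_chrom):
        ms = by_chrom[chrom]
        anchor = ms[0].genetic_pos
        bins: dict[int, list[Marker]] = {}
        for m in ms:
            bins.setdefault(int((m.genetic_pos - anchor) // 1.0), []).append(m)
        for b in sorted(bins):
            chosen = sorted(bins[b], key=lambda m: (-m.sample_maf(), m.genetic_pos, m.id))
            out.extend(sorted(chosen[:density], key=lambda m: (m.genetic_pos, m.id)))
    return out


def ld_r2(m1: Marker, m2: Marker, ped: Pedigree) -> float:
    """Composite (phase-free) LD: squared Pearson correlation of
    allele dosages over founders with calls at both markers."""
    d1, d2 = [], []
    for i in ped.founders:
        g1 = m1.genotypes.get(i, MISSING)
        g2 = m2.genotypes.get(i, MISSING)
        if g1 != MISSING and g2 != MISSING:
            d1.append(DOSAGE[g1])
            d2.append(DOSAGE[g2])
    if len(d1) < 2:
        raise DomainError("need >= 2 founders typed at both markers")
    a, b = np.asarray(d1, float), np.asarray(d2, float)
    if a.var() == 0 or b.var() == 0:
        raise LdUndefinedError(
            f"r^2 undefined: monomorphic dosages for {m1.id!r}/{m2.id!r}"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_cluster_adjacent(
    markers: Sequence[Marker], ped: Pedigree, threshold: float = 0.15
) -> list[list[Marker]]:
    """Greedy clustering of map-adjacent markers while pairwise r^2 > threshold.

    Undefined r^2 (monomorphic founders) breaks the cluster.  Haplotype
    modelling within clusters is not performed; downstream analyses use
    one representative per cluster (see :func:`ld_prune`).
    """
    clusters: list[list[Marker]] = []
    for m in sorted(markers, key=lambda m: (m.chrom, m.genetic_pos, m.id)):
        if clusters and clusters[-1][-1].chrom == m.chrom:
            try:
                r2 = ld_r2(clusters[-1][-1], m, ped)
            except LdUndefinedError:
                r2 = 0.0
            if r2 > threshold:
                clusters[-1].append(m)
                continue
        clusters.append([m])
    return clusters


def ld_prune(
    markers: Sequence[Marker], ped: Pedigree, threshold: float = 0.15
) -> list[Marker]:
    """Keep one representative (highest sample MAF) per adjacent-LD cluster."""
    reps = []
    for cluster in ld_cluster_adjacent(markers, ped, threshold):
        reps.append(max(cluster, key=lambda m: (m.sample_maf(), -m.genetic_pos)))
    return reps


# -- inheritance-vector engine -----------------------------------------------


class InheritanceEngine:
    """Exact enumeration of inheritance vectors for one pedigree.

    Bit layout: nonfounders in topological order; nonfounder k owns bits
    2k (its paternal meiosis) and 2k+1 (maternal); bit value 0 transmits
    the parent's grand-paternal allele, 1 the grand-maternal.  Founder
    f's two alleles carry the labels (2f, 2f+1), assigned in topological
    order, so descent is deterministic given the vector.
    """

    def __init__(self, ped: Pedigree, bit_limit: int = DEFAULT_BIT_LIMIT):
        self.ped = ped
        self.n_bits = ped.meiosis_count
        if self.n_bits > bit_limit:
            raise CapacityError(
                f"pedigree has {self.n_bits} meioses > bit limit {bit_limit}; "
                "analyse a sub-pedigree or raise the limit explicitly"
            )
        self.founders = ped.founders
        self.nonfounders = ped.nonfounders
        self.members = ped.members
        self.n_vectors = 1 << self.n_bits
        self._founder_index = {f: k for k, f in enumerate(self.founders)}
        self._nonfounder_index = {i: k for k, i in enumerate(self.nonfounders)}
        self._descent_cache: tuple[np.ndarray, np.ndarray] | None = None

    # descent of founder-allele labels under every vector, vectorized
    def descent(self) -> tuple[np.ndarray, np.ndarray]:
        """(pat, mat) uint16 arrays of shape (n_vectors, n_members):
        founder-allele label carried on each member's paternal/maternal
        chromosome under each inheritance vector."""
        if self._descent_cache is not None:
            return self._descent_cache
        V, n = self.n_vectors, len(self.members)
        idx = {m: i for i, m in enumerate(self.members)}
        vecs = np.arange(V, dtype=np.int64)
        pat = np.empty((V, n), dtype=np.uint16)
        mat = np.empty((V, n), dtype=np.uint16)
        for m in self.members:  # topological order: parents first
            i = idx[m]
            ind = self.ped.individuals[m]
            if ind.is_founder:
                f = self._founder_index[m]
                pat[:, i] = 2 * f
                mat[:, i] = 2 * f + 1
            else:
                k = self._nonfounder_index[m]
                fi, mi = idx[ind.father_id], idx[ind.mother_id]
                b_pat = (vecs >> (2 * k)) & 1
                b_mat = (vecs >> (2 * k + 1)) & 1
                pat[:, i] = np.where(b_pat == 0, pat[:, fi], mat[:, fi])
                mat[:, i] = np.where(b_mat == 0, pat[:, mi], mat[:, mi])
        self._descent_cache = (pat, mat)
        return self._descent_cache

    def descent_for(self, vector: int) -> dict[str, tuple[int, int]]:
        """Founder-allele labels (paternal, maternal) per member for one vector."""
        labels: dict[str, tuple[int, int]] = {}
        for m in self.members:
            ind = self.ped.individuals[m]
            if ind.is_founder:
                f = self._founder_index[m]
                labels[m] = (2 * f, 2 * f + 1)
            else:
                k = self._nonfounder_index[m]
                fa, mo = labels[ind.father_id], labels[ind.mother_id]
                labels[m] = (
                    fa[(vector >> (2 * k)) & 1],
                    mo[(vector >> (2 * k + 1)) & 1],
                )
        return labels

    def affected(self) -> list[str]:
        aff, _ = self.ped.affected_partition()
        if len(aff) < 2:
            raise DomainError("sharing statistics need >= 2 affected members")
        return aff

    def s_pairs_values(self) -> np.ndarray:
        """S_pairs for every inheritance vector."""
        aff = self.affected()
        pat, mat = self.descent()
        idx = {m: i for i, m in enumerate(self.members)}
        cols = [(pat[:, idx[a]], mat[:, idx[a]]) for a in aff]
        total = np.zeros(self.n_vectors)
        for i in range(len(aff)):
            for j in range(i + 1, len(aff)):
                for x in cols[i]:
                    for y in cols[j]:
                        total += x == y
        return total

    def s_all_values(self) -> np.ndarray:
        """Whittemore-Halpern S_all for every inheritance vector:
        2^-a * sum over allele collections h of prod_i b_i(h)!"""
        aff = self.affected()
        a = len(aff)
        pat, mat = self.descent()
        idx = {m: i for i, m in enumerate(self.members)}
        cols = [(pat[:, idx[x]], mat[:, idx[x]]) for x in aff]
        total = np.zeros(self.n_vectors)
        for choice in product((0, 1), repeat=a):
            labels = [cols[i][c] for i, c in enumerate(choice)]
            prod = np.ones(self.n_vectors)
            for j in range(a):
                factor = np.ones(self.n_vectors)
                for k in range(j):
                    factor += labels[k] == labels[j]
                prod *= factor
            total += prod
        return total / (1 << a)

    def statistic_values(self, statistic: Statistic) -> np.ndarray:
        if statistic == "s_pairs":
            return self.s_pairs_values()
        if statistic == "s_all":
            return self.s_all_values()
        raise ConfigurationError(f"unknown statistic {statistic!r}")


def enumerate_vectors(
    ped: Pedigree, bit_limit: int = DEFAULT_BIT_LIMIT
) -> tuple[np.ndarray, np.ndarray]:
    """All inheritance vectors (as integers) with their uniform prior weights."""
    eng = InheritanceEngine(ped, bit_limit)
    return (
        np.arange(eng.n_vectors, dtype=np.int64),
        np.full(eng.n_vectors, 1.0 / eng.n_vectors),
    )


def s_pairs(vector: int, ped: Pedigree, bit_limit: int = DEFAULT_BIT_LIMIT) -> float:
    """S_pairs: total IBD allele sharing summed over affected pairs, for one vector."""
    eng = InheritanceEngine(ped, bit_limit)
    labels = eng.descent_for(vector)
    aff = eng.affected()
    total = 0
    for i in range(len(aff)):
        for j in range(i + 1, len(aff)):
            for x in labels[aff[i]]:
                for y in labels[aff[j]]:
                    total += x == y
    return float(total)


def s_all(vector: int, ped: Pedigree, bit_limit: int = DEFAULT_BIT_LIMIT) -> float:
    """Whittemore-Halpern S_all for one inheritance vector."""
    eng = InheritanceEngine(ped, bit_limit)
    labels = eng.descent_for(vector)
    aff = eng.affected()
    a = len(aff)
    total = 0.0
    for choice in product((0, 1), repeat=a):
        picked = [labels[aff[i]][c] for i, c in enumerate(choice)]
        prod = 1.0
        counts: dict[int, int] = {}
        for lab in picked:
            counts[lab] = counts.get(lab, 0) + 1
            prod *= counts[lab]
        total += prod
    return total / (1 << a)


def null_distribution(
    ped: Pedigree, statistic: Statistic = "s_all", bit_limit: int = DEFAULT_BIT_LIMIT
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution (support, probabilities) of the raw
    statistic over uniformly weighted inheritance vectors."""
    eng = InheritanceEngine(ped, bit_limit)
    values = eng.statistic_values(statistic)
    support, counts = np.unique(values, return_counts=True)
    return support, counts / eng.n_vectors


def null_moments(
    ped: Pedigree, statistic: Statistic = "s_all", bit_limit: int = DEFAULT_BIT_LIMIT
) -> tuple[float, float]:
    """Exact (mean, variance) of the statistic under the uniform null."""
    support, probs = null_distribution(ped, statistic, bit_limit)
    mean = float(np.dot(support, probs))
    var = float(np.dot((support - mean) ** 2, probs))
    return mean, var


def standardized_null(
    ped: Pedigree, statistic: Statistic = "s_all", bit_limit: int = DEFAULT_BIT_LIMIT
) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the standardized statistic Z = (S - mu) / sigma."""
    support, probs = null_distribution(ped, statistic, bit_limit)
    mean = float(np.dot(support, probs))
    var = float(np.dot((support - mean) ** 2, probs))
    if var <= 0:
        raise DomainError("statistic is degenerate on this pedigree (zero variance)")
    return (support - mean) / math.sqrt(var), probs


# -- multipoint HMM ----------------------------------------------------------


def haldane_theta(d_cm: float) -> float:
    """Recombination fraction for d centimorgans under the Haldane map."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def _emission(eng: InheritanceEngine, marker: Marker) -> np.ndarray:
    """P(observed genotypes | inheritance vector) for every vector.

    Sums over all founder-allele state assignments (each founder allele
    independently carries allele 2 with frequency q); genotypes are
    matched as unphased dosages, missing calls are uninformative.
    """
    pat, mat = eng.descent()
    idx = {m: i for i, m in enumerate(eng.members)}
    typed = [
        (idx[m], DOSAGE[g])
        for m, g in marker.genotypes.items()
        if g != MISSING and m in idx
    ]
    n_alleles = 2 * len(eng.founders)
    if n_alleles > 20:
        raise CapacityError(
            f"{n_alleles} founder alleles exceed the emission enumeration limit"
        )
    q = marker.allele_freqs[1]
    emission = np.zeros(eng.n_vectors)
    for state_bits in range(1 << n_alleles):
        state = np.array(
            [(state_bits >> k) & 1 for k in range(n_alleles)], dtype=np.uint8
        )
        prob = float(np.prod(np.where(state == 1, q, 1 - q)))
        match = np.ones(eng.n_vectors, dtype=bool)
        for col, dose in typed:
            match &= (state[pat[:, col]] + state[mat[:, col]]) == dose
        emission += prob * match
    return emission


def _transition(dist: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """Propagate a distribution over vectors across one map interval:
    each meiosis bit flips independently with probability theta."""
    if theta <= 0:
        return dist
    out = dist
    V = out.size
    idx = np.arange(V)
    for b in range(n_bits):
        flipped = out[idx ^ (1 << b)]
        out = (1 - theta) * out + theta * flipped
    return out


def multipoint_distribution(
    ped: Pedigree,
    markers: Sequence[Marker],
    positions: Sequence[float],
    bit_limit: int = DEFAULT_BIT_LIMIT,
) -> np.ndarray:
    """Posterior distribution over inheritance vectors at each query position.

    Standard forward-backward over the marker chain; emissions come from
    founder-allele-frequency genotype likelihoods, transitions from
    independent per-meiosis recombination at the Haldane fraction for
    the inter-position distance.  Returns an array of shape
    (len(positions), 2**meioses); rows sum to 1.
    """
    eng = InheritanceEngine(ped, bit_limit)
    cms = [m.genetic_pos for m in markers]
    if any(b < a for a, b in zip(cms, cms[1:])):
        raise ConfigurationError("markers must be sorted by genetic position")
    if any(markers[0].chrom != m.chrom for m in markers):
        raise ConfigurationError("multipoint markers must share a chromosome")

    # nodes: (cM, emission or None for a query), markers before queries at ties
    nodes: list[tuple[float, int, np.ndarray | None]] = []
    for m in markers:
        nodes.append((m.genetic_pos, 0, _emission(eng, m)))
    for qi, pos in enumerate(positions):
        nodes.append((float(pos), 1, None))
    nodes.sort(key=lambda t: (t[0], t[1]))

    V, nb = eng.n_vectors, eng.n_bits
    uniform = np.full(V, 1.0 / V)

    # forward[i]: P(data at nodes <= i, state at node i), unnormalized
    forward: list[np.ndarray] = []
    cur = uniform.copy()
    prev_pos = None
    for pos, _, emis in nodes:
        if prev_pos is not None:
            cur = _transition(cur, haldane_theta(pos - prev_pos), nb)
        if emis is not None:
            cur = cur * emis
        total = cur.sum()
        if total <= 0:
            raise DomainError("marker genotypes are inconsistent with the pedigree")
        cur = cur / total  # scaled forward; posteriors are normalized anyway
        forward.append(cur.copy())
        prev_pos = pos

    # backward[i]: P(data at nodes > i | state at node i)
    backward: list[np.ndarray] = [np.ones(V) for _ in nodes]
    cur = np.ones(V)
    next_pos = None
    for i in range(len(nodes) - 1, -1, -1):
        pos, _, emis = nodes[i]
        if next_pos is not None:
            cur = _transition(cur, haldane_theta(next_pos - pos), nb)
        backward[i] = cur.copy()
        if emis is not None:
            cur = cur * emis
            cur = cur / cur.sum()
        next_pos = pos

    out = np.empty((len(positions), V))
    qi = 0
    for i, (pos, kind, emis) in enumerate(nodes):
        if kind == 1:
            post = forward[i] * backward[i]
            out[qi] = post / post.sum()
            qi += 1
    return out


# -- Kong-Cox LOD ------------------------------------------------------------


def _kc_linear_loglik(delta: float, z: np.ndarray, w: np.ndarray) -> float:
    terms = 1.0 + delta * w * z
    if np.any(terms <= 0):
        return -math.inf
    return float(np.log(terms).sum())


def _kc_exponential_loglik(
    delta: float,
    z: np.ndarray,
    w: np.ndarray,
    null_dists: Sequence[tuple[np.ndarray, np.ndarray]],
) -> float:
    ll = 0.0
    for zf, wf, (support, probs) in zip(z, w, null_dists):
        kappa = float(logsumexp(delta * wf * support, b=probs))
        ll += delta * wf * zf - kappa
    return ll


def kong_cox_lod(
    z_scores: Sequence[float],
    weights: Sequence[float] | None = None,
    model: Model = "exponential",
    null_dists: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[float, float]:
    """Kong-Cox one-parameter LOD from per-family standardized scores.

    Returns ``(delta_hat, lod)`` where delta maximizes the one-sided
    (delta >= 0) tilted likelihood and LOD is the maximized
    log10-likelihood ratio against delta = 0.

    linear model
        l(d) = sum_f log(1 + d * w_f * Z_f), with d bounded so every
        attainable standardized score keeps its term positive (the bound
        uses the minimum of each family's null support, so ``null_dists``
        — from :func:`standardized_null` — is required unless some
        observed score is negative).

    exponential model
        l(d) = sum_f w_f * [d Z_f - kappa_f(d)] with kappa_f the
        cumulant-generating function of family f's standardized null
        statistic; requires ``null_dists``.  When every Z_f sits at its
        family's maximum attainable score the supremum is reached as
        d -> inf and equals -sum_f w_f log P_f(max); that limit is
        returned with ``delta_hat = inf``.
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise DomainError("need at least one family z score")
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != z.shape or np.any(w <= 0):
        raise ConfigurationError("weights must be positive, one per family")

    if model == "linear":
        if null_dists is not None:
            mins = np.array([w[f] * null_dists[f][0].min() for f in range(z.size)])
        else:
            mins = w * z
        neg = mins[mins < 0]
        if neg.size == 0:
            raise DomainError(
                "linear model needs null support (null_dists) to bound delta "
                "when all observed scores are non-negative"
            )
        delta_max = float((-1.0 / neg).min())
        res = optimize.minimize_scalar(
            lambda d: -_kc_linear_loglik(d, z, w),
            bounds=(0.0, delta_max * (1 - 1e-12)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        candidates = [(0.0, 0.0), (float(res.x), _kc_linear_loglik(float(res.x), z, w))]
        delta_hat, ll = max(candidates, key=lambda t: t[1])
        return delta_hat, max(ll, 0.0) / math.log(10)

    if model == "exponential":
        if null_dists is None:
            raise ConfigurationError("exponential model requires null_dists")
        maxes = np.array([float(np.max(s)) for s, _ in null_dists])
        if np.all(z >= maxes - 1e-12):
            # supremum at delta -> inf: each family contributes -log P(max)
            ll = 0.0
            for zf, wf, (support, probs) in zip(z, w, null_dists):
                p_max = float(probs[np.isclose(support, support.max())].sum())
                ll += -wf * math.log(p_max)
            return math.inf, ll / math.log(10)

        def nll(d: float) -> float:
            return -_kc_exponential_loglik(d, z, w, null_dists)

        # concave in delta: expand the bracket until the tail slope is negative
        hi = 1.0
        while _kc_exponential_loglik(hi + 1e-6, z, w, null_dists) > _kc_exponential_loglik(
            hi, z, w, null_dists
        ):
            hi *= 2.0
            if hi > 1e6:
                break
        res = optimize.minimize_scalar(
            nll, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-12}
        )
        delta_hat = float(res.x)
        ll = _kc_exponential_loglik(delta_hat, z, w, null_dists)
        if ll <= 1e-10:  # numerically indistinguishable from the null optimum
            return 0.0, 0.0
        return delta_hat, ll / math.log(10)

    raise ConfigurationError(f"unknown model {model!r}")


def max_expected_lod(
    ped: Pedigree,
    model: Model = "exponential",
    statistic: Statistic = "s_all",
    bit_limit: int = DEFAULT_BIT_LIMIT,
) -> float:
    """LOD attained at perfect IBD information and maximal sharing.

    The pedigree's ceiling on linkage evidence: every family member
    exhibits the maximal standardized sharing score.
    """
    support, probs = standardized_null(ped, statistic, bit_limit)
    z_max = float(support.max())
    _, lod = kong_cox_lod([z_max], model=model, null_dists=[(support, probs)])
    return lod


def npl_scan(
    ped: Pedigree,
    markers: Sequence[Marker],
    positions: Sequence[float],
    bit_limit: int = DEFAULT_BIT_LIMIT,
) -> list[NplResult]:
    """Multipoint NPL scan for a single family.

    At each query position: posterior-expected S_pairs and S_all,
    standardized Z scores, and single-family Kong-Cox LODs (linear and
    exponential) computed from Z_all; ``delta_hat`` is the exponential
    model's estimate.
    """
    eng = InheritanceEngine(ped, bit_limit)
    posteriors = multipoint_distribution(ped, markers, positions, bit_limit)
    results = []
    vals = {st: eng.statistic_values(st) for st in ("s_pairs", "s_all")}
    moments = {}
    for st, v in vals.items():
        mean = float(v.mean())
        sd = float(v.std())
        moments[st] = (mean, sd)
    support_all, probs_all = standardized_null(ped, "s_all", bit_limit)
    for pos, post in zip(positions, posteriors):
        exp_sp = float(np.dot(post, vals["s_pairs"]))
        exp_sa = float(np.dot(post, vals["s_all"]))
        z_sp = (exp_sp - moments["s_pairs"][0]) / moments["s_pairs"][1]
        z_sa = (exp_sa - moments["s_all"][0]) / moments["s_all"][1]
        _, lod_lin = kong_cox_lod(
            [z_sa], model="linear", null_dists=[(support_all, probs_all)]
        )
        d_exp, lod_exp = kong_cox_lod(
            [z_sa], model="exponential", null_dists=[(support_all, probs_all)]
        )
        results.append(
            NplResult(
                position=float(pos),
                s_pairs=exp_sp,
                s_all=exp_sa,
                z_pairs=z_sp,
                z_all=z_sa,
                delta_hat=d_exp,
                lod_linear=lod_lin,
                lod_exponential=lod_exp,
            )
        )
    return results


def lod_regions(
    results: Sequence[NplResult],
    chrom: str,
    cm_to_bp: dict[float, int],
    lod_threshold: float = 2.0,
    model: Model = "exponential",
) -> list[tuple[str, int, int]]:
    """Contiguous runs of scan positions with LOD above threshold, as
    (chrom, start_bp, end_bp) using the supplied cM->bp lookup."""
    runs: list[tuple[str, int, int]] = []
    current: list[float] = []
    for r in results:
        lod = r.lod_exponential if model == "exponential" else r.lod_linear
        if lod > lod_threshold:
            current.append(r.position)
        elif current:
            runs.append((chrom, cm_to_bp[current[0]], cm_to_bp[current[-1]]))
            current = []
    if current:
        runs.append((chrom, cm_to_bp[current[0]], cm_to_bp[current[-1]]))
    return runs


# -- PED/MAP marker I/O -------------------------------------------------------


def read_map(path: str) -> list[tuple[str, str, float, int]]:
    """Read a 4-column MAP file: chrom, id, genetic position (cM), bp."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError("MAP line has fewer than 4 columns", lineno)
            try:
                rows.append((fields[0], fields[1], float(fields[2]), int(fields[3])))
            except ValueError:
                raise ParseError("bad MAP coordinates", lineno) from None
    return rows


def read_marker_ped(
    ped_path: str, map_path: str, allele_freqs: Sequence[tuple[float, float]] | None = None
) -> list[Marker]:
    """Read LINKAGE-format marker genotypes (PED columns 7+ as allele
    pairs coded 1/2, 0 = missing) against a MAP file.

    Population allele frequencies may be supplied per marker; otherwise
    they are estimated from the non-missing calls (clipped away from 0/1).
    """
    mapping = read_map(map_path)
    calls: list[dict[str, str]] = [dict() for _ in mapping]
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * len(mapping):
                raise ParseError(
                    f"expected {6 + 2 * len(mapping)} columns, got {len(fields)}",
                    lineno,
                )
            iid = fields[1]
            for k in range(len(mapping)):
                a1, a2 = fields[6 + 2 * k], fields[7 + 2 * k]
                if a1 == "0" or a2 == "0":
                    calls[k][iid] = MISSING
                else:
                    dose = (a1 == "2") + (a2 == "2")
                    calls[k][iid] = (HOM_REF, HET, HOM_ALT)[dose]
    markers = []
    for k, (chrom, mid, cm, bp) in enumerate(mapping):
        if allele_freqs is not None:
            freqs = allele_freqs[k]
        else:
            doses = [DOSAGE[g] for g in calls[k].values() if g != MISSING]
            f2 = sum(doses) / (2 * len(doses)) if doses else 0.5
            f2 = min(max(f2, 1e-3), 1 - 1e-3)
            freqs = (1 - f2, f2)
        markers.append(
            Marker(
                id=mid,
                chrom=chrom,
                genetic_pos=cm,
                physical_pos=bp,
                allele_freqs=freqs,
                genotypes=calls[k],
            )
        )
    return markers


_PED_ALLELES = {HOM_REF: ("1", "1"), HET: ("1", "2"), HOM_ALT: ("2", "2"), MISSING: ("0", "0")}


def write_marker_files(
    markers: Sequence[Marker],
    ped: Pedigree,
    ped_path: str,
    map_path: str,
    family_id: str = "FAM1",
) -> None:
    """Write markers as LINKAGE PED (genotype columns) + MAP files."""
    from .pedigree import _AFF_OUT, _SEX_OUT  # shared dialect tables

    with open(map_path, "w") as fh:
        for m in markers:
            fh.write(f"{m.chrom}\t{m.id}\t{m.genetic_pos:g}\t{m.physical_pos}\n")
    with open(ped_path, "w") as fh:
        for i in ped.members:
            ind = ped.individuals[i]
            row = [
                family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_OUT[ind.sex],
                _AFF_OUT[ind.affection],
            ]
            for m in markers:
                row.extend(_PED_ALLELES[m.genotypes.get(i, MISSING)])
            fh.write("\t".join(row) + "\n")
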