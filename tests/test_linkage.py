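"""Linkage machinery: marker QC/pruning, inheritance-vector enumeration,
sharing statistics, multipoint HMM and Kong-Cox LOD — each checked against
an independent oracle (hand computation, brute-force enumeration, grid
search or Monte Carlo)."""

import math
from itertools import product

import numpy as np
import pytest

from famvarkit.errors import CapacityError, ConfigurationError, DomainError, LdUndefinedError
from famvarkit.linkage import (
    InheritanceEngine,
    Marker,
    QcThresholds,
    enumerate_vectors,
    haldane_theta,
    kong_cox_lod,
    ld_cluster_adjacent,
    ld_prune,
    ld_r2,
    max_expected_lod,
    multipoint_distribution,
    npl_scan,
    null_moments,
    qc_markers,
    read_marker_ped,
    s_all,
    s_pairs,
    standardized_null,
    thin_markers,
    write_marker_files,
)
from famvarkit.pedigree import (
    FEMALE,
    HET,
    HOM_ALT,
    HOM_REF,
    MALE,
    MISSING,
    Individual,
    Pedigree,
)
from famvarkit.simulate import drop_descent, sib_pair_pedigree, sib_trio_pedigree


def founders_only(n):
    return Pedigree(
        [Individual(id=f"P{k}", sex=MALE if k % 2 == 0 else FEMALE) for k in range(n)]
    )


def marker_from_counts(ped, n_hom_ref, n_het, n_hom_alt, n_missing=0, mid="m"):
    codes = (
        [HOM_REF] * n_hom_ref + [HET] * n_het + [HOM_ALT] * n_hom_alt + [MISSING] * n_missing
    )
    genotypes = dict(zip(ped.members, codes))
    return Marker(mid, "1", 0.0, 1, (0.5, 0.5), genotypes)


class TestQcMarkers:
    def test_low_maf_removed(self):
        ped = founders_only(50)
        m = marker_from_counts(ped, 21, 19, 10)  # sample MAF 0.39
        assert m.sample_maf() == pytest.approx(0.39)
        assert qc_markers([m], ped) == []

    def test_excess_missingness_removed(self):
        ped = founders_only(50)
        m = marker_from_counts(ped, 12, 23, 12, n_missing=3)  # 6% missing
        assert qc_markers([m], ped) == []

    def test_clean_marker_retained(self):
        ped = founders_only(50)
        m = marker_from_counts(ped, 15, 25, 10)  # MAF 0.45, HWE-consistent
        assert qc_markers([m], ped) == [m]

    def test_mendelian_error_removed(self):
        ped = Pedigree([
            Individual(id="F", sex=MALE),
            Individual(id="M", sex=FEMALE),
            Individual(id="C", father_id="F", mother_id="M", sex=MALE),
        ])
        m = Marker("m", "1", 0.0, 1, (0.5, 0.5), {"F": HOM_REF, "M": HOM_REF, "C": HET})
        assert qc_markers([m], ped, QcThresholds(maf=0.0, max_missing=1.0)) == []

    def test_hwe_failure_removed(self):
        ped = founders_only(50)
        m = marker_from_counts(ped, 25, 0, 25)  # no hets at freq 0.5
        assert qc_markers([m], ped, QcThresholds(maf=0.1)) == []


class TestThinning:
    def mk(self, cm, n_het, mid):
        ped = founders_only(30)  # sample MAF = n_het / 60, distinct per n_het
        genotypes = dict(zip(ped.members, [HET] * n_het + [HOM_REF] * (30 - n_het)))
        return Marker(mid, "1", cm, int(cm * 1e6) + 1, (0.5, 0.5), genotypes)

    def test_dense_bin_thinned(self):
        markers = [self.mk(0.01 * k, k, f"m{k}") for k in range(25)]
        out = thin_markers(markers, density=5)
        assert len(out) == 5
        assert [m.id for m in out] == ["m20", "m21", "m22", "m23", "m24"]

    def test_sparse_bin_untouched(self):
        markers = [self.mk(0.1 * k, 9, f"m{k}") for k in range(3)]
        assert len(thin_markers(markers, density=5)) == 3

    def test_permutation_invariant(self, rng):
        markers = [self.mk(0.03 * k, 3 + (k % 7), f"m{k}") for k in range(30)]
        out1 = thin_markers(markers, density=5)
        shuffled = list(markers)
        rng.shuffle(shuffled)
        out2 = thin_markers(shuffled, density=5)
        assert [m.id for m in out1] == [m.id for m in out2]


class TestLd:
    def founders4(self, d1, d2):
        ped = founders_only(4)
        code = {0: HOM_REF, 1: HET, 2: HOM_ALT}
        m1 = Marker("a", "1", 0.0, 1, (0.5, 0.5), {p: code[x] for p, x in zip(ped.members, d1)})
        m2 = Marker("b", "1", 0.1, 2, (0.5, 0.5), {p: code[x] for p, x in zip(ped.members, d2)})
        return ped, m1, m2

    def test_hand_computed_case(self):
        # dosages (0,1,2,1) vs (0,1,1,2): r = 1/2, r^2 = 1/4
        ped, m1, m2 = self.founders4((0, 1, 2, 1), (0, 1, 1, 2))
        assert ld_r2(m1, m2, ped) == pytest.approx(0.25, abs=1e-12)

    def test_identical_vectors(self):
        ped, m1, m2 = self.founders4((0, 1, 2, 0), (0, 1, 2, 0))
        assert ld_r2(m1, m2, ped) == pytest.approx(1.0)

    def test_zero_covariance(self):
        ped, m1, m2 = self.founders4((0, 0, 2, 2), (0, 2, 0, 2))
        assert ld_r2(m1, m2, ped) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_is_undefined(self):
        ped, m1, m2 = self.founders4((1, 1, 1, 1), (0, 1, 2, 0))
        with pytest.raises(LdUndefinedError):
            ld_r2(m1, m2, ped)

    def test_cluster_and_prune(self):
        ped, m1, m2 = self.founders4((0, 1, 2, 0), (0, 1, 2, 0))
        m3 = Marker("c", "1", 0.2, 3, (0.5, 0.5),
                    {p: g for p, g in zip(ped.members, (HOM_REF, HOM_ALT, HOM_REF, HOM_ALT))})
        clusters = ld_cluster_adjacent([m1, m2, m3], ped)
        assert [len(c) for c in clusters] == [2, 1]
        assert len(ld_prune([m1, m2, m3], ped)) == 2


class TestEnumeration:
    def test_vector_counts(self, sib_pair):
        vectors, weights = enumerate_vectors(sib_pair)
        assert len(vectors) == 16 and weights.sum() == pytest.approx(1.0)

    def test_single_child(self):
        ped = Pedigree([
            Individual(id="F", sex=MALE),
            Individual(id="M", sex=FEMALE),
            Individual(id="C", father_id="F", mother_id="M", sex=MALE),
        ])
        vectors, _ = enumerate_vectors(ped)
        assert len(vectors) == 4

    def test_capacity_error(self):
        inds = [Individual(id="F", sex=MALE), Individual(id="M", sex=FEMALE)]
        inds += [
            Individual(id=f"C{k}", father_id="F", mother_id="M", sex=MALE)
            for k in range(11)
        ]
        with pytest.raises(CapacityError):
            enumerate_vectors(Pedigree(inds))  # 22 meioses > 20-bit limit


class TestSharingStatistics:
    def test_s_pairs_ibd2_and_ibd0(self, sib_pair):
        # bits (0,1) sib1, (2,3) sib2; equal bits -> same parental alleles
        assert s_pairs(0b0000, sib_pair) == 2.0
        assert s_pairs(0b1100, sib_pair) == 0.0
        assert s_pairs(0b0100, sib_pair) == 1.0

    def test_s_pairs_domain_error(self):
        ped = sib_trio_pedigree(n_affected=1, n_sibs=2)
        with pytest.raises(DomainError):
            s_pairs(0, ped)

    def test_s_all_matches_exhaustive_collection_sum(self, sib_trio):
        """Vectorized S_all equals a brute-force evaluation of the
        Whittemore-Halpern sum for every inheritance vector."""
        eng = InheritanceEngine(sib_trio)
        values = eng.s_all_values()
        for vector in range(0, eng.n_vectors, 7):
            labels = eng.descent_for(vector)
            aff, _ = sib_trio.affected_partition()
            total = 0.0
            for choice in product((0, 1), repeat=len(aff)):
                picked = [labels[a][c] for a, c in zip(aff, choice)]
                prod = 1.0
                for lab in set(picked):
                    prod *= math.factorial(picked.count(lab))
                total += prod
            assert values[vector] == pytest.approx(total / 2 ** len(aff), abs=1e-12)

    def test_scalar_and_vectorized_agree(self, sib_trio):
        eng = InheritanceEngine(sib_trio)
        sp, sa = eng.s_pairs_values(), eng.s_all_values()
        for vector in (0, 5, 21, 63):
            assert s_pairs(vector, sib_trio) == sp[vector]
            assert s_all(vector, sib_trio) == pytest.approx(sa[vector], abs=1e-12)


class TestNullMoments:
    def test_sib_pair_s_pairs_analytic(self, sib_pair):
        mean, var = null_moments(sib_pair, "s_pairs")
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert var == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("statistic", ["s_pairs", "s_all"])
    def test_standardized_moments_by_enumeration(self, statistic, sib_pair, sib_trio, family):
        """Exact standardization: mean 0, variance 1 to 1e-9 on small pedigrees."""
        peds = [sib_pair, sib_trio, sib_trio_pedigree(n_affected=2, n_sibs=4)]
        for ped in peds:
            sup, probs = standardized_null(ped, statistic)
            assert float(np.dot(sup, probs)) == pytest.approx(0.0, abs=1e-9)
            assert float(np.dot(sup**2, probs)) == pytest.approx(1.0, abs=1e-9)

    def test_s_all_moments_vs_monte_carlo(self, sib_trio):
        """Enumerated moments agree with gene-dropping simulation within 3 SE."""
        mean, var = null_moments(sib_trio, "s_all")
        n = 100_000
        pat, mat = drop_descent(sib_trio, seed=99, n_drops=n)
        idx = {m: k for k, m in enumerate(sib_trio.members)}
        aff, _ = sib_trio.affected_partition()
        cols = [(pat[:, idx[a]], mat[:, idx[a]]) for a in aff]
        total = np.zeros(n)
        for choice in product((0, 1), repeat=len(aff)):
            labels = [cols[i][c] for i, c in enumerate(choice)]
            prod = np.ones(n)
            for j in range(len(aff)):
                factor = np.ones(n)
                for k in range(j):
                    factor += labels[k] == labels[j]
                prod *= factor
            total += prod
        draws = total / 2 ** len(aff)
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - mean) < 3 * se


def _emission_oracle(ped, marker):
    """Independent genotype-likelihood computation: explicit loops over
    founder allele states and per-vector descent."""
    eng = InheritanceEngine(ped)
    q = marker.allele_freqs[1]
    n_alleles = 2 * len(ped.founders)
    out = np.zeros(eng.n_vectors)
    for vector in range(eng.n_vectors):
        labels = eng.descent_for(vector)
        for state in product((0, 1), repeat=n_alleles):
            prob = 1.0
            for s in state:
                prob *= q if s else 1 - q
            ok = True
            for member, g in marker.genotypes.items():
                if g == MISSING:
                    continue
                dose = state[labels[member][0]] + state[labels[member][1]]
                if dose != {HOM_REF: 0, HET: 1, HOM_ALT: 2}[g]:
                    ok = False
                    break
            if ok:
                out[vector] += prob
    return out


class TestMultipoint:
    @pytest.fixture()
    def trio(self):
        return Pedigree([
            Individual(id="F", sex=MALE),
            Individual(id="M", sex=FEMALE),
            Individual(id="C", father_id="F", mother_id="M", sex=MALE),
        ])

    def test_single_marker_equals_bayes_rule(self, sib_pair):
        m = Marker("m", "1", 0.0, 1, (0.7, 0.3),
                   {"F": HET, "M": HET, "C1": HOM_ALT, "C2": HET})
        post = multipoint_distribution(sib_pair, [m], [0.0])[0]
        emission = _emission_oracle(sib_pair, m)
        expected = emission / emission.sum()  # uniform prior
        np.testing.assert_allclose(post, expected, atol=1e-12)

    def test_rows_sum_to_one(self, sib_pair):
        m1 = Marker("m1", "1", 0.0, 1, (0.5, 0.5),
                    {"F": HET, "M": HOM_REF, "C1": HET, "C2": HOM_REF})
        m2 = Marker("m2", "1", 5.0, 2, (0.5, 0.5),
                    {"F": HET, "M": HET, "C1": HOM_ALT, "C2": HET})
        post = multipoint_distribution(sib_pair, [m1, m2], [0.0, 2.5, 5.0])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_distant_markers_factorize(self, sib_pair):
        m1 = Marker("m1", "1", 0.0, 1, (0.5, 0.5),
                    {"F": HET, "M": HET, "C1": HOM_ALT, "C2": HOM_ALT})
        m2 = Marker("m2", "1", 1e4, 2, (0.5, 0.5),
                    {"F": HET, "M": HET, "C1": HOM_REF, "C2": HOM_REF})
        joint = multipoint_distribution(sib_pair, [m1, m2], [0.0, 1e4])
        single1 = multipoint_distribution(sib_pair, [m1], [0.0])
        single2 = multipoint_distribution(sib_pair, [m2], [1e4])
        np.testing.assert_allclose(joint[0], single1[0], atol=1e-9)
        np.testing.assert_allclose(joint[1], single2[0], atol=1e-9)

    def test_two_markers_match_brute_force_joint(self, trio):
        """Forward-backward equals exhaustive enumeration over the 16
        inheritance-vector pairs of a parent-offspring trio."""
        d = 20.0
        theta = haldane_theta(d)
        m1 = Marker("m1", "1", 0.0, 1, (0.6, 0.4), {"F": HET, "M": HOM_REF, "C": HET})
        m2 = Marker("m2", "1", d, 2, (0.5, 0.5), {"F": HET, "M": HET, "C": HOM_ALT})
        e1, e2 = _emission_oracle(trio, m1), _emission_oracle(trio, m2)
        n_bits = 2
        joint = np.zeros((4, 4))
        for v1 in range(4):
            for v2 in range(4):
                flips = bin(v1 ^ v2).count("1")
                trans = theta**flips * (1 - theta) ** (n_bits - flips)
                joint[v1, v2] = 0.25 * trans * e1[v1] * e2[v2]
        joint /= joint.sum()
        post = multipoint_distribution(trio, [m1, m2], [0.0, d])
        np.testing.assert_allclose(post[0], joint.sum(axis=1), atol=1e-10)
        np.testing.assert_allclose(post[1], joint.sum(axis=0), atol=1e-10)

    def test_unsorted_markers_rejected(self, sib_pair):
        m1 = Marker("m1", "1", 5.0, 1, (0.5, 0.5), {})
        m2 = Marker("m2", "1", 0.0, 2, (0.5, 0.5), {})
        with pytest.raises(ConfigurationError):
            multipoint_distribution(sib_pair, [m1, m2], [0.0])


class TestKongCox:
    def test_all_zero_scores(self, sib_pair):
        sup, probs = standardized_null(sib_pair, "s_pairs")
        for model in ("linear", "exponential"):
            delta, lod = kong_cox_lod([0.0, 0.0], model=model, null_dists=[(sup, probs)] * 2)
            assert delta == 0.0 and lod == 0.0

    def test_linear_matches_grid_search(self, sib_pair):
        sup, probs = standardized_null(sib_pair, "s_pairs")
        z = 1.2
        _, lod = kong_cox_lod([z], model="linear", null_dists=[(sup, probs)])
        delta_max = -1.0 / float(sup.min())
        grid = np.linspace(0.0, delta_max * (1 - 1e-9), 10_001)
        oracle = np.log(1.0 + grid * z).max() / math.log(10)
        assert lod == pytest.approx(oracle, abs=1e-4)

    def test_exponential_matches_grid_search(self, sib_trio):
        sup, probs = standardized_null(sib_trio, "s_all")
        z = 1.0
        _, lod = kong_cox_lod([z], model="exponential", null_dists=[(sup, probs)])
        grid = np.linspace(0.0, 50.0, 50_001)
        kappa = np.log(probs @ np.exp(np.outer(sup, grid)))
        oracle = (grid * z - kappa).max() / math.log(10)
        assert lod == pytest.approx(oracle, abs=1e-4)

    def test_order_invariance(self, sib_pair, sib_trio):
        d1 = standardized_null(sib_pair, "s_all")
        d2 = standardized_null(sib_trio, "s_all")
        z = [0.9, 1.3]
        _, lod_a = kong_cox_lod(z, model="exponential", null_dists=[d1, d2])
        _, lod_b = kong_cox_lod(z[::-1], model="exponential", null_dists=[d2, d1])
        assert lod_a == pytest.approx(lod_b, abs=1e-9)

    def test_negative_scores_give_zero_lod(self, sib_pair):
        sup, probs = standardized_null(sib_pair, "s_pairs")
        for model in ("linear", "exponential"):
            delta, lod = kong_cox_lod([-1.0], model=model, null_dists=[(sup, probs)])
            assert delta == 0.0 and lod == 0.0


class TestMaxExpectedLod:
    def test_sib_pair_equals_neg_log10_p_max(self, sib_pair):
        """At full information and maximal sharing the exponential-model
        LOD is -log10 P(maximal sharing) = -log10(1/4) for a sib pair."""
        lod = max_expected_lod(sib_pair, "exponential", "s_pairs")
        assert lod == pytest.approx(-math.log10(0.25), abs=1e-12)
        # direct tilt maximization approaches the same supremum
        sup, probs = standardized_null(sib_pair, "s_pairs")
        grid = np.linspace(0.0, 60.0, 60_001)
        kappa = np.log(probs @ np.exp(np.outer(sup, grid)))
        oracle = (grid * float(sup.max()) - kappa).max() / math.log(10)
        assert lod == pytest.approx(oracle, abs=1e-3)

    def test_single_affected_is_domain_error(self):
        ped = sib_trio_pedigree(n_affected=1, n_sibs=3)
        with pytest.raises(DomainError):
            max_expected_lod(ped)

    def test_two_identical_families_double_the_lod(self, sib_pair):
        sup, probs = standardized_null(sib_pair, "s_pairs")
        z_max = float(sup.max())
        _, one = kong_cox_lod([z_max], model="exponential", null_dists=[(sup, probs)])
        _, two = kong_cox_lod([z_max] * 2, model="exponential", null_dists=[(sup, probs)] * 2)
        assert two == pytest.approx(2 * one, abs=1e-12)


class TestNplScanAndIo:
    def test_scan_fully_informative_marker(self, sib_pair):
        m = Marker("m", "1", 0.0, 1, (0.5, 0.5),
                   {"F": HET, "M": HET, "C1": HOM_ALT, "C2": HOM_ALT})
        (res,) = npl_scan(sib_pair, [m], [0.0])
        # both sibs hom-alt from het x het parents forces IBD 2
        assert res.s_pairs == pytest.approx(2.0, abs=1e-9)
        assert res.z_pairs == pytest.approx((2 - 1) / math.sqrt(0.5), abs=1e-9)
        assert res.lod_exponential > res.lod_linear > 0

    def test_marker_ped_round_trip(self, tmp_path, sib_trio):
        markers = [
            Marker("m1", "1", 0.0, 100, (0.6, 0.4),
                   {"F": HET, "M": HOM_REF, "C1": HET, "C2": HOM_REF, "C3": MISSING}),
            Marker("m2", "1", 1.5, 200, (0.5, 0.5),
                   {"F": HOM_ALT, "M": HET, "C1": HOM_ALT, "C2": HET, "C3": HET}),
        ]
        ped_path, map_path = tmp_path / "m.ped", tmp_path / "m.map"
        write_marker_files(markers, sib_trio, str(ped_path), str(map_path))
        back = read_marker_ped(str(ped_path), str(map_path),
                               allele_freqs=[m.allele_freqs for m in markers])
        assert [m.id for m in back] == ["m1", "m2"]
        for orig, rt in zip(markers, back):
            assert rt.genetic_pos == orig.genetic_pos
            assert rt.physical_pos == orig.physical_pos
            assert rt.genotypes == orig.genotypes
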