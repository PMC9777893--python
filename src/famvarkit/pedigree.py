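"""Pedigree data model, relatedness coefficients and Mendelian checking.

The pedigree is a directed parent graph over uniquely labelled
individuals.  Consanguinity loops (e.g. a first-cousin marriage) are
allowed and representable; half-founders (exactly one recorded parent)
are rejected at construction time, following the LINKAGE/PED convention
where "0" marks an absent parent and parents come in pairs.

Genotypes at a biallelic site are represented by the string codes
``hom_ref``, ``het``, ``hom_alt`` and ``missing`` throughout the
package; :data:`DOSAGE` maps them to alt-allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigurationError, IdentifierError, ParseError

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

AFFECTED = "affected"
UNAFFECTED = "unaffected"

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)

#: alt-allele dosage per genotype code (missing has no dosage)
DOSAGE = {HOM_REF: 0, HET: 1, HOM_ALT: 2}

# alleles a parent of the given genotype can transmit (0=ref, 1=alt)
_TRANSMISSIBLE = {HOM_REF: {0}, HET: {0, 1}, HOM_ALT: {1}}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both set or both ``None``
    (no half-founders).  ``generation_label`` carries the conventional
    pedigree-drawing label (e.g. ``"II-6"``) when one exists.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    affection: str = UNKNOWN
    sequenced: bool = False
    generation_label: str | None = None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise ConfigurationError(
                f"individual {self.id!r}: father and mother must both be "
                "present or both absent (half-founders are not supported)"
            )
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise ConfigurationError(f"individual {self.id!r}: bad sex {self.sex!r}")
        if self.affection not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise ConfigurationError(
                f"individual {self.id!r}: bad affection {self.affection!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A validated pedigree: acyclic parent graph with paired parents."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ConfigurationError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self._validate()
        self._order = self._topological_order()
        self._depth = {i: d for d, i in enumerate(self._order)}
        self._kinship_cache: dict[tuple[str, str], float] = {}

    def _validate(self) -> None:
        for ind in self.individuals.values():
            for pid, want_sex, role in (
                (ind.father_id, MALE, "father"),
                (ind.mother_id, FEMALE, "mother"),
            ):
                if pid is None:
                    continue
                parent = self.individuals.get(pid)
                if parent is None:
                    raise ConfigurationError(
                        f"individual {ind.id!r}: {role} {pid!r} not in pedigree"
                    )
                if parent.sex != want_sex:
                    raise ConfigurationError(
                        f"individual {ind.id!r}: {role} {pid!r} has sex "
                        f"{parent.sex!r}, expected {want_sex!r}"
                    )

    def _topological_order(self) -> list[str]:
        """Founders-first order; raises on ancestry cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(i: str, stack: list[str]) -> None:
            st = state.get(i)
            if st == 1:
                return
            if st == 0:
                raise ConfigurationError(
                    f"pedigree cycle: {' -> '.join(stack + [i])}"
                )
            state[i] = 0
            ind = self.individuals[i]
            if ind.father_id is not None:
                visit(ind.father_id, stack + [i])
                visit(ind.mother_id, stack + [i])
            state[i] = 1
            order.append(i)

        for i in sorted(self.individuals):
            visit(i, [])
        return order

    # -- derived sets ------------------------------------------------------

    @property
    def founders(self) -> list[str]:
        return [i for i in self._order if self.individuals[i].is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i in self._order if not self.individuals[i].is_founder]

    @property
    def meiosis_count(self) -> int:
        return 2 * len(self.nonfounders)

    @property
    def members(self) -> list[str]:
        """All ids in topological (founders-first) order."""
        return list(self._order)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, i: str) -> bool:
        return i in self.individuals

    def _get(self, i: str) -> Individual:
        try:
            return self.individuals[i]
        except KeyError:
            raise IdentifierError(f"unknown individual id {i!r}") from None

    # -- relatedness -------------------------------------------------------

    def kinship(self, i: str, j: str) -> float:
        """Malecot kinship coefficient phi(i, j).

        Probability that one allele drawn at random from each of i and j
        is identical by descent.  Computed by the standard recursion,
        expanding the individual that appears later in a founders-first
        topological order (so the expanded one is never an ancestor of
        the other).  phi(i, i) = (1 + F_i) / 2.
        """
        self._get(i), self._get(j)
        return self._kinship(i, j)

    def _kinship(self, i: str, j: str) -> float:
        key = (i, j) if i <= j else (j, i)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        if self._depth[i] < self._depth[j]:
            i, j = j, i
        ind = self.individuals[i]
        if i == j:
            if ind.is_founder:
                phi = 0.5
            else:
                phi = 0.5 + 0.5 * self._kinship(ind.father_id, ind.mother_id)
        elif ind.is_founder:
            # both founders (j is no deeper than i): unrelated by convention
            phi = 0.0
        else:
            phi = 0.5 * (
                self._kinship(ind.father_id, j) + self._kinship(ind.mother_id, j)
            )
        self._kinship_cache[key] = phi
        return phi

    def inbreeding(self, i: str) -> float:
        """Inbreeding coefficient F(i) = kinship of i's parents (0 for founders)."""
        ind = self._get(i)
        if ind.is_founder:
            return 0.0
        return self._kinship(ind.father_id, ind.mother_id)

    # -- phenotype partitions ---------------------------------------------

    def affected_partition(
        self, sequenced_only: bool = False
    ) -> tuple[list[str], list[str]]:
        """Split members into (affected, unaffected); unknowns appear in neither."""
        affected, unaffected = [], []
        for i in self._order:
            ind = self.individuals[i]
            if sequenced_only and not ind.sequenced:
                continue
            if ind.affection == AFFECTED:
                affected.append(i)
            elif ind.affection == UNAFFECTED:
                unaffected.append(i)
        return affected, unaffected


def mendelian_check(
    ped: Pedigree, genotypes: Mapping[str, str]
) -> list[tuple[str, str, str]]:
    """Find Mendelian-impossible trios at one biallelic site.

    Returns ``(child, father, mother)`` triples whose called genotypes
    are incompatible with biallelic transmission.  A trio with any
    missing call is never reported: low-coverage no-calls are treated as
    non-informative rather than as evidence of error.
    """
    violations = []
    for i in ped.nonfounders:
        ind = ped.individuals[i]
        gc = genotypes.get(i, MISSING)
        gf = genotypes.get(ind.father_id, MISSING)
        gm = genotypes.get(ind.mother_id, MISSING)
        if MISSING in (gc, gf, gm):
            continue
        ta, tb = _TRANSMISSIBLE[gf], _TRANSMISSIBLE[gm]
        if gc == HOM_REF:
            ok = 0 in ta and 0 in tb
        elif gc == HOM_ALT:
            ok = 1 in ta and 1 in tb
        else:  # het
            ok = (0 in ta and 1 in tb) or (1 in ta and 0 in tb)
        if not ok:
            violations.append((i, ind.father_id, ind.mother_id))
    return violations


# -- LINKAGE/PED I/O -------------------------------------------------------

_SEX_IN = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_OUT = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
_AFF_IN = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_AFF_OUT = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}


def with_sequenced(ped: Pedigree, sample_ids: Iterable[str]) -> Pedigree:
    """Copy of the pedigree with ``sequenced`` set for the given ids.

    PED files carry no sequencing flag, so pipelines mark the members
    that actually have genotype columns in the accompanying VCF.
    """
    wanted = set(sample_ids)
    unknown = wanted - set(ped.individuals)
    if unknown:
        raise ConfigurationError(
            f"sequenced samples not in pedigree: {sorted(unknown)}"
        )
    return Pedigree(
        Individual(
            id=ind.id,
            father_id=ind.father_id,
            mother_id=ind.mother_id,
            sex=ind.sex,
            affection=ind.affection,
            sequenced=ind.id in wanted,
            generation_label=ind.generation_label,
        )
        for ind in ped.individuals.values()
    )


def read_ped(path: str) -> Pedigree:
    """Read a 6-column LINKAGE/PED pedigree file.

    Columns: family_id, individual_id, father_id, mother_id,
    sex (1=male, 2=female, 0=unknown), phenotype (1=unaffected,
    2=affected, 0 or -9=unknown).  "0" denotes an absent parent.
    Multiple family ids in one file are rejected.
    """
    individuals: list[Individual] = []
    family_id: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError("PED line has fewer than 6 columns", lineno)
            fam, iid, fid, mid, sex, pheno = fields[:6]
            if family_id is None:
                family_id = fam
            elif fam != family_id:
                raise ParseError(
                    f"multiple family ids ({family_id!r}, {fam!r}) in one file",
                    lineno,
                )
            if sex not in _SEX_IN:
                raise ParseError(f"bad sex code {sex!r}", lineno)
            if pheno not in _AFF_IN:
                raise ParseError(f"bad phenotype code {pheno!r}", lineno)
            try:
                individuals.append(
                    Individual(
                        id=iid,
                        father_id=None if fid == "0" else fid,
                        mother_id=None if mid == "0" else mid,
                        sex=_SEX_IN[sex],
                        affection=_AFF_IN[pheno],
                    )
                )
            except ConfigurationError as exc:
                raise ParseError(str(exc), lineno) from None
    return Pedigree(individuals)


def write_ped(ped: Pedigree, path: str, family_id: str = "FAM1") -> None:
    """Write the 6-column LINKAGE/PED dialect read by :func:`read_ped`."""
    with open(path, "w") as fh:
        for i in ped.members:
            ind = ped.individuals[i]
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        _AFF_OUT[ind.affection],
                    ]
                )
                + "\n"
            )
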