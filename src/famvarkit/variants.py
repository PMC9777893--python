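"""Annotated variant records, genomic intervals and chromatin-state tracks.

Internal coordinates are 1-based fully closed (the VCF convention);
BED's 0-based half-open intervals are converted at the file boundary.
"A reference-panel allele frequency of ``None`` means the variant is
novel (absent from the frequency panel), which is distinct from a
frequency of 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

from .errors import ParseError
from .pedigree import HET, HOM_ALT, HOM_REF, MISSING

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: default INFO-key names for the annotation bundle
DEFAULT_INFO_KEYS = {
    "impact": "IMPACT",
    "af": "AF_PANEL",
    "gerp": "GERP",
    "pp2": "PP2",
    "sift": "SIFT",
    "cadd": "CADD",
}


@dataclass(frozen=True)
class GenomicInterval:
    """1-based fully closed interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def distance_to(self, chrom: str, pos: int) -> float:
        """bp distance from pos to the interval (0 inside; inf off-chromosome)."""
        if chrom != self.chrom:
            return math.inf
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0.0


@dataclass(frozen=True)
class ChromatinSegment:
    """A chromatin-state segment (e.g. "Strong_Enhancer") in one cell line."""

    interval: GenomicInterval
    state: str
    cell_line: str = ""


@dataclass
class VariantRecord:
    """One biallelic variant with its annotation bundle and genotype calls.

    Multiallelic VCF sites are split on read, one record per alt allele,
    with genotypes recoded against that alt (other alts count as ref).
    ``ref_panel_af is None`` encodes a novel variant.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    impact: str | None = None
    ref_panel_af: float | None = None
    gerp: float | None = None
    pp2: float | None = None
    sift: float | None = None
    cadd: float | None = None
    genotypes: dict[str, str] = field(default_factory=dict)
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"bad alleles {self.ref!r}>{self.alt!r}")

    @property
    def is_novel(self) -> bool:
        return self.ref_panel_af is None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def in_interval(v: VariantRecord, region: GenomicInterval) -> bool:
    """True iff the variant position lies in the region (bounds inclusive)."""
    return region.contains(v.chrom, v.pos)


# -- VCF -------------------------------------------------------------------


def _gt_code(gt_type: int) -> str:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}[gt_type]


def _split_info(value, n_alt: int, alt_index: int):
    """Pick the per-alt entry from an INFO value (Number=A style tuples)."""
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    return value


def read_vcf(
    path: str,
    info_key_map: Mapping[str, str] | None = None,
    samples: Sequence[str] | None = None,
) -> list[VariantRecord]:
    """Read a VCF 4.x file into :class:`VariantRecord` objects.

    ``info_key_map`` names the INFO keys holding the annotation bundle
    (defaults to :data:`DEFAULT_INFO_KEYS`); absent keys yield absent
    annotation fields.  Multiallelic sites are split into one record per
    alt allele: for each alt, genotypes are recoded so that any other
    alt allele counts as reference.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_key_map:
        keys.update(info_key_map)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise ParseError(f"cannot open VCF {path!r}: {exc}") from exc
    sample_names = list(vcf.samples)
    records: list[VariantRecord] = []
    try:
        for var in vcf:
            alts = var.ALT or []
            for ai, alt in enumerate(alts):
                alt_code = ai + 1
                genotypes: dict[str, str] = {}
                for si, name in enumerate(sample_names):
                    alleles = var.genotypes[si][:-1]  # last entry is phasing
                    if any(a < 0 for a in alleles):
                        genotypes[name] = MISSING
                    else:
                        dose = sum(1 for a in alleles if a == alt_code)
                        genotypes[name] = (HOM_REF, HET, HOM_ALT)[dose]
                anno = {}
                for field_name, info_key in keys.items():
                    raw = var.INFO.get(info_key)
                    if raw is None:
                        anno[field_name] = None
                        continue
                    val = _split_info(raw, len(alts), ai)
                    if val is None or (isinstance(val, str) and val == "."):
                        anno[field_name] = None
                    elif field_name == "impact":
                        anno[field_name] = str(val)
                    else:
                        anno[field_name] = float(val)
                records.append(
                    VariantRecord(
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF,
                        alt=alt,
                        impact=anno["impact"],
                        ref_panel_af=anno["af"],
                        gerp=anno["gerp"],
                        pp2=anno["pp2"],
                        sift=anno["sift"],
                        cadd=anno["cadd"],
                        genotypes=genotypes,
                        id=var.ID or ".",
                    )
                )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"malformed VCF record in {path!r}: {exc}") from exc
    if samples is not None:
        missing = set(samples) - set(sample_names)
        if missing:
            raise ParseError(f"VCF lacks samples {sorted(missing)}")
    return records


_GT_OUT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

# numeric annotations are declared Type=String so readers recover the
# full double-precision repr (VCF Float is 32-bit in htslib-based parsers)
_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID={impact},Number=1,Type=String,Description="Predicted impact class">',
    '##INFO=<ID={af},Number=1,Type=String,Description="Reference-panel allele frequency">',
    '##INFO=<ID={gerp},Number=1,Type=String,Description="GERP++ rejected-substitution score">',
    '##INFO=<ID={pp2},Number=1,Type=String,Description="PolyPhen2 probability">',
    '##INFO=<ID={sift},Number=1,Type=String,Description="SIFT score">',
    '##INFO=<ID={cadd},Number=1,Type=String,Description="CADD PHRED score">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(
    records: Iterable[VariantRecord],
    path: str,
    samples: Sequence[str],
    info_key_map: Mapping[str, str] | None = None,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write records as a minimal VCF 4.2 file with GT-only genotype columns.

    Float annotations are printed with :func:`repr` so that a
    write-then-read round trip preserves them bit-exactly.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_key_map:
        keys.update(info_key_map)
    records = list(records)
    lines = [ln.format(**keys) for ln in _VCF_HEADER_LINES]
    for contig in contigs or sorted({r.chrom for r in records}):
        lines.insert(1, f"##contig=<ID={contig}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header_cols + list(samples)))
    for r in records:
        info_parts = []
        for field_name, value in (
            ("impact", r.impact),
            ("af", r.ref_panel_af),
            ("gerp", r.gerp),
            ("pp2", r.pp2),
            ("sift", r.sift),
            ("cadd", r.cadd),
        ):
            if value is None:
                continue
            rendered = value if field_name == "impact" else repr(float(value))
            info_parts.append(f"{keys[field_name]}={rendered}")
        row = [
            r.chrom,
            str(r.pos),
            r.id,
            r.ref,
            r.alt,
            ".",
            "PASS",
            ";".join(info_parts) or ".",
            "GT",
        ]
        row.extend(_GT_OUT[r.genotypes.get(s, MISSING)] for s in samples)
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- BED -------------------------------------------------------------------


def read_bed(path: str, state_column: int = 3) -> list[ChromatinSegment]:
    """Read BED3+ into chromatin segments (1-based closed internally).

    ``state_column`` is the 0-based index of the column used as the
    state label (BED "name" column by default); missing columns yield an
    empty state.  A trailing column may carry the cell line.
    """
    segments: list[ChromatinSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError("BED line has fewer than 3 columns", lineno)
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer BED coordinates {fields[1]!r}/{fields[2]!r}", lineno
                ) from None
            state = fields[state_column] if len(fields) > state_column else ""
            cell = fields[4] if len(fields) > 4 else ""
            segments.append(
                ChromatinSegment(
                    interval=GenomicInterval(chrom, start0 + 1, end0),
                    state=state,
                    cell_line=cell,
                )
            )
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return segments


def write_bed(segments: Iterable[ChromatinSegment], path: str) -> None:
    """Write segments back to BED4(+cell) with 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for s in segments:
            cols = [
                s.interval.chrom,
                str(s.interval.start - 1),
                str(s.interval.end),
                s.state,
            ]
            if s.cell_line:
                cols.append(s.cell_line)
            fh.write("\t".join(cols) + "\n")
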