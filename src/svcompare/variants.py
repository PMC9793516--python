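"""Normalized structural-variant records and per-record filtering.

The comparison engine works on a light-weight, VCF-independent record type.
Coordinates are internally 0-based half-open:

* deletions span the deleted reference bases, so ``end - start == svlen``
  (the VCF anchor base is trimmed);
* insertions span the single anchor base, ``end == start + 1``, and their
  substituted allele sequence is the full ALT (anchor + inserted bases).
  A strictly positive span keeps the strict reference-distance inequality
  well-behaved for events that have no physical span over the reference.

Breakend (BND) records are recognized but never enter comparison streams.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import NamedTuple


class SVType(enum.Enum):
    DEL = "DEL"
    INS = "INS"
    INV = "INV"
    DUP = "DUP"
    OTHER = "OTHER"
    BND = "BND"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Genotype(NamedTuple):
    """Allele indices for one sample; ``None`` marks a missing allele."""

    alleles: tuple
    phased: bool = False

    @property
    def alt_count(self) -> int:
        return sum(1 for a in self.alleles if a is not None and a > 0)

    @property
    def is_present(self) -> bool:
        """Non-reference-homozygous, i.e. carries at least one ALT allele."""
        return self.alt_count > 0


class UnsizedRecordError(ValueError):
    """A symbolic record with no SVLEN/END cannot be sized."""


class MultiallelicError(ValueError):
    """Multiallelic sites must be split upstream (one ALT per record)."""


_BND_RE = re.compile(r"[\[\]]")
_SYMBOLIC_RE = re.compile(r"^<(\w+)(:[\w:]+)?>$")

_NON_BND_TYPES = frozenset(t.value for t in SVType if t is not SVType.BND)


def infer_svtype(ref_allele: str | None, alt_allele: str | None,
                 info_svtype: str | None = None) -> SVType:
    """Classify a VCF allele pair into an SV type.

    An explicit, recognized INFO/SVTYPE wins.  Otherwise the allele lengths
    decide between DEL and INS; symbolic ALTs map to their token; breakend
    notation maps to BND.  Anything unparseable is OTHER, never an error.
    """
    if info_svtype:
        token = info_svtype.upper()
        if token == "BND" or token == "TRA":
            return SVType.BND
        if token in _NON_BND_TYPES:
            return SVType[token]
    if alt_allele:
        if _BND_RE.search(alt_allele) or alt_allele in (".", "*"):
            return SVType.BND if _BND_RE.search(alt_allele) else SVType.OTHER
        m = _SYMBOLIC_RE.match(alt_allele)
        if m:
            token = m.group(1).upper()
            if token in _NON_BND_TYPES:
                return SVType[token]
            if token == "BND" or token == "TRA":
                return SVType.BND
            return SVType.OTHER
    if ref_allele and alt_allele:
        if len(ref_allele) > len(alt_allele):
            return SVType.DEL
        if len(alt_allele) > len(ref_allele):
            return SVType.INS
        return SVType.OTHER
    return SVType.OTHER


@dataclass
class VariantRecord:
    """One normalized, sequence-resolved (or symbolic) SV call.

    ``start``/``end`` follow the internal convention documented in the module
    docstring; ``vcf_pos`` keeps the original 0-based VCF POS so records
    round-trip losslessly.  ``allele_seq`` is the sequence substituted over
    ``[start, end)`` when building local haplotypes (``None`` for symbolic
    alleles, which cannot be sequence-compared).
    """

    contig: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    svtype: SVType
    svlen: int
    qual: float | None = None
    filters: frozenset = frozenset()
    genotypes: dict = field(default_factory=dict)
    source: str = ""
    record_id: str | None = None
    allele_seq: str | None = None
    vcf_pos: int = 0
    info: dict = field(default_factory=dict)
    sample_fields: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"start {self.start} > end {self.end} at {self.contig}:{self.vcf_pos + 1}")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def is_sequence_resolved(self) -> bool:
        return self.allele_seq is not None

    @property
    def key(self) -> tuple:
        return (self.contig, self.vcf_pos, self.ref_allele, self.alt_allele, self.source)

    def __repr__(self):  # pragma: no cover - debugging aid
        return (f"VariantRecord({self.contig}:{self.start}-{self.end} "
                f"{self.svtype} {self.svlen}bp src={self.source!r})")


def make_record(contig: str, pos0: int, ref_allele: str, alt_allele: str, *,
                info_svtype: str | None = None, info_svlen: int | None = None,
                info_end: int | None = None, qual: float | None = None,
                filters=(), genotypes: dict | None = None, source: str = "",
                record_id: str | None = None, info: dict | None = None,
                sample_fields: dict | None = None) -> VariantRecord:
    """Normalize one VCF-style allele pair into a :class:`VariantRecord`.

    ``pos0`` is the 0-based POS.  Raises :class:`UnsizedRecordError` for
    symbolic alleles carrying neither SVLEN nor END.
    """
    svtype = infer_svtype(ref_allele, alt_allele, info_svtype)
    symbolic = bool(_SYMBOLIC_RE.match(alt_allele)) or svtype is SVType.BND

    if symbolic:
        if info_svlen is not None:
            svlen = abs(info_svlen)
        elif info_end is not None:
            svlen = max(1, info_end - (pos0 + 1))
        elif svtype is SVType.BND:
            svlen = 1
        else:
            raise UnsizedRecordError(
                f"symbolic {svtype} at {contig}:{pos0 + 1} has neither SVLEN nor END")
        allele_seq = None
        if svtype is SVType.INS:
            start, end = pos0, pos0 + 1
        else:
            start, end = pos0 + 1, pos0 + 1 + svlen
    else:
        if info_svlen is not None:
            svlen = abs(info_svlen)
        else:
            svlen = abs(len(alt_allele) - len(ref_allele))
        svlen = max(1, svlen)
        if svtype is SVType.INS:
            # anchor-base span; full ALT substitutes the anchor
            start, end = pos0, pos0 + 1
            allele_seq = alt_allele
        else:
            # trim the shared leading anchor base when present
            if ref_allele and alt_allele and ref_allele[0] == alt_allele[0]:
                start = pos0 + 1
                end = pos0 + len(ref_allele)
                allele_seq = alt_allele[1:]
            else:
                start = pos0
                end = pos0 + len(ref_allele)
                allele_seq = alt_allele

    return VariantRecord(
        contig=contig, start=start, end=end, ref_allele=ref_allele,
        alt_allele=alt_allele, svtype=svtype, svlen=svlen, qual=qual,
        filters=frozenset(filters), genotypes=genotypes or {}, source=source,
        record_id=record_id, allele_seq=allele_seq, vcf_pos=pos0,
        info=info or {}, sample_fields=sample_fields or {})


def infer_size(record: VariantRecord) -> int:
    """Length of the variant in bp (a DEL's size equals its reference span)."""
    if record.svtype is SVType.BND:
        raise ValueError("breakend records have no defined size")
    return record.svlen


@dataclass
class FilterParams:
    """Per-record inclusion rules applied by the chunker before grouping.

    ``include_regions`` maps contig -> list of 0-based half-open intervals;
    a record is kept when its start lies inside any interval of its contig.
    ``require_present_genotype`` names a sample that must carry an ALT allele.
    """

    sizemin: int = 50
    sizemax: int = 50_000
    passonly: bool = False
    include_regions: dict | None = None
    require_present_genotype: str | None = None

    def __post_init__(self):
        if not (0 < self.sizemin <= self.sizemax):
            raise ValueError(f"need 0 < sizemin <= sizemax, got "
                             f"{self.sizemin}..{self.sizemax}")


_PASSING_FILTERS = (frozenset(), frozenset({"PASS"}), frozenset({"."}))


def passes_filters(record: VariantRecord, filters: FilterParams) -> bool:
    """True when the record survives size/FILTER/region/genotype restriction."""
    if not (filters.sizemin <= record.svlen <= filters.sizemax):
        return False
    if filters.passonly and record.filters not in _PASSING_FILTERS:
        return False
    if filters.include_regions is not None:
        intervals = filters.include_regions.get(record.contig, ())
        if not any(s <= record.start < e for s, e in intervals):
            return False
    if filters.require_present_genotype is not None:
        sample = filters.require_present_genotype
        if sample not in record.genotypes:
            raise KeyError(
                f"sample {sample!r} absent from record at "
                f"{record.contig}:{record.vcf_pos + 1} (source {record.source!r})")
        if not record.genotypes[sample].is_present:
            return False
    return True
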