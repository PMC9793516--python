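"""VCF and BED input/output behind the normalized record model.

Reading goes through pysam; each ALT is normalized into a
:class:`~svcompare.variants.VariantRecord`.  Multiallelic sites are rejected
with an instructive error — every similarity formula is defined on a single
allele, so inputs must be split upstream (e.g. ``bcftools norm -m-any``).

Writers rebuild pysam headers carrying the INFO tags this package emits
(TruScore, PctSeqSimilarity, ...) and, when given a source header, the
FORMAT definitions needed to round-trip per-sample fields.
"""

from __future__ import annotations

import json
import os
from typing import Iterator

import pysam

from .variants import Genotype, MultiallelicError, VariantRecord, make_record

# INFO tags emitted on output records (id, number, type, description)
INFO_TAGS = [
    ("SVTYPE", "1", "String", "Type of structural variant"),
    ("SVLEN", "1", "Integer", "Length of structural variant"),
    ("END", "1", "Integer", "End position of structural variant"),
    ("TruScore", "1", "Float", "Mean of fractional similarity metrics x100"),
    ("PctSeqSimilarity", "1", "Float", "Haplotype sequence similarity"),
    ("PctSizeSimilarity", "1", "Float", "min(len)/max(len) size similarity"),
    ("PctRecOverlap", "1", "Float", "Reciprocal overlap over the max span"),
    ("StartDistance", "1", "Integer", "Base start minus comp start (bp)"),
    ("EndDistance", "1", "Integer", "Base end minus comp end (bp)"),
    ("GTMatch", "1", "Integer", "1 when designated-sample genotypes agree"),
    ("MatchId", "1", "String", "Identifier linking matched records"),
    ("CollapseId", "1", "String", "Representative record of this call's cluster"),
    ("NumCollapsed", "1", "Integer", "Number of calls collapsed into this record"),
    ("NumNeighbors", "1", "Integer", "Other calls within the neighbor distance"),
    ("NeighId", "1", "Integer", "Transitive proximity-group identifier"),
    ("TRmotif", "1", "String", "Tandem repeat motif"),
    ("TRcopydiff", "1", "Integer", "Signed motif copy-number difference"),
]

_FLOAT_TAGS = {"TruScore", "PctSeqSimilarity", "PctSizeSimilarity", "PctRecOverlap"}


class VCFReader:
    """Stream one sorted VCF as normalized records tagged with a source."""

    def __init__(self, path, source: str | None = None):
        self.path = str(path)
        self.variant_file = pysam.VariantFile(self.path)
        self.header = self.variant_file.header
        self.samples = list(self.header.samples)
        self.source = source if source is not None else self.path

    def __iter__(self) -> Iterator[VariantRecord]:
        for rec in self.variant_file:
            yield self.convert(rec)

    def convert(self, rec) -> VariantRecord:
        alts = rec.alts or ()
        if len(alts) != 1:
            raise MultiallelicError(
                f"record at {rec.chrom}:{rec.pos} has {len(alts)} ALT alleles; "
                "split multiallelic sites upstream (e.g. bcftools norm -m-any)")
        info = dict(rec.info)
        svtype = info.get("SVTYPE")
        if isinstance(svtype, tuple):
            svtype = svtype[0]
        svlen = info.get("SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        genotypes = {}
        sample_fields = {}
        for s in self.samples:
            fmt = rec.samples[s]
            gt = fmt.get("GT")
            if gt is None:
                gt = (None, None)
            genotypes[s] = Genotype(tuple(gt), bool(fmt.phased))
            extra = {k: v for k, v in fmt.items() if k != "GT"}
            if extra:
                sample_fields[s] = extra
        return make_record(
            rec.chrom, rec.start, rec.ref, alts[0],
            info_svtype=svtype,
            info_svlen=int(svlen) if svlen is not None else None,
            info_end=rec.stop, qual=rec.qual,
            filters=set(rec.filter.keys()), genotypes=genotypes,
            source=self.source, record_id=rec.id, info=info,
            sample_fields=sample_fields)

    def close(self):
        self.variant_file.close()


def build_header(contigs: dict, samples=(), template=None) -> pysam.VariantHeader:
    """Header with this package's INFO tags; ``template`` (a pysam header)
    contributes FORMAT definitions so carried per-sample fields round-trip."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for tag, number, typ, desc in INFO_TAGS:
        header.info.add(tag, number, typ, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    if template is not None:
        for key, fmt in template.formats.items():
            if key not in header.formats:
                header.formats.add(fmt.id, fmt.number, fmt.type,
                                   fmt.description or key)
        for fl in template.filters.keys():
            if fl not in ("PASS",) and fl not in header.filters:
                header.filters.add(fl, None, None,
                                   template.filters[fl].description or fl)
    for s in samples:
        header.add_sample(s)
    return header


def _format_info_value(tag: str, value):
    if tag in _FLOAT_TAGS and value is not None:
        return round(float(value), 4)
    return value


def write_vcf(path, records, contigs: dict, samples=(),
              template=None, annotations: dict | None = None) -> str:
    """Write normalized records to a plain-text VCF, sorted by position.

    ``annotations`` maps a record's ``key`` to extra INFO ``{tag: value}``
    pairs (tags must be in :data:`INFO_TAGS`).  Returns the path.
    """
    samples = list(samples)
    header = build_header(contigs, samples, template)
    known_formats = set(header.formats.keys())
    out = pysam.VariantFile(str(path), "w", header=header)
    try:
        for rec in sorted(records, key=lambda r: (r.contig, r.vcf_pos, r.ref_allele,
                                                  r.alt_allele, r.source)):
            row = out.new_record(
                contig=rec.contig, start=rec.vcf_pos,
                alleles=(rec.ref_allele, rec.alt_allele),
                id=rec.record_id, qual=rec.qual)
            row.stop = rec.vcf_pos + max(1, len(rec.ref_allele))
            for f in sorted(rec.filters):
                if f in header.filters:
                    row.filter.add(f)
            extra = dict(rec.info)
            if annotations:
                extra.update(annotations.get(rec.key, {}))
            row.info["SVTYPE"] = rec.svtype.value
            row.info["SVLEN"] = rec.svlen
            for tag, value in extra.items():
                if tag in ("SVTYPE", "SVLEN", "END") or value is None:
                    continue
                if tag in header.info:
                    row.info[tag] = _format_info_value(tag, value)
            for s in samples:
                g = rec.genotypes.get(s)
                if g is not None:
                    row.samples[s]["GT"] = g.alleles
                    row.samples[s].phased = g.phased
                else:
                    row.samples[s]["GT"] = (None, None)
                for k, v in rec.sample_fields.get(s, {}).items():
                    if k in known_formats and k != "GT":
                        row.samples[s][k] = v
            out.write(row)
    finally:
        out.close()
    return str(path)


def contigs_from_records(records, reference=None) -> dict:
    """Contig -> length map, from the reference when given else from spans."""
    contigs: dict = {}
    if reference is not None and isinstance(reference, dict):
        return {name: len(seq) for name, seq in reference.items()}
    if reference is not None and hasattr(reference, "references"):
        return dict(zip(reference.references, reference.lengths))
    for rec in records:
        cur = contigs.get(rec.contig, 0)
        contigs[rec.contig] = max(cur, rec.end + 1000)
    return contigs


def read_bed(path) -> dict:
    """BED (0-based half-open) -> {contig: [(start, end), ...]}."""
    regions: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2])))
    for intervals in regions.values():
        intervals.sort()
    return regions


def read_bed_named(path) -> list:
    """BED with names -> [(contig, start, end, name), ...] (4th col optional)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else f"interval_{i}"
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out


def write_json(obj, path) -> str:
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return str(path)
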