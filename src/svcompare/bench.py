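"""Benchmark a comparison callset against a baseline truth set.

The two sorted VCFs are zipped into one stream, chunked, and every
(baseline, comparison) pair within a chunk is measured.  Single-best
assignment (default) consumes each record at most once; with
``multimatch`` every record reports its best passing partner and may
participate in several matches.  The classified records partition the
filtered inputs into TP-base / TP-comp / FP / FN, summarized as precision,
recall, F1 and genotype concordance.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

from .matching import (Assignment, MatchParams, assign_multi,
                       assign_single_best, match_matrix)
from .stream import chunk_stream, default_chunksize, zip_variants
from .variants import FilterParams, VariantRecord
from .vcfio import VCFReader, contigs_from_records, write_json, write_vcf

BASE = "base"
COMP = "comp"


class BenchError(RuntimeError):
    """Benchmarking cannot proceed (e.g. empty baseline after filtering)."""


@dataclass
class BenchSummary:
    """TP/FP/FN tallies and the derived rates.

    ``precision = tp_comp / call_cnt``; ``recall = tp_base / base_cnt``;
    ``f1 = 2 * precision * recall / (precision + recall)``.  Undefined
    (zero-denominator) rates are ``None``, never 0.  ``filtered`` counts
    comparison calls removed by the pre-comparison filters and excluded
    from ``call_cnt``.
    """

    tp_base: int = 0
    tp_comp: int = 0
    fp: int = 0
    fn: int = 0
    base_cnt: int = 0
    call_cnt: int = 0
    filtered: int = 0
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    gt_concordance: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(tp_base: int, tp_comp: int, fp: int, fn: int, filtered: int = 0,
              gt_pairs: int = 0, gt_matched: int = 0) -> BenchSummary:
    """Populate a :class:`BenchSummary` from classification counts."""
    s = BenchSummary(tp_base=tp_base, tp_comp=tp_comp, fp=fp, fn=fn,
                     base_cnt=tp_base + fn, call_cnt=tp_comp + fp,
                     filtered=filtered)
    if s.call_cnt > 0:
        s.precision = s.tp_comp / s.call_cnt
    if s.base_cnt > 0:
        s.recall = s.tp_base / s.base_cnt
    if s.precision is not None and s.recall is not None \
            and (s.precision + s.recall) > 0:
        s.f1 = 2 * s.precision * s.recall / (s.precision + s.recall)
    if gt_pairs > 0:
        s.gt_concordance = gt_matched / gt_pairs
    return s


@dataclass
class BenchResult:
    """Classified record streams plus the summary.

    ``tp_base``/``tp_comp`` hold ``(record, best MatchResult)`` pairs;
    ``fp``/``fn`` hold bare records.  Every filtered input record appears in
    exactly one of the four sets.
    """

    summary: BenchSummary
    tp_base: list = field(default_factory=list)
    tp_comp: list = field(default_factory=list)
    fp: list = field(default_factory=list)
    fn: list = field(default_factory=list)
    filtered_comp: list = field(default_factory=list)
    filtered_base: list = field(default_factory=list)
    pairs: list = field(default_factory=list)


def _as_stream(source_obj, tag: str):
    """(records iterator, samples, template header) for a path or record list."""
    if isinstance(source_obj, (str, os.PathLike)):
        reader = VCFReader(source_obj, source=tag)
        return iter(reader), reader.samples, reader.header

    def retag(records):
        for rec in records:
            yield dataclasses.replace(rec, source=tag) \
                if rec.source != tag else rec

    records = list(source_obj)
    samples: list = []
    for rec in records:
        for s in rec.genotypes:
            if s not in samples:
                samples.append(s)
    return retag(records), samples, None


def run_bench(base, comp, reference=None, params: MatchParams | None = None,
              filters: FilterParams | None = None, chunksize: int | None = None,
              base_sample: str | None = None,
              comp_sample: str | None = None) -> BenchResult:
    """Classify a comparison callset against a baseline.

    ``base``/``comp`` are VCF paths or iterables of normalized records;
    ``reference`` is required whenever ``params.pctseq > 0``.  Genotype
    concordance is evaluated on one designated sample per file (the first
    sample unless overridden).
    """
    params = params or MatchParams()
    base_stream, base_samples, base_header = _as_stream(base, BASE)
    comp_stream, comp_samples, comp_header = _as_stream(comp, COMP)
    if base_sample is None and base_samples:
        base_sample = base_samples[0]
    if comp_sample is None and comp_samples:
        comp_sample = comp_samples[0]

    filtered: list = []
    stream = zip_variants([base_stream, comp_stream])
    chunks = chunk_stream(stream, chunksize or default_chunksize(params.refdist),
                          filters, filtered)

    result = BenchResult(summary=BenchSummary())
    gt_pairs = gt_matched = 0
    for chunk in chunks:
        bases = chunk.by_source(BASE)
        comps = chunk.by_source(COMP)
        if not bases or not comps:
            result.fn.extend(bases)
            result.fp.extend(comps)
            continue
        matrix = match_matrix(bases, comps, params, reference,
                              base_sample, comp_sample)
        assigner = assign_multi if params.multimatch else assign_single_best
        asn: Assignment = assigner(matrix, bases, comps)
        result.pairs.extend(asn.tp_pairs)
        row_best: dict = {}
        col_best: dict = {}
        for m in asn.tp_pairs:
            if m.base_idx not in row_best \
                    or m.truscore > row_best[m.base_idx].truscore:
                row_best[m.base_idx] = m
            if m.comp_idx not in col_best \
                    or m.truscore > col_best[m.comp_idx].truscore:
                col_best[m.comp_idx] = m
            if m.gt_match is not None:
                gt_pairs += 1
                gt_matched += int(m.gt_match)
        result.tp_base.extend((bases[i], m) for i, m in sorted(row_best.items()))
        result.tp_comp.extend((comps[j], m) for j, m in sorted(col_best.items()))
        result.fn.extend(asn.fn_bases)
        result.fp.extend(asn.fp_comps)

    result.filtered_base = [r for r in filtered if r.source == BASE]
    result.filtered_comp = [r for r in filtered if r.source == COMP]

    if len(result.tp_base) + len(result.fn) == 0:
        raise BenchError("baseline is empty after filtering; recall undefined")
    result.summary = summarize(
        tp_base=len(result.tp_base), tp_comp=len(result.tp_comp),
        fp=len(result.fp), fn=len(result.fn),
        filtered=len(result.filtered_comp),
        gt_pairs=gt_pairs, gt_matched=gt_matched)
    result._headers = (base_header, comp_header)  # for output writing
    return result


def _match_annotations(match) -> dict:
    return {
        "TruScore": match.truscore,
        "PctSeqSimilarity": match.seqsim,
        "PctSizeSimilarity": match.sizesim,
        "PctRecOverlap": match.recovl,
        "StartDistance": match.start_distance,
        "EndDistance": match.end_distance,
        "GTMatch": None if match.gt_match is None else int(match.gt_match),
        "MatchId": f"{match.base.contig}:{match.base.vcf_pos + 1}",
    }


def write_bench_output(result: BenchResult, outdir, reference=None) -> dict:
    """Write tp-base.vcf / tp-comp.vcf / fp.vcf / fn.vcf / summary.json.

    Returns ``{name: path}`` for the files written.
    """
    os.makedirs(str(outdir), exist_ok=True)
    base_header, comp_header = getattr(result, "_headers", (None, None))
    everything = ([r for r, _ in result.tp_base] + [r for r, _ in result.tp_comp]
                  + result.fp + result.fn)
    contigs = contigs_from_records(everything, reference)
    out = {}

    def samples_of(records, header):
        if header is not None:
            return list(header.samples)
        seen: list = []
        for rec in records:
            for s in rec.genotypes:
                if s not in seen:
                    seen.append(s)
        return seen

    sets = {
        "tp-base": ([r for r, _ in result.tp_base],
                    {r.key: _match_annotations(m) for r, m in result.tp_base},
                    base_header),
        "tp-comp": ([r for r, _ in result.tp_comp],
                    {r.key: _match_annotations(m) for r, m in result.tp_comp},
                    comp_header),
        "fn": (result.fn, None, base_header),
        "fp": (result.fp, None, comp_header),
    }
    for name, (records, annotations, header) in sets.items():
        path = os.path.join(str(outdir), f"{name}.vcf")
        write_vcf(path, records, contigs, samples_of(records, header),
                  template=header, annotations=annotations)
        out[name] = path
    out["summary"] = write_json(result.summary.to_dict(),
                                os.path.join(str(outdir), "summary.json"))
    return out
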