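"""Interval annotations and the tandem-repeat merge audit.

``num_neighbors`` counts, per call, how many other calls lie within a given
distance and assigns a shared neighborhood id to each transitive proximity
group.  ``breakpoint_overlap`` intersects calls with an annotation file
(genes, repeat tracks), reporting breakpoint hits and containment
relations.  The tandem-repeat audit consumes precomputed (motif,
copy-number) annotations — produced upstream by a TRF-style tool or by the
synthetic generator — and labels alleles with identical annotations as
redundant; comparing a merged locus against the exact-merge baseline counts
how many unique alleles the merge lost (missing, over-merging) and how many
redundant representations it left behind (under-merging).
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .variants import SVType, VariantRecord

LOG = logging.getLogger(__name__)


def num_neighbors(records: list, distance: int = 1000) -> list:
    """Per-record neighbor counts and neighborhood ids.

    Two calls are neighbors when the gap between their closest span edges is
    at most ``distance``; a neighborhood is a transitive proximity group (so
    non-neighboring calls bridged by an intermediate share an id).  Input
    must be position-sorted.  Returns ``[(count, neigh_id), ...]`` aligned
    with the input.
    """
    out = [(0, -1)] * len(records)
    neigh_id = -1
    group: list = []  # (index, record)
    max_end = None

    def flush():
        for i, (idx_a, a) in enumerate(group):
            count = 0
            for j, (idx_b, b) in enumerate(group):
                if i == j:
                    continue
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap <= distance:
                    count += 1
            out[idx_a] = (count, neigh_id)

    for idx, rec in enumerate(records):
        if group and (rec.contig != group[-1][1].contig
                      or rec.start > max_end + distance):
            flush()
            group = []
        if not group:
            neigh_id += 1
            max_end = rec.end
        else:
            max_end = max(max_end, rec.end)
        group.append((idx, rec))
    if group:
        flush()
    return out


class IntervalIndex:
    """Static per-contig interval lookup (sorted starts + running max end)."""

    def __init__(self, intervals: list):
        """``intervals``: [(contig, start, end, name), ...]; malformed
        entries (end <= start) are skipped with a warning."""
        self._by_contig: dict = {}
        for contig, start, end, name in intervals:
            if end <= start:
                LOG.warning("skipping malformed interval %s:%d-%d (%s)",
                            contig, start, end, name)
                continue
            self._by_contig.setdefault(contig, []).append((start, end, name))
        self._arrays: dict = {}
        for contig, ivs in self._by_contig.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            self._arrays[contig] = (starts, ends, np.maximum.accumulate(ends), ivs)

    def overlapping(self, contig: str, start: int, end: int) -> list:
        """All (start, end, name) intervals overlapping [start, end)."""
        if contig not in self._arrays:
            return []
        starts, ends, _maxends, ivs = self._arrays[contig]
        hi = bisect_right(starts.tolist(), end - 1)
        idx = np.nonzero(ends[:hi] > start)[0]
        return [ivs[i] for i in idx]


# relation labels
START_HIT = "start_hit"
END_HIT = "end_hit"
CONTAINED_WITHIN = "contained_within"
COMPLETELY_OVERLAPS = "completely_overlaps"


def _relation(rec: VariantRecord, iv_start: int, iv_end: int) -> str:
    if rec.svtype is SVType.INS:
        # point events only register breakpoint hits
        return START_HIT
    if rec.start <= iv_start and iv_end <= rec.end:
        return COMPLETELY_OVERLAPS
    if iv_start <= rec.start and rec.end <= iv_end:
        return CONTAINED_WITHIN
    if iv_start <= rec.start < iv_end:
        return START_HIT
    return END_HIT


def breakpoint_overlap(records: list, intervals) -> list:
    """Intersect each call with annotation intervals.

    ``intervals`` is an :class:`IntervalIndex` or a raw
    ``[(contig, start, end, name), ...]`` list.  Returns, per record, a list
    of ``(name, relation)`` hits where relation is one of ``start_hit``,
    ``end_hit``, ``contained_within`` (variant inside the interval) or
    ``completely_overlaps`` (variant spans the whole interval).
    """
    index = intervals if isinstance(intervals, IntervalIndex) \
        else IntervalIndex(list(intervals))
    out = []
    for rec in records:
        hits = [(name, _relation(rec, s, e))
                for s, e, name in index.overlapping(rec.contig, rec.start, rec.end)]
        out.append(hits)
    return out


@dataclass(frozen=True)
class TRAnnotation:
    """Tandem-repeat annotation of one allele: motif and signed copy change."""

    locus_id: str
    motif: str
    copy_diff: int

    def __post_init__(self):
        if abs(self.copy_diff) < 1:
            raise ValueError("copy_diff must be non-zero")
        if len(self.motif) < 1:
            raise ValueError("motif must be non-empty")

    @property
    def key(self) -> tuple:
        return (self.motif, self.copy_diff)


def classify_tr_alleles(annotations: list) -> list:
    """Label each allele of one locus as ``unique`` or ``redundant``.

    Within each (motif, copy_diff) group the first allele is the unique
    representative and the rest are redundant.  All annotations must share a
    locus id.
    """
    loci = {a.locus_id for a in annotations}
    if len(loci) > 1:
        raise ValueError(f"annotations span multiple loci: {sorted(loci)}")
    seen: set = set()
    labels = []
    for a in annotations:
        if a.key in seen:
            labels.append("redundant")
        else:
            seen.add(a.key)
            labels.append("unique")
    return labels


@dataclass
class TRLocusAudit:
    """Per-locus merge audit: distinct, leftover-redundant, and lost alleles."""

    locus_id: str
    unique_count: int
    redundant_count: int
    missing_count: int

    @property
    def total_error(self) -> int:
        return self.redundant_count + self.missing_count


def audit_merge(baseline: list, merged: list) -> TRLocusAudit:
    """Audit one locus of a merged callset against the exact-merge baseline.

    ``missing`` counts baseline (motif, copy_diff) keys with no
    representative left after the merge (over-merging); ``redundant`` counts
    merged alleles beyond one per key (under-merging).
    """
    base_loci = {a.locus_id for a in baseline}
    merged_loci = {a.locus_id for a in merged}
    if len(base_loci | merged_loci) > 1:
        raise ValueError(
            f"locus mismatch: baseline {sorted(base_loci)} vs merged "
            f"{sorted(merged_loci)}")
    locus_id = next(iter(base_loci | merged_loci))
    base_keys = {a.key for a in baseline}
    merged_keys = [a.key for a in merged]
    distinct = set(merged_keys)
    return TRLocusAudit(
        locus_id=locus_id,
        unique_count=len(distinct),
        redundant_count=len(merged_keys) - len(distinct),
        missing_count=len(base_keys - distinct))


@dataclass
class TRAuditTable:
    """Audit results across loci, with the identical-loci exclusion rule."""

    audits: dict = field(default_factory=dict)  # locus_id -> [TRLocusAudit per merge]

    def summary(self, exclude_identical: bool = True) -> dict:
        """Aggregate missing/redundant per merge; loci whose audits are
        identical across every compared merge are excluded."""
        n_merges = max((len(v) for v in self.audits.values()), default=0)
        totals = [dict(missing=0, redundant=0, loci=0) for _ in range(n_merges)]
        for _locus, audits in sorted(self.audits.items()):
            if exclude_identical and len({(a.missing_count, a.redundant_count,
                                           a.unique_count) for a in audits}) == 1 \
                    and len(audits) > 1:
                continue
            for t, a in zip(totals, audits):
                t["missing"] += a.missing_count
                t["redundant"] += a.redundant_count
                t["loci"] += 1
        return {"per_merge": totals, "n_loci": len(self.audits)}


def read_tr_annotations(path) -> dict:
    """Read a 5-column TSV (contig, start, locus_id, motif, copy_diff).

    Returns ``{(contig, start): TRAnnotation}`` with 0-based starts, for
    joining onto VCF records by anchor position.
    """
    out: dict = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            contig, start, locus_id, motif, copy_diff = row[:5]
            out[(contig, int(start))] = TRAnnotation(
                locus_id=locus_id, motif=motif, copy_diff=int(copy_diff))
    return out


def write_tr_annotations(annotated: list, path) -> str:
    """Write ``[(record, TRAnnotation), ...]`` as the 5-column TSV."""
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec, ann in annotated:
            w.writerow([rec.contig, rec.vcf_pos, ann.locus_id, ann.motif,
                        ann.copy_diff])
    return str(path)


def annotations_for_records(records: list, table: dict) -> list:
    """Join VCF records to TR annotations by (contig, 0-based POS)."""
    out = []
    for rec in records:
        ann = table.get((rec.contig, rec.vcf_pos))
        if ann is not None:
            out.append(ann)
    return out
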