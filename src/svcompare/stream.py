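"""Zipper/chunker: merge sorted variant streams and group comparable calls.

Multiple sorted VCF streams are treated as a single stack ("zipped"): the
globally merge-sorted stream, ordered by (contig, position), stable for ties
in input order.  The zipped stream is then "chunked": a new chunk starts
exactly when the next variant's start exceeds the running maximum end of the
current chunk plus ``chunksize``, or when the contig changes.  Because no two
records in different chunks can be closer than ``chunksize``, choosing
``chunksize >= refdist`` guarantees no cross-chunk pair can ever satisfy the
reference-distance check — chunking is then a pure performance device.

The chunker also applies per-record filtering; excluded records are reported
through an optional side list so benchmarking can count filtered calls.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .variants import FilterParams, SVType, VariantRecord, passes_filters


class SortOrderError(ValueError):
    """Input VCF violates (contig, position) sort order."""


def _checked(stream: Iterable[VariantRecord], rank: int) -> Iterator[tuple]:
    """Tag records with a merge key, enforcing ascending sort per stream."""
    last = None
    for i, rec in enumerate(stream):
        key = (rec.contig, rec.vcf_pos)
        if last is not None:
            if key[0] == last[0] and key[1] < last[1]:
                raise SortOrderError(
                    f"out-of-order record at {rec.contig}:{rec.vcf_pos + 1} "
                    f"(previous position {last[1] + 1}) in source {rec.source!r}")
            if key[0] < last[0]:
                raise SortOrderError(
                    f"contig {rec.contig!r} follows {last[0]!r} in source "
                    f"{rec.source!r}; contigs must ascend alphanumerically")
        last = key
        yield (rec.contig, rec.vcf_pos, rank, i, rec)


def zip_variants(streams: list) -> Iterator[VariantRecord]:
    """Merge-sort several per-source record streams into one stack.

    Ties at the same (contig, position) keep input order (base before comp
    when the base stream is passed first).  Each input must already be sorted
    with contigs in ascending alphanumeric order.
    """
    tagged = [_checked(s, rank) for rank, s in enumerate(streams)]
    for *_key, rec in heapq.merge(*tagged):
        yield rec


@dataclass
class Chunk:
    """A positionally isolated group of co-comparable variants."""

    contig: str
    members: list = field(default_factory=list)

    @property
    def span(self) -> tuple:
        return (min(m.start for m in self.members),
                max(m.end for m in self.members))

    def by_source(self, source: str) -> list:
        return [m for m in self.members if m.source == source]

    def __len__(self):
        return len(self.members)


def chunk_stream(stream: Iterable[VariantRecord], chunksize: int = 1000,
                 filters: FilterParams | None = None,
                 filtered_out: list | None = None) -> Iterator[Chunk]:
    """Group a zipped stream into chunks of mutually comparable records.

    Records failing ``filters`` (and all BND records) are excluded before
    grouping and appended to ``filtered_out`` when given.  Concatenating the
    emitted chunks reproduces the filtered stream exactly.
    """
    cur: Chunk | None = None
    max_end = None
    for rec in stream:
        if rec.svtype is SVType.BND or (
                filters is not None and not passes_filters(rec, filters)):
            if filtered_out is not None:
                filtered_out.append(rec)
            continue
        if cur is None or rec.contig != cur.contig or rec.start > max_end + chunksize:
            if cur is not None:
                yield cur
            cur = Chunk(contig=rec.contig, members=[rec])
            max_end = rec.end
        else:
            cur.members.append(rec)
            max_end = max(max_end, rec.end)
    if cur is not None:
        yield cur


def default_chunksize(refdist: int) -> int:
    """Chunk size guaranteeing no cross-chunk pair can pass refdist."""
    return max(1000, refdist + 1)
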