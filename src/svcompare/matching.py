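"""Pairwise SV similarity metrics, match matrices, and match assignment.

Two calls are compared across five metrics — SV-type match, reference
distance, reciprocal overlap, size similarity, and haplotype sequence
similarity — plus an optional genotype check.  A pair fails as soon as any
enabled metric violates its threshold.  The fractional metrics are averaged
into a TruScore in [0, 100] used to rank candidate matches.

Conventions worth noting:

* Insertions have no physical span over the reference; for reciprocal
  overlap only, an insertion's span is expanded by half its length upstream
  and downstream.
* Sequence similarity is ``1 - edit_distance/(|H1| + |H2|)`` over the two
  local haplotypes built on the shared reference window.  Under this printed
  normalization two unrelated equal-length sequences score ~0.5, not 0; an
  alternative ``1 - 2*ed/(|H1|+|H2|)`` normalization is available via
  ``MatchParams.rescale_seqsim`` (off by default).
* Sequence similarity is skipped (treated as passing, and excluded from the
  TruScore mean) when ``pctseq == 0`` so sequence-free callsets are not
  penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .editdist import edit_distance
from .variants import SVType, VariantRecord


class SequenceComparisonError(ValueError):
    """Sequence similarity requested for a non-sequence-resolved allele."""


@dataclass
class MatchParams:
    """Thresholds for one comparison.

    Benchmarking defaults: 70% sequence and size similarity, 500 bp reference
    distance, SV-type matching, 0% reciprocal overlap.  Collapse uses 95%
    sequence and size similarity (see :meth:`collapse_defaults`).
    """

    refdist: int = 500
    pctseq: float = 0.7
    pctsize: float = 0.7
    pctovl: float = 0.0
    typematch: bool = True
    gtmatch: bool = False
    multimatch: bool = False
    rescale_seqsim: bool = False

    def __post_init__(self):
        for name in ("pctseq", "pctsize", "pctovl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.refdist < 0:
            raise ValueError(f"refdist must be >= 0, got {self.refdist}")

    @classmethod
    def collapse_defaults(cls, **kwargs) -> "MatchParams":
        kwargs.setdefault("pctseq", 0.95)
        kwargs.setdefault("pctsize", 0.95)
        return cls(**kwargs)


@dataclass
class MatchResult:
    """Measured similarity and pass/fail state for one (base, comp) pair.

    ``seqsim`` is ``None`` when sequence comparison was disabled or skipped
    (pair already failed a cheaper check); skipped metrics are excluded from
    the TruScore mean.  Breakpoint distances are signed, base minus comp.
    """

    base: VariantRecord
    comp: VariantRecord
    seqsim: float | None
    sizesim: float
    recovl: float
    start_distance: int
    end_distance: int
    type_match: bool
    gt_match: bool | None
    truscore: float
    state: bool
    base_idx: int = 0
    comp_idx: int = 0

    def sort_key(self) -> tuple:
        """Greedy sweep order: passing first, then TruScore desc, then position."""
        return (not self.state, -self.truscore,
                self.base.start, self.comp.start, self.base_idx, self.comp_idx)


def fetch_reference(reference, contig: str, start: int, end: int) -> str:
    """Reference slice as an upper-case string.

    Accepts a plain ``{contig: sequence}`` dict, a :class:`pyfaidx.Fasta`,
    or a :class:`pysam.FastaFile`.
    """
    if start >= end:
        return ""
    if isinstance(reference, dict):
        return reference[contig][start:end].upper()
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        return reference.fetch(contig, start, end).upper()
    sub = reference[contig][start:end]  # pyfaidx.Fasta
    return str(getattr(sub, "seq", sub)).upper()


def overlap_span(rec: VariantRecord) -> tuple:
    """Span used for reciprocal overlap; INS expanded by half its length."""
    if rec.svtype is SVType.INS:
        half = rec.svlen // 2
        return (rec.start - half, rec.end + half)
    return (rec.start, rec.end)


def reference_distance_ok(a: VariantRecord, b: VariantRecord, refdist: int) -> bool:
    """Strict positional-wobble check: max(S1-rd, S2) < min(E1+rd, E2)."""
    if a.contig != b.contig:
        return False
    return max(a.start - refdist, b.start) < min(a.end + refdist, b.end)


def reciprocal_overlap(a: VariantRecord, b: VariantRecord) -> float:
    """Overlapping bases over the maximum variant span, in [0, 1]."""
    s1, e1 = overlap_span(a)
    s2, e2 = overlap_span(b)
    o_s = max(s1, s2)
    o_e = min(e1, e2)
    if o_s >= o_e:
        return 0.0
    return (o_e - o_s) / max(e1 - s1, e2 - s2)


def size_similarity(a: VariantRecord, b: VariantRecord) -> float:
    """Minimum variant length over maximum variant length."""
    return min(a.svlen, b.svlen) / max(a.svlen, b.svlen)


def build_haplotypes(a: VariantRecord, b: VariantRecord, reference) -> tuple:
    """Local haplotypes over the shared window [min(S1,S2), max(E1,E2)).

    Each variant's allele sequence replaces its own [S, E) span inside the
    window; the surrounding reference context is shared, so two equivalent
    representations produce identical (or near-identical) haplotypes.
    """
    if not a.is_sequence_resolved or not b.is_sequence_resolved:
        raise SequenceComparisonError(
            "sequence similarity requires sequence-resolved alleles; "
            "set pctseq=0 to compare symbolic calls")
    start = min(a.start, b.start)
    end = max(a.end, b.end)
    h1 = (fetch_reference(reference, a.contig, start, a.start) + a.allele_seq
          + fetch_reference(reference, a.contig, a.end, end))
    h2 = (fetch_reference(reference, b.contig, start, b.start) + b.allele_seq
          + fetch_reference(reference, b.contig, b.end, end))
    return h1, h2


def sequence_similarity(a: VariantRecord, b: VariantRecord, reference,
                        rescale: bool = False) -> float:
    """1 - edit_distance/totlen over the pair's local haplotypes, clamped.

    Identical haplotypes (including the degenerate both-empty case for
    identical deletions) score 1.0.  With ``rescale`` the distance is
    normalized by the mean rather than the sum of the haplotype lengths.
    """
    h1, h2 = build_haplotypes(a, b, reference)
    if h1 == h2:
        return 1.0
    totlen = len(h1) + len(h2)
    dist = edit_distance(h1, h2)
    if rescale:
        dist *= 2
    return min(1.0, max(0.0, 1.0 - dist / totlen))


def genotypes_match(a: VariantRecord, b: VariantRecord,
                    a_sample: str | None = None,
                    b_sample: str | None = None) -> bool | None:
    """Compare sorted allele indices of the designated samples, ignoring phase.

    Defaults to each record's first sample; ``None`` when either side has no
    genotype to compare.
    """
    if a_sample is None:
        a_sample = next(iter(a.genotypes), None)
    if b_sample is None:
        b_sample = next(iter(b.genotypes), None)
    if a_sample is None or b_sample is None:
        return None
    ga = a.genotypes.get(a_sample)
    gb = b.genotypes.get(b_sample)
    if ga is None or gb is None:
        return None
    norm = lambda g: tuple(sorted(-1 if x is None else x for x in g.alleles))
    return norm(ga) == norm(gb)


def build_match(a: VariantRecord, b: VariantRecord, params: MatchParams,
                reference=None, base_idx: int = 0, comp_idx: int = 0,
                a_sample: str | None = None,
                b_sample: str | None = None) -> MatchResult:
    """Measure one (base, comp) pair against every enabled metric.

    Sequence similarity is only computed when the cheaper checks pass (its
    cost is quadratic in the window size and a failed pair's exact score can
    only influence ordering among other failed pairs, never the output
    classification).  Symbolic alleles with ``pctseq > 0`` raise
    :class:`SequenceComparisonError` regardless.
    """
    type_match = a.svtype is b.svtype
    ref_ok = reference_distance_ok(a, b, params.refdist)
    sizesim = size_similarity(a, b)
    recovl = reciprocal_overlap(a, b)
    gt_match = genotypes_match(a, b, a_sample, b_sample)

    if params.pctseq > 0 and (not a.is_sequence_resolved
                              or not b.is_sequence_resolved):
        raise SequenceComparisonError(
            f"non-sequence-resolved allele at {a.contig}:{a.vcf_pos + 1} or "
            f"{b.contig}:{b.vcf_pos + 1}; set pctseq=0 to compare symbolic calls")

    cheap_ok = ((type_match or not params.typematch) and ref_ok
                and sizesim >= params.pctsize and recovl >= params.pctovl)
    seqsim: float | None = None
    if params.pctseq > 0 and cheap_ok:
        seqsim = sequence_similarity(a, b, reference, params.rescale_seqsim)

    state = cheap_ok
    if params.pctseq > 0:
        state = state and seqsim is not None and seqsim >= params.pctseq
    if params.gtmatch:
        state = state and bool(gt_match)

    fractions = [recovl, sizesim]
    if seqsim is not None:
        fractions.append(seqsim)
    truscore = 100.0 * sum(fractions) / len(fractions)

    return MatchResult(
        base=a, comp=b, seqsim=seqsim, sizesim=sizesim, recovl=recovl,
        start_distance=a.start - b.start, end_distance=a.end - b.end,
        type_match=type_match, gt_match=gt_match, truscore=truscore,
        state=state, base_idx=base_idx, comp_idx=comp_idx)


def match_matrix(bases: list, comps: list, params: MatchParams,
                 reference=None, base_sample: str | None = None,
                 comp_sample: str | None = None) -> list:
    """All pairwise MatchResults for one chunk (row-major, N x M raveled)."""
    out = []
    for i, a in enumerate(bases):
        for j, b in enumerate(comps):
            out.append(build_match(a, b, params, reference, i, j,
                                   base_sample, comp_sample))
    return out


@dataclass
class Assignment:
    """Classification of one chunk: matched pairs plus leftover FN/FP."""

    tp_pairs: list = field(default_factory=list)
    fn_bases: list = field(default_factory=list)
    fp_comps: list = field(default_factory=list)


def assign_single_best(matches: list, bases: list, comps: list) -> Assignment:
    """Greedy single-best assignment over the raveled, sorted match matrix.

    Pairs are swept passing-first in descending TruScore order (ties broken
    by base then comp start position).  A pair is emitted only when neither
    member was previously consumed; records left without a passing partner
    are false negatives (base side) or false positives (comp side).  Every
    input record is classified exactly once.
    """
    used_base: set = set()
    used_comp: set = set()
    matched_base: set = set()
    matched_comp: set = set()
    out = Assignment()
    for m in sorted(matches, key=MatchResult.sort_key):
        if m.base_idx in used_base or m.comp_idx in used_comp:
            continue
        used_base.add(m.base_idx)
        used_comp.add(m.comp_idx)
        if m.state:
            out.tp_pairs.append(m)
            matched_base.add(m.base_idx)
            matched_comp.add(m.comp_idx)
    out.fn_bases = [b for i, b in enumerate(bases) if i not in matched_base]
    out.fp_comps = [c for j, c in enumerate(comps) if j not in matched_comp]
    return out


def assign_multi(matches: list, bases: list, comps: list) -> Assignment:
    """Row/column-best assignment allowing records in multiple matches.

    Each base reports its best-scoring passing comp partner and vice versa;
    the emitted pair set is the union of both choices (deduplicated), so a
    single baseline call matched by several comparison representations yields
    one TP-base and several TP-comp records.
    """
    best_row: dict = {}
    best_col: dict = {}
    for m in matches:
        if not m.state:
            continue
        key = (m.truscore, -m.comp.start, -m.comp_idx)
        if m.base_idx not in best_row or key > best_row[m.base_idx][0]:
            best_row[m.base_idx] = (key, m)
        key = (m.truscore, -m.base.start, -m.base_idx)
        if m.comp_idx not in best_col or key > best_col[m.comp_idx][0]:
            best_col[m.comp_idx] = (key, m)
    chosen: dict = {}
    for _, m in list(best_row.values()) + list(best_col.values()):
        chosen[(m.base_idx, m.comp_idx)] = m
    out = Assignment(tp_pairs=sorted(chosen.values(),
                                     key=lambda m: (m.base_idx, m.comp_idx)))
    out.fn_bases = [b for i, b in enumerate(bases) if i not in best_row]
    out.fp_comps = [c for j, c in enumerate(comps) if j not in best_col]
    return out
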