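"""Redundancy-aware merging of SV representations (collapse).

Within each chunk an NxN comparison of all calls identifies clusters of
redundant representations of one allele.  Each cluster keeps a single
representative (most upstream, highest QUAL, or most common) and
consolidates genotypes — e.g. two heterozygous representations of the same
allele in one sample become a single homozygous call.  The remaining
members are written to a removed-records stream annotated with their
representative, so ``|kept| + |removed| == |input|`` always holds.

Two collapse-specific switches:

* ``hap`` — haplotype-aware single-sample mode: calls whose genotypes
  cannot coexist on opposite haplotypes (e.g. two hom-ALT calls) are never
  merged.
* ``chain`` — transitive matching: clusters are connected components of the
  passing-match graph, so two calls that only share an intermediate match
  still merge.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

from .matching import MatchParams, build_match
from .stream import chunk_stream, default_chunksize, zip_variants
from .variants import FilterParams, Genotype, VariantRecord

LOG = logging.getLogger(__name__)

KEEP_STRATEGIES = ("first", "maxqual", "common")


@dataclass
class CollapseParams:
    """Collapse configuration; matching defaults are 95%/95%/500 bp."""

    match: MatchParams = field(default_factory=MatchParams.collapse_defaults)
    hap: bool = False
    chain: bool = False
    keep: str = "first"

    def __post_init__(self):
        if self.keep not in KEEP_STRATEGIES:
            raise ValueError(f"keep must be one of {KEEP_STRATEGIES}")


@dataclass
class Cluster:
    """One set of mutually redundant calls and its chosen representative."""

    members: list
    representative: VariantRecord | None = None
    matches: list = field(default_factory=list)


def gt_compatible(a: VariantRecord, b: VariantRecord, sample: str) -> bool:
    """Can these two calls coexist in one individual on separate haplotypes?

    False when both calls place an ALT allele on an overlapping haplotype
    slot: any hom-ALT call conflicts with any other ALT-carrying call, and
    two phased hets conflict when their ALT sits on the same haplotype.
    Unphased het pairs could lie on opposite haplotypes and are compatible.
    Missing genotypes are treated as compatible (logged).
    """
    ga = a.genotypes.get(sample)
    gb = b.genotypes.get(sample)
    if ga is None or gb is None or \
            all(x is None for x in ga.alleles) or \
            all(x is None for x in gb.alleles):
        LOG.debug("missing genotype for %s; treating pair as compatible", sample)
        return True
    if not ga.is_present or not gb.is_present:
        return True
    if ga.alt_count >= 2 or gb.alt_count >= 2:
        return False
    if ga.phased and gb.phased:
        slot = lambda g: next(i for i, x in enumerate(g.alleles)
                              if x is not None and x > 0)
        return slot(ga) != slot(gb)
    return True


def _pair_ok(a: VariantRecord, b: VariantRecord, params: CollapseParams,
             reference, sample: str | None):
    m = build_match(a, b, params.match, reference)
    ok = m.state
    if ok and params.hap and sample is not None:
        ok = gt_compatible(a, b, sample)
    return ok, m


def form_clusters(members: list, params: CollapseParams, reference,
                  sample: str | None = None) -> list:
    """Partition one chunk's calls into clusters of redundant representations.

    Without ``chain``: a position-ordered greedy sweep.  The most upstream
    unconsumed call seeds a cluster and gathers every unconsumed call whose
    pairwise match with the seed passes; because every member directly
    matches its seed and seeds never match each other, re-collapsing the
    kept output removes nothing.  With ``chain``: connected components
    (union-find) of the full passing-match graph.
    """
    if params.chain:
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        evidence = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ok, m = _pair_ok(members[i], members[j], params, reference, sample)
                if ok:
                    parent[find(i)] = find(j)
                    evidence.append(m)
        comps: dict = {}
        for i, rec in enumerate(members):
            comps.setdefault(find(i), []).append(rec)
        clusters = [Cluster(members=group) for _, group in sorted(comps.items())]
        if clusters and evidence:
            clusters[0].matches = evidence  # chunk-level evidence
        return clusters

    clusters = []
    unconsumed = list(members)
    while unconsumed:
        seed = unconsumed.pop(0)
        cluster = Cluster(members=[seed])
        rest = []
        for other in unconsumed:
            ok, m = _pair_ok(seed, other, params, reference, sample)
            if ok:
                cluster.members.append(other)
                cluster.matches.append(m)
            else:
                rest.append(other)
        unconsumed = rest
        clusters.append(cluster)
    return clusters


def _alt_allele_total(rec: VariantRecord) -> int:
    return sum(g.alt_count for g in rec.genotypes.values())


def choose_representative(cluster: Cluster, keep: str = "first") -> VariantRecord:
    """Deterministic representative selection per keep strategy.

    Ties (and a maxqual cluster with no QUAL at all) fall back to the most
    upstream member, then input order.
    """
    members = cluster.members
    order = {id(m): i for i, m in enumerate(members)}
    upstream = lambda m: (m.start, m.vcf_pos, order[id(m)])
    if keep == "first":
        rep = min(members, key=upstream)
    elif keep == "maxqual":
        with_qual = [m for m in members if m.qual is not None]
        if not with_qual:
            LOG.warning("keep=maxqual but no member has QUAL; falling back "
                        "to keep=first")
            rep = min(members, key=upstream)
        else:
            best = max(m.qual for m in with_qual)
            rep = min((m for m in with_qual if m.qual == best), key=upstream)
    elif keep == "common":
        best = max(_alt_allele_total(m) for m in members)
        rep = min((m for m in members if _alt_allele_total(m) == best),
                  key=upstream)
    else:  # pragma: no cover - guarded by CollapseParams
        raise ValueError(keep)
    cluster.representative = rep
    return rep


def consolidate_genotypes(cluster: Cluster) -> tuple:
    """Merge members' genotypes onto the representative.

    Per sample the consolidated ALT count is ``min(2, sum of members' ALT
    counts)`` (diploid saturation; saturation events and ALT alleles lost to
    the cap are counted and returned).  Phase is preserved only when the
    representative's own genotype is unchanged; per-sample fields come from
    the member that contributed the call.
    """
    rep = cluster.representative or cluster.members[0]
    samples: list = []
    for m in cluster.members:
        for s in m.genotypes:
            if s not in samples:
                samples.append(s)
    genotypes: dict = {}
    sample_fields: dict = {}
    saturated = 0
    lost = 0
    for s in samples:
        total = sum(m.genotypes[s].alt_count
                    for m in cluster.members if s in m.genotypes)
        if total > 2:
            saturated += 1
            lost += total - 2
        alt = min(2, total)
        rep_gt = rep.genotypes.get(s)
        if rep_gt is not None and rep_gt.alt_count == alt:
            genotypes[s] = rep_gt
        else:
            genotypes[s] = Genotype((0, 1) if alt == 1 else
                                    ((1, 1) if alt == 2 else (0, 0)), False)
        contributor = next((m for m in cluster.members
                            if s in m.genotypes and m.genotypes[s].is_present),
                           rep)
        if s in contributor.sample_fields:
            sample_fields[s] = contributor.sample_fields[s]
    return genotypes, sample_fields, saturated, lost


@dataclass
class CollapseResult:
    """Kept and removed record partitions plus the clusters behind them."""

    kept: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    filtered: list = field(default_factory=list)
    saturated_genotypes: int = 0
    alt_alleles_lost: int = 0


def _rep_id(rep: VariantRecord) -> str:
    return rep.record_id or f"{rep.contig}:{rep.vcf_pos + 1}"


def run_collapse(inputs, reference=None, params: CollapseParams | None = None,
                 filters: FilterParams | None = None,
                 chunksize: int | None = None,
                 sample: str | None = None) -> CollapseResult:
    """Collapse redundant SV representations in one or more sorted inputs.

    ``inputs`` is a VCF path / record iterable or a list of them; several
    inputs are zipped into one multi-sample stream.  ``hap`` mode requires a
    single-sample input; ``sample`` overrides which sample's genotypes gate
    hap-mode compatibility.
    """
    from .bench import _as_stream  # shared path/record-list adapter

    params = params or CollapseParams()
    if not isinstance(inputs, (list, tuple)) or (
            inputs and isinstance(inputs[0], VariantRecord)):
        inputs = [inputs]
    streams, all_samples = [], []
    for k, obj in enumerate(inputs):
        st, samples, _header = _as_stream(obj, f"input{k}")
        streams.append(st)
        for s in samples:
            if s not in all_samples:
                all_samples.append(s)
    if params.hap:
        if len(all_samples) > 1:
            raise ValueError("--hap requires single-sample input; got samples "
                             + ", ".join(all_samples))
        sample = sample or (all_samples[0] if all_samples else None)

    result = CollapseResult()
    stream = zip_variants(streams)
    chunks = chunk_stream(stream,
                          chunksize or default_chunksize(params.match.refdist),
                          filters, result.filtered)
    for chunk in chunks:
        for cluster in form_clusters(chunk.members, params, reference, sample):
            rep = choose_representative(cluster, params.keep)
            genotypes, sample_fields, saturated, lost = \
                consolidate_genotypes(cluster)
            result.saturated_genotypes += saturated
            result.alt_alleles_lost += lost
            info = dict(rep.info)
            info["NumCollapsed"] = len(cluster.members) - 1
            kept = dataclasses.replace(rep, genotypes=genotypes,
                                       sample_fields=sample_fields, info=info)
            result.kept.append(kept)
            for m in cluster.members:
                if m is not rep:
                    info = dict(m.info)
                    info["CollapseId"] = _rep_id(rep)
                    result.removed.append(dataclasses.replace(m, info=info))
            result.clusters.append(cluster)
    result.kept.sort(key=lambda r: (r.contig, r.vcf_pos))
    result.removed.sort(key=lambda r: (r.contig, r.vcf_pos))
    return result
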