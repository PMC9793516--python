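"""Synthetic references, truth callsets, perturbed replicas, and TR loci.

Everything the comparison engine consumes can be generated here without
external data: random reference contigs (optionally with planted tandem
repeat arrays), implanted sequence-resolved DEL/INS truth sets with
genotypes over any number of samples, noise-perturbed replicate callsets
with a machine-readable ledger of the expected benchmarking outcome, and a
worked tandem-repeat locus where eight insertion alleles carry +2..+5
copies of a 29-bp motif across 10 samples (four of the alleles being
redundant representations placed at shifted anchors inside the array).

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .annotate import TRAnnotation
from .variants import Genotype, SVType, VariantRecord, make_record

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_reference(n_contigs: int = 1, length: int = 100_000, seed: int = 0,
                   repeats: list | None = None) -> tuple:
    """Random reference contigs, optionally with planted tandem-repeat arrays.

    ``repeats`` is a list of (motif, copies) pairs planted at evenly spaced
    positions on the first contig.  Returns ``({contig: seq}, placements)``
    where placements are ``(contig, pos, motif, copies)``.
    """
    if length < 10_000:
        raise ValueError("contig length must be at least 10 kb")
    rng = np.random.default_rng(seed)
    reference = {f"ctg{i + 1}": _random_seq(rng, length)
                 for i in range(n_contigs)}
    placements = []
    if repeats:
        contig = "ctg1"
        seq = list(reference[contig])
        slot = length // (len(repeats) + 1)
        for i, (motif, copies) in enumerate(repeats):
            pos = slot * (i + 1)
            array = motif * copies
            if pos + len(array) >= length:
                raise ValueError("repeat array does not fit in contig")
            seq[pos:pos + len(array)] = array
            placements.append((contig, pos, motif, copies))
        reference[contig] = "".join(seq)
    return reference, placements


def _genotype(rng: np.random.Generator, hom_fraction: float) -> Genotype:
    return Genotype((1, 1) if rng.random() < hom_fraction else (0, 1), False)


def implant_svs(reference: dict, n_del: int = 25, n_ins: int = 25,
                size_range: tuple = (100, 1000), n_samples: int = 1,
                seed: int = 0, hom_fraction: float = 0.3,
                spacing: int = 3000, source: str = "truth") -> tuple:
    """Implant non-overlapping sequence-resolved DEL/INS truth records.

    Loci are separated by at least ``spacing`` bp so every locus is
    positionally isolated at default matching thresholds.  Each record is
    present (het or hom) in one random sample and hom-ref elsewhere.
    Returns ``(records, ledger)``; the ledger records ids, types, sizes and
    positions.  Raises when the SVs cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    svtypes = [SVType.DEL] * n_del + [SVType.INS] * n_ins
    rng.shuffle(svtypes)
    samples = [f"sample{i + 1}" for i in range(n_samples)]
    records, entries = [], []
    contigs = sorted(reference)
    ci = 0
    cursor = 1000
    for i, svtype in enumerate(svtypes):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        while ci < len(contigs):
            contig = contigs[ci]
            room = len(reference[contig]) - 1000
            if cursor + size + spacing < room:
                break
            ci += 1
            cursor = 1000
        else:
            raise ValueError(
                f"cannot place SV {i + 1}/{len(svtypes)} without overlap; "
                "use fewer/smaller SVs or longer contigs")
        pos = cursor + int(rng.integers(0, 500))
        seq = reference[contig]
        if svtype is SVType.DEL:
            ref_allele = seq[pos:pos + size + 1]
            alt_allele = seq[pos]
            footprint_end = pos + size + 1
        else:
            ref_allele = seq[pos]
            alt_allele = seq[pos] + _random_seq(rng, size)
            footprint_end = pos + 1
        genotypes = {s: Genotype((0, 0), False) for s in samples}
        carrier = samples[int(rng.integers(0, n_samples))]
        genotypes[carrier] = _genotype(rng, hom_fraction)
        rec = make_record(contig, pos, ref_allele, alt_allele,
                          genotypes=genotypes, source=source,
                          record_id=f"sv{i + 1}")
        records.append(rec)
        entries.append({"id": rec.record_id, "contig": contig, "pos": pos,
                        "svtype": svtype.value, "size": size,
                        "carrier": carrier})
        cursor = footprint_end + spacing
    records.sort(key=lambda r: (r.contig, r.vcf_pos))
    ledger = {"seed": seed, "n_samples": n_samples, "records": entries,
              "samples": samples}
    return records, ledger


VIOLATIONS = ("refdist", "size", "seq")


@dataclass
class PerturbationModel:
    """Noise regime applied to a truth callset.

    Within-threshold defaults emulate replicate-callset noise (breakpoint
    wobble, small size jitter, per-base errors) that stays inside the 70%/70%
    /500 bp benchmarking thresholds by construction.  ``violation`` pushes a
    fraction of insertion records past exactly one threshold: ``refdist``
    (shift 600-1000 bp), ``size`` (doubled length) or ``seq`` (inserted
    sequence replaced by a homopolymer).
    """

    pos_shift: tuple = (0, 20)
    size_jitter: float = 0.05
    seq_error_rate: float = 0.01
    drop_rate: float = 0.0
    novel_rate: float = 0.0
    violation: str | None = None
    violation_rate: float = 0.0

    def __post_init__(self):
        for name in ("size_jitter", "seq_error_rate", "drop_rate",
                     "novel_rate", "violation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.violation is not None and self.violation not in VIOLATIONS:
            raise ValueError(f"violation must be one of {VIOLATIONS}")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _homopolymer_replacement(ins: str) -> str:
    """Least frequent base, repeated — guarantees seqsim well below 0.70."""
    counts = {b: ins.count(b) for b in "ACGT"}
    base = min(sorted(counts), key=counts.get)
    return base * len(ins)


def perturb_callset(truth: list, model: PerturbationModel, reference: dict,
                    seed: int = 0, source: str = "comp") -> tuple:
    """Perturb a truth callset into a synthetic comparison callset.

    Deletions pass through exact: under the context-free haplotype
    construction a shifted or resized deletion in random sequence has
    near-zero sequence similarity, so no within-threshold DEL perturbation
    exists outside repeat context (see docs/methods.md).  Insertions receive
    breakpoint shifts, size jitter and per-base errors per the model.

    Returns ``(records, ledger)``; the ledger lists the truth ids expected
    to be re-found (``expected_tp``), lost (``expected_fn``) and the comp
    record ids expected to be false positives (``expected_fp``), so a
    benchmarking run's outcome is computable rather than guessed.
    """
    rng = np.random.default_rng(seed)
    records = []
    expected_tp, expected_fn, expected_fp = [], [], []
    for rec in sorted(truth, key=lambda r: (r.contig, r.vcf_pos)):
        if rng.random() < model.drop_rate:
            expected_fn.append(rec.record_id)
            continue
        violate = (model.violation is not None and rec.svtype is SVType.INS
                   and rng.random() < model.violation_rate)
        if rec.svtype is not SVType.INS:
            records.append(dataclasses.replace(rec, source=source))
            expected_tp.append(rec.record_id)
            continue
        seq = reference[rec.contig]
        pos = rec.vcf_pos
        ins = rec.alt_allele[1:]
        if violate:
            if model.violation == "refdist":
                pos = pos + int(rng.integers(600, 1001))
            elif model.violation == "size":
                ins = ins + _random_seq(rng, len(ins))
            else:  # seq
                ins = _homopolymer_replacement(ins)
            expected_fn.append(rec.record_id)
            expected_fp.append(rec.record_id)
        else:
            shift = int(rng.integers(model.pos_shift[0], model.pos_shift[1] + 1))
            pos = pos + (shift if rng.random() < 0.5 else -shift)
            pos = max(1, pos)
            ins = _mutate(rng, ins, model.seq_error_rate)
            if model.size_jitter > 0:
                delta = int(rng.integers(0, int(len(ins) * model.size_jitter) + 1))
                if delta:
                    if rng.random() < 0.5:
                        ins = ins[:-delta]
                    else:
                        ins = ins + _random_seq(rng, delta)
            expected_tp.append(rec.record_id)
        alt = seq[pos] + ins
        records.append(make_record(
            rec.contig, pos, seq[pos], alt, genotypes=dict(rec.genotypes),
            source=source, record_id=rec.record_id))

    # novel calls in the gaps between truth loci (isolated by construction)
    if model.novel_rate > 0:
        truth_sorted = sorted(truth, key=lambda r: (r.contig, r.vcf_pos))
        n_novel = int(rng.binomial(len(truth_sorted), model.novel_rate))
        slots = []
        for a, b in zip(truth_sorted, truth_sorted[1:]):
            if a.contig == b.contig and b.vcf_pos - a.end >= 2800:
                slots.append((a.contig, (a.end + b.vcf_pos) // 2))
        for k in range(min(n_novel, len(slots))):
            contig, pos = slots[k]
            size = int(rng.integers(100, 500))
            seq = reference[contig]
            rec = make_record(contig, pos, seq[pos],
                              seq[pos] + _random_seq(rng, size),
                              genotypes={}, source=source,
                              record_id=f"novel{k + 1}")
            records.append(rec)
            expected_fp.append(rec.record_id)

    records.sort(key=lambda r: (r.contig, r.vcf_pos))
    ledger = {"seed": seed, "expected_tp": expected_tp,
              "expected_fn": expected_fn, "expected_fp": expected_fp}
    return records, ledger


@dataclass
class Fig4aLocus:
    """Worked tandem-repeat locus: 8 INS alleles, +2..+5 copies, 10 samples."""

    reference: dict
    records: list
    annotations: list  # TRAnnotation aligned with records
    motif: str
    array_start: int
    array_copies: int
    samples: list = field(default_factory=list)

    @property
    def annotated(self) -> list:
        return list(zip(self.records, self.annotations))


def make_fig4a_locus(seed: int = 0, motif_len: int = 29,
                     copy_range: tuple = (2, 5), pair_shift_copies: int = 4,
                     n_samples: int = 10) -> Fig4aLocus:
    """One tandem-repeat locus with redundant insertion representations.

    The reference carries a ``motif_len``-bp motif repeated 10 times.  For
    each copy number k in ``copy_range`` two records insert the identical
    k-copy sequence at anchors ``pair_shift_copies`` motif lengths apart
    inside the array — alignment-ambiguity style redundancy: the two
    representations yield literally identical haplotypes (sequence
    similarity 1.0) while alleles with different copy numbers differ in
    size similarity below the collapse threshold.  Alleles are spread over
    ``n_samples`` samples, one heterozygous carrier each.
    """
    rng = np.random.default_rng(seed)
    motif = _random_seq(rng, motif_len)
    while len(set(motif)) < 2:  # avoid degenerate homopolymer motifs
        motif = _random_seq(rng, motif_len)
    reference, placements = make_reference(
        1, 10_000, seed=int(rng.integers(0, 2**31)), repeats=[(motif, 10)])
    contig, array_start, _, copies = placements[0]
    seq = reference[contig]

    ks = list(range(copy_range[0], copy_range[1] + 1))
    samples = [f"sample{i + 1}" for i in range(n_samples)]
    records, annotations = [], []
    idx = 0
    for member in range(2):
        for slot, k in enumerate(ks):
            col = member * pair_shift_copies + slot
            pos = array_start - 1 + motif_len * col  # base before a copy boundary
            genotypes = {s: Genotype((0, 0), False) for s in samples}
            genotypes[samples[idx % n_samples]] = Genotype((0, 1), False)
            rec = make_record(
                contig, pos, seq[pos], seq[pos] + motif * k,
                genotypes=genotypes, source="input",
                record_id=f"allele{idx + 1}")
            records.append(rec)
            annotations.append(TRAnnotation(locus_id="locus_1", motif=motif,
                                            copy_diff=k))
            idx += 1
    order = sorted(range(len(records)), key=lambda i: records[i].vcf_pos)
    return Fig4aLocus(
        reference=reference,
        records=[records[i] for i in order],
        annotations=[annotations[i] for i in order],
        motif=motif, array_start=array_start, array_copies=copies,
        samples=samples)


def write_fasta(reference: dict, path, width: int = 60) -> str:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return str(path)


def write_fixture_dir(outdir, reference: dict, records: list, samples: list,
                      ledger: dict | None = None,
                      annotated: list | None = None) -> dict:
    """Write a FASTA + VCF (+ ledger JSON, + TR TSV) fixture set."""
    from .annotate import write_tr_annotations
    from .vcfio import write_json, write_vcf

    os.makedirs(str(outdir), exist_ok=True)
    out = {
        "reference": write_fasta(reference, os.path.join(str(outdir), "reference.fa")),
        "vcf": write_vcf(os.path.join(str(outdir), "variants.vcf"), records,
                         {c: len(s) for c, s in reference.items()}, samples),
    }
    if ledger is not None:
        out["ledger"] = write_json(ledger, os.path.join(str(outdir), "ledger.json"))
    if annotated is not None:
        out["tr_annotations"] = write_tr_annotations(
            annotated, os.path.join(str(outdir), "tr_annotations.tsv"))
    return out
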