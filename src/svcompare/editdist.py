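"""Unit-cost edit distance via Biopython's pairwise aligner.

With match score 0 and mismatch/gap scores -1, the optimal global alignment
score equals minus the Levenshtein distance.  The aligner's C implementation
keeps haplotype comparison fast without an external edit-distance library.
"""

from __future__ import annotations

from Bio import Align

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two sequences."""
    if not a or not b:
        return len(a) + len(b)
    if a == b:
        return 0
    return int(-_aligner.score(a, b))
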