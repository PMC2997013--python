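"""Pairwise alignment helpers built on Bio.Align.PairwiseAligner.

Default scoring follows the clustering stage: match +1, mismatch -1,
gap -2, with identity defined as matches / alignment columns.
"""

from __future__ import annotations

from Bio import Align

__all__ = ["make_aligner", "global_alignment", "alignment_stats", "global_identity"]


def make_aligner(mode: str = "global", match: float = 1.0,
                 mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


_GLOBAL = make_aligner("global")


def global_alignment(a: str, b: str, aligner: Align.PairwiseAligner | None = None):
    """Best global alignment of two sequences (first reported, deterministic)."""
    return (aligner or _GLOBAL).align(a, b)[0]


def alignment_stats(alignment) -> tuple[int, int]:
    """(matches, alignment columns) for a pairwise alignment."""
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches, len(a)


def global_identity(a: str, b: str) -> float:
    """Global end-to-end identity: matches / alignment length, in [0, 1]."""
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    matches, cols = alignment_stats(global_alignment(a, b))
    return matches / cols
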