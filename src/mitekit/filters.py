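"""Pseudo-MITE filtering.

Three member-level flags mirror the pseudo-element classes: sequences
containing undetermined bases (N), sequences essentially composed of short
tandem simple repeats, and elements nested inside high-copy repeats
(detected through the multiplicity of their genomic flanks).  A family is
rejected when more than half of its members carry any flag; per-member
flags are retained in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GenomeSequence
from .miner import CandidateFamily, MiteCandidate

__all__ = [
    "FilterVerdict",
    "FilterReport",
    "has_undetermined",
    "is_simple_repeat",
    "is_nested_in_repeat",
    "filter_families",
]


@dataclass(frozen=True)
class FilterVerdict:
    candidate: MiteCandidate
    flags: frozenset[str]

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


@dataclass
class FilterReport:
    kept: list[CandidateFamily]
    rejected: list[CandidateFamily]
    verdicts: dict[str, list[FilterVerdict]] = field(default_factory=dict)


def has_undetermined(seq: str) -> bool:
    """True iff the sequence contains at least one undetermined base (N)."""
    return "N" in seq


def tandem_repeat_cover(seq: str, max_period: int = 6, min_units: int = 2,
                        min_region: int = 8) -> float:
    """Fraction of positions lying in a tandem repeat of period <= max_period.

    For period p, a maximal stretch of exact self-overlap (seq[i] ==
    seq[i-p]) defines a periodic region; it qualifies when it spans at
    least ``min_units`` full units and at least ``min_region`` bp (so
    incidental 2-3 bp coincidences in random sequence do not count).
    Qualifying regions over all periods are merged positionally, which
    equals scoring maximal runs greedily longest-first.
    """
    n = len(seq)
    covered = bytearray(n)
    for p in range(1, max_period + 1):
        i = p
        while i < n:
            if seq[i] == seq[i - p] and seq[i] != "N":
                j = i
                while j < n and seq[j] == seq[j - p] and seq[j] != "N":
                    j += 1
                region_start = i - p
                region_len = j - region_start
                if region_len >= max(min_units * p, min_region):
                    covered[region_start:j] = b"\x01" * region_len
                i = j + 1
            else:
                i += 1
    return sum(covered) / n if n else 0.0


def is_simple_repeat(seq: str, min_cover: float = 0.8, max_period: int = 6) -> bool:
    """True iff >= min_cover of the sequence lies in short tandem repeats."""
    return tandem_repeat_cover(seq, max_period) >= min_cover


def _count_approx_occurrences(pattern: str, genome_seq: str, max_mismatch: int,
                              seed_len: int = 16, cap: int | None = None) -> int:
    """Occurrences of ``pattern`` in ``genome_seq`` with <= max_mismatch
    substitutions, counted via exact seed words verified by Hamming check."""
    m = len(pattern)
    n_seeds = max(1, max_mismatch + 1)
    step = max(1, (m - seed_len) // max(1, n_seeds - 1)) if n_seeds > 1 else 1
    offsets = sorted({min(i * step, m - seed_len) for i in range(n_seeds)})
    starts: set[int] = set()
    for off in offsets:
        seed = pattern[off:off + seed_len]
        pos = genome_seq.find(seed)
        while pos != -1:
            start = pos - off
            if 0 <= start <= len(genome_seq) - m:
                starts.add(start)
            pos = genome_seq.find(seed, pos + 1)
    count = 0
    for start in starts:
        window = genome_seq[start:start + m]
        mm = sum(1 for a, b in zip(window, pattern) if a != b)
        if mm <= max_mismatch:
            count += 1
            if cap is not None and count > cap:
                return count
    return count


def is_nested_in_repeat(candidate: MiteCandidate,
                        genome: GenomeSequence | list[GenomeSequence],
                        flank: int = 50, max_flank_hits: int = 20) -> bool:
    """True iff BOTH ``flank``-bp flanks recur more than ``max_flank_hits``
    times genome-wide at >= 90% identity (elements inside larger repeats)."""
    seqs = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    host = next((s for s in seqs if s.id == candidate.chrom), None)
    if host is None:
        return False
    if candidate.start < flank or candidate.end + flank > host.length:
        return False
    left = host.seq[candidate.start - flank:candidate.start]
    right = host.seq[candidate.end:candidate.end + flank]
    max_mm = flank - int(0.9 * flank) if flank >= 10 else 0
    for pattern in (left, right):
        total = 0
        for s in seqs:
            total += _count_approx_occurrences(pattern, s.seq, max_mm,
                                               cap=max_flank_hits + 1)
            if total > max_flank_hits:
                break
        if total <= max_flank_hits:
            return False
    return True


def filter_families(families: list[CandidateFamily],
                    genome: GenomeSequence | list[GenomeSequence] | None = None,
                    member_fraction: float = 0.5, flank: int = 50,
                    max_flank_hits: int = 20) -> FilterReport:
    """Apply the three pseudo-element flags and reject flagged families.

    A family is pseudo when more than ``member_fraction`` of its members
    carry any flag.  The nested-in-repeat flag needs the genome; when it is
    not supplied only the sequence-level flags apply.  Idempotent.
    """
    kept, rejected = [], []
    verdicts: dict[str, list[FilterVerdict]] = {}
    for fam in families:
        fam_verdicts = []
        n_flagged = 0
        for member in fam.members:
            flags = set()
            if has_undetermined(member.seq):
                flags.add("has_N")
            if len(member.seq) >= 20 and is_simple_repeat(member.seq):
                flags.add("simple_repeat")
            if genome is not None and is_nested_in_repeat(
                    member, genome, flank, max_flank_hits):
                flags.add("nested_in_repeat")
            if flags:
                n_flagged += 1
            fam_verdicts.append(FilterVerdict(member, frozenset(flags)))
        verdicts[fam.family_id] = fam_verdicts
        if n_flagged > member_fraction * len(fam.members):
            rejected.append(fam)
        else:
            kept.append(fam)
    return FilterReport(kept=kept, rejected=rejected, verdicts=verdicts)
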