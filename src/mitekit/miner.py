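"""Structure-based detection of candidate MITEs and clustering into families.

A candidate is an element of 100-600 bp whose termini form a terminal
inverted repeat (TIR, 8-50 bp, mismatch fraction bounded) and which is
flanked on both sides by an identical target-site duplication (TSD,
2-30 bp, exact).  Detection is seed-and-extend: exact inverted k-mer seed
pairs are extended into a maximal inverted-repeat region and every terminal
trim of that region is tested for a flanking TSD.  Overlapping calls are
resolved by a deterministic total order (longer TIR, then longer TSD, then
leftmost).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from ._align import global_identity
from ._seq import revcomp
from .io import GenomeSequence

__all__ = [
    "ScanParams",
    "MiteCandidate",
    "CandidateFamily",
    "scan_candidates",
    "pairwise_identity",
    "cluster_families",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ScanParams:
    """Structural constraints for the scan (defaults follow known MITEs)."""

    tir_min: int = 8
    tir_max: int = 50
    tsd_min: int = 2
    tsd_max: int = 30
    len_min: int = 100
    len_max: int = 600
    seed_word: int = 8
    max_tir_mismatch: float = 0.10


@dataclass(frozen=True)
class MiteCandidate:
    """A structurally detected element; span excludes the TSD copies."""

    chrom: str
    start: int
    end: int
    tir5: str
    tir3: str
    tsd: str
    seq: str
    tir_mismatches: int

    @property
    def tir_len(self) -> int:
        return len(self.tir5)

    @property
    def tsd_len(self) -> int:
        return len(self.tsd)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateFamily:
    """A single-linkage cluster of candidates sharing >0.8 identity."""

    family_id: str
    members: list[MiteCandidate]
    representative: int = 0

    @property
    def representative_member(self) -> MiteCandidate:
        return self.members[self.representative]


def _tir_length(seq: str, start: int, end: int, params: ScanParams) -> tuple[int, int] | None:
    """Longest admissible TIR for element seq[start:end]; (length, mismatches).

    The TIR of length L is the element prefix of L bases paired against the
    reverse complement of its suffix of L bases; admissible when mismatches
    <= floor(max_tir_mismatch * L) and both the outermost and the innermost
    pair match (a terminal repeat reaches the terminus and does not end on
    a mismatch), with 2L fitting inside the element.
    """
    length = end - start
    max_l = min(params.tir_max, length // 2)
    if max_l < params.tir_min:
        return None
    best = None
    mm = 0
    for t in range(max_l):
        left = seq[start + t]
        right = seq[end - 1 - t]
        if left == "N" or right == "N":
            break
        matched = left == _COMP[right]
        if not matched:
            if t == 0:
                return None
            mm += 1
        l = t + 1
        if matched and l >= params.tir_min and mm <= int(params.max_tir_mismatch * l):
            best = (l, mm)
    return best


def _is_mononucleotide_artifact(seq: str, s: int, e: int, tsd: str) -> bool:
    """Reject single-base TSDs that merely extend a mononucleotide run."""
    base = tsd[0]
    if any(c != base for c in tsd):
        return False
    lt = len(tsd)
    left_out = s - lt - 1
    right_out = e + lt
    if left_out >= 0 and seq[left_out] == base:
        return True
    if right_out < len(seq) and seq[right_out] == base:
        return True
    return False


def _find_tsd(seq: str, s: int, e: int, params: ScanParams) -> str | None:
    """Longest exact direct repeat flanking [s, e); None if no admissible TSD."""
    n = len(seq)
    for lt in range(min(params.tsd_max, s, n - e), params.tsd_min - 1, -1):
        left = seq[s - lt:s]
        if "N" in left:
            continue
        if left == seq[e:e + lt]:
            if _is_mononucleotide_artifact(seq, s, e, left):
                continue
            return left
    return None


def _validate(seq: str, chrom: str, s: int, e: int, params: ScanParams) -> MiteCandidate | None:
    length = e - s
    if length < params.len_min or length > params.len_max:
        return None
    if s < params.tsd_min or e + params.tsd_min > len(seq):
        return None
    element = seq[s:e]
    if "N" in element:
        return None
    tir = _tir_length(seq, s, e, params)
    if tir is None:
        return None
    tsd = _find_tsd(seq, s, e, params)
    if tsd is None:
        return None
    tir_len, mm = tir
    return MiteCandidate(
        chrom=chrom, start=s, end=e,
        tir5=element[:tir_len], tir3=element[-tir_len:],
        tsd=tsd, seq=element, tir_mismatches=mm,
    )


def resolve_shadowing(candidates: list[MiteCandidate]) -> list[MiteCandidate]:
    """Keep a non-redundant candidate set.

    Candidates sharing more than half of the shorter span are competing
    calls of the same locus; priority is longer TIR, then longer TSD, then
    leftmost start, then leftmost end.
    """
    order = sorted(
        candidates,
        key=lambda c: (-c.tir_len, -c.tsd_len, c.start, c.end),
    )
    kept: list[MiteCandidate] = []
    for cand in order:
        clash = False
        for other in kept:
            if other.chrom != cand.chrom:
                continue
            ov = min(cand.end, other.end) - max(cand.start, other.start)
            if ov > 0 and ov > 0.5 * min(cand.length, other.length):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.chrom, c.start, c.end))
    return kept


def scan_candidates(genome: GenomeSequence, params: ScanParams | None = None) -> list[MiteCandidate]:
    """All maximal, shadow-resolved structural candidates on one sequence.

    The scan is strand-symmetric by construction (an inverted-repeat element
    reads the same on either strand), so only the forward strand is indexed.
    """
    params = params or ScanParams()
    seq = genome.seq
    n = len(seq)
    if n < params.len_min + 2 * params.tsd_min:
        return []
    w = params.seed_word

    # index all exact seed words
    index: dict[str, list[int]] = {}
    for i in range(n - w + 1):
        word = seq[i:i + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)

    # seed geometry: with the seed inside the 5' TIR at position i and its
    # inverted partner ending the 3' TIR at j+w, the element [s, e) obeys
    # s <= i and e >= j + w, so j - i ranges over [w, len_max - w].
    lo_gap, hi_gap = w, params.len_max - w
    mm_cap = int(params.max_tir_mismatch * params.tir_max)
    out_cap = params.tir_max  # boundary lies within tir_max of the seed

    seen: dict[tuple[int, int], MiteCandidate] = {}
    for word, positions in index.items():
        partners = index.get(revcomp(word))
        if not partners:
            continue
        for i in positions:
            jlo = bisect_left(partners, i + lo_gap)
            jhi = bisect_right(partners, i + hi_gap)
            for j in partners[jlo:jhi]:
                _extend_and_collect(seq, genome.id, i, j, w, params,
                                    mm_cap, out_cap, seen)
    return resolve_shadowing(list(seen.values()))


def _extend_and_collect(seq: str, chrom: str, i: int, j: int, w: int,
                        params: ScanParams, mm_cap: int, out_cap: int,
                        seen: dict) -> None:
    """Extend seed pair (i, j) outward and test every terminal trim."""
    n = len(seq)
    # outward extension: position i-1-t pairs with j+w+t
    ext = 0
    mm = 0
    a, b = i - 1, j + w
    while ext < out_cap and a >= 0 and b < n:
        ca, cb = seq[a], seq[b]
        if ca == "N" or cb == "N":
            break
        if ca != _COMP[cb]:
            mm += 1
            if mm > mm_cap:
                break
        ext += 1
        a -= 1
        b += 1
    # candidate boundaries: trim d outer columns off the maximal extension
    s0, e0 = i - ext, j + w + ext
    for d in range(ext + 1):
        s, e = s0 + d, e0 - d
        key = (s, e)
        if key in seen:
            continue
        cand = _validate(seq, chrom, s, e, params)
        if cand is not None:
            seen[key] = cand


def pairwise_identity(a: str, b: str) -> float:
    """Global end-to-end identity between two sequences, in [0, 1]."""
    return global_identity(a, b)


def cluster_families(candidates: list[MiteCandidate], min_identity: float = 0.8,
                     min_members: int = 3) -> list[CandidateFamily]:
    """Single-linkage clustering on the identity graph.

    Two candidates are linked when their global identity exceeds
    ``min_identity``; connected components with fewer than ``min_members``
    members are dropped.  The representative is the member whose length is
    closest to the component's median length (ties: lowest coordinate).
    """
    n = len(candidates)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for x in range(n):
        for y in range(x + 1, n):
            # cheap length gate: identity <= min/max possible length ratio
            la, lb = candidates[x].length, candidates[y].length
            if min(la, lb) / max(la, lb) <= min_identity:
                continue
            if pairwise_identity(candidates[x].seq, candidates[y].seq) > min_identity:
                union(x, y)

    groups: dict[int, list[int]] = {}
    for x in range(n):
        groups.setdefault(find(x), []).append(x)

    families: list[CandidateFamily] = []
    kept = [sorted(idxs) for idxs in groups.values() if len(idxs) >= min_members]
    kept.sort(key=lambda idxs: (candidates[idxs[0]].chrom, candidates[idxs[0]].start))
    for fam_no, idxs in enumerate(kept, start=1):
        members = [candidates[k] for k in idxs]
        lengths = sorted(m.length for m in members)
        median = lengths[(len(lengths) - 1) // 2] if len(lengths) % 2 else \
            (lengths[len(lengths) // 2 - 1] + lengths[len(lengths) // 2]) / 2.0
        rep = min(
            range(len(members)),
            key=lambda k: (abs(members[k].length - median),
                           members[k].chrom, members[k].start, members[k].end),
        )
        families.append(CandidateFamily(f"FAM-{fam_no}", members, rep))
    return families
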