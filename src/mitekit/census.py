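"""Genome-wide homology census per family.

A representative member is searched against both strands of the genome by
seed-and-extend local alignment; hits passing the identity (>0.90) and
representative-coverage (>0.80) thresholds are emitted as copies.  A copy is
intact when the alignment fully covers both TIR spans of the representative
and each TIR aligns at >= 90% identity, otherwise fragmentary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import make_aligner
from ._seq import revcomp
from .errors import UndefinedInputError
from .io import GenomeSequence
from .tables import round_half_away

__all__ = [
    "MiteCopy",
    "FamilyCensus",
    "homology_search",
    "classify_intact",
    "at_content",
    "classify_superfamily",
    "census_family",
    "infer_tsd_motif",
]

_LOCAL = make_aligner("local")


@dataclass
class MiteCopy:
    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    intact: bool = False
    score: float = 0.0
    # per-representative-position alignment bookkeeping (None = unaligned)
    _rep_match: np.ndarray | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FamilyCensus:
    family_id: str
    n_total: int
    n_intact: int
    n_fragmentary: int
    full_length_pct: int
    at_content_pct: int
    superfamily: str
    tsd_motif: str = ""
    tir_consensus: str = ""


def at_content(seq: str) -> float:
    """(A+T) / (A+C+G+T); N is excluded from the denominator."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedInputError("AT content undefined for an all-N sequence")
    return (counts["A"] + counts["T"]) / denom


def _seed_windows(rep: str, target: str, seed_len: int = 12,
                  stride: int = 4, pad: int = 80) -> list[tuple[int, int]]:
    """Candidate target windows anchored by exact seed matches, merged."""
    m = len(rep)
    anchors: list[int] = []  # implied window starts (target pos of rep start)
    for off in range(0, m - seed_len + 1, stride):
        seed = rep[off:off + seed_len]
        if "N" in seed:
            continue
        pos = target.find(seed)
        while pos != -1:
            anchors.append(pos - off)
            pos = target.find(seed, pos + 1)
    if not anchors:
        return []
    anchors.sort()
    # cluster anchors: nearby anchors belong to one copy, distant ones are
    # distinct copies even when their padded windows would overlap
    clusters: list[list[int]] = [[anchors[0], anchors[0]]]
    for a in anchors[1:]:
        if a - clusters[-1][1] <= 60:
            clusters[-1][1] = a
        else:
            clusters.append([a, a])
    return [(max(0, lo - pad), min(len(target), hi + m + pad))
            for lo, hi in clusters]


def _align_window(rep: str, target: str, win: tuple[int, int]):
    """Local alignment of the representative inside one window.

    Returns (t_start, t_end, identity, coverage, score, rep_match) or None,
    where rep_match is a boolean array over representative positions that
    aligned to an identical target base (NaN-free bookkeeping for the
    intactness call).
    """
    lo, hi = win
    segment = target[lo:hi]
    if not segment:
        return None
    try:
        alignment = _LOCAL.align(rep, segment)[0]
    except (IndexError, ValueError):
        return None
    blocks_rep, blocks_t = alignment.aligned
    if len(blocks_rep) == 0:
        return None
    rep_aligned = np.zeros(len(rep), dtype=bool)
    rep_match = np.zeros(len(rep), dtype=bool)
    matches = 0
    for (ra, rb), (ta, tb) in zip(blocks_rep, blocks_t):
        rep_aligned[ra:rb] = True
        for k in range(rb - ra):
            if rep[ra + k] == segment[ta + k]:
                rep_match[ra + k] = True
                matches += 1
    r_start, r_end = int(blocks_rep[0][0]), int(blocks_rep[-1][1])
    t_start, t_end = int(blocks_t[0][0]), int(blocks_t[-1][1])
    # alignment columns within the locally aligned region
    cols = (r_end - r_start) + (t_end - t_start) - sum(
        int(rb - ra) for (ra, rb) in blocks_rep)
    identity = matches / cols if cols else 0.0
    coverage = (r_end - r_start) / len(rep)
    rep_match &= rep_aligned
    return (lo + t_start, lo + t_end, identity, coverage,
            float(alignment.score), rep_match, rep_aligned)


def homology_search(genome: GenomeSequence | list[GenomeSequence],
                    representative: str, family_id: str = "",
                    min_identity: float = 0.90, min_coverage: float = 0.80,
                    min_alignment_len: int = 50,
                    tir_len: int | None = None) -> list[MiteCopy]:
    """All genome copies of the representative passing both thresholds.

    Both strands are scanned; hits overlapping more than half of the
    shorter hit on the same strand are deduplicated by score, then leftmost
    start.  When ``tir_len`` is given, each emitted copy also carries the
    intact/fragmentary call.
    """
    seqs = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    rep = representative.upper()
    hits: list[MiteCopy] = []
    for rec in seqs:
        for strand in "+-":
            target = rec.seq if strand == "+" else revcomp(rec.seq)
            for win in _seed_windows(rep, target):
                res = _align_window(rep, target, win)
                if res is None:
                    continue
                t_start, t_end, ident, cov, score, rep_match, rep_aligned = res
                if t_end - t_start < min_alignment_len:
                    continue
                if ident <= min_identity or cov <= min_coverage:
                    continue
                if strand == "+":
                    g_start, g_end = t_start, t_end
                else:
                    g_start, g_end = rec.length - t_end, rec.length - t_start
                copy = MiteCopy(
                    family_id=family_id, chrom=rec.id, start=g_start,
                    end=g_end, strand=strand, identity=ident, coverage=cov,
                    score=score,
                )
                copy._rep_match = np.stack([rep_match, rep_aligned])
                if tir_len is not None:
                    copy.intact = classify_intact(copy, (tir_len, len(rep)))
                hits.append(copy)
    return _dedupe(hits)


def _dedupe(hits: list[MiteCopy]) -> list[MiteCopy]:
    order = sorted(hits, key=lambda h: (-h.score, h.chrom, h.start, h.end, h.strand))
    kept: list[MiteCopy] = []
    for h in order:
        clash = False
        for other in kept:
            if other.chrom != h.chrom or other.strand != h.strand:
                continue
            ov = min(h.end, other.end) - max(h.start, other.start)
            if ov > 0 and ov > 0.5 * min(h.length, other.length):
                clash = True
                break
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand))
    return kept


def classify_intact(copy: MiteCopy, family_tirs: tuple[int, int],
                    min_tir_identity: float = 0.90) -> bool:
    """Intact iff both TIR spans of the representative are fully covered by
    the alignment and each aligns at >= ``min_tir_identity`` identity.

    ``family_tirs`` is (tir_length, representative_length).
    """
    if copy._rep_match is None:
        raise ValueError("copy carries no alignment bookkeeping")
    tir_len, rep_len = family_tirs
    rep_match, rep_aligned = copy._rep_match[0], copy._rep_match[1]
    for span in ((0, tir_len), (rep_len - tir_len, rep_len)):
        a, b = span
        if not rep_aligned[a:b].all():
            return False
        if rep_match[a:b].sum() < min_tir_identity * (b - a):
            return False
    return True


_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "W": {"A", "T"}, "D": {"A", "G", "T"}, "N": {"A", "C", "G", "T"},
}
_SET_TO_LETTER = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AT"): "W", frozenset("AGT"): "D",
    frozenset("ACGT"): "N",
}


def infer_tsd_motif(tsds: list[str]) -> str:
    """Degenerate motif over the most common TSD length (W={A,T}, D={A,G,T})."""
    if not tsds:
        return ""
    modal_len = max(set(len(t) for t in tsds),
                    key=lambda l: (sum(len(t) == l for t in tsds), -l))
    pool = [t for t in tsds if len(t) == modal_len]
    motif = []
    for i in range(modal_len):
        seen = frozenset(t[i] for t in pool)
        motif.append(_SET_TO_LETTER.get(seen, "N"))
    return "".join(motif)


def _motif_matches(motif: str, pattern: str) -> bool:
    """True if every sequence the motif allows is allowed by the pattern."""
    for alt in motif.upper().split("/"):
        if len(alt) != len(pattern):
            continue
        if all(_IUPAC_SETS.get(m, {m}) <= _IUPAC_SETS.get(p, {p})
               for m, p in zip(alt, pattern)):
            return True
    return False


_PEGASUS_TIR = "CAGTGGCGGAT"

DEFAULT_SUPERFAMILY_RULES = (
    ("stowaway_tsd", "Stowaway-like"),
    ("tourist_tsd", "Tourist-like"),
    ("pegasus_tsd_tir", "Pegasus-like"),
)


def classify_superfamily(tsd_motif: str, tir_consensus: str = "",
                         rules=DEFAULT_SUPERFAMILY_RULES) -> tuple[str, str]:
    """Superfamily label from TSD composition (and TIR for the 8-bp class).

    TA TSDs diagnose Stowaway-like elements; TWA/TDA diagnose Tourist-like;
    an 8-bp nonspecific TSD whose TIR starts with >= 80% identity to the
    CAGTGGCGGAT motif class diagnoses Pegasus-like; anything else is novel.
    First matching rule wins; returns (label, rule_id).
    """
    for rule_id, label in rules:
        if rule_id == "stowaway_tsd" and _motif_matches(tsd_motif, "TA"):
            return label, rule_id
        if rule_id == "tourist_tsd" and (_motif_matches(tsd_motif, "TWA")
                                         or _motif_matches(tsd_motif, "TDA")):
            return label, rule_id
        if rule_id == "pegasus_tsd_tir":
            alts = tsd_motif.upper().split("/")
            if any(len(a) == 8 for a in alts) and len(tir_consensus) >= len(_PEGASUS_TIR):
                head = tir_consensus[:len(_PEGASUS_TIR)]
                ident = sum(a == b for a, b in zip(head, _PEGASUS_TIR)) / len(_PEGASUS_TIR)
                if ident >= 0.8:
                    return label, rule_id
    return "novel", "default"


def census_family(genome: GenomeSequence | list[GenomeSequence],
                  representative: str, tir_len: int, family_id: str,
                  tsd_motif: str = "", tir_consensus: str = "") -> tuple[FamilyCensus, list[MiteCopy]]:
    """Run the homology census for one family and summarise it."""
    copies = homology_search(genome, representative, family_id=family_id,
                             tir_len=tir_len)
    n_total = len(copies)
    n_intact = sum(c.intact for c in copies)
    seqs = [genome] if isinstance(genome, GenomeSequence) else list(genome)
    by_id = {s.id: s.seq for s in seqs}
    at_vals = []
    for c in copies:
        sub = by_id[c.chrom][c.start:c.end]
        if set(sub) != {"N"}:
            at_vals.append(at_content(sub))
    label, _rule = classify_superfamily(tsd_motif or "", tir_consensus or representative[:tir_len])
    census = FamilyCensus(
        family_id=family_id, n_total=n_total, n_intact=n_intact,
        n_fragmentary=n_total - n_intact,
        full_length_pct=round_half_away(100.0 * n_intact / n_total) if n_total else 0,
        at_content_pct=round_half_away(100.0 * float(np.mean(at_vals))) if at_vals else 0,
        superfamily=label, tsd_motif=tsd_motif,
        tir_consensus=tir_consensus or representative[:tir_len],
    )
    return census, copies
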