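"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, closed forms) without sharing code with the implementation
they check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(c, "N") for c in reversed(seq))


def oracle_tir(seq: str, s: int, e: int, tir_min=8, tir_max=50,
               max_mm=0.10) -> tuple[int, int] | None:
    """Longest admissible TIR for element seq[s:e], by direct enumeration."""
    best = None
    limit = min(tir_max, (e - s) // 2)
    mm = 0
    for t in range(limit):
        a, b = seq[s + t], seq[e - 1 - t]
        if a == "N" or b == "N":
            break
        matched = a == _COMP[b]
        if not matched:
            if t == 0:
                return None  # a terminal repeat reaches the terminus
            mm += 1
        l = t + 1
        # an inverted repeat does not end on a mismatch
        if matched and l >= tir_min and mm <= int(max_mm * l):
            best = (l, mm)
    return best


def oracle_tsd(seq: str, s: int, e: int, tsd_min=2, tsd_max=30) -> str | None:
    """Longest exact flanking direct repeat, with the mononucleotide-run rule."""
    for lt in range(min(tsd_max, s, len(seq) - e), tsd_min - 1, -1):
        left = seq[s - lt:s]
        if "N" in left or left != seq[e:e + lt]:
            continue
        if len(set(left)) == 1:
            base = left[0]
            if s - lt - 1 >= 0 and seq[s - lt - 1] == base:
                continue
            if e + lt < len(seq) and seq[e + lt] == base:
                continue
        return left
    return None


def brute_force_candidates(seq: str, chrom: str = "x", len_min=100, len_max=600,
                           **kw) -> list[tuple]:
    """Exhaustive enumeration of every admissible (start, end, tir, tsd).

    Returns tuples (chrom, start, end, tir_len, tsd) for all structural
    candidates, before overlap resolution.
    """
    n = len(seq)
    out = []
    for s in range(2, n - len_min - 2):
        for e in range(s + len_min, min(s + len_max, n - 2) + 1):
            tir = oracle_tir(seq, s, e, **kw)
            if tir is None:
                continue
            if "N" in seq[s:e]:
                continue
            tsd = oracle_tsd(seq, s, e)
            if tsd is None:
                continue
            out.append((chrom, s, e, tir[0], tsd))
    return out


def resolve_overlaps(cands: list[tuple]) -> list[tuple]:
    """Same total order the scanner documents: longer TIR, longer TSD,
    leftmost; drop candidates sharing >50% of the shorter span."""
    order = sorted(cands, key=lambda c: (-c[3], -len(c[4]), c[1], c[2]))
    kept = []
    for c in order:
        ok = True
        for k in kept:
            ov = min(c[2], k[2]) - max(c[1], k[1])
            if ov > 0 and ov > 0.5 * min(c[2] - c[1], k[2] - k[1]):
                ok = False
                break
        if ok:
            kept.append(c)
    return sorted(kept, key=lambda c: (c[1], c[2]))


def tandem_cover_fraction(seq: str, max_period=6, min_region=8) -> float:
    """Position-wise tandem-repeat cover by direct window enumeration."""
    n = len(seq)
    covered = set()
    for p in range(1, max_period + 1):
        # enumerate maximal periodic windows directly
        start = 0
        while start < n - p:
            length = p
            while start + length < n and seq[start + length] == seq[start + length - p] \
                    and seq[start + length] != "N":
                length += 1
            if length >= max(2 * p, min_region) and length > p:
                covered.update(range(start, start + length))
                start = start + length - p + 1
            else:
                start += 1
    return len(covered) / n if n else 0.0


def count_exact(pattern: str, text: str) -> int:
    """Exact substring occurrence count (overlapping)."""
    count = 0
    pos = text.find(pattern)
    while pos != -1:
        count += 1
        pos = text.find(pattern, pos + 1)
    return count


def mst_edges_and_weight(haplotypes: list[str]):
    """Minimum spanning tree over Hamming distances (networkx oracle)."""
    g = nx.Graph()
    g.add_nodes_from(haplotypes)
    for a, b in combinations(sorted(set(haplotypes)), 2):
        g.add_edge(a, b, weight=sum(x != y for x, y in zip(a, b)))
    mst = nx.minimum_spanning_tree(g)
    return mst, sum(d["weight"] for _, _, d in mst.edges(data=True))


def steiner_improvable(haplotypes: list[str]) -> bool:
    """Exhaustive check: does the median of any triple lower the MST weight?"""
    from itertools import combinations as comb
    haps = sorted(set(haplotypes))
    _, base = mst_edges_and_weight(haps)
    for u, v, w in comb(haps, 3):
        med = "".join(x if x == y or x == z else (y if y == z else min(x, y, z))
                      for x, y, z in zip(u, v, w))
        if med in haps:
            continue
        _, cost = mst_edges_and_weight(haps + [med])
        if cost < base:
            return True
    return False
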