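"""Per-family evolutionary analytics.

Members are multiple-aligned by center-star around the family
representative (members are census-guaranteed near-identical to it, where
center-star is within known bounds of the optimum), a majority consensus is
built, each member is dated from its Kimura 2-parameter distance to the
consensus through T = k / (2 r), regional diversity is profiled in
non-overlapping 20-bp windows classified by the +/-2 SD rule, and
intrafamily structure is summarised as a median-joining haplotype network
(epsilon = 0, gaps as a fifth state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from ._align import global_alignment, make_aligner
from .errors import ParameterError, SaturationError, UndefinedInputError

__all__ = [
    "FamilyAlignment",
    "AgeEstimate",
    "DiversityProfile",
    "HaplotypeNetwork",
    "align_family",
    "consensus",
    "k2p_distance",
    "insertion_age",
    "family_ages",
    "sliding_pi",
    "mj_network",
    "star_statistic",
    "DEFAULT_RATE",
]

# neutral substitution rate, substitutions/site/year (fruit-fly rate,
# conventionally applied to silkworm)
DEFAULT_RATE = 1.56e-8

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_ALIGNER = make_aligner("global")


@dataclass
class FamilyAlignment:
    family_id: str
    rows: list[str]                 # equal length, gap char '-'
    row_ids: list[str]
    center: str                     # ungapped center (representative)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class AgeEstimate:
    member_id: str
    k: float
    t_years: float
    rate: float

    @property
    def t_my(self) -> float:
        return self.t_years / 1e6


@dataclass(frozen=True)
class DiversityProfile:
    windows: list[tuple[int, int, float]]   # (start, end, pi) on consensus coords
    mean_pi: float
    sd_pi: float
    classes: list[str]                      # conserved / intermediate / variable
    undefined: list[bool]


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                          # nodes: haplotype strings
    multiplicity: dict[str, int]
    median_vectors: list[str]

    @property
    def nodes(self) -> list[tuple[str, int]]:
        return sorted((h, m) for h, m in self.multiplicity.items())


def align_family(members: list[str], center: str | None = None,
                 member_ids: list[str] | None = None,
                 family_id: str = "") -> FamilyAlignment:
    """Center-star multiple alignment of near-identical family members.

    Every member is globally aligned to the center; columns are merged on
    center coordinates with per-slot maximal insertion widths.  A member
    with no alignable overlap is excluded (its id is dropped from row_ids).
    """
    if len(members) < 2:
        raise ParameterError("need at least two members to align")
    center = center or members[0]
    ids = member_ids or [f"m{i}" for i in range(len(members))]
    m = len(center)
    # per-member: insertions[slot] (slot 0..m) and per-center-position char
    parsed = []
    kept_ids = []
    for seq, sid in zip(members, ids):
        aln = global_alignment(center, seq, _ALIGNER)
        c_row, s_row = str(aln[0]), str(aln[1])
        if all(a == "-" or b == "-" for a, b in zip(c_row, s_row)):
            continue  # zero alignable overlap
        ins: list[str] = [""] * (m + 1)
        chars: list[str] = [""] * m
        cpos = 0
        for a, b in zip(c_row, s_row):
            if a == "-":
                ins[cpos] += b
            else:
                chars[cpos] = b
                cpos += 1
        parsed.append((ins, chars))
        kept_ids.append(sid)
    widths = [max(len(p[0][j]) for p in parsed) for j in range(m + 1)]
    rows = []
    for ins, chars in parsed:
        row = []
        for j in range(m):
            row.append(ins[j].ljust(widths[j], "-"))
            row.append(chars[j])
        row.append(ins[m].ljust(widths[m], "-"))
        rows.append("".join(row))
    return FamilyAlignment(family_id=family_id, rows=rows, row_ids=kept_ids,
                           center=center)


def consensus(alignment: FamilyAlignment) -> str:
    """Per-column majority base; gap-majority columns omitted; base ties
    broken alphabetically (A < C < G < T)."""
    if len(alignment.rows) < 2:
        raise ParameterError("consensus needs at least two rows")
    out = []
    for col in zip(*alignment.rows):
        gaps = sum(1 for c in col if c == "-")
        bases = [c for c in col if c in "ACGT"]
        if gaps > len(col) - gaps or not bases:
            continue
        counts = {b: bases.count(b) for b in sorted(set(bases))}
        best = max(counts, key=lambda b: (counts[b], -ord(b)))
        out.append(best)
    return "".join(out)


def _consensus_columns(alignment: FamilyAlignment) -> list[int]:
    """Indices of alignment columns that survive into the consensus."""
    keep = []
    for idx, col in enumerate(zip(*alignment.rows)):
        gaps = sum(1 for c in col if c == "-")
        bases = sum(1 for c in col if c in "ACGT")
        if gaps > len(col) - gaps or bases == 0:
            continue
        keep.append(idx)
    return keep


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance over shared ungapped sites.

    k = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the transition and
    transversion proportions.  Raises on saturation or zero shared sites.
    """
    shared = 0
    p_count = 0
    q_count = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        shared += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            p_count += 1
        else:
            q_count += 1
    if shared == 0:
        raise UndefinedInputError("no shared ungapped sites")
    p = p_count / shared
    q = q_count / shared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined at P={p:.4f}, Q={q:.4f} (saturated)")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def insertion_age(k: float, r: float = DEFAULT_RATE) -> float:
    """Insertion age in years: T = k / (2 r)."""
    if r <= 0:
        raise ParameterError("substitution rate must be positive")
    if k < 0:
        raise ParameterError("distance must be non-negative")
    return k / (2.0 * r)


def family_ages(alignment: FamilyAlignment, r: float = DEFAULT_RATE) -> list[AgeEstimate]:
    """K2P distance to the family consensus and age for every member."""
    cols = _consensus_columns(alignment)
    cons = consensus(alignment)
    out = []
    for row, rid in zip(alignment.rows, alignment.row_ids):
        member_on_cons = "".join(row[i] for i in cols)
        k = k2p_distance(member_on_cons, cons)
        out.append(AgeEstimate(rid, k, insertion_age(k, r), r))
    return out


def sliding_pi(alignment: FamilyAlignment, window: int = 20,
               step: int = 20) -> DiversityProfile:
    """Nucleotide diversity in sliding windows of consensus coordinates.

    pi per window is the average over sequence pairs of differences per
    compared site, excluding site-pairs with a gap.  Windows are classified
    variable (pi >= mean + 2 SD) or conserved (pi <= mean - 2 SD, threshold
    floored at 0); with SD = 0 every window is intermediate.  A trailing
    partial window is dropped; a window with no comparable site-pair is
    flagged undefined and classed intermediate.
    """
    cols = _consensus_columns(alignment)
    if len(cols) < window:
        raise ParameterError("alignment shorter than one window")
    rows = alignment.rows
    pairs = list(combinations(range(len(rows)), 2))
    windows = []
    undefined = []
    for w_start in range(0, len(cols) - window + 1, step):
        w_cols = cols[w_start:w_start + window]
        ratios = []
        for i, j in pairs:
            diffs = 0
            comp = 0
            for c in w_cols:
                x, y = rows[i][c], rows[j][c]
                if x in "ACGT" and y in "ACGT":
                    comp += 1
                    if x != y:
                        diffs += 1
            if comp:
                ratios.append(diffs / comp)
        if ratios:
            pi = sum(ratios) / len(ratios)
            undefined.append(False)
        else:
            pi = float("nan")
            undefined.append(True)
        windows.append((w_start, w_start + window, pi))
    defined = [w[2] for w, u in zip(windows, undefined) if not u]
    mean_pi = sum(defined) / len(defined) if defined else float("nan")
    if len(defined) > 1:
        var = sum((x - mean_pi) ** 2 for x in defined) / (len(defined) - 1)
        sd_pi = math.sqrt(var)
    else:
        sd_pi = 0.0
    classes = []
    lo = max(mean_pi - 2.0 * sd_pi, 0.0)
    hi = mean_pi + 2.0 * sd_pi
    for (s, e, pi), und in zip(windows, undefined):
        if und or sd_pi == 0.0 or math.isnan(pi):
            classes.append("intermediate")
        elif pi >= hi:
            classes.append("variable")
        elif pi <= lo:
            classes.append("conserved")
        else:
            classes.append("intermediate")
    return DiversityProfile(windows, mean_pi, sd_pi, classes, undefined)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _msn(haplotypes: list[str]) -> nx.Graph:
    """Minimum spanning network: union of all minimum spanning trees."""
    g = nx.Graph()
    g.add_nodes_from(haplotypes)
    if len(haplotypes) < 2:
        return g
    edges = sorted(
        ((a, b, _hamming(a, b)) for a, b in combinations(sorted(haplotypes), 2)),
        key=lambda e: (e[2], e[0], e[1]),
    )
    comp = nx.utils.UnionFind(haplotypes)
    i = 0
    connected = False
    while i < len(edges) and not connected:
        w = edges[i][2]
        batch = []
        while i < len(edges) and edges[i][2] == w:
            a, b, _ = edges[i]
            if comp[a] != comp[b]:
                batch.append((a, b))
            i += 1
        for a, b in batch:
            g.add_edge(a, b, weight=w)
            comp.union(a, b)
        connected = len({comp[h] for h in haplotypes}) == 1
    return g


def _mst_weight(haplotypes: list[str]) -> int:
    g = nx.Graph()
    g.add_nodes_from(haplotypes)
    for a, b in combinations(sorted(haplotypes), 2):
        g.add_edge(a, b, weight=_hamming(a, b))
    return int(sum(d["weight"] for _, _, d in
                   nx.minimum_spanning_edges(g, data=True)))


def _median(u: str, v: str, w: str) -> str:
    """Per-position majority of three sequences; all-distinct positions keep
    the lexicographically smallest observed state (gap sorts before bases)."""
    out = []
    for x, y, z in zip(u, v, w):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))
    return "".join(out)


def mj_network(sequences: list[str], epsilon: int = 0) -> HaplotypeNetwork:
    """Median-joining network of aligned sequences (gap = fifth state).

    Identical sequences are condensed into haplotypes with multiplicities.
    Median (Steiner) vectors are added greedily whenever a triple centred
    on a network node admits a median that strictly lowers the spanning
    cost; obsolete medians are pruned.  With epsilon = 0 and tree-like
    data the result equals the minimum spanning tree.
    """
    if not sequences:
        raise ParameterError("need at least one sequence")
    if epsilon != 0:
        raise ParameterError("only epsilon = 0 is implemented")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ParameterError("sequences must be aligned to equal length")
    multiplicity: dict[str, int] = {}
    for s in sequences:
        multiplicity[s] = multiplicity.get(s, 0) + 1
    sampled = sorted(multiplicity)
    current = list(sampled)
    medians: list[str] = []

    improved = True
    while improved:
        improved = False
        g = _msn(current)
        base_cost = _mst_weight(current)
        best: tuple[int, str] | None = None
        for v in sorted(g.nodes):
            nbrs = sorted(g.neighbors(v))
            for u, w in combinations(nbrs, 2):
                m = _median(u, v, w)
                if m in multiplicity or m in medians or m in current:
                    continue
                cost = _mst_weight(current + [m])
                if cost < base_cost and (best is None or (cost, m) < best):
                    best = (cost, m)
        if best is not None:
            medians.append(best[1])
            current.append(best[1])
            improved = True

    # prune median vectors whose removal does not raise the spanning cost
    changed = True
    while changed:
        changed = False
        for m in sorted(medians):
            rest = [h for h in current if h != m]
            if _mst_weight(rest) <= _mst_weight(current):
                current = rest
                medians.remove(m)
                changed = True
                break

    g = _msn(current)
    for h in current:
        g.nodes[h]["multiplicity"] = multiplicity.get(h, 0)
        g.nodes[h]["is_median"] = h not in multiplicity
    return HaplotypeNetwork(graph=g, multiplicity=dict(multiplicity),
                            median_vectors=sorted(medians))


def star_statistic(network: HaplotypeNetwork) -> float:
    """Fraction of other nodes adjacent to the modal (highest multiplicity)
    node; near 1 for a recent single-source burst."""
    g = network.graph
    if g.number_of_nodes() <= 1:
        return 1.0
    modal = max(sorted(network.multiplicity), key=lambda h: network.multiplicity[h])
    return g.degree(modal) / (g.number_of_nodes() - 1)
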