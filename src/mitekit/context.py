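"""Genomic context of insertions: category calls, chromosome-distribution
statistics, the randomised insertion-site null, and the germline-silencing
probability.

A copy is assigned exactly one category by its midpoint: exon if the
midpoint overlaps an exon, intron if it overlaps a gene but no exon,
5flank/3flank if the nearest gene lies within the flank limit (the side is
strand-aware), else intergenic.  The null simulation classifies randomly
sampled fragment midpoints with the identical rule, so observed-vs-null
comparisons share one convention.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError, UndefinedInputError
from .io import GeneModel, GenomeSequence

__all__ = [
    "InsertionContext",
    "ChiSquareResult",
    "NullSimResult",
    "CorrelationResult",
    "GeneIndex",
    "classify_insertion",
    "flank_bins",
    "chrom_distribution_test",
    "simulate_null",
    "enrichment_test",
    "density_correlation",
    "germline_silencing_prob",
]

CATEGORIES = ("exon", "intron", "5flank", "3flank", "intergenic")


@dataclass(frozen=True)
class InsertionContext:
    chrom: str
    position: int            # the classified midpoint
    category: str
    nearest_gene: str | None = None
    distance: int = 0

    @property
    def in_gene_region(self) -> bool:
        return self.category != "intergenic"


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: tuple
    expected: tuple
    low_expected_warning: bool = False


@dataclass(frozen=True)
class NullSimResult:
    n: int
    seed: int | None
    category_fractions: dict[str, float]
    in_gene_fraction: float
    category_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    p_value: float
    df: int


class GeneIndex:
    """Per-chromosome sorted gene/exon lookup for midpoint classification."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._max_end: dict[str, list[int]] = {}
        for chrom, glist in self._by_chrom.items():
            glist.sort(key=lambda g: (g.start, g.end))
            self._starts[chrom] = [g.start for g in glist]
            running = []
            m = 0
            for g in glist:
                m = max(m, g.end)
                running.append(m)
            self._max_end[chrom] = running

    def _overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        glist = self._by_chrom.get(chrom, [])
        if not glist:
            return []
        hi = bisect_right(self._starts[chrom], pos)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._max_end[chrom][i] <= pos:
                break
            g = glist[i]
            if g.start <= pos < g.end:
                out.append(g)
        out.reverse()
        return out

    def classify(self, chrom: str, pos: int, flank_limit: int = 5000) -> InsertionContext:
        overlapping = self._overlapping(chrom, pos)
        for g in overlapping:
            for a, b in g.exons:
                if a <= pos < b:
                    return InsertionContext(chrom, pos, "exon", g.gene_id, 0)
        if overlapping:
            g = overlapping[0]
            return InsertionContext(chrom, pos, "intron", g.gene_id, 0)

        glist = self._by_chrom.get(chrom, [])
        best: tuple[int, int, GeneModel] | None = None  # (distance, side_rank, gene)
        if glist:
            hi = bisect_right(self._starts[chrom], pos)
            # nearest gene to the right, and candidates to the left
            neighbours = []
            if hi < len(glist):
                neighbours.append(glist[hi])
            for i in range(hi - 1, max(-1, hi - 8), -1):
                neighbours.append(glist[i])
            for g in neighbours:
                if pos < g.start:
                    dist = g.start - pos
                    side = "5flank" if g.strand == "+" else "3flank"
                elif pos >= g.end:
                    dist = pos - (g.end - 1)
                    side = "3flank" if g.strand == "+" else "5flank"
                else:
                    continue
                if dist > flank_limit:
                    continue
                side_rank = 0 if side == "5flank" else 1  # exact tie -> 5flank
                key = (dist, side_rank)
                if best is None or key < (best[0], best[1]):
                    best = (dist, side_rank, g)
        if best is not None:
            dist, side_rank, g = best
            side = "5flank" if side_rank == 0 else "3flank"
            return InsertionContext(chrom, pos, side, g.gene_id, dist)
        return InsertionContext(chrom, pos, "intergenic", None, 0)


def _midpoint(copy) -> tuple[str, int]:
    return copy.chrom, (copy.start + copy.end) // 2


def classify_insertion(copy, genes: list[GeneModel] | GeneIndex,
                       flank_limit: int = 5000) -> InsertionContext:
    """Category of one copy (anything with chrom/start/end) by its midpoint."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    chrom, mid = _midpoint(copy)
    return index.classify(chrom, mid, flank_limit)


def flank_bins(contexts: list[InsertionContext],
               bins: tuple[int, ...] = (500, 3000, 5000)) -> dict[str, dict[str, int]]:
    """Subdivide flank categories by distance bins (half-open upper edges).

    With the default bins the labels are '<=500', '500-3000', '3000-5000'.
    """
    edges = list(bins)
    labels = [f"<={edges[0]}"] + [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
    out = {side: {lab: 0 for lab in labels} for side in ("5flank", "3flank")}
    for ctx in contexts:
        if ctx.category not in ("5flank", "3flank"):
            continue
        for lab, hi in zip(labels, edges):
            if ctx.distance <= hi:
                out[ctx.category][lab] += 1
                break
    return out


def chrom_distribution_test(counts: dict[str, int] | list[int],
                            lengths: dict[str, int] | list[int]) -> ChiSquareResult:
    """Chi-square test of copy counts against a length-proportional expectation."""
    if isinstance(counts, dict):
        keys = sorted(counts)
        obs = np.array([counts[k] for k in keys], dtype=float)
        lens = np.array([lengths[k] for k in keys], dtype=float)
    else:
        obs = np.asarray(counts, dtype=float)
        lens = np.asarray(lengths, dtype=float)
    if obs.size < 2:
        raise ParameterError("need at least two chromosomes")
    if np.any(lens <= 0):
        raise ParameterError("chromosome lengths must be positive")
    if obs.sum() <= 0:
        raise ParameterError("no copies to test")
    expected = obs.sum() * lens / lens.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(stat, df, p, tuple(obs), tuple(expected),
                           bool(np.any(expected < 1)))


def simulate_null(sequences: list[GenomeSequence], genes: list[GeneModel] | GeneIndex,
                  n: int = 5000, fragment: int = 10_000, flank_limit: int = 5000,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> NullSimResult:
    """Randomised insertion-site null.

    ``n`` fragment start positions are sampled uniformly over the genome;
    each fragment extends up to ``fragment`` bp (truncated at the sequence
    end) and its midpoint is classified exactly like an observed copy.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    lens = np.array([s.length for s in sequences], dtype=np.int64)
    total = int(lens.sum())
    if total <= fragment:
        raise ParameterError("genome shorter than one fragment")
    cum = np.concatenate([[0], np.cumsum(lens)])
    offsets = rng.integers(0, total, size=n)
    counts = {c: 0 for c in CATEGORIES}
    for off in offsets:
        ci = int(np.searchsorted(cum, off, side="right") - 1)
        pos = int(off - cum[ci])
        chrom = sequences[ci].id
        end = min(pos + fragment, int(lens[ci]))
        mid = (pos + end) // 2
        counts[index.classify(chrom, mid, flank_limit).category] += 1
    fractions = {c: counts[c] / n for c in CATEGORIES}
    in_gene = 1.0 - fractions["intergenic"]
    return NullSimResult(n=n, seed=seed, category_fractions=fractions,
                         in_gene_fraction=in_gene, category_counts=counts)


def enrichment_test(obs_in_gene: int, obs_total: int,
                    null_in_gene: int, null_total: int,
                    correction: bool = False) -> ChiSquareResult:
    """2x2 chi-square test of the in-gene proportion, observed vs null."""
    table = np.array([
        [obs_in_gene, obs_total - obs_in_gene],
        [null_in_gene, null_total - null_in_gene],
    ], dtype=float)
    stat, p, df, expected = stats.chi2_contingency(table, correction=correction)
    return ChiSquareResult(float(stat), int(df), float(p),
                           tuple(table.ravel()), tuple(expected.ravel()),
                           bool(np.any(expected < 1)))


def enrichment_from_contexts(contexts: list[InsertionContext],
                             null: NullSimResult) -> ChiSquareResult:
    obs_in = sum(1 for c in contexts if c.in_gene_region)
    null_in = null.n - null.category_counts["intergenic"]
    return enrichment_test(obs_in, len(contexts), null_in, null.n)


def density_correlation(mite_counts: list[int] | np.ndarray,
                        gene_counts: list[int] | np.ndarray,
                        lengths: list[int] | np.ndarray) -> CorrelationResult:
    """Pearson correlation of per-Mb MITE and gene densities across chromosomes."""
    m = np.asarray(mite_counts, dtype=float)
    g = np.asarray(gene_counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if m.size < 3:
        raise ParameterError("need at least three chromosomes")
    dm = m / (l / 1e6)
    dg = g / (l / 1e6)
    if np.allclose(dm.std(), 0) or np.allclose(dg.std(), 0):
        raise UndefinedInputError("zero variance in a density vector")
    r, p = stats.pearsonr(dm, dg)
    return CorrelationResult(float(r * r), float(p), int(m.size - 2))


def germline_silencing_prob(expressed: int = 8431, total: int = 10_393,
                            n_genes: int = 5) -> float:
    """Probability that ``n_genes`` randomly chosen genes are all unexpressed,
    given ``expressed`` of ``total`` genes are expressed in the tissue."""
    if total <= 0:
        raise ParameterError("total genes must be positive")
    if not 0 <= expressed <= total:
        raise ParameterError("expressed count outside [0, total]")
    if n_genes < 0:
        raise ParameterError("n_genes must be non-negative")
    return (1.0 - expressed / total) ** n_genes
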