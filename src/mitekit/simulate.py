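"""Truth-labelled synthetic genomes with planted MITE families.

The generator emulates the statistical structure the analysis assumes: an
i.i.d. nucleotide background at a configurable AT content, gene models with
exon/intron structure, and planted element copies of the form

    TSD + TIR + internal + revcomp(TIR) + TSD

where each copy is mutated under a two-rate substitution model (transition
probability kappa/(kappa+2)) at a per-copy divergence drawn around the
family mean, and a configurable fraction of copies loses one terminal TIR
plus at least 10 bp (truncation).  Decoy pseudo-elements (tandem simple
repeats, N-runs, elements nested in high-copy repeats) are planted on a
dedicated decoy scaffold so that existing coordinates stay valid.

Insertion sites are rejection-sampled so that an exact intact copy is
structurally unambiguous: no outward shift of the element boundary yields a
competing TIR+TSD call that would outrank the planted one under the
scanner's deterministic tie-break.  This makes planted coordinates exactly
recoverable, which real insertion sites need not be.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import miner as _miner
from ._seq import mutate, random_seq, revcomp
from .errors import PackingError, ParameterError
from .io import GeneModel, GenomeSequence, write_fasta, write_gff3

__all__ = [
    "FamilySpec",
    "TruthRecord",
    "GenomeBundle",
    "make_genome",
    "make_decoys",
    "default_family_specs",
    "write_truth",
    "read_truth",
    "burst_haplotypes",
    "two_epoch_haplotypes",
]

_DEGENERATE = {"W": "AT", "D": "AGT", "N": "ACGT"}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted family."""

    family_id: str
    tir: str
    tsd_motif: str            # over ACGT + W/D/N; alternatives split on '/'
    internal_length: int
    n_copies: int
    divergence_mean: float = 0.0
    divergence_sd: float = 0.0
    truncation_fraction: float = 0.0
    at_content: float = 0.65

    def __post_init__(self) -> None:
        if not 8 <= len(self.tir) <= 50:
            raise ParameterError(f"{self.family_id}: TIR length must be 8-50 bp")
        if not 100 <= self.element_length <= 600:
            raise ParameterError(
                f"{self.family_id}: element length {self.element_length} outside 100-600 bp")
        if not 0.0 <= self.truncation_fraction <= 1.0:
            raise ParameterError(f"{self.family_id}: truncation_fraction outside [0, 1]")
        if self.divergence_mean < 0:
            raise ParameterError(f"{self.family_id}: negative divergence")

    @property
    def element_length(self) -> int:
        return 2 * len(self.tir) + self.internal_length


@dataclass(frozen=True)
class TruthRecord:
    """One planted element (or decoy) in final genome coordinates."""

    chrom: str
    start: int               # element span excluding the TSD copies
    end: int
    family_id: str
    k_planted: float         # realized substitutions per site on this copy
    intact: bool
    category_truth: str = "intergenic"
    decoy_class: str | None = None
    tsd: str = ""


@dataclass
class GenomeBundle:
    """A synthetic genome with its gene annotation and planted-element truth."""

    sequences: list[GenomeSequence]
    genes: list[GeneModel]
    truth: list[TruthRecord]
    specs: list[FamilySpec] = field(default_factory=list)
    masters: dict[str, str] = field(default_factory=dict)  # family_id -> master element

    def sequence(self, chrom: str) -> GenomeSequence:
        for rec in self.sequences:
            if rec.id == chrom:
                return rec
        raise KeyError(chrom)

    def element_seq(self, rec: TruthRecord) -> str:
        return self.sequence(rec.chrom).seq[rec.start:rec.end]

    def write(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": prefix.with_suffix(".fa"),
            "gff3": prefix.with_suffix(".gff3"),
            "truth": prefix.with_suffix(".truth.tsv"),
        }
        write_fasta(self.sequences, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        write_truth(self.truth, paths["truth"])
        return paths


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfamily_id\tk_planted\tintact\t"
                 "category_truth\tdecoy_class\n")
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.family_id}\t"
                     f"{t.k_planted:.6f}\t{int(t.intact)}\t{t.category_truth}\t"
                     f"{t.decoy_class or '.'}\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("chrom\t")
        for line in fh:
            c, s, e, fam, k, intact, cat, dec = line.rstrip("\n").split("\t")
            out.append(TruthRecord(c, int(s), int(e), fam, float(k),
                                   bool(int(intact)), cat,
                                   None if dec == "." else dec))
    return out


def _sample_tsd(motif: str, rng: np.random.Generator) -> str:
    alternatives = motif.upper().split("/")
    pattern = alternatives[int(rng.integers(len(alternatives)))]
    out = []
    for ch in pattern:
        choices = _DEGENERATE.get(ch, ch)
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _make_gene(rng: np.random.Generator) -> tuple[int, list[tuple[int, int]], str]:
    """(span length, exon intervals relative to gene start, strand)."""
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(150, 401, size=n_exons)
    intron_lens = rng.integers(300, 1501, size=n_exons - 1)
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    return pos, exons, strand


def _place_genes(rng: np.random.Generator, length: int, gene_density: float,
                 chrom: str, min_gap: int = 12_000) -> list[GeneModel]:
    n = int(round(gene_density * length / 1e6))
    if n == 0:
        return []
    plans = [_make_gene(rng) for _ in range(n)]
    total = sum(p[0] for p in plans)
    slack = length - total - (n + 1) * min_gap
    if slack < 0:
        raise PackingError(
            f"cannot place {n} genes (total span {total} bp) in {length} bp")
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    genes = []
    pos = 0
    for i, (span, exons, strand) in enumerate(plans):
        pos += min_gap + int(extra[i])
        genes.append(GeneModel(
            gene_id=f"gene{i + 1:04d}", chrom=chrom, start=pos, end=pos + span,
            strand=strand, exons=[(pos + a, pos + b) for a, b in exons],
        ))
        pos += span
    return genes


def _build_master(spec: FamilySpec, rng: np.random.Generator) -> str:
    internal = random_seq(rng, spec.internal_length, spec.at_content)
    return spec.tir + internal + revcomp(spec.tir)


def _unambiguous(local: str, s: int, e: int, params: _miner.ScanParams) -> bool:
    """True when the planted boundary wins the scanner's tie-break locally."""
    planted = _miner._validate(local, "x", s, e, params)
    if planted is None:
        return False
    # outward shifts: a competitor with a longer TIR -- or an equal TIR with
    # a longer TSD -- would outrank the planted call (it also starts left).
    mm_cap = int(params.max_tir_mismatch * params.tir_max)
    ext, mm = 0, 0
    a, b = s - 1, e
    n = len(local)
    while ext < params.tir_max and a >= 0 and b < n:
        ca, cb = local[a], local[b]
        if ca == "N" or cb == "N":
            break
        if ca != _miner._COMP.get(cb, "?"):
            mm += 1
            if mm > mm_cap:
                break
        ext += 1
        a -= 1
        b += 1
    for d in range(1, ext + 1):
        comp = _miner._validate(local, "x", s - d, e + d, params)
        if comp is not None and (comp.tir_len, comp.tsd_len) >= (planted.tir_len,
                                                                 planted.tsd_len):
            return False
    return True


def _choose_position(rng: np.random.Generator, length: int, taken: list[int],
                     min_sep: int, margin: int) -> int:
    for _ in range(200):
        p = int(rng.integers(margin, length - margin))
        if all(abs(p - q) >= min_sep for q in taken):
            return p
    raise PackingError("could not find a free insertion site; genome too crowded")


def make_genome(specs: list[FamilySpec], gene_density: float = 30.0,
                genome_length: int = 100_000, ts_tv_ratio: float = 2.0,
                seed: int | None = None, *, at_content: float = 0.62,
                chrom_id: str = "chr1", allow_exonic: bool = False,
                category_weights: dict[str, float] | None = None,
                rng: np.random.Generator | None = None) -> GenomeBundle:
    """Generate one chromosome with planted families, genes and truth labels.

    ``category_weights`` optionally biases insertion sites toward genomic
    categories (keys among exon/intron/5flank/3flank/intergenic); the truth
    label is always recomputed from the assembled genome with the same
    midpoint convention the context classifier uses.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    params = _miner.ScanParams()
    total_planted = sum((s.element_length + 20) * s.n_copies for s in specs)
    if total_planted >= genome_length // 2:
        raise PackingError(
            f"planted content ({total_planted} bp) too large for a "
            f"{genome_length} bp background")

    bg = random_seq(rng, genome_length, at_content)
    genes = _place_genes(rng, genome_length, gene_density, chrom_id)

    from .context import GeneIndex
    bg_index = GeneIndex(genes)

    # plan all insertions in background coordinates
    insertions: list[tuple[int, str, dict]] = []  # (pos, block, meta)
    taken: list[int] = []
    masters: dict[str, str] = {}
    margin = 150
    min_sep = 120
    for spec in specs:
        master = _build_master(spec, rng)
        masters[spec.family_id] = master
        tir_len = len(spec.tir)
        for _ in range(spec.n_copies):
            if spec.divergence_sd > 0:
                k_i = max(0.0, float(rng.normal(spec.divergence_mean,
                                                spec.divergence_sd)))
            else:
                k_i = spec.divergence_mean
            elem, n_sub = mutate(master, k_i, ts_tv_ratio, rng)
            intact = True
            if spec.truncation_fraction > 0 and rng.random() < spec.truncation_fraction:
                intact = False
                cut = tir_len + 10 + int(rng.integers(0, 11))
                cut = max(tir_len + 10, min(cut, int(0.18 * len(elem))))
                if rng.random() < 0.5:
                    elem = elem[cut:]
                else:
                    elem = elem[:-cut]
            want = None
            if category_weights:
                cats = sorted(category_weights)
                probs = np.array([category_weights[c] for c in cats], dtype=float)
                want = cats[int(rng.choice(len(cats), p=probs / probs.sum()))]
            placed = False
            for _ in range(300):
                # the TSD instance is re-drawn per attempt: a degenerate motif
                # may admit instances whose ends pair with the TIR, which makes
                # the planted boundary structurally ambiguous at any site
                tsd = _sample_tsd(spec.tsd_motif, rng)
                block = tsd + elem + tsd
                p = _choose_position(rng, genome_length, taken, min_sep, margin)
                if want is not None:
                    if bg_index.classify(chrom_id, p).category != want:
                        continue
                elif not allow_exonic and bg_index.classify(chrom_id, p).category == "exon":
                    continue
                local = bg[max(0, p - 80):p] + block + bg[p:p + 80]
                s_loc = min(p, 80) + len(tsd)
                e_loc = s_loc + len(elem)
                if intact and n_sub == 0 and not _unambiguous(local, s_loc, e_loc, params):
                    continue
                taken.append(p)
                insertions.append((p, block, {
                    "family_id": spec.family_id,
                    "k_planted": n_sub / len(master),
                    "intact": intact,
                    "tsd": tsd,
                }))
                placed = True
                break
            if not placed:
                raise PackingError(
                    f"{spec.family_id}: no admissible insertion site found")

    insertions.sort(key=lambda t: t[0])

    # assemble the final sequence and shift annotations
    pieces = []
    truth: list[TruthRecord] = []
    prev = 0
    shift = 0
    ins_positions = [p for p, _, _ in insertions]
    block_lens = [len(b) for _, b, _ in insertions]
    for (p, block, meta) in insertions:
        pieces.append(bg[prev:p])
        pieces.append(block)
        tsd_len = len(meta["tsd"])
        start = p + shift + tsd_len
        end = start + len(block) - 2 * tsd_len
        truth.append(TruthRecord(
            chrom=chrom_id, start=start, end=end,
            family_id=meta["family_id"], k_planted=meta["k_planted"],
            intact=meta["intact"], tsd=meta["tsd"],
        ))
        prev = p
        shift += len(block)
    pieces.append(bg[prev:])
    final_seq = "".join(pieces)

    cum = np.cumsum([0] + block_lens)

    def shift_le(x: int) -> int:   # blocks inserted at positions <= x
        return int(cum[np.searchsorted(ins_positions, x, side="right")])

    def shift_lt(x: int) -> int:
        return int(cum[np.searchsorted(ins_positions, x, side="left")])

    shifted_genes = []
    for g in genes:
        shifted_genes.append(GeneModel(
            gene_id=g.gene_id, chrom=g.chrom,
            start=g.start + shift_le(g.start), end=g.end + shift_lt(g.end),
            strand=g.strand,
            exons=[(a + shift_le(a), b + shift_lt(b)) for a, b in g.exons],
        ))

    bundle = GenomeBundle([GenomeSequence(chrom_id, final_seq)], shifted_genes,
                          truth, list(specs), masters)
    _assign_truth_categories(bundle)
    return bundle


def _assign_truth_categories(bundle: GenomeBundle) -> None:
    from .context import GeneIndex
    idx = GeneIndex(bundle.genes)
    labelled = []
    for t in bundle.truth:
        ctx = idx.classify(t.chrom, (t.start + t.end) // 2)
        labelled.append(replace(t, category_truth=ctx.category))
    bundle.truth = labelled


def make_decoys(bundle: GenomeBundle, n_simple: int = 0, n_nrun: int = 0,
                n_nested: int = 0, seed: int | None = None,
                decoy_chrom: str = "chrD", flank_copies: int = 21,
                rng: np.random.Generator | None = None) -> GenomeBundle:
    """Append a decoy scaffold carrying pseudo-element families.

    Three decoy classes mimic the pseudo-MITE filters: elements whose
    internal sequence is a tandem simple repeat, elements containing an
    N-run, and elements whose 50-bp flanks recur ``flank_copies`` times in
    the genome (nested-in-repeat mimics).  Copies of one class share a
    master so they cluster into a family.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    blocks: list[tuple[str, dict]] = []

    def _tir_and_tsd():
        tir = random_seq(rng, 14, 0.5)
        tsd = random_seq(rng, 3, 0.5)
        return tir, tsd

    if n_simple:
        tir, tsd = _tir_and_tsd()
        period = int(rng.integers(1, 7))
        unit = random_seq(rng, period, 0.5)
        internal = (unit * (180 // period + 1))[:180]
        elem = tir + internal + revcomp(tir)
        for _ in range(n_simple):
            blocks.append((tsd + elem + tsd, {
                "family_id": "DECOY-SIMPLE", "decoy_class": "decoy_simple",
                "tsd": tsd}))
    if n_nrun:
        tir, tsd = _tir_and_tsd()
        inner = random_seq(rng, 180, 0.5)
        internal = inner[:80] + "NNNN" + inner[84:]
        elem = tir + internal + revcomp(tir)
        for _ in range(n_nrun):
            blocks.append((tsd + elem + tsd, {
                "family_id": "DECOY-NRUN", "decoy_class": "decoy_nrun",
                "tsd": tsd}))
    nested_flanks: list[str] = []
    if n_nested:
        tir, tsd = _tir_and_tsd()
        elem = tir + random_seq(rng, 180, 0.5) + revcomp(tir)
        lf, rf = random_seq(rng, 50, 0.5), random_seq(rng, 50, 0.5)
        nested_flanks = [lf, rf]
        for _ in range(n_nested):
            blocks.append((lf + tsd + elem + tsd + rf, {
                "family_id": "DECOY-NESTED", "decoy_class": "decoy_nested",
                "tsd": tsd, "flank": 50}))

    n_blocks = len(blocks) + (2 * flank_copies if nested_flanks else 0)
    bg_len = max(30_000, 400 * n_blocks)
    bg = random_seq(rng, bg_len, 0.55)

    taken: list[int] = []
    placements: list[tuple[int, str, dict | None]] = []
    for block, meta in blocks:
        p = _choose_position(rng, bg_len, taken, 450, 200)
        taken.append(p)
        placements.append((p, block, meta))
    for flank in nested_flanks:
        for _ in range(flank_copies):
            p = _choose_position(rng, bg_len, taken, 120, 200)
            taken.append(p)
            placements.append((p, flank, None))
    placements.sort(key=lambda t: t[0])

    pieces = []
    truth_new: list[TruthRecord] = []
    prev = 0
    shift = 0
    for p, block, meta in placements:
        pieces.append(bg[prev:p])
        pieces.append(block)
        if meta is not None:
            tsd_len = len(meta["tsd"])
            flank = meta.get("flank", 0)
            start = p + shift + flank + tsd_len
            end = p + shift + len(block) - flank - tsd_len
            truth_new.append(TruthRecord(
                chrom=decoy_chrom, start=start, end=end,
                family_id=meta["family_id"], k_planted=0.0, intact=True,
                category_truth="intergenic", decoy_class=meta["decoy_class"],
                tsd=meta["tsd"],
            ))
        prev = p
        shift += len(block)
    pieces.append(bg[prev:])

    return GenomeBundle(
        sequences=bundle.sequences + [GenomeSequence(decoy_chrom, "".join(pieces))],
        genes=list(bundle.genes),
        truth=list(bundle.truth) + truth_new,
        specs=list(bundle.specs),
        masters=dict(bundle.masters),
    )


def default_family_specs(n_copies: int = 30, divergence_mean: float = 0.02,
                         truncation_fraction: float = 0.2) -> list[FamilySpec]:
    """Three planted families modelled on published silkworm MITE rows.

    TIR strings, TSD motifs, sizes and AT contents follow the packaged
    per-family table; copy numbers are scaled to desk size.
    """
    from .tables import TABLE1

    rows = {r.family_id: r for r in TABLE1}
    out = []
    for fid in ("BmMITE-2", "BmMITE-9", "BmMITE-13"):
        r = rows[fid]
        out.append(FamilySpec(
            family_id=fid, tir=r.tir, tsd_motif=r.tsd,
            internal_length=r.size_bp - 2 * len(r.tir), n_copies=n_copies,
            divergence_mean=divergence_mean,
            truncation_fraction=truncation_fraction,
            at_content=r.at_pct / 100.0,
        ))
    return out


def burst_haplotypes(n: int = 40, length: int = 200, mean_muts: float = 0.5,
                     seed: int | None = None) -> list[str]:
    """Haplotypes from a very recent expansion: one ancestor, few fresh
    mutations per copy -- the star-like regime."""
    rng = np.random.default_rng(seed)
    anc = random_seq(rng, length, 0.6)
    out = []
    for _ in range(n):
        hap = list(anc)
        for _ in range(rng.poisson(mean_muts)):
            pos = int(rng.integers(length))
            hap[pos] = "ACGT"[(("ACGT".index(hap[pos])) + 1 + int(rng.integers(3))) % 4]
        out.append("".join(hap))
    return out


def two_epoch_haplotypes(n: int = 40, length: int = 200, n_lineages: int = 6,
                         deep_muts: int = 8, recent_mean: float = 0.5,
                         seed: int | None = None) -> list[str]:
    """Haplotypes from an old expansion: deeply diverged lineages, each with
    a few recent copies -- long internal branches, no dominant hub."""
    rng = np.random.default_rng(seed)
    anc = random_seq(rng, length, 0.6)
    founders = []
    for _ in range(n_lineages):
        hap = list(anc)
        positions = rng.choice(length, size=deep_muts, replace=False)
        for pos in positions:
            hap[pos] = "ACGT"[(("ACGT".index(hap[pos])) + 1 + int(rng.integers(3))) % 4]
        founders.append("".join(hap))
    out = []
    for i in range(n):
        base = list(founders[i % n_lineages])
        for _ in range(rng.poisson(recent_mean)):
            pos = int(rng.integers(length))
            base[pos] = "ACGT"[(("ACGT".index(base[pos])) + 1 + int(rng.integers(3))) % 4]
        out.append("".join(base))
    return out
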