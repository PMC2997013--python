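# Methods

This note documents the models, conventions and numerical choices behind
`mitekit`, and what the synthetic-data tests do and do not establish about
real genomes.

## Coordinates and alphabets

All internal coordinates are 0-based half-open; GFF3 converts at the I/O
boundary (1-based inclusive on disk) and BED is emitted natively. Input
sequences are upper-cased and any character outside ACGT collapses to N.
N is excluded from alignments and from AT-content denominators; elements
containing N are never emitted as structural candidates (N-containing
elements are a pseudo-element class).

## Structural model of a candidate element

A candidate is a span `[s, e)` of 100–600 bp such that:

- **TIR**: the element prefix of length `L` (8–50 bp) pairs with the
  reverse complement of its suffix of length `L` with at most
  `floor(0.10·L)` mismatches. Two additional conventions make the call
  well-defined: the *outermost* pair must match (a terminal repeat reaches
  the terminus — otherwise the interior of a TSD can be re-read as a longer
  TIR with a shifted boundary) and the *innermost* pair must match (a
  repeat does not end on a mismatch — otherwise the canonical TIR greedily
  absorbs trailing mismatches). The reported TIR is the longest admissible
  `L`.
- **TSD**: an exact direct repeat of 2–30 bp immediately flanking both
  ends; the longest such repeat is reported. A single-base TSD pattern that
  merely extends a mononucleotide run on either side is rejected
  (poly-A/poly-T tracts otherwise generate degenerate TSD calls).

Detection is seed-and-extend: exact `w`-mers (default `w = 8`) are indexed;
for every inverted seed pair at an element-compatible spacing the inverted
repeat is extended outward, and every terminal trim of the extension is
validated against the definition above. Overlapping candidates sharing more
than half of the shorter span are resolved by a deterministic total order:
longer TIR, then longer TSD, then leftmost start. The scan runs on the
forward strand only — an inverted-repeat element presents the same
structure on either strand.

**Completeness.** An exact seed of length `w` is guaranteed inside an
admissible TIR only when `w ≤ ceil((L − m)/(m + 1))` for `L ≥ tir_min`
mismatches `m`. The default `w = 8` is complete for exact TIRs (and for
any TIR whose mismatches leave an 8-bp exact run); `w = 5` is complete for
every TIR admissible under the 10% mismatch allowance, at roughly 5–10×
the index cost. The brute-force equivalence tests therefore run the
scanner at `w = 5`; genome-scale runs use the default.

## Family definition and filtering

Candidates are clustered by single linkage on the graph with an edge
wherever global identity exceeds 0.8 (Needleman–Wunsch, match +1, mismatch
−1, gap −2; identity = matches / alignment columns). Components with fewer
than three members are discarded; the representative is the member whose
length is closest to the component median (ties: lowest coordinate).

Pseudo-element flags are member-level: presence of N; tandem simple-repeat
cover ≥ 0.8 of the sequence (exact self-overlap runs of period ≤ 6
spanning ≥ 2 units and ≥ 8 bp — the 8 bp floor keeps incidental 2–3 bp
coincidences in random sequence from counting, so random 300-bp sequence
scores well below the 0.8 threshold while genuine microsatellite decoys
score near 1); and nested-in-repeat, operationalised as both 50-bp flanks
recurring more than 20 times genome-wide at ≥ 90% identity. A family is
rejected when more than half its members carry any flag — the filter
operates per family, and the >50% member threshold keeps a single
sequencing artifact inside a genuine family from condemning it.

## Copy census and the intact call

A family representative is searched against both strands by seed-anchored
local alignment (12-mer seeds, anchors clustered at a 60 bp gap so adjacent
copies are not merged into one window). Hits must exceed 0.90 identity and
0.80 representative coverage, with a 50 bp minimum alignment length
standing in for an E-value cutoff. Same-strand hits overlapping more than
half of the shorter hit are deduplicated by score, then leftmost start.

A copy is **intact** when the alignment fully covers both TIR spans of the
representative and each TIR aligns at ≥ 90% identity; otherwise
**fragmentary**. Because local alignment clips terminal mismatches,
intactness is slightly underestimated for highly diverged copies; the
truncation-recovery checks therefore plant undiverged copies, as the
definition's own examples do.

## Substitution model and dating

The generator mutates each copy site-wise with probability `k`; a
substituted site becomes a transition with probability `κ/(κ+2)` (default
`κ = 2`, giving equal expected transition and transversion proportions
`P = Q = k/2`). This yields a known expected K2P distance for recovery
tests: at `k = 0.0312` the multiple-hit correction inflates K2P by
~7 × 10⁻⁴, well inside 3 standard errors at the test sizes.

Members are dated from their K2P distance to the family consensus,
`T = k/(2r)` with `r = 1.56 × 10⁻⁸` substitutions·site⁻¹·year⁻¹ (the
fruit-fly neutral rate, conventional for silkworm; overridable). K2P
raises a saturation error when `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` rather
than returning a clipped value.

## Alignment, consensus, diversity

Families are aligned center-star around the representative: every member
is globally aligned to the center and columns are merged on center
coordinates with per-slot maximal insertion widths. Census membership
guarantees members are near-identical to the representative, the regime
where center-star is within known bounds of the optimal multiple
alignment; this replaces an external aligner dependency.

Consensus is per-column majority over {A,C,G,T}; columns with a strict gap
majority are omitted; base ties break alphabetically (the upstream tools'
tie rules are unpublished, so a deterministic convention is chosen).

Nucleotide diversity π is computed in non-overlapping 20-bp windows
indexed on consensus coordinates (trailing partial window dropped). Per
window, π is the mean over unordered sequence pairs of differences per
compared site, with gap-containing site-pairs excluded pairwise
(pairwise deletion); a window with no comparable pair is flagged undefined
and classed intermediate. Windows are *variable* when π ≥ mean + 2 SD and
*conserved* when π ≤ max(mean − 2 SD, 0); when SD = 0 all windows are
intermediate. Note that the unordered-pair mean is not invariant under
duplicating the row set (the frequency-weighted population estimator
would be); the per-window examples fix the unordered-pair definition.

## Median-joining networks

Identical sequences condense into haplotypes with multiplicities; gaps act
as a fifth character state. The network is built as a minimum spanning
network (all minimum-spanning ties retained) over Hamming distances, with
median (Steiner) vectors added greedily whenever the median of a triple
centred on a network node strictly lowers the spanning cost, then pruned
when removable without raising it (ε = 0 only; ties resolved by
lexicographic haplotype order, so the result is input-order independent).
On tree-like data the network equals the minimum spanning tree, which the
tests verify against an exhaustive Steiner-improvability oracle on small
sets. The **star statistic** — the fraction of nodes adjacent to the
modal haplotype — summarises topology: near 1 for a recent single-source
burst, low for old structured expansions.

## Genomic context

Each copy is classified by its midpoint, so every copy gets exactly one
category: exon if the midpoint overlaps an exon; intron if it overlaps a
gene but no exon; otherwise 5′-/3′-flank if the nearest gene lies within
the 5 kb flank limit (side strand-aware; the nearer gene wins, an exact
tie goes to 5′-flank); else intergenic. Flank distances bin half-open:
≤ 500, (500, 3000], (3000, 5000].

The null simulation samples `n` fragment starts uniformly over the genome,
truncates fragments of up to 10 kb at sequence ends, and classifies each
fragment midpoint with the identical rule, so observed-vs-null comparisons
share one convention. The χ² chromosome-distribution test uses
length-proportional expected counts with `df = #chromosomes − 1`;
gene-density correlation is Pearson on per-Mb densities with `df = n − 2`;
2×2 enrichment χ² is computed without continuity correction by default.
The germline-silencing probability is `(1 − expressed/total)^n_genes`.

## Synthetic genomes: what they emulate, and what they do not

Backgrounds are i.i.d. nucleotides at a configurable AT content (default
0.62); genes are placed non-overlapping with 2–5 exons and 0.3–1.5 kb
introns; copies are planted as `TSD + element + TSD` blocks, with
coordinates of downstream annotations shifted exactly. Truncated copies
lose one terminal TIR plus 10–20 bp (capped at 18% of the element so
fragments remain census-detectable, matching the coverage threshold).
Truth categories are assigned *after* assembly with the same classifier
the analysis uses.

Insertion sites are rejection-sampled so that an exact intact copy is
structurally unambiguous: no outward boundary shift yields a TIR+TSD call
that outranks the planted one under the scanner's tie-break, and for
degenerate TSD motifs the instance is re-drawn per attempt. This is a
deliberate property of the generator, not of real genomes — for
palindromic-ended TSDs (TA/AT and relatives) the element boundary is
genuinely ambiguous by structure alone, which is why exact-coordinate
recovery is provable on synthetic data but only approximate on real data.

Decoys are planted on a dedicated scaffold appended to the bundle so
existing coordinates stay valid: tandem-repeat elements, N-run elements,
and nested mimics whose 50-bp flanks are scattered 21 times genome-wide.

The backgrounds carry no real repeat landscape, no indel divergence within
families (truncation substitutes for coverage loss), no nested real
elements and no GC isochores. Passing tests therefore demonstrate
correctness of the implemented rules and statistical calibration under the
stated model — not end-to-end accuracy on a real genome assembly, where
raw structural candidates are dominated by chance inverted repeats and the
family-size and pseudo-element filters carry the load.

## Problem sizes and defaults

Test and acceptance runs use 80–500 kb genomes, families of 5–200 copies,
10-seed replications for recall/precision and decoy-rejection properties,
and `n = 50,000` draws for null-convergence checks (against an exact
enumeration of the fragment-midpoint measure). Default generator
conditions follow the packaged per-family table (TIR strings, TSD motifs,
element sizes, AT contents); the within-family divergence distribution is
not published, so the generator exposes mean and dispersion
(`divergence_mean`, `divergence_sd`, default dispersion 0) as free
parameters.
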