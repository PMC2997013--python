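"""Reject pseudo-element families, then census genome-wide copy numbers.

Adds the three decoy classes (tandem simple repeats, N-runs, elements nested
in high-copy repeats) to a genome with one real family, shows the family
filter rejecting exactly the decoys, and runs the homology census with the
intact/fragmentary call (>90% identity, >80% coverage, both TIRs present).
"""

from mitekit import census_family, filter_families
from mitekit.miner import CandidateFamily, MiteCandidate
from mitekit.simulate import FamilySpec, make_decoys, make_genome

spec = FamilySpec("BmMITE-2", "TGAGTCGACTATTATCAAAG", "TA/AT", 238,
                  n_copies=25, divergence_mean=0.02, truncation_fraction=0.3)
bundle = make_decoys(
    make_genome([spec], gene_density=0, genome_length=120_000, seed=7),
    n_simple=4, n_nrun=4, n_nested=4, seed=8)

# group truth records into candidate families (as the miner+clusterer would)
groups = {}
for t in bundle.truth:
    seq = bundle.element_seq(t)
    groups.setdefault(t.family_id, []).append(
        MiteCandidate(t.chrom, t.start, t.end, seq[:10], seq[-10:], t.tsd, seq, 0))
families = [CandidateFamily(fid, m) for fid, m in sorted(groups.items())]

report = filter_families(families, bundle.sequences)
print("kept families:    ", [f.family_id for f in report.kept])
print("rejected families:", [f.family_id for f in report.rejected],
      " (the three pseudo-element classes)")

census, copies = census_family(bundle.sequences, bundle.masters["BmMITE-2"],
                               tir_len=20, family_id="BmMITE-2", tsd_motif="TA")
print(f"census: {census.n_total} copies, {census.n_intact} intact "
      f"({census.full_length_pct}%), {census.n_fragmentary} fragmentary; "
      f"AT content {census.at_content_pct}%; superfamily {census.superfamily}")
print("(a TA target-site duplication diagnoses the Stowaway-like superfamily)")
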