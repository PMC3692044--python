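"""Scan a 3'-UTR for seed matches of a miRNA and classify the sites.

A target site is a UTR window reverse-complementary to the miRNA seed
(positions 2-7 or 2-8 from the 5' end), in one of the canonical classes
6mer < 7mer-A1 / 7mer-m8 < 8mer. Coordinates are 0-based half-open.
"""

from mirtarget import MiRNA, NucSequence, find_sites, seed_match

mirna = MiRNA(name="mir-x", residues="UGGAAUGUAAAGAAGUAUGUAU")
print(f"miRNA {mirna.name}: {mirna.residues}")
print(f"6-nt seed match (positions 2-7):  {seed_match(mirna, (2, 7))}")
print(f"7-nt seed match (positions 2-8):  {seed_match(mirna, (2, 8))}")

# a UTR carrying one 8mer site and one bare 6mer site
utr = NucSequence(
    "demo-utr",
    "GCGCGCGCGC" + "ACAUUCCA" + "GCGCGCGCGCGCGCGC" + "CAUUCC" + "GGCGCGCGCG",
)
for site in find_sites(utr, mirna):
    print(
        f"site [{site.start:>3},{site.end:>3})  class {site.site_type}"
        f"  sequence {utr.residues[site.start:site.end]}"
    )
# Each line is one seed match: its half-open UTR coordinates, its class
# (the maximal one for that window) and the matched UTR subsequence.
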