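"""Evolutionary features: branch length score and phyloP-style test.

The site is evolved on a 7-species tree with rate scale 0.1 (strong
negative selection) while the rest of the UTR evolves neutrally. BLS
sums the branch lengths of the subtree connecting species that retain
the seed match; the phyloP-style LRT estimates the site-specific rate
scale lambda and tests lambda = 1.
"""

from mirtarget import MiRNA, read_newick
from mirtarget.conservation import conservation_features
from mirtarget.site_scanner import SiteType, find_sites, seed_match
from mirtarget.synthetic_fixtures import gen_alignment, gen_utr, plant_sites

tree = read_newick(
    "(((((human:0.08,chimp:0.09):0.12,mouse:0.35):0.1,"
    "(cow:0.25,dog:0.22):0.08):0.15,opossum:0.55):0.2,chicken:0.9);"
)
mirna = MiRNA(name="mir-x", residues="UGGAAUGUAAAGAAGUAUGUAU")
root, (site,) = plant_sites(
    gen_utr(120, seed=5, utr_id="root"), mirna, [50], [SiteType.SEVEN_MER_M8], seed=2
)
aln = gen_alignment(
    tree, root, window_scales={(site.start, site.end): 0.1}, seed=3,
    ref_species="human",
)

# rescan the evolved human row: the conserved site is still there
human_sites = [
    s for s in find_sites(
        type(root)("human", aln.ref_ungapped()), mirna
    )
    if s.start == site.start
]
res = conservation_features(
    tree, aln, human_sites[0], seed_match(mirna, (2, 7))
)
print(f"total tree length          : {tree.total_length():.2f} subs/site")
print(f"BLS of the site            : {res.bls:.2f} subs/site")
print(f"fitted rate scale lambda   : {res.lam:.3f}  (< 1 = conserved)")
print(f"phyloP p-value             : {res.phylop_p:.3e}")
print(f"phyloP score (-log10 p)    : {res.phylop_score:.2f}  (> 0 = conserved)")
# A large BLS and a positive phyloP score together say the site has
# persisted and evolved slower than the neutral expectation.
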