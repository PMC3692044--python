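"""Free-energy features of one target site.

dg_duplex / dg_binding score the miRNA-target hybrid (minimum free
energy and ensemble), dg_seed_* the seed region alone, dg_open the cost
of unfolding the UTR around the site, dg_total = dg_duplex + dg_open.
All values in kcal/mol at 37 C; more negative = more stable binding,
larger dg_open = less accessible site.
"""

from mirtarget import MiRNA, NucSequence, find_sites, reverse_complement
from mirtarget.thermodynamics import site_energies

mirna = MiRNA(name="mir-x", residues="UGGAAUGUAAAGAAGUAUGUAU")
site_seq = "ACAUUCCA"  # 8mer match of mir-x

# embed the site in a UTR whose upstream flank folds back onto the site,
# so opening it costs energy
utr = NucSequence(
    "structured-utr",
    "AAAA" + reverse_complement(site_seq) + "AAAAA" + site_seq + "AAAAAAAAAA",
)
(site,) = find_sites(utr, mirna)
e = site_energies(utr, mirna, site)
print(f"site [{site.start},{site.end}) class {site.site_type}")
print(f"dg_duplex       = {e.dg_duplex:7.2f} kcal/mol")
print(f"dg_binding      = {e.dg_binding:7.2f} kcal/mol  (<= dg_duplex always)")
print(f"dg_seed_duplex  = {e.dg_seed_duplex:7.2f} kcal/mol")
print(f"dg_seed_binding = {e.dg_seed_binding:7.2f} kcal/mol")
print(f"dg_open         = {e.dg_open:7.2f} kcal/mol  (>= 0: cost of opening)")
print(f"dg_total        = {e.dg_total:7.2f} kcal/mol  (duplex + open)")
# A strongly negative dg_total means the duplex gain outweighs the cost
# of making the site accessible.
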