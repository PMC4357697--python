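"""Scan a duplex for predicted sites and predict its gel banding.

The ACC^U motif is matched on both strands (a bottom-strand hit is
canonicalized to a top-strand bond via the overhang geometry); an in-silico
complete digest then yields product sizes in gel order.
"""

from minicleave import DsSegment, IupacMotif, banding_table, insilico_digest, scan_duplex

# a 234-bp substrate with one consensus site: bond between residues 89|90
backbone = ("AGU" * 83)[:234]
seq = backbone[:82] + "AAAGACCUCGAAAA" + backbone[96:]
substrate = DsSegment(id="pKS-like", top_sequence=seq)

motif = IupacMotif.from_string("ACC^U")
hits = scan_duplex(substrate, motif)
for h in hits:
    print(f"site: bond {h.site.i_top}|{h.site.i_top + 1} "
          f"(motif on the {h.strand} strand, match start {h.start})")

products = insilico_digest(substrate, [h.site for h in hits])
for p in products:
    print(f"product {p.index}: top {p.top_length} nt, bottom {p.bottom_length} nt, "
          f"apparent {p.apparent_size} nt")
print(f"predicted bands (gel order): {banding_table(products)}")
print("(one site in a 234-bp duplex gives two bands, ~147 and ~89 nt —")
print(" the staggered ends make the two strands of each product differ by 2 nt)")
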