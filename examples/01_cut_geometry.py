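"""Staggered-cut coordinate algebra on the 30-bp oligonucleotide substrate.

A Mini-III RNase cuts a perfect duplex with a 2-nt stagger, leaving 3'
overhangs.  Given the top-strand cut position, the geometry fixes the
bottom-strand cut; given both, the overhang is recoverable.
"""

from minicleave import bottom_bond_from_top, infer_overhang, termination_to_bond

i_top, length = 14, 30
b_bottom = bottom_bond_from_top(i_top, length, overhang=2)
print(f"top strand cut between residues {i_top}|{i_top + 1}")
print(f"bottom strand cut between bottom residues {b_bottom}|{b_bottom + 1}")
print(f"inferred overhang: {infer_overhang(i_top, b_bottom, length)} nt (3')")

# a primer-extension assay reads the cut indirectly: the strong reverse-
# transcription stop marks the residue just 3' of the scissile bond
stop = termination_to_bond("top", strong_termination_pos=90)
print(f"strong RT stop at residue 90 -> scissile bond {stop.index}|{stop.index + 1}")
print("(the weaker +1 band is non-templated addition and is ignored)")
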