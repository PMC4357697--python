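"""Saturation mutagenesis of a cleavage-site window and consensus derivation.

Every position of the 14-nt window around the scissile bond is substituted
to every other base (42 variants); relative cleavage rates define which
bases are tolerated and which are preferred, rendered as a consensus with
^ at the bond.
"""

from minicleave import ConsensusSpec, derive_consensus, design_saturation
from minicleave.simulate import simulate_satmut_rates

wild_type = "AAAGACCUCGAAAA"  # the preferred window; bond between positions 7|8
variants = design_saturation(wild_type)
print(f"wild-type window: {wild_type[:7]}^{wild_type[7:]}")
print(f"single-substitution variants designed: {len(variants)}")

# a planted "truth" with an obligate CC core and graded flanks
truth = ConsensusSpec(
    tolerated=[frozenset("ACGU")] * 3
    + [frozenset("GAU"), frozenset("AU"), frozenset("C"), frozenset("C"),
       frozenset("UA"), frozenset("CAU"), frozenset("GAU")]
    + [frozenset("ACGU")] * 4,
    preferred=wild_type,
    bond_offset=7,
)
records = simulate_satmut_rates(truth, noise_sd=0.0, rng=0)
derived = derive_consensus(records, wild_type, tolerance=0.5)
print(f"derived consensus: {derived.render()}")
print("(positions tolerating all four bases are trimmed; the CC core admits")
print(" no substitution, so it prints as literal CC around the ^ bond)")
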