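"""Encode residue blocks into the eight-group chemical alphabet.

Two blocks with zero residue identity can carry the same chemical signature:
every position holds a residue from the same side-chain class.
"""

from chemseq import encode_sequence, group_members

for block in ["DRSMYI", "EKTCWV", "FPKATD", "QLRCNGVL"]:
    enc = encode_sequence(block, block)
    print(f"{block:>10} -> {enc.digits}")

print()
print("Group 7 (hydroxyl-containing):", sorted(group_members(7)))
print("DRSMYI and EKTCWV share the digit string 127634: each column pairs")
print("two residues of one chemical group (D/E acidic, R/K basic, ...).")
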