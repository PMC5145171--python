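"""Sliding-window chemical similarity of a conserved block.

The 20-residue block conserved across conventional myosin II is scanned
against myosin I motor-domain blocks: the score counts positions whose
residues share a chemical group, (m/L) x 100.
"""

from chemseq import aligned_percent, batch_report, encode_sequence

MYH14 = "FGNAKTVKNDNSSRFGKFIR"  # reference block, digit string 34842742818772342342
myoI = {
    "MYO1A": "FGNAKTIRNNNSSRFGKYMD",
    "MYO1B": "FGNAKTVRNDNSSRFGKYMD",
    "MYO1G": "FGNARTNRNHNSSRFGKYMD",
}

print("Illustration: DRSMYI vs EKTCWV ->",
      aligned_percent("DRSMYI", "EKTCWV"), "% (zero residue identity)")
print("One substitution (QRSMYI vs DRSMYI) ->",
      round(aligned_percent("QRSMYI", "DRSMYI"), 2), "% (5 of 6 positions)\n")

encs = [encode_sequence(name, block) for name, block in myoI.items()]
frame = batch_report({"MYH14": MYH14}, encs)
print(frame[["target_id", "best_percent", "rendered"]].to_string(index=False))
print("\nbest_percent is the best window score; 'rendered' shows the 1-based")
print("position and residues of the best-matching window (position-residues).")
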