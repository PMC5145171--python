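"""Ordered-pair (transition) analysis and the '#G-#X' summary table.

For each chemical group i, #Gi counts its residues and #Xi the adjacent
pairs that start in group i and leave it.  Groups whose (#G, #X) ranges are
disjoint between two halves of a sequence set discriminate the split.
"""

from chemseq import (build_summary_table, build_transition_matrix,
                     encode_sequence, find_discriminating_groups,
                     render_summary_table)

encs = [
    encode_sequence("left1", "DKDKDKSSTMY"),
    encode_sequence("left2", "DKDKDKTTSMW"),
    encode_sequence("right1", "DKDKDKDKDKSY"),
    encode_sequence("right2", "DKDKDKDKDKTW"),
]

m = build_transition_matrix(encs[0])
print(f"{encs[0].seq_id}: {m.total} ordered pairs "
      f"(= length {len(encs[0])} - 1); G1->G2 count = {m.count(1, 2)}")

table = build_summary_table(encs)
print("\nF table ('#G-#X' per group, one column per sequence):")
print(render_summary_table(table).to_string())

hits = find_discriminating_groups(table, ["left1", "left2"],
                                  ["right1", "right2"])
print("\nDiscriminating groups (both #G and #X ranges disjoint):")
for h in hits:
    print(f"  G{h.group_id}: left a){h.a_left} b){h.b_left}  "
          f"right a){h.a_right} b){h.b_right}  gap={h.gap:.2f}")
print("Sulfur content (G6, present left / absent right) separates most")
print("sharply; acidic (G1) and basic (G2) totals also split the halves.")
print("The normalized gap ranks which group explains the split best.")
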