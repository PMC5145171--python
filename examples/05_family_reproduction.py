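"""Full family analysis on a user-supplied FASTA of motor-domain sequences.

Usage:  python 05_family_reproduction.py FAMILY.fa [NONMUSCLE_IDS]

Runs the complete pipeline on any sequence set — e.g. the 14 human myosin II
head domains (UniProt accessions, N-terminal prefixes of the stated head
lengths): the '#G-#X' transition summary, maximal common chemical patterns
with and without group repetition, and, when a comma-separated id list for
one subgroup is given, discriminating groups and subgroup-specific patterns.
No sequences ship with the package; supply your own FASTA.
"""

import sys

from chemseq import (build_summary_table, classify_patterns, encode_records,
                     find_discriminating_groups, locate_pattern,
                     maximal_common_pattern, read_fasta,
                     render_summary_table)

if len(sys.argv) < 2:
    sys.exit(__doc__)

records = read_fasta(sys.argv[1])
encs = encode_records(records)
ids = [e.seq_id for e in encs]
print(f"{len(encs)} sequences, lengths {min(map(len, encs))}-"
      f"{max(map(len, encs))}\n")

table = build_summary_table(encs)
print("F table (#G-#X per chemical group):")
print(render_summary_table(table).to_string(), "\n")

for mode in ("norepeat", "repeat"):
    L, cps = maximal_common_pattern(encs, mode)
    print(f"Maximal common length ({mode}): {L}; patterns: {cps.patterns}")
    for pat in cps.patterns[:3]:
        hits = locate_pattern(pat, encs[0])
        print(f"  {pat} in {encs[0].seq_id}: "
              f"{[(h.position, h.residue_block) for h in hits]}")
print()

if len(sys.argv) > 2:
    side_a = sys.argv[2].split(",")
    side_b = [i for i in ids if i not in side_a]
    print(f"Bipartition {side_a} vs {side_b}")
    for h in find_discriminating_groups(table, side_a, side_b):
        print(f"  G{h.group_id}: a){h.a_left}/{h.a_right} "
              f"b){h.b_left}/{h.b_right} gap={h.gap:.3f}")
    res = classify_patterns(encs, side_a, side_b, 6, "norepeat")
    print(f"Length-6 norepeat patterns: {len(res.common_all)} common, "
          f"{len(res.a_only)} A-only, {len(res.b_only)} B-only")
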