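# Methods

## Model

A protein sequence is reduced to a digit string by the map

| group | 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 |
|---|---|---|---|---|---|---|---|---|
| chemistry | acidic | basic | aromatic | aliphatic | cyclic | sulfur | hydroxyl | acidic amide |
| residues | D,E | R,H,K | Y,F,W | I,L,V,A,G | P | M,C | S,T | Q,N |

The partition is frozen as the default (`EIGHT_GROUPS`), but every operation
accepts an alternative `ChemicalAlphabet`; the type validates that any
grouping is a true partition of the 20 standard residues, so coarser or
finer reductions (down to the 20-group identity) plug in unchanged.

All analyses are functions of the digit string only. This is the model's
central assumption: positionwise side-chain chemistry is the conserved
signal, and within-group residue identity is noise. Consequences the suite
tests as invariants: encoding is positionally local (encoding a
concatenation is the concatenation of encodings); replacing any residue by
another member of its group changes no similarity score, no pattern hit, no
transition count.

### Transition analysis

For an encoded sequence of length n, the transition matrix counts the n−1
adjacent ordered digit pairs; cell (i, j) is the number of group-i → group-j
steps. Per group i the summary pair is (#Gi, #Xi): #Gi is the **total**
residue count of group i — including a final residue, which starts no pair,
so #Gi can exceed the matrix row sum by one — and #Xi is the row sum minus
the diagonal (pairs that leave the group). A *discriminating* ("hitting")
group for a bipartition of a sequence set is one whose #G interval **and**
#X interval (closed, min–max across each side) are both disjoint between the
sides. Touching endpoints count as overlap (conservative). Hits are ranked
by a normalized gap — the distance between the two intervals divided by the
midpoint of their union span, taking the larger of the #G and #X gaps — with
ties broken by group id. The ranking comparator is one isolated function;
the disjointness criterion, not the ranking, carries the scientific content.

### Common patterns

A length-L digit pattern is *common* to a set when it occurs as a contiguous
substring of every sequence's digit string. The defined result of a search
is exactly the intersection of the per-sequence L-mer sets, filtered by the
mode constraint (`norepeat`: pairwise-distinct digits, so L ≤ 8 by
pigeonhole; `repeat`: unconstrained). Three strategies compute it and are
cross-checked against an independent brute-force oracle in the tests:

- `intersect` (default): per-sequence k-mer hash sets intersected — O(total
  length) per L.
- `enumerate` (norepeat): test all 8!/(8−L)! distinct-digit permutations.
- `grow` (repeat, L ≥ 4): seeded tetramer growth — common 4-mers are found
  first, then extended a tetramer at a time, pruning extensions absent from
  any sequence; a final round appends common r-mers for the remainder
  r = L mod 4. Because every substring of a common pattern is itself common,
  concatenating common chunks generates all candidates, so growth is an
  optimization, not a different semantics. Appending common r-mers rather
  than all 8^r suffixes is a pruning with an identical post-filter result.

Maximal-length search walks L upward until the common set empties, which is
sound because common sets are antitone in L (apriori property, also tested).
Subgroup classification calls a pattern A-only when it is common to every
member of subset A but not common to every member of subset B (and
symmetrically); "not common to B" does **not** mean absent from every B
member. Positions are 1-based throughout and overlapping occurrences are all
reported.

### Block similarity

Two equal-length blocks score (m/L)×100 where m counts positions whose
residues share a group — symmetric, 100 exactly when the digit strings are
equal. The sliding-window scan is strictly ungapped: every length-L window
of the target is scored left to right and the report keeps **all** argmax
positions, not just the first. Percentages are exact rationals rendered to
two decimals; nothing is rounded internally (the 5/6 case is 83.33, not 84).

## Handling of non-standard residues

Default policy is strict: any character outside the 20 standard codes
(ambiguity codes B/J/O/U/X/Z, gaps, stops) raises an error naming the
character, record, and 1-based offset. The alternative `mask` policy encodes
such characters as the break digit `'0'`, which never matches anything
(including itself) and severs adjacency: no transition pair, pattern
occurrence, or similarity match crosses it. Silently deleting invalid
characters would fabricate adjacencies and shift every downstream position,
which is why it is not offered. Case is folded to upper before lookup;
lowercase soft-masking has no semantics here.

## Synthetic data

`generate_fixtures` emulates the study design the method was built for: a
family of sequences sharing chemically conserved blocks while the literal
residues drift. Each planted digit is realized by a uniform draw from its
group's members, independently per occurrence and sequence, so the chemical
pattern is exactly invariant and the residue realizations vary — the
S↔T / Y↔F style of conservation. Background positions default to a uniform
draw over the 20 residues; per-residue weights are accepted for skewed
compositions. Defaults (5 sequences of 120–200 residues) are sized like
small protein-family analyses at sub-domain scale. Planted occurrences are
placed by joint rejection sampling to be non-overlapping; a spec whose
patterns cannot fit raises rather than silently truncating. The generator is
fully determined by its seed.

What the fixtures do not emulate: real phylogenetic correlation structure
(positions are i.i.d. apart from the planted blocks), insertions/deletions,
compositional drift along a sequence, and near-miss motifs (one group off).
Passing planted-motif recovery therefore shows the scanners are correct and
sensitive to exact chemical conservation, not that real families will carry
motifs of any particular length; on real data the maximal common length is
an empirical output.

## Numerical and degenerate-input choices

- Empty and length-1 sequences are legal for encoding and transition
  counting (zero pairs); an empty *set* of sequences is an error.
- A pattern length exceeding the shortest sequence yields an empty result,
  not an error; a norepeat length over 8 is an error (pigeonhole).
- Output ordering is deterministic everywhere: patterns lexicographic, hits
  by (sequence order, position), discriminating groups by (−gap, group id).
- Similarity with equal-length query and target degenerates to the aligned
  score at position 1 (tested).

## Limitations

- The similarity scan is ungapped by design; it cannot absorb indels between
  query and target, and no substitution-matrix weighting of partial chemical
  affinity is attempted (a within-group match counts 1, anything else 0).
- No statistical significance is attached to discovered patterns; at small L
  over an 8-letter alphabet, common patterns arise easily by chance, and the
  user must judge lengths against the sequence lengths and set size.
- The discriminating-group ranking is a documented heuristic; different gap
  normalizations reorder hits but never change the hit set.
- Group weighting and alternative group counts are supported structurally
  (any partition alphabet) but no guidance is offered on choosing one.
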