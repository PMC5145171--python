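"""Common chemical-pattern discovery across sequence sets.

A *pattern* is a digit string over '1'-'8'; it is *common* to a set of
encoded sequences when it occurs as a contiguous substring of every
sequence's digit string.  Because residues of the same chemical group share a
digit, a common pattern captures conservation that survives within-group
substitutions (S↔T, Y↔F, D↔E ...), invisible to exact residue matching.

Two modes are searched:

``norepeat``
    Patterns whose digits are pairwise distinct (length ≤ 8 by pigeonhole);
    candidates are enumerable as permutations of the eight digits.

``repeat``
    Arbitrary digit strings.  For tractability at large L, candidates are
    grown in tetramer-sized chunks: the common 4-mers are found first, then
    extended four digits at a time, pruning extensions absent from any
    sequence, with a final shorter round for the remainder L mod 4.

Whatever the search strategy, the defined result is exactly the intersection
of the per-sequence L-mer sets, filtered by the mode's repetition constraint;
the growth strategy is an optimisation, not a different semantics.  All
positions are 1-based and overlapping occurrences are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

from .alphabet import BREAK_DIGIT, EncodedSequence

__all__ = [
    "PatternHit",
    "CommonPatternSet",
    "ClassifiedPatterns",
    "enumerate_norepeat_patterns",
    "find_common_patterns",
    "maximal_common_pattern",
    "locate_pattern",
    "classify_patterns",
]

_DIGITS = "12345678"


@dataclass(frozen=True)
class PatternHit:
    """One occurrence of a digit pattern in one sequence (1-based start)."""

    pattern: str
    seq_id: str
    position: int
    residue_block: str


@dataclass(frozen=True)
class CommonPatternSet:
    """Digit patterns of one length common to every sequence of a set.

    ``hits`` maps pattern -> {seq_id -> [1-based positions]}; every pattern
    has at least one position in every input sequence.
    """

    length: int
    mode: str
    hits: dict[str, dict[str, list[int]]]

    @property
    def patterns(self) -> list[str]:
        return sorted(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def __contains__(self, pattern: str) -> bool:
        return pattern in self.hits


@dataclass(frozen=True)
class ClassifiedPatterns:
    """Common patterns split by subgroup: all, A-only, B-only."""

    common_all: CommonPatternSet
    a_only: CommonPatternSet
    b_only: CommonPatternSet


def _check_mode(mode: str) -> None:
    if mode not in ("norepeat", "repeat"):
        raise ValueError(f"mode must be 'norepeat' or 'repeat', got {mode!r}")


def enumerate_norepeat_patterns(L: int) -> list[str]:
    """All length-L digit strings over 1-8 with pairwise-distinct digits.

    Exactly 8!/(8-L)! strings in lexicographic order.  L > 8 is impossible
    by pigeonhole and raises.
    """
    if not 1 <= L <= 8:
        raise ValueError(f"norepeat pattern length must be in 1..8, got {L}")
    return ["".join(p) for p in permutations(_DIGITS, L)]


def _kmers(digits: str, L: int) -> set[str]:
    """All length-L substrings made of valid digits (break runs excluded)."""
    out: set[str] = set()
    for run in digits.split(BREAK_DIGIT):
        for i in range(len(run) - L + 1):
            out.add(run[i:i + L])
    return out


def _common_kmers(encs: list[EncodedSequence], L: int) -> set[str]:
    """Intersection of the per-sequence L-mer sets (the canonical result)."""
    sets = (_kmers(e.digits, L) for e in encs)
    common = next(sets)
    for s in sets:
        common &= s
        if not common:
            break
    return common


def _grow_common_repeat(encs: list[EncodedSequence], L: int) -> set[str]:
    """Seeded tetramer growth for repeat-mode patterns of length L ≥ 4.

    Start from the common 4-mers; each round appends a common 4-mer and
    prunes candidates absent from any sequence (membership checked against
    per-sequence k-mer hash sets at the current length).  A final round
    appends common r-mers for the remainder r = L mod 4.  Any substring of a
    common pattern is itself common, so concatenating common chunks generates
    every candidate; the result equals the substring intersection.
    """
    if L < 4:
        raise ValueError("seeded growth requires L >= 4")
    q, r = divmod(L, 4)
    seed = sorted(_common_kmers(encs, 4))
    cands = list(seed)
    cur = 4
    for _ in range(q - 1):
        cur += 4
        ksets = [_kmers(e.digits, cur) for e in encs]
        cands = [a + b for a in cands for b in seed
                 if all(a + b in ks for ks in ksets)]
        if not cands:
            return set()
    if r:
        tail = sorted(_common_kmers(encs, r))
        cur += r
        ksets = [_kmers(e.digits, cur) for e in encs]
        cands = [a + b for a in cands for b in tail
                 if all(a + b in ks for ks in ksets)]
    return set(cands)


def _find_positions(pattern: str, digits: str) -> list[int]:
    """1-based start positions of overlapping occurrences of ``pattern``."""
    positions = []
    start = digits.find(pattern)
    while start != -1:
        positions.append(start + 1)
        start = digits.find(pattern, start + 1)
    return positions


def locate_pattern(pattern: str, enc: EncodedSequence) -> list[PatternHit]:
    """All occurrences of a digit pattern in one sequence.

    Overlapping occurrences are included; an absent pattern yields an empty
    list.  Each hit carries the matching amino-acid block.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    hits = []
    for pos in _find_positions(pattern, enc.digits):
        block = enc.residues[pos - 1: pos - 1 + len(pattern)]
        hits.append(PatternHit(pattern=pattern, seq_id=enc.seq_id,
                               position=pos, residue_block=block))
    return hits


def _build_set(encs: list[EncodedSequence], patterns: set[str], L: int,
               mode: str) -> CommonPatternSet:
    hits: dict[str, dict[str, list[int]]] = {}
    for pat in sorted(patterns):
        hits[pat] = {e.seq_id: _find_positions(pat, e.digits) for e in encs}
    return CommonPatternSet(length=L, mode=mode, hits=hits)


def find_common_patterns(encs: list[EncodedSequence], L: int, mode: str,
                         strategy: str = "auto") -> CommonPatternSet:
    """Length-L patterns common to every sequence, with all hit positions.

    Parameters
    ----------
    encs : list of EncodedSequence
        At least one sequence.
    L : int
        Pattern length, ≥ 1 (norepeat additionally ≤ 8).  L exceeding the
        shortest sequence yields an empty result, not an error.
    mode : {"norepeat", "repeat"}
        Whether pattern digits must be pairwise distinct.
    strategy : {"auto", "intersect", "enumerate", "grow"}
        How candidates are searched.  All strategies return the same set:
        ``intersect`` intersects per-sequence k-mer sets; ``enumerate``
        (norepeat only) tests every distinct-digit permutation; ``grow``
        (repeat, L ≥ 4 only) uses seeded tetramer growth.  ``auto`` picks
        ``intersect``.
    """
    _check_mode(mode)
    if not encs:
        raise ValueError("at least one sequence is required")
    if L < 1:
        raise ValueError(f"pattern length must be >= 1, got {L}")
    if mode == "norepeat" and L > 8:
        raise ValueError("norepeat patterns cannot exceed length 8 "
                         "(only 8 distinct digits exist)")

    if strategy == "auto":
        strategy = "intersect"
    if strategy == "intersect":
        patterns = _common_kmers(encs, L)
    elif strategy == "enumerate":
        if mode != "norepeat":
            raise ValueError("enumerate strategy applies to norepeat mode")
        kmer_sets = [_kmers(e.digits, L) for e in encs]
        patterns = {p for p in enumerate_norepeat_patterns(L)
                    if all(p in ks for ks in kmer_sets)}
    elif strategy == "grow":
        if mode != "repeat" or L < 4:
            raise ValueError("grow strategy applies to repeat mode, L >= 4")
        patterns = _grow_common_repeat(encs, L)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if mode == "norepeat":
        patterns = {p for p in patterns if len(set(p)) == len(p)}
    return _build_set(encs, patterns, L, mode)


def maximal_common_pattern(encs: list[EncodedSequence],
                           mode: str) -> tuple[int, CommonPatternSet]:
    """Largest L with a nonempty common pattern set, and that set.

    Common sets are antitone in L (every sub-string of a common pattern is
    common), so the scan walks L upward until the set empties.  Returns
    ``(0, empty set)`` when even single digits are not shared.
    """
    _check_mode(mode)
    if not encs:
        raise ValueError("at least one sequence is required")
    cap = min(len(e) for e in encs)
    if mode == "norepeat":
        cap = min(cap, 8)
    best_L = 0
    best = CommonPatternSet(length=0, mode=mode, hits={})
    for L in range(1, cap + 1):
        common = _common_kmers(encs, L)
        if mode == "norepeat":
            common = {p for p in common if len(set(p)) == len(p)}
        if not common:
            break
        best_L, best = L, _build_set(encs, common, L, mode)
    return best_L, best


def classify_patterns(encs: list[EncodedSequence], subset_a: list[str],
                      subset_b: list[str], L: int,
                      mode: str) -> ClassifiedPatterns:
    """Split length-L patterns into common-to-all / A-only / B-only.

    ``subset_a`` and ``subset_b`` are disjoint sequence-id lists whose union
    covers all of ``encs``.  A pattern is *A-only* when it is common to every
    subset-A sequence but not to every subset-B sequence (and symmetrically);
    the three sets are pairwise disjoint by construction.
    """
    by_id = {e.seq_id: e for e in encs}
    a_set, b_set = set(subset_a), set(subset_b)
    if a_set & b_set:
        raise ValueError("subsets must be disjoint")
    if a_set | b_set != set(by_id) or not a_set or not b_set:
        raise ValueError("subsets must be nonempty and partition the "
                         "sequence ids")
    encs_a = [by_id[i] for i in subset_a]
    encs_b = [by_id[i] for i in subset_b]
    in_a = find_common_patterns(encs_a, L, mode).hits.keys()
    in_b = find_common_patterns(encs_b, L, mode).hits.keys()
    common = set(in_a) & set(in_b)
    return ClassifiedPatterns(
        common_all=_build_set(encs, common, L, mode),
        a_only=_build_set(encs_a, set(in_a) - common, L, mode),
        b_only=_build_set(encs_b, set(in_b) - common, L, mode),
    )
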