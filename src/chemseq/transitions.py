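"""Chemical-group transition (ordered-pair) analysis.

Reading an encoded sequence left to right, every adjacent digit pair (x, y)
is an ordered pair, or *transition*, from group x to group y.  The n×n count
matrix of these pairs summarises the local chemical texture of the sequence.
Per group i two scalars are reported: #Gi, the total number of group-i
residues in the sequence, and #Xi, the number of ordered pairs starting at
group i excluding the self pair (i, i).  A table of (#Gi, #Xi) over a set of
sequences is the *F table*; groups whose value ranges are disjoint between
two halves of a set ("hitting" or discriminating groups) explain bipartitions
such as phylogenetic branch points.

Pairs spanning the mask break digit '0' are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import BREAK_DIGIT, EncodedSequence

__all__ = [
    "TransitionMatrix",
    "GroupSummary",
    "RangeReport",
    "build_transition_matrix",
    "summarize_groups",
    "build_summary_table",
    "render_summary_table",
    "find_discriminating_groups",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """n×n ordered-pair counts; cell (i, j) counts adjacent pairs group i→j."""

    seq_id: str
    counts: np.ndarray  # shape (n, n), dtype int64

    def count(self, i: int, j: int) -> int:
        """Count of ordered pairs from group ``i`` to group ``j`` (1-based)."""
        return int(self.counts[i - 1, j - 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sum(self, i: int) -> int:
        return int(self.counts[i - 1].sum())


@dataclass(frozen=True)
class GroupSummary:
    """Per-group (#G, #X): residue totals and non-self pair counts."""

    seq_id: str
    total_count: np.ndarray    # #Gi, shape (n,)
    nonself_pairs: np.ndarray  # #Xi, shape (n,)

    def for_group(self, i: int) -> tuple[int, int]:
        """(#Gi, #Xi) for group ``i`` (1-based)."""
        return int(self.total_count[i - 1]), int(self.nonself_pairs[i - 1])


@dataclass(frozen=True)
class RangeReport:
    """Value ranges of one group's (#G, #X) across the two sides of a split.

    ``a_*`` intervals are over #G (residue totals, "with self-transition"),
    ``b_*`` over #X (non-self pairs).  Closed intervals; touching endpoints
    count as overlapping.  ``gap`` is the larger of the two normalized
    separations, (distance between intervals) / (midpoint of the union span).
    """

    group_id: int
    a_left: tuple[int, int]
    a_right: tuple[int, int]
    b_left: tuple[int, int]
    b_right: tuple[int, int]
    a_disjoint: bool
    b_disjoint: bool
    gap: float


def _digit_runs(digits: str):
    """Maximal runs of valid digits (no break symbol)."""
    for run in digits.split(BREAK_DIGIT):
        if run:
            yield run


def build_transition_matrix(enc: EncodedSequence,
                            n_groups: int = 8) -> TransitionMatrix:
    """Count adjacent ordered group pairs of an encoded sequence.

    The matrix total equals ``len(seq) - 1`` for sequences without mask
    breaks (zero for empty or single-residue input).
    """
    counts = np.zeros((n_groups, n_groups), dtype=np.int64)
    for run in _digit_runs(enc.digits):
        for x, y in zip(run, run[1:]):
            counts[int(x) - 1, int(y) - 1] += 1
    return TransitionMatrix(seq_id=enc.seq_id, counts=counts)


def summarize_groups(enc: EncodedSequence, n_groups: int = 8) -> GroupSummary:
    """Per-group residue totals #Gi and non-self pair counts #Xi.

    #Gi counts every group-i residue including the final one (which starts
    no pair), so #Gi can exceed the matrix row sum by one.
    """
    totals = np.zeros(n_groups, dtype=np.int64)
    for d in enc.digits:
        if d != BREAK_DIGIT:
            totals[int(d) - 1] += 1
    m = build_transition_matrix(enc, n_groups).counts
    nonself = m.sum(axis=1) - np.diag(m)
    return GroupSummary(seq_id=enc.seq_id, total_count=totals,
                        nonself_pairs=nonself)


def build_summary_table(encs: list[EncodedSequence],
                        n_groups: int = 8) -> pd.DataFrame:
    """F table: one column pair per sequence, one row per chemical group.

    Returns a DataFrame indexed by group id 1..n with MultiIndex columns
    ``(seq_id, 'total')`` (#G) and ``(seq_id, 'nonself')`` (#X).
    """
    if not encs:
        raise ValueError("at least one sequence is required")
    data: dict[tuple[str, str], np.ndarray] = {}
    for enc in encs:
        s = summarize_groups(enc, n_groups)
        data[(enc.seq_id, "total")] = s.total_count
        data[(enc.seq_id, "nonself")] = s.nonself_pairs
    frame = pd.DataFrame(data, index=pd.RangeIndex(1, n_groups + 1,
                                                   name="group"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["seq_id", "metric"])
    return frame


def render_summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render an F table with '#G-#X' hyphenated cells (one column per seq)."""
    seq_ids = table.columns.get_level_values("seq_id").unique()
    out = {}
    for sid in seq_ids:
        tot = table[(sid, "total")]
        non = table[(sid, "nonself")]
        out[sid] = [f"{t}-{x}" for t, x in zip(tot, non)]
    return pd.DataFrame(out, index=table.index)


def _interval(values) -> tuple[int, int]:
    return int(min(values)), int(max(values))


def _disjoint(a: tuple[int, int], b: tuple[int, int]) -> bool:
    # closed intervals: touching endpoints overlap
    return a[1] < b[0] or b[1] < a[0]


def _norm_gap(a: tuple[int, int], b: tuple[int, int]) -> float:
    if not _disjoint(a, b):
        return 0.0
    lo, hi = (a, b) if a[1] < b[0] else (b, a)
    dist = hi[0] - lo[1]
    span_mid = (min(a[0], b[0]) + max(a[1], b[1])) / 2.0
    if span_mid == 0:
        return float("inf")
    return dist / span_mid


def find_discriminating_groups(table: pd.DataFrame,
                               left_ids: list[str],
                               right_ids: list[str]) -> list[RangeReport]:
    """Groups whose #G and #X ranges are both disjoint between two sides.

    ``left_ids`` / ``right_ids`` name table columns (sequence ids) on either
    side of a bipartition.  A group is *hitting* only if both its #G ("a")
    and #X ("b") closed intervals are disjoint across the sides.  Hits are
    ranked by descending normalized gap (larger of the a/b gaps), ties broken
    by ascending group id; the result is symmetric under swapping sides.
    """
    left, right = list(left_ids), list(right_ids)
    if not left or not right:
        raise ValueError("both sides of the split must be nonempty")
    if set(left) & set(right):
        raise ValueError("left and right id sets must be disjoint")
    known = set(table.columns.get_level_values("seq_id"))
    unknown = (set(left) | set(right)) - known
    if unknown:
        raise ValueError(f"unknown sequence ids: {sorted(unknown)}")

    hits: list[RangeReport] = []
    for gid in table.index:
        a_l = _interval([table.loc[gid, (s, "total")] for s in left])
        a_r = _interval([table.loc[gid, (s, "total")] for s in right])
        b_l = _interval([table.loc[gid, (s, "nonself")] for s in left])
        b_r = _interval([table.loc[gid, (s, "nonself")] for s in right])
        a_dis = _disjoint(a_l, a_r)
        b_dis = _disjoint(b_l, b_r)
        if a_dis and b_dis:
            gap = max(_norm_gap(a_l, a_r), _norm_gap(b_l, b_r))
            hits.append(RangeReport(group_id=int(gid), a_left=a_l,
                                    a_right=a_r, b_left=b_l, b_right=b_r,
                                    a_disjoint=True, b_disjoint=True,
                                    gap=gap))
    hits.sort(key=lambda r: (-r.gap, r.group_id))
    return hits
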