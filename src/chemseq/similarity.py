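"""Chemical-group block similarity and sliding-window scanning.

Two equal-length residue blocks are compared position by position; a position
matches when both residues belong to the same chemical group.  The similarity
percentage is (m/L) × 100 for m matching positions out of L.  Under the
eight-group alphabet, blocks with zero residue identity can be 100% similar
(e.g. DRSMYI vs EKTCWV), which is the method's core claim: conservation of
chemistry, not of letters.

``scan_best`` slides a block over a full-length target one position at a
time (strictly ungapped) and reports the best percentage together with every
window position achieving it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import (BREAK_DIGIT, ChemicalAlphabet, EIGHT_GROUPS,
                       EncodedSequence, encode_sequence)

__all__ = ["SimilarityReport", "aligned_percent", "scan_best", "batch_report"]


@dataclass(frozen=True)
class SimilarityReport:
    """Best-match result of one query block against one target sequence.

    ``hits`` lists every 1-based window start achieving the maximal match
    count m, with the window's residues; ``best_percent`` = (m/L) × 100.
    """

    query_block: str
    target_id: str
    best_percent: float
    hits: list[tuple[int, str, int]]  # (position, residue_block, matches)


def _match_count(da: str, db: str) -> int:
    # break digits never match anything, including themselves
    return sum(1 for x, y in zip(da, db)
               if x == y and x != BREAK_DIGIT)


def aligned_percent(block_a: str, block_b: str,
                    alphabet: ChemicalAlphabet = EIGHT_GROUPS,
                    policy: str = "strict") -> float:
    """Positionwise chemical similarity of two equal-length blocks, 0-100.

    Symmetric; equals 100 exactly when the two blocks encode to the same
    digit string.  Unequal lengths raise ``ValueError``.

    >>> aligned_percent("DRSMYI", "EKTCWV")
    100.0
    >>> round(aligned_percent("QRSMYI", "DRSMYI"), 2)
    83.33
    """
    if not block_a or not block_b:
        raise ValueError("blocks must be nonempty")
    if len(block_a) != len(block_b):
        raise ValueError(f"blocks must have equal length "
                         f"({len(block_a)} vs {len(block_b)})")
    da = encode_sequence("a", block_a, alphabet, policy).digits
    db = encode_sequence("b", block_b, alphabet, policy).digits
    return 100.0 * _match_count(da, db) / len(block_a)


def scan_best(block: str, enc: EncodedSequence,
              alphabet: ChemicalAlphabet = EIGHT_GROUPS,
              policy: str = "strict") -> SimilarityReport:
    """Best chemical match of a block against all windows of a target.

    Every length-L window of the target is scored left to right; the report
    carries the maximal percentage and the complete list of argmax positions
    (1-based).  The block must not be longer than the target.
    """
    if not block:
        raise ValueError("block must be nonempty")
    L = len(block)
    if L > len(enc):
        raise ValueError(f"block length {L} exceeds target "
                         f"{enc.seq_id!r} length {len(enc)}")
    dq = encode_sequence("query", block, alphabet, policy).digits
    best_m = -1
    hits: list[tuple[int, str, int]] = []
    for start in range(len(enc) - L + 1):
        m = _match_count(dq, enc.digits[start:start + L])
        if m > best_m:
            best_m = m
            hits = [(start + 1, enc.residues[start:start + L], m)]
        elif m == best_m:
            hits.append((start + 1, enc.residues[start:start + L], m))
    return SimilarityReport(query_block=block, target_id=enc.seq_id,
                            best_percent=100.0 * best_m / L, hits=hits)


def batch_report(blocks: dict[str, str] | list[tuple[str, str]],
                 encs: list[EncodedSequence],
                 alphabet: ChemicalAlphabet = EIGHT_GROUPS,
                 policy: str = "strict") -> "pd.DataFrame":
    """Scan every named block against every target; one row per pair.

    Columns: block_id, target_id, best_percent, position (first argmax),
    residue_block, n_hits, and a 'position-residues' rendering.  A block
    longer than a target produces a row with an ``error`` note rather than
    aborting the batch.
    """
    import pandas as pd

    items = list(blocks.items()) if isinstance(blocks, dict) else list(blocks)
    rows = []
    for block_id, block in items:
        for enc in encs:
            row = {"block_id": block_id, "target_id": enc.seq_id,
                   "best_percent": None, "position": None,
                   "residue_block": None, "n_hits": 0,
                   "rendered": None, "error": None}
            try:
                rep = scan_best(block, enc, alphabet, policy)
            except ValueError as exc:
                row["error"] = str(exc)
            else:
                pos, res, _ = rep.hits[0]
                row.update(best_percent=round(rep.best_percent, 2),
                           position=pos, residue_block=res,
                           n_hits=len(rep.hits), rendered=f"{pos}-{res}")
            rows.append(row)
    return pd.DataFrame(rows)
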