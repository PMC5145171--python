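"""Synthetic protein-like sequences with planted chemical-group motifs.

The generator emulates the study design of the real analyses: a set of
homologous protein sequences that share chemically conserved blocks while
their literal residues drift within groups.  Each planted occurrence of a
digit pattern is realized by independently sampling a residue from the
pattern digit's group members, so the chemical pattern is invariant across
sequences but the amino acids vary (S↔T, Y↔F, D↔E ... conservation).
Background positions are drawn from a configurable residue composition
(uniform over the 20 standard residues by default).

Everything is reproducible from the seed; the returned manifest records every
planted position (1-based) for ground-truth checks of the pattern-discovery
and similarity scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ChemicalAlphabet, EIGHT_GROUPS
from .fastaio import SequenceRecord

__all__ = ["FixtureSpec", "PlantedHit", "generate_fixtures"]


@dataclass(frozen=True)
class PlantedHit:
    """Ground truth for one planted occurrence (1-based start)."""

    seq_id: str
    pattern: str
    position: int
    residue_block: str


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic sequence set with planted motifs.

    Parameters
    ----------
    n_sequences : int
        Number of sequences, ids ``seq1..seqN``.
    length_range : (int, int)
        Inclusive range of sequence lengths, sampled uniformly.
    planted : list of (pattern, count)
        Digit patterns over '1'-'8' planted ``count`` times per sequence at
        non-overlapping positions.
    background : dict or None
        Per-residue sampling weights for background positions; None means
        uniform over the 20 standard residues.
    seed : int
        Fully determines the output.
    """

    n_sequences: int = 5
    length_range: tuple[int, int] = (120, 200)
    planted: list = field(default_factory=list)
    background: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length range {self.length_range}")
        for pattern, count in self.planted:
            if count < 1:
                raise ValueError("planted counts must be >= 1")
            if not pattern or any(d not in "12345678" for d in pattern):
                raise ValueError(f"invalid digit pattern {pattern!r}")
            if len(pattern) > lo:
                raise ValueError(f"pattern {pattern!r} longer than the "
                                 f"minimum sequence length {lo}")


def _background_sampler(spec: FixtureSpec, rng: np.random.Generator):
    if spec.background is None:
        residues = sorted("ACDEFGHIKLMNPQRSTVWY")
        probs = np.full(len(residues), 1.0 / len(residues))
    else:
        residues = sorted(spec.background)
        w = np.array([spec.background[r] for r in residues], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("background weights must be non-negative and "
                             "sum to a positive value")
        probs = w / w.sum()

    def draw(n: int) -> list[str]:
        return list(rng.choice(residues, size=n, p=probs))

    return draw


def _place_slots(rng: np.random.Generator, length: int,
                 widths: list[int]) -> list[int]:
    """Non-overlapping 0-based starts for blocks of the given widths."""
    # rejection sampling: draw all starts jointly, retry on overlap
    for _ in range(1000):
        cand = [int(rng.integers(0, length - w + 1)) for w in widths]
        taken: list[tuple[int, int]] = []
        ok = True
        for s, w in zip(cand, widths):
            if any(s < e and t < s + w for t, e in taken):
                ok = False
                break
            taken.append((s, s + w))
        if ok:
            return cand
    raise ValueError("could not place planted patterns without overlap; "
                     "lengthen the sequences or plant fewer patterns")


def generate_fixtures(spec: FixtureSpec,
                      alphabet: ChemicalAlphabet = EIGHT_GROUPS
                      ) -> tuple[list[SequenceRecord], list[PlantedHit]]:
    """Generate synthetic records plus a manifest of planted positions.

    Each planted digit is realized by a uniform draw from its group's member
    residues, independently per occurrence and per sequence.  Identical spec
    and seed give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    draw_bg = _background_sampler(spec, rng)
    records: list[SequenceRecord] = []
    manifest: list[PlantedHit] = []

    occurrences: list[str] = []
    for pattern, count in spec.planted:
        occurrences.extend([pattern] * count)

    lo, hi = spec.length_range
    for k in range(spec.n_sequences):
        seq_id = f"seq{k + 1}"
        length = int(rng.integers(lo, hi + 1))
        chars = draw_bg(length)
        if occurrences:
            starts = _place_slots(rng, length, [len(p) for p in occurrences])
            for start, pattern in zip(starts, occurrences):
                block = "".join(
                    str(rng.choice(sorted(alphabet.members(int(d)))))
                    for d in pattern)
                chars[start:start + len(pattern)] = list(block)
                manifest.append(PlantedHit(seq_id=seq_id, pattern=pattern,
                                           position=start + 1,
                                           residue_block=block))
        records.append(SequenceRecord(seq_id=seq_id,
                                      description="synthetic",
                                      residues="".join(chars)))
    manifest.sort(key=lambda h: (h.seq_id, h.position))
    return records, manifest
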