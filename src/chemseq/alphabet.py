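"""Reduced chemical alphabet for protein sequences.

The 20 standard amino acids are partitioned into eight groups by side-chain
chemistry (acidic, basic, aromatic, aliphatic, cyclic, sulfur-containing,
hydroxyl-containing, acidic amide).  A protein sequence is encoded as a digit
string over '1'-'8', one digit per residue; residues in the same group encode
to the same digit, so e.g. ``DRSMYI`` and ``EKTCWV`` both encode to
``127634``.  All downstream analyses (transition counting, common-pattern
mining, block similarity) operate on these digit strings.

The eight-group partition is exposed as :data:`EIGHT_GROUPS`; every operation
takes an ``alphabet`` parameter so alternative groupings (down to the trivial
20-group identity) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "ChemicalGroup",
    "ChemicalAlphabet",
    "EncodedSequence",
    "InvalidResidueError",
    "EIGHT_GROUPS",
    "STANDARD_RESIDUES",
    "BREAK_DIGIT",
    "encode_residue",
    "encode_sequence",
    "group_members",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Break symbol emitted for invalid residues under ``policy="mask"``.  No
#: pattern, transition pair or similarity window may span it.
BREAK_DIGIT = "0"


class InvalidResidueError(ValueError):
    """A character outside the alphabet's residue set was encountered.

    Raised under the strict policy for ambiguity codes (B, J, O, U, X, Z),
    gaps ('-'), stops ('*') or any other non-standard character.
    """

    def __init__(self, residue: str, position: int | None = None,
                 seq_id: str | None = None):
        self.residue = residue
        self.position = position
        self.seq_id = seq_id
        ctx = ""
        if seq_id is not None:
            ctx += f" in sequence {seq_id!r}"
        if position is not None:
            ctx += f" at position {position}"  # 1-based
        super().__init__(f"invalid residue {residue!r}{ctx}: not one of the "
                         f"20 standard amino acids")


@dataclass(frozen=True)
class ChemicalGroup:
    """One side-chain class: an integer id, a name, and its member residues."""

    group_id: int
    name: str
    residues: frozenset[str]


@dataclass(frozen=True)
class ChemicalAlphabet:
    """A partition of the 20 standard residues into numbered chemical groups.

    Group ids must be 1..n consecutively; the residue sets must be pairwise
    disjoint and cover exactly the 20 standard amino acids.
    """

    groups: tuple[ChemicalGroup, ...]
    _lookup: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.groups]
        if ids != list(range(1, len(self.groups) + 1)):
            raise ValueError(f"group ids must be 1..{len(self.groups)} in "
                             f"order, got {ids}")
        lookup: dict[str, int] = {}
        for g in self.groups:
            for r in g.residues:
                if r in lookup:
                    raise ValueError(f"residue {r!r} assigned to two groups")
                lookup[r] = g.group_id
        if set(lookup) != STANDARD_RESIDUES:
            missing = STANDARD_RESIDUES - set(lookup)
            extra = set(lookup) - STANDARD_RESIDUES
            raise ValueError(f"groups must cover exactly the 20 standard "
                             f"residues (missing {sorted(missing)}, "
                             f"extra {sorted(extra)})")
        object.__setattr__(self, "_lookup", lookup)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def digits(self) -> str:
        """The digit characters this alphabet encodes to, in group order."""
        return "".join(str(g.group_id) for g in self.groups)

    def group_of(self, residue: str) -> int:
        """Group id owning ``residue`` (uppercase, strict)."""
        try:
            return self._lookup[residue]
        except KeyError:
            raise InvalidResidueError(residue) from None

    def members(self, group_id: int) -> frozenset[str]:
        if not 1 <= group_id <= len(self.groups):
            raise ValueError(f"group id {group_id} out of range "
                             f"1..{len(self.groups)}")
        return self.groups[group_id - 1].residues


def _grp(gid: int, name: str, residues: str) -> ChemicalGroup:
    return ChemicalGroup(gid, name, frozenset(residues))


#: The standard eight-group chemical partition.
EIGHT_GROUPS = ChemicalAlphabet((
    _grp(1, "acidic", "DE"),
    _grp(2, "basic", "RHK"),
    _grp(3, "aromatic", "YFW"),
    _grp(4, "aliphatic", "ILVAG"),
    _grp(5, "cyclic", "P"),
    _grp(6, "sulfur-containing", "MC"),
    _grp(7, "hydroxyl-containing", "ST"),
    _grp(8, "acidic amide", "QN"),
))


@dataclass(frozen=True)
class EncodedSequence:
    """A residue sequence paired with its digit-string encoding.

    ``digits[i]`` is the group id of ``residues[i]``; under the mask policy
    invalid residues appear uppercased in ``residues`` with ``'0'`` in
    ``digits``.
    """

    seq_id: str
    residues: str
    digits: str

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.digits):
            raise ValueError("residues and digits must have equal length")

    def __len__(self) -> int:
        return len(self.residues)


def encode_residue(residue: str, alphabet: ChemicalAlphabet = EIGHT_GROUPS) -> int:
    """Map a one-letter residue code to its chemical-group id.

    Lowercase input is normalized to uppercase.  Raises
    :class:`InvalidResidueError` for non-standard codes.

    >>> encode_residue('D')
    1
    >>> encode_residue('p')
    5
    """
    if not isinstance(residue, str) or len(residue) != 1:
        raise ValueError(f"expected a single character, got {residue!r}")
    return alphabet.group_of(residue.upper())


def encode_sequence(seq_id: str, residues: str,
                    alphabet: ChemicalAlphabet = EIGHT_GROUPS,
                    policy: str = "strict") -> EncodedSequence:
    """Encode a residue string into its chemical-group digit string.

    Parameters
    ----------
    seq_id : str
        Identifier carried through to downstream reports.
    residues : str
        Amino-acid sequence; lowercase is uppercased before lookup.
    alphabet : ChemicalAlphabet
        The group partition (default: the eight-group chemistry).
    policy : {"strict", "mask"}
        ``strict`` raises :class:`InvalidResidueError` on any non-standard
        character; ``mask`` replaces it with the break digit ``'0'``, which
        no pattern, transition pair or similarity window may span.

    >>> encode_sequence("q", "FPKATD").digits
    '352471'
    """
    if policy not in ("strict", "mask"):
        raise ValueError(f"unknown policy {policy!r}")
    upper = residues.upper()
    out = []
    for i, r in enumerate(upper):
        try:
            out.append(str(alphabet.group_of(r)))
        except InvalidResidueError:
            if policy == "strict":
                raise InvalidResidueError(r, position=i + 1, seq_id=seq_id) \
                    from None
            out.append(BREAK_DIGIT)
    return EncodedSequence(seq_id=seq_id, residues=upper, digits="".join(out))


def group_members(group_id: int,
                  alphabet: ChemicalAlphabet = EIGHT_GROUPS) -> frozenset[str]:
    """Residue set of one chemical group (e.g. group 6 -> {'M', 'C'})."""
    return alphabet.members(group_id)
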