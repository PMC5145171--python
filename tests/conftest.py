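import random

import pytest
from hypothesis import HealthCheck, settings

from chemseq import encode_sequence

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(RESIDUES) for _ in range(length))


def brute_force_common(digit_strings: list[str], L: int) -> set[str]:
    """Independent oracle: all length-L substrings present in every string.

    Enumerates windows of the first string directly and checks the rest with
    plain substring containment — no k-mer hashing, no shared code with the
    implementation under test.
    """
    first = digit_strings[0]
    out = set()
    for i in range(len(first) - L + 1):
        cand = first[i:i + L]
        if all(cand in s for s in digit_strings[1:]):
            out.add(cand)
    return out


@pytest.fixture
def rng():
    return random.Random(20260927)


@pytest.fixture
def enc():
    """Shorthand encoder: enc('DRSMYI') -> EncodedSequence."""
    def _enc(residues, seq_id="s", **kw):
        return encode_sequence(seq_id, residues, **kw)
    return _enc
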