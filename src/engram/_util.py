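"""Small shared helpers: seeding, sequences, Hamming distance."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic child seed from a master seed and a text label.

    Keeps every stream reproducible from one integer while decorrelating
    samples; result fits in a signed 32-bit integer.
    """
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, label))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def check_nucleotides(seq: str, alphabet: str = "ACGT") -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} (alphabet {alphabet})")
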