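"""Low-level DNA string utilities shared across the pipeline.

Sequences are plain Python strings over the IUPAC nucleotide alphabet.
All coordinates elsewhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import numpy as np

#: IUPAC nucleotide codes mapped to the set of concrete bases they allow.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: frozen base set -> single IUPAC code.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC.items()}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(_COMPLEMENT)

ALPHABET = frozenset(IUPAC)


def normalize(seq: str) -> str:
    """Uppercase a sequence, map U to T, and reject non-IUPAC characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (M<->K, R<->Y, ...)."""
    return seq.translate(_COMP_TABLE)[::-1]


def iupac_match(pattern: str, text: str) -> bool:
    """True iff every base of ``text`` is allowed by the aligned IUPAC code
    of ``pattern``.  Both strings must have equal length."""
    if len(pattern) != len(text):
        raise ValueError(
            f"iupac_match requires equal lengths ({len(pattern)} vs {len(text)})"
        )
    return all(t in IUPAC[p] for p, t in zip(pattern, text))


def iupac_compatible(pattern: str, text: str) -> bool:
    """True iff at every position the two IUPAC codes share at least one
    allowed base (symmetric, unlike :func:`iupac_match`)."""
    if len(pattern) != len(text):
        raise ValueError("equal lengths required")
    return all(IUPAC[p] & IUPAC[t] for p, t in zip(pattern, text))


def iupac_mismatches(pattern: str, text: str) -> int:
    """Number of positions of ``text`` not allowed by ``pattern`` (equal lengths)."""
    if len(pattern) != len(text):
        raise ValueError("equal lengths required")
    return sum(t not in IUPAC[p] for p, t in zip(pattern, text))


def resolve_iupac(pattern: str, rng: np.random.Generator | None = None) -> str:
    """Replace ambiguity codes by concrete bases.

    With an ``rng``, each ambiguous position is resolved uniformly at random
    over its allowed set (a degenerate primer pool contains every variant);
    without one, the alphabetically first allowed base is chosen.
    """
    out = []
    for p in pattern:
        allowed = sorted(IUPAC[p])
        if len(allowed) == 1:
            out.append(allowed[0])
        elif rng is None:
            out.append(allowed[0])
        else:
            out.append(allowed[int(rng.integers(len(allowed)))])
    return "".join(out)


def ambiguity_code(bases) -> str:
    """IUPAC code for a set of concrete bases, e.g. {A, C} -> M."""
    return CODE_FOR_SET[frozenset(bases)]


# Encoding used by the numeric kernels (window matching, Fitch masks).
_ENC = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = 1 << _i
for _code, _set in IUPAC.items():
    _ENC[ord(_code)] = np.bitwise_or.reduce([_ENC[ord(b)] for b in _set])


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 bitmask vector (A=1, C=2, G=4, T=8;
    ambiguity codes are unions; anything else 0)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
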