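"""Small RNA-sequence primitives used by the simulator and site predictors."""

from __future__ import annotations

import numpy as np

RNA_ALPHABET = "ACGU"

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: Watson-Crick pairs (GU wobble is handled separately where it matters).
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not an RNA base: {base!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement over the RNA alphabet."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def as_rna(seq: str) -> str:
    """Uppercase and convert T->U; reject anything outside the RNA alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def random_rna(rng: np.random.Generator, length: int) -> str:
    """Uniform random RNA sequence."""
    return "".join(rng.choice(list(RNA_ALPHABET), size=length))


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_pair(a: str, b: str) -> bool:
    """Watson-Crick or GU wobble."""
    return (a, b) in WC_PAIRS or (a, b) in GU_PAIRS
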