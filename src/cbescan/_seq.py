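"""Small sequence helpers shared across modules."""

from __future__ import annotations

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The three codons whose first-position C -> T conversion creates a stop.
STOP_FORMING_CODONS = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_w(base: str) -> bool:
    """True iff *base* is a weak base (A or T). N never counts."""
    return base in ("A", "T", "a", "t")
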