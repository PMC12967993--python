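"""Small shared sequence helpers: encoding, complement, translation, IUPAC sets."""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

# A/C/G/T -> 0..3; every other character -> 4 so that two ambiguous bases never
# score as a match in the aligner.
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate frame 0; trailing partial codon dropped; '*' marks stops."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


# IUPAC degenerate code -> set of concrete bases (e.g. R -> {A, G}).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code.upper(): frozenset(bases.upper())
    for code, bases in IUPACData.ambiguous_dna_values.items()
}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

# aa -> sorted list of codons, for reverse translation.
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
STOP_CODONS = frozenset(_STANDARD.stop_codons)


def reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Pick one codon per residue uniformly at random (never a stop codon)."""
    return "".join(CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))]
                   for aa in aa_seq)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))
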