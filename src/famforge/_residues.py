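"""Shared residue-level constants: alphabets, background frequencies, BLOSUM62.

The amino-acid background is a fixed Robinson--Robinson style frequency
table shipped with the package so that no external download is needed and
every run is reproducible.
"""
from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

#: Canonical residue order used by every matrix in the package.  Index 20 is
#: the wildcard 'X' which scores 0 against everything.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_WITH_X = AA_ORDER + "X"
AA_INDEX = {a: i for i, a in enumerate(AA_WITH_X)}

DNA_ORDER = "ACGT"
DNA_INDEX = {b: i for i, b in enumerate(DNA_ORDER)}

# Robinson & Robinson (1991)-style amino-acid frequencies.
_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def aa_background() -> np.ndarray:
    """Background amino-acid frequencies in :data:`AA_ORDER`, summing to 1."""
    freqs = np.array([_ROBINSON[a] for a in AA_ORDER], dtype=float)
    return freqs / freqs.sum()


def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 float array over :data:`AA_WITH_X`.

    'X' rows/columns are zero (wildcard), per the scoring-scheme contract.
    """
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = raw[a, b]
    return mat


def encode_protein(seq: str, *, name: str = "sequence") -> np.ndarray:
    """Encode a protein string to integer indices, validating the alphabet.

    Raises ``ValueError`` naming the offending position for any character
    outside the 20-letter alphabet plus 'X'.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for pos, ch in enumerate(seq):
        idx = AA_INDEX.get(ch)
        if idx is None:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} in {name}"
            )
        out[pos] = idx
    return out


STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(STANDARD_TABLE.stop_codons)
#: codon -> one-letter amino acid (stop codons excluded)
CODON_TO_AA = dict(STANDARD_TABLE.forward_table)

SENSE_CODONS = tuple(sorted(CODON_TO_AA))
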