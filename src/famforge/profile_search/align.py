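"""Pairwise local and global alignment under an affine-gap scoring scheme."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from famforge._residues import AA_WITH_X, blosum62, encode_protein
from famforge.profile_search import _dp


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both positive costs).

    A gap of length ``k`` costs ``gap_open + k * gap_extend`` (BLAST
    convention with the default 11/1).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.matrix_name != "BLOSUM62":
            raise ValueError(f"unsupported matrix {self.matrix_name!r}")

    @property
    def matrix(self) -> np.ndarray:
        return _BLOSUM62

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[AA_WITH_X.index(a), AA_WITH_X.index(b)])


_BLOSUM62 = blosum62()
_BLOSUM62.setflags(write=False)


@dataclass
class LocalAlignment:
    """Best local alignment: score plus 0-based half-open segment coordinates."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str = field(default="", repr=False)
    aligned_target: str = field(default="", repr=False)

    @property
    def is_empty(self) -> bool:
        return self.query_start == self.query_end


def smith_waterman(
    query: str, target: str, scheme: ScoringScheme | None = None
) -> LocalAlignment:
    """Optimal local alignment of two residue sequences.

    The score is the maximum over all local alignments under the affine-gap
    scheme; a maximum of 0 yields an empty alignment.  The alignment end is
    the first (row-major) cell attaining the maximum; traceback prefers
    diagonal over gap-in-target over gap-in-query, which makes the result
    deterministic.
    """
    scheme = scheme or ScoringScheme()
    a = encode_protein(query, name="query")
    b = encode_protein(target, name="target")
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    H, E, F = _dp.sw_fill(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    score = float(H.max())
    if score <= 0.0:
        return LocalAlignment(0.0, 0, 0, 0, 0)
    end_i, end_j = np.unravel_index(int(np.argmax(H)), H.shape)
    qa, ta, start_i, start_j = _traceback_local(
        query, target, a, b, H, E, F, int(end_i), int(end_j), scheme
    )
    return LocalAlignment(score, start_i, int(end_i), start_j, int(end_j), qa, ta)


def _traceback_local(query, target, a, b, H, E, F, i, j, scheme):
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    qa: list[str] = []
    ta: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                break
            if np.isclose(h, H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]):
                qa.append(query[i - 1])
                ta.append(target[j - 1])
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in target: consume query residue
            qa.append(query[i - 1])
            ta.append("-")
            leave = np.isclose(F[i, j], H[i - 1, j] - go - ge)
            i -= 1
            if leave:
                state = "H"
        else:  # state == "E": gap in query: consume target residue
            qa.append("-")
            ta.append(target[j - 1])
            leave = np.isclose(E[i, j], H[i, j - 1] - go - ge)
            j -= 1
            if leave:
                state = "H"
    return "".join(reversed(qa)), "".join(reversed(ta)), i, j


@dataclass
class GlobalAlignment:
    score: float
    aligned_a: str
    aligned_b: str


def global_align(
    a_seq: str, b_seq: str, scheme: ScoringScheme | None = None
) -> GlobalAlignment:
    """Needleman-Wunsch global alignment with affine gaps (end gaps charged)."""
    scheme = scheme or ScoringScheme()
    a = encode_protein(a_seq, name="a")
    b = encode_protein(b_seq, name="b")
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    H, E, F = _dp.nw_fill(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    sub = scheme.matrix
    go, ge = scheme.gap_open, scheme.gap_extend
    i, j = a.size, b.size
    qa: list[str] = []
    ta: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and np.isclose(
                H[i, j], H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            ):
                qa.append(a_seq[i - 1])
                ta.append(b_seq[j - 1])
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            qa.append(a_seq[i - 1])
            ta.append("-")
            leave = j == 0 and i == 1 or np.isclose(F[i, j], H[i - 1, j] - go - ge)
            i -= 1
            if leave:
                state = "H"
        else:
            qa.append("-")
            ta.append(b_seq[j - 1])
            leave = i == 0 and j == 1 or np.isclose(E[i, j], H[i, j - 1] - go - ge)
            j -= 1
            if leave:
                state = "H"
    return GlobalAlignment(float(H[a.size, b.size]), "".join(reversed(qa)), "".join(reversed(ta)))


def sequence_identity(
    a_seq: str, b_seq: str, scheme: ScoringScheme | None = None
) -> float:
    """Identity fraction: identical aligned residues / shorter sequence length.

    The denominator convention matches CD-HIT; alignment is global.
    """
    scheme = scheme or ScoringScheme()
    a = encode_protein(a_seq, name="a")
    b = encode_protein(b_seq, name="b")
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    matches = _dp.nw_identity(
        a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    return int(matches) / min(len(a_seq), len(b_seq))


def local_score(a_seq: str, b_seq: str, scheme: ScoringScheme | None = None) -> float:
    """Score-only Smith-Waterman (no traceback; used for all-vs-all searches)."""
    scheme = scheme or ScoringScheme()
    a = encode_protein(a_seq, name="a")
    b = encode_protein(b_seq, name="b")
    return float(
        _dp.sw_score(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    )
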