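"""Seed-MSA profile scanning and iterative profile expansion.

The family-discovery loop: build a profile from the seed alignment, score
every protein by best profile-to-sequence local alignment, accept hits below
the E-value threshold, rebuild the profile from the matched domain segments
of everything accepted so far, and repeat until membership stops growing or
the iteration cap is reached.  Membership is monotone non-decreasing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from famforge._residues import encode_protein
from famforge.profile_search import _dp
from famforge.profile_search.pssm import (
    PROFILE_GAP_EXTEND,
    PROFILE_GAP_OPEN,
    ProfileMatrix,
    build_pssm,
    calibrate_profile,
    estimate_evalue,
    seed_rows_for_profile,
)

DEFAULT_EVALUE = 1e-2
DEFAULT_INCLUSION = 1e-2
DEFAULT_MAX_ITER = 10


@dataclass(frozen=True)
class SearchHit:
    """A scored local match of the profile inside one protein."""

    protein_id: str
    start: int  # 0-based half-open protein coordinates of the segment
    end: int
    raw_score: float
    evalue: float
    aligned_columns: str = field(default="", repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("hit segment must satisfy 0 <= start < end")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class FamilySet:
    """Accepted membership after one expansion iteration."""

    iteration: int
    members: tuple[SearchHit, ...]
    converged: bool

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(h.protein_id for h in self.members)


def _align_profile(profile: ProfileMatrix, seq: str, gap_open: float, gap_extend: float):
    """Best local profile-vs-sequence alignment with per-column traceback.

    Returns (score, target_start, target_end, column string) where the
    column string has exactly ``profile.length`` characters: the residue
    matched at each profile column, ``-`` where the column was skipped.
    Target insertions between columns are dropped.
    """
    b = encode_protein(seq, name="target")
    H, E, F = _dp.profile_sw_fill(profile.scores, b, gap_open, gap_extend)
    score = float(H.max())
    if score <= 0.0:
        return 0.0, 0, 0, "-" * profile.length
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    end_j = j
    cols = ["-"] * profile.length
    state = "H"
    go, ge = gap_open, gap_extend
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0.0:
                break
            if abs(h - (H[i - 1, j - 1] + profile.scores[i - 1, b[j - 1]])) < 1e-9:
                cols[i - 1] = seq[j - 1]
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # skip a profile column
            leave = abs(F[i, j] - (H[i - 1, j] - go - ge)) < 1e-9
            i -= 1
            if leave:
                state = "H"
        else:  # insertion in the target; residue dropped from the column view
            leave = abs(E[i, j] - (H[i, j - 1] - go - ge)) < 1e-9
            j -= 1
            if leave:
                state = "H"
    return score, j, end_j, "".join(cols)


def _validate_seed(seed_msa: list[str]) -> list[str]:
    if not seed_msa:
        raise ValueError("seed MSA is empty")
    width = len(seed_msa[0])
    if any(len(r) != width for r in seed_msa):
        raise ValueError("seed MSA rows must be equal length")
    if width < 10:
        raise ValueError("seed MSA must have at least 10 columns")
    return [r.upper() for r in seed_msa]


def scan_proteome(
    profile: ProfileMatrix,
    proteome: dict[str, str],
    evalue: float = DEFAULT_EVALUE,
    *,
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> list[SearchHit]:
    """Score every protein against a calibrated profile; keep E <= threshold.

    Hits are sorted by (evalue, protein id) — the stable lexicographic
    tie-break used throughout the package.
    """
    n_db = len(proteome)
    hits: list[SearchHit] = []
    for pid in sorted(proteome):
        seq = proteome[pid]
        if not seq:
            continue
        score, t_start, t_end, cols = _align_profile(profile, seq, gap_open, gap_extend)
        if t_start == t_end:
            continue
        ev = estimate_evalue(score, profile, len(seq), n_db)
        if ev <= evalue:
            hits.append(SearchHit(pid, t_start, t_end, score, ev, cols))
    hits.sort(key=lambda h: (h.evalue, h.protein_id))
    return hits


def scan_with_seed_msa(
    seed_msa: list[str],
    proteome: dict[str, str],
    evalue: float = DEFAULT_EVALUE,
    *,
    pseudocount_weight: float = 1.0,
    calibration_seed: int = 2003,
) -> list[SearchHit]:
    """Single-pass family scan from a seed alignment (the seeding stage)."""
    rows = _validate_seed(seed_msa)
    if not proteome:
        raise ValueError("proteome is empty")
    profile = build_pssm(rows, pseudocount_weight=pseudocount_weight)
    calibrate_profile(profile, [s for s in proteome.values() if s], seed=calibration_seed)
    return scan_proteome(profile, proteome, evalue)


def iterative_expand(
    seed_msa: list[str],
    proteome: dict[str, str],
    evalue: float = DEFAULT_EVALUE,
    inclusion: float = DEFAULT_INCLUSION,
    max_iter: int = DEFAULT_MAX_ITER,
    *,
    pseudocount_weight: float = 1.0,
    calibration_seed: int = 2003,
) -> list[FamilySet]:
    """Iterative profile search; returns the membership after each iteration.

    Proteins whose best hit reaches ``evalue`` are reported; those reaching
    ``inclusion`` join the profile for the next round.  Members are never
    removed, so membership grows monotonically; the final
    :class:`FamilySet` has ``converged=True`` when an iteration added
    nobody (or scored the identical membership twice).
    """
    rows = _validate_seed(seed_msa)
    if not proteome:
        raise ValueError("proteome is empty")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    db_seqs = [s for s in proteome.values() if s]

    profile = build_pssm(rows, pseudocount_weight=pseudocount_weight)
    seed_rows = seed_rows_for_profile(rows, profile)
    members: dict[str, SearchHit] = {}
    history: list[FamilySet] = []
    for iteration in range(1, max_iter + 1):
        calibrate_profile(profile, db_seqs, seed=calibration_seed)
        hits = scan_proteome(profile, proteome, max(evalue, inclusion))
        added = False
        for hit in hits:
            if hit.evalue > inclusion:
                continue
            prev = members.get(hit.protein_id)
            if prev is None:
                members[hit.protein_id] = hit
                added = True
            elif hit.raw_score > prev.raw_score:
                # refresh the segment but keep membership monotone
                members[hit.protein_id] = replace(hit, evalue=min(hit.evalue, prev.evalue))
        converged = not added
        snapshot = tuple(members[p] for p in sorted(members))
        history.append(FamilySet(iteration, snapshot, converged))
        if converged:
            break
        segments = seed_rows + [members[p].aligned_columns for p in sorted(members)]
        profile = build_pssm(
            segments, pseudocount_weight=pseudocount_weight, drop_gappy=False
        )
    return history
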