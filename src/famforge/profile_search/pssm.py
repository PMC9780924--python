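"""Position-specific scoring matrices and empirical E-value calibration.

Scores are per-column log-odds in bits::

    score(a) = log2((f_a + w * b_a) / ((1 + w) * b_a))

with ``f_a`` the observed column frequency, ``b_a`` the background frequency
and ``w`` the pseudocount weight.  Minus infinity (a residue never observed,
``w = 0``) is capped at -8 bits (-16 half-bits) so the dynamic program stays
finite without changing optima in practice.

E-values come from an empirical Gumbel fit on shuffled-sequence scores
rather than Karlin-Altschul theory, which does not cover gapped profile
scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from famforge._residues import AA_WITH_X, aa_background, encode_protein

SCORE_FLOOR = -8.0  # bits; equivalently -16 half-bits
GAP_CHAR = "-"

#: default affine gap penalties for profile-vs-sequence alignment, in bits
PROFILE_GAP_OPEN = 5.5
PROFILE_GAP_EXTEND = 0.5


@dataclass(frozen=True)
class Calibration:
    """Gumbel null fit: per-sequence score ~ Gumbel(loc, scale)."""

    loc: float
    scale: float
    mean_null_length: float
    n_shuffles: int


@dataclass
class ProfileMatrix:
    """Column x residue log-odds profile (bits) with its background."""

    scores: np.ndarray  # (length, 21); column 20 is the 'X' wildcard (0)
    background: np.ndarray  # (20,)
    pseudocount_weight: float
    kept_columns: tuple[int, ...] = ()
    calibration: Calibration | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AA_WITH_X):
            raise ValueError("scores must be (length, 21)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if not np.all(np.isfinite(self.scores).any(axis=1)):
            raise ValueError("every profile column needs a finite score")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


def build_pssm(
    segments: list[str],
    background: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
    *,
    drop_gappy: bool = True,
) -> ProfileMatrix:
    """Build a profile from equal-length aligned segments (gap = ``-``).

    Columns with more than 50% gap characters are dropped when
    ``drop_gappy`` is set (it is disabled when rebuilding from fixed-width
    hit segments during iterative expansion, where column geometry must stay
    stable).
    """
    if not segments:
        raise ValueError("need at least one aligned segment")
    width = len(segments[0])
    if width == 0 or any(len(s) != width for s in segments):
        raise ValueError("aligned segments must share a positive length")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    bg = aa_background() if background is None else np.asarray(background, float)

    rows = [s.upper() for s in segments]
    n_rows = len(rows)
    kept: list[int] = []
    for c in range(width):
        gaps = sum(1 for r in rows if r[c] == GAP_CHAR)
        if drop_gappy and gaps * 2 > n_rows:
            continue
        if gaps == n_rows:
            continue  # all-gap columns carry no signal even when keeping
        kept.append(c)
    if not kept:
        raise ValueError("all columns are gap-dominated; cannot build profile")

    w = pseudocount_weight
    scores = np.zeros((len(kept), len(AA_WITH_X)))
    for out_c, c in enumerate(kept):
        counts = np.zeros(20)
        for r in rows:
            ch = r[c]
            if ch == GAP_CHAR or ch == "X":
                continue
            idx = AA_WITH_X.index(ch)
            counts[idx] += 1.0
        total = counts.sum()
        freqs = counts / total if total > 0 else np.zeros(20)
        with np.errstate(divide="ignore"):
            col = np.log2((freqs + w * bg) / ((1.0 + w) * bg))
        col = np.maximum(col, SCORE_FLOOR)
        scores[out_c, :20] = col
        scores[out_c, 20] = 0.0  # X wildcard
    return ProfileMatrix(scores, bg, w, kept_columns=tuple(kept))


def seed_rows_for_profile(segments: list[str], profile: ProfileMatrix) -> list[str]:
    """Restrict seed MSA rows to the profile's kept columns."""
    return ["".join(row[c] for c in profile.kept_columns) for row in segments]


def calibrate_profile(
    profile: ProfileMatrix,
    proteome_sequences: list[str],
    *,
    n_shuffles: int = 200,
    seed: int = 2003,
    gap_open: float = PROFILE_GAP_OPEN,
    gap_extend: float = PROFILE_GAP_EXTEND,
) -> ProfileMatrix:
    """Fit the profile's Gumbel null from shuffled proteome sequences.

    Sequences are drawn cyclically from the proteome and residue-shuffled
    with a generator derived from ``seed``, so calibration is deterministic.
    The fit is stored on the profile and consumed by :func:`estimate_evalue`.
    """
    from famforge.profile_search import _dp

    if not proteome_sequences:
        raise ValueError("cannot calibrate against an empty proteome")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    lengths = np.empty(n_shuffles)
    for k in range(n_shuffles):
        seq = proteome_sequences[k % len(proteome_sequences)]
        arr = encode_protein(seq, name="null sequence")
        rng.shuffle(arr)
        scores[k] = _dp.profile_sw_score(profile.scores, arr, gap_open, gap_extend)
        lengths[k] = arr.size
    loc, scale = stats.gumbel_r.fit(scores)
    profile.calibration = Calibration(
        float(loc), float(scale), float(lengths.mean()), n_shuffles
    )
    return profile


def estimate_evalue(
    raw_score: float,
    profile: ProfileMatrix,
    target_length: int,
    database_size: int,
) -> float:
    """Expected number of chance hits scoring >= ``raw_score``.

    Uses the calibrated Gumbel tail, scaled linearly to the target length
    and multiplied by the database size; monotone decreasing in the score
    and -> 0 as the score grows.
    """
    cal = profile.calibration
    if cal is None:
        raise RuntimeError("profile is not calibrated; run calibrate_profile first")
    z = (raw_score - cal.loc) / cal.scale
    # Gumbel survival, computed stably: 1 - exp(-exp(-z))
    tail = float(-np.expm1(-np.exp(-z)))
    length_factor = target_length / cal.mean_null_length if cal.mean_null_length else 1.0
    return max(database_size * length_factor * tail, 0.0)
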