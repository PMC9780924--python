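"""Family characterization: progressive multiple alignment, conserved-site
statistics and C-terminal domain-architecture annotation.

The conserved-site rule: at each alignment column, the two most abundant
non-gap residues are the conserved pair, and the reported percentage uses
the *total* number of MSA rows (rows gapped at that column included) as the
denominator, rounded to two decimals.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from famforge._residues import AA_WITH_X, blosum62
from famforge.profile_search.pssm import ProfileMatrix, build_pssm, calibrate_profile
from famforge.profile_search.search import SearchHit, _align_profile
from famforge.profile_search.pssm import PROFILE_GAP_EXTEND, PROFILE_GAP_OPEN


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("all MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped(self, index: int) -> str:
        return self.rows[index].replace("-", "")


# ---------------------------------------------------------------------------
# progressive alignment

_GAP_RES = -4.0  # residue-vs-gap pair score in the mean-of-pairs objective


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0 if a != b else 0.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    union = ka | kb
    return 1.0 - len(ka & kb) / len(union)


def _column_score(col_a: list[str], col_b: list[str], sub: np.ndarray) -> float:
    total = 0.0
    n = 0
    for x in col_a:
        for y in col_b:
            if x == "-" and y == "-":
                pass
            elif x == "-" or y == "-":
                total += _GAP_RES
            else:
                total += sub[AA_WITH_X.index(x), AA_WITH_X.index(y)]
            n += 1
    return total / n


def _profile_nw(rows_a: list[str], rows_b: list[str], sub: np.ndarray) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with mean-of-pairs column scoring.

    Gap columns score the mean of residue-vs-gap pairs; the recursion is the
    plain (linear-gap) Needleman-Wunsch over column scores.
    """
    cols_a = [[r[c] for r in rows_a] for c in range(len(rows_a[0]))]
    cols_b = [[r[c] for r in rows_b] for c in range(len(rows_b[0]))]
    m, n = len(cols_a), len(cols_b)
    gap_a = ["-"] * len(rows_a)
    gap_b = ["-"] * len(rows_b)
    score = np.zeros((m + 1, n + 1))
    for i in range(1, m + 1):
        score[i, 0] = score[i - 1, 0] + _column_score(cols_a[i - 1], gap_b, sub)
    for j in range(1, n + 1):
        score[0, j] = score[0, j - 1] + _column_score(gap_a, cols_b[j - 1], sub)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + _column_score(cols_a[i - 1], cols_b[j - 1], sub),
                score[i - 1, j] + _column_score(cols_a[i - 1], gap_b, sub),
                score[i, j - 1] + _column_score(gap_a, cols_b[j - 1], sub),
            )
    # traceback, preferring diagonal then column-from-a then column-from-b
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and np.isclose(
                score[i, j],
                score[i - 1, j - 1] + _column_score(cols_a[i - 1], cols_b[j - 1], sub),
            )
        ):
            out_a.append("".join(cols_a[i - 1]))
            out_b.append("".join(cols_b[j - 1]))
            i -= 1
            j -= 1
        elif i > 0 and np.isclose(
            score[i, j], score[i - 1, j] + _column_score(cols_a[i - 1], gap_b, sub)
        ):
            out_a.append("".join(cols_a[i - 1]))
            out_b.append("-" * len(rows_b))
            i -= 1
        else:
            out_a.append("-" * len(rows_a))
            out_b.append("".join(cols_b[j - 1]))
            j -= 1
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[r] for col in out_a) for r in range(len(rows_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(rows_b))]
    return new_a, new_b


def progressive_align(sequences: dict[str, str]) -> Msa:
    """Progressive MSA: 3-mer distance UPGMA guide tree, then profile-profile
    Needleman-Wunsch merges with BLOSUM62 mean-of-pairs scoring."""
    ids = sorted(sequences)
    if not ids:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        return Msa(ids, [sequences[ids[0]]])
    sub = blosum62()
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(sequences[ids[i]], sequences[ids[j]])
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")

    # node id -> (ids, rows) profiles, merged bottom-up along the guide tree
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [sequences[ids[i]]]) for i in range(n)
    }
    for step, (left, right, _d, _cnt) in enumerate(linkage):
        ids_l, rows_l = profiles.pop(int(left))
        ids_r, rows_r = profiles.pop(int(right))
        new_l, new_r = _profile_nw(rows_l, rows_r, sub)
        profiles[n + step] = (ids_l + ids_r, new_l + new_r)
    final_ids, final_rows = profiles.popitem()[1]
    order = sorted(range(len(final_ids)), key=lambda i: final_ids[i])
    return Msa([final_ids[i] for i in order], [final_rows[i] for i in order])


def sum_of_pairs(msa: Msa, gap_res: float = _GAP_RES) -> float:
    """Sum-of-pairs score of an MSA under BLOSUM62 with linear gap scoring
    (residue-gap = ``gap_res``, gap-gap = 0)."""
    sub = blosum62()
    total = 0.0
    for c in range(msa.n_columns):
        col = [r[c] for r in msa.rows]
        for i in range(len(col)):
            for j in range(i + 1, len(col)):
                x, y = col[i], col[j]
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += gap_res
                else:
                    total += sub[AA_WITH_X.index(x), AA_WITH_X.index(y)]
    return total


# ---------------------------------------------------------------------------
# conserved sites


@dataclass(frozen=True)
class ConservedSite:
    column: int  # 1-based MSA column
    top_residue: str
    top_count: int
    second_residue: str | None
    second_count: int
    percent: float  # 100 * top_count / total rows, two decimals


def conserved_sites(msa: Msa, min_fraction: float | None = None) -> list[ConservedSite]:
    """Per-column conserved pairs: the two most abundant non-gap residues.

    Ties are broken alphabetically.  ``percent`` divides by the total row
    count (not the non-gap count) and is rounded to two decimals.  With
    ``min_fraction``, only columns whose top residue reaches that fraction
    of the rows are returned.
    """
    if msa.n_rows == 0:
        raise ValueError("MSA is empty")
    total = msa.n_rows
    sites: list[ConservedSite] = []
    for c in range(msa.n_columns):
        counts = Counter(r[c] for r in msa.rows if r[c] != "-")
        if not counts:
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top, top_n = ranked[0]
        second, second_n = (ranked[1] if len(ranked) > 1 else (None, 0))
        percent = round(100.0 * top_n / total, 2)
        if min_fraction is not None and top_n / total < min_fraction:
            continue
        sites.append(ConservedSite(c + 1, top, top_n, second, second_n, percent))
    return sites


def conservation_percent(count: int, total: int) -> float:
    """The conserved-site percentage statistic: 100 * count / total, 2 dp."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, 2)


def cross_species_conserved_overlap(
    per_species_sites: dict[str, list[ConservedSite]],
) -> float:
    """Fraction of conserved columns shared by all species.

    Numerator: joint-MSA columns where the top-2 residue sets of *all*
    species intersect; denominator: columns conserved in at least one
    species.  Site lists must already be in joint-MSA column coordinates.
    Returns 0.0 (with a warning) when every list is empty.
    """
    if not per_species_sites or all(not s for s in per_species_sites.values()):
        import warnings

        warnings.warn("no conserved sites supplied; overlap is 0", stacklevel=2)
        return 0.0
    by_column: dict[int, dict[str, set[str]]] = {}
    for species, sites in per_species_sites.items():
        for site in sites:
            pair = {site.top_residue}
            if site.second_residue is not None:
                pair.add(site.second_residue)
            by_column.setdefault(site.column, {})[species] = pair
    n_species = len(per_species_sites)
    union_cols = set(by_column)
    shared = 0
    for col, per_sp in by_column.items():
        if len(per_sp) < n_species:
            continue
        inter = set.intersection(*per_sp.values())
        if inter:
            shared += 1
    return shared / len(union_cols)


# ---------------------------------------------------------------------------
# C-terminal domain architecture


@dataclass(frozen=True)
class DomainHit:
    name: str
    start: int  # protein coordinates, 0-based half-open
    end: int
    score: float
    evalue: float


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domains: tuple[DomainHit, ...]  # N->C order, non-overlapping
    architecture: str  # "F-box", "F-box+<names>" or "FBXU"


@dataclass
class DomainLibrary:
    """Named profile models built from per-domain seed alignments."""

    profiles: dict[str, ProfileMatrix]

    @classmethod
    def from_seed_msas(
        cls,
        seed_msas: dict[str, list[str]],
        calibration_sequences: list[str],
        *,
        pseudocount_weight: float = 1.0,
        calibration_seed: int = 2003,
    ) -> "DomainLibrary":
        if not seed_msas:
            raise ValueError("domain model library is empty")
        profiles = {}
        for name in sorted(seed_msas):
            profile = build_pssm(seed_msas[name], pseudocount_weight=pseudocount_weight)
            calibrate_profile(profile, calibration_sequences, seed=calibration_seed)
            profiles[name] = profile
        return cls(profiles)


def annotate_cterm_domains(
    protein_id: str,
    sequence: str,
    fbox_hit: SearchHit,
    library: DomainLibrary,
    evalue_threshold: float = 1e-2,
    *,
    database_size: int = 1,
) -> DomainAnnotation:
    """Scan the region downstream of the family-domain hit with every model.

    Hits above threshold are resolved to a non-overlapping set greedily by
    (best score, leftmost start, name); the architecture label is
    ``F-box+<names in N->C order>``, or ``FBXU`` when nothing survives.
    """
    if not (0 <= fbox_hit.start < fbox_hit.end <= len(sequence)):
        raise ValueError(
            f"family-domain hit {fbox_hit.start}..{fbox_hit.end} lies outside "
            f"protein {protein_id!r} (length {len(sequence)})"
        )
    from famforge.profile_search.pssm import estimate_evalue

    cterm_offset = fbox_hit.end
    cterm = sequence[cterm_offset:]
    candidates: list[DomainHit] = []
    if cterm:
        for name, profile in library.profiles.items():
            score, t_start, t_end, _cols = _align_profile(
                profile, cterm, PROFILE_GAP_OPEN, PROFILE_GAP_EXTEND
            )
            if t_start == t_end:
                continue
            ev = estimate_evalue(score, profile, len(cterm), database_size)
            if ev <= evalue_threshold:
                candidates.append(
                    DomainHit(name, cterm_offset + t_start, cterm_offset + t_end, score, ev)
                )
    candidates.sort(key=lambda h: (-h.score, h.start, h.name))
    kept: list[DomainHit] = []
    for hit in candidates:
        if all(hit.end <= other.start or hit.start >= other.end for other in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    if kept:
        architecture = "F-box+" + "+".join(h.name for h in kept)
    else:
        architecture = "FBXU"
    return DomainAnnotation(protein_id, tuple(kept), architecture)


def domain_census(annotations_by_species: dict[str, list[DomainAnnotation]]):
    """Count proteins containing each domain type per species.

    A protein with two different domain types increments both rows; proteins
    with no surviving C-terminal hit count under ``FBXU``.  Returns a
    pandas DataFrame (domain type x species), empty when no annotations.
    """
    import pandas as pd

    counts: dict[str, Counter] = {}
    for species, annotations in annotations_by_species.items():
        tally: Counter = Counter()
        for ann in annotations:
            types = {h.name for h in ann.domains}
            if not types:
                tally["FBXU"] += 1
            else:
                for t in types:
                    tally[t] += 1
        counts[species] = tally
    frame = pd.DataFrame(counts).fillna(0).astype(int)
    return frame.sort_index()
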