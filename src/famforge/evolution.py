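"""Duplicate-gene evolution: identity clustering, tandem classification,
Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction, and reciprocal-best-hit
ortholog pairing.

NG86 conventions implemented here:

* Site counting: for each codon and each of its three positions, the
  synonymous site fraction is (number of the three possible single-nucleotide
  changes that are synonymous) / 3; changes creating a stop codon are never
  synonymous, so each codon contributes s + n = 3 sites.  S and N are
  averaged over the two sequences.
* Difference counting: for a codon pair differing at d positions, all d!
  orderings of the single steps are enumerated; pathways passing through a
  stop codon are excluded and the synonymous/nonsynonymous step counts are
  averaged over the remaining pathways with equal weight (all pathways are
  used if every one passes through a stop).
* Correction: Jukes-Cantor, d = -(3/4) ln(1 - (4/3) p).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from famforge._residues import CODON_TO_AA, STOP_CODONS
from famforge.profile_search.align import (
    ScoringScheme,
    global_align,
    local_score,
    sequence_identity,
)
from famforge.profile_search.cluster import IdentityCluster, greedy_identity_cluster


@dataclass(frozen=True)
class GeneLocus:
    """Gene coordinates, internally 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"gene {self.gene_id}: chromosome must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


class RatioFlag(str, Enum):
    DEFINED = "defined"
    IDENTICAL = "identical"  # Ka = Ks = 0: ratio reported as 0 by convention
    INFINITE = "infinite"  # Ks = 0, Ka > 0
    UNDEFINED = "undefined"  # Jukes-Cantor correction does not exist (p >= 3/4)


class DupClass(str, Enum):
    TANDEM = "tandem"
    DISPERSED = "dispersed"


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float
    flag: RatioFlag
    sd: float  # synonymous differences
    nd: float  # nonsynonymous differences
    s_sites: float
    n_sites: float
    n_codons: int


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float
    ka: float
    ks: float
    ratio: float
    flag: RatioFlag
    dup_class: DupClass


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float


# ---------------------------------------------------------------------------
# duplicate detection and tandem classification


@dataclass(frozen=True)
class DuplicateReport:
    groups: tuple[tuple[str, ...], ...]
    n_total: int

    @property
    def n_duplicates(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def duplicate_fraction_percent(self) -> float:
        """100 x duplicate genes / family size, rounded to two decimals."""
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_duplicates / self.n_total, 2)


def find_duplicates(
    proteins: dict[str, str],
    threshold: float = 0.9,
    scheme: ScoringScheme | None = None,
) -> DuplicateReport:
    """Cluster family proteins at ``threshold`` identity; groups of >= 2 are
    duplicate groups (members of one cluster are considered duplicated)."""
    if not proteins:
        raise ValueError("proteins must be non-empty")
    clusters: list[IdentityCluster] = greedy_identity_cluster(
        proteins, threshold, scheme
    )
    groups = tuple(
        tuple(sorted(c.member_ids)) for c in clusters if len(c.member_ids) >= 2
    )
    return DuplicateReport(groups=groups, n_total=len(proteins))


def classify_tandem(
    gene_a: str,
    gene_b: str,
    loci: dict[str, GeneLocus],
    max_gap: int = 200_000,
) -> DupClass:
    """Tandem iff same chromosome and |start_a - start_b| <= max_gap (inclusive)."""
    try:
        a = loci[gene_a]
    except KeyError:
        raise KeyError(f"no locus for gene {gene_a!r}") from None
    try:
        b = loci[gene_b]
    except KeyError:
        raise KeyError(f"no locus for gene {gene_b!r}") from None
    if a.chrom == b.chrom and abs(a.start - b.start) <= max_gap:
        return DupClass.TANDEM
    return DupClass.DISPERSED


# ---------------------------------------------------------------------------
# codon alignment and NG86


def _translate(cds: str, name: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} is not a multiple of 3")
    protein = []
    for k in range(0, len(cds), 3):
        codon = cds[k : k + 3]
        if codon in STOP_CODONS:
            if k + 3 < len(cds):
                raise ValueError(f"{name}: internal stop codon at nucleotide {k}")
            break
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"{name}: unknown codon {codon!r} at nucleotide {k}")
        protein.append(aa)
    return "".join(protein)


def align_codons(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str] | None = None,
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, str]]:
    """Back-translate a protein alignment to codon columns.

    Returns the list of (codon_a, codon_b) pairs for columns where both
    sequences have a residue; gapped columns are excluded from counting.
    When no protein alignment is supplied, one is computed by global
    alignment of the translations.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = _translate(cds_a, "cds_a")
    prot_b = _translate(cds_b, "cds_b")
    if protein_alignment is None:
        aln = global_align(prot_a, prot_b, scheme)
        aligned_a, aligned_b = aln.aligned_a, aln.aligned_b
    else:
        aligned_a, aligned_b = protein_alignment
        if aligned_a.replace("-", "") != prot_a or aligned_b.replace("-", "") != prot_b:
            raise ValueError("protein alignment does not match the translated CDS")
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for ra, rb in zip(aligned_a, aligned_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ra != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if rb != "-" else None
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
        if codon_a is not None and codon_b is not None:
            columns.append((codon_a, codon_b))
    return columns


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over all shortest
    mutational pathways between two codons, excluding pathways through stop
    codons (falling back to all pathways if every one is excluded)."""
    diff_pos = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    through_stops: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                # steps touching a stop codon cannot be classified
                hit_stop = True
            elif CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if hit_stop:
            through_stops.append((syn, nonsyn))
        else:
            valid.append((syn, nonsyn))
    pool = valid if valid else through_stops
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    if not valid:
        # stop-passing pathways drop the stop-creating step from the counts;
        # rescale so every pathway still explains len(diff_pos) differences
        total = sd + nd
        if total > 0:
            sd *= len(diff_pos) / total
            nd *= len(diff_pos) / total
    return sd, nd


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); raises ValueError when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise ValueError("Jukes-Cantor correction undefined for p >= 3/4")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def ng86_kaks(codon_alignment: list[tuple[str, str]]) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks over an aligned list of codon pairs."""
    if not codon_alignment:
        raise ValueError("codon alignment is empty")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for codon_a, codon_b in codon_alignment:
        for codon, name in ((codon_a, "a"), (codon_b, "b")):
            if len(codon) != 3 or any(c not in "ACGT" for c in codon):
                raise ValueError(f"malformed codon {codon!r} in sequence {name}")
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon!r} in counted columns")
        sa, _ = _codon_site_counts(codon_a)
        sb, _ = _codon_site_counts(codon_b)
        s_a += sa
        s_b += sb
        d_s, d_n = _pair_differences(codon_a, codon_b)
        sd += d_s
        nd += d_n
    n_codons = len(codon_alignment)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites

    def corrected(diffs: float, sites: float) -> float | None:
        if sites <= 0:
            return 0.0 if diffs == 0 else None
        p = diffs / sites
        try:
            return jukes_cantor(p)
        except ValueError:
            return None

    ka = corrected(nd, n_sites)
    ks = corrected(sd, s_sites)
    if ka is None or ks is None:
        return KaKsResult(
            math.nan if ka is None else ka,
            math.nan if ks is None else ks,
            math.nan,
            RatioFlag.UNDEFINED,
            sd, nd, s_sites, n_sites, n_codons,
        )
    if ka == 0.0 and ks == 0.0:
        return KaKsResult(0.0, 0.0, 0.0, RatioFlag.IDENTICAL, sd, nd, s_sites, n_sites, n_codons)
    if ks == 0.0:
        return KaKsResult(ka, 0.0, math.inf, RatioFlag.INFINITE, sd, nd, s_sites, n_sites, n_codons)
    return KaKsResult(ka, ks, ka / ks, RatioFlag.DEFINED, sd, nd, s_sites, n_sites, n_codons)


# ---------------------------------------------------------------------------
# summaries and ortholog pairing


@dataclass(frozen=True)
class SelectionSummary:
    n: int
    n_defined: int
    mean_ratio: float
    min_ratio: float
    max_ratio: float
    n_positive: int  # defined ratio > 1
    n_purifying: int  # defined ratio < 1
    n_flagged: int  # identical / infinite / undefined


def selection_summary(pairs: list[DuplicatePair]) -> SelectionSummary:
    """Summarize selection over duplicate pairs; flagged ratios are excluded
    from the mean/range and counted separately."""
    defined = [p.ratio for p in pairs if p.flag is RatioFlag.DEFINED]
    n_flagged = sum(1 for p in pairs if p.flag is not RatioFlag.DEFINED)
    if defined:
        mean = float(np.mean(defined))
        lo, hi = float(min(defined)), float(max(defined))
    else:
        mean = lo = hi = math.nan
    return SelectionSummary(
        n=len(pairs),
        n_defined=len(defined),
        mean_ratio=mean,
        min_ratio=lo,
        max_ratio=hi,
        n_positive=sum(1 for r in defined if r > 1.0),
        n_purifying=sum(1 for r in defined if r < 1.0),
        n_flagged=n_flagged,
    )


def analyze_duplicate_pairs(
    cds: dict[str, str],
    proteins: dict[str, str],
    loci: dict[str, GeneLocus],
    pairs: list[tuple[str, str]],
    max_gap: int = 200_000,
    scheme: ScoringScheme | None = None,
) -> list[DuplicatePair]:
    """Full per-pair analysis: identity, NG86 Ka/Ks and tandem class."""
    out: list[DuplicatePair] = []
    for a, b in pairs:
        ident = sequence_identity(proteins[a], proteins[b], scheme)
        res = ng86_kaks(align_codons(cds[a], cds[b], scheme=scheme))
        out.append(
            DuplicatePair(
                a, b, ident, res.ka, res.ks, res.ratio, res.flag,
                classify_tandem(a, b, loci, max_gap),
            )
        )
    return out


def rbh_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    scheme: ScoringScheme | None = None,
    min_score: float = 0.0,
) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes by local-alignment score.

    Ties for "best" are broken by partner id order, so the result is a
    deterministic matching: no gene appears in more than one pair.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    a_ids = sorted(proteome_a)
    b_ids = sorted(proteome_b)
    scores = np.zeros((len(a_ids), len(b_ids)))
    for i, a in enumerate(a_ids):
        for j, b in enumerate(b_ids):
            scores[i, j] = local_score(proteome_a[a], proteome_b[b], scheme)
    pairs: list[OrthologPair] = []
    best_b_for_a = scores.argmax(axis=1)  # argmax takes the first = lowest id
    best_a_for_b = scores.argmax(axis=0)
    for i, a in enumerate(a_ids):
        j = int(best_b_for_a[i])
        if scores[i, j] <= min_score:
            continue
        if int(best_a_for_b[j]) == i:
            pairs.append(OrthologPair(a, b_ids[j], float(scores[i, j])))
    return pairs
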