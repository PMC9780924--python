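"""Truth-tagged synthetic data generators.

Every generator is deterministic given its spec's integer seed.  Randomness
flows from that one seed through a *named* sub-stream per concern (sequence
content, genomic coordinates, counts, ...), so adding a new stream can never
perturb an existing one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from famforge._residues import AA_ORDER, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, aa_background
from famforge.evolution import GeneLocus
from famforge.phenotype import GradeTable

_STREAMS = {
    "family.sequence": 11,
    "family.layout": 12,
    "dups.sequence": 21,
    "dups.coordinates": 22,
    "expr.counts": 31,
    "grades.draw": 41,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child generator: stable under addition of new stream names."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


# ---------------------------------------------------------------------------
# family proteome


@dataclass(frozen=True)
class SynthFamilySpec:
    """Parameters of a planted-domain-family proteome."""

    n_background_proteins: int = 470
    n_family_members: int = 30
    domain_length: int = 48
    domain_identity_to_seed: float = 0.8
    cterm_domain_mix: dict[str, float] = field(
        default_factory=lambda: {"unknown": 1.0}
    )
    protein_length_range: tuple[int, int] = (200, 400)
    seed: int = 0
    # knobs beyond the minimal contract
    diverged_fraction: float = 0.0  # fraction of members diverged further
    diverged_identity: float = 0.35
    n_seed_sequences: int = 8
    seed_identity: float = 0.9
    cterm_domain_length: int = 60
    cterm_identity: float = 0.9

    def __post_init__(self) -> None:
        _require(self.n_background_proteins >= 0, "n_background_proteins must be >= 0")
        _require(self.n_family_members >= 0, "n_family_members must be >= 0")
        _require(self.domain_length >= 10, "domain_length must be >= 10")
        _require(
            0.0 <= self.domain_identity_to_seed <= 1.0,
            "domain_identity_to_seed must lie in [0, 1]",
        )
        _require(
            0.0 <= self.diverged_fraction <= 1.0,
            "diverged_fraction must lie in [0, 1]",
        )
        _require(
            abs(sum(self.cterm_domain_mix.values()) - 1.0) <= 1e-9,
            "cterm_domain_mix fractions must sum to 1",
        )
        _require(
            all(f >= 0 for f in self.cterm_domain_mix.values()),
            "cterm_domain_mix fractions must be >= 0",
        )
        lo, hi = self.protein_length_range
        min_needed = self.domain_length + self.cterm_domain_length + 20
        _require(
            lo >= min_needed and hi >= lo,
            f"protein_length_range must be ordered with minimum >= {min_needed}",
        )


@dataclass
class FamilyProteome:
    proteome: dict[str, str]
    seed_msa: list[str]
    domain_consensus: str
    cterm_library: dict[str, list[str]]  # domain name -> seed MSA rows
    truth: pd.DataFrame


def _random_protein(rng: np.random.Generator, length: int, background: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=background)
    return "".join(AA_ORDER[i] for i in idx)


def _mutate_protein(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute each position with probability 1 - identity, always to a
    different residue, so expected identity to ``seq`` equals ``identity``."""
    out = []
    for ch in seq:
        if rng.random() < 1.0 - identity:
            choices = AA_ORDER.replace(ch, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(ch)
    return "".join(out)


def _allocate_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over named fractions."""
    names = sorted(fractions)
    floors = {k: int(math.floor(fractions[k] * n)) for k in names}
    leftover = n - sum(floors.values())
    remainders = sorted(
        names, key=lambda k: (-(fractions[k] * n - floors[k]), k)
    )
    for k in remainders[:leftover]:
        floors[k] += 1
    return floors


def make_family_proteome(spec: SynthFamilySpec) -> FamilyProteome:
    """Generate a proteome with a planted domain family and truth labels.

    Family members embed a mutated copy of the seed-domain consensus at a
    recorded offset (diverged to approximately
    ``spec.domain_identity_to_seed``); members assigned a named C-terminal
    domain embed a mutated copy of that domain's consensus downstream of the
    family domain.  Background proteins are i.i.d. draws from the fixed
    amino-acid background distribution.
    """
    rng = _stream(spec.seed, "family.sequence")
    layout_rng = _stream(spec.seed, "family.layout")
    background = aa_background()

    consensus = _random_protein(rng, spec.domain_length, background)
    seed_msa = [
        _mutate_protein(rng, consensus, spec.seed_identity)
        for _ in range(spec.n_seed_sequences)
    ]

    cterm_names = sorted(n for n in spec.cterm_domain_mix if n != "unknown")
    cterm_consensus = {
        name: _random_protein(rng, spec.cterm_domain_length, background)
        for name in cterm_names
    }
    cterm_library = {
        name: [
            _mutate_protein(rng, cons, spec.cterm_identity) for _ in range(5)
        ]
        for name, cons in cterm_consensus.items()
    }

    counts = _allocate_counts(spec.cterm_domain_mix, spec.n_family_members)
    member_cterm: list[str] = []
    for name in sorted(counts):
        member_cterm.extend([name] * counts[name])

    n_diverged = int(math.floor(spec.diverged_fraction * spec.n_family_members + 0.5))

    proteome: dict[str, str] = {}
    rows: list[dict] = []
    lo, hi = spec.protein_length_range
    width = max(4, len(str(max(spec.n_family_members, spec.n_background_proteins))))
    for i in range(spec.n_family_members):
        pid = f"FAM{i + 1:0{width}d}"
        diverged = i >= spec.n_family_members - n_diverged
        identity = spec.diverged_identity if diverged else spec.domain_identity_to_seed
        total_len = int(layout_rng.integers(lo, hi + 1))
        cterm_name = member_cterm[i]
        domain = _mutate_protein(rng, consensus, identity)
        cterm_seq = (
            _mutate_protein(rng, cterm_consensus[cterm_name], spec.cterm_identity)
            if cterm_name != "unknown"
            else ""
        )
        flank_total = total_len - len(domain) - len(cterm_seq)
        n_flank = int(layout_rng.integers(5, max(6, flank_total // 3)))
        linker_len = max(5, (flank_total - n_flank) // 2)
        c_flank = flank_total - n_flank - linker_len
        seq = (
            _random_protein(rng, n_flank, background)
            + domain
            + _random_protein(rng, linker_len, background)
            + cterm_seq
            + _random_protein(rng, c_flank, background)
        )
        domain_start = n_flank
        cterm_start = n_flank + len(domain) + linker_len
        proteome[pid] = seq
        rows.append(
            {
                "protein_id": pid,
                "is_family": True,
                "domain_start": domain_start,
                "domain_end": domain_start + len(domain),
                "domain_identity": identity,
                "diverged": diverged,
                "cterm_domain": cterm_name,
                "cterm_start": cterm_start if cterm_seq else -1,
                "cterm_end": cterm_start + len(cterm_seq) if cterm_seq else -1,
                "architecture": "FBXU" if cterm_name == "unknown" else f"F-box+{cterm_name}",
            }
        )
    for i in range(spec.n_background_proteins):
        pid = f"BG{i + 1:0{width}d}"
        total_len = int(layout_rng.integers(lo, hi + 1))
        proteome[pid] = _random_protein(rng, total_len, background)
        rows.append(
            {
                "protein_id": pid,
                "is_family": False,
                "domain_start": -1,
                "domain_end": -1,
                "domain_identity": float("nan"),
                "diverged": False,
                "cterm_domain": "",
                "cterm_start": -1,
                "cterm_end": -1,
                "architecture": "",
            }
        )
    truth = pd.DataFrame(rows).set_index("protein_id", drop=False)
    return FamilyProteome(proteome, seed_msa, consensus, cterm_library, truth)


# ---------------------------------------------------------------------------
# duplicate gene pairs


@dataclass(frozen=True)
class SynthDupSpec:
    """Parameters of a duplicate-pair CDS/coordinate set."""

    n_pairs: int = 50
    omega: float = 1.0  # target dN/dS of the accept/reject process
    target_identity: float = 0.85  # nucleotide-level identity of a pair
    tandem_fraction: float = 0.6
    tandem_max_gap: int = 200_000
    n_chromosomes: int = 12
    seed: int = 0
    n_codons: int = 300

    def __post_init__(self) -> None:
        _require(self.n_pairs >= 0, "n_pairs must be >= 0")
        _require(self.omega > 0, "omega must be > 0")
        _require(
            0.0 <= self.tandem_fraction <= 1.0, "tandem_fraction must lie in [0, 1]"
        )
        _require(0.0 < self.target_identity <= 1.0, "target_identity must lie in (0, 1]")
        _require(self.tandem_max_gap > 0, "tandem_max_gap must be > 0")
        _require(self.n_chromosomes >= 1, "n_chromosomes must be >= 1")
        _require(self.n_codons >= 10, "n_codons must be >= 10")


@dataclass
class DuplicateSet:
    cds: dict[str, str]
    loci: dict[str, GeneLocus]
    truth: pd.DataFrame

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(r.gene_a, r.gene_b) for r in self.truth.itertuples()]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _evolve_cds(
    rng: np.random.Generator, cds: str, n_accepted: int, omega: float
) -> str:
    """Accept/reject point-mutation walk: nonsynonymous changes accepted
    with probability ``omega`` *relative* to synonymous ones (for omega > 1
    the synonymous acceptance is scaled down instead, keeping the ratio);
    proposals creating stop codons are rejected outright."""
    seq = list(cds)
    accepted = 0
    p_nonsyn = min(omega, 1.0)
    p_syn = min(1.0, 1.0 / omega)
    while accepted < n_accepted:
        pos = int(rng.integers(len(seq)))
        current = seq[pos]
        base = "ACGT".replace(current, "")[rng.integers(3)]
        c0 = 3 * (pos // 3)
        codon = "".join(seq[c0 : c0 + 3])
        mutant = codon[: pos - c0] + base + codon[pos - c0 + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[codon] == CODON_TO_AA[mutant]
        p_accept = p_syn if synonymous else p_nonsyn
        if rng.random() < p_accept:
            seq[pos] = base
            accepted += 1
    return "".join(seq)


def make_duplicate_set(spec: SynthDupSpec) -> DuplicateSet:
    """Generate CDS pairs evolved at a known omega with planted coordinates.

    Exactly round-half-up(tandem_fraction x n_pairs) pairs are placed within
    ``tandem_max_gap`` of each other on one chromosome (the first such pair
    sits exactly at the boundary distance); the rest go to different
    chromosomes, or beyond the gap when only one chromosome exists.
    """
    seq_rng = _stream(spec.seed, "dups.sequence")
    coord_rng = _stream(spec.seed, "dups.coordinates")

    n_tandem = int(math.floor(spec.tandem_fraction * spec.n_pairs + 0.5))
    gene_len = 3 * spec.n_codons
    mutations_total = int(round((1.0 - spec.target_identity) * gene_len))

    cds: dict[str, str] = {}
    loci: dict[str, GeneLocus] = {}
    rows: list[dict] = []
    next_free = {c: 10_000 for c in range(spec.n_chromosomes)}

    def place(chrom: int, min_start: int) -> int:
        start = max(next_free[chrom], min_start)
        start += int(coord_rng.integers(0, 5_000))
        next_free[chrom] = start + gene_len + 1_000
        return start

    for k in range(spec.n_pairs):
        ancestor = _random_cds(seq_rng, spec.n_codons)
        m_a = mutations_total // 2
        m_b = mutations_total - m_a
        seq_a = _evolve_cds(seq_rng, ancestor, m_a, spec.omega)
        seq_b = _evolve_cds(seq_rng, ancestor, m_b, spec.omega)
        gid_a = f"DUP{k + 1:04d}A"
        gid_b = f"DUP{k + 1:04d}B"
        cds[gid_a] = seq_a
        cds[gid_b] = seq_b

        tandem = k < n_tandem
        if tandem:
            chrom = k % spec.n_chromosomes
            start_a = place(chrom, 0)
            if k == 0:
                gap = spec.tandem_max_gap  # exact boundary case
            else:
                gap = int(coord_rng.integers(gene_len + 1_000, spec.tandem_max_gap + 1))
            start_b = start_a + gap
            next_free[chrom] = max(next_free[chrom], start_b + gene_len + 1_000)
            chrom_a = chrom_b = chrom
        else:
            chrom_a = k % spec.n_chromosomes
            if spec.n_chromosomes > 1:
                chrom_b = (chrom_a + 1) % spec.n_chromosomes
                start_a = place(chrom_a, 0)
                start_b = place(chrom_b, 0)
            else:
                chrom_b = chrom_a
                start_a = place(chrom_a, 0)
                start_b = place(chrom_a, start_a + spec.tandem_max_gap + gene_len + 1)
        loci[gid_a] = GeneLocus(gid_a, f"chr{chrom_a + 1:02d}", start_a, start_a + gene_len)
        loci[gid_b] = GeneLocus(gid_b, f"chr{chrom_b + 1:02d}", start_b, start_b + gene_len)
        rows.append(
            {
                "pair_id": f"PAIR{k + 1:04d}",
                "gene_a": gid_a,
                "gene_b": gid_b,
                "dup_class": "tandem" if tandem else "dispersed",
                "omega": spec.omega,
                "n_mutations": mutations_total,
            }
        )
    truth = pd.DataFrame(rows)
    return DuplicateSet(cds, loci, truth)


# ---------------------------------------------------------------------------
# expression counts


@dataclass(frozen=True)
class SynthExprSpec:
    """Parameters of a planted-cluster negative-binomial count matrix."""

    n_genes: int = 100
    n_samples: int = 12
    k_clusters: int = 4
    dispersion: float = 0.05  # NB overdispersion alpha: var = mu + alpha mu^2
    size_factors: tuple[float, ...] | None = None
    seed: int = 0
    mean_low: float = 20.0
    mean_high: float = 500.0

    def __post_init__(self) -> None:
        _require(self.n_genes >= 1, "n_genes must be >= 1")
        _require(self.n_samples >= 2, "n_samples must be >= 2")
        _require(
            1 <= self.k_clusters <= self.n_genes,
            "k_clusters must lie in [1, n_genes]",
        )
        _require(self.dispersion >= 0, "dispersion must be >= 0")
        if self.size_factors is not None:
            _require(
                len(self.size_factors) == self.n_samples,
                "size_factors must have one entry per sample",
            )
            _require(
                all(s > 0 for s in self.size_factors),
                "size_factors must be > 0",
            )


@dataclass
class ExpressionTruth:
    clusters: pd.Series  # gene id -> 1-based cluster id
    archetypes: pd.DataFrame  # cluster x sample mean profiles
    size_factors: np.ndarray


def make_expression_matrix(spec: SynthExprSpec) -> tuple[pd.DataFrame, ExpressionTruth]:
    """Planted-cluster NB counts: mean = archetype x size factor.

    Cluster archetypes are block profiles (each cluster peaks in its own
    subset of samples), genes are assigned round-robin, and counts are drawn
    NB(mu, dispersion).  ``dispersion = 0`` is the noise-free limit: counts
    equal the rounded means exactly.
    """
    rng = _stream(spec.seed, "expr.counts")
    size_factors = (
        np.ones(spec.n_samples)
        if spec.size_factors is None
        else np.asarray(spec.size_factors, dtype=float)
    )
    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(spec.n_samples)]

    archetypes = np.full((spec.k_clusters, spec.n_samples), spec.mean_low)
    for j in range(spec.k_clusters):
        peak = np.arange(spec.n_samples) % spec.k_clusters == j
        archetypes[j, peak] = spec.mean_high

    cluster_of = np.arange(spec.n_genes) % spec.k_clusters
    mu = archetypes[cluster_of] * size_factors[None, :]
    if spec.dispersion == 0.0:
        counts = np.rint(mu).astype(np.int64)
    else:
        n_param = 1.0 / spec.dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    frame = pd.DataFrame(counts, index=genes, columns=samples)
    truth = ExpressionTruth(
        clusters=pd.Series(cluster_of + 1, index=genes, name="cluster"),
        archetypes=pd.DataFrame(archetypes, index=np.arange(1, spec.k_clusters + 1), columns=samples),
        size_factors=size_factors,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# phenotype grades


def make_grade_table(
    n_plants: int,
    grade_probs: tuple[float, float, float, float, float],
    seed: int,
    treatment: str = "synthetic",
    day: int = 0,
) -> GradeTable:
    """Multinomial per-plant grades over the 0-4 scale; deterministic."""
    _require(n_plants >= 1, "n_plants must be >= 1")
    probs = np.asarray(grade_probs, dtype=float)
    _require(probs.shape == (5,), "grade_probs must have five entries (grades 0..4)")
    _require(bool(np.all(probs >= 0)), "grade_probs must be >= 0")
    _require(abs(probs.sum() - 1.0) <= 1e-9, "grade_probs must sum to 1")
    rng = _stream(seed, "grades.draw")
    counts = rng.multinomial(n_plants, probs)
    grades = tuple(g for g in range(5) for _ in range(int(counts[g])))
    return GradeTable(treatment=treatment, grades=grades, day=day)
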