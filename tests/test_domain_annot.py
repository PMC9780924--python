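from __future__ import annotations

import numpy as np
import pytest

from famforge import domain_annot as da
from famforge import synthetic_data as sd
from famforge.domain_annot import (
    DomainLibrary,
    Msa,
    annotate_cterm_domains,
    conservation_percent,
    conserved_sites,
    cross_species_conserved_overlap,
    domain_census,
    progressive_align,
    sum_of_pairs,
)
from famforge.profile_search.search import SearchHit

from .conftest import random_protein
from .oracles import msa3_optimum


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        msa = progressive_align({f"s{i}": "ACDEFGHIKL" for i in range(4)})
        assert all(r == "ACDEFGHIKL" for r in msa.rows)

    def test_single_sequence_passthrough(self):
        msa = progressive_align({"only": "ACDEFG"})
        assert msa.rows == ["ACDEFG"]

    def test_two_sequences_match_pairwise(self):
        from famforge.profile_search import global_align

        a, b = "ACDEFGHIKL", "ACDEGHIKL"
        msa = progressive_align({"a": a, "b": b})
        # both rows ungap back to their inputs and have one aligned column set
        idx = {sid: i for i, sid in enumerate(msa.ids)}
        assert msa.rows[idx["a"]].replace("-", "") == a
        assert msa.rows[idx["b"]].replace("-", "") == b
        aln = global_align(a, b)
        assert len(msa.rows[0]) == len(aln.aligned_a)

    def test_three_way_near_optimal(self, rng):
        triples = [
            ("ACDEFGHIKL", "ACDEFGHIKL", "ACDEGHIKL"),
            ("WKLNPEQDST", "WKLNPEQDT", "WKLNPQDST"),
            ("MKVLITAGPT", "MKVLTAGPT", "MKVLITAGPA"),
        ]
        for s1, s2, s3 in triples:
            msa = progressive_align({"a": s1, "b": s2, "c": s3})
            achieved = sum_of_pairs(msa)
            optimum = msa3_optimum(s1, s2, s3)
            assert optimum > 0
            assert achieved >= 0.95 * optimum

    def test_ungap_roundtrip_property(self, rng):
        seqs = {f"s{i}": random_protein(rng, int(rng.integers(10, 25))) for i in range(5)}
        msa = progressive_align(seqs)
        for sid, row in zip(msa.ids, msa.rows):
            assert row.replace("-", "") == seqs[sid]


class TestConservedSites:
    def test_paper_style_percent_arithmetic(self):
        assert conservation_percent(293, 389) == 75.32
        assert conservation_percent(270, 389) == 69.41
        assert conservation_percent(265, 389) == 68.12

    def test_column_from_large_msa(self):
        rows = ["L" for _ in range(293)] + ["V" for _ in range(80)] + ["-"] * 16
        msa = Msa([f"s{i}" for i in range(389)], rows)
        sites = conserved_sites(msa)
        assert len(sites) == 1
        site = sites[0]
        assert site.top_residue == "L" and site.top_count == 293
        assert site.second_residue == "V" and site.second_count == 80
        assert site.percent == 75.32  # denominator is all 389 rows

    def test_pure_column(self):
        msa = Msa([f"s{i}" for i in range(100)], ["L"] * 100)
        sites = conserved_sites(msa)
        assert sites[0].top_count == 100
        assert sites[0].second_residue is None
        assert sites[0].percent == 100.0

    def test_direct_tally_with_tie_break(self):
        rows = ["L"] * 5 + ["P"] * 3 + ["K"] * 2
        msa = Msa([f"s{i}" for i in range(10)], rows)
        site = conserved_sites(msa)[0]
        assert (site.top_residue, site.top_count) == ("L", 5)
        assert (site.second_residue, site.second_count) == ("P", 3)
        assert site.percent == 50.0

    def test_alphabetical_tie_break(self):
        rows = ["W"] * 3 + ["A"] * 3 + ["C"] * 3
        msa = Msa([f"s{i}" for i in range(9)], rows)
        site = conserved_sites(msa)[0]
        assert site.top_residue == "A"
        assert site.second_residue == "C"

    def test_top2_agrees_with_full_sort_oracle(self, rng):
        from collections import Counter

        rows = [random_protein(rng, 12) for _ in range(30)]
        msa = Msa([f"s{i}" for i in range(30)], rows)
        for site in conserved_sites(msa):
            column = [r[site.column - 1] for r in rows]
            ranked = sorted(Counter(column).items(), key=lambda kv: (-kv[1], kv[0]))
            assert (site.top_residue, site.top_count) == ranked[0]
            assert site.percent == round(100 * ranked[0][1] / 30, 2)

    def test_min_fraction_filter(self):
        rows = ["L"] * 9 + ["V"]
        msa = Msa([f"s{i}" for i in range(10)], rows)
        assert len(conserved_sites(msa, min_fraction=0.95)) == 0
        assert len(conserved_sites(msa, min_fraction=0.9)) == 1

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError):
            conserved_sites(Msa([], []))


class TestCrossSpeciesOverlap:
    def _sites(self, spec: dict[int, tuple[str, str]]):
        return [
            da.ConservedSite(col, top, 10, second, 5, 50.0)
            for col, (top, second) in spec.items()
        ]

    def test_identical_lists_full_overlap(self):
        sites = {1: ("L", "V"), 2: ("P", "A")}
        species = {s: self._sites(sites) for s in "ABCD"}
        assert cross_species_conserved_overlap(species) == 1.0

    def test_disjoint_residues_zero(self):
        species = {
            "A": self._sites({1: ("L", "V")}),
            "B": self._sites({1: ("P", "K")}),
        }
        assert cross_species_conserved_overlap(species) == 0.0

    def test_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert cross_species_conserved_overlap({"A": [], "B": []}) == 0.0

    def test_simulated_related_species_share_majority(self):
        rng = np.random.default_rng(5)
        ancestor = random_protein(rng, 40)

        def species_msa(seed):
            r = np.random.default_rng(seed)
            rows = []
            for _ in range(30):
                chars = list(ancestor)
                for p in range(40):
                    if r.random() < 0.1:
                        chars[p] = "ACDEFGHIKLMNPQRSTVWY"[r.integers(20)]
                rows.append("".join(chars))
            return Msa([f"s{i}" for i in range(30)], rows)

        per_species = {
            f"sp{k}": conserved_sites(species_msa(100 + k), min_fraction=0.5)
            for k in range(4)
        }
        assert cross_species_conserved_overlap(per_species) >= 0.5


@pytest.fixture(scope="module")
def setup(small_family):
    library = DomainLibrary.from_seed_msas(
        small_family.cterm_library, list(small_family.proteome.values())
    )
    return small_family, library


class TestCtermAnnotation:
    def test_planted_architectures_recovered(self, setup):
        family, library = setup
        truth = family.truth
        correct = 0
        members = truth[truth.is_family]
        for row in members.itertuples():
            fbox = SearchHit(
                row.protein_id, int(row.domain_start), int(row.domain_end), 50.0, 1e-6
            )
            ann = annotate_cterm_domains(
                row.protein_id, family.proteome[row.protein_id], fbox, library
            )
            if ann.architecture == row.architecture:
                correct += 1
        assert correct >= 0.9 * len(members)

    def test_random_cterm_is_fbxu(self, setup, rng):
        _family, library = setup
        seq = random_protein(rng, 300)
        fbox = SearchHit("p", 10, 58, 40.0, 1e-5)
        ann = annotate_cterm_domains("p", seq, fbox, library)
        assert ann.architecture == "FBXU"
        assert ann.domains == ()

    def test_two_domains_reported_n_to_c(self, setup, rng):
        family, library = setup
        kelch = family.cterm_library["Kelch"][0]
        lrr = family.cterm_library["LRR"][0]
        seq = random_protein(rng, 50) + kelch + random_protein(rng, 10) + lrr
        fbox = SearchHit("p", 0, 50, 40.0, 1e-5)
        ann = annotate_cterm_domains("p", seq, fbox, library)
        assert [h.name for h in ann.domains] == ["Kelch", "LRR"]
        assert ann.architecture == "F-box+Kelch+LRR"
        assert ann.domains[0].end <= ann.domains[1].start

    def test_hit_outside_protein_rejected(self, setup):
        _family, library = setup
        with pytest.raises(ValueError, match="outside"):
            annotate_cterm_domains(
                "p", "ACDEFGHIKL", SearchHit("p", 2, 50, 10.0, 1e-3), library
            )

    def test_fbxu_iff_no_surviving_hits(self, setup):
        family, library = setup
        truth = family.truth
        for row in truth[truth.is_family].itertuples():
            fbox = SearchHit(
                row.protein_id, int(row.domain_start), int(row.domain_end), 50.0, 1e-6
            )
            ann = annotate_cterm_domains(
                row.protein_id, family.proteome[row.protein_id], fbox, library
            )
            assert (ann.architecture == "FBXU") == (len(ann.domains) == 0)


class TestDomainCensus:
    def test_all_fbxu(self):
        anns = [da.DomainAnnotation(f"p{i}", (), "FBXU") for i in range(7)]
        census = domain_census({"spA": anns})
        assert census.loc["FBXU", "spA"] == 7

    def test_planted_mix_counts(self, small_family):
        truth = small_family.truth
        anns = []
        for row in truth[truth.is_family].itertuples():
            if row.cterm_domain == "unknown":
                anns.append(da.DomainAnnotation(row.protein_id, (), "FBXU"))
            else:
                hit = da.DomainHit(row.cterm_domain, 0, 10, 10.0, 1e-9)
                anns.append(
                    da.DomainAnnotation(row.protein_id, (hit,), f"F-box+{row.cterm_domain}")
                )
        census = domain_census({"syn": anns})
        mix = truth[truth.is_family].cterm_domain.value_counts()
        assert census.loc["Kelch", "syn"] == mix["Kelch"]
        assert census.loc["LRR", "syn"] == mix["LRR"]
        assert census.loc["FBXU", "syn"] == mix["unknown"]

    def test_multi_domain_counted_per_type(self):
        hits = (
            da.DomainHit("Kelch", 0, 10, 5.0, 1e-9),
            da.DomainHit("PAS", 20, 30, 5.0, 1e-9),
        )
        anns = [da.DomainAnnotation("p1", hits, "F-box+Kelch+PAS")]
        census = domain_census({"sp": anns})
        assert census["sp"].sum() == 2  # one protein, two domain types

    def test_empty_input_empty_table(self):
        census = domain_census({})
        assert census.empty


class TestMsaInvariants:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            Msa(["a", "b"], ["ACD", "AC"])

    def test_ungapped_accessor(self):
        msa = Msa(["a"], ["A-C-D"])
        assert msa.ungapped(0) == "ACD"
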