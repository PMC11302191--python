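import numpy as np
import pytest

from offsieve import (
    Genome,
    GuideRNA,
    SearchParams,
    enumerate_sites,
    match_pam,
    reverse_complement,
    score_alignment,
)
from offsieve.search import (
    EmptyGenomeError,
    SitesParseError,
    read_sites,
    write_sites,
)

from conftest import random_seq
from oracles import brute_force_sites


def site_keys(sites):
    return {
        (s.locus.chrom, s.locus.strand, s.locus.start, s.bulge_type, s.mismatches, s.bulge_offset)
        for s in sites
    }


class TestMatchPam:
    @pytest.mark.parametrize(
        "seq,pat,expected",
        [
            ("AGG", "NGG", True),
            ("AGA", "NGG", False),
            ("NGG", "NGG", False),  # genomic N matches no pattern character
            ("TGA", "NGA", True),
            ("CT", "YY", True),
        ],
    )
    def test_examples(self, seq, pat, expected):
        assert match_pam(seq, pat) is expected

    def test_errors(self):
        with pytest.raises(ValueError):
            match_pam("AG", "NGG")
        with pytest.raises(ValueError):
            match_pam("AGG", "NGQ")


class TestScoreAlignment:
    def test_identity_and_substitutions(self):
        g = "ACGTACGTACGTACGTACGT"
        assert score_alignment(g, g) == 0
        assert score_alignment("AAAA", "AATA") == 1

    def test_dna_bulge_not_counted_as_mismatch(self):
        # guide AA-AA aligned to genomic AACAA: gap column is free
        assert score_alignment("AAAA", "AACAA", "dna", 2) == 0

    def test_rna_bulge(self):
        # guide AACAA with base C unpaired vs genomic AAAA
        assert score_alignment("AACAA", "AAAA", "rna", 2) == 0

    def test_genomic_n_counts_as_mismatch(self):
        assert score_alignment("AAAA", "AANA") == 1

    @pytest.mark.parametrize("btype,site,offset", [("dna", "AACAA", 0), ("dna", "AACAA", 4),
                                                   ("rna", "AAA", 0), ("rna", "AAA", 3)])
    def test_terminal_bulge_rejected(self, btype, site, offset):
        with pytest.raises(ValueError):
            score_alignment("AAAA", site, btype, offset)

    def test_length_consistency(self):
        with pytest.raises(ValueError):
            score_alignment("AAAA", "AAA")
        with pytest.raises(ValueError):
            score_alignment("AAAA", "AAAA", "dna", 2)

    def test_dna_bulge_matches_bruteforce_minimum(self):
        # brute force over all single-gap placements confirms the minimum
        guide, site = "AAAA", "AACAA"
        mins = min(score_alignment(guide, site, "dna", b) for b in range(1, 4))
        assert mins == 0


class TestEnumerateSites:
    def test_exact_planted_match(self, rng):
        guide = GuideRNA("g", random_seq(rng, 20))
        bg = random_seq(rng, 400)
        g = Genome({"chr1": bg[:200] + guide.protospacer + "AGG" + bg[200:]})
        sites = enumerate_sites(g, guide, SearchParams(0, 0, 0))
        assert len(sites) == 1
        s = sites[0]
        assert (s.locus.start, s.locus.strand, s.mismatches, s.bulge_type) == (200, "+", 0, "none")
        assert s.pam_seq == "AGG"

    def test_minus_strand_planted(self, rng):
        guide = GuideRNA("g", random_seq(rng, 20))
        bg = random_seq(rng, 400)
        cassette = reverse_complement(guide.protospacer + "TGG")
        g = Genome({"chr1": bg[:150] + cassette + bg[150:]})
        sites = enumerate_sites(g, guide, SearchParams(0, 0, 0))
        assert len(sites) == 1
        assert sites[0].locus.strand == "-"
        assert sites[0].pam_seq == "TGG"

    def test_planting_k_exact_matches_yields_k_sites(self, rng):
        guide = GuideRNA("g", random_seq(rng, 18))
        chunks = [random_seq(rng, 120) for _ in range(4)]
        seq = chunks[0]
        for c in chunks[1:]:
            seq += guide.protospacer + "CGG" + c
        sites = enumerate_sites(Genome({"c": seq}), guide, SearchParams(0, 0, 0))
        exact = [s for s in sites if s.mismatches == 0]
        assert len(exact) == 3

    def test_empty_genome_errors(self, toy_guide):
        with pytest.raises(EmptyGenomeError):
            enumerate_sites(Genome({}), toy_guide)

    def test_guide_longer_than_chromosome_is_empty(self):
        g = Genome({"c": "ACGTACGT"})
        guide = GuideRNA("g", "ACGTACGTACGTACGTACGT")
        assert enumerate_sites(g, guide, SearchParams(2, 1, 1)) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_genomes(self, seed):
        rng = np.random.default_rng(seed + 1000)
        L = int(rng.integers(8, 15))
        n = int(rng.integers(300, 2000))
        seq = random_seq(rng, n)
        if seed % 4 == 0:  # assembly gap: N run must spawn no sites
            i = int(rng.integers(0, n - 10))
            seq = seq[:i] + "N" * 8 + seq[i + 8 :]
        guide = GuideRNA("g", random_seq(rng, L))
        mm = int(rng.integers(0, 4))
        db, rb = int(rng.integers(0, 2)), int(rng.integers(0, 2))
        got = site_keys(enumerate_sites(Genome({"c": seq}), guide, SearchParams(mm, db, rb)))
        expected = brute_force_sites({"c": seq}, guide.protospacer, "NGG", mm, db, rb)
        assert got == expected

    def test_mismatch_monotonicity(self, rng, toy_genome, toy_guide):
        loose = site_keys(enumerate_sites(toy_genome, toy_guide, SearchParams(3, 1, 1)))
        for m in range(3):
            strict = enumerate_sites(toy_genome, toy_guide, SearchParams(m, 1, 1))
            assert site_keys(strict) <= loose

    def test_bulges_disabled_subset_of_enabled(self, toy_genome, toy_guide):
        no_bulge = enumerate_sites(toy_genome, toy_guide, SearchParams(3, 0, 0))
        with_bulge = enumerate_sites(toy_genome, toy_guide, SearchParams(3, 1, 1))
        assert site_keys(no_bulge) <= site_keys(with_bulge)

    def test_strand_symmetry(self, rng):
        seq = random_seq(rng, 1200)
        guide = GuideRNA("g", random_seq(rng, 10))
        params = SearchParams(2, 1, 1)
        fwd = enumerate_sites(Genome({"c": seq}), guide, params)
        rev = enumerate_sites(Genome({"c": reverse_complement(seq)}), guide, params)
        n = len(seq)
        flipped = {
            (s.locus.chrom, "-" if s.locus.strand == "+" else "+",
             n - s.locus.end, s.bulge_type, s.mismatches, s.bulge_offset)
            for s in rev
        }
        assert site_keys(fwd) == flipped

    def test_reported_sites_rescore_and_pam_recheck(self, rng):
        from offsieve import fetch, match_pam

        seq = random_seq(rng, 2500)
        guide = GuideRNA("g", random_seq(rng, 11))
        sites = enumerate_sites(Genome({"c": seq}), guide, SearchParams(3, 1, 1))
        assert sites, "fixture produced no sites; enlarge genome"
        g = Genome({"c": seq})
        for s in sites:
            refetched = fetch(g, s.locus)
            assert score_alignment(guide.protospacer, refetched, s.bulge_type, s.bulge_offset) == s.mismatches
            assert match_pam(fetch(g, s.pam_locus), guide.pam)

    def test_output_sorted(self, toy_genome, toy_guide):
        sites = enumerate_sites(toy_genome, toy_guide, SearchParams(3, 1, 1))
        keys = [(s.locus.chrom, s.locus.start, s.locus.strand) for s in sites]
        assert keys == sorted(keys)


class TestSitesTsv:
    def test_roundtrip(self, tmp_path, toy_genome, toy_guide):
        sites = enumerate_sites(toy_genome, toy_guide, SearchParams(3, 1, 1))[:5]
        p = tmp_path / "sites.tsv"
        write_sites(sites, p)
        assert read_sites(p) == sites

    def test_empty_roundtrip(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_sites([], p)
        assert read_sites(p) == []

    def test_malformed_names_line_number(self, tmp_path, rng):
        guide = GuideRNA("g", random_seq(rng, 15))
        cassette = guide.protospacer + "TGG"
        seq = random_seq(rng, 100) + cassette + random_seq(rng, 100) + cassette + random_seq(rng, 50)
        sites = enumerate_sites(Genome({"c": seq}), guide, SearchParams(0, 0, 0))
        assert len(sites) >= 2
        p = tmp_path / "bad.tsv"
        write_sites(sites, p)
        lines = p.read_text().splitlines()
        lines[2] = lines[2].rsplit("\t", 1)[0]  # drop a column on data line 2
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(SitesParseError, match="line 3"):
            read_sites(p)


def test_guide_validation():
    with pytest.raises(ValueError):
        GuideRNA("g", "")
    with pytest.raises(ValueError):
        GuideRNA("g", "ACGN")
    with pytest.raises(ValueError):
        GuideRNA("g", "ACGT", pam="")
    with pytest.raises(ValueError):
        SearchParams(max_dna_bulge=2)
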