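import numpy as np
import pytest

from offsieve import (
    Genome,
    GenomicInterval,
    GuideRNA,
    SearchParams,
    VariantRecord,
    WindowParams,
    annotate_known_variation,
    assign_verdicts,
    classify_validation,
    enumerate_sites,
    intersect_sites,
    subtract_parental,
    summarize_frequencies,
    verify_pam_identity,
)
from offsieve.intersect import OffTargetCall, UnsortedSitesError, format_frequency, _gap
from offsieve.search import CandidateSite
from offsieve.fixtures import validation_worked_examples

from conftest import random_seq


def make_site(chrom, start0, end0, strand="+", guide_name="g", mm=0):
    """A site whose protospacer+PAM footprint is exactly [start0, end0)."""
    if strand == "+":
        locus = GenomicInterval(chrom, start0, end0 - 3, strand)
        pam = GenomicInterval(chrom, end0 - 3, end0, strand)
    else:
        locus = GenomicInterval(chrom, start0 + 3, end0, strand)
        pam = GenomicInterval(chrom, start0, start0 + 3, strand)
    L = len(locus)
    return CandidateSite(guide_name, locus, pam, mm, "none", None, "A" * L, "A" * L, "AGG")


def indel(chrom="chr1", pos=1000, ref="GA", alt="G"):
    return VariantRecord(chrom, pos, ref, (alt,), filter_status=())


class TestIntersect:
    def test_within_pad_distance(self):
        site = make_site("chr1", 1039, 1062)
        calls = intersect_sites([indel(pos=1000, ref="G", alt="GA")], [site])
        assert len(calls) == 1
        assert calls[0].distance_bp == 39

    def test_beyond_pad_not_paired(self):
        site = make_site("chr1", 1060, 1083)
        assert intersect_sites([indel(pos=1000, ref="G", alt="GA")], [site]) == []

    def test_zero_pad_overlap_only(self):
        site = make_site("chr1", 990, 1013)
        calls = intersect_sites([indel(pos=1000)], [site], WindowParams(0))
        assert len(calls) == 1 and calls[0].distance_bp == 0
        assert intersect_sites([indel(pos=960)], [site], WindowParams(0)) == []

    def test_variant_overlapping_k_sites_yields_k_calls(self):
        sites = [make_site("chr1", 980, 1003), make_site("chr1", 1010, 1033)]
        calls = intersect_sites([indel(pos=1000)], sites)
        assert len(calls) == 2

    def test_unsorted_sites_rejected(self):
        sites = [make_site("chr1", 1010, 1033), make_site("chr1", 980, 1003)]
        with pytest.raises(UnsortedSitesError):
            intersect_sites([indel()], sites)

    def test_chromosome_disjoint_inputs_yield_no_calls(self):
        assert intersect_sites([indel(chrom="chr9")], [make_site("chr1", 10, 33)]) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_all_pairs_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        sites = []
        for chrom in ("c1", "c2"):
            starts = sorted(int(x) for x in rng.integers(0, 5000, size=15))
            sites.extend(make_site(chrom, s, s + 23) for s in starts)
        sites.sort(key=lambda s: (s.locus.chrom, s.locus.start))
        indels = [
            indel(chrom=str(rng.choice(["c1", "c2"])), pos=int(rng.integers(1, 5000)),
                  ref="G" * int(rng.integers(1, 30)) + "A", alt="G")
            for _ in range(40)
        ]
        pad = int(rng.integers(0, 80))
        w = WindowParams(pad)
        got = {
            (id(c.variant), c.site.locus.chrom, c.site.locus.start, c.distance_bp)
            for c in intersect_sites(indels, sites, w)
        }
        expected = set()
        for v in indels:  # quadratic scan
            for s in sites:
                if s.locus.chrom != v.chrom:
                    continue
                span = (min(s.locus.start, s.pam_locus.start), max(s.locus.end, s.pam_locus.end))
                d = _gap(v.span, span)
                if d <= pad:
                    expected.add((id(v), s.locus.chrom, s.locus.start, d))
        assert got == expected

    def test_pad_monotonicity(self, rng):
        sites = [make_site("c", s, s + 23) for s in range(100, 4000, 150)]
        indels = [indel(chrom="c", pos=int(p)) for p in rng.integers(1, 4000, size=30)]
        counts = [len(intersect_sites(indels, sites, WindowParams(p))) for p in (0, 10, 50, 200)]
        assert counts == sorted(counts)


class TestParentalSubtraction:
    def test_exact_allele_match_flags(self):
        call = OffTargetCall(indel(pos=500), make_site("chr1", 480, 503), 0)
        out = subtract_parental([call], [indel(pos=500)])
        assert out[0].in_parent

    def test_different_alt_does_not_flag(self):
        call = OffTargetCall(indel(pos=500, ref="GA", alt="G"), make_site("chr1", 480, 503), 0)
        out = subtract_parental([call], [indel(pos=500, ref="GA", alt="GT")])
        assert not out[0].in_parent

    def test_trio_inherited_counts(self, rng):
        # 50 offspring InDels of which 30 are present in the sire
        offspring = [indel(pos=100 + 40 * i, ref="CA", alt="C") for i in range(50)]
        parental = offspring[:30]
        calls = [OffTargetCall(v, make_site("chr1", v.pos - 10, v.pos + 13), 0) for v in offspring]
        flagged = [c for c in subtract_parental(calls, parental) if c.in_parent]
        assert len(flagged) == 30

    def test_multiallelic_any_alt_match_flags(self):
        v = VariantRecord("chr1", 500, "GA", ("G", "GT"), filter_status=())
        call = OffTargetCall(v, make_site("chr1", 480, 503), 0)
        assert subtract_parental([call], [indel(pos=500, ref="GA", alt="GT")])[0].in_parent


class TestVerifyPam:
    def _planted(self, rng, pam="AGG", L=20):
        guide = GuideRNA("g", random_seq(rng, L))
        bg = random_seq(rng, 600)
        seq = bg[:300] + guide.protospacer + pam + bg[300:]
        return Genome({"c": seq}), guide

    def test_exact_site_verifies_at_zero(self, rng):
        genome, guide = self._planted(rng)
        [site] = enumerate_sites(genome, guide, SearchParams(0, 0, 0))
        call = OffTargetCall(indel(chrom="c", pos=site.locus.start + 5), site, 0)
        out = verify_pam_identity(call, genome, guide, 6)
        assert out.pam_verified and out.realign_mismatches == 0

    def test_mutated_pam_fails(self, rng):
        genome, guide = self._planted(rng)
        [site] = enumerate_sites(genome, guide, SearchParams(0, 0, 0))
        seq = list(genome.sequences["c"])
        seq[site.pam_locus.start : site.pam_locus.end] = list("ATT")
        mutated = Genome({"c": "".join(seq)})
        call = OffTargetCall(indel(chrom="c", pos=site.locus.start + 5), site, 0)
        out = verify_pam_identity(call, mutated, guide, 6)
        assert not out.pam_verified

    def test_search_self_consistency(self, rng):
        # sites straight out of the search engine re-verify at <= their
        # recorded mismatch count (the same cassette is re-found)
        seq = random_seq(rng, 3000)
        guide = GuideRNA("g", random_seq(rng, 12))
        genome = Genome({"c": seq})
        sites = enumerate_sites(genome, guide, SearchParams(3, 1, 1))
        assert sites
        for site in sites[:10]:
            call = OffTargetCall(indel(chrom="c", pos=site.locus.start + 1), site, 0)
            out = verify_pam_identity(call, genome, guide, 3)
            assert out.pam_verified
            assert out.realign_mismatches <= site.mismatches


class TestVerdictsAndFrequencies:
    def _call(self, **kw):
        return OffTargetCall(indel(), make_site("chr1", 980, 1003), 0, **kw)

    def test_precedence(self):
        cases = [
            (dict(in_parent=True, known_natural=True, pam_verified=True), "excluded_parental"),
            (dict(known_natural=True, pam_verified=True), "natural_variation"),
            (dict(pam_verified=True), "plausible_crispr"),
            (dict(), "unresolved"),
        ]
        out = assign_verdicts([self._call(**kw) for kw, _ in cases])
        assert [c.verdict for c in out] == [v for _, v in cases]

    def test_known_annotation(self):
        call = self._call()
        assert annotate_known_variation([call], [indel()])[0].known_natural
        assert not annotate_known_variation([call], [])[0].known_natural
        assert not annotate_known_variation([call], [indel(alt="GTT")])[0].known_natural

    @pytest.mark.parametrize("k,n,expected", [(2, 6, "2/6 (33.3%)"), (1, 6, "1/6 (16.7%)"), (0, 4, "0/4 (0.0%)")])
    def test_frequency_format(self, k, n, expected):
        assert format_frequency(k, n) == expected

    def test_summarize_counts_carriers_per_locus(self):
        site = make_site("chr1", 980, 1003)
        verified = assign_verdicts([OffTargetCall(indel(), site, 0, pam_verified=True)])[0]
        unver = assign_verdicts([OffTargetCall(indel(), site, 0)])[0]
        rows = summarize_frequencies(
            {"a1": [verified], "a2": [verified], "a3": [unver], "a4": [], "a5": [], "a6": []}
        )
        assert len(rows) == 1
        assert rows[0]["frequency"] == "2/6 (33.3%)"
        assert rows[0]["carriers"] <= rows[0]["animals"]


class TestValidationClassifier:
    def test_worked_examples(self):
        outcomes = {f.name: classify_validation(f.embryos, f.locus, f.known, f.genome, f.guide)
                    for f in validation_worked_examples()}
        assert outcomes["ECT2L-like"] == "confirmed_off_target"
        assert outcomes["DDRGK1-like"] == "confirmed_off_target"
        assert outcomes["RPS6KC1-like"] == "natural_variation"

    def test_all_wildtype_not_detected(self):
        f = validation_worked_examples()[0]
        wildtype = {e: [] for e in f.embryos}
        assert classify_validation(wildtype, f.locus, f.known, f.genome, f.guide) == "not_detected"

    def test_requires_embryos(self):
        f = validation_worked_examples()[0]
        with pytest.raises(ValueError):
            classify_validation({}, f.locus, f.known, f.genome, f.guide)
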