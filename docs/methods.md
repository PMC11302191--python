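# Methods

## Problem setting

In outbred species, a gene-edited founder differs from the reference
genome at millions of positions, almost all of them natural variation.
Direct inspection of a VCF therefore cannot reveal off-target Cas9
activity. The screen implemented here narrows the candidate set by
requiring three independent kinds of evidence to coincide: (i) the locus
must resemble the guide closely enough for Cas9 binding (the site
search), (ii) the sample must carry a small InDel there (the signature
of NHEJ repair after a double-strand break), and (iii) the variant must
not be explainable by inheritance from the sequenced sire or by known
natural variation in other breeds. The maternal genome is assumed
unknown, as is typical when oocytes come from abattoir-derived ovaries;
maternally inherited variants therefore cannot be subtracted and
surface as unresolved or falsely plausible candidates. This is a
documented limitation of the design, not of the implementation.

## Site search model

A site is any genomic window that aligns to the protospacer with at
most `max_mismatches` substitutions (default 6) and at most one
single-base bulge, with the PAM pattern (default NGG, IUPAC codes
supported) immediately 3' of the protospacer on the site's strand.
Alignment geometry:

* *gapless* — window length L;
* *DNA bulge* — one extra genomic base unpaired at an internal
  alignment column (window L+1);
* *RNA bulge* — one guide base unpaired (window L−1).

Terminal bulges are excluded because a terminal gap is equivalent to a
shifted gapless alignment that is already reported. Gaps are never
counted as mismatches; only substitutions in paired columns count.
A genomic `N` pairs with nothing and satisfies no PAM character
(including pattern `N`), so assembly gaps cannot spawn sites.

Reporting is deduplicated to one record per (chromosome, strand, locus
start, bulge type), keeping the minimum-mismatch alignment and breaking
ties by the smallest bulge offset. One physical cassette can therefore
appear as up to three records (gapless and bulged interpretations at
adjacent starts); downstream stages treat these as neighbouring site
records of the same locus. The scan is a vectorised linear pass
(prefix/suffix mismatch sums per bulge offset) over each chromosome and
strand — adequate for desk-scale genomes, and validated exactly against
a naive brute-force enumeration in the test suite.

## Hard filtering

With no model-based recalibration, the canonical published hard-filter
thresholds are applied per class: SNPs fail on QD < 2, FS > 60,
MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8, SOR > 3; InDels fail
on QD < 2, FS > 200, ReadPosRankSum < −20, SOR > 10. Any tripped test
fails the record; a missing annotation skips that single test (the
behaviour of the standard VariantFiltration tool). Records mixing SNP
and InDel alternate alleles are filtered with the InDel thresholds and
retained in the InDel stream, so a CRISPR deletion sharing a record
with a SNP is never silently dropped. All thresholds are overridable
via YAML. No depth or genotype-quality filtering is applied beyond
this.

## Normalization and matching

Variants are left-aligned and parsimony-trimmed (the vt / `bcftools
norm` definition: shared trailing bases trimmed with leftward reference
extension, then shared leading bases trimmed keeping one anchor).
Parental and known-variation matching is allele-exact on normalized
(chrom, pos, ref, alt) and genotype-agnostic — any record in the sire,
regardless of genotype, excludes the candidate, matching the screening
logic of subtracting everything inheritance can explain. Each alternate
allele of a multiallelic record is matched independently; any match
flags the call. The in-package normalizer is cross-checked against
`bcftools norm` and against a string-surgery haplotype-equivalence
oracle in the tests.

## Window geometry

"Within 50 bp" is implemented as: pad the variant's REF span by
`pad_bp` (default 50) on each side and test overlap against the site's
protospacer+PAM footprint; equivalently, a pair is emitted when the gap
between the unpadded intervals is at most `pad_bp`. Padding the variant
rather than the site is symmetric for point InDels and fixed here for
determinism with long deletions. The interval-tree implementation is
verified against an all-pairs quadratic scan.

## Verification and verdicts

Each surviving call's locus (footprint ± pad) is re-fetched from the
reference and every guide placement in the window — both strands, all
gapless and single-bulge alignments — is rescored. The question the
verification answers is whether some PAM-adjacent placement reproduces
guide identity within the mismatch budget; the best PAM-adjacent
mismatch count is recorded. (Scoring only the single globally best
placement would let a spurious lower-mismatch, PAM-less alignment in
the window mask a genuine high-mismatch site; this mattered in
practice for 6-mismatch sites.)

Verdict precedence is fixed: parental match → `excluded_parental`;
else known-variation match → `natural_variation`; else verified →
`plausible_crispr`; else `unresolved`. Stages flag rather than delete,
so funnel counts are reconstructible from the calls table alone.
Carrier frequencies are reported per locus as `k/n (percent to one
decimal)` over the supplied animals.

The validation classifier applies the same logic to independent
per-embryo genotypes at one locus: a locus-specific InDel in at least
one embryo, absent from known variation, next to a verified PAM, is
`confirmed_off_target`; a known-variation match is
`natural_variation`; no InDel (or a failed PAM re-verification) is
`not_detected`.

## Mosaicism

"Allele" counts distinct normalized InDel records overlapping the
on-target window; the wild-type allele is not counted, so a tissue with
no call is wild-type-only with zero alleles. An animal is mosaic when
the union across tissues exceeds two alleles (more than a diploid can
carry germline) or when any two tissues disagree, including one tissue
wild-type while another is edited. Allele-fraction estimation from read
depth is out of scope; input is called variants only.

## Synthetic cohorts

The generator emulates the study design, not the sequencing: it starts
at the VCF level (no reads), with parameters chosen to mirror a
founder-cohort screen.

* Genome: 3 chromosomes × 20 kb of i.i.d. uniform A/C/G/T. After
  planting, the genome is swept with the search engine and every
  accidental site outside a planted cassette has its PAM broken,
  iterating to a fixed point, so the planted loci are provably the only
  sites (asserted in tests, cluster-wise per cassette).
* Guide: one random 20-mer; 8 planted off-target cassettes cycling
  through mismatch counts 2–6 with and without bulges, plus one exact
  on-target cassette; cassettes are spaced at least 2× the window pad
  apart.
* Natural variation: per-animal Poisson backgrounds at 5×10⁻⁴ InDels
  and 2×10⁻³ SNPs per bp — the per-bp rates implied by the millions of
  variants a single outbred genome shows against a reference. Each
  natural variant is inherited (copied to the sire's VCF) with
  probability 0.5, Mendelian-style; de novo variants stand in for the
  unknown maternal contribution and never enter the sire's VCF. The
  sire's VCF contains exactly the union of inherited variants, keeping
  the truth-table conservation invariant exact. 5% of natural variants
  are emitted with failing annotations (QD = 1) to exercise the hard
  filter.
* Edits: per animal and planted site, with probability
  `crispr_edit_penetrance` (default 0.3, echoing the low per-animal
  carrier counts a real screen reports; acceptance uses 1.0), a
  deletion of 1–32 bp or insertion of 1–6 bp is anchored within 10 bp
  of the cut position 3 bp inside the PAM-proximal end — the size range
  observed at real on-target loci. One third of animals (default) are
  mosaic: 3–4 distinct on-target alleles distributed leave-one-out
  across tissues with one wild-type tissue; non-mosaic animals carry
  the same 1–2 alleles in every tissue.
* All records are normalized at generation time and all randomness
  flows from one seeded generator, so a bundle is byte-reproducible.

What passing on these cohorts shows: the funnel's bookkeeping —
search completeness, filtering, windowing, subtraction, verification —
is exact under the stated model. What it does not show: robustness to
alignment artefacts, caller-specific annotation distributions,
structural variants or repeat-dense sequence, none of which the
generator emulates (short-read screens are similarly blind to
inversions).

## Worked-example fixtures

The bundled worked examples reproduce, in-memory, the printed summary
tables of a founder-pig screen: the four-allele mosaic founder
(per-tissue on-target rows on a placeholder chromosome, since the
printed rows give positions only), the ten-candidate-locus report with
its per-guide attributions and `k/n` frequencies, and three
validation-outcome fixtures. The validation genomes and guides are
synthetic constructions (the original sequences are not printed); they
reproduce the logical structure of each outcome — embryo-private InDel
with intact PAM (confirmed, ×2) versus a deletion present in another
breed (natural variation).

## Numerical and scale choices

Problem sizes in the tests and acceptance script — genomes of a few kb,
guides of 8–20 nt, cohorts of 3–6 animals — are chosen so the
brute-force oracles remain exhaustive and the whole suite runs in
seconds on one CPU; the search contract is a linear scan, and no
FM-index backend is provided for gigabase genomes. Genome-scale counts
from real screens (thousands of predicted sites per guide, millions of
variants) are not reproducible at this scale and are not asserted
anywhere. Coordinates are 0-based half-open internally; VCF (1-based)
and the report tables (1-based inclusive) convert at the boundary.
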