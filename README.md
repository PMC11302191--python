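# offsieve

Whole-genome-sequencing-based discovery of CRISPR-Cas9 off-target edits in
**outbred, genetically heterogeneous organisms** — founder pigs being the
motivating case — where millions of natural variants against the reference
genome mask the handful of lesions a nuclease may have introduced, and
where the maternal genome is typically unknown (abattoir-derived oocytes).

`offsieve` starts from called variants (VCF) and a reference genome and
implements the downstream screening funnel:

1. **Site search** — enumerate every genomic locus matching a guide's
   protospacer within *m* mismatches (default 6), allowing at most one
   single-base DNA or RNA bulge, with an NGG PAM immediately 3' of the
   protospacer on the site strand.
2. **Hard filtering** — GATK-style per-annotation thresholds for SNPs and
   InDels (QD, FS, MQ, rank sums, SOR); only PASS InDels continue, since
   small InDels are the signature lesion of NHEJ repair after a Cas9
   double-strand break.
3. **Windowed intersection** — pair each InDel with every predicted site
   within ±50 bp of its REF span, so large deletions are still captured.
4. **Parental subtraction** — flag variants that also appear in the
   sequenced sire (allele-exact after left-alignment/trimming), removing
   inherited variation from the candidate set.
5. **Verification** — re-fetch each surviving locus, realign the guide
   across the window, and confirm sequence identity plus an adjacent PAM;
   optionally annotate candidates found in a known natural-variation VCF.
6. **Reporting** — per-stage funnel counts, a calls table with full
   provenance flags, per-locus carrier frequencies ("k/n (percent)"), and
   a multi-tissue **mosaicism** report for the on-target locus (an animal
   carrying more than two alleles, or discordant tissues, was edited
   after the first zygotic cleavage).

A first-class synthetic-data module generates deterministic cohorts —
toy genome, planted off-target cassettes, sire/offspring VCFs with
inherited and de novo variants, per-tissue on-target allele mixtures —
with a machine-readable truth table, so the whole funnel is testable
without any download.

## Worked example

Generate a three-animal cohort at full edit penetrance and run the
funnel end to end:

```bash
offsieve simulate --seed 11 --out-dir fixtures --n-animals 3 --penetrance 1.0
cat > pipeline.yaml <<EOF
fasta: fixtures/genome.fa
guides: fixtures/guides.tsv
sample_vcfs:
  pig1: fixtures/pig1/brain.vcf
  pig2: fixtures/pig2/brain.vcf
  pig3: fixtures/pig3/brain.vcf
parental_vcf: fixtures/parental.vcf
out_dir: run
EOF
offsieve run --config pipeline.yaml
```

prints (abridged):

```
{
  "n_sites": 24,
  "funnel": {
    "pig1": {
      "total_variants": 166,
      "indels_pass": 42,
      "window_matched": 12,
      "post_parental": 12,
      "plausible_crispr": 12
    },
    ...
  }
}
```

Read the funnel left to right: 166 raw variants in pig1's VCF, 42 PASS
InDels after hard filtering, 12 distinct InDels within ±50 bp of a
predicted site, 12 surviving parental subtraction, and 12 verified
against guide identity + PAM (this cohort plants every edit, so nothing
is lost). `run/calls.tsv` holds one row per variant–site pairing with
all flags and the final verdict; `run/frequencies.tsv` gives per-locus
carrier counts such as `3/3 (100.0%)`.

Mosaicism across tissues of one animal:

```bash
offsieve mosaic --locus chr1:107-126 --animal pig1 \
  --vcf brain=fixtures/pig1/brain.vcf --vcf lung=fixtures/pig1/lung.vcf \
  --vcf muscle=fixtures/pig1/muscle.vcf --vcf spleen=fixtures/pig1/spleen.vcf
```

```
{
  "animal": "pig1",
  "distinct_alleles": 4,
  "per_tissue_counts": {"brain": 4, "lung": 0, "muscle": 3, "spleen": 3},
  "uniform": false,
  "mosaic": true
}
```

Four distinct on-target alleles across tissues (more than a diploid can
carry) and a wild-type lung: this founder is mosaic.

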