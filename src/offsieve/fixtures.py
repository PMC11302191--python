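"""Bundled worked examples.

Small, fully in-memory datasets mirroring the published summary tables of
a founder-pig WGS off-target screen, used in the documentation and as
end-to-end checks of the report layer:

* ``mosaic_worked_example`` — the per-tissue on-target allele rows of one
  mosaic knockout founder (four distinct InDel alleles split across
  brain, muscle and spleen; lung wild-type), on a placeholder chromosome
  because the printed rows give positions only.
* ``locus_report_worked_example`` — the ten novel candidate off-target
  loci attributed to the RAG2/IL2RG and IGH guide sets, with per-locus
  carrier frequencies over six animals.
* ``validation_worked_examples`` — synthetic stand-ins for the embryo
  validation genotyping: two loci with embryo-private InDels next to an
  intact PAM (confirmed off-targets), and one locus whose deletion is
  known natural variation in another breed. The genomes and guides here
  are synthetic constructions, not the original sequences (which are not
  printed); only the logical structure of each outcome is reproduced.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .intersect import format_frequency
from .reference import Genome, GenomicInterval
from .search import GuideRNA
from .variants import VariantRecord, write_vcf

__all__ = [
    "mosaic_worked_example",
    "locus_report_worked_example",
    "validation_worked_examples",
    "ValidationFixture",
    "MOSAIC_CHROM",
    "MOSAIC_LOCUS",
]

MOSAIC_CHROM = "chr_placeholder"

# Printed on-target rows for the mosaic founder: (tissue, pos, ref, alt)
_MOSAIC_ROWS = [
    ("brain", 189715872, "TCCAGGCGGCCAGCAGGACCAGTG", "T"),
    ("brain", 189715888, "GA", "G"),
    ("brain", 189715890, "CCAGTG", "C"),
    ("brain", 189715896, "CCAAACCGGGCAGCATCGCGACCCTGCGCGGG", "C"),
    ("muscle", 189715888, "GA", "G"),
    ("muscle", 189715890, "CCAGTG", "C"),
    ("muscle", 189715896, "CCAAACCGGGCAGCATCGCGACCCTGCGCGGG", "C"),
    ("spleen", 189715872, "TCCAGGCGGCCAGCAGGACCAGTG", "T"),
    ("spleen", 189715888, "GA", "G"),
    ("spleen", 189715890, "CCAGTG", "C"),
    ("spleen", 189715896, "CCAAACCGGGCAGCATCGCGACCCTGCGCGGG", "C"),
]

MOSAIC_LOCUS = GenomicInterval(MOSAIC_CHROM, 189715850, 189715950, "+")


def mosaic_worked_example(out_dir: str | os.PathLike | None = None) -> Dict[str, List[VariantRecord]]:
    """Per-tissue on-target VCF records for the mosaic founder (animal 2-3)."""
    tissues: Dict[str, List[VariantRecord]] = {"brain": [], "lung": [], "muscle": [], "spleen": []}
    for tissue, pos, ref, alt in _MOSAIC_ROWS:
        tissues[tissue].append(
            VariantRecord(MOSAIC_CHROM, pos, ref, (alt,), genotypes={"2-3": (0, 1)})
        )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        contigs = {MOSAIC_CHROM: 200000000}
        for tissue, recs in tissues.items():
            write_vcf(recs, os.path.join(os.fspath(out_dir), f"2-3_{tissue}.vcf"),
                      contigs, samples=["2-3"])
    return tissues


# (guide, gene, location, region, reference accession, carriers, animals)
_LOCUS_ROWS = [
    ("RAG2-1", "HHAT", "NC_010451.4 (132518281-132518381)", "Intron", "XM_013979981.2", 1, 6),
    ("RAG2-2", "ECT2L", "NC_010443.5 (25595738-25595838)", "Intron", "XM_021087372.1", 1, 6),
    ("RAG2-2", "UBR1", "NC_010443.5 (128356823-128356923)", "Intron", "XM_021097089", 1, 6),
    ("RAG2-2", "FAM155A", "NC_010453.5 (74742560-74742660)", "Exon", "XM_021065383.1", 1, 6),
    ("RAG2-2", "LOC102159977", "NC_010445.4 (117155315-117155415)", "LncRNA", "XR_002342830.1", 1, 6),
    ("IL2RG-1", "LOC110260974", "NC_010448.4 (41622985-41623085)", "LncRNA", "XR_002344622.1", 1, 6),
    ("IL2RG-3", "LOC110257355", "NC_010459.5 (40282022-40282122)", "LncRNA", "XR_002339844.1", 1, 6),
    ("IL2RG-3", "DDRGK1.1", "NC_010459.5 (32483037-32483139)", "Exon", "NM_001190212.1", 2, 6),
    ("IGH-2", "RPS6KC1", "NC_010451.4 (130251247-130251272)", "Intron", "XM_021063835.1", 1, 6),
    ("IGH-2", "LOC102163174", "NC_010456.5 (60538300-60538400)", "Unannotated", "XR_002338974.1", 1, 6),
]


def locus_report_worked_example() -> List[Dict[str, object]]:
    """The ten-candidate-locus report with per-locus carrier frequencies."""
    rows: List[Dict[str, object]] = []
    for guide, gene, location, region, accession, k, n in _LOCUS_ROWS:
        rows.append(
            {
                "guide": guide,
                "gene": gene,
                "location": location,
                "region": region,
                "accession": accession,
                "carriers": k,
                "animals": n,
                "frequency": format_frequency(k, n),
            }
        )
    return rows


@dataclass
class ValidationFixture:
    """One validation locus: embryo genotypes + the context to re-verify it."""

    name: str
    genome: Genome
    guide: GuideRNA
    locus: GenomicInterval
    embryos: Dict[str, List[VariantRecord]]
    known: List[VariantRecord]
    truth: str  # synthetic ground-truth classification for this fixture


def _validation_fixture(
    name: str, seed: int, truth: str, n_embryos: int = 20, n_carriers: int = 1
) -> ValidationFixture:
    """Build one synthetic validation locus (see module docstring)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chrom = "chrV"
    seq = list("".join(bases[rng.integers(0, 4, size=800)]))
    guide_seq = "".join(bases[rng.integers(0, 4, size=20)])
    start = 400
    seq[start : start + 20] = list(guide_seq)
    seq[start + 20 : start + 23] = list("AGG")  # intact PAM 3' of the protospacer
    genome = Genome({chrom: "".join(seq)})
    guide = GuideRNA(name, guide_seq)
    locus = GenomicInterval(chrom, start, start + 23, "+")

    # a locus-specific small deletion near the cut site (3 bp inside the PAM)
    anchor0 = start + 14
    dl = 4
    ref = genome.sequences[chrom][anchor0 : anchor0 + dl + 1]
    alt = genome.sequences[chrom][anchor0]
    deletion = VariantRecord(chrom, anchor0 + 1, ref, (alt,))

    embryos: Dict[str, List[VariantRecord]] = {}
    for i in range(n_embryos):
        embryo = f"embryo{i + 1:02d}"
        embryos[embryo] = [deletion] if i < n_carriers else []
    known = [deletion] if truth == "natural_variation" else []
    return ValidationFixture(name, genome, guide, locus, embryos, known, truth)


def validation_worked_examples() -> List[ValidationFixture]:
    """The three validation outcomes seen in the screen, as synthetic loci.

    Two loci (ECT2L-like and DDRGK1-like) carry an embryo-private InDel
    next to an intact PAM and absent from known variation -> confirmed;
    one locus (RPS6KC1-like) carries a 4 bp deletion that is known natural
    variation in another breed -> natural variation.
    """
    return [
        _validation_fixture("ECT2L-like", seed=101, truth="confirmed_off_target",
                            n_carriers=1),
        _validation_fixture("DDRGK1-like", seed=202, truth="confirmed_off_target",
                            n_carriers=2),
        _validation_fixture("RPS6KC1-like", seed=303, truth="natural_variation",
                            n_carriers=2),
    ]
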