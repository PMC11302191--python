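"""On-target mosaicism detection across tissues of one animal.

An animal edited after the first zygotic cleavage can carry more than two
alleles at the target locus, or different allele sets in different
tissues. "Allele" here counts distinct InDel records overlapping the
on-target window; the wild-type allele is not counted, so a tissue with
no InDel call is wild-type-only with zero alleles.

An animal is called mosaic when the union of tissue allele sets exceeds
two (a diploid cannot carry three germline alleles) OR when any two
tissues disagree (including one tissue wild-type while another is
edited).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple

from .reference import GenomicInterval
from .variants import VariantRecord

__all__ = [
    "TissueAlleleProfile",
    "MosaicismReport",
    "build_profiles",
    "detect_mosaicism",
    "ProfileMixError",
]

Allele = Tuple[int, str, str]  # (pos, ref, alt), normalized


class ProfileMixError(ValueError):
    """Profiles from different animals or loci were mixed."""


@dataclass(frozen=True)
class TissueAlleleProfile:
    """The set of on-target InDel alleles observed in one tissue."""

    animal_id: str
    tissue: str
    locus: GenomicInterval
    alleles: FrozenSet[Allele]

    @property
    def wildtype_only(self) -> bool:
        return not self.alleles


@dataclass(frozen=True)
class MosaicismReport:
    animal_id: str
    distinct_alleles: int
    per_tissue_counts: Mapping[str, int]
    uniform: bool
    mosaic: bool


def build_profiles(
    vcfs: Mapping[str, Sequence[VariantRecord]], locus: GenomicInterval, animal_id: str = ""
) -> List[TissueAlleleProfile]:
    """Collect, per tissue, the distinct InDel alleles overlapping ``locus``."""
    profiles: List[TissueAlleleProfile] = []
    for tissue, records in vcfs.items():
        alleles: set = set()
        for rec in records:
            if rec.chrom != locus.chrom:
                continue
            if rec.var_class == "SNP":
                continue
            lo, hi = rec.span
            if lo < locus.end and locus.start < hi:
                for alt in rec.alts:
                    if len(alt) != len(rec.ref):
                        alleles.add((rec.pos, rec.ref, alt))
        profiles.append(
            TissueAlleleProfile(
                animal_id=animal_id, tissue=tissue, locus=locus, alleles=frozenset(alleles)
            )
        )
    return profiles


def detect_mosaicism(profiles: Sequence[TissueAlleleProfile]) -> MosaicismReport:
    """Summarize allele composition across tissues and call mosaicism.

    ``distinct_alleles`` is the size of the union of tissue allele sets;
    ``uniform`` is true when every tissue has the identical set; the
    animal is mosaic when distinct_alleles > 2 or the tissues disagree.
    """
    if not profiles:
        raise ValueError("at least one tissue profile is required")
    animals = {p.animal_id for p in profiles}
    loci = {p.locus for p in profiles}
    if len(animals) > 1 or len(loci) > 1:
        raise ProfileMixError(
            f"profiles mix animals {sorted(animals)} / loci {len(loci)}"
        )
    union: set = set()
    for p in profiles:
        union |= p.alleles
    uniform = len({p.alleles for p in profiles}) == 1
    mosaic = (len(union) > 2) or (not uniform)
    return MosaicismReport(
        animal_id=profiles[0].animal_id,
        distinct_alleles=len(union),
        per_tissue_counts={p.tissue: len(p.alleles) for p in profiles},
        uniform=uniform,
        mosaic=mosaic,
    )
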