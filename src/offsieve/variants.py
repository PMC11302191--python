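"""VCF ingestion, hard filtering, normalization and InDel selection.

Hard filtering follows the canonical published threshold set for
germline short-variant discovery when model-based recalibration is not
used: a record fails if ANY configured annotation trips its threshold;
a missing annotation skips that single test (the behaviour of GATK's
VariantFiltration). SNP and InDel classes use separate threshold sets;
mixed SNP/InDel multiallelic records are filtered with the InDel set and
retained in the InDel stream so that a CRISPR-induced deletion sharing a
locus with a SNP is never silently dropped.

Normalization is the standard left-align + parsimony-trim definition
(vt / ``bcftools norm``): trailing bases shared by all alleles are
trimmed (extending left with reference sequence when an allele would
empty), then shared leading bases are trimmed keeping one anchor base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import pysam
import yaml

from .reference import Genome

__all__ = [
    "VariantRecord",
    "HardFilterConfig",
    "read_vcf",
    "write_vcf",
    "classify_variant",
    "apply_hard_filters",
    "select_indels",
    "normalize_variant",
    "VcfParseError",
    "ReferenceMismatchError",
]

HARD_FILTER_ANNOTATIONS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")


class VcfParseError(ValueError):
    """A VCF file could not be parsed."""


class ReferenceMismatchError(ValueError):
    """A record's REF allele disagrees with the reference genome."""


@dataclass(frozen=True)
class VariantRecord:
    """One VCF record (multiallelic records stay single records).

    ``filter_status`` is ``None`` before filtering, ``()`` for PASS, or a
    tuple of the names of the tripped filters.
    """

    chrom: str
    pos: int                                  # 1-based, as in VCF
    ref: str
    alts: Tuple[str, ...]
    info: Mapping[str, float] = field(default_factory=dict)
    filter_status: Optional[Tuple[str, ...]] = None
    genotypes: Mapping[str, Tuple[Optional[int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("REF allele must be non-empty")
        for alt in self.alts:
            if not alt:
                raise ValueError("ALT alleles must be non-empty")
            if alt == self.ref:
                raise ValueError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def is_pass(self) -> bool:
        return self.filter_status == ()

    @property
    def var_class(self) -> str:
        return classify_variant(self)

    @property
    def span(self) -> Tuple[int, int]:
        """0-based half-open interval covered by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def allele_keys(self) -> List[Tuple[str, int, str, str]]:
        """(chrom, pos, ref, alt) per ALT — the identity used for matching."""
        return [(self.chrom, self.pos, self.ref, alt) for alt in self.alts]


def classify_variant(rec: VariantRecord) -> str:
    """Classify as SNP, InDel, or mixed by REF/ALT length comparison."""
    kinds = set()
    for alt in rec.alts:
        kinds.add("InDel" if len(alt) != len(rec.ref) else "SNP")
    if kinds == {"SNP"}:
        return "SNP"
    if kinds == {"InDel"}:
        return "InDel"
    return "mixed"


@dataclass(frozen=True)
class HardFilterConfig:
    """Per-class annotation thresholds: name -> (comparator, cutoff).

    Comparator ``"<"`` fails a record when the annotation value is below
    the cutoff; ``">"`` when above. Records lacking an annotation pass
    that single test.
    """

    snp_thresholds: Mapping[str, Tuple[str, float]] = field(
        default_factory=lambda: {
            "QD": ("<", 2.0),
            "FS": (">", 60.0),
            "MQ": ("<", 40.0),
            "MQRankSum": ("<", -12.5),
            "ReadPosRankSum": ("<", -8.0),
            "SOR": (">", 3.0),
        }
    )
    indel_thresholds: Mapping[str, Tuple[str, float]] = field(
        default_factory=lambda: {
            "QD": ("<", 2.0),
            "FS": (">", 200.0),
            "ReadPosRankSum": ("<", -20.0),
            "SOR": (">", 10.0),
        }
    )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "HardFilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        def parse(section: dict) -> Dict[str, Tuple[str, float]]:
            return {k: (v[0], float(v[1])) for k, v in section.items()}
        kwargs = {}
        if "snp_thresholds" in raw:
            kwargs["snp_thresholds"] = parse(raw["snp_thresholds"])
        if "indel_thresholds" in raw:
            kwargs["indel_thresholds"] = parse(raw["indel_thresholds"])
        return cls(**kwargs)


def read_vcf(path: str | os.PathLike) -> List[VariantRecord]:
    """Read a VCF 4.x file (plain or bgzipped) into VariantRecords."""
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: {exc}") from None
    records: List[VariantRecord] = []
    with vf:
        for i, rec in enumerate(vf.fetch() if vf.index is not None else vf, start=1):
            try:
                info: Dict[str, float] = {}
                for key in HARD_FILTER_ANNOTATIONS:
                    if key in rec.info:
                        val = rec.info[key]
                        if isinstance(val, tuple):
                            val = val[0]
                        if val is not None:
                            info[key] = float(val)
                genotypes = {
                    sample: tuple(rec.samples[sample].get("GT", (None,)))
                    for sample in rec.samples
                }
                alts = tuple(a for a in (rec.alts or ()) if a is not None)
                if not alts:
                    continue  # no called alternate allele
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=alts,
                        info=info,
                        genotypes=genotypes,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise VcfParseError(f"{path}: record {i}: {exc}") from None
    return records


def write_vcf(
    records: List[VariantRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int],
    samples: Optional[List[str]] = None,
    filter_descriptions: Optional[Mapping[str, str]] = None,
) -> None:
    """Write records as VCF 4.2, populating FILTER from ``filter_status``."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for key in HARD_FILTER_ANNOTATIONS:
        header.info.add(key, number=1, type="Float", description=f"{key} annotation")
    header.formats.add("GT", number=1, type="String", description="Genotype")
    used_filters = sorted({f for r in records for f in (r.filter_status or ())})
    for name in used_filters:
        desc = (filter_descriptions or {}).get(name, f"Failed hard filter {name}")
        header.filters.add(name, None, None, desc)
    if samples is None:
        seen: Dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, *r.alts)
            )
            for key, val in r.info.items():
                rec.info[key] = val
            if r.filter_status == ():
                rec.filter.add("PASS")
            elif r.filter_status:
                for f in r.filter_status:
                    rec.filter.add(f)
            for s in samples:
                gt = r.genotypes.get(s)
                if gt is not None:
                    rec.samples[s]["GT"] = gt
            out.write(rec)


def apply_hard_filters(
    recs: List[VariantRecord], cfg: HardFilterConfig = HardFilterConfig()
) -> List[VariantRecord]:
    """Return annotated copies with ``filter_status`` set (input untouched)."""
    out: List[VariantRecord] = []
    for rec in recs:
        thresholds = (
            cfg.snp_thresholds if rec.var_class == "SNP" else cfg.indel_thresholds
        )
        failed: List[str] = []
        for name, (op, cutoff) in thresholds.items():
            value = rec.info.get(name)
            if value is None:
                continue  # missing annotation: this single test passes
            if op == "<":
                tripped = value < cutoff
            elif op == ">":
                tripped = value > cutoff
            else:
                raise ValueError(f"unknown comparator {op!r} for {name}")
            if tripped:
                failed.append(name)
        out.append(replace(rec, filter_status=tuple(sorted(failed))))
    return out


def select_indels(recs: List[VariantRecord]) -> List[VariantRecord]:
    """PASS records whose class is InDel or mixed (the downstream stream)."""
    return [r for r in recs if r.is_pass and r.var_class in ("InDel", "mixed")]


def normalize_variant(rec: VariantRecord, genome: Genome) -> VariantRecord:
    """Left-align and parsimony-trim a variant against the reference.

    Raises :class:`ReferenceMismatchError` if REF does not match the
    genome at ``pos``. SNPs and already-minimal records are returned
    unchanged (the operation is idempotent).
    """
    if rec.chrom not in genome:
        raise ReferenceMismatchError(f"unknown chromosome {rec.chrom}")
    seq = genome.sequences[rec.chrom]
    start0 = rec.pos - 1
    if seq[start0 : start0 + len(rec.ref)] != rec.ref:
        raise ReferenceMismatchError(
            f"{rec.chrom}:{rec.pos} REF {rec.ref} != reference "
            f"{seq[start0:start0 + len(rec.ref)]!r}"
        )
    alleles = [rec.ref, *rec.alts]
    pos = rec.pos
    changed = True
    while changed:
        changed = False
        # trim shared trailing base; extend left if an allele would empty
        if len(set(a[-1] for a in alleles)) == 1:
            if any(len(a) == 1 for a in alleles):
                if pos == 1:
                    break  # cannot extend past the chromosome start
                pos -= 1
                left = seq[pos - 1]
                alleles = [left + a[:-1] for a in alleles]
            else:
                alleles = [a[:-1] for a in alleles]
            changed = True
    # trim shared leading bases, keeping at least one anchor base
    while all(len(a) >= 2 for a in alleles) and len(set(a[0] for a in alleles)) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    if pos == rec.pos and alleles[0] == rec.ref and tuple(alleles[1:]) == rec.alts:
        return rec
    return replace(rec, pos=pos, ref=alleles[0], alts=tuple(alleles[1:]))
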