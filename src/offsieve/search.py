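"""Genome-wide guide RNA off-target site enumeration.

Finds every genomic locus that a SpCas9 guide could bind within a mismatch
budget, allowing at most one single-base bulge (an unpaired base on either
the genomic strand, a "DNA bulge", or the guide strand, an "RNA bulge"),
and requiring a PAM motif (default NGG) immediately 3' of the protospacer
on the site's strand.

Alignment geometry
------------------
For a guide of length L the alignment against a genomic window is one of:

* ``none`` — gapless, window length L;
* ``dna``  — one extra genomic base at alignment column ``b`` (gap in the
  guide track), window length L+1, ``b`` in 1..L-1;
* ``rna``  — guide base ``b`` unpaired (gap in the genome track), window
  length L-1, ``b`` in 1..L-2.

Terminal bulges are forbidden: a gap at either end of the alignment is
equivalent to a shifted gapless match, which is already reported. Gaps are
never counted as mismatches; only substitutions in paired columns count.
A genomic N pairs with nothing — it always counts as a mismatch and never
satisfies any PAM pattern character, so assembly gaps cannot spawn sites.

The scan is a vectorised linear pass per chromosome and strand (desk-scale
genomes); no index structure is built.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .reference import Genome, GenomicInterval, fetch, reverse_complement

__all__ = [
    "GuideRNA",
    "SearchParams",
    "CandidateSite",
    "match_pam",
    "score_alignment",
    "enumerate_sites",
    "write_sites",
    "read_sites",
    "read_guides",
    "SitesParseError",
    "EmptyGenomeError",
]

# IUPAC nucleotide ambiguity classes (pattern side only; genomic N matches none)
IUPAC: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class EmptyGenomeError(ValueError):
    """enumerate_sites was given a genome with no sequences."""


class SitesParseError(ValueError):
    """A sites TSV file is malformed."""


@dataclass(frozen=True)
class GuideRNA:
    """A guide RNA query: PAM-less protospacer plus a 3' PAM pattern."""

    name: str
    protospacer: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if not self.protospacer:
            raise ValueError("protospacer must be non-empty")
        if not set(self.protospacer) <= set("ACGT"):
            raise ValueError(
                f"protospacer may only contain A/C/G/T, got {self.protospacer!r}"
            )
        if not self.pam:
            raise ValueError("PAM pattern must be non-empty")
        bad = set(self.pam) - set(IUPAC)
        if bad:
            raise ValueError(f"illegal PAM pattern characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.protospacer)


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances: mismatch budget and single-base bulge allowances."""

    max_mismatches: int = 6
    max_dna_bulge: int = 1
    max_rna_bulge: int = 1
    strands: Tuple[str, ...] = ("+", "-")

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be non-negative")
        if self.max_dna_bulge not in (0, 1) or self.max_rna_bulge not in (0, 1):
            raise ValueError("bulge sizes are limited to 0 or 1")
        if not set(self.strands) <= {"+", "-"} or not self.strands:
            raise ValueError("strands must be a non-empty subset of {+, -}")


@dataclass(frozen=True)
class CandidateSite:
    """One genomic locus matching a guide, with its best alignment."""

    guide_name: str
    locus: GenomicInterval          # protospacer span on the reference (PAM excluded)
    pam_locus: GenomicInterval
    mismatches: int
    bulge_type: str                 # none | dna | rna
    bulge_offset: Optional[int]
    aligned_genome_seq: str         # site strand 5'->3'; '-' marks an RNA-bulge gap
    aligned_guide_seq: str          # '-' marks a DNA-bulge gap
    pam_seq: str


def match_pam(genome_seq: str, pattern: str) -> bool:
    """True iff each genomic base is in the IUPAC class of the pattern character.

    A genomic ``N`` matches no pattern character, including pattern ``N``.
    """
    if len(genome_seq) != len(pattern):
        raise ValueError(
            f"sequence length {len(genome_seq)} != pattern length {len(pattern)}"
        )
    for base, pat in zip(genome_seq, pattern):
        if pat not in IUPAC:
            raise ValueError(f"illegal PAM pattern character {pat!r}")
        if base not in IUPAC[pat]:
            return False
    return True


def score_alignment(
    guide: str, site: str, bulge_type: str = "none", bulge_offset: Optional[int] = None
) -> int:
    """Count substitutions in the paired columns of a guide/site alignment.

    ``site`` is the genomic window on the site's strand: length ``|guide|``
    for a gapless alignment, ``|guide|+1`` for a DNA bulge (extra genomic
    base at alignment column ``bulge_offset``), ``|guide|-1`` for an RNA
    bulge (guide base ``bulge_offset`` unpaired). The gap itself is not a
    mismatch.
    """
    L = len(guide)
    if bulge_type == "none":
        if len(site) != L:
            raise ValueError("gapless alignment requires |site| == |guide|")
        return sum(a != b for a, b in zip(guide, site))
    if bulge_offset is None:
        raise ValueError("bulged alignments require a bulge_offset")
    b = bulge_offset
    if bulge_type == "dna":
        if len(site) != L + 1:
            raise ValueError("DNA bulge requires |site| == |guide| + 1")
        if not 1 <= b <= L - 1:
            raise ValueError(f"DNA bulge offset {b} is terminal for guide length {L}")
        return sum(a != c for a, c in zip(guide[:b], site[:b])) + sum(
            a != c for a, c in zip(guide[b:], site[b + 1 :])
        )
    if bulge_type == "rna":
        if len(site) != L - 1:
            raise ValueError("RNA bulge requires |site| == |guide| - 1")
        if not 1 <= b <= L - 2:
            raise ValueError(f"RNA bulge offset {b} is terminal for guide length {L}")
        return sum(a != c for a, c in zip(guide[:b], site[:b])) + sum(
            a != c for a, c in zip(guide[b + 1 :], site[b:])
        )
    raise ValueError(f"unknown bulge_type {bulge_type!r}")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode("latin1"),
        dtype=np.uint8,
    )


def _pam_ok(enc: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean array over PAM start positions 0 .. n - |pattern|."""
    n = len(enc)
    plen = len(pattern)
    m = n - plen + 1
    if m <= 0:
        return np.zeros(0, dtype=bool)
    ok = np.ones(m, dtype=bool)
    for k, pat in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for base in IUPAC[pat]:
            allowed[_BASE_CODE[base]] = True
        # code 4 (N) stays False: genomic N never satisfies a PAM character
        ok &= allowed[enc[k : k + m]]
    return ok


def _scan_strand(
    seq: str, guide: GuideRNA, params: SearchParams
) -> List[Tuple[int, int, str, int, int]]:
    """Scan one oriented sequence; return (start, site_len, bulge_type, offset, mm).

    ``start`` is the 0-based site start on the scanned (already oriented)
    sequence. Deduplication happens later in reference coordinates.
    """
    L = len(guide.protospacer)
    plen = len(guide.pam)
    n = len(seq)
    if n < L + plen:
        return []
    enc = _encode(seq)
    g = _encode(guide.protospacer)
    max_mm = params.max_mismatches

    # M0[j, i] = guide[j] vs seq[i+j]; M1 shifts the genome by +1 (DNA bulge
    # downstream half); Mm1 shifts by -1 (RNA bulge downstream half).
    # Out-of-range comparisons are padded as mismatches and later clipped
    # away by the valid-start bound for each site length.
    M0 = np.ones((L, n), dtype=np.int16)
    M1 = np.ones((L, n), dtype=np.int16)
    Mm1 = np.ones((L, n), dtype=np.int16)
    for j in range(L):
        M0[j, : n - j] = (enc[j:] != g[j]) | (enc[j:] == 4)
        if n - j - 1 > 0:
            M1[j, : n - j - 1] = (enc[j + 1 :] != g[j]) | (enc[j + 1 :] == 4)
        if j >= 1:
            Mm1[j, : n - j + 1] = (enc[j - 1 :] != g[j]) | (enc[j - 1 :] == 4)

    P = np.zeros((L + 1, n), dtype=np.int16)          # P[b] = sum_{j<b} M0[j]
    np.cumsum(M0, axis=0, out=P[1:])
    S1 = np.zeros((L + 1, n), dtype=np.int16)          # S1[b] = sum_{j>=b} M1[j]
    S1[:L] = np.cumsum(M1[::-1], axis=0)[::-1]
    Sm1 = np.zeros((L + 1, n), dtype=np.int16)         # Sm1[b] = sum_{j>=b} Mm1[j]
    Sm1[:L] = np.cumsum(Mm1[::-1], axis=0)[::-1]

    pam = _pam_ok(enc, guide.pam)
    out: List[Tuple[int, int, str, int, int]] = []

    def collect(mm: np.ndarray, site_len: int, btype: str, offset: int) -> None:
        last = n - site_len - plen  # last valid start (PAM must fit)
        if last < 0:
            return
        valid = mm[: last + 1] <= max_mm
        valid &= pam[site_len : site_len + last + 1]
        for i in np.flatnonzero(valid):
            out.append((int(i), site_len, btype, offset, int(mm[i])))

    collect(P[L], L, "none", -1)
    if params.max_dna_bulge and L >= 2:
        for b in range(1, L):
            collect(P[b] + S1[b], L + 1, "dna", b)
    if params.max_rna_bulge and L >= 3:
        for b in range(1, L - 1):
            collect(P[b] + Sm1[b + 1], L - 1, "rna", b)
    return out


def enumerate_sites(
    genome: Genome, guide: GuideRNA, params: SearchParams = SearchParams()
) -> List[CandidateSite]:
    """Enumerate every candidate site for ``guide`` in ``genome``.

    One site is reported per (chromosome, strand, locus start, bulge type):
    the minimum-mismatch alignment, ties broken by the smallest bulge
    offset. Output is sorted by (chrom, start, strand, bulge type).
    """
    if not genome.sequences:
        raise EmptyGenomeError("cannot search an empty genome")
    plen = len(guide.pam)
    # best[(chrom, strand, start, btype)] = (mm, offset, site_len)
    best: Dict[Tuple[str, str, int, str], Tuple[int, int, int]] = {}
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        for strand in params.strands:
            oriented = seq if strand == "+" else reverse_complement(seq)
            for i, site_len, btype, offset, mm in _scan_strand(oriented, guide, params):
                if strand == "+":
                    start = i
                else:
                    start = n - (i + site_len)
                key = (chrom, strand, start, btype)
                cand = (mm, offset, site_len)
                if key not in best or cand < best[key]:
                    best[key] = cand

    sites: List[CandidateSite] = []
    order = {"none": 0, "dna": 1, "rna": 2}
    for (chrom, strand, start, btype), (mm, offset, site_len) in sorted(
        best.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][1], order[kv[0][3]])
    ):
        locus = GenomicInterval(chrom, start, start + site_len, strand)
        if strand == "+":
            pam_locus = GenomicInterval(chrom, locus.end, locus.end + plen, "+")
        else:
            pam_locus = GenomicInterval(chrom, locus.start - plen, locus.start, "-")
        site_seq = fetch(genome, locus)
        pam_seq = fetch(genome, pam_locus)
        gseq = guide.protospacer
        if btype == "none":
            aligned_genome, aligned_guide = site_seq, gseq
            bulge_offset: Optional[int] = None
        elif btype == "dna":
            aligned_genome = site_seq
            aligned_guide = gseq[:offset] + "-" + gseq[offset:]
            bulge_offset = offset
        else:  # rna
            aligned_genome = site_seq[:offset] + "-" + site_seq[offset:]
            aligned_guide = gseq
            bulge_offset = offset
        sites.append(
            CandidateSite(
                guide_name=guide.name,
                locus=locus,
                pam_locus=pam_locus,
                mismatches=mm,
                bulge_type=btype,
                bulge_offset=bulge_offset,
                aligned_genome_seq=aligned_genome,
                aligned_guide_seq=aligned_guide,
                pam_seq=pam_seq,
            )
        )
    return sites


_SITE_COLUMNS = [
    "guide",
    "chrom",
    "start_1based",
    "end_1based",
    "strand",
    "mismatches",
    "bulge_type",
    "bulge_offset",
    "aligned_genome",
    "aligned_guide",
    "pam_seq",
]


def write_sites(sites: Iterable[CandidateSite], path: str | os.PathLike) -> None:
    """Write sites as TSV; coordinates are emitted 1-based inclusive."""
    with open(path, "w", newline="") as out:
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        w.writerow(_SITE_COLUMNS)
        for s in sites:
            w.writerow(
                [
                    s.guide_name,
                    s.locus.chrom,
                    s.locus.start + 1,
                    s.locus.end,
                    s.locus.strand,
                    s.mismatches,
                    s.bulge_type,
                    "." if s.bulge_offset is None else s.bulge_offset,
                    s.aligned_genome_seq,
                    s.aligned_guide_seq,
                    s.pam_seq,
                ]
            )


def read_sites(path: str | os.PathLike) -> List[CandidateSite]:
    """Read a sites TSV written by :func:`write_sites`."""
    sites: List[CandidateSite] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SitesParseError(f"{path}: empty file") from None
        if header != _SITE_COLUMNS:
            raise SitesParseError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_SITE_COLUMNS):
                raise SitesParseError(
                    f"{path}: line {lineno}: expected {len(_SITE_COLUMNS)} columns, got {len(row)}"
                )
            try:
                start = int(row[2]) - 1
                end = int(row[3])
                mm = int(row[5])
                offset = None if row[7] == "." else int(row[7])
            except ValueError as exc:
                raise SitesParseError(f"{path}: line {lineno}: {exc}") from None
            strand = row[4]
            locus = GenomicInterval(row[1], start, end, strand)
            plen = len(row[10])
            if strand == "+":
                pam_locus = GenomicInterval(row[1], end, end + plen, "+")
            else:
                pam_locus = GenomicInterval(row[1], start - plen, start, "-")
            sites.append(
                CandidateSite(
                    guide_name=row[0],
                    locus=locus,
                    pam_locus=pam_locus,
                    mismatches=mm,
                    bulge_type=row[6],
                    bulge_offset=offset,
                    aligned_genome_seq=row[8],
                    aligned_guide_seq=row[9],
                    pam_seq=row[10],
                )
            )
    return sites


def read_guides(path: str | os.PathLike) -> List[GuideRNA]:
    """Read guides from TSV/plain text: name, protospacer[, PAM] per line."""
    guides: List[GuideRNA] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:
                parts = [f"guide{lineno}", parts[0]]
            if len(parts) == 2:
                guides.append(GuideRNA(parts[0], parts[1].upper()))
            elif len(parts) == 3:
                guides.append(GuideRNA(parts[0], parts[1].upper(), parts[2].upper()))
            else:
                raise ValueError(f"{path}: line {lineno}: expected 1-3 fields")
    return guides
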