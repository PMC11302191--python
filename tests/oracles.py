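"""Independent brute-force oracles used to validate the implementation.

Deliberately naive: direct loops over every window, strand, and gap
placement, with no shared code paths with the package's vectorised scan
(only the frozen alignment-geometry convention is common, since both
sides must describe the same model).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _pam_ok(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, pattern))  # genomic N in no class


def _mismatches(guide: str, site: str, btype: str, b: int) -> int:
    if btype == "none":
        return sum(x != y or y == "N" for x, y in zip(guide, site))
    if btype == "dna":
        pairs = list(zip(guide[:b], site[:b])) + list(zip(guide[b:], site[b + 1 :]))
    else:  # rna
        pairs = list(zip(guide[:b], site[:b])) + list(zip(guide[b + 1 :], site[b:]))
    return sum(x != y or y == "N" for x, y in pairs)


def brute_force_sites(
    sequences: Dict[str, str],
    protospacer: str,
    pam: str = "NGG",
    max_mm: int = 3,
    dna_bulge: int = 1,
    rna_bulge: int = 1,
    strands: Tuple[str, ...] = ("+", "-"),
) -> Set[Tuple[str, str, int, str, int, Optional[int]]]:
    """All (chrom, strand, ref_start, bulge_type, mismatches, offset) tuples.

    Deduplicated per (chrom, strand, ref_start, bulge_type) keeping the
    minimum mismatch count, ties broken by smallest bulge offset — the
    documented reporting policy.
    """
    L = len(protospacer)
    plen = len(pam)
    configs: List[Tuple[str, int, int]] = [("none", 0, L)]
    if dna_bulge:
        configs += [("dna", b, L + 1) for b in range(1, L)]
    if rna_bulge:
        configs += [("rna", b, L - 1) for b in range(1, L - 1)]

    best: Dict[Tuple[str, str, int, str], Tuple[int, int]] = {}
    for chrom, seq in sequences.items():
        n = len(seq)
        for strand in strands:
            oriented = seq if strand == "+" else revcomp(seq)
            for btype, b, slen in configs:
                if slen <= 0:
                    continue
                for i in range(0, n - slen - plen + 1):
                    site = oriented[i : i + slen]
                    if not _pam_ok(oriented[i + slen : i + slen + plen], pam):
                        continue
                    mm = _mismatches(protospacer, site, btype, b)
                    if mm > max_mm:
                        continue
                    ref_start = i if strand == "+" else n - (i + slen)
                    key = (chrom, strand, ref_start, btype)
                    cand = (mm, b)
                    if key not in best or cand < best[key]:
                        best[key] = cand
    return {
        (chrom, strand, start, btype, mm, None if btype == "none" else b)
        for (chrom, strand, start, btype), (mm, b) in best.items()
    }


def apply_variant(seq: str, pos1: int, ref: str, alt: str) -> str:
    """Edited haplotype from string surgery (normalization oracle)."""
    start = pos1 - 1
    assert seq[start : start + len(ref)] == ref
    return seq[:start] + alt + seq[start + len(ref) :]
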