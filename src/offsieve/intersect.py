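"""The candidate funnel: match InDels to predicted sites, subtract parental
variants, verify guide identity + PAM, annotate known natural variation,
and assign verdicts.

Stages flag rather than delete, so the whole funnel stays auditable: every
(variant, site) pairing survives to the final table with its provenance
flags, and stage counts can be reconstructed from the calls alone.

Verdict precedence: a variant also present in the parental line is
``excluded_parental`` (inheritance explains it); otherwise a match to the
known-natural-variation set is ``natural_variation``; otherwise a call
whose locus re-verifies (guide identity within the mismatch budget plus an
adjacent PAM) is ``plausible_crispr``; anything left is ``unresolved``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .reference import Genome, GenomicInterval, fetch
from .search import CandidateSite, GuideRNA, SearchParams, enumerate_sites, match_pam
from .variants import VariantRecord

__all__ = [
    "OffTargetCall",
    "WindowParams",
    "intersect_sites",
    "subtract_parental",
    "verify_pam_identity",
    "annotate_known_variation",
    "assign_verdicts",
    "summarize_frequencies",
    "classify_validation",
    "UnsortedSitesError",
]

VERDICTS = ("excluded_parental", "natural_variation", "plausible_crispr", "unresolved")


class UnsortedSitesError(ValueError):
    """intersect_sites requires sites sorted by (chrom, start)."""


@dataclass(frozen=True)
class WindowParams:
    """Symmetric padding (bp) applied around a variant's REF span."""

    pad_bp: int = 50

    def __post_init__(self) -> None:
        if self.pad_bp < 0:
            raise ValueError("pad_bp must be non-negative")


@dataclass(frozen=True)
class OffTargetCall:
    """One (variant, candidate site) pairing with provenance flags."""

    variant: VariantRecord
    site: CandidateSite
    distance_bp: int
    in_parent: bool = False
    known_natural: bool = False
    pam_verified: bool = False
    realign_mismatches: Optional[int] = None
    verdict: str = "unresolved"


def _site_span(site: CandidateSite) -> Tuple[int, int]:
    """Protospacer + PAM footprint on the reference, 0-based half-open."""
    return (
        min(site.locus.start, site.pam_locus.start),
        max(site.locus.end, site.pam_locus.end),
    )


def _gap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Distance between two half-open intervals; 0 when touching/overlapping."""
    return max(0, a[0] - b[1], b[0] - a[1])


def intersect_sites(
    indels: Sequence[VariantRecord],
    sites: Sequence[CandidateSite],
    w: WindowParams = WindowParams(),
) -> List[OffTargetCall]:
    """Pair each InDel with every predicted site within the padded window.

    A pair is emitted when the variant's REF span, padded by ``pad_bp`` on
    each side, reaches the site's protospacer+PAM footprint, i.e. when the
    gap between the unpadded intervals is at most ``pad_bp``. A variant
    overlapping k sites yields k calls.
    """
    for prev, cur in zip(sites, sites[1:]):
        if (prev.locus.chrom, prev.locus.start) > (cur.locus.chrom, cur.locus.start):
            raise UnsortedSitesError(
                f"sites not sorted at {cur.locus.chrom}:{cur.locus.start}"
            )
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, site in enumerate(sites):
        lo, hi = _site_span(site)
        trees[site.locus.chrom].addi(lo, hi, idx)
    calls: List[OffTargetCall] = []
    for var in indels:
        tree = trees.get(var.chrom)
        if tree is None:
            continue
        lo, hi = var.span
        # query one bp wider on each side; the exact gap test below decides
        hits = sorted(tree.overlap(lo - w.pad_bp - 1, hi + w.pad_bp + 1), key=lambda h: h.data)
        for hit in hits:
            site = sites[hit.data]
            d = _gap(var.span, _site_span(site))
            if d <= w.pad_bp:
                calls.append(OffTargetCall(variant=var, site=site, distance_bp=d))
    return calls


def _allele_key_set(records: Iterable[VariantRecord]) -> Set[Tuple[str, int, str, str]]:
    keys: Set[Tuple[str, int, str, str]] = set()
    for rec in records:
        keys.update(rec.allele_keys())
    return keys


def subtract_parental(
    calls: Sequence[OffTargetCall], parental: Sequence[VariantRecord]
) -> List[OffTargetCall]:
    """Flag calls whose variant also appears in the parental line.

    Matching is allele-exact on normalized (chrom, pos, ref, alt) and
    genotype-agnostic; any ALT allele match flags the call. Calls are
    flagged, never deleted.
    """
    parental_keys = _allele_key_set(parental)
    out: List[OffTargetCall] = []
    for call in calls:
        hit = any(k in parental_keys for k in call.variant.allele_keys())
        out.append(replace(call, in_parent=hit))
    return out


def annotate_known_variation(
    calls: Sequence[OffTargetCall], known: Sequence[VariantRecord]
) -> List[OffTargetCall]:
    """Flag calls whose variant matches the known natural-variation set."""
    known_keys = _allele_key_set(known)
    out: List[OffTargetCall] = []
    for call in calls:
        hit = any(k in known_keys for k in call.variant.allele_keys())
        out.append(replace(call, known_natural=hit))
    return out


def _best_window_alignment(
    window_seq: str, guide: GuideRNA, params: SearchParams
) -> Tuple[Optional[int], Optional[int]]:
    """Best guide placements in a window.

    Scores every gapless and single-bulge placement on both strands and
    returns ``(best_mm_any, best_mm_pam)``: the minimum mismatch count
    over all placements, and over placements with a PAM-matching triplet
    immediately 3' of the protospacer. Either is None when no placement
    of that kind fits in the window.
    """
    from .reference import reverse_complement
    from .search import score_alignment

    L = len(guide.protospacer)
    plen = len(guide.pam)
    best_any: Optional[int] = None
    best_pam: Optional[int] = None
    for oriented in (window_seq, reverse_complement(window_seq)):
        n = len(oriented)
        placements: List[Tuple[int, str, int]] = [(L, "none", 0)]
        placements += [(L + 1, "dna", b) for b in range(1, L)]
        if L >= 3:
            placements += [(L - 1, "rna", b) for b in range(1, L - 1)]
        for site_len, btype, b in placements:
            for i in range(0, n - site_len + 1):
                site = oriented[i : i + site_len]
                mm = score_alignment(
                    guide.protospacer, site, btype, b if btype != "none" else None
                )
                if best_any is None or mm < best_any:
                    best_any = mm
                pam_seq = oriented[i + site_len : i + site_len + plen]
                if len(pam_seq) == plen and match_pam(pam_seq, guide.pam):
                    if best_pam is None or mm < best_pam:
                        best_pam = mm
    return best_any, best_pam


def verify_pam_identity(
    call: OffTargetCall,
    genome: Genome,
    guide: GuideRNA,
    max_realign_mm: int = 6,
    w: WindowParams = WindowParams(),
    params: Optional[SearchParams] = None,
) -> OffTargetCall:
    """Re-fetch the site's padded window, realign the guide, re-check the PAM.

    Scores every placement of the guide in the window; the verification
    asks whether some PAM-adjacent placement reproduces guide identity
    within ``max_realign_mm`` mismatches. ``realign_mismatches`` records
    the best PAM-adjacent mismatch count (falling back to the best
    overall placement when no PAM-adjacent one exists, with
    ``pam_verified`` False). Windows are clipped at chromosome ends.
    """
    if params is None:
        params = SearchParams(max_mismatches=max_realign_mm)
    lo, hi = _site_span(call.site)
    chrom_len = genome.lengths[call.site.locus.chrom]
    lo = max(0, lo - w.pad_bp)
    hi = min(chrom_len, hi + w.pad_bp)
    window = fetch(genome, GenomicInterval(call.site.locus.chrom, lo, hi, "+"))
    best_any, best_pam = _best_window_alignment(window, guide, params)
    verified = best_pam is not None and best_pam <= max_realign_mm
    realign = best_pam if best_pam is not None else best_any
    return replace(call, realign_mismatches=realign, pam_verified=verified)


def assign_verdicts(calls: Sequence[OffTargetCall]) -> List[OffTargetCall]:
    """Apply verdict precedence: parental > known-natural > PAM-verified."""
    out: List[OffTargetCall] = []
    for call in calls:
        if call.in_parent:
            verdict = "excluded_parental"
        elif call.known_natural:
            verdict = "natural_variation"
        elif call.pam_verified:
            verdict = "plausible_crispr"
        else:
            verdict = "unresolved"
        out.append(replace(call, verdict=verdict))
    return out


def summarize_frequencies(
    calls_by_animal: Mapping[str, Sequence[OffTargetCall]],
) -> List[Dict[str, object]]:
    """Per-locus carrier frequency across animals, as "k/n (percent)" rows.

    A locus (guide, chrom, site span) counts an animal as a carrier when
    the animal has at least one ``plausible_crispr`` call there. ``n`` is
    the number of animals supplied.
    """
    n = len(calls_by_animal)
    carriers: Dict[Tuple[str, str, int, int], Set[str]] = defaultdict(set)
    site_meta: Dict[Tuple[str, str, int, int], CandidateSite] = {}
    for animal, calls in calls_by_animal.items():
        for call in calls:
            if call.verdict != "plausible_crispr":
                continue
            key = (
                call.site.guide_name,
                call.site.locus.chrom,
                call.site.locus.start,
                call.site.locus.end,
            )
            carriers[key].add(animal)
            site_meta.setdefault(key, call.site)
    rows: List[Dict[str, object]] = []
    for key in sorted(carriers):
        guide_name, chrom, start, end = key
        k = len(carriers[key])
        pct = round(100.0 * k / n, 1) if n else 0.0
        rows.append(
            {
                "guide": guide_name,
                "chrom": chrom,
                "start_1based": start + 1,
                "end_1based": end,
                "carriers": k,
                "animals": n,
                "frequency": f"{k}/{n} ({pct}%)",
            }
        )
    return rows


def format_frequency(k: int, n: int) -> str:
    """Render a carrier count as the conventional "k/n (percent)" string."""
    pct = round(100.0 * k / n, 1) if n else 0.0
    return f"{k}/{n} ({pct}%)"


def classify_validation(
    validation_genotypes: Mapping[str, Sequence[VariantRecord]],
    locus: GenomicInterval,
    known: Sequence[VariantRecord],
    genome: Genome,
    guide: GuideRNA,
    max_realign_mm: int = 6,
    w: WindowParams = WindowParams(),
) -> str:
    """Classify a candidate locus from independent validation genotypes.

    ``validation_genotypes`` maps embryo id -> variants called in that
    embryo. The locus is ``confirmed_off_target`` when at least one embryo
    carries a locus-specific InDel, the InDel set does not match known
    natural variation, and the guide re-verifies at the locus (identity
    within the mismatch budget plus an adjacent PAM). A known-variation
    match is ``natural_variation``; no InDel in any embryo (or a failed
    PAM re-verification) is ``not_detected``.
    """
    if not validation_genotypes:
        raise ValueError("at least one embryo genotype is required")
    locus_span = (locus.start, locus.end)
    hits: List[VariantRecord] = []
    for _embryo, recs in validation_genotypes.items():
        for rec in recs:
            if rec.chrom != locus.chrom or rec.var_class == "SNP":
                continue
            if _gap(rec.span, locus_span) == 0:
                hits.append(rec)
    if not hits:
        return "not_detected"
    known_keys = _allele_key_set(known)
    if any(k in known_keys for rec in hits for k in rec.allele_keys()):
        return "natural_variation"
    chrom_len = genome.lengths[locus.chrom]
    lo = max(0, locus.start - w.pad_bp)
    hi = min(chrom_len, locus.end + w.pad_bp)
    window = fetch(genome, GenomicInterval(locus.chrom, lo, hi, "+"))
    _best_any, best_pam = _best_window_alignment(
        window, guide, SearchParams(max_mismatches=max_realign_mm)
    )
    if best_pam is not None and best_pam <= max_realign_mm:
        return "confirmed_off_target"
    return "not_detected"
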