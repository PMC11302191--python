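"""Self-contained synthetic fixture generation.

Emulates the study design of a gene-edited founder cohort from an outbred
species: a small multi-chromosome reference, one guide, planted off-target
sites (known mismatch/bulge profiles plus an NGG PAM), an exact on-target
locus, per-animal offspring VCFs containing inherited natural variants
(shared with a sequenced sire), de novo natural variants (standing in for
the unknown maternal contribution), and CRISPR-induced InDels at planted
sites; plus per-tissue on-target allele mixtures so that a configurable
fraction of animals is mosaic. Every emitted record carries a provenance
label in a machine-readable truth table.

The background genome is i.i.d. uniform A/C/G/T. After planting, the
genome is swept with the search engine and any accidental site outside
the planted cassettes has its PAM broken (a G of the NGG is mutated),
repeating until the only sites found lie within planted cassettes. All
randomness flows from a single numpy generator, so a seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .reference import Genome, GenomicInterval, reverse_complement, write_fasta
from .search import GuideRNA, SearchParams, enumerate_sites
from .variants import VariantRecord, normalize_variant, write_vcf

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "SimulationBundle",
    "simulate",
    "write_bundle",
    "InfeasibleConfigError",
]

_BASES = np.array(list("ACGT"))


class InfeasibleConfigError(ValueError):
    """The requested sites/variants cannot be placed in the genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 20000
    guide_length: int = 20
    n_planted_sites: int = 8
    # (mismatches, bulge_type) cycled over planted off-target sites
    planted_mismatch_profile: Tuple[Tuple[int, str], ...] = (
        (2, "none"),
        (3, "none"),
        (4, "none"),
        (6, "none"),
        (3, "dna"),
        (4, "rna"),
        (5, "none"),
        (6, "dna"),
    )
    natural_indel_rate: float = 5e-4       # per bp, per animal
    natural_snp_rate: float = 2e-3         # per bp, per animal
    lowqual_fraction: float = 0.05         # natural variants given failing annotations
    inherited_fraction: float = 0.5        # natural variant also present in the sire
    crispr_edit_penetrance: float = 0.3    # planted site edited in a given animal
    n_animals: int = 6
    tissues: Tuple[str, ...] = ("brain", "lung", "muscle", "spleen")
    mosaic_animal_fraction: float = 1.0 / 3.0
    pad_bp: int = 50
    max_mismatches: int = 6
    max_dna_bulge: int = 1
    max_rna_bulge: int = 1
    max_sanitize_rounds: int = 60

    def search_params(self) -> SearchParams:
        return SearchParams(self.max_mismatches, self.max_dna_bulge, self.max_rna_bulge)


@dataclass(frozen=True)
class PlantedSite:
    site_id: str
    kind: str                 # on_target | off_target
    chrom: str
    start: int                # protospacer span, 0-based half-open
    end: int
    strand: str
    mismatches: int
    bulge_type: str

    @property
    def cassette(self) -> Tuple[int, int]:
        """Protospacer + PAM footprint on the reference."""
        if self.strand == "+":
            return (self.start, self.end + 3)
        return (self.start - 3, self.end)

    @property
    def cut_pos(self) -> int:
        """Approximate blunt cut: 3 bp inside the PAM-proximal end."""
        return self.end - 3 if self.strand == "+" else self.start + 3


@dataclass
class SimulationBundle:
    """An in-memory fixture cohort plus its ground truth."""

    config: SimulationConfig
    genome: Genome
    guide: GuideRNA
    planted_sites: List[PlantedSite]
    on_target: PlantedSite
    parental: List[VariantRecord]
    tissue_records: Dict[str, Dict[str, List[VariantRecord]]]  # animal -> tissue -> recs
    truth_rows: List[Dict[str, object]]
    animal_truth: Dict[str, Dict[str, object]]

    @property
    def animals(self) -> List[str]:
        return list(self.tissue_records)

    def animal_records(self, animal: str) -> List[VariantRecord]:
        """The representative whole-animal sample (first tissue's VCF)."""
        first = self.config.tissues[0]
        return self.tissue_records[animal][first]

    @property
    def on_target_locus(self) -> GenomicInterval:
        s = self.on_target
        return GenomicInterval(s.chrom, s.start, s.end, s.strand)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _site_sequence(
    rng: np.random.Generator, guide: str, mismatches: int, bulge_type: str
) -> str:
    """Derive a genomic protospacer carrying the requested divergence."""
    L = len(guide)
    seq = list(guide)
    if mismatches > L:
        raise InfeasibleConfigError(f"{mismatches} mismatches exceed guide length {L}")
    for j in rng.choice(L, size=mismatches, replace=False):
        seq[j] = _mutate_base(rng, seq[j])
    if bulge_type == "none":
        return "".join(seq)
    if bulge_type == "dna":  # extra genomic base, internal column
        b = int(rng.integers(1, L))
        return "".join(seq[:b]) + str(_BASES[rng.integers(0, 4)]) + "".join(seq[b:])
    if bulge_type == "rna":  # one guide base unpaired: genomic window is shorter
        b = int(rng.integers(1, L - 1))
        return "".join(seq[:b]) + "".join(seq[b + 1 :])
    raise ValueError(f"unknown bulge_type {bulge_type!r}")


def _plant(
    chrom_seqs: Dict[str, list],
    site: str,
    pam: str,
    chrom: str,
    pos: int,
    strand: str,
) -> Tuple[int, int]:
    """Write a protospacer+PAM cassette into the genome; return protospacer span."""
    cassette = site + pam if strand == "+" else reverse_complement(site + pam)
    seq = chrom_seqs[chrom]
    seq[pos : pos + len(cassette)] = list(cassette)
    if strand == "+":
        return pos, pos + len(site)
    return pos + len(pam), pos + len(cassette)


def _good_info(rng: np.random.Generator) -> Dict[str, float]:
    return {
        "QD": round(float(rng.uniform(15, 35)), 2),
        "FS": round(float(rng.uniform(0, 5)), 3),
        "MQ": 60.0,
        "MQRankSum": round(float(np.clip(rng.normal(0, 1), -3, 3)), 3),
        "ReadPosRankSum": round(float(np.clip(rng.normal(0, 1), -3, 3)), 3),
        "SOR": round(float(rng.uniform(0.5, 2.0)), 3),
    }


def _lowqual_info(rng: np.random.Generator) -> Dict[str, float]:
    info = _good_info(rng)
    info["QD"] = 1.0  # trips the QD < 2.0 hard filter for SNPs and InDels alike
    return info


def _overlaps_any(start: int, end: int, zones: Sequence[Tuple[int, int]]) -> bool:
    return any(start < z1 and z0 < end for z0, z1 in zones)


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Generate one deterministic cohort bundle from ``config``."""
    rng = np.random.default_rng(config.seed)
    L = config.guide_length
    guide = GuideRNA("sgRNA-sim", _rand_seq(rng, L))
    pad = config.pad_bp

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_seqs: Dict[str, list] = {
        name: list(_rand_seq(rng, config.chrom_length)) for name in chrom_names
    }

    # --- plant the on-target cassette plus the off-target cassettes -------
    slot_width = L + 1 + 3
    spacing = slot_width + 2 * pad + 60
    per_chrom_slots: Dict[str, int] = {name: 0 for name in chrom_names}
    n_sites_total = config.n_planted_sites + 1
    capacity = config.n_chroms * ((config.chrom_length - 200) // spacing)
    if n_sites_total > capacity:
        raise InfeasibleConfigError(
            f"{n_sites_total} sites do not fit: capacity {capacity} "
            f"({config.n_chroms} x {config.chrom_length} bp at spacing {spacing})"
        )

    planted: List[PlantedSite] = []
    profile = config.planted_mismatch_profile
    for idx in range(n_sites_total):
        chrom = chrom_names[idx % config.n_chroms]
        slot = per_chrom_slots[chrom]
        per_chrom_slots[chrom] += 1
        pos = 100 + slot * spacing + int(rng.integers(0, 40))
        if idx == 0:
            mm, btype, kind, site_id = 0, "none", "on_target", "on_target"
            site_seq = guide.protospacer
            strand = "+"
        else:
            mm, btype = profile[(idx - 1) % len(profile)]
            kind, site_id = "off_target", f"site{idx:02d}"
            site_seq = _site_sequence(rng, guide.protospacer, mm, btype)
            strand = "+" if rng.random() < 0.5 else "-"
        pam_seq = str(_BASES[rng.integers(0, 4)]) + "GG"
        start, end = _plant(chrom_seqs, site_seq, pam_seq, chrom, pos, strand)
        planted.append(
            PlantedSite(site_id, kind, chrom, start, end, strand, mm, btype)
        )

    cassettes: Dict[str, List[Tuple[int, int]]] = {name: [] for name in chrom_names}
    for s in planted:
        cassettes[s.chrom].append(s.cassette)

    # --- sweep out accidental sites by breaking their PAMs ----------------
    params = config.search_params()
    for round_no in range(config.max_sanitize_rounds):
        genome = Genome({name: "".join(seq) for name, seq in chrom_seqs.items()})
        extras = [
            s
            for s in enumerate_sites(genome, guide, params)
            if not _overlaps_any(s.locus.start, s.locus.end, cassettes[s.locus.chrom])
        ]
        if not extras:
            break
        for s in extras:
            # mutate one G of the NGG (reference coordinates) to kill the PAM
            if s.locus.strand == "+":
                targets = [s.pam_locus.start + 1, s.pam_locus.start + 2]
                breakers = "ACT"
            else:
                targets = [s.pam_locus.start, s.pam_locus.start + 1]  # CCN on ref
                breakers = "AGT"
            patched = False
            for t in targets:
                if not _overlaps_any(t, t + 1, cassettes[s.locus.chrom]):
                    chrom_seqs[s.locus.chrom][t] = breakers[int(rng.integers(0, 3))]
                    patched = True
                    break
            if not patched:
                # PAM shared with a cassette: degrade the protospacer instead
                for t in range(s.locus.start, s.locus.end):
                    if not _overlaps_any(t, t + 1, cassettes[s.locus.chrom]):
                        chrom_seqs[s.locus.chrom][t] = _mutate_base(
                            rng, chrom_seqs[s.locus.chrom][t]
                        )
    else:
        raise InfeasibleConfigError(
            f"accidental-site sweep did not converge in {config.max_sanitize_rounds} rounds"
        )
    genome = Genome({name: "".join(seq) for name, seq in chrom_seqs.items()})

    on_target = planted[0]
    off_sites = planted[1:]

    # --- per-animal variants ----------------------------------------------
    animals = [f"pig{idx + 1}" for idx in range(config.n_animals)]
    truth_rows: List[Dict[str, object]] = []
    animal_truth: Dict[str, Dict[str, object]] = {}
    parental: List[VariantRecord] = []
    parental_keys: Set[Tuple[str, int, str, str]] = set()
    de_novo_keys: Set[Tuple[str, int, str, str]] = set()
    tissue_records: Dict[str, Dict[str, List[VariantRecord]]] = {}

    # naturals are kept out of the on-target neighbourhood so the mosaic
    # allele accounting stays exact; off-target windows are fair game
    on_zone = (
        max(0, on_target.cassette[0] - pad - 60),
        on_target.cassette[1] + pad + 60,
    )

    def natural_indel(chrom: str, anchor0: int, info: Dict[str, float], sample: str) -> VariantRecord:
        seq = genome.sequences[chrom]
        if rng.random() < 0.5:  # deletion of 1-5 bp
            dl = int(rng.integers(1, 6))
            ref = seq[anchor0 : anchor0 + dl + 1]
            alt = seq[anchor0]
        else:  # insertion of 1-5 bp
            ref = seq[anchor0]
            alt = ref + _rand_seq(rng, int(rng.integers(1, 6)))
        rec = VariantRecord(chrom, anchor0 + 1, ref, (alt,), info=info,
                            genotypes={sample: (0, 1)})
        return normalize_variant(rec, genome)

    def natural_snp(chrom: str, anchor0: int, info: Dict[str, float], sample: str) -> VariantRecord:
        seq = genome.sequences[chrom]
        ref = seq[anchor0]
        return VariantRecord(chrom, anchor0 + 1, ref, (_mutate_base(rng, ref),),
                             info=info, genotypes={sample: (0, 1)})

    def crispr_indel(site: PlantedSite, sample: str) -> VariantRecord:
        seq = genome.sequences[site.chrom]
        cut = site.cut_pos
        if rng.random() < 0.7:  # deletion of 1-32 bp spanning near the cut
            dl = int(rng.integers(1, 33))
            anchor0 = max(1, cut - int(rng.integers(0, 11)) - 1)
            anchor0 = min(anchor0, len(seq) - dl - 2)
            ref = seq[anchor0 : anchor0 + dl + 1]
            alt = seq[anchor0]
        else:  # insertion of 1-6 bp at the cut
            anchor0 = max(1, cut - 1)
            ref = seq[anchor0]
            alt = ref + _rand_seq(rng, int(rng.integers(1, 7)))
        rec = VariantRecord(site.chrom, anchor0 + 1, ref, (alt,),
                            info=_good_info(rng), genotypes={sample: (0, 1)})
        return normalize_variant(rec, genome)

    for animal in animals:
        sample = animal
        used_keys: Set[Tuple[str, int, str, str]] = set()
        shared: List[Tuple[VariantRecord, str, str]] = []  # (rec, label, expected_filter)

        # natural background variants
        for chrom in chrom_names:
            clen = len(genome.sequences[chrom])
            n_ind = int(rng.poisson(config.natural_indel_rate * clen))
            n_snp = int(rng.poisson(config.natural_snp_rate * clen))
            for kind, count in (("indel", n_ind), ("snp", n_snp)):
                for _ in range(count):
                    for _try in range(30):
                        anchor0 = int(rng.integers(1, clen - 40))
                        if chrom == on_target.chrom and on_zone[0] <= anchor0 < on_zone[1]:
                            continue
                        lowq = rng.random() < config.lowqual_fraction
                        info = _lowqual_info(rng) if lowq else _good_info(rng)
                        rec = (
                            natural_indel(chrom, anchor0, info, sample)
                            if kind == "indel"
                            else natural_snp(chrom, anchor0, info, sample)
                        )
                        key = rec.allele_keys()[0]
                        inherited = rng.random() < config.inherited_fraction
                        if key in used_keys:
                            continue
                        if inherited and key in de_novo_keys:
                            continue
                        if not inherited and key in parental_keys:
                            continue
                        used_keys.add(key)
                        label = "natural_inherited" if inherited else "natural_de_novo"
                        if inherited:
                            if key not in parental_keys:
                                parental_keys.add(key)
                                parental.append(
                                    VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts,
                                                  info=dict(rec.info),
                                                  genotypes={"sire": (0, 1)})
                                )
                        else:
                            de_novo_keys.add(key)
                        shared.append((rec, label, "FAIL" if lowq else "PASS"))
                        break

        # CRISPR off-target edits per planted site
        for site in off_sites:
            if rng.random() < config.crispr_edit_penetrance:
                for _try in range(30):
                    rec = crispr_indel(site, sample)
                    key = rec.allele_keys()[0]
                    if key in used_keys or key in parental_keys:
                        continue
                    used_keys.add(key)
                    shared.append((rec, "crispr_off_target", "PASS"))
                    truth_rows.append(
                        {"animal": animal, "tissues": "*", "chrom": rec.chrom,
                         "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                         "label": "crispr_off_target", "expected_filter": "PASS",
                         "site_id": site.site_id}
                    )
                    break

        for rec, label, expected in shared:
            if label.startswith("natural"):
                truth_rows.append(
                    {"animal": animal, "tissues": "*", "chrom": rec.chrom,
                     "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                     "label": label, "expected_filter": expected, "site_id": ""}
                )

        # on-target allele mixture across tissues
        mosaic = rng.random() < config.mosaic_animal_fraction
        n_alleles = int(rng.integers(3, 5)) if mosaic else int(rng.integers(1, 3))
        pool: List[VariantRecord] = []
        pool_keys: Set[Tuple[int, str, str]] = set()
        for _try in range(200):
            if len(pool) == n_alleles:
                break
            rec = crispr_indel(on_target, sample)
            k = (rec.pos, rec.ref, rec.alts[0])
            if k in pool_keys:
                continue
            pool_keys.add(k)
            pool.append(rec)
        if len(pool) < n_alleles:
            raise InfeasibleConfigError("could not draw distinct on-target alleles")

        tissues = list(config.tissues)
        tissue_alleles: Dict[str, List[VariantRecord]] = {}
        if mosaic and len(tissues) >= 2:
            # one wild-type tissue plus leave-one-out mixtures elsewhere
            tissue_alleles[tissues[0]] = list(pool)
            tissue_alleles[tissues[1]] = []
            for j, t in enumerate(tissues[2:]):
                drop = j % n_alleles
                tissue_alleles[t] = [r for i, r in enumerate(pool) if i != drop]
        else:
            for t in tissues:
                tissue_alleles[t] = list(pool)

        base_records = [rec for rec, _label, _exp in shared]
        tissue_records[animal] = {}
        for t in tissues:
            recs = base_records + tissue_alleles[t]
            recs.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alts))
            tissue_records[animal][t] = recs
        for rec in pool:
            carrying = sorted(t for t in tissues if rec in tissue_alleles[t])
            truth_rows.append(
                {"animal": animal, "tissues": ",".join(carrying), "chrom": rec.chrom,
                 "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
                 "label": "crispr_on_target", "expected_filter": "PASS",
                 "site_id": "on_target"}
            )
        animal_truth[animal] = {
            "mosaic": bool(mosaic and (len(tissues) >= 2 or n_alleles > 2)),
            "n_on_alleles": len(pool),
        }

    parental.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alts))
    return SimulationBundle(
        config=config,
        genome=genome,
        guide=guide,
        planted_sites=off_sites,
        on_target=on_target,
        parental=parental,
        tissue_records=tissue_records,
        truth_rows=truth_rows,
        animal_truth=animal_truth,
    )


def write_bundle(bundle: SimulationBundle, out_dir: str | os.PathLike) -> Dict[str, str]:
    """Emit the bundle as FASTA + guides TSV + VCFs + truth TSVs; return paths."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    fasta = os.path.join(out_dir, "genome.fa")
    write_fasta(bundle.genome, fasta)
    paths["fasta"] = fasta

    guides = os.path.join(out_dir, "guides.tsv")
    with open(guides, "w") as fh:
        fh.write(f"{bundle.guide.name}\t{bundle.guide.protospacer}\t{bundle.guide.pam}\n")
    paths["guides"] = guides

    contigs = bundle.genome.lengths
    parental_path = os.path.join(out_dir, "parental.vcf")
    write_vcf(bundle.parental, parental_path, contigs, samples=["sire"])
    paths["parental"] = parental_path

    for animal, tissues in bundle.tissue_records.items():
        for tissue, recs in tissues.items():
            vdir = os.path.join(out_dir, animal)
            os.makedirs(vdir, exist_ok=True)
            vpath = os.path.join(vdir, f"{tissue}.vcf")
            write_vcf(recs, vpath, contigs, samples=[animal])
            paths[f"{animal}/{tissue}"] = vpath

    truth = os.path.join(out_dir, "truth_variants.tsv")
    with open(truth, "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["animal", "tissues", "chrom", "pos", "ref", "alt",
                        "label", "expected_filter", "site_id"],
            delimiter="\t", lineterminator="\n",
        )
        w.writeheader()
        for row in bundle.truth_rows:
            w.writerow(row)
    paths["truth_variants"] = truth

    sites = os.path.join(out_dir, "truth_sites.tsv")
    with open(sites, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["site_id", "kind", "chrom", "start_1based", "end_1based",
                    "strand", "mismatches", "bulge_type"])
        for s in [bundle.on_target] + bundle.planted_sites:
            w.writerow([s.site_id, s.kind, s.chrom, s.start + 1, s.end,
                        s.strand, s.mismatches, s.bulge_type])
    paths["truth_sites"] = sites

    animals = os.path.join(out_dir, "truth_animals.tsv")
    with open(animals, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["animal", "mosaic", "n_on_alleles"])
        for animal, info in bundle.animal_truth.items():
            w.writerow([animal, int(bool(info["mosaic"])), info["n_on_alleles"]])
    paths["truth_animals"] = animals
    return paths
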