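"""Synthetic mosaic-genome datasets with known ground truth.

The generator emulates the statistical structure a resequencing-based
introgression analysis assumes: a focal inbred line whose genome is a
cultivated background carrying wild-donor segments with strongly elevated
variant density; a multi-species accession panel for tree building; gene
models whose functional descriptions do or do not carry candidate
keywords; QTL intervals overlapping some genes; and promoters with
planted cis-element motifs.  Every file the pipeline consumes is emitted,
together with a :class:`TruthSet` recording what was planted where.

All randomness flows from the single ``seed`` through one
``numpy.random.Generator``; identical configs give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import candidate_prioritization as cp
from .effect_annotation import (
    HIGH,
    IMPACT_OF,
    MODERATE,
    EffectAnnotation,
    GeneIndex,
    GeneModel,
    annotate_effect,
    annotate_variants,
    locate_variant,
    write_gff3,
)
from .errors import ConfigurationError, UnsatisfiableEffectError
from .promoter_motifs import Motif, load_motif_catalog, write_motif_catalog
from .variant_io import HOM_ALT, SNP, VariantRecord, write_vcf

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)

KEYWORD_DESCRIPTIONS = (
    "Heat shock protein 70",
    "Chaperone protein DnaJ",
    "Heat stress transcription factor A-2",
    "Flowering locus T",
    "Pollen-specific LRR extensin-like protein",
    "Anther-specific protein LAT52",
)
NEUTRAL_DESCRIPTIONS = (
    "Ubiquitin ligase",
    "Ribosomal protein L3",
    "Cytochrome P450",
    "Kinesin motor domain protein",
    "Pectin methylesterase",
    "Unknown protein",
)

# effects planted by default in each targeted gene
DEFAULT_PLANTED_EFFECTS = (
    "missense_variant",
    "synonymous_variant",
    "stop_gained",
    "frameshift_variant",
    "conservative_inframe_deletion",
    "disruptive_inframe_insertion",
    "intron_variant",
    "five_prime_UTR_variant",
    "upstream_gene_variant",
)


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 3
    chrom_length_bp: int = 10_000_000
    n_genes_per_chrom: int = 20
    # (chrom, start, end), 1-based inclusive
    introgression_segments: tuple[tuple[str, int, int], ...] = (("chr1", 2_000_001, 8_000_000),)
    background_rate: float = 50.0       # expected variants per Mb outside segments
    introgression_rate: float = 1000.0  # expected variants per Mb inside segments
    indel_fraction: float = 0.12
    n_species: int = 4
    n_accessions_per_species: int = 3
    species_divergence: float = 0.05    # per-site alt probability per species branch
    n_panel_sites_per_chrom: int = 300
    plant_effects: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes: must be >= 1")
        if self.chrom_length_bp < 100_000:
            raise ConfigurationError("chrom_length_bp: must be >= 100000")
        if self.n_genes_per_chrom < 1:
            raise ConfigurationError("n_genes_per_chrom: must be >= 1")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate: must be >= 0")
        if self.introgression_rate < self.background_rate:
            raise ConfigurationError(
                "introgression_rate: must be >= background_rate "
                f"({self.introgression_rate} < {self.background_rate})"
            )
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ConfigurationError("indel_fraction: must be in [0, 1]")
        if self.n_species < 2:
            raise ConfigurationError("n_species: must be >= 2 (cultivated + >=1 wild)")
        if self.n_accessions_per_species < 1:
            raise ConfigurationError("n_accessions_per_species: must be >= 1")
        if not 0.0 <= self.species_divergence <= 1.0:
            raise ConfigurationError("species_divergence: must be in [0, 1]")
        chroms = set(self.chromosomes)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.introgression_segments:
            if chrom not in chroms:
                raise ConfigurationError(f"introgression_segments: unknown chromosome {chrom!r}")
            if not (1 <= s < e <= self.chrom_length_bp):
                raise ConfigurationError(
                    f"introgression_segments: ({chrom},{s},{e}) outside chromosome bounds"
                )
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ConfigurationError(f"introgression_segments: overlap on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosomes}

    def segments_on(self, chrom: str) -> list[tuple[int, int]]:
        return sorted((s, e) for c, s, e in self.introgression_segments if c == chrom)

    @property
    def species(self) -> list[str]:
        return ["cultivated"] + [f"wild_{i}" for i in range(1, self.n_species)]

    @property
    def donor_species(self) -> str:
        return "wild_1"


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    segments: list[dict]                      # chrom/start/end of true introgressions
    planted_variants: list[dict]              # variant key + intended effect and tier
    donor_variant_keys: list[list]            # (chrom,pos,ref,alt) carried by the donor
    planted_motifs: list[dict]                # gene, motif, promoter offset
    intended_candidates: list[str]            # gene ids the prioritization should select
    planted_candidates: list[str]             # subset guaranteed by planting alone
    focal_variant_count: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    @property
    def donor_key_set(self) -> set[tuple[str, int, str, str]]:
        return {(c, int(p), r, a) for c, p, r, a in self.donor_variant_keys}


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    outdir: Path
    reference_fasta: Path
    genes_gff: Path
    focal_vcf: Path
    donor_vcf: Path
    panel_vcf: Path
    qtl_tsv: Path
    motif_tsv: Path
    truth_json: Path
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: TruthSet


# ---------------------------------------------------------------------------
# helpers

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _comp(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


def _build_genes(
    rng: np.random.Generator, cfg: SimulationConfig, chrom: str, seq: np.ndarray
) -> list[GeneModel]:
    """Place gene models in evenly spaced slots and patch the reference so
    every CDS encodes a clean ORF (ATG .. stop, no internal stop)."""
    genes = []
    slot = cfg.chrom_length_bp // cfg.n_genes_per_chrom
    for k in range(cfg.n_genes_per_chrom):
        # keep clear of slot edges so 3 kb promoters never touch a neighbour
        anchor = k * slot + slot // 2 + int(rng.integers(-slot // 8, slot // 8))
        strand = "+" if rng.random() < 0.5 else "-"
        utr5, utr3 = int(rng.integers(120, 240)), int(rng.integers(120, 240))
        c1, c2, c3 = (int(rng.integers(40, 110)) * 3 for _ in range(3))
        i1, i2 = int(rng.integers(200, 420)), int(rng.integers(200, 420))
        # genomic layout left->right; biological orientation set by strand
        if strand == "+":
            lens = [utr5 + c1, i1, c2, i2, c3 + utr3]
        else:
            lens = [utr3 + c3, i2, c2, i1, c1 + utr5]
        tx_start = anchor
        pos = tx_start
        blocks = []
        for L in lens:
            blocks.append((pos, pos + L - 1))
            pos += L
        tx_end = pos - 1
        exon1, intron1, exon2, intron2, exon3 = blocks
        if strand == "+":
            cds = ((exon1[0] + utr5, exon1[1]), exon2, (exon3[0], exon3[1] - utr3))
        else:
            cds = ((exon1[0] + utr3, exon1[1]), exon2, (exon3[0], exon3[1] - utr5))
        g = GeneModel(
            id=f"G{chrom[3:]}_{k + 1:03d}",
            chrom=chrom,
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            exons=(exon1, exon2, exon3),
            cds=cds,
            description="",  # assigned afterwards
        )
        # patch ORF into the reference
        n_codons = g.cds_len // 3
        orf = "ATG" + "".join(
            _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        ) + STOPS[int(rng.integers(0, 3))]
        positions: list[int] = []
        for s, e in g.cds:
            positions.extend(range(s, e + 1))
        if strand == "-":
            positions = positions[::-1]
        for base, p in zip(orf, positions):
            seq[p - 1] = (base if strand == "+" else _comp(base)).encode()
        genes.append(g)
    return genes


def _assign_descriptions(rng: np.random.Generator, genes: list[GeneModel]) -> list[GeneModel]:
    """Half the genes get keyword-bearing descriptions, half neutral ones."""
    out = []
    n = len(genes)
    keyword_flags = np.zeros(n, dtype=bool)
    keyword_flags[: n // 2] = True
    rng.shuffle(keyword_flags)
    for g, kw in zip(genes, keyword_flags):
        pool = KEYWORD_DESCRIPTIONS if kw else NEUTRAL_DESCRIPTIONS
        desc = pool[int(rng.integers(0, len(pool)))]
        out.append(
            GeneModel(g.id, g.chrom, g.strand, g.tx_start, g.tx_end, g.exons, g.cds, desc)
        )
    return out


def _random_variant(
    rng: np.random.Generator, chrom: str, pos: int, seq: str, indel: bool
) -> VariantRecord | None:
    L = len(seq)
    ref_base = seq[pos - 1]
    if ref_base not in "ACGT":
        return None
    qual = float(np.round(rng.uniform(30, 60), 1))
    depth = float(int(np.clip(np.round(rng.normal(30, 4)), 16, 60)))
    if not indel:
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref_base:
            alt = "ACGT"[int(rng.integers(0, 4))]
        return VariantRecord(chrom, pos, ref_base, alt, qual=qual, depth=depth, genotype=HOM_ALT)
    if rng.random() < 0.5 and pos + 3 <= L:  # deletion of 1-3 bases
        dlen = int(rng.integers(1, 4))
        ref = seq[pos - 1 : pos + dlen]
        return VariantRecord(chrom, pos, ref, ref_base, qual=qual, depth=depth, genotype=HOM_ALT)
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
    return VariantRecord(chrom, pos, ref_base, ref_base + ins, qual=qual, depth=depth, genotype=HOM_ALT)


def _poisson_positions(
    rng: np.random.Generator, start: int, end: int, rate_per_mb: float
) -> np.ndarray:
    """Poisson-process positions on [start, end] at the given density."""
    lam = rate_per_mb * (end - start + 1) / 1e6
    n = rng.poisson(lam)
    if n == 0:
        return np.array([], dtype=int)
    return np.unique(rng.integers(start, end + 1, size=n))


# ---------------------------------------------------------------------------
# effect planting

def plant_effect_variants(
    gene: GeneModel,
    ref_seq: str,
    requested_effects: Sequence[str],
    rng: np.random.Generator | None = None,
    genes: GeneIndex | None = None,
    flank_bp: int = 5000,
    avoid_positions: set[int] | None = None,
) -> list[tuple[VariantRecord, str, str]]:
    """Construct variants whose re-annotation yields exactly the requested
    effects.  Every emitted variant is verified by the annotator before it
    is returned; an unrealisable request raises
    :class:`UnsatisfiableEffectError`."""
    if not gene.cds:
        raise UnsatisfiableEffectError(f"{gene.id}: gene has no CDS")
    rng = rng if rng is not None else np.random.default_rng(0)
    index = genes or GeneIndex([gene])
    used = set() if avoid_positions is None else avoid_positions
    out = []
    for eff in requested_effects:
        if eff not in IMPACT_OF:
            raise UnsatisfiableEffectError(f"unknown effect term {eff!r}")
        vr = _plant_one(gene, ref_seq, eff, rng, index, flank_bp, used)
        used.update(range(vr.pos, vr.pos + len(vr.ref)))
        out.append((vr, eff, IMPACT_OF[eff]))
    return out


def _verify(
    v: VariantRecord, gene: GeneModel, ref_seq: str, eff: str, index: GeneIndex, flank_bp: int
) -> bool:
    try:
        g_located, region = locate_variant(v, index, flank_bp)
    except Exception:
        return False
    if eff == "intergenic_variant":
        if g_located is not None and region != "intergenic":
            return False
        ann = annotate_effect(v, g_located, ref_seq, region=region, flank_bp=flank_bp)
        return ann.effect == eff
    if g_located is None or g_located.id != gene.id:
        return False
    try:
        ann = annotate_effect(v, gene, ref_seq, flank_bp=flank_bp)
    except Exception:
        return False
    return ann.effect == eff


def _mk_snp(chrom: str, pos: int, seq: str, alt: str, rng) -> VariantRecord | None:
    ref = seq[pos - 1]
    if ref not in "ACGT" or alt == ref:
        return None
    return VariantRecord(
        chrom, pos, ref, alt,
        qual=float(np.round(rng.uniform(35, 60), 1)),
        depth=float(int(np.clip(np.round(rng.normal(30, 4)), 16, 60))),
        genotype=HOM_ALT,
    )


def _candidate_positions(gene: GeneModel, eff: str, seq_len: int, flank_bp: int) -> list[int]:
    g = gene
    introns = g.introns
    if eff in ("missense_variant", "synonymous_variant", "stop_gained"):
        pos = [p for s, e in g.cds for p in range(s, e + 1)]
        # stay clear of splice junctions so the coding call is unambiguous
        return [p for p in pos if all(abs(p - x) > 4 for s_, e_ in introns for x in (s_, e_))]
    if eff == "stop_lost":
        # terminal codon in transcription order
        positions = [p for s, e in g.cds for p in range(s, e + 1)]
        if g.strand == "-":
            positions = positions[::-1]
        return positions[-3:]
    if eff == "intron_variant":
        return [p for s, e in introns for p in range(s + 8, e - 7)]
    if eff == "splice_donor_variant":
        return [s if g.strand == "+" else e for s, e in introns]
    if eff == "splice_acceptor_variant":
        return [e if g.strand == "+" else s for s, e in introns]
    if eff == "splice_region_variant":
        return [p for s, e in introns for p in (s + 2, e - 2)]
    if eff in ("five_prime_UTR_variant", "five_prime_UTR_premature_start_codon_gain_variant"):
        lo, hi = (g.tx_start, g.cds_start - 1) if g.strand == "+" else (g.cds_end + 1, g.tx_end)
        return [p for p in range(lo + 2, hi - 1)]
    if eff == "three_prime_UTR_variant":
        lo, hi = (g.cds_end + 1, g.tx_end) if g.strand == "+" else (g.tx_start, g.cds_start - 1)
        return [p for p in range(lo + 2, hi - 1)]
    if eff == "upstream_gene_variant":
        if g.strand == "+":
            return list(range(max(1, g.tx_start - flank_bp // 2), g.tx_start - 10))
        return list(range(g.tx_end + 10, min(seq_len, g.tx_end + flank_bp // 2)))
    if eff == "downstream_gene_variant":
        if g.strand == "+":
            return list(range(g.tx_end + 10, min(seq_len, g.tx_end + flank_bp // 2)))
        return list(range(max(1, g.tx_start - flank_bp // 2), g.tx_start - 10))
    if eff == "intergenic_variant":
        far = 2 * flank_bp
        cands = list(range(g.tx_end + far, min(seq_len, g.tx_end + far + 2000)))
        cands += list(range(max(1, g.tx_start - far - 2000), max(1, g.tx_start - far)))
        return cands
    return []


def _plant_one(
    gene: GeneModel,
    ref_seq: str,
    eff: str,
    rng,
    index: GeneIndex,
    flank_bp: int,
    avoid: set[int] | None = None,
) -> VariantRecord:
    chrom = gene.chrom
    L = len(ref_seq)
    avoid = avoid or set()
    max_tries = 4000

    def try_snp_positions(positions: Iterable[int]) -> VariantRecord | None:
        tries = 0
        for p in positions:
            if p in avoid:
                continue
            for alt in "ACGT":
                v = _mk_snp(chrom, p, ref_seq, alt, rng)
                if v is None:
                    continue
                tries += 1
                if _verify(v, gene, ref_seq, eff, index, flank_bp):
                    return v
                if tries > max_tries:
                    return None
        return None

    indel_effects = {
        "frameshift_variant",
        "conservative_inframe_deletion",
        "disruptive_inframe_deletion",
        "conservative_inframe_insertion",
        "disruptive_inframe_insertion",
    }
    if eff in indel_effects:
        # anchors across CDS interiors, shuffled for variety
        anchors = [
            p
            for s, e in gene.cds
            for p in range(s + 3, e - 6)
            if all(abs(p - x) > 8 for s_, e_ in gene.introns for x in (s_, e_))
        ]
        rng.shuffle(anchors)
        anchors = [p for p in anchors if not any(q in avoid for q in range(p, p + 4))]
        for p in anchors[:600]:
            if eff == "frameshift_variant":
                ref = ref_seq[p - 1 : p + 1]
                cand = [VariantRecord(chrom, p, ref, ref[0], qual=50.0, depth=30.0, genotype=HOM_ALT)]
            elif eff.endswith("deletion"):
                ref = ref_seq[p - 1 : p + 3]
                cand = [VariantRecord(chrom, p, ref, ref[0], qual=50.0, depth=30.0, genotype=HOM_ALT)]
            else:  # insertions
                ref = ref_seq[p - 1]
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3))
                cand = [VariantRecord(chrom, p, ref, ref + ins, qual=50.0, depth=30.0, genotype=HOM_ALT)]
            for v in cand:
                if _verify(v, gene, ref_seq, eff, index, flank_bp):
                    return v
        raise UnsatisfiableEffectError(f"{gene.id}: cannot realise {eff}")

    positions = _candidate_positions(gene, eff, L, flank_bp)
    positions = list(positions)
    rng.shuffle(positions)
    v = try_snp_positions(positions)
    if v is None:
        raise UnsatisfiableEffectError(f"{gene.id}: cannot realise {eff}")
    return v


# ---------------------------------------------------------------------------
# panel simulation

def _simulate_panel(
    rng: np.random.Generator, cfg: SimulationConfig, genome: dict[str, str]
) -> tuple[list[str], list[tuple[str, int, str, str]], np.ndarray, dict[str, str]]:
    """Star species tree with species-private alleles and accession noise.

    Returns (samples, sites, dosage matrix, species_of) with the focal
    sample appended last as a cultivated/donor mosaic.
    """
    species = cfg.species
    samples: list[str] = []
    species_of: dict[str, str] = {}
    for sp in species:
        for i in range(cfg.n_accessions_per_species):
            name = f"{sp}_{i + 1}"
            samples.append(name)
            species_of[name] = sp
    sites: list[tuple[str, int, str, str]] = []
    chrom_site_slices: dict[str, slice] = {}
    for chrom in cfg.chromosomes:
        seq = genome[chrom]
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_panel_sites_per_chrom))
        start = len(sites)
        for p in pos:
            ref = seq[p - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref:
                alt = "ACGT"[int(rng.integers(0, 4))]
            sites.append((chrom, int(p), ref, alt))
        chrom_site_slices[chrom] = slice(start, len(sites))
    n_sites = len(sites)
    # species haplotypes: private alt alleles at the divergence rate
    sp_geno = {
        sp: (rng.random(n_sites) < cfg.species_divergence).astype(np.int8) * 2 for sp in species
    }
    rows = []
    for name in samples:
        g = sp_geno[species_of[name]].copy()
        flip = rng.random(n_sites) < 0.01
        g[flip] = 1  # accession-level heterozygous noise
        miss = rng.random(n_sites) < 0.02
        g[miss] = -1
        rows.append(g)
    # focal mosaic: cultivated background, donor alleles inside segments
    focal = sp_geno["cultivated"].copy()
    donor = sp_geno[cfg.donor_species]
    for chrom in cfg.chromosomes:
        sl = chrom_site_slices[chrom]
        positions = np.array([p for _, p, _, _ in sites[sl]])
        mask = np.zeros(len(positions), dtype=bool)
        for s, e in cfg.segments_on(chrom):
            mask |= (positions >= s) & (positions <= e)
        idx = np.arange(sl.start, sl.stop)[mask]
        focal[idx] = donor[idx]
    samples.append("focal")
    species_of["focal"] = "focal"
    rows.append(focal)
    return samples, sites, np.stack(rows, axis=0), species_of


def _write_panel_vcf(
    path: Path,
    samples: Sequence[str],
    sites: Sequence[tuple[str, int, str, str]],
    calls: np.ndarray,
    chrom_lengths: dict[str, int],
) -> None:
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = sorted(range(len(sites)), key=lambda i: (sites[i][0], sites[i][1]))
        for i in order:
            chrom, pos, ref, alt = sites[i]
            gts = "\t".join(f"{gt_of[int(calls[s, i])]}:60:30" for s in range(len(samples)))
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t60\t.\t.\tGT:GQ:DP\t{gts}\n")


# ---------------------------------------------------------------------------
# main entry

def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SyntheticDataset:
    """Generate the full synthetic input bundle and its truth set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chromosomes

    # 1. reference and gene models (reference patched with clean ORFs)
    seq_arrays = {c: _random_sequence(rng, cfg.chrom_length_bp) for c in chroms}
    genes: list[GeneModel] = []
    for c in chroms:
        genes.extend(_build_genes(rng, cfg, c, seq_arrays[c]))
    genes = _assign_descriptions(rng, genes)

    # 2. planted promoter motifs (patched into the reference upstream of TSS)
    catalog = load_motif_catalog()
    by_name = {m.name: m for m in catalog}
    planted_motifs: list[dict] = []
    motif_targets = [g for g in genes if g.id.endswith("001") or g.id.endswith("002")]
    for g in motif_targets:
        for motif_name, offset in (("ARE", 500), ("ABRE", 1200)):
            m = by_name[motif_name]
            realization = "".join(IUPAC_choice(rng, c) for c in m.consensus)
            _patch_promoter(seq_arrays[g.chrom], g, offset, realization)
            planted_motifs.append({"gene": g.id, "motif": motif_name, "offset": offset})

    genome = {c: seq_arrays[c].tobytes().decode() for c in chroms}
    index = GeneIndex(genes)

    # 3. planted effect variants
    planted: list[tuple[VariantRecord, str, str]] = []
    if cfg.plant_effects:
        segs_genes = [
            g for g in genes if any(
                s <= g.tx_start <= e for s, e in cfg.segments_on(g.chrom)
            )
        ]
        kw_heat, kw_rep = cp.keyword_select(genes, cp.EXTENDED_KEYWORDS)
        kw_ids = {g.id for g in kw_heat} | {g.id for g in kw_rep}
        in_seg_kw = [g for g in segs_genes if g.id in kw_ids][:4]
        out_seg_kw = [
            g for g in genes
            if g.id in kw_ids and not any(
                s <= g.tx_start <= e for s, e in cfg.segments_on(g.chrom)
            )
        ]
        qtl_target = out_seg_kw[0] if out_seg_kw else None
        targets = in_seg_kw + ([qtl_target] if qtl_target else [])
        for g in targets:
            planted.extend(
                plant_effect_variants(g, genome[g.chrom], DEFAULT_PLANTED_EFFECTS, rng, index)
            )
    planted_pos = {(v.chrom, p) for v, _, _ in planted for p in range(v.pos - 5, v.pos + len(v.ref) + 5)}

    # 4. random focal variants (Poisson background / introgression densities)
    focal: list[VariantRecord] = []
    for chrom in chroms:
        seq = genome[chrom]
        segs = cfg.segments_on(chrom)
        pieces: list[tuple[int, int, float]] = []
        cursor = 1
        for s, e in segs:
            if cursor < s:
                pieces.append((cursor, s - 1, cfg.background_rate))
            pieces.append((s, e, cfg.introgression_rate))
            cursor = e + 1
        if cursor <= cfg.chrom_length_bp:
            pieces.append((cursor, cfg.chrom_length_bp, cfg.background_rate))
        for s, e, rate in pieces:
            for p in _poisson_positions(rng, s, e, rate):
                if (chrom, int(p)) in planted_pos:
                    continue
                indel = rng.random() < cfg.indel_fraction
                v = _random_variant(rng, chrom, int(p), seq, indel)
                if v is not None:
                    focal.append(v)
    focal.extend(v for v, _, _ in planted)
    focal.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    # drop exact duplicate positions (possible planted/random collisions)
    seen_pos: set[tuple[str, int]] = set()
    focal_unique = []
    for v in focal:
        if (v.chrom, v.pos) in seen_pos:
            continue
        seen_pos.add((v.chrom, v.pos))
        focal_unique.append(v)
    focal = focal_unique

    # 5. donor call set: everything focal carries inside segments, plus
    #    donor-private variants focal does not carry
    donor_keys: list[tuple[str, int, str, str]] = []
    for v in focal:
        if any(s <= v.pos <= e for s, e in cfg.segments_on(v.chrom)):
            donor_keys.append(v.key)
    donor_records = [
        VariantRecord(c, p, r, a, qual=55.0, depth=30.0, genotype=HOM_ALT)
        for c, p, r, a in donor_keys
    ]
    for chrom in chroms:
        seq = genome[chrom]
        for p in _poisson_positions(rng, 1, cfg.chrom_length_bp, cfg.background_rate / 2):
            if (chrom, int(p)) in seen_pos:
                continue
            v = _random_variant(rng, chrom, int(p), seq, rng.random() < cfg.indel_fraction)
            if v is not None:
                donor_records.append(v)
                donor_keys.append(v.key)
    donor_records.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))

    # 6. panel
    samples, sites, calls, species_of = _simulate_panel(rng, cfg, genome)

    # 7. QTLs: a few per chromosome; one flower-number QTL is anchored on a
    #    keyword gene so colocalization always has a positive case
    qtls: list[cp.QTLInterval] = []
    qid = 0
    trait_pool = [
        ("flower number", "flower number"),
        ("flowering time of the first inflorescence", "flowering time"),
        ("fruit set under heat", "fruit set"),
        ("pollen viability", "pollen viability"),
        ("anther length", "anther length"),
    ]
    kw_heat, kw_rep = cp.keyword_select(genes, cp.EXTENDED_KEYWORDS)
    kw_ids = {g.id for g in kw_heat} | {g.id for g in kw_rep}
    anchor_candidates = [
        g for g in genes
        if g.id in kw_ids and not any(s <= g.tx_start <= e for s, e in cfg.segments_on(g.chrom))
    ]
    if anchor_candidates:
        g = anchor_candidates[0]
        qid += 1
        qtls.append(
            cp.QTLInterval(
                qtl_id=f"Q-sim{qid:02d}",
                trait="flower number",
                trait_class="flower number",
                chrom=g.chrom,
                start=max(1, g.tx_start - 50_000),
                end=min(cfg.chrom_length_bp, g.tx_end + 50_000),
                source="synthetic",
            )
        )
    qtl_span = max(100_000, min(2_000_000, cfg.chrom_length_bp // 4))
    for chrom in chroms:
        for _ in range(2):
            trait, tclass = trait_pool[int(rng.integers(0, len(trait_pool)))]
            s = int(rng.integers(1, cfg.chrom_length_bp - qtl_span))
            e = s + int(rng.integers(qtl_span // 2, qtl_span))
            qid += 1
            qtls.append(
                cp.QTLInterval(
                    qtl_id=f"Q-sim{qid:02d}",
                    trait=trait,
                    trait_class=tclass,
                    chrom=chrom,
                    start=s,
                    end=min(e, cfg.chrom_length_bp),
                    source="synthetic",
                )
            )

    # 8. truth bookkeeping
    segments = [
        {"chrom": c, "start": s, "end": e} for c, s, e in sorted(cfg.introgression_segments)
    ]
    focal_keys = {v.key for v in focal}
    planted_variant_dicts = [
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "effect": eff, "impact": tier,
        }
        for v, eff, tier in sorted(planted, key=lambda t: (t[0].chrom, t[0].pos))
        if v.key in focal_keys
    ]
    annotations = annotate_variants(focal, index, genome)
    intended = _intended_candidates(genes, annotations, cfg, qtls)
    planted_cand = _planted_candidates(genes, planted, cfg, qtls)
    truth = TruthSet(
        segments=segments,
        planted_variants=planted_variant_dicts,
        donor_variant_keys=sorted([list(k) for k in set(donor_keys)]),
        planted_motifs=planted_motifs,
        intended_candidates=sorted(intended),
        planted_candidates=sorted(planted_cand),
        focal_variant_count=len(focal),
    )

    # 9. write everything
    ref_fa = outdir / "reference.fasta"
    SeqIO.write(
        [SeqRecord(Seq(genome[c]), id=c, description="") for c in chroms], str(ref_fa), "fasta"
    )
    gff = outdir / "genes.gff3"
    write_gff3(genes, gff)
    focal_vcf = outdir / "focal.vcf"
    write_vcf(focal, focal_vcf, cfg.chrom_lengths, sample="focal")
    donor_vcf = outdir / "donor.vcf"
    write_vcf(donor_records, donor_vcf, cfg.chrom_lengths, sample="donor")
    panel_vcf = outdir / "panel.vcf"
    _write_panel_vcf(panel_vcf, samples, sites, calls, cfg.chrom_lengths)
    qtl_tsv = outdir / "qtls.tsv"
    cp.write_qtl_tsv(qtls, qtl_tsv)
    motif_tsv = outdir / "motif_catalog.tsv"
    write_motif_catalog(catalog, motif_tsv)
    truth_json = outdir / "truth.json"
    truth.to_json(truth_json)
    return SyntheticDataset(
        config=cfg,
        outdir=outdir,
        reference_fasta=ref_fa,
        genes_gff=gff,
        focal_vcf=focal_vcf,
        donor_vcf=donor_vcf,
        panel_vcf=panel_vcf,
        qtl_tsv=qtl_tsv,
        motif_tsv=motif_tsv,
        truth_json=truth_json,
        genome=genome,
        genes=genes,
        truth=truth,
    )


def IUPAC_choice(rng: np.random.Generator, code: str) -> str:
    from .promoter_motifs import IUPAC

    opts = IUPAC[code.upper()]
    return opts[int(rng.integers(0, len(opts)))]


def _patch_promoter(seq: np.ndarray, g: GeneModel, offset: int, realization: str) -> None:
    """Write a motif realization at a 1-based promoter offset (promoter is
    the 3 kb upstream of the TSS in transcript orientation)."""
    if g.strand == "+":
        start = g.tx_start - 3000 + (offset - 1)  # genomic, 1-based
        for i, b in enumerate(realization):
            seq[start - 1 + i] = b.encode()
    else:
        start = g.tx_end + 3000 - (offset - 1)  # genomic position of motif base 1
        for i, b in enumerate(realization):
            seq[start - 1 - i] = _comp(b).encode()


def _in_any_segment(g: GeneModel, cfg: SimulationConfig) -> bool:
    return any(s <= g.tx_start and g.tx_end <= e for s, e in cfg.segments_on(g.chrom))


def _gene_qtl_flower_overlap(g: GeneModel, qtls: Sequence, classes=cp.DEFAULT_FLOWER_TRAIT_CLASSES) -> bool:
    return any(
        q.chrom == g.chrom and q.start <= g.tx_end and g.tx_start <= q.end and q.trait_class in classes
        for q in qtls
    )


def _intended_candidates(
    genes: Sequence[GeneModel],
    annotations: Sequence[EffectAnnotation],
    cfg: SimulationConfig,
    qtls: Sequence,
) -> list[str]:
    kw_heat, kw_rep = cp.keyword_select(genes, cp.EXTENDED_KEYWORDS)
    kw_ids = {g.id for g in kw_heat} | {g.id for g in kw_rep}
    hm: dict[str, int] = {}
    for a in annotations:
        if a.gene and a.impact in (HIGH, MODERATE):
            hm[a.gene] = hm.get(a.gene, 0) + 1
    out = []
    for g in genes:
        if g.id not in kw_ids or hm.get(g.id, 0) == 0:
            continue
        in_seg = any(
            s <= g.tx_end and g.tx_start <= e for s, e in cfg.segments_on(g.chrom)
        )
        if in_seg or _gene_qtl_flower_overlap(g, qtls):
            out.append(g.id)
    return out


def _planted_candidates(
    genes: Sequence[GeneModel],
    planted: Sequence[tuple[VariantRecord, str, str]],
    cfg: SimulationConfig,
    qtls: Sequence,
) -> list[str]:
    kw_heat, kw_rep = cp.keyword_select(genes, cp.EXTENDED_KEYWORDS)
    kw_ids = {g.id for g in kw_heat} | {g.id for g in kw_rep}
    by_gene: dict[str, int] = {}
    gene_by_id = {g.id: g for g in genes}
    for v, eff, tier in planted:
        if tier in (HIGH, MODERATE):
            for g in genes:
                if g.chrom == v.chrom and g.tx_start <= v.pos <= g.tx_end:
                    by_gene[g.id] = by_gene.get(g.id, 0) + 1
    out = []
    for gid, n in by_gene.items():
        g = gene_by_id[gid]
        if gid not in kw_ids or n == 0:
            continue
        in_seg = any(s <= g.tx_end and g.tx_start <= e for s, e in cfg.segments_on(g.chrom))
        if in_seg or _gene_qtl_flower_overlap(g, qtls):
            out.append(gid)
    return out
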