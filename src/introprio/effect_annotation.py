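"""Variant effect annotation against gene models.

A compact SnpEff-style classifier: each variant is located relative to a
set of gene models (exon / intron / UTR / splice region / up- and
downstream flank / intergenic), its protein-level effect is predicted from
the coding sequence where relevant, and the effect is mapped onto the four
conventional impact tiers (HIGH, MODERATE, LOW, MODIFIER).

Coordinates are 1-based inclusive throughout.  Only the standard nuclear
genetic code is used; start-codon edge cases are reported as missense.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import InputError, ReferenceMismatchError
from .variant_io import SNP, VariantRecord

# ---------------------------------------------------------------------------
# Effect vocabulary and impact tiers

HIGH = "HIGH"
MODERATE = "MODERATE"
LOW = "LOW"
MODIFIER = "MODIFIER"

IMPACT_OF: dict[str, str] = {
    "frameshift_variant": HIGH,
    "stop_gained": HIGH,
    "stop_lost": HIGH,
    "splice_donor_variant": HIGH,
    "splice_acceptor_variant": HIGH,
    "bidirectional_gene_fusion": HIGH,
    "missense_variant": MODERATE,
    "conservative_inframe_insertion": MODERATE,
    "disruptive_inframe_insertion": MODERATE,
    "conservative_inframe_deletion": MODERATE,
    "disruptive_inframe_deletion": MODERATE,
    "synonymous_variant": LOW,
    "splice_region_variant": LOW,
    "intergenic_variant": MODIFIER,
    "upstream_gene_variant": MODIFIER,
    "downstream_gene_variant": MODIFIER,
    "intron_variant": MODIFIER,
    "five_prime_UTR_variant": MODIFIER,
    "three_prime_UTR_variant": MODIFIER,
    "five_prime_UTR_premature_start_codon_gain_variant": MODIFIER,
}

SEVERITY_ORDER = (HIGH, MODERATE, LOW, MODIFIER)
_SEVERITY_RANK = {t: i for i, t in enumerate(SEVERITY_ORDER)}

# region labels
INTERGENIC = "intergenic"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
FIVE_UTR = "five_prime_utr"
THREE_UTR = "three_prime_utr"
INTRON = "intron"
EXON = "exon"
SPLICE_REGION = "splice_region"

SPLICE_CORE = 2      # first/last intron bases -> donor/acceptor
SPLICE_FLANK = 3     # distance from an exon-intron junction for splice_region
DEFAULT_FLANK_BP = 5000


Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding (or non-coding, if ``cds`` is empty) gene model."""

    id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()
    description: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"{self.id}: strand must be + or -")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(tuple(c) for c in self.cds)))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise InputError(f"{self.id}: exons overlap or are unsorted")
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in exons):
                raise InputError(f"{self.id}: CDS segment ({s},{e}) outside exons")

    # -- interval helpers -------------------------------------------------
    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 - e1 > 1
        )

    @property
    def cds_start(self) -> int:
        return self.cds[0][0]

    @property
    def cds_end(self) -> int:
        return self.cds[-1][1]

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the coding sequence,
        counted in transcription order."""
        if not self.in_cds(pos):
            raise InputError(f"{self.id}: position {pos} not in CDS")
        if self.strand == "+":
            off = 0
            for s, e in self.cds:
                if pos > e:
                    off += e - s + 1
                else:
                    return off + pos - s
        else:
            off = 0
            for s, e in reversed(self.cds):
                if pos < s:
                    off += e - s + 1
                else:
                    return off + e - pos
        raise AssertionError("unreachable")

    def cds_sequence(self, ref_seq: str) -> str:
        parts = [ref_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def utr_side(self, pos: int) -> str:
        """five/three prime UTR label for an exonic, non-CDS position."""
        if not self.cds:
            return FIVE_UTR
        before_cds = pos < self.cds_start
        if self.strand == "+":
            return FIVE_UTR if before_cds else THREE_UTR
        return THREE_UTR if before_cds else FIVE_UTR


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantRecord
    gene: str | None
    region: str
    effect: str
    impact: str = field(default="", compare=False)

    def __post_init__(self):
        object.__setattr__(self, "impact", IMPACT_OF[self.effect])


class GeneIndex:
    """Genes grouped by chromosome, position-sortable for flank queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda g: (g.tx_start, g.tx_end))
        self._starts = {c: [g.tx_start for g in lst] for c, lst in self.by_chrom.items()}

    def __iter__(self):
        for lst in self.by_chrom.values():
            yield from lst

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        out = []
        lst = self.by_chrom.get(chrom, [])
        i = bisect_right(self._starts.get(chrom, []), end)
        for g in lst[:i]:
            if g.tx_end >= start:
                out.append(g)
        return out

    def nearby(self, chrom: str, pos: int, flank_bp: int) -> list[GeneModel]:
        return self.overlapping(chrom, pos - flank_bp, pos + flank_bp)


# ---------------------------------------------------------------------------
# Location

def _region_in_gene(g: GeneModel, pos: int, flank_bp: int) -> str | None:
    """Region label of ``pos`` relative to one gene, or None if unrelated."""
    if g.contains(pos):
        # within SPLICE_FLANK bases of an exon-intron junction, on either side
        near_junction = any(
            s - SPLICE_FLANK <= pos <= s + SPLICE_FLANK - 1
            or e - SPLICE_FLANK + 1 <= pos <= e + SPLICE_FLANK
            for s, e in g.introns
        )
        if near_junction:
            return SPLICE_REGION
        if g.in_exon(pos):
            return EXON if g.in_cds(pos) or not g.cds else g.utr_side(pos)
        return INTRON
    if g.strand == "+":
        if g.tx_start - flank_bp <= pos < g.tx_start:
            return UPSTREAM
        if g.tx_end < pos <= g.tx_end + flank_bp:
            return DOWNSTREAM
    else:
        if g.tx_end < pos <= g.tx_end + flank_bp:
            return UPSTREAM
        if g.tx_start - flank_bp <= pos < g.tx_start:
            return DOWNSTREAM
    return None


def locate_variant(
    v: VariantRecord, genes: GeneIndex, flank_bp: int = DEFAULT_FLANK_BP
) -> tuple[GeneModel | None, str]:
    """Place a variant relative to the gene set.

    Containment wins over flanks; among several containing genes the first
    in genomic order is returned (per-gene annotation is handled by
    :func:`annotate_variants`).
    """
    pos = v.pos
    containing = [g for g in genes.overlapping(v.chrom, pos, pos)]
    if containing:
        g = containing[0]
        return g, _region_in_gene(g, pos, flank_bp)
    flank_hits = []
    for g in genes.nearby(v.chrom, pos, flank_bp):
        reg = _region_in_gene(g, pos, flank_bp)
        if reg is not None:
            dist = min(abs(pos - g.tx_start), abs(pos - g.tx_end))
            flank_hits.append((dist, g.tx_start, g.id, g, reg))
    if flank_hits:
        flank_hits.sort(key=lambda t: t[:3])
        _, _, _, g, reg = flank_hits[0]
        return g, reg
    return None, INTERGENIC


# ---------------------------------------------------------------------------
# Effect prediction

def _trim_allele(v: VariantRecord) -> tuple[int, str, str]:
    """Strip the common prefix of ref/alt (VCF anchor base).

    Returns (first changed genomic position, remaining ref, remaining alt).
    """
    ref, alt = v.ref, v.alt
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    return v.pos + p, ref[p:], alt[p:]


def _check_reference(v: VariantRecord, ref_seq: str) -> None:
    obs = ref_seq[v.pos - 1 : v.pos - 1 + len(v.ref)].upper()
    if obs != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} REF={v.ref} but reference has {obs!r}"
        )


def _splice_effect(g: GeneModel, span: Interval) -> str | None:
    """HIGH donor/acceptor if the change touches the 2 terminal intron bases;
    LOW splice_region if it comes within 3 bp of an exon-intron junction."""
    lo, hi = span
    for s, e in g.introns:
        donor_first = g.strand == "+"
        # intron 5' end in transcription orientation
        five = (s, min(e, s + SPLICE_CORE - 1)) if donor_first else (max(s, e - SPLICE_CORE + 1), e)
        three = (max(s, e - SPLICE_CORE + 1), e) if donor_first else (s, min(e, s + SPLICE_CORE - 1))
        if lo <= five[1] and hi >= five[0]:
            return "splice_donor_variant"
        if lo <= three[1] and hi >= three[0]:
            return "splice_acceptor_variant"
    for s, e in g.introns:
        near = (lo <= s + SPLICE_FLANK - 1 and hi >= s) or (lo <= e and hi >= e - SPLICE_FLANK + 1)
        if near:
            return "splice_region_variant"
    return None


def _snp_cds_effect(g: GeneModel, pos: int, alt: str, ref_seq: str) -> str:
    cds_seq = g.cds_sequence(ref_seq)
    off = g.cds_offset(pos)
    alt_base = alt if g.strand == "+" else str(Seq(alt).reverse_complement())
    codon_i = off // 3
    within = off % 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:  # trailing partial codon in a malformed model
        return "synonymous_variant"
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new_codon).translate())
    if aa_old == aa_new:
        return "synonymous_variant"
    if aa_new == "*":
        return "stop_gained"
    if aa_old == "*":
        return "stop_lost"
    return "missense_variant"


def _indel_cds_effect(g: GeneModel, changed_pos: int, ref_rem: str, alt_rem: str) -> str:
    if ref_rem and alt_rem:
        # complex substitution: classify by net length change only
        net = len(alt_rem) - len(ref_rem)
        if net % 3 != 0:
            return "frameshift_variant"
        return "disruptive_inframe_insertion" if net > 0 else "disruptive_inframe_deletion"
    if ref_rem:  # deletion of ref_rem at [changed_pos, changed_pos+len-1]
        lo, hi = changed_pos, changed_pos + len(ref_rem) - 1
        del_in_cds = sum(max(0, min(hi, e) - max(lo, s) + 1) for s, e in g.cds)
        if del_in_cds % 3 != 0:
            return "frameshift_variant"
        # conservative iff whole codons are removed; first deleted base in
        # transcription order must sit on a codon boundary
        pos_in_order = hi if g.strand == "-" else lo
        try:
            off = g.cds_offset(pos_in_order)
        except InputError:
            return "disruptive_inframe_deletion"
        aligned = off % 3 == 0 and del_in_cds == len(ref_rem)
        return "conservative_inframe_deletion" if aligned else "disruptive_inframe_deletion"
    # insertion of alt_rem between changed_pos-1 and changed_pos
    if len(alt_rem) % 3 != 0:
        return "frameshift_variant"
    after = changed_pos if g.strand == "+" else changed_pos - 1
    try:
        off = g.cds_offset(after)
    except InputError:
        return "disruptive_inframe_insertion"
    return "conservative_inframe_insertion" if off % 3 == 0 else "disruptive_inframe_insertion"


_REGION_EFFECT = {
    INTERGENIC: "intergenic_variant",
    UPSTREAM: "upstream_gene_variant",
    DOWNSTREAM: "downstream_gene_variant",
    INTRON: "intron_variant",
    FIVE_UTR: "five_prime_UTR_variant",
    THREE_UTR: "three_prime_UTR_variant",
}


def _utr5_start_gain(g: GeneModel, v: VariantRecord, ref_seq: str) -> bool:
    """Did a 5'UTR SNP create a new ATG in transcript orientation?"""
    if v.vclass != SNP:
        return False
    lo = max(1, v.pos - 2)
    hi = min(len(ref_seq), v.pos + 2)
    before = ref_seq[lo - 1 : hi]
    after = before[: v.pos - lo] + v.alt + before[v.pos - lo + 1 :]
    if g.strand == "-":
        before = str(Seq(before).reverse_complement())
        after = str(Seq(after).reverse_complement())
    return after.count("ATG") > before.count("ATG")


def annotate_effect(
    v: VariantRecord,
    g: GeneModel | None,
    ref_seq: str,
    region: str | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> EffectAnnotation:
    """Predict the effect of one variant in the context of one gene.

    ``ref_seq`` is the full chromosome sequence the coordinates refer to.
    """
    _check_reference(v, ref_seq)
    if g is None:
        return EffectAnnotation(v, None, INTERGENIC, "intergenic_variant")
    if region is None:
        region = _region_in_gene(g, v.pos, flank_bp) or INTERGENIC
    changed_pos, ref_rem, alt_rem = _trim_allele(v)
    span: Interval = (
        (changed_pos, changed_pos + max(len(ref_rem) - 1, 0))
        if ref_rem
        else (changed_pos - 1, changed_pos)
    )
    if region in (UPSTREAM, DOWNSTREAM, INTERGENIC):
        return EffectAnnotation(v, g.id if region != INTERGENIC else None, region, _REGION_EFFECT[region])

    splice = _splice_effect(g, span)
    touches_cds = any(span[0] <= e and span[1] >= s for s, e in g.cds)

    if touches_cds:
        if v.vclass == SNP:
            effect = _snp_cds_effect(g, v.pos, v.alt, ref_seq)
        else:
            effect = _indel_cds_effect(g, changed_pos, ref_rem, alt_rem)
        # a HIGH splice hit outranks moderate/low coding calls
        if splice in ("splice_donor_variant", "splice_acceptor_variant"):
            effect = splice
        return EffectAnnotation(v, g.id, region, effect)

    if splice is not None:
        return EffectAnnotation(v, g.id, SPLICE_REGION, splice)

    if region == FIVE_UTR and _utr5_start_gain(g, v, ref_seq):
        return EffectAnnotation(v, g.id, region, "five_prime_UTR_premature_start_codon_gain_variant")
    if region in (FIVE_UTR, THREE_UTR, INTRON):
        return EffectAnnotation(v, g.id, region, _REGION_EFFECT[region])
    if region == EXON:  # non-coding gene exon
        return EffectAnnotation(v, g.id, region, "intron_variant")
    return EffectAnnotation(v, g.id, region, "intergenic_variant")


def annotate_variants(
    variants: Iterable[VariantRecord],
    genes: GeneIndex | Iterable[GeneModel],
    genome: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[EffectAnnotation]:
    """Annotate all variants; one annotation per overlapped gene.

    A deletion spanning coding sequence of two genes on opposite strands is
    reported as a bidirectional gene fusion for both genes.
    """
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes)
    out: list[EffectAnnotation] = []
    for v in variants:
        ref_seq = genome[v.chrom]
        changed_pos, ref_rem, _ = _trim_allele(v)
        span = (changed_pos, changed_pos + max(len(ref_rem) - 1, 0)) if ref_rem else (v.pos, v.pos)
        overlapped = genes.overlapping(v.chrom, span[0], span[1])
        cds_hit = [
            g for g in overlapped if any(span[0] <= e and span[1] >= s for s, e in g.cds)
        ]
        fusion = (
            ref_rem
            and len(cds_hit) >= 2
            and len({g.strand for g in cds_hit}) == 2
        )
        if fusion:
            for g in cds_hit:
                ann = EffectAnnotation(v, g.id, EXON, "bidirectional_gene_fusion")
                out.append(ann)
            continue
        if overlapped:
            for g in overlapped:
                out.append(annotate_effect(v, g, ref_seq, flank_bp=flank_bp))
        else:
            g, region = locate_variant(v, genes, flank_bp)
            out.append(annotate_effect(v, g, ref_seq, region=region, flank_bp=flank_bp))
    return out


# ---------------------------------------------------------------------------
# Summaries and export

def summarize_impacts(annotations: Sequence[EffectAnnotation]) -> dict:
    """Tallies by impact tier and effect term.

    When a variant carries several per-gene annotations only its most
    severe one is counted, so percentages refer to variants, not rows.
    """
    best: dict[tuple, EffectAnnotation] = {}
    for a in annotations:
        k = a.variant.key
        if k not in best or _SEVERITY_RANK[a.impact] < _SEVERITY_RANK[best[k].impact]:
            best[k] = a
    by_impact = {t: 0 for t in SEVERITY_ORDER}
    by_effect: dict[str, int] = {}
    for a in best.values():
        by_impact[a.impact] += 1
        by_effect[a.effect] = by_effect.get(a.effect, 0) + 1
    n = len(best)
    pct = {t: round(100.0 * c / n, 1) if n else 0.0 for t, c in by_impact.items()}
    return {"n": n, "by_impact": by_impact, "by_effect": by_effect, "impact_pct": pct}


def write_annotations_tsv(annotations: Iterable[EffectAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tregion\teffect\timpact\n")
        for a in annotations:
            v = a.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{a.gene or '.'}\t{a.region}\t{a.effect}\t{a.impact}\n"
            )


def read_annotations_tsv(path: str | Path) -> list[EffectAnnotation]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for r in df.itertuples(index=False):
        v = VariantRecord(r.chrom, int(r.pos), r.ref, r.alt)
        gene = None if r.gene in (".", "") else r.gene
        out.append(EffectAnnotation(v, gene, r.region, r.effect))
    return out


def ann_info_tag(a: EffectAnnotation) -> str:
    """`ANN=gene|region|effect|impact` VCF INFO payload."""
    return f"{a.gene or '.'}|{a.region}|{a.effect}|{a.impact}"


# ---------------------------------------------------------------------------
# GFF3 I/O (description attribute carried on the gene feature)

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            attrs = f"ID={g.id};description={g.description}"
            fh.write(
                f"{g.chrom}\tintroprio\tgene\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tintroprio\tmRNA\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\t"
                f"ID={g.id}.1;Parent={g.id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tintroprio\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.id}.1\n"
                )
            phase = 0
            cds_iter = g.cds if g.strand == "+" else tuple(reversed(g.cds))
            for s, e in cds_iter:
                fh.write(
                    f"{g.chrom}\tintroprio\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tParent={g.id}.1\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
        fh.flush()


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene/exon/CDS features of a GFF3 file into GeneModels."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
        )
    except Exception as exc:
        raise InputError(f"{path}: cannot parse as GFF3 ({exc})") from exc
    out = []
    for gene in db.features_of_type("gene"):
        exons = sorted((c.start, c.end) for c in db.children(gene, featuretype="exon"))
        cds = sorted((c.start, c.end) for c in db.children(gene, featuretype="CDS"))
        out.append(
            GeneModel(
                id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=gene.start,
                tx_end=gene.end,
                exons=tuple(exons) or ((gene.start, gene.end),),
                cds=tuple(cds),
                description=gene.attributes.get("description", [""])[0],
            )
        )
    out.sort(key=lambda g: (g.chrom, g.tx_start, g.id))
    return out
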