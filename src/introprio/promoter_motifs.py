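"""Promoter extraction, IUPAC cis-element scanning and two-genotype comparison.

Promoters are the 3000 bp upstream of the transcription start (strand
aware).  Cis-elements come from an editable catalog of named IUPAC
consensus strings patterned on the public PlantCARE motif descriptions;
scanning reports every (possibly overlapping) match on either strand.
Comparing two genotypes' promoters aligns them end-gap-free and flags a
motif occurrence as "mutated" when its footprint covers a differing
column, or when it is present in only one genotype.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .effect_annotation import GeneModel
from .errors import CatalogError, InputError
from .variant_io import VariantRecord

DEFAULT_PROMOTER_BP = 3000

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Motif:
    name: str
    consensus: str
    category: str = ""

    def __post_init__(self):
        bad = [c for c in self.consensus.upper() if c not in IUPAC]
        if not self.consensus or bad:
            raise CatalogError(f"motif {self.name!r}: invalid IUPAC consensus {self.consensus!r}")
        object.__setattr__(self, "consensus", self.consensus.upper())


@dataclass(frozen=True)
class MotifHit:
    motif: str
    offset: int  # 1-based from the promoter 5' end (forward orientation)
    strand: str
    matched: str


def load_motif_catalog(path: str | Path | None = None) -> list[Motif]:
    """Load a TSV motif catalog; default is the packaged catalog."""
    if path is None:
        from importlib.resources import files

        path = str(files("introprio").joinpath("data", "motif_catalog.tsv"))
    df = pd.read_csv(path, sep="\t")
    return [Motif(r.name, r.consensus, getattr(r, "category", "")) for r in df.itertuples(index=False)]


def write_motif_catalog(catalog: Iterable[Motif], path: str | Path) -> None:
    pd.DataFrame(
        [(m.name, m.consensus, m.category) for m in catalog],
        columns=["name", "consensus", "category"],
    ).to_csv(path, sep="\t", index=False)


def _iupac_regex(consensus: str) -> re.Pattern:
    # N must not match N in the sequence: restrict every class to ACGT
    return re.compile("".join(f"[{IUPAC[c]}]" for c in consensus))


def extract_promoter(
    g: GeneModel, genome: Mapping[str, str], length_bp: int = DEFAULT_PROMOTER_BP
) -> str:
    """Strand-aware promoter: the ``length_bp`` bases immediately upstream
    of the transcription start, in promoter 5'->3' orientation."""
    if g.chrom not in genome:
        raise InputError(f"{g.id}: chromosome {g.chrom!r} absent from genome")
    seq = genome[g.chrom]
    if g.strand == "+":
        start = max(1, g.tx_start - length_bp)
        out = seq[start - 1 : g.tx_start - 1]
    else:
        end = min(len(seq), g.tx_end + length_bp)
        out = str(Seq(seq[g.tx_end : end]).reverse_complement())
    if len(out) < length_bp:
        warnings.warn(
            f"{g.id}: promoter truncated to {len(out)} bp at chromosome edge", stacklevel=2
        )
    return out.upper()


def scan_motifs(
    seq: str, catalog: Sequence[Motif], both_strands: bool = True
) -> list[MotifHit]:
    """All (overlapping) IUPAC consensus matches.

    Minus-strand hits are reported at the forward-strand offset of the
    match footprint, with the forward-strand slice as ``matched``.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for m in catalog:
        pat = _iupac_regex(m.consensus)
        for i in range(len(seq) - len(m.consensus) + 1):
            window = seq[i : i + len(m.consensus)]
            if pat.fullmatch(window):
                hits.append(MotifHit(m.name, i + 1, "+", window))
        if both_strands:
            rc = str(Seq(m.consensus).reverse_complement())
            pat_rc = _iupac_regex(rc)
            for i in range(len(seq) - len(rc) + 1):
                window = seq[i : i + len(rc)]
                if pat_rc.fullmatch(window):
                    hits.append(MotifHit(m.name, i + 1, "-", window))
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def apply_variants_to_interval(
    seq: str, interval_start: int, variants: Iterable[VariantRecord]
) -> str:
    """Apply VCF-style variants to the subsequence starting at 1-based
    genomic coordinate ``interval_start`` (sequence given in forward
    orientation).  Variants outside the interval are ignored."""
    end = interval_start + len(seq) - 1
    edits = []
    for v in sorted(variants, key=lambda v: v.pos):
        if v.pos < interval_start or v.pos > end:
            continue
        off = v.pos - interval_start
        if seq[off : off + len(v.ref)].upper() != v.ref.upper():
            continue  # ref mismatch at interval edge; skip rather than corrupt
        edits.append((off, v.ref, v.alt))
    out = []
    cursor = 0
    for off, ref, alt in edits:
        if off < cursor:
            continue  # overlapping edit; first wins
        out.append(seq[cursor:off])
        out.append(alt)
        cursor = off + len(ref)
    out.append(seq[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Two-genotype comparison

def _end_gap_free_alignment(a: str, b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner.align(a, b)[0]


@dataclass(frozen=True)
class PromoterComparison:
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    mutated_motifs: int
    hse_present_a: bool
    hse_present_b: bool


def _columns_of(alignment, which: int, seq_len: int) -> list[int]:
    """Alignment column index of every sequence position."""
    cols = [0] * seq_len
    col = 0
    seqs = alignment.aligned  # pairs of aligned blocks
    # walk the alignment strings instead: robust for arbitrary gaps
    a_str = alignment[which]
    pos = 0
    for col, ch in enumerate(a_str):
        if ch != "-":
            cols[pos] = col
            pos += 1
    return cols


def compare_promoters(
    seq_a: str, seq_b: str, catalog: Sequence[Motif], hse_name: str = "HSE"
) -> PromoterComparison:
    """Count motif hits per genotype and motif occurrences mutated between
    the two.  ``seq_a``/``seq_b`` are the two genotypes' promoters for the
    same gene."""
    if not seq_a or not seq_b:
        raise InputError("empty promoter sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    hits_a = scan_motifs(seq_a, catalog)
    hits_b = scan_motifs(seq_b, catalog)
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for h in hits_a:
        counts_a[h.motif] = counts_a.get(h.motif, 0) + 1
    for h in hits_b:
        counts_b[h.motif] = counts_b.get(h.motif, 0) + 1

    if seq_a == seq_b:
        return PromoterComparison(
            counts_a, counts_b, 0,
            any(h.motif == hse_name for h in hits_a),
            any(h.motif == hse_name for h in hits_b),
        )

    aln = _end_gap_free_alignment(seq_a, seq_b)
    a_str, b_str = str(aln[0]), str(aln[1])
    diff_cols = {i for i, (x, y) in enumerate(zip(a_str, b_str)) if x != y}
    cols_a = _columns_of(aln, 0, len(seq_a))
    cols_b = _columns_of(aln, 1, len(seq_b))

    def footprint_cols(hit: MotifHit, cols: list[int]) -> tuple[int, ...]:
        start = hit.offset - 1
        return tuple(cols[start : start + len(hit.matched)])

    fps_a = {(h.motif, h.strand, footprint_cols(h, cols_a)): h for h in hits_a}
    fps_b = {(h.motif, h.strand, footprint_cols(h, cols_b)): h for h in hits_b}
    mutated = 0
    for key in fps_a:
        if key not in fps_b:
            mutated += 1
        elif any(c in diff_cols for c in key[2]):
            mutated += 1  # same footprint but covering a differing column
    for key in fps_b:
        if key not in fps_a:
            mutated += 1
    return PromoterComparison(
        counts_a, counts_b, mutated,
        any(h.motif == hse_name for h in hits_a),
        any(h.motif == hse_name for h in hits_b),
    )


def write_hits_tsv(hits_by_gene: Mapping[str, Sequence[MotifHit]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmotif\toffset\tstrand\tsequence\n")
        for gene in hits_by_gene:
            for h in hits_by_gene[gene]:
                fh.write(f"{gene}\t{h.motif}\t{h.offset}\t{h.strand}\t{h.matched}\n")


def write_comparison_tsv(
    comparisons: Mapping[str, PromoterComparison], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmotif\tcount_a\tcount_b\tmutated_n\thse_present_a\thse_present_b\n")
        for gene, c in comparisons.items():
            motifs = sorted(set(c.counts_a) | set(c.counts_b))
            if not motifs:
                fh.write(f"{gene}\t-\t0\t0\t{c.mutated_motifs}\t{c.hse_present_a}\t{c.hse_present_b}\n")
            for m in motifs:
                fh.write(
                    f"{gene}\t{m}\t{c.counts_a.get(m, 0)}\t{c.counts_b.get(m, 0)}\t"
                    f"{c.mutated_motifs}\t{c.hse_present_a}\t{c.hse_present_b}\n"
                )
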