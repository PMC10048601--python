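"""Shared-vs-private variant classification and per-gene percent identity.

A focal variant is "shared" with the wild donor when an identical
(chrom, pos, ref, alt) key exists in the donor call set — both call sets
are against the same reference build, so key equality is exact and
order-free.  Percent identity between a gene's two haplotype sequences is
computed from a global Needleman-Wunsch alignment with affine gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .errors import InputError, ReferenceMismatchError
from .variant_io import VariantRecord

VariantKey = tuple[str, int, str, str]


def classify_variant_sharing(
    focal: Sequence[VariantRecord],
    donor: Iterable[VariantRecord] | Iterable[VariantKey],
) -> dict[VariantKey, str]:
    """Label each focal variant 'shared' or 'private' against the donor set.

    Raises on a coordinate-system mismatch: same (chrom, pos) with
    disagreeing REF alleles.
    """
    donor_keys: set[VariantKey] = set()
    donor_ref_at: dict[tuple[str, int], str] = {}
    for d in donor:
        key = d.key if isinstance(d, VariantRecord) else tuple(d)  # type: ignore[assignment]
        donor_keys.add(key)  # type: ignore[arg-type]
        donor_ref_at[(key[0], key[1])] = key[2]
    out: dict[VariantKey, str] = {}
    for v in focal:
        ref_there = donor_ref_at.get((v.chrom, v.pos))
        if ref_there is not None and ref_there != v.ref and v.key not in donor_keys:
            raise ReferenceMismatchError(
                f"{v.chrom}:{v.pos} REF disagrees between call sets ({v.ref} vs {ref_there}); "
                "are they on the same reference build?"
            )
        out[v.key] = "shared" if v.key in donor_keys else "private"
    return out


def _aligner(match: float = 1, mismatch: float = -1, gap_open: float = -2, gap_extend: float = -1):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def alignment_score(seq_a: str, seq_b: str, **scores) -> float:
    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    return float(_aligner(**scores).score(seq_a.upper(), seq_b.upper()))


def percent_identity(seq_a: str, seq_b: str, **scores) -> float:
    """Matches / alignment columns x 100, to 2 decimals, from a global
    affine-gap alignment (match=1, mismatch=-1, open=-2, extend=-1).

    Co-optimal alignments can differ in identity, so the pair is ordered
    canonically before aligning; the statistic is therefore symmetric.
    """
    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        seq_a, seq_b = seq_b, seq_a
    aln = _aligner(**scores).align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    return round(100.0 * counts.identities / columns, 2)


@dataclass(frozen=True)
class SharingReport:
    gene: str
    shared_variants: int
    private_variants: int
    identity_vs_donor: float
    fully_donor: bool


def gene_sharing_report(
    gene_id: str,
    focal_variants: Sequence[VariantRecord],
    donor_variants: Iterable[VariantRecord] | Iterable[VariantKey],
    focal_seq: str | None = None,
    donor_seq: str | None = None,
) -> SharingReport:
    """Sharing report for one gene.

    ``focal_variants`` are the gene's high/moderate variants; identity is
    computed when both gene sequences are supplied, else from variant
    sharing alone (100 iff every variant is shared).
    """
    labels = classify_variant_sharing(focal_variants, donor_variants)
    shared = sum(1 for s in labels.values() if s == "shared")
    private = len(labels) - shared
    if focal_seq is not None and donor_seq is not None:
        ident = percent_identity(focal_seq, donor_seq)
    else:
        ident = 100.0 if private == 0 else round(100.0 * shared / max(len(labels), 1), 2)
    return SharingReport(gene_id, shared, private, ident, ident == 100.0)


def write_sharing_tsv(reports: Sequence[SharingReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tshared_n\tprivate_n\tidentity\tfully_donor\n")
        for r in reports:
            fh.write(
                f"{r.gene}\t{r.shared_variants}\t{r.private_variants}\t"
                f"{r.identity_vs_donor:.2f}\t{r.fully_donor}\n"
            )


def apply_variants(seq: str, start: int, variants: Iterable[VariantRecord]) -> str:
    """Apply variants to a forward-orientation subsequence whose first base
    has 1-based genomic coordinate ``start``."""
    from .promoter_motifs import apply_variants_to_interval

    return apply_variants_to_interval(seq, start, variants)
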