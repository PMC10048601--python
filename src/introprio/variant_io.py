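"""Reading, filtering and writing of called variants.

A :class:`VariantRecord` is one ALT allele at one site (multi-allelic sites
are split on read).  Filtering reproduces the conventional VCFtools-style
semantics: phred quality >= ``min_qual``, mean depth >= ``min_mean_depth``,
and (for a single resequenced line) homozygous-alternate calls only.
Thresholds are inclusive.  Missing QUAL/DP are carried as -1 so they fail
any positive threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .errors import VcfParseError

MISSING = -1.0

SNP = "SNP"
INDEL = "InDel"

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
GT_MISSING = "missing"

# cyvcf2 gt_types codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_CODE = {0: HOM_REF, 1: HET, 2: GT_MISSING, 3: HOM_ALT}


def classify_allele(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases; any length change is an InDel."""
    return SNP if len(ref) == 1 and len(alt) == 1 else INDEL


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float = MISSING
    depth: float = MISSING
    genotype: str = HOM_ALT
    vclass: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"ref/alt must be non-empty and differ: {self.ref!r}/{self.alt!r}")
        expected = classify_allele(self.ref, self.alt)
        if not self.vclass:
            object.__setattr__(self, "vclass", expected)
        elif self.vclass != expected:
            raise ValueError(f"vclass {self.vclass!r} inconsistent with alleles {self.ref}/{self.alt}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Quality filter. Defaults follow the common resequencing practice of
    minQ = 15 with a minimum mean depth of 15, keeping homozygous-alt calls."""

    min_qual: float = 15.0
    min_mean_depth: float = 15.0
    homozygous_alt_only: bool = True
    max_missing: float = 0.5  # site-level missingness cap for multi-sample files

    def __post_init__(self):
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.min_mean_depth < 0:
            raise ValueError("min_mean_depth must be >= 0")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


def read_variants(path: str | Path, sample: str | None = None) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, one per ALT allele.

    ``sample`` selects whose genotype is reported; default is the first
    sample (or hom_alt for a site-only VCF with no samples).
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises plain OSError/Exception on bad headers
        raise VcfParseError(f"{path}: cannot open as VCF ({exc})") from exc
    sample_idx = 0
    if sample is not None:
        if sample not in vcf.samples:
            raise VcfParseError(f"{path}: sample {sample!r} not in VCF")
        sample_idx = vcf.samples.index(sample)
    records: list[VariantRecord] = []
    line_no = 0
    try:
        for v in vcf:
            line_no += 1
            qual = float(v.QUAL) if v.QUAL is not None else MISSING
            depth = _mean_depth(v)
            if len(vcf.samples) == 0:
                gt = HOM_ALT
            else:
                gt = _GT_CODE.get(int(v.gt_types[sample_idx]), GT_MISSING)
            for alt in v.ALT:
                if alt in (".", "", "*", "<NON_REF>"):
                    continue
                records.append(
                    VariantRecord(v.CHROM, v.POS, v.REF, alt, qual=qual, depth=depth, genotype=gt)
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF near record {line_no + 1} ({exc})") from exc
    finally:
        vcf.close()
    return records


def _mean_depth(v) -> float:
    try:
        dp = v.format("DP")
        if dp is not None:
            vals = [float(x) for x in dp.flatten() if x >= 0]
            if vals:
                return sum(vals) / len(vals)
    except Exception:
        pass
    info_dp = v.INFO.get("DP")
    return float(info_dp) if info_dp is not None else MISSING


def filter_variants(records: Iterable[VariantRecord], cfg: FilterConfig | None = None) -> list[VariantRecord]:
    """Keep records passing all thresholds (inclusive). Order preserved."""
    cfg = cfg or FilterConfig()
    kept = []
    for r in records:
        if r.qual < cfg.min_qual or r.depth < cfg.min_mean_depth:
            continue
        if cfg.homozygous_alt_only and r.genotype != HOM_ALT:
            continue
        kept.append(r)
    return kept


def split_kept_removed(
    records: Sequence[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    kept = filter_variants(records, cfg)
    kept_ids = {id(r) for r in kept}
    return kept, [r for r in records if id(r) not in kept_ids]


def to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.pos, r.ref, r.alt, r.qual, r.depth, r.genotype, r.vclass) for r in records],
        columns=["chrom", "pos", "ref", "alt", "qual", "depth", "genotype", "vclass"],
    )


def write_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    to_frame(records)[["chrom", "pos", "ref", "alt", "vclass"]].to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        VariantRecord(row.chrom, int(row.pos), row.ref, row.alt)
        for row in df.itertuples(index=False)
    ]


_GT_FIELD = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", GT_MISSING: "./."}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    sample: str = "sample",
) -> None:
    """Write a minimal single-sample VCF v4.2 (GT, GQ, DP populated)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in records:
            qual = "." if r.qual == MISSING else f"{r.qual:g}"
            dp = "." if r.depth == MISSING else f"{int(round(r.depth))}"
            gq = "." if r.qual == MISSING else f"{int(round(min(99, r.qual)))}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t"
                f"DP={dp}\tGT:GQ:DP\t{_GT_FIELD[r.genotype]}:{gq}:{dp}\n"
            )


__all__ = [
    "VariantRecord",
    "FilterConfig",
    "classify_allele",
    "read_variants",
    "filter_variants",
    "split_kept_removed",
    "to_frame",
    "write_tsv",
    "read_tsv",
    "write_vcf",
    "MISSING",
    "SNP",
    "INDEL",
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "GT_MISSING",
]
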