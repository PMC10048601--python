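"""Keyword candidate lists, QTL colocalization and candidate-gene priority.

Genes are screened by case-insensitive substring match of configurable
keywords against their functional description, split into a heat-response
list (chaperones and heat-stress transcription factors) and a reproduction
list (flowering and pollen/anther development).  Candidates are genes from
either list that carry at least one HIGH or MODERATE impact variant and
that fall in a highly polymorphic region or overlap a QTL for a
flowering-related trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .density_regions import PolymorphicRegion
from .effect_annotation import HIGH, MODERATE, EffectAnnotation, GeneModel
from .errors import NamespaceError

# Trait classes of the reproduction QTL catalogue.
TRAIT_CLASSES = (
    "flowering time",
    "flower number",
    "inflorescence number",
    "flowers per inflorescence",
    "inflorescence with a single cyme",
    "stigma length/protrusion/exertion",
    "anther length",
    "pollen number",
    "pollen viability",
    "fruit set",
    "fruit number",
)

# Prioritization keeps genes overlapping QTLs for these trait classes.
DEFAULT_FLOWER_TRAIT_CLASSES = frozenset(
    {"flower number", "flowers per inflorescence", "inflorescence number", "flowering time"}
)
STRICT_FLOWER_TRAIT_CLASSES = frozenset({"flower number"})


@dataclass(frozen=True)
class QTLInterval:
    qtl_id: str
    trait: str
    trait_class: str
    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.qtl_id}: start must be < end")
        if self.trait_class not in TRAIT_CLASSES:
            raise ValueError(f"{self.qtl_id}: unknown trait_class {self.trait_class!r}")


@dataclass(frozen=True)
class KeywordConfig:
    """Case-insensitive substring keywords applied to gene descriptions."""

    heat_keywords: tuple[str, ...] = ("heat", "hsp", "hsf")
    reproduction_keywords: tuple[str, ...] = ("flower", "pollen", "anthesis", "anther", "fruit set")

    def __post_init__(self):
        if not self.heat_keywords or not self.reproduction_keywords:
            raise ValueError("keyword lists must be non-empty")
        object.__setattr__(self, "heat_keywords", tuple(k.lower() for k in self.heat_keywords))
        object.__setattr__(
            self, "reproduction_keywords", tuple(k.lower() for k in self.reproduction_keywords)
        )


# Extension of the heat keywords to the annotation vocabulary actually used in
# gene functional descriptions (chaperones are rarely described with the bare
# word "heat").
EXTENDED_HEAT_KEYWORDS = ("heat", "hsp", "hsf", "dnaj", "chaperone", "heat shock")
EXTENDED_KEYWORDS = KeywordConfig(heat_keywords=EXTENDED_HEAT_KEYWORDS)

_HSF_MARKERS = ("hsf", "heat stress transcription factor", "heat shock factor", "heat shock transcription factor")
_POLLEN_MARKERS = ("pollen", "anther", "anthesis")


def _matches(description: str, keywords: Sequence[str]) -> bool:
    d = description.lower()
    return any(k in d for k in keywords)


def heat_subcategory(description: str) -> str:
    d = description.lower()
    return "HSF" if any(m in d for m in _HSF_MARKERS) else "HSP"


def reproduction_subcategory(description: str) -> str:
    d = description.lower()
    if "flower" in d:
        return "flower"
    if any(m in d for m in _POLLEN_MARKERS):
        return "pollen"
    return "flower"


def keyword_select(
    genes: Iterable[GeneModel], kw: KeywordConfig | None = None
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Split genes into (heat list, reproduction list) by description.

    A gene may appear in both lists; membership is purely a substring test.
    """
    kw = kw or KeywordConfig()
    heat, repro = [], []
    for g in genes:
        if _matches(g.description, kw.heat_keywords):
            heat.append(g)
        if _matches(g.description, kw.reproduction_keywords):
            repro.append(g)
    return heat, repro


# ---------------------------------------------------------------------------
# Colocalization

def _interval_tree(intervals: Sequence, chroms: Iterable[str]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    for iv in intervals:
        # IntervalTree is half-open; +1 keeps 1-based inclusive semantics
        trees[iv.chrom].addi(iv.start, iv.end + 1, iv)
    return trees


def colocalize(
    genes: Sequence[GeneModel],
    intervals: Sequence[QTLInterval] | Sequence[PolymorphicRegion],
    strict_namespace: bool = True,
) -> dict[str, list]:
    """Map gene id -> overlapping intervals (1-based inclusive overlap).

    With ``strict_namespace`` (default), completely disjoint chromosome
    name sets raise, which catches naming-convention mixups (chr1 vs
    SL4.0ch01) early.
    """
    gene_chroms = {g.chrom for g in genes}
    iv_chroms = {iv.chrom for iv in intervals}
    unmatched = iv_chroms - gene_chroms
    if strict_namespace and intervals and gene_chroms and unmatched == iv_chroms:
        raise NamespaceError(
            f"no shared chromosome names; interval chroms {sorted(unmatched)} "
            f"vs gene chroms {sorted(gene_chroms)}"
        )
    trees = _interval_tree(intervals, iv_chroms)
    out: dict[str, list] = {}
    for g in genes:
        tree = trees.get(g.chrom)
        hits = [h.data for h in tree.overlap(g.tx_start, g.tx_end + 1)] if tree else []
        hits.sort(key=lambda iv: (iv.start, iv.end, getattr(iv, "qtl_id", getattr(iv, "label", ""))))
        out[g.id] = hits
    return out


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    list_name: str  # heat | reproduction
    subcategory: str  # HSP | HSF | flower | pollen
    high_n: int
    moderate_n: int
    region_label: str | None
    qtl_ids: tuple[str, ...]
    description: str
    chrom: str = ""
    tx_start: int = 0


def prioritize(
    heat: Sequence[GeneModel],
    reproduction: Sequence[GeneModel],
    annotations: Sequence[EffectAnnotation],
    regions: Sequence[PolymorphicRegion],
    qtls: Sequence[QTLInterval],
    flower_trait_classes: frozenset[str] | set[str] = DEFAULT_FLOWER_TRAIT_CLASSES,
) -> list[CandidateGene]:
    """Select candidate genes.

    A gene is kept iff it is on a candidate list, carries >=1 HIGH or
    MODERATE variant, and lies in a polymorphic region or overlaps a QTL
    whose trait class is flowering-related.  Output is sorted by
    chromosome then position.
    """
    listed: dict[str, tuple[GeneModel, str]] = {}
    for g in heat:
        listed[g.id] = (g, "heat")
    for g in reproduction:
        listed.setdefault(g.id, (g, "reproduction"))
    both = {g.id for g in heat} & {g.id for g in reproduction}

    high_n: dict[str, int] = {}
    mod_n: dict[str, int] = {}
    for a in annotations:
        if a.gene is None:
            continue
        if a.impact == HIGH:
            high_n[a.gene] = high_n.get(a.gene, 0) + 1
        elif a.impact == MODERATE:
            mod_n[a.gene] = mod_n.get(a.gene, 0) + 1

    gene_models = [gm for gm, _ in listed.values()]
    region_of = (
        colocalize(gene_models, list(regions), strict_namespace=False)
        if regions
        else {g.id: [] for g in gene_models}
    )
    flower_qtls = [q for q in qtls if q.trait_class in flower_trait_classes]
    qtl_of = (
        colocalize(gene_models, flower_qtls, strict_namespace=False)
        if flower_qtls
        else {g.id: [] for g in gene_models}
    )

    out = []
    for gid, (g, list_name) in listed.items():
        hn, mn = high_n.get(gid, 0), mod_n.get(gid, 0)
        if hn + mn == 0:
            continue
        regs = region_of.get(gid, [])
        qs = qtl_of.get(gid, [])
        if not regs and not qs:
            continue
        sub = heat_subcategory(g.description) if list_name == "heat" else reproduction_subcategory(g.description)
        out.append(
            CandidateGene(
                gene=gid,
                list_name=list_name if gid not in both else "heat+reproduction",
                subcategory=sub,
                high_n=hn,
                moderate_n=mn,
                region_label=regs[0].label if regs else None,
                qtl_ids=tuple(q.qtl_id for q in qs),
                description=g.description,
                chrom=g.chrom,
                tx_start=g.tx_start,
            )
        )
    out.sort(key=lambda c: (c.chrom, c.tx_start, c.gene))
    return out


def summarize_candidates(candidates: Sequence[CandidateGene]) -> dict:
    regions = {c.region_label for c in candidates if c.region_label}
    by_list: dict[str, int] = {}
    by_sub: dict[str, int] = {}
    for c in candidates:
        for name in c.list_name.split("+"):
            by_list[name] = by_list.get(name, 0) + 1
        by_sub[c.subcategory] = by_sub.get(c.subcategory, 0) + 1
    return {
        "total_genes": len(candidates),
        "distinct_regions": len(regions),
        "genes_with_high": sum(1 for c in candidates if c.high_n >= 1),
        "by_list": by_list,
        "by_subcategory": by_sub,
    }


# ---------------------------------------------------------------------------
# Tabular I/O and packaged fixtures

def candidates_to_frame(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene,
                c.list_name,
                c.subcategory,
                c.high_n,
                c.moderate_n,
                c.region_label or "-",
                ";".join(c.qtl_ids) or "-",
                c.description,
            )
            for c in candidates
        ],
        columns=["gene", "list", "subcategory", "high_n", "moderate_n", "region", "qtl", "description"],
    )


def write_candidates_tsv(candidates: Sequence[CandidateGene], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_qtl_tsv(path: str | Path) -> list[QTLInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        QTLInterval(
            qtl_id=r.qtl_id,
            trait=r.trait,
            trait_class=r.trait_class,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            source=getattr(r, "source", ""),
        )
        for r in df.itertuples(index=False)
    ]


def write_qtl_tsv(qtls: Sequence[QTLInterval], path: str | Path) -> None:
    pd.DataFrame(
        [(q.qtl_id, q.trait, q.trait_class, q.chrom, q.start, q.end, q.source) for q in qtls],
        columns=["qtl_id", "trait", "trait_class", "chrom", "start", "end", "source"],
    ).to_csv(path, sep="\t", index=False)


def _fixture_path(name: str) -> Path:
    from importlib.resources import files

    return Path(str(files("introprio").joinpath("data", name)))


def load_qtl_class_counts() -> pd.DataFrame:
    """Packaged per-trait QTL counts of the published reproduction-QTL catalogue."""
    return pd.read_csv(_fixture_path("qtl_trait_counts.tsv"), sep="\t")


def load_candidate_table() -> pd.DataFrame:
    """Packaged 35-gene candidate table (gene, variant counts, region, QTL, function)."""
    return pd.read_csv(_fixture_path("candidate_genes.tsv"), sep="\t", keep_default_na=False)


def candidates_from_table(df: pd.DataFrame, kw: KeywordConfig = EXTENDED_KEYWORDS) -> list[CandidateGene]:
    """Re-type a published-style candidate table as CandidateGene rows,
    classifying each gene's list membership by keyword."""
    out = []
    for r in df.itertuples(index=False):
        desc = r.protein_function
        is_heat = _matches(desc, kw.heat_keywords)
        is_rep = _matches(desc, kw.reproduction_keywords)
        if is_heat:
            list_name = "heat" if not is_rep else "heat+reproduction"
            sub = heat_subcategory(desc)
        elif is_rep:
            list_name = "reproduction"
            sub = reproduction_subcategory(desc)
        else:
            list_name = "unclassified"
            sub = "-"
        region = r.polymorphic_region if r.polymorphic_region not in ("-", "") else None
        qtls = tuple(q.strip() for q in str(r.qtl).split(";") if q.strip() and q.strip() != "-")
        out.append(
            CandidateGene(
                gene=r.gene,
                list_name=list_name,
                subcategory=sub,
                high_n=int(r.high_n),
                moderate_n=int(r.moderate_n),
                region_label=region,
                qtl_ids=qtls,
                description=desc,
                chrom=r.gene[5:7],
                tx_start=0,
            )
        )
    return out
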