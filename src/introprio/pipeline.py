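"""End-to-end orchestration: filter -> densities -> regions -> annotation ->
prioritization -> phylogeny/origin -> promoter comparison -> donor sharing.

A :class:`PipelineConfig` either points at real input files or embeds a
:class:`~introprio.synthetic_data.SimulationConfig`; a run writes every
stage's tabular output plus a manifest (config hash, seed, version,
per-stage record counts) into the output directory.  Runs are
deterministic: the same config produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from . import candidate_prioritization as cp
from . import density_regions as dr
from . import phylogeny as phylo
from . import promoter_motifs as pm
from . import sequence_compare as sc
from . import synthetic_data as sd
from . import variant_io as vio
from .effect_annotation import HIGH, MODERATE, GeneIndex, annotate_variants, read_gff3, summarize_impacts, write_annotations_tsv
from .errors import ConfigurationError, IntroprioError

log = logging.getLogger("introprio")

_INPUT_KEYS = ("reference_fasta", "genes_gff", "focal_vcf", "panel_vcf", "qtl_tsv")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    simulate: sd.SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    filter: vio.FilterConfig = field(default_factory=vio.FilterConfig)
    region: dr.RegionConfig = field(default_factory=dr.RegionConfig)
    keywords: cp.KeywordConfig = field(default_factory=lambda: cp.EXTENDED_KEYWORDS)
    flower_trait_classes: frozenset[str] = cp.DEFAULT_FLOWER_TRAIT_CLASSES
    promoter_bp: int = pm.DEFAULT_PROMOTER_BP
    focal_sample: str = "focal"
    flank_bp: int = 5000

    def __post_init__(self):
        if self.simulate is None:
            missing = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ConfigurationError(
                    f"inputs: missing {missing} (provide them or a `simulate` block)"
                )
        elif self.inputs:
            raise ConfigurationError("config must not mix `simulate` with explicit `inputs`")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "simulate" in kw and kw["simulate"] is not None:
            sim = dict(kw["simulate"])
            if "introgression_segments" in sim:
                sim["introgression_segments"] = tuple(
                    (c, int(s), int(e)) for c, s, e in sim["introgression_segments"]
                )
            kw["simulate"] = sd.SimulationConfig(**sim)
        if "filter" in kw:
            kw["filter"] = vio.FilterConfig(**kw["filter"])
        if "region" in kw:
            kw["region"] = dr.RegionConfig(**kw["region"])
        if "keywords" in kw:
            kc = dict(kw["keywords"])
            kw["keywords"] = cp.KeywordConfig(
                heat_keywords=tuple(kc.get("heat_keywords", cp.EXTENDED_HEAT_KEYWORDS)),
                reproduction_keywords=tuple(
                    kc.get("reproduction_keywords", cp.KeywordConfig().reproduction_keywords)
                ),
            )
        if "flower_trait_classes" in kw:
            kw["flower_trait_classes"] = frozenset(kw["flower_trait_classes"])
        try:
            return cls(**kw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def canonical_json(self) -> str:
        # output_dir is deliberately excluded: the hash identifies the
        # scientific configuration, not the destination
        d = {
            "seed": self.seed,
            "simulate": asdict(self.simulate) if self.simulate else None,
            "inputs": dict(sorted(self.inputs.items())),
            "filter": asdict(self.filter),
            "region": asdict(self.region),
            "keywords": {
                "heat_keywords": list(self.keywords.heat_keywords),
                "reproduction_keywords": list(self.keywords.reproduction_keywords),
            },
            "flower_trait_classes": sorted(self.flower_trait_classes),
            "promoter_bp": self.promoter_bp,
            "focal_sample": self.focal_sample,
            "flank_bp": self.flank_bp,
        }
        return json.dumps(d, sort_keys=True, default=list)


def _read_genome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the summary report dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- inputs ----------------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        log.info("simulating dataset (seed=%d)", cfg.simulate.seed)
        ds = sd.simulate_dataset(cfg.simulate, out / "simulated_inputs")
        genome = ds.genome
        genes = ds.genes
        focal_vcf, panel_vcf, donor_vcf = ds.focal_vcf, ds.panel_vcf, ds.donor_vcf
        qtls = cp.read_qtl_tsv(ds.qtl_tsv)
        catalog = pm.load_motif_catalog(ds.motif_tsv)
        chrom_lengths = cfg.simulate.chrom_lengths
        truth = ds.truth
    else:
        genome = _read_genome(cfg.inputs["reference_fasta"])
        genes = read_gff3(cfg.inputs["genes_gff"])
        focal_vcf = Path(cfg.inputs["focal_vcf"])
        panel_vcf = Path(cfg.inputs["panel_vcf"])
        donor_vcf = Path(cfg.inputs["donor_vcf"]) if "donor_vcf" in cfg.inputs else None
        qtls = cp.read_qtl_tsv(cfg.inputs["qtl_tsv"])
        catalog = pm.load_motif_catalog(cfg.inputs.get("motif_catalog"))
        chrom_lengths = {c: len(s) for c, s in genome.items()}
    index = GeneIndex(genes)
    counts["genes"] = len(genes)

    # --- filter ----------------------------------------------------------
    raw = vio.read_variants(focal_vcf)
    filtered = vio.filter_variants(raw, cfg.filter)
    counts["raw_variants"] = len(raw)
    counts["filtered_variants"] = len(filtered)
    log.info("filter: %d raw -> %d kept", len(raw), len(filtered))
    vio.write_tsv(filtered, out / "filtered_variants.tsv")

    # --- windows + regions ----------------------------------------------
    windows = dr.count_in_windows(filtered, chrom_lengths, cfg.region)
    regions = dr.detect_polymorphic_regions(windows, cfg.region)
    counts["windows"] = len(windows)
    counts["polymorphic_regions"] = len(regions)
    dr.write_windows_tsv(windows, out / "window_densities.tsv")
    dr.write_regions_tsv(regions, out / "polymorphic_regions.tsv")
    dr.write_regions_bed(regions, out / "polymorphic_regions.bed")

    # --- effect annotation ----------------------------------------------
    annotations = annotate_variants(filtered, index, genome, cfg.flank_bp)
    counts["annotations"] = len(annotations)
    write_annotations_tsv(annotations, out / "effect_annotations.tsv")
    impact_summary = summarize_impacts(annotations)

    # --- candidate prioritization ---------------------------------------
    heat, repro = cp.keyword_select(genes, cfg.keywords)
    counts["heat_list"] = len(heat)
    counts["reproduction_list"] = len(repro)
    candidates = cp.prioritize(
        heat, repro, annotations, regions, qtls, cfg.flower_trait_classes
    )
    counts["candidates"] = len(candidates)
    cp.write_candidates_tsv(candidates, out / "candidate_genes.tsv")
    candidate_summary = cp.summarize_candidates(candidates)

    # --- phylogeny and origin assignment --------------------------------
    gm = phylo.read_genotype_matrix(
        panel_vcf, min_qual=cfg.filter.min_qual, max_missing=cfg.filter.max_missing
    )
    species_of = {
        s: s.rsplit("_", 1)[0] for s in gm.samples if s != cfg.focal_sample
    }
    origins: dict[str, list[phylo.OriginCall]] = {}
    newick_dir = out / "trees"
    newick_dir.mkdir(exist_ok=True)
    for chrom in gm.chroms:
        sub = gm.subset_chrom(chrom)
        dm = phylo.genotype_distance(sub)
        tree = phylo.neighbor_joining(dm)
        phylo.write_newick(tree, newick_dir / f"{chrom}.nwk")
        if cfg.focal_sample in dm.labels:
            origins[chrom] = phylo.assign_origin(tree, cfg.focal_sample, species_of)
    phylo.origin_report(origins, out / "origin_assignment.tsv")
    counts["panel_sites"] = len(gm.sites)

    # --- promoter comparison (focal vs reference) -----------------------
    gene_by_id = {g.id: g for g in genes}
    comparisons: dict[str, pm.PromoterComparison] = {}
    for c in candidates:
        g = gene_by_id.get(c.gene)
        if g is None:
            continue
        ref_prom = pm.extract_promoter(g, genome, cfg.promoter_bp)
        if g.strand == "+":
            start = max(1, g.tx_start - cfg.promoter_bp)
            fwd = genome[g.chrom][start - 1 : g.tx_start - 1]
            edited = sc.apply_variants(fwd, start, filtered)
            focal_prom = edited.upper()
        else:
            start = g.tx_end + 1
            fwd = genome[g.chrom][g.tx_end : min(len(genome[g.chrom]), g.tx_end + cfg.promoter_bp)]
            edited = sc.apply_variants(fwd, start, filtered)
            from Bio.Seq import Seq

            focal_prom = str(Seq(edited).reverse_complement()).upper()
        if not ref_prom or not focal_prom:
            continue
        comparisons[c.gene] = pm.compare_promoters(focal_prom, ref_prom, catalog)
    pm.write_comparison_tsv(comparisons, out / "promoter_comparison.tsv")
    counts["promoters_compared"] = len(comparisons)

    # --- donor sharing ---------------------------------------------------
    sharing: list[sc.SharingReport] = []
    donor_records = None
    if cfg.simulate is not None and truth is not None:
        donor_records = truth.donor_key_set
    elif donor_vcf is not None:
        donor_records = vio.read_variants(donor_vcf)
    if donor_records is not None:
        for c in candidates:
            g = gene_by_id.get(c.gene)
            if g is None:
                continue
            gene_vars = [
                a.variant
                for a in annotations
                if a.gene == c.gene and a.impact in (HIGH, MODERATE)
            ]
            sharing.append(sc.gene_sharing_report(c.gene, gene_vars, donor_records))
    sc.write_sharing_tsv(sharing, out / "donor_sharing.tsv")
    counts["genes_shared_with_donor"] = sum(1 for r in sharing if r.private_variants == 0 and r.shared_variants > 0)

    # --- manifest + report ----------------------------------------------
    report = {
        "counts": counts,
        "impact_summary": impact_summary,
        "candidate_summary": candidate_summary,
        "origin_top_species": {c: (o[0].species if o else None) for c, o in origins.items()},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
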