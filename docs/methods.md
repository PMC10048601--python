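# Methods

This note documents the models, definitions and numerical choices behind
`introprio`, and what the synthetic benchmarks do and do not demonstrate.

## Variant filtering

A `VariantRecord` is one ALT allele at one site; multi-allelic sites are
split before anything else so genotype and class semantics are per-allele.
SNP vs InDel is decided purely by allele lengths (`len(ref)==len(alt)==1`
is a SNP). Filtering keeps records with `qual >= min_qual` (default 15),
`depth >= min_mean_depth` (default 15) and, for a single inbred focal line,
homozygous-alternate genotype. Thresholds are **inclusive**, matching the
conventional semantics of VCFtools' `--minQ`/`--min-meanDP`; missing
QUAL/DP are carried as −1 so they fail any positive threshold. The
homozygosity filter is applied together with the quality thresholds; for
multi-sample panels it is disabled and a per-site missingness cap
(`max_missing`, default 0.5) applies instead.

## Window densities and polymorphic regions

Counts are tallied in non-overlapping windows of `window_bp` (default
1 Mb); window *i* covers [(i−1)·W+1, i·W], the terminal window is clipped.
A window qualifies when its SNP count **strictly exceeds** the SNP
threshold or its InDel count strictly exceeds the InDel threshold.
Thresholds come in two modes:

* `fold_mean` (default): k× the genome-wide mean per-window count for that
  variant class, k = 3 by default. Fold-over-mean adapts to overall
  variant density and is the mode used by all benchmarks.
* `absolute`: per-window counts given directly, for analyses that quote
  absolute cutoffs.

Runs of qualifying windows separated by at most `merge_gap_windows`
(default 1) quiet windows merge into one region; the gap tolerance absorbs
single noisy windows inside a real introgression. Regions are labelled
`p{chrom}_{k}` with k increasing along the chromosome. Coordinates are
1-based inclusive internally; BED export converts to 0-based half-open.

A note on the fold-mean mode: with contrast ratio r = λ_intro/λ_bg and
introgressed genome fraction f, detection at k× the mean requires
r > k(1−f) + k·r·f, i.e. f < (r−k)/(k(r−1)). At r = 20, k = 3 this means
the introgressed fraction must stay below ≈30% of the genome — the
benchmark configurations keep it near 20%.

## Effect annotation

A compact re-implementation of the familiar annotation semantics:

* **Regions.** Containment in the transcript span beats flanks; within the
  span, exon/intron/UTR by interval membership with strand-aware UTR
  sidedness; positions within 3 bp of an exon–intron junction are reported
  as `splice_region`; positions within `flank_bp` (default 5 kb, the usual
  annotation-tool convention) upstream/downstream of the span are
  `upstream`/`downstream` (strand-aware); everything else is intergenic.
* **Coding SNPs.** The affected codon is translated before and after the
  substitution (standard nuclear code, strand-aware): same residue →
  synonymous; new stop → stop_gained; lost stop → stop_lost; otherwise
  missense. Start-codon edge cases are deliberately reported as missense.
* **Coding indels.** After trimming the VCF anchor base, a length change
  that is not a multiple of 3 is a frameshift. In-frame deletions are
  *conservative* iff whole codons are removed (first deleted base in
  transcript order on a codon boundary, deletion entirely coding),
  otherwise *disruptive*; insertions are conservative iff the insertion
  point falls on a codon boundary.
* **Splice core.** The first/last 2 intron bases give
  splice_donor/splice_acceptor (HIGH), orientation decided by strand; a
  HIGH splice hit outranks a coincident coding call.
* **Fusions.** A deletion spanning coding sequence of two genes on
  opposite strands is reported as `bidirectional_gene_fusion` for both
  genes — minimal semantics for the term, flagged as approximate.
* **Multiple genes.** One annotation per overlapped gene is emitted (no
  most-severe-only collapsing), so per-gene variant counts are exact;
  impact *summaries* count each variant once at its most severe
  annotation.

The impact tier is a fixed pure function of the effect term (HIGH:
frameshift, stop gained/lost, splice donor/acceptor, fusion; MODERATE:
missense and in-frame indels; LOW: synonymous, splice region; MODIFIER:
everything non-coding). A 5′UTR SNP that creates a new upstream ATG is
reported as the premature-start-gain MODIFIER term.

## Phylogeny and origin assignment

The pairwise distance is **genotype discordance**: the fraction of sites,
non-missing in both samples, at which alt-allele dosages (0/1/2) differ.
This is the package's own definition — the simplest statistic consistent
with NJ input from a merged VCF — and is documented as a deviation surface:
other tools may weight heterozygous differences differently. A pair with
zero co-observed sites is an error, not a zero.

Trees use the canonical Saitou–Nei neighbor-joining agglomeration
(Q-matrix minimization, standard branch-length and distance-update
formulas), authored here and cross-checked in the tests against
scikit-bio's independent implementation and against brute-force
path-length oracles; on additive matrices recovery is exact to 1e−9.
Negative branch lengths, possible on noisy input, are clamped to zero with
the deficit moved to the sibling branch so Newick output is nonnegative.
The final join produces the usual trifurcating root of an unrooted tree.

Origin assignment is defined on the unrooted tree (no midpoint rooting is
guessed): species are ranked by (1) minimum path length from the focal
leaf to any accession of the species, then (2) size of the smallest clade
containing the focal leaf and a member, then (3) species name. Trees are
built per chromosome, so a mosaic line can have different origins on
different chromosomes.

## Candidate prioritization

Keyword membership is case-insensitive substring matching on the gene
functional description only. The base heat list is {heat, hsp, hsf}; the
`EXTENDED_KEYWORDS` variant adds {dnaj, chaperone, heat shock} because
chaperones are rarely described with the bare word "heat" — the packaged
candidate table classifies 24 heat vs 11 reproduction genes only under the
extended set, so it is the default for pipeline runs. Reproduction
keywords are {flower, pollen, anthesis, anther, fruit set}. Subcategories:
HSF when the description names a heat-stress transcription factor, else
HSP; "flower" when the description contains *flower*, else "pollen".

A gene is selected iff it is on a list, carries ≥1 HIGH or MODERATE
variant, and lies in a polymorphic region **or** overlaps a QTL whose
trait class is flowering-related. `flower_trait_classes` defaults to
{flower number, flowers per inflorescence, inflorescence number, flowering
time}: the broader default matches candidate tables that include
flowering-time QTLs; a strict mode restricts to flower number only.
Gene–interval overlap is 1-based inclusive (a single shared base counts),
implemented over interval trees.

## Promoters and cis-elements

The promoter is the 3000 bp upstream of the transcription start
(strand-aware; truncated with a warning at chromosome edges). "Gene start
site" is read as the transcription start, not the ATG; a CDS-start mode is
available via the gene model's CDS coordinates. The motif catalog is an
editable TSV of named IUPAC consensus strings patterned on the public
PlantCARE motif descriptions; consensus strings are configuration data,
not package constants. Scanning reports every match position, overlaps
included, on both strands; an N in the sequence never satisfies a non-N
consensus symbol.

Two-genotype comparison aligns the promoters end-gap-free (match 1,
mismatch −1, gap −2) and calls a motif occurrence **mutated** when its
footprint covers at least one differing alignment column, or when the
occurrence exists in exactly one genotype. This is the package's own
definition of "mutated motif"; per-gene mutated counts are therefore
comparable within a run but not across tools.

## Donor sharing and identity

A focal variant is shared with the donor iff an identical
(chrom, pos, ref, alt) key exists in the donor call set — both call sets
are against the same reference build, so key equality is exact; a REF
disagreement at a shared position raises a coordinate-system error.
Percent identity is matches/columns × 100 (2 decimals) from a global
Needleman–Wunsch alignment with affine gaps (1/−1/−2 open/−1 extend).
Because co-optimal alignments can differ in identity, the sequence pair is
ordered canonically before aligning, making the statistic symmetric.

## Synthetic data: what it emulates, and what it does not

The generator draws everything from one `numpy` Generator seeded by the
single config seed; identical configs give byte-identical files.

* **Variant placement** is a Poisson process: per-region counts
  Poisson(λ·length) with uniform positions (duplicates dropped), λ_bg
  outside introgressed segments (default 50/Mb) and λ_intro inside
  (default 1000/Mb, a 20× contrast — the contrast ratio is a modeling
  choice, since density ratios of real introgressions vary widely).
  The default genome is 3 × 10 Mb with one 6-Mb segment (20% of the
  genome). The InDel fraction defaults to 0.12, in line with
  resequencing call sets. There is no interaction, recombination map or
  mutation-spectrum realism — exactly the independence the window-count
  analysis assumes.
* **The panel** is a star species tree: each of `n_species` species
  carries private alt alleles at `species_divergence` per site (default
  0.05), accessions add 1% heterozygous flips and 2% missingness. The
  focal sample is a cultivated/donor mosaic: inside introgressed segments
  it copies the designated donor species' genotypes. This yields
  species-level clustering — sufficient for origin assignment — but no
  coalescent variance, incomplete lineage sorting or admixture gradients.
* **Gene models** are three-exon genes in evenly spaced slots; the
  reference is patched so every CDS is a clean ORF (ATG, no internal
  stop, terminal stop), which makes all effect terms plantable. Half the
  descriptions come from a keyword pool, half from a neutral pool.
* **Planted effects** are constructed by candidate search and verified by
  re-annotation before being emitted, so the round-trip test is
  meaningful: disagreement between planting and annotation is impossible
  by construction, and the *independent* check is the separate
  full-protein-translation oracle in the acceptance tests.
* **Donor call set**: everything the focal line carries inside segments
  plus donor-private variants at λ_bg/2 elsewhere, giving exact ground
  truth for shared/private classification.
* **Truth bookkeeping** records segments, planted variants/motifs, donor
  keys, and two candidate sets: `planted_candidates` (guaranteed by
  planting alone) and `intended_candidates` (the selection rule applied
  to the full annotated call set, so that random background variants that
  legitimately create candidates are accounted for).

Consequently, passing benchmarks demonstrate correctness of the
*algorithms* under the stated statistical assumptions; they do not
demonstrate robustness to alignment artefacts, reference bias, segmental
duplications or annotation errors in real data.

## Benchmark problem sizes

The test-suite benchmarks use scaled-down genomes chosen to keep the
statistical signal unambiguous: introgression recovery uses 3 × 6 Mb
genomes with a 4-Mb segment (22% of the genome, 20× contrast) over 20
seeds, and the false-positive control 100 seeds at equal rates; origin
assignment uses 20 panels of 13 samples × 250 sites per chromosome with
introgressed chromosomes copied whole from the donor, mirroring a line
whose affected chromosomes cluster with the wild species; the annotator
oracle covers 40 genes × 17 effect terms (680 planted variants). The NJ
exactness suite covers 50 random 6–10 leaf trees.

## Known limitations

* The annotator covers single transcripts per gene; no isoform ranking,
  NMD prediction or HGVS nomenclature.
* Indel normalization (left-alignment) is out of scope; call sets must be
  consistently represented for key-equality sharing to be exact.
* The NJ implementation is O(n³) and intended for panels of tens to a few
  hundred samples.
* The mutated-motif and genotype-discordance definitions are local to
  this package (documented above) and not guaranteed to match any
  specific external tool.
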