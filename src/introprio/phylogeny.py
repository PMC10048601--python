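"""Per-chromosome neighbor-joining trees from multi-sample genotypes.

The distance between two samples is their genotype discordance: the
fraction of sites, non-missing in both, at which their alt-allele dosages
differ.  Trees are built with the canonical Saitou-Nei neighbor-joining
agglomeration, which recovers the generating tree exactly on additive
distance matrices.  The focal sample's putative origin on a chromosome is
the species whose accessions sit closest to it in the tree.

The discordance statistic is this module's own definition of "distance";
it is the simplest pairwise statistic consistent with NJ input from a
merged VCF and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .errors import InputError, InsufficientOverlapError, VcfParseError

MISSING_DOSAGE = -1


@dataclass
class GenotypeMatrix:
    """samples x sites alt-allele dosages in {0,1,2}, -1 for missing."""

    samples: list[str]
    sites: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt)
    calls: np.ndarray  # shape (n_samples, n_sites), int8

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise InputError("calls shape does not match samples x sites")

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        idx = [i for i, s in enumerate(self.sites) if s[0] == chrom]
        return GenotypeMatrix(
            list(self.samples), [self.sites[i] for i in idx], self.calls[:, idx]
        )

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, *_ in self.sites:
            seen.setdefault(c, None)
        return list(seen)


def read_genotype_matrix(
    path: str | Path,
    min_qual: float = 15.0,
    max_missing: float = 0.5,
) -> GenotypeMatrix:
    """Load a merged multi-sample VCF into a dosage matrix.

    Sites with QUAL below ``min_qual`` or with a missing-call fraction
    above ``max_missing`` are dropped (the conventional merged-panel
    filter).  Multi-allelic sites contribute one column per ALT allele.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"{path}: cannot open as VCF ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: no samples in VCF")
    sites = []
    cols = []
    for v in vcf:
        if v.QUAL is not None and v.QUAL < min_qual:
            continue
        # dosage of the first ALT allele; additional ALTs become extra columns
        gts = np.array(v.gt_types)  # 0 hom_ref, 1 het, 2 unknown, 3 hom_alt
        dos = np.where(gts == 0, 0, np.where(gts == 1, 1, np.where(gts == 3, 2, MISSING_DOSAGE)))
        if np.mean(dos == MISSING_DOSAGE) > max_missing:
            continue
        for alt in v.ALT:
            sites.append((v.CHROM, v.POS, v.REF, alt))
            cols.append(dos.astype(np.int8))
    vcf.close()
    calls = (
        np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, calls)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InputError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(self.d < 0):
            raise InputError("distance matrix has negative entries")
        np.fill_diagonal(self.d, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.d[i, j])


def genotype_distance(m: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise genotype discordance over co-observed sites."""
    if len(m.samples) < 2:
        raise InputError("need at least 2 samples")
    calls = m.calls
    n = len(m.samples)
    obs = calls != MISSING_DOSAGE
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        diff = (calls[i][None, :] != calls) & both
        co = both.sum(axis=1)
        for j in range(i + 1, n):
            if co[j] == 0:
                raise InsufficientOverlapError(
                    f"samples {m.samples[i]!r} and {m.samples[j]!r} share no co-observed site"
                )
            d[i, j] = d[j, i] = diff[j].sum() / co[j]
    return DistanceMatrix(list(m.samples), d)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou & Nei agglomeration)

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree.

    Negative branch lengths (possible on non-additive input) are clamped
    to zero with the deficit moved to the sibling branch, so emitted
    Newick always carries nonnegative lengths.  On additive input the
    tree's path-length matrix reproduces the input exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))
    D = d  # working copy, indexed by original positions via `active`

    while len(active) > 2:
        m_ = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m_ - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = divmod(int(np.argmin(q)), m_)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m_ - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = TreeNode()
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent.extend([child_i, child_j])
        # distances from the new node
        new_row = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b = active
    dab = max(D[a, b], 0.0)
    na, nb = nodes[a], nodes[b]
    # attach the remaining pair directly: the last internal node becomes the
    # (arbitrary) trifurcating root of the unrooted tree
    if na.is_tip():
        na, nb = nb, na
    nb.length = float(dab)
    na.append(nb)
    na.length = None
    return na


def tree_distance(tree: TreeNode, a: str, b: str) -> float:
    return float(tree.find(a).distance(tree.find(b)))


def path_length_matrix(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    tip = {lab: tree.find(lab) for lab in labels}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tip[labels[i]].distance(tip[labels[j]])
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


# ---------------------------------------------------------------------------
# Origin assignment

@dataclass(frozen=True)
class OriginCall:
    species: str
    min_path_length: float
    min_clade_size: int


def assign_origin(
    tree: TreeNode, focal: str, species_of: Mapping[str, str]
) -> list[OriginCall]:
    """Rank candidate species of origin for the focal leaf.

    Primary key: minimum path length from the focal leaf to any accession
    of the species.  Secondary key: size of the smallest clade (in the
    arbitrarily rooted representation) containing the focal leaf and at
    least one accession of the species.  Ties break on species name.
    """
    tips = {t.name for t in tree.tips()}
    if focal not in tips:
        raise InputError(f"focal sample {focal!r} is not a leaf of the tree")
    focal_tip = tree.find(focal)
    species_members: dict[str, list[str]] = {}
    for t in tips:
        if t == focal:
            continue
        sp = species_of.get(t)
        if sp is None:
            raise InputError(f"leaf {t!r} has no species assignment")
        species_members.setdefault(sp, []).append(t)

    # walk rootward from the focal tip: first ancestor containing a member
    # of each species gives the smallest enclosing clade
    clade_size: dict[str, int] = {}
    anc = focal_tip
    seen_species: set[str] = set()
    while anc is not None and len(seen_species) < len(species_members):
        leaf_names = {t.name for t in anc.tips()} if not anc.is_tip() else {anc.name}
        for sp, members in species_members.items():
            if sp not in seen_species and any(m in leaf_names for m in members):
                clade_size[sp] = len(leaf_names)
                seen_species.add(sp)
        anc = anc.parent

    calls = []
    for sp, members in species_members.items():
        dmin = min(focal_tip.distance(tree.find(m)) for m in members)
        calls.append(OriginCall(sp, float(dmin), clade_size.get(sp, len(tips))))
    calls.sort(key=lambda c: (c.min_path_length, c.min_clade_size, c.species))
    return calls


def origin_report(
    per_chrom_calls: Mapping[str, Sequence[OriginCall]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\trank\tspecies\tmin_path_length\tmin_clade_size\n")
        for chrom in per_chrom_calls:
            for rank, c in enumerate(per_chrom_calls[chrom], start=1):
                fh.write(f"{chrom}\t{rank}\t{c.species}\t{c.min_path_length:.6g}\t{c.min_clade_size}\n")
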