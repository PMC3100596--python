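"""Distance trees and the species-vs-gametolog clustering verdict.

The discriminating question for homomorphic sex chromosomes: in a gene
tree of X and Y alleles sampled across species, do tips cluster by
species (ongoing X-Y exchange keeps conspecific gametologs coalescing
recently) or by gametolog (X and Y diverged before the species did)?

The in-repo tree estimator is neighbor-joining on Jukes-Cantor distances
with deterministic tie-breaking; externally inferred trees can be fed to
:func:`classify_clustering` through the Newick reader instead.  Fitch
parsimony change counts for the species and gametolog characters are
reported alongside the categorical verdict as continuous scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datamodel import Alignment, LabeledTree, TipLabel


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    labels: list  # tip-name strings, fixed order
    matrix: np.ndarray
    model: str  # "p" | "JC"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        finite = np.isfinite(m)
        if not np.allclose(np.where(finite, m, 0.0),
                           np.where(finite, m, 0.0).T):
            raise ValueError("distance matrix must be symmetric")
        if (m[finite] < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.matrix).any())


_CODE = {b: i for i, b in enumerate("ACGT")}


def pairwise_distance(alignment: Alignment, model: str = "JC") -> DistanceMatrix:
    """p- or Jukes-Cantor distances with pairwise deletion of gaps.

    p = mismatches / compared sites; JC = -(3/4) ln(1 - (4/3) p), flagged
    infinite when p >= 0.75 (beyond the model's resolvable range).  A pair
    with no shared ungapped site is an error.
    """
    if model not in ("p", "JC"):
        raise ValueError("model must be 'p' or 'JC'")
    labels = [str(lab) for lab in alignment.labels]
    enc = np.array(
        [[_CODE.get(c, -1) for c in seq] for _, seq in alignment.records],
        dtype=np.int8,
    )
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (enc[i] >= 0) & (enc[j] >= 0)
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError(
                    f"no compared sites between {labels[i]} and {labels[j]}"
                )
            p = float((enc[i, ok] != enc[j, ok]).sum()) / ncomp
            if model == "p":
                dist = p
            elif p >= 0.75:
                dist = math.inf
            else:
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d, model)


# ---------------------------------------------------------------------------
# Neighbor-joining


def nj_tree(dm: DistanceMatrix) -> LabeledTree:
    """Canonical neighbor-joining (Saitou-Nei Q criterion).

    Ties in Q are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest tip), so the topology is
    invariant to input tip order.  Negative branch lengths are clamped to
    zero and flagged on the returned tree.
    """
    if dm.has_infinite or np.isnan(dm.matrix).any():
        raise ValueError("neighbor-joining requires finite distances")
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor-joining needs at least 3 tips")

    taxa = dendropy.TaxonNamespace()
    nodes, dist = {}, {}
    clamped = False
    for i, lab in enumerate(dm.labels):
        node = dendropy.Node(taxon=taxa.new_taxon(lab))
        nodes[lab] = node
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            if i < j:
                dist[frozenset((a, b))] = float(dm.matrix[i, j])
    active = sorted(nodes)

    def d(a, b):
        return dist[frozenset((a, b))]

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d(a, b) - r[a] - r[b]
                key = (q, a, b)  # lexicographic pair breaks ties
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d(a, b) - la
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = clamp(la)
        nodes[b].edge.length = clamp(lb)
        new_label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_label, c))] = max(
                0.0, 0.5 * (d(a, c) + d(b, c) - d(a, b))
            )
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
        nodes[new_label] = parent

    a, b, c = active
    root = dendropy.Node()
    for x, y, z in ((a, b, c), (b, a, c), (c, a, b)):
        lx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
        root.add_child(nodes[x])
        nodes[x].edge.length = clamp(lx)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    out = LabeledTree(tree)
    out.negative_lengths_clamped = clamped
    return out


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(alignment: Alignment, B: int = 1000, seed: int = 0,
                      model: str = "JC") -> LabeledTree:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement B times; the support of each
    internal edge of the full-data tree is the percentage of replicate
    trees containing the same bipartition.  Replicates whose resampled
    distances are saturated (infinite) are skipped; supports use the
    effective replicate count.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    tree = nj_tree(pairwise_distance(alignment, model))
    counts = {split: 0 for split in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    L = alignment.length
    effective = 0
    for _ in range(B):
        cols = rng.integers(L, size=L)
        boot = Alignment(
            [(lab, "".join(seq[c] for c in cols)) for lab, seq in alignment.records]
        )
        try:
            splits = nj_tree(pairwise_distance(boot, model)).bipartitions()
        except ValueError:
            continue
        effective += 1
        for split in counts:
            if split in splits:
                counts[split] += 1

    all_tips = frozenset(tree.tip_names)
    anchor = min(all_tips)
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_tips - side
        if side in counts and effective > 0:
            node.label = f"{100.0 * counts[side] / effective:g}"
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony


def fitch_changes(tree: LabeledTree, character) -> int:
    """Minimum state changes for a tip character on the tree.

    ``character`` maps a :class:`TipLabel` to a state (e.g. its species or
    gametolog).  Multifurcations are folded child by child; the count is
    invariant to rooting for the binary trees produced here.
    """
    changes = 0

    def fold(states):
        nonlocal changes
        acc = states[0]
        for s in states[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        return acc

    def post(node):
        if node.is_leaf():
            return {character(TipLabel.parse(node.taxon.label))}
        return fold([post(c) for c in node.child_nodes()])

    post(tree.tree.seed_node)
    return changes


# ---------------------------------------------------------------------------
# Clustering classification


@dataclass
class ClusteringResult:
    verdict: str  # species_clustered | gametolog_clustered | mixed
    species_monophyly: dict  # species -> bool (X∪Y tips form a split)
    gametolog_clade: bool  # sister-group Y tips form a clade apart from X
    fitch_species: int
    fitch_gametolog: int
    reference: str
    sister_species: tuple
    tips_per_group: dict = field(default_factory=dict)


def classify_clustering(tree: LabeledTree, sister_species=None,
                        reference: str | None = None) -> ClusteringResult:
    """Classify a gametolog gene tree as species- or gametolog-clustered.

    * ``species_clustered`` — every species' pooled X and Y tips are
      monophyletic (as an unrooted bipartition test): the signature of an
      autosomal marker or of sex chromosomes kept similar by X-Y exchange.
    * ``gametolog_clustered`` — the pooled Y tips of the designated sister
      group form a clade excluding their conspecific X tips: the signature
      of a frozen ancestral Y (or of a reference-species turnover from the
      ancestral X, which spares the reference but not its sister group).
    * ``mixed`` — neither pattern.

    ``reference`` defaults to the lexicographically smallest species name
    and ``sister_species`` to all others.  When both patterns hold the
    species verdict wins (monophyly of every species is the stronger
    statement).
    """
    tips = tree.tip_labels
    for t in tips:
        if t.gametolog not in ("X", "Y"):
            raise ValueError(
                f"tip {t} lacks an X/Y gametolog label; cannot classify"
            )
    by_species: dict = {}
    for t in tips:
        by_species.setdefault(t.species, []).append(t)
    with_both = {
        sp for sp, ts in by_species.items()
        if {x.gametolog for x in ts} >= {"X", "Y"}
    }
    if len(with_both) < 2:
        raise ValueError("need >=2 species sampled for both gametologs")
    species_names = sorted(by_species)
    if reference is None:
        reference = species_names[0]
    if reference not in by_species:
        raise ValueError(f"reference species {reference!r} not in tree")
    if sister_species is None:
        sister_species = tuple(sp for sp in species_names if sp != reference)
    else:
        sister_species = tuple(sister_species)
        missing = set(sister_species) - set(species_names)
        if missing:
            raise ValueError(f"sister species not in tree: {sorted(missing)}")

    mono = {
        sp: tree.is_split([str(t) for t in ts])
        for sp, ts in by_species.items()
    }
    sister_y = [
        str(t) for t in tips if t.species in sister_species and t.gametolog == "Y"
    ]
    gametolog_clade = len(sister_y) >= 1 and tree.is_split(sister_y)

    if all(mono.values()):
        verdict = "species_clustered"
    elif gametolog_clade:
        verdict = "gametolog_clustered"
    else:
        verdict = "mixed"
    return ClusteringResult(
        verdict=verdict,
        species_monophyly=mono,
        gametolog_clade=gametolog_clade,
        fitch_species=fitch_changes(tree, lambda t: t.species),
        fitch_gametolog=fitch_changes(tree, lambda t: t.gametolog),
        reference=reference,
        sister_species=sister_species,
        tips_per_group={
            (sp, g): sum(1 for t in ts if t.gametolog == g)
            for sp, ts in by_species.items()
            for g in ("X", "Y")
        },
    )
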