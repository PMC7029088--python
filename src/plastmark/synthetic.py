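"""Synthetic data: species trees, discordant gene trees, and sequence
evolution, so the whole marker-ranking pipeline can be exercised offline.

The generator is deliberately phenomenological.  Gene-tree discordance is
modelled by random nearest-neighbor interchanges (NNI) applied to the
species tree rather than by a coalescent process, and rate variation by
scalar branch-length multipliers; this is sufficient to exercise nRF
ranking, regression/prediction-interval outlier detection and primer
design, but it does not emulate incomplete lineage sorting, indels or
among-site rate heterogeneity beyond codon-position multipliers.

Everything is deterministic under a fixed seed; ``simulate_marker_panel``
returns a manifest that fully describes regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import dendropy
import numpy as np

from .alignment import Alignment

__all__ = [
    "GeneSpec",
    "PanelSpec",
    "PanelResult",
    "simulate_yule_tree",
    "rescale_tree",
    "perturb_topology_nni",
    "evolve_sequences",
    "simulate_marker_panel",
    "default_panel_spec",
]

_BASES = np.array(list("ACGT"))
# base encoding 0=A 1=C 2=G 3=T; transitions are A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# tree simulation


def simulate_yule_tree(n_taxa: int, birth_rate: float = 1.0,
                       seed=None) -> dendropy.Tree:
    """Pure-birth (Yule) tree with leaves labelled t1..tn.

    Starting from the root split (two lineages), each lineage splits at rate
    ``birth_rate``; the process stops one waiting time after the n-th
    lineage appears, so the expected root-to-tip depth at rate 1 is
    sum_{k=2..n} 1/k.  The tree is ultrametric and binary.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    k = 2
    while True:
        dt = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += dt
        if k == n_taxa:
            break
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
        k += 1
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    order = rng.permutation(n_taxa)
    for node, li in zip(active, order):
        node.taxon = ns.require_taxon(label=labels[li])
    tree.is_rooted = True
    return tree


def rescale_tree(tree: dendropy.Tree, mean_depth: float) -> dendropy.Tree:
    """Clone *tree* with branch lengths scaled so the mean root-to-tip path
    equals ``mean_depth`` (in expected substitutions per site)."""
    out = tree.clone(depth=1)
    depths = []
    for leaf in out.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    cur = float(np.mean(depths))
    if cur <= 0:
        raise ValueError("tree has zero depth")
    f = mean_depth / cur
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
    return out


def _scale_branches(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


def perturb_topology_nni(tree: dendropy.Tree, n_moves: int,
                         seed=None, distinct: bool = False) -> dendropy.Tree:
    """Apply ``n_moves`` random nearest-neighbor interchanges.

    Each move swaps a random child of a random internal (non-root) node with
    that node's sibling, changing exactly one bipartition.  ``n_moves=0``
    returns a topological copy.  With ``distinct=True`` the whole sequence
    of moves is resampled until the result differs from the input by exactly
    one bipartition per move (RF distance ``2*n_moves``), so successive
    interchanges never cancel or overlap.
    """
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    rng = _rng(seed)

    def _one_round() -> dendropy.Tree:
        out = tree.clone(depth=1)
        root = out.seed_node
        for _ in range(n_moves):
            internal = [
                nd for nd in out.preorder_node_iter()
                if nd.parent_node is not None and not nd.is_leaf()
            ]
            if not internal:
                raise ValueError("tree has no internal edges to rearrange")
            for _attempt in range(100):
                v = internal[int(rng.integers(len(internal)))]
                parent = v.parent_node
                siblings = [c for c in parent.child_nodes() if c is not v]
                s = siblings[int(rng.integers(len(siblings)))]
                if parent is root and len(root.child_nodes()) == 2:
                    # both root edges are one unrooted edge: swapping v's
                    # child with its sibling only re-roots the tree, so the
                    # exchange partner must be a child of the sibling
                    if s.is_leaf():
                        continue  # pendant edge in unrooted terms
                    s_parent = s
                    s = s.child_nodes()[
                        int(rng.integers(len(s.child_nodes())))]
                else:
                    s_parent = parent
                break
            else:
                raise ValueError("no eligible internal edge for NNI")
            children = v.child_nodes()
            c = children[int(rng.integers(len(children)))]
            v.remove_child(c)
            s_parent.remove_child(s)
            v.add_child(s)
            s_parent.add_child(c)
        return out

    if not distinct or n_moves == 0:
        return _one_round()
    from .treekit import rf_distance, unroot  # deferred: avoids import cycle

    base = unroot(tree)
    for _ in range(200):
        out = _one_round()
        if rf_distance(base, unroot(out)) == 2 * n_moves:
            return out
    raise RuntimeError(
        f"could not realize {n_moves} non-overlapping NNI moves"
    )


# ---------------------------------------------------------------------------
# sequence evolution


def _k80_probs(d: np.ndarray, kappa: float):
    """Per-site (p_same, p_transition, p_transversion_each) under K80 with
    distance d in expected substitutions/site; kappa = ts/tv rate ratio."""
    e1 = np.exp(-4.0 * d / (kappa + 2.0))
    e2 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def evolve_sequences(tree: dendropy.Tree, n_sites: int,
                     model: str = "JC69", kappa: float = 2.0,
                     rate_scalar: float = 1.0, seed=None,
                     site_rates: Optional[np.ndarray] = None) -> Alignment:
    """Evolve a gap-free NT alignment down *tree*.

    The root sequence is uniform over A/C/G/T; each site evolves
    independently along each branch under JC69 or K80(kappa), with branch
    lengths interpreted as expected substitutions per site after
    multiplication by ``rate_scalar`` and the per-site ``site_rates``.
    """
    if model not in ("JC69", "K80"):
        raise ValueError(f"unknown model {model!r}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = _rng(seed)
    if site_rates is None:
        site_rates = np.ones(n_sites)
    site_rates = np.asarray(site_rates, dtype=float)
    if site_rates.shape != (n_sites,):
        raise ValueError("site_rates must have length n_sites")

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=n_sites)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise ValueError("every branch must have a length")
        d = node.edge.length * rate_scalar * site_rates
        parent_seq = seqs[id(node.parent_node)]
        seq = parent_seq.copy()
        if model == "JC69":
            p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            hit = rng.random(n_sites) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                shift = rng.integers(1, 4, size=n_hit)
                seq[hit] = (seq[hit] + shift) % 4
        else:
            p_same, p_ts, p_tv = _k80_probs(d, kappa)
            u = rng.random(n_sites)
            ts = (u >= p_same) & (u < p_same + p_ts)
            tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
            tv2 = u >= p_same + p_ts + p_tv
            seq[ts] = _TRANSITION[parent_seq[ts]]
            seq[tv1] = _TRANSVERSIONS[parent_seq[tv1], 0]
            seq[tv2] = _TRANSVERSIONS[parent_seq[tv2], 1]
        seqs[id(node)] = seq

    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    taxa = [lf.taxon.label for lf in leaves]
    rows = ["".join(_BASES[seqs[id(lf)]]) for lf in leaves]
    return Alignment(taxa, rows, "nt")


# ---------------------------------------------------------------------------
# marker panels


@dataclass
class GeneSpec:
    name: str
    n_codons: int = 300
    rate_scalar: float = 1.0
    n_nni: int = 0          # topological discordance vs the species tree
    omega: float = 1.0      # 1st/2nd codon-position rate relative to 3rd


@dataclass
class PanelSpec:
    n_taxa: int
    genes: list[GeneSpec]
    seed: int = 0
    depth: float = 0.3      # mean root-to-tip depth, substitutions/site
    model: str = "JC69"
    kappa: float = 2.0
    min_internal: float = 0.015  # floor on species-tree internal edges,
    # substitutions/site; keeps every target split resolvable in principle
    shallow_sizes: tuple = (0.015, 0.02, 0.025, 0.03)  # the shortest
    # internal edges are pinned to this graded spectrum of lengths:
    # controlled "shallow splits" that genes resolve progressively more
    # reliably as their divergence grows

    def __post_init__(self) -> None:
        if self.n_taxa < 5:
            raise ValueError("n_taxa must be >= 5")
        for g in self.genes:
            if g.n_codons < 10:
                raise ValueError(f"gene {g.name}: n_codons must be >= 10")
            if g.n_nni < 0:
                raise ValueError(f"gene {g.name}: n_nni must be >= 0")


@dataclass
class PanelResult:
    species_tree: dendropy.Tree
    alignments: dict[str, Alignment]
    gene_trees: dict[str, dendropy.Tree]  # true (generating) trees
    manifest: dict


def simulate_marker_panel(spec: PanelSpec) -> PanelResult:
    """Simulate a marker panel: one Yule species tree, plus per gene a true
    tree (species tree after ``n_nni`` NNI moves, branch lengths scaled by
    ``rate_scalar``) and a codon-structured alignment evolved on it."""
    if not spec.genes:
        raise ValueError("spec.genes must be non-empty")
    names = [g.name for g in spec.genes]
    if len(set(names)) != len(names):
        raise ValueError("gene names must be unique")
    species = simulate_yule_tree(spec.n_taxa, 1.0,
                                 np.random.default_rng([spec.seed, 0]))
    species = rescale_tree(species, spec.depth)
    if spec.min_internal > 0:
        internal = [
            nd for nd in species.preorder_node_iter()
            if nd.parent_node is not None and not nd.is_leaf()
        ]
        for nd in internal:
            if nd.edge.length < spec.min_internal:
                nd.edge.length = spec.min_internal
        # pin the shortest internal edges to a graded spectrum of short
        # lengths: controlled shallow splits, the hardest part of the
        # target topology
        internal.sort(key=lambda nd: nd.edge.length)
        for nd, size in zip(internal, sorted(spec.shallow_sizes)):
            nd.edge.length = size
    alignments: dict[str, Alignment] = {}
    gene_trees: dict[str, dendropy.Tree] = {}
    for i, g in enumerate(spec.genes):
        true_tree = perturb_topology_nni(
            species, g.n_nni, np.random.default_rng([spec.seed, i + 1, 1]),
            distinct=True)
        true_tree = _scale_branches(true_tree, g.rate_scalar)
        n_sites = 3 * g.n_codons
        site_rates = np.tile([g.omega, g.omega, 1.0], g.n_codons)
        aln = evolve_sequences(
            true_tree, n_sites, model=spec.model, kappa=spec.kappa,
            seed=np.random.default_rng([spec.seed, i + 1, 2]),
            site_rates=site_rates)
        alignments[g.name] = aln
        gene_trees[g.name] = true_tree
    manifest = {
        "seed": spec.seed,
        "n_taxa": spec.n_taxa,
        "depth": spec.depth,
        "model": spec.model,
        "kappa": spec.kappa,
        "genes": [asdict(g) for g in spec.genes],
    }
    return PanelResult(species, alignments, gene_trees, manifest)


def default_panel_spec(seed: int = 0, n_taxa: int = 15, n_genes: int = 30,
                       n_concordant: int = 3, n_nni: int = 3,
                       n_codons: int = 1000,
                       rate_range: tuple[float, float] = (0.035, 1.2),
                       depth: float = 0.4) -> PanelSpec:
    """Study-condition panel: ``n_genes`` genes across a divergence gradient
    (rate scalars log-spaced over ``rate_range``), of which ``n_concordant``
    evolve on the true species topology and the rest on ``n_nni``-move
    perturbations of it.  Concordant genes are spread across the gradient."""
    rates = np.geomspace(rate_range[0], rate_range[1], n_genes)
    conc_idx = set(
        int(round(q * (n_genes - 1)))
        for q in np.linspace(0.3, 0.9, n_concordant)
    )
    genes = [
        GeneSpec(
            name=f"g{i + 1:02d}",
            n_codons=n_codons,
            rate_scalar=float(rates[i]),
            n_nni=0 if i in conc_idx else n_nni,
        )
        for i in range(n_genes)
    ]
    return PanelSpec(n_taxa=n_taxa, genes=genes, seed=seed, depth=depth)
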