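"""Synthetic data with the statistical structure the ERC analysis assumes.

The generator plants known covariation so every pipeline stage can be
exercised and calibrated without external data.  The model, per gene g and
branch k of a species tree with base lengths t_k:

    b_gk = s_g * t_k * exp(sigma * e_gk - sigma^2 / 2)

where s_g ~ lognormal is the gene-wide rate, sigma is the branch-level
log-rate noise and e_gk is standard normal.  Genes in a planted group with
covariation strength lambda share a per-branch factor f_k:

    e_gk = sqrt(lambda) * f_k + sqrt(1 - lambda) * z_gk,

so lambda is the variance-partition coefficient: the expected log-rate
correlation between two same-group genes is exactly lambda, which makes
parameter recovery checkable analytically.  The -sigma^2/2 offset keeps
the multiplicative noise mean-one, so the expected branch length is
s_g * t_k regardless of sigma and the expected tree stays well defined.

Sequences evolve along the tree under a 20-state equal-rates model: on a
branch of length l (expected substitutions/site) each site changes to a
uniformly chosen different residue with probability
p(l) = (19/20) * (1 - exp(-(20/19) * l)), the exact transition probability
of that Markov chain, so branch composition is consistent.

Missing species are emulated by masking each species independently per
gene; genes falling below the minimum-species floor (default 5, matching
the analysis threshold) are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .branch_rates import BranchRateVector
from .io import AA20, OrthologAlignment
from .tree import Phylogeny, PruneCache

__all__ = [
    "DEFAULT_SPECIES",
    "SimulationSpec",
    "default_tree",
    "random_topology",
    "simulate_branch_rates",
    "apply_missingness",
    "simulate_alignment",
    "simulate_dataset",
]

# Twelve Drosophila-like taxa; the default topology and branch lengths are
# drawn once with a fixed seed so the shipped tree is a constant fixture
# with depth heterogeneity resembling a real clade.
DEFAULT_SPECIES = (
    "dana", "dere", "dgri", "dmel", "dmoj", "dper",
    "dpse", "dsec", "dsim", "dvir", "dwil", "dyak",
)
_DEFAULT_TREE_SEED = 721
_MEAN_BRANCH_LENGTH = 0.1


def random_topology(
    n_leaves: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mean_length: float = _MEAN_BRANCH_LENGTH,
    names: Optional[Sequence[str]] = None,
) -> Phylogeny:
    """Random unrooted binary topology by sequential leaf attachment,
    branch lengths i.i.d. Exponential(mean_length)."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    if rng is None:
        rng = np.random.default_rng(seed)
    if names is None:
        width = len(str(n_leaves))
        names = [f"s{i + 1:0{width}d}" for i in range(n_leaves)]
    elif len(names) != n_leaves:
        raise ValueError("names length does not match n_leaves")

    next_node = n_leaves  # 0..n_leaves-1 are leaves
    center = next_node
    next_node += 1
    edges: List[List] = [[center, 0, None], [center, 1, None], [center, 2, None]]
    for leaf in range(3, n_leaves):
        eidx = int(rng.integers(len(edges)))
        u, v, _l = edges[eidx]
        mid = next_node
        next_node += 1
        edges[eidx] = [u, mid, None]
        edges.append([mid, v, None])
        edges.append([mid, leaf, None])
    lengths = rng.exponential(mean_length, size=len(edges))
    labelled = [(u, v, float(l)) for (u, v, _), l in zip(edges, lengths)]
    return Phylogeny(labelled, {i: names[i] for i in range(n_leaves)})


_default_tree_cache: Optional[Phylogeny] = None


def default_tree() -> Phylogeny:
    """The fixed 12-taxon species tree used as the default simulation
    condition (seeded once; identical across sessions)."""
    global _default_tree_cache
    if _default_tree_cache is None:
        _default_tree_cache = random_topology(
            12, seed=_DEFAULT_TREE_SEED, names=DEFAULT_SPECIES
        )
    return _default_tree_cache


@dataclass
class SimulationSpec:
    """Conditions for one simulated ortholog universe.

    Defaults mirror the study conditions the analysis is calibrated under:
    a 12-taxon tree, several hundred genes, gene-wide lognormal rate
    variation (sigma_s = 0.5), branch-level log-rate noise sigma = 0.5,
    full species coverage unless ``missing_prob`` is raised, and the
    5-species analysis floor.
    """

    n_genes: int = 500
    tree: Optional[Phylogeny] = None
    gene_rate_mu: float = 0.0
    gene_rate_sigma: float = 0.5
    branch_noise_sd: float = 0.5
    groups: Tuple[Tuple[int, float], ...] = ()
    missing_prob: float = 0.0
    min_species: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.tree is None:
            self.tree = default_tree()
        if not self.tree.has_lengths:
            raise ValueError("simulation tree needs branch lengths")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.branch_noise_sd < 0:
            raise ValueError("branch_noise_sd must be >= 0")
        if self.gene_rate_sigma < 0:
            raise ValueError("gene_rate_sigma must be >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        self.groups = tuple((int(n), float(lam)) for n, lam in self.groups)
        for n, lam in self.groups:
            if n < 1:
                raise ValueError("group size must be positive")
            if not 0.0 <= lam <= 1.0:
                raise ValueError("covariation strength must be in [0, 1]")
        if sum(n for n, _ in self.groups) > self.n_genes:
            raise ValueError("groups larger than n_genes")


def simulate_branch_rates(spec: SimulationSpec):
    """Draw per-gene branch-rate vectors under the spec's model.

    Group members occupy the leading gene indices, in group order.
    Returns ``(vectors, membership)`` with ``membership`` mapping gene id
    to its group index (ungrouped genes map to ``None``).  Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    t = tree.lengths_array()
    B = len(t)
    n = spec.n_genes
    s = rng.lognormal(spec.gene_rate_mu, spec.gene_rate_sigma, size=n)
    Z = rng.standard_normal((n, B))
    E = Z.copy()
    membership: Dict[str, Optional[int]] = {}
    width = max(4, len(str(n)))
    ids = [f"g{i:0{width}d}" for i in range(n)]
    gi = 0
    for k, (size, lam) in enumerate(spec.groups):
        f = rng.standard_normal(B)
        E[gi : gi + size] = np.sqrt(lam) * f + np.sqrt(1.0 - lam) * Z[gi : gi + size]
        for g in ids[gi : gi + size]:
            membership[g] = k
        gi += size
    for g in ids[gi:]:
        membership[g] = None
    sig = spec.branch_noise_sd
    Bmat = s[:, None] * t[None, :] * np.exp(sig * E - sig * sig / 2.0)
    vectors = [
        BranchRateVector(
            gene_id=ids[i],
            species_set=tree.leaf_names,
            branch_ids=tree.branch_ids,
            lengths=Bmat[i],
        )
        for i in range(n)
    ]
    return vectors, membership


def apply_missingness(
    vectors: Sequence[BranchRateVector],
    missing_prob: float,
    tree: Phylogeny,
    min_species: int = 5,
    seed: int = 0,
    cache: Optional[PruneCache] = None,
):
    """Mask species independently per gene with the given probability.

    Surviving genes are restricted (pruned, lengths summed) to their
    retained species; genes below ``min_species`` are dropped.  Returns
    ``(kept_vectors, dropped_gene_ids)``; deterministic under seed.
    """
    from .projection import restrict_vector

    if not 0.0 <= missing_prob <= 1.0:
        raise ValueError("missing_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cache = cache or PruneCache(tree)
    kept: List[BranchRateVector] = []
    dropped: List[str] = []
    for vec in vectors:
        species = sorted(vec.species_set)
        mask = rng.random(len(species)) < missing_prob
        remaining = frozenset(sp for sp, m in zip(species, mask) if not m)
        if len(remaining) < min_species:
            dropped.append(vec.gene_id)
            continue
        if remaining == vec.species_set:
            kept.append(vec)
        else:
            kept.append(restrict_vector(vec, cache, remaining))
    return kept, dropped


def substitution_probability(length: float) -> float:
    """P(site differs) across a branch under the 20-state equal-rates
    model: (19/20) * (1 - exp(-(20/19) * length))."""
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * length))


def simulate_alignment(
    tree: Phylogeny,
    rates: BranchRateVector,
    n_sites: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> OrthologAlignment:
    """Evolve an ungapped amino-acid alignment along the gene's tree.

    The root sequence is uniform over the 20 residues; each branch applies
    the exact equal-rates transition kernel for its length in the gene's
    branch-rate vector.  Deterministic under seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    sub = (
        tree
        if tree.leaf_names == rates.species_set
        else tree.prune(rates.species_set)[0]
    )
    if set(sub.branch_ids) != set(rates.branch_ids):
        raise ValueError(
            f"{rates.gene_id}: branch ids do not match the pruned topology"
        )
    lengths = dict(zip(rates.branch_ids, rates.lengths))
    root, walk = sub.traversal()
    seqs = {root: rng.integers(0, 20, size=n_sites)}
    alphabet = np.array(list(AA20))
    rows: Dict[str, str] = {}
    lab = sub.leaf_label(root)
    if lab is not None:
        rows[lab] = "".join(alphabet[seqs[root]])
    for parent, child, bid in walk:
        p = substitution_probability(lengths[bid])
        seq = seqs[parent].copy()
        hit = rng.random(n_sites) < p
        k = int(hit.sum())
        if k:
            seq[hit] = (seq[hit] + rng.integers(1, 20, size=k)) % 20
        seqs[child] = seq
        lab = sub.leaf_label(child)
        if lab is not None:
            rows[lab] = "".join(alphabet[seq])
    return OrthologAlignment(rates.gene_id, rows)


def simulate_dataset(spec: SimulationSpec):
    """Rates plus missingness in one call.

    Returns ``(vectors, membership, dropped)``.  The missingness mask uses
    a seed derived from ``spec.seed`` so the whole dataset is reproducible
    from the spec alone.
    """
    vectors, membership = simulate_branch_rates(spec)
    if spec.missing_prob > 0:
        vectors, dropped = apply_missingness(
            vectors,
            spec.missing_prob,
            spec.tree,
            min_species=spec.min_species,
            seed=(spec.seed + 1) % (2**31),
        )
    else:
        dropped = []
    return vectors, membership, dropped
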