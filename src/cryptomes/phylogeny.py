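"""Crypt phylogenies from somatic genotypes.

Crypts of one patient are related through crypt fission; variants shared
by a subset of crypts mark the clade descending from the fission event on
which they arose.  The builder is a greedy perfect-phylogeny
construction: variants are clustered by their crypt-sharing pattern,
patterns are ranked by support, and compatible patterns are attached as
nested clades (conflicting, lower-support patterns are dropped).
Mutations are then assigned to branches by maximum likelihood under a
binomial read model, and branch SBS1 burdens divided by the patient's
SBS1 rate convert the tree to time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import VariantCounts

DEFAULT_GENOTYPE_VAF = 0.25
DEFAULT_GENOTYPE_MIN_ALT = 3
DEFAULT_ERROR_RATE = 1e-3


@dataclass
class PhyloNode:
    node_id: int
    clade: frozenset
    parent: int | None
    children: list[int] = field(default_factory=list)
    mutations: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.mutations)


@dataclass
class CryptPhylogeny:
    """Rooted clade tree over one patient's crypts.

    Each node carries the branch above it; the root branch holds
    mutations shared by every crypt.  ``unassigned`` collects variants
    that could not be placed (zero depth everywhere).
    """

    nodes: dict[int, PhyloNode]
    root: int
    leaves: dict[str, int]  # crypt -> leaf node id
    unassigned: list[str] = field(default_factory=list)

    def branches(self) -> list[PhyloNode]:
        """Nodes in rootward-first (pre)order."""
        order, stack = [], [self.root]
        while stack:
            nid = stack.pop()
            order.append(self.nodes[nid])
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def depth(self, node_id: int) -> int:
        d, nid = 0, node_id
        while self.nodes[nid].parent is not None:
            nid = self.nodes[nid].parent
            d += 1
        return d

    def clades(self) -> set[frozenset]:
        return {n.clade for n in self.nodes.values()}

    def to_newick(self, lengths: dict[int, float] | None = None) -> str:
        def rec(nid: int) -> str:
            node = self.nodes[nid]
            ln = lengths[nid] if lengths is not None else node.length
            if len(node.clade) == 1:
                return f"{next(iter(node.clade))}:{ln:g}"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}):{ln:g}"

        return rec(self.root) + ";"


def genotypes_from_counts(
    counts: VariantCounts,
    vaf_threshold: float = DEFAULT_GENOTYPE_VAF,
    min_alt: int = DEFAULT_GENOTYPE_MIN_ALT,
) -> pd.DataFrame:
    """Binary genotype matrix: carrier iff VAF >= threshold and alt >= min_alt."""
    vaf = counts.vaf().fillna(0.0)
    return (vaf >= vaf_threshold) & (counts.alt >= min_alt)


def build_tree(genotypes: pd.DataFrame) -> CryptPhylogeny:
    """Greedy perfect-phylogeny topology from a variant x crypt matrix.

    Sharing patterns are ordered by support (number of variants showing
    the pattern); each is accepted if laminar with everything accepted so
    far, so conflicts resolve in favour of the better-supported pattern.
    With no informative variants the result is a star tree.
    """
    crypts = list(genotypes.columns)
    all_set = frozenset(crypts)
    support: dict[frozenset, int] = {}
    for _, row in genotypes.iterrows():
        pattern = frozenset(np.array(crypts)[row.values])
        if 0 < len(pattern):
            support[pattern] = support.get(pattern, 0) + 1

    ranked = sorted(
        support.items(),
        key=lambda kv: (-kv[1], -len(kv[0]), tuple(sorted(kv[0]))),
    )
    accepted: list[frozenset] = [all_set] + [frozenset([c]) for c in crypts]
    for pattern, _ in ranked:
        if pattern in accepted:
            continue
        if all(
            pattern <= a or a <= pattern or not (pattern & a) for a in accepted
        ):
            accepted.append(pattern)

    # laminar family -> tree; parent = smallest strict superset
    accepted_sorted = sorted(set(accepted), key=lambda s: (-len(s), tuple(sorted(s))))
    nodes: dict[int, PhyloNode] = {}
    ids = {clade: i for i, clade in enumerate(accepted_sorted)}
    for clade, nid in ids.items():
        supersets = [c for c in accepted_sorted if clade < c]
        parent = ids[min(supersets, key=len)] if supersets else None
        nodes[nid] = PhyloNode(nid, clade, parent)
    for nid, node in nodes.items():
        if node.parent is not None:
            nodes[node.parent].children.append(nid)
    for node in nodes.values():
        node.children.sort(key=lambda c: tuple(sorted(nodes[c].clade)))
    leaves = {next(iter(n.clade)): n.node_id for n in nodes.values() if len(n.clade) == 1}
    return CryptPhylogeny(nodes, ids[all_set], leaves)


def assign_mutations(
    tree: CryptPhylogeny,
    counts: VariantCounts,
    error_rate: float = DEFAULT_ERROR_RATE,
    clone_vaf: pd.Series | float = 0.5,
) -> pd.Series:
    """Maximum-likelihood branch assignment for every variant.

    For branch b the expected VAF is the crypt's clone VAF inside b's
    clade and ``error_rate`` outside; the variant goes to the branch with
    the highest binomial likelihood, ties resolved toward the root.
    Variants with zero depth in every crypt land in the unassigned bin
    (branch id -1).  Updates the tree's per-branch mutation sets in place
    and returns a variant_id -> branch_id Series.
    """
    samples = counts.samples
    if isinstance(clone_vaf, pd.Series):
        cv = clone_vaf.reindex(samples).fillna(0.5).values
    else:
        cv = np.full(len(samples), float(clone_vaf))
    branch_nodes = sorted(
        tree.nodes.values(), key=lambda n: (tree.depth(n.node_id), n.node_id)
    )
    P = np.empty((len(branch_nodes), len(samples)))
    for bi, node in enumerate(branch_nodes):
        inside = np.array([s in node.clade for s in samples])
        P[bi] = np.where(inside, cv, error_rate)
    logP, log1mP = np.log(P), np.log1p(-P)

    alt = counts.alt.values.astype(float)
    depth = counts.depth.values.astype(float)
    loglik = alt @ logP.T + (depth - alt) @ log1mP.T  # variants x branches
    best = np.argmax(loglik, axis=1)  # first max = most rootward (sorted order)
    no_data = depth.sum(axis=1) == 0

    for node in tree.nodes.values():
        node.mutations = []
    tree.unassigned = []
    out = {}
    for vi, vid in enumerate(counts.alt.index):
        if no_data[vi]:
            out[vid] = -1
            tree.unassigned.append(vid)
        else:
            node = branch_nodes[best[vi]]
            out[vid] = node.node_id
            node.mutations.append(vid)
    return pd.Series(out, name="branch_id")


@dataclass
class BranchTiming:
    branch_id: int
    cumulative_sbs1: float
    age_estimate: float
    lower: float
    upper: float


def time_branches(
    tree: CryptPhylogeny,
    sbs1_per_branch: dict[int, float],
    sbs1_rate: float,
) -> pd.DataFrame:
    """Convert branch SBS1 burdens to node ages via the patient's SBS1
    molecular clock.

    A node's age is the cumulative root-to-node SBS1 burden divided by the
    per-year rate; the event interval of the branch above the node runs
    from the parent's age (lower) to the node's own age (upper), with the
    root bounded below by 0.
    """
    if sbs1_rate <= 0:
        raise ValueError("SBS1 rate must be positive")
    ages: dict[int, float] = {}
    rows = []
    for node in tree.branches():  # preorder: parents first
        parent_age = ages[node.parent] if node.parent is not None else 0.0
        cum = parent_age * sbs1_rate + sbs1_per_branch.get(node.node_id, 0.0)
        age = cum / sbs1_rate
        ages[node.node_id] = age
        rows.append(BranchTiming(node.node_id, cum, age, parent_age, age))
    return pd.DataFrame([r.__dict__ for r in rows])
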