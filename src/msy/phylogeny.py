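"""Parsimony tree / median-joining network from informative variants.

For binary haploid characters that are pairwise compatible (every two
derived-carrier sets nested or disjoint — guaranteed by the classification
stage), the median-joining network at epsilon = 0 degenerates to the unique
perfect phylogeny, which is simply the Hasse diagram of the carrier-set
inclusion lattice.  Nodes are haplotypes (samples sharing the same derived
set collapse onto one node), edges carry the SNPs separating two
haplotypes, and the root is the all-ancestral haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import MSYError

logger = logging.getLogger(__name__)


@dataclass
class NetNode:
    node_id: str
    carriers: frozenset[str]          # samples derived for this node's clade
    samples: set[str] = field(default_factory=set)  # samples placed here
    parent: "NetNode | None" = None
    children: list["NetNode"] = field(default_factory=list)
    edge_snps: list[int] = field(default_factory=list)  # SNPs on edge to parent

    def subtree_samples(self) -> set[str]:
        out = set(self.samples)
        for c in self.children:
            out |= c.subtree_samples()
        return out

    def is_leaf_like(self) -> bool:
        return not self.children


@dataclass
class PhyloNetwork:
    root: NetNode
    nodes: list[NetNode]
    rooted: bool = False

    @property
    def n_variants(self) -> int:
        return sum(len(n.edge_snps) for n in self.nodes)

    def edges(self) -> list[NetNode]:
        """Non-root nodes; each represents the edge from its parent."""
        return [n for n in self.nodes if n.parent is not None]

    def preorder(self) -> list[NetNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def to_newick(self) -> str:
        def rec(node: NetNode) -> str:
            label = node.node_id
            if node.is_leaf_like():
                body = label
            else:
                inner = ",".join(rec(c) for c in node.children)
                body = f"({inner}){label}"
            if node.parent is None:
                return body
            return f"{body}:{len(node.edge_snps)}"

        return rec(self.root) + ";"


def build_network(
    classified: pd.DataFrame,
    sample_ids: list[str],
    statuses: tuple[str, ...] = ("informative",),
) -> PhyloNetwork:
    """Build the perfect phylogeny of the informative variants.

    ``classified`` is the classification table (needs columns ``status``,
    ``pos`` and ``carriers``); rows whose status is in ``statuses`` are
    placed (informative only by default; singletons, whose size-1 carrier
    sets are compatible with anything, may be added to hang each sample's
    private variants off its haplotype, as drawn in median-joining network
    figures).  Distinct carrier sets become nodes ordered by inclusion;
    each variant sits on the edge above the node of its carrier set.
    Raises if two placed carrier sets are incompatible (upstream contract
    violation), naming the two positions.
    """
    inf = classified[classified["status"].isin(statuses)]
    groups: dict[frozenset, list[int]] = {}
    for pos, carriers in zip(inf["pos"], inf["carriers"]):
        groups.setdefault(carriers, []).append(int(pos))

    # pairwise compatibility (nested or disjoint); sorted by size so any
    # violation is found between a set and a non-superset overlap
    sets_sorted = sorted(groups, key=lambda s: (-len(s), min(groups[s])))
    for i, a in enumerate(sets_sorted):
        for b in sets_sorted[i + 1:]:
            if (a & b) and not (b <= a):
                raise MSYError(
                    f"incompatible informative variants at positions "
                    f"{groups[a][0]} and {groups[b][0]}"
                )

    all_samples = frozenset(sample_ids)
    root = NetNode(node_id="N0", carriers=all_samples)
    nodes = [root]
    # largest first: the parent of each set is the smallest proper superset
    # already placed (the laminar family forms a forest under inclusion)
    placed: list[NetNode] = [root]
    for k, s in enumerate(sets_sorted, start=1):
        parent = root
        for cand in placed:
            if s < cand.carriers and len(cand.carriers) < len(parent.carriers):
                parent = cand
        node = NetNode(node_id=f"N{k}", carriers=s, parent=parent,
                       edge_snps=sorted(groups[s]))
        parent.children.append(node)
        placed.append(node)
        nodes.append(node)

    # each sample is placed at the node of the smallest carrier set holding it
    for sample in sample_ids:
        best = root
        for node in nodes[1:]:
            if sample in node.carriers and len(node.carriers) < len(best.carriers):
                best = node
        best.samples.add(sample)
    return PhyloNetwork(root=root, nodes=nodes)


def root_network(network: PhyloNetwork, classified: pd.DataFrame) -> PhyloNetwork:
    """Anchor the network at the all-ancestral haplotype.

    The construction already orients edges ancestral -> derived given the
    per-variant polarities; if no placed variant has resolved polarity the
    network is returned unrooted with a warning (the outgroup then carries
    no signal about the MRCA).
    """
    inf = classified[classified["status"] == "informative"]
    if len(inf) and (inf["polarity"] == "unresolved").all():
        logger.warning("no polarized variants: network left unrooted")
        network.rooted = False
    else:
        network.rooted = True
    return network


@dataclass
class SkeletonStats:
    """SNP counts on the deep internal structure of the rooted tree."""

    skeleton_snp_count: int
    total_informative: int
    per_haplogroup_root_path: dict[str, int]

    @property
    def skeleton_fraction(self) -> float:
        if self.total_informative == 0:
            return 0.0
        return self.skeleton_snp_count / self.total_informative


def skeleton_stats(
    network: PhyloNetwork,
    haplogroup_clades: dict[str, frozenset] | None = None,
    min_descendants: int = 2,
) -> SkeletonStats:
    """Count SNPs on the tree's skeleton.

    The skeleton comprises the edges whose descendant haplotypes hold at
    least ``min_descendants`` samples — the deep branches separating the
    main clades, as opposed to terminal twigs.  When ``haplogroup_clades``
    is given (haplogroup name -> sample set), the SNP count on the path
    from the root to each clade's subtending node is also reported.
    """
    # descendant sample counts per node
    desc: dict[str, int] = {}
    for node in reversed(network.preorder()):
        desc[node.node_id] = len(node.samples) + sum(
            desc[c.node_id] for c in node.children
        )
    skeleton = sum(
        len(n.edge_snps) for n in network.edges() if desc[n.node_id] >= min_descendants
    )
    per_hg: dict[str, int] = {}
    if haplogroup_clades:
        for name, clade in haplogroup_clades.items():
            if not clade:
                continue
            # deepest node whose carrier set contains the clade
            best = network.root
            for node in network.nodes:
                if clade <= node.carriers and len(node.carriers) < len(best.carriers):
                    best = node
            count, cur = 0, best
            while cur.parent is not None:
                count += len(cur.edge_snps)
                cur = cur.parent
            per_hg[name] = count
    return SkeletonStats(
        skeleton_snp_count=skeleton,
        total_informative=network.n_variants,
        per_haplogroup_root_path=per_hg,
    )


def branch_class_decomposition(
    network: PhyloNetwork, classified: pd.DataFrame
) -> pd.DataFrame:
    """Per-edge SNP counts split by sequence class.

    Returns a DataFrame indexed by the child node id of each edge with one
    column per region class; row sums equal the edge SNP-list lengths, so
    summing any column over all edges recovers that class's informative
    total exactly.
    """
    class_of = {
        int(p): c for p, c in zip(classified["pos"], classified["region_class"])
    }
    records = {}
    for node in network.edges():
        counts: dict[str, int] = {}
        for pos in node.edge_snps:
            c = class_of.get(pos, "unassigned")
            counts[c] = counts.get(c, 0) + 1
        records[node.node_id] = counts
    out = pd.DataFrame.from_dict(records, orient="index").fillna(0).astype(int)
    out.index.name = "node_id"
    return out.sort_index()
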