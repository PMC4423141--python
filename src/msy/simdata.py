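"""Synthetic haploid Y-chromosome datasets with known truth.

Real MSY resequencing data of the kind this pipeline targets are
controlled-access, so every downstream stage is exercised against simulated
genealogies instead.  The generator emulates the features that matter to the
pipeline:

* a rooted bifurcating genealogy whose first split separates a small
  "haplogroup A"-like clade from the rest of the sample;
* named haplogroup clades with defining markers (an ISOGG-style table);
* clade-private derived alleles (the clean, phylogenetically informative
  signal), recurrent variants mutated independently on conflicting branches
  (the discarded class), and true singletons on terminal branches;
* per-sequence-class mutation-density heterogeneity over a BED-described
  class layout;
* missing calls, sub-threshold mapping qualities, and an outgroup sequence
  that occasionally carries a third allele.

Everything is driven by a single integer seed: identical
:class:`SimConfig` + seed give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALT,
    MISSING,
    REF,
    HaploidCallMatrix,
    InvalidConfigError,
    OutgroupTable,
    RegionMap,
)

_BASES = np.array(list("ACGT"))

#: 1-based start of the first MSY analysis window on GRCh37 chrY; simulated
#: class intervals are laid out consecutively from here so that simulated
#: VCFs survive the default window filter.
SIM_ORIGIN = 2_650_368

#: default class layout: 1/10-scale versions of the published class sizes
#: (X-degenerate 8.6 Mbp, X-transposed 3.4 Mbp, Ampliconic 9.7 Mbp split
#: ~2.8/6.9 into non-palindromic/palindromic, Other 0.4 Mbp,
#: readable heterochromatin 1.0 Mbp).
DEFAULT_CLASS_LAYOUT = (
    ("X-degenerate", 860_000),
    ("X-transposed", 340_000),
    ("Ampliconic-nonpalindromic", 280_000),
    ("Ampliconic-palindromic", 690_000),
    ("Other", 40_000),
    ("Heterochromatic", 100_000),
)

#: default expected true SNPs per 10 kbp by class, matching the density
#: profile of the published per-class totals (all phylogenetic statuses).
DEFAULT_MUTATION_DENSITY = {
    "X-degenerate": 25.0,
    "X-transposed": 13.0,
    "Ampliconic-nonpalindromic": 17.2,
    "Ampliconic-palindromic": 2.9,
    "Other": 25.7,
    "Heterochromatic": 49.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a desk-scale version of a ~1,200-male low-pass MSY
    resequencing study: 200 haploid samples, 50 named haplogroups with 5
    equivalent defining markers each (ISOGG nomenclature is fine-grained
    and lists many phylogenetically equivalent SNPs per clade), ~15%
    recurrent and ~34% singleton sites
    (the published discarded/singleton shares), 30% missing calls typical of
    low-pass coverage, and a chimpanzee outgroup that shows a third allele
    at ~0.1% of sites.
    """

    n_samples: int = 200
    n_haplogroups: int = 50
    class_layout: tuple[tuple[str, int], ...] = DEFAULT_CLASS_LAYOUT
    mutation_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_DENSITY)
    )
    recurrent_fraction: float = 0.15
    singleton_fraction: float = 0.34
    missing_rate: float = 0.30
    outgroup_third_allele_rate: float = 0.001
    low_mq_fraction: float = 0.10
    markers_per_haplogroup: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise InvalidConfigError("n_samples must be >= 2")
        if not (1 <= self.n_haplogroups <= self.n_samples):
            raise InvalidConfigError("need 1 <= n_haplogroups <= n_samples")
        for name, length in self.class_layout:
            if length <= 0:
                raise InvalidConfigError(f"class {name!r} length must be > 0")
        rates = {
            "recurrent_fraction": self.recurrent_fraction,
            "singleton_fraction": self.singleton_fraction,
            "missing_rate": self.missing_rate,
            "outgroup_third_allele_rate": self.outgroup_third_allele_rate,
            "low_mq_fraction": self.low_mq_fraction,
        }
        for key, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{key} must be in [0, 1], got {value}")
        if self.recurrent_fraction + self.singleton_fraction > 1.0:
            raise InvalidConfigError(
                "recurrent_fraction + singleton_fraction must be <= 1"
            )
        if self.markers_per_haplogroup < 1:
            raise InvalidConfigError("markers_per_haplogroup must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        if "class_layout" in raw:
            raw["class_layout"] = tuple((c, int(l)) for c, l in raw["class_layout"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


class SimNode:
    """Node of the simulated genealogy (binary, rooted)."""

    __slots__ = ("node_id", "children", "parent", "leaf_name", "haplogroup")

    def __init__(self, node_id: int, leaf_name: str | None = None):
        self.node_id = node_id
        self.children: list[SimNode] = []
        self.parent: SimNode | None = None
        self.leaf_name = leaf_name
        self.haplogroup: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Genealogy:
    """Rooted bifurcating sample genealogy with labelled haplogroup nodes."""

    def __init__(self, root: SimNode, sample_ids: list[str]):
        self.root = root
        self.sample_ids = sample_ids
        self._clades: dict[int, frozenset[str]] | None = None

    def preorder(self) -> list[SimNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def clades(self) -> dict[int, frozenset[str]]:
        """node_id -> frozenset of descendant leaf names (leaf: itself)."""
        if self._clades is None:
            memo: dict[int, frozenset[str]] = {}
            for node in reversed(self.preorder()):
                if node.is_leaf:
                    memo[node.node_id] = frozenset({node.leaf_name})
                else:
                    memo[node.node_id] = frozenset().union(
                        *(memo[c.node_id] for c in node.children)
                    )
            self._clades = memo
        return self._clades

    def labelled_nodes(self) -> list[SimNode]:
        return [n for n in self.preorder() if n.haplogroup is not None]

    def to_newick(self) -> str:
        def rec(node: SimNode) -> str:
            if node.is_leaf:
                return node.leaf_name
            inner = ",".join(rec(c) for c in node.children)
            label = node.haplogroup or ""
            return f"({inner}){label}"

        return rec(self.root) + ";"


def simulate_genealogy(config: SimConfig, rng: np.random.Generator | None = None) -> Genealogy:
    """Grow a Yule-style random binary genealogy and label haplogroup clades.

    The tree grows by uniform random leaf attachment (each step splits a
    uniformly chosen leaf into a cherry), which realises the Yule
    pure-birth topology distribution.  ``n_haplogroups`` clades are then
    named: the smaller child of the root becomes haplogroup "A" (mirroring
    the deep A-versus-rest split at the MSY root), and the remaining labels
    go to the largest clades.  Because a clade's ancestor always contains
    more leaves, the labelled set is automatically closed under ancestry,
    so named haplogroups nest properly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    width = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    counter = [0]

    def new_node(leaf_name: str | None = None) -> SimNode:
        node = SimNode(counter[0], leaf_name)
        counter[0] += 1
        return node

    root = new_node()
    leaves = []
    for _ in range(2):
        child = new_node(leaf_name="pending")
        child.parent = root
        root.children.append(child)
        leaves.append(child)
    while len(leaves) < n:
        idx = int(rng.integers(len(leaves)))
        split = leaves[idx]
        split.leaf_name = None
        for _ in range(2):
            child = new_node(leaf_name="pending")
            child.parent = split
            split.children.append(child)
            leaves.append(child)
        leaves.pop(idx)
    # name leaves in preorder for determinism
    tree = Genealogy(root, sample_ids)
    leaf_iter = iter(sample_ids)
    for node in tree.preorder():
        if node.is_leaf:
            node.leaf_name = next(leaf_iter)
    tree._clades = None

    clades = tree.clades()
    a_child = min(
        root.children, key=lambda c: (len(clades[c.node_id]), c.node_id)
    )
    a_child.haplogroup = "A"
    preorder_index = {node.node_id: i for i, node in enumerate(tree.preorder())}
    candidates = [
        node
        for node in tree.preorder()
        if node is not root and node is not a_child
    ]
    candidates.sort(
        key=lambda nd: (-len(clades[nd.node_id]), preorder_index[nd.node_id])
    )
    for node in candidates[: config.n_haplogroups - 1]:
        node.haplogroup = f"H{preorder_index[node.node_id]:04d}"
    return tree


@dataclass
class TruthTable:
    """Ground truth for every emitted site.

    ``sites`` has one row per VCF record: position, status
    (clean / recurrent / singleton), the true branch (node ids, joined by
    ``;`` for recurrent sites), true ancestral allele, carrier count and an
    ``is_marker`` flag.  ``genotypes`` is the pre-missingness sample x site
    call grid (0 ancestral-allele call, 1 derived-allele call).
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def carriers(self, i: int) -> frozenset[str]:
        idx = np.flatnonzero(self.genotypes[:, i] == 1)
        return frozenset(self.sample_ids[j] for j in idx)


@dataclass
class SimResult:
    config: SimConfig
    tree: Genealogy
    matrix: HaploidCallMatrix
    truth: TruthTable
    outgroup: OutgroupTable
    region_map: RegionMap
    marker_table: pd.DataFrame  # haplogroup, parent, marker, position, ancestral, derived

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import formats

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "calls.vcf",
            "bed": outdir / "classes.bed",
            "markers": outdir / "markers.tsv",
            "outgroup": outdir / "outgroup.tsv",
            "truth": outdir / "truth.tsv",
            "tree": outdir / "genealogy.nwk",
        }
        formats.write_vcf(self.matrix, paths["vcf"])
        formats.write_bed(self.region_map, paths["bed"])
        formats.write_marker_table(self.marker_table, paths["markers"])
        formats.write_outgroup(self.outgroup, paths["outgroup"])
        truth = self.truth.sites.copy()
        truth.insert(0, "#pos", truth.pop("pos"))
        truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["tree"].write_text(self.tree.to_newick() + "\n")
        return paths


def _direct_sets(tree: Genealogy) -> dict[str, frozenset[str]]:
    """Haplogroup -> samples in its clade but in no labelled descendant clade."""
    clades = tree.clades()
    labelled = tree.labelled_nodes()
    out: dict[str, frozenset[str]] = {}
    for node in labelled:
        mine = set(clades[node.node_id])
        stack = list(node.children)
        while stack:
            child = stack.pop()
            if child.haplogroup is not None:
                mine -= clades[child.node_id]
            else:
                stack.extend(child.children)
        out[node.haplogroup] = frozenset(mine)
    # samples under no labelled node sit directly on the synthetic root
    covered = frozenset().union(*(clades[n.node_id] for n in labelled))
    out["ROOT"] = frozenset(tree.sample_ids) - covered
    return out


def plant_mutations(
    tree: Genealogy, config: SimConfig, rng: np.random.Generator | None = None
) -> SimResult:
    """Plant SNPs on the genealogy and emit the full synthetic dataset.

    Per class, the number of density-driven sites is Poisson with mean
    ``density * length / 10 kbp``.  Each site is clean (derived carriers =
    one true clade), a singleton (one terminal branch) or recurrent
    (independent mutation on >= 2 conflicting branches) per the configured
    fractions.  Recurrent branch pairs are rejection-sampled so that the
    combined carrier set is genuinely conflicting: disjoint clades whose
    union is neither a true clade nor contained in a single haplogroup's
    paragroup — otherwise the site would be indistinguishable from clean
    signal.  Additionally ``markers_per_haplogroup`` clean marker sites are
    planted on the branch above every named haplogroup and reported in the
    ISOGG-style marker table.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    clades = tree.clades()
    n = config.n_samples
    sample_index = {s: i for i, s in enumerate(tree.sample_ids)}
    preorder = tree.preorder()
    internal_multi = [
        nd for nd in preorder
        if nd is not tree.root and len(clades[nd.node_id]) >= 2
    ]
    leaves = [nd for nd in preorder if nd.is_leaf]
    labelled = tree.labelled_nodes()
    direct = _direct_sets(tree)
    clade_family = set(clades.values())
    all_samples = frozenset(tree.sample_ids)

    # --- positions -------------------------------------------------------
    layout = list(config.class_layout)
    n_density = []
    expected_total = 0.0
    for cname, length in layout:
        lam = config.mutation_density.get(cname, 0.0) * length / 10_000.0
        expected_total += lam
        n_density.append(int(rng.poisson(lam)))
    if expected_total == 0.0:
        raise InvalidConfigError("configuration yields zero expected mutations")
    n_marker_total = config.markers_per_haplogroup * len(labelled)
    lengths = np.array([l for _, l in layout], dtype=float)
    marker_class = rng.choice(len(layout), size=n_marker_total, p=lengths / lengths.sum())
    n_per_class = np.array(n_density) + np.bincount(marker_class, minlength=len(layout))

    starts, intervals = [], []
    cursor = SIM_ORIGIN - 1  # 0-based
    for cname, length in layout:
        intervals.append((cursor, cursor + length, cname))
        starts.append(cursor)
        cursor += length
    region_map = RegionMap(intervals)

    pos_by_class: list[np.ndarray] = []
    for (cname, length), k, s in zip(layout, n_per_class, starts):
        if k > length:
            raise InvalidConfigError(f"class {cname!r} too short for {k} sites")
        # 1-based positions inside [s, s+length), unique
        p = rng.choice(length, size=int(k), replace=False) + s + 1
        pos_by_class.append(np.sort(p))

    # --- site plan -------------------------------------------------------
    records: list[dict] = []
    marker_rows: list[dict] = []
    geno_cols: list[np.ndarray] = []

    def add_site(pos: int, status: str, branch: str, carriers: frozenset[str],
                 is_marker: bool) -> tuple[dict, np.ndarray]:
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_b, alt_b = _BASES[ref], _BASES[alt]
        g = np.zeros(n, dtype=np.int8)
        for s in carriers:
            g[sample_index[s]] = 1
        rec = {
            "pos": int(pos),
            "status": status,
            "branch": branch,
            "ancestral": ref_b,  # generator convention: REF carries the ancestral state
            "ref": ref_b,
            "alt": alt_b,
            "n_carriers": len(carriers),
            "is_marker": is_marker,
        }
        return rec, g

    def draw_recurrent() -> tuple[str, frozenset[str]]:
        nodes = [nd for nd in preorder if nd is not tree.root]
        for _ in range(10_000):
            i, j = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[int(i)], nodes[int(j)]
            ca, cb = clades[a.node_id], clades[b.node_id]
            if ca & cb:
                continue  # nested or overlapping: not two independent origins
            union = ca | cb
            if union in clade_family or union == all_samples:
                continue
            if any(union <= d for d in direct.values()):
                continue
            return f"{a.node_id};{b.node_id}", union
        raise InvalidConfigError("could not plant a conflicting recurrent site")

    # marker sites take the tail of each class's position draw
    marker_slots: list[tuple[int, int]] = []  # (class_idx, position)
    used = [0] * len(layout)
    for ci in marker_class:
        ci = int(ci)
        used[ci] += 1
        marker_slots.append((ci, int(pos_by_class[ci][-used[ci]])))

    slot_iter = iter(marker_slots)
    for node in labelled:
        carriers = clades[node.node_id]
        parent_hg = "ROOT"
        cur = node.parent
        while cur is not None and cur.haplogroup is None:
            cur = cur.parent
        if cur is not None and cur.haplogroup is not None:
            parent_hg = cur.haplogroup
        for m in range(config.markers_per_haplogroup):
            _ci, pos = next(slot_iter)
            rec, g = add_site(pos, "clean", str(node.node_id), carriers, True)
            records.append(rec)
            geno_cols.append(g)
            marker_rows.append(
                {
                    "haplogroup": node.haplogroup,
                    "parent": parent_hg,
                    "marker": f"M_{node.haplogroup}_{m}",
                    "position": pos,
                    "ancestral": rec["ancestral"],
                    "derived": rec["alt"],
                }
            )

    for ci, k in enumerate(n_density):
        avail = pos_by_class[ci][: len(pos_by_class[ci]) - used[ci]]
        for pos in avail:
            u = rng.random()
            if u < config.recurrent_fraction:
                branch, carriers = draw_recurrent()
                status = "recurrent"
            elif u < config.recurrent_fraction + config.singleton_fraction:
                leaf = leaves[int(rng.integers(len(leaves)))]
                branch = str(leaf.node_id)
                carriers = clades[leaf.node_id]
                status = "singleton"
            else:
                if not internal_multi:
                    raise InvalidConfigError(
                        "genealogy has no multi-sample clade to mutate"
                    )
                node = internal_multi[int(rng.integers(len(internal_multi)))]
                branch = str(node.node_id)
                carriers = clades[node.node_id]
                status = "clean"
            rec, g = add_site(int(pos), status, branch, carriers, False)
            records.append(rec)
            geno_cols.append(g)

    sites = pd.DataFrame.from_records(records)
    order = np.argsort(sites["pos"].to_numpy(), kind="stable")
    sites = sites.iloc[order].reset_index(drop=True)
    genotypes = np.stack([geno_cols[i] for i in order], axis=1)

    # --- observation layer ----------------------------------------------
    n_sites = len(sites)
    mq = np.full(n_sites, 60, dtype=int)
    low = rng.random(n_sites) < config.low_mq_fraction
    mq[low] = rng.integers(0, 60, size=int(low.sum()))

    calls = genotypes.copy()
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int8)

    outg = {}
    third = rng.random(n_sites) < config.outgroup_third_allele_rate
    for i in range(n_sites):
        anc = sites["ancestral"].iat[i]
        if third[i]:
            others = [b for b in "ACGT" if b not in (sites["ref"].iat[i], sites["alt"].iat[i])]
            anc = others[int(rng.integers(len(others)))]
        outg[int(sites["pos"].iat[i])] = anc
    sites = sites.assign(outgroup_is_third=third)

    matrix = HaploidCallMatrix(
        sample_ids=list(tree.sample_ids),
        sites=pd.DataFrame(
            {
                "pos": sites["pos"].to_numpy(),
                "ref": sites["ref"].to_numpy(),
                "alt": sites["alt"].to_numpy(),
                "mq": mq,
            }
        ),
        calls=calls,
    )
    truth = TruthTable(
        sample_ids=list(tree.sample_ids),
        sites=sites,
        genotypes=genotypes,
    )
    marker_table = pd.DataFrame.from_records(
        marker_rows,
        columns=["haplogroup", "parent", "marker", "position", "ancestral", "derived"],
    )
    return SimResult(
        config=config,
        tree=tree,
        matrix=matrix,
        truth=truth,
        outgroup=OutgroupTable(outg),
        region_map=region_map,
        marker_table=marker_table,
    )


def simulate(config: SimConfig) -> SimResult:
    """One-call convenience: genealogy + mutations from a single seed."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_genealogy(config, rng)
    return plant_mutations(tree, config, rng)
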