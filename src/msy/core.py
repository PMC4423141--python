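"""Core in-memory containers for the MSY SNP pipeline.

The pipeline's central object is the :class:`HaploidCallMatrix`: hard haploid
calls (REF / ALT / MISSING) for every sample at every retained site of the
male-specific region of the Y chromosome (MSY).  Sites carry a 1-based
position on the Y reference, single-base REF/ALT alleles, a Phred-scaled
mapping quality and (after annotation) a sequence-class label.

Coordinate conventions
----------------------
* variant positions: 1-based, as in VCF;
* region intervals: 0-based half-open, as in BED.  A 1-based position ``p``
  falls in the BED interval ``[s, e)`` iff ``s < p <= e``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# call encodings in the sample x site grid
REF = 0
ALT = 1
MISSING = -1

#: canonical MSY sequence-class names (BED column 4 / site annotation)
SEQUENCE_CLASSES = (
    "X-degenerate",
    "X-transposed",
    "Ampliconic-palindromic",
    "Ampliconic-nonpalindromic",
    "Other",
    "Heterochromatic",
)
UNASSIGNED = "unassigned"

#: default MSY analysis windows (1-based inclusive) on GRCh37 chrY:
#: euchromatin plus the readable heterochromatic stretch, PARs excluded.
DEFAULT_MSY_WINDOWS = ((2_650_368, 10_094_615), (13_109_251, 28_818_849))

_BASES = frozenset("ACGT")


class MSYError(Exception):
    """Base error for pipeline contract violations."""


class InvalidConfigError(MSYError):
    pass


class FormatError(MSYError):
    pass


@dataclass
class HaploidCallMatrix:
    """Samples x sites grid of haploid calls over {REF, ALT, MISSING}.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``calls``).
    sites
        DataFrame with columns ``pos`` (1-based int), ``ref``, ``alt``
        (single bases), ``mq`` (Phred int) and optionally ``region_class``.
    calls
        ``(n_samples, n_sites)`` int8 array with values in {0, 1, -1}.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise MSYError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if "region_class" not in self.sites.columns:
            self.sites = self.sites.assign(region_class=UNASSIGNED)
        pos = self.sites["pos"].to_numpy()
        if len(pos) and (np.diff(pos) <= 0).any():
            raise MSYError("sites must be strictly sorted by position")
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise MSYError("calls must be in {REF=0, ALT=1, MISSING=-1}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return self.sites["pos"].to_numpy()

    def take_sites(self, index: np.ndarray) -> "HaploidCallMatrix":
        """Return a new matrix restricted to the given site indices (in order)."""
        return HaploidCallMatrix(
            sample_ids=list(self.sample_ids),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def site_index(self, pos: int) -> int:
        i = int(np.searchsorted(self.positions, pos))
        if i >= self.n_sites or self.positions[i] != pos:
            raise KeyError(f"no site at position {pos}")
        return i


@dataclass
class RegionMap:
    """Non-overlapping 0-based half-open intervals labelled by sequence class."""

    intervals: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (s1, e1, _), (s2, _e2, _c) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping region intervals at {s2} < {e1}")
        for s, e, _ in ivs:
            if e <= s:
                raise FormatError(f"empty/inverted interval [{s}, {e})")
        self.intervals = ivs

    @property
    def class_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s, e, c in self.intervals:
            out[c] = out.get(c, 0) + (e - s)
        return out

    def class_of(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised class lookup for 1-based positions (``unassigned`` if none)."""
        starts = np.array([s for s, _, _ in self.intervals], dtype=np.int64)
        ends = np.array([e for _, e, _ in self.intervals], dtype=np.int64)
        names = np.array([c for _, _, c in self.intervals], dtype=object)
        pos = np.asarray(positions, dtype=np.int64)
        out = np.full(len(pos), UNASSIGNED, dtype=object)
        if len(starts):
            # 1-based p is inside [s, e) iff s < p <= e, i.e. 0-based p-1 in [s, e)
            i = np.searchsorted(starts, pos - 1, side="right") - 1
            ok = (i >= 0) & (pos - 1 < ends[np.clip(i, 0, None)])
            out[ok] = names[i[ok]]
        return out


@dataclass
class Marker:
    """A haplogroup-defining SNP: position plus ancestral/derived alleles."""

    name: str
    position: int
    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if self.ancestral not in _BASES or self.derived not in _BASES:
            raise FormatError(f"marker {self.name}: alleles must be A/C/G/T")
        if self.ancestral == self.derived:
            raise FormatError(f"marker {self.name}: ancestral == derived")


@dataclass
class HaplogroupNode:
    name: str
    parent: "HaplogroupNode | None" = None
    children: list["HaplogroupNode"] = field(default_factory=list)
    markers: list[Marker] = field(default_factory=list)
    #: samples assigned directly to this node (its paragroup), filled by classify
    direct_samples: set[str] = field(default_factory=set)

    def clade_samples(self) -> set[str]:
        out = set(self.direct_samples)
        for c in self.children:
            out |= c.clade_samples()
        return out

    @property
    def is_terminal(self) -> bool:
        return not self.children


class HaplogroupTree:
    """Rooted reference tree of named haplogroups with defining markers.

    The tree is the hierarchy against which variants are validated: a sample
    is placed on the deepest haplogroup whose defining markers it carries in
    the derived state, and a variant is "univocally associated" when its
    carriers correspond to exactly one clade of this tree.
    """

    def __init__(self, nodes: Mapping[str, HaplogroupNode], root: HaplogroupNode):
        self.nodes = dict(nodes)
        self.root = root

    @classmethod
    def from_edges(
        cls,
        parent_of: Mapping[str, str | None],
        markers: Mapping[str, Iterable[Marker]] | None = None,
    ) -> "HaplogroupTree":
        nodes = {name: HaplogroupNode(name=name) for name in parent_of}
        root = None
        for name, parent in parent_of.items():
            if parent is None:
                if root is not None:
                    raise FormatError("haplogroup tree has more than one root")
                root = nodes[name]
            else:
                if parent not in nodes:
                    raise FormatError(f"unknown parent haplogroup {parent!r}")
                nodes[name].parent = nodes[parent]
                nodes[parent].children.append(nodes[name])
        if root is None:
            raise FormatError("haplogroup tree has no root")
        # acyclicity: every node must reach the root
        for node in nodes.values():
            seen, cur = set(), node
            while cur is not None:
                if cur.name in seen:
                    raise FormatError(f"cycle in haplogroup parent links at {cur.name!r}")
                seen.add(cur.name)
                cur = cur.parent
            if root.name not in seen:
                raise FormatError(f"haplogroup {node.name!r} does not reach the root")
        if markers:
            for name, ms in markers.items():
                nodes[name].markers.extend(ms)
        return cls(nodes, root)

    def clear_assignments(self) -> None:
        for node in self.nodes.values():
            node.direct_samples.clear()

    def depth(self, name: str) -> int:
        d, cur = 0, self.nodes[name]
        while cur.parent is not None:
            d += 1
            cur = cur.parent
        return d

    def ancestors(self, name: str) -> list[str]:
        """Names from this node up to (and including) the root."""
        out, cur = [], self.nodes[name]
        while cur is not None:
            out.append(cur.name)
            cur = cur.parent
        return out

    def preorder(self) -> list[HaplogroupNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def clade_sets(self) -> dict[str, frozenset[str]]:
        """Haplogroup name -> full clade sample set (after assignment)."""
        memo: dict[str, frozenset[str]] = {}

        def rec(node: HaplogroupNode) -> frozenset[str]:
            s = frozenset(node.direct_samples).union(*(rec(c) for c in node.children)) \
                if node.children else frozenset(node.direct_samples)
            memo[node.name] = s
            return s

        rec(self.root)
        return memo


class OutgroupTable:
    """Position -> outgroup (chimpanzee) allele; positions may be absent."""

    def __init__(self, alleles: Mapping[int, str]):
        for pos, a in alleles.items():
            if a not in _BASES:
                raise FormatError(f"outgroup allele at {pos} must be A/C/G/T, got {a!r}")
        self._alleles = dict(alleles)

    def get(self, position: int) -> str | None:
        return self._alleles.get(position)

    def __len__(self) -> int:
        return len(self._alleles)

    def items(self):
        return self._alleles.items()
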