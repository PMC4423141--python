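"""Hierarchical phylogenetic validation of MSY variants.

The pipeline's core inference.  After mapping-quality filtering and removal
of monomorphic sites, every variant is

1. *polarized* against the chimpanzee outgroup (which allele is ancestral?),
2. *missing-resolved*: missing calls are imputed ancestral or derived from
   the smallest haplogroup clade containing the observed derived carriers,
3. *classified* by a hierarchical consistency test against the reference
   haplogroup tree: a variant is **informative** when its derived carriers
   correspond univocally to one haplogroup clade (or define a compatible new
   subclade inside a single haplogroup's paragroup), a **singleton** when
   private to one individual and not a known marker, and **discarded** when
   its carriers conflict with the tree (recurrent mutation or mapping
   artefact).

Statuses mirror the three-way accounting of MSY resequencing studies:
informative + singleton + discarded = all retained polymorphic sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ALT,
    MISSING,
    REF,
    HaploidCallMatrix,
    HaplogroupTree,
    MSYError,
    OutgroupTable,
)

logger = logging.getLogger(__name__)

INFORMATIVE = "informative"
SINGLETON = "singleton"
DISCARDED = "discarded"
DROPPED = "dropped"

ALT_DERIVED = "alt-derived"
REF_DERIVED = "ref-derived"
UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# site-level filters
# ---------------------------------------------------------------------------

def filter_mq(matrix: HaploidCallMatrix, threshold: int = 60) -> HaploidCallMatrix:
    """Drop sites with Phred-scaled mapping quality below ``threshold``.

    The default of 60 demands that both reads of a pair mapped without
    ambiguity, guarding against X-homologous sequence bleeding into the Y.
    """
    mq = matrix.sites["mq"].to_numpy()
    keep = np.flatnonzero(mq >= threshold)
    n_removed = matrix.n_sites - len(keep)
    if n_removed:
        logger.info("MQ filter removed %d of %d sites", n_removed, matrix.n_sites)
    return matrix.take_sites(keep)


def drop_monomorphic(matrix: HaploidCallMatrix) -> HaploidCallMatrix:
    """Drop sites whose non-missing calls are all identical (or all missing)."""
    has_ref = (matrix.calls == REF).any(axis=0)
    has_alt = (matrix.calls == ALT).any(axis=0)
    keep = np.flatnonzero(has_ref & has_alt)
    all_missing = int((~has_ref & ~has_alt).sum())
    if all_missing:
        logger.warning("%d sites had only missing calls", all_missing)
    return matrix.take_sites(keep)


# ---------------------------------------------------------------------------
# sample -> haplogroup assignment
# ---------------------------------------------------------------------------

def _marker_states(matrix: HaploidCallMatrix, tree: HaplogroupTree):
    """For each haplogroup, columns of the matrix carrying its markers.

    Returns ``{haplogroup: [(site_index, derived_call_code), ...]}`` using
    the marker table's own ancestral/derived alleles; markers whose alleles
    do not match the site's REF/ALT pair are ignored.
    """
    pos_to_idx = {int(p): i for i, p in enumerate(matrix.positions)}
    out: dict[str, list[tuple[int, int]]] = {}
    for node in tree.nodes.values():
        cols = []
        for m in node.markers:
            i = pos_to_idx.get(m.position)
            if i is None:
                continue
            ref = matrix.sites["ref"].iat[i]
            alt = matrix.sites["alt"].iat[i]
            if {ref, alt} != {m.ancestral, m.derived}:
                logger.warning(
                    "marker %s alleles %s/%s do not match site %d (%s/%s); ignored",
                    m.name, m.ancestral, m.derived, m.position, ref, alt,
                )
                continue
            cols.append((i, ALT if alt == m.derived else REF))
        if cols:
            out[node.name] = cols
    return out


def assign_samples(
    matrix: HaploidCallMatrix, tree: HaplogroupTree
) -> tuple[HaplogroupTree, set[str]]:
    """Place every sample on the deepest consistent haplogroup.

    Walking down from the root, a sample descends into a child haplogroup
    when the child's subtree shows derived evidence (at least one observed
    derived marker at the child or any of its descendants) and the child
    itself shows no observed ancestral marker; missing calls neither
    support nor contradict, so a node whose markers all went uncalled is
    traversed when a deeper marker is derived — on the non-recombining MSY
    a derived descendant state implies derived ancestors.  If two
    incomparable children both carry derived evidence the sample is
    flagged inconsistent and stays at their deepest common ancestor; a
    sample ancestral at every marker stays at the root.  Fills
    ``node.direct_samples`` in place and returns the tree plus the set of
    inconsistent samples.
    """
    states = _marker_states(matrix, tree)
    if not states:
        raise MSYError("reference tree unanchored: no haplogroup marker found in matrix")
    tree.clear_assignments()
    inconsistent: set[str] = set()

    def observe(sample_idx: int, hg: str) -> tuple[int, int]:
        derived = ancestral = 0
        for i, derived_code in states.get(hg, ()):
            call = matrix.calls[sample_idx, i]
            if call == MISSING:
                continue
            if call == derived_code:
                derived += 1
            else:
                ancestral += 1
        return derived, ancestral

    for s_idx, sample in enumerate(matrix.sample_ids):
        # evidence per node, then propagate derived support up the tree
        derived_here: dict[str, bool] = {}
        contradicted: dict[str, bool] = {}
        for name in tree.nodes:
            d, a = observe(s_idx, name)
            derived_here[name] = d >= 1
            contradicted[name] = a >= 1
        subtree_support: dict[str, bool] = {}
        for node in reversed(tree.preorder()):
            subtree_support[node.name] = derived_here[node.name] or any(
                subtree_support[c.name] for c in node.children
            )
        node = tree.root
        while True:
            nxt = [
                c
                for c in node.children
                if subtree_support[c.name] and not contradicted[c.name]
            ]
            if len(nxt) == 1:
                node = nxt[0]
            else:
                if len(nxt) > 1:
                    inconsistent.add(sample)
                break
        node.direct_samples.add(sample)
    return tree, inconsistent


# ---------------------------------------------------------------------------
# polarization and missing-call resolution
# ---------------------------------------------------------------------------

def polarize(ref: str, alt: str, position: int, outgroup: OutgroupTable) -> str:
    """Determine the ancestral state by comparison with the outgroup allele.

    outgroup == REF -> ``alt-derived``; outgroup == ALT -> ``ref-derived``
    (the reference sequence carries the derived state); outgroup matching
    neither allele, or absent, -> ``unresolved``.
    """
    og = outgroup.get(position)
    if og is None:
        return UNRESOLVED
    if og == ref:
        return ALT_DERIVED
    if og == alt:
        return REF_DERIVED
    return UNRESOLVED


class _CladeIndex:
    """Sorted haplogroup clade sets for smallest-containing-clade queries."""

    def __init__(self, tree: HaplogroupTree):
        sets = tree.clade_sets()
        depth = {name: tree.depth(name) for name in sets}
        # ascending size, deeper first on ties -> first superset hit is the
        # smallest (deepest) containing clade
        self.ordered = sorted(
            sets.items(), key=lambda kv: (len(kv[1]), -depth[kv[0]])
        )
        self.by_name = dict(sets)
        self.depth = depth
        # paragroups: samples assigned directly to each node
        self.direct = {
            name: frozenset(node.direct_samples) for name, node in tree.nodes.items()
        }

    def smallest_containing(self, carriers: frozenset[str]) -> tuple[str, frozenset[str]]:
        for name, s in self.ordered:
            if carriers <= s:
                return name, s
        raise MSYError("carrier set not contained in the root clade")

    def exact_match(self, carriers: frozenset[str]) -> str | None:
        best = None
        for name, s in self.by_name.items():
            if s == carriers and (best is None or self.depth[name] > self.depth[best]):
                best = name
        return best

    def containing_paragroup(self, carriers: frozenset[str]) -> str | None:
        for name, s in self.direct.items():
            if s and carriers <= s:
                return name
        return None


def resolve_missing(
    derived: np.ndarray,
    sample_ids: list[str],
    clade_index: _CladeIndex,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute missing calls for one site by hierarchical inference.

    ``derived`` codes each sample 1 (derived), 0 (ancestral) or -1
    (missing).  Let C be the smallest haplogroup clade containing every
    observed derived carrier: if all non-missing members of C are derived,
    missing members of C are imputed derived and everything outside C
    ancestral; if C is mixed the site's missing calls are all imputed
    ancestral (the conservative branch, so imputation can never fabricate a
    clade).  Returns the completed 0/1 vector and the imputed-call mask.
    """
    missing = derived == -1
    out = derived.copy()
    carriers = frozenset(
        sample_ids[i] for i in np.flatnonzero(derived == 1)
    )
    if not carriers:
        out[missing] = 0
        return out, missing
    _, clade = clade_index.smallest_containing(carriers)
    member = np.fromiter((s in clade for s in sample_ids), bool, len(sample_ids))
    observed = ~missing
    clade_pure = bool((out[member & observed] == 1).all())
    if clade_pure:
        out[missing & member] = 1
        out[missing & ~member] = 0
    else:
        out[missing] = 0
    return out, missing


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Accounting of the classification run (Table-1-style denominators)."""

    n_input_sites: int
    n_mq_removed: int
    n_dropped: int
    n_informative: int = 0
    n_singleton: int = 0
    n_discarded: int = 0
    n_unresolved_polarity: int = 0
    n_inconsistent_samples: int = 0
    derived_alleles_mean: float = 0.0
    derived_alleles_sd: float = 0.0
    by_status_class: dict = field(default_factory=dict)

    @property
    def total_polymorphic(self) -> int:
        return self.n_informative + self.n_singleton + self.n_discarded

    @property
    def candidate_pool(self) -> int:
        """Multi-carrier sites plus known-marker singletons: everything that
        entered hierarchical validation (informative + discarded)."""
        return self.n_informative + self.n_discarded

    def to_dict(self) -> dict:
        return {
            "n_input_sites": self.n_input_sites,
            "n_mq_removed": self.n_mq_removed,
            "n_dropped": self.n_dropped,
            "n_informative": self.n_informative,
            "n_singleton": self.n_singleton,
            "n_discarded": self.n_discarded,
            "total_polymorphic": self.total_polymorphic,
            "candidate_pool": self.candidate_pool,
            "n_unresolved_polarity": self.n_unresolved_polarity,
            "n_inconsistent_samples": self.n_inconsistent_samples,
            "derived_alleles_mean": self.derived_alleles_mean,
            "derived_alleles_sd": self.derived_alleles_sd,
            "by_status_class": {
                status: dict(classes) for status, classes in self.by_status_class.items()
            },
        }


def _marker_index(tree: HaplogroupTree) -> dict[int, tuple[str, object]]:
    out = {}
    for node in tree.nodes.values():
        for m in node.markers:
            out[m.position] = (node.name, m)
    return out


def classify_all(
    matrix: HaploidCallMatrix,
    tree: HaplogroupTree,
    outgroup: OutgroupTable,
    *,
    mq_threshold: int = 60,
    assigned: bool = False,
) -> tuple[pd.DataFrame, np.ndarray, ClassificationReport]:
    """Run the full per-site validation and return the classified table.

    Returns ``(classified, resolved, report)`` where ``classified`` has one
    row per retained site (pos, region_class, status, haplogroup, polarity,
    n_carriers, known_marker, carriers) and ``resolved`` is the
    missing-resolved derived/ancestral call grid aligned with its rows.
    """
    n_input = matrix.n_sites
    matrix = filter_mq(matrix, mq_threshold)
    n_mq_removed = n_input - matrix.n_sites
    matrix = drop_monomorphic(matrix)

    inconsistent: set[str] = set()
    if not assigned:
        tree, inconsistent = assign_samples(matrix, tree)
    clade_index = _CladeIndex(tree)
    marker_index = _marker_index(tree)
    sample_ids = matrix.sample_ids
    all_samples = frozenset(sample_ids)
    n_samples = len(sample_ids)

    n_sites = matrix.n_sites
    resolved = np.zeros((n_samples, n_sites), dtype=np.int8)
    rows: list[dict] = []
    carriers_per_site: list[frozenset[str]] = []
    sites = matrix.sites

    for j in range(n_sites):
        ref, alt = sites["ref"].iat[j], sites["alt"].iat[j]
        pos = int(sites["pos"].iat[j])
        polarity = polarize(ref, alt, pos, outgroup)
        calls = matrix.calls[:, j]
        derived_code = REF if polarity == REF_DERIVED else ALT  # unresolved -> ALT
        derived = np.where(
            calls == MISSING, -1, (calls == derived_code).astype(np.int8)
        ).astype(np.int8)
        completed, _ = resolve_missing(derived, sample_ids, clade_index)
        resolved[:, j] = completed
        carriers = frozenset(sample_ids[i] for i in np.flatnonzero(completed == 1))
        carriers_per_site.append(carriers)
        known = pos in marker_index and {ref, alt} == {
            marker_index[pos][1].ancestral,
            marker_index[pos][1].derived,
        }
        rows.append(
            {
                "pos": pos,
                "region_class": sites["region_class"].iat[j],
                "polarity": polarity,
                "n_carriers": len(carriers),
                "known_marker": known,
            }
        )

    # --- decision procedure ----------------------------------------------
    status = [None] * n_sites
    haplogroup = [None] * n_sites
    subset_candidates: list[int] = []
    for j, carriers in enumerate(carriers_per_site):
        if not carriers or carriers == all_samples:
            status[j] = DROPPED
            if not carriers:
                logger.warning("site %d: empty carrier set after resolution", rows[j]["pos"])
            continue
        if len(carriers) == 1:
            hg = None
            if rows[j]["known_marker"]:
                hg_name = marker_index[rows[j]["pos"]][0]
                (carrier,) = carriers
                if carrier in clade_index.by_name.get(hg_name, frozenset()):
                    hg = hg_name
            if hg is not None:
                status[j] = INFORMATIVE
                haplogroup[j] = hg
            else:
                status[j] = SINGLETON
            continue
        hg = clade_index.exact_match(carriers)
        if hg is not None:
            status[j] = INFORMATIVE
            haplogroup[j] = hg
        else:
            subset_candidates.append(j)

    # subset-type candidates: a new subclade inside one haplogroup's
    # paragroup, accepted largest-first (ties by position) so that the
    # pairwise-compatibility test is independent of input order
    accepted_in: dict[str, list[frozenset[str]]] = {}
    subset_candidates.sort(key=lambda j: (-len(carriers_per_site[j]), rows[j]["pos"]))
    for j in subset_candidates:
        carriers = carriers_per_site[j]
        hg = clade_index.containing_paragroup(carriers)
        if hg is None:
            status[j] = DISCARDED
            continue
        ok = all(
            carriers <= prev or prev <= carriers or not (carriers & prev)
            for prev in accepted_in.get(hg, ())
        )
        if ok:
            status[j] = INFORMATIVE
            haplogroup[j] = hg
            accepted_in.setdefault(hg, []).append(carriers)
        else:
            status[j] = DISCARDED

    classified = pd.DataFrame(rows)
    classified["status"] = status
    classified["haplogroup"] = haplogroup
    classified["carriers"] = carriers_per_site

    keep = classified["status"] != DROPPED
    n_dropped_post = int((~keep).sum())
    classified = classified[keep].reset_index(drop=True)
    resolved = resolved[:, keep.to_numpy()]

    report = ClassificationReport(
        n_input_sites=n_input,
        n_mq_removed=n_mq_removed,
        n_dropped=(n_input - n_mq_removed - n_sites) + n_dropped_post,
        n_informative=int((classified["status"] == INFORMATIVE).sum()),
        n_singleton=int((classified["status"] == SINGLETON).sum()),
        n_discarded=int((classified["status"] == DISCARDED).sum()),
        n_unresolved_polarity=int(
            (
                (classified["polarity"] == UNRESOLVED)
                & (classified["status"] == INFORMATIVE)
            ).sum()
        ),
        n_inconsistent_samples=len(inconsistent),
    )
    mean, sd = derived_allele_stats(classified, resolved)
    report.derived_alleles_mean = mean
    report.derived_alleles_sd = sd
    tab = (
        classified.groupby(["status", "region_class"]).size().unstack(fill_value=0)
    )
    report.by_status_class = {
        status_name: {c: int(v) for c, v in row.items() if v}
        for status_name, row in tab.iterrows()
    }
    return classified, resolved, report


def derived_allele_stats(
    classified: pd.DataFrame, resolved: np.ndarray
) -> tuple[float, float]:
    """Mean and population SD of per-sample derived-allele counts over
    informative sites."""
    mask = (classified["status"] == INFORMATIVE).to_numpy()
    if not mask.any():
        return 0.0, 0.0
    counts = resolved[:, mask].sum(axis=1)
    return float(counts.mean()), float(counts.std(ddof=0))
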