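"""Model/Results interface wiring the pipeline stages together.

:class:`YPhylogenyModel` is built from the data (call matrix, reference
haplogroup tree, outgroup table, optional region map); ``fit()`` runs
mapping-quality filtering, monomorphic-site removal, sample placement,
polarization, missing-call resolution, variant classification, perfect
phylogeny construction and per-class accounting, returning a
:class:`YPhylogenyResults` carrying every artefact plus a ``summary()``
table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import formats, phylogeny, summarize as _summarize
from .core import (
    DEFAULT_MSY_WINDOWS,
    HaploidCallMatrix,
    HaplogroupTree,
    OutgroupTable,
    RegionMap,
)

logger = logging.getLogger(__name__)


class YPhylogenyModel:
    """Phylogenetic validation model for MSY haploid variant calls.

    Parameters
    ----------
    matrix
        Haploid calls (samples x sites).
    markers
        Reference haplogroup tree with defining markers (ISOGG-style).
    outgroup
        Chimpanzee alleles by position, used to polarize variants.
    region_map
        Sequence-class intervals; optional (sites default to 'unassigned').
    mq_threshold
        Minimum Phred mapping quality (default 60: unambiguous read pairs).
    min_descendants
        Minimum descendant samples for an edge to count towards the tree
        skeleton (default 2: internal edges).
    """

    def __init__(
        self,
        matrix: HaploidCallMatrix,
        markers: HaplogroupTree,
        outgroup: OutgroupTable,
        region_map: RegionMap | None = None,
        *,
        mq_threshold: int = 60,
        min_descendants: int = 2,
    ):
        self.matrix = matrix
        self.markers = markers
        self.outgroup = outgroup
        self.region_map = region_map
        self.mq_threshold = mq_threshold
        self.min_descendants = min_descendants

    @classmethod
    def from_files(
        cls,
        vcf: str | Path,
        markers: str | Path,
        outgroup: str | Path,
        bed: str | Path | None = None,
        *,
        msy_windows=DEFAULT_MSY_WINDOWS,
        **kwargs,
    ) -> "YPhylogenyModel":
        matrix = formats.load_calls(vcf, msy_windows)
        tree = formats.load_marker_table(markers)
        og = formats.load_outgroup(outgroup)
        region_map = formats.load_bed(bed) if bed is not None else None
        return cls(matrix, tree, og, region_map, **kwargs)

    def fit(self) -> "YPhylogenyResults":
        matrix = self.matrix
        if self.region_map is not None:
            matrix = formats.annotate_regions(matrix, self.region_map)
        classified, resolved, report = _classify.classify_all(
            matrix,
            self.markers,
            self.outgroup,
            mq_threshold=self.mq_threshold,
        )
        network = phylogeny.build_network(classified, matrix.sample_ids)
        network = phylogeny.root_network(network, classified)
        clades = self.markers.clade_sets()
        skeleton = phylogeny.skeleton_stats(
            network, clades, min_descendants=self.min_descendants
        )
        decomposition = phylogeny.branch_class_decomposition(network, classified)
        region_summary = _summarize.summarize(classified, self.region_map)
        identities = _summarize.report_identities(region_summary, report)
        return YPhylogenyResults(
            model=self,
            classified=classified,
            resolved=resolved,
            report=report,
            network=network,
            skeleton=skeleton,
            decomposition=decomposition,
            region_summary=region_summary,
            identities=identities,
        )


@dataclass
class YPhylogenyResults:
    """Fit artefacts: classification, network, skeleton and accounting."""

    model: YPhylogenyModel
    classified: pd.DataFrame
    resolved: np.ndarray
    report: _classify.ClassificationReport
    network: phylogeny.PhyloNetwork
    skeleton: phylogeny.SkeletonStats
    decomposition: pd.DataFrame
    region_summary: _summarize.RegionSummary
    identities: dict

    def summary(self) -> str:
        r = self.report
        total = r.total_polymorphic

        def pct(n: int) -> str:
            return f"{100.0 * n / total:5.1f}%" if total else "   - "

        lines = [
            "MSY phylogenetic classification results",
            "=" * 47,
            f"samples                {len(self.model.matrix.sample_ids):>10d}",
            f"input sites            {r.n_input_sites:>10d}",
            f"removed (MQ < {self.model.mq_threshold:2d})      {r.n_mq_removed:>10d}",
            f"dropped (monomorphic)  {r.n_dropped:>10d}",
            f"polymorphic retained   {total:>10d}",
            "-" * 47,
            f"informative            {r.n_informative:>10d}  ({pct(r.n_informative)})",
            f"singletons             {r.n_singleton:>10d}  ({pct(r.n_singleton)})",
            f"discarded              {r.n_discarded:>10d}  ({pct(r.n_discarded)})",
            "-" * 47,
            f"derived alleles/sample {r.derived_alleles_mean:>12.1f} "
            f"(+/- {r.derived_alleles_sd:.1f})",
            f"unresolved polarity    {r.n_unresolved_polarity:>10d} of {r.n_informative}",
            f"skeleton SNPs          {self.skeleton.skeleton_snp_count:>10d} "
            f"({100.0 * self.skeleton.skeleton_fraction:.1f}% of informative)",
            f"identities             "
            + ("all pass" if all(v["pass"] for v in self.identities.values()) else "FAIL"),
        ]
        return "\n".join(lines)

    def classified_table(self) -> pd.DataFrame:
        """Flat per-site table with carriers serialised for TSV output."""
        df = self.classified.copy()
        df["carriers"] = df["carriers"].map(lambda s: ",".join(sorted(s)))
        return df[
            [
                "pos",
                "region_class",
                "status",
                "haplogroup",
                "polarity",
                "n_carriers",
                "known_marker",
                "carriers",
            ]
        ]

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "classified": outdir / "classified.tsv",
            "report": outdir / "report.json",
            "network": outdir / "network.nwk",
            "edges": outdir / "edges.tsv",
            "summary": outdir / "summary.tsv",
        }
        df = self.classified_table()
        df = df.rename(columns={"pos": "#pos"})
        df.to_csv(paths["classified"], sep="\t", index=False)
        payload = self.report.to_dict()
        payload["skeleton_snp_count"] = self.skeleton.skeleton_snp_count
        payload["skeleton_fraction"] = self.skeleton.skeleton_fraction
        payload["identities"] = self.identities
        paths["report"].write_text(json.dumps(payload, indent=2) + "\n")
        formats.write_newick(self.network, paths["network"])
        edges = self.decomposition.copy()
        edges.insert(0, "n_snps", edges.sum(axis=1))
        edges.to_csv(paths["edges"], sep="\t")
        formats.write_summary(self.region_summary, paths["summary"])
        return paths
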