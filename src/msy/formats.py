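"""Readers and writers for every on-disk format the pipeline touches.

Strict dialect contracts:

* VCF v4.2 in/out, haploid GT ("0"/"1"/"."); diploid-encoded male calls are
  accepted and collapsed (0/0 -> REF, 1/1 -> ALT, anything else MISSING,
  since a heterozygous call on the haploid MSY indicates a mapping
  artefact); per-site mapping quality from INFO/MQ.
* BED6 region classes, 0-based half-open, class name in column 4.
* ISOGG-style marker table: 6-column TSV (haplogroup, parent, marker,
  position, ancestral, derived); one row per marker, the root appears only
  as a parent (or with parent "." / "").
* outgroup alleles: 2-column TSV (1-based position, allele).
* Newick out for haplotype networks, with branch lengths = SNP counts.

Every writer/reader pair round-trips.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ALT,
    DEFAULT_MSY_WINDOWS,
    MISSING,
    REF,
    FormatError,
    HaploidCallMatrix,
    HaplogroupTree,
    Marker,
    OutgroupTable,
    RegionMap,
)

logger = logging.getLogger(__name__)

_GT_MAP = {
    (0,): REF,
    (1,): ALT,
    (-1,): MISSING,
    (0, 0): REF,
    (1, 1): ALT,
}


def load_calls(
    vcf_source: str | Path,
    msy_windows=DEFAULT_MSY_WINDOWS,
) -> HaploidCallMatrix:
    """Read haploid calls from a VCF, keeping only sites inside the MSY windows.

    ``msy_windows`` are 1-based inclusive intervals; the defaults are the two
    analysis windows on GRCh37 chrY (euchromatin plus readable
    heterochromatin, pseudoautosomal regions excluded).  Multi-allelic sites
    are skipped with a warning; heterozygous or half-missing diploid
    genotypes collapse to MISSING.
    """
    from cyvcf2 import VCF

    windows = sorted(tuple(w) for w in msy_windows)
    for (s1, e1), (s2, _) in zip(windows, windows[1:]):
        if s2 <= e1:
            raise FormatError("MSY windows must be disjoint and sorted")

    vcf = VCF(str(vcf_source))
    sample_ids = list(vcf.samples)
    rows = []
    call_cols = []
    for variant in vcf:
        pos = variant.POS
        if not any(s <= pos <= e for s, e in windows):
            continue
        if len(variant.ALT) != 1:
            logger.warning("skipping multi-allelic site at %d", pos)
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            logger.warning("skipping non-SNP site at %d", pos)
            continue
        mq = variant.INFO.get("MQ")
        mq = int(round(float(mq))) if mq is not None else 0
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            alleles = tuple(int(a) for a in g[:-1])  # last item is phasing flag
            if alleles in _GT_MAP:
                col[i] = _GT_MAP[alleles]
            elif any(a == -1 for a in alleles) or len(set(alleles)) > 1:
                col[i] = MISSING
            else:
                raise FormatError(
                    f"malformed genotype {alleles} for sample "
                    f"{sample_ids[i]} at position {pos}"
                )
        rows.append((pos, ref, alt, mq))
        call_cols.append(col)

    if rows:
        order = np.argsort([r[0] for r in rows], kind="stable")
        positions = [rows[i][0] for i in order]
        if len(set(positions)) != len(positions):
            raise FormatError("duplicate positions in VCF")
        sites = pd.DataFrame.from_records(
            [rows[i] for i in order], columns=["pos", "ref", "alt", "mq"]
        )
        calls = np.stack([call_cols[i] for i in order], axis=1)
    else:
        sites = pd.DataFrame(columns=["pos", "ref", "alt", "mq"])
        calls = np.empty((len(sample_ids), 0), dtype=np.int8)
    return HaploidCallMatrix(sample_ids=sample_ids, sites=sites, calls=calls)


def write_vcf(matrix: HaploidCallMatrix, path: str | Path, contig: str = "chrY") -> None:
    """Write a plain-text haploid VCF v4.2 (GT 0/1/., INFO MQ)."""
    sym = {REF: "0", ALT: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Integer,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        sites = matrix.sites
        for j in range(matrix.n_sites):
            gts = "\t".join(sym[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{contig}\t{sites['pos'].iat[j]}\t.\t{sites['ref'].iat[j]}\t"
                f"{sites['alt'].iat[j]}\t.\tPASS\tMQ={int(sites['mq'].iat[j])}\tGT\t{gts}\n"
            )


def load_bed(path: str | Path) -> RegionMap:
    """Load a BED file of sequence classes (start, end 0-based half-open, name col 4)."""
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"BED line {line_no}: need >= 4 columns")
            intervals.append((int(parts[1]), int(parts[2]), parts[3]))
    return RegionMap(intervals)


def write_bed(region_map: RegionMap, path: str | Path, contig: str = "chrY") -> None:
    with open(path, "w") as fh:
        for s, e, c in region_map.intervals:
            fh.write(f"{contig}\t{s}\t{e}\t{c}\t0\t+\n")


def annotate_regions(matrix: HaploidCallMatrix, region_map: RegionMap) -> HaploidCallMatrix:
    """Assign each site its sequence class by interval lookup (else 'unassigned')."""
    classes = region_map.class_of(matrix.positions)
    sites = matrix.sites.assign(region_class=classes)
    return HaploidCallMatrix(matrix.sample_ids, sites, matrix.calls)


_NULL_PARENTS = {"", ".", "-", "NA", "none", "None"}


def load_marker_table(path: str | Path) -> HaplogroupTree:
    """Load the 6-column marker TSV into a :class:`HaplogroupTree`.

    The root may appear explicitly (parent "." or empty) or implicitly as
    the single parent name never listed as a haplogroup itself.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment=None,
        dtype=str,
        keep_default_na=False,
    )
    return marker_table_to_tree(df)


def marker_table_to_tree(df: pd.DataFrame) -> HaplogroupTree:
    """Build a :class:`HaplogroupTree` from an in-memory marker table."""
    df = df.astype(str)
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"haplogroup", "parent", "marker", "position", "ancestral", "derived"}
    if not required <= set(df.columns):
        raise FormatError(f"marker table needs columns {sorted(required)}")

    parent_of: dict[str, str | None] = {}
    markers: dict[str, list[Marker]] = {}
    seen_markers: set[str] = set()
    for row in df.itertuples(index=False):
        hg = row.haplogroup
        parent = None if row.parent in _NULL_PARENTS else row.parent
        if hg in parent_of and parent_of[hg] != parent:
            raise FormatError(
                f"haplogroup {hg!r} listed with two parents "
                f"({parent_of[hg]!r} and {parent!r})"
            )
        parent_of[hg] = parent
        if row.marker:
            if row.marker in seen_markers:
                raise FormatError(f"duplicate marker name {row.marker!r}")
            seen_markers.add(row.marker)
            markers.setdefault(hg, []).append(
                Marker(row.marker, int(row.position), row.ancestral, row.derived)
            )
    # implicit root: parent names never defined as haplogroups
    implicit = {p for p in parent_of.values() if p is not None and p not in parent_of}
    explicit_roots = [h for h, p in parent_of.items() if p is None]
    if len(implicit) + len(explicit_roots) != 1:
        raise FormatError(
            f"marker table must define exactly one root, found "
            f"{sorted(implicit) + explicit_roots}"
        )
    for name in implicit:
        parent_of[name] = None
    return HaplogroupTree.from_edges(parent_of, markers)


def write_marker_table(marker_df_or_tree, path: str | Path) -> None:
    """Write the marker table from a DataFrame or a :class:`HaplogroupTree`."""
    if isinstance(marker_df_or_tree, HaplogroupTree):
        rows = []
        for node in marker_df_or_tree.preorder():
            parent = node.parent.name if node.parent else "."
            if node.markers:
                for m in node.markers:
                    rows.append((node.name, parent, m.name, m.position, m.ancestral, m.derived))
            elif node.parent is not None:
                rows.append((node.name, parent, "", 0, "A", "C"))
        # marker-less nodes get a placeholder row (empty marker name) so the
        # tree structure survives the round trip; the loader ignores the
        # placeholder's position/allele fields
        df = pd.DataFrame(
            rows,
            columns=["haplogroup", "parent", "marker", "position", "ancestral", "derived"],
        )
    else:
        df = marker_df_or_tree.copy()
    df = df.rename(columns={df.columns[0]: "#" + df.columns[0].lstrip("#")})
    df.to_csv(path, sep="\t", index=False)


def load_outgroup(path: str | Path) -> OutgroupTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    if not {"position", "allele"} <= set(df.columns):
        raise FormatError("outgroup table needs columns position, allele")
    return OutgroupTable({int(p): a for p, a in zip(df["position"], df["allele"])})


def write_outgroup(outgroup: OutgroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#position\tallele\n")
        for pos in sorted(dict(outgroup.items())):
            fh.write(f"{pos}\t{outgroup.get(pos)}\n")


def write_newick(network, path: str | Path | None = None) -> str:
    """Serialise a haplotype network as Newick (labels = node ids,
    branch lengths = SNP counts on the edge above each node)."""
    text = network.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_summary(summary, path: str | Path) -> None:
    """Write a RegionSummary table as a commented TSV."""
    df = summary.table.copy()
    df = df.rename(columns={df.columns[0]: "#" + str(df.columns[0])})
    df.to_csv(path, sep="\t", index=False)
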