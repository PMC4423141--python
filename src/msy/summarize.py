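"""Per-sequence-class accounting of classified variants.

Produces the canonical cross-tabulation of MSY resequencing studies: for
each phylogenetic status (informative / singleton / discarded), the SNP
count, the percentage of that status's total, and the density in SNPs per
10 kbp of each sequence class, with the Ampliconic class reported both
whole and split into its palindromic and non-palindromic sub-regions, and
an X-degenerate versus non-X-degenerate contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .core import RegionMap

STATUSES = ("informative", "singleton", "discarded")

#: approximate published sizes of the MSY sequence classes (bp); the exact
#: mask behind any given study is unpublished, so these are defaults the
#: caller should override with a real RegionMap when available.
DEFAULT_CLASS_LENGTHS = {
    "X-degenerate": 8_600_000,
    "X-transposed": 3_400_000,
    "Ampliconic-nonpalindromic": 2_800_000,
    "Ampliconic-palindromic": 6_900_000,
    "Other": 400_000,
    "Heterochromatic": 1_000_000,
}

_BASE_CLASSES = (
    "X-degenerate",
    "X-transposed",
    "Ampliconic-nonpalindromic",
    "Ampliconic-palindromic",
    "Other",
    "Heterochromatic",
)


def _round(x: float, nd: int) -> float:
    """Round half away from zero (matches hand-tabulated tables)."""
    q = Decimal(1).scaleb(-nd)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RegionSummary:
    """Counts, percentages and densities per (status, sequence class)."""

    counts: dict[str, dict[str, int]]  # status -> base class -> count
    class_lengths: dict[str, int]
    table: pd.DataFrame

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, dict[str, int]],
        class_lengths: dict[str, int] | None = None,
    ) -> "RegionSummary":
        lengths = dict(class_lengths or DEFAULT_CLASS_LENGTHS)
        counts = {s: dict(counts.get(s, {})) for s in STATUSES}

        extra_classes = sorted(
            {c for by_class in counts.values() for c in by_class}
            - set(_BASE_CLASSES)
        )
        base = list(_BASE_CLASSES) + extra_classes

        def agg_len(classes) -> int:
            return sum(lengths.get(c, 0) for c in classes)

        rows = []
        # the "all" block pools the three statuses: shares of everything retained
        blocks = list(STATUSES) + ["all"]
        grand_total = sum(sum(counts[s].values()) for s in STATUSES)
        for status in blocks:
            if status == "all":
                by_class = {
                    c: sum(counts[s].get(c, 0) for s in STATUSES) for c in base
                }
            else:
                by_class = {c: counts[status].get(c, 0) for c in base}
            total = sum(by_class.values())
            denom = total if status != "all" else grand_total

            def row(label: str, classes: list[str]) -> dict:
                n = sum(by_class.get(c, 0) for c in classes)
                length = agg_len(classes)
                pct = _round(100.0 * n / denom, 1) if denom else 0.0
                dens = _round(n / (length / 10_000.0), 2) if length else None
                return {
                    "status": status,
                    "class": label,
                    "n_snps": n,
                    "pct": pct,
                    "snps_per_10kbp": dens,
                }

            non_xdeg = [c for c in base if c != "X-degenerate"]
            rows.append(row("X-degenerate", ["X-degenerate"]))
            rows.append(row("non X-degenerate", non_xdeg))
            rows.append(row("X-transposed", ["X-transposed"]))
            rows.append(
                row("Ampliconic", ["Ampliconic-nonpalindromic", "Ampliconic-palindromic"])
            )
            rows.append(row("Ampliconic-nonpalindromic", ["Ampliconic-nonpalindromic"]))
            rows.append(row("Ampliconic-palindromic", ["Ampliconic-palindromic"]))
            rows.append(row("Other", ["Other"]))
            rows.append(row("Heterochromatic", ["Heterochromatic"]))
            for c in extra_classes:
                rows.append(row(c, [c]))
            rows.append(row("Total", base))
        table = pd.DataFrame(rows)
        return cls(counts=counts, class_lengths=lengths, table=table)

    def get(self, status: str, class_label: str, column: str = "n_snps"):
        t = self.table
        sel = t[(t["status"] == status) & (t["class"] == class_label)]
        if len(sel) != 1:
            raise KeyError((status, class_label))
        return sel[column].iloc[0]

    def status_total(self, status: str) -> int:
        return int(self.get(status, "Total"))


def summarize(
    classified: pd.DataFrame, region_map: RegionMap | dict[str, int] | None = None
) -> RegionSummary:
    """Cross-tabulate a classified variant table by status and class."""
    lengths = None
    if isinstance(region_map, RegionMap):
        lengths = region_map.class_lengths
    elif isinstance(region_map, dict):
        lengths = region_map
    counts: dict[str, dict[str, int]] = {s: {} for s in STATUSES}
    if len(classified):
        tab = classified.groupby(["status", "region_class"]).size()
        for (status, cls_name), n in tab.items():
            if status in counts:
                counts[status][cls_name] = int(n)
    return RegionSummary.from_counts(counts, lengths)


def report_identities(
    summary: RegionSummary,
    report=None,
    expected_total: int | None = None,
    expected_candidate_pool: int | None = None,
) -> dict[str, dict]:
    """Check the report-level accounting identities.

    Identities: (1) informative + singleton + discarded equals the stated
    polymorphic total; (2) informative + discarded equals the stated
    candidate pool; (3) per-class counts sum across statuses to the pooled
    block; (4) per-status class counts sum to the status total.  Failures
    are reported, never raised.
    """
    if report is not None:
        expected_total = report.total_polymorphic
        expected_candidate_pool = report.candidate_pool
    totals = {s: summary.status_total(s) for s in STATUSES}
    out: dict[str, dict] = {}

    def record(name: str, lhs, rhs) -> None:
        out[name] = {"pass": lhs == rhs, "lhs": lhs, "rhs": rhs}

    three_way = totals["informative"] + totals["singleton"] + totals["discarded"]
    if expected_total is not None:
        record("three_way_total", three_way, expected_total)
    if expected_candidate_pool is not None:
        record(
            "candidate_pool",
            totals["informative"] + totals["discarded"],
            expected_candidate_pool,
        )
    pooled_ok = all(
        sum(summary.counts[s].get(c, 0) for s in STATUSES)
        == summary.get("all", c)
        for c in _BASE_CLASSES
    )
    record("per_class_pooled_sums", pooled_ok, True)
    status_ok = all(
        sum(summary.counts[s].values()) == totals[s] for s in STATUSES
    )
    record("per_status_class_sums", status_ok, True)
    return out
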