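"""Shared fixtures: a hand-checkable 6-sample toy dataset and session-scoped
simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from msy.core import (
    ALT,
    MISSING,
    REF,
    HaploidCallMatrix,
    HaplogroupTree,
    Marker,
    OutgroupTable,
)
from msy.model import YPhylogenyModel
from msy.simdata import SimConfig, simulate
from msy import formats

TOY_SAMPLES = ["S1", "S2", "S3", "S4", "S5", "S6"]

# toy haplogroup layout: A={S1}, BT={S2..S6}, E={S2,S3}, I={S4,S5,S6},
# I2={S5,S6}; each haplogroup has one defining marker at a fixed position
TOY_CLADES = {
    "A": {"S1"},
    "BT": {"S2", "S3", "S4", "S5", "S6"},
    "E": {"S2", "S3"},
    "I": {"S4", "S5", "S6"},
    "I2": {"S5", "S6"},
}
TOY_MARKER_POS = {"A": 100, "BT": 200, "E": 300, "I": 400, "I2": 500}


def make_toy_tree(extra_markers: dict[str, list[Marker]] | None = None) -> HaplogroupTree:
    parent_of = {"Y-Adam": None, "A": "Y-Adam", "BT": "Y-Adam", "E": "BT",
                 "I": "BT", "I2": "I"}
    markers = {
        hg: [Marker(f"M_{hg}", pos, "A", "G")] for hg, pos in TOY_MARKER_POS.items()
    }
    for hg, ms in (extra_markers or {}).items():
        markers.setdefault(hg, []).extend(ms)
    return HaplogroupTree.from_edges(parent_of, markers)


def make_toy_matrix(
    extra_sites: list[tuple[int, set[str]]] | None = None,
    missing: list[tuple[int, set[str]]] | None = None,
    mq: dict[int, int] | None = None,
) -> HaploidCallMatrix:
    """Marker sites (carriers = toy clades) plus ``extra_sites``:
    (position, derived carrier set); ``missing`` marks (position, samples)
    as uncalled.  All sites are A->G with the reference ancestral."""
    sites = [(pos, TOY_CLADES[hg]) for hg, pos in TOY_MARKER_POS.items()]
    sites += list(extra_sites or [])
    sites.sort()
    miss = dict(missing or [])
    rows, cols = [], []
    for pos, carriers in sites:
        col = np.array(
            [ALT if s in carriers else REF for s in TOY_SAMPLES], dtype=np.int8
        )
        for s in miss.get(pos, ()):
            col[TOY_SAMPLES.index(s)] = MISSING
        rows.append((pos, "A", "G", (mq or {}).get(pos, 60)))
        cols.append(col)
    return HaploidCallMatrix(
        sample_ids=list(TOY_SAMPLES),
        sites=pd.DataFrame(rows, columns=["pos", "ref", "alt", "mq"]),
        calls=np.stack(cols, axis=1),
    )


def toy_outgroup(matrix: HaploidCallMatrix, overrides: dict[int, str] | None = None) -> OutgroupTable:
    """Outgroup = ancestral (REF) allele everywhere unless overridden."""
    alleles = {int(p): r for p, r in zip(matrix.sites["pos"], matrix.sites["ref"])}
    alleles.update(overrides or {})
    return OutgroupTable(alleles)


@pytest.fixture
def toy_tree():
    return make_toy_tree()


@pytest.fixture
def toy_matrix():
    return make_toy_matrix()


# --- session-scoped simulated datasets -----------------------------------

CLEAN_CONFIG = SimConfig(
    seed=2024,
    missing_rate=0.0,
    recurrent_fraction=0.0,
    singleton_fraction=0.0,
    outgroup_third_allele_rate=0.0,
    low_mq_fraction=0.0,
)


def fit_sim(result):
    tree = formats.marker_table_to_tree(result.marker_table)
    model = YPhylogenyModel(result.matrix, tree, result.outgroup, result.region_map)
    return model.fit()


def truth_merge(fit, result) -> pd.DataFrame:
    """Classified table joined with ground truth on position."""
    truth = result.truth.sites[
        ["pos", "status", "branch", "n_carriers", "is_marker", "outgroup_is_third"]
    ].rename(columns={"status": "true_status", "n_carriers": "true_n_carriers"})
    return fit.classified.merge(truth, on="pos", validate="1:1")


@pytest.fixture(scope="session")
def clean_sim():
    """No error processes: the parameter-recovery regime."""
    return simulate(CLEAN_CONFIG)


@pytest.fixture(scope="session")
def clean_fit(clean_sim):
    return fit_sim(clean_sim)


@pytest.fixture(scope="session")
def default_sim():
    """All error processes at their default (study-condition) rates."""
    return simulate(SimConfig(seed=777))


@pytest.fixture(scope="session")
def default_fit(default_sim):
    return fit_sim(default_sim)
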