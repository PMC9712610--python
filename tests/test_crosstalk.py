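"""Tissue->cell crosstalk: ligand specificity, pathway activation,
network assembly."""

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from macatlas.core_io import (
    GeneSetCollection,
    LRPairs,
    RegulonTable,
    ValidationError,
    population_means,
)
from macatlas.crosstalk import (
    build_crosstalk_network,
    cell_specific_tfs,
    hypergeom_upper_tail,
    pathway_activation,
    tissue_specific_ligands,
)

from conftest import make_design, make_matrix


# ---------------------------------------------------------------------------
# Tissue-specific ligands
# ---------------------------------------------------------------------------


def test_single_tissue_ligand_is_specific():
    tissues = [f"T{i}" for i in range(8)]
    means = pd.DataFrame(0.0, index=["L1"], columns=tissues)
    means.loc["L1", "T0"] = 7.0  # ratio v / (v/8) = 8 >= 1.5
    out = tissue_specific_ligands(means, ["L1"])
    assert out["T0"] == ["L1"]
    assert all(not out[t] for t in tissues[1:])


def test_uniform_ligand_specific_nowhere():
    tissues = [f"T{i}" for i in range(8)]
    means = pd.DataFrame(5.0, index=["L1"], columns=tissues)
    out = tissue_specific_ligands(means, ["L1"])
    assert all(not v for v in out.values())


def test_ligand_toy_hand_derived():
    tissues = [f"T{i}" for i in range(8)]
    rows = {
        "L_A": [8.0, 1, 1, 1, 1, 1, 1, 1],        # ratio 8/1.875 = 4.27 in T0
        "L_B": [2.0] * 8,                          # ratio 1 everywhere
        "L_C": [3.0, 3.0, 0, 0, 0, 0, 0, 0],       # ratio 4 in T0 and T1
        "L_D": [0, 0, 0, 0, 0, 0, 0, 1.2],         # only T7
        "L_E": [1.4, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # 1.32 < 1.5 nowhere
    }
    means = pd.DataFrame(rows, index=tissues).T
    out = tissue_specific_ligands(means, list(rows))
    assert out["T0"] == ["L_A", "L_C"]
    assert out["T1"] == ["L_C"]
    assert out["T7"] == ["L_D"]
    for t in ("T2", "T3", "T4", "T5", "T6"):
        assert out[t] == []


# ---------------------------------------------------------------------------
# Hypergeometric upper tail
# ---------------------------------------------------------------------------


def enumerate_upper_tail(k, K, n, N):
    """Oracle: exact sum of hypergeometric point masses."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def test_hypergeom_worked_example():
    assert hypergeom_upper_tail(3, 4, 3, 10) == pytest.approx(4 / 120)


def test_hypergeom_forced_outcomes():
    assert hypergeom_upper_tail(0, 4, 3, 10) == pytest.approx(1.0)
    assert hypergeom_upper_tail(5, 5, 5, 5) == pytest.approx(1.0)


def test_hypergeom_matches_enumeration_for_all_small_parameters():
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    got = hypergeom_upper_tail(k, K, n, N)
                    want = enumerate_upper_tail(k, K, n, N)
                    assert abs(got - want) < 1e-12, (k, K, n, N)


def test_hypergeom_rejects_inconsistent_counts():
    with pytest.raises(ValidationError):
        hypergeom_upper_tail(5, 4, 3, 10)
    with pytest.raises(ValidationError):
        hypergeom_upper_tail(1, 4, 11, 10)


# ---------------------------------------------------------------------------
# Pathway activation
# ---------------------------------------------------------------------------


def _activation_setup():
    universe = [f"G{i}" for i in range(30)] + ["REC1", "TF1"]
    detected = ["G0", "G1", "REC1", "TF1"]
    pathways = GeneSetCollection(sets={
        "ACTIVE": frozenset(["REC1", "TF1", "G0", "G1"]),
        "NO_TF": frozenset(["REC1", "G0", "G1"]),
        "NO_REC": frozenset(["TF1", "G0", "G1"]),
    })
    return pathways, universe, detected


def test_pathway_activation_gating_and_p():
    pathways, universe, detected = _activation_setup()
    table = pathway_activation(pathways, universe, detected,
                               specific_tfs=["TF1"], receptors_hit=["REC1"])
    # intermediates of ACTIVE = all 4 members (no ligand tier), all detected
    want_p = enumerate_upper_tail(4, 4, 4, 32)
    assert table.loc["ACTIVE", "p"] == pytest.approx(want_p)
    assert want_p < 0.05
    assert bool(table.loc["ACTIVE", "active"])
    assert not bool(table.loc["NO_TF", "active"])     # gating beats any p
    assert not bool(table.loc["NO_REC", "active"])


def test_pathway_without_usable_intermediates_skipped():
    pathways = GeneSetCollection(sets={"GHOST": frozenset(["X1", "X2"])})
    table = pathway_activation(pathways, universe=["A", "B"], detected=["A"],
                               specific_tfs=[], receptors_hit=[])
    assert "GHOST" not in table.index


def test_cell_specific_tf_rule():
    means = pd.DataFrame(
        {"P0": [30.0, 10.0], "P1": [10.0, 10.0], "P2": [10.0, 10.0]},
        index=["TFX", "TFY"])
    assert cell_specific_tfs(means, ["TFX", "TFY"], "P0") == ["TFX"]


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


def _toy_network(tf_is_specific=True):
    tissues = ["TA", "TB"]
    tissue_means = pd.DataFrame(
        {"TA": [10.0, 1.0], "TB": [1.0, 1.0]}, index=["LIG1", "LIG2"])
    pops = ["C0", "C1", "C2"]
    samples = [f"{p}_r{j}" for p in pops for j in (1, 2)]
    design = make_design(samples, [s.split("_r")[0] for s in samples])
    tf_vals = ([90.0, 90.0] + [10.0] * 4) if tf_is_specific else [30.0] * 6
    rows = {
        "REC1": [50.0] * 6,
        "TF1": tf_vals,
        "TG1": [40.0] * 6,
        "TG2": [40.0] * 6,
    }
    # a wide, mostly undetected background so that full detection of the
    # pathway's nodes is genuinely surprising (hypergeometric p < 0.05)
    for i in range(30):
        rows[f"OTHER{i}"] = [5.0] * 2 if i < 2 else [np.nan] * 2
        rows[f"OTHER{i}"] = rows[f"OTHER{i}"] + [5.0] * 4
    m = make_matrix({s: [rows[g][i] for g in rows] for i, s in enumerate(samples)},
                    list(rows))
    lr = LRPairs(pd.DataFrame({"ligand": ["LIG1"], "receptor": ["REC1"]}))
    pathways = GeneSetCollection(sets={
        "PW1": frozenset(["REC1", "TF1", "TG1", "TG2"])})
    regulons = RegulonTable({"TF1": frozenset(["TG1", "TG2"])})
    return tissue_means, m, design, lr, pathways, regulons


def test_toy_network_has_four_edges():
    tissue_means, m, design, lr, pathways, regulons = _toy_network()
    net = build_crosstalk_network(tissue_means, m, design, lr, pathways,
                                  regulons, tissue="TA", population="C0",
                                  tf_list=["TF1"])
    assert net.link_count == 4
    assert set(net.graph.nodes) == {"LIG1", "REC1", "TF1", "TG1", "TG2"}
    assert net.graph.has_edge("LIG1", "REC1")
    assert net.graph.has_edge("REC1", "TF1")
    assert net.graph.has_edge("TF1", "TG1")
    assert net.graph.has_edge("TF1", "TG2")


def test_toy_network_without_tf_specificity_keeps_one_edge():
    tissue_means, m, design, lr, pathways, regulons = _toy_network(
        tf_is_specific=False)
    net = build_crosstalk_network(tissue_means, m, design, lr, pathways,
                                  regulons, tissue="TA", population="C0",
                                  tf_list=["TF1"])
    assert net.link_count == 1
    assert list(net.graph.edges) == [("LIG1", "REC1")]


def test_no_specific_ligand_gives_empty_network():
    tissue_means, m, design, lr, pathways, regulons = _toy_network()
    net = build_crosstalk_network(tissue_means, m, design, lr, pathways,
                                  regulons, tissue="TB", population="C0",
                                  tf_list=["TF1"])
    assert net.link_count == 0


def test_every_edge_reachable_from_a_ligand():
    tissue_means, m, design, lr, pathways, regulons = _toy_network()
    net = build_crosstalk_network(tissue_means, m, design, lr, pathways,
                                  regulons, tissue="TA", population="C0",
                                  tf_list=["TF1"])
    reachable = set()
    for lig in net.ligands:
        reachable |= nx.descendants(net.graph, lig) | {lig}
    assert reachable == set(net.graph.nodes)


def test_link_count_invariant_to_input_row_order():
    tissue_means, m, design, lr, pathways, regulons = _toy_network()
    lr2 = LRPairs(lr.table.iloc[::-1].reset_index(drop=True))
    m2 = m.with_values(m.values.iloc[::-1])
    net1 = build_crosstalk_network(tissue_means, m, design, lr, pathways,
                                   regulons, tissue="TA", population="C0",
                                   tf_list=["TF1"])
    net2 = build_crosstalk_network(tissue_means.iloc[::-1], m2, design, lr2,
                                   pathways, regulons, tissue="TA",
                                   population="C0", tf_list=["TF1"])
    assert net1.link_count == net2.link_count
    assert set(net1.graph.edges) == set(net2.graph.edges)


# ---------------------------------------------------------------------------
# Fixture recovery
# ---------------------------------------------------------------------------


def test_fixture_active_pathways_and_link_separation(default_bundle,
                                                     default_copies):
    bundle = default_bundle
    tissue_means = population_means(bundle.tissue_matrix, bundle.tissue_design)
    ligands = tissue_specific_ligands(tissue_means, bundle.annotation.ligands)
    for tissue, planted in bundle.truth.tissue_ligands.items():
        assert set(ligands[tissue]) == set(planted)
    link_counts = {}
    for tissue, pop in (bundle.truth.resident_pairs
                        + bundle.truth.recruited_pairs):
        net = build_crosstalk_network(
            tissue_means, default_copies, bundle.design, bundle.lr_pairs,
            bundle.pathways, bundle.regulons, tissue=tissue, population=pop,
            tf_list=bundle.annotation.tfs)
        active = set(net.pathway_table.index[net.pathway_table["active"]])
        assert active == set(bundle.truth.active_pathways[(tissue, pop)])
        link_counts[(tissue, pop)] = net.link_count
    resident = [link_counts[p] for p in bundle.truth.resident_pairs]
    recruited = [link_counts[p] for p in bundle.truth.recruited_pairs]
    assert min(resident) > max(recruited)
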