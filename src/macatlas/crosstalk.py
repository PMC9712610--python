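"""Hierarchical tissue -> cell crosstalk network inference.

The network has four tiers: tissue-specific ligands, receptors
detected in the cell population, cell-type-specific TFs reached
through significantly activated pathways, and those TFs' regulon
targets detected in the cell.  Tier rules:

* a ligand is tissue-specific when its expression in the focal tissue
  is at least 1.5x the average over all studied tissues;
* a pathway is *active* for a (tissue, cell) pair when it contains a
  receptor paired to a specific ligand and detected in the cell,
  contains a cell-type-specific TF (1.5x-over-average rule), and its
  intermediate nodes are enriched among the cell's detected proteins
  (hypergeometric upper tail, raw p < alpha);
* edges: ligand->receptor for each detected pair, receptor->TF within
  each active pathway, TF->target for detected regulon targets of the
  wired TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    GeneSetCollection,
    LRPairs,
    RegulonTable,
    SampleDesign,
    ValidationError,
    logger,
    population_means,
)


# ---------------------------------------------------------------------------
# Tier rules
# ---------------------------------------------------------------------------


def tissue_specific_ligands(
    tissue_means: pd.DataFrame,
    ligand_list,
    fold: float = 1.5,
    leave_one_out: bool = False,
) -> dict[str, list[str]]:
    """Per-tissue specific ligand sets under the fold-over-average rule.

    ``tissue_means`` is a gene x tissue table of replicate means.  A
    ligand is specific to tissue t when its value there is at least
    ``fold`` times the arithmetic mean over all tissues (including t;
    ``leave_one_out`` excludes it).  Non-detections count as 0 in the
    average; ligands detected nowhere are skipped.
    """
    if tissue_means.shape[1] < 2:
        raise ValidationError("need >= 2 tissues")
    tissues = list(tissue_means.columns)
    out: dict[str, list[str]] = {t: [] for t in tissues}
    for lig in ligand_list:
        if lig not in tissue_means.index:
            continue
        row = tissue_means.loc[lig].fillna(0.0)
        if (row == 0).all():
            continue
        for t in tissues:
            ref = row.drop(t).mean() if leave_one_out else row.mean()
            if ref == 0:
                if row[t] > 0:
                    out[t].append(lig)
            elif row[t] >= fold * ref:
                out[t].append(lig)
    return out


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes,
    n draws)."""
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N and k >= 0):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cell_specific_tfs(
    cell_means: pd.DataFrame,
    tf_list,
    population: str,
    fold: float = 1.5,
) -> list[str]:
    """TFs passing the 1.5x-over-average rule in one population
    (average over all populations, non-detections as 0)."""
    if population not in cell_means.columns:
        raise ValidationError(f"population {population!r} absent")
    out = []
    for tf in tf_list:
        if tf not in cell_means.index:
            continue
        row = cell_means.loc[tf].fillna(0.0)
        ref = row.mean()
        if ref == 0:
            continue
        if row[population] >= fold * ref:
            out.append(tf)
    return out


def pathway_activation(
    pathways: GeneSetCollection,
    universe,
    detected,
    specific_tfs,
    receptors_hit,
    ligand_genes=frozenset(),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every pathway for activation in one (tissue, cell) pair.

    ``universe`` is the cell's quantified gene space (matrix rows),
    ``detected`` the genes detected in the focal population.
    Intermediate nodes are the pathway members minus the ligand tier;
    enrichment is the hypergeometric upper tail of detected
    intermediates against the detected fraction of the universe.
    A pathway is active iff it contains a hit receptor, contains a
    specific TF, and p < alpha.  Pathways with no intermediate in the
    universe are skipped.
    """
    universe = frozenset(universe)
    detected = frozenset(detected) & universe
    specific_tfs = frozenset(specific_tfs)
    receptors_hit = frozenset(receptors_hit)
    ligand_genes = frozenset(ligand_genes)
    N = len(universe)
    n = len(detected)
    rows = []
    for name, members in pathways.items():
        intermediates = (members - ligand_genes) & universe
        if not intermediates:
            logger.info("pathway %r has no intermediate in the universe; skipped",
                        name)
            continue
        K = len(intermediates)
        k = len(intermediates & detected)
        p = hypergeom_upper_tail(k, K, n, N)
        has_receptor = bool(members & receptors_hit)
        has_tf = bool(members & specific_tfs)
        rows.append((name, K, k, p, has_receptor, has_tf,
                     has_receptor and has_tf and p < alpha))
    table = pd.DataFrame(
        rows,
        columns=["pathway", "n_intermediates", "n_detected", "p",
                 "has_receptor", "has_specific_tf", "active"],
    ).set_index("pathway")
    return table


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


@dataclass
class CrosstalkNetwork:
    tissue: str
    population: str
    graph: nx.DiGraph = field(repr=False)
    ligands: list[str] = field(default_factory=list)
    receptors: list[str] = field(default_factory=list)
    tfs: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    pathway_table: pd.DataFrame | None = None

    @property
    def link_count(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "tier", "pathway"])


def detected_genes(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    population: str,
    min_replicates: int = 2,
) -> frozenset[str]:
    """Genes detected in >= min_replicates replicates of a population."""
    samples = [s for s in design.samples_for(population)
               if s in matrix.values.columns]
    if not samples:
        raise ValidationError(f"no samples for population {population!r}")
    counts = matrix.values[samples].notna().sum(axis=1)
    return frozenset(counts.index[counts >= min_replicates])


def build_crosstalk_network(
    tissue_means: pd.DataFrame,
    cell_matrix: ExpressionMatrix,
    cell_design: SampleDesign,
    lr_pairs: LRPairs,
    pathways: GeneSetCollection,
    regulons: RegulonTable,
    tissue: str,
    population: str,
    ligand_list=None,
    tf_list=None,
    ligand_fold: float = 1.5,
    tf_fold: float = 1.5,
    alpha: float = 0.05,
    min_replicates: int = 2,
) -> CrosstalkNetwork:
    """Assemble the four-tier crosstalk network for one (tissue, cell)
    pair.

    ``ligand_list`` defaults to the ligand genes of the LR table;
    ``tf_list`` defaults to all regulon TFs.  No specific ligands means
    an empty network, not an error.
    """
    ligand_list = list(ligand_list) if ligand_list is not None \
        else sorted(lr_pairs.ligand_genes)
    tf_list = list(tf_list) if tf_list is not None else sorted(regulons)

    graph = nx.DiGraph()
    spec_ligands = tissue_specific_ligands(
        tissue_means, ligand_list, fold=ligand_fold
    ).get(tissue, [])
    detected = detected_genes(cell_matrix, cell_design, population,
                              min_replicates=min_replicates)
    cell_means = population_means(cell_matrix, cell_design,
                                  min_detected=min_replicates)
    spec_tfs = cell_specific_tfs(cell_means, tf_list, population, fold=tf_fold)

    # tier 1: ligand -> detected receptor
    receptors_hit: set[str] = set()
    for lig in spec_ligands:
        for rec in lr_pairs.receptors_for(lig):
            if rec in detected:
                graph.add_edge(lig, rec, tier="ligand->receptor", pathway="")
                receptors_hit.add(rec)

    pathway_table = pathway_activation(
        pathways,
        universe=cell_matrix.values.index,
        detected=detected,
        specific_tfs=spec_tfs,
        receptors_hit=receptors_hit,
        ligand_genes=frozenset(ligand_list),
        alpha=alpha,
    )

    # tier 2: receptor -> specific TF within each active pathway
    wired_tfs: set[str] = set()
    for name, row in pathway_table[pathway_table["active"]].iterrows():
        members = pathways[name]
        for rec in sorted(receptors_hit & members):
            for tf in sorted(set(spec_tfs) & members):
                graph.add_edge(rec, tf, tier="receptor->tf", pathway=name)
                wired_tfs.add(tf)

    # tier 3: TF -> detected regulon target
    target_nodes: set[str] = set()
    for tf in sorted(wired_tfs):
        if tf not in regulons:
            continue
        for tg in sorted(regulons[tf]):
            if tg in detected:
                graph.add_edge(tf, tg, tier="tf->target", pathway="")
                target_nodes.add(tg)

    return CrosstalkNetwork(
        tissue=tissue,
        population=population,
        graph=graph,
        ligands=[l for l in spec_ligands if l in graph],
        receptors=sorted(receptors_hit),
        tfs=sorted(wired_tfs),
        targets=sorted(target_nodes),
        pathway_table=pathway_table,
    )
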