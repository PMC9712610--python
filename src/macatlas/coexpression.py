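"""Weighted co-expression module detection (WGCNA-style).

Pipeline: soft-threshold selection by scale-free topology fit, an
unsigned adjacency ``a_ij = |cor_ij|^beta``, topological-overlap
similarity, average-linkage hierarchical clustering on ``1 - TOM``
with a static cut, module eigengenes (first principal component), and
module-trait statistics with gene-significance (GS) and
module-membership (MM) filtering.

Numerical contract: expression enters as log10 copies; gene-gene
correlations are Pearson on pairwise-complete observations, genes
present in fewer than 25% of samples are excluded from the network,
and pairs sharing fewer than ``MIN_COMMON_SAMPLES`` samples get
correlation 0 (too little evidence to support a power-12 adjacency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import ExpressionMatrix, SampleDesign, ValidationError, logger

#: Floor on shared detected samples for a pairwise-complete correlation;
#: the network additionally requires half the sample count (chance
#: correlations on tiny overlaps explode under a power-12 adjacency).
MIN_COMMON_SAMPLES = 8

#: Minimum fraction of samples in which a gene must be detected.
MIN_DETECTION_FRACTION = 0.25


def _log10_frame(matrix: ExpressionMatrix) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        return np.log10(matrix.values)


def _network_correlation(matrix: ExpressionMatrix, genes) -> np.ndarray:
    """Pairwise-complete correlation matrix for the network, requiring
    support on at least half of the samples."""
    min_common = max(MIN_COMMON_SAMPLES, len(matrix.sample_ids) // 2)
    return pairwise_pearson(_log10_frame(matrix).loc[genes],
                            min_common=min_common)


def network_genes(matrix: ExpressionMatrix) -> pd.Index:
    """Genes eligible for the network: detected in >= 25% of samples
    and non-constant."""
    vals = matrix.values
    frac = vals.notna().mean(axis=1)
    keep = frac >= MIN_DETECTION_FRACTION
    # constant rows carry no correlation signal
    spread = vals.max(axis=1, skipna=True) - vals.min(axis=1, skipna=True)
    constant = keep & (spread == 0)
    if constant.any():
        logger.warning("dropping %d constant gene rows from the network",
                       int(constant.sum()))
        keep &= ~constant
    return vals.index[keep]


def pairwise_pearson(frame: pd.DataFrame,
                     min_common: int = MIN_COMMON_SAMPLES) -> np.ndarray:
    """Gene x gene Pearson correlation on pairwise-complete observations.

    Vectorized via masked cross-products; entries supported by fewer
    than ``min_common`` shared samples, or with zero variance on the
    common support, are set to 0.
    """
    x = frame.to_numpy(dtype=float)
    mask = np.isfinite(x)
    a = np.where(mask, x, 0.0)
    m = mask.astype(float)
    n = m @ m.T
    sx = a @ m.T
    sy = sx.T
    sxy = a @ a.T
    sxx = (a * a) @ m.T
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r = cov / np.sqrt(varx * vary)
    bad = (n < min_common) | ~np.isfinite(r)
    r[bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Soft threshold
# ---------------------------------------------------------------------------


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame      # power, scale_free_r2, mean_connectivity
    power: int               # chosen beta
    reached_target: bool


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k (negative-slope convention)."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    lx = np.log10(centers[keep])
    ly = np.log10(counts[keep] / counts.sum())
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2


def pick_soft_threshold(
    matrix: ExpressionMatrix,
    candidates: list[int] | None = None,
    target_r2: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scan candidate powers and report the scale-free topology fit.

    The chosen power is the smallest candidate whose signed R^2 reaches
    ``target_r2``; if none does, the argmax with a logged warning.
    """
    candidates = list(candidates) if candidates is not None else list(range(1, 21))
    if not candidates:
        raise ValidationError("no candidate powers supplied")
    genes = network_genes(matrix)
    if len(genes) < 50 or len(matrix.sample_ids) < 8:
        raise ValidationError("soft-threshold scan needs >= 50 genes and >= 8 samples")
    cor = np.abs(_network_correlation(matrix, genes))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in candidates:
        adj = cor ** beta
        k = adj.sum(axis=1)
        rows.append((beta, _scale_free_fit(k, n_bins=n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "scale_free_r2", "mean_connectivity"])
    reached = table["scale_free_r2"] >= target_r2
    if reached.any():
        power = int(table.loc[reached.idxmax(), "power"])
        ok = True
    else:
        power = int(table.loc[table["scale_free_r2"].idxmax(), "power"])
        ok = False
        logger.warning(
            "no candidate power reaches scale-free R^2 %.2f; best is %d (R^2=%.3f)",
            target_r2, power, float(table["scale_free_r2"].max()),
        )
    return SoftThresholdReport(table=table, power=power, reached_target=ok)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap t_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), with t_ii = 1 by convention."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (min_k + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleAssignment:
    labels: pd.Series                 # gene -> module id (0 = unassigned)
    linkage_matrix: np.ndarray = field(repr=False)
    cut_height: float = float("nan")
    power: int = 0

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


def detect_modules(
    matrix: ExpressionMatrix,
    power: int,
    min_module_size: int = 30,
    cut_quantile: float = 0.995,
) -> ModuleAssignment:
    """Detect co-expression modules.

    Adjacency ``|cor|^power`` -> TOM -> average-linkage clustering on
    ``1 - TOM`` -> static cut at ``cut_quantile`` times the tallest
    merge height; clusters below ``min_module_size`` fall into module 0.
    Module ids are assigned by decreasing size.  All genes of the input
    matrix receive a label (ineligible genes get 0).
    """
    genes = network_genes(matrix)
    labels = pd.Series(0, index=matrix.values.index, dtype=int, name="module")
    if len(genes) < min_module_size:
        return ModuleAssignment(labels=labels, linkage_matrix=np.empty((0, 4)),
                                power=power)
    cor = np.abs(_network_correlation(matrix, genes))
    adj = cor ** power
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    cut = float(cut_quantile * z[:, 2].max())
    raw = fcluster(z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes.index[sizes >= min_module_size]
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels.loc[genes] = [remap.get(c, 0) for c in raw]
    return ModuleAssignment(labels=labels, linkage_matrix=z, cut_height=cut,
                            power=power)


# ---------------------------------------------------------------------------
# Eigengenes and module-trait statistics
# ---------------------------------------------------------------------------


def _standardized_expression(matrix: ExpressionMatrix,
                             genes: list[str]) -> np.ndarray:
    """Row-standardized log10 expression with missing values imputed to
    the gene mean (i.e. zero after centering) — used only for the
    eigengene decomposition, never for testing."""
    block = _log10_frame(matrix).loc[genes].to_numpy(dtype=float)
    mean = np.nanmean(block, axis=1, keepdims=True)
    sd = np.nanstd(block, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zed = (block - mean) / sd
    return np.nan_to_num(zed, nan=0.0)


def module_eigengene(matrix: ExpressionMatrix,
                     assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component of each module's standardized
    expression, as a unit-norm vector over samples.

    The sign is chosen so the mean correlation with member genes is
    positive; a single-gene module's eigengene is that standardized
    gene (normalized).
    """
    samples = matrix.sample_ids
    out = {}
    for mid in assignment.module_ids:
        members = assignment.members(mid)
        zed = _standardized_expression(matrix, members)
        if zed.shape[0] == 1:
            v = zed[0]
            v = v / (np.linalg.norm(v) or 1.0)
        else:
            _, _, vt = np.linalg.svd(zed, full_matrices=False)
            v = vt[0]
        member_cor = np.array([np.corrcoef(row, v)[0, 1] for row in zed])
        if np.nanmean(member_cor) < 0:
            v = -v
        out[mid] = v
    eg = pd.DataFrame(out, index=pd.Index(samples, name="sample"))
    eg.columns.name = "module"
    return eg


@dataclass
class ModuleStats:
    module_trait_cor: pd.DataFrame    # module x population Pearson
    matched_population: dict[int, str]
    gene_stats: pd.DataFrame          # gene -> module, GS, MM
    filtered_genes: pd.DataFrame      # subset passing GS/MM cutoffs
    kept_modules: list[int]

    def filtered_for_population(self, population: str) -> list[str]:
        mods = [m for m, p in self.matched_population.items() if p == population]
        t = self.filtered_genes
        return list(t.index[t["module"].isin(mods)])


def _pairwise_cor(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def module_trait_stats(
    matrix: ExpressionMatrix,
    assignment: ModuleAssignment,
    design: SampleDesign,
    gs_min: float = 0.6,
    mm_min: float = 0.5,
    cor_min: float = 0.5,
) -> ModuleStats:
    """Module-trait correlation, GS and MM, and the filtered gene list.

    Traits are per-population indicator vectors over the matrix
    samples.  Each module is matched to the population maximizing the
    eigengene-trait Pearson correlation; modules below ``cor_min`` are
    dropped.  GS = |cor(gene, matched trait)| and MM = |cor(gene,
    eigengene)| on pairwise-complete log10 values; the filtered list
    keeps genes with GS >= gs_min and MM >= mm_min.
    """
    samples = matrix.sample_ids
    pops = design.populations
    traits = {}
    for pop in pops:
        ind = np.array(
            [1.0 if design.table.loc[s, "population"] == pop else 0.0
             for s in samples]
        )
        if np.ptp(ind) == 0:
            raise ValidationError(f"degenerate trait for population {pop!r}")
        traits[pop] = ind
    eigengenes = module_eigengene(matrix, assignment)
    mt = pd.DataFrame(
        {pop: {mid: _pairwise_cor(eigengenes[mid].to_numpy(), ind)
               for mid in assignment.module_ids}
         for pop, ind in traits.items()}
    )
    matched: dict[int, str] = {}
    kept: list[int] = []
    for mid in assignment.module_ids:
        row = mt.loc[mid]
        pop = row.idxmax()
        if row[pop] >= cor_min:
            matched[mid] = pop
            kept.append(mid)
    log_frame = _log10_frame(matrix)
    rows = {}
    for mid in kept:
        trait = traits[matched[mid]]
        ev = eigengenes[mid].to_numpy()
        for gene in assignment.members(mid):
            expr = log_frame.loc[gene].to_numpy(dtype=float)
            gs = abs(_pairwise_cor(expr, trait))
            mm = abs(_pairwise_cor(expr, ev))
            rows[gene] = (mid, gs, mm)
    gene_stats = pd.DataFrame.from_dict(
        rows, orient="index", columns=["module", "GS", "MM"]
    )
    gene_stats.index.name = "gene"
    passing = gene_stats[(gene_stats["GS"] >= gs_min) & (gene_stats["MM"] >= mm_min)]
    return ModuleStats(
        module_trait_cor=mt,
        matched_population=matched,
        gene_stats=gene_stats,
        filtered_genes=passing,
        kept_modules=kept,
    )
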