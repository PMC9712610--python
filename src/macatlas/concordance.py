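"""Proteome-transcriptome concordance.

Four views of how well the two layers agree:

* which genes are seen in one layer but never in the other
  (missing proteins / missing transcripts);
* a four-quadrant classification of those missing features by their
  mean expression and identification frequency in the *other* layer;
* the across-gene Spearman correlation between protein and mRNA copy
  numbers within one population;
* gene-wise Spearman correlations across populations, with an exact
  permutation p-value for small population counts, classified as
  positively / negatively significant or not.

The exact null matters here: with only ~12 populations the asymptotic
Spearman p-value is unreliable, and the operating threshold |r| > 0.57
at alpha = 0.05 is only meaningful against the exact permutation
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, ValidationError, logger

#: Largest n for which the exact Spearman permutation null is used.
EXACT_N_MAX = 12


# ---------------------------------------------------------------------------
# Exact Spearman permutation null
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def spearman_null_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of Spearman's D = sum of squared rank
    differences for untied data of size ``n``.

    Computed by dynamic programming over subsets of assigned ranks:
    state (set of used ranks, partial D) -> number of partial
    permutations.  Returns ``(d_values, probabilities)``; probabilities
    sum to 1 over all n! permutations.
    """
    if not 2 <= n <= EXACT_N_MAX:
        raise ValidationError(f"exact null supported for 2 <= n <= {EXACT_N_MAX}")
    max_d = n * (n * n - 1) // 3
    counts = np.zeros((1 << n, max_d + 1))
    counts[0, 0] = 1.0
    popcount = np.array([bin(m).count("1") for m in range(1 << n)])
    for mask in range(1 << n):
        row = counts[mask]
        if not row.any():
            continue
        i = popcount[mask]  # next position to fill (0-based)
        for j in range(n):
            if mask >> j & 1:
                continue
            d2 = (i - j) ** 2
            counts[mask | (1 << j), d2:] += row[: max_d + 1 - d2]
    total = counts[(1 << n) - 1]
    d_values = np.arange(max_d + 1)
    keep = total > 0
    probs = total[keep] / total[keep].sum()
    return d_values[keep], probs


def spearman_exact_pvalue(r: float, n: int) -> float:
    """Exact two-sided permutation p-value P(|rho_null| >= |r|) for
    untied data of size ``n``."""
    d, p = spearman_null_distribution(n)
    rho = 1.0 - 6.0 * d / (n * (n * n - 1))
    return float(p[np.abs(rho) >= abs(r) - 1e-12].sum())


def spearman_with_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman r with an exact permutation p for small untied samples.

    Falls back to the asymptotic p (scipy) when n > 12 or when either
    vector contains ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    if np.isnan(r):
        return r, float("nan")
    tied = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= EXACT_N_MAX and not tied:
        return r, spearman_exact_pvalue(r, n)
    return r, float(res.pvalue)


# ---------------------------------------------------------------------------
# Missing-feature detection and quadrant classification
# ---------------------------------------------------------------------------


def detect_missing_features(
    protein_matrix: ExpressionMatrix, rna_matrix: ExpressionMatrix
) -> tuple[frozenset[str], frozenset[str]]:
    """Genes detected in one layer and never in the other.

    A *missing protein* is a gene detected in at least one RNA sample
    but in zero protein samples; a *missing transcript* is the mirror
    case.  Genes absent from a layer's row index count as undetected
    there.
    """
    pg = set(protein_matrix.gene_ids)
    rg = set(rna_matrix.gene_ids)
    if not pg & rg:
        raise ValidationError("protein and RNA matrices share no genes")
    prot_det = protein_matrix.detected_mask().any(axis=1)
    rna_det = rna_matrix.detected_mask().any(axis=1)

    def detected(series: pd.Series, gene: str) -> bool:
        return bool(series.get(gene, False))

    missing_protein = frozenset(
        g for g in rg if detected(rna_det, g) and not detected(prot_det, g)
    )
    missing_transcript = frozenset(
        g for g in pg if detected(prot_det, g) and not detected(rna_det, g)
    )
    return missing_protein, missing_transcript


def quadrant_classify(
    gene_set,
    source_matrix: ExpressionMatrix,
    expr_cutoff: float | None = None,
    freq_cutoff: float | None = None,
) -> pd.DataFrame:
    """Classify genes into four regions by mean expression and
    identification frequency in ``source_matrix``.

    Per gene: mean of log10 present values and the count of samples
    where present.  Auto cutoffs are the median mean-expression over
    the gene set and half the number of samples.  Regions (expression
    axis / frequency axis): R1 high/high, R2 low/high, R3 low/low,
    R4 high/low; ties resolve as ">= cutoff is high".  Genes never
    detected have mean expression -inf (always "low").
    """
    genes = [g for g in gene_set if g in source_matrix.values.index]
    out = pd.DataFrame(columns=["mean_expression", "frequency", "region"])
    if not genes:
        return out
    block = source_matrix.values.loc[genes]
    freq = block.notna().sum(axis=1).astype(float)
    with np.errstate(divide="ignore"):
        log_block = np.log10(block)
    mean_expr = log_block.mean(axis=1, skipna=True)
    mean_expr = mean_expr.fillna(-np.inf)
    if expr_cutoff is None:
        expr_cutoff = float(mean_expr.replace(-np.inf, np.nan).median())
    if freq_cutoff is None:
        freq_cutoff = len(source_matrix.sample_ids) / 2.0
    high_expr = mean_expr >= expr_cutoff
    high_freq = freq >= freq_cutoff
    region = np.where(
        high_expr, np.where(high_freq, "R1", "R4"), np.where(high_freq, "R2", "R3")
    )
    return pd.DataFrame(
        {"mean_expression": mean_expr, "frequency": freq, "region": region},
        index=pd.Index(genes, name="gene"),
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def across_gene_correlation(
    protein_means: pd.DataFrame,
    rna_means: pd.DataFrame,
    population: str,
    min_genes: int = 10,
) -> tuple[float, float]:
    """Spearman correlation between log10 protein and mRNA copy means
    over genes co-present in one population.

    Inputs are gene x population replicate-mean tables (see
    :func:`macatlas.core_io.population_means`).
    """
    if population not in protein_means.columns or population not in rna_means.columns:
        raise ValidationError(f"population {population!r} absent from a mean table")
    shared = protein_means.index.intersection(rna_means.index)
    p = protein_means.loc[shared, population]
    r = rna_means.loc[shared, population]
    ok = p.notna() & r.notna() & (p > 0) & (r > 0)
    if int(ok.sum()) < min_genes:
        raise ValidationError(
            f"only {int(ok.sum())} co-present genes in {population!r}; "
            f"need >= {min_genes}"
        )
    res = stats.spearmanr(np.log10(p[ok]), np.log10(r[ok]))
    return float(res.statistic), float(res.pvalue)


@dataclass
class GeneCorrelationResult:
    table: pd.DataFrame          # gene -> r, p, class
    n_excluded: int


def genewise_correlation(
    protein_means: pd.DataFrame,
    rna_means: pd.DataFrame,
    r_threshold: float = 0.57,
    alpha: float = 0.05,
    min_populations: int = 5,
) -> GeneCorrelationResult:
    """Per-gene Spearman correlation between the two layers across
    populations, with class labels.

    A gene enters if its replicate-mean value is present in at least
    ``min_populations`` populations in both layers.  p-values use the
    exact permutation null for n <= 12 (untied), asymptotic otherwise.
    Classes: ``positive_significant`` / ``negative_significant`` when
    |r| > r_threshold and p < alpha, else ``ns``.  Degenerate genes
    (constant in a layer) are excluded and counted.
    """
    shared_genes = protein_means.index.intersection(rna_means.index)
    shared_pops = [c for c in protein_means.columns if c in rna_means.columns]
    rows = {}
    excluded = 0
    for gene in shared_genes:
        p = protein_means.loc[gene, shared_pops].astype(float)
        r = rna_means.loc[gene, shared_pops].astype(float)
        ok = p.notna() & r.notna()
        if int(ok.sum()) < min_populations:
            excluded += 1
            continue
        x, y = p[ok].to_numpy(), r[ok].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded += 1
            continue
        rho, pval = spearman_with_exact_p(np.log10(x), np.log10(y))
        if np.isnan(rho):
            excluded += 1
            continue
        if abs(rho) > r_threshold and pval < alpha:
            cls = "positive_significant" if rho > 0 else "negative_significant"
        else:
            cls = "ns"
        rows[gene] = (rho, pval, int(ok.sum()), cls)
    if excluded:
        logger.info("genewise_correlation: excluded %d genes below coverage "
                    "floor or degenerate", excluded)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["r", "p", "n_populations", "class"]
    )
    table.index.name = "gene"
    return GeneCorrelationResult(table=table, n_excluded=excluded)
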