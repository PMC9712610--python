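"""Differential expression, unsupervised clustering, PCA and gene-set
aggregate scores.

The DEP (differentially expressed protein) caller applies a dual rule:

1. genes quantified in both groups are called when the linear-mean
   fold change is >= ``fold`` (default 5) and a two-sided Student's
   t-test on log10 values gives p < ``alpha``;
2. genes quantifiable in only one group are called on a
   presence/absence rule: detected in *all* replicates of one group
   with a coefficient of variation <= ``cv_max`` and never detected in
   the other.

Clustering and PCA operate on ``log10(x + 1)`` with missing values set
to 0 — a completeness requirement of distance computations, used for
these two operations only and never for statistical testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .core_io import ExpressionMatrix, SampleDesign, ValidationError


# ---------------------------------------------------------------------------
# DEP caller
# ---------------------------------------------------------------------------


def call_deps(
    copies: ExpressionMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    fold: float = 5.0,
    alpha: float = 0.05,
    cv_max: float = 0.6,
) -> pd.DataFrame:
    """Call DEPs between two populations under the dual rule.

    Returns a table with group means, linear fold change (A over B),
    p-value, BH-adjusted q (reported for transparency, not used in the
    call), call reason (``fc_p`` or ``presence_cv``) and direction
    (``up`` = higher in A).  Swapping the groups flips directions and
    inverts fold changes but preserves the call set.
    """
    if group_a == group_b:
        raise ValidationError("groups must differ")
    sa = [s for s in design.samples_for(group_a) if s in copies.values.columns]
    sb = [s for s in design.samples_for(group_b) if s in copies.values.columns]
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("each group needs >= 2 replicates")
    va, vb = copies.values[sa], copies.values[sb]
    rows = []
    for gene in copies.values.index:
        a = va.loc[gene].dropna().to_numpy()
        b = vb.loc[gene].dropna().to_numpy()
        mean_a = a.mean() if a.size else np.nan
        mean_b = b.mean() if b.size else np.nan
        reason, direction, p, fc = None, None, np.nan, np.nan
        if a.size >= 2 and b.size >= 2:
            fc = mean_a / mean_b if mean_b > 0 else np.inf
            _, p = stats.ttest_ind(np.log10(a), np.log10(b), equal_var=True)
            if max(fc, 1.0 / fc) >= fold and p < alpha:
                reason = "fc_p"
                direction = "up" if fc >= 1 else "down"
        elif a.size == len(sa) and b.size == 0:
            cv = a.std(ddof=1) / a.mean() if a.mean() > 0 else np.inf
            if cv <= cv_max:
                reason, direction = "presence_cv", "up"
        elif b.size == len(sb) and a.size == 0:
            cv = b.std(ddof=1) / b.mean() if b.mean() > 0 else np.inf
            if cv <= cv_max:
                reason, direction = "presence_cv", "down"
        rows.append((gene, mean_a, mean_b, fc, p, reason, direction))
    table = pd.DataFrame(
        rows,
        columns=["gene", "mean_a", "mean_b", "fold_change", "p", "reason",
                 "direction"],
    ).set_index("gene")
    tested = table["p"].notna()
    q = pd.Series(np.nan, index=table.index)
    if tested.any():
        q[tested] = stats.false_discovery_control(table.loc[tested, "p"])
    table["q"] = q
    table["called"] = table["reason"].notna()
    return table


# ---------------------------------------------------------------------------
# Clustering and PCA
# ---------------------------------------------------------------------------


def _complete_log_frame(matrix: ExpressionMatrix) -> pd.DataFrame:
    return np.log10(matrix.values.fillna(0.0) + 1.0)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray = field(repr=False)
    labels: pd.Series | None
    items: list[str]
    distance_matrix: pd.DataFrame = field(repr=False)


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    metric: str = "euclidean",
    method: str = "complete",
    k: int | None = None,
    axis: str = "samples",
) -> ClusterResult:
    """Agglomerative clustering of samples (or genes) on log10(x+1)
    values with missing set to 0.

    Euclidean distance with complete linkage by default; ``k`` cuts the
    tree into flat clusters.
    """
    frame = _complete_log_frame(matrix)
    if axis == "samples":
        data = frame.T
    elif axis == "genes":
        data = frame
    else:
        raise ValidationError("axis must be 'samples' or 'genes'")
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 items to cluster")
    items = list(data.index)
    d = pdist(data.to_numpy(), metric=metric)
    z = linkage(d, method=method)
    labels = None
    if k is not None:
        labels = pd.Series(fcluster(z, t=k, criterion="maxclust"), index=items)
    dist = pd.DataFrame(squareform(d), index=items, columns=items)
    return ClusterResult(linkage_matrix=z, labels=labels, items=items,
                         distance_matrix=dist)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # sample x component
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(matrix: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of samples on gene-centered log10(x+1) values.

    Coordinates are orthogonal; explained variances are non-increasing
    and sum to the total variance across the retained components.
    """
    frame = _complete_log_frame(matrix)
    if frame.shape[1] < 3:
        raise ValidationError("PCA needs >= 3 samples")
    x = frame.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    if np.allclose(x, 0.0, atol=1e-12):
        raise ValidationError("constant matrix")
    n_samples = x.shape[1]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s ** 2 / (n_samples - 1)
    if n_components is not None:
        s, vt, var = s[:n_components], vt[:n_components], var[:n_components]
    coords = pd.DataFrame(
        (vt * s[:, None]).T,
        index=pd.Index(frame.columns, name="sample"),
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    total_var = float((x ** 2).sum() / (n_samples - 1))
    return PCAResult(
        coordinates=coords,
        explained_variance=var,
        explained_variance_ratio=var / total_var,
    )


# ---------------------------------------------------------------------------
# Gene-set aggregate scores
# ---------------------------------------------------------------------------


def geneset_score(copies: ExpressionMatrix, gene_set,
                  design: SampleDesign | None = None) -> pd.Series:
    """Per-sample total expression of a gene set: sum of copies over
    detected members (missing contribute 0)."""
    members = [g for g in gene_set if g in copies.values.index]
    if not members:
        raise ValidationError("no gene-set member is quantified in the matrix")
    return copies.values.loc[members].sum(axis=0, skipna=True)


def geneset_score_correlation(
    copies: ExpressionMatrix,
    set_a,
    set_b,
    design: SampleDesign,
    populations: list[str] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of two gene-set scores across population
    means (e.g. mobility receptors vs pattern-recognition receptors
    over paired resident/recruited populations)."""
    score_a = geneset_score(copies, set_a)
    score_b = geneset_score(copies, set_b)
    pops = populations if populations is not None else design.populations
    ma, mb = [], []
    for pop in pops:
        samples = [s for s in design.samples_for(pop)
                   if s in copies.values.columns]
        if not samples:
            raise ValidationError(f"no samples for population {pop!r}")
        ma.append(float(score_a[samples].mean()))
        mb.append(float(score_b[samples].mean()))
    if len(ma) < 3:
        raise ValidationError("need >= 3 populations for a correlation")
    r, p = stats.pearsonr(ma, mb)
    return float(r), float(p)
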