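"""Transcription-factor specificity and regulon-activity calling.

Three stages:

* **specific TFs** — a TF is specific to a population when its
  replicate-mean expression there is at least ``fold`` (default 5)
  times the median of its expression over the *other* populations
  (non-detections count as 0 in that median), optionally additionally
  required to sit in a cell-type module passing the GS/MM filter;
* **CSPS** — the cell-specificity score, the relative entropy (bits)
  of a gene's fractional expression across populations against the
  uniform null: ``CSPS = sum_j f_j log2(f_j / (1/P))``.  It is 0 for a
  uniformly expressed gene and ``log2 P`` for a one-population gene;
* **ctmTFs** — cell-type-maintenance TFs: specific TFs whose regulon's
  mean expression z-score in the focal population exceeds the maximum
  of ``B`` size-matched random draws from all quantified proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpression import ModuleStats
from .core_io import (
    ExpressionMatrix,
    RegulonTable,
    SampleDesign,
    ValidationError,
    logger,
    population_means,
)


# ---------------------------------------------------------------------------
# Specific TFs (5x rule)
# ---------------------------------------------------------------------------


def call_specific_tfs(
    copies: ExpressionMatrix,
    design: SampleDesign,
    tf_list,
    fold: float = 5.0,
    module_stats: ModuleStats | None = None,
    include_self: bool = False,
    min_replicates: int = 2,
) -> dict[str, list[str]]:
    """Per-population specific TF sets under the ``fold``-times-median rule.

    The focal mean requires detection in at least ``min_replicates``
    replicates.  The comparison median is taken over the *other*
    populations by default (``include_self=True`` medians over all).
    Non-detected populations contribute 0 to the median; a positive
    focal mean against an all-zero median passes for any fold, and a
    0-vs-0 comparison never passes.  With ``module_stats`` given, the
    TF must additionally be a GS/MM-filtered member of a module matched
    to the focal population.
    """
    means = population_means(copies, design, min_detected=min_replicates)
    pops = list(means.columns)
    out: dict[str, list[str]] = {p: [] for p in pops}
    missing = [tf for tf in tf_list if tf not in copies.values.index]
    if missing:
        logger.info("call_specific_tfs: %d TFs absent from the matrix", len(missing))
    for tf in tf_list:
        if tf not in means.index:
            continue
        row = means.loc[tf].fillna(0.0)
        for pop in pops:
            focal = row[pop]
            if not focal > 0:
                continue
            others = row if include_self else row.drop(pop)
            med = float(others.median())
            if med == 0 or focal >= fold * med:
                if module_stats is not None and tf not in set(
                    module_stats.filtered_for_population(pop)
                ):
                    continue
                out[pop].append(tf)
    return out


# ---------------------------------------------------------------------------
# CSPS
# ---------------------------------------------------------------------------


@dataclass
class CSPSResult:
    fractions: np.ndarray
    q: float
    value: float   # bits


def csps(expression_by_population) -> CSPSResult:
    """Cell-specificity score: relative entropy of fractional
    expression against the uniform distribution, in bits.

    ``0 * log 0`` is taken as 0; an all-zero vector is an error.  The
    score lies in ``[0, log2 P]`` and is 0 iff expression is uniform.
    """
    e = np.asarray(expression_by_population, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValidationError("need a 1-D vector over >= 2 populations")
    if (e < 0).any() or not np.isfinite(e).all():
        raise ValidationError("expression must be finite and non-negative")
    total = e.sum()
    if total == 0:
        raise ValidationError("all-zero expression vector")
    f = e / total
    q = 1.0 / len(e)
    nz = f > 0
    value = float((f[nz] * np.log2(f[nz] / q)).sum())
    # relative entropy is >= 0; residues below 1e-12 bits are rounding
    # noise (a uniform vector must score exactly 0)
    if abs(value) < 1e-12:
        value = 0.0
    return CSPSResult(fractions=f, q=q, value=max(0.0, value))


# ---------------------------------------------------------------------------
# ctmTFs (permutation-null regulon activity)
# ---------------------------------------------------------------------------


@dataclass
class CtmTFCall:
    tf: str
    population: str
    observed: float          # mean z of detected regulon targets
    null_max: float
    null_scores: np.ndarray
    called: bool
    empirical_p: float
    n_targets: int
    B: int
    seed: int


def _population_zscores(copies: ExpressionMatrix,
                        design: SampleDesign) -> pd.DataFrame:
    """Gene x population z-scores of log10 replicate-mean copies.

    Populations where a gene is undetected enter as 0 copies
    (log10(x + 1) transform); genes with zero variance across
    populations are dropped.
    """
    means = population_means(copies, design, min_detected=1).fillna(0.0)
    x = np.log10(means + 1.0)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    z = x[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z


def call_ctmtfs(
    specific_tfs: dict[str, list[str]],
    regulons: RegulonTable,
    copies: ExpressionMatrix,
    design: SampleDesign,
    B: int = 1000,
    seed: int | None = None,
    min_regulon: int = 3,
) -> list[CtmTFCall]:
    """Permutation-null regulon-activity test for every specific TF.

    For TF t specific in population c: the observed statistic is the
    mean population z-score (log10 copies) of its detected targets in
    c; the null is ``B`` draws of equally many genes, uniformly without
    replacement from all quantified proteins, scored identically.  A
    ctmTF call requires the observed score to exceed the null maximum.
    The empirical p ``(1 + #{null >= obs}) / (B + 1)`` is also
    reported.  Deterministic given (seed, B).
    """
    if seed is None:
        raise ValidationError("a seed is mandatory for the permutation null")
    if B < 1:
        raise ValidationError("B must be >= 1")
    z = _population_zscores(copies, design)
    n_genes = len(z.index)
    position = {g: i for i, g in enumerate(z.index)}
    rng = np.random.default_rng(seed)
    calls: list[CtmTFCall] = []
    for pop, tfs in specific_tfs.items():
        if pop not in z.columns:
            continue
        zc = z[pop].to_numpy()
        for tf in tfs:
            if tf not in regulons:
                logger.info("ctmTF: no regulon for %s; skipped", tf)
                continue
            targets = sorted(g for g in regulons[tf] if g in position)
            if len(targets) < min_regulon:
                logger.info("ctmTF: regulon of %s has %d scored targets "
                            "(min %d); skipped", tf, len(targets), min_regulon)
                continue
            observed = float(zc[[position[g] for g in targets]].mean())
            m = len(targets)
            null = np.empty(B)
            for b in range(B):
                null[b] = float(zc[rng.choice(n_genes, size=m,
                                              replace=False)].mean())
            null_max = float(null.max())
            called = observed > null_max
            p_emp = float((1 + (null >= observed).sum()) / (B + 1))
            calls.append(CtmTFCall(
                tf=tf, population=pop, observed=observed, null_max=null_max,
                null_scores=null, called=called, empirical_p=p_emp,
                n_targets=m, B=B, seed=seed,
            ))
    return calls
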