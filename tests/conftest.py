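"""Shared fixtures: synthetic atlases at the benchmark conditions.

Session-scoped so the expensive bundles are generated once and shared
between unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from macatlas.core_io import ExpressionMatrix, SampleDesign
from macatlas.quantify import RulerParams, proteomic_ruler
from macatlas.synthetic import AtlasConfig, generate_atlas


@pytest.fixture(scope="session")
def default_bundle():
    """The benchmark atlas: 12 populations x 3 replicates, 2000 genes,
    8 planted modules, replicate noise sigma(ln)=0.2."""
    return generate_atlas(AtlasConfig(seed=1))


@pytest.fixture(scope="session")
def default_copies(default_bundle):
    """Protein copies per cell estimated by the ruler on the benchmark
    atlas (iBAQ signal, mole-proportional)."""
    cfg = default_bundle.config
    return proteomic_ruler(
        default_bundle.protein_ibaq,
        default_bundle.annotation,
        RulerParams(dna_mass_per_cell=cfg.dna_mass_per_cell),
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Noise-free, fully detected atlas for invertibility checks."""
    cfg = AtlasConfig(
        seed=1,
        noise_cv=0.0,
        mrna_scatter_sigma=0.0,
        protein_detection_midpoint=None,
        rna_detection_midpoint=None,
    )
    return generate_atlas(cfg)


@pytest.fixture(scope="session")
def complete_bundle():
    """Benchmark noise levels but complete detection (for distance-based
    operations that zero-fill missing values)."""
    cfg = AtlasConfig(seed=1, protein_detection_midpoint=None,
                      rna_detection_midpoint=None)
    return generate_atlas(cfg)


@pytest.fixture
def small_config():
    """A miniature but complete atlas configuration."""
    return AtlasConfig(
        seed=3, n_genes=200, n_populations=4, n_modules=2,
        genes_per_module=30, n_tissues=2, ligands_per_tissue=2,
        pathway_intermediates=10, n_decoy_pathways=1, regulon_size=10,
    )


def make_matrix(values: dict[str, list[float]], genes: list[str],
                unit: str = "copies_per_cell") -> ExpressionMatrix:
    """Small helper: build a matrix from {sample: column} lists."""
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), dtype=float),
        unit=unit,
    )


def make_design(samples: list[str], populations: list[str],
                layer: str = "protein") -> SampleDesign:
    reps: dict[str, int] = {}
    rows = []
    for s, p in zip(samples, populations):
        reps[p] = reps.get(p, 0) + 1
        rows.append((p, reps[p], layer, pd.NA))
    return SampleDesign(pd.DataFrame(
        rows, index=pd.Index(samples, name="sample"),
        columns=["population", "replicate", "layer", "tissue"],
    ))
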