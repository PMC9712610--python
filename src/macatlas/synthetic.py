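"""Synthetic paired proteome/transcriptome atlas with planted ground truth.

The generator emulates the statistical shape of a multi-population
cell atlas so that every downstream stage (rulers, concordance,
co-expression modules, TF specificity / regulon activity, tissue
crosstalk, differential expression) can be exercised against a known
answer without any external download:

* protein copies per cell span ~7 orders of magnitude, transcript
  copies ~5, with a mean protein/mRNA copy ratio of ~8000;
* histone genes carry a configured total mass (default: exactly the
  DNA mass per cell), making the histone-anchored ruler invertible;
* ribosomal-protein genes share one fixed copy number (1:1 ribosome
  stoichiometry), anchoring the RNA ruler;
* planted co-expression modules are multiplicatively up-shifted in one
  home population each; planted specific TFs exceed the 5x rule in
  their population and their regulon genes are co-up-shifted;
* tissues carry tissue-specific ligands and planted active pathways
  linking ligand -> receptor -> TF -> targets for "resident-like"
  tissue/population pairs;
* each replicate value is truth times lognormal noise, observed with a
  logistic detection probability in log10 abundance, independently per
  replicate — so identification frequency has non-trivial structure.

Everything is driven by a single integer seed; the same config and
seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneSetCollection,
    LRPairs,
    RegulonTable,
    SampleDesign,
    ValidationError,
    write_annotation,
    write_design,
    write_expression_matrix,
    write_gmt,
    write_lr_pairs,
    write_regulons,
)

LN10 = float(np.log(10.0))


@dataclass
class AtlasConfig:
    """Study conditions for the synthetic atlas.

    Defaults reproduce the benchmark conditions used throughout the
    test-suite: 12 populations x 3 replicates, 2000 genes, 8 planted
    modules, lognormal replicate noise with sigma(ln) = 0.2, protein
    copies over 7 decades, transcripts over 5, and a mean protein/mRNA
    copy ratio of 8000.
    """

    n_populations: int = 12
    n_replicates: int = 3
    n_genes: int = 2000

    n_modules: int = 8
    genes_per_module: int = 100
    module_fold: float = 8.0

    n_specific_tfs: int = 2          # per moduled population
    regulon_size: int = 20
    tf_fold: float = 8.0
    n_decoy_tfs: int = 4             # uniformly expressed TFs, random regulons

    protein_log10_min: float = 2.0
    protein_log10_max: float = 9.0
    rna_log10_span: float = 5.0
    protein_mrna_ratio: float = 8000.0
    mrna_scatter_sigma: float = 0.35  # log10 gene-wise scatter around the ratio

    noise_cv: float = 0.2             # sigma of ln(replicate/truth)
    intensity_scale_sigma: float = 0.2  # log10 per-sample MS scale scatter

    # logistic detection curves in log10 abundance; midpoint None = complete
    protein_detection_midpoint: float | None = 4.5
    protein_detection_slope: float = 3.0
    rna_detection_midpoint: float | None = -0.4
    rna_detection_slope: float = 3.0

    n_histones: int = 10
    histone_mass_vs_dna: float = 1.0  # total histone mass as fraction of DNA mass
    dna_mass_per_cell: float = 5.5e-12
    n_ribosomal: int = 30
    ribosome_count: float = 3.0e6

    n_tissues: int = 8
    ligands_per_tissue: int = 3
    ligand_fold: float = 8.0
    pathways_per_resident_pair: int = 2
    pathway_intermediates: int = 25
    n_decoy_pathways: int = 5

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_populations": self.n_populations,
            "n_replicates": self.n_replicates,
            "n_genes": self.n_genes,
            "n_modules": self.n_modules,
            "genes_per_module": self.genes_per_module,
            "n_histones": self.n_histones,
            "n_ribosomal": self.n_ribosomal,
            "n_tissues": self.n_tissues,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.n_modules > self.n_populations:
            raise ValidationError("n_modules cannot exceed n_populations")
        if self.n_planted_genes > self.n_genes:
            raise ValidationError(
                f"config demands {self.n_planted_genes} planted genes but "
                f"n_genes is only {self.n_genes}"
            )
        if self.regulon_size - 1 > self.genes_per_module:
            raise ValidationError("regulon_size exceeds genes_per_module + TF")
        if self.pathway_intermediates > self.genes_per_module:
            raise ValidationError("pathway_intermediates exceeds genes_per_module")

    @property
    def n_planted_genes(self) -> int:
        n_tf = self.n_modules * self.n_specific_tfs + self.n_decoy_tfs
        n_lr = 2 * self.n_tissues * self.ligands_per_tissue
        return (
            self.n_histones + self.n_ribosomal + n_tf + n_lr
            + self.n_modules * self.genes_per_module
            # decoy pathways draw from background; keep some room
            + self.n_decoy_pathways * (self.pathway_intermediates + 2)
        )

    @classmethod
    def from_yaml(cls, path) -> "AtlasConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Planted truth of a generated atlas (population level, noiseless)."""

    protein_copies: pd.DataFrame        # gene x population
    mrna_copies: pd.DataFrame           # gene x population
    module_membership: pd.Series        # gene -> module id (0 = none)
    module_home_population: dict[int, str]
    specific_tfs: dict[str, list[str]]  # population -> planted specific TFs
    ctm_tfs: dict[str, list[str]]       # population -> planted ctmTFs
    tf_home: dict[str, str]
    tissue_ligands: dict[str, list[str]]
    active_pathways: dict[tuple[str, str], list[str]]  # (tissue, pop) -> names
    resident_pairs: list[tuple[str, str]]
    recruited_pairs: list[tuple[str, str]]
    dna_mass_per_cell: float
    ribosome_count: float


@dataclass
class AtlasBundle:
    """Everything :func:`generate_atlas` produces."""

    protein_intensity: ExpressionMatrix
    protein_ibaq: ExpressionMatrix
    rna_fpkm: ExpressionMatrix
    design: SampleDesign
    annotation: GeneAnnotation
    regulons: RegulonTable
    pathways: GeneSetCollection
    lr_pairs: LRPairs
    tissue_matrix: ExpressionMatrix
    tissue_design: SampleDesign
    truth: GroundTruth
    config: AtlasConfig

    def rna_to_protein_sample(self) -> dict[str, str]:
        """Map each RNA sample to its replicate-matched protein sample."""
        t = self.design.table
        prot = {
            (row.population, row.replicate): sid
            for sid, row in t[t["layer"] == "protein"].iterrows()
        }
        return {
            sid: prot[(row.population, row.replicate)]
            for sid, row in t[t["layer"] == "rna"].iterrows()
        }


def _detection_mask(rng, log10_vals: np.ndarray, midpoint: float | None,
                    slope: float) -> np.ndarray:
    """Bernoulli observation mask from a logistic curve in log10 abundance."""
    if midpoint is None:
        return np.ones_like(log10_vals, dtype=bool)
    p = expit(slope * (log10_vals - midpoint))
    return rng.random(log10_vals.shape) < p


def generate_atlas(config: AtlasConfig | None = None) -> AtlasBundle:
    """Generate the full paired atlas with planted ground truth."""
    cfg = config or AtlasConfig()
    rng = np.random.default_rng(cfg.seed)

    pops = [f"POP{i:02d}" for i in range(cfg.n_populations)]
    tissues = [f"TIS{i:02d}" for i in range(cfg.n_tissues)]

    # ---- gene universe -----------------------------------------------------
    histones = [f"HIST{i:02d}" for i in range(cfg.n_histones)]
    ribos = [f"RPL{i:02d}" for i in range(cfg.n_ribosomal)]
    tf_names = [
        f"TF{m:02d}_{k}" for m in range(cfg.n_modules) for k in range(cfg.n_specific_tfs)
    ]
    decoy_tfs = [f"TFD{i:02d}" for i in range(cfg.n_decoy_tfs)]
    ligands = [f"LIG{i:03d}" for i in range(cfg.n_tissues * cfg.ligands_per_tissue)]
    receptors = [f"REC{i:03d}" for i in range(len(ligands))]
    module_genes = [
        [f"MG{m:02d}_{g:03d}" for g in range(cfg.genes_per_module)]
        for m in range(cfg.n_modules)
    ]
    special = (
        histones + ribos + tf_names + decoy_tfs + ligands + receptors
        + [g for mod in module_genes for g in mod]
    )
    n_background = cfg.n_genes - len(special)
    background = [f"BG{i:04d}" for i in range(n_background)]
    genes = special + background
    gene_index = pd.Index(genes, name="gene")

    # ---- annotation --------------------------------------------------------
    mw = pd.Series(10 ** rng.normal(4.65, 0.2, size=len(genes)), index=gene_index)
    mw[histones] = rng.uniform(11_000, 22_000, size=len(histones))
    pep = np.maximum(1, np.round(mw / 3000.0)).astype(int)
    ann = pd.DataFrame(
        {
            "molecular_weight": mw,
            "theoretical_peptide_count": pep,
            "is_histone": [g in set(histones) for g in genes],
            "is_ribosomal_protein": [g in set(ribos) for g in genes],
            "is_tf": [g in set(tf_names) | set(decoy_tfs) for g in genes],
            "is_ligand": [g in set(ligands) for g in genes],
            "is_receptor": [g in set(receptors) for g in genes],
        },
        index=gene_index,
    )
    annotation = GeneAnnotation(ann)

    # ---- baseline log10 protein copies ------------------------------------
    lo, hi = cfg.protein_log10_min, cfg.protein_log10_max
    center = (lo + hi) / 2.0
    base = pd.Series(rng.uniform(lo, hi, size=len(genes)), index=gene_index)
    # planted entities sit in the well-detected mid-range, symmetric about
    # the dynamic-range center so the layer-wise copy ratio is unbiased
    planted_mid = [g for mod in module_genes for g in mod] + tf_names + decoy_tfs \
        + ligands + receptors
    base[planted_mid] = rng.uniform(center - 0.75, center + 0.75,
                                    size=len(planted_mid))
    # histone copies satisfy the configured total-mass constraint exactly
    w = rng.uniform(0.5, 1.5, size=len(histones))
    target_mass = cfg.histone_mass_vs_dna * cfg.dna_mass_per_cell
    from .quantify import AVOGADRO

    hist_copies = target_mass * AVOGADRO * w / float((w * mw[histones].values).sum())
    base[histones] = np.log10(hist_copies)
    base[ribos] = np.log10(cfg.ribosome_count)

    # ---- population-level truth (log10) ------------------------------------
    truth_log = pd.DataFrame(
        np.tile(base.values[:, None], (1, cfg.n_populations)),
        index=gene_index, columns=pops,
    )
    module_membership = pd.Series(0, index=gene_index, dtype=int)
    module_home: dict[int, str] = {}
    specific_tfs: dict[str, list[str]] = {p: [] for p in pops}
    tf_home: dict[str, str] = {}
    shift = np.log10(cfg.module_fold)
    tf_shift = np.log10(cfg.tf_fold)
    for m in range(cfg.n_modules):
        home = pops[m]
        module_home[m + 1] = home
        members = module_genes[m]
        truth_log.loc[members, home] += shift
        module_membership[members] = m + 1
        for k in range(cfg.n_specific_tfs):
            tf = f"TF{m:02d}_{k}"
            truth_log.loc[tf, home] += tf_shift
            specific_tfs[home].append(tf)
            tf_home[tf] = home
            module_membership[tf] = m + 1  # the TF shares its module's profile

    protein_truth = 10.0 ** truth_log

    # ---- mRNA truth: compressed dynamic range, fixed mean copy ratio -------
    slope_rna = cfg.rna_log10_span / (hi - lo)
    scatter = pd.Series(
        rng.normal(0.0, cfg.mrna_scatter_sigma, size=len(genes)), index=gene_index
    )
    mrna_log = (
        (truth_log - center) * slope_rna + center
        - np.log10(cfg.protein_mrna_ratio)
    ).add(scatter, axis=0)
    mrna_truth = 10.0 ** mrna_log

    # ---- regulons ----------------------------------------------------------
    regulons: dict[str, frozenset[str]] = {}
    for m in range(cfg.n_modules):
        for k in range(cfg.n_specific_tfs):
            tf = f"TF{m:02d}_{k}"
            targets = rng.choice(module_genes[m], size=cfg.regulon_size - 1,
                                 replace=False)
            regulons[tf] = frozenset(targets)
    for tf in decoy_tfs:
        regulons[tf] = frozenset(
            rng.choice(background, size=cfg.regulon_size, replace=False)
        )
    regulon_table = RegulonTable(regulons)

    # ---- cell-layer replicate matrices -------------------------------------
    sigma10 = cfg.noise_cv / LN10
    design_rows = []
    prot_cols: dict[str, np.ndarray] = {}
    rna_cols: dict[str, np.ndarray] = {}
    for pop in pops:
        for r in range(1, cfg.n_replicates + 1):
            psid, rsid = f"{pop}_prot_r{r}", f"{pop}_rna_r{r}"
            design_rows.append((psid, pop, r, "protein", pd.NA))
            design_rows.append((rsid, pop, r, "rna", pd.NA))
            pvals = protein_truth[pop].values * 10 ** rng.normal(
                0.0, sigma10, size=len(genes))
            pmask = _detection_mask(rng, np.log10(pvals),
                                    cfg.protein_detection_midpoint,
                                    cfg.protein_detection_slope)
            prot_cols[psid] = np.where(pmask, pvals, np.nan)
            rvals = mrna_truth[pop].values * 10 ** rng.normal(
                0.0, sigma10, size=len(genes))
            rmask = _detection_mask(rng, np.log10(rvals),
                                    cfg.rna_detection_midpoint,
                                    cfg.rna_detection_slope)
            rna_cols[rsid] = np.where(rmask, rvals, np.nan)

    design = SampleDesign(
        pd.DataFrame(
            [r[1:] for r in design_rows],
            index=pd.Index([r[0] for r in design_rows], name="sample"),
            columns=["population", "replicate", "layer", "tissue"],
        )
    )
    prot_copies_obs = pd.DataFrame(prot_cols, index=gene_index)

    # intensity = copies x MW x per-sample global scale; iBAQ = intensity/pep
    scales = 10 ** rng.normal(0.0, cfg.intensity_scale_sigma,
                              size=len(prot_copies_obs.columns))
    intensity = prot_copies_obs.mul(mw, axis=0) * scales
    protein_intensity = ExpressionMatrix(intensity, unit="intensity")
    protein_ibaq = ExpressionMatrix(intensity.div(pd.Series(pep, index=gene_index),
                                                  axis=0), unit="ibaq")

    rna_obs = pd.DataFrame(rna_cols, index=gene_index)
    fpkm = rna_obs.div(rna_obs.sum(axis=0, skipna=True), axis=1) * 1e6
    rna_fpkm = ExpressionMatrix(fpkm, unit="fpkm")

    # ---- tissue layer -------------------------------------------------------
    tissue_truth_log = pd.DataFrame(
        np.tile(base.values[:, None], (1, cfg.n_tissues)),
        index=gene_index, columns=tissues,
    )
    tissue_ligands: dict[str, list[str]] = {}
    lig_shift = np.log10(cfg.ligand_fold)
    for i, tis in enumerate(tissues):
        mine = ligands[i * cfg.ligands_per_tissue:(i + 1) * cfg.ligands_per_tissue]
        tissue_truth_log.loc[mine, tis] += lig_shift
        tissue_ligands[tis] = mine
    tissue_truth = 10.0 ** tissue_truth_log

    tis_rows, tis_cols = [], {}
    for tis in tissues:
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{tis}_t_r{r}"
            tis_rows.append((sid, tis, r, "protein", tis))
            vals = tissue_truth[tis].values * 10 ** rng.normal(
                0.0, sigma10, size=len(genes))
            mask = _detection_mask(rng, np.log10(vals),
                                   cfg.protein_detection_midpoint,
                                   cfg.protein_detection_slope)
            tis_cols[sid] = np.where(mask, vals, np.nan)
    tissue_obs = pd.DataFrame(tis_cols, index=gene_index)
    tissue_fot = tissue_obs.div(tissue_obs.sum(axis=0, skipna=True), axis=1) * 1e7
    tissue_matrix = ExpressionMatrix(tissue_fot, unit="fot")
    tissue_design = SampleDesign(
        pd.DataFrame(
            [r[1:] for r in tis_rows],
            index=pd.Index([r[0] for r in tis_rows], name="sample"),
            columns=["population", "replicate", "layer", "tissue"],
        )
    )

    # ---- ligand-receptor pairs and pathways ---------------------------------
    lr = LRPairs(pd.DataFrame(
        {"ligand": ligands, "receptor": receptors, "source": "synthetic"}
    ))
    receptor_of = dict(zip(ligands, receptors))

    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    active: dict[tuple[str, str], list[str]] = {}
    resident_pairs: list[tuple[str, str]] = []
    recruited_pairs: list[tuple[str, str]] = []
    n_resident = min(cfg.n_tissues, cfg.n_modules)
    for i in range(n_resident):
        tis, pop = tissues[i], pops[i]
        resident_pairs.append((tis, pop))
        names = []
        for j in range(cfg.pathways_per_resident_pair):
            lig = tissue_ligands[tis][j % cfg.ligands_per_tissue]
            tf = specific_tfs[pop][j % max(1, cfg.n_specific_tfs)]
            inter = rng.choice(module_genes[i], size=cfg.pathway_intermediates,
                               replace=False)
            name = f"PW_{tis}_{pop}_{j}"
            sets[name] = frozenset([receptor_of[lig], tf, *inter])
            descriptions[name] = f"planted active pathway {tis}->{pop}"
            names.append(name)
        active[(tis, pop)] = names
    # populations without a module act as "recruited" partners of the
    # first tissues: no specific TFs, hence no active pathways
    for i, pop in enumerate(pops[cfg.n_modules:]):
        tis = tissues[i % cfg.n_tissues]
        recruited_pairs.append((tis, pop))
        active[(tis, pop)] = []
    for k in range(cfg.n_decoy_pathways):
        members = rng.choice(background, size=cfg.pathway_intermediates + 2,
                             replace=False)
        name = f"PW_decoy_{k}"
        sets[name] = frozenset(members)
        descriptions[name] = "decoy pathway without specific TF"
    pathways = GeneSetCollection(sets=sets, descriptions=descriptions)

    truth = GroundTruth(
        protein_copies=protein_truth,
        mrna_copies=mrna_truth,
        module_membership=module_membership,
        module_home_population=module_home,
        specific_tfs=specific_tfs,
        ctm_tfs={p: list(tfs) for p, tfs in specific_tfs.items()},
        tf_home=tf_home,
        tissue_ligands=tissue_ligands,
        active_pathways=active,
        resident_pairs=resident_pairs,
        recruited_pairs=recruited_pairs,
        dna_mass_per_cell=cfg.dna_mass_per_cell,
        ribosome_count=cfg.ribosome_count,
    )
    return AtlasBundle(
        protein_intensity=protein_intensity,
        protein_ibaq=protein_ibaq,
        rna_fpkm=rna_fpkm,
        design=design,
        annotation=annotation,
        regulons=regulon_table,
        pathways=pathways,
        lr_pairs=lr,
        tissue_matrix=tissue_matrix,
        tissue_design=tissue_design,
        truth=truth,
        config=cfg,
    )


def write_fixture(bundle: AtlasBundle, directory: str | Path,
                  force: bool = False) -> list[Path]:
    """Serialize a generated bundle as TSV/GMT files plus a manifest."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ValidationError(
            f"directory {directory} is not empty; pass force=True to overwrite"
        )
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(fn, obj, name):
        path = directory / name
        fn(obj, path)
        written.append(path)

    _w(write_expression_matrix, bundle.protein_intensity, "protein_intensity.tsv")
    _w(write_expression_matrix, bundle.protein_ibaq, "protein_ibaq.tsv")
    _w(write_expression_matrix, bundle.rna_fpkm, "rna_fpkm.tsv")
    _w(write_expression_matrix, bundle.tissue_matrix, "tissue_fot.tsv")
    _w(write_design, bundle.design, "design.tsv")
    _w(write_design, bundle.tissue_design, "tissue_design.tsv")
    _w(write_annotation, bundle.annotation, "annotation.tsv")
    _w(write_regulons, bundle.regulons, "regulons.tsv")
    _w(write_gmt, bundle.pathways, "pathways.gmt")
    _w(write_lr_pairs, bundle.lr_pairs, "lr_pairs.tsv")

    tp = bundle.truth.protein_copies.copy()
    tp.index.name = "gene"
    tp.to_csv(directory / "truth_protein_copies.tsv", sep="\t",
              float_format="%.17g")
    written.append(directory / "truth_protein_copies.tsv")
    tm = bundle.truth.mrna_copies.copy()
    tm.index.name = "gene"
    tm.to_csv(directory / "truth_mrna_copies.tsv", sep="\t", float_format="%.17g")
    written.append(directory / "truth_mrna_copies.tsv")

    meta = {
        "seed": bundle.config.seed,
        "config_hash": bundle.config.digest(),
        "config": dataclasses.asdict(bundle.config),
        "module_membership": bundle.truth.module_membership.to_dict(),
        "module_home_population": {
            str(k): v for k, v in bundle.truth.module_home_population.items()
        },
        "specific_tfs": bundle.truth.specific_tfs,
        "ctm_tfs": bundle.truth.ctm_tfs,
        "tissue_ligands": bundle.truth.tissue_ligands,
        "active_pathways": {
            f"{t}|{p}": v for (t, p), v in bundle.truth.active_pathways.items()
        },
        "resident_pairs": bundle.truth.resident_pairs,
        "recruited_pairs": bundle.truth.recruited_pairs,
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    written.append(directory / "manifest.json")
    return written
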