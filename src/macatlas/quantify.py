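"""Absolute quantification: iBAQ, FOT and the protein/mRNA copy-number rulers.

The protein ruler anchors arbitrary-scale MS signal to absolute copies
per cell through the assumption that the total mass of histones in a
cell approximately equals the total mass of its DNA.  Given a per-cell
DNA mass ``m_DNA`` and a signal ``s_i`` per protein, the estimate is

* mass-proportional signal (raw intensity):
  ``mass_i = m_DNA * s_i / sum_h s_h`` over histones ``h``, and
  ``copies_i = mass_i * N_A / MW_i``;
* mole-proportional signal (iBAQ):
  ``copies_i = m_DNA * N_A * s_i / sum_h (s_h * MW_h)``.

Both are invariant to a per-sample global rescaling of the signal,
which is what makes the ruler usable on label-free MS runs.

The RNA ruler chains off the protein ruler: ribosomal-protein copies
give the ribosome count (1:1 protein:rRNA stoichiometry per ribosome),
rRNA is a fixed fraction of total RNA mass, mRNA is a fixed mass
fraction with a mean molar mass, and FPKM (molar-proportional) then
distributes the resulting mRNA molecule count over genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneAnnotation, ValidationError, logger

AVOGADRO = 6.02214076e23

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class RulerParams:
    """Constants for the copy-number rulers.

    dna_mass_per_cell
        Grams of DNA per cell; default 5.5e-12 g for a diploid mouse
        genome.
    signal_kind
        ``mole_proportional`` for iBAQ-like signals (the default),
        ``mass_proportional`` for raw intensity.
    rrna_mass_per_ribosome
        Molar mass (g/mol) of the rRNA content of one ribosome.
    rrna_fraction_of_total_rna
        rRNA share of total cellular RNA mass (~0.80).
    mrna_mass_fraction_of_total_rna
        mRNA share of total cellular RNA mass.
    mean_mrna_molar_mass
        Average molar mass of an mRNA molecule (g/mol); default
        340 g/mol per nucleotide x 1800 nt.
    """

    dna_mass_per_cell: float = 5.5e-12
    avogadro: float = AVOGADRO
    signal_kind: str = "mole_proportional"
    rrna_mass_per_ribosome: float = 2.2e6
    rrna_fraction_of_total_rna: float = 0.80
    mrna_mass_fraction_of_total_rna: float = 0.04
    mean_mrna_molar_mass: float = 340.0 * 1800.0

    def __post_init__(self) -> None:
        if self.signal_kind not in ("mass_proportional", "mole_proportional"):
            raise ValidationError(f"unknown signal_kind {self.signal_kind!r}")
        for name in ("dna_mass_per_cell", "avogadro", "rrna_mass_per_ribosome",
                     "mean_mrna_molar_mass"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("rrna_fraction_of_total_rna", "mrna_mass_fraction_of_total_rna"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RulerParams":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def count_theoretical_peptides(sequence: str) -> int:
    """Count fully tryptic peptides of length 7-30 in a protein sequence.

    Trypsin cleaves C-terminal to K or R but not when the next residue
    is P (Keil rule); zero missed cleavages.  Only the standard 20
    amino-acid letters are accepted.
    """
    if not sequence:
        raise ValidationError("empty protein sequence")
    seq = sequence.upper()
    for pos, letter in enumerate(seq):
        if letter not in _AA:
            raise ValidationError(
                f"non-standard amino acid {letter!r} at position {pos + 1}"
            )
    count = 0
    start = 0
    for i, aa in enumerate(seq):
        cleave_here = (
            aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P")
        )
        if cleave_here or i + 1 == len(seq):
            if 7 <= i + 1 - start <= 30:
                count += 1
            start = i + 1
    return count


def count_theoretical_peptides_many(sequences: Mapping[str, str]) -> pd.Series:
    """Vector version: id -> theoretical peptide count."""
    return pd.Series(
        {name: count_theoretical_peptides(seq) for name, seq in sequences.items()},
        dtype=int,
    )


def compute_ibaq(
    intensity_matrix: ExpressionMatrix, annotation: GeneAnnotation
) -> ExpressionMatrix:
    """iBAQ = intensity / theoretical peptide count, elementwise.

    Every quantified gene (>= 1 present value) must carry a positive
    peptide count; offenders are listed in the error.
    """
    intensity_matrix.require_unit("intensity")
    vals = intensity_matrix.values
    counts = annotation.table["theoretical_peptide_count"].reindex(vals.index)
    quantified = vals.notna().any(axis=1)
    bad = sorted(vals.index[quantified & ~(counts > 0)])
    if bad:
        raise ValidationError(
            f"theoretical peptide count missing or zero for quantified genes: {bad}"
        )
    ibaq = vals.div(counts, axis=0)
    return ExpressionMatrix(values=ibaq, unit="ibaq")


def compute_fot(ibaq_matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fraction of total: per sample, iBAQ / sum(present iBAQ) * 1e7."""
    ibaq_matrix.require_unit("ibaq")
    vals = ibaq_matrix.values
    totals = vals.sum(axis=0, skipna=True)
    empty = sorted(totals.index[vals.notna().sum(axis=0) == 0])
    if empty:
        raise ValidationError(f"all-missing sample columns: {empty}")
    fot = vals.div(totals, axis=1) * 1e7
    return ExpressionMatrix(values=fot, unit="fot")


def proteomic_ruler(
    signal_matrix: ExpressionMatrix,
    annotation: GeneAnnotation,
    params: RulerParams | None = None,
) -> ExpressionMatrix:
    """Histone-anchored protein copies per cell from MS signal.

    Requires at least one detected histone per sample and a molecular
    weight for every quantified gene.  Missing values stay missing.
    """
    params = params or RulerParams()
    signal_matrix.require_unit("intensity", "ibaq")
    vals = signal_matrix.values
    mw = annotation.table["molecular_weight"].reindex(vals.index)
    quantified = vals.notna().any(axis=1)
    no_mw = sorted(vals.index[quantified & mw.isna()])
    if no_mw:
        raise ValidationError(f"molecular weight missing for quantified genes: {no_mw}")
    histones = [h for h in annotation.histones if h in vals.index]
    if not histones:
        raise ValidationError("no histone gene present in the matrix")

    m_dna = params.dna_mass_per_cell
    n_a = params.avogadro
    out = {}
    for sample in vals.columns:
        col = vals[sample]
        hist = col.reindex(histones).dropna()
        if hist.empty:
            raise ValidationError(f"no detected histone in sample {sample!r}")
        if params.signal_kind == "mass_proportional":
            mass = m_dna * col / hist.sum()
            copies = mass * n_a / mw
        else:  # mole_proportional: weight histone signal by MW
            denom = float((hist * mw.reindex(hist.index)).sum())
            copies = m_dna * n_a * col / denom
        out[sample] = copies
    return ExpressionMatrix(values=pd.DataFrame(out), unit="copies_per_cell")


def rna_ruler(
    fpkm_matrix: ExpressionMatrix,
    protein_copies: ExpressionMatrix,
    annotation: GeneAnnotation,
    params: RulerParams | None = None,
    sample_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Ribosome-anchored mRNA copies per cell from FPKM.

    Per RNA sample: the ribosome count is the median of detected
    ribosomal-protein copies in the matched protein sample (robust to
    paralog dropout); total RNA mass, then mRNA molecule count
    ``N_mRNA``, follow from the ruler constants; FPKM shares distribute
    ``N_mRNA`` over genes, so ``sum(copies) == N_mRNA`` exactly.

    ``sample_map`` maps each FPKM column to a protein-copy column; when
    omitted, identical column names are assumed.
    """
    params = params or RulerParams()
    fpkm_matrix.require_unit("fpkm")
    protein_copies.require_unit("copies_per_cell")
    fpkm = fpkm_matrix.values
    pc = protein_copies.values
    ribo = [g for g in annotation.ribosomal_proteins if g in pc.index]
    out = {}
    for sample in fpkm.columns:
        partner = sample_map[sample] if sample_map is not None else sample
        if partner not in pc.columns:
            raise ValidationError(
                f"no matched protein sample for RNA sample {sample!r}"
            )
        ribo_copies = pc.loc[ribo, partner].dropna()
        if len(ribo_copies) < 3:
            raise ValidationError(
                f"fewer than 3 detected ribosomal proteins in {partner!r}"
            )
        n_ribosome = float(ribo_copies.median())
        total_rna_mass = (
            n_ribosome * params.rrna_mass_per_ribosome / params.avogadro
            / params.rrna_fraction_of_total_rna
        )
        n_mrna = (
            total_rna_mass * params.mrna_mass_fraction_of_total_rna
            * params.avogadro / params.mean_mrna_molar_mass
        )
        col = fpkm[sample]
        total_fpkm = col.sum(skipna=True)
        if not total_fpkm > 0:
            raise ValidationError(f"zero total FPKM in sample {sample!r}")
        out[sample] = col / total_fpkm * n_mrna
    return ExpressionMatrix(values=pd.DataFrame(out), unit="copies_per_cell")


def histone_mass_identity_error(
    copies: ExpressionMatrix,
    annotation: GeneAnnotation,
    params: RulerParams | None = None,
) -> pd.Series:
    """Per-sample relative error of sum(histone copies * MW) / N_A vs m_DNA.

    Diagnostic for the ruler's anchoring assumption; ~0 on ruler output.
    """
    params = params or RulerParams()
    vals = copies.values
    histones = [h for h in annotation.histones if h in vals.index]
    mw = annotation.table["molecular_weight"].reindex(histones)
    out = {}
    for sample in vals.columns:
        hist = vals.loc[histones, sample].dropna()
        mass = float((hist * mw.reindex(hist.index)).sum()) / params.avogadro
        out[sample] = abs(mass - params.dna_mass_per_cell) / params.dna_mass_per_cell
    return pd.Series(out)
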