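"""Data model and file I/O shared by every analysis stage.

The atlas pipeline moves five kinds of tables around: gene x sample
expression matrices with a declared unit, a sample design (population /
replicate / layer / tissue), per-gene annotation (molecular weight,
theoretical peptide count, role flags), TF->target regulons, and
ligand-receptor pairs, plus named gene sets in GMT form.  All tables are
plain TSV (UTF-8, header row); missing expression values are empty cells
or ``NA`` and are kept as ``NaN`` internally — never silently imputed to
zero, because "not identified" is a different statement than "low
abundance".

Downstream modules consume only the types defined here; no analysis
stage reads files directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("macatlas")

#: Recognised unit tags for an ExpressionMatrix.
UNITS = ("intensity", "ibaq", "copies_per_cell", "fpkm", "fot")

#: Units that can legitimately describe each layer.
LAYER_UNITS = {
    "protein": {"intensity", "ibaq", "copies_per_cell", "fot"},
    "rna": {"fpkm", "copies_per_cell"},
}

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A gene x sample table of non-negative values with a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample ids as columns.
        ``NaN`` marks a missing (not identified) value.
    unit
        One of :data:`UNITS`.  Operations that require a specific unit
        (e.g. the proteomic ruler wants ``intensity`` or ``ibaq``)
        reject mismatches.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(
                f"unknown unit {self.unit!r}; expected one of {UNITS}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        vals = self.values.to_numpy(dtype=float)
        neg = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative value at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        self.values = self.values.astype(float)

    # -- convenience accessors ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def detected_mask(self) -> pd.DataFrame:
        """Boolean gene x sample frame: True where a value is present."""
        return self.values.notna()

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, unit=unit or self.unit)

    def require_unit(self, *units: str) -> None:
        if self.unit not in units:
            raise ValidationError(
                f"operation requires unit in {units}, got {self.unit!r}"
            )


@dataclass
class SampleDesign:
    """Sample -> (population, replicate, layer, tissue) mapping.

    The population order is the order of first appearance in the input,
    never sorted, so outputs are reproducible against fixtures.
    """

    table: pd.DataFrame  # index: sample_id; columns population, replicate, layer, tissue

    REQUIRED = ("population", "replicate", "layer")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"design is missing column {col!r}")
        if "tissue" not in self.table.columns:
            self.table = self.table.assign(tissue=pd.NA)
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in design: {dups}")
        bad_layer = set(self.table["layer"]) - set(LAYER_UNITS)
        if bad_layer:
            raise ValidationError(f"unknown layer labels: {sorted(bad_layer)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[str]:
        """Populations in stable first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.table["population"]:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.table["tissue"].dropna():
            seen.setdefault(t, None)
        return list(seen)

    def samples_for(self, population: str, layer: str | None = None) -> list[str]:
        t = self.table
        mask = t["population"] == population
        if layer is not None:
            mask &= t["layer"] == layer
        return list(t.index[mask])

    def subset(self, layer: str) -> "SampleDesign":
        return SampleDesign(self.table[self.table["layer"] == layer].copy())


@dataclass
class GeneAnnotation:
    """Per-gene metadata: molecular weight, peptide count, role flags."""

    table: pd.DataFrame

    FLAGS = ("is_histone", "is_ribosomal_protein", "is_tf", "is_ligand", "is_receptor")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValidationError(f"duplicate genes in annotation: {dups}")
        for col in ("molecular_weight", "theoretical_peptide_count"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        mw = self.table["molecular_weight"]
        if (mw.dropna() <= 0).any():
            bad = sorted(self.table.index[mw <= 0])
            raise ValidationError(f"non-positive molecular weight for genes: {bad}")
        for flag in self.FLAGS:
            if flag not in self.table.columns:
                self.table[flag] = False
            self.table[flag] = self.table[flag].fillna(False).astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def flagged(self, flag: str) -> list[str]:
        if flag not in self.FLAGS:
            raise KeyError(flag)
        return list(self.table.index[self.table[flag]])

    @property
    def histones(self) -> list[str]:
        return self.flagged("is_histone")

    @property
    def ribosomal_proteins(self) -> list[str]:
        return self.flagged("is_ribosomal_protein")

    @property
    def tfs(self) -> list[str]:
        return self.flagged("is_tf")

    @property
    def ligands(self) -> list[str]:
        return self.flagged("is_ligand")

    @property
    def receptors(self) -> list[str]:
        return self.flagged("is_receptor")

    def molecular_weight(self, genes: Iterable[str]) -> pd.Series:
        return self.table["molecular_weight"].reindex(list(genes))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass
class RegulonTable:
    """TF -> target-gene sets.  Self-edges are dropped with a warning."""

    regulons: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        cleaned: dict[str, frozenset[str]] = {}
        for tf, targets in self.regulons.items():
            targets = frozenset(targets)
            if tf in targets:
                logger.warning("dropping self-edge %s -> %s", tf, tf)
                targets = targets - {tf}
            cleaned[tf] = targets
        self.regulons = cleaned

    def __len__(self) -> int:
        return len(self.regulons)

    def __iter__(self) -> Iterator[str]:
        return iter(self.regulons)

    def __getitem__(self, tf: str) -> frozenset[str]:
        return self.regulons[tf]

    def __contains__(self, tf: str) -> bool:
        return tf in self.regulons

    def items(self):
        return self.regulons.items()


@dataclass
class LRPairs:
    """Ligand-receptor pair table; duplicate pairs are dropped with a warning."""

    table: pd.DataFrame  # columns: ligand, receptor, source

    def __post_init__(self) -> None:
        for col in ("ligand", "receptor"):
            if col not in self.table.columns:
                raise ValidationError(f"LR pair table is missing column {col!r}")
            if (self.table[col].astype(str).str.len() == 0).any():
                raise ValidationError(f"empty symbol in LR column {col!r}")
        if "source" not in self.table.columns:
            self.table = self.table.assign(source="")
        dup = self.table.duplicated(subset=["ligand", "receptor"])
        if dup.any():
            logger.warning("dropping %d duplicate ligand-receptor rows", int(dup.sum()))
            self.table = self.table[~dup].reset_index(drop=True)

    def receptors_for(self, ligand: str) -> list[str]:
        t = self.table
        return list(t.loc[t["ligand"] == ligand, "receptor"])

    @property
    def ligand_genes(self) -> frozenset[str]:
        return frozenset(self.table["ligand"])

    @property
    def receptor_genes(self) -> frozenset[str]:
        return frozenset(self.table["receptor"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a gene x sample TSV into an :class:`ExpressionMatrix`.

    First column holds gene symbols, header row holds sample ids; empty
    cells or ``NA`` denote missing.  Duplicate gene or sample ids and
    negative values are hard errors.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False, float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ``NA`` for missing values (round-trip safe)."""
    out = matrix.values.copy()
    out.index.name = "gene"
    # repr-format floats so write->read reproduces values bit-exactly
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"replicate": int},
                     na_values=list(MISSING_TOKENS), keep_default_na=False)
    df.index = df.index.astype(str)
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    out = design.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=list(MISSING_TOKENS), keep_default_na=False,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    for flag in GeneAnnotation.FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].map(
                {True: True, False: False, "True": True, "False": False,
                 "1": True, "0": False, 1: True, 0: False}
            )
    return GeneAnnotation(df)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name, description, tab-separated members).

    Duplicate members within a line are deduplicated with a logged
    warning; a line with fewer than 3 fields is a hard error naming the
    line number.  An empty file yields an empty collection.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "GMT set %r: deduplicated %d repeated members",
                    name, len(members) - len(unique),
                )
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            sets[name] = frozenset(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_regulons(path: str | Path) -> RegulonTable:
    """Read a TF->target TSV with columns ``tf`` and ``target``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("tf", "target"):
        if col not in df.columns:
            raise ValidationError(f"regulon table is missing column {col!r}")
    regulons: dict[str, set[str]] = {}
    for tf, target in zip(df["tf"], df["target"]):
        regulons.setdefault(tf, set()).add(target)
    return RegulonTable({tf: frozenset(tg) for tf, tg in regulons.items()})


def write_regulons(regulons: RegulonTable, path: str | Path) -> None:
    rows = [
        {"tf": tf, "target": target}
        for tf, targets in regulons.items()
        for target in sorted(targets)
    ]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_lr_pairs(path: str | Path) -> LRPairs:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=list(MISSING_TOKENS),
                     keep_default_na=False)
    return LRPairs(df)


def write_lr_pairs(pairs: LRPairs, path: str | Path) -> None:
    pairs.table.to_csv(path, sep="\t", index=False)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id (first header token)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_design(
    matrix: ExpressionMatrix, design: SampleDesign
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Check the bijection between matrix columns and design rows.

    Also checks layer/unit consistency: an RNA-layer design cannot be
    attached to an intensity or iBAQ matrix, and vice versa.  Returns
    the validated pair unchanged.
    """
    matrix_samples = set(matrix.sample_ids)
    design_samples = set(design.sample_ids)
    only_matrix = sorted(matrix_samples - design_samples)
    only_design = sorted(design_samples - matrix_samples)
    if only_matrix or only_design:
        raise ValidationError(
            "matrix/design sample mismatch: "
            f"in matrix only {only_matrix}; in design only {only_design}"
        )
    layers = set(design.table["layer"])
    for layer in layers:
        if matrix.unit not in LAYER_UNITS[layer]:
            raise ValidationError(
                f"design layer {layer!r} is inconsistent with matrix unit "
                f"{matrix.unit!r} (allowed: {sorted(LAYER_UNITS[layer])})"
            )
    return matrix, design


def population_means(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    min_detected: int = 1,
) -> pd.DataFrame:
    """Replicate-mean expression per population (gene x population).

    A gene's mean in a population is defined only where it is detected
    in at least ``min_detected`` replicates of that population;
    elsewhere it is ``NaN``.  Populations keep design order.
    """
    out: dict[str, pd.Series] = {}
    for pop in design.populations:
        samples = [s for s in design.samples_for(pop) if s in matrix.values.columns]
        if not samples:
            continue
        block = matrix.values[samples]
        mean = block.mean(axis=1, skipna=True)
        nd = block.notna().sum(axis=1)
        mean[nd < min_detected] = np.nan
        out[pop] = mean
    return pd.DataFrame(out)
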