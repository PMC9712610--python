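"""iBAQ, FOT and copy-number ruler behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macatlas.core_io import GeneAnnotation, ValidationError
from macatlas.quantify import (
    AVOGADRO,
    RulerParams,
    compute_fot,
    compute_ibaq,
    count_theoretical_peptides,
    histone_mass_identity_error,
    proteomic_ruler,
    rna_ruler,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Theoretical peptide counting
# ---------------------------------------------------------------------------


def naive_tryptic_count(seq: str) -> int:
    """Independent oracle: explicit fragment enumeration."""
    fragments, cur = [], ""
    for i, aa in enumerate(seq):
        cur += aa
        if aa in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            fragments.append(cur)
            cur = ""
    if cur:
        fragments.append(cur)
    return sum(7 <= len(f) <= 30 for f in fragments)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACDEFGHILM", 1),              # whole chain, length 10, no K/R
        ("AAAAKAAAAAAR", 1),            # AAAAK (5) too short, AAAAAAR (7) counted
        ("AAAAAAKPAAAAAAR", 1),         # no cleavage before P -> one 15-mer
        ("AAAAAAK", 1),                 # exactly 7
        ("A" * 30 + "K", 0),            # 31-mer above the window
        ("AAAAAAKAAAAAAK", 2),
        ("KKKKKKK", 0),                 # seven 1-mers
    ],
)
def test_tryptic_peptide_counts(seq, expected):
    assert count_theoretical_peptides(seq) == expected
    assert naive_tryptic_count(seq) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=120))
def test_tryptic_count_matches_enumeration_oracle(seq):
    assert count_theoretical_peptides(seq) == naive_tryptic_count(seq)


def test_tryptic_count_rejects_bad_input():
    with pytest.raises(ValidationError, match="empty"):
        count_theoretical_peptides("")
    with pytest.raises(ValidationError, match="position 3"):
        count_theoretical_peptides("AAXAAA")


# ---------------------------------------------------------------------------
# iBAQ and FOT
# ---------------------------------------------------------------------------


def _annotation(genes, mw=None, counts=None, histones=()):
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    table["molecular_weight"] = mw if mw is not None else 50_000.0
    table["theoretical_peptide_count"] = counts if counts is not None else 10
    table["is_histone"] = [g in histones for g in genes]
    return GeneAnnotation(table)


def test_ibaq_divides_by_peptide_count():
    m = make_matrix({"s1": [1000.0, 40.0], "s2": [np.nan, 80.0]},
                    ["A", "B"], unit="intensity")
    ann = _annotation(["A", "B"], counts=[10, 1])
    ibaq = compute_ibaq(m, ann)
    assert ibaq.unit == "ibaq"
    assert ibaq.values.loc["A", "s1"] == 100.0
    assert ibaq.values.loc["B", "s1"] == 40.0          # count 1 -> identity
    assert np.isnan(ibaq.values.loc["A", "s2"])        # missing stays missing


def test_ibaq_missing_count_listed():
    m = make_matrix({"s1": [1000.0, 10.0]}, ["A", "B"], unit="intensity")
    ann = _annotation(["A", "B"], counts=[10, 0])
    with pytest.raises(ValidationError, match="B"):
        compute_ibaq(m, ann)


def test_fot_normalization():
    m = make_matrix({"s1": [30.0, 10.0], "s2": [5.0, np.nan]},
                    ["A", "B"], unit="ibaq")
    fot = compute_fot(m)
    assert fot.values.loc["A", "s1"] == pytest.approx(7.5e6)
    assert fot.values.loc["B", "s1"] == pytest.approx(2.5e6)
    assert fot.values.loc["A", "s2"] == pytest.approx(1e7)  # sole present protein
    sums = fot.values.sum(axis=0, skipna=True)
    assert np.allclose(sums, 1e7)


def test_fot_all_missing_column_error():
    m = make_matrix({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]},
                    ["A", "B"], unit="ibaq")
    with pytest.raises(ValidationError, match="s2"):
        compute_fot(m)


# ---------------------------------------------------------------------------
# Proteomic ruler
# ---------------------------------------------------------------------------


def test_single_histone_arithmetic():
    # sole histone, MW 15 kg/mol, m_DNA 6e-12 g:
    # copies = 6e-12 * N_A / 15000
    m = make_matrix({"s1": [100.0, 50.0]}, ["H1", "A"], unit="intensity")
    ann = _annotation(["H1", "A"], mw=[15_000.0, 30_000.0], histones=("H1",))
    params = RulerParams(dna_mass_per_cell=6e-12, signal_kind="mass_proportional")
    copies = proteomic_ruler(m, ann, params)
    expected_h1 = 6e-12 * AVOGADRO / 15_000.0
    assert copies.values.loc["H1", "s1"] == pytest.approx(expected_h1, rel=1e-12)
    assert expected_h1 == pytest.approx(2.409e8, rel=1e-3)
    # protein A: half the histone signal -> half the mass, MW twice -> 1/4 copies
    assert copies.values.loc["A", "s1"] == pytest.approx(expected_h1 / 4, rel=1e-12)


def test_ruler_invariant_to_global_sample_scaling(default_bundle):
    cfg = default_bundle.config
    ann = default_bundle.annotation
    params = RulerParams(dna_mass_per_cell=cfg.dna_mass_per_cell)
    base = proteomic_ruler(default_bundle.protein_ibaq, ann, params)
    rng = np.random.default_rng(0)
    scales = 10 ** rng.uniform(-2, 2, size=10)
    vals = default_bundle.protein_ibaq.values
    for scale in scales:
        scaled = default_bundle.protein_ibaq.with_values(vals * scale)
        again = proteomic_ruler(scaled, ann, params)
        pd.testing.assert_frame_equal(base.values, again.values,
                                      rtol=1e-12, atol=0.0)


def test_ruler_inverts_generator_noiselessly(noiseless_bundle):
    cfg = noiseless_bundle.config
    params = RulerParams(dna_mass_per_cell=cfg.dna_mass_per_cell,
                         signal_kind="mass_proportional")
    est = proteomic_ruler(noiseless_bundle.protein_intensity,
                          noiseless_bundle.annotation, params)
    for pop in ["POP00", "POP07"]:
        truth = noiseless_bundle.truth.protein_copies[pop]
        got = est.values[f"{pop}_prot_r1"]
        rel = ((got - truth).abs() / truth).dropna()
        assert rel.median() < 1e-6
    err = histone_mass_identity_error(est, noiseless_bundle.annotation, params)
    assert (err < 1e-9).all()


def test_ibaq_and_intensity_modes_agree_when_counts_track_mw():
    # intensity = copies * MW; peptide count proportional to MW
    genes = ["H1", "A", "B"]
    mw = np.array([15_000.0, 42_000.0, 88_000.0])
    copies_true = np.array([2.0e8, 5.0e5, 3.0e3])
    intensity = copies_true * mw
    m_int = make_matrix({"s1": list(intensity)}, genes, unit="intensity")
    counts = mw / 1000.0
    m_ibaq = make_matrix({"s1": list(intensity / counts)}, genes, unit="ibaq")
    ann = _annotation(genes, mw=list(mw), counts=list(counts), histones=("H1",))
    m_dna = copies_true[0] * mw[0] / AVOGADRO  # histone mass anchors exactly
    a = proteomic_ruler(m_int, ann, RulerParams(
        dna_mass_per_cell=m_dna, signal_kind="mass_proportional"))
    b = proteomic_ruler(m_ibaq, ann, RulerParams(
        dna_mass_per_cell=m_dna, signal_kind="mole_proportional"))
    pd.testing.assert_frame_equal(a.values, b.values, rtol=1e-12)
    assert np.allclose(a.values["s1"], copies_true, rtol=1e-12)


def test_ruler_mode_agreement_on_noisy_fixture(default_bundle, default_copies):
    cfg = default_bundle.config
    params = RulerParams(dna_mass_per_cell=cfg.dna_mass_per_cell,
                         signal_kind="mass_proportional")
    mass_mode = proteomic_ruler(default_bundle.protein_intensity,
                                default_bundle.annotation, params)
    a = np.log10(mass_mode.values).to_numpy().ravel()
    b = np.log10(default_copies.values).to_numpy().ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    assert r > 0.9


def test_ruler_errors():
    m = make_matrix({"s1": [np.nan, 5.0]}, ["H1", "A"], unit="intensity")
    ann = _annotation(["H1", "A"], histones=("H1",))
    with pytest.raises(ValidationError, match="s1"):
        proteomic_ruler(m, ann)
    m2 = make_matrix({"s1": [3.0, 5.0]}, ["H1", "A"], unit="intensity")
    ann2 = _annotation(["H1", "A"], mw=[15_000.0, np.nan], histones=("H1",))
    with pytest.raises(ValidationError, match="A"):
        proteomic_ruler(m2, ann2)


# ---------------------------------------------------------------------------
# RNA ruler
# ---------------------------------------------------------------------------


def _rna_setup():
    genes = ["R1", "R2", "R3", "A", "B"]
    pc = make_matrix({"p1": [1e6, 2e6, 3e6, 5e4, np.nan]}, genes,
                     unit="copies_per_cell")
    fpkm = make_matrix({"p1": [10.0, 20.0, 30.0, 5.0, 35.0]}, genes, unit="fpkm")
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    table["molecular_weight"] = 30_000.0
    table["theoretical_peptide_count"] = 10
    table["is_ribosomal_protein"] = [g.startswith("R") for g in genes]
    return fpkm, pc, GeneAnnotation(table)


def test_rna_ruler_conserves_mrna_count_exactly():
    fpkm, pc, ann = _rna_setup()
    params = RulerParams()
    out = rna_ruler(fpkm, pc, ann, params)
    n_ribosome = 2e6  # median of ribosomal-protein copies
    total_rna_mass = (n_ribosome * params.rrna_mass_per_ribosome
                      / params.avogadro / params.rrna_fraction_of_total_rna)
    n_mrna = (total_rna_mass * params.mrna_mass_fraction_of_total_rna
              * params.avogadro / params.mean_mrna_molar_mass)
    assert out.values["p1"].sum() == pytest.approx(n_mrna, rel=1e-12)


def test_rna_ruler_invariant_to_fpkm_scaling():
    fpkm, pc, ann = _rna_setup()
    out1 = rna_ruler(fpkm, pc, ann)
    out2 = rna_ruler(fpkm.with_values(fpkm.values * 2), pc, ann)
    pd.testing.assert_frame_equal(out1.values, out2.values, rtol=1e-12)


def test_rna_ruler_rank_preservation_noiseless(noiseless_bundle):
    from scipy.stats import spearmanr

    cfg = noiseless_bundle.config
    copies = proteomic_ruler(
        noiseless_bundle.protein_intensity, noiseless_bundle.annotation,
        RulerParams(dna_mass_per_cell=cfg.dna_mass_per_cell,
                    signal_kind="mass_proportional"))
    est = rna_ruler(noiseless_bundle.rna_fpkm, copies,
                    noiseless_bundle.annotation,
                    sample_map=noiseless_bundle.rna_to_protein_sample())
    col = est.values["POP00_rna_r1"].dropna()
    truth = noiseless_bundle.truth.mrna_copies.loc[col.index, "POP00"]
    assert spearmanr(col, truth).statistic > 1 - 1e-12


def test_rna_ruler_needs_three_ribosomal_proteins():
    fpkm, pc, ann = _rna_setup()
    pc.values.loc["R3", "p1"] = np.nan
    with pytest.raises(ValidationError, match="ribosomal"):
        rna_ruler(fpkm, pc, ann)
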