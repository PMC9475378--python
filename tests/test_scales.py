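"""Scale registry, normalization procedure, and per-atom assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydroscore as hs
from hydroscore.scales import CANONICAL_RESIDUES, RESIDUE_SCALES
from hydroscore.structure import Atom, Structure

# original Kyte-Doolittle hydropathy constants (the raw inputs to normalization)
KD_RAW = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5, "GLN": -3.5,
    "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5, "LEU": 3.8, "LYS": -3.9,
    "MET": 1.9, "PHE": 2.8, "PRO": -1.6, "SER": -0.8, "THR": -0.7, "TRP": -0.9,
    "TYR": -1.3, "VAL": 4.2,
}


@pytest.mark.parametrize("scale,residue,expected", [
    ("kyte-doolittle", "ILE", 1.68),
    ("jain", "GLY", 0.00),
    ("wimley-white", "TRP", 2.33),
    ("black-mould", "PHE", 1.52),
    ("meek", "GLU", -2.23),
])
def test_packaged_scale_values(scale, residue, expected):
    assert hs.load_scale(scale).values[residue] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("name", RESIDUE_SCALES)
def test_packaged_scales_are_normalized(name):
    """Gly sits at zero and the 20 values have unit variance, per scale."""
    scale = hs.load_scale(name)
    assert scale.normalized
    vals = np.array([scale.values[r] for r in CANONICAL_RESIDUES])
    assert abs(scale.values["GLY"]) <= 0.005
    assert np.var(vals) == pytest.approx(1.0, abs=0.02)
    assert np.all(np.isfinite(vals))


def test_unknown_scale_lists_registry():
    with pytest.raises(KeyError, match="kyte-doolittle"):
        hs.load_scale("nope")


def test_normalization_recovers_packaged_kyte_doolittle():
    """Applying the procedure to the raw hydropathy constants reproduces the
    packaged column at its printed 2-decimal precision."""
    out = hs.normalize_scale(KD_RAW)
    packaged = hs.load_scale("kyte-doolittle")
    for res in CANONICAL_RESIDUES:
        assert round(out.values[res], 2) == pytest.approx(packaged.values[res])
    assert round(out.values["ILE"], 2) == 1.68
    assert round(out.values["ARG"], 2) == -1.41


@pytest.mark.parametrize("name", RESIDUE_SCALES)
def test_normalization_is_idempotent(name):
    packaged = hs.load_scale(name)
    again = hs.normalize_scale(dict(packaged.values))
    for res in CANONICAL_RESIDUES:
        assert again.values[res] == pytest.approx(packaged.values[res], abs=0.02)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(shift=st.floats(-50, 50), factor=st.floats(0.01, 100), seed=st.integers(0, 2**16))
def test_normalization_invariant_to_affine_input(shift, factor, seed):
    rng = np.random.default_rng(seed)
    raw = dict(zip(CANONICAL_RESIDUES, rng.normal(size=20)))
    base = hs.normalize_scale(raw)
    moved = hs.normalize_scale({k: factor * v + shift for k, v in raw.items()})
    for res in CANONICAL_RESIDUES:
        assert moved.values[res] == pytest.approx(base.values[res], abs=1e-9)


def test_normalization_sign_convention():
    """Negating the input leaves the output unchanged: hydrophobics stay positive."""
    flipped = hs.normalize_scale({k: -v for k, v in KD_RAW.items()})
    base = hs.normalize_scale(KD_RAW)
    for res in CANONICAL_RESIDUES:
        assert flipped.values[res] == pytest.approx(base.values[res])
    assert np.mean([base.values[r] for r in ("ILE", "LEU", "PHE", "VAL")]) > 0


def test_normalization_near_constant_input():
    """19 residues at 5.0, GLY at 0: hand oracle gives 5/sd with sd^2 = var(x)."""
    raw = {r: (0.0 if r == "GLY" else 5.0) for r in CANONICAL_RESIDUES}
    x = np.array([raw[r] for r in CANONICAL_RESIDUES])
    expected = 5.0 / np.std(x)
    out = hs.normalize_scale(raw)
    assert out.values["GLY"] == 0.0
    for res in CANONICAL_RESIDUES:
        if res != "GLY":
            assert out.values[res] == pytest.approx(expected)


def test_normalization_errors():
    incomplete = {k: v for k, v in KD_RAW.items() if k != "TRP"}
    with pytest.raises(ValueError, match="TRP"):
        hs.normalize_scale(incomplete)
    with pytest.raises(ValueError, match="spread"):
        hs.normalize_scale({r: 3.3 for r in CANONICAL_RESIDUES})


def test_assignment_residue_scale(gag_fixture, kd_scale):
    st_ = gag_fixture.structure
    h = hs.assign_hydrophobicity(st_, kd_scale)
    assert len(h) == len(st_.atoms)
    for atom, val in zip(st_.atoms, h):
        assert val == pytest.approx({"GLY": 0.00, "ALA": 0.76}[atom.res_name])


def test_assignment_histidine_protonation_variants():
    """HID/HIE/HIP all receive the HIS value of a residue scale."""
    jain = hs.load_scale("jain")
    for variant in ("HID", "HIE", "HIP"):
        atom = Atom(0, "CA", "C", variant, 1, "A", np.zeros(3))
        h = hs.assign_hydrophobicity(Structure([atom]), jain)
        assert h[0] == pytest.approx(0.03)


def test_assignment_unknown_residue_policy(kd_scale):
    lig = Structure([Atom(0, "C1", "C", "LIG", 1, "A", np.zeros(3))])
    with pytest.raises(KeyError, match="LIG"):
        hs.assign_hydrophobicity(lig, kd_scale)
    with pytest.warns(UserWarning):
        h = hs.assign_hydrophobicity(lig, kd_scale, on_unknown="skip")
    assert h[0] == 0.0


@pytest.mark.parametrize("name", ["crippen", "eisenberg-dg"])
def test_atomic_scale_covers_all_residues(all20_fixture, name):
    """Atomic typing of a peptide spanning the 20 residues raises no error."""
    scale = hs.load_scale(name)
    h = hs.assign_hydrophobicity(all20_fixture.structure, scale)
    assert len(h) == len(all20_fixture.structure.atoms)
    assert np.all(np.isfinite(h))


def test_crippen_aromatic_nitrogen_hydrogens_are_amine_type():
    """H on aromatic N of TRP and HIS carries the amine-class value, not alcohol."""
    table = hs.load_atom_table("crippen")
    amine_h = 0.2142
    alcohol_h = -0.2677
    for key in [("TRP", "HE1"), ("HIS", "HD1"), ("HIS", "HE2"),
                ("HID", "HD1"), ("HIE", "HE2"), ("HIP", "HD1"), ("HIP", "HE2")]:
        label, value = table.entries[key]
        assert value == pytest.approx(amine_h)
        assert label == "H3"
    # a genuine alcohol hydrogen keeps the alcohol value
    assert table.entries[("SER", "HG")][1] == pytest.approx(alcohol_h)


def test_atomic_assignment_resolves_name_synonyms():
    atom = Atom(0, "HN", "H", "ALA", 1, "A", np.zeros(3))
    h = hs.assign_hydrophobicity(Structure([atom]), hs.load_scale("crippen"))
    table = hs.load_atom_table("crippen")
    assert h[0] == pytest.approx(table.entries[("ALA", "H")][1])
    bad = Structure([Atom(0, "QQ7", "H", "ALA", 1, "A", np.zeros(3))])
    with pytest.raises(KeyError, match="QQ7"):
        hs.assign_hydrophobicity(bad, hs.load_scale("crippen"))
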