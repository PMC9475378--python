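"""Surface scores, SAP, MLP/Heiden, ensemble reweighting, Pearson benchmark."""

import numpy as np
import pytest

import hydroscore as hs
from hydroscore.scoring import BOLTZMANN_KCAL, ScoringParams
from hydroscore.ses import SurfaceMesh
from hydroscore.structure import Atom, Structure

from conftest import two_atom_toy


def test_surf_score_symmetry_and_single_term():
    st, h = two_atom_toy((1.0, -1.0))
    sasa = hs.shrake_rupley(st, n_points=240)
    assert hs.surf_score(st, sasa, h) == pytest.approx(0.0, abs=1e-9)

    fx = hs.make_single_atom()
    res = hs.shrake_rupley(fx.structure, n_points=960)
    assert hs.surf_score(fx.structure, res, np.array([2.0])) == pytest.approx(
        2.0 * res.total)


def test_surf_score_per_residue_grouping(gag_fixture, kd_scale):
    """Per-atom sum equals the per-residue formulation for a residue scale."""
    st = gag_fixture.structure
    sasa = hs.shrake_rupley(st, n_points=240)
    h = hs.assign_hydrophobicity(st, kd_scale)
    per_atom = hs.surf_score(st, sasa, h)
    per_residue = sum(
        kd_scale.values[atoms[0].res_name] * sum(sasa.atom_area[a.index] for a in atoms)
        for _, atoms in st.residues())
    assert per_atom == pytest.approx(per_residue, rel=1e-9)
    ala_area = sum(sasa.atom_area[a.index] for a in st.atoms if a.res_name == "ALA")
    assert per_atom == pytest.approx(0.76 * ala_area, rel=1e-9)


def test_pos_surf_score_clamps_negative():
    st, h = two_atom_toy((1.0, -1.0))
    sasa = hs.shrake_rupley(st, n_points=240)
    assert hs.pos_surf_score(st, sasa, h) == pytest.approx(sasa.atom_area[0])


def test_all_gly_positive_score_is_zero(kd_scale):
    fx = hs.make_ideal_peptide("GGG", seed=4)
    sasa = hs.shrake_rupley(fx.structure, n_points=240)
    h = hs.assign_hydrophobicity(fx.structure, kd_scale)
    assert hs.pos_surf_score(fx.structure, sasa, h) == 0.0


def test_pos_surf_dominates_surf():
    rng = np.random.default_rng(17)
    for trial in range(10):
        fx = hs.make_random_cluster(20, rng=rng)
        sasa = hs.shrake_rupley(fx.structure, n_points=96)
        h = rng.normal(size=20)
        s = hs.surf_score(fx.structure, sasa, h)
        p = hs.pos_surf_score(fx.structure, sasa, h)
        assert p >= max(s, 0.0) - 1e-12


def test_length_mismatch_rejected(gag_fixture):
    st = gag_fixture.structure
    sasa = hs.shrake_rupley(st, n_points=96)
    with pytest.raises(ValueError, match="atoms"):
        hs.surf_score(st, sasa, np.ones(3))


def sap_oracle(structure, sasa, h, ref, cutoff):
    """Independent O(n^2) evaluation with the same accumulation order."""
    coords = structure.coords
    side = structure.sidechain_mask
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        for j in range(len(coords)):
            if not side[j]:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                out[i] += sasa.atom_area[j] / ref[structure.atoms[j].res_name] * h[j]
    return out


def test_sap_single_atom_self_term():
    fx = hs.make_single_atom(residue="ALA")
    fx.structure.atoms[0].is_sidechain = True
    sasa = hs.shrake_rupley(fx.structure, n_points=960)
    ref = {"ALA": sasa.total}
    sap = hs.sap_per_atom(fx.structure, sasa, np.array([0.5]), ref)
    assert sap[0] == pytest.approx(0.5)
    assert hs.sap_score(sap) == pytest.approx(0.5)


def test_sap_tiny_cutoff_reduces_to_self_terms():
    fx = hs.make_random_cluster(25, rng=3)
    st = fx.structure
    sasa = hs.shrake_rupley(st, n_points=96)
    h = np.random.default_rng(3).normal(size=25)
    ref = {r: 50.0 for r in set(a.res_name for a in st.atoms)}
    params = ScoringParams(cutoff=0.05)
    sap = hs.sap_per_atom(st, sasa, h, ref, params)
    side = st.sidechain_mask
    expected = np.where(side, sasa.atom_area / 50.0 * h, 0.0)
    assert np.allclose(sap, expected, rtol=1e-12)


def test_sap_matches_brute_force_oracle():
    ref = hs.reference_sidechain_sasa()
    rng = np.random.default_rng(42)
    for trial in range(10):
        fx = hs.make_random_cluster(30, rng=rng)
        st = fx.structure
        sasa = hs.shrake_rupley(st, n_points=96)
        h = rng.normal(size=30)
        fast = hs.sap_per_atom(st, sasa, h, ref)
        slow = hs.sap_per_atom(st, sasa, h, ref, brute_force=True)
        oracle = sap_oracle(st, sasa, h, ref, 5.0)
        assert np.array_equal(fast, slow)
        assert np.array_equal(fast, oracle)


def test_sap_score_properties():
    assert hs.sap_score(np.array([-1.0, -0.5])) == 0.0
    assert hs.sap_score(np.array([0.5])) == 0.5


def test_sap_scales_linearly_on_positive_cone():
    fx = hs.make_random_cluster(20, rng=9)
    st = fx.structure
    sasa = hs.shrake_rupley(st, n_points=96)
    h = np.abs(np.random.default_rng(9).normal(size=20))
    ref = {r: 50.0 for r in set(a.res_name for a in st.atoms)}
    s1 = hs.sap_score(hs.sap_per_atom(st, sasa, h, ref))
    s2 = hs.sap_score(hs.sap_per_atom(st, sasa, 2.0 * h, ref))
    assert s2 == pytest.approx(2.0 * s1, rel=1e-12)


def test_sap_missing_reference_entry():
    fx = hs.make_single_atom(residue="ALA")
    fx.structure.atoms[0].is_sidechain = True
    sasa = hs.shrake_rupley(fx.structure, n_points=96)
    with pytest.raises(KeyError, match="ALA"):
        hs.sap_per_atom(fx.structure, sasa, np.array([1.0]), {"GLY": 30.0})


def test_logistic_weight_closed_forms():
    params = ScoringParams()  # R = 5, alpha = 1.5
    assert params.g(2.5) == pytest.approx(0.5)
    assert params.g(0.0) == pytest.approx(1.0 / (np.exp(-1.5 * 2.5) + 1.0))
    assert round(float(params.g(0.0)), 3) == 0.977


def test_mlp_constant_field_on_single_atom(single_atom, single_atom_mesh):
    st = single_atom.structure
    mesh = hs.mlp_vertices(single_atom_mesh, st, np.array([0.8]))
    assert np.allclose(mesh.vertex_values, 0.8)
    assert hs.heiden_score(mesh) == pytest.approx(0.8 * mesh.area, rel=1e-9)
    hs.mlp_vertices(mesh, st, np.array([-0.8]))
    assert hs.heiden_score(mesh) == 0.0


def test_mlp_symmetry_two_opposite_atoms():
    st, h = two_atom_toy((1.0, -1.0), separation=4.0)
    mid = np.array([[2.0, 0.0, 0.0]])
    mesh = SurfaceMesh(vertices=mid, triangles=np.empty((0, 3), dtype=int),
                       vertex_areas=np.array([1.0]))
    hs.mlp_vertices(mesh, st, h)
    assert mesh.vertex_values[0] == pytest.approx(0.0, abs=1e-12)


def test_mlp_bounded_by_contributing_atoms(gag_fixture, kd_scale):
    st = gag_fixture.structure
    grid = hs.build_distance_grid(st, spacing=0.6)
    mesh = hs.extract_ses(grid, structure=st)
    h = hs.assign_hydrophobicity(st, kd_scale)
    hs.mlp_vertices(mesh, st, h)
    assert mesh.vertex_values.min() >= h.min() - 1e-12
    assert mesh.vertex_values.max() <= h.max() + 1e-12


def test_mlp_starved_vertex_warns():
    st, h = two_atom_toy((1.0, 1.0))
    far = SurfaceMesh(vertices=np.array([[500.0, 0.0, 0.0]]),
                      triangles=np.empty((0, 3), dtype=int),
                      vertex_areas=np.array([1.0]))
    with pytest.warns(UserWarning, match="no atom within"):
        hs.mlp_vertices(far, st, h)
    assert far.vertex_values[0] == 0.0


def test_heiden_rigid_body_invariance(single_atom):
    from scipy.spatial.transform import Rotation

    st = single_atom.structure
    grid = hs.build_distance_grid(st, spacing=0.5)
    mesh = hs.mlp_vertices(hs.extract_ses(grid, structure=st), st, np.array([0.8]))
    base = hs.heiden_score(mesh)
    R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    moved = st.transformed(rotation=R, translation=np.array([7.0, -1.0, 2.0]))
    grid2 = hs.build_distance_grid(moved, spacing=0.5)
    mesh2 = hs.mlp_vertices(hs.extract_ses(grid2, structure=moved), moved, np.array([0.8]))
    assert hs.heiden_score(mesh2) == pytest.approx(base, rel=0.02)


def test_clamp_monotonicity_in_single_h():
    """Raising one atom's hydrophobicity never lowers the clamped scores."""
    rng = np.random.default_rng(11)
    ref = hs.reference_sidechain_sasa()
    for trial in range(5):
        fx = hs.make_random_cluster(15, rng=rng)
        st = fx.structure
        sasa = hs.shrake_rupley(st, n_points=96)
        h = rng.normal(size=15)
        i = int(rng.integers(0, 15))
        h2 = h.copy()
        h2[i] += abs(rng.normal()) + 0.1
        assert hs.pos_surf_score(st, sasa, h2) >= hs.pos_surf_score(st, sasa, h) - 1e-12
        s1 = hs.sap_score(hs.sap_per_atom(st, sasa, h, ref))
        s2 = hs.sap_score(hs.sap_per_atom(st, sasa, h2, ref))
        assert s2 >= s1 - 1e-12


def make_frames(n, label="f"):
    frames = []
    for k in range(n):
        atom = Atom(0, "O", "O", "GLY", 1, "A", np.array([float(k), 0.0, 0.0]),
                    1.52, False)
        frames.append(Structure([atom], label=f"{label}{k}"))
    return frames


def test_ensemble_uniform_when_boost_constant():
    frames = make_frames(4)
    ens = hs.FrameEnsemble(frames, [np.full(5, 2.5)] * 4, temperature=300.0)
    w = hs.ensemble_weights(ens)
    assert np.allclose(w, 0.25)
    scores = {f.label: s for f, s in zip(frames, [1.0, 2.0, 3.0, 6.0])}
    avg = hs.ensemble_score(ens, lambda f: scores[f.label])
    assert avg == pytest.approx(3.0)


def test_ensemble_single_frame():
    ens = hs.FrameEnsemble(make_frames(1))
    assert hs.ensemble_weights(ens)[0] == 1.0
    assert hs.ensemble_score(ens, lambda f: 7.5) == 7.5


def test_ensemble_two_frame_hand_example():
    """DeltaV of 0 vs (1/beta) ln 3 with zero variance gives weights 1/4, 3/4."""
    beta = 1.0 / (BOLTZMANN_KCAL * 300.0)
    frames = make_frames(2)
    ens = hs.FrameEnsemble(frames, [np.array([0.0]), np.array([np.log(3.0) / beta])])
    w = hs.ensemble_weights(ens)
    assert w[0] == pytest.approx(0.25, abs=1e-12)
    assert w[1] == pytest.approx(0.75, abs=1e-12)


def test_ensemble_weights_shift_invariant_and_normalized():
    rng = np.random.default_rng(23)
    frames = make_frames(5)
    blocks = [rng.normal(3.0, 0.5, size=10) for _ in range(5)]
    ens = hs.FrameEnsemble(frames, blocks)
    w = hs.ensemble_weights(ens)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    shifted = hs.FrameEnsemble(frames, [b + 17.3 for b in blocks])
    assert np.allclose(hs.ensemble_weights(shifted), w, atol=1e-12)


def test_ensemble_validation():
    frames = make_frames(2)
    with pytest.raises(ValueError, match="blocks"):
        hs.FrameEnsemble(frames, [np.array([1.0])])
    with pytest.raises(ValueError, match="temperature"):
        hs.FrameEnsemble(frames, None, temperature=-1.0)
    bad = make_frames(1) + [Structure([
        Atom(0, "N", "N", "GLY", 1, "A", np.zeros(3), 1.55, False)])]
    with pytest.raises(ValueError, match="atom names"):
        hs.FrameEnsemble(bad)


def scores_df(values, scale="jain", method="pos-surf"):
    import pandas as pd

    return pd.DataFrame([{"id": f"ab{i}", "scale": scale, "method": method,
                          "score": v} for i, v in enumerate(values)])


def test_pearson_perfect_and_anti_correlation():
    df = scores_df([1.0, 2.0, 3.0, 4.0])
    exp = {f"ab{i}": 10.0 + 2.0 * (i + 1) for i in range(4)}
    r = hs.pearson_benchmark(df, exp)["pearson_r"].iloc[0]
    assert r == pytest.approx(1.0)
    exp_neg = {f"ab{i}": -v for i, v in enumerate([2.0, 4.0, 6.0, 8.0])}
    r = hs.pearson_benchmark(df, exp_neg)["pearson_r"].iloc[0]
    assert r == pytest.approx(-1.0)


def test_pearson_hand_example():
    df = scores_df([1.0, 2.0, 3.0, 4.0])
    exp = {"ab0": 2.0, "ab1": 1.0, "ab2": 4.0, "ab3": 3.0}
    r = hs.pearson_benchmark(df, exp)["pearson_r"].iloc[0]
    assert r == pytest.approx(0.6)


def test_pearson_requires_three_matches_and_spread():
    df = scores_df([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="matched"):
        hs.pearson_benchmark(df, {"ab0": 1.0, "ab1": 2.0})
    with pytest.raises(ValueError, match="variance"):
        hs.pearson_benchmark(df, {"ab0": 5.0, "ab1": 5.0, "ab2": 5.0})


def test_pearson_logs_unmatched_ids(caplog):
    import logging

    df = scores_df([1.0, 2.0, 3.0, 4.0])
    exp = {f"ab{i}": float(i) for i in range(3)}
    exp["zzz"] = 9.0
    with caplog.at_level(logging.WARNING, logger="hydroscore.scoring"):
        hs.pearson_benchmark(df, exp)
    joined = " ".join(caplog.messages)
    assert "ab3" in joined and "zzz" in joined
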