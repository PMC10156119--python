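"""Structure reading, SASA, secondary structure and antigen profiles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import sbaval as sv
from sbaval.simulate import build_peptide
from sbaval.structure import (
    MAX_SASA,
    backbone_dihedrals,
    profiles_frame,
    residue_sasa,
    sphere_points,
)

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 50.00           C
ATOM      2  CA  ALA B   1      10.000   0.000   0.000  1.00 50.00           C
END
"""

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 75.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00 25.00           C
ENDMDL
END
"""


def test_read_structure_plddt_from_b_factor(tmp_path):
    model = build_peptide([-57.0] * 3, [-47.0] * 3, plddt=[90.0, 50.0, 20.0])
    sv.write_structure_model(model, tmp_path / "m.pdb")
    sv.write_structure_model(model, tmp_path / "m.cif")
    from_pdb = sv.read_structure_model(tmp_path / "m.pdb")
    from_cif = sv.read_structure_model(tmp_path / "m.cif")
    assert list(from_pdb.residue_plddt().values()) == [90.0, 50.0, 20.0]
    assert from_pdb.residue_plddt() == from_cif.residue_plddt()
    assert np.allclose(from_pdb.coords, from_cif.coords, atol=1e-3)


def test_two_chain_file_rejected(tmp_path):
    (tmp_path / "two.pdb").write_text(TWO_CHAIN_PDB)
    with pytest.raises(ValueError, match="chains"):
        sv.read_structure_model(tmp_path / "two.pdb")


def test_multi_model_uses_first_with_warning(tmp_path):
    (tmp_path / "multi.pdb").write_text(MULTI_MODEL_PDB)
    with pytest.warns(UserWarning, match="models"):
        model = sv.read_structure_model(tmp_path / "multi.pdb")
    assert model.residue_plddt()[1] == 75.0
    assert np.allclose(model.coords[0], [0.0, 0.0, 0.0])


def test_isolated_atom_sasa_analytic():
    areas = sv.shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.4]), probe=1.4)
    exact = 4 * math.pi * 2.8**2
    assert abs(areas[0] - exact) / exact < 0.005


def test_distant_atoms_do_not_occlude():
    coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    areas = sv.shrake_rupley_sasa(coords, np.array([1.7, 1.7]))
    iso = 4 * math.pi * (1.7 + 1.4) ** 2
    assert np.allclose(areas, iso, rtol=1e-9)


def test_two_sphere_overlap_closed_form():
    r, probe, d = 1.7, 1.4, 2.0
    R = r + probe
    areas = sv.shrake_rupley_sasa(np.array([[0, 0, 0], [d, 0, 0.0]]), np.array([r, r]), probe)
    exact = 4 * math.pi * R * R - 2 * math.pi * R * (R - d / 2)
    assert np.allclose(areas, exact, rtol=0.02)


def test_sasa_point_count_convergence():
    model = build_peptide([-57.0] * 8, [-47.0] * 8)
    coarse = residue_sasa(model, n_points=240)
    fine = residue_sasa(model, n_points=960)
    for rid in coarse:
        assert abs(coarse[rid] - fine[rid]) / fine[rid] < 0.03


def test_sasa_matches_independent_implementation():
    """Cross-check against biotite's Shrake-Rupley on the same radii."""
    import biotite.structure as struc
    from sbaval.structure import _radii_for, _to_atom_array

    model = build_peptide([-57.0] * 10, [-47.0] * 10)
    mine = sv.shrake_rupley_sasa(model.coords, _radii_for(model.elements), 1.4, 960)
    ref = struc.sasa(
        _to_atom_array(model), probe_radius=1.4, point_number=960, vdw_radii="Single"
    )
    assert abs(mine.sum() - np.nansum(ref)) / np.nansum(ref) < 0.05


def test_sphere_points_are_unit_and_spread():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.linalg.norm(pts.mean(axis=0)) < 0.01


def test_relative_sasa_bounds():
    rel = sv.relative_sasa([MAX_SASA["ALA"], 0.0], ["ALA", "GLY"])
    assert rel[0] == 1.0 and rel[1] == 0.0
    with pytest.warns(UserWarning, match="clipped"):
        over = sv.relative_sasa([MAX_SASA["ALA"] * 1.1], ["ALA"])
    assert over[0] == 1.0


def test_secondary_structure_ideal_conformations():
    helix = sv.assign_secondary_structure(build_peptide([-57.0] * 10, [-47.0] * 10))
    assert set(list(helix.values())[1:-1]) == {"helix"}
    sheet = sv.assign_secondary_structure(build_peptide([-139.0] * 10, [135.0] * 10))
    assert set(list(sheet.values())[1:-1]) == {"sheet"}
    tiny = sv.assign_secondary_structure(build_peptide([-57.0] * 2, [-47.0] * 2))
    assert set(tiny.values()) == {"coil"}


def test_builder_round_trips_dihedrals():
    model = build_peptide([-70.0] * 6, [120.0] * 6)
    d = backbone_dihedrals(model)
    assert np.allclose(d["phi"].dropna(), -70.0, atol=0.5)
    assert np.allclose(d["psi"].dropna(), 120.0, atol=0.5)


def test_antigen_profile_means_and_fractions():
    ann = pd.DataFrame(
        {
            "res_id": [1, 2, 3, 4],
            "res_name": ["ALA"] * 4,
            "plddt": [70.0] * 4,
            "abs_sasa": [50.0] * 4,
            "ss": ["coil"] * 4,
            "rel_sasa": [0.4] * 4,
        }
    )
    prof = sv.antigen_profile(ann, (1, 4), "AB1")
    assert prof.mean_plddt == 70.0
    assert prof.ss_fractions == {"helix": 0.0, "sheet": 0.0, "coil": 1.0}
    assert abs(sum(prof.ss_fractions.values()) - 1.0) < 1e-9

    single = sv.antigen_profile(ann, (2, 2), "AB1")
    assert single.length == 1
    assert sorted(single.ss_fractions.values()) == [0.0, 0.0, 1.0]

    with pytest.warns(UserWarning, match="incomplete"):
        partial = sv.antigen_profile(ann, (3, 6), "AB1")
    assert not partial.complete


def test_ss_fractions_always_sum_to_one():
    trips = sv.simulate_antigen_structures(n_per_class=3, max_length=25, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for model, span, _ in trips:
            ann = sv.extract_residue_annotations(model, n_points=120)
            prof = sv.antigen_profile(ann, span)
            assert abs(sum(prof.ss_fractions.values()) - 1.0) < 1e-9


def test_compare_groups_conventions():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(
        {
            "class": ["a"] * 50 + ["b"] * 50,
            "length": np.concatenate([np.arange(50), np.arange(50)]),
            "mean_plddt": np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]),
            "mean_rel_sasa": rng.uniform(size=100),
            "helix": rng.uniform(size=100),
            "sheet": rng.uniform(size=100),
            "coil": rng.uniform(size=100),
        }
    )
    stats = sv.compare_groups(frame)
    identical = stats[(stats.metric == "length") & (stats.comparison == "a vs b")]
    assert identical["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-6)
    separated = stats[(stats.metric == "mean_plddt") & (stats.comparison == "a vs b")]
    assert separated["p_value"].iloc[0] < 1e-10
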