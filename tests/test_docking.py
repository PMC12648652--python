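"""Deterministic embedding, mock docking, best-pose selection, screening."""

import itertools

import numpy as np
import pytest

from focuslib.docking import (
    DockingConfig,
    DockingResult,
    Pose,
    box_from_residues,
    dock,
    dock_mock,
    embed_conformer,
    mock_score,
    prepare_inputs,
    count_pdbqt_heavy_atoms,
    count_pdbqt_torsions,
    screen,
    select_best_pose,
)
from focuslib.errors import ContractError, EngineNotFoundError
from focuslib.fixtures import build_pocket


@pytest.fixture(scope="module")
def toy_receptor():
    return build_pocket("hydrophobic", dist=3.9).receptor


def coords_of(mol):
    conf = mol.GetConformer()
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])


def test_embedding_is_deterministic():
    a = embed_conformer("O=S(=O)(Nc1cnccn1)c1ccccc1", seed=42)
    b = embed_conformer("O=S(=O)(Nc1cnccn1)c1ccccc1", seed=42)
    assert np.allclose(coords_of(a), coords_of(b))
    assert a.GetNumConformers() == 1


def test_methane_embeds_tetrahedrally():
    mol = embed_conformer("C", seed=1)
    assert mol.GetNumAtoms() == 5
    xyz = coords_of(mol)
    center, hydrogens = xyz[0], xyz[1:]
    angles = []
    for i, j in itertools.combinations(range(4), 2):
        v1, v2 = hydrogens[i] - center, hydrogens[j] - center
        cosine = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angles.append(np.degrees(np.arccos(cosine)))
    assert np.allclose(angles, 109.47, atol=3.0)


def test_mock_score_matches_brute_force(toy_receptor):
    rng = np.random.default_rng(0)
    ligand = rng.normal(scale=3.0, size=(8, 3))
    receptor_xyz = toy_receptor.atoms.coord
    expected_contacts = sum(
        1 for l in ligand if min(np.linalg.norm(l - r) for r in receptor_xyz) <= 4.0
    )
    expected_clashes = sum(
        1 for l in ligand for r in receptor_xyz if np.linalg.norm(l - r) < 2.0
    )
    assert mock_score(ligand, receptor_xyz) == pytest.approx(
        -0.1 * expected_contacts + 1.0 * expected_clashes
    )


def test_mock_dock_outside_pocket_scores_zero(toy_receptor):
    mol = embed_conformer("CC", seed=3)
    config = DockingConfig(box_center=(100.0, 100.0, 100.0), engine="mock")
    result = dock_mock(mol, toy_receptor, config, "far")
    assert result.poses[0].score == 0.0


def test_mock_dock_centered_toy_ligand(toy_receptor):
    # single heavy atom at box center: receptor carbon is 3.9 A away -> one contact
    mol = embed_conformer("C", seed=3)
    config = DockingConfig(box_center=(0.0, 0.0, 0.0), engine="mock")
    result = dock_mock(mol, toy_receptor, config, "center")
    assert result.poses[0].score == pytest.approx(-0.1)


def test_select_best_pose_minimum_and_ties():
    poses = [Pose("x", r + 1, s, ()) for r, s in enumerate([-7.2, -6.8, -6.1])]
    result = DockingResult("x", poses, "d", "mock-1")
    assert select_best_pose(result).score == -7.2
    tie = DockingResult("x", [Pose("x", 1, -5.0, ()), Pose("x", 2, -5.0, ())], "d", "mock-1")
    assert select_best_pose(tie).rank == 1
    for perm in itertools.permutations(poses):
        shuffled = DockingResult("x", list(perm), "d", "mock-1")
        assert select_best_pose(shuffled).score == -7.2
    with pytest.raises(ContractError):
        select_best_pose(DockingResult("x", [], "d", "mock-1"))


def test_screen_rows_and_worker_invariance(toy_receptor):
    species = ["C", "CC", "CCC", "c1ccccc1", "CCO", "CCN", "CCCl", "CC=O", "CCC=O", "CCCC"]
    config = DockingConfig(engine="mock")
    t1 = screen(species, toy_receptor, config, workers=1)
    t4 = screen(species, toy_receptor, config, workers=4)
    assert t1.equals(t4)
    assert len(t1) == len(species)
    assert set(t1["status"]) == {"ok"}


def test_screen_matches_per_species_oracle(toy_library, toy_receptor):
    config = DockingConfig(engine="mock")
    structures = toy_library.structures()
    table = screen(structures, toy_receptor, config)
    for _, row in table.iterrows():
        mol = embed_conformer(row["species_id"], seed=config.seed)
        expected = dock_mock(mol, toy_receptor, config).poses[0].score
        assert row["best_score"] == pytest.approx(expected)


def test_vina_engine_missing_binary_is_environment_error(toy_receptor, monkeypatch):
    monkeypatch.setenv("PATH", "/nonexistent")
    mol = embed_conformer("C", seed=1)
    config = DockingConfig(engine="external_vina")
    with pytest.raises(EngineNotFoundError):
        dock(mol, toy_receptor, config, "x")


def test_prepare_inputs_conserves_heavy_atoms(tmp_path, toy_receptor):
    mol = embed_conformer("O=S(=O)(Nc1cnccn1)c1ccccc1", seed=42)
    n_heavy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
    manifest = prepare_inputs(toy_receptor, mol, tmp_path)
    assert count_pdbqt_heavy_atoms(manifest["ligand_pdbqt"]) == n_heavy
    assert "Babel" in manifest["preparation_toolkit"] or manifest["preparation_toolkit"]


def test_prepare_inputs_rigid_ring_has_no_torsions(tmp_path, toy_receptor):
    mol = embed_conformer("c1ccccc1", seed=7)
    manifest = prepare_inputs(toy_receptor, mol, tmp_path)
    assert count_pdbqt_torsions(manifest["ligand_pdbqt"]) == 0


def test_box_from_residues(toy_receptor):
    center, size = box_from_residues(toy_receptor, ["Leu40"], margin=5.0)
    assert center == pytest.approx((3.9, 0.0, 0.0))
    assert size == pytest.approx((10.0, 10.0, 10.0))


def test_docking_config_validation():
    with pytest.raises(ContractError):
        DockingConfig(box_size=(0.0, 10.0, 10.0))
    with pytest.raises(ContractError):
        DockingConfig(exhaustiveness=0)
    assert DockingConfig().digest() == DockingConfig().digest()
    assert DockingConfig(seed=1).digest() != DockingConfig(seed=2).digest()
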