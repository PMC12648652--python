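"""Synthetic-data generators for every pipeline stage.

These stand in for the study's deposited data package: configurable block
sets whose products are provably pairwise distinct, toy receptor pockets
with analytically placed contact geometry, and seeded 4PL dose-response
curves with embedded ground truth. Everything is deterministic under its
seed and uses the same file formats as the production modules.

The default block chemistry emulates the screening library: substituted
2-aminopyrazines coupled with substituted benzenesulfonyl chlorides. Each
block carries a unique halogen/alkyl substituent so the enumerated library
has exactly ``n_amines * n_sulfonyls`` unique products.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .chem import canonical_smiles
from .docking import Receptor
from .errors import ContractError

_HALO = ("F", "Cl", "Br")


@dataclass
class FixtureSpec:
    n_amines: int = 3
    n_sulfonyls: int = 4
    r_group_palette: Optional[Sequence[str]] = None
    seed: int = 0
    pocket_spec: Optional[Sequence[tuple]] = None  # (resname, element, (x, y, z))
    curve_spec: tuple = (6.0, 1.0, 100.0, 0.0, 0.0, 8)  # pic50, hill, top, bottom, noise_sd, n_points


def r_group(index: int) -> str:
    """Unique halogen-terminated alkyl substituent for a block index."""
    return "C" * (index // len(_HALO)) + _HALO[index % len(_HALO)]


def _substituents(n: int, palette: Optional[Sequence[str]]) -> list[str]:
    if palette is not None:
        if len(palette) < n:
            raise ContractError(f"palette of {len(palette)} substituents cannot seed {n} blocks")
        return list(palette[:n])
    return [r_group(i) for i in range(n)]


def gen_blocks(spec: FixtureSpec, out_dir: "str | Path") -> tuple[Path, Path]:
    """Write amine and sulfonyl-chloride SMILES files plus a role sidecar CSV.

    Amines are 6-substituted pyrazin-2-amines, sulfonyl chlorides are
    4-substituted benzenesulfonyl chlorides; the substituent encodes the
    block index, which guarantees pairwise-distinct coupling products.
    """
    if spec.n_amines < 1 or spec.n_sulfonyls < 1:
        raise ContractError("fixture needs at least one block of each role")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    amines_path = out_dir / "amines.smi"
    sulfonyls_path = out_dir / "sulfonyls.smi"
    rows = []
    with open(amines_path, "w") as fh:
        for i, r in enumerate(_substituents(spec.n_amines, spec.r_group_palette)):
            smiles = canonical_smiles(f"Nc1cncc({r})n1")
            block_id = f"A{i + 1:03d}"
            fh.write(f"{smiles} {block_id}\n")
            rows.append((block_id, "amino_heteroarene"))
    with open(sulfonyls_path, "w") as fh:
        for j, r in enumerate(_substituents(spec.n_sulfonyls, spec.r_group_palette)):
            smiles = canonical_smiles(f"ClS(=O)(=O)c1ccc({r})cc1")
            block_id = f"S{j + 1:03d}"
            fh.write(f"{smiles} {block_id}\n")
            rows.append((block_id, "sulfonyl_chloride"))
    with open(out_dir / "roles.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "role", "availability"])
        for block_id, role in rows:
            writer.writerow([block_id, role, "in stock"])
    return amines_path, sulfonyls_path


# ---------------------------------------------------------------------------
# toy pockets


def _ligand_from_atoms(atoms: Sequence[tuple[str, int]],
                       bonds: Sequence[tuple[int, int]],
                       coords: np.ndarray) -> Chem.Mol:
    """Build a posed RDKit molecule with full hydrogen/charge control."""
    rw = Chem.RWMol()
    for symbol, charge in atoms:
        atom = Chem.Atom(symbol)
        atom.SetFormalCharge(charge)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in bonds:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                     | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for idx, xyz in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(idx, [float(x) for x in xyz])
    mol.AddConformer(conf)
    return mol


def _benzene(center: np.ndarray, tilt_deg: float = 0.0, radius: float = 1.39) -> np.ndarray:
    """Regular aromatic hexagon in the z-plane, optionally tilted about x."""
    angles = np.radians(np.arange(6) * 60.0)
    ring = np.stack([radius * np.cos(angles), radius * np.sin(angles), np.zeros(6)], axis=1)
    t = math.radians(tilt_deg)
    rot = np.array([[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]])
    return ring @ rot.T + np.asarray(center)


def _aromatic_ligand_ring() -> Chem.Mol:
    rw = Chem.RWMol()
    for _ in range(6):
        atom = Chem.Atom("C")
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(True)
        rw.AddAtom(atom)
    for i in range(6):
        bond = rw.AddBond(i, (i + 1) % 6, Chem.BondType.AROMATIC)
        rw.GetBondWithIdx(bond - 1).SetIsAromatic(True)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    conf = Chem.Conformer(6)
    for idx, xyz in enumerate(_benzene(np.zeros(3))):
        conf.SetAtomPosition(idx, [float(x) for x in xyz])
    mol.AddConformer(conf)
    return mol


def _receptor_from_atoms(entries: Sequence[tuple[str, int, str, str, np.ndarray]]) -> Receptor:
    """entries: (resname, resnum, atom_name, element, xyz)."""
    atoms = []
    for resname, resnum, name, element, xyz in entries:
        atom = struc.Atom(
            coord=np.asarray(xyz, dtype=float),
            chain_id="A",
            res_id=resnum,
            res_name=resname,
            atom_name=name,
            element=element,
            hetero=False,
        )
        atoms.append(atom)
    return Receptor(struc.array(atoms), source="toy-pocket")


def place_at_angle(vertex: np.ndarray, reference: np.ndarray,
                   distance: float, angle_deg: float) -> np.ndarray:
    """A point at ``distance`` from ``vertex`` making ``angle_deg`` with ``reference``.

    The angle is measured at ``vertex`` between the direction to
    ``reference`` and the direction to the new point; the construction stays
    in the z=0 plane through the two inputs.
    """
    u = reference - vertex
    u = u / np.linalg.norm(u)
    # any vector orthogonal to u in-plane
    v = np.array([-u[1], u[0], 0.0])
    if np.linalg.norm(v) < 1e-9:
        v = np.array([1.0, 0.0, 0.0])
    v = v / np.linalg.norm(v)
    t = math.radians(angle_deg)
    return vertex + distance * (math.cos(t) * u + math.sin(t) * v)


@dataclass
class PocketFixture:
    receptor: Receptor
    ligand: Chem.Mol
    golden: list[dict]  # expected contacts: {kind, resname, resnum, n} entries


def build_pocket(kind: str, **geometry) -> PocketFixture:
    """Construct a toy pocket with analytically known contacts.

    Kinds: ``hbond`` (dist, angle), ``halogen`` (dist, donor_angle,
    acceptor_angle), ``pistack`` (dist, tilt), ``hydrophobic`` (dist),
    ``saltbridge`` (dist), ``empty`` (min_dist).
    """
    if kind == "hbond":
        dist = geometry.get("dist", 2.9)
        angle = geometry.get("angle", 155.0)
        n_pos = np.array([0.0, 0.0, 0.0])
        h_pos = np.array([1.0, 0.0, 0.0])
        c_pos = np.array([-1.47, 0.0, 0.0])
        # solve the D-H-A triangle: |DA| = dist with the angle at H
        r1 = np.linalg.norm(h_pos - n_pos)
        theta = math.radians(angle)
        t = r1 * math.cos(theta) + math.sqrt(dist**2 - (r1 * math.sin(theta)) ** 2)
        acceptor = place_at_angle(h_pos, n_pos, t, angle)
        assert abs(np.linalg.norm(acceptor - n_pos) - dist) < 1e-9
        ligand = _ligand_from_atoms(
            [("C", 0), ("N", 0), ("H", 0)], [(0, 1), (1, 2)],
            np.stack([c_pos, n_pos, h_pos]),
        )
        # backbone-carbonyl acceptor, C=O pointing away from the ligand
        carbonyl_c = acceptor + 1.23 * (acceptor - n_pos) / np.linalg.norm(acceptor - n_pos)
        receptor = _receptor_from_atoms([
            ("GLY", 10, "C", "C", carbonyl_c),
            ("GLY", 10, "O", "O", acceptor),
        ])
        expected_hbond = dist <= 4.1 and angle >= 100.0
        golden = [{"kind": "hbond", "resname": "GLY", "resnum": 10, "n": 1}] if expected_hbond else []
        return PocketFixture(receptor, ligand, golden)

    if kind == "halogen":
        dist = geometry.get("dist", 3.3)
        donor_angle = geometry.get("donor_angle", 170.0)
        acceptor_angle = geometry.get("acceptor_angle", 115.0)
        c_pos = np.array([0.0, 0.0, 0.0])
        x_pos = np.array([1.77, 0.0, 0.0])  # C-Cl bond
        acceptor = place_at_angle(x_pos, c_pos, dist, donor_angle)
        carbonyl_c = place_at_angle(acceptor, x_pos, 1.23, acceptor_angle)
        ligand = _ligand_from_atoms([("C", 0), ("Cl", 0)], [(0, 1)], np.stack([c_pos, x_pos]))
        receptor = _receptor_from_atoms([
            ("GLY", 20, "C", "C", carbonyl_c),
            ("GLY", 20, "O", "O", acceptor),
        ])
        ok = (dist <= 4.0 and abs(donor_angle - 165.0) <= 30.0
              and abs(acceptor_angle - 120.0) <= 30.0)
        golden = [{"kind": "halogen_bond", "resname": "GLY", "resnum": 20, "n": 1}] if ok else []
        return PocketFixture(receptor, ligand, golden)

    if kind == "pistack":
        dist = geometry.get("dist", 3.8)
        tilt = geometry.get("tilt", 5.0)
        ligand = _aromatic_ligand_ring()
        ring = _benzene(np.array([0.0, 0.0, dist]), tilt_deg=tilt)
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        receptor = _receptor_from_atoms(
            [("PHE", 30, n, "C", xyz) for n, xyz in zip(names, ring)]
        )
        golden = []
        if dist <= 5.5 and min(tilt, abs(90 - tilt)) <= 30.0:
            golden.append({"kind": "pi_stack", "resname": "PHE", "resnum": 30, "n": 1})
        # eclipsed carbons also sit in hydrophobic range when planes are close
        lig_ring = _benzene(np.zeros(3))
        pair_d = np.linalg.norm(lig_ring[:, None, :] - ring[None, :, :], axis=2)
        n_hydrophobic = int(np.sum(pair_d.min(axis=1) <= 4.0))
        if n_hydrophobic:
            golden.append({"kind": "hydrophobic", "resname": "PHE", "resnum": 30,
                           "n": n_hydrophobic})
        return PocketFixture(receptor, ligand, golden)

    if kind == "hydrophobic":
        dist = geometry.get("dist", 3.9)
        ligand = _ligand_from_atoms([("C", 0)], [], np.array([[0.0, 0.0, 0.0]]))
        receptor = _receptor_from_atoms([("LEU", 40, "CD1", "C", np.array([dist, 0.0, 0.0]))])
        golden = [{"kind": "hydrophobic", "resname": "LEU", "resnum": 40, "n": 1}] if dist <= 4.0 else []
        return PocketFixture(receptor, ligand, golden)

    if kind == "saltbridge":
        dist = geometry.get("dist", 4.0)
        ligand = _ligand_from_atoms([("N", 1)], [], np.array([[0.0, 0.0, 0.0]]))
        receptor = _receptor_from_atoms([
            ("ASP", 50, "OD1", "O", np.array([dist, 0.6, 0.0])),
            ("ASP", 50, "OD2", "O", np.array([dist, -0.6, 0.0])),
        ])
        golden = [{"kind": "salt_bridge", "resname": "ASP", "resnum": 50, "n": 1}] if dist <= 5.5 else []
        return PocketFixture(receptor, ligand, golden)

    if kind == "empty":
        min_dist = geometry.get("min_dist", 8.0)
        ligand = _ligand_from_atoms([("C", 0)], [], np.array([[0.0, 0.0, 0.0]]))
        receptor = _receptor_from_atoms([
            ("LEU", 60, "CD1", "C", np.array([min_dist, 0.0, 0.0])),
            ("SER", 61, "OG", "O", np.array([0.0, min_dist, 0.0])),
        ])
        return PocketFixture(receptor, ligand, [])

    raise ContractError(f"unknown pocket kind {kind!r}")


def rigid_transform(fixture: PocketFixture, rotation: np.ndarray,
                    translation: np.ndarray) -> PocketFixture:
    """Apply one rotation+translation to receptor and ligand alike."""
    atoms = fixture.receptor.atoms.copy()
    atoms.coord = atoms.coord @ rotation.T + translation
    receptor = Receptor(atoms, source=fixture.receptor.source)
    ligand = Chem.Mol(fixture.ligand)
    conf = ligand.GetConformer()
    for i in range(ligand.GetNumAtoms()):
        xyz = np.array(list(conf.GetAtomPosition(i)))
        conf.SetAtomPosition(i, [float(x) for x in (rotation @ xyz + translation)])
    return PocketFixture(receptor, ligand, list(fixture.golden))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def gen_pocket(spec: FixtureSpec, out_dir: "str | Path",
               kind: str = "hbond", **geometry) -> tuple[Path, Path, list[dict]]:
    """Write a toy receptor PDB and ligand SDF; return paths + golden list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec.pocket_spec:
        entries = [
            (resname, i + 1, element, element, np.asarray(xyz, dtype=float))
            for i, (resname, element, xyz) in enumerate(spec.pocket_spec)
        ]
        fixture = PocketFixture(
            _receptor_from_atoms(entries),
            _ligand_from_atoms([("C", 0)], [], np.array([[0.0, 0.0, 0.0]])),
            [],
        )
    else:
        fixture = build_pocket(kind, **geometry)
    receptor_path = out_dir / "receptor.pdb"
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(fixture.receptor.atoms)
    pdb_file.write(str(receptor_path))
    ligand_path = out_dir / "ligand.sdf"
    writer = Chem.SDWriter(str(ligand_path))
    writer.write(fixture.ligand)
    writer.close()
    return receptor_path, ligand_path, fixture.golden


# ---------------------------------------------------------------------------
# dose-response curves


def four_pl(conc_molar: np.ndarray, bottom: float, top: float,
            hill: float, log_ic50: float) -> np.ndarray:
    """Variable-slope logistic in log10-concentration space."""
    logc = np.log10(conc_molar)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - logc) * hill))


def gen_curves(spec: FixtureSpec, out_path: "str | Path",
               seed: Optional[int] = None) -> dict:
    """Write a synthetic dose-response CSV; returns the generating truth.

    The curve is a 4PL with the spec parameters, sampled on a log-spaced
    concentration grid spanning +/-3 log units around the IC50, with seeded
    Gaussian noise of ``noise_sd`` response units.
    """
    pic50, hill, top, bottom, noise_sd, n_points = spec.curve_spec
    if n_points < 4:
        raise ContractError("curve needs at least 4 points")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    log_ic50 = -pic50
    logc = np.linspace(log_ic50 - 3.0, log_ic50 + 3.0, int(n_points))
    conc = 10.0 ** logc
    response = four_pl(conc, bottom, top, hill, log_ic50)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=len(conc))
    out_path = Path(out_path)
    with open(out_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concentration_molar", "response", "replicate"])
        for c, r in zip(conc, response):
            writer.writerow([f"{c:.10e}", f"{r:.8f}", 1])
    return {
        "pic50": pic50, "hill": hill, "top": top, "bottom": bottom,
        "noise_sd": noise_sd, "n_points": int(n_points), "path": str(out_path),
    }
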