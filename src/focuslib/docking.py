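"""Seeded, reproducible docking orchestration with a pluggable backend.

The protocol mirrors a standard single-conformer virtual screen: exactly one
3D conformer is embedded per species with a fixed random seed, inputs are
prepared in PDBQT, and the engine is invoked with a fixed exhaustiveness and
seed (study protocol: exhaustiveness 8, seed 42). Only the rank-1 (lowest
score) pose flows into triage; all poses are archived.

Two engines are provided:

* ``external_vina`` shells out to an AutoDock Vina binary on PATH.
* ``mock`` is an exact, fast stand-in used for pipeline tests: the conformer
  is placed at the box center unrotated and scored as
  ``-0.1 * C + 1.0 * K`` where C counts ligand heavy atoms with any receptor
  heavy atom within 4.0 A and K counts ligand-receptor heavy-atom pairs
  closer than 2.0 A (a clash penalty).
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import subprocess
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .chem import as_mol
from .errors import (
    ContractError,
    EmbeddingError,
    EngineNotFoundError,
    EngineRunError,
    InputFileError,
)

log = logging.getLogger(__name__)

MOCK_CONTACT_DIST = 4.0  # A, favourable ligand-receptor proximity
MOCK_CLASH_DIST = 2.0  # A, steric clash


class Receptor:
    """A receptor structure with optional generic residue numbering.

    Wraps a biotite ``AtomArray``; ``residue_map`` translates residue keys
    like ``"Glu302"`` (or ``"A:Glu302"``) into Ballesteros-Weinstein labels
    such as ``"8.48"``.
    """

    def __init__(self, atoms: struc.AtomArray, source: str = "",
                 residue_map: Optional[dict[str, str]] = None):
        if not np.all(np.isfinite(atoms.coord)):
            raise ContractError("receptor has non-finite coordinates")
        self.atoms = atoms
        self.source = source
        self.residue_map = dict(residue_map or {})
        if self.residue_map:
            missing = [k for k in self.residue_map if not self._resolve_key(k)]
            if missing:
                raise ContractError(f"residue_map keys not in structure: {missing}")

    @classmethod
    def from_pdb(cls, path: "str | Path", residue_map: Optional[dict[str, str]] = None) -> "Receptor":
        path = Path(path)
        if not path.exists():
            raise InputFileError(f"no such receptor file: {path}")
        pdb_file = pdb.PDBFile.read(str(path))
        atoms = pdb_file.get_structure(model=1)
        return cls(atoms, source=str(path), residue_map=residue_map)

    # -- residue helpers ---------------------------------------------------
    def _resolve_key(self, key: str) -> bool:
        chain, resname, resnum = parse_residue_key(key)
        mask = (self.atoms.res_id == resnum) & (self.atoms.res_name == resname.upper())
        if chain:
            mask &= self.atoms.chain_id == chain
        return bool(np.any(mask))

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.atoms.element != "H"

    def residue_ids(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for chain, resnum, resname in zip(self.atoms.chain_id, self.atoms.res_id, self.atoms.res_name):
            seen.setdefault((str(chain), int(resnum), str(resname)), None)
        return list(seen)

    def select_residues(self, names: Sequence[str]) -> np.ndarray:
        """Boolean atom mask for residue keys like ["Glu302", "Lys303"]."""
        mask = np.zeros(len(self.atoms), dtype=bool)
        for key in names:
            chain, resname, resnum = parse_residue_key(key)
            sub = (self.atoms.res_id == resnum) & (self.atoms.res_name == resname.upper())
            if chain:
                sub &= self.atoms.chain_id == chain
            mask |= sub
        return mask


def parse_residue_key(key: str) -> tuple[str, str, int]:
    """Split "A:Glu302" / "Glu302" into (chain, resname, resnum)."""
    chain = ""
    if ":" in key:
        chain, key = key.split(":", 1)
    alpha = "".join(c for c in key if c.isalpha())
    digits = "".join(c for c in key if c.isdigit())
    if not alpha or not digits:
        raise ContractError(f"unparseable residue key: {key!r}")
    return chain, alpha, int(digits)


@dataclass(frozen=True)
class DockingConfig:
    box_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    box_size: tuple[float, float, float] = (20.0, 20.0, 20.0)
    exhaustiveness: int = 8
    seed: int = 42
    n_poses_kept: int = 9
    engine: str = "mock"  # mock | external_vina

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ContractError("box_size must be positive componentwise")
        if self.exhaustiveness < 1:
            raise ContractError("exhaustiveness must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def box_from_residues(receptor: Receptor, residue_keys: Sequence[str],
                      margin: float = 5.0) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Axis-aligned box around a pocket residue selection plus a margin.

    The default pocket definition when no explicit box is given: the
    bounding box of the named residues padded by ``margin`` A per side.
    """
    mask = receptor.select_residues(residue_keys)
    if not np.any(mask):
        raise ContractError(f"no atoms matched pocket residues {list(residue_keys)}")
    coords = receptor.atoms.coord[mask]
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    center = tuple(float(x) for x in (lo + hi) / 2)
    size = tuple(float(x) for x in (hi - lo) + 2 * margin)
    return center, size


@dataclass(frozen=True)
class Pose:
    species_id: str
    rank: int  # 1-based, as reported by the engine
    score: float  # kcal/mol, lower is better
    coordinates: tuple  # (n_atoms, 3) nested tuples, heavy+H as embedded


@dataclass
class DockingResult:
    species_id: str
    poses: list[Pose]
    config_digest: str
    engine: str


def embed_conformer(species: "str | Chem.Mol", seed: int = 42) -> Chem.Mol:
    """Embed exactly one 3D conformer, deterministically for a given seed."""
    mol = Chem.AddHs(as_mol(species))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(mol, params) != 0:
        # fall back once to random coordinates, still seeded
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise EmbeddingError(f"could not embed conformer: {Chem.MolToSmiles(mol)}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
    return mol


def _obabel(args: list[str]) -> subprocess.CompletedProcess:
    exe = shutil.which("obabel")
    if exe is None:
        raise EngineNotFoundError("obabel not found on PATH (needed for PDBQT preparation)")
    proc = subprocess.run([exe, *args], capture_output=True, text=True)
    if proc.returncode != 0:
        raise EngineRunError(f"obabel failed: {proc.stderr.strip()}")
    return proc


def prepare_inputs(receptor: Receptor, mol3d: Chem.Mol, out_dir: "str | Path") -> dict:
    """Write engine-ready PDBQT files for receptor and ligand.

    Charges and the ligand torsion tree come from Open Babel; the toolkit
    name and version are recorded in the returned manifest. Heavy-atom
    counts are preserved (PDBQT merges nonpolar hydrogens by design).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if np.any(receptor.atoms.element == ""):
        raise ContractError("receptor atoms lack element fields")

    receptor_pdb = out_dir / "receptor.pdb"
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(receptor.atoms)
    pdb_file.write(str(receptor_pdb))
    receptor_pdbqt = out_dir / "receptor.pdbqt"
    _obabel([str(receptor_pdb), "-opdbqt", "-O", str(receptor_pdbqt), "-xr"])

    ligand_sdf = out_dir / "ligand.sdf"
    writer = Chem.SDWriter(str(ligand_sdf))
    writer.write(mol3d)
    writer.close()
    ligand_pdbqt = out_dir / "ligand.pdbqt"
    _obabel([str(ligand_sdf), "-opdbqt", "-O", str(ligand_pdbqt)])

    version = _obabel(["-V"]).stdout.strip()
    return {
        "receptor_pdbqt": str(receptor_pdbqt),
        "ligand_pdbqt": str(ligand_pdbqt),
        "preparation_toolkit": version or "Open Babel",
    }


def count_pdbqt_heavy_atoms(path: "str | Path") -> int:
    n = 0
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            element = line[76:79].strip().rstrip("+-")
            if element.upper() not in ("H", "HD", "HS"):
                n += 1
    return n


def count_pdbqt_torsions(path: "str | Path") -> int:
    for line in Path(path).read_text().splitlines():
        if line.startswith("TORSDOF"):
            return int(line.split()[1])
    return 0


# ---------------------------------------------------------------------------
# engines


def mock_score(ligand_coords: np.ndarray, receptor_coords: np.ndarray) -> float:
    """The mock engine's exact score on heavy-atom coordinates."""
    if len(ligand_coords) == 0 or len(receptor_coords) == 0:
        return 0.0
    diff = ligand_coords[:, None, :] - receptor_coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    contacts = int(np.sum(dist.min(axis=1) <= MOCK_CONTACT_DIST))
    clashes = int(np.sum(dist < MOCK_CLASH_DIST))
    return -0.1 * contacts + 1.0 * clashes


def _heavy_coords(mol3d: Chem.Mol) -> np.ndarray:
    conf = mol3d.GetConformer()
    return np.array(
        [list(conf.GetAtomPosition(a.GetIdx())) for a in mol3d.GetAtoms() if a.GetAtomicNum() > 1]
    )


def dock_mock(mol3d: Chem.Mol, receptor: Receptor, config: DockingConfig,
              species_id: str = "") -> DockingResult:
    """Deterministic mock docking: translate to box center, score once."""
    conf = mol3d.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol3d.GetNumAtoms())])
    heavy = np.array([a.GetAtomicNum() > 1 for a in mol3d.GetAtoms()])
    centroid = coords[heavy].mean(axis=0) if heavy.any() else coords.mean(axis=0)
    placed = coords - centroid + np.asarray(config.box_center, dtype=float)
    score = mock_score(placed[heavy], receptor.atoms.coord[receptor.heavy_mask])
    pose = Pose(
        species_id=species_id,
        rank=1,
        score=round(float(score), 6),
        coordinates=tuple(tuple(float(x) for x in row) for row in placed),
    )
    return DockingResult(species_id, [pose], config.digest(), engine="mock-1")


def dock_vina(receptor_pdbqt: "str | Path", ligand_pdbqt: "str | Path",
              config: DockingConfig, species_id: str = "") -> DockingResult:
    """Invoke an AutoDock Vina binary on prepared PDBQT inputs."""
    exe = shutil.which("vina")
    if exe is None:
        raise EngineNotFoundError(
            "AutoDock Vina binary 'vina' not found on PATH; install it or use engine='mock'"
        )
    out_path = Path(ligand_pdbqt).with_suffix(".out.pdbqt")
    cx, cy, cz = config.box_center
    sx, sy, sz = config.box_size
    cmd = [
        exe,
        "--receptor", str(receptor_pdbqt),
        "--ligand", str(ligand_pdbqt),
        "--center_x", str(cx), "--center_y", str(cy), "--center_z", str(cz),
        "--size_x", str(sx), "--size_y", str(sy), "--size_z", str(sz),
        "--exhaustiveness", str(config.exhaustiveness),
        "--seed", str(config.seed),
        "--num_modes", str(config.n_poses_kept),
        "--out", str(out_path),
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise EngineRunError(f"vina exited {proc.returncode}: {proc.stderr.strip()}")
    poses = _parse_vina_out(out_path, species_id)
    version_line = next((l for l in proc.stdout.splitlines() if "AutoDock Vina" in l), "vina")
    return DockingResult(species_id, poses, config.digest(), engine=version_line.strip())


def _parse_vina_out(path: "str | Path", species_id: str) -> list[Pose]:
    poses: list[Pose] = []
    rank = 0
    score = None
    coords: list[tuple[float, float, float]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            rank += 1
            coords = []
        elif line.startswith("REMARK VINA RESULT:"):
            score = float(line.split()[3])
        elif line.startswith(("ATOM", "HETATM")):
            coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
        elif line.startswith("ENDMDL"):
            poses.append(Pose(species_id, rank, float(score), tuple(coords)))
    return poses


def dock(species3d: Chem.Mol, receptor: Receptor, config: DockingConfig,
         species_id: str = "", workdir: "str | Path | None" = None) -> DockingResult:
    """Dock one embedded species with the configured engine."""
    if config.engine == "mock":
        return dock_mock(species3d, receptor, config, species_id)
    if config.engine == "external_vina":
        import tempfile

        workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="focuslib_dock_"))
        prepared = prepare_inputs(receptor, species3d, workdir)
        return dock_vina(prepared["receptor_pdbqt"], prepared["ligand_pdbqt"], config, species_id)
    raise ContractError(f"unknown engine {config.engine!r}")


def select_best_pose(result: DockingResult) -> Pose:
    """The pose with the minimal score; ties broken by lowest rank."""
    if not result.poses:
        raise ContractError(f"empty docking result for {result.species_id}")
    return min(result.poses, key=lambda p: (p.score, p.rank))


def screen(species_list: Sequence, receptor: Receptor, config: DockingConfig,
           workers: int = 1) -> pd.DataFrame:
    """Dock every species; one row each, deterministic for any worker count.

    ``species_list`` holds objects with ``species_id`` and ``structure``
    attributes (or plain SMILES strings). Per-species failures become
    ``skipped`` rows instead of aborting the run.
    """

    def entry(item) -> tuple[str, str]:
        if isinstance(item, str):
            return item, item
        return item.species_id, item.structure

    def run_one(item) -> dict:
        species_id, smiles = entry(item)
        try:
            mol3d = embed_conformer(smiles, seed=config.seed)
            result = dock(mol3d, receptor, config, species_id)
            best = select_best_pose(result)
            return {"species_id": species_id, "best_score": best.score, "status": "ok"}
        except (EmbeddingError, EngineRunError) as exc:
            log.warning("species %s skipped: %s", species_id, exc)
            return {"species_id": species_id, "best_score": float("nan"),
                    "status": f"skipped: {type(exc).__name__}"}

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(run_one, species_list))
    else:
        rows = [run_one(item) for item in species_list]
    table = pd.DataFrame(rows, columns=["species_id", "best_score", "status"])
    return table.sort_values("species_id", kind="mergesort").reset_index(drop=True)
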