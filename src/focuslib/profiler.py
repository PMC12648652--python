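"""Geometric protein-ligand interaction profiling.

Rule-based detection of typed noncovalent contacts between a receptor
structure and a posed ligand, in the style of the standard interaction
profilers: hydrogen bonds, hydrophobic contacts, halogen bonds, pi-stacking
and salt bridges, each decided purely by distance/angle thresholds that are
all exposed in :class:`ProfilerConfig`. Every emitted contact carries the
geometry that satisfied its rule, so profiles are auditable.

Thresholds are closed intervals: a distance exactly at a maximum threshold
is detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .docking import Receptor, parse_residue_key
from .errors import ContractError

#: Sidechain ring atom names for receptor aromatic systems.
_RESIDUE_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [
        ["CG", "CD1", "CD2", "NE1", "CE2"],
        ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

#: Receptor charged groups: residue -> (atom names for the centroid, sign).
_RESIDUE_CHARGES: dict[str, tuple[list[str], int]] = {
    "ASP": (["OD1", "OD2"], -1),
    "GLU": (["OE1", "OE2"], -1),
    "LYS": (["NZ"], +1),
    "ARG": (["NE", "NH1", "NH2"], +1),
}

_HALOGENS = {"F", "CL", "BR", "I"}


@dataclass(frozen=True)
class ProfilerConfig:
    hbond_dist_max: float = 4.1  # A, donor-acceptor heavy atoms
    hbond_angle_min: float = 100.0  # deg, at the donor hydrogen
    hydrophobic_dist_max: float = 4.0  # A, carbon-carbon
    halogen_dist_max: float = 4.0  # A, X...acceptor
    halogen_donor_angle: float = 165.0  # deg, C-X...A target
    halogen_donor_tol: float = 30.0
    halogen_acceptor_angle: float = 120.0  # deg, Y-A...X target
    halogen_acceptor_tol: float = 30.0
    pistack_centroid_max: float = 5.5  # A
    pistack_angle_tol: float = 30.0  # deg, parallel or perpendicular
    saltbridge_dist_max: float = 5.5  # A, charged-group centroids
    shell_radius: float = 5.0  # A, pocket shell

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ContractError(f"profiler threshold {name} must be > 0")


@dataclass(frozen=True)
class Contact:
    kind: str  # hbond | hydrophobic | halogen_bond | pi_stack | salt_bridge
    chain: str
    resnum: int
    resname: str
    ligand_atoms: tuple[int, ...]
    geometry: tuple[tuple[str, float], ...]  # decision distances (A) / angles (deg)
    bw_label: Optional[str] = None

    @property
    def residue(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.resname)


@dataclass
class InteractionProfile:
    contacts: list[Contact]
    shell_residues: list[tuple[str, int, str]]
    receptor_residues: list[tuple[str, int, str]] = field(default_factory=list)
    hydrogen_mode: str = "explicit"  # explicit | heavy-proxy

    def by_kind(self, kind: str) -> list[Contact]:
        return [c for c in self.contacts if c.kind == kind]

    def contacted_residues(self, kind: Optional[str] = None) -> set[tuple[str, int, str]]:
        return {c.residue for c in self.contacts if kind is None or c.kind == kind}


# ---------------------------------------------------------------------------
# geometry helpers


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    cosine = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0))))


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


class _LigandView:
    """Coordinates, elements and bonding of a posed RDKit ligand."""

    def __init__(self, mol: Chem.Mol):
        if mol.GetNumConformers() == 0:
            raise ContractError("ligand has no 3D coordinates")
        self.mol = mol
        conf = mol.GetConformer()
        self.coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        self.elements = [a.GetSymbol().upper() for a in mol.GetAtoms()]
        self.heavy = np.array([a.GetAtomicNum() > 1 for a in mol.GetAtoms()])
        self.has_explicit_h = any(e == "H" for e in self.elements)

    def neighbors(self, idx: int) -> list[int]:
        return [n.GetIdx() for n in self.mol.GetAtomWithIdx(idx).GetNeighbors()]

    def donors(self) -> list[tuple[int, list[int]]]:
        """(heavy donor atom, attached hydrogen indices); proxy mode if no H."""
        out = []
        for atom in self.mol.GetAtoms():
            if atom.GetSymbol() not in ("N", "O", "S"):
                continue
            hydrogens = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
            if hydrogens or (not self.has_explicit_h and atom.GetTotalNumHs() > 0):
                out.append((atom.GetIdx(), hydrogens))
        return out

    def acceptors(self) -> list[int]:
        return [
            a.GetIdx()
            for a in self.mol.GetAtoms()
            if a.GetSymbol() in ("N", "O") and a.GetFormalCharge() <= 0
        ]

    def hydrophobic_carbons(self) -> list[int]:
        out = []
        for atom in self.mol.GetAtoms():
            if atom.GetSymbol() != "C":
                continue
            if all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors()):
                out.append(atom.GetIdx())
        return out

    def halogen_donors(self) -> list[tuple[int, int]]:
        """(halogen atom, bonded carbon) pairs."""
        out = []
        for atom in self.mol.GetAtoms():
            if atom.GetSymbol().upper() in _HALOGENS:
                carbons = [n.GetIdx() for n in atom.GetNeighbors() if n.GetSymbol() == "C"]
                if carbons:
                    out.append((atom.GetIdx(), carbons[0]))
        return out

    def aromatic_rings(self) -> list[list[int]]:
        info = self.mol.GetRingInfo()
        rings = []
        for ring in info.AtomRings():
            if all(self.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                rings.append(list(ring))
        return rings

    def charged_atoms(self) -> list[tuple[int, int]]:
        return [
            (a.GetIdx(), a.GetFormalCharge())
            for a in self.mol.GetAtoms()
            if a.GetFormalCharge() != 0
        ]


class _ReceptorView:
    """Receptor atoms with distance-inferred covalent adjacency."""

    BOND_CUTOFF = 1.75  # A, heavy-heavy covalent
    H_CUTOFF = 1.30  # A, X-H covalent

    def __init__(self, receptor: Receptor):
        atoms = receptor.atoms
        self.coords = atoms.coord
        self.elements = np.array([e.upper() for e in atoms.element])
        self.names = atoms.atom_name
        self.chains = atoms.chain_id
        self.resnums = atoms.res_id
        self.resnames = atoms.res_name
        self.heavy = self.elements != "H"
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        self._dist = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(self._dist, np.inf)

    def residue_of(self, idx: int) -> tuple[str, int, str]:
        return (str(self.chains[idx]), int(self.resnums[idx]), str(self.resnames[idx]))

    def bonded(self, idx: int) -> list[int]:
        cutoff = np.where(self.elements == "H", self.H_CUTOFF, self.BOND_CUTOFF)
        row = self._dist[idx]
        limit = np.minimum(cutoff, self.H_CUTOFF if self.elements[idx] == "H" else self.BOND_CUTOFF)
        return list(np.nonzero(row <= limit)[0])

    def attached_h(self, idx: int) -> list[int]:
        return [j for j in self.bonded(idx) if self.elements[j] == "H"]

    def heavy_neighbors(self, idx: int) -> list[int]:
        return [j for j in self.bonded(idx) if self.elements[j] != "H"]

    @property
    def has_hydrogens(self) -> bool:
        return bool(np.any(self.elements == "H"))

    def donors(self) -> list[tuple[int, list[int]]]:
        out = []
        for idx in np.nonzero(np.isin(self.elements, ("N", "O", "S")))[0]:
            idx = int(idx)
            hydrogens = self.attached_h(idx)
            if not hydrogens and self.has_hydrogens:
                continue
            if not hydrogens and self.elements[idx] == "O":
                # proxy mode: a double-bonded (carbonyl-like) oxygen cannot donate
                if any(self._dist[idx, j] < 1.28 for j in self.heavy_neighbors(idx)):
                    continue
            out.append((idx, hydrogens))
        return out

    def acceptors(self) -> list[int]:
        return [int(i) for i in np.nonzero(np.isin(self.elements, ("N", "O")))[0]]

    def hydrophobic_carbons(self) -> list[int]:
        out = []
        for idx in np.nonzero(self.elements == "C")[0]:
            neighbor_elements = {self.elements[j] for j in self.bonded(int(idx))}
            if neighbor_elements <= {"C", "H"}:
                out.append(int(idx))
        return out

    def rings(self) -> list[tuple[tuple[str, int, str], np.ndarray]]:
        out = []
        for residue in sorted(set(zip(map(str, self.chains), map(int, self.resnums),
                                      map(str, self.resnames)))):
            chain, resnum, resname = residue
            for ring_names in _RESIDUE_RINGS.get(resname, []):
                mask = (
                    (self.chains == chain)
                    & (self.resnums == resnum)
                    & (self.resnames == resname)
                    & np.isin(self.names, ring_names)
                )
                if mask.sum() == len(ring_names):
                    out.append((residue, self.coords[mask]))
        return out

    def charged_groups(self) -> list[tuple[tuple[str, int, str], np.ndarray, int]]:
        out = []
        for residue in sorted(set(zip(map(str, self.chains), map(int, self.resnums),
                                      map(str, self.resnames)))):
            chain, resnum, resname = residue
            if resname not in _RESIDUE_CHARGES:
                continue
            atom_names, sign = _RESIDUE_CHARGES[resname]
            mask = (
                (self.chains == chain)
                & (self.resnums == resnum)
                & np.isin(self.names, atom_names)
            )
            if mask.any():
                out.append((residue, self.coords[mask].mean(axis=0), sign))
        return out


def _within(value: float, target: float, tol: float) -> bool:
    return target - tol <= value <= target + tol


# ---------------------------------------------------------------------------
# detectors


def detect_hbonds(receptor: Receptor, ligand3d: Chem.Mol,
                  config: Optional[ProfilerConfig] = None) -> list[Contact]:
    """Donor-acceptor pairs within distance, with the D-H...A angle test.

    Both directions are scanned (ligand donor -> receptor acceptor and
    receptor donor -> ligand acceptor). Without explicit hydrogens on a
    side, that side degrades to the heavy-atom distance criterion.
    """
    config = config or ProfilerConfig()
    lig, rec = _LigandView(ligand3d), _ReceptorView(receptor)
    contacts = []

    def angle_ok(donor_xyz, h_coords, acceptor_xyz) -> tuple[bool, float]:
        if len(h_coords) == 0:
            return True, float("nan")  # heavy-proxy mode
        best = max(_angle(donor_xyz, h, acceptor_xyz) for h in h_coords)
        return best >= config.hbond_angle_min, best

    for donor_idx, hydrogens in lig.donors():
        for acceptor_idx in rec.acceptors():
            d = float(np.linalg.norm(lig.coords[donor_idx] - rec.coords[acceptor_idx]))
            if d > config.hbond_dist_max:
                continue
            ok, angle = angle_ok(lig.coords[donor_idx], [lig.coords[h] for h in hydrogens],
                                 rec.coords[acceptor_idx])
            if ok:
                contacts.append(Contact(
                    "hbond", *rec.residue_of(acceptor_idx), ligand_atoms=(donor_idx,),
                    geometry=(("dist", d), ("angle", angle)),
                ))
    for donor_idx, hydrogens in rec.donors():
        for acceptor_idx in lig.acceptors():
            d = float(np.linalg.norm(rec.coords[donor_idx] - lig.coords[acceptor_idx]))
            if d > config.hbond_dist_max:
                continue
            ok, angle = angle_ok(rec.coords[donor_idx], [rec.coords[h] for h in hydrogens],
                                 lig.coords[acceptor_idx])
            if ok:
                contacts.append(Contact(
                    "hbond", *rec.residue_of(donor_idx), ligand_atoms=(acceptor_idx,),
                    geometry=(("dist", d), ("angle", angle)),
                ))
    return _dedup(contacts)


def detect_hydrophobic(receptor: Receptor, ligand3d: Chem.Mol,
                       config: Optional[ProfilerConfig] = None) -> list[Contact]:
    """Apolar carbon-carbon proximity (both carbons bonded only to C/H)."""
    config = config or ProfilerConfig()
    lig, rec = _LigandView(ligand3d), _ReceptorView(receptor)
    contacts = []
    for li in lig.hydrophobic_carbons():
        for ri in rec.hydrophobic_carbons():
            d = float(np.linalg.norm(lig.coords[li] - rec.coords[ri]))
            if d <= config.hydrophobic_dist_max:
                contacts.append(Contact(
                    "hydrophobic", *rec.residue_of(ri), ligand_atoms=(li,),
                    geometry=(("dist", d),),
                ))
    return _dedup(contacts)


def detect_halogen(receptor: Receptor, ligand3d: Chem.Mol,
                   config: Optional[ProfilerConfig] = None) -> list[Contact]:
    """C-X...A halogen bonds with donor and acceptor angle windows."""
    config = config or ProfilerConfig()
    lig, rec = _LigandView(ligand3d), _ReceptorView(receptor)
    contacts = []
    for x_idx, c_idx in lig.halogen_donors():
        for a_idx in rec.acceptors():
            d = float(np.linalg.norm(lig.coords[x_idx] - rec.coords[a_idx]))
            if d > config.halogen_dist_max:
                continue
            donor_angle = _angle(lig.coords[c_idx], lig.coords[x_idx], rec.coords[a_idx])
            if not _within(donor_angle, config.halogen_donor_angle, config.halogen_donor_tol):
                continue
            neighbor_angles = [
                _angle(rec.coords[y], rec.coords[a_idx], lig.coords[x_idx])
                for y in rec.heavy_neighbors(a_idx)
            ]
            acceptor_ok = not neighbor_angles or any(
                _within(a, config.halogen_acceptor_angle, config.halogen_acceptor_tol)
                for a in neighbor_angles
            )
            if acceptor_ok:
                acc_angle = neighbor_angles[0] if neighbor_angles else float("nan")
                contacts.append(Contact(
                    "halogen_bond", *rec.residue_of(a_idx), ligand_atoms=(x_idx,),
                    geometry=(("dist", d), ("donor_angle", donor_angle),
                              ("acceptor_angle", acc_angle)),
                ))
    return _dedup(contacts)


def detect_pistack(receptor: Receptor, ligand3d: Chem.Mol,
                   config: Optional[ProfilerConfig] = None) -> list[Contact]:
    """Aromatic ring stacking: centroid distance + parallel/perpendicular normals."""
    config = config or ProfilerConfig()
    lig, rec = _LigandView(ligand3d), _ReceptorView(receptor)
    contacts = []
    for ring in lig.aromatic_rings():
        lig_coords = lig.coords[ring]
        lig_centroid = lig_coords.mean(axis=0)
        lig_normal = _ring_normal(lig_coords)
        for residue, ring_coords in rec.rings():
            centroid = ring_coords.mean(axis=0)
            d = float(np.linalg.norm(lig_centroid - centroid))
            if d > config.pistack_centroid_max:
                continue
            normal = _ring_normal(ring_coords)
            delta = _angle(lig_normal + centroid, centroid, normal + centroid)
            delta = min(delta, 180.0 - delta)
            parallel = delta <= config.pistack_angle_tol
            perpendicular = abs(delta - 90.0) <= config.pistack_angle_tol
            if parallel or perpendicular:
                contacts.append(Contact(
                    "pi_stack", *residue, ligand_atoms=tuple(sorted(ring)),
                    geometry=(("dist", d), ("normal_angle", delta)),
                ))
    return _dedup(contacts)


def detect_saltbridge(receptor: Receptor, ligand3d: Chem.Mol,
                      config: Optional[ProfilerConfig] = None) -> list[Contact]:
    """Opposite formal charges within the centroid distance threshold."""
    config = config or ProfilerConfig()
    lig, rec = _LigandView(ligand3d), _ReceptorView(receptor)
    contacts = []
    for atom_idx, charge in lig.charged_atoms():
        for residue, centroid, sign in rec.charged_groups():
            if charge * sign >= 0:
                continue
            d = float(np.linalg.norm(lig.coords[atom_idx] - centroid))
            if d <= config.saltbridge_dist_max:
                contacts.append(Contact(
                    "salt_bridge", *residue, ligand_atoms=(atom_idx,),
                    geometry=(("dist", d),),
                ))
    return _dedup(contacts)


def _dedup(contacts: list[Contact]) -> list[Contact]:
    seen = {}
    for c in contacts:
        key = (c.kind, c.residue, c.ligand_atoms)
        if key not in seen:
            seen[key] = c
    return sorted(seen.values(), key=lambda c: (c.kind, c.residue, c.ligand_atoms))


_DETECTORS: tuple[Callable, ...] = (
    detect_hbonds,
    detect_hydrophobic,
    detect_halogen,
    detect_pistack,
    detect_saltbridge,
)


def shell_residues(receptor: Receptor, ligand3d: Chem.Mol,
                   radius: float = 5.0) -> list[tuple[str, int, str]]:
    """Residues with any heavy atom within ``radius`` of any ligand heavy atom."""
    lig = _LigandView(ligand3d)
    rec = _ReceptorView(receptor)
    lig_heavy = lig.coords[lig.heavy]
    out = []
    for residue in sorted(set(zip(map(str, rec.chains), map(int, rec.resnums),
                                  map(str, rec.resnames)))):
        chain, resnum, resname = residue
        mask = ((rec.chains == chain) & (rec.resnums == resnum)
                & (rec.resnames == resname) & rec.heavy)
        if not mask.any() or len(lig_heavy) == 0:
            continue
        diff = rec.coords[mask][:, None, :] - lig_heavy[None, :, :]
        if np.sqrt((diff**2).sum(axis=2)).min() <= radius:
            out.append(residue)
    return out


def profile_pose(receptor: Receptor, ligand3d: Chem.Mol,
                 config: Optional[ProfilerConfig] = None) -> InteractionProfile:
    """Full typed-contact profile of one pose.

    Contacts are the union of the per-kind detectors, restricted to the
    pocket shell (residues within ``shell_radius`` of the ligand).
    """
    config = config or ProfilerConfig()
    shell = shell_residues(receptor, ligand3d, config.shell_radius)
    shell_set = set(shell)
    contacts = []
    for detector in _DETECTORS:
        contacts.extend(c for c in detector(receptor, ligand3d, config)
                        if c.residue in shell_set)
    rec = _ReceptorView(receptor)
    mode = "explicit" if rec.has_hydrogens and _LigandView(ligand3d).has_explicit_h else "heavy-proxy"
    return InteractionProfile(
        contacts=sorted(contacts, key=lambda c: (c.kind, c.residue, c.ligand_atoms)),
        shell_residues=shell,
        receptor_residues=[(str(c), int(n), str(r)) for c, n, r in
                           sorted(set(zip(map(str, rec.chains), map(int, rec.resnums),
                                          map(str, rec.resnames))))],
        hydrogen_mode=mode,
    )


# ---------------------------------------------------------------------------
# prevalence over frames and residue-map application


def hbond_to_at_least(residue_keys: Sequence[str], k: int = 1) -> Callable[[InteractionProfile], bool]:
    """Named predicate: H-bond contact with at least ``k`` of the residues."""
    targets = [parse_residue_key(key) for key in residue_keys]

    def predicate(profile: InteractionProfile) -> bool:
        contacted = profile.contacted_residues("hbond")
        hits = sum(
            any(resname.upper() == c_name and resnum == c_num
                and (not chain or chain == c_chain)
                for c_chain, c_num, c_name in contacted)
            for chain, resname, resnum in targets
        )
        return hits >= k

    predicate.__name__ = f"hbond_to_at_least_{k}_of_{len(targets)}"
    return predicate


@dataclass
class PrevalenceResult:
    fraction: float
    trail: list[bool]  # per-frame booleans, in frame order


def prevalence(frames: Sequence[tuple[Receptor, Chem.Mol]],
               config: Optional[ProfilerConfig] = None,
               predicate: Optional[Callable[[InteractionProfile], bool]] = None) -> PrevalenceResult:
    """Fraction of frames whose profile satisfies the predicate."""
    if not frames:
        raise ContractError("prevalence requires at least one frame")
    if predicate is None:
        raise ContractError("prevalence requires a named predicate")
    config = config or ProfilerConfig()
    trail = [bool(predicate(profile_pose(receptor, ligand, config)))
             for receptor, ligand in frames]
    return PrevalenceResult(sum(trail) / len(trail), trail)


def apply_residue_map(profile: InteractionProfile,
                      residue_map: dict[str, str]) -> InteractionProfile:
    """Annotate contacts with generic (Ballesteros-Weinstein) labels.

    Keys like ``"Glu302"`` must resolve against the receptor's residues;
    unmapped residues keep a blank label, never a guessed one.
    """
    if not residue_map:
        return profile
    known = {(num, name.upper()) for _, num, name in profile.receptor_residues}
    parsed = {}
    missing = []
    for key, label in residue_map.items():
        chain, resname, resnum = parse_residue_key(key)
        if (resnum, resname.upper()) not in known:
            missing.append(key)
        parsed[(resnum, resname.upper())] = label
    if missing:
        raise ContractError(f"residue_map keys not in receptor: {missing}")
    contacts = [
        replace(c, bw_label=parsed.get((c.resnum, c.resname.upper()), c.bw_label))
        for c in profile.contacts
    ]
    return InteractionProfile(contacts, list(profile.shell_residues),
                              list(profile.receptor_residues), profile.hydrogen_mode)
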