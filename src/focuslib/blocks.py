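"""Building-block modeling: loading, role classification and retrosynthesis.

The combinatorial chemistry of the toolkit is amine N-sulfonylation: a
primary amine on an azine ring (2-aminopyrazines and relatives) reacts with
an aryl sulfonyl chloride to give an N-(azinyl) arylsulfonamide. This module
owns the substructure vocabulary for the two block roles and the product
scaffold, and the inverse operation (retro-decomposition of a sulfonamide
back into its block pair).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem

from .chem import as_mol, canonical_smiles, mol_from_smiles
from .errors import EmptyInputError, InputFileError, ParseError

log = logging.getLogger(__name__)

#: Primary aromatic amine attached to a six-membered azine ring. The three
#: recursive alternatives place a ring nitrogen ortho, meta or para to the
#: attachment carbon, which covers every mono/poly-azine by symmetry.
AMINE_SMARTS = "[NX3;H2][c;r6;$(c1aaaan1),$(c1aaana1),$(c1aanaa1)]"

#: Aryl sulfonyl chloride.
SULFONYL_CHLORIDE_SMARTS = "[c]S(=O)(=O)Cl"

#: Product scaffold query as used for substructure searches of the series
#: (ring-aryl sulfonamide of 2-aminopyrazine).
SCAFFOLD_SMARTS = "[c;R]S(O)(O)Nc1cnccn1"


class Role(str, Enum):
    AMINO_HETEROARENE = "amino_heteroarene"
    SULFONYL_CHLORIDE = "sulfonyl_chloride"
    UNKNOWN = "unknown"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BuildingBlock:
    """A reactive fragment with canonical structure and provenance."""

    id: str
    structure: str  # canonical SMILES (salt-stripped, neutralized)
    role: Role = Role.UNKNOWN
    availability: Optional[str] = None
    source_file: Optional[str] = None

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.structure)


def _compile_scaffold(smarts: str) -> Chem.Mol:
    """Compile the scaffold query with sulfonyl S-O bonds relaxed to any order.

    Substructure engines used for registry searches treat a query drawn as
    S(O)(O) as matching the sulfonyl group; SMARTS default bond semantics
    (single-or-aromatic) would not. Terminal oxygens on a query sulfur
    therefore get an unspecified bond order here so the printed query matches
    every coupling product.
    """
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise ParseError(f"invalid SMARTS: {smarts!r}")
    for bond in query.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        pair = {a.GetAtomicNum(), b.GetAtomicNum()}
        if pair == {16, 8}:
            oxygen = a if a.GetAtomicNum() == 8 else b
            if oxygen.GetDegree() == 1:
                bond.SetQuery(Chem.BondFromSmarts("~"))
    return query


@dataclass
class PatternSet:
    """The role-defining and scaffold substructure queries."""

    amine_pattern: str = AMINE_SMARTS
    sulfonyl_chloride_pattern: str = SULFONYL_CHLORIDE_SMARTS
    scaffold_pattern: str = SCAFFOLD_SMARTS
    _compiled: dict = field(default_factory=dict, repr=False)

    def _query(self, name: str, smarts: str, scaffold: bool = False) -> Chem.Mol:
        if name not in self._compiled:
            q = _compile_scaffold(smarts) if scaffold else Chem.MolFromSmarts(smarts)
            if q is None:
                raise ParseError(f"invalid SMARTS for {name}: {smarts!r}")
            self._compiled[name] = q
        return self._compiled[name]

    @property
    def amine_query(self) -> Chem.Mol:
        return self._query("amine", self.amine_pattern)

    @property
    def sulfonyl_query(self) -> Chem.Mol:
        return self._query("sulfonyl", self.sulfonyl_chloride_pattern)

    @property
    def scaffold_query(self) -> Chem.Mol:
        return self._query("scaffold", self.scaffold_pattern, scaffold=True)


def classify_block(block: BuildingBlock, patterns: Optional[PatternSet] = None) -> Role:
    """Assign a role from the substructure vocabulary.

    A block matching both role patterns is flagged ``AMBIGUOUS`` (it would be
    self-reactive) and is excluded from enumeration by the callers.
    """
    patterns = patterns or PatternSet()
    mol = block.mol()
    is_amine = mol.HasSubstructMatch(patterns.amine_query)
    is_sulfonyl = mol.HasSubstructMatch(patterns.sulfonyl_query)
    if is_amine and is_sulfonyl:
        log.warning("block %s matches both role patterns; flagged ambiguous", block.id)
        return Role.AMBIGUOUS
    if is_amine:
        return Role.AMINO_HETEROARENE
    if is_sulfonyl:
        return Role.SULFONYL_CHLORIDE
    return Role.UNKNOWN


def n_reactive_sites(block: BuildingBlock, patterns: Optional[PatternSet] = None) -> int:
    """Count distinct reactive sites for the block's role (0 for unknown)."""
    patterns = patterns or PatternSet()
    mol = block.mol()
    role = classify_block(block, patterns)
    if role is Role.AMINO_HETEROARENE:
        query = patterns.amine_query
    elif role is Role.SULFONYL_CHLORIDE:
        query = patterns.sulfonyl_query
    else:
        return 0
    return len(mol.GetSubstructMatches(query))


def parse_block_file(path: "str | Path") -> tuple[list[tuple[str, str]], int]:
    """Read a SMILES (``structure [id]`` per line) or SDF file.

    Returns ``(records, n_rejected)`` where records are ``(smiles, id)``
    pairs for every parseable molecule. Rejections are counted and logged,
    never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    records: list[tuple[str, str]] = []
    n_rejected = 0
    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_rejected += 1
                log.warning("%s: SDF record %d unparseable", path, i + 1)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{path.stem}_{i + 1}"
            records.append((Chem.MolToSmiles(mol), name or f"{path.stem}_{i + 1}"))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                smiles = fields[0]
                name = fields[1] if len(fields) > 1 else f"{path.stem}_{i + 1}"
                if Chem.MolFromSmiles(smiles) is None:
                    n_rejected += 1
                    log.warning("%s: line %d unparseable: %r", path, i + 1, smiles)
                    continue
                records.append((smiles, name))
    return records, n_rejected


def load_blocks(
    path: "str | Path",
    role_hint: Optional[Role] = None,
    patterns: Optional[PatternSet] = None,
    availability: Optional[dict[str, str]] = None,
) -> list[BuildingBlock]:
    """Load building blocks from a structure file and classify them.

    Every parseable record yields one block with canonical structure;
    unparseable records are counted in the log. ``role_hint`` is only a
    cross-check: classification always comes from the patterns, and a
    mismatch with the hint is logged.
    """
    patterns = patterns or PatternSet()
    records, n_rejected = parse_block_file(path)
    if not records:
        raise EmptyInputError(f"{path}: no parseable records ({n_rejected} rejected)")
    blocks = []
    for smiles, block_id in records:
        block = BuildingBlock(
            id=block_id,
            structure=canonical_smiles(smiles),
            source_file=str(path),
            availability=(availability or {}).get(block_id),
        )
        role = classify_block(block, patterns)
        if role_hint is not None and role is not role_hint:
            log.warning("block %s classified %s, hint was %s", block_id, role.value, role_hint.value)
        blocks.append(BuildingBlock(block.id, block.structure, role, block.availability, block.source_file))
    if n_rejected:
        log.info("%s: %d blocks loaded, %d records rejected", path, len(blocks), n_rejected)
    return blocks


def load_role_sidecar(path: "str | Path") -> dict[str, dict[str, str]]:
    """Read an ``id,role,availability`` CSV sidecar into a mapping."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = {"role": row.get("role", ""), "availability": row.get("availability", "")}
    return out


def write_block_table(blocks: Iterable[BuildingBlock], path: "str | Path",
                      patterns: Optional[PatternSet] = None) -> None:
    """Write the normalized block table CSV."""
    patterns = patterns or PatternSet()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "canonical_structure", "role", "n_reactive_sites", "source_file"])
        for b in blocks:
            source = Path(b.source_file).name if b.source_file else ""
            writer.writerow([b.id, b.structure, b.role.value, n_reactive_sites(b, patterns), source])


def match_scaffold(molecule: "str | Chem.Mol", patterns: Optional[PatternSet] = None) -> bool:
    """True iff the product-scaffold query has at least one embedding."""
    patterns = patterns or PatternSet()
    return as_mol(molecule).HasSubstructMatch(patterns.scaffold_query)


#: Sulfonamide linkage in the scaffold context: ring-aryl S(=O)(=O) bonded to
#: an N-H nitrogen on an azine carbon. Atom order: aryl-C, S, O, O, N, azinyl-C.
_RETRO_SMARTS = "[c;R:1][S:2](~[OX1])(~[OX1])[NX3;H1:3][c;r6;$(c1aaaan1),$(c1aaana1),$(c1aanaa1):4]"


def retro_decompose(molecule: "str | Chem.Mol",
                    patterns: Optional[PatternSet] = None) -> list[tuple[str, str]]:
    """Cut each scaffold-context sulfonamide N-S bond into its block pair.

    Returns canonical ``(amine, sulfonyl_chloride)`` SMILES pairs, one per
    distinct cut: the amine recovers its N-H, the sulfur is capped with Cl.
    Molecules without a matching bond yield an empty list.
    """
    del patterns  # retro context is fixed by the coupling chemistry
    mol = Chem.AddHs(as_mol(molecule))
    query = Chem.MolFromSmarts(_RETRO_SMARTS)
    pairs: list[tuple[str, str]] = []
    seen = set()
    for match in mol.GetSubstructMatches(query):
        s_idx, n_idx = match[1], match[4]
        rw = Chem.RWMol(mol)
        rw.RemoveBond(s_idx, n_idx)
        chlorine = rw.AddAtom(Chem.Atom(17))
        rw.AddBond(s_idx, chlorine, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(n_idx).SetNumExplicitHs(1)
        cut = rw.GetMol()
        frag_indices = Chem.GetMolFrags(cut)
        fragments = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=False)
        amine = sulfonyl = None
        for indices, frag in zip(frag_indices, fragments):
            Chem.SanitizeMol(frag)
            smiles = canonical_smiles(Chem.RemoveHs(frag))
            if n_idx in indices:
                amine = smiles
            elif s_idx in indices:
                sulfonyl = smiles
        if amine and sulfonyl and (amine, sulfonyl) not in seen:
            seen.add((amine, sulfonyl))
            pairs.append((amine, sulfonyl))
    return sorted(pairs)
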