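"""Small-molecule canonicalization helpers shared across modules.

All structures handled by the toolkit are normalized through
:func:`canonical_smiles` before identity comparisons: the largest covalent
fragment is kept (salt stripping) and formal charges are neutralized where
chemically sensible. Ionization is reintroduced deliberately, later, by the
state-expansion stage; everything upstream works on the neutral parent.
"""

from __future__ import annotations

import hashlib

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ParseError

RDLogger.DisableLog("rdApp.*")

_UNCHARGER = rdMolStandardize.Uncharger()
_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`ParseError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def as_mol(molecule: "str | Chem.Mol") -> Chem.Mol:
    """Accept either a SMILES string or an RDKit Mol."""
    if isinstance(molecule, Chem.Mol):
        return molecule
    return mol_from_smiles(molecule)


def normalize(mol: Chem.Mol) -> Chem.Mol:
    """Salt-strip (largest fragment) and neutralize formal charges."""
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def canonical_smiles(molecule: "str | Chem.Mol", strip_salts: bool = True) -> str:
    """Canonical isomeric SMILES after normalization.

    Idempotent: ``canonical_smiles(canonical_smiles(x)) == canonical_smiles(x)``.
    """
    mol = as_mol(molecule)
    if strip_salts:
        mol = normalize(mol)
    return Chem.MolToSmiles(mol)


def structure_hash(canonical: str, length: int = 16) -> str:
    """Stable cross-platform identifier: truncated SHA-256 of a canonical SMILES."""
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:length]
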