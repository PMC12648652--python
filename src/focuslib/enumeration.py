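"""Exhaustive virtual N-sulfonylation of amine x sulfonyl-chloride blocks.

The coupling is expressed as an RDKit reaction template (primary azinyl
amine + aryl sulfonyl chloride -> sulfonamide, HCl lost). Enumeration runs
the template over the full Cartesian product of the two role classes,
canonicalizes and deduplicates the products, and keeps every contributing
block pair as provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .blocks import BuildingBlock, PatternSet, Role, classify_block
from .chem import canonical_smiles, structure_hash
from .errors import EmptyInputError, FormatError, RoleError

log = logging.getLogger(__name__)

#: Amine N-sulfonylation: the amine nitrogen keeps one hydrogen, the
#: chloride leaves. The amine carbon is constrained to a six-membered
#: aromatic ring; role classification upstream restricts it to azines.
N_SULFONYLATION_SMARTS = (
    "[NX3;H2:1][c;r6:2].[S:3](=[O:4])(=[O:5])[Cl]>>[NX3;H1:1]([c:2])[S:3](=[O:4])(=[O:5])"
)


@dataclass(frozen=True)
class ReactionTemplate:
    name: str = "amine_n_sulfonylation"
    transform: str = N_SULFONYLATION_SMARTS

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.transform)
        rxn.Initialize()
        return rxn


@dataclass(frozen=True)
class LibraryProduct:
    """One unique coupling product with full block provenance."""

    product_id: str  # stable hash of the canonical structure
    structure: str  # canonical neutral product SMILES
    provenance: tuple[tuple[str, str], ...]  # all contributing (amine_id, sulfonyl_id)
    reaction: str = "amine_n_sulfonylation"

    @property
    def amine_id(self) -> str:
        return self.provenance[0][0]

    @property
    def sulfonyl_id(self) -> str:
        return self.provenance[0][1]


@dataclass
class Library:
    products: list[LibraryProduct]
    template: str = "amine_n_sulfonylation"
    n_amines: int = 0
    n_sulfonyls: int = 0

    def __len__(self) -> int:
        return len(self.products)

    def structures(self) -> list[str]:
        return [p.structure for p in self.products]


def couple(
    amine: BuildingBlock,
    sulfonyl: BuildingBlock,
    template: Optional[ReactionTemplate] = None,
    patterns: Optional[PatternSet] = None,
) -> list[LibraryProduct]:
    """Apply the coupling to one block pair.

    One product per distinct reactive-site combination, canonically
    deduplicated (symmetric sites collapse). Role mismatch is a contract
    error, not a silent empty result.
    """
    template = template or ReactionTemplate()
    patterns = patterns or PatternSet()
    if classify_block(amine, patterns) is not Role.AMINO_HETEROARENE:
        raise RoleError(f"block {amine.id} is not an amino-heteroarene")
    if classify_block(sulfonyl, patterns) is not Role.SULFONYL_CHLORIDE:
        raise RoleError(f"block {sulfonyl.id} is not a sulfonyl chloride")
    rxn = template.reaction()
    products: dict[str, LibraryProduct] = {}
    for product_set in rxn.RunReactants((amine.mol(), sulfonyl.mol())):
        for product in product_set:
            try:
                Chem.SanitizeMol(product)
            except Exception:  # noqa: BLE001 - malformed site combination
                continue
            smiles = canonical_smiles(product)
            if smiles not in products:
                products[smiles] = LibraryProduct(
                    product_id=structure_hash(smiles),
                    structure=smiles,
                    provenance=((amine.id, sulfonyl.id),),
                    reaction=template.name,
                )
    return [products[s] for s in sorted(products)]


def enumerate_library(
    amines: Sequence[BuildingBlock],
    sulfonyls: Sequence[BuildingBlock],
    template: Optional[ReactionTemplate] = None,
    patterns: Optional[PatternSet] = None,
) -> Library:
    """Couple every amine with every sulfonyl chloride and deduplicate.

    The result is sorted by canonical structure, so it is invariant to the
    input order; duplicate products arising from different block pairs keep
    every contributing pair in their provenance.
    """
    template = template or ReactionTemplate()
    patterns = patterns or PatternSet()
    if not amines:
        raise EmptyInputError("no amino-heteroarene blocks to enumerate")
    if not sulfonyls:
        raise EmptyInputError("no sulfonyl-chloride blocks to enumerate")
    merged: dict[str, list[tuple[str, str]]] = {}
    for amine in amines:
        for sulfonyl in sulfonyls:
            for product in couple(amine, sulfonyl, template, patterns):
                merged.setdefault(product.structure, []).extend(product.provenance)
    products = [
        LibraryProduct(
            product_id=structure_hash(smiles),
            structure=smiles,
            provenance=tuple(sorted(set(merged[smiles]))),
            reaction=template.name,
        )
        for smiles in sorted(merged)
    ]
    log.info("enumerated %d unique products from %d x %d blocks",
             len(products), len(amines), len(sulfonyls))
    return Library(products, template.name, len(amines), len(sulfonyls))


def _digest_file(path: "str | Path") -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_library(library: Library, path: "str | Path",
                  input_files: Iterable["str | Path"] = ()) -> dict:
    """Write the library as tab-separated SMILES plus a JSON manifest.

    One row per (product, provenance pair); the manifest records counts, the
    template name and digests of the input block files. Returns the manifest.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("structure\tproduct_id\tamine_id\tsulfonyl_id\n")
        for product in library.products:
            for amine_id, sulfonyl_id in product.provenance:
                fh.write(f"{product.structure}\t{product.product_id}\t{amine_id}\t{sulfonyl_id}\n")
    manifest = {
        "count": len(library),
        "template": library.template,
        "n_amines": library.n_amines,
        "n_sulfonyls": library.n_sulfonyls,
        "input_digests": {Path(p).name: _digest_file(p) for p in input_files},
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_library(path: "str | Path") -> Library:
    """Read a library file back; lossless inverse of :func:`write_library`."""
    path = Path(path)
    merged: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["structure", "product_id", "amine_id", "sulfonyl_id"]:
            raise FormatError(f"{path}: unexpected header {header!r}")
        for i, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 or not all(fields):
                raise FormatError(f"{path}: malformed record at line {i}: {line!r}")
            structure, product_id, amine_id, sulfonyl_id = fields
            entry = merged.setdefault(structure, {"product_id": product_id, "pairs": []})
            if entry["product_id"] != product_id:
                raise FormatError(f"{path}: conflicting product_id at line {i}")
            entry["pairs"].append((amine_id, sulfonyl_id))
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    template = "amine_n_sulfonylation"
    n_amines = n_sulfonyls = 0
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        template = manifest.get("template", template)
        n_amines = manifest.get("n_amines", 0)
        n_sulfonyls = manifest.get("n_sulfonyls", 0)
    products = [
        LibraryProduct(
            product_id=merged[s]["product_id"],
            structure=s,
            provenance=tuple(sorted(set(merged[s]["pairs"]))),
            reaction=template,
        )
        for s in sorted(merged)
    ]
    return Library(products, template, n_amines, n_sulfonyls)
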