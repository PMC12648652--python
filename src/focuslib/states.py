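"""Protonation and tautomer ("chemical species") expansion of a library.

Docking treats each protonation/tautomer variant as a separate species.
Expansion works the way pH-window rule engines do: every ionizable site is
matched against the vendored pKa rule table (:mod:`focuslib.pka_table`); a
site whose pKa +/- ``pka_precision`` interval overlaps the configured pH
window contributes both its neutral and its ionized form, a site clearly
outside the window contributes only its dominant form. Tautomers are
enumerated first (RDKit canonical tautomer rules), protomers second, and
the cross-product is canonically deduplicated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem import as_mol, canonical_smiles, structure_hash
from .enumeration import Library
from .errors import ParseError
from .pka_table import PKA_RULES, TABLE_VERSION, PkaRule

log = logging.getLogger(__name__)

TAUTOMER_RULESET = "rdkit-rdMolStandardize-TautomerEnumerator"


@dataclass(frozen=True)
class StateConfig:
    """pH window and caps for species enumeration.

    The defaults are the physiologically relevant window used for the
    screening library: pH 6.0-7.2, site pKa precision 1.0 pH unit, at most
    128 protonation variants per molecule.
    """

    ph_min: float = 6.0
    ph_max: float = 7.2
    pka_precision: float = 1.0
    max_variants: int = 128
    enumerate_tautomers: bool = True
    tautomer_cap: int = 16

    def __post_init__(self) -> None:
        if self.ph_min > self.ph_max:
            raise ValueError("ph_min must be <= ph_max")
        if self.max_variants < 1:
            raise ValueError("max_variants must be >= 1")


@dataclass(frozen=True)
class Species:
    species_id: str
    structure: str  # canonical SMILES with explicit formal charges
    parent_product_id: str
    kind: str  # protomer | tautomer | protomer+tautomer


def _match_sites(mol: Chem.Mol) -> list[tuple[int, PkaRule]]:
    """Assign at most one pKa rule per atom, first matching rule wins."""
    claimed: dict[int, PkaRule] = {}
    for rule in PKA_RULES:
        query = Chem.MolFromSmarts(rule.smarts)
        for match in mol.GetSubstructMatches(query):
            atom = match[rule.atom_index]
            if atom not in claimed:
                claimed[atom] = rule
    return sorted(claimed.items())


def _site_states(rule: PkaRule, config: StateConfig) -> list[int]:
    """Charge deltas (-1 deprotonated, 0 neutral, +1 protonated) for a site."""
    lo, hi = rule.pka - config.pka_precision, rule.pka + config.pka_precision
    overlaps = lo <= config.ph_max and hi >= config.ph_min
    if rule.kind == "acid":
        if overlaps:
            return [0, -1]
        return [-1] if hi < config.ph_min else [0]
    # base: protonated below its pKa
    if overlaps:
        return [0, +1]
    return [+1] if lo > config.ph_max else [0]


def _apply_states(mol: Chem.Mol, assignment: list[tuple[int, int]]) -> Optional[str]:
    """Apply per-atom charge deltas; returns canonical SMILES or None."""
    rw = Chem.RWMol(mol)
    for atom_idx, delta in assignment:
        atom = rw.GetAtomWithIdx(atom_idx)
        if delta == -1:
            if atom.GetTotalNumHs() < 1:
                return None
            atom.SetFormalCharge(atom.GetFormalCharge() - 1)
            atom.SetNumExplicitHs(max(atom.GetTotalNumHs() - 1, 0))
            atom.SetNoImplicit(True)
        elif delta == +1:
            atom.SetFormalCharge(atom.GetFormalCharge() + 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            atom.SetNoImplicit(True)
    try:
        product = rw.GetMol()
        Chem.SanitizeMol(product)
    except Exception:  # noqa: BLE001 - chemically impossible combination
        return None
    return canonical_smiles(product, strip_salts=False)


def enumerate_protomers(molecule: "str | Chem.Mol", config: Optional[StateConfig] = None) -> list[str]:
    """All protonation variants relevant in the configured pH window.

    Always contains at least one state (the input itself when no site is
    ionizable in the window); canonically deduplicated, sorted, and capped
    at ``max_variants`` by keeping the lexicographically first structures.
    """
    config = config or StateConfig()
    mol = as_mol(molecule)
    sites = _match_sites(mol)
    variants: set[str] = set()
    site_choices = [[(idx, delta) for delta in _site_states(rule, config)] for idx, rule in sites]
    # keep the combinatorics bounded before the variant cap is applied
    if site_choices:
        n_combinations = 1
        for choices in site_choices:
            n_combinations *= len(choices)
        if n_combinations > 4 * config.max_variants:
            site_choices = site_choices[: max(1, config.max_variants.bit_length() + 1)]
        for assignment in itertools.product(*site_choices):
            smiles = _apply_states(mol, list(assignment))
            if smiles is not None:
                variants.add(smiles)
    if not variants:  # no ionizable center, or every edit was impossible
        variants.add(canonical_smiles(mol, strip_salts=False))
    return sorted(variants)[: config.max_variants]


def enumerate_tautomers(molecule: "str | Chem.Mol", cap: int = 16) -> list[str]:
    """Canonical deduplicated tautomer list, guaranteed to contain the input."""
    mol = as_mol(molecule)
    own = canonical_smiles(mol, strip_salts=False)
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(max(cap, 1))
    others = sorted(
        {canonical_smiles(t, strip_salts=False) for t in enumerator.Enumerate(mol)} - {own}
    )
    return ([own] + others)[: max(cap, 1)]


def _classify_kind(structure: str, parent: str) -> str:
    """Label a species relative to its neutral parent product."""
    if structure == parent:
        return "protomer"  # the unshifted neutral protomer
    mol = Chem.MolFromSmiles(structure)
    charged = any(a.GetFormalCharge() != 0 for a in mol.GetAtoms())
    neutralized = canonical_smiles(structure)  # uncharges back to a neutral frame
    taut_shifted = neutralized != parent
    if charged and taut_shifted:
        return "protomer+tautomer"
    if taut_shifted:
        return "tautomer"
    return "protomer"


def expand_product(structure: str, config: Optional[StateConfig] = None) -> list[tuple[str, str]]:
    """Expand one product into ``(structure, kind)`` species, deduplicated."""
    config = config or StateConfig()
    parent = canonical_smiles(structure)
    tautomers = (
        enumerate_tautomers(parent, config.tautomer_cap)
        if config.enumerate_tautomers
        else [parent]
    )
    seen: dict[str, str] = {}
    for tautomer in tautomers:
        for protomer in enumerate_protomers(tautomer, config):
            if protomer not in seen:
                seen[protomer] = _classify_kind(protomer, parent)
    return [(s, seen[s]) for s in sorted(seen)]


def expand_library(library: Library, config: Optional[StateConfig] = None) -> tuple[list[Species], dict]:
    """Expand every product; returns (species, stage manifest).

    Species are globally deduplicated on (parent product, canonical
    structure) and deterministically ordered by (parent, structure). Parse
    failures are reported with the offending product_id.
    """
    config = config or StateConfig()
    species: list[Species] = []
    for product in library.products:
        try:
            expanded = expand_product(product.structure, config)
        except ParseError as exc:
            raise ParseError(f"product {product.product_id}: {exc}") from exc
        for structure, kind in expanded:
            species.append(
                Species(
                    species_id=structure_hash(f"{product.product_id}:{structure}"),
                    structure=structure,
                    parent_product_id=product.product_id,
                    kind=kind,
                )
            )
    species.sort(key=lambda s: (s.parent_product_id, s.structure))
    manifest = {
        "products_in": len(library),
        "species_out": len(species),
        "config": {
            "ph_min": config.ph_min,
            "ph_max": config.ph_max,
            "pka_precision": config.pka_precision,
            "max_variants": config.max_variants,
            "enumerate_tautomers": config.enumerate_tautomers,
            "tautomer_cap": config.tautomer_cap,
        },
        "order": "tautomers-then-protomers",
        "pka_table": TABLE_VERSION,
        "tautomer_ruleset": TAUTOMER_RULESET,
    }
    log.info("expanded %d products into %d species", len(library), len(species))
    return species, manifest


def write_species(species: list[Species], path, manifest: Optional[dict] = None) -> None:
    """Write species as tab-separated SMILES plus an optional manifest."""
    import json
    from pathlib import Path

    path = Path(path)
    with open(path, "w") as fh:
        fh.write("structure\tspecies_id\tparent_product_id\tkind\n")
        for s in species:
            fh.write(f"{s.structure}\t{s.species_id}\t{s.parent_product_id}\t{s.kind}\n")
    if manifest is not None:
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
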