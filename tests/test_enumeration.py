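"""Combinatorial enumeration against an independent brute-force oracle."""

import pytest

from focuslib.blocks import BuildingBlock, Role
from focuslib.chem import canonical_smiles
from focuslib.enumeration import (
    ReactionTemplate,
    couple,
    enumerate_library,
    read_library,
    write_library,
)
from focuslib.errors import EmptyInputError, FormatError, RoleError
from focuslib.fixtures import r_group


def oracle_products(amine_subs, sulfonyl_subs):
    """Independent construction of the expected product set.

    The fixture chemistry is fully predictable, so products can be written
    down directly as SMILES strings (no reaction engine involved) and
    canonicalized for comparison.
    """
    return {
        canonical_smiles(f"O=S(=O)(Nc1cncc({ra})n1)c1ccc({rs})cc1")
        for ra in amine_subs
        for rs in sulfonyl_subs
    }


def make_blocks(amine_subs, sulfonyl_subs):
    amines = [
        BuildingBlock(f"A{i}", canonical_smiles(f"Nc1cncc({r})n1"), Role.AMINO_HETEROARENE)
        for i, r in enumerate(amine_subs)
    ]
    sulfonyls = [
        BuildingBlock(f"S{j}", canonical_smiles(f"ClS(=O)(=O)c1ccc({r})cc1"), Role.SULFONYL_CHLORIDE)
        for j, r in enumerate(sulfonyl_subs)
    ]
    return amines, sulfonyls


def test_couple_gives_single_known_product():
    amine = BuildingBlock("a", canonical_smiles("Nc1cnccn1"))
    sulfonyl = BuildingBlock("s", canonical_smiles("ClS(=O)(=O)c1ccccc1"))
    products = couple(amine, sulfonyl)
    assert len(products) == 1
    assert products[0].structure == canonical_smiles("O=S(=O)(Nc1cnccn1)c1ccccc1")


def test_couple_role_mismatch_is_contract_error():
    benzene = BuildingBlock("b", "c1ccccc1")
    sulfonyl = BuildingBlock("s", canonical_smiles("ClS(=O)(=O)c1ccccc1"))
    with pytest.raises(RoleError):
        couple(benzene, sulfonyl)


def test_symmetric_diamine_collapses_to_one_product():
    # two equivalent amino sites on pyrazine-2,6-diamine
    diamine = BuildingBlock("d", canonical_smiles("Nc1cncc(N)n1"))
    sulfonyl = BuildingBlock("s", canonical_smiles("ClS(=O)(=O)c1ccccc1"))
    products = couple(diamine, sulfonyl)
    assert len(products) == 1


def test_reaction_template_invariant():
    template = ReactionTemplate()
    amine = BuildingBlock("a", canonical_smiles("Nc1cnccn1"))
    sulfonyl = BuildingBlock("s", canonical_smiles("ClS(=O)(=O)c1ccccc1"))
    assert len(couple(amine, sulfonyl, template)) == 1


def test_enumeration_matches_oracle_3x4():
    amine_subs = [r_group(i) for i in range(3)]
    sulfonyl_subs = [r_group(j) for j in range(4)]
    amines, sulfonyls = make_blocks(amine_subs, sulfonyl_subs)
    library = enumerate_library(amines, sulfonyls)
    assert len(library) == 12
    assert set(library.structures()) == oracle_products(amine_subs, sulfonyl_subs)


def test_empty_role_class_raises():
    _, sulfonyls = make_blocks([], ["F"])
    with pytest.raises(EmptyInputError):
        enumerate_library([], sulfonyls)


def test_permutation_invariance():
    amines, sulfonyls = make_blocks(["F", "Cl", "Br"], ["F", "CC"])
    forward = enumerate_library(amines, sulfonyls)
    backward = enumerate_library(list(reversed(amines)), list(reversed(sulfonyls)))
    assert forward.structures() == backward.structures()
    assert [p.product_id for p in forward.products] == [p.product_id for p in backward.products]


def test_dedup_keeps_all_provenance():
    # two identical amines under different ids: same product, both pairs kept
    amines, sulfonyls = make_blocks(["F"], ["Cl"])
    twin = BuildingBlock("A_twin", amines[0].structure, Role.AMINO_HETEROARENE)
    library = enumerate_library(amines + [twin], sulfonyls)
    assert len(library) == 1
    assert set(library.products[0].provenance) == {("A0", "S0"), ("A_twin", "S0")}


def test_dedup_idempotence(toy_library, toy_blocks):
    amines, sulfonyls = toy_blocks
    again = enumerate_library(amines, sulfonyls)
    assert again.structures() == toy_library.structures()


def test_product_ids_stable_and_unique(toy_library):
    ids = [p.product_id for p in toy_library.products]
    assert len(set(ids)) == len(ids)
    # hash of canonical structure, not of insertion order
    from focuslib.chem import structure_hash

    assert all(p.product_id == structure_hash(p.structure) for p in toy_library.products)


def test_library_roundtrip(tmp_path, toy_library):
    path = tmp_path / "library.smi"
    manifest = write_library(toy_library, path)
    assert manifest["count"] == len(toy_library)
    back = read_library(path)
    assert back.structures() == toy_library.structures()
    assert [p.provenance for p in back.products] == [p.provenance for p in toy_library.products]


def test_truncated_library_file_is_format_error(tmp_path, toy_library):
    path = tmp_path / "library.smi"
    write_library(toy_library, path)
    content = path.read_text().splitlines()
    (tmp_path / "bad.smi").write_text("\n".join(content[:3]) + "\nbroken\trecord\n")
    with pytest.raises(FormatError):
        read_library(tmp_path / "bad.smi")
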