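"""Hit triage: ranking, contact filters, motifs, novelty, reporting."""

import pandas as pd
import pytest

from focuslib.errors import ContractError
from focuslib.fixtures import build_pocket
from focuslib.profiler import hbond_to_at_least, profile_pose
from focuslib.triage import (
    TriageConfig,
    filter_contacts,
    motif_table,
    novelty,
    novelty_stats,
    rank,
    read_report,
    report,
    triage_hits,
)


def scored(entries):
    return pd.DataFrame(
        [{"species_id": k, "best_score": v, "status": "ok"} for k, v in entries],
        columns=["species_id", "best_score", "status"],
    )


STRUCTURES = {"A": "CCO", "B": "CCN", "C": "CCC", "D": "CC"}


def test_rank_ascending_by_score():
    table = scored([("A", -9.5), ("B", -7.0), ("C", -8.2)])
    assert list(rank(table, STRUCTURES)["species_id"]) == ["A", "C", "B"]


def test_rank_tie_break_by_structure_permutation_invariant():
    forward = rank(scored([("A", -7.0), ("B", -7.0)]), STRUCTURES)
    backward = rank(scored([("B", -7.0), ("A", -7.0)]), STRUCTURES)
    assert list(forward["species_id"]) == list(backward["species_id"])
    # CCN < CCO lexicographically, so B ranks first
    assert list(forward["species_id"]) == ["B", "A"]


def test_rank_empty_is_contract_error():
    with pytest.raises(ContractError):
        rank(pd.DataFrame(columns=["species_id", "best_score", "status"]), {})


@pytest.fixture(scope="module")
def pocket_profiles():
    hit = build_pocket("hbond", dist=2.9)
    miss = build_pocket("hbond", dist=5.0)
    return {
        "A": profile_pose(hit.receptor, hit.ligand),
        "B": profile_pose(miss.receptor, miss.ligand),
        "C": profile_pose(hit.receptor, hit.ligand),
    }


def test_filter_contacts_keeps_satisfying_species(pocket_profiles):
    ranked = rank(scored([("A", -9.0), ("B", -8.0), ("C", -7.0)]), STRUCTURES)
    predicate = hbond_to_at_least(["Gly10"], k=1)
    filtered, detail = filter_contacts(ranked, pocket_profiles, [predicate])
    assert list(filtered["species_id"]) == ["A", "C"]
    assert detail["B"][predicate.__name__] is False
    assert len(filtered) <= len(ranked)


def test_filter_contacts_empty_predicates_is_identity(pocket_profiles):
    ranked = rank(scored([("A", -9.0), ("B", -8.0)]), STRUCTURES)
    filtered, _ = filter_contacts(ranked, pocket_profiles, [])
    assert list(filtered["species_id"]) == list(ranked["species_id"])


def test_filter_contacts_missing_profile_raises(pocket_profiles):
    ranked = rank(scored([("D", -5.0)]), STRUCTURES)
    with pytest.raises(ContractError):
        filter_contacts(ranked, pocket_profiles, [])


def test_motif_table_counts_match_brute_force():
    hits = ["Cc1ccccc1", "Cc1ccc(F)cc1", "c1ccccc1", "Fc1ccccc1"]
    patterns = {"methyl_on_aryl": "[CH3][c]", "fluoro_on_aryl": "F[c]"}
    table = motif_table(hits, patterns)
    by_motif = dict(zip(table["motif"], zip(table["count"], table["fraction"])))
    assert by_motif["methyl_on_aryl"] == (2, 0.5)
    assert by_motif["fluoro_on_aryl"] == (2, 0.5)
    none = motif_table(hits, {"nitro": "[N+](=O)[O-]"})
    assert none["count"].iloc[0] == 0 and none["fraction"].iloc[0] == 0.0


def test_novelty_identity_and_disjoint():
    assert novelty("c1ccccc1", ["c1ccccc1"]) == pytest.approx(1.0)
    assert novelty("CCCC", ["c1ccccn1"]) == pytest.approx(0.0)
    with pytest.raises(ContractError):
        novelty("CCO", [])


def test_novelty_bounds_and_stats():
    stats = novelty_stats("O=S(=O)(Nc1cnccn1)c1ccccc1", ["c1ccccc1", "Nc1cnccn1"])
    assert 0.0 <= stats["mean"] <= stats["max"] <= 1.0
    assert stats["max"] == novelty("O=S(=O)(Nc1cnccn1)c1ccccc1", ["c1ccccc1", "Nc1cnccn1"])


def test_triage_and_report_roundtrip(tmp_path, pocket_profiles):
    ranked = rank(scored([("A", -9.0), ("B", -8.0), ("C", -7.0)]), STRUCTURES)
    config = TriageConfig(top_n=2, required_contacts=[hbond_to_at_least(["Gly10"], 1)],
                          reference_set=["CCO"])
    hits = triage_hits(ranked, pocket_profiles, config)
    assert [h.species_id for h in hits] == ["A", "C"]
    manifest = report(hits, tmp_path / "report", config)
    assert manifest["n_hits"] == 2
    back = read_report(tmp_path / "report")
    assert [h["species_id"] for h in back] == ["A", "C"]
    assert back[0]["best_score"] == pytest.approx(-9.0)


def test_empty_report_is_valid(tmp_path):
    manifest = report([], tmp_path / "empty", TriageConfig())
    assert manifest["n_hits"] == 0
    assert read_report(tmp_path / "empty") == []


def test_config_digest_changes_with_any_field():
    base = TriageConfig()
    assert base.digest() == TriageConfig().digest()
    assert base.digest() != TriageConfig(top_n=11).digest()
    assert base.digest() != TriageConfig(fp_bits=2048).digest()
    with pytest.raises(ContractError):
        TriageConfig(motif_patterns={"bad": "[[["})
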