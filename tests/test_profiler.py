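"""Geometric contact detection on analytically constructed pockets."""

import numpy as np
import pytest

from focuslib.errors import ContractError
from focuslib.fixtures import build_pocket, random_rotation, rigid_transform
from focuslib.profiler import (
    ProfilerConfig,
    apply_residue_map,
    detect_halogen,
    detect_hbonds,
    detect_hydrophobic,
    detect_pistack,
    detect_saltbridge,
    hbond_to_at_least,
    prevalence,
    profile_pose,
)

ALL_KINDS = ["hbond", "halogen", "pistack", "hydrophobic", "saltbridge", "empty"]


def contact_counts(profile):
    counts = {}
    for c in profile.contacts:
        counts[c.kind] = counts.get(c.kind, 0) + 1
    return counts


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_golden_fixtures_reproduced_exactly(kind):
    fixture = build_pocket(kind)
    profile = profile_pose(fixture.receptor, fixture.ligand)
    expected = {g["kind"]: g["n"] for g in fixture.golden}
    assert contact_counts(profile) == expected


def test_hbond_geometry_thresholds():
    ok = build_pocket("hbond", dist=2.9, angle=155.0)
    assert len(profile_pose(ok.receptor, ok.ligand).by_kind("hbond")) == 1
    far = build_pocket("hbond", dist=5.0, angle=155.0)
    assert profile_pose(far.receptor, far.ligand).contacts == []
    bent = build_pocket("hbond", dist=2.9, angle=80.0)
    assert profile_pose(bent.receptor, bent.ligand).by_kind("hbond") == []


def test_threshold_boundary_is_closed():
    boundary = build_pocket("hbond", dist=4.1, angle=155.0)
    profile = profile_pose(boundary.receptor, boundary.ligand)
    assert len(profile.by_kind("hbond")) == 1
    hydro = build_pocket("hydrophobic", dist=4.0)
    assert len(profile_pose(hydro.receptor, hydro.ligand).by_kind("hydrophobic")) == 1
    beyond = build_pocket("hydrophobic", dist=4.5)
    assert profile_pose(beyond.receptor, beyond.ligand).contacts == []


def test_halogen_bond_angle_rules():
    good = build_pocket("halogen", dist=3.3, donor_angle=170.0, acceptor_angle=115.0)
    assert len(profile_pose(good.receptor, good.ligand).by_kind("halogen_bond")) == 1
    bad_donor = build_pocket("halogen", dist=3.3, donor_angle=120.0, acceptor_angle=115.0)
    assert profile_pose(bad_donor.receptor, bad_donor.ligand).by_kind("halogen_bond") == []


def test_pistack_parallel_and_perpendicular():
    parallel = build_pocket("pistack", dist=3.8, tilt=5.0)
    assert len(profile_pose(parallel.receptor, parallel.ligand).by_kind("pi_stack")) == 1
    tshape = build_pocket("pistack", dist=5.0, tilt=88.0)
    assert len(profile_pose(tshape.receptor, tshape.ligand).by_kind("pi_stack")) == 1
    oblique = build_pocket("pistack", dist=3.8, tilt=45.0)
    assert profile_pose(oblique.receptor, oblique.ligand).by_kind("pi_stack") == []


def test_rigid_motion_invariance_over_20_motions():
    rng = np.random.default_rng(2024)
    for kind in ["hbond", "halogen", "pistack", "saltbridge"]:
        fixture = build_pocket(kind)
        reference = profile_pose(fixture.receptor, fixture.ligand)
        ref_set = [(c.kind, c.residue, c.ligand_atoms) for c in reference.contacts]
        ref_dists = [dict(c.geometry).get("dist") for c in reference.contacts]
        for _ in range(5):
            moved = rigid_transform(fixture, random_rotation(rng), rng.normal(scale=20.0, size=3))
            profile = profile_pose(moved.receptor, moved.ligand)
            assert [(c.kind, c.residue, c.ligand_atoms) for c in profile.contacts] == ref_set
            dists = [dict(c.geometry).get("dist") for c in profile.contacts]
            assert np.allclose(dists, ref_dists, atol=1e-6)


def test_detector_union_equals_profile():
    fixture = build_pocket("pistack")
    config = ProfilerConfig()
    union = []
    for detector in (detect_hbonds, detect_hydrophobic, detect_halogen,
                     detect_pistack, detect_saltbridge):
        union.extend(detector(fixture.receptor, fixture.ligand, config))
    profile = profile_pose(fixture.receptor, fixture.ligand, config)
    shell = set(profile.shell_residues)
    union_keys = sorted((c.kind, c.residue, c.ligand_atoms) for c in union if c.residue in shell)
    profile_keys = sorted((c.kind, c.residue, c.ligand_atoms) for c in profile.contacts)
    assert union_keys == profile_keys


def test_contacts_are_within_shell():
    fixture = build_pocket("saltbridge")
    profile = profile_pose(fixture.receptor, fixture.ligand)
    shell = set(profile.shell_residues)
    assert all(c.residue in shell for c in profile.contacts)


def test_prevalence_counting_and_determinism():
    hit = build_pocket("hbond", dist=2.9)
    miss = build_pocket("hbond", dist=5.0)
    predicate = hbond_to_at_least(["Gly10"], k=1)
    frames = [(hit.receptor, hit.ligand)] * 3 + [(miss.receptor, miss.ligand)]
    result = prevalence(frames, ProfilerConfig(), predicate)
    assert result.fraction == pytest.approx(0.75)
    assert result.trail == [True, True, True, False]
    dup = prevalence([(hit.receptor, hit.ligand)] * 2, ProfilerConfig(), predicate)
    assert dup.fraction in (0.0, 1.0)
    with pytest.raises(ContractError):
        prevalence([], ProfilerConfig(), predicate)


def test_predicate_on_empty_residue_set():
    hit = build_pocket("hbond", dist=2.9)
    predicate = hbond_to_at_least([], k=1)
    assert prevalence([(hit.receptor, hit.ligand)], ProfilerConfig(), predicate).fraction == 0.0


def test_apply_residue_map():
    fixture = build_pocket("hbond", dist=2.9)
    profile = profile_pose(fixture.receptor, fixture.ligand)
    mapped = apply_residue_map(profile, {"Gly10": "8.48"})
    assert all(c.bw_label == "8.48" for c in mapped.contacts)
    unchanged = apply_residue_map(profile, {})
    assert [c.bw_label for c in unchanged.contacts] == [c.bw_label for c in profile.contacts]
    with pytest.raises(ContractError):
        apply_residue_map(profile, {"Glu302": "8.48"})


def test_config_threshold_validation():
    with pytest.raises(ContractError):
        ProfilerConfig(hbond_dist_max=-1.0)
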