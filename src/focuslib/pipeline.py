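"""End-to-end workflow orchestration with provenance manifests.

Stages run in a fixed order (blocks -> enumerate -> expand -> dock ->
profile -> triage), each writing its outputs plus a stage manifest with
input/output digests and counts into the report directory. All randomness
fans out deterministically from a single root seed; with the mock engine a
re-run under the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path
from . import blocks as blocks_mod
from . import states as states_mod
from .docking import DockingConfig, Receptor, dock_mock, embed_conformer, screen
from .enumeration import enumerate_library, write_library
from .errors import ConfigError
from .fixtures import FixtureSpec, gen_blocks
from .profiler import ProfilerConfig, hbond_to_at_least, profile_pose
from .triage import TriageConfig, rank, report, triage_hits

log = logging.getLogger(__name__)

STAGES = ("blocks", "enumerate", "expand", "dock", "profile", "triage")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _validate(config: dict) -> None:
    problems = []
    if "run" not in config:
        problems.append("missing [run] section")
    dock_cfg = config.get("dock", {})
    engine = dock_cfg.get("engine", "mock")
    if engine not in ("mock", "external_vina"):
        problems.append(f"dock.engine must be mock or external_vina, got {engine!r}")
    if engine == "external_vina":
        for key in ("box_center", "box_size"):
            if key not in dock_cfg:
                problems.append(f"dock.{key} is required with engine=external_vina")
    if "blocks" not in config and "fixture" not in config:
        problems.append("either [blocks] (input files) or [fixture] (generator) is required")
    if problems:
        raise ConfigError("; ".join(problems))


def load_config(config_file: "str | Path") -> dict:
    path = Path(config_file)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path, "rb") as fh:
        config = tomllib.load(fh)
    _validate(config)
    return config


def run_pipeline(config_file: "str | Path",
                 out_dir: "str | Path | None" = None) -> Path:
    """Execute the full workflow; returns the report directory.

    Any stage failure propagates with the stage named in the log. The mock
    engine plus ``deterministic = true`` (the default) makes the whole
    report byte-identical across runs and worker counts.
    """
    config = load_config(config_file)
    run_cfg = config.get("run", {})
    root_seed = int(run_cfg.get("seed", 42))
    deterministic = bool(run_cfg.get("deterministic", True))
    workers = int(run_cfg.get("workers", 1))
    out = Path(out_dir or run_cfg.get("out_dir", "focuslib_report"))
    out.mkdir(parents=True, exist_ok=True)
    manifests: dict[str, dict] = {}

    def record(stage: str, manifest: dict, outputs: list[Path]) -> None:
        manifest = dict(manifest)
        manifest["stage"] = stage
        manifest["output_digests"] = {p.name: _digest(p) for p in outputs}
        if not deterministic:
            manifest["timestamp"] = time.time()
        manifests[stage] = manifest
        (out / f"manifest_{stage}.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        log.info("stage %s done: %s", stage, {k: v for k, v in manifest.items()
                                              if isinstance(v, int)})

    # -- blocks -------------------------------------------------------------
    if "fixture" in config:
        spec = FixtureSpec(
            n_amines=int(config["fixture"].get("n_amines", 3)),
            n_sulfonyls=int(config["fixture"].get("n_sulfonyls", 4)),
            seed=stage_seed(root_seed, "blocks"),
        )
        amines_path, sulfonyls_path = gen_blocks(spec, out / "blocks")
    else:
        amines_path = Path(config["blocks"]["amines"])
        sulfonyls_path = Path(config["blocks"]["sulfonyls"])
    amines = blocks_mod.load_blocks(amines_path, role_hint=blocks_mod.Role.AMINO_HETEROARENE)
    sulfonyls = blocks_mod.load_blocks(sulfonyls_path, role_hint=blocks_mod.Role.SULFONYL_CHLORIDE)
    block_table = out / "blocks.csv"
    blocks_mod.write_block_table(amines + sulfonyls, block_table)
    record("blocks", {"n_amines": len(amines), "n_sulfonyls": len(sulfonyls),
                      "input_digests": {amines_path.name: _digest(amines_path),
                                        sulfonyls_path.name: _digest(sulfonyls_path)}},
           [block_table])

    # -- enumerate ----------------------------------------------------------
    library = enumerate_library(amines, sulfonyls)
    library_path = out / "library.smi"
    write_library(library, library_path, input_files=[amines_path, sulfonyls_path])
    record("enumerate", {"products": len(library)}, [library_path])

    # -- expand -------------------------------------------------------------
    expand_cfg = config.get("expand", {})
    state_config = states_mod.StateConfig(
        ph_min=float(expand_cfg.get("ph_min", 6.0)),
        ph_max=float(expand_cfg.get("ph_max", 7.2)),
        pka_precision=float(expand_cfg.get("pka_precision", 1.0)),
        max_variants=int(expand_cfg.get("max_variants", 128)),
        enumerate_tautomers=bool(expand_cfg.get("enumerate_tautomers", True)),
        tautomer_cap=int(expand_cfg.get("tautomer_cap", 16)),
    )
    species, expand_manifest = states_mod.expand_library(library, state_config)
    species_path = out / "species.smi"
    states_mod.write_species(species, species_path, expand_manifest)
    record("expand", expand_manifest, [species_path])

    # -- dock ---------------------------------------------------------------
    dock_cfg = config.get("dock", {})
    receptor_path = dock_cfg.get("receptor")
    if receptor_path is None:
        # self-contained runs (fixtures, mock engine) use a built-in toy pocket
        from .fixtures import build_pocket

        receptor = build_pocket("hydrophobic", dist=3.9).receptor
    else:
        receptor = Receptor.from_pdb(receptor_path)
    docking_config = DockingConfig(
        box_center=tuple(dock_cfg.get("box_center", (0.0, 0.0, 0.0))),
        box_size=tuple(dock_cfg.get("box_size", (20.0, 20.0, 20.0))),
        exhaustiveness=int(dock_cfg.get("exhaustiveness", 8)),
        seed=int(dock_cfg.get("seed", stage_seed(root_seed, "dock"))),
        engine=dock_cfg.get("engine", "mock"),
    )
    scored = screen(species, receptor, docking_config, workers=workers)
    scores_path = out / "scores.csv"
    scored.to_csv(scores_path, index=False, float_format="%.6f")
    record("dock", {"species_in": len(species), "rows_out": len(scored),
                    "engine": docking_config.engine,
                    "config_digest": docking_config.digest()}, [scores_path])

    # -- profile ------------------------------------------------------------
    profiler_config = ProfilerConfig()
    profiles = {}
    profile_rows = []
    for sp in species:
        mol3d = embed_conformer(sp.structure, seed=docking_config.seed)
        result = dock_mock(mol3d, receptor, docking_config, sp.species_id)
        conf = mol3d.GetConformer()
        for idx, xyz in enumerate(result.poses[0].coordinates):
            conf.SetAtomPosition(idx, list(xyz))
        profile = profile_pose(receptor, mol3d, profiler_config)
        profiles[sp.species_id] = profile
        profile_rows.append({
            "species_id": sp.species_id,
            "n_contacts": len(profile.contacts),
            "kinds": ";".join(sorted({c.kind for c in profile.contacts})),
        })
    profiles_path = out / "profiles.csv"
    with open(profiles_path, "w") as fh:
        fh.write("species_id,n_contacts,kinds\n")
        for row in sorted(profile_rows, key=lambda r: r["species_id"]):
            fh.write(f"{row['species_id']},{row['n_contacts']},{row['kinds']}\n")
    record("profile", {"poses_profiled": len(profiles)}, [profiles_path])

    # -- triage -------------------------------------------------------------
    triage_cfg = config.get("triage", {})
    required = []
    for entry in triage_cfg.get("required_hbond_residues", []):
        required.append(hbond_to_at_least(entry["residues"], int(entry.get("k", 1))))
    triage_config = TriageConfig(
        top_n=int(triage_cfg.get("top_n", 10)),
        required_contacts=required,
        reference_set=list(triage_cfg.get("reference_set", [])),
    )
    structures = {sp.species_id: sp.structure for sp in species}
    ranked = rank(scored, structures)
    hits = triage_hits(ranked, profiles, triage_config)
    triage_dir = out / "triage"
    report(hits, triage_dir, triage_config,
           extra_manifest={"root_seed": root_seed, "stage_seeds": {
               s: stage_seed(root_seed, s) for s in STAGES}})
    record("triage", {"ranked": len(ranked), "hits": len(hits)},
           [triage_dir / "hits.csv", triage_dir / "hits.json"])

    (out / "manifest.json").write_text(json.dumps(manifests, indent=2, sort_keys=True) + "\n")
    return out


def report_digest(out_dir: "str | Path") -> str:
    """Digest over every file of a report directory (order-independent)."""
    out_dir = Path(out_dir)
    h = hashlib.sha256()
    for path in sorted(p for p in out_dir.rglob("*") if p.is_file()):
        h.update(path.relative_to(out_dir).as_posix().encode())
        h.update(path.read_bytes())
    return h.hexdigest()
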