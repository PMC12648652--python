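"""Hit triage: score ranking, required-contact filtering, motifs, novelty.

Triage reproduces a standard prioritization flow for a docked library:
sort every species ascending by its best docking score, keep only species
whose poses maintain the required contacts (e.g. hydrogen bonds with the
conserved intracellular-pocket residues), tabulate recurring substructure
motifs among the top hits, and quantify novelty against a reference set as
the maximum Tanimoto similarity of hashed circular (Morgan) fingerprints.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem import as_mol
from .errors import ContractError
from .profiler import InteractionProfile

DEFAULT_MOTIFS = {
    # recurring patterns among top-scoring members of the series
    "methyl_on_aryl": "[CH3][c]",
    "fluoro_on_aryl": "F[c]",
    "hba_adjacent_to_pyrazine": "[N,O;!$([NX3;H2])]-,=[c,C;$([c,C]~c1cnccn1)]",
}


@dataclass
class TriageConfig:
    top_n: int = 10
    required_contacts: list = field(default_factory=list)  # predicates on profiles
    motif_patterns: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    fp_radius: int = 2
    fp_bits: int = 1024
    reference_set: list = field(default_factory=list)  # SMILES for novelty

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ContractError("top_n must be >= 1")
        for name, smarts in self.motif_patterns.items():
            if Chem.MolFromSmarts(smarts) is None:
                raise ContractError(f"motif pattern {name!r} does not compile: {smarts!r}")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "top_n": self.top_n,
                "required_contacts": [getattr(p, "__name__", repr(p)) for p in self.required_contacts],
                "motif_patterns": self.motif_patterns,
                "fp_radius": self.fp_radius,
                "fp_bits": self.fp_bits,
                "reference_set": list(self.reference_set),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class HitRecord:
    species_id: str
    structure: str
    best_score: float
    passes_contacts: bool
    contact_detail: dict
    motif_hits: list
    max_ref_similarity: Optional[float] = None
    mean_ref_similarity: Optional[float] = None
    availability: Optional[str] = None


def rank(scored_table: pd.DataFrame, structures: dict[str, str]) -> pd.DataFrame:
    """Ascending score sort (best first), ties broken by canonical structure.

    Skipped species (no score) are dropped from the ranking but remain in
    the input table. Stable and invariant to input permutation.
    """
    if scored_table.empty:
        raise ContractError("scored table is empty")
    ok = scored_table[scored_table["status"] == "ok"].copy()
    ok["structure"] = ok["species_id"].map(structures)
    ok = ok.sort_values(["best_score", "structure"], kind="mergesort").reset_index(drop=True)
    return ok


def filter_contacts(ranked: pd.DataFrame, profiles: dict[str, InteractionProfile],
                    required_contacts: Sequence[Callable]) -> tuple[pd.DataFrame, dict]:
    """Keep species whose profile satisfies every predicate; order preserved.

    Returns (filtered table, per-species predicate report).
    """
    report: dict[str, dict[str, bool]] = {}
    keep = []
    for species_id in ranked["species_id"]:
        if species_id not in profiles:
            raise ContractError(f"no interaction profile for species {species_id}")
        profile = profiles[species_id]
        detail = {
            getattr(p, "__name__", f"predicate_{i}"): bool(p(profile))
            for i, p in enumerate(required_contacts)
        }
        report[species_id] = detail
        keep.append(all(detail.values()))
    return ranked[keep].reset_index(drop=True), report


def motif_table(top_hits: Sequence[str], motif_patterns: dict[str, str]) -> pd.DataFrame:
    """Per-motif count and fraction among the given structures."""
    queries = {name: Chem.MolFromSmarts(s) for name, s in motif_patterns.items()}
    for name, q in queries.items():
        if q is None:
            raise ContractError(f"motif pattern {name!r} does not compile")
    mols = [as_mol(s) for s in top_hits]
    rows = []
    for name, query in queries.items():
        count = sum(1 for m in mols if m.HasSubstructMatch(query))
        rows.append({"motif": name, "count": count,
                     "fraction": count / len(mols) if mols else 0.0})
    return pd.DataFrame(rows, columns=["motif", "count", "fraction"])


def morgan_fingerprint(molecule: "str | Chem.Mol", radius: int = 2, n_bits: int = 1024):
    generator = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return generator.GetFingerprint(as_mol(molecule))


def novelty(molecule: "str | Chem.Mol", reference_set: Sequence[str],
            fp_radius: int = 2, fp_bits: int = 1024) -> float:
    """Max Tanimoto similarity of the molecule to the reference set."""
    if not reference_set:
        raise ContractError("novelty needs a non-empty reference set")
    fp = morgan_fingerprint(molecule, fp_radius, fp_bits)
    return max(
        DataStructs.TanimotoSimilarity(fp, morgan_fingerprint(ref, fp_radius, fp_bits))
        for ref in reference_set
    )


def novelty_stats(molecule: "str | Chem.Mol", reference_set: Sequence[str],
                  fp_radius: int = 2, fp_bits: int = 1024) -> dict:
    """Max (conservative) and mean reference similarity."""
    if not reference_set:
        raise ContractError("novelty needs a non-empty reference set")
    fp = morgan_fingerprint(molecule, fp_radius, fp_bits)
    sims = [
        DataStructs.TanimotoSimilarity(fp, morgan_fingerprint(ref, fp_radius, fp_bits))
        for ref in reference_set
    ]
    return {"max": max(sims), "mean": sum(sims) / len(sims)}


def triage_hits(ranked: pd.DataFrame, profiles: dict[str, InteractionProfile],
                config: TriageConfig,
                availability: Optional[dict[str, str]] = None) -> list[HitRecord]:
    """Full triage of a ranked table into hit records."""
    filtered, report = filter_contacts(ranked, profiles, config.required_contacts)
    top = filtered.head(config.top_n)
    hits = []
    for _, row in top.iterrows():
        structure = row["structure"]
        mol = as_mol(structure)
        motifs = [
            name for name, smarts in config.motif_patterns.items()
            if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))
        ]
        sims = (
            novelty_stats(mol, config.reference_set, config.fp_radius, config.fp_bits)
            if config.reference_set
            else {"max": None, "mean": None}
        )
        hits.append(HitRecord(
            species_id=row["species_id"],
            structure=structure,
            best_score=float(row["best_score"]),
            passes_contacts=True,
            contact_detail=report[row["species_id"]],
            motif_hits=motifs,
            max_ref_similarity=sims["max"],
            mean_ref_similarity=sims["mean"],
            availability=(availability or {}).get(row["species_id"]),
        ))
    return hits


def report(hits: Sequence[HitRecord], out_dir: "str | Path",
           config: Optional[TriageConfig] = None,
           extra_manifest: Optional[dict] = None) -> dict:
    """Write hits as CSV + JSON with a run manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "hits.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([
            "species_id", "structure", "best_score", "passes_contacts",
            "motif_hits", "max_ref_similarity", "mean_ref_similarity", "availability",
        ])
        for h in hits:
            writer.writerow([
                h.species_id, h.structure, f"{h.best_score:.6f}", h.passes_contacts,
                ";".join(h.motif_hits),
                "" if h.max_ref_similarity is None else f"{h.max_ref_similarity:.6f}",
                "" if h.mean_ref_similarity is None else f"{h.mean_ref_similarity:.6f}",
                h.availability or "",
            ])
    json_path = out_dir / "hits.json"
    json_path.write_text(json.dumps([h.__dict__ for h in hits], indent=2, sort_keys=True,
                                    default=str) + "\n")
    manifest = {
        "n_hits": len(hits),
        "config_digest": config.digest() if config else None,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def read_report(out_dir: "str | Path") -> list[dict]:
    """Read back the JSON hit report."""
    return json.loads((Path(out_dir) / "hits.json").read_text())
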