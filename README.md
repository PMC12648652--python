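# focuslib

A toolkit for focused, reaction-based virtual screening against GPCR
intracellular allosteric pockets, built around one concrete chemistry:
N-sulfonylation of 2-aminoazines (amino-pyrazine + aryl sulfonyl chloride →
N-(azinyl) arylsulfonamide). It is written for computational medicinal
chemists who want a small, fully reproducible screening pipeline — from
vendor building-block files to a triaged hit list — plus the downstream
assay mathematics used to evaluate synthesized analogues.

## What it does

- **building blocks** — load SMILES/SDF block files, canonicalize
  (salt-strip, neutralize), classify into amino-heteroarene vs sulfonyl
  chloride roles by substructure patterns, and retro-decompose any
  scaffold-bearing sulfonamide back into its block pair.
- **enumeration** — exhaustively couple amines × sulfonyl chlorides through
  an RDKit reaction template, with canonical deduplication and full
  provenance (every contributing block pair is kept).
- **state expansion** — enumerate tautomers (RDKit rules) and protonation
  states from a vendored substructure/pKa rule table over a pH window
  (default 6.0–7.2, precision 1.0, ≤128 variants per molecule), producing
  the "chemical species" that are actually docked.
- **docking** — one deterministic 3D conformer per species (seeded ETKDG),
  PDBQT preparation via Open Babel, and a pluggable engine: an external
  AutoDock Vina binary (exhaustiveness 8, seed 42 by default) or an exact
  `mock` engine for fully reproducible pipeline testing. Only the lowest
  scoring pose flows to triage.
- **interaction profiling** — rule-based geometric detection of hydrogen
  bonds, hydrophobic contacts, halogen bonds, π-stacking and salt bridges,
  with every threshold exposed and every contact carrying its decision
  geometry; prevalence of named contacts over trajectory frames; optional
  Ballesteros–Weinstein residue labels.
- **triage** — ascending score ranking, required-contact filtering (e.g.
  "hydrogen bond to ≥2 of the conserved helix-8 residues"), motif frequency
  among top hits, and novelty as maximum Tanimoto similarity on Morgan
  fingerprints (radius 2, 1024 bits).
- **assay math** — percent displacement/inhibition normalization,
  four-parameter logistic (4PL) dose–response fits, EC80 derivation, and
  Cheng–Prusoff conversion Ki = IC50 / (1 + [L]/KD).
- **fixtures** — seeded generators for synthetic block sets (provably
  distinct products), toy receptor pockets with analytically known contact
  geometry, and 4PL curves with embedded ground truth.

## The model in brief

The library is the Cartesian product of two block classes under one virtual
reaction, deduplicated on canonical structure:

    L = dedup{ couple(a, s) : a ∈ A, s ∈ S }

Each product is expanded into species (tautomers × pH-window protomers).
Each species gets exactly one seeded conformer and one docking run; the
best pose score is the primary ranking criterion. Triage then applies
contact predicates computed by the geometric profiler. On the assay side,

    y(c) = bottom + (top − bottom) / (1 + 10^((log10 IC50 − log10 c)·h)),
    Ki = IC50 / (1 + [L]/KD),   ECf = EC50·(f/(1−f))^(1/h).

## Worked example

```python
from focuslib.fixtures import FixtureSpec, gen_blocks
from focuslib import load_blocks, enumerate_library, expand_library
from focuslib.states import StateConfig

amines_path, sulfonyls_path = gen_blocks(FixtureSpec(3, 4), "blocks/")
amines = load_blocks(amines_path)
sulfonyls = load_blocks(sulfonyls_path)
library = enumerate_library(amines, sulfonyls)
species, manifest = expand_library(library, StateConfig())

print(f"{len(amines)} amines x {len(sulfonyls)} sulfonyl chlorides -> "
      f"{len(library)} unique products")
print("first product:", library.products[0].structure, library.products[0].provenance)
print(f"expanded to {manifest['species_out']} chemical species (pH 6.0-7.2)")
```

prints:

```
3 amines x 4 sulfonyl chlorides -> 12 unique products
first product: O=S(=O)(Nc1cncc(Br)n1)c1ccc(Br)cc1 (('A003', 'S003'),)
expanded to 36 chemical species (pH 6.0-7.2)
```

Twelve products because every fixture block carries a unique substituent
(3·4 couplings, no duplicates); 36 species because each product has an
ionizable sulfonamide N–H in the pH window plus one annular tautomer.
The assay side from the command line:

```
$ focuslib assay ki --ic50-nm 10790
{
  "ki_nm": 5526.585365853658,
  "pki": 5.257543117302905
}
```

i.e. a 10.79 µM displacement IC50 corresponds to Ki ≈ 5.5 µM under the
default radioligand conditions (6 nM ligand, KD 6.3 nM).

The full pipeline runs from a TOML config:

```bash
focuslib run config.toml          # blocks -> enumerate -> expand -> dock -> profile -> triage
```

and writes per-stage manifests; with `engine = "mock"` the entire report
directory is byte-identical across re-runs and worker counts.

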