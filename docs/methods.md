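# Methods

This note documents the models, rules and numerical choices behind
focuslib, module by module, including what the synthetic fixtures do and do
not emulate.

## Chemistry model

The toolkit targets one coupling: N-sulfonylation of a primary amine on a
six-membered azine ring by an aryl sulfonyl chloride, giving an
N-(azinyl) arylsulfonamide and HCl. The reaction template is

    [NX3;H2:1][c;r6:2] . [S:3](=[O:4])(=[O:5])Cl  >>  [NX3;H1:1]([c:2])[S:3](=[O:4])(=[O:5])

Role classification is substructure-based. The amine pattern requires a
primary aromatic amine whose attachment ring is an azine (a ring nitrogen
ortho, meta or para to the attachment carbon, expressed as three recursive
SMARTS alternatives); aliphatic amines and anilines without ring nitrogens
classify as `unknown` because the coupling chemistry of this series does
not use them. A block matching both role patterns is flagged `ambiguous`
(self-reactive) and excluded from enumeration with a warning.

All identity comparisons go through one canonicalization: keep the largest
covalent fragment (salt stripping), neutralize formal charges, emit RDKit
canonical SMILES. Ionization is reintroduced deliberately by state
expansion, never carried in from vendor files.

**Scaffold query normalization.** The product-scaffold substructure query
is written in registry style, `[c;R]S(O)(O)Nc1cnccn1`, where the sulfonyl
oxygens carry no explicit bond order. Under strict SMARTS semantics an
unspecified bond means single-or-aromatic and would never match S=O;
substructure registries treat such a query as matching the sulfonyl group.
Pattern compilation therefore relaxes terminal S–O query bonds to
any-order, so the default query matches every coupling product, as a
registry search would.

**Retro-decomposition** inverts the coupling: every sulfonamide N–S bond in
the scaffold context is cut, the sulfur capped with Cl, the nitrogen
re-protonated, and both fragments canonicalized. For any enumerated
product this recovers exactly the source block pair (tested as a
round-trip invariant).

## Enumeration

Enumeration is the canonical-dedup union of `couple(a, s)` over the full
Cartesian product. Products are stored neutral with unspecified
stereochemistry (the coupling creates no stereocenters for this
chemistry). `product_id` is a truncated SHA-256 of the canonical SMILES,
so identifiers are stable across runs and machines. Duplicate products
arising from different block pairs keep *all* provenance pairs, because
availability-aware triage needs every synthetic route. Output order is
sorted by canonical structure, making the library invariant to input
permutation.

## State expansion

Species generation runs tautomers first, then protomers, then global
canonical deduplication — the order is recorded in the stage manifest.

Tautomers come from RDKit's `TautomerEnumerator` (rule set name recorded
in the manifest); the input's canonical form is always retained and the
list is capped (default 16) deterministically.

Protonation uses a pH-window rule engine over a pKa table vendored in
`focuslib/pka_table.py` (version tag `focuslib-pka-rules-1`). Each rule is
a SMARTS pattern, the index of the ionizable atom, a representative pKa
for the site class, and acid/base polarity; rules are matched in order and
the first rule claiming an atom wins, so specific environments
(N-azinyl sulfonamide, pKa 6.4) shadow generic ones (plain sulfonamide,
10.1). A site whose interval pKa ± precision (default 1.0) overlaps the pH
window (default 6.0–7.2) contributes both its neutral and ionized forms; a
site clearly outside contributes only its dominant form. The cross-product
over sites is applied by formal-charge/hydrogen edits, sanitized,
deduplicated and capped at `max_variants` (default 128) keeping the
lexicographically first canonical structures — truncation is therefore
deterministic. The table is frozen in the repository precisely so species
counts do not drift with upstream toolkit releases; the representative
pKas are the usual compilation values for each class (e.g. aliphatic
amines ~10, imidazole ~7, pyridine ring N 5.2, diazine ring N 0.6,
N-azinyl sulfonamides ~6.4 reflecting anion stabilization by the
electron-poor heteroarene).

Consequences worth knowing: every product of the toolkit's own scaffold
has an ionizable sulfonamide N–H inside the physiological window, so it
expands to ≥2 protomers; the pyrazine ring nitrogens (pKa ≈ 0.6) never
protonate in-window.

## Docking protocol

One conformer per species, embedded with ETKDGv3 at a fixed random seed
and MMFF-relaxed — identical inputs give identical coordinates. Receptor
structures are parsed with biotite; PDBQT preparation (partial charges,
torsion tree) shells out to Open Babel, and the toolkit name/version is
recorded in the preparation manifest. The external engine is AutoDock
Vina invoked with explicit box, exhaustiveness (default 8) and seed
(default 42); pose ranks and scores are parsed from its output. Selection
keeps the pose with the minimal score, ties broken by the engine's rank.

When no pocket box is given explicitly, the default is the axis-aligned
bounding box of a named pocket-residue selection padded by 5 Å per side.

**Mock engine.** For testing the full pipeline contract without an
external binary, the mock engine places the embedded conformer at the box
center unrotated and scores

    score = −0.1·C + 1.0·K

where C is the number of ligand heavy atoms with any receptor heavy atom
within 4.0 Å and K the number of ligand–receptor heavy-atom pairs closer
than 2.0 Å. It is exact, fast, and bit-reproducible across runs and
worker counts; it is a test harness, not an affinity model.

Screening produces one row per species always — species that fail 3D
embedding become `skipped` rows with the reason, never silent omissions —
and the output table is sorted by species id, so it is identical for any
worker count and input order.

## Interaction profiler

Typed contacts are decided purely by geometry; all thresholds are closed
intervals (a distance exactly at a maximum is detected) and every contact
records the distances/angles that satisfied its rule.

Defaults: hydrogen bond ≤4.1 Å donor–acceptor with D–H···A angle ≥100° at
the donor hydrogen; hydrophobic carbon–carbon ≤4.0 Å (both carbons bonded
only to C/H); halogen bond X···acceptor ≤4.0 Å with C–X···A in 165±30° and
Y–A···X in 120±30°; π-stacking ring-centroid ≤5.5 Å with ring normals
parallel or perpendicular within 30°; salt bridge charged-group centroids
≤5.5 Å. These mirror the published defaults of the standard geometric
profilers; every value is config-exposed.

Receptor covalent structure is inferred by distance (heavy–heavy ≤1.75 Å,
X–H ≤1.30 Å). Donor/acceptor typing is element-plus-environment: N/O/S
with attached hydrogens donate, N/O accept. If a structure lacks explicit
hydrogens the hydrogen-bond angle test degrades to the heavy-atom distance
criterion (with carbonyl-like oxygens excluded as donors since they cannot
donate); the mode used (`explicit` vs `heavy-proxy`) is recorded per
profile. Receptor aromatic rings and charged groups come from residue
atom-name tables (PHE/TYR/TRP/HIS rings; ASP/GLU negative, LYS/ARG
positive); ligand rings, formal charges and halogen donors come from the
molecular graph.

A profile is the union of the five detectors restricted to the pocket
shell — residues with any heavy atom within 5 Å of any ligand heavy atom —
so every contact's residue is guaranteed to be in the shell. Prevalence
over trajectory frames is the fraction of frames whose profile satisfies a
named predicate (e.g. "hydrogen bond to ≥2 of a conserved residue set"),
with the per-frame boolean trail retained. Ballesteros–Weinstein labels
are applied only from an explicit, validated residue map; unmapped
residues stay blank, never guessed.

Note on boundary geometry: a contact placed *exactly* at a threshold is
detected, but it is numerically degenerate — an arbitrary rigid motion in
floating point can move it to either side. Rigid-motion invariance is
therefore a property of non-degenerate geometry (and is tested as such);
boundary semantics are tested statically on constructed fixtures.

## Triage

Ranking is ascending by best-pose score with ties broken by canonical
structure, which makes it stable and permutation-invariant. Contact
filtering never reorders and keeps a per-species predicate report.
Novelty is the maximum Tanimoto similarity over a reference set on Morgan
fingerprints (radius 2, 1024 bits) — the most conservative choice; the
mean is reported alongside. Availability/price criteria are pass-through
metadata (allow/deny lists), not scraped data. The hit report (CSV + JSON
+ manifest with config digests and seeds) round-trips losslessly.

## Assay mathematics

Percent displacement is 100·(total − sample)/(total − NSB), percent
inhibition 100·(stimulated − sample)/(stimulated − basal); both are affine
invariant, reject degenerate windows, and flag values outside [0, 100]
rather than silently clamping. The dose–response model is the
variable-slope 4PL in log10-concentration space. Initialization is
deterministic: bottom/top from the data extremes, log IC50 from the
concentration nearest half-maximal response, Hill slope ±1 by curve
direction; the converged fit is reported in the orientation bottom ≤ top
(the two orientations are the same curve with negated slope). Ki uses the
Cheng–Prusoff correction; the study constants (radioligand 6 nM, KD
6.3 nM, agonist EC80 challenge 5.15 nM) are defaults on the convenience
wrapper but explicit parameters in the API. ECf = EC50·(f/(1−f))^(1/h)
gives EC80 and relatives in closed form.

## Pipeline and provenance

Stages run in fixed order (blocks → enumerate → expand → dock → profile →
triage); each writes a manifest with counts and SHA-256 digests of its
inputs/outputs, keyed by file name so reports are relocatable. All
randomness fans out from one root seed via per-stage hashing. With the
mock engine and `deterministic = true` (the default) a re-run is
byte-identical; wall-clock timestamps are only written when
`deterministic = false`, since timestamps and byte-identical reports are
mutually exclusive. Exit codes: 0 success, 2 config error, 3 environment
error (missing engine/toolkit), 4 data error.

## Synthetic fixtures: what they do and do not show

`gen_blocks` emits substituted 2-aminopyrazines and 4-substituted
benzenesulfonyl chlorides whose substituents encode the block index
(halogen-terminated alkyl chains), so the enumerated library has exactly
n_amines·n_sulfonyls distinct products — count assertions are exact. The
default study-scale spec is 60 amines × 140 sulfonyl chlorides: the unique
split of 200 blocks whose product count is 8,400. Real vendor files
contain duplicates, salts, mixed roles and unparseable records; the
fixtures exercise those paths only through dedicated corrupt-record tests.
Passing fixture-based tests demonstrates the correctness of the machinery
(enumeration, dedup, provenance, determinism), not the chemistry coverage
of any real block catalogue, and the fixture species counts depend on the
vendored pKa table, so they are not comparable to counts produced by other
protonation tools on other block sets.

`build_pocket`/`gen_pocket` construct toy receptors with contacts placed
analytically (solving the donor-angle triangle, tilted ring planes, etc.),
giving golden contact lists that are known by construction rather than by
running the profiler. They emulate pocket geometry, not protein context:
no backbone, no competing contacts, no solvation. Trajectory emulation is
limited to frame lists with scripted contact toggling.

`gen_curves` samples the 4PL on a log-spaced grid ±3 log units around the
IC50 with seeded Gaussian noise and embeds the generating parameters for
recovery tests. It does not emulate plate artifacts, outliers or
heteroscedastic noise.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the enumeration oracle on 50
random specs up to 10×10, the study-scale fixture at 60×140 (8,400
products, expanded in full), the mock pipeline on the 3×4 fixture, 20
random rigid motions per profiler fixture, and a 3×3 (pIC50 × Hill) 4PL
recovery grid with 100 replicates per cell at 5% noise. These sizes keep
the whole suite under a minute apart from the study-scale enumeration and
expansion, which take a few minutes combined.

## Known limitations

- The protonation rule table is deliberately small and class-based; it is
  not a continuum pKa predictor and ignores conformation and
  intramolecular interactions.
- The external-engine path requires `vina` and `obabel` on PATH and is
  exercised only through its error contracts in environments without them.
- The profiler's receptor perception is distance-based and atom-name
  driven; exotic residues, metals and waters are out of scope
  (water-mediated bridges and solvent terms are explicit non-goals).
- Stereochemistry is not enumerated; couplings creating stereocenters
  would be flagged rather than silently resolved.
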