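"""Vendored substructure-matched pKa rule table for protonation enumeration.

Each rule names an ionizable site by a SMARTS pattern, the index of the
ionizable atom within that pattern, a representative pKa for the site class,
and whether the neutral form is the acid (loses H+) or the base (gains H+).
Values are the usual textbook/compilation numbers for the site classes; the
table is deliberately frozen in the repository so species counts are stable
across releases of upstream toolkits.

Rules are matched in order and the first rule claiming an atom wins, so
specific environments (e.g. N-azinyl sulfonamide) must precede generic ones.
"""

from __future__ import annotations

from dataclasses import dataclass

TABLE_VERSION = "focuslib-pka-rules-1"


@dataclass(frozen=True)
class PkaRule:
    name: str
    smarts: str
    atom_index: int  # ionizable atom within the SMARTS match
    pka: float
    kind: str  # "acid" (neutral -> anion) or "base" (neutral -> cation)


PKA_RULES: tuple[PkaRule, ...] = (
    # --- acids, specific first ---
    PkaRule("carboxylic_acid", "[CX3](=O)[OX2H1]", 2, 4.2, "acid"),
    PkaRule("sulfonic_acid", "[SX4](=O)(=O)[OX2H1]", 3, -1.0, "acid"),
    # N-azinyl sulfonamides are markedly more acidic than plain sulfonamides
    # (electron-poor heteroarene stabilizes the anion); this is the series'
    # own scaffold.
    PkaRule(
        "n_azinyl_sulfonamide",
        "[SX4](=O)(=O)[NX3;H1][c;$(c1aaaan1),$(c1aaana1),$(c1aanaa1)]",
        3,
        6.4,
        "acid",
    ),
    PkaRule("sulfonamide", "[SX4](=O)(=O)[NX3;H1]", 3, 10.1, "acid"),
    PkaRule("tetrazole", "[nX3;H1]1nnnc1", 0, 4.9, "acid"),
    PkaRule("imide", "[CX3](=O)[NX3;H1][CX3](=O)", 2, 8.3, "acid"),
    PkaRule("phenol", "[c][OX2H1]", 1, 10.0, "acid"),
    PkaRule("thiol", "[#6][SX2H1]", 1, 8.3, "acid"),
    # --- bases, specific first ---
    PkaRule("guanidine", "[NX3][CX3](=[NX2])[NX3]", 2, 13.5, "base"),
    PkaRule("amidine", "[CX3](=[NX2])[NX3;!$(N[SX4])]", 1, 11.5, "base"),
    PkaRule("imidazole_n", "[nX2;H0]1c[nX3;H1]cc1", 0, 7.0, "base"),
    PkaRule("morpholine_n", "[NX3;!$(NC=O);!$(N[SX4]);$(N1CCOCC1)]", 0, 8.4, "base"),
    PkaRule(
        "aliphatic_amine",
        "[NX3;!$(NC=O);!$(N[SX4]);!$(Nc);!$(N=*);!$(N[OX1]);$(N(-[C,#1])(-[C,#1])-[C,#1])]",
        0,
        10.0,
        "base",
    ),
    PkaRule("aniline_nh2", "[NX3;H2][c;!$(c1aaaan1);!$(c1aaana1);!$(c1aanaa1)]", 0, 4.6, "base"),
    PkaRule("amino_azine_nh2", "[NX3;H2][c;$(c1aaaan1),$(c1aaana1),$(c1aanaa1)]", 0, 3.1, "base"),
    # Azine ring nitrogens: one-N rings (pyridines) are weakly basic, rings
    # with a second nitrogen (pyrazine/pyrimidine/pyridazine) much less so.
    PkaRule("diazine_ring_n", "[nX2;H0;$(n1aaaaa1);$(n:a:a:a:[nX2]),$(n:a:[nX2]),$(n:[nX2])]", 0, 0.6, "base"),
    PkaRule("pyridine_ring_n", "[nX2;H0;$(n1ccccc1)]", 0, 5.2, "base"),
)
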