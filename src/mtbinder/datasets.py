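"""Published reference tables for the dynein MTBD–microtubule systems.

Small datasets transcribed from the published analysis of cytoplasmic and
axonemal dynein microtubule-binding domains (MTBDs) interacting with
microtubule E-hooks: per-segment and per-residue contact totals, cluster
cross-state RMSD matrices for the chain-D E-hook, and MM/GB binding-energy
components.  They serve as worked-example inputs for the aggregation,
ranking, matrix-minimum and binding-energy arithmetic in this package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "OFFSET_DISTANCES",
    "ALPHA_TAIL_SEQUENCE", "BETA_TAIL_SEQUENCE",
    "SEGMENT_CONTACTS", "RESIDUE_CONTACTS",
    "CROSS_STATE_BLOCKS", "BINDING_ENERGY_ROWS",
]

#: Perpendicular MTBD–microtubule offsets analysed (Å).
OFFSET_DISTANCES = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0, 55.0)

#: Bos taurus tubulin C-terminal tail (E-hook) sequences.
ALPHA_TAIL_SEQUENCE = "VGVDSVEGEGEEEGEEY"
BETA_TAIL_SEQUENCE = "DATADEQGEFEEEGEEDEA"

#: E-hook contact totals per MTBD segment at the bound position (0 Å).
SEGMENT_CONTACTS = {
    "cytoplasmic": {
        "LH1": 401, "H1": 5, "H2": 0, "H3": 0, "H4": 0, "H5": 159, "H6": 0,
    },
    "axonemal": {
        "LH1": 95, "H1": 0, "H2": 1871, "H3": 0, "H4": 0, "H5": 1081,
        "H6": 0, "FLAP": 4780, "LF": 3799,
    },
}

#: Published per-segment contact percentages (two-decimal, half-up).
SEGMENT_PERCENTAGES = {
    "cytoplasmic": {
        "LH1": 70.97, "H1": 0.88, "H2": 0.00, "H3": 0.00, "H4": 0.00,
        "H5": 28.14, "H6": 0.00,
    },
    "axonemal": {
        "LH1": 0.82, "H1": 0.00, "H2": 16.10, "H3": 0.00, "H4": 0.00,
        "H5": 9.30, "H6": 0.00, "FLAP": 41.11, "LF": 32.67,
    },
}

# Per-residue contact totals vs offset distance.  Keys are
# (chain, residue number, residue name); values map offset (Å) → count.
_CYTO_B = {
    ("C", 3295, "LYS"): {0: 16, 5: 7, 15: 1, 25: 0, 35: 0},
    ("C", 3296, "SER"): {0: 16, 5: 0, 15: 1, 25: 0, 35: 0},
    ("C", 3297, "ILE"): {0: 6, 5: 0, 15: 0, 25: 0, 35: 0},
    ("C", 3298, "LYS"): {0: 363, 5: 505, 15: 334, 25: 97, 35: 4},
    ("C", 3299, "LYS"): {0: 4, 5: 0, 15: 30, 25: 162, 35: 14},
    ("C", 3300, "GLN"): {0: 1, 5: 0, 15: 58, 25: 68, 35: 2},
}
_CYTO_D = {
    ("C", 3361, "ILE"): {0: 4, 5: 1, 15: 0},
    ("C", 3364, "LYS"): {0: 141, 5: 39, 15: 68},
    ("C", 3367, "LYS"): {0: 14, 5: 28, 15: 125},
}
_AXO_B = {
    ("A", 22, "THR"): {0: 14, 5: 5, 15: 0, 25: 0, 35: 0},
    ("A", 23, "LEU"): {0: 8, 5: 0, 15: 0, 25: 0, 35: 0},
    ("A", 24, "LYS"): {0: 73, 5: 517, 15: 16, 25: 50, 35: 5},
    ("A", 29, "THR"): {0: 0, 5: 0, 15: 0, 25: 4, 35: 4},
}
_AXO_D = {
    ("A", 42, "ARG"): {0: 51, 5: 0, 15: 0, 25: 0, 35: 0, 45: 241},
    ("A", 43, "ARG"): {0: 1820, 5: 0, 15: 155, 25: 0, 35: 0, 45: 0},
    ("A", 51, "MET"): {0: 659, 5: 0, 15: 0, 25: 0, 35: 0, 45: 0},
    ("A", 52, "LYS"): {0: 209, 5: 0, 15: 1, 25: 0, 35: 0, 45: 0},
    ("A", 53, "GLY"): {0: 233, 5: 1, 15: 13, 25: 0, 35: 0, 45: 0},
    ("A", 54, "VAL"): {0: 388, 5: 0, 15: 4, 25: 0, 35: 0, 45: 0},
    ("A", 55, "LYS"): {0: 1715, 5: 7, 15: 11, 25: 0, 35: 26, 45: 0},
    ("A", 56, "PRO"): {0: 595, 5: 0, 15: 0, 25: 0, 35: 0, 45: 0},
    ("A", 57, "ALA"): {0: 966, 5: 0, 15: 0, 25: 0, 35: 2, 45: 0},
    ("A", 58, "ARG"): {0: 2126, 5: 0, 15: 1269, 25: 256, 35: 0, 45: 177},
    ("A", 59, "VAL"): {0: 4, 5: 0, 15: 1, 25: 0, 35: 0, 45: 0},
    ("A", 60, "LYS"): {0: 35, 5: 0, 15: 563, 25: 15, 35: 628, 45: 104},
    ("A", 61, "ASP"): {0: 1, 5: 2, 15: 2, 25: 1, 35: 1, 45: 5},
    ("A", 62, "THR"): {0: 0, 5: 0, 15: 2, 25: 25, 35: 1, 45: 0},
    ("A", 63, "ALA"): {0: 1, 5: 213, 15: 37, 25: 37, 35: 3, 45: 1},
    ("A", 64, "SER"): {0: 0, 5: 457, 15: 20, 25: 6, 35: 147, 45: 27},
    ("A", 65, "GLY"): {0: 0, 5: 10, 15: 3, 25: 3, 35: 0, 45: 5},
    ("A", 66, "ARG"): {0: 1629, 5: 4492, 15: 1352, 25: 105, 35: 1189,
                       45: 620},
    ("A", 67, "MET"): {0: 18, 5: 1, 15: 2, 25: 1, 35: 0, 45: 1},
    ("A", 68, "VAL"): {0: 0, 5: 6, 15: 0, 25: 1, 35: 0, 45: 4},
    ("A", 103, "LYS"): {0: 208, 5: 5, 15: 56, 25: 7, 35: 0, 45: 0},
    ("A", 105, "ARG"): {0: 774, 5: 0, 15: 0, 25: 0, 35: 0, 45: 0},
    ("A", 106, "PRO"): {0: 24, 5: 0, 15: 0, 25: 0, 35: 0, 45: 0},
    ("A", 107, "PHE"): {0: 75, 5: 0, 15: 3, 25: 1, 35: 0, 45: 0},
}

#: (system, E-hook chain) → residue contact table.
RESIDUE_CONTACTS = {
    ("cytoplasmic", "B"): _CYTO_B,
    ("cytoplasmic", "D"): _CYTO_D,
    ("axonemal", "B"): _AXO_B,
    ("axonemal", "D"): _AXO_D,
}


def residue_contacts_at(system: str, hook: str, offset: float) -> dict:
    """Per-residue contact counts at one offset, keyed by residue triple."""
    table = RESIDUE_CONTACTS[(system, hook)]
    return {key: counts.get(offset, counts.get(int(offset), 0))
            for key, counts in table.items()}


#: Free-state cluster populations (%) of the chain-D E-hook, shared across
#: all four cross-state blocks (rows of the matrices below).
FREE_EHOOK_POPULATIONS = (59.8, 8.1, 6.5, 5.3, 4.7)

#: Cross-state RMSD blocks (Å): free-state representatives (rows) vs
#: bound-state representatives (columns) of the chain-D E-hook.
CROSS_STATE_BLOCKS = {
    ("cytoplasmic", 0.0): {
        "col_populations": (51.2, 20.85, 8.6, 7.95, 4.45),
        "rmsd": np.array([
            [5.00, 5.20, 5.17, 4.79, 5.86],
            [3.83, 3.56, 3.58, 3.33, 4.10],
            [3.32, 3.27, 3.21, 4.08, 5.39],
            [2.90, 3.00, 3.03, 3.50, 5.57],
            [2.68, 2.28, 2.31, 3.06, 4.30],
        ]),
    },
    ("cytoplasmic", 25.0): {
        "col_populations": (33.0, 19.1, 12.65, 9.32, 5.05),
        "rmsd": np.array([
            [7.04, 4.91, 6.31, 6.35, 5.82],
            [6.67, 3.28, 4.66, 5.68, 5.94],
            [6.35, 3.37, 5.98, 6.29, 6.36],
            [6.37, 2.87, 5.50, 5.94, 6.01],
            [5.63, 2.80, 5.29, 5.65, 5.90],
        ]),
    },
    ("axonemal", 0.0): {
        "col_populations": (31.54, 16.12, 7.44, 4.94, 4.24),
        "rmsd": np.array([
            [4.35, 5.83, 5.58, 4.51, 5.39],
            [3.25, 3.96, 4.62, 4.99, 4.28],
            [2.88, 4.08, 5.69, 3.88, 5.17],
            [2.24, 3.89, 4.92, 3.14, 4.69],
            [3.47, 4.28, 5.53, 4.72, 4.90],
        ]),
    },
    ("axonemal", 25.0): {
        "col_populations": (36.15, 27.3, 16.35, 6.65, 4.8),
        "rmsd": np.array([
            [5.01, 4.98, 5.18, 4.87, 4.73],
            [3.60, 3.84, 4.25, 3.50, 3.57],
            [2.21, 3.42, 2.95, 2.72, 2.67],
            [2.20, 2.87, 2.66, 2.37, 2.15],
            [3.18, 2.97, 3.62, 2.86, 3.35],
        ]),
    },
}

#: Published bolded cells (row, col) of each cross-state block — the
#: per-column minima as printed.
CROSS_STATE_BOLD = {
    ("cytoplasmic", 0.0): {(4, 0), (4, 1), (4, 2), (4, 3), (1, 4)},
    ("cytoplasmic", 25.0): {(4, 0), (4, 1), (1, 2), (4, 3), (4, 4)},
    ("axonemal", 0.0): {(3, 0), (3, 1), (1, 2), (3, 3), (1, 4)},
    ("axonemal", 25.0): {(3, 0), (3, 1), (3, 2), (3, 3), (3, 4)},
}

#: MM/GB binding-energy components (kcal/mol): label → (E_complex, E_MTBD,
#: E_MT, published ΔE, published SD).
BINDING_ENERGY_ROWS = {
    "cytoplasmic_with_ehooks": (-22243.6, -3906.06, -18296.7, -40.84, 7.56),
    "cytoplasmic_without_ehooks": (-20113.2, -3906.06, -16227.9, 20.76, 6.71),
    "axonemal_with_ehooks": (-21851.2, -3520.25, -18302.2, -28.75, 6.33),
    "axonemal_without_ehooks": (-19726.0, -3520.25, -16230.8, 25.05, 10.29),
}
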