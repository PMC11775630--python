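"""Pinned physical constants: monoisotopic atomic masses and isotope abundances.

Values follow the CODATA/AME compilations used throughout bottom-up proteomics.
Heavy oxygen (``O18``) is carried as a distinct element species so that
¹⁸O-labelled C-termini can be expressed compositionally rather than as an
opaque mass offset.
"""

from __future__ import annotations

PROTON_MASS: float = 1.00727646688

#: Monoisotopic mass (Da) of the most abundant isotope of each element species.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    # enriched heavy oxygen used for C-terminal labelling; treated as pure
    "O18": 17.9991610,
}

#: Natural isotope ladders per element: list of (mass, relative abundance),
#: most abundant isotope first.  Abundances per IUPAC representative values.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [
        (15.9949146196, 0.99757),
        (16.9991317, 0.00038),
        (17.9991610, 0.00205),
    ],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "P": [(30.97376163, 1.0)],
    # the label is modelled as isotopically pure heavy oxygen
    "O18": [(17.9991610, 1.0)],
}

#: Residue elemental formulas (C, H, N, O, S) for the 20 canonical amino acids,
#: as residues (i.e. minus one water relative to the free amino acid).
RESIDUE_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

#: Mass of a neutron-count step between adjacent isotopologue peaks (Da).
ISOTOPE_SPACING: float = 1.0033548378
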