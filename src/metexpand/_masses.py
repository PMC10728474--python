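"""Static monoisotopic atomic masses (IUPAC most-abundant isotope, Da).

Embedded so that mass arithmetic is deterministic and works offline.
Values carry >= 6 decimal places.
"""

# most-abundant-isotope masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825032,
    "C": 12.000000000,
    "N": 14.003074005,
    "O": 15.994914620,
    "F": 18.998403163,
    "Na": 22.989769282,
    "P": 30.973761998,
    "S": 31.972071174,
    "Cl": 34.968852682,
    "K": 38.963706487,
}

# electron-corrected proton mass: matches 4-decimal precursor m/z reporting
# conventions of singly protonated/deprotonated species
PROTON_MASS: float = 1.007276

ELECTRON_MASS: float = 0.000548580

# lowest common valences, used for ring-and-double-bond equivalents
VALENCE: dict[str, int] = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "F": 1,
    "Na": 1,
    "P": 3,
    "S": 2,
    "Cl": 1,
    "K": 1,
}

#: default element alphabet for formula parsing and decomposition
DEFAULT_ALPHABET: tuple[str, ...] = ("C", "H", "N", "O", "P", "S", "Na", "Cl")
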