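"""Physical constants and element tables.

Units used throughout the package: length in Å, energy in kcal/mol,
time in fs, temperature in K, mass in amu (g/mol).
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/fs² (the AKMA-style internal unit system).
KCAL_PER_MOL_TO_AKMA = 4.184e-4

#: Bondi-style van der Waals radii (Å) by element symbol.  The radius of an
#: element missing from this table falls back to ``DEFAULT_VDW_RADIUS``.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
}

DEFAULT_VDW_RADIUS = 1.70

#: Residue names recognised as water.
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL"}

#: Side-chain carboxylate oxygens of acidic residues (salt-bridge acceptor side).
ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Side-chain nitrogens of basic residues (salt-bridge donor side).
BASIC_SIDECHAIN_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
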