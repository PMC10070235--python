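"""Unit conversions.

Internal representation is atomic units (hartree, bohr) everywhere; file
interfaces use eV and angstrom.
"""

HARTREE_TO_EV = 27.211386
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

BOHR_TO_ANGSTROM = 0.52917721
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
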