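"""Frozen physical constants for intact-protein average-mass arithmetic.

Average (not monoisotopic) masses are used throughout because the observed
masses come from deconvoluted electrospray spectra of intact ~20 kDa
glycoproteins, where isotopic resolution is not achieved.

The table is frozen here rather than imported from a library so that
computed masses are bit-reproducible across environments.
"""

from __future__ import annotations

from types import MappingProxyType

#: Average residue masses in Da (monomer minus water), standard values as
#: used by the ExPASy pI/Mr tool.
RESIDUE_AVG_MASS = MappingProxyType(
    {
        "G": 57.0519,
        "A": 71.0788,
        "S": 87.0782,
        "P": 97.1167,
        "V": 99.1326,
        "T": 101.1051,
        "C": 103.1388,
        "L": 113.1594,
        "I": 113.1594,
        "N": 114.1038,
        "D": 115.0886,
        "Q": 128.1307,
        "K": 128.1741,
        "E": 129.1155,
        "M": 131.1926,
        "H": 137.1411,
        "F": 147.1766,
        "R": 156.1875,
        "Y": 163.1760,
        "W": 186.2132,
    }
)

#: Mass of one water molecule (Da), added once per peptide chain.
WATER = 18.01528

#: Average mass of one hydrogen atom (Da); a disulfide bridge removes two.
H_ATOM = 1.00794

#: N-acetylhexosamine residue mass (Da) used for glycan arithmetic.
HEXNAC = 203.19

#: Hexose residue mass (Da) used for glycan arithmetic.
HEXOSE = 162.14

#: The 20 standard residues accepted in mature-protein sequences.
STANDARD_RESIDUES = frozenset(RESIDUE_AVG_MASS)
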