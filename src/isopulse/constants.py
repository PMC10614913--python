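"""Physical constants: isotope masses and abundances.

Monoisotopic masses (Da) from the AME2020 atomic-mass evaluation; natural
isotopic abundances are the IUPAC-CIAAW representative values. The natural
15N abundance used throughout the chemistry is 0.00364; the MIMS display
convention uses a separately configurable 0.37% (= 0.0037) baseline.
"""

PROTON_MASS = 1.007276466879  # Da, for m/z = (M + z*PROTON_MASS)/z

# element -> list of (neutron shift relative to principal isotope, mass, abundance)
ISOTOPES = {
    "C": [(0, 12.0, 0.9893), (1, 13.00335483507, 0.0107)],
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177785, 0.000115)],
    "N": [(0, 14.0030740048, 0.99636), (1, 15.0001088989, 0.00364)],
    "O": [
        (0, 15.9949146196, 0.99757),
        (1, 16.9991317565, 0.00038),
        (2, 17.9991596129, 0.00205),
    ],
    "S": [
        (0, 31.9720711744, 0.9499),
        (1, 32.9714589098, 0.0075),
        (2, 33.967867004, 0.0425),
        (4, 35.96708071, 0.0001),
    ],
}

NATURAL_15N = 0.00364          # chemistry default (CIAAW)
MIMS_BASELINE_RATIO = 0.0037   # 0.37% 15N/14N, the imaging "0% above background"

DELTA_MASS_15N = ISOTOPES["N"][1][1] - ISOTOPES["N"][0][1]  # m(15N) - m(14N)

WATER = {"H": 2, "O": 1}
# carbamidomethylation of cysteine adds CH2-CO-NH2 (+57.02146 Da)
CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1}

# monoisotopic residue formulas of the 20 canonical amino acids
RESIDUE_FORMULAS = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}
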