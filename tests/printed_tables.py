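"""Frozen published values used as test fixtures.

PRINTED_Z_1X1 is the published pairwise Z matrix over the ten 1×1 internal
loops (rows/columns in descending frequency order).  The published table
contains two entries whose printed sign contradicts antisymmetry (rows
U/U and C/U against column G/G); the signs here follow antisymmetry, the
magnitudes are as printed.
"""

Z_LABELS = ("G/G", "A/C", "C/A", "U/U", "U/C", "C/U", "A/A", "C/C", "G/A", "A/G")

PRINTED_Z_1X1 = {
    "G/G": (0.00, 1.26, 1.47, 1.56, 4.67, 5.70, 8.46, 9.42, 9.42, 10.43),
    "A/C": (-1.26, 0.00, 0.22, 0.30, 3.42, 4.46, 7.25, 8.23, 8.23, 9.26),
    "C/A": (-1.47, -0.22, 0.00, 0.09, 3.21, 4.25, 7.04, 8.03, 8.03, 9.06),
    "U/U": (-1.56, -0.30, -0.09, 0.00, 3.12, 4.17, 6.96, 7.95, 7.95, 8.98),
    "U/C": (-4.67, -3.42, -3.21, -3.12, 0.00, 1.05, 3.90, 4.92, 4.92, 5.99),
    "C/U": (-5.70, -4.46, -4.25, -4.17, -1.05, 0.00, 2.86, 3.89, 3.89, 4.97),
    "A/A": (-8.46, -7.25, -7.04, -6.96, -3.90, -2.86, 0.00, 1.04, 1.04, 2.15),
    "C/C": (-9.42, -8.23, -8.03, -7.95, -4.92, -3.89, -1.04, 0.00, 0.00, 1.11),
    "G/A": (-9.42, -8.23, -8.03, -7.95, -4.92, -3.89, -1.04, 0.00, 0.00, 1.11),
    "A/G": (-10.43, -9.26, -9.06, -8.98, -5.99, -4.97, -2.15, -1.11, -1.11, 0.00),
}

#: published frequency groups of the ten 1×1 internal loops
PRINTED_GROUPS_1X1 = [
    ["G/G", "A/C", "C/A", "U/U"],
    ["U/C", "C/U"],
    ["A/A", "C/C", "G/A", "A/G"],
]
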