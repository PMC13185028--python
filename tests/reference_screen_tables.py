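"""Published gene-level log2FC pairs from 2D/3D hepatocyte time-course screens.

Each entry is (gene, log2FC at the earlier time point vs baseline, log2FC at
the later time point vs baseline) for genes reported as time-dependent
essential (TDE, continuously depleted) or time-dependent growth-inhibitory
(TDGI, continuously enriched). Both guides were reported significant at both
time points, so these pairs exercise the monotonicity component of the
classifier with significance assumed.
"""

TDE_2D = [
    ("ABCB7", -2.86, -3.15),
    ("ADAM2", -1.77, -1.88),
    ("DDX11", -1.32, -2.04),
    ("DDX52", -1.51, -2.39),
    ("DIS3", -1.87, -2.09),
    ("MYBBP1A", -2.95, -3.11),
    ("POLR3C", -1.71, -2.38),
    ("YARS2", -3.22, -3.75),
    ("GOLGA8S", -2.58, -3.14),
]

TDE_3D = [
    ("CCDC63", -2.91, -3.15),
    ("FDXACB1", -3.17, -3.51),
    ("MYH7B", -3.10, -3.62),
    ("NBPF9", -3.43, -3.73),
    ("TAF6", -2.74, -3.80),
    ("TLP1", -2.18, -3.25),
]

TDGI_2D = [
    ("CYP2A13", 1.21, 1.31),
    ("KMT2C", 1.08, 1.08),  # tie: monotonicity must be non-strict
    ("OTOP3", 1.21, 1.53),
    ("ZNF556", 1.5, 1.54),
]

# the first and last printed rows of the (much larger) 3D enriched list
TDGI_3D_SAMPLE = [
    ("A2ML1", 2.39, 3.79),
    ("ABCA10", 1.99, 4.40),
    ("ABCB5", 2.86, 5.11),
    ("UGT1A10", 3.51, 6.75),
    ("UGT2A1", 2.82, 5.90),
]
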