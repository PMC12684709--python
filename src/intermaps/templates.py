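"""Ideal-geometry heavy-atom residue templates for the synthetic
fixture generator.

Coordinates (Angstrom) are energy-minimized ideal geometries for the
residues the interaction motifs use, plus a planar chlorobenzene-like
het group (CLB) carrying the halogen, water and a magnesium ion.
"""

TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    'ALA': {
        'N': (-1.1920, -1.1794, -0.3657),
        'CA': (-0.2655, -0.0301, -0.4792),
        'CB': (-0.8429, 1.1548, 0.2827),
        'C': (1.1167, -0.4089, 0.0626),
        'O': (1.4416, -1.4930, 0.5243),
    },
    'GLY': {
        'N': (-1.6582, -0.1246, 0.1570),
        'CA': (-0.4346, 0.6428, -0.1435),
        'C': (0.7955, -0.2529, -0.1091),
        'O': (0.8207, -1.4505, 0.1296),
    },
    'SER': {
        'N': (0.0148, 0.9886, 1.1981),
        'CA': (-0.0857, 0.3187, -0.1234),
        'CB': (1.1012, -0.6282, -0.3289),
        'OG': (2.3179, 0.1254, -0.3719),
        'C': (-1.4037, -0.4397, -0.2431),
        'O': (-1.5675, -1.5709, -0.6725),
    },
    'CYS': {
        'N': (0.3519, 1.5368, 0.7477),
        'CA': (-0.1201, 0.4418, -0.1338),
        'CB': (0.8160, -0.7733, -0.0532),
        'SG': (2.5133, -0.3790, -0.6114),
        'C': (-1.5630, 0.0801, 0.2434),
        'O': (-2.4055, 0.8485, 0.6867),
    },
    'ASP': {
        'N': (-0.0285, -1.5960, -1.1053),
        'CA': (-0.5954, -0.7134, -0.0592),
        'CB': (0.5039, -0.1598, 0.8424),
        'CG': (1.4139, 0.8116, 0.1412),
        'OD1': (1.1112, 1.6518, -0.6885),
        'OD2': (2.6856, 0.7256, 0.5840),
        'C': (-1.4762, 0.3727, -0.6895),
        'O': (-1.9501, 0.3527, -1.8165),
    },
    'GLU': {
        'N': (1.1996, -0.7357, 1.5769),
        'CA': (1.1500, -0.4211, 0.1331),
        'CB': (-0.1747, 0.2692, -0.2135),
        'CG': (-1.4006, -0.5734, 0.1279),
        'CD': (-2.6438, 0.0386, -0.4476),
        'OE1': (-3.2770, -0.3842, -1.4003),
        'OE2': (-3.0299, 1.1533, 0.1986),
        'C': (2.3665, 0.4437, -0.2400),
        'O': (3.4103, 0.5257, 0.3926),
    },
    'ASN': {
        'N': (-0.4793, -1.5236, -1.1550),
        'CA': (-0.6661, -0.5774, -0.0269),
        'CB': (0.3661, 0.5478, -0.1249),
        'CG': (1.6970, 0.1449, 0.4650),
        'OD1': (1.9276, -0.9255, 1.0139),
        'ND2': (2.6690, 1.0990, 0.3608),
        'C': (-2.1034, -0.0411, -0.0352),
        'O': (-3.0527, -0.5143, -0.6436),
    },
    'LYS': {
        'N': (2.2757, -0.8146, -0.5396),
        'CA': (1.4349, 0.1359, 0.2262),
        'CB': (0.2937, -0.6051, 0.9373),
        'CG': (-0.6604, -1.3779, 0.0165),
        'CD': (-1.3599, -0.5453, -1.0634),
        'CE': (-2.2363, 0.5693, -0.4928),
        'NZ': (-2.9171, 1.2785, -1.5703),
        'C': (2.2817, 0.9097, 1.2511),
        'O': (1.8786, 1.4819, 2.2510),
    },
    'PHE': {
        'N': (-1.6965, -0.0859, -1.5498),
        'CA': (-1.6768, -0.4157, -0.1031),
        'CB': (-0.7441, 0.5403, 0.6621),
        'CG': (0.7146, 0.3722, 0.2951),
        'CD1': (1.3174, 1.2297, -0.6349),
        'CE1': (2.6576, 1.0628, -0.9857),
        'CZ': (3.4070, 0.0379, -0.4113),
        'CE2': (2.8171, -0.8214, 0.5139),
        'CD2': (1.4765, -0.6568, 0.8657),
        'C': (-3.1111, -0.3733, 0.4444),
        'O': (-4.1399, -0.4760, -0.2094),
    },
    'G': {
        "C1'": (2.5395, -1.1379, 0.0781),
        'N9': (1.6535, -0.0674, 0.4499),
        'C8': (1.9704, 1.0235, 1.2164),
        'N7': (0.9403, 1.8314, 1.3754),
        'C5': (-0.0755, 1.2269, 0.6775),
        'C4': (0.3406, 0.0488, 0.0989),
        'N3': (-0.3751, -0.8166, -0.6584),
        'N1': (-2.1539, 0.7103, -0.2963),
        'C2': (-1.6145, -0.4430, -0.8304),
        'N2': (-2.4573, -1.2125, -1.5650),
        'C6': (-1.4487, 1.6301, 0.4690),
        'O6': (-1.9718, 2.6551, 0.8951),
    },
    'CLB': {
        'C1': (1.3900, 0.0000, 0.0000),
        'C2': (0.6950, 1.2038, 0.0000),
        'C3': (-0.6950, 1.2038, 0.0000),
        'C4': (-1.3900, 0.0000, 0.0000),
        'C5': (-0.6950, -1.2038, 0.0000),
        'C6': (0.6950, -1.2038, 0.0000),
        'CL': (3.1300, 0.0000, 0.0000),
    },
    'HOH': {
        'O': (0.0000, 0.0000, 0.0000),
    },
    'MG': {
        'MG': (0.0000, 0.0000, 0.0000),
    },
}

ELEMENT_OVERRIDES = {'CL': 'Cl', 'MG': 'Mg'}
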