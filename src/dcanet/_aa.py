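"""Amino-acid constants and default physicochemical scales."""

# The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

STANDARD_AA_SET = frozenset(STANDARD_AA)

# Kyte-Doolittle hydropathy index. Positive = hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Side-chain net charge at pH 7; histidine carries a small partial
# positive charge from its ~6.0 pKa imidazole.
SIDE_CHAIN_CHARGE: dict[str, float] = {
    **{aa: 0.0 for aa in STANDARD_AA},
    "K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0,
}


def validate_code(code: str) -> str:
    """Return ``code`` if it is a standard one-letter amino acid, else raise."""
    if code not in STANDARD_AA_SET:
        raise ValueError(f"unknown amino-acid code {code!r}")
    return code
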