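"""Fixed amino-acid alphabet used throughout the package.

All matrices, profiles and files use the 20 standard residues in
alphabetical single-letter order.  Reordering (e.g. by physicochemical
property, as figures often do) is a presentation concern handled outside
the data structures.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = 20

#: residue codes that may appear in sequences/alignments but carry no
#: counting information (ambiguity codes, rare residues, stop, gap)
NON_STANDARD: frozenset[str] = frozenset("XBZJUO*-")

STOP: str = "*"


def is_standard(aa: str) -> bool:
    """True if *aa* is one of the 20 standard single-letter residues."""
    return aa in AA_INDEX
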