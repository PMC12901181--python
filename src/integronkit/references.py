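"""Bundled reference attI sites used to anchor truncated-site classification.

A truncated attI (delta-attI) site is classified by walking upstream from its
minimal consensus match and comparing the flanking sequence base by base with
the 3' end of a full reference attI site, so the package ships one reference
per integron class.

Both bundled sequences are SYNTHETIC: they are constructed stand-ins that
reproduce every structural constraint of the published reference sites
(class 1: 65 bp total, L box 5'-CCCTAAA-3', R box matching 5'-GTTRRRY-3',
two direct repeats, and the 3' run ...CCCTAAAACAAAG ending at the crossover
G that yields the minimal consensus 5'-AAACAAAGTTRRRY-3'; class 2: a 311 bp
region ending ...AATAAAATG^TTAACC, whose last 9 bases upstream of and
including the crossover G realize the 5'-AATAAAAT-3' head of the minimal
consensus 5'-AATAAAATGTTRRRY-3'), without being copies of any database
record. The accessions of the sites they model are recorded as provenance
in :mod:`integronkit.config`. Classification results depend only on the
position<->length arithmetic anchored at the crossover G, which these
sequences reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ReferenceAttI:
    """A full attI site with its crossover G coordinate and labelled boxes.

    ``crossover_g_index`` is 1-based within ``sequence``; the base there is
    the conserved G at which strand exchange occurs. ``boxes`` maps region
    labels (L_box, R_box, DR1, DR2) to 1-based inclusive (start, end) spans;
    class 2 has no experimentally defined boxes and may leave it empty.
    """

    class_label: str
    sequence: str
    crossover_g_index: int
    source_accession: str
    boxes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.crossover_g_index <= len(self.sequence):
            raise ValueError("crossover_g_index outside the reference sequence")
        if self.sequence[self.crossover_g_index - 1] != "G":
            raise ValueError("reference base at crossover_g_index is not G")

    @property
    def upstream_of_crossover(self) -> str:
        """Sequence up to and including the crossover G."""
        return self.sequence[: self.crossover_g_index]


# Class 1 reference: 65 bp; crossover G at position 56, so the site spans
# crossover-relative positions -56..-1 plus 9 downstream bases (the realized
# R box GTTAGAC and a 3-nt tail). Synthetic construction, see module docstring.
ATTI1_REFERENCE = ReferenceAttI(
    class_label="1",
    sequence=(
        "ACGCCGTGGGTCGAACGCCGTTGCAGCATGAAGTAGCGGATCT"
        "CCCTAAAACAAAGTTAGACGCA"
    ),
    crossover_g_index=56,
    source_accession="NC_028464 (modelled; synthetic stand-in)",
    boxes={"DR1": (1, 7), "DR2": (15, 21), "L_box": (44, 50), "R_box": (56, 62)},
)

# Class 2 reference: 311 bp region ending at the proposed attI2 crossover
# 5'-G'TTAACC-3' (G at position 305). No boxes are defined for attI2.
# Synthetic construction, see module docstring.
ATTI2_REFERENCE = ReferenceAttI(
    class_label="2",
    sequence=(
        "ATGTTTATGCGAGCTAACCTCGTCGGCCATTACTCACGGCAGCAGTGCACGCATCGTAAT"
        "ACATTAAAATAGCAATGCTAAGAGGCGGCGGGCTGTCACCGCTTCATTTGACTTGGAGCA"
        "AACGAGGCCGTCGCGATCTGGAATCCACCGCTTGGAGCTTGCTACCGGAGTGAGAACTAG"
        "ATTTTTATCGCCTTTGGCGCGATCTGCAGCATTCCGACTAGCAGAACTCGGATGCGCCCC"
        "TTGCAGTCTTACAAACCGTTTCCTAAATAAGCAATATTGAAAGGCGAGGTAGCGAGAATA"
        "AAATGTTAACC"
    ),
    crossover_g_index=305,
    source_accession="DQ176450 (modelled; synthetic stand-in)",
)

BUNDLED_REFERENCES: dict[str, ReferenceAttI] = {
    "1": ATTI1_REFERENCE,
    "2": ATTI2_REFERENCE,
}

assert len(ATTI1_REFERENCE.sequence) == 65
assert len(ATTI2_REFERENCE.sequence) == 311
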