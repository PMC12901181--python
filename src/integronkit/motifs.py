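"""Degenerate (IUPAC) motif definition and strand-aware scanning.

This is the primitive underneath all site detection in the package: the
consensus sequences of integron recombination sites (the core site
5'-GTTRRRY-3', the inverse core site 5'-RYYYAAC-3', and the minimal
truncated-attI consensus motifs) are degenerate IUPAC strings, and every
detector starts from exhaustive, overlapping matches of such a motif on one
or both strands.

Coordinates in all reported hits are 1-based inclusive on the forward
strand (GenBank convention). A hit on the minus strand still carries
forward-strand coordinates; its ``matched`` field is the subsequence as
read 5'->3' on the hit strand (i.e. the reverse complement of the
forward-strand slice).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "IUPACMotif",
    "MotifHit",
    "expand_iupac",
    "iupac_for_bases",
    "reverse_complement",
    "scan",
    "read_fasta",
    "load_motifs",
    "write_hits_tsv",
    "write_hits_gff3",
    "BUILTIN_MOTIFS",
]

# Base sets for the 15 IUPAC nucleotide codes (A,C,G,T,R,Y,S,W,K,M,B,D,H,V,N).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
# Minimal IUPAC code for each base set (used by consensus derivation).
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

SEQUENCE_ALPHABET = frozenset("ACGTN")


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC code stands for.

    ``R`` (purine) -> {A, G}; ``Y`` (pyrimidine) -> {C, T}; ``N`` -> all four.
    """
    try:
        return IUPAC_SETS[code.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def iupac_for_bases(bases: Iterable[str]) -> str:
    """Return the minimal IUPAC code whose base set equals ``bases``."""
    key = frozenset(b.upper() for b in bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement; degenerate codes map to their complements (R<->Y...)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A named motif over the IUPAC nucleotide alphabet."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("motif pattern must be non-empty")
        for ch in pat:
            if ch not in IUPAC_SETS:
                raise ValueError(
                    f"invalid IUPAC nucleotide code: {ch!r} in pattern {pat!r}"
                )
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complement(self) -> "IUPACMotif":
        return IUPACMotif(self.name, reverse_complement(self.pattern))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence. ``start``/``end`` are 1-based inclusive, forward strand."""

    seq_id: str
    start: int
    end: int
    strand: str
    matched: str
    motif_name: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("hit span does not match the matched subsequence length")


# Consensus motifs printed for the sites this package detects.
BUILTIN_MOTIFS: dict[str, IUPACMotif] = {
    m.name: m
    for m in (
        IUPACMotif("core_site", "GTTRRRY"),           # R' (CS)
        IUPACMotif("inverse_core_site", "RYYYAAC"),    # R'' (ICS)
        IUPACMotif("delta_attI1", "AAACAAAGTTRRRY"),   # minimal DeltaattI1 consensus
        IUPACMotif("delta_attI2", "AATAAAATGTTRRRY"),  # minimal DeltaattI2 consensus
        IUPACMotif("L_box", "CCCTAAA"),                # attI1 L box
    )
}


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return seq


def _column_class(code: str) -> str:
    """Regex character class for one pattern column.

    N in the subject matches only pattern N (the curated sites this package
    models are exact sequences; an ambiguous subject base is never credited
    with a specific-base match).
    """
    bases = IUPAC_SETS[code]
    if bases == IUPAC_SETS["N"]:
        return "[ACGTN]"
    if len(bases) == 1:
        return next(iter(bases))
    return "[" + "".join(sorted(bases)) + "]"


def _pattern_regex(pattern: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all reported.
    return re.compile("(?=(" + "".join(_column_class(c) for c in pattern) + "))")


def _scan_one_strand(
    seq: str, pattern: str, max_mismatches: int
) -> Iterator[tuple[int, str]]:
    """Yield (0-based start, matched slice) on the given (already oriented) sequence."""
    m = len(pattern)
    if m > len(seq):
        return
    if max_mismatches == 0:
        for match in _pattern_regex(pattern).finditer(seq):
            yield match.start(), match.group(1)
        return
    sets = [IUPAC_SETS[c] for c in pattern]
    full = IUPAC_SETS["N"]
    for i in range(len(seq) - m + 1):
        mm = 0
        for j in range(m):
            base = seq[i + j]
            ok = base in sets[j] if base != "N" else sets[j] == full
            if not ok:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            yield i, seq[i : i + m]


def scan(
    sequence: str,
    motif: IUPACMotif,
    strand_mode: str = "both",
    *,
    seq_id: str = "",
    max_mismatches: int = 0,
) -> list[MotifHit]:
    """Find all (overlapping) occurrences of ``motif`` in ``sequence``.

    Parameters
    ----------
    strand_mode
        ``"forward"``, ``"reverse"`` or ``"both"``.
    max_mismatches
        Number of pattern columns allowed to fail. Defaults to 0: the
        curated consensus motifs are exact, and tolerance in the original
        screens was applied by human curation, not by the matcher.

    Hits are sorted by start coordinate, then strand (``+`` before ``-``).
    """
    if strand_mode not in ("forward", "reverse", "both"):
        raise ValueError(f"invalid strand_mode: {strand_mode!r}")
    seq = _validate_sequence(sequence)
    if not seq:
        return []
    hits: list[MotifHit] = []
    if strand_mode in ("forward", "both"):
        for i, matched in _scan_one_strand(seq, motif.pattern, max_mismatches):
            hits.append(
                MotifHit(seq_id, i + 1, i + len(motif), "+", matched, motif.name)
            )
    if strand_mode in ("reverse", "both"):
        rc_pat = reverse_complement(motif.pattern)
        for i, matched in _scan_one_strand(seq, rc_pat, max_mismatches):
            hits.append(
                MotifHit(
                    seq_id,
                    i + 1,
                    i + len(motif),
                    "-",
                    reverse_complement(matched),
                    motif.name,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, wrapped, mixed-case) FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def load_motifs(source) -> dict[str, IUPACMotif]:
    """Load motif definitions keyed by name.

    ``source`` may be a mapping ``{name: pattern}`` or a path to a YAML file
    with a top-level ``motifs:`` mapping (or a plain mapping).
    """
    if isinstance(source, dict):
        mapping = source
    else:
        import yaml

        with open(source) as fh:
            data = yaml.safe_load(fh)
        mapping = data.get("motifs", data) if isinstance(data, dict) else {}
    return {name: IUPACMotif(name, pattern) for name, pattern in mapping.items()}


_TSV_HEADER = "seq_id\tstart\tend\tstrand\tmotif_name\tmatched"


def write_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.motif_name}\t{h.matched}\n"
            )


def write_hits_gff3(hits: Iterable[MotifHit], path, *, source: str = "integronkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            attrs = f"Name={h.motif_name};matched={h.matched}"
            fh.write(
                f"{h.seq_id}\t{source}\tnucleotide_motif\t{h.start}\t{h.end}\t.\t{h.strand}\t.\t{attrs}\n"
            )
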