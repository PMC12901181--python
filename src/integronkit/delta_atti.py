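"""Detection and classification of truncated attI (delta-attI) cassette sites.

An unusual delta-attI-type gene cassette carries, in place of the canonical
attC, a variable-length fragment of an attI site. Every such fragment ends
at the recombination crossover G followed by the 6-nt remainder of the core
site (TTRRRY, contributed by the downstream joint), and extends a variable
number of bases upstream with identity to the reference attI. Sites are
labelled by their crossover-relative upstream extent: a site reaching
position -X retains ``X + 6`` nt of attI-derived sequence, e.g. the class-1
minimal consensus 5'-AAACAAAGTTRRRY-3' (14 nt) is the -8 site, and a 17-nt
fragment is the -11 site.

Classification anchors each minimal-consensus match to the bundled
reference attI of its class and walks upstream base by base until the first
mismatch, reference exhaustion (the full attI is present), or a contig
edge (flagged as truncated).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .motifs import (
    BUILTIN_MOTIFS,
    IUPACMotif,
    MotifHit,
    expand_iupac,
    iupac_for_bases,
    reverse_complement,
    scan,
)
from .references import BUNDLED_REFERENCES, ReferenceAttI

logger = logging.getLogger("integronkit")

# nt of the core site downstream of the crossover G (the TTRRRY remainder).
CORE_REMAINDER = 6

_MOTIF_CLASS = {"delta_attI1": "1", "delta_attI2": "2"}


@dataclass(frozen=True)
class Orf:
    """A protein-coding feature used as cassette-context for site filtering."""

    orf_id: str
    start: int
    end: int
    strand: str = "+"
    name: Optional[str] = None

    @property
    def display_name(self) -> str:
        return self.name or self.orf_id

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class DeltaAttISite:
    """A classified truncated attI site.

    ``position_label`` is the (negative) crossover-relative upstream extent;
    ``retained_length`` the nt count of the attI-derived fragment including
    the 6-nt core remainder, so ``retained_length == |position_label| + 6``.
    ``full_site`` marks matches whose upstream walk exhausted the reference:
    the complete attI site is present, not a truncation of it.
    """

    class_label: str
    position_label: int
    retained_length: int
    hit: MotifHit
    upstream_extension: int
    core_matched: str
    seq_id: str
    start: int
    end: int
    strand: str
    crossover_pos: int
    orf_id: Optional[str] = None
    truncated: bool = False
    full_site: bool = False

    def __post_init__(self) -> None:
        if self.retained_length != -self.position_label + CORE_REMAINDER:
            raise ValueError("retained_length inconsistent with position_label")

    @property
    def label(self) -> str:
        if self.full_site:
            return f"attI{self.class_label}"
        return f"ΔattI{self.class_label}{self.position_label}"


def classify_delta_atti(
    hit: MotifHit,
    context_sequence: str,
    reference: ReferenceAttI,
    *,
    max_mismatches: int = 0,
) -> DeltaAttISite:
    """Classify a minimal-consensus match against a reference attI.

    Walks upstream from the match, comparing the context sequence with the
    reference 3' end base by base; by default identity must be exact
    (``max_mismatches`` tolerated mismatches may be allowed for exploratory
    screens, at the cost of inflated position labels).
    """
    cls = _MOTIF_CLASS.get(hit.motif_name)
    if cls is None:
        raise ValueError(
            f"hit motif {hit.motif_name!r} is not a delta-attI minimal consensus"
        )
    if cls != reference.class_label:
        raise ValueError(
            f"hit class {cls} does not match reference class {reference.class_label}"
        )
    seq = context_sequence.upper()
    n = len(seq)
    hit_len = hit.end - hit.start + 1
    u0 = hit_len - CORE_REMAINDER  # consensus bases upstream of & including the G
    if hit.strand == "+":
        oriented, ostart = seq, hit.start
    else:
        oriented, ostart = reverse_complement(seq), n - hit.end + 1

    ext = 0
    mismatches = 0
    truncated = False
    full_site = False
    while True:
        rpos = reference.crossover_g_index - u0 - ext
        if rpos < 1:
            full_site = True
            break
        cpos = ostart - 1 - ext
        if cpos < 1:
            truncated = True
            logger.warning(
                "delta-attI context window truncated by a contig edge (%s:%d)",
                hit.seq_id,
                hit.start,
            )
            break
        if oriented[cpos - 1] != reference.sequence[rpos - 1]:
            if mismatches < max_mismatches:
                mismatches += 1
            else:
                break
        ext += 1

    upstream_run = u0 + ext
    position_label = -upstream_run
    retained = upstream_run + CORE_REMAINDER

    s0, e0 = ostart - ext, ostart + hit_len - 1
    xo = ostart + u0 - 1  # oriented crossover G position
    if hit.strand == "+":
        start, end, crossover = s0, e0, xo
    else:
        start, end, crossover = n - e0 + 1, n - s0 + 1, n - xo + 1

    return DeltaAttISite(
        class_label=cls,
        position_label=position_label,
        retained_length=retained,
        hit=hit,
        upstream_extension=ext,
        core_matched=hit.matched[-7:],
        seq_id=hit.seq_id,
        start=start,
        end=end,
        strand=hit.strand,
        crossover_pos=crossover,
        truncated=truncated,
        full_site=full_site,
    )


def _context_orf(site: DeltaAttISite, orfs: Sequence[Orf], window: int) -> Optional[Orf]:
    """The nearest same-strand ORF whose stop codon lies within ``window`` nt
    upstream of the site's attI-derived fragment (in the ORF's orientation).

    The window is anchored at the fragment start, not the consensus match:
    long truncations (e.g. a 244-nt -238 fragment) begin right after the
    stop codon while their minimal consensus sits hundreds of nt further in.
    """
    best: Optional[tuple[int, Orf]] = None
    for orf in orfs:
        if orf.strand != site.strand:
            continue
        if site.strand == "+":
            dist = site.start - orf.end
        else:
            dist = orf.start - site.end
        if 0 < dist <= window and (best is None or dist < best[0]):
            best = (dist, orf)
    return best[1] if best else None


def find_delta_atti_cassette_sites(
    sequence: str,
    orfs: Optional[Sequence[Orf]],
    references: Mapping[str, ReferenceAttI] = BUNDLED_REFERENCES,
    *,
    seq_id: str = "",
    window: int = 150,
    require_orf_context: bool = True,
    motifs: Mapping[str, IUPACMotif] = BUILTIN_MOTIFS,
    max_extension_mismatches: int = 0,
) -> list[DeltaAttISite]:
    """Scan a sequence for cassette-borne delta-attI sites.

    Only consensus matches that begin within ``window`` nt downstream of an
    ORF stop codon (in the ORF's orientation) are returned; matches inside
    ORFs are excluded. Each returned site records its upstream ORF.
    """
    if require_orf_context and not orfs:
        raise ValueError(
            "delta-attI cassette detection needs ORF annotations (GenBank CDS "
            "features or synthetic truth); supply them or pass "
            "require_orf_context=False to classify context-free matches"
        )
    orfs = list(orfs or [])
    sites: list[DeltaAttISite] = []
    for motif_name in ("delta_attI1", "delta_attI2"):
        motif = motifs[motif_name]
        ref = references[_MOTIF_CLASS[motif_name]]
        for hit in scan(sequence, motif, "both", seq_id=seq_id):
            if any(o.contains(hit.start) or o.contains(hit.end) for o in orfs):
                continue
            site = classify_delta_atti(
                hit, sequence, ref, max_mismatches=max_extension_mismatches
            )
            orf = _context_orf(site, orfs, window)
            if require_orf_context and orf is None:
                continue
            if orf is not None:
                site = dataclasses.replace(site, orf_id=orf.orf_id)
            sites.append(site)
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def derive_consensus(instances: Iterable[str]) -> str:
    """Minimal IUPAC consensus of aligned equal-length sequences.

    Per column, returns the IUPAC code whose base set equals the union of
    the observed bases (degenerate input codes contribute their full sets).
    """
    seqs = [s.upper() for s in instances]
    if not seqs:
        raise ValueError("derive_consensus needs at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("derive_consensus needs equal-length sequences")
    out = []
    for col in range(length):
        union: set[str] = set()
        for s in seqs:
            union |= expand_iupac(s[col])
        out.append(iupac_for_bases(union))
    return "".join(out)


_SITE_TSV_HEADER = (
    "seq_id\torf_id\tclass\tposition_label\tretained_length\tstart\tend\tstrand"
)


def write_sites_tsv(sites: Iterable[DeltaAttISite], path) -> None:
    with open(path, "w") as fh:
        fh.write(_SITE_TSV_HEADER + "\n")
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.orf_id or '.'}\t{s.class_label}\t{s.position_label}"
                f"\t{s.retained_length}\t{s.start}\t{s.end}\t{s.strand}\n"
            )


def write_sites_gff3(sites: Iterable[DeltaAttISite], path, *, source="integronkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in sites:
            attrs = (
                f"Name={s.label};position_label={s.position_label};"
                f"retained_length={s.retained_length};core_matched={s.core_matched}"
            )
            if s.orf_id:
                attrs += f";upstream_orf={s.orf_id}"
            fh.write(
                f"{s.seq_id}\t{source}\trecombination_site\t{s.start}\t{s.end}"
                f"\t.\t{s.strand}\t.\t{attrs}\n"
            )
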