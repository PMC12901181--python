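"""Cassette-array assembly, architecture typing, and tandem-run detection.

A gene cassette is one ORF flanked by its nearest upstream and downstream
recombination sites; cassette boundaries run from crossover G to crossover
G, so consecutive cassettes tile the variable region without overlap. The
architecture label of a cassette is derived from its two flanking site
types (e.g. ``attI1-ORF-attC``, ``attC-ORF-ΔattI2-11``). Arrays are
reported 5'->3' relative to the attI/intI end of the integron.

Tandem runs are maximal stretches of >= 2 consecutive cassettes whose keyed
sequences are pairwise identical at a configurable threshold; the default
key is the full cassette (ORF plus downstream site) at exact identity,
matching how duplicated cassettes are described in integron surveys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import edlib

from .attc import AttCSite
from .delta_atti import DeltaAttISite, Orf

logger = logging.getLogger("integronkit")


@dataclass(frozen=True)
class AttISite:
    """A full attI site placed on a record (e.g. the integron's primary site)."""

    class_label: str
    seq_id: str
    start: int
    end: int
    strand: str
    crossover_pos: int

    @property
    def label(self) -> str:
        return f"attI{self.class_label}"


Site = Union[AttISite, AttCSite, DeltaAttISite]


@dataclass(frozen=True)
class Cassette:
    """One ORF with its flanking recombination sites.

    ``cassette_sequence`` runs from the base after the upstream crossover G
    through the downstream crossover G inclusive, so consecutive cassettes
    partition the variable region.
    """

    orf: Orf
    upstream_site: Optional[Site]
    downstream_site: Optional[Site]
    architecture: str
    cassette_sequence: str
    orf_sequence: str
    downstream_site_sequence: str = ""

    @property
    def orf_id(self) -> str:
        return self.orf.orf_id


@dataclass
class CassetteArray:
    integron_id: str
    class_label: str
    cassettes: list[Cassette]
    orphans: list[Orf] = field(default_factory=list)
    tandem_runs: list["TandemRun"] = field(default_factory=list)

    def array_string(self) -> str:
        """One-line array rendering, e.g. ``attI1|aadB|ΔattI1-11``."""
        if not self.cassettes:
            return ""
        parts = []
        first_up = self.cassettes[0].upstream_site
        parts.append(first_up.label if first_up else "edge")
        for c in self.cassettes:
            parts.append(c.orf.display_name)
            parts.append(c.downstream_site.label if c.downstream_site else "edge")
        return "|".join(parts)


@dataclass(frozen=True)
class TandemRun:
    start_index: int  # index of the first cassette of the run
    length: int
    identity: float

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("a tandem run has at least two cassettes")


def _resolve_overlaps(sites: Sequence[Site]) -> list[Site]:
    """Leftmost-longest conflict resolution among overlapping sites."""
    ordered = sorted(sites, key=lambda s: (s.start, -(s.end - s.start)))
    kept: list[Site] = []
    for site in ordered:
        if kept and site.start <= kept[-1].end:
            logger.warning(
                "overlapping sites at %s:%d-%d resolved leftmost-longest",
                getattr(site, "seq_id", "?"),
                site.start,
                site.end,
            )
            continue
        kept.append(site)
    return kept


def build_array(
    sites: Sequence[Site],
    orfs: Sequence[Orf],
    integron_class: str,
    sequence: str,
    *,
    integron_id: str = "",
    edge_window: int = 150,
) -> CassetteArray:
    """Assemble the ordered cassette array of one (orientation-normalized) record.

    Each ORF flanked by a nearest upstream and downstream site becomes a
    cassette with crossover-G boundaries; ORFs lacking an upstream site are
    orphans, and ORFs whose downstream flank is the contig edge (within
    ``edge_window`` nt) are emitted with a ``-truncated`` architecture.
    """
    seq = sequence.upper()
    n = len(seq)
    resolved = _resolve_overlaps(sites)
    cassettes: list[Cassette] = []
    orphans: list[Orf] = []
    for orf in sorted(orfs, key=lambda o: o.start):
        upstream = [s for s in resolved if s.crossover_pos < orf.start]
        downstream = [s for s in resolved if s.crossover_pos > orf.end]
        up = max(upstream, key=lambda s: s.crossover_pos) if upstream else None
        down = min(downstream, key=lambda s: s.crossover_pos) if downstream else None
        if up is None:
            orphans.append(orf)
            continue
        if down is None:
            if n - orf.end > edge_window:
                orphans.append(orf)
                continue
            architecture = f"{up.label}-ORF-truncated"
            cassette_seq = seq[up.crossover_pos : n]
            down_seq = ""
        else:
            architecture = f"{up.label}-ORF-{down.label}"
            cassette_seq = seq[up.crossover_pos : down.crossover_pos]
            down_seq = seq[down.start - 1 : down.end]
        cassettes.append(
            Cassette(
                orf=orf,
                upstream_site=up,
                downstream_site=down,
                architecture=architecture,
                cassette_sequence=cassette_seq,
                orf_sequence=seq[orf.start - 1 : orf.end],
                downstream_site_sequence=down_seq,
            )
        )
    return CassetteArray(
        integron_id=integron_id,
        class_label=integron_class,
        cassettes=cassettes,
        orphans=orphans,
    )


def _identity(a: str, b: str) -> float:
    """Length-normalized global identity of two sequences."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def detect_tandem(
    array: CassetteArray,
    identity_threshold: float = 1.0,
    key: str = "full_cassette",
) -> list[TandemRun]:
    """Maximal runs of >=2 consecutive cassettes pairwise identical at threshold.

    ``key`` selects what is compared: ``"full_cassette"`` (ORF plus
    downstream site, the default reading of "identical cassettes" — the
    upstream flank is excluded so the first copy of a run is not penalized
    for following a different site type) or ``"orf"`` (repeat-identity
    reading).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if key == "full_cassette":
        keyed = [c.orf_sequence + c.downstream_site_sequence for c in array.cassettes]
    elif key == "orf":
        keyed = [c.orf_sequence for c in array.cassettes]
    else:
        raise ValueError(f"unknown tandem key: {key!r}")
    runs: list[TandemRun] = []
    i = 0
    n = len(keyed)
    while i < n - 1:
        members = [i]
        worst = 1.0
        j = i + 1
        while j < n:
            idents = [_identity(keyed[j], keyed[m]) for m in members]
            if min(idents) >= identity_threshold:
                worst = min(worst, *idents)
                members.append(j)
                j += 1
            else:
                break
        if len(members) >= 2:
            runs.append(TandemRun(i, len(members), worst))
            i = members[-1] + 1
        else:
            i += 1
    array.tandem_runs = runs
    return runs


def write_array_tsv(arrays: Iterable[CassetteArray], path) -> None:
    with open(path, "w") as fh:
        fh.write("integron_id\tindex\torf_id\tarchitecture\ttandem_flag\n")
        for arr in arrays:
            in_run = set()
            for run in arr.tandem_runs:
                in_run.update(range(run.start_index, run.start_index + run.length))
            for idx, c in enumerate(arr.cassettes):
                flag = "tandem" if idx in in_run else "."
                fh.write(
                    f"{arr.integron_id}\t{idx}\t{c.orf_id}\t{c.architecture}\t{flag}\n"
                )
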