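"""attC site detection, bottom-strand folding, and extrahelical-base calling.

An attC site (57-141 bp) is bounded by the inverse core site R''
(5'-RYYYAAC-3') and the core site R' (5'-GTTRRRY-3') and carries two
regions of inverted homology, R''-L'' and L'-R', whose pairing folds the
single (bottom) strand into a stem-loop. Imperfections of the inverted
repeat protrude from the stem as extrahelical bases (EHBs), which the
integron integrase requires for recognition.

The fold here is a pairing-topology model, not a thermodynamic one: the
left arm is globally aligned against the reverse complement of the right
arm (Watson-Crick match +1, mismatch 0, linear gap penalty), because the
structural claims the package evaluates concern which positions pair and
which bases are extruded, not free energies.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .motifs import BUILTIN_MOTIFS, MotifHit, scan

logger = logging.getLogger("integronkit")

WC = {"A": "T", "T": "A", "G": "C", "C": "G"}

ATTC_MIN_LENGTH = 57
ATTC_MAX_LENGTH = 141
CORE_LEN = 7


def _complementary(a: str, b: str, wobble: bool) -> bool:
    if WC.get(a) == b:
        return True
    return wobble and {a, b} == {"G", "T"}


@dataclass(frozen=True)
class EHB:
    """An extrahelical (unpaired, gapped) base within the stem.

    ``position`` is 1-based within its arm (5'->3'); ``stem_offset`` counts
    from the core-proximal end of the stem (the R''/R' end), which is the
    coordinate the canonical-EHB check uses.
    """

    arm: str  # "left" | "right"
    position: int
    base: str
    stem_offset: int


@dataclass(frozen=True)
class FoldResult:
    """Arm pairing of an attC bottom strand.

    ``pairs`` holds (left_arm_position, right_arm_position) 1-based pairs,
    all Watson-Crick complementary; ``stem_score`` is the number of paired
    positions minus ``gap_penalty`` units per gapped base.
    """

    pairs: tuple[tuple[int, int], ...]
    ehbs: tuple[EHB, ...]
    stem_score: int
    n_pairs: int
    n_gaps: int


@dataclass(frozen=True)
class AttCSite:
    """A candidate or accepted attC site (cores, spans, arms, optional fold)."""

    seq_id: str
    r2_core: MotifHit  # R'' (inverse core site), upstream
    r1_core: MotifHit  # R' (core site), downstream
    start: int
    end: int
    total_length: int
    arm_left: str
    arm_right: str
    loop: str
    strand: str = "+"
    fold: Optional[FoldResult] = None

    def __post_init__(self) -> None:
        if self.r2_core.start >= self.r1_core.start:
            raise ValueError("R'' must precede R' on the cassette top strand")

    @property
    def label(self) -> str:
        return "attC"

    @property
    def crossover_pos(self) -> int:
        """Forward coordinate of the crossover G (first base of R')."""
        return self.r1_core.start if self.strand == "+" else self.r1_core.end


def find_core_pairs(
    sequence: str,
    *,
    seq_id: str = "",
    min_length: int = ATTC_MIN_LENGTH,
    max_length: int = ATTC_MAX_LENGTH,
    min_loop: int = 10,
) -> list[AttCSite]:
    """Every ordered (R'', R') core pair whose implied site length is in bounds.

    Candidates are unfolded; nested and overlapping candidates are all
    reported (downstream consumers resolve conflicts). Scanning is on the
    given (top) strand: the core pair is self-complementary as a pair, so a
    bottom-strand attC shows up as a top-strand pair on the flipped record.
    """
    seq = sequence.upper()
    r2_hits = scan(seq, BUILTIN_MOTIFS["inverse_core_site"], "forward", seq_id=seq_id)
    r1_hits = scan(seq, BUILTIN_MOTIFS["core_site"], "forward", seq_id=seq_id)
    out: list[AttCSite] = []
    for r2 in r2_hits:
        for r1 in r1_hits:
            if r1.start <= r2.end:
                continue
            total = r1.end - r2.start + 1
            if not min_length <= total <= max_length:
                continue
            site = seq[r2.start - 1 : r1.end]
            arm = max(CORE_LEN, (total - min_loop) // 2)
            arm = min(arm, total // 2)
            out.append(
                AttCSite(
                    seq_id=seq_id,
                    r2_core=r2,
                    r1_core=r1,
                    start=r2.start,
                    end=r1.end,
                    total_length=total,
                    arm_left=site[:arm],
                    arm_right=site[-arm:],
                    loop=site[arm : total - arm],
                )
            )
    out.sort(key=lambda s: (s.start, s.end))
    return out


def fold_bottom_strand(
    candidate: AttCSite,
    *,
    gap_penalty: int = 1,
    wobble: bool = False,
) -> FoldResult:
    """Fold a candidate by arm alignment and report pairs and EHBs.

    Global alignment of the left arm against the reverse complement of the
    right arm, maximizing Watson-Crick pairs with a linear gap penalty.
    Ties are broken deterministically, preferring to place gaps (EHBs) at
    the core-proximal end of the stem.
    """
    left, right = candidate.arm_left, candidate.arm_right
    if len(left) < CORE_LEN or len(right) < CORE_LEN:
        raise ValueError("attC arms shorter than the 7-nt cores cannot be folded")
    return _align_arms(left, right, gap_penalty=gap_penalty, wobble=wobble)


def _align_arms(
    left: str, right: str, *, gap_penalty: int = 1, wobble: bool = False
) -> FoldResult:
    """Needleman-Wunsch of ``left`` vs reversed ``right`` with pairing scores."""
    L = left.upper()
    Rv = right.upper()[::-1]  # index 0 = core-proximal end of the right arm
    nL, nR = len(L), len(Rv)
    g = gap_penalty
    # DP matrices: score and deterministic move preference (diag > up > left,
    # applied during traceback; "up" consumes a left-arm base, i.e. a gap in
    # the right arm).
    score = [[0] * (nR + 1) for _ in range(nL + 1)]
    for i in range(1, nL + 1):
        score[i][0] = -g * i
    for k in range(1, nR + 1):
        score[0][k] = -g * k
    for i in range(1, nL + 1):
        row, prev = score[i], score[i - 1]
        li = L[i - 1]
        for k in range(1, nR + 1):
            match = 1 if _complementary(li, Rv[k - 1], wobble) else 0
            row[k] = max(prev[k - 1] + match, prev[k] - g, row[k - 1] - g)

    pairs: list[tuple[int, int]] = []
    ehbs: list[EHB] = []
    n_gaps = 0
    i, k = nL, nR
    while i > 0 or k > 0:
        s = score[i][k]
        if i > 0 and k > 0:
            match = 1 if _complementary(L[i - 1], Rv[k - 1], wobble) else 0
            if s == score[i - 1][k - 1] + match:
                if match:
                    pairs.append((i, nR - k + 1))
                i, k = i - 1, k - 1
                continue
        if i > 0 and s == score[i - 1][k] - g:
            ehbs.append(EHB("left", i, L[i - 1], i))
            n_gaps += 1
            i -= 1
            continue
        # gap in the left arm: right-arm base k (core-proximal offset k) extruded
        ehbs.append(EHB("right", nR - k + 1, Rv[k - 1], k))
        n_gaps += 1
        k -= 1
    pairs.reverse()
    ehbs.reverse()
    n_pairs = len(pairs)
    return FoldResult(
        pairs=tuple(pairs),
        ehbs=tuple(ehbs),
        stem_score=n_pairs - g * n_gaps,
        n_pairs=n_pairs,
        n_gaps=n_gaps,
    )


def check_canonical_ehbs(
    fold: FoldResult,
    config: Optional[Sequence[dict]] = None,
    *,
    tolerance: int = 1,
) -> tuple[bool, list[dict]]:
    """Check presence of the two canonical EHBs required for single-stranded
    recognition of an attC site.

    ``config`` lists the expected EHBs as dicts with keys ``base`` and
    ``stem_offset`` (core-proximal stem coordinate) and optionally ``arm``;
    an EHB matches if base identity agrees and the offset is within
    ``tolerance``. Returns (all_present, report_of_missing).
    """
    if not config:
        raise ValueError(
            "no canonical EHB specification configured; supply a list of "
            "{'base', 'stem_offset'[, 'arm']} entries (see config.DEFAULT_CONFIG)"
        )
    missing: list[dict] = []
    for want in config:
        found = any(
            e.base == want["base"].upper()
            and abs(e.stem_offset - int(want["stem_offset"])) <= tolerance
            and ("arm" not in want or e.arm == want["arm"])
            for e in fold.ehbs
        )
        if not found:
            missing.append(dict(want))
    return (not missing, missing)


def find_attc_sites(
    sequence: str,
    *,
    seq_id: str = "",
    min_length: int = ATTC_MIN_LENGTH,
    max_length: int = ATTC_MAX_LENGTH,
    min_loop: int = 10,
    min_paired_fraction: float = 0.75,
    gap_penalty: int = 1,
    wobble: bool = False,
) -> list[AttCSite]:
    """Candidate core pairs filtered by fold quality, conflicts resolved.

    A candidate is accepted when the fraction of arm positions paired by the
    fold reaches ``min_paired_fraction`` (true attC arms are near-perfect
    inverted repeats; spurious core pairs over random sequence are not).
    Overlapping accepted candidates are resolved leftmost-longest.
    """
    accepted: list[AttCSite] = []
    for cand in find_core_pairs(
        sequence,
        seq_id=seq_id,
        min_length=min_length,
        max_length=max_length,
        min_loop=min_loop,
    ):
        fold = fold_bottom_strand(cand, gap_penalty=gap_penalty, wobble=wobble)
        frac = fold.n_pairs / max(len(cand.arm_left), len(cand.arm_right))
        if frac >= min_paired_fraction:
            accepted.append(dataclasses.replace(cand, fold=fold))
    accepted.sort(key=lambda s: (s.start, -(s.end - s.start)))
    kept: list[AttCSite] = []
    for site in accepted:
        if kept and site.start <= kept[-1].end:
            continue
        kept.append(site)
    return kept


def fold_dot_bracket(site: AttCSite) -> str:
    """Dot-bracket rendering of a folded site over its full span."""
    if site.fold is None:
        raise ValueError("site has no fold; run fold_bottom_strand first")
    chars = ["."] * site.total_length
    nL = len(site.arm_left)
    right_offset = site.total_length - len(site.arm_right)
    for lp, rp in site.fold.pairs:
        chars[lp - 1] = "("
        chars[right_offset + rp - 1] = ")"
    return "".join(chars)


def write_ehbs_tsv(sites: Iterable[AttCSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tsite_start\tsite_end\tarm\tposition\tbase\tstem_offset\n")
        for s in sites:
            if s.fold is None:
                continue
            for e in s.fold.ehbs:
                fh.write(
                    f"{s.seq_id}\t{s.start}\t{s.end}\t{e.arm}\t{e.position}"
                    f"\t{e.base}\t{e.stem_offset}\n"
                )


def write_attc_gff3(sites: Iterable[AttCSite], path, *, source="integronkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in sites:
            attrs = f"Name=attC;total_length={s.total_length}"
            if s.fold is not None:
                attrs += f";stem_pairs={s.fold.n_pairs};ehbs={len(s.fold.ehbs)}"
            fh.write(
                f"{s.seq_id}\t{source}\tattC_site\t{s.start}\t{s.end}\t.\t{s.strand}\t.\t{attrs}\n"
            )
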