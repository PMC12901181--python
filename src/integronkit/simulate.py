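"""Ground-truth synthetic integron generator.

Builds annotated integron records — a leading recombination site followed by
gene cassettes (ORF plus downstream site) — with a truth table of every
planted feature, so detection, classification, array assembly and tandem
calling can be validated round-trip without any external data. Also
simulates the colony-count data of in vivo recombination assays.

Design points that make the truth exact at mutation rate 0:

* Inter-site filler, spacers and ORF interiors are regenerated until they
  contain no accidental occurrence of the core-site / inverse-core-site
  consensus on either strand (the two patterns are mutual reverse
  complements, so screening the forward strand for both covers both
  strands, and every detector motif in this package contains one of them).
  Junctions are vetted with 6 nt of flanking context so no motif can arise
  across a boundary.
* attC sites are built as perfect inverted repeats (R''-arm ... loop ...
  arm'-R') with extrahelical bases inserted on request; delta-attI sites
  are cut from the bundled reference attI at the requested crossover-
  relative position and completed with a realized TTRRRY core remainder.
* Tandem duplicates are byte-for-byte copies of the whole cassette unit,
  and each unit is vetted against its own tail context so copy-after-copy
  junctions stay clean.
* Point mutations are substitutions only (truth coordinates stay stable)
  and never touch the 7-mer cores or minimal consensus footprints.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay import AssayReplicate
from .motifs import reverse_complement
from .references import BUNDLED_REFERENCES
from .survey import IntegronRecord
from .delta_atti import Orf

# Realized TTRRRY core remainders appended downstream of the crossover G
# (contributed in vivo by the downstream joint / R'' of the next cassette).
CORE_REMAINDER_REALIZED = {"1": "TTAGAC", "2": "TTAGGT"}

# aadB-style realized cores for synthetic attC sites.
ATTC_R2 = "GCCTAAC"          # matches RYYYAAC
ATTC_R2_DEAD = "GCCTAGG"     # the point-inactivated R'' used as a negative control

_STRAY_RES = (
    re.compile(r"(?=(GTT[AG][AG][AG][CT]))"),  # core site GTTRRRY
    re.compile(r"(?=([AG][CT][CT][CT]AAC))"),  # inverse core site RYYYAAC
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _stray_spans(seq: str) -> list[tuple[int, int]]:
    """0-based inclusive spans of every core/inverse-core occurrence."""
    out = []
    for rx in _STRAY_RES:
        for m in rx.finditer(seq):
            out.append((m.start(), m.start() + 6))
    return out


def _is_clean(seq: str, allowed: Sequence[tuple[int, int]] = ()) -> bool:
    for s, e in _stray_spans(seq):
        if not any(a <= s and e <= b for a, b in allowed):
            return False
    return True


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _clean_filler(
    rng: np.random.Generator, n: int, left: str = "", right: str = ""
) -> str:
    """Random filler vetted (with junction context) to contain no stray core."""
    for _ in range(1000):
        seg = _rand_seq(rng, n)
        if _is_clean(left[-6:] + seg + right[:6]):
            return seg
    raise RuntimeError("could not generate clean filler (contexts too constrained)")


@dataclass(frozen=True)
class CassettePlan:
    """Plan for one cassette: an ORF and its downstream site.

    ``downstream_site`` is one of ``"attC"``, ``"attI1_full"``,
    ``"dattI1:-X"`` / ``"dattI2:-X"`` (a delta-attI cut at crossover-relative
    position -X). ``ehbs`` lists extrahelical-base insertions for attC sites
    as (arm, stem_offset, base) with stem_offset > 7 (cores stay intact).
    ``duplicate_of`` makes this cassette a byte-identical copy of an earlier
    plan entry (tandem duplication).
    """

    orf_length: int = 300
    downstream_site: str = "attC"
    name: Optional[str] = None
    duplicate_of: Optional[int] = None
    ehbs: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.orf_length < 30 or self.orf_length % 3:
            raise ValueError("orf_length must be >= 30 and a multiple of 3")
        for arm, off, base in self.ehbs:
            if arm not in ("left", "right") or off <= 7 or base not in "ACGT":
                raise ValueError(f"invalid EHB insertion spec: {(arm, off, base)}")


@dataclass(frozen=True)
class SyntheticIntegronSpec:
    integron_id: str = "synthetic_integron"
    integron_class: str = "1"
    leading_site: str = "attI1"  # attI1 | attI2 | attC
    cassette_plan: tuple[CassettePlan, ...] = ()
    mutation_rate: float = 0.0
    seed: int = 0
    orf_spacer: int = 20   # nt between upstream site and ORF start
    site_spacer: int = 8   # nt between ORF stop codon and downstream site
    flank: int = 60        # leading/trailing filler

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.integron_class not in ("1", "2", "SCI"):
            raise ValueError("integron_class must be 1, 2 or SCI")
        if self.site_spacer < 1:
            raise ValueError("site_spacer must be >= 1 (the base before a "
                             "planted site delimits its identity run)")
        for i, plan in enumerate(self.cassette_plan):
            if plan.duplicate_of is not None and not 0 <= plan.duplicate_of < i:
                raise ValueError("duplicate_of must reference an earlier cassette")


@dataclass(frozen=True)
class TruthRow:
    record_id: str
    feature_type: str  # orf | attI | attC | delta_attI
    label: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    cassette_index: Optional[int] = None
    tandem_group: Optional[int] = None


@dataclass
class SyntheticIntegron:
    record: IntegronRecord
    truth: list[TruthRow]
    tandem_runs: list[tuple[int, int]]  # (first cassette index, run length)
    spec: SyntheticIntegronSpec

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.truth])


@dataclass(frozen=True)
class _SiteBytes:
    seq: str
    site_type: str
    label: str
    crossover_offset: int  # 1-based within seq; 0 if not applicable
    protected: tuple[tuple[int, int], ...]  # 0-based inclusive, mutation-protected
    ehbs: tuple[tuple[str, int, str], ...] = ()
    # reference base that must NOT immediately precede the planted fragment
    # (it would silently extend the attI identity run by one position)
    blocked_base: Optional[str] = None


def _build_delta_atti(class_label: str, position: int) -> _SiteBytes:
    ref = BUNDLED_REFERENCES[class_label]
    x = -position
    floor = 8 if class_label == "1" else 9
    if x < floor:
        raise ValueError(
            f"delta-attI{class_label} position must be <= -{floor}, got {position}"
        )
    if x > ref.crossover_g_index:
        raise ValueError(
            f"position {position} exceeds the bundled attI{class_label} extent "
            f"(-{ref.crossover_g_index})"
        )
    frag = ref.upstream_of_crossover[-x:] + CORE_REMAINDER_REALIZED[class_label]
    u0 = floor  # consensus bases upstream of & including the crossover G
    # protect the minimal consensus footprint (incl. realized core remainder)
    prot_start = x - u0
    blocked = (
        ref.sequence[ref.crossover_g_index - x - 1]
        if x < ref.crossover_g_index
        else None
    )
    return _SiteBytes(
        seq=frag,
        site_type="delta_attI",
        label=f"ΔattI{class_label}{position}",
        crossover_offset=x,
        protected=((prot_start, len(frag) - 1),),
        blocked_base=blocked,
    )


def _build_atti_full(class_label: str) -> _SiteBytes:
    ref = BUNDLED_REFERENCES[class_label]
    # protect the consensus/core region around the crossover
    u0 = 8 if class_label == "1" else 9
    lo = ref.crossover_g_index - u0
    hi = min(len(ref.sequence), ref.crossover_g_index + 6) - 1
    return _SiteBytes(
        seq=ref.sequence,
        site_type="attI",
        label=f"attI{class_label}",
        crossover_offset=ref.crossover_g_index,
        protected=((lo, hi),),
    )


def _build_attc(
    rng: np.random.Generator,
    ehbs: tuple[tuple[str, int, str], ...] = (),
    *,
    arm_extension: int = 20,
    loop_length: int = 10,
) -> _SiteBytes:
    """A synthetic attC: perfect inverted-repeat arms around an unpaired loop,
    with requested extrahelical-base insertions."""
    for _ in range(1000):
        ext = _rand_seq(rng, arm_extension)
        loop = _rand_seq(rng, loop_length)
        left = ATTC_R2 + ext
        right = reverse_complement(left)
        for arm, off, base in ehbs:
            if arm == "left":
                if off > len(left):
                    raise ValueError("EHB stem_offset beyond the arm")
                left = left[:off] + base + left[off:]
            else:
                if off > len(right):
                    raise ValueError("EHB stem_offset beyond the arm")
                pos = len(right) - off  # core-proximal offset from the 3' end
                right = right[:pos] + base + right[pos:]
        site = left + loop + right
        allowed = ((0, 6), (len(site) - 7, len(site) - 1))
        if _is_clean(site, allowed):
            return _SiteBytes(
                seq=site,
                site_type="attC",
                label="attC",
                crossover_offset=len(site) - 6,  # the G of R'
                protected=allowed,
                ehbs=ehbs,
            )
    raise RuntimeError("could not build a clean synthetic attC site")


def _build_site(rng: np.random.Generator, spec: str, ehbs=()) -> _SiteBytes:
    if spec == "attC":
        return _build_attc(rng, tuple(ehbs))
    if spec in ("attI1_full", "attI1"):
        return _build_atti_full("1")
    if spec in ("attI2_full", "attI2"):
        return _build_atti_full("2")
    m = re.fullmatch(r"dattI([12]):(-\d+)", spec)
    if m:
        return _build_delta_atti(m.group(1), int(m.group(2)))
    raise ValueError(f"unknown site spec: {spec!r}")


def _build_orf(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3 - 2
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "ATG" + "".join(_CODONS[i] for i in idx) + "TAA"


@dataclass(frozen=True)
class _Unit:
    seq: str
    orf_rel: tuple[int, int]   # 0-based inclusive within unit
    site_rel: tuple[int, int]
    site: _SiteBytes


def _build_unit(
    rng: np.random.Generator,
    plan: CassettePlan,
    spec: SyntheticIntegronSpec,
    left_ctx: str,
) -> _Unit:
    site = _build_site(rng, plan.downstream_site, plan.ehbs)
    for _ in range(1000):
        spacer1 = _rand_seq(rng, spec.orf_spacer)
        orf = _build_orf(rng, plan.orf_length)
        spacer2 = _rand_seq(rng, spec.site_spacer)
        if site.blocked_base and spacer2[-1] == site.blocked_base:
            continue  # would extend the attI identity run past the planted cut
        unit = spacer1 + orf + spacer2 + site.seq
        site_start = len(unit) - len(site.seq)
        # Vet against the actual left context and the unit's own tail (so a
        # byte-copy can follow another copy without creating a junction motif).
        ok = True
        for ctx in {left_ctx[-6:], unit[-6:]}:
            shift = len(ctx)
            allowed = [(site_start + shift, len(unit) - 1 + shift)]
            if not _is_clean(ctx + unit, allowed):
                ok = False
                break
        if ok:
            orf_start = len(spacer1)
            return _Unit(
                seq=unit,
                orf_rel=(orf_start, orf_start + plan.orf_length - 1),
                site_rel=(site_start, len(unit) - 1),
                site=site,
            )
    raise RuntimeError("could not assemble a clean cassette unit")


def _tandem_groups(plans: Sequence[CassettePlan]) -> dict[int, int]:
    """Map cassette index -> root index of its duplicate group."""
    root: dict[int, int] = {}
    for i, plan in enumerate(plans):
        if plan.duplicate_of is None:
            root[i] = i
        else:
            root[i] = root[plan.duplicate_of]
    return root


def generate_integron(spec: SyntheticIntegronSpec) -> SyntheticIntegron:
    """Emit one synthetic integron record with features and truth table.

    Deterministic for a fixed spec (including its seed); run twice, the
    emitted bytes are identical.
    """
    rng = np.random.default_rng(spec.seed)
    rec_id = spec.integron_id

    parts: list[str] = []
    pos = 0  # 0-based length so far

    def _append(seg: str) -> int:
        nonlocal pos
        parts.append(seg)
        start = pos
        pos += len(seg)
        return start

    truth: list[TruthRow] = []
    protected: list[tuple[int, int]] = []  # 0-based inclusive, absolute
    site_anchors: list[tuple[int, _SiteBytes]] = []  # (abs 0-based start, site)

    lead = _build_site(rng, spec.leading_site)
    filler = _clean_filler(rng, spec.flank, right=lead.seq)
    _append(filler)
    lead_start = _append(lead.seq)
    site_anchors.append((lead_start, lead))
    truth.append(
        TruthRow(rec_id, lead.site_type, lead.label, lead_start + 1,
                 lead_start + len(lead.seq), "+")
    )
    protected.extend((lead_start + a, lead_start + b) for a, b in lead.protected)

    groups = _tandem_groups(spec.cassette_plan)
    units: dict[int, _Unit] = {}
    orfs: list[Orf] = []
    for i, plan in enumerate(spec.cassette_plan):
        if plan.duplicate_of is not None:
            unit = units[plan.duplicate_of]
            # junction safety: the original was vetted against its own tail
            shift = 6
            allowed = [(unit.site_rel[0] + shift, len(unit.seq) - 1 + shift)]
            if not _is_clean("".join(parts)[-6:] + unit.seq, allowed):
                raise ValueError(
                    f"impossible plan: duplicate cassette {i} creates a junction motif"
                )
        else:
            unit = _build_unit(rng, plan, spec, "".join(parts[-2:]))
        units[i] = unit
        u_start = _append(unit.seq)
        group = groups[i]
        tgroup = group if any(
            groups[j] == group for j in range(len(spec.cassette_plan)) if j != i
        ) else None
        orf_start = u_start + unit.orf_rel[0]
        orf_end = u_start + unit.orf_rel[1]
        base_plan = spec.cassette_plan[group]
        orf = Orf(
            orf_id=f"{rec_id}_orf{i}",
            start=orf_start + 1,
            end=orf_end + 1,
            strand="+",
            name=base_plan.name,
        )
        orfs.append(orf)
        truth.append(
            TruthRow(rec_id, "orf", base_plan.name or orf.orf_id,
                     orf.start, orf.end, "+", i, tgroup)
        )
        site = unit.site
        s_start = u_start + unit.site_rel[0]
        truth.append(
            TruthRow(rec_id, site.site_type, site.label, s_start + 1,
                     s_start + len(site.seq), "+", i, tgroup)
        )
        site_anchors.append((s_start, site))
        protected.extend((s_start + a, s_start + b) for a, b in site.protected)

    _append(_clean_filler(rng, spec.flank, left="".join(parts[-1:])))
    sequence = "".join(parts)

    # tandem runs implied by the plan (consecutive members of one group)
    runs: list[tuple[int, int]] = []
    i = 0
    plans = spec.cassette_plan
    while i < len(plans) - 1:
        j = i + 1
        while j < len(plans) and groups[j] == groups[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = max(j, i + 1)

    if spec.mutation_rate > 0:
        sequence = _mutate(rng, sequence, spec.mutation_rate, protected)

    record = IntegronRecord(
        record_id=rec_id,
        class_label=spec.integron_class,
        sequence=sequence,
        orfs=orfs,
        source="synthetic",
    )
    return SyntheticIntegron(record=record, truth=truth, tandem_runs=runs, spec=spec)


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    rate: float,
    protected: Sequence[tuple[int, int]],
) -> str:
    """Substitutions only (no indels), never inside protected core footprints."""
    n = len(sequence)
    mask = rng.random(n) < rate
    for a, b in protected:
        mask[a : b + 1] = False
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    idx = np.nonzero(mask)[0]
    if idx.size:
        # substitute with one of the three other bases
        cur = np.searchsorted(_BASES, arr[idx])
        offs = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + offs) % 4]
    return arr.tobytes().decode()


def generate_corpus(
    specs: Sequence[SyntheticIntegronSpec], seed: int
) -> tuple[list[SyntheticIntegron], pd.DataFrame]:
    """Generate one record per spec with per-record seeds derived from ``seed``.

    The planted composition is invariant to the master seed; only the
    concrete sequences change.
    """
    if not specs:
        raise ValueError("generate_corpus needs at least one spec")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    sims = []
    for i, (spec, s) in enumerate(zip(specs, child_seeds)):
        sims.append(generate_integron(dataclasses.replace(spec, seed=int(s))))
    merged = pd.DataFrame(
        [dataclasses.asdict(r) for s in sims for r in s.truth]
    )
    return sims, merged


def generate_assay_counts(
    true_p: float,
    n_replicates: int = 3,
    n_colonies: int = 30,
    seed: int = 0,
    *,
    construct_id: str = "construct",
    event_type: str = "excision",
) -> list[AssayReplicate]:
    """Binomial colony-PCR counts: each replicate picks ``n_colonies`` colonies
    and scores each positive with probability ``true_p``."""
    if not 0 <= true_p <= 1:
        raise ValueError("true_p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ks = rng.binomial(n_colonies, true_p, size=n_replicates)
    return [
        AssayReplicate(construct_id, event_type, n_colonies, int(k)) for k in ks
    ]


# ---------------------------------------------------------------------------
# text-format emitters


def write_corpus_fasta(sims: Sequence[SyntheticIntegron], path) -> None:
    with open(path, "w") as fh:
        for sim in sims:
            fh.write(f">{sim.record.record_id}\n")
            seq = sim.record.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_tsv(sims: Sequence[SyntheticIntegron], path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(r) for s in sims for r in s.truth])
    frame.to_csv(path, sep="\t", index=False)


def write_record_genbank(sim: SyntheticIntegron, path) -> None:
    """GenBank flat file with CDS features for ORFs and misc_recombination
    features for planted sites."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(sim.record.sequence),
        id=sim.record.record_id[:16],
        name=sim.record.record_id[:16],
        description=f"synthetic integron (class {sim.record.class_label})",
        annotations={"molecule_type": "DNA"},
    )
    for orf in sim.record.orfs:
        loc = FeatureLocation(orf.start - 1, orf.end, strand=1 if orf.strand == "+" else -1)
        feat = SeqFeature(loc, type="CDS")
        feat.qualifiers["locus_tag"] = [orf.orf_id]
        if orf.name:
            feat.qualifiers["gene"] = [orf.name]
        rec.features.append(feat)
    for row in sim.truth:
        if row.feature_type == "orf":
            continue
        loc = FeatureLocation(row.start - 1, row.end, strand=1)
        feat = SeqFeature(loc, type="misc_recomb")
        feat.qualifiers["note"] = [row.label]
        rec.features.append(feat)
    from Bio import SeqIO

    SeqIO.write(rec, str(path), "genbank")
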