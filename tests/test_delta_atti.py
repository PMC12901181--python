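"""Truncated-attI classification: position<->length convention, context filter,
consensus derivation."""

import pytest

from integronkit.delta_atti import (
    Orf,
    classify_delta_atti,
    derive_consensus,
    find_delta_atti_cassette_sites,
    write_sites_gff3,
    write_sites_tsv,
)
from integronkit.motifs import BUILTIN_MOTIFS, reverse_complement, scan
from integronkit.references import ATTI1_REFERENCE, ATTI2_REFERENCE, BUNDLED_REFERENCES
from integronkit.simulate import CORE_REMAINDER_REALIZED

CLASS_REF = {"1": ATTI1_REFERENCE, "2": ATTI2_REFERENCE}
CLASS_MOTIF = {"1": "delta_attI1", "2": "delta_attI2"}


def fragment(class_label: str, position: int) -> str:
    """The attI-derived fragment ending at crossover-relative position
    ``position``: reference bases -|position|..-1 plus a realized TTRRRY."""
    ref = CLASS_REF[class_label]
    return (
        ref.upstream_of_crossover[position:]
        + CORE_REMAINDER_REALIZED[class_label]
    )


def blocker(class_label: str, position: int) -> str:
    """A base that differs from the reference base just upstream of a
    fragment cut at ``position``, so the upstream walk stops exactly there."""
    ref = CLASS_REF[class_label]
    idx = ref.crossover_g_index + position - 1  # 0-based, base before the fragment
    if idx < 0:
        return "C"
    return "C" if ref.sequence[idx] != "C" else "A"


def padded(class_label: str, position: int, *, left: str = "CCATG") -> str:
    """Fragment embedded with non-extending flanks."""
    return (
        left
        + blocker(class_label, position)
        + fragment(class_label, position)
        + "CCATGG"
    )


def classify_fragment(class_label: str, position: int):
    seq = padded(class_label, position)
    hits = scan(seq, BUILTIN_MOTIFS[CLASS_MOTIF[class_label]], "forward")
    assert len(hits) == 1
    return classify_delta_atti(hits[0], seq, CLASS_REF[class_label])


# every (position, retained length) pair the convention must reproduce
PRINTED_PAIRS = [
    ("1", -12, 18),
    ("1", -11, 17),
    ("1", -10, 16),
    ("1", -8, 14),
    ("2", -11, 17),
    ("2", -10, 16),
    ("2", -9, 15),
    ("2", -238, 244),
]


class TestPositionLengthConvention:
    @pytest.mark.parametrize("cls,position,retained", PRINTED_PAIRS)
    def test_printed_pairs(self, cls, position, retained):
        site = classify_fragment(cls, position)
        assert site.position_label == position
        assert site.retained_length == retained
        assert site.class_label == cls
        assert not site.truncated and not site.full_site

    def test_bare_minimal_consensus_is_class_floor(self):
        """A consensus match with zero upstream extension is the -8 (class 1)
        or -9 (class 2) site, matching the consensus length."""
        for cls, floor in (("1", -8), ("2", -9)):
            site = classify_fragment(cls, floor)
            assert site.upstream_extension == 0
            assert site.retained_length == len(BUILTIN_MOTIFS[CLASS_MOTIF[cls]])

    @pytest.mark.parametrize("cls,krange", [("1", range(14, 57)), ("2", range(15, 60))])
    def test_planted_k_nt_fragment_yields_minus_k_minus_6(self, cls, krange):
        """A k-nt reference-identical fragment always classifies as -(k-6)."""
        for k in krange:
            site = classify_fragment(cls, -(k - 6))
            assert site.position_label == -(k - 6)
            assert site.retained_length == k

    @pytest.mark.parametrize("cls,position", [("1", -20), ("2", -30)])
    def test_truncating_one_upstream_base_drops_retained_by_one(self, cls, position):
        a = classify_fragment(cls, position)
        b = classify_fragment(cls, position + 1)
        assert a.retained_length - b.retained_length == 1

    def test_retained_minus_label_is_six_everywhere(self):
        for cls, position, _ in PRINTED_PAIRS:
            site = classify_fragment(cls, position)
            assert site.retained_length - (-site.position_label) == 6

    def test_classification_is_deterministic_and_idempotent(self):
        runs = [classify_fragment("1", -11) for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]


class TestClassifyEdges:
    def test_contig_edge_sets_truncated_flag(self):
        # fragment cut at -11 but with only 2 context bases upstream of it
        frag = fragment("1", -11)
        seq = frag[2:] + "CCATGG"  # upstream walk runs off the contig start
        hits = scan(seq, BUILTIN_MOTIFS["delta_attI1"], "forward")
        site = classify_delta_atti(hits[0], seq, ATTI1_REFERENCE)
        assert site.truncated
        assert site.position_label == -9  # only one upstream base matched

    def test_full_reference_present_flags_full_site(self):
        ref = ATTI1_REFERENCE
        seq = "CCATGG" + ref.sequence + "CCATGG"
        hits = scan(seq, BUILTIN_MOTIFS["delta_attI1"], "forward")
        site = classify_delta_atti(hits[0], seq, ref)
        assert site.full_site
        assert site.position_label == -ref.crossover_g_index
        assert site.label == "attI1"

    def test_class_mismatch_rejected(self):
        seq = padded("1", -11)
        hits = scan(seq, BUILTIN_MOTIFS["delta_attI1"], "forward")
        with pytest.raises(ValueError, match="class"):
            classify_delta_atti(hits[0], seq, ATTI2_REFERENCE)

    def test_minus_strand_fragment_classified_with_same_label(self):
        plus = blocker("1", -11) + fragment("1", -11)
        seq = "CCATGG" + reverse_complement(plus) + "CCATGG"
        hits = scan(seq, BUILTIN_MOTIFS["delta_attI1"], "both")
        assert len(hits) == 1 and hits[0].strand == "-"
        site = classify_delta_atti(hits[0], seq, ATTI1_REFERENCE)
        assert site.position_label == -11
        assert site.retained_length == 17
        assert site.strand == "-"
        # span covers the whole 17-nt fragment on forward coordinates
        assert site.end - site.start + 1 == 17


class TestContextFilter:
    def _orf(self, start, end, strand="+", orf_id="orfA"):
        return Orf(orf_id=orf_id, start=start, end=end, strand=strand)

    def test_site_shortly_after_stop_codon_is_linked(self):
        orf = "ATG" + "GCT" * 20 + "TAA"
        seq = "CCATGG" + orf + "CCAT" + blocker("1", -11) + fragment("1", -11) + "CCATGG"
        orfs = [self._orf(7, 6 + len(orf))]
        sites = find_delta_atti_cassette_sites(seq, orfs)
        assert len(sites) == 1
        assert sites[0].orf_id == "orfA"
        assert sites[0].position_label == -11

    def test_consensus_inside_orf_is_excluded(self):
        # embed the minimal consensus mid-ORF: context filter must drop it
        insert = "AAACAAAGTTAGAC"  # 14 nt, frame-preserving but irrelevant here
        orf = "ATG" + "GCT" * 6 + insert + "GCT" * 6 + "TAA"
        seq = "CCATGG" + orf + "CCATGG"
        orfs = [self._orf(7, 6 + len(orf))]
        assert find_delta_atti_cassette_sites(seq, orfs) == []

    def test_beyond_window_is_excluded(self):
        orf = "ATG" + "GCT" * 20 + "TAA"
        gap = "CCATGG" * 29 + "CCATG" + blocker("1", -11)  # 180 nt > default 150 window
        seq = "CC" + orf + gap + fragment("1", -11) + "CC"
        orfs = [self._orf(3, 2 + len(orf))]
        assert find_delta_atti_cassette_sites(seq, orfs) == []
        relaxed = find_delta_atti_cassette_sites(seq, orfs, window=200)
        assert len(relaxed) == 1

    def test_two_cassettes_reported_in_array_order(self):
        orf1 = "ATG" + "GCT" * 15 + "TAA"
        orf2 = "ATG" + "CAT" * 15 + "TAA"
        frag = blocker("2", -11) + fragment("2", -11)
        seq = "CCATGG" + orf1 + "CCAT" + frag + "CCATGG" + orf2 + "CCAT" + frag + "CC"
        o1 = self._orf(7, 6 + len(orf1), orf_id="o1")
        s2 = seq.index(orf2) + 1
        o2 = self._orf(s2, s2 + len(orf2) - 1, orf_id="o2")
        sites = find_delta_atti_cassette_sites(seq, [o1, o2])
        assert [s.orf_id for s in sites] == ["o1", "o2"]
        assert [s.position_label for s in sites] == [-11, -11]
        assert sites[0].start < sites[1].start

    def test_missing_orf_annotations_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="ORF annotations"):
            find_delta_atti_cassette_sites("ACGT" * 30, [])

    def test_context_filter_can_be_disabled(self):
        seq = padded("1", -11)
        sites = find_delta_atti_cassette_sites(seq, [], require_orf_context=False)
        assert len(sites) == 1 and sites[0].orf_id is None


class TestDeriveConsensus:
    def test_union_columns_produce_printed_consensus(self):
        got = derive_consensus(["AAACAAAGTTAGAC", "AAACAAAGTTGAGT"])
        assert got == "AAACAAAGTTRRRY"

    def test_single_sequence_is_itself(self):
        assert derive_consensus(["ACGT"]) == "ACGT"

    def test_full_union_is_n(self):
        assert derive_consensus(["AAAA", "CCCC", "GGGG", "TTTT"]) == "NNNN"

    def test_degenerate_inputs_contribute_their_sets(self):
        assert derive_consensus(["AR", "AG"]) == "AR"

    def test_empty_and_ragged_rejected(self):
        with pytest.raises(ValueError):
            derive_consensus([])
        with pytest.raises(ValueError):
            derive_consensus(["ACG", "AC"])


def test_site_writers(tmp_path):
    site = classify_fragment("1", -11)
    tsv, gff = tmp_path / "sites.tsv", tmp_path / "sites.gff3"
    write_sites_tsv([site], tsv)
    write_sites_gff3([site], gff)
    row = tsv.read_text().splitlines()[1].split("\t")
    assert row[2:5] == ["1", "-11", "17"]
    assert "recombination_site" in gff.read_text()


def test_bundled_references_are_wired_by_class():
    assert BUNDLED_REFERENCES["1"] is ATTI1_REFERENCE
    assert BUNDLED_REFERENCES["2"] is ATTI2_REFERENCE
    assert ATTI1_REFERENCE.sequence[ATTI1_REFERENCE.crossover_g_index - 1] == "G"
    assert ATTI2_REFERENCE.sequence[ATTI2_REFERENCE.crossover_g_index - 1] == "G"
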