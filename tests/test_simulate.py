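"""Generator guarantees: determinism, exact round-trip truth, graceful
degradation under mutation."""

import dataclasses

import pytest

from integronkit.attc import check_canonical_ehbs
from integronkit.config import default_config
from integronkit.motifs import BUILTIN_MOTIFS, scan
from integronkit.simulate import (
    CassettePlan,
    SyntheticIntegronSpec,
    generate_corpus,
    generate_integron,
)
from integronkit.survey import analyze_record


def variety_specs():
    """A corpus exercising every planted feature type."""
    P = CassettePlan
    return [
        SyntheticIntegronSpec("v0", "1", "attI1", (P(downstream_site="dattI1:-11"),), seed=1),
        SyntheticIntegronSpec("v1", "1", "attI1", (P(downstream_site="dattI1:-12"), P(downstream_site="attC")), seed=2),
        SyntheticIntegronSpec("v2", "1", "attI1", (P(downstream_site="dattI1:-8"),), seed=3),
        SyntheticIntegronSpec("v3", "1", "attC", (P(downstream_site="dattI1:-10"),), seed=4),
        SyntheticIntegronSpec("v4", "2", "attI2", (P(downstream_site="dattI2:-11"),), seed=5),
        SyntheticIntegronSpec("v5", "2", "attI2", (P(downstream_site="dattI2:-9"), P(downstream_site="dattI2:-238")), seed=6),
        SyntheticIntegronSpec("v6", "2", "attI2", (P(downstream_site="dattI2:-10"),), seed=7),
        SyntheticIntegronSpec("v7", "1", "attI1", (P(downstream_site="attI1_full"),), seed=8),
        SyntheticIntegronSpec("v8", "1", "attI1", (P(name="dup"), P(duplicate_of=0), P(duplicate_of=0), P(duplicate_of=0)), seed=9),
        SyntheticIntegronSpec("v9", "1", "attI1", (P(name="two"), P(duplicate_of=0), P(downstream_site="dattI1:-11")), seed=10),
        # class-2 site inside a class-1 integron (cross-class)
        SyntheticIntegronSpec("v10", "1", "attI1", (P(downstream_site="dattI2:-11"),), seed=11),
        SyntheticIntegronSpec(
            "v11", "1", "attI1",
            (P(downstream_site="attC", ehbs=(("left", 13, "G"), ("left", 19, "T"))),),
            seed=12,
        ),
    ]


def truth_site_rows(sim):
    return [r for r in sim.truth if r.feature_type in ("attI", "attC", "delta_attI")]


def detected_site_keys(res):
    keys = set()
    for s in res.atti_sites:
        keys.add(("attI", f"attI{s.class_label}", s.start, s.end))
    for s in res.attc_sites:
        keys.add(("attC", "attC", s.start, s.end))
    for s in res.delta_sites:
        keys.add(("delta_attI", s.label, s.start, s.end))
    return keys


class TestDeterminism:
    def test_same_spec_same_bytes(self):
        spec = variety_specs()[1]
        a, b = generate_integron(spec), generate_integron(spec)
        assert a.record.sequence == b.record.sequence
        assert a.truth == b.truth

    def test_master_seed_changes_sequences_not_composition(self):
        specs = variety_specs()[:4]
        sims1, truth1 = generate_corpus(specs, seed=1)
        sims2, truth2 = generate_corpus(specs, seed=2)
        assert any(
            a.record.sequence != b.record.sequence for a, b in zip(sims1, sims2)
        )
        comp1 = sorted(truth1[truth1.feature_type != "orf"].label)
        comp2 = sorted(truth2[truth2.feature_type != "orf"].label)
        assert comp1 == comp2

    def test_corpus_size_matches_specs(self):
        sims, _ = generate_corpus(variety_specs()[:10], seed=5)
        assert len(sims) == 10


class TestRoundTrip:
    def test_recall_and_precision_one_at_mutation_rate_zero(self):
        """Every planted site is detected with exact coordinates and exact
        variant label, and nothing else is detected, corpus-wide."""
        sims, _ = generate_corpus(variety_specs(), seed=42)
        for sim in sims:
            res = analyze_record(sim.record)
            want = {
                (r.feature_type, r.label, r.start, r.end) for r in truth_site_rows(sim)
            }
            got = detected_site_keys(res)
            assert got == want, sim.record.record_id

    def test_planted_tandem_recovered_in_truth_and_detection(self):
        sims, _ = generate_corpus(variety_specs(), seed=43)
        by_id = {s.record.record_id: s for s in sims}
        assert by_id["v8"].tandem_runs == [(0, 4)]
        res = analyze_record(by_id["v8"].record)
        assert [(r.start_index, r.length) for r in res.array.tandem_runs] == [(0, 4)]
        res9 = analyze_record(by_id["v9"].record)
        assert [(r.start_index, r.length) for r in res9.array.tandem_runs] == [(0, 2)]

    def test_no_stray_core_motifs_outside_truth_spans(self):
        """Every core/inverse-core occurrence in the emitted sequence lies
        inside a planted site span (on either strand)."""
        sims, _ = generate_corpus(variety_specs(), seed=44)
        for sim in sims:
            spans = [(r.start, r.end) for r in truth_site_rows(sim)]
            for motif in ("core_site", "inverse_core_site"):
                for hit in scan(sim.record.sequence, BUILTIN_MOTIFS[motif], "both"):
                    assert any(a <= hit.start and hit.end <= b for a, b in spans), (
                        sim.record.record_id, motif, hit,
                    )

    def test_planted_ehbs_recovered_and_canonical_check_passes(self):
        sims, _ = generate_corpus(variety_specs(), seed=45)
        sim = next(s for s in sims if s.record.record_id == "v11")
        res = analyze_record(sim.record)
        (site,) = res.attc_sites
        ehbs = site.fold.ehbs
        assert len(ehbs) >= 2
        cfg = default_config()["attc"]
        ok, missing = check_canonical_ehbs(
            site.fold, cfg["canonical_ehbs"], tolerance=cfg["ehb_position_tolerance"]
        )
        assert ok, missing
        # an unbulged attC fails the same canonical check
        plain = next(s for s in sims if s.record.record_id == "v1")
        plain_res = analyze_record(plain.record)
        ok_plain, missing_plain = check_canonical_ehbs(
            plain_res.attc_sites[0].fold, cfg["canonical_ehbs"]
        )
        assert not ok_plain and len(missing_plain) == 2


class TestMutationDegradation:
    def _recall(self, rate: float) -> float:
        specs = [
            dataclasses.replace(s, mutation_rate=rate) for s in variety_specs()
        ]
        sims, _ = generate_corpus(specs, seed=77)
        matched = total = 0
        for sim in sims:
            res = analyze_record(sim.record)
            got = detected_site_keys(res)
            for r in truth_site_rows(sim):
                total += 1
                matched += (r.feature_type, r.label, r.start, r.end) in got
        return matched / total

    def test_recall_non_increasing_in_mutation_rate(self):
        r0, r1, r5 = self._recall(0.0), self._recall(0.01), self._recall(0.05)
        assert r0 == 1.0
        assert r0 >= r1 >= r5

    def test_mutations_are_substitutions_only(self):
        spec = dataclasses.replace(variety_specs()[0], mutation_rate=0.05)
        mutated = generate_integron(spec)
        clean = generate_integron(dataclasses.replace(spec, mutation_rate=0.0))
        assert len(mutated.record.sequence) == len(clean.record.sequence)
        assert mutated.truth == clean.truth  # coordinates stable


class TestSpecValidation:
    def test_orf_length_constraints(self):
        with pytest.raises(ValueError):
            CassettePlan(orf_length=31)
        with pytest.raises(ValueError):
            CassettePlan(orf_length=27)

    def test_duplicate_must_reference_earlier(self):
        with pytest.raises(ValueError):
            SyntheticIntegronSpec(
                cassette_plan=(CassettePlan(duplicate_of=1), CassettePlan())
            )

    def test_delta_position_bounds(self):
        with pytest.raises(ValueError, match="-8"):
            generate_integron(
                SyntheticIntegronSpec(cassette_plan=(CassettePlan(downstream_site="dattI1:-7"),))
            )
        with pytest.raises(ValueError, match="extent"):
            generate_integron(
                SyntheticIntegronSpec(cassette_plan=(CassettePlan(downstream_site="dattI1:-57"),))
            )

    def test_mutation_rate_bounds(self):
        with pytest.raises(ValueError):
            SyntheticIntegronSpec(mutation_rate=1.0)

    def test_bad_ehb_spec(self):
        with pytest.raises(ValueError):
            CassettePlan(ehbs=(("left", 3, "G"),))  # inside the core

    def test_unknown_site_spec(self):
        with pytest.raises(ValueError, match="site spec"):
            generate_integron(
                SyntheticIntegronSpec(cassette_plan=(CassettePlan(downstream_site="attX"),))
            )


def test_truth_frame_columns(single_cassette_sim):
    frame = single_cassette_sim.truth_frame()
    assert {"record_id", "feature_type", "label", "start", "end", "strand"} <= set(
        frame.columns
    )
    assert (frame.start <= frame.end).all()
    n = len(single_cassette_sim.record.sequence)
    assert (frame.end <= n).all()
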