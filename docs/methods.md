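# Methods

## Site model

Integron recombination sites are modelled at the sequence-pattern level, as
the screening scripts used for curated integron datasets model them:

* **Core geometry.** The cassette-top-strand core site R' follows
  5'-GTTRRRY-3' and the inverse core site R'' follows 5'-RYYYAAC-3' (the
  two consensi are mutual reverse complements). The recombination crossover
  lies between the first (G) and second nucleotides of the core.
* **ΔattI sites.** A truncated attI site is a run of attI-derived sequence
  that ends at the crossover G and continues with the 6-nt TTRRRY remainder
  of the core (contributed by the downstream joint). Sites are labelled by
  their upstream extent: position −X ⇒ retained length X + 6 nt. The
  class-1 minimal consensus (AAACAAAGTTRRRY, 14 nt) is the −8 site and the
  class-2 minimal consensus (AATAAAATGTTRRRY, 15 nt) the −9 site; this is
  the only convention consistent with all printed (position, length) pairs
  for both classes, and it is enforced as a dataclass invariant.
* **attC sites.** A candidate attC is any ordered (R'', R') pair spanning
  57–141 bp. Its bottom strand is folded by globally aligning the left arm
  against the reverse complement of the right arm (Watson–Crick pair +1,
  aligned mismatch 0, linear gap −1). Gapped positions are reported as
  extrahelical bases (EHBs). This is a pairing-topology model, not a
  thermodynamic one: the claims it supports concern which bases pair and
  which are extruded, not free energies, so a full RNA-folding energy model
  would add parameters without adding discriminative power here.

## Classification procedure

1. Scan both strands for the minimal ΔattI consensus of each class.
2. Discard matches inside annotated ORFs; anchor the remainder to the
   bundled reference attI of the class and walk upstream base by base until
   the first mismatch, reference exhaustion, or a contig edge.
3. Accept a site only if its attI-derived fragment begins within a window
   (default 150 nt) downstream of a same-strand ORF stop codon. The window
   is anchored at the fragment start rather than the consensus match, since
   long truncations (e.g. a 244-nt −238 fragment) start right after the
   stop codon while their consensus lies hundreds of nt further downstream.
4. A walk that exhausts the reference means the complete attI site is
   present; such matches are promoted to full attI sites, not counted as
   truncations.

Upstream extension demands exact identity (the curated sites these labels
describe are 100%-identity fragments); a mismatch budget exists for
exploratory screens but is off by default.

## Bundled references

The two reference attI sites are synthetic stand-ins constructed to honor
every published structural constraint (class 1: 65 bp, DR1/DR2 direct
repeats, L box CCCTAAA, R box matching GTTRRRY, 3' run …CCCTAAAACAAAG^
ending at the crossover G at position 56; class 2: a 311-bp region ending
…AATAAAATG^TTAACC with the crossover G at position 305), vetted to contain
no accidental core/consensus motif occurrence on either strand. Every
classification quantity depends only on the position↔length arithmetic
anchored at the crossover G, which the stand-ins reproduce exactly; the
accessions they model are recorded in `config.DEFAULT_CONFIG["references"]`.
The class-1 site's full extent (−56) is stored as an explicit crossover
index because the published 65-bp span does not follow the X + 6 rule that
governs the truncations.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `delta_atti.orf_context_window` | 150 | nt | cassette ΔattI sites sit a few nt after the stop codon; 150 nt bounds the search without reaching the next cassette |
| `attc.min_length` / `max_length` | 57 / 141 | bp | the documented attC length envelope |
| `attc.min_loop` | 10 | nt | minimal unpaired central region assumed when slicing candidate arms |
| `attc.gap_penalty` | 1 | score units | one lost pair per extruded base |
| `attc.min_paired_fraction` | 0.75 | fraction | fold-quality acceptance: true inverted-repeat arms score ≥ 0.9; random arms behind spurious core pairs score ≈ 0.42 (max ≈ 0.67 over 300 trials), leaving a wide margin |
| `attc.canonical_ehbs` | G@13, T@19 (±1) | stem offset | literature-derived default for the two EHBs required for single-stranded recognition; configurable, and validated only against synthetic folds |
| `arrays.tandem_identity_threshold` | 1.0 | fraction | "identical cassettes" read strictly; relaxed thresholds available |
| `arrays.tandem_key` | full_cassette | — | ORF + downstream site; the upstream flank is excluded so the first copy of a run is not penalized for following a different site type |
| `assay.alpha` | 0.05 | — | conventional significance level |

G·T wobble pairs count as non-complementary by default because EHB
definitions in the structural literature are Watson–Crick based; a wobble
mode exists as a config switch.

## Numerical choices

* Coordinates are 1-based inclusive on the forward strand everywhere a
  result is reported; minus-strand work happens on reverse-complemented
  copies with coordinates mapped at the boundary.
* Fold tie-break: traceback prefers diagonal, then left-arm-consuming
  moves, which places gaps (EHBs) toward the core-proximal end of the stem;
  the stem score itself is tie-independent and is what the exhaustive
  oracle checks.
* Welch's test degenerate corner: two zero-variance samples with equal
  means give t = 0, p = 1; with unequal means the comparison is flagged
  degenerate and reported p = 0 with a warning (the saturated 100% vs 100%
  and 100% vs 0% comparisons make this corner reachable in practice).
* Letter grouping is a greedy clique cover in construct order with an
  absorb step when a new letter opens, so a construct indistinguishable
  from two mutually different groups receives both letters ("ab").
* Empirical size of the Welch test under the assay's own conditions
  (two groups, 3 replicates of 30 colonies, equal true frequency, 10,000
  simulations): ≈ 0.033 at nominal α = 0.05 — slightly conservative on
  discrete proportions, not inflated; the suite asserts the 0.02–0.06 band.
* No multiple-testing correction is applied to the pairwise Welch matrix by
  default (only "p < 0.05" is specified for this assay family); Holm's
  step-down is available via `correction="holm"`.

## Synthetic data: what it emulates and what it does not

`integronkit.simulate` emits integrons as: leading site (attI1, attI2 or
attC) → cassettes (spacer, stop-free ORF, spacer, downstream site) →
flanking filler. Planted sites are exact by construction: ΔattI fragments
are cut from the bundled references; attC arms are perfect inverted repeats
(7-nt core + 20-nt extension, 10-nt loop, 64 bp total — within the 57–141
envelope) with EHBs inserted on request; tandem duplicates are byte-exact
copies of whole cassette units. All filler, spacers and ORF interiors are
rejected-and-resampled until they contain no core/inverse-core occurrence
on either strand (junctions vetted with 6-nt context), and the base
immediately upstream of a ΔattI fragment is constrained to differ from the
next reference base — together these make mutation-rate-0 ground truth
exact: detection recovers every planted feature at exact coordinates with
no false positives, which the round-trip suite asserts corpus-wide.

Point mutations are substitutions only (coordinates stay stable) and never
touch core/consensus footprints. Because the mutation mask at a higher rate
is a superset of the mask at a lower rate for the same seed, detection
recall is non-increasing in mutation rate by construction, and the suite
checks it at rates 0, 0.01 and 0.05.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels and rearrangements, sequencing error,
GC-content and codon-usage structure, attC length/loop heterogeneity
(VCR-type long sites), degenerate site families diverged from the bundled
references, and integrase-mediated dynamics themselves. Published corpus
tallies from curated databases are snapshot-dependent and are exercised
only in spirit: the survey must recover a generator corpus planted with the
same composition (96/14 ΔattI1/ΔattI2 sites, 90× and 8× −11 variants, 65
identical blaOXA-10-type array strings, 2 cross-class events, 28
tandem-bearing integrons including one run of four) exactly, on a corpus of
~150 records — the counts, not the database size, carry the information.

## Problem sizes

The test suite and the reproduction script run on synthetic records of
roughly 0.5–1.3 kb, corpora of up to ~150 records, fold oracles on arms of
≤ 12 nt, and 10,000-replicate assay simulations; the full suite completes
in a few seconds on one CPU.

## Known limitations

* Integron class is metadata, never inferred from the integrase gene;
  records without ORF annotations get no ΔattI calls (the context filter
  is the in-silico stand-in for manual curation, plus a per-site review
  TSV with flanking sequence for human inspection).
* attC detection requires both cores to match their consensus exactly;
  atypical cores (e.g. a GTTATGA recognized in vivo) are findable only by
  explicit user-supplied motifs.
* Full-attI placement on a record is detected by exact reference match, so
  diverged full sites appear as long truncations instead.
* The fold model reports one optimal pairing; co-optimal alternative folds
  are resolved by the deterministic tie-break, not enumerated.
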