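# integronkit

Analysis of the recombination sites that organize **integron gene-cassette
arrays**, aimed at people who curate integron sequence collections or run
in vivo recombination assays.

Integrons capture and shuffle mobile gene cassettes through site-specific
recombination mediated by an integrase (IntI). A cassette is normally one
ORF followed by an *attC* site (57–141 bp), and the platform carries a
primary *attI* site next to the integrase gene. Some "unusual" cassettes
instead end in a **truncated attI fragment (ΔattI)**: a variable-length run
of *attI*-derived sequence ending at the recombination crossover G plus the
6-nt remainder of the core site. `integronkit` detects and classifies these
sites, types whole cassette arrays, finds tandem-duplicated cassettes, and
computes the statistics of colony-count recombination assays.

## What it computes

- **Degenerate motif scanning** (`integronkit.motifs`): exhaustive,
  strand-aware matching of IUPAC consensus motifs — the core site
  5'-GTTRRRY-3', the inverse core site 5'-RYYYAAC-3', and the minimal ΔattI
  consensus motifs 5'-AAACAAAGTTRRRY-3' (class 1) and
  5'-AATAAAATGTTRRRY-3' (class 2).
- **ΔattI classification** (`integronkit.delta_atti`): each consensus match
  is anchored to a bundled reference *attI* and extended upstream base by
  base; a site reaching crossover-relative position −X retains X + 6 nt
  (so ΔattI1₋₁₁ retains 17 nt, and the bare class-1 consensus is the
  14-nt −8 site). Matches are only accepted in cassette context (within a
  window downstream of an ORF stop codon).
- **attC modelling** (`integronkit.attc`): candidate sites from ordered
  (R'', R') core pairs, bottom-strand folding by arm alignment
  (Watson–Crick match +1, gap −1), and calling of **extrahelical bases
  (EHBs)** — the unpaired bases the integrase requires for single-stranded
  recognition — including a canonical-EHB presence check.
- **Array assembly and tandem detection** (`integronkit.arrays`): cassettes
  delimited by crossover-G boundaries, architecture labels such as
  `attI1-ORF-attC` or `attC-ORF-ΔattI2-11`, and maximal runs of ≥2
  consecutive identical cassettes.
- **Survey aggregation** (`integronkit.survey`): per-variant ΔattI tallies,
  ranked unusual-array strings, cross-class events (a class-2 site inside a
  class-1 integron), tandem summaries.
- **Assay statistics** (`integronkit.assay`): per-replicate excision /
  insertion frequencies from colony-PCR counts (mean ± sample SD), pairwise
  Welch's t-tests `t = (ā−b̄)/√(s²ₐ/nₐ + s²ᵦ/nᵦ)` with Welch–Satterthwaite
  degrees of freedom, and compact letter groupings at α = 0.05.
- **Synthetic ground truth** (`integronkit.simulate`): annotated integron
  records with planted sites, duplications, mutations and binomial colony
  counts, so the whole pipeline is testable round-trip without downloads.

## Worked example

Generate a two-cassette class-1 integron (attI1 | ORF | ΔattI1₋₁₁ | ORF |
attC) and classify its sites:

```bash
$ integronkit simulate --n-cassettes 2 --site dattI1:-11 --site attC \
      --seed 4 --fasta sim.fasta --truth sim.tsv --genbank sim.gb
wrote sim.fasta (922 nt) and sim.tsv

$ integronkit classify sim.gb
seq_id            orf_id                   class  position_label  retained_length  start  end  strand
synthetic_integr  synthetic_integron_orf0  1      -11             17               454    470  +
```

The classifier found one truncated class-1 attI site: its attI-identical
fragment extends to crossover-relative position −11, so it retains
11 + 6 = 17 nt (positions 454–470), and it sits directly downstream of the
first cassette ORF. The second cassette ends in a canonical attC, which the
`survey` subcommand folds and reports separately.

Assay statistics from a colony-count table
(`construct_id,event_type,replicate,n_colonies,k_positive`):

```bash
$ integronkit freq assay.csv
construct    event     mean       sd  n letter_group
       c1 excision 0.800000 0.100000  3            a
       c2 excision 0.033333 0.033333  3            b
```

Construct c1 excises in 80% ± 10% of colonies, c2 in ~3%; the disjoint
letters mean the difference is significant under pairwise Welch's t-tests
at α = 0.05.

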