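# Methods

## The classification model

`mitotax` decides between two closely related candidate species (SP1,
SP2) for a low-coverage ancient DNA sample using only the sample's reads
aligned to the two species' mitochondrial reference genomes.

1. **Target sites.** A global affine-gap pairwise alignment of the two
   references defines the set of single-nucleotide differences between
   them. Only **transversions** are kept as diagnostic sites: post-mortem
   cytosine deamination in ancient DNA produces C→T (and, on the
   complementary strand, G→A) artifacts, i.e. transitions, and
   high-frequency transitions are also the most homoplasy-prone class.
   A transversion site cannot be converted from one species' allele to
   the other's by deamination, which the test suite checks exhaustively
   over the 4×4 base table.
2. **Read labelling.** After standard aDNA filtering, each read is
   genotyped at the target sites it covers. A read whose informative
   observations all match the SP1 allele is labelled SP1; symmetrically
   for SP2; reads showing both species' alleles are *inconsistent* and
   excluded; reads with no informative observation are *uninformative*.
3. **Decision.** Under the null hypothesis that reads are equally likely
   to be labelled either species, the SP1 count among the
   `n = n_SP1 + n_SP2` assigned reads is Binomial(n, 0.5). The verdict
   is the majority species when the exact two-sided p-value is below α
   (default 0.05); otherwise *unidentified* (*no_data* when n = 0). The
   two-sided p-value uses the minimum-likelihood convention (sum of all
   outcome probabilities no larger than the observed one), which for
   p₀ = 0.5 equals twice the smaller tail capped at 1; a one-tailed
   variant exists for benchmarking samples of known identity, where the
   expected direction is known in advance.

An optional **type-2** site list removes positions known to be
polymorphic *within* either species (a position is called polymorphic
when a reference-aligned within-species panel shows ≥2 distinct
non-missing bases there). An optional **shared-reads** mode restricts
the analysis to read IDs aligned to both references, cancelling
reference-quality asymmetry at a substantial cost in power. Both options
are conservative variants, not defaults.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| alignment scoring | match +1, mismatch −2, gap open 10, gap extend 4 | score | plain affine scheme for ~90%-identical organelle genomes; a length-L gap costs `open + L·extend`. The derived site list depends on the scoring, so it is recorded in every site-set's provenance and exposed as configuration. |
| `min_mapq` | 30 | phred | discard ambiguous mappings; a documented preset of 20 (`MODERN_EQUID_FILTERS`) suits workflows aligning modern reads to mtDNA only. |
| `min_length` | 35 | bp | shorter fragments map unreliably in mammal-sized search spaces. |
| `max_mismatch_frac` | 0.10 | fraction of aligned bases | removes contaminant/damaged junk; mismatches = NM minus inserted/deleted bases. |
| dedup | on | — | reads with identical (reference, start, end, strand) are PCR duplicates; the highest-quality copy is kept (ties: smallest read ID) |
| `min_base_qual` | 13 | phred | drop untrustworthy base calls at target sites. |
| α | 0.05 | — | significance level of the verdict. |

## The read simulator

The simulator emulates a degraded, non-UDG-treated ancient library
sequenced on a modern short-read instrument:

* **Fragment lengths**: lognormal, median ≈ 65 bp, truncated to
  [35, 150] bp — the short-fragment regime of ancient extracts.
* **Placement**: uniform over the (linearised) reference, strand fair.
* **Damage**: double-strand deamination. C→T at 5′-position *i*
  (1-based) with probability `d_max·exp(−decay·(i−1))`, mirrored G→A
  from the 3′ end; defaults `d_max = 0.3`, `decay = 0.3`, chosen so that
  terminal damage clearly exceeds the >20% threshold conventionally used
  to authenticate ancient libraries.
* **Sequencing error**: uniform per-base substitution at 1%.
* **Base qualities**: constant Q30 (qualities carry no information in
  this simulator; FASTQ output exists for interoperability).

Every applied edit is recorded, and reads are emitted as truth
alignments at their true positions, so the downstream modules consume
them exactly as they would consume a mapped BAM. `project_reads`
re-expresses truth alignments against the *other* reference through the
alignment's coordinate map — substituting for the re-alignment step of a
real workflow. Synthetic reference pairs are generated by planting a
controlled number of transversions, transitions and short indels
(pairwise gaps forced > indel length + 1 so the planted truth list is
unambiguous) into a random sequence.

What the simulator does **not** model: adapter artifacts and read
merging, paired-end structure, microbial background, mappability
differences between the two references, NUMT contamination, UDG
treatment, within-species polymorphism in the sample, or
incomplete lineage sorting. Passing sweeps therefore demonstrate the
statistical behaviour of the decision procedure under idealised mapping,
not robustness to reference bias or contamination; on real data those
effects produce the small fraction of misassigned reads that the
binomial test is designed to absorb.

## Evaluation conventions

A sweep simulates replicate samples of both species across a coverage
grid and pools both species per coverage:

* TP = verdict matches the source species; FP = the other species;
  FN = *unidentified*;
* trials in which no read overlapped a target site are *not evaluable*
  and excluded from the denominators, reported separately;
* precision = TP/(TP+FP), recall = TP/(TP+FN),
  accuracy = TP/(TP+FP+FN) — three categories, no true-negative class.

Per-trial seeds derive from `SeedSequence(master, (coverage index,
species index, replicate))`, so any single trial is re-runnable in
isolation and whole sweeps are bit-reproducible for a fixed master seed.
The bundled sweeps (tests and `scripts/acceptance.py`) use 25 replicates
per species per coverage over {0.1, 0.3, 0.5, 1, 2, 3, 4, 5}×, on
synthetic pairs whose divergence matches the two worked species pairs
(197 transversions + 1502 transitions in 16,616 bp; 117 + 1147 in
16,660 bp) — sizes chosen so a full sweep runs in minutes on one core
while leaving the plateau behaviour (full precision and recall at
≥0.5×) well resolved. Sub-plateau recall depends on the fragment and
damage model, so only its qualitative decline with coverage is asserted,
not point values.

## Numerical and design choices

* **Alignment traceback ties** are resolved by Biopython's deterministic
  first-traceback rule; identical inputs and scoring always give the
  identical site list.
* **Ambiguity codes**: any alignment column containing a non-ACGT
  character yields no site — better to lose a site than fabricate an
  allele.
* **Circular genomes are treated as linear** strings exactly as
  deposited; no rotation search. A substitution falling at the deposited
  origin could be missed, which is negligible against ~200 sites.
* **Third alleles** (a read base matching neither species at a site)
  are non-evidence, not inconsistency: a single sequencing error should
  not discard an otherwise consistent read.
* **Cross-reference conflicts**: observations from a read's alignments
  to both references are pooled into one list before labelling, so a
  read supporting different species on the two references becomes
  inconsistent and is excluded.
* **Verdicts require a strict majority** in addition to significance —
  defensive only, since at p₀ = 0.5 a significant tie is impossible.
* **Degenerate inputs**: zero assigned reads → *no_data*; an empty site
  set classifies every sample as *no_data*; `n = 0` is an error at the
  test level and is mapped to *no_data* by the caller.
* **Coordinates** are 0-based half-open in memory and 1-based inclusive
  in every text file, stated in each writer.

## Known limitations

* The exact site counts derived from a given reference pair depend on
  the alignment scoring; with other scorings than the recorded one the
  counts may shift by a few sites. The scoring travels in provenance so
  any site list is reproducible.
* Only two candidate species are supported; hybrids, mixtures and
  "neither species" are outside the model (a sample from a third taxon
  tends to *unidentified*, but this is not guaranteed).
* Mitochondrial introgression between the candidate species invalidates
  the premise and cannot be detected from mtDNA alone.
* The binomial test treats reads as independent; overlapping reads from
  the same template violate this mildly after deduplication.
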