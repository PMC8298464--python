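# Methods

## Model and assumptions

`uidscaffold` treats scaffolding of a repeat-rich assembly as an
anchor-chaining problem over *unique regions*: maximal unmasked
stretches of at least `min_unique_len` bases. The model assumes that

- repeat annotations are trustworthy enough that masked sequence
  carries no reliable pairwise signal (the similarity of two repeat
  stretches is summarised only by their family labels, never by their
  bases);
- two contigs that truly abut on the genome share at least one unique
  stretch long enough to align (≥ `min_anchor_len` at
  ≥ `min_identity`); junctions whose shared sequence is entirely
  repetitive are out of reach of this method by construction;
- merges are sequence overlaps, not gapped joins: no N-spacers are ever
  inserted, and a merge is executed only where an anchor chain implies
  a concrete relative placement of the two contigs.

Coordinates are 0-based half-open everywhere internally; the 1-based
inclusive conventions of RepeatMasker `.out`, BLAST tabular, AGP and
GFF3 are converted exactly once at the format boundary.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `min_unique_len` | 100 | bp | minimum unmasked stretch to become a unique region |
| `min_anchor_len` | 500 | bp | minimum alignment length of an anchor (applied per anchor — the stricter reading; `min_chain_len`, default 0, additionally bounds the summed chain length) |
| `min_identity` | 80 | % | minimum alignment identity, 100 × matched columns / alignment columns |
| `repeat_agreement_min` | 0.5 | — | weighted-Jaccard threshold for repeat-family agreement between inter-anchor gaps |
| `max_cycles` | 32 | — | upper bound on merge cycles (iteration normally stops earlier, at the first 0-merge cycle) |
| `seed_k` / `min_shared_seeds` | 15 / 3 | — | canonical k-mer seed length and the number of distinct shared seeds required before a region pair is aligned |

The 100 bp / 500 bp / 80% values are the published criteria of the
strategy this package implements; the repeat-agreement metric and its
0.5 threshold, and the seeding parameters, are this implementation's
configuration points (the source strategy states only that repeat
families "must agree" and used an external BLASTN search).

Alignment scoring is match +1, mismatch −2, linear gap −2.5
(Bio.Align.PairwiseAligner in local mode). Identity counts matched
columns over all alignment columns including gaps — the stricter,
fully testable reading of "percent similarity".

## Criterion semantics

1. **Sequential appearance.** Anchors of a chain must be strictly
   increasing in the unique-region ordinals of both contigs
   (orientation-adjusted for `-` chains). The chainer can only produce
   such chains — it solves a weighted longest-increasing-subsequence
   over ordinal pairs — and the evaluator re-verifies defensively.
2. **Length.** Every anchor alignment must be ≥ `min_anchor_len`
   columns.
3. **Orientation.** All anchors of a chain share one strand; when both
   strands of a contig pair yield passing chains, the heavier chain
   (total anchor length, tie → `+`) survives, because a physical join
   has a single relative orientation.
4. **Consensus.** Candidates are ranked by composite score
   Σ(anchor length × identity/100). Each contig exposes two attachment
   points (left/right end, derived from the chain geometry; a contained
   contig consumes both of its own ends). When a candidate claims an
   end already taken, the two competing partner contigs are themselves
   matched, chained and evaluated: if they form a passing chain, that
   chain joins the candidate pool — laying the partners out
   transitively into one path — and otherwise only the incumbent
   (higher score, ties broken by contig id then strand) survives.
5. **Repeat agreement.** For each pair of consecutive anchors, the mask
   intervals in the gap on either contig are reduced to per-family base
   coverage vectors and compared by weighted Jaccard
   (Σ_f min / Σ_f max). Two repeat-free gaps score 1.0; a single-anchor
   chain has no gaps and passes vacuously. The chain passes when the
   minimum gap score reaches `repeat_agreement_min`.

## Merge execution

A chain implies an offset of (oriented) contig *b* on contig *a*'s
axis, taken from the first anchor. Four geometries follow: dovetail
(either order), and containment (either direction). Dovetails keep the
non-overlapping parts of both contigs and take the overlap bases from a
single *donor* — the contig with fewer masked bases inside the overlap
(ties: the longer contig, then the lexicographically smaller id). No
base-level consensus is called: the donor rule is deterministic and
exactly testable, and no per-base quality data exists at this stage.
Containments keep the container unchanged and record the contained
contig (AGP comment line; the W-lines must tile the scaffold).

Masks and the AGP-style component layout are lifted onto merged
coordinates; unique regions are re-extracted from the lifted masks at
the start of every cycle, so UIDs always refer to current coordinates
while base-level lineage stays traceable through the layout.

Within a cycle, the accepted (end-disjoint) merges are executed
sequentially in score order; a merge whose partner was already consumed
this cycle is simply re-discovered on the merged contig in the next
cycle. This keeps every executed merge's coordinates exact and reaches
the same fixed point as batch path execution. The pipeline contains no
randomness; contigs are processed in sorted-id order, so identical
inputs give identical outputs.

## Synthetic data

The simulator emulates the study conditions this method targets: a
200 kb genome containing three 5-kb repeat families × 8 copies (60%
repeat bases) with 2% per-copy substitution divergence, fragmented into
contigs of ≥ 10 kb that share 2 kb junction windows. Repeat copies are
separated by two kinds of unique gaps: short *anchor gaps*
(0.8–1.6 kb; every second inter-copy gap) and larger background gaps
carrying the remaining unique sequence. A breakpoint window covers one
complete anchor gap with both window ends inside the flanking repeat
copies, so contig ends terminate in repeats and the merge evidence is a
short internal unique anchor — the hard case the method exists for.
When no repeat-flanked gap fits a window (e.g. a repeat-free genome),
windows fall back to uniform placement. Each fragment is independently
reverse-complemented with probability 1/2; fragment annotations are
remapped, and neighbour identity plus relative orientation are recorded
as truth. All randomness flows from one seeded generator.

What the simulator does *not* emulate: sequencing errors or read-level
artefacts (both fragments of a junction carry byte-identical overlap
sequence, so anchors align at 100% identity), nested or truncated
repeat insertions, segmental duplications of unique sequence, and
assembly chimeras. Passing the benchmark therefore shows that the
criteria, chaining, conflict resolution and layout algebra are correct
and that recovery is complete when the model's assumptions hold — not
that the thresholds are optimal for noisy real assemblies, where
anchor identity below 100% and misannotated repeats will reduce
recall first (precision is protected by the 500 bp/80% floor and the
repeat-agreement check).

At these problem sizes (13 ± 2 contigs per replicate, 20 replicates)
a full pipeline run takes a few seconds, so the benchmark sweeps 20
seeds in both the default and the zero-divergence setting.

## Numerical and design choices

- **Seeding.** Region pairs are aligned only when they share ≥ 3
  distinct canonical 15-mers. At ≥ 80% identity over ≥ 500 bp the
  expected number of shared 15-mers is ≫ 3, so the filter is
  conservative; the test suite checks exact equality of the seeded and
  the exhaustive all-pairs search on small assemblies.
- **Tie-breaks.** Strand ties prefer `+`; equal-score candidates are
  ordered by contig ids; the family of a merged mask interval is the
  family covering most bases (ties: lexicographically smallest).
- **Degenerate inputs.** N runs are always masked (family `N`);
  contigs shorter than the seed length are simply never matched;
  repeat-only contigs (no unique stretch ≥ 100 bp) bypass merging and
  are flagged in the output, with an option to drop them.
- **GC%.** N bases are excluded from numerator and denominator.
- **Built-in maskers.** The k-mer masker (canonical 15-mers with
  assembly-wide count ≥ 4) and the exact tandem-unit masker are
  conveniences for running without external annotations; when both
  annotations and the built-in masker are used, the interval sets are
  unioned, with external annotations authoritative for family labels
  in their intervals.

## Known limitations

- Merges are overlap joins only; adjacencies whose junction has no
  unique anchor ≥ `min_anchor_len` are unrecoverable by design.
- Criterion 4's consensus probe aligns competing partners but does not
  verify sequence agreement outside anchor chains, so adversarial
  inputs with contradictory overlaps can still merge (the five criteria
  are the complete decision rule, by design).
- The chain-implied placement uses the first anchor's offset; large
  indels between anchors shift the donor overlap accordingly but are
  not re-aligned at base level.
- The cycle loop is greedy per cycle, not a global optimisation over
  all candidate joins.
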