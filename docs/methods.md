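# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `taxbench`. Notation follows the README: ranks are
ordered domain > phylum > class > order > family > genus > species
("lower" = more specific); d is integer-rounded percent identity.

## Pairwise identity

Identity is the fraction of matching columns in an optimal pairwise
alignment:

- **global mode** (default; used for all statistics and for the TOP
  classifier): global alignment, match +1, mismatch −2, internal affine gap
  of length L costing 10 + (L − 1), terminal gaps costing 1 per position.
  Terminal gap columns are *excluded* from the identity denominator, so a
  short query that is an exact substring of a longer target scores 100%.
- **local mode** (LTOP classifier): best local alignment under the same
  substitution/gap scores; identity over the local alignment's columns.

Two numerical choices deserve explanation:

1. *Terminal gaps are lightly penalized, not free.* With a mismatch penalty
   of 2 and free end gaps, the optimal "alignment" of any pair below ~67%
   true identity is a short perfect staggered overlap — every diverged pair
   reports 100% identity. A penalty of 1 per terminal position keeps
   homologous markers aligned over their full overlap while still tolerating
   genuine length differences (e.g., amplicon vs. full-length).
2. *Symmetry by canonicalization.* Co-optimal alignments can differ in
   identity (same score, different match counts). The pair is aligned in
   lexicographic order so identity(a, b) = identity(b, a) exactly.

Integer identities round half up (87.5 → 88). Alignment is delegated to a
C implementation (Biopython's `PairwiseAligner`); the test suite contains an
independent three-state affine-gap dynamic program with full traceback
enumeration and checks, over hundreds of random short pairs, that the
implementation's score is optimal and its identity is attained by an optimal
alignment.

Top-hit search is an exhaustive scan. Global mode ranks candidates by
identity, local mode by alignment score (a local alignment's identity is
trivially 100% whenever any exact word is shared), and the k-mer metric by
the number of shared *unique* 8-mers. Ties always resolve to the earliest
database record, which makes every search deterministic and reproducible
given the input order. Self-masking compares record ids, not sequences, so
identical sequences under different ids remain eligible.

## LCR probability statistics

All n(n−1)/2 unordered distinct record pairs contribute one observation
(d, LCR). Self-pairs are excluded: a self-pair always lands at d = 100 with
LCR equal to its own lowest rank and would only bias the top row. Pairs that
share no name at any compared rank are assigned a virtual rank ("NONE")
above domain; it occupies probability mass in P(LCR = r | d) — rows always
normalize to 1 — but is excluded from the cumulative P_CR and can never be
the most probable LCR.

MLR ties break toward the lower (more specific) rank. Rank identity
thresholds are a direct scan: RIT(r) = min{d : MLR(d) = r}; ranks that are
never most probable have no threshold, which genuinely happens (a rank can
be "skipped" when its band is dominated by a neighbor).

The known/novel estimator multiplies each top-hit identity histogram bin
N_d by P_CR(r | d) (known) and 1 − P_CR(r | d) (novel). When a histogram
bin has no probability row — possible on sparse references — P_CR is
linearly interpolated between the nearest occupied rows and clamped at the
range ends; each such case is logged. Rows built from fewer than 10 pairs
are flagged as statistically weak but still reported.

## Cross-validation by identity

For target identity d with deviation δ (defaults: δ = 0 at d = 100, 0.5 at
99/97/95, 1.0 at 90), the reference is partitioned into test set S, top-hit
set T, training remainder W and discard pile Z; the training set is
A = T ∪ W. The contract — every test sequence's top training hit has raw
identity in [d − δ, d + δ] — is what `verify_split` re-checks by scanning
the identity matrix; the builder is a best-effort greedy with no optimality
claim:

1. compute all raw pairwise identities (once, shared across all d);
2. visit candidates q in seeded-shuffled order; q joins S when some
   eligible t has identity to q within [d − δ, d + δ] and no committed
   training member exceeds d + δ with q; the in-range t closest to d joins
   T (ties to the earlier record), and every record with identity > d + δ
   to q is barred from the training set;
3. leftovers go to W when their identity to every member of S is < d
   (the strict `< d` rule, not `< d − δ`), otherwise to Z.

Constraints are evaluated on raw identities; the reported split identity is
the integer rounding. d = 100 is special-cased: S = T = R, W = Z = ∅ (the
constraint is trivially satisfied by testing the reference against itself),
and classification at d = 100 does not self-mask. Different seeds shuffle
the candidate order and so explore different admissible splits.

Leave-one-out evaluation masks each query by id at classification time
(no training-set copies); a taxon with a single sequence is novel for its
own query, which caps Acc_RDP at the non-singleton fraction.

## Classifiers

**TOP / LTOP / KTOP** copy the full lineage of the top hit with confidence
1.0 at every rank — by construction they never under-classify and always
over-classify novel taxa when any hit exists.

**Naive Bayes bootstrap (RDP-style).** Words are unique 8-mers; the class
variable is the genus. Training records per-genus document frequencies
n_g(w) (sequences containing w) and the smoothed conditional probability
P(w|g) = (n_g(w) + 0.5)/(N_g + 1). A query's full-word score per genus is
Σ log P(w|g) over its V unique words; the predicted lineage is the
full-word winner's (each genus carries the lineage of its first training
record, truncated at genus). Each of 100 bootstraps draws ⌊V/8⌋ words with
replacement and re-scores; confidence at a rank is the fraction of
bootstrap winners agreeing with the predicted name there. Under
leave-one-out masking the query's own contribution (one document) is
subtracted at scoring time; a genus emptied by masking is removed from the
candidate set.

**Word-voting bootstrap (SINTAX-style).** Each of 100 bootstraps draws 32
words with replacement from the query's unique-word set and votes the
lineage of the database record sharing the most drawn words (ties to the
earliest record; a bootstrap sharing no word votes for nothing). The
predicted lineage is the full-word k-mer top hit's — making the
zero-cutoff prediction coincide with KTOP — and confidence at a rank is
the vote fraction agreeing with it.

Predictions are gapless rank prefixes truncated at the first rank whose
confidence falls below the cutoff; confidence exactly at the cutoff is
kept. Cutoffs are fractions with presets {0, 0.5, 0.8}. Per-query bootstrap
streams are derived by stable hashing of (seed, query id), so results are
independent of query order and bit-reproducible.

## Metrics

Counts and rates are defined in the README. Implementation decisions:

- "Known" is exact string equality (after whitespace trimming at parse
  time) between the test name and any training name at that rank; no
  synonym handling.
- A test sequence lacking a name at the evaluated rank is excluded from N
  at that rank, keeping counts well-defined on truncated annotations.
- The minimum-denominator rule (10) is applied per metric per (rank, d)
  row; unit tests may disable it (`min_denominator=1`). Averaging over
  identities skips unreported rows and records the number of contributing
  identities, since equal-weight averaging over reported rows is the only
  policy that never fabricates a value.
- Rates are percentages printed with one decimal; unreported cells render
  as `NA`.

## Synthetic reference generator

The generator emulates the identity–rank structure of real marker-gene
references. A taxonomy tree is grown with per-rank child counts (fixed or
uniform ranges) and a root sequence is evolved down the tree. The per-rank
divergence parameter div(r) is the expected substitution fraction from a
rank-r node down to a leaf, so two leaves whose lowest common rank is r are
separated by ≈ 2·div(r) and their expected identity is
≈ 100·(1 − 2·div(r)) (before back-mutations, which are not corrected for;
substitutions are uniform over the three alternative bases).

Default conditions, chosen to cover the benchmark's identity range with
both within- and cross-taxon pairs at a size that keeps a full five-identity
sweep within minutes on one CPU (~200–260 records of 300 nt):

| parameter | default | rationale |
|---|---|---|
| branching (phylum…species) | 2, 2, 2, 3, 1–4, 1–3 | ~50–60 genera incl. singletons |
| sequences per species | 1–3 | uneven sampling, singleton taxa |
| div(species…phylum) | 0.008, 0.025, 0.08, 0.12, 0.18, 0.25 | bands at ≈98/95/84/76/64/50% |
| top divergence | 0.30 | cross-phylum separation |
| rate jitter | ±30% per edge | lineage rate variation; blurs bands into a continuum |
| shallow genus edges | 20% of genus edges × 0.2 | near-identical sister genera |
| indels | off | alignment identity then tracks substitution distance |

The rate jitter and shallow sister genera are what make every integer
identity in 88–100% populated (roughly 25–80 pairs each at default size),
so that admissible test/training pairs exist at all five target identities.
Within-genus identities exceed 91%, so at d = 90 the builder's exclusion
rule forces every genus-mate of a test sequence out of the training set and
essentially all d = 90 test genera are novel; at 95–99% test genera are
almost all known. Novelty at high identity would require single-record
genera whose nearest neighbor falls exactly in the target band, which is
rare at this scale — over-classification is therefore typically reportable
only at d = 90 (its rate is 100% for top-hit methods wherever it is
reportable at all).

What the generator does **not** emulate: realistic substitution processes
(GTR, rate heterogeneity across sites), indel structure of real rRNA/ITS,
chimeras, sequencing error, and real databases' extreme genus-size skew
(thousands of sequences for a few genera). Passing tests on synthetic
references therefore validate the benchmark machinery — split contracts,
metric algebra, classifier mechanics, estimator identities — not the
absolute accuracy values any method would achieve on real references.

Query simulation mutates seeded copies of reference records toward a target
identity and verifies by realignment, resampling with a feedback-adjusted
rate until within ±1%; it errors out after 30 attempts.

## Determinism

Every source of randomness (tree growth, subsampling, split shuffling,
bootstraps, query mutation) flows from one top-level seed through stable
SHA-256-derived sub-seeds keyed by stage and item id, so identical
configurations reproduce byte-identical outputs regardless of evaluation
order.

## Known limitations

- The greedy split builder makes no attempt to maximize |S| optimally; test
  sets at narrow bands can be small, and a reference with no pairs in a
  band yields an empty test set (reported with a warning, excluded from
  averages).
- Local-mode identity is score-ranked but its identity values are over the
  local alignment only; they are not comparable with global identities and
  are not used in the statistics modules.
- Amplicon extraction takes the leftmost admissible forward-primer site and
  the leftmost reverse site after it; multi-site amplicons are not
  enumerated. Mismatch tolerance and strand policy are package choices, as
  primer-trimming conventions vary between pipelines.
- LCR statistics assume internally consistent lineage annotations; if two
  lineages agree at a rank but disagree above it, the lowest agreeing rank
  is still reported.
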