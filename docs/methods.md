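# Methods

## The crawl

The aligner treats a k-mer enrichment table as a graph whose edges are the
two relations a binding-site window respects: single-base substitution
(same register) and 1–2 bp overlap (register shifted by ∓1 or ∓2). The
crawl is a greedy traversal of this graph in strictly descending metric
order: the global maximum seeds the origin, and each round the
highest-metric aligned-but-unexpanded k-mer recruits its unaligned
neighbours. Three properties follow by construction and are enforced by
tests: the seed always sits at shift 0; a shift, once assigned, is never
revised; and each round retires exactly one reference, so the crawl
terminates after at most n rounds. K-mers not reachable from the seed
(disconnected from the enriched cloud) are reported separately rather than
forced into the alignment.

Determinism where the procedure is otherwise underspecified:

* metric ties (for the seed and for reference selection) break
  lexicographically by sequence;
* within a round, substitution neighbours are recruited before overlap
  neighbours, and overlaps in the order −1, +1, −2, +2 — same-register
  evidence is the strongest, smaller displacements beat larger ones, and
  5′ precedes 3′;
* a candidate matching several overlap offsets (possible for periodic
  sequences) is taken at the first offset in that order.

Reverse-complement handling is off by default — each input row is an
independent species, which keeps behaviour provable against hand-worked
examples. An optional mode collapses each k-mer with its reverse complement
onto the lexicographically smaller strand before crawling (metrics of an
observed pair must agree exactly), recording per-input orientations.

## PWM construction and PWM-based alignment

The alignment summary PWM weights each k-mer's base observations by its
metric (intended input: linear relative enrichment, which approximates
relative affinity; log enrichments must be exponentiated first, and
negative weights are rejected with that advice). Rows beyond ±`max_abs_shift`
(default 5, matched to 10-mer practice) are excluded; each matrix position
is normalized over the sequences actually covering it, so gaps contribute
nothing. Positions covered by no sequence fall back to the background
distribution with a warning. The resulting PWM has width
`2·max_abs_shift + k` and carries an `anchor` marking the shift-0 column,
so PWM-based shifts and crawl shifts share an origin.

PWM-based k-mer alignment pads any matrix with neutral (background)
columns — which score exactly 0 in log-odds — and slides each k-mer over
every placement, assigning the best-scoring offset. Probabilities are
floored at 1e−4 per cell so a zero-probability base scores ≈ −13.3 bits
instead of −∞; score ties resolve to the smaller |shift|, 5′ first (a
uniform matrix therefore maps everything to 0). Padding beyond the
internally applied k−1 columns never changes an assignment, a property the
tests fuzz.

Because independent aligners anchor their origins arbitrarily, the shift
agreement statistic first reconciles origins: it applies the single global
offset maximizing the number of matches (the mode of the per-k-mer shift
differences) before counting. Without this step the statistic would measure
origin conventions, not registration.

## Shape features

Minor groove width (Å) and electrostatic potential (kT/e) are looked up per
position from the pentamer centred on it; the two positions at each end of
a k-mer lack full context and are dropped rather than imputed, giving k−4
values per feature. Tables are validated for completeness (all 1,024
pentamers), finiteness and reverse-complement symmetry (within 0.01, the
typical precision of published tables). No literature table ships with the
package; `synthetic_shape_table()` provides a deterministic, RC-symmetric
synthetic stand-in spanning physically plausible ranges (MGW 2.85–6.20 Å,
EP −12 to −2 kT/e), sufficient for testing the machinery. Conclusions about
real shape readout require a real table, supplied as a TSV.

## Evaluation harness

"Significantly enriched" k-mers are those with metric Z-score > 2 (sample
standard deviation, n−1 — pinned by test since both conventions are
defensible). Features over the aligned window: 4 one-hot columns per window
position (all-zero where a k-mer does not reach) and one column per shape
feature per interior window position, column-mean imputed where undefined
so that rows with different shifts remain comparable. The response is log
enrichment.

The regression is an elastic net fit under 5-fold cross-validation: rows
are shuffled once by a seeded RNG and split contiguously; per fold,
predictors are standardized on the training split and the mixing ratio
(grid 0.1 / 0.5 / 0.9) and penalty strength (automatic 20-value path) are
chosen by inner 3-fold CV on the training split only. Held-out R² is
1 − SS_res/SS_tot with SS_tot centred on the held-out fold's own mean; the
median over folds is the headline number. Identical seeds give bit-identical
results on one platform.

## The synthetic-data generator

The generator emulates the situation the aligner exists for: a TF with an
additive per-position binding-energy matrix over a core of width w,
observed through k-mers windowing the site at every offset. A k-mer's log
enrichment is the score of its best placement (energies summed over the
core positions covered; flanking positions contribute 0, as unbiased flank
DNA carries no specificity) plus Gaussian noise; placement ties resolve to
the smaller |offset|. Unenriched library content is modelled as uniform
random k-mers at score 0 plus noise. The true offset — the argmax
placement — is recorded for every signal k-mer whose best placement covers
at least min(w, k) − 2 bp of the core, and is the ground truth for
recovery tests.

Signal k-mers are generated as every consensus-core window over **all**
flank base combinations, plus single-base core mutants in sampled flank
contexts (8 per mutation by default). The exhaustive flank enumeration is
what makes the signal cloud dense enough to be substitution- and
overlap-connected — the property that makes real, deeply sequenced k-mer
tables alignable in the first place. What the generator does *not* emulate:
read-level sampling noise, PCR bias, positional epistasis (energies are
strictly additive), and double-strandedness (one strand only). Passing
recovery tests therefore demonstrates algorithmic correctness under the
additive model, not robustness to those real-data effects.

Default study conditions, chosen once: core widths 7–12 with k = 10
(k-mers window typical eukaryotic TF sites), consensus energies U(1.0, 2.0)
per position against U(0, 0.5) for other bases (a best-vs-next gap of
roughly one unit, i.e. e-fold-per-mutation specificity), 2,000 background
k-mers, and noise expressed as a fraction of the consensus score.

Two experiments use different noise regimes, deliberately:

* **Shift recovery** stresses the aligner at noise = 5% of the consensus
  score (≈ half a typical single-mutation effect): ≥ 90% of ground-truth
  offsets are recovered, origin-reconciled, in ≥ 9 of 10 seeds. The
  occasional failing seed is informative: a period-2 self-similar consensus
  (e.g. `CGTGTGG`) makes ±2-register assignments genuinely ambiguous for
  k-mers that cover the core only partially — a limitation any
  rank-dependent aligner shares for periodic motifs.
* **The regression comparison** (aligned window vs. forcing every k-mer to
  shift 0) uses noise = 1% of the consensus score and background at 4× the
  signal count. Both choices follow from what the experiment measures: the
  Z > 2 filter is only meaningful when unenriched k-mers dominate the
  table, and after filtering the retained response range is narrow, so at
  5% noise the noise floor alone caps attainable R² near 0.2–0.4
  (R² ≤ 1 − σ²/var(y)) for *any* feature set — masking the quantity of
  interest. At 1% noise, k-mer-level metrics are reproducible relative to
  mutation effects (the regime deep-sequenced enrichment tables are prized
  for), aligned-window models reach R² ≈ 0.87–0.97, and the aligned-minus-
  unaligned margin exceeds 0.1 in 10 of 10 seeds (the test requires 8).

## Numerical and degenerate-input choices

* Alignment output writes metrics via shortest-exact-round-trip formatting,
  so file round-trips are bit-exact; shifts are redundantly encoded as a
  column and as leading-gap counts, and the reader cross-validates the two.
* PWM files use the minimal MEME letter-probability format; positions
  deviating from sum 1 by > 1e−3 are fatal, smaller deviations are
  renormalized. The in-memory anchor is not persisted (the format has no
  slot for it); cross-file comparisons rely on origin reconciliation.
* Duplicate input k-mers are an error, not aggregated — an aggregation
  policy (sum vs. max) would be a silent scientific choice.
* A table with no mutual neighbours yields a single-k-mer alignment, with
  everything else reported unaligned; a constant metric column makes the
  Z-filter fatal (sd = 0).
* Problem sizes in the test suite (k-mer universes ≤ 1,024 for oracle
  equivalence, ~2,000–16,000-row synthetic tables, 10 generator seeds per
  claim) were chosen as the smallest scales at which each property is
  meaningfully exercised.

## Known limitations

* Strand handling is minimal: the default treats orientations as distinct
  species, and the merge mode requires exactly-equal pair metrics.
* The crawl offers no confidence measure per assignment; a k-mer recruited
  late through a long chain carries the same weight as a direct neighbour
  of the seed.
* Periodic motifs can produce systematic ±period register errors (see
  above).
* The evaluation harness assumes metrics are on the log scale for both the
  Z-filter and the regression response; it does not verify this.
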