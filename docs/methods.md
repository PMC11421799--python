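# Methods

## Problem and model

Pseudo-Seq detects pseudouridine (Ψ) through CMC-dependent reverse-
transcription stops: a CMC adduct on Ψ blocks the polymerase one nucleotide
downstream (3′, in transcript orientation) of the modified uridine, so the
truncated cDNA's 5′ end piles up at U+1.  Mock-treated libraries share all
CMC-independent stop sources — strong secondary structure, other
modifications, transcript ends — so CMC dependence separates Ψ from those
artifacts.  `psistop` models this comparison as a per-uridine decision
problem on raw 5′-end count tracks.

### The winsorized Z-score

For a uridine *u* the score is computed at the stop position *p* = *u*+1
(strand-aware; site reporting subtracts the offset again):

* **Window.**  A contiguous 101-position genomic interval containing *p*,
  giving 100 background positions once the target is excluded.  The window
  is centered when possible and shifted by the smallest displacement that
  satisfies the transcript-end constraints below; ties break toward the
  transcript 3′ direction.
* **Coverage.**  The window (background plus target) must carry at least
  `coverage_min` = 100 reads; otherwise the site is not scored.
* **Winsorization.**  Background values above their 95th percentile are set
  to that percentile.  The target is never altered, and the target is also
  excluded from the background mean/sd — including it would deflate the very
  peaks being sought.  The percentile interpolates linearly between order
  statistics by default (`method="linear"`); note that full re-winsorization
  is then not exactly idempotent, because capping lowers the re-computed
  interpolated percentile (e.g. `[0, 1]` caps at 0.95, then at 0.9025).
  With `method="lower"` the cap is an order statistic and the operation is
  exactly idempotent; both are exposed, linear is the default for its
  familiarity as the common percentile definition.
* **Score.**  `z = (count[p] − mean(w)) / sd(w)` with the population
  (divide-by-n) standard deviation over the winsorized background `w`.  A
  zero-dispersion background leaves `z` undefined and the site uncallable —
  no epsilon floor, since that would manufacture arbitrarily large scores.

Z is computed on raw counts.  Within a single window a transcript-level
normalization is a positive scale factor, and the statistic is scale
invariant, so raw counts give the same Z while avoiding isoform-assignment
ambiguity.

### Transcript-end-aware window shifting

Read coverage collapses or spikes near transcript boundaries, which would
poison a background estimate.  Annotated (Rend-Seq-derived) ends constrain
window placement; classifying each end as upstream or downstream of the
target in transcript orientation:

| end | side | rule |
|---|---|---|
| 5′ end | upstream | window 5′ boundary ≥ end + 40 nt |
| 3′ end | upstream | window 5′ boundary ≥ end + 5 nt |
| 3′ end | downstream | window 3′ boundary ≤ end − 25 nt |
| 5′ end | downstream | window 3′ boundary ≤ end − 5 nt |

The feasible placements form an interval of start positions; the start
nearest the centered position is chosen, and `shifted` records whether the
centered window violated any rule.  If the interval is empty (e.g. a 5′ end
closer than ~40 nt upstream of the target), the window is infeasible and
the site reported as insufficiently covered.

### Decision rules

* **Calling:** Z(CMC) ≥ `z_min` (15) and Z(CMC) ≥ `mock_fold` (3) ×
  Z(mock); a mock Z ≤ 0 satisfies the ratio trivially.  Uncovered or
  degenerate windows in either library leave the site `insufficient`.
* **Enzyme assignment:** for each knockout library, the peak is *absent*
  when the knockout window is covered, Z(knockout) < `ko_z_max` (10), and
  Z(CMC) ≥ `ko_fold` (4) × Z(knockout); the three criteria are conjunctive.
  Exactly one absence with every other knockout present ⇒ `assigned`;
  two or more absences ⇒ `ambiguous` (no secondary ranking — redundant
  modification and technical dropouts are indistinguishable here); zero
  absences, or one absence alongside a knockout without coverage, ⇒
  `unassigned`.  The last case is a deliberate conservative choice: an
  uncovered knockout could conceal a redundant second enzyme, so coverage
  loss anywhere withholds assignment but never re-assigns a site.
  The knockout coverage threshold reuses `coverage_min`, as no separate
  value is established for knockout libraries.

## Synthetic data generator

The generator emulates the statistical structure of RT-stop libraries, not
their chemistry.  Per library of configured depth *D* (held exactly —
read counts are multinomial over transcripts, proportional to a log-normal
expression distribution):

1. a read picks a 3′ start uniformly on its transcript (fragmentation),
2. walking 5′-ward, it truncates at a planted site's U+1 with probability
   `stop_efficiency × stoichiometry` (CMC libraries only, and only when the
   site's enzyme is not the simulated knockout),
3. elsewhere it truncates at an independent per-position background rate
   (default 10⁻³), and
4. otherwise it runs through to the transcript 5′ end, producing the
   characteristic end pileup; `end_pileup_weight` (default 2%) adds extra
   mass there.

Planted sites carry a UURAA motif with the site U at motif position 1, so
sequence-context machinery can be exercised on the same truth set.  Defaults
(20 transcripts × 1 kb, σ = 1 log-normal expression, 400k reads/library)
describe a small bacterial-like study in which default thresholds operate
comfortably.  Deliberately not modeled: insert-size selection, sequencing
error, UMI artifacts, and RT processivity decay — the caller consumes
truncation-position statistics only, so these would add realism without
changing what the tests can demonstrate.  Mock libraries carry no residual
Ψ signal by default (read-through noise at Ψ is not quantified in the
source data; a nonzero residual can be configured via `stop_efficiency`).

The BID-seq simulator draws per-position deletion counts binomially: at a
modified site the deletion probability is `deletion_rate_at_full_mod`
(default 0.9 — the calibration constant for 100% Ψ is not established, so it
is an explicit parameter) times stoichiometry, plus a 2×10⁻³ error rate
elsewhere; 1–2 nt deletion events are anchored at their 5′-most position.

What passing tests on this generator do show: the statistic, window logic,
decision rules, subsampling and aggregation machinery are correct against
independent oracles and recover planted truth with high specificity.  What
they do not show: robustness to real-library artifacts such as
structure-induced stop hotspots shared between CMC and mock, coverage
heteroskedasticity, or mapping biases.

## Saturation analysis

Libraries are pooled by summing counts; subsampling draws exactly *d* reads
without replacement (multivariate hypergeometric over per-position counts),
one draw per depth per seed.  The mock pool is subsampled to the same
fraction of its own reads so CMC/mock ratios remain comparable.  Cumulative-
unique counts accumulate distinct (position, strand) calls across the depth
ladder; no asymptote is fitted.

## Sequence and structure context

Motif classes partition RNA 5-mers whose first base is the site U:
`UURAA` (R ∈ {A,G}), `UURBA` (B ∈ {C,G,U}), `UUYAA` (Y ∈ {C,U}), else
`other`; the classes are mutually exclusive because R/Y and A/B are
disjoint.  Background-site selection keeps all UURAA first-U positions in
genes with RPKM ≥ 105, removing candidates within 100 nt (same strand) of a
called site; the set is exhaustive unless `n_max` requests a seeded uniform
subsample.

Structure context extracts the 100-nt window around each site (101
positions, site-centered), attaches DMS reactivities at A/C positions
(placeholder −999 elsewhere, the convention the downstream folding engine
expects), and folds through a pluggable engine contract: sequence +
optional constraint table → symmetric base-pair probability matrix.  The
bundled adapters are a deterministic stub (tests, fixtures) and an external
RNAfold driver (partition-function mode, 37 °C, SHAPE-style soft
constraints with the Z-score-based reactivity conversion).  Per-position
pairing probability is the matrix column sum, clipped to [0, 1]; a column
sum exceeding 1 by more than 0.05 warns of an inconsistent matrix.
Profiles aggregate across sites by offset relative to the site (−50…+50),
retaining raw values with medians/quartiles derived on demand.

## Numerical and reproducibility choices

* Internal coordinates are 0-based half-open; wiggle I/O converts to
  1-based at the boundary, bedGraph/BED stay 0-based half-open.
* On the minus strand "downstream" means decreasing genomic coordinate;
  all offset logic goes through a single orientation helper, and a
  strand-reflection test (reverse-complement the genome, mirror tracks and
  annotations) asserts Z-scores are invariant.
* All randomness flows from explicit seeds through `numpy.random.Generator`;
  simulated tracks and subsamples are bit-reproducible, and the pipeline
  driver writes a manifest (versions, seeds, thresholds) sufficient to
  reproduce a run.
* Overlapping gene spans resolve a position to the span whose midpoint is
  nearest (ties by gene id) — isoform resolution is not otherwise defined
  for bacterial operons.
* Test and acceptance problem sizes (20 transcripts × 1 kb, 0.4–1.5 M reads,
  8-depth ladders) were chosen as the smallest sizes at which the study
  conditions — site windows above 2000 reads, a 100-fold expression range
  reaching saturation — hold comfortably.

## Known limitations

* The caller uses fixed thresholds, as published; no FDR control is
  attempted, so threshold choices transfer to new datasets only with
  similar depth and background behavior.
* Closely spaced modifications mask each other (the more 3′ stop consumes
  read-through), a physics-level limitation of RT-stop methods that the
  simulator reproduces only implicitly via truncation competition.
* BID-seq stoichiometry estimates are relative to an unknown calibration
  constant; the package recovers proportionality, not absolute occupancy.
* The wiggle reader supports `variableStep` (the format emitted here);
  `fixedStep` tracks are rejected explicitly.
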