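# Methods

This note documents the models, conventions and numerical choices behind
eoskit. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthesis error channel (`eoskit.simulate`)

The simulator emulates cycle-by-cycle solid-phase enzymatic synthesis as
a statistical channel. Each of the `r` cycles attempts one controlled
incorporation with three mutually exclusive outcomes:

- **deletion**, probability `p_del`: no base incorporated;
- **substitution**, unconditional probability `p_sub` (drawn with
  conditional probability `p_sub / (1 − p_del)` given no deletion): one
  wrong base from `sub_base_dist` (uniform by default);
- **correct incorporation** otherwise.

Independently of the outcome, with probability `p_ins` one uncontrolled
extra base (from `ins_base_dist`, uniform by default) is appended after
the cycle. This event algebra keeps the per-cycle expectations analytic:
the classification-rate estimator `N_error / (reads × r)` is unbiased for
each per-cycle probability, which is what the recovery tests exercise.

Reads are assembled as `anchor + payload + polyA tail` with the 24-nt
initiator context `AGTGCTACTAGGACGACTCGAATT` and a polyA tail of fixed
length 20 by default (configurable; a geometric law is available; a
minimum of 10 is enforced because extraction requires ten consecutive
adenines). An optional uniform per-base substitution rate emulates
sequencing noise on the finished read. Ground truth — one event token per
cycle — is written into each read header, and `replay_events` reproduces
the payload from it, so classifier accuracy can be scored exactly.

Default simulation conditions used in the tests and acceptance script are
the study's: 20,000 reads for rate-recovery runs; per-cycle deletion
0.0305 for the 9-mer `GCTGCTGCT` and 0.0045 for the `CCC` homopolymer
(the measured TDN-scaffold deletion rates); 10,000 reads per repetition
at per-cycle deletion 0.0318 for the 60-cycle storage runs, where 0.0318
is the complement of the observed 96.82% stepwise yield.

What the channel does **not** model: enzyme kinetics, surface crowding,
scaffold geometry, PCR amplification bias, quality-score structure,
paired-end artifacts, or position-dependent error rates. Passing recovery
tests therefore show that the analysis pipeline correctly measures the
channel it defines, not that real NGS data are free of these effects.

## Extraction and classification (`eoskit.read_processing`)

Payloads are extracted by the leftmost, non-greedy pattern
`anchor (.*?) A{10}`; anchors must match exactly (no mismatches
tolerated). If the forward strand has no match, the reverse complement is
searched. A zero-length payload is a valid observation (`r` deletions).
A read whose payload itself ends in ten or more adenines would be
truncated by the non-greedy tail match; none of the bundled targets can
produce one. Payloads longer than 20× the target length are dropped as
pathological matches and counted; everything shorter is classified
(insertion-dominated alignments included).

Alignment is global Needleman–Wunsch under unit edit costs (match 0,
substitution 1, gap 1). Under unit costs the three class totals are fully
determined by the edit distance and the length difference, so co-optimal
alignments differ only in where they place events. The traceback is
deterministic: diagonal steps are preferred over gaps, which pushes
deletions leftmost within homopolymer runs; per-position tallies are
therefore reproducible. The alignment cost is cross-checked in the tests
against an independent implementation (edlib) exhaustively on all
two-letter-alphabet pairs up to length 8, and edlib itself is validated
against a recursive enumeration on tiny pairs.

Metrics follow the standard definitions: per-class error rate
`N_class / (S_all × r)`, correct proportion `N_right / (S_all × r)`,
full-length yield `Y_total = S_right / S_all`, stepwise yield
`Y_total^(1/r)`. `S_all` is defined as the number of *extracted* reads
(reads that never match the pattern are counted and logged but excluded
from denominators). Identical payload strings share one alignment
(weighted by multiplicity), which makes 20,000-read runs fast.

`per_position_profile` reports, per target position, the frequencies of
A/C/G/T/deleted from the alignment outcomes. In the conditional mode
(the heatmap convention) a read contributes at position k only if all its
outcomes before k were correct matches; its first error is tallied and
the read then leaves the profile, so the deleted fraction at each
position estimates the per-cycle deletion probability. In the
unconditional mode all positions are tallied except trailing gaps beyond
a read's last aligned base, so short reads do not inflate deletion
frequencies at positions they never reached. The denominator rule for
reads shorter than the profile length is this package's definition.

## Consensus decoding (`eoskit.consensus`)

Two majority-vote procedures recover the dominant synthesized sequence:

- `global_majority`: the modal full payload string (the default notion of
  "dominant sequence"), with the distinct-payload frequency table.
- `conditional_consensus`: iterate positions 1..L; at position k, tally
  the base among reads that survived the screen through k−1 and are at
  least k long; call the plurality base; survivors at k are the reads
  matching the called base. The screen is referenced to the evolving
  consensus by default — usable without knowing the target — or to a
  supplied reference for target-referenced error profiling. Reads shorter
  than k leave the tally from position k onward but keep their earlier
  contributions. The survivor trajectory is non-increasing by
  construction, and an emptied survivor set raises an error naming the
  position reached.

Ties are broken lexicographically (A<C<G<T) and flagged, never
randomized. Decoding delegates to the storage codec and inherits its
strictness: a consensus containing anything but A/C/G/T is rejected.

## Storage codec (`eoskit.storage_codec`)

Two bits per base, MSB-first within bytes, left-to-right pairing:
00→G, 01→T, 10→C, 11→A by default; any bijection over the four bases is
accepted. This bit order is the unique convention under which the bundled
60-nt fragment decodes to a meaningful 15-byte message (three CJK
characters as big-endian 16-bit code units, then nine ASCII letters); the
demo profile `demo_message()` pins that byte layout. The codec is
deliberately minimal: no error correction, no addressing, no GC or
homopolymer constraints — reliability comes from population-level
consensus, not the code.

## Kinetics and assay calculations (`eoskit.kinetics`)

- **Standard curve**: ordinary least squares of luminescence on PPi
  concentration; r² reported; inversion maps intensity to concentration.
  Spike recovery is `100 × measured / spiked`.
- **Initial rate**: the slope of the longest time-course prefix (≥ 3
  points) whose linear fit reaches r² ≥ 0.999, falling back to the first
  three points. The strict threshold is this package's definition of the
  "initial linear phase": at 0.99 the accepted prefix of a saturating
  course already carries enough curvature to bias the rate low by ~18%,
  while at 0.999 the bias stays under 10% for time constants down to
  ~2.5× the sampling window. The threshold is an argument for callers who
  prefer the looser rule.
- **Michaelis–Menten fitting**: nonlinear least squares on the hyperbola,
  deterministically initialized at `Vmax = max(V)`, `Km = median([S])`,
  with optional per-point rate uncertainties (for multiplicative
  luminescence noise, weights proportional to the rate are the correct
  choice); or the Lineweaver–Burk double-reciprocal regression (slope
  `Km/Vmax`, intercept `1/Vmax`), which requires strictly positive rates
  and a positive intercept. On noiseless data both methods agree with the
  generating parameters to machine precision.
- **kcat** is `Vmax / [E]` and requires a molar enzyme concentration from
  the caller — a mass concentration alone does not determine it, so no
  default conversion is hard-coded. Km and the parameter gains are
  invariant to whether rates are in luminescence units or µM/s.
- **Parameter gains**: for Km (lower is better) `100×(ss−tdn)/ss`; for
  kcat and catalytic efficiency (higher is better) `100×(tdn−ss)/ss`.
  Gains are computed from whatever values are supplied; note that gains
  recomputed from *rounded* Km and kcat need not equal gains computed
  from unrounded fits — the efficiency gains are therefore checked from
  the printed efficiency values themselves, not from the Km/kcat quotient.
- **FRET efficiency**: `E = 1 − I_DA/I_D`, donor intensity with and
  without acceptor.

## Statistical checks and problem sizes

Recovery assertions use exact binomial standard errors: a per-cycle rate
p estimated from n reads of an r-cycle target has standard error
`sqrt(p(1−p)/(n·r))`, and simulation-based tests assert agreement within
three standard errors at n = 20,000. The end-to-end storage check runs 20
seeded repetitions of 10,000 reads × 60 cycles and requires message
recovery in ≥ 99% of them; at these error rates the per-position majority
margins are so large that failures are not expected at all. The noisy
Michaelis–Menten recovery check generates triplicate rates (the assay's
replication level) at 5% relative noise; because the per-seed Km standard
error of the weighted estimator on this design is about 5%, recovery
within 15% is asserted for the estimate aggregated across the 20 seeded
repetitions rather than for each seed, a bound no unbiased per-seed
estimator could guarantee.

## Pipeline (`eoskit.pipeline`, `eoskit.cli`)

`run_pipeline` executes simulate → extract → analyze → consensus → decode
with a flat configuration, writes per-stage artifacts (reads, payload
table, metrics, consensus with count matrix, decoded bytes) plus a JSON
summary, stage timings and the resolved configuration for provenance. A
seed is mandatory whenever simulation is enabled; identical configurations
produce identical outputs. Stage errors abort the run naming the stage.

## Known limitations

- The error channel is position-homogeneous; real EOS error rates vary
  with sequence context (homopolymers, secondary structure) in ways the
  simulator only captures through user-supplied per-run parameters.
- Extraction tolerates no anchor mismatches, so sequencing errors inside
  the anchor or tail lose reads rather than payload bases.
- The conditional consensus assumes the dominant base at each position is
  correct; it has no mechanism to recover from a position where errors
  outnumber correct bases (e.g., per-cycle error rates near 50%).
- Lineweaver–Burk fitting inherits the classical reciprocal-space noise
  amplification; the nonlinear mode is preferred for noisy data.
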