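# Methods

## The model

For a focal amino-acid type (or an ordered substitution type X→Y) the
unit of analysis is the flanking offset: the position at signed distance
i ∈ {−W..−1, +1..+W} from a focal occurrence, negative on the N-terminal
side. At each offset the observed residue distribution P is compared to
a background Q by relative entropy in bits,

    D(i) = Σₐ P(a) log₂(P(a)/Q(a)),

with per-residue components d(a) = P(a) log₂(P(a)/Q(a)) and the
convention d(a) = 0 when P(a) = 0. D is nonnegative and zero iff P = Q
(Gibbs' inequality); a large D(i) means the residues at offset i deviate
from what the background predicts, i.e. a positional preference.

The logarithm base is 2 throughout. Base only rescales every entropy,
threshold and SD by the same constant, so significance calls are
base-invariant; bits were chosen for interpretability.

### Context extraction

A focal occurrence contributes its N-side flank iff at least W residues
precede it and its C-side flank iff at least W follow — the two sides
are independent, which is why the N and C data sizes generally differ
and why the two sides carry separate null thresholds. Contexts are
stored verbatim (not just counted) so the shuffle null and the bootstrap
resample exactly the material that was counted.

The unknown symbol `X` (to which all non-canonical letters are mapped on
input) occupies window slots — a window containing `X` is still
"complete", preserving coordinates against the structure track — but is
excluded from every count and from P's normalizer, so P sums to 1 over
exactly the 20 canonical residues. The alternative of dropping any
context containing an ambiguous residue would discard data
asymmetrically near sequencing artifacts; it is not the default.

Structure-stratified extraction (window 6 rather than 20, because
secondary-structure segments are short) additionally requires the focal
residue *and* its flank to lie inside one maximal segment of the
requested H/E/C class. Whether flanks may cross segment boundaries is
genuinely open; confinement is the default because it is the reading
under which segment length limits the usable window, and
`confine_to_segment=False` provides the other convention.

### Backgrounds

* Global mode: canonical-residue frequencies of the dataset in scope —
  all records, the residues of one structure class, or the records of
  one group label. Used for neighbor-preference profiles.
* Per-offset mode: for substitution profiles, Q at offset k is the
  residue distribution at offset k around *all* occurrences of the
  pre-substituted residue X in the reference dataset. This corrects for
  X's own neighbor preferences: if X→Y events sample X's occurrences
  without regard to context, every D(i) tends to 0 regardless of how
  structured X's neighborhoods are.

A positive observed count over a zero background frequency is a hard
error by default; an optional pseudocount (α = 0.5 added to every
background count before normalizing) is available behind a flag, because
silently regularizing changes the entropy values.

Substitution contexts are read from the ancestral sequence, in ungapped
ancestral coordinates: the background correction is keyed to the
pre-substituted residue, and ancestral context is the only pairing
consistent with that. Columns adjacent to a substitution that themselves
carry substitutions are not excluded from contexts (no exclusion rule is
obviously right; excluding would bias against clustered change).

### Significance

Null hypothesis: no positional structure within the flanks. Each stored
flanking string has its W positions permuted independently (per-string
composition is preserved — the natural null for positional preference);
all W per-offset entropies are recomputed against the same background;
500 repeats give a pool of 500·W values per side. The threshold is the
k-th highest pool value with k = max(1, round(α · pool size)): at
α = 0.001 the 10th of 10,000 for W = 20 and the 3rd of 3,000 for W = 6.
Ties count separately; an alternative single-permutation-per-repeat
granularity is implemented (`granularity="global"`) but per-string is
the default. An offset is significant iff its observed D exceeds its
side's threshold.

Bootstrap SDs: contexts are resampled with replacement per side at the
original n, 100 replicates, SD with the n−1 denominator; a side with a
single context reports a missing SD.

One seed parameter drives both procedures through independent
sub-streams (`numpy` `SeedSequence.spawn`), so shuffle and bootstrap
results are individually reproducible.

Note that the shuffled pool compares flank-averaged compositions to the
background, so when the observed flanks are strongly position-structured
the null pool is inflated relative to pure sampling noise and the
threshold is conservative. This is intended: it is what makes the
substitution negative control robust even when the ancestral residue has
strong planted neighbor preferences.

### Outliers

At each offset the 20 components d(a) are screened with the Tukey
boxplot rule: above Q3 + 1.5·IQR flags "high", below Q1 − 1.5·IQR flags
"low". Quartiles use linear interpolation between order statistics
(numpy's default, "type 7"); the convention is exposed as configuration
since plotting software differs.

### Calling context dependence

A substitution type is retained when max(n_N, n_C) ≥ 100 events
(`min_events_per_side`; below that the multinomial noise floor
19/(2 ln 2 · n) ≈ 0.14 bits approaches realistic signal sizes) and
called context dependent when at least one offset is significant. The
per-type count of significant offsets is reported alongside so stricter
operational definitions can be applied by the user.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
with machine-readable ground truth, at desk scale. Defaults: sequence
lengths uniform in [150, 400] (so full 20-site windows exist), uniform
composition, fixed seeds.

* `gen_iid` — no positional structure; calibration null. On this input
  the per-offset exceedance of the 0.001 threshold is itself ≈ 0.001.
* `gen_collagen_mix` — a fraction of records (default experiments use
  0.3) carry a (G-X-Y)₃₀ block at a random position, X/Y drawn from the
  composition with G removed; plants the 3n-periodic glycine signal.
* `gen_self_clustering` — homopolymer runs (Poisson rate per residue,
  fixed run length) overwritten into i.i.d. background; emulates
  slippage-driven self-preference.
* `gen_helix_pairing` — all-H chains built left to right; at positions
  whose residue d sites upstream is X, the sampling distribution has Y's
  probability multiplied by the enrichment. The renormalization holds
  P(X) itself fixed: naively renormalizing would deplete X at +d and
  thereby plant a spurious X-deficit signal at −d of the X profile, so
  keeping X i.i.d. is what makes "Y at +d" the *only* planted signal.
* `gen_context_substitutions` — per-site independent substitutions on
  given ancestors, gapless alignments; one rule multiplies the
  from→to rate when a given neighbor residue is present at a given
  offset; other residues substitute uniformly at the base rate. The
  exact event list is returned and equals what `infer_events` recovers.

What the generators do **not** emulate: real proteome composition
(uniform by default), domain architecture, indels (pairs are gapless;
gap handling is exercised by hand-written alignments), correlated
substitutions along a phylogeny, and codon-level mechanisms such as CpG
hypermutation (the planted neighbor rules emulate its protein-level
footprint phenomenologically). Passing the recovery experiments
therefore shows the *statistics* behave correctly — calibrated nulls,
unbiased correction, signal recovery — not that any particular
biological effect size will be significant in real data.

## Experiment sizes

The bundled experiments (tests and `scripts/acceptance.py`) use: 2,000 ×
200-residue i.i.d. sequences for threshold calibration; 1,500 sequences
at collagen fraction 0.3; 1,500 all-H chains with (E,K) enrichment 5 at
+4; ~6,000 context-independent S→P events on 4,000 self-clustering
ancestors for the negative control; and 3,000 × 300-residue ancestors at
base rate 0.02 with a 5× S→P rule at +1 for recovery. These sizes give
clear separation between planted signals and the 0.001 thresholds while
keeping a full run in minutes on one CPU.

## Numerical notes

- Entropy arithmetic is vectorized float64; agreement with a 50-digit
  term-by-term oracle is within 1e−10 on random tables.
- An offset whose canonical counts are all zero (possible only when
  every context carries the unknown symbol there) is an error, not a
  zero.
- Profile TSVs round-trip numeric fields at 12 significant digits
  (`%.12g`).
- `threshold_rank` uses banker's rounding via Python's `round`; at the
  documented pool sizes (10,000 and 3,000 at α = 0.001) the product is
  an exact integer and no tie arises.

## Known limitations

- The shuffle null conditions on per-flank composition only; it does not
  model between-record heterogeneity, so datasets mixing very different
  compositions can yield conservative thresholds.
- Per-offset backgrounds require every offset of a populated side to
  have at least one canonical count in the reference; sparse references
  need the pseudocount flag.
- The CLI profiles one dataset per invocation; cross-species or
  cross-branch comparisons are left to the caller.
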