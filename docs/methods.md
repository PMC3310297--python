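# Methods

This note records the definitions the package implements, the conventions
it had to fix where common usage is ambiguous, the defaults and why, and
what the synthetic controls do and do not establish.

## Sequences and alphabets

A sequence is an ordered tuple of tokens over a finite ordered alphabet.
Two alphabets are built in: the nucleotides in the order A, C, G, T, and
the 20 amino-acid letters in the order M, E, Q, D, R, T, N, H, V, G, L,
S, P, F, I, C, A, K, Y, W.  Alphabet order is a contract, not a
convenience: the unit-root encoding sends the `j`-th symbol to
`exp(2πi(j−1)/M)`, so reordering an alphabet relabels the roots.

Codon translation always reads frame 1 of the given strand and discards
the trailing partial codon; there is no ORF scanning, reverse-complement
or 6-frame logic.  Stop codons (TAA, TAG, TGA) are skipped by default;
with `stop_policy="symbol"` they are emitted as `*`, a token deliberately
outside the 20-letter alphabet so it can never be root-encoded — the
result must be filtered before encoding.  Translating a genome prefix of
`3k` nucleotides therefore yields `k` letters only when no stop falls in
the window; otherwise `k` minus the number of stops.

FASTA reading (via Biopython) uppercases and keeps tokens as-is;
validation is a separate, explicit step.  `policy="error"` names the
1-based position of the first foreign token; `policy="drop"` removes
ambiguity codes such as N and logs the count.  Dropping is the default in
the CLI because silently encoding an N would corrupt the signal, while
aborting on a single N in a megabase genome is rarely what one wants.

## Synthetic controls

The pseudorandom generator draws i.i.d. uniform symbols; the
pseudoperiodic generator draws one random block of the given period and
concatenates copies, trimming the length to a whole number of blocks.
Both are driven by `numpy.random.default_rng(seed)`.

A period of 1 is taken literally — a repeated 1-block, i.e. a constant
sequence.  The informal shorthand that "period 1 is the random case"
contradicts the construction itself; we follow the construction and say
so loudly in the docstring, since a constant sequence and a random one
sit at opposite ends of every index in this package.

`random_unit_complex` draws `(−1)^r i^s` with `r` uniform on {0, 1} and
`s` uniform on {0, 1, 2, 3}.  The exponent distribution is the minimal
choice that makes every term unit-modulus and the four values
{1, i, −1, −i} equally likely, matching the statistics of an encoded
uniform nucleotide stream.

These controls emulate composition only.  They have no codon structure,
no GC skew, no repeats, no strand asymmetry; passing the control-table
checks says the indices behave correctly on known inputs, not that real
genomes will score near any particular value.

## Walks and the two sign conventions

The constructive root assignment (A→1, C→i, G→−1, T→−i) implies
`Im(z_n) = c_n − t_n` for the walk.  A widely used alternative writes the
walk coordinates as `(a_n − g_n, t_n − c_n)`, which corresponds to
swapping the C and T roots.  The two conventions produce complex-conjugate
signals and identical |z|; both are supported via
`convention={"CT","TC"}` with `"CT"` (the constructive one) as default.
The count identities are cross-checked in tests against independently
accumulated prefix counts.

## Complexity indices

- **Randomness** `R = 1 − spread(frequencies)` over the first `n`
  symbols.  The spread is the population variance by default, with the
  population standard deviation as an option.  At `n = 10⁴` a uniform
  random sequence scores ≈ 0.9999 under variance and ≈ 0.996 under std;
  published organism values in the 0.7–0.98 range are reachable under
  neither, so this index is used comparatively, not as an absolute.
  Default window 10 000 symbols.
- **Complexity** `K` uses natural logarithm, evaluated exactly through
  log-gamma.  The uniform 4-letter maximum at `n = 100` is
  `ln(100!/(25!)⁴)/100 ≈ 1.3172`; an i.i.d. uniform sequence averages
  ≈ 1.303 over seeds.  Natural log is forced by those magnitudes: base-10
  or base-4 would cap the index at 0.57 / 0.95.  Default window 100.
- **Entropy** is normalized by `ln M` (alphabet cardinality), the only
  normalizer that puts `H` in [0, 1] for every alphabet including the
  1-letter edge case (where `H = 0` by convention); `0·ln 0 = 0`.
  Default window 100.
- **Box-counting dimension** of the dot plot: for each minor size `n` in
  `n_range` (default 2..10), `minors_per_size` (default 30) contiguous
  `n×n` minors are sampled uniformly at random (`None` = exhaustive);
  `p(n)` is the mean count of ones, and the estimate is the mean of
  `log p(n)/log n`.  Sizes with `p(n) = 0` are skipped with a warning
  rather than propagating −∞.  An alternative `paper_half` normalization
  divides the sum of terms by `2N` instead of the number of sizes; it is
  provided for comparability but its absolute values are much smaller
  (≈ 0.8 for a random plot at N = 100), and no published convention we
  are aware of pins the protocol down.  The all-ones matrix scores
  exactly 2 under the default; any binary matrix scores in [0, 2]
  whenever every sampled size has at least one dot.

### Known limitation: ranking random vs. periodic dot plots

Under any count-of-ones statistic the dimension estimate increases with
dot-plot density at every minor size.  A period-2 sequence's plot has
expected density `½·1 + ½·¼ = 0.625` (same-parity positions always
match), versus `Σ p_x² ≈ 0.25` for a uniform random sequence, so the
periodic plot out-scores the random one essentially always.  A published
comparison that places the random control slightly above the periodic
one (1.298 vs 1.285) is therefore not reproducible from this definition;
its sampling protocol and normalization are not stated precisely enough
to implement.  The corresponding ordering check in the acceptance suite
is left failing by design rather than redefining the estimator to force
the ordering; use `K`, `H` or the cluster occupancy to separate random
from periodic structure — all three do so robustly.

## Short Haar transform

The order-`N` Haar matrix (`N = 2^M`) is built by the recursive Kronecker
product with base `W₂ = [[1,1],[−1,1]]/√2`; rows are the sampled scaling
and wavelet step functions with unit L2 norm, verified in tests against
both a direct function-sampling construction and PyWavelets' filter bank.
The detail sign convention is "later half minus earlier half"
(`β₀⁰ = ½(Y₂−Y₀+Y₃−Y₁)` at `p = 4`).

The short transform splits the signal into `⌊N/p⌋` non-overlapping,
left-aligned windows (`p ∈ {4, 8, 16, 32}`), discards the trailing
remainder, and transforms the real and imaginary channels independently
— equivalent to one complex-linear transform, since the matrix is real.
The default `orthonormal` convention conserves energy per window to
1e−12 and inverts exactly (transpose); the alternative `eq57_average`
rescales only the first row so that α is the plain window mean, which is
convenient for reading α as local composition but sacrifices the
isometry, so `inverse_haar` refuses it.

Coefficient clustering tallies the distinct
`(real-channel, imag-channel)` pairs of each coefficient index across
windows, rounding to 10 decimals to merge floating-point twins.  For
4th-root signals at `p = 4` the support is finite and small: the fine
details are `(Y_{i+1}−Y_i)/√2` with root differences in a 9-element set,
and α and β₀⁰ each occupy at most 25 points.  Tests assert the observed
support equals a brute-force enumeration over all 4⁴ windows, and that
the attainable detail-value set for `p = 8` (enumerated over all 4⁸
windows) is at least as large as for `p = 4` — the discreteness that
long-window transforms lose.

## Batch runs

`RunConfig` freezes inputs, windows, conventions, the wavelet settings
and one run seed; sub-seeds for minor sampling are derived from it
deterministically, so identical configs give byte-identical TSVs.  Every
output table starts with `# genowave config=<hash> seed=<n>`.  Default
control sizes for report runs: a 10 000-symbol pseudorandom sequence and
a period-4 pseudoperiodic one — long enough for the 10 000-window
randomness index, small enough that a full report takes seconds.

## Problem sizes used in the checks

Control-table reproduction averages 250 seeds at window 100 (K, H) and
30 seeds at 10 000 (R); cluster-support equality uses 4096 windows
(16 384 nt), enough that all 256 window types appear with probability
1 − 3·10⁻⁵; transform oracles run on thousands of random windows.  These
sizes keep the whole suite under a few minutes on one CPU while leaving
sampling error an order of magnitude below every asserted tolerance.
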