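# Methods

## Model

The scorer is a hidden Markov model whose hidden states are the `4^k`
k-mers over `N = {A, C, G, T}`, encoded lexicographically (A=0 … T=3, first
character most significant).  A contig is tokenized into *non-overlapping*
k-length windows starting at position 0; the trailing partial window is
dropped, and any window containing an ambiguous base (N or other IUPAC
codes) is skipped while the chain is treated as contiguous across the gap.
Lowercase is folded to uppercase; sequences are scored as given, with no
reverse-complement canonicalization (strandedness is the user's choice of
training material).

The hidden chain is first-order: `P[X] = π0(x_1) Π P[x_i | x_{i-1}]`.
Emissions factorize per base under conditional independence,
`e(y|x) = Π_j e(y_j|x_j)`, so the full emission model is one 4×4
row-stochastic substitution matrix; the k-mer emission matrix used by the
forward pass is its k-fold Kronecker power.

### Transition estimation

Adjacent k-mer pairs (window `[i, i+k)` → `[i+k, i+2k)`) are counted over
the training sequences.  Two counting modes exist:

* `sliding` (default): every start offset `i` contributes, pooling all k
  phase offsets.  The chain model itself is non-overlapping, but pooling
  phases is phase-invariant and makes the fullest use of limited training
  data.
* `chunked`: a single phase (`i = 0, k, 2k, …`), exactly mirroring the
  tokenization used at scoring time.

Rows are additively smoothed: `P̂[i|s] = (c_si + a) / (Σ_i c_si + 4^k a)`
with pseudocount `a` (default 1.0; `a = 0` requires every state to occur as
a transition source and raises otherwise).  `π0` is estimated from the
identically smoothed global k-mer frequencies of the training set (all
valid sliding windows); nothing in the underlying formulation pins down how
`π0` should be obtained, and the global frequency is the stationary-like
choice consistent with scoring contigs that start at arbitrary genomic
positions.

### Emission construction

Emissions are *constructed*, never fitted (no Baum-Welch): the user's
confidence in the data is an input, not an estimand.

* `build_emission_manual(p_match)` — diagonal `p_match ∈ (0, 1]`, the
  remaining row mass split evenly (or by a 4×3 bias matrix).  `p_match = 1`
  gives the identity and the HMM degenerates to the Markov chain.
* `build_emission_from_vcf(vcf, p_var)` — diagonal `1 − p_var`; the row
  mass `p_var` (default 0.15) is split over alternative bases
  proportionally to biallelic-expanded SNP record *counts* (REF=x → ALT=y);
  rows with no counts fall back to an even split.  Record counts rather
  than allele frequencies are used because a site list is the minimal,
  always-available information in a SNP database; indels and MNPs are
  skipped.

### Scoring

The forward recursion `α(n,i) = Σ_s α(n−1,s) p_si e(y_n|i)` runs with
per-step renormalization: the pre-normalization mass `a_t` of the working
vector is recorded, the vector divided by it, and with `c_t := 1/a_t` the
exact log-likelihood is `log P[Y] = Σ_t log a_t = −Σ_t log c_t`.  The
per-contig normalized score is the per-frame log-likelihood

    ŝ = −Σ_t log(c_t) / (k·m) = log P[Y] / (k·m).

`m` counts only *scored* k-mers — skipped ambiguous windows contribute
neither to the likelihood nor to the normalizer, so `k·m` is the number of
nucleotides actually modeled (the dropped tail is likewise excluded).  A
zero-probability observation (possible with sparse emissions, e.g. the
identity) yields a `−inf` sentinel and a `zero_probability` flag on the
contig rather than aborting the run.  The recursion is dense; k is capped
at 8 because the transition matrix grows as `16^k`.

### Assembly summary

Contig scores are standardized against a reference distribution of
normalized scores (`z = (ŝ − μ)/σ`), mapped through the standard unit
logistic (no slope/offset — none is defined by the formulation), and the
assembly coefficient is `m_h / s_h` with `s_h` the *sample* (n−1) standard
deviation, the natural choice for the small contig sets the summary serves.
The coefficient is undefined (reported as such, never silently patched)
when all corrected scores are identical.  95% intervals use the normal
approximation `mean ± 1.96·sd/√n`.  `too_short` contigs are excluded from
score statistics but counted in the contig total.

The reference distribution defaults to *simulated* mode — 30,000 sequences
of 1,000 nt drawn from the trained model (hidden chain from `π0`/`P`, then
per-base emission noise), scored, and summarized — with the seed recorded
in the output.  The original fixed benchmark of real-sequence scores is not
distributable, so results are reproducible per run but not tied to any
external artifact; file mode accepts any pre-computed score set.

## Synthetic data

`synthetic_reference` generates the training pseudo-genome from an
order-3 base-level Markov chain whose conditional rows are drawn once from
a Dirichlet(0.5): a deliberately patterned sequence, since an i.i.d. string
has no transition structure for the model to learn and would make any
discrimination study vacuous.  Order 3 and concentration 0.5 give local
dependency of a strength comparable to what k ∈ {1,3,5} models can
progressively resolve.  What this emulates is *local* genomic pattern; it
has no repeats, isochores, coding structure, or strand asymmetry, so
passing benchmarks here demonstrate the mechanics of pattern recognition,
not organism-scale performance — absolute error rates and coefficients on
real genomes depend entirely on the training material and are expected to
differ.

The discrimination benchmark draws, per length in 10–100 nt (step 10),
1,000 "true" sequences (uniform ambiguity-free substrings of the reference)
and 1,000 "random" sequences (i.i.d., composition-matched to the measured
reference composition — the worst case: separation must come from
transitions, not base proportions), scores both cohorts at k ∈ {1, 3, 5}
under emission diagonal 0.85, and reports per-k statistics pooled over all
lengths: the mean ŝ difference, a Welch two-sample t-test with 95% CI, and
the naive-Bayes error of the two fitted Gaussians.  The NB error is
evaluated analytically — decision boundaries are the roots of the quadratic
log-density difference, and the error is the corresponding Gaussian tail
masses (`0.5 ∫ min(f_t, f_r)`) — rather than by resampling, which is exact
given the fitted densities.

One deliberate parameter choice: the benchmark trains with per-row unit
pseudo-mass (`a = 4^-k`) instead of the library default `a = 1`.  At 100 kb
of training data, Laplace `a = 1` adds `4^k` pseudo-observations per row —
at k = 5 that is ~10× the real counts, which washes out exactly the
k-dependence the benchmark measures.  Constant per-row pseudo-mass keeps
smoothing strength comparable across k.  This is configurable
(`BenchmarkConfig.pseudocount`).

## Numerical choices

* All logarithms natural; entropies in nats.
* Row-stochasticity is enforced to within 1e-12 at construction and
  checked by `validate()`.
* Matrix files serialize probabilities at `%.17g`, so a written model
  re-reads bit-exactly.
* With the identity emission the scaled forward pass multiplies exactly the
  same factors as the Markov-chain path probability, so the two agree
  bit-for-bit, not merely approximately.
* `ŝ` for sequences with `m = 0` is an error (`too_short` at the contig
  level), not a NaN.
* Batch scoring (`forward_batch`) vectorizes equal-length sequence sets
  through one matrix product per step; it is used for reference
  distributions and benchmarks and agrees with the scalar path to
  relative 1e-12.

## Problem sizes

The shipped studies use a 100 kb synthetic reference, 1,000 sequences per
length per cohort (20,000 scores per k), a 30,000-sequence simulated
reference distribution at 1 kb, and 500 model-drawn sequences for the
length-decorrelation check; `scripts/acceptance.py` runs all of it in
about half a minute on one CPU.  These sizes give stable estimates at
desk scale (Welch p-values underflow to 0; NB errors move by well under a
point between seeds) while keeping the whole study trivially re-runnable.

## Known limitations

* Scores are strand-sensitive; score the strand you assembled or train on
  both strands.
* At large k with small training sets, most transition rows are dominated
  by the smoothing prior; the benchmark's per-row pseudo-mass mitigates
  but does not remove this — k beyond ~5 needs genome-scale training data.
* The assembly coefficient saturates when contigs score far above the
  reference distribution (logistic ≈ 1, tiny spread → very large
  coefficients); it ranks assemblies reliably but its magnitude is only
  meaningful relative to the same reference distribution.
* Summary CIs use the normal approximation; for assemblies with very few
  contigs they are indicative only.
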