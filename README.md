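# himme

Alignment-free genome-assembly reliability scoring with k-mer hidden Markov
models.

Genome assemblers disagree: different tools (or the same tool with different
heuristics) produce different assemblies from the same reads, and when no
reference genome is available there is little to compare them against.
`himme` scores assemblies by their *genetic patterns* instead of by
alignment.  A hidden Markov model whose states are the `4^k` non-overlapping
k-mers over `{A, C, G, T}` is trained on any FASTA a researcher trusts — the
organism's reference, a related species' genome, or a gene set — and each
contig of an assembly is scored by how well its k-mer transitions match the
training patterns, at a cost linear in contig length.  This works in a
*de-novo* setting where alignment rates are meaningless, and it yields a
per-contig metric (usable as a filtering cut-off) in addition to one number
per assembly.

## The model

* **Hidden chain.** States are non-overlapping k-mers; the transition matrix
  `P[x_i | x_{i-1}]` and initial distribution `π0` are estimated from the
  training FASTA by counting adjacent k-mer windows, with additive
  smoothing.
* **Emissions.** The observed contig is a noisy read-out of the hidden
  chain.  Under conditional independence, `e(y|x) = Π_j e(y_j|x_j)`, so
  emissions reduce to a 4×4 per-base substitution matrix: set manually
  (e.g. diagonal 0.85, off-diagonals 0.05) or estimated from a SNP database
  in VCF format.  A diagonal matrix recovers a plain Markov chain; an
  all-0.25 matrix imposes maximum uncertainty.
* **Scoring.** The forward algorithm computes `log P[Y; Θ]` in `O(m·|E|²)`
  with per-step scaling factors `c_t` to avoid underflow.  The per-contig
  score is the *per-frame log-likelihood*

  ```
  ŝ = −Σ_t log(c_t) / (k·m) = log P[Y; Θ] / (k·m)   (ŝ ≤ 0, higher is better)
  ```

  which removes the linear length dependence of the raw log-likelihood, so
  contigs of different lengths are comparable.
* **Assembly coefficient.** Each ŝ is z-scored against a reference
  distribution of normalized scores, mapped to (0,1) with the standard
  logistic, and the assembly is summarized by `HiMMe_coeff = m_h / s_h`, the
  mean over the standard deviation of the logistic scores — rewarding
  assemblies whose contigs score high *and* consistently.

## Worked example

```python
from himme import KmerHMM, build_emission_manual
from himme.simulate import synthetic_reference, sample_sequences_from_reference

ref = synthetic_reference(100_000, seed=11)          # patterned pseudo-genome
model = KmerHMM(ref, k=3, emission=build_emission_manual(0.85))
res = model.fit()
print(res.summary())

contigs = [(f"contig_{i+1}", s) for i, s in
           enumerate(sample_sequences_from_reference(ref, 5, 800, seed=3))]
for sc in res.score_contigs(contigs):
    print(sc.contig_id, sc.length_nt, round(sc.raw_score, 2),
          round(sc.normalized_score, 4))
```

prints

```
k-mer hidden Markov model
================================================
k-mer size:               3
hidden states (4^k):      64
training sequences:       1
training bases:           100000
transitions counted:      99995
counting mode:            sliding
pseudocount:              1
pi0 entropy (nats):       3.9489 / 4.1589 max
emission source:          manual
emission diagonal:        0.850, 0.850, 0.850, 0.850
================================================

contig_1 800 -790.83 -0.991
contig_2 800 -768.88 -0.9635
contig_3 800 -806.26 -1.0104
contig_4 800 -787.95 -0.9874
contig_5 800 -792.93 -0.9936
```

Each contig's raw score is its forward log-likelihood; the last column is
ŝ = raw/(k·m).  Here ŝ ≈ −0.99 nats per base: the contigs are genuine
substrings of the training material, so they sit well above what
noise-bearing or random sequences reach (random composition-matched
1 kb sequences average ŝ ≈ −1.47 under this model).  An assembly summary
(`res.summarize_assembly(scores, res.reference_distribution(...))`)
z-scores the contigs against a simulated benchmark and reports the
coefficient: assemblies made of training-like material get coefficients
orders of magnitude above random assemblies (which land near 2 in this
setup), because their logistic scores saturate high with tiny spread.

## Command line

The four workflow steps, plus a benchmark and a fixture generator:

```sh
himme transition-matrix --training ref.fa --k 3 --out trans.tsv.gz
himme emission-matrix   --p-match 0.85 --out emit.tsv.gz       # or --vcf snps.vcf
himme score   --assembly asm.fa --transition trans.tsv.gz \
              --emission emit.tsv.gz --out scores.tsv.gz
himme summary --scores scores.tsv.gz --ref-dist simulate \
              --transition trans.tsv.gz --emission emit.tsv.gz --out summary.tsv.gz
himme benchmark --training ref.fa --out-dir bench/
himme fixtures  --kind reference --length 100000 --seed 11 --out ref.fa
```

All outputs are gzip TSV with self-describing `#key=value` headers (k,
alphabet, smoothing, input checksums), so `score` detects mismatched
matrices and every file records the run that produced it.

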