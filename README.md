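# zipfent

Model-based Shannon entropy estimation for symbolic sequences — text,
DNA/protein, or any token stream — designed for the undersampled regime
where plug-in estimation is badly biased.

## The problem

The entropy H = −Σᵢ p(xᵢ) log₂ p(xᵢ) of an M-symbol source is usually
estimated by plugging in maximum-likelihood frequencies, which requires
enough data to resolve *every* symbol probability, including the rarest.
For natural sequences (language, coding DNA, animal vocalisations) the
symbol distribution is heavily skewed, and most of the sample budget is
spent pinning down the tail.

`zipfent` instead assumes the source follows an analytic rank model and
reconstructs the whole distribution from one easy measurement: the mean
**coincidence distance** D̄ of a high-ranked symbol (the number of draws
between consecutive occurrences, counting the first occurrence as draw 1
— in `abcdabc` the symbol `a` recurs at distance 5).

## The model and the estimator

The Zipf–Mandelbrot–Li (ZML) law gives rank probabilities

    P(r; M) = γ / (r + β)^α,   α = log(M+1)/log(M),   β = M/(M+1)

whose parameters depend only on the alphabet size M (normalised
numerically over ranks 1..M). Two *linguistically constrained* variants
shrink the admissible word space of the underlying random-typing model:
with continuation branching B (B = M−1 forbids adjacent repeated
letters; smaller B emulates continuation-n-gram lexicon reduction),

    α̃ = log(M+1)/log(B),   β̃ = M/(B−1).

The estimation pipeline is

    D̄  →  M̂ = G(θ; D̄)  →  P(r; M̂)  →  Ĥ = −Σ_r P log₂ P,

where the forward model G is calibrated once by simulation (seeded
ensembles over a grid of alphabet sizes; a calibration ships with the
package and `zipfent calibrate` regenerates it). A
Dvoretzky–Kiefer–Wolfowitz planner quantifies the sample savings: rank-1
estimation needs a factor λ_f(M) = P₁Δ₁²/(P_M Δ_M²) fewer samples than
resolving the bottom rank — several orders of magnitude for M in 20–40.

Block entropies H_N over n-gram alphabets and conditional entropy rates
h_N = H_N − H_{N−1} (bits per character) reuse any of the estimators,
with the usual text prefiltering (lowercase alphanumerics, single
spaces, within-word n-grams only).

## Worked example

Simulate 2×10⁵ symbols from a 30-symbol ZML source and estimate its
entropy from the rank-1 coincidence distances alone:

```
$ zipfent simulate --family zml --m 30 --length 200000 --seed 42 --out stream.txt
$ zipfent estimate --input stream.txt --input-format tokens --method zml_coincidence
{
  "M_hat": 29.93773884263223,
  "n_samples": 200000,
  "perplexity": 20.861344948271327,
  "value_bits": 4.382760267493457,
  ...
}
```

The estimated alphabet size M̂ = 29.94 recovers the true M = 30, and the
entropy estimate 4.38276 bits sits 4×10⁻⁵ bits from the true model
entropy (−Σ P(r;30) log₂ P(r;30) = 4.38280 bits); the perplexity 20.9 is
the effective number of equiprobable alternatives, 2^Ĥ.

Planning: how many samples does the rank-1 measurement need?

```
$ zipfent plan --m 30 --rank 1 --confidence 0.95
{
  "Delta_r": 0.0573...,   # gap P(1) - P(2)
  "N_r": 1517,            # DKW-sufficient samples for rank 1
  "lambda_f": 428703.8    # sample-savings factor vs resolving rank M
}
```

Other subcommands: `entropy-rate` (block-entropy series as TSV),
`model-pmf` (analytic rank probabilities), `calibrate`, `experiment`
(convergence-vs-sample-size table), all with `--help`.

As a library:

```python
import zipfent as z

seq = z.sample_iid_sequence(z.make_zml(30), 200_000, seed=42)
est = z.estimate_entropy_model(seq, z.default_calibration("zml"))
print(est.value, est.M_hat)   # 4.3827... 29.93...
```

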