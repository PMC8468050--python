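# Methods

## Rank models

The package's analytic rank distributions all have the Mandelbrot form
P(r; M) ∝ (r + β)^(−α) over ranks r = 1..M, with parameters that are
closed-form functions of the alphabet size M. They arise from a
random-typing word model: an alphabet of M letters plus a delimiter
emits words; all words of length L share probability ∝ (M+1)^(−L), and
ranking words by probability (shorter first) converts the length
variable into rank.

* **Unconstrained (zml)** — admissible words of length L number M^L;
  α = log(M+1)/log(M), β = M/(M+1), and the word-space normalisation
  constant is γ_w = (M+1)²/M.
* **Constrained (czml1, czml2)** — a per-position continuation
  branching factor B < M shrinks the lexicon to M·B^(L−1) words of
  length L. Rank then grows like B^L while probability still decays
  like (M+1)^(−L), so α̃ = log(M+1)/log(B). The offset follows from the
  cumulative count N(L) = M(B^L − 1)/(B − 1): shifting rank by
  M/(B − 1) makes the length-L band edge an exact power of B^L, so
  β̃ = M/(B − 1). `czml1` is the no-adjacent-repeated-letters model
  (B = M − 1, requiring M ≥ 3); `czml2` takes B free in [2, M−1]
  (default ⌈(M−1)/2⌉), emulating continuation-n-gram lexicon reduction.
  Relative to `zml`, the larger offset flattens the head and the larger
  exponent steepens the tail: mid ranks gain probability, the top and
  bottom ranks lose it.

Every distribution is renormalised by direct summation over its finite
rank support (the κ step), so the closed-form normalisers are metadata
and conservation holds to 1e−9 by construction. Non-integer M is
accepted — the estimator produces continuous alphabet-size estimates —
with rank support round(M), floor 2. Note that P(r; M) as a function of
continuous M is therefore piecewise: nearly flat within a half-integer
band and jumping where the support increments. A uniform
(`equiprobable`) family is included as the degenerate flat limit.

The constrained offset β̃ = M/(B−1) exceeds 1, unlike the published
unconstrained value β = M/(M+1); the unconstrained model follows the
published constants, the constrained ones follow the band-edge
derivation above, and at B = M−1 the two constrained families coincide
by construction.

## Coincidence distances

Observed distances use the convention D = (position gap) + 1: the first
occurrence counts as draw 1 and the repeat as draw D, so adjacent
repeats have the minimal distance 2. All consecutive occurrence pairs
of a symbol contribute to the mean D̄ — at small sample sizes this uses
every coincidence the sequence contains. For a symbol of probability p
in an i.i.d. stream, gaps are geometric and E[D̄] → 1/p + 1.

The model-side first-coincidence law (the probability that the first
repeat of *any* symbol occurs at draw n) is computed exactly from the
no-repeat survival probability F̃(n) = n!·e_n(p), where e_n is the n-th
elementary symmetric polynomial of the rank probabilities (an O(M·n)
dynamic program). For an equiprobable alphabet this reduces to the
birthday product Π_{h≤n}(1 − (h−1)/M); the expectation E[n] at M = 365
is the classic 24.62-draw birthday value. These two quantities —
per-symbol recurrence and any-symbol first collision — are related but
distinct; the estimator is built on the former, the collision law is
exposed for analysis and validated against exhaustive enumeration.

## Calibration

The forward model M = G(θ; D) is calibrated by simulation. For each M
on a grid, Nv independent sequences of Ns symbols are drawn from the
family distribution; in each sequence the symbols are ranked
*empirically* (count, ties by first occurrence) and the mean distance
of the rank-r symbol is recorded. Using the empirical ranking — exactly
what the estimator does on observed data — matters: the empirically
most frequent symbol is a selected symbol whose distances are slightly
biased low, and performing the same selection during calibration
cancels the effect (for flat distributions it is worth several
hundredths of a bit).

Two fit forms are provided per rank:

* **power** M = a·D^b + c, initialised from a log–log regression with
  c = 0, inverted in closed form D = ((M − c)/a)^(1/b);
* **polynomial** M = Σᵢ θᵢ Dⁱ (degree ≤ 6, weighted by 1/M so relative
  errors are balanced), inverted numerically by bracketed root finding.

A fit is rejected unless the ensemble distances are strictly increasing
in M and the fitted curve is strictly increasing on the calibrated
range. Outside that range the polynomial is continued linearly from the
edge (high-degree polynomials diverge when extrapolated) and an
`ExtrapolationWarning` is raised.

The shipped default calibration uses 40 log-spaced alphabet sizes in
[8, 160] — bracketing, with margin, the 20–40 range typical of natural
alphabets — with Nv = 50 trials and Ns = 10⁶ samples per trial for the
`zml` and `equiprobable` families (2×10⁵ for the constrained families),
seed 1, PCG64. The polynomial form is the default for the Zipfian
families because the distance→M curve is close to exponential: over
even one decade of M a three-parameter power law misfits by tens of
percent, while the degree-6 polynomial tracks the curve to ≲0.3%
(dominated by simulation noise at the small-M end). The equiprobable
family is exactly linear (D = M + 1) and ships as a power model. All
protocol parameters and the full ensemble are stored in the model
metadata, and `scripts/build_default_calibration.py` regenerates the
bundle.

## Entropy estimation

The model-based estimate of a sequence is

D̄(rank r) → M̂ = G(θ; D̄) → family distribution at M̂ → Ĥ = −Σ P log₂ P,

reported in bits with perplexity 2^Ĥ. Rank 1 is the default: the most
frequent symbol accumulates the most coincidences, hence the tightest
D̄ (and the DKW analysis below shows it is also the cheapest rank to
resolve). A multi-rank mode averages the per-rank M̂ weighted by
coincidence counts. The continuous M̂ enters the closed-form α, β; the
rank support is round(M̂). The equiprobable variant reports
Ĥ₀ = log₂(M̂) directly. Estimation fails loudly (rather than silently
degrading) when the ranked symbol has no coincidence or M̂ rounds below
2. Baselines: the plug-in estimator and its Miller–Madow correction
Ĥ + (m−1)/(2N ln 2).

Error structure, measured on i.i.d. zml(M=30) data (the package's own
convergence experiment): the estimator's per-trial spread is large when
coincidences are few (≈0.5 bits at Ns ≈ 200–500, where D̄ rests on a
few dozen gaps), and the convex distance→M map leaves a small residual
bias (≈10⁻³ bits at Ns ≥ 10⁴). Its advantage over plug-in estimation is
therefore in *bias* in the undersampled regime: at Ns ≤ 10³ the
model-based mean is 2–6× closer to the truth than the plug-in mean
(−0.17 vs −0.23 bits at Ns = 100; −0.007 vs −0.044 at Ns = 500), and by
Ns = 10⁶ the mean estimate is within ~10⁻⁵ bits of the true entropy. A
faithful plug-in over a small alphabet is itself nearly unbiased once
Ns ≫ M (its bias is −(m−1)/(2N ln 2)), so for M = 30 the two methods
are statistically indistinguishable around Ns ≈ 10⁴–10⁵; the
model-based estimator's edge is at small samples — and for the large
effective alphabets of n-gram blocks, where plug-in bias is severe at
any realistic corpus size.

## Sample-size planning

The DKW inequality gives ζ′ = 1 − 2e^(−2nε²) confidence that an
empirical probability sits within ε of its target. Taking ε_r = Δ_r/2
(Δ_r = P(r) − P(r+1), the largest precision that still separates
adjacent ranks) yields the sufficient count
N_r = ⌈8P_r/Δ_r² · ln(2/(1−ζ′))⌉. The convergence factor compares the
easiest and hardest symbols, λ_f(M) = P₁Δ₁²/(P_M Δ_M²) with the
bottom-rank gap Δ_M = P(M−1) − P(M); the confidence terms cancel, so
λ_f is independent of ζ′. This orientation is the one that is ≥ 1 for
every M ≥ 2 and grows monotonically (roughly like M⁵ up to logs) —
about 6×10⁴ at M = 20 and 4×10⁵ at M = 30 — quantifying why rank-1
coincidence counting needs orders of magnitude fewer samples than
resolving the full distribution.

## Entropy rate

Block entropy H_N treats each distinct n-gram as one symbol of a
derived alphabet and applies any estimator to that stream; the
conditional rate is h_N = H_N − H_{N−1} (equal to the conditional
entropy for stationary sources). Text preprocessing lowercases, keeps
alphanumerics and spaces, collapses space runs (digits are retained as
alphanumeric; both choices are recorded here because published
protocols differ), and optionally drops n-grams spanning word
boundaries. H_N is flagged unreliable once distinct n-grams exceed 10%
of the stream — block estimates degrade well before the n-gram space
saturates — and the reported rate is h_N at the largest reliable N,
with the full series always available for inspection.

## Synthetic data

All fixtures are generated in-package with seeded PCG64 generators:
i.i.d. inverse-CDF draws from any rank distribution (also for the
constrained families — the constraints reshape the rank law, not the
sampling dependence assumed by the coincidence theory), uniform
sampling of no-adjacent-repeat words (first letter uniform, each
continuation uniform over the other M−1 letters), and first-order
Markov chains with known transition matrices, whose analytic
conditional entropy Σπᵢ Σⱼ Pᵢⱼ log₂(1/Pᵢⱼ) anchors the entropy-rate
tests. These emulate stationary ergodic sources with known truth; they
do not emulate the nonstationarity, long-range dependence or
orthographic structure of real corpora, so passing tests demonstrate
correctness of the estimators under their own model assumptions, not
model adequacy for any particular natural dataset. The convergence
experiment follows the protocol of M = 30, Nv = 75 trials, sample sizes
log-spaced up to Ns = 10⁶, with per-trial prefix nesting so each trial
behaves like a single growing data stream.

## Numerical choices

* Rank support for continuous M: round half up, floor 2.
* Word-space quantities are evaluated in log space (M^L overflows
  float64 long before the associated probabilities stop mattering).
* Survival probabilities use the elementary-symmetric DP, numerically
  stable for M up to several hundred.
* Polynomial inversion brackets the root over the calibrated range
  ±25%; power inversion is closed-form and refuses M ≤ c.
* Rank ties: lexicographic token order in rank tables, first-occurrence
  order in sequences — both deterministic.
* Calibration serialisation is canonical JSON (sorted keys), so equal
  seeds give byte-identical models.

## Known limitations

* The estimator is consistent only insofar as the data match the chosen
  family; on real text the fitted M̂ absorbs model mismatch (it is an
  *effective* alphabet size, and can exceed the calibrated range, where
  predictions are extrapolated with a warning).
* Calibration residuals are not propagated into entropy error bars; no
  confidence intervals are reported.
* For flat (near-uniform) sources the empirical-rank selection bias is
  cancelled by calibration only near the calibration sample size; at
  very different sequence lengths a residual of order 0.01–0.03 bits
  remains.
* The bottom-rank DKW bound uses the adjacent gap Δ_M; for genuinely
  flat distributions all gaps vanish and the planner (correctly)
  refuses.
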