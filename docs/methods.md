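# Methods

This note documents the models implemented in `pwmscale`, the
conventions and numerical choices behind them, what the synthetic
generators do and do not emulate, and the known limitations.

## Scoring model

A position frequency matrix (PFM) holds nucleotide counts `n(i,k)` from
aligned binding sites, rows canonicalized to A,C,G,T. Against a
background model with frequencies `f_i` and a pseudocount μ (default 1),
the adjusted column probabilities and log-odds weights are

    v(i,k) = (n(i,k) + f_i·μ) / (N_k + μ),   w(i,k) = log2(v(i,k)/f_i)

with `N_k` the column count sum. A window's score is the sum of the
weights of its bases; the consensus score `S_max` is the sum of
per-column maxima. Scores are gauge-dependent (adding a per-column
constant shifts every score equally) but score *differences* are not,
which is why λ — defined from a score difference — is shift-invariant
and scale-equivariant (weights × c ⇒ λ × c).

Motif information content is the summed per-column KL divergence

    If = Σ_k Σ_i p(i,k) · log2(p(i,k)/f_i)   (bits, always ≥ 0)

computed with the same pseudocount adjustment. All logarithms in the
package are base 2; all energies are in bits.

Background presets: uniform (0.25 each); fly A/T 0.28, G/C 0.22; yeast
A/T 0.31, C/G 0.19; vertebrate A/T 0.29, C/G 0.21. Windows containing
non-ACGT symbols are skipped everywhere (scored as an unscorable NaN
sentinel in the single-window API): ambiguous-base scoring has no
defined semantics here, and skipping biases tail quantiles least.

## Score landscapes and quantiles

The top-0.1 % score of a background landscape, `S_top`, is the anchor
of the λ equation. Two landscape kinds are provided:

- **Empirical**: every valid window of the supplied sequences, on the
  forward strand or both (default both; each strand's score at an
  offset is a separate observation). Quantiles use the nearest-rank
  (inverted-CDF) convention: `S_top(q)` is the rank-⌈q·n⌉ score from
  the top. No interpolation — discrete score distributions make
  interpolation conventions visible and implementation-dependent.
- **Exact**: the distribution of the score of one i.i.d. background
  k-mer, by column-wise convolution on a score grid of width ε
  (default 0.001 bits). Each grid bin accumulates, besides its
  probability, the probability-weighted sum of unrounded scores, and
  reports their ratio as the bin's support value: cumulative
  probabilities are placed within ε·L, and support values are exact
  whenever a bin holds a single distinct score (always the case for
  sparse, well-separated supports such as the worked example's
  binomial). For L ≤ 8 the DP is verified against full 4^L enumeration
  in the test suite.

`log_quantile(s) = −log10 P(score ≥ s)` maps the top-0.1 % boundary to
exactly 3.0 and is the axis on which residence-time profiles are
binned.

## The λ equation

    λ = (S_max − S_top0.1%) / E_maxMismatch
    E_maxMismatch = ⟨E⟩ · If / ⟨If⟩,   ⟨E⟩ = 6 bits, ⟨If⟩ = 13.2 bits

The 6-bit average maximum mismatch energy comes from microfluidic
binding-energy measurements (binding decays to background after ~2–3
mismatches at ~2 bits each); 13.2 bits is the average information
content those measurements correspond to. Both are configuration, not
constants: a different top-score threshold requires a correspondingly
adjusted ⟨E⟩, which is why the threshold-robustness property is stated
on λ *ranks* (Spearman), not values. `E = ⟨E⟩·(If/⟨If⟩)` is evaluated
with the ratio grouped so that `If = ⟨If⟩` yields exactly ⟨E⟩ in
floating point.

Degenerate cases raise rather than return: zero information content
(λ undefined) and `S_top = S_max` (score range collapsed at the
quantile — motifs shorter than ~6 bp against the 0.1 % threshold, or
landscapes too small to resolve it).

For cross-TF comparison of motifs of different lengths, λ values are
z-scored within motif-length groups 7–8, 9–10, 11–12, 13–15, ≥16 bp.
Length-6 motifs (which pass the length filter but fall below the first
group) are assigned to the 7–8 bp group. The population (n-denominator)
standard deviation is used, making a two-member group map to exactly
{−1, +1}; singleton or zero-spread groups raise.

Binding-strength tracks report, for each site at or above `S_top`,
`strength = E_maxMismatch − E_mismatch` (bits): non-negative,
zero at the threshold, maximal (= the motif's mismatch budget) at the
consensus, and comparable across TFs. The BED score column scales
strength to 0–1000 relative to the motif's budget.

## Residence times and λ conversion

Under facilitated diffusion the expected residence time at a site is
exponential in the scaled score. The package uses

    τ_j = τ0(λ) · exp(+S_j/λ),   τ0(λ) = 1 / mean_j exp(S_j/λ)

Two conventions are deliberate:

- **Sign.** The source formalism prints exp(−S/λ), which contradicts
  its own premise that stronger-scoring sites are bound longer; the
  monotone-increasing convention is adopted. Only τ ratios and
  profile comparisons matter downstream, so the choice affects no
  conversion result, but it makes profiles increase with site
  strength as stated.
- **Normalization.** The original τ0 is delegated to an external
  facilitated-diffusion simulator and has a different value per PWM.
  Here τ0 normalizes the landscape-average residence time to exactly
  1 time unit. Both objectives compare τ across PWMs only under a
  common normalization, so any per-PWM constant cancels; this choice
  makes every number reproducible without a simulator. A consequence
  worth noting: normalized residence times are bounded by the
  landscape size, so the whole computation is overflow-safe after a
  single log-space mean (evaluated via log-sum-exp).

Sites beyond log-quantile 3.0 are assigned to bins [3.0,3.1),
[3.1,3.2), … up to the best site's log-quantile (bin membership depends
only on score ranks, never on λ, so profiles at many λ are cheap). A
conversion run computes the reference profile once at the known λ, the
candidate profile at every grid point (default 0.1–3.0, step 0.01 — the
step is unstated in the source and 0.01 makes equivariance statements
meaningful), and selects the feasible minimizer of the chosen
objective:

- `mse`: mean squared difference of bin means over bins occupied in
  both profiles (≥ 2 required);
- `abslog`: Σ |ln τ_cand − ln τ_ref| over the same bins.

Feasibility requires the candidate's shared-bin means to stay within
the [min, max] range of the reference's occupied bins; infeasible
points are the heatmap's blank regions and concentrate at small λ,
where the top bins explode exponentially. Ties break to the smallest
λ; if no grid point is feasible the global minimizer is returned
flagged `forced`, with a warning.

### Consistency and its limits

Self-conversion returns the reference λ exactly (the objective is
identically zero there), and converting to a weight-scaled copy of the
same PWM recovers the scaled λ to within one grid step. Round-trip
conversion (PWM1→PWM2→PWM1) is exact for identical PWMs and drifts
roughly linearly with the difference between the motifs: measured on
count-blended PWM pairs over 400 kb landscapes, the drift is ~0.01–0.02
at a 1 % count perturbation and reaches ~0.05–0.09 at 5 %, identically
for both objectives. This is not an artifact of either objective but
projection non-invertibility: each conversion projects onto a
one-parameter family of profiles, and when the families do not
intersect (genuinely different motifs) the two projections are not
mutual inverses. Smaller landscapes add sampling noise on top (top
bins hold few sites); 100 kb roughly doubles the small-perturbation
drift relative to 400 kb. Conversions between substantially different
PWMs of the same TF are therefore best read as calibrated estimates
with a few-percent scale uncertainty, not exact transfers.

## Synthetic data

All fixtures flow from one integer seed (independent substreams per
generator; bitwise reproducible):

- `random_sequence`: i.i.d. bases with P(G)=P(C)=gc/2. This emulates
  what the λ equation needs from a background — the score-tail shape —
  and nothing else: no repeats, CpG islands, or local composition.
  Passing tests on random backgrounds therefore validate the
  machinery and the surrogacy claim at matched GC, not robustness to
  genome structure.
- `random_pfm`: per column, nucleotide propensities ~
  Dirichlet(concentration ×(1,1,1,1)), then `n_sequences` multinomial
  counts (default depth 50, concentration 0.5 — information contents
  around 5–9 bits for 10-mers, matching the realistic motif range).
  Small concentration ⇒ sharp, information-rich columns.
- `perturbed_pwm_pair`: counts blended with a uniform-Dirichlet draw,
  `counts₂ = (1−noise)·counts₁ + noise·n·Dirichlet(1)` per column.
  noise=0 gives an identical pair; the default 0.05 emulates the
  scale of difference between independently derived database motifs
  (it shifts If by ~10–15 %), and the round-trip consistency check
  uses 0.01, the small-perturbation regime in which the conversion
  operator's continuity guarantees recovery.

## Problem sizes

Tests and the acceptance script run desk-scale: 100 kb landscapes
(both strands, ~2·10⁵ observations) for λ estimation and objective
comparisons, 400 kb for round-trip conversion, 1 Mb forward-strand
scans for empirical-vs-exact quantile coverage, 20-seed panels for
stochastic rates, and a 30-motif panel for rank robustness. These
sizes put the top-0.1 % boundary on ≥ 200 sites and the binomial
3-sigma band within ~0.1 bit of the exact quantile, which is the
regime the methods need; genome-scale inputs only sharpen the same
quantities.

## Known limitations

- The PWM independence assumption: λ inherits any inaccuracy of the
  PWM itself (dinucleotide dependencies, biased site collections).
- The 6-bit/13.2-bit calibration stems from a handful of TFs of one
  family; for motifs with extreme information content (≳ 20 bits) the
  linear scaling of the mismatch budget likely overestimates the
  energy drop and depresses λ.
- Flanking low-information columns inflate If (and motif length) with
  no principled correction; the length-group z-scores mitigate, not
  solve, this.
- Quantile anchoring needs the k-mer space to be much larger than the
  1/q threshold: motifs under ~6 bp (or thresholds beyond the
  landscape's resolution) are rejected rather than extrapolated.
- Residence-time conversion assumes the two PWMs describe the same
  binding process; TF–TF interactions (dimer stabilization) and
  chromatin context are outside the model.
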