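# pwmscale

Energetic scaling of position weight matrix (PWM) scores for comparing
transcription factor (TF) binding site strength **across** TFs.

## The problem

Scanning DNA with a PWM gives each site a log-odds score in bits, but raw
scores of different TFs live on different scales: a "good" score for one
factor can be a mismatch for another. For quantitative models of TF
binding dynamics and enhancer activity one needs binding *energies*, and
the bridge from score to energy is a per-TF scaling parameter λ:

    E_mismatch(j) = (S_max − S_j) / λ

where `S_j` is a site's PWM score and `S_max` the consensus score, so
`E_mismatch` is the energetic penalty (in bits) of the site relative to
the factor's best possible site.

`pwmscale` provides two estimators of λ:

1. **The λ equation.** Anchor the score of the top 0.1 % of background
   positions, `S_top0.1%` (the lower boundary of plausible binding
   sites), to the maximum tolerable mismatch energy:

       λ = (S_max − S_top0.1%) / E_maxMismatch,
       E_maxMismatch = ⟨E⟩ · If / ⟨If⟩

   with `If` the motif's information content (summed per-column KL
   divergence against the background, bits) and calibration averages
   ⟨E⟩ = 6 bits, ⟨If⟩ = 13.2 bits from in-vitro binding energy
   measurements. Only a PWM and a background sequence landscape are
   needed — no ChIP or accessibility data.

2. **Residence-time conversion.** When two PWMs describe the same TF
   (e.g. from different databases) and λ is known for one, the second λ
   is chosen on a grid (0.1–3.0, step 0.01) so that the bin-averaged
   residence times τ = τ₀·exp(S/λ) of top-scoring sites, stratified by
   −log₁₀ score quantile (bins of 0.1 starting at 3.0), match the
   reference profile — by mean squared error or by the sum of absolute
   log differences. Grid points that push residence times off the
   reference scale are flagged infeasible ("blank regions").

Background landscapes may be genomic FASTA or GC-matched random
sequence, which is a validated surrogate at these sample sizes; the
`synthetic` module generates such sequences plus random and perturbed
motifs, so everything is testable offline.

## Worked example

```
python examples/estimate_lambda.py
```

prints, for a six-column motif that always prefers A (counts 8,0,0,0
per column) against a uniform background:

```
information content If = 8.72462 bits
consensus score  S_max = 11.24681 bits
top-0.1% score   S_top = 6.20242 bits
max mismatch energy    = 3.96574 bits
lambda                 = 1.27199
```

The exact score distribution of this motif is binomial (how many of the
six positions show an A); the top-0.1 % boundary falls on the
five-matches score 6.20242 bits, the motif's information content scales
the 6-bit average mismatch budget down to 3.96574 bits, and the λ
equation gives 1.272. A site scoring 1 bit below consensus therefore
costs 1/1.272 ≈ 0.79 bits of binding energy for this TF.

The other scripts in `examples/` walk through λ tables with
motif-length z-scores, λ conversion between PWM pairs, binding-strength
annotation (where raw-score rankings across TFs invert), and exact vs
empirical landscapes.

## Command line

A thin CLI wires the same library calls into reproducible runs:

```
pwmscale simulate --seed 1 --length 200000 --out-fasta bg.fa --out-pfm m.jaspar
pwmscale estimate --pfm m.jaspar --fasta bg.fa --min-sequences 10 --out lambdas.tsv
pwmscale convert  --ref-pfm a.jaspar --cand-pfm b.jaspar --ref-lambda 1.6 \
                  --fasta bg.fa --out-json conv.json --out-heatmap heat.tsv
pwmscale scan     --pfm m.jaspar --target-fasta enhancer.fa --fasta bg.fa \
                  --out-bed sites.bed
```

PFMs are read in JASPAR plain-text dialects (headed, bracketed,
label-reordered, or bare 4-row matrices); outputs are TSV/JSON/BED/
bedGraph with provenance headers.

## Layout

- `src/pwmscale/motif.py` — PFM/PWM types, parsing, pseudocounts,
  information content, scoring, reverse complement
- `src/pwmscale/landscape.py` — empirical scans, exact DP score
  distributions, top-quantile and log-quantile queries
- `src/pwmscale/estimation.py` — the λ equation, mismatch energies,
  binding-strength tracks, motif-length z-scores
- `src/pwmscale/residence.py` — residence times, log-quantile profiles,
  grid conversion, feasibility, heatmap export
- `src/pwmscale/synthetic.py` — seeded random sequences, PFMs, and
  perturbed PWM pairs
- `src/pwmscale/cli.py` — the `pwmscale` command

See `docs/methods.md` for the model, conventions and limitations.
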