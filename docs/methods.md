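# Methods

## The measurement scale

A microfluidic qPCR run reports, per well × gene reaction, the cycle
threshold *ct* at which fluorescence crosses a preset level, up to a cycle
bound *ct_max* (default 40, configurable). Reactions that never cross are
recorded as undetected. All analysis happens on the *expression threshold*

    et = ct_max − ct,     et = 0  ⇔  undetected,

which is proportional to log₂ mRNA abundance because each cycle doubles
product (primers are assumed fully efficient). The untransformed abundance
is `y = 2^et` for detected reactions and exactly 0 for undetected ones.
This map is deliberately discontinuous at 0 (limit from above 1, value 0):
an undetected reaction is modelled as zero molecules, and in practice
detected reactions sit many cycles above the bound, so the gap carries no
information. Displays and the deviance objective use the shifted log
`log2(y + 1)`, which pins zero at zero and returns to the et scale for
large values (the difference is < 0.01 for et ≥ 8).

Undetected entries are stored as exactly 0 rather than as missing values;
every downstream formula uses the detection indicator `u = 1{et > 0}`, so a
0/positive encoding is both sufficient and unambiguous. The concordance
analysis (below) is the empirical justification: treating undetected as
zero agrees with multi-cell aggregates far better than treating it as
missing.

## The hurdle model

Single-cell expression of gene *j* is a two-part mixture:

    U_ij ~ Bernoulli(π_j)
    et_ij | U_ij = 1 ~ N(μ_j, σ_j²)        (log-normal in abundance)
    et_ij | U_ij = 0 = 0                   (point mass at zero)

Three parameters per gene: the expression frequency π (share of cells with
the gene on), and the conditional mean μ (cycles) and variance σ²
(cycles²) of the positive et values. Maximum-likelihood estimates are the
obvious ones: π̂ = n⁺/n, μ̂ the mean of positive values, σ̂² the 1/n⁺
variance. μ̂ is undefined (NaN) without a positive well, σ̂² without two;
σ̂² = 0 (all positives tied) is flagged degenerate.

## Combined likelihood-ratio test

For two groups the likelihood factorizes into a Bernoulli factor over all
wells and a Gaussian factor over expressed wells, so the log-LRT for

    H0: (π, μ) common     vs     H1: (π_g, μ_g) group-specific

decomposes exactly as Λ = Λ_binom + Λ_normal, each part maximized
independently. σ² is held common to the two groups under both hypotheses
and re-estimated under each — the equal-variance model implied by the
test's two degrees of freedom. Closed forms are used: the Bernoulli part
is the G-statistic of the 2×2 detection table (with 0·log 0 = 0 at the
boundaries), and the Gaussian part is n⁺·ln(SST/SSE), the classical
variance-ratio form with total and within-group sums of squares over
positive values. The implementation is cross-checked in the test suite
against direct numerical maximization of the full two-part likelihood.

Degenerate layouts carry no continuous information and set Λ_normal = 0:
fewer than two positives overall; one group with no positives and the
other with fewer than two; and the (1, 1) layout, where the within-group
SSE is identically zero and the Gaussian likelihood unbounded. The
combined statistic then gracefully reduces to the Bernoulli LRT, with the
degrees of freedom kept at 2 for p-value continuity.

Under H0, Λ is asymptotically χ² with 2 df. The approximation degrades
when few cells express the gene: with `tot` pooled positives the Gaussian
part is `tot·ln(1 + F/(tot−2))` with `F ~ F(1, tot−2)` exactly under
normality, which rejects a nominal-0.05 χ²(1) bound at ≈ 0.072 when
tot = 16 and approaches 0.05 only as tot grows. Results therefore carry a
`small_sample_flag` when either group has fewer than 8 expressed wells,
and a permutation p-value (add-one estimator, `(1 + #{Λ* ≥ Λ})/(B + 1)`,
seeded and vectorized) is available and recommended below that point. The
reported direction of change is the sign of π̂₁μ̂₁ − π̂₀μ̂₀, the
zero-inflated mean on the et scale, so it reflects overall expression
change whether driven by frequency or level; undefined μ̂ counts as 0.

## Quality control

Two robust scores screen wells, in a fixed order:

1. *Null wells* (no detected gene) are removed first. They would otherwise
   drag the median/MAD behind the ζ score toward zero and mask real
   outliers — the test suite demonstrates the breakdown on a plate with
   40 % empty wells.
2. Per gene, the robust z-score of positive et values,
   `z = (et − median⁺)/(c·MAD⁺)` with c = 1.4826 ≈ 1/Φ⁻¹(3/4) (the unique
   constant making the MAD estimate a normal SD). Genes with fewer than 3
   positive wells (configurable) emit no scores — their median/MAD are too
   unstable. A zero MAD maps ties to z = 0 and everything else to ±∞
   (flagged).
3. Per well, ζ: the robust z of `f = arcsin(√p)`, the variance-stabilizing
   transform of the fraction of the panel detected.
4. A well is removed whole when any of its genes has |z| > k_z or when
   |ζ| > k_zeta. Filtering never edits retained values (pure row
   selection), and lowering either threshold can only grow the flag set.

Default thresholds are k_z = k_zeta = 9 — deliberately conservative,
several times larger than the biggest plausible biological group
difference, so that only gross technical artifacts are removed; they are
tunable against aggregate ground truth (below). The housekeeper R²
diagnostic (squared Pearson correlation of two putative housekeeping genes
over co-expressed wells, NaN below 3 shared wells) is provided to check
whether housekeeping-based normalization would even be defensible; no
normalization is implemented, since per-cell sorting already fixes the
amount of input material.

## Concordance and threshold tuning

Plates carrying n-cell aggregate wells (e.g. 100 cells pooled per
reaction) allow a fidelity check. For each gene × unit the *in-silico*
average is the mean abundance over single-cell wells (zeros included; a
positive-wells-only "missing" mode exists solely for the comparison), and
the *in-vitro* average is the aggregate abundance divided by its cell
count, averaged over aggregate replicates. Agreement is measured by Lin's
concordance correlation coefficient

    ρ_c = 2·cov(x, y) / (var(x) + var(y) + (mean x − mean y)²)

computed with population (1/n) moments on the shifted-log scale — the
scale on which the comparison is displayed and which keeps the zero class
at zero — and by the weighted deviance

    D = Σ n⁺ (slog(insilico) − slog(invitro))² / Σ n⁺,

a weighted *mean* (normalizing by total weight makes D comparable across
datasets of different size). The weights n⁺ are *ex-ante* positive-well
counts, fixed before filtering: if they were recomputed after filtering,
removing cells would shrink the weights and the tuning objective would
degenerate. Threshold tuning sweeps a (k_z, k_zeta) grid (default
{2,…,9,12,15}²), filters single-cell wells at each point, recomputes D
against the untouched aggregates, and returns the argmin; ties break
toward the most permissive corner so a clean plate keeps all its data. A
unit whose single-cell wells are all filtered away contributes an
in-silico average of 0 (zero expression, large deviance), which is what
penalizes over-aggressive thresholds.

The per-cell aggregate mean relates to the single-cell parameters as
π·E[y | expressed], so its log₂ sits ≈ log₂ π below the positive-well
single-cell mean — the offset structure that makes the zeros-included
convention necessary, reproduced by simulation in the test suite.

## Screening and summaries

`run_screen` applies, per gene within each unit, any of: the combined LRT,
its Bernoulli and normal components alone (each against χ²(1)), and a
Welch t-test on the zero-inflated et values (the naive baseline). Units
missing a group are skipped with a warning; genes expressed nowhere in a
unit are skipped with a log entry and excluded from the multiplicity
denominator. Raw p-values are adjusted per test by Benjamini–Hochberg
(via statsmodels); BH is the standard step-up choice, applied within the
treatment block a screen call represents. Summaries: discovery counts
across an FDR grid, and the signed −log₁₀ p matrix (sign = direction,
genes × units) for heatmapping.

## Synthetic plates

The generator draws wells from the model above. Positive et values use the
normal distribution truncated to et > 0 (the model's support); sampling is
by rejection where the truncated mass is small and scipy's truncnorm
otherwise, and a validator warns when the truncated mass exceeds 1e−3
(μ/σ < 3.09), where positive-part moments would be visibly biased. Default
gene parameters are sampled uniformly: π ∈ [0.05, 0.9] (a wide frequency
spectrum, as observed on real plates), μ ∈ [10, 30] cycles, σ ∈ [1, 3]
cycles. Wells: 96 genes × 96 single-cell wells per unit by default; a
two-group design applies per-gene effects (Δπ, Δμ) to group 1 with shared
σ, paired within units.

Injected artifacts:

- *Empty wells*: all genes forced to 0 (a cell was never loaded).
- *Contaminated wells*: a constant et inflation added to every expressed
  gene of the well. The SimConfig default is +6 cycles (subtle
  contamination); the canonical contaminated fixture uses +15 cycles with
  20 % empty wells — gross pre-amplification contamination, which the
  exponential chemistry turns into a ~3×10⁴-fold abundance error, the
  regime the conservative default thresholds (k = 9) are meant to catch.
- *Aggregates*: abundances of n independently simulated cells are summed
  on the linear scale and re-logged (`et = log₂ Σ y`, clipped to
  (0, ct_max]; undetected if every cell is off) — the physical composition
  of pooled mRNA.

All randomness flows from one root seed through per-(unit, group) spawned
sub-streams, so identical configs are bitwise reproducible and partial
re-simulation is stable.

What the generator does **not** emulate: amplification noise and primer
efficiency differences, fluorescence-curve artifacts, correlation between
genes within a cell, plate/batch effects, and cell-cycle or cell-size
covariates. Passing tests therefore demonstrate internal consistency of
the statistical machinery under the model's own assumptions plus the two
injected artifact types — not robustness to every failure mode of real
plates.

## Numerical choices and edge cases

- 0·log 0 = 0 throughout Bernoulli likelihoods (`scipy.special.xlogy`).
- p-values are floored at the smallest positive double so they stay in
  (0, 1].
- Operations whose result is genuinely undefined (ρ_c with zero
  denominator, averages with no eligible wells, housekeeper R² below 3
  shared wells, t-test with zero pooled variance) return NaN; contract
  violations raise `ConfigError`/`ValidationError`.
- Sums of squares are clipped at 0 before logs/ratios to absorb negative
  rounding residue.
- Calibration studies (test suite and `scripts/acceptance.py`) use a
  vectorized batch LRT over replicate × well arrays; it is asserted
  equal to the scalar path. Problem sizes: 10,000 replicates per null
  condition at 60 wells/group, 100 replicate screens of 96 genes × 16
  units × 90 wells/group for the power comparison — sizes chosen so every
  Monte-Carlo bound quoted has standard error well under its margin.

## Known limitations

- The χ²(2) reference is anti-conservative below ≈ 8–12 expressed cells
  per group (exact F analysis above); use permutation p-values there.
- The equal-variance (common σ²) model is assumed, matching the 2-df
  test; no unequal-variance alternative is provided.
- Two groups only, paired within unit; no mixed-effects extension for
  comparisons across units.
- ζ's median/MAD are computed per plate; pooling across plates of a
  multi-plate study is left to the caller.
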