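# Methods

This note records the model, the algorithms, the defaults and the design
choices behind `bayesgrowth`, and what the synthetic studies do and do not
demonstrate.

## Growth model

The Baranyi–Roberts model describes `y(t) = ln x(t)` with four parameters:
initial log concentration `y0`, maximum specific growth rate `μmax`,
dimensionless lag parameter `h0 = λ·μmax`, and log carrying capacity
`ymax`. The adjustment function `A(t)` suppresses growth for
`t ≲ λ = h0/μmax` and approaches the shifted asymptote `t − h0/μmax`
afterwards, so the curve has the familiar lag/exponential/stationary
sigmoid on the log scale.

Conventions:

- The equations are evaluated on the natural-log scale exactly as written;
  every user-facing quantity (data, priors, posteriors, reports) is on
  log10. `y0`, `ymax` and `μmax` convert by a factor `ln 10`; `h0` and λ
  are scale-invariant.
- Numerical stability: both interior logarithms are computed with
  log-sum-exp shifts, and the saturation term is rewritten as
  `y = y0 + g + m − ln(e^g + e^m − 1)` with `g = ymax − y0`,
  `m = μmax·A(t)`. Values of `μmax·t` (and `h0`) up to ~700 stay finite;
  `t = 0` and `h0 = 0` are special-cased so that `A(0) = 0` and
  `A(t) = t` hold exactly.
- Reduced variants are parameter restrictions: no-lag (`h0 = 0`),
  no-stationary-phase (`ymax = ∞`), linear (both), with 3, 3 and 2 free
  parameters. They share the full model's code path.

## Likelihood

Viable counts have roughly constant *relative* error across serial
dilutions, so errors in `log10 x` are treated as i.i.d. Gaussian with a
single constant σ per analysis. σ can be prescribed or (recommended,
default) inferred with a Jeffreys prior `∝ 1/σ` on `[10⁻³, r]`, where `r`
is the data's log10 range.

Below-detection observations (flagged `censored`, with threshold `T` =
0.7 or 1.3 log10 CFU typically) contribute `ln(1/T)` regardless of the
model value while the model stays below `T` — a uniform density on
`[0, T]` — plus an unnormalised Gaussian tail
`−(y_model − T)²/(2·tail_sd²)` when the model rises above the threshold.
The tail is a numerical device to avoid `−∞` log-likelihoods, not a
probability statement; `tail_sd` defaults to 0.05 log10 units, well below
typical data noise, so it acts as a soft barrier. The slight
non-normalisation is accepted deliberately.

In two-curve analyses one σ is shared between both curves within each
hypothesis (a per-curve pair can be passed explicitly to `joint_loglik`).
Sharing keeps the hypotheses' parameter counts minimal and makes their
evidences directly comparable.

## Priors

Default priors are uniform with bounds scaled to the data (range
`r = d_max − d_min`, floored at 1 for degenerate curves; time span
`t_span`):

| parameter | support | rationale |
| --- | --- | --- |
| `y0` | `[d_min − r/2, d_max]` | initial level near the low data |
| `ymax` | `[d_min, d_max + r/2]` | capacity near the high data |
| `μmax` | `(10⁻⁶, 10·r/t_span]` | up to 10× the mean observed slope |
| `h0` | `[0, μ_upper·t_max]` | lag cannot exceed the record |
| σ | `[10⁻³, r]`, Jeffreys | scale-invariant noise prior |

The joint constraint `ymax > y0` is enforced as zero prior mass (the
likelihood returns `−∞`), not by reparameterisation; the sampler simply
never keeps such points. This slightly reduces the normalised prior volume
identically across hypotheses, so Bayes factors are unaffected in
practice.

Cluster-informed priors summarise `N` previously analysed curves by the
law of total variance (between-member spread plus mean within-member
variance) and use the result as location/scale of a truncated Gaussian or
Cauchy on `μmax`. The same scale is used for both families — the Cauchy's
heavier tails then express the weaker commitment. Informative priors are
truncated to `location ± 10·scale` (intersected with positivity) and
renormalised; truncation keeps the inverse-CDF map well-conditioned and
costs negligible mass.

## Nested sampling

Evidence and posterior come from a single Skilling-style nested-sampling
implementation:

- `n_live` points (default 100) are drawn from the prior via the
  inverse-CDF map from the unit hypercube; all sampling happens in cube
  coordinates.
- Deterministic shrinkage `X_k = exp(−k/n_live)` (the expectation of the
  shrinkage factor) rather than sampled Beta shrinkage: simpler, standard,
  and exactly reproducible.
- Replacement draws run a random walk of `max_mcmc_steps` (default 20)
  Gaussian steps, reflected at the cube boundary, started from a random
  surviving live point and accepting any proposal above the current
  likelihood floor `L*`. Step sizes are per-dimension: a global factor
  (adapted by ×1.5/×0.5 between iterations to keep acceptance within
  [20 %, 60 %], frozen during each walk) multiplies the live set's
  per-coordinate standard deviation. Matching the proposal to the live
  set's anisotropy is essential here — posterior widths for `μmax` and
  `y0` differ by orders of magnitude in cube coordinates, and an isotropic
  step leaves the walk unmixed and the evidence noisy.
- On a likelihood plateau (no live point strictly above `L*`) the
  acceptance rule relaxes to ≥, so constant-likelihood problems remain
  well-defined; a walk with zero acceptances returns its start point with
  a logged warning.
- Termination when `L_max · X_k < tol · Z` (default `tol = 10⁻⁶`), i.e.
  the largest conceivable remaining contribution is negligible; the
  remaining live points are then added with width `X_final/n_live` each.
  A hard iteration cap flags the result instead of failing.
- `ln Z` is accumulated in log space; the reported uncertainty is
  `sqrt(H/n_live)` with `H` the information. Posterior summaries use the
  weights `w_k = h_k L_k / Z`; staircase resampling (inverse-CDF on the
  cumulative weights) yields equally weighted draws.
- All randomness flows from one seeded `numpy` generator; pair comparisons
  spawn three independent child generators (one per hypothesis) from the
  top-level seed.

The likelihood hot loop is a scalar kernel compiled with numba when
available (a pure-Python fallback implements identical arithmetic); the
public API functions validate inputs and share the same mathematics, and a
test pins the two paths together.

## Hypothesis comparison and the F-test

`compare_pair` scores H1 (replicates), H2 (shared rate) and H3
(independent) with the same sampler settings and equal prior hypothesis
probabilities. Per-curve nuisance parameters always use their own curve's
data-scaled bounds; shared parameters (H1, and `μmax` under H2) use the
union of the two curves' bounds. The decision rule for "different growth
rates" is substantial evidence on Jeffreys' scale: `2 ln B32 ≥ 2`. H1 is
reported alongside so callers can rank all three (e.g. identical data sets
rank H1 first — the built-in Occam penalty at work).

The F-test baseline fits the two curves by bounded multistart least
squares (best of ≥10 seeded starts; internally parameterised with
`g = ymax − y0 > 0` so the support constraint is a box constraint):
*separated* = two independent 4-parameter fits, *unified* = 7 parameters
with one shared rate. The statistic divides the unified-vs-separated
discrepancy by the separated residual sum scaled by `1/(N₁+N₂−1)`, with
df (1, N₁+N₂−7); the conventional extra-sum-of-squares statistic (which
divides the residual term by its df instead) is available behind
`conventional=True`. The default form is mildly conservative (its
denominator divisor exceeds the residual df), which shows up as a type-I
error slightly below nominal in the synthetic studies. A numerically
perfect separated fit (residual sum ≤ 10⁻¹²) is reported as degenerate
with `p = 0` rather than dividing by zero.

## Synthetic studies

`generate_curve` draws evenly spaced points on `[0, t_max]`, adds i.i.d.
Gaussian log10 noise, and flags values below an optional detection
threshold. The default truth — `y0 = 3`, `ymax = 9` log10 CFU, `h0 = 1`,
`μmax = 0.11` log10 units/h, 32 points over 60 h (enough to pass 95 % of
the rise), σ = 0.1 — is chosen to look like routine viable-count data;
the noise grid for detection studies is {0.05, 0.1, 0.2, 0.4, 0.8}.

Three drivers mirror the study designs at desk scale (10–20 replicates
per condition rather than 50; every output row carries its full
generating configuration, and everything is reproducible from one seed):

1. **Perturbation sweep** — curve A fixed at rate 0.11, curve B
   regenerated per replicate at rate 0.11 + Δμ; reports mean/sd of
   `ln B23`. Larger Δμ, more points or less noise push the statistic
   further negative (finer differences become detectable).
2. **Detection comparison** — per noise level, the percentage of correct
   equal/different verdicts for the F-test and the Bayes rule under
   uniform and cluster-informed priors; clusters come from four
   previously analysed curves per condition (analysed at σ = 0.1 — the
   premise is that prior knowledge derives from reasonable-quality data).
3. **Cluster ranking sweep** — two clusters of four simulated curves with
   rates 0.09–0.11 (A) and 0.15–0.17 (B); a fresh target curve's evidence
   is computed under uniform, Gaussian-A/B and Cauchy-A/B priors as its
   rate moves between the clusters. Gaussian priors gain evidence inside
   their own cluster's range and pay a large penalty far from it, the
   Cauchy penalty is much smaller, and the uniform prior barely moves.

What these studies do *not* show: the generator matches the model family
exactly (no model misspecification), noise is exactly Gaussian and
homoscedastic, and time grids are regular — real viable-count series have
irregular sampling, occasional gross errors and between-batch effects.
Passing the synthetic suite therefore validates the inferential machinery,
not robustness to real-data pathologies.

## Numerical and scale choices

- Problem sizes in the test suite and acceptance script (toy evidence at
  `n_live = 400`, 10–20 replicates per detection condition, 200 pairs for
  the type-I error) are desk-scale choices that keep a full run within
  minutes on one CPU while leaving the statistical assertions
  well-separated from their thresholds.
- Seeds are fixed constants in tests; experiment drivers spawn
  `SeedSequence` children so that replicate streams are independent.
- Evidence comparisons between priors on the same data reuse the same
  target curves, so prior effects are paired and the curve-to-curve
  variability cancels in the differences.

## Known limitations

- The constrained walk is a simple anisotropic random walk; strongly
  curved or multimodal posteriors (not typical for this model with
  informative data) would mix better with slice or ellipsoid samplers,
  which are out of scope.
- Evidence scatter for the 8–9-parameter two-curve hypotheses is a few
  nats between seeded runs — adequate for the decision rule (which acts
  at |2 ln B| = 2 with typical margins of tens), but close comparisons
  near the threshold should average several seeds, as the pair-comparison
  studies do.
- `h0` is the least constrained parameter (its posterior is broad when
  few points sit in the lag phase); lag-time estimates inherit that
  uncertainty.
- The censored-point density is not renormalised jointly with its
  Gaussian tail; with many censored points and a model hovering at the
  threshold this mildly penalises threshold-hugging fits.
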