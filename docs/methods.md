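# Methods

## Problem

Muscle synergy analysis factorizes preprocessed surface-EMG envelopes
`V` (muscles × time) as `V ≈ W C` with non-negative weights `W`
(muscles × n) and activation coefficients `C` (n × time). The
factorization needs the number of synergies `n` as an input, and the
choice of `n` is the scientifically loaded step: it is read as a measure
of motor-control complexity and differs between healthy and pathological
gait. This package implements, for cyclic locomotion:

* the classical VAF-based criteria — threshold (T-VAF at 90% and 95%),
  elbow (E-VAF) and plateau (P-VAF);
* the ChoOSyn criterion, which scores candidate orders by the
  *consistency* of the decomposition across epochs of the walk and the
  *redundancy* within the synergy basis, without a reconstruction-error
  threshold;
* a pseudo-real sEMG simulator providing ground truth, and a benchmark
  harness that scores every criterion against it.

## Pipeline

Every walk is processed on the normalized timebase of 1000 samples per
gait cycle (nominally 1000 Hz):

1. **Segmentation.** Cycles `[e_i, e_{i+1})` between consecutive
   cycle-start events are linearly resampled to 1000 samples.
2. **Envelopes.** On the whole-walk concatenation: zero-phase 8th-order
   Butterworth high-pass at 35 Hz, per-muscle demeaning, full-wave
   rectification, zero-phase 5th-order Butterworth low-pass at 12 Hz,
   then clipping of ringing negatives to zero. Filtering the
   concatenation (rather than each cycle) avoids per-cycle edge
   transients; zero-phase filtering keeps activation timing unshifted.
3. **Amplitude normalization.** Each muscle is divided by its global
   maximum over the walk, so all envelopes live in [0, 1].
4. **Subgroups.** Consecutive blocks of 10 cycles are concatenated into
   `floor(N/10)` matrices of size muscles × 10,000; leftover cycles are
   discarded. Subgroups are the "epochs" whose mutual consistency
   ChoOSyn exploits.
5. **Factorization.** Each subgroup is factorized at every order
   n = 1..8 by alternating non-negative least squares (ANLS): exact
   block updates of `C` given `W` and `W` given `C`, each solved by a
   block-principal-pivoting NNLS kernel on the normal equations.
   Five restarts from uniform-random initializations (seeds
   `seed + r`); the restart with the smallest Frobenius residual is
   kept. Stopping: 1000 iterations, relative residual < 1e-6, relative
   factor change < 1e-6, or relative residual improvement per iteration
   < 1e-6 (the last rule is what terminates in practice; without it the
   alternation always exhausts the iteration cap while changing the
   factors only in the 7th digit). `W` columns are normalized to unit
   Euclidean norm with the inverse scale absorbed into `C`.
6. **Averaging and sorting.** The 10,000-sample coefficients are
   averaged over their ten 1000-sample windows. For each order, all
   subgroups' weight columns are pooled and clustered by k-means under
   cosine distance (k = n, 15 replicas, up to 1e5 iterations, centroids
   = arithmetic means, empty clusters re-seeded with the worst-fitting
   point); within each subgroup synergies are assigned one-to-one to
   clusters by exhaustive minimum-cost permutation (n ≤ 8), and
   coefficients are re-ordered accordingly. Centroids `W̄_i`, `C̄_i` are
   means across subgroups.

## Selection criteria

With `VAF = (1 − Σ(M − R)² / ΣM²) × 100` (uncentered, summed over all
entries) computed per subgroup and averaged into one curve over orders:

* **T-VAF(θ)**: smallest n with VAF(n) ≥ θ; θ ∈ {90, 95}.
* **E-VAF**: interior order with the largest perpendicular distance from
  the chord joining the curve's endpoints (ties to the smaller order; an
  exactly linear curve raises an error). Chord distance is the standard
  robust operationalization of "highest curvature" for a percent-scale
  curve whose discrete second differences are noise-dominated in the
  plateau.
* **P-VAF**: first order from which an ordinary least-squares line
  through the remaining points (at least 3) fits with MSE < 1e-2 on the
  percent scale. On the fraction scale the same threshold would be
  vacuous (every tail would pass); a 2-point fit is excluded because its
  MSE is identically zero.

ChoOSyn scores each order n = 2..8 with four cosine-based parameters:

* `ICV_W`, `ICV_C`: for each synergy, one minus the mean cosine between
  its per-subgroup members and its centroid; the maximum over synergies
  (worst case) is kept.
* `WS`: largest pairwise cosine between weight centroids.
* `CS`: cosine between the averaged coefficients of the two synergies
  that emerge from splitting one order-(n−1) synergy; the pair is found
  by clustering the n weight centroids into n−1 groups (k-means, cosine
  distance, initialized at the order-(n−1) centroids). For n = 2 the
  pair is trivially the two synergies. If several groups are multiply
  occupied, the largest within-group similarity is used (worst case).

The profiles `ChoOSyn_W = WS + ICV_W` and `ChoOSyn_C = CS + ICV_C` stay
low and stable up to the correct order and jump beyond it. With signed
differences `d(n) = value(n+1) − value(n)` and threshold θ = mean |d|:

* a **step** sits at n when `d(n) > θ` and the preceding difference was
  stable (`|d(n−1)| ≤ θ`, or n is the first order) — the candidate is
  the level *before* the sharp rise;
* a **local minimum** sits at n when `−d(n−1) > θ` and `d(n) > θ`.

Only the two highest candidate orders per profile are kept. A common
candidate of both profiles wins; otherwise the candidate minimizing
`ChoOSyn_W(n) + ChoOSyn_C(n)` wins; if neither profile produced
candidates (flat profiles), the order minimizing that sum over 2..8 is
returned with a fallback flag in the diagnostics. The step/minimum
formalization uses signed differences because direction matters ("abrupt
decrease followed by abrupt increase"), while θ is the mean of absolute
differences; stability is enforced only on the preceding difference so
that steps at the right edge of the profile remain detectable.

## Simulator

Real ground truth is unavailable, so the simulator synthesizes it with
the statistical structure the pipeline assumes — low-rank, cycle-locked,
non-negative — and the separability of expert-curated "clearly
recognizable" synergy sets:

* **Weights**: muscles are partitioned into disjoint primary groups, one
  per synergy (loadings U(0.6, 1.0)); each non-primary muscle receives a
  weak cross-loading (U(0.05, 0.18)) with probability 0.05; columns are
  unit-normalized and resampled until all pairwise cosines are ≤ 0.6.
* **Coefficients**: the gait cycle is treated as circular (heel strike
  is an arbitrary phase origin). Each synergy owns one phase slot of the
  cycle and fires one Gaussian burst per cycle inside it, with
  cycle-to-cycle jitter of the center (σ = 2% of the cycle) and
  amplitude (lognormal σ = 0.05), over a small tonic baseline (4–10% of
  the burst amplitude, postural tone). Burst FWHM is 30–45% of the slot,
  scaled inversely with the synergy's primary-muscle count so that every
  synergy contributes a comparable share of energy to the
  amplitude-normalized envelopes; activation templates are resampled
  until pairwise cosines (baseline removed) are ≤ 0.6. An optional
  bimodal-burst mode exists in the config (off by default; cross-slot
  secondary bursts measurably blur the rank signature at high orders).
* **Energy balance rationale**: after per-muscle amplitude
  normalization, a synergy's envelope energy is essentially
  (primary-muscle count) × (burst duty cycle) — burst amplitude cancels.
  Balancing these shares gives envelope matrices whose singular spectrum
  is flat up to the true rank, i.e. VAF curves that ramp and then
  corner, which is the regime in which curve-shape criteria are
  well-posed and which the donor selection of the emulated study design
  implies.
* **Signal**: `S = envelope × G_S + G_N` per muscle, with `G_S` an
  i.i.d. standard-normal carrier and `G_N` background noise of σ =
  `10^(−SNR/20)` (omitted in the no-additive-noise condition, which is a
  distinguished flag, not an infinite SNR). The coefficient matrix is
  scaled so the largest envelope sample is 1 a.u., anchoring the SNR
  definition.
* **Dataset**: per true-n level (default 4, 5, 6), five subjects are
  drawn and augmented to 25 "simulated subjects" by pairing every weight
  matrix with every coefficient matrix; each set is synthesized under
  every SNR condition (default: no noise, 30, 25, 20, 15 dB), giving 375
  recordings. The dataset is evaluated lazily from a manifest that
  records every seed, so it is a pure function of the configuration.

What the simulator does **not** model: motion artifacts, electrode
crosstalk beyond static cross-loadings, non-Gaussian EMG statistics,
inter-cycle cadence variation, fatigue or electrode drift
(nonstationarity), and within-day changes of synergy structure. Passing
benchmarks on this generator therefore demonstrates correct recovery
under the stated signal model, not robustness to every pathology of real
recordings; in particular the plateau criterion, whose failure modes on
real data involve tail wiggle from nonstationarity, is close to ideal
here.

## Numerical choices

* ANLS inner solver: block principal pivoting on the normal equations,
  grouping columns with identical passive sets through one Cholesky
  factorization; warm-started across alternations (numba-compiled).
* NMF determinism: restart r of subgroup j at order n uses a seed
  derived from (master seed, j, n) via `SeedSequence`, plus r.
* Desk-scale preset (used by the benchmark harness, the acceptance
  script and the heavy tests): 30 cycles per walk (3 subgroups), 3 NMF
  restarts, 150 alternating iterations, and factor fitting on every 5th
  envelope sample followed by one exact full-resolution NNLS solve for
  `C`. The 12-Hz-low-passed envelopes are oversampled at 1000
  samples/cycle, so fifth-resolution fitting changes VAF values by less
  than 0.01% in A/B comparisons; the full preset (150 cycles, 5
  restarts, 1000 iterations, no decimation) reproduces the printed
  parameter set exactly.
* Degenerate inputs: zero-norm vectors raise domain errors in all
  cosine-based parameters; a muscle whose envelope is identically zero
  is left unscaled (with a warning) rather than divided by zero; an
  exactly linear VAF curve has no elbow and raises; T-VAF/P-VAF raise a
  no-selection error that the benchmark counts as a failed
  (incorrect) trial and excludes from ME/RMSE.
* Tie-breaks: two common ChoOSyn candidates resolve by the smaller
  combined profile value, exact ties by the smaller order.

## Benchmark metrics

For selected orders `n_i` against true orders `n_c,i`:
`ME = mean(n_i − n_c,i)` (sign: under- vs over-estimation) and
`RMSE = sqrt(mean((n_i − n_c,i)²))`, with the fraction of correct
classifications counted over all trials. Reports embed the dataset
manifest and all seeds; rebuilding from the manifest reproduces the
report bit-for-bit.

## Known limitations

* The normalized-timebase convention (1000 samples/cycle ≈ 1000 Hz)
  makes the 35/12 Hz cutoffs nominal: for cadences far from 1 cycle/s
  the physical frequency axis is distorted. This mirrors the
  normalize-then-filter ordering of the emulated protocol and is
  configurable (`fs_nominal`).
* ChoOSyn's step/local-minimum rules are a formalization of a verbal
  description; profiles that are flat or rise perfectly smoothly have no
  candidates and trigger the documented fallback.
* With only 3 subgroups (desk preset) the intra-cluster variability
  estimates are coarse; the full preset's 15 subgroups stabilize them.
* The simulator's stationarity makes the 15 dB condition easier for the
  plateau criterion than real recordings would be.
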