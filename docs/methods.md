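# Methods

This note documents the model implemented by the `sapm` package, the
numerical choices behind the fitting procedure, the synthetic data used
for validation, and the limits of what the packaged tests demonstrate.

## The signaling model

The package models coordinated signaling across a network of `n` brain
(stem)/spinal-cord regions observed through region-averaged BOLD fMRI
time series in percent-signal-change units. Two coupled linear relations
define the model over `N = n + nL` nodes (regions plus `nL` latent
inputs; row = receiver, column = sender):

    S_input  = M_input  · S_output
    S_output = M_output · S_output

* `M_input` (`n × N`) holds the **D values** — non-negative weights with
  which each sender's output contributes to a region's summed input. A
  region's measured BOLD course is identified with its total input
  signaling (presynaptic activity dominates the metabolic demand that
  drives BOLD).
* `M_output` (`N × N`) holds the **DB values** — signed weights
  describing how each input drives the receiving region's output.
  Positive DB is excitatory (more input, more output), negative DB is
  inhibitory. **B = DB / D** is the per-connection input-to-output
  conversion factor ("apparent transmission effect").
* The bottom-right `nL × nL` block of `M_output` is the identity. This
  guarantees one eigenvector with eigenvalue exactly 1 per latent input.
  Scaling eigenvector `k` to unit value at latent `k`'s row yields
  `M_eigv` (`N × nL`), computed in closed form: the region part of
  column `k` solves `(I − A) x = a_k` with `A` the region block and
  `a_k` latent `k`'s column. Condition numbers above 1e12 raise an
  unstable-network error (latent drive cannot settle to a finite
  response).

Latent inputs are the only source of temporal variation: regions cannot
drive themselves. Given latent time courses `L` (`nL × T`),

    S_output = M_eigv · L,      S_input = M_input · M_eigv · L = M1 · L.

"Variable" latents have freely estimated time courses. A "fixed" latent
has a prescribed template — the stimulation boxcar convolved with the
canonical double-gamma HRF (peak-delay 6 s, undershoot 16 s, ratio 1/6,
all configurable) sampled at the TR — and only its amplitude is
estimated. No hemodynamic deconvolution is performed anywhere; all
modeled signals live in the BOLD domain.

Variable-latent weights into their target region are fixed at 1 and not
fitted: a latent's column scale and its time-course scale multiply the
same term, so fitting both would leave the likelihood flat along that
ray. The scale lives in `L`.

## Solving and scoring a parameter point

Given D/DB values (and a fixed-latent amplitude), the variable latent
time courses have the closed-form least-squares solution
`L = (M1ᵀM1)⁻¹ M1ᵀ S_BOLD`, restricted to the variable columns of `M1`
after subtracting the fixed-latent contribution (amplitude × template)
from the data. Fit quality is summarized by

* `err_ssqd` — squared error summed over regions and volumes;
* `r2_total = 1 − err_ssqd / ΣΣ S_BOLD²` — explained-variance fraction
  pooled over regions;
* `r2_per_region[r] = 1 − SSres(r) / SSdata(r)` and `r2_average`, their
  mean. Regions with zero data sum of squares are excluded from the
  average and reported.

R² is defined as an explained fraction (1 − residual/total) with the
*data* sum of squares in the denominator. The ratio-of-sums form with
the modeled signal in the denominator is sometimes written for the same
quantity; the explained-fraction convention matches the verbal
definition ("proportion of variance explained") and standard usage, and
is what the null-calibration numbers below refer to.

## Parameter estimation

D, DB, and fixed-latent amplitudes are estimated by multi-start
finite-difference gradient descent on

    objective = err_ssqd + λ · Σ |DB|

with the latent solve nested inside each evaluation. Defaults: 15 random
starts (D ~ U(0.5, 1.5) — D values typically sit near 1; DB ~
U(−0.2, 0.2); amplitude ~ U(0, 1)) descended for 15 iterations each;
the start with the lowest residual error (ties → lowest start index)
continues for up to 250 iterations. Each iteration estimates the
gradient by perturbing every free parameter by 1e−3, steps along the
max-normalized gradient with scale 0.1, and halves the scale whenever
the objective fails to decrease (floor 1e−6 stops the descent). D values
are clipped at 1e−2. Unstable or degenerate parameter points evaluate to
+∞ and are simply avoided. The accepted objective is non-increasing by
construction, and the whole fit is a pure function of (data, model,
config seed). Multiple runs are concatenated along time and fitted
jointly; the fixed-latent template tiles across runs.

**L1 weight.** λ defaults to 1e−4 × the residual error at the first
start's initial point, making the penalty a tie-break far below the
error term: among near-equivalent fits, smaller |DB| wins. This weight
was chosen by a sensitivity analysis on Gaussian null data (10 regions,
5 runs × 40 volumes):

| λ / err_init | mean r2_average | median across-sim SD of DB | null calibration |
|---|---|---|---|
| 1e−2 | 0.237 | 0.0002 | collapsed: FWE ≈ 0.9, KS fails |
| 1e−3 | 0.258 | 0.10 | still partially collapsed |
| 1e−4 | 0.262 | 0.29 | healthy: FWE ≈ 1–2%, KS passes |
| 0    | 0.262 | 0.31 | healthy, but no sparsity preference |

At 1e−2 the per-parameter penalty gradient exceeds the error gradient
for most connections, soft-thresholding their DB values to a common
near-zero point in every dataset. That destroys the across-dataset DB
distributions on which the entire statistical layer rests (T values
against a null reference): group sems collapse and the family-wise
false-positive rate explodes. 1e−4 preserves the distributions while
retaining the sparsity preference.

**Variance normalization.** Before fitting, each region's series is
scaled so all regions share the dataset's mean variance; otherwise
high-variance regions dominate the objective. DB values and all R²
metrics are invariant to this scaling (verified by paired fits); D
values are reported in the normalized space, and
`SAPMFit.d_values_original_units()` divides each connection's D by its
target region's scale factor to refer them back to raw units.

## Identifiability, and what parameter recovery tests show

From a single dataset the joint (D, DB) estimate is scale-degenerate: a
region's output can be rescaled at will if its consumers' D values (and
its own incoming DB values) compensate, and latent time courses absorb
further scale. Exact-fit solutions therefore form a continuum, and the
L1 tie-break selects a minimal-|DB| representative that need not equal
the generating parameters — DB *signs* are preserved under the positive
rescalings involved, but magnitudes are not. The recovery harness
therefore pins D at its generating values (`FitConfig.freeze_d`) and
tests DB estimation conditional on the input weightings, on a 4-region
toy built to be fully identified: two variable latents enter regions
with no other inputs (their time courses are read off the data
directly), and the remaining regions form a two-node cycle whose
coupling appears separably in the observed inputs. On noiseless data the
fit recovers all DB signs and magnitudes to well under 10%; this
demonstrates the estimator, not identifiability of the full joint
problem on arbitrary networks.

## Null calibration and group inference

Fitting the network to pure Gaussian noise still explains ~25% of the
variance — the share of a 10-dimensional noise process that an optimally
oriented latent subspace (two free spatial directions plus the fixed
stimulus component) can absorb — and null DB values are not centered
exactly at zero. Group inference therefore compares each connection's
group-mean DB to a **null reference**: the per-connection DB
distribution across many fits to independent null datasets of the study
shape.

* `T = (mean DB − null reference mean) / sem(DB)`, two-tailed p from
  Student's T with N−1 df (a zero-reference mode is also provided).
* Family-wise error is controlled by Bonferroni over the connection
  count: with 32 connections and family-wise α = 0.05, uncorrected
  p < 0.05/32 = 0.0015625.
* Behavioral association uses Pearson R per connection with Fisher's
  transform `Z = atanh(R)·√(N−3)` against the standard normal.
* D values are positive by construction and are not significance-tested.

Calibration at the defaults (56 null simulations): mean r2_average
0.26 ± 0.008 per dataset; every connection's |null mean DB| is below one
null SD; resampled groups of 20 produce a family-wise positive rate of
~1% at α = 0.05; per-connection T values pass Kolmogorov–Smirnov tests
against Student's T.

**Finite-pool caveat.** Resampled groups drawn from a pool of `N` fits
and compared against that pool's mean have T values deflated by
`√(1 − n/N)` — negligible for pools of ~1000, material at the scaled-down
pool sizes used here. `null_group_tvalue_distribution` exposes an
optional correction dividing this factor out; the distributional (KS)
checks use it, while significance counting follows the literal
(conservative) resampling procedure.

## Sub-regions and the search

Regions are split into k = 5 sub-regions by k-means on voxel time series
concatenated across runs and participants (similarity of response, not
location). Plain k-means only approximates the near-equal cluster
volumes the method aims for, so the cluster size balance is reported and
an optional balanced variant caps the largest cluster at twice the
smallest by iterative boundary reassignment. Distances are Euclidean on
raw percent-change courses by default; a correlation mode (per-voxel
z-scoring) is provided.

With 10 regions × 5 clusters there are 5¹⁰ = 9,765,625 combinations of
one sub-region per region, so the best-fitting combination is found by
coordinate ascent: visit regions in random order, score every cluster of
the visited region by the group-mean average R² of a network fit with
the others held fixed, keep the best, and sweep until a full pass yields
no improvement. Pinned regions (`fixed=`) are never changed, supporting
repeated searches with chosen sub-regions held fixed. Candidate fits may
use a reduced iteration budget; the final selection is re-scored at the
full budget. Achieved R² is non-decreasing along the accepted trace.

## Two-source SEM scan

Candidate edges are nominated from the data by regressing every
region/cluster node on every pair of nodes from other regions (no
intercept; series are mean-removed percent change), one participant at a
time: `S_target = β1·S_source1 + β2·S_source2`. Group t-tests on each
coefficient are Bonferroni-corrected over the emitted test count
(`R·c` targets × `C((R−1)·c, 2)` pairs × 2 coefficients). Edges are
classified by the window in which they reach significance —
pre-stimulation, stimulation-inclusive (onset to end of run), or both;
window cuts follow the paradigm epochs and are configurable. The scan
proposes edges for human judgment; it never edits a network model.

## Synthetic data

* **Null datasets** — i.i.d. standard-normal values per region per
  volume, organized as repeated runs (default 10 × 5 × 40).
* **Forward-simulated network data** — `S_BOLD = M_input M_eigv L +
  noise` from a `GroundTruth` (model, D/DB, amplitudes, noise SD, seed).
  Variable latents are smoothed Gaussian processes (Gaussian kernel,
  SD 2 volumes, unit variance) plus optional paradigm-locked components;
  the smoothness stands in for the autocorrelation hemodynamics impose
  on any real latent drive, but is a fixture convention, not a claim
  about real data.
* **Voxel data** — round-robin assignment of voxels to cluster profiles
  plus Gaussian noise, with generating labels returned for recovery
  scoring.

Every generator is a pure function of its seed and parameters. Signals
are generated directly in percent-change units around zero; baseline
division, scanner physics, physiological noise structure, and motion are
not emulated. Passing tests on these fixtures demonstrate the internal
consistency and calibration of the method — they do not demonstrate that
real BOLD data satisfy the model's assumptions (linearity, single output
per region, completeness of the network).

## Problem sizes used by the packaged checks

The packaged test suite and the reproduction script use 56 null
simulations (per-dataset average R² has SD ≈ 0.008, so the mean is
determined to ±0.002), 250 resampled groups for error-rate estimates,
and 300 groups for distributional checks. These sizes give stable
verdicts for every quantity checked; larger pools shrink the
finite-pool deflation but do not change any conclusion.

## Known limitations

* Results depend on the choice of network model; the shipped 32-edge
  network includes reconstructed edges (flagged in the config) where the
  literature motivates but does not pin down the edge set.
* Gradient descent with random restarts offers no global-optimality
  guarantee; results are exactly reproducible given the seed but can
  depend on initialization ranges.
* Latent time courses and output signals need not be unique; they are
  plausible representatives consistent with the data.
* The linear, single-output-per-region model is a deliberate
  simplification; apparent connections can be mediated by regions
  outside the network.
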