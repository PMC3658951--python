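# Methods

## The problem

Affymetrix expression arrays interrogate each transcript with a probe set of
~11 PM/MM probe pairs whose positions cluster within ~600 bp of the 3' end.
When the labeling protocol runs the reverse-transcription/IVT loop twice
(two-cycle amplification, needed for nanogram-scale inputs), the measured PM
intensity acquires a strong dependence on the probe's position along the
transcript: probes near the 5' end are depressed by RNA degradation during
the long IVT incubations and by incomplete first-strand synthesis from
random primers, and probes very close to the 3' end are depressed by 3'
exonucleolytic degradation. Left uncorrected, this positional bias inflates
within-probe-set dispersion and distorts downstream summaries.

`ampbias` models the bias generatively and removes it at the probe level,
upstream of any standard preprocessing (PDNN/RMA/dChip are consumed as
downstream steps, never reimplemented here).

## The endpoint-shortening model

A transcript occupies `[0, L]` (bp), with 0 the 3' end. The surviving
fragment `[A, B]` starts at `[0, L]` and shrinks three times:

1. **Cycle-1 degradation.** `A1 ~ U[0, a]`, `B1 ~ U[L − b, L]`, with `a`
   and `b` the maximal per-cycle degradation extents from the 3' and 5'
   ends. Degradation is assumed sequence-independent and uniform up to
   these limits.
2. **Random-primer truncation.** First-strand synthesis in cycle 2 primes
   anywhere on the antisense RNA, so only the 5' side shortens:
   `A2 = A1`, `B2 ~ U[A1, B1]`.
3. **Cycle-2 degradation.** `A3 ~ U[A2, A2 + a]`, `B3 ~ U[B2 − b, B2]`,
   with the same `(a, b)` as cycle 1.

The *retaining rate* `p_i(z)` is the probability that position `z` (distance
of the probe's middle nucleotide from the 3' end) is still covered after
stage `i`. Cycle 1 has the closed form

    p1(z) = P(A1 ≤ z) · P(B1 ≥ z) = min(z/a, 1) · min((L − z)/b, 1),

the familiar ramp–plateau–ramp when `a + b < L`. Positions are treated as
continuous, accurate for transcripts beyond a few hundred bp.

For cycle 2, conditioning on `(A1, B2)` makes the two final endpoints
independent uniforms, so

    p2(z) = E[ clip((z − A1)/a, 0, 1) · clip((B2 − z)/b, 0, 1) ].

The inner average over `B2 ~ U[A1, B1]` has a closed-form antiderivative
(the clamped ramp integrates piecewise-quadratically), leaving a smooth 2-D
integral over the independent uniforms `(A1, B1)` that we evaluate with the
trapezoid rule at step `max(1 bp, L/2000)` by default. Halving the step
changes values by well under 1e-3 at the defaults; an optional convergence
check re-evaluates at half the step and warns beyond a tolerance. An
independent Monte-Carlo route (simulate trajectories, count coverage;
default 1e6 trajectories, seeded) serves as the oracle in tests: the two
routes agree within ~1e-3 everywhere at reference parameters.

Model facts the implementation relies on and the tests assert:

* `p2(z) ≤ p1(z) ≤ 1` pathwise (`A3 ≥ A1`, `B3 ≤ B1`);
* `p1(0) = p1(L) = p2(0) = p2(L) = 0`;
* as `a, b → 0`, only the random-primer truncation survives and
  `p2(z) → 1 − z/L` — pointwise for `z > 0` but not uniformly: the
  convergence breaks down in an `O(a + b)` boundary layer at the 3' end
  (where `p2` must still vanish), so the limit is checked on
  `z ≥ 2(a + b)`;
* fully degraded fragments (`B3 < A3`) have positive probability and simply
  cover nothing; they are never resampled.

**Short transcripts** (`a + b ≥ L`): the plateau vanishes and some cycle-1
fragments are already empty. The product form of `p1` remains valid; in the
trajectory sampler an empty fragment collapses (`B2 := A1`) and covers
nothing downstream; in the quadrature the `B1 ≤ A1` region contributes 0.
Constructing `DegradationParams` in this regime warns but proceeds.

## Probe-level correction

Observed intensities follow the linear model

    PM_i = IPS · p(z_i) + ε_i,    ε_i ~ N(0, σ²) i.i.d. within a probe set,

with `IPS` the ideal (unbiased) probe-set intensity. Under Gaussian noise
the MLE equals the least-squares solution

    IPS = Σ_i PM_i p(z_i) / Σ_i p(z_i)²,

computed per probe set per sample, with no sharing across samples. A
negative estimate (noise-dominated sets) is clamped to 0 and flagged. The
reported `residual_scale` is the RMS of `PM_i − IPS·p(z_i)`.

Two per-probe correction modes:

* **mle-residual** (default): `PM_i' = IPS + (PM_i − IPS·p(z_i))` — puts
  back the lost expected signal and carries the raw residual unscaled.
  Within-set dispersion collapses to the noise scale regardless of how
  small `p(z_i)` is. Negative outputs are clamped to 0 and flagged.
* **invert**: `PM_i' = PM_i / max(p(z_i), p_floor)` — the noise-free
  inversion of the model. The floor (default 0.05) bounds noise
  amplification where the retaining rate is tiny, but floored probes stay
  under-corrected and remain downward outliers within their set.

We made mle-residual the default after measuring both at reference scale:
inversion with the floor reduces the median per-probe-set CV only modestly
(≈0.64 → 0.61) because 3'-proximal probes with `p < p_floor` cannot be
fully restored, whereas the residual mode reduces it to the noise scale
(≈0.64 → 0.09) and preserves the clear separation from the curve-adjustment
baseline that motivates the model in the first place. Inversion remains
available (`mode="invert"`) for users who want strictly multiplicative
corrections. MM intensities, when present, are corrected with the same
retaining rates — the rate is a property of the transcript position, not of
probe chemistry.

Guard rails: sets whose retaining rates all sit at/below `p_floor` are
passed through flagged `uncorrectable`; sets with fewer than 3 probes above
the floor pass through flagged `too_few_probes`. All correction happens on
the linear intensity scale; log transforms belong downstream. Saturation,
background and cross-hybridization are out of scope (hand off to PDNN/RMA).

## Fitting the degradation limits

`(a, b)` are global per labeling protocol, not per transcript. The fit
matches the observed mean-PM-by-position profile (present probe sets,
positions rounded to integer bp, window 12–577 bp by default, normalized to
unit mean) against `c · p2(z)` over a grid of `(a, b)` candidates, with `c`
the per-candidate least-squares scale; the SSE minimizer wins, ties broken
toward smaller `a`, then smaller `b`. The default grid spans 100–500 bp for
`a` and 50–450 bp for `b` in 50-bp steps; quadrature step 2 bp. The fit is
deterministic and takes about a minute at the default grid. Flat or empty
profiles raise a fit error rather than returning an arbitrary corner.

## Curve Adjustment baseline

The comparator that motivates the model: pool probes across samples, take
the mean PM per integer position in 12–588 bp, lowess-smooth (fraction 0.3
— the choice is conventional, since mean profiles at ~100 probes/position
are already fairly smooth), normalize the smoothed values to unit mean, and
multiply each probe's PM by the reciprocal of the normalized value at its
nearest tabulated position. Probes outside the window pass through flagged.

CA flattens the *mean* profile by construction but has no per-set notion of
ideal intensity, so it cannot reduce within-set dispersion the way the
model correction does: on reference synthetic data CA's median-CV reduction
is ≈0.06 versus ≈0.55 for the model. Two systematic lowess artifacts are
worth knowing: (i) at the steeply curved 3'-end ramp the smoother is biased
high, so the edge weight (~7) underestimates the true correction (~300 at
z = 12) and recomputed second-pass weights deviate from 1 by up to ~6%
around z ≈ 100 at any sample size; (ii) the deep 3'-end dip drags the
window mean down, so the 5'-edge weight sits below 1 even though the
profile declines there relative to its peak.

## qPCR degradation proportion

Amplicons tiled along a transcript are assayed in a pre-amplification
reference (PAM) and in amplified samples (OCS/TCS). With replicate CTs
averaged first, relative expression per amplicon is `R = 2^(−ΔCT)` against
the reference (one extra cycle = half the template; amplicon-specific
efficiencies cancel through the reference), and the degradation proportion
is `DP = 1 − R / max(R)`, clamped to [0, 1]. All amplicons tied at the
maximum get DP exactly 0. DP is invariant to adding a constant to a
sample's CTs. Primer design, dissociation QC and efficiency calibration
beyond the 2^(−ΔCT) form are out of scope.

## Evaluation statistics

* **CV**: sample sd (n−1) over mean of a set's PM values, linear scale;
  undefined (flagged NaN) below 2 probes or at non-positive mean.
* **Paired Wilcoxon**: one-sided signed-rank test that CV decreased,
  zero differences dropped; exact null up to 25 pairs, normal approximation
  with continuity correction above. With ~20,000 nearly-all-positive
  differences the p-value underflows double precision and is reported as 0.
* **Correlation/clustering**: Pearson between sample columns of a
  probe-set × sample summary matrix; agglomerative clustering at distance
  `1 − r` with average linkage (the common microarray convention; both the
  distance and linkage are configurable), dendrogram emitted as Newick.
  SciPy's linkage breaks equal-distance merges by lowest cluster index, so
  results are deterministic.

## Synthetic data generator

The generator draws datasets from the model's own generative direction so
every other module is testable without array downloads. Reference
conditions (the defaults): 20,000 probe sets × 11 probes, `L = 1000` bp,
positions uniform on [12, 600] bp from the 3' end (mimicking real designs'
3'-concentration), true intensities log-normal (log2 mean 8, sd 1.5),
`a = 300`, `b = 200`, Gaussian noise, negatives truncated at 0 and flagged.
Probe positions are drawn once per set and shared across samples, as on a
physical chip. Two noise models: `constant` (default; per-set
sd = 0.1 · IPS, the model's literal homoscedastic assumption) and
`proportional` (sd = 0.1 · IPS · p(z), closer to real chips' signal-scaled
noise). Replicate-group designs multiply per-set intensities by per-group
log2-normal effects (sd 1.0 by default); replicates differ by noise only.

What the generator does *not* emulate — and hence what passing tests do not
establish about real arrays: cross-hybridization, MM binding chemistry,
chip saturation, sequence/GC-dependent degradation speeds, and
transcript-length variation (fixed `L` by default). Recovery results on
synthetic data are best-case statements about the estimator under its own
model.

A calibration fact worth recording: under the constant noise model the
IPS estimator's sampling sd is `0.1·IPS / sqrt(Σ p(z_i)²)`; at the
reference position distribution `Σp² ≈ 0.9`, giving a median relative
error of ≈7% — the intrinsic accuracy limit at these conditions, matched
by measurement to within 1%. Under proportional noise the median error is
≈2.5%.

## Problem sizes used in the checked examples

The test suite exercises reference scale where the claim depends on it
(20,000 probe sets for CV/recovery statements; 1e6 trajectories for the
Monte-Carlo oracle at 50 grid points × 3 parameter settings) and ~2,000
sets elsewhere, keeping the full suite under two minutes. The
reproduction script regenerates its dataset at full reference scale from
the supplied seed on every run.

## Known limitations

* Degradation is modeled as uniform-endpoint and sequence-independent; GC
  content and secondary structure are known to modulate decay and are not
  captured.
* The closed-form piecewise expression of the third-shortening joint CDF is
  not reproduced symbolically; `p2` is a numerical contract validated
  against simulation.
* `(a, b)` are fit from the pooled mean profile; transcript-specific or
  sample-specific degradation is averaged over.
* Binary CEL/CDF parsing is deliberately excluded; an external converter
  must produce the long-format TSV.
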