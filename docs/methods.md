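# Methods

This note records the models, algorithms and numerical conventions the
package implements, the open design choices that were made, and what the
synthetic-data tests do and do not demonstrate about real data.

## Data model

A SEC-SAXS run is held as an n_q × n_t matrix I(q, t) with a matching σ
matrix, one shared strictly-increasing q grid (Å⁻¹) and strictly
increasing integer frame ordinals. Frames are columns; chromatograms
I_q(t) are rows. Transposition is pure reindexing — no interpolation —
so the round trip is bit-exact. Frame files are 3-column whitespace
ASCII (q, I, σ); a missing σ column is an error unless the caller opts
into the fill rule σ = k·sqrt(max(I, floor)), because beamline-provided
uncertainties should normally be present. Two grids are "the same" when
they agree to a relative 1e−8 — grids from one detector geometry differ
only by formatting. Frame order comes from the trailing integer in each
filename (overridable by passing the list in manifest order).

Noise-only chromatograms can be trimmed by a mean signal-to-noise
threshold (mean over frames of I/σ, default 1.5). This rule is this
package's own criterion for "contains only noise"; it is deliberately
simple and is reported (dropped q values listed) rather than silent.

## Longest-run similarity statistics

Two curves on one grid are compared through C, the length of the longest
run of same-sign differences. Under the null hypothesis that the curves
differ only by independent symmetric noise, each difference is a fair
sign, and

P(longest run ≥ C among n signs) = 1 − A(n, C−1)/2ⁿ,

where A(n, k) counts binary sequences of length n with no run longer
than k: A(n, k) = 2·(number of compositions of n into parts ≤ k),
computed by an integer recursion and divided as an exact integer
complement — one float division at the end, so the test suite can demand
*equality* with exhaustive 2ⁿ enumeration for n ≤ 16. Exact zero
differences break runs and belong to none; identical curves therefore
give C = 0 and P = 1 exactly.

Comparisons are restricted to q ≤ q_max_cutoff (default 0.05 Å⁻¹, the
information-rich region) and optionally subsampled by a stride; the null
sample size n is the number of points actually compared, after cutoff
and stride. Stride exists because wide beam footprints correlate
neighbouring detector pixels, which inflates run lengths; subsampling
every other point restores the independent-sign null in the common case
where the correlation length is about one pixel.

Pairwise maps colour each pair green (P ≥ 0.05), yellow (0.01 ≤ P <
0.05) or red (P < 0.01). With the Holm–Bonferroni step-down adjustment
the same three colours are assigned from the step thresholds: red =
rejected by the Holm procedure at level 0.01, yellow = rejected at 0.05
but not 0.01. (The exact bookkeeping behind the original tool's adjusted
colouring is not published; this reconstruction is the natural one and
is flagged here for anyone reconciling outputs.) Red clusters are
maximal 4-connected components of red cells in the full symmetric map,
diagonal excluded; class percentages are over the m = n(n−1)/2 pairs.
The run-test null is discrete, so the actual probability of "red" under
the null is the largest achievable level below 0.01 — e.g. 0.60% at
n = 60 — not 1%; tests that bracket observed red fractions use the exact
discrete level, with a margin that allows for the variance inflation
caused by pairs sharing frames.

## Integral baseline correction

Model: each exposed frame deposits material on the capillary in
proportion γ(q) to the sample scattering during that frame, deposits are
never removed, and buffer/instrument background do not deposit. The
spurious baseline is then

B(q, t_k) = B(q, t_{k−1}) + γ(q)·[I(q, t_{k−1}) − B(q, t_{k−1})],  B(q, t_0) = 0,

and its end level must match I_BL(q), the mean intensity over the final
steady-state window [t_s1, t_sm] where only buffer (plus accumulated
deposits) flows. The correction is computed per q by fixed-point
iteration: given the current baseline B_i, form the signal estimate
s_i = I − B_i over the elution region (first frame up to t_s1), set
γ_i = I_BL / Σ s_i, rebuild B_{i+1} as the running sum of γ_i·s_i
(shifted by one frame, held constant at I_BL past t_s1), and stop when
max|B_{i+1} − B_i| ≤ ε (default 0, meaning run to the iteration cap
unless the baseline repeats exactly; cap default 5). The true baseline
is a fixed point of this map by construction: on noiseless
forward-simulated data the iteration recovers B and the clean signal to
machine precision. Convergence slows as the total deposit grows — for
γ·(elution length) of order one, ~40 iterations are needed for 1e−6
recovery, so quantitative studies should raise `max_iter`; the default
cap of 5 is sized for interactive use, where mild fouling converges in a
handful of iterations.

Guards and conventions: if I_BL ≤ 0 no correction is needed (zero
baseline, zero iterations). If the signal integral S_i is non-positive —
typical at high q where the signal vanishes — subtracting would *add*
intensity; the row is skipped, flagged, and written with the `0s`
filename suffix. The chromatogram fed to the baseline computation is
Gaussian-smoothed first (normalised kernel over 7 points by default,
σ = (points−1)/6, edge renormalisation) to stop the iteration chasing
noise oscillations, but the subtraction is always applied to the raw
data and σ is never modified.

The steady-state window is found by two sliding-window indicators
(window default 20 frames): (1) the average red-cluster size of the
window's pairwise P-value map, compared with the same statistic over all
equal windows of a buffer-only data set (candidate when within the
buffer mean + 1 s.d.); (2) the windowed mean ± s.d. of the per-frame
cumulative intensity over q ≤ 0.05 Å⁻¹. The chosen region is the latest
contiguous run of candidate windows, and within it the window with the
smallest indicator-2 s.d. (the flattest). The suggestion is "integral
baseline" when the minimum windowed cumulative intensity stays above
zero (material remained on the capillary), otherwise "none/linear". A
linear tool (line through two anchor windows) is provided for simple
drift; it is not suitable for fouling.

## Peak shapes

All shapes use a0 = area, a1 = center, a2 = width on the frame axis
(dimensionless frame index; seconds are metadata). The EMG is the
Gaussian ⊗ one-sided-exponential convolution with time constant a3
(first moment a1 + a3; a3 < 0 mirrors to a fronting peak), evaluated via
erfcx where the erfc argument is non-negative — the exponent then
collapses to the plain Gaussian one — and via the direct expression
where it is negative, whose exponent is provably ≤ −a2²/(2a3²): no
overflow anywhere, down to |a3|/a2 = 1e−3 and 50 widths into the wings.
|a3| < 1e−4·a2 routes to the Gaussian limit to avoid cancellation. The
GMG is the Gaussian ⊗ half-Gaussian convolution (a skew-normal density):
its mean is a1 + a3·√(2/π) and its second central moment is
a2² + a3²(1 − 2/π) — the half-Gaussian leg contributes less than a3²
because half of its mass sits at the mean. The EMG+GMG hybrid is the
equal-weight average ½EMG(a3) + ½GMG(a4) sharing one (a0, a1, a2); other
affine combinations exist in commercial packages and the ½–½ convention
is flagged for anyone reconciling parameter values across tools. All
four shapes are non-negative and integrate to a0 (verified by adaptive
quadrature to 1e−6 relative in the tests).

## Decomposition

The physical assumption: each eluting species has *one* elution profile,
scaled at each q by its form factor. Hence one peak family per species
with center, width and distortions shared across every chromatogram, and
a free non-negative amplitude (area) per (q, family). Distortions are in
addition tied across families by default — the column–matrix interaction
mode is assumed common to all species — and can be released.

Fitting is weighted (1/σ) least squares with `scipy.optimize.least_squares`
(trust-region reflective, box bounds, Jacobian column scaling). Because
the model is linear in the amplitudes, they are eliminated: at every
trial value of the shared parameters the per-q amplitudes are re-solved
by non-negative linear least squares, and only the shared parameters are
iterated (variable projection). This keeps the optimisation dimension at
2N + distortions regardless of how many chromatograms are fitted, and
guarantees the global fit never ends above its initialisation. Center
crossings are forbidden by bounding each center inside the midpoints to
its neighbours (family identity must be stable); widths are positive;
fit limits default to excluding the first and last 5% of frames, where
chromatograms are noisiest.

The EMG+GMG hybrid has a known soft direction trading a3 against a4 and
the widths: two distortion assignments can describe one data set almost
equally well. `global_fit(distortion_starts=...)` therefore accepts a
deterministic grid of distortion starting values and keeps the
lowest-cost solution; there is no random restarting, and results are
reproducible given the inputs. The demo layout uses strongly tailed
peaks sampled over 800 frames precisely so that every shared parameter
is statistically identifiable at 1% noise (Fisher-information s.d.
≤ 0.7% of each parameter value); with weak skew the distortions of this
hybrid are *not* individually identifiable at realistic noise, and the
fit quality — not the parameter values — is then the meaningful output.

SVD of the frame matrix suggests the component count via the largest
gap ratio in the singular spectrum, advisory only: species near the
noise floor (the demo's faintest is) may or may not clear a knee
heuristic, and the choice stays with the user.

Per-q goodness of fit is reported as reduced χ² and the longest-run P
value of data vs fit inside the fit limits. Back-generated frames assign
intensity = family shape × per-q amplitude; experimental σ is reassigned
unchanged, and optionally a fraction of the local |data − total fit|
discrepancy — apportioned by the family's share of the total model
intensity at that point — is added in quadrature. The fraction has no
published default and is a required explicit choice.

## Concentration channel

The trace keeps its native time base and is shifted and linearly
interpolated onto the frame grid (a cross-correlation lag suggestion is
provided; it is only reliable when the reference chromatogram has a
composition similar to the trace). The trace is decomposed with the
SAXS-optimised peak set: centers bounded to ±2% of the SAXS values,
widths fixed by default (widths and distortions are strongly coupled;
the SAXS shapes are the reference), distortions and areas free,
unweighted residuals on an absolute scale since traces rarely carry σ.
Band broadening between the concentration and SAXS detectors is then
corrected by *reshaping*: each concentration family adopts the SAXS
family's shape with its own fitted area (area conservation is a copy,
hence exact). Per-frame concentrations follow as signal/(E·path) with E
in ml·mg⁻¹·cm⁻¹ and a 1 cm default path (dn/dc plays E's role for RI
detectors). Note the intended circularity: frames normalised by
*reshaped* concentrations superimpose essentially exactly, because both
sides then carry the same shape — the reshaped route makes the
per-frame mass artificially constant, which is precisely its purpose.
With overlapping broadened peaks the fitted per-family areas can
redistribute between neighbours (the total is conserved); on
well-separated peaks they are recovered to 0.1%.

## Scattering analysis

Guinier: weighted linear regression of ln I on q² with σ_lnI = σ/I;
R_g = √(−3·slope), I(0) = exp(intercept), parameter s.d. from the
weighted-regression covariance (verified honest by Monte Carlo). The
automatic upper limit iterates q_max ← limit/R_g until q_max·R_g ≤ 1.3
(a community convention; configurable). A positive slope is flagged
unphysical rather than returned as a number.

Rambo–Tainer mass: V_c = I(0)/∫₀^0.2 q·I dq (trapezoid), the unmeasured
low-q gap filled with the fitted Guinier form from q = 0; Q_R = V_c²/R_g;
M = (Q_R/0.1231)^1.0 Da with the published protein calibration, reported
in kg·mol⁻¹. Warnings are issued when the grid stops short of 0.2 Å⁻¹
or the limit is changed. The absolute-scale mass is
M = I(0)·N_A/(c·Δρ_M²) with Δρ_M = r_e·(3.22×10²³ e/g − ρ_solvent·v̄),
defaults v̄ = 0.735 ml/g and 334 e/nm³ for aqueous buffer.

Fit score: χ = sqrt(Σ((I_exp − s·I_calc)/σ)²/(n−1)) with the closed-form
optimal scale s, and r_σ = RMS of σ (plain mean available as an option —
both make the product invariant; RMS is the default). The product χ·r_σ
is exactly invariant under global σ rescaling, i.e. independent of a
data set's overall noise level, which is what makes it comparable across
data sets. NNLS model combination solves the σ-weighted non-negative
problem and also reports the single best curve by χ·r_σ, with weights
renormalised to percentages.

## Synthetic data

The generator builds I(q,t) = Σ_s F_s(q)·peak_s(t) + B*(q,t) + noise with
the fouling recursion B*(q,t_k) = B*(q,t_{k−1}) + γ·s(q,t_{k−1}) — the
same physics the baseline algorithm assumes, which is the point: the
acceptance protocol is parameter recovery under the stated model. Form
factors are Guinier spheres (exact Guinier behaviour everywhere) or
homogeneous spheres (realistic decay with minima); noise is Gaussian
with σ = a·I + b·max I (defaults a = 0.01, b = 1e−3), emulating
counting-statistics heteroscedasticity, with a Poisson option. Buffer
frames are zero-mean noise at the floor σ; an optional moving-average
kernel along q (width 2 by default when enabled) imposes the
adjacent-pixel correlation of a wide beam footprint — lag-1 correlation
1/2, zero at lag 2, so stride-2 sampling decorrelates it exactly. The
concentration channel applies a Gaussian band-broadening kernel and a
transport lag.

What the passing tests do *not* show about real data: fouling that
violates proportionality or cleans the capillary; species-dependent γ
(the API reserves the extension, nothing fits it); detector artefacts
beyond the σ model; elution shapes outside the four implemented
families; and the SVD-subspace denoising route, which is out of scope.

## Problem sizes

The shipped validation protocol uses 500-frame noiseless fouling
simulations, 60×60-frame buffer maps, a 120-q × 800-frame four-species
surface with a 40-chromatogram global fit, and 200 Guinier Monte-Carlo
replicates — sizes chosen so the whole protocol runs in seconds on one
CPU while every estimator operates well inside its asymptotic regime.
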