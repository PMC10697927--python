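# Methods

## The problem and the model

A heart VOI in mouse PET mixes several tissue signals: left- and
right-ventricular blood, myocardial uptake and, depending on VOI placement,
hepatic spill-over. Each tissue has a characteristic time-activity curve
(TAC), so the voxel-TAC matrix `Z` (frames × voxels) is, to good
approximation, a non-negative mixture `Z ≈ G H`: `G` holds the tissue TACs,
`H` the per-voxel tissue weights. The package factorizes `Z` under
non-negativity and reads the left-ventricle input function off the voxels
dominated by the blood-pool component.

NMF converges to a local optimum, so initialization matters. The chain used
here — PCA to the target rank, symmetric (ZCA) whitening, then non-negative
ICA by rotation descent — produces a non-negative, already-unmixed starting
point. Two conventions are fixed deliberately:

* the covariance eigenvectors are computed from centered data, but the
  reduction `x = BᵀZ` and whitening `z = Mx` are applied to the *uncentered*
  data: non-negativity of the sources lives in the uncentered geometry, and
  cov(`Mx`) is the identity regardless;
* each eigenvector's largest-magnitude entry is made positive, which makes
  the whole chain bit-reproducible across platforms.

Non-negative ICA minimizes `J(W) = mean(min(Wz,0)²)` over orthogonal `W` by
geodesic steps `W ← exp(−μ T) W` along the torque
`T = (y⁻ yᵀ − y y⁻ᵀ)/N`; μ is halved on objective increase and grown 50%
after acceptance, so the recorded objective never increases. The theory
assumes uncorrelated, "well-grounded" sources (positive probability mass
near zero). Spatial tissue maps with disjoint support are mildly
*anti*-correlated, so the rotation cannot reach the exact sources; this is
precisely why the NMF refinement — which is not restricted to rotations —
follows, using Lee–Seung multiplicative updates (monotone in the Frobenius
error; zero factor entries are absorbing, hence zero-component initializers
are rejected).

A residual, data-dependent limitation remains: when two tissue TACs are
proportional over part of the scan (e.g. near-identical recirculation
tails), exact factorizations form a continuum and the component TACs in `G`
can carry a few percent cross-contamination. Region TACs are therefore
computed as plain averages of the measured TACs of voxels with relative
probability `r_ij = h_ij/Σ_i h_ij > 0.9` (strict), which preserves both
shape and absolute scale; on the separable phantom these averages recover
the truth exactly even where `G` columns saturate at r ≈ 0.99.

### Component labeling and model order

Labels follow cardiac transit: among non-hepatic components, the earliest
peak is RV, then LV, then MYO (three remaining) or LV then MYO (two
remaining); any other remainder is labeled unknown with a warning. The
hepatic signature is a peak in the final third of the scan *or* late
activity (last 3 frames) more than twice the early activity (frames 2–5) —
a threshold chosen from the qualitative shape of hepatic uptake curves and
exposed as code, not config, since it only gates an optional label. Peak
ties break toward the earlier activity centre of mass.

Model order is selected by decomposing with n = 2, 3, 4 in turn and
stopping when either (a) two components are redundant — identical peak
frame, or both TAC correlation *and* probability-map correlation above 0.7
(the conjunction avoids flagging genuinely distinct tissues whose late
tails correlate) — or (b) the data cannot support another component (rank
deficiency of the VOI covariance; the noise-free analogue of redundancy).
Under realistic noise the redundancy rule is conservative: a split
myocardium occupies different voxels, so auto-selection can overshoot to
n = 4; `extract_nmf_idif` then steps n down until an LV selection exists,
mirroring the practice of adjusting the component count by inspection. For
controlled comparisons a fixed n is the recommended mode.

## The phantom

The generator emulates a 32³-voxel thorax sub-volume at 0.776 × 0.776 ×
0.796 mm with the standard 60-minute framing (12×10 s, 3×20 s, 3×30 s,
3×60 s, 3×150 s, 9×300 s). Geometry: LV sphere (1.5 mm radius), RV sphere
(1.2 mm, 3 mm off-axis), myocardial shell (1.8–3.2 mm) and optionally a
hepatic slab below the heart. Compartment TACs are analytic: gamma-variate
boluses (RV peak 10 s; LV peak 20 s with a 4 s filling delay) with small,
fast-clearing recirculation tails; a delayed, broader myocardial bolus
(peak 60 s) with strong late retention; and saturating hepatic uptake.
TACs are evaluated at frame mid-times (the package-wide sampling
convention).

Rendering applies an isotropic Gaussian PSF of 1.2 mm FWHM — the
resolution regime of resolution-modeled small-animal OSEM reconstructions;
at markedly worse resolution the central LV voxels' true blood fraction
drops below the 0.9 selection rule and no pure blood-pool voxels exist, so
the PSF width is the knob that controls task difficulty — and adds Gaussian
noise with σ = noise_scale · sqrt(activity / frame duration), the standard
surrogate for count-limited reconstruction noise (longer frames are
quieter). noise_scale defaults to 0.7, i.e. ≈5% relative noise at the LV
peak in 10 s frames.

What the phantom does *not* emulate: correlated (reconstruction-kernel)
noise, spatially variant resolution, attenuation/scatter residuals, cardiac
and respiratory motion, and myocardial-to-blood activity ratios specific to
any real tracer. Passing tests therefore demonstrate correctness of the
algorithms and the claimed orderings under controlled mixing, not clinical
performance. One deliberate exaggeration: the myocardial shell occupies
most of the VOI volume, so the threshold baseline's reference frame and
voxel selection are myocardium-dominated and its bias is larger than
typically seen in vivo; the comparisons here are directional, not
effect-size calibrated.

## Blood correction

Population-based, per anesthesia condition: ordinary least squares for the
plasma/whole-blood ratio (clipped at zero on prediction) and a decreasing
four-parameter logistic `pf(t) = floor + (ceiling−floor)/(1+(t/midpoint)^s)`
for the parent fraction, fitted by bounded least squares with a
grid-plus-jitter multi-start over midpoint and steepness. The
parameterization (floor, then ceiling as floor + (1−floor)·b with
b ∈ [0,1]) makes 0 ≤ floor ≤ ceiling ≤ 1 structural. The corrected input is
the pointwise product wb(t)·ratio(t)·pf(t) evaluated analytically at frame
mid-times.

## Kinetics

The reversible 2TCM is solved analytically: the tissue response is the
plasma input convolved with `φ₁ e^{−θ₁t} + φ₂ e^{−θ₂t}`, where θ₁,₂ are
the roots of `s² − (k2+k3+k4)s + k2k4` (a repeated root is nudged by 1e-9
rather than special-cased). The input is linearly upsampled to a 1 s grid
anchored at zero activity at injection, and each exponential convolution is
evaluated exactly for piecewise-linear input via a first-order recursion
(`scipy.signal.lfilter`), so one model evaluation is O(n) and matches stiff
ODE integration to ~1e-6 % (tested). Rates are per minute internally;
seconds at all I/O boundaries.

Fitting is bounded nonlinear least squares in log-parameter space
(K1 ∈ [1e-3, 5] mL/cm³/min, k2..k4 ∈ [1e-4, 10] /min) with five seeded
starts (one heuristic, four log-uniform); the best SSE wins and a
convergence flag is carried. Weights are uniform by default (matched to
the constant-variance noise used in the validation experiments), with
optional sqrt-frame-duration weighting. The blood-volume fraction vB is 0
by default and can be fitted in [0, 0.2]. No delay or dispersion
correction is applied between input and tissue.

V_T = K1/k2·(1+k3/k4) is only reported for k2, k4 > 0. Goodness of fit is
wsMAPE, weighting each frame's symmetric percentage error by the frame
duration so long late frames are not drowned out by the many short early
ones.

## Numerical choices and degenerate inputs

* NMF/nnICA: max_iter 500, tol 1e-6 (relative objective/error decrease);
  the seed is a required argument of every stochastic routine.
* Voxel matrices clip small reconstruction negatives to zero and record the
  clipped mass; all-zero voxels are flagged degenerate and excluded from
  probability-based selection.
* VOI membership: voxel centre within the sphere radius (≤), voxel centres
  at (index + 0.5) · spacing from the grid corner; frame timing always in a
  CSV sidecar, never the NIfTI header.
* Empty region selections raise with a remedial hint (lower r-threshold or
  fewer components) rather than returning silent empties.

## Validation experiments and problem sizes

The shipped experiments use the 32³ phantom (360 VOI voxels, 33 frames),
10 noise replicates for the ordering comparisons, 20 random parameter sets
for the oracle check, and 50 noisy fits (noise 1–3% of the tissue peak)
for V_T recovery — sizes at which every conclusion is stable across seeds
while the full suite and the acceptance script each finish in a couple of
minutes. The contaminated-input experiment replaces the plasma curve with
0.7·LV + 0.3·MYO, the mixture a 30% myocardial spill would produce, and
reproduces the expected direction: fitted V_T drops in essentially all
replicates.

## Known limitations

* The automatic component count is a heuristic; cross-validated order
  selection is out of scope.
* G-column TACs can carry small cross-contamination when tissue TACs are
  partially collinear (see above); always use the voxel-average region
  TACs, as the API does.
* The 2TCM fit does not model delay/dispersion, and with an input function
  whose late tail is near zero the V_T of slow compartments (1/k4 longer
  than the scan) is identifiable only to a few percent even at low noise.
* Real anesthesia-dependent physiology (the motivation for separate
  correction models per condition) is represented only through
  configuration, not simulated.
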