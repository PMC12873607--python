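# Methods

## The measurement being modeled

Fast live-cell single-particle tracking (SPT) of a Halo-tagged nuclear
protein: molecules are sparsely labeled, imaged with inclined (HiLo)
illumination at a ~10 ms frame interval with 0.16 µm pixels, localized
frame by frame, linked into trajectories, and the distribution of 2D jump
lengths at several time gaps is fit with a small mixture of diffusive
states. The headline outputs are the fraction of molecules in the
near-immobile ("chromatin-bound") state, F_bound, and the diffusion
coefficients of the slow and fast freely diffusing states, D_free1 and
D_free2 (µm²/s), reported per cell and compared across conditions.

## Jump-length mixture model

For a molecule in state s with diffusion coefficient D_s, the observed 2D
displacement r over a time gap Δτ follows

    p_s(r) = r / (2 (D_s Δτ + σ²)) · exp( −r² / (4 (D_s Δτ + σ²)) ),

a Rayleigh density whose per-axis variance 2(D_s Δτ + σ²) is inflated by
the localization error σ. The data density at each Δτ is a two- or
three-state mixture of these. Model densities are computed as exact bin
integrals (differences of the per-state CDF across the 0.01 µm bin edges,
divided by the bin width), which makes the discrete normalization exact and
matches how the empirical histogram represents its density.

Bounded least squares is run jointly over all non-empty time gaps
(Δτ = 1..7 frames). Diffusion coefficients are constrained to
non-overlapping boxes (three-state: D_bound ∈ [1e-4, 0.05],
D_free1 ∈ [0.05, 1], D_free2 ∈ [1, 10] µm²/s; two-state:
D_bound ∈ [1e-4, 0.5], D_free ∈ [0.5, 10]); fractions are parameterized by
stick-breaking so they sum to one by construction; σ is fitted within
[0.01, 0.075] µm by default (the acquisition does not pin it down a
priori), with a fixed-σ mode available. Ten seeded restarts (one heuristic
start, the rest uniform in the bounds) guard against local minima; two
restarts are ample for routine per-cell fits and are used in the
large-batch analyses.

**Bin weighting.** Residuals are scaled by the inverse counting noise,
1/√max(p̂_b, p_floor) with p̂_b the observed per-bin probability and a
fixed relative floor of 10 % of the uniform probability. With unweighted
densities, the near-empty tail bins are so cheap that a phantom fast
component (~10 % weight at D ≈ 10 µm²/s) can absorb the noise floor — a
pure-bound simulation then fits with F_bound ≈ 0.89. Weighted, the same
data recover F_bound ≥ 0.99, and three-state recovery is unchanged or
better. Because the weights depend on densities only, the fit is invariant
to a global rescaling of histogram counts. The reported `residual` remains
the plain sum of squared density errors, so it is comparable across
weighting choices.

## Defocalization (axial censoring) correction

Fast molecules leave the ~0.7 µm axial detection slice between frames, so
raw histograms under-represent them at long Δτ. The correction rescales
each free state's mixture weight at each Δτ by the probability that a
molecule of that mobility, started uniformly inside the slice, has not
crossed either slice boundary by Δτ. That probability is computed from the
absorbing-boundary image-series solution (alternating Gaussian-CDF images,
truncated at 1e-10) averaged over the start depth with 64-point
Gauss-Legendre quadrature; it is exact to ~1e-9 and vectorized over (D, Δτ).
The attenuation is applied to all states (it is ≈ 1 for the bound state)
and the mixture is renormalized per Δτ, so only relative weights matter.

The independent check is a Monte-Carlo walker oracle. Because discrete
position checks miss within-step crossings (a ~0.02–0.05 bias in survival
at 100 substeps — larger than the quantity's useful precision), the walker
update includes the exact Brownian-bridge first-passage probability between
checks: for endpoints inside the slab the probability of having crossed a
boundary b between checks is exp(−2(b−z₀)(b−z₁)/(2DΔt)), and the two
boundaries combine additively. With the bridge draw the oracle is unbiased
for the continuous first-passage problem; analytic and Monte-Carlo values
agree to ≤ 0.001 at 1e6 walkers across D ∈ [0.01, 10] µm²/s and
Δτ ∈ [10, 70] ms. The discrete-only mode is kept as an option.

## What the trajectory generator emulates

Each labeled molecule is assigned a state once (the fitted model is a
static mixture; Markov switching at user-supplied rates is available as a
stress-test mode only, without re-entry). It diffuses in 3D from a uniform
start in an extended axial domain (2× the slice thickness, reflecting
walls standing in for the rest of the nucleus) and is observable while it
is inside the detection slice and unbleached. Observed positions are the
true (x, y) plus isotropic Gaussian noise of 35 nm per axis. Photobleaching
lifetimes are geometric with mean 6 frames; starting frames are uniform
over a 1000-frame movie. An observed trajectory is a maximal run of frames
over which the molecule stayed in the slice *continuously* — within-frame
crossings are resolved with the same Brownian-bridge draw as the oracle —
and a molecule that exits and re-enters starts a new trajectory id (the
`molecule_id` column ties fragments together). Under this stationary
re-entry scheme the expected number of Δτ-jumps from state s is
proportional to F_s · S_s(Δτ) — exactly the survival-weighted mixture the
fit assumes — so the generator and the estimator are mutually consistent
by construction rather than by calibration.

Not emulated: camera EM gain and read noise, sub-frame motion blur,
blinking photophysics, anisotropic or anomalous diffusion, spatial
heterogeneity within the nucleus, and detection failures other than axial
censoring. Passing recovery tests therefore demonstrate correctness of the
estimator under its own model assumptions, not robustness to every
real-data artifact.

**Jump sampling and the per-trajectory cap.** The pipeline default keeps at
most the first 4 jumps per trajectory per time gap, the standard guard
against long tracks dominating histograms compiled from real tracker
output. On idealized simulated data this cap itself distorts the state
composition (bound tracks are long and get clipped ~2× harder than the
short censored fast fragments), biasing F_bound low by ~0.03–0.04, whereas
uncapped sampling is exactly model-consistent (see above). The recovery
analyses therefore use `jumps_per_trajectory=None`; the cap remains the
default for tracker output and for the contrast statistics, where the bias
is common-mode across conditions. Jumps spanning a closed gap are always
excluded (they would mix time gaps); displacements beyond the 1.2 µm
histogram range are dropped and the model is renormalized over the same
range.

## Localization and tracking

Detection is a PSF-matched Gaussian filter (σ = 1.35 px) with an amplitude
threshold at the 10^(−5) per-pixel false-positive quantile of the robustly
(median/MAD) estimated filtered-noise null; maxima closer than 2 px keep
the brighter peak. Refinement is Poisson-weighted least squares of a
fixed-width 2D Gaussian (free: x, y, amplitude, background) in a 9×9
window; candidates whose window is clipped by the image edge, or whose fit
fails or returns non-positive amplitude, are discarded. At 500
photons/spot on a background of 100 photons/px this reaches the numeric
Cramér-Rao bound (0.199 px ≈ 0.032 µm per axis). One deflation pass —
subtract fitted spots, re-detect on the residual at a 100× stricter error
level, then two block-coordinate re-fit sweeps with neighbours removed —
resolves emitter pairs down to ~2.5 px that a single matched-filter pass
merges (merged maxima are unavoidable below ~√2·2σ separation). The
benchmark protocol counts a true spot as detected when any localization
lies within 0.4 µm (a merged close pair detects both members), and
measures RMSE per axis on isolated spots (no neighbour within 4 px), the
regime in which single-emitter precision is defined.

Linking solves a per-frame-pair optimal assignment (Hungarian, squared
displacement) with a hard gate r_max(k) = √(4·D_max·k·Δt)·safety (D_max =
5 µm²/s, safety 1.0), greedy over the span k = 1, 2, 3: direct links are
assigned first, and only leftover ends and detections compete at longer
spans (up to 2 gap frames). Unmatched detections start new trajectories;
assignment is deterministic. One consequence worth knowing: a molecule
that leaves the focal slice for ≤ 2 frames and returns is re-joined by gap
closing into one trajectory, while the simulation truth splits it — the
tracker's jump counts still match the truth's because gap-spanning pairs
are excluded from histograms.

## Statistics

Group comparisons are two-sample two-tailed t-tests on per-cell values —
pooled-variance Student by default (df = n_a+n_b−2), Welch optional —
with closed-form statistics and 95 % CIs; degenerate zero-variance cases
return t=0, p=1 (equal means) or an underflow flag. Pairwise tests are
reported without multiplicity correction, matching per-panel practice; a
Holm adjustment helper is provided. Cells with fewer than 500 trajectories
are excluded before statistics (fits below that size are unstable at these
track lengths). Bimodality of a per-cell parameter is declared when a
2-component Gaussian mixture beats 1 component by BIC *and* the component
means are separated by more than 2 pooled standard deviations; both the
criterion and the separation rule are package choices, since bimodality is
otherwise a qualitative call.

Model selection between the two- and three-state fits uses BIC on the
binned least-squares objective (n = number of fitted bins). The BIC
penalty separates the two cleanly in simulation (improvement statistic
~400 on three-state data vs 0–13 on two-state data); AIC's constant
penalty of 2 per parameter mis-selects three states on roughly a third of
two-state datasets.

## Numerical and interface choices

- Coordinates: image origin top-left, x rightward, y downward, 0-based
  frames; µm and seconds everywhere except at the image boundary.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical tables.
- Trajectory CSVs carry (trajectory_id, frame, x_um, y_um, cell_id) plus
  simulation-only truth columns; trajectory ids are unique within a cell
  and tables are validated (strictly increasing frames) on read and write.
- Results bundles embed the configuration, its SHA-256 hash, the seeds and
  the package version.
- Problem sizes in the shipped analyses and checks — 20-seed recovery runs
  of ~2·10⁴ jumps, 20-cell groups of 1000 trajectories, 3·10⁵–10⁶ Monte-
  Carlo walkers — were chosen to give comfortable statistical margins on a
  single CPU within minutes.

## Known limitations

- The static-mixture fit ignores state switching within a trajectory; with
  fast exchange the recovered fractions are effective, not kinetic,
  quantities.
- The defocalization correction assumes a sharp-edged detection slice; a
  real detection profile is smooth in z, which shifts the effective dz.
- The per-trajectory jump cap, kept for parity with common practice on
  real tracker output, is biased on idealized data (quantified above).
- Fitted σ absorbs any residual static localization bias; it should not be
  over-interpreted as the instrument's true precision.
- The bimodality test assumes Gaussian components and n ≥ 10 cells.
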