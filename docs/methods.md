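# Methods

## Diffusion models

FCS autocorrelation curves are modelled with the standard Gaussian-volume
forms. The detection volume is a 3D Gaussian with lateral 1/e² waist
`wxy` and axial extent `s·wxy`; `s` (> 1) is the structure parameter. The
one-component model describes free 3D diffusion of a single species,

    G(τ) = (1/N) · (1 + τ/τd)⁻¹ · (1 + τ/(s²τd))⁻¹ᐟ²,

and the two-component model adds a slow species diffusing in 2D within a
membrane that crosses the focal volume:

    G(τ) = (1/N) · [ F1·(1 + τ/τd1)⁻¹·(1 + τ/(s²τd1))⁻¹ᐟ² + (1−F1)·(1 + τ/τd2)⁻¹ ].

The 2D term carries no axial factor because a membrane-confined diffuser
never leaves the focal plane. Amplitudes are fluctuation-normalized
(G(0) = 1/N, G → 0 at long lags); there is no triplet term, no
background-correction term and, by default, no additive offset — the model
curve is the whole curve. `F1` is an amplitude fraction: it equals a number
fraction only when the two species are equally bright, which holds for a
single fluorophore partitioning between compartments.

Diffusion coefficients come from the translational times through
`D = wxy²/(4 τd)`. The geometry is calibrated on a reference dye of known
`D` (default Atto-488, 400 µm²/s at 37 °C): the dye ACF is fitted with the
one-component model with `s` free — the only fit in which it is — and
`wxy = sqrt(4·D_ref·τd)`; `s` is then fixed for all cell fits.

FRAP recoveries are modelled with the anomalous-diffusion ("diffusion in a
crowded environment") form

    F(t) = (fd + fi·(t/m)^α) / (1 + (t/m)^α),

with `fd` the normalized fluorescence immediately after bleaching, `fi` the
plateau, `m` the half-recovery time (F(m) = (fd+fi)/2 exactly, for any α)
and `α` the anomalous exponent (α = 1 is simple diffusion-like recovery).
The mobile fraction uses the standard convention `(fi − fd)/(1 − fd)`,
clipped to [0, 1.05]. Bounds 0 < α ≤ 2 are a package choice; fitted α
values are reported but rarely well constrained by coarse time series.

## Units

Seconds and micrometres everywhere in memory. Lag axes are written and read
as milliseconds at the CSV boundary, matching instrument exports; beam
waists are reported in both µm and nm.

## Multi-tau correlator

Traces are correlated with a multi-tau scheme: 16 channels per octave by
default, mean-rebinning by two at each octave change. The estimator is
symmetrically normalized — each lag's product sum is divided by the means
of the left and right trace segments actually entering the sum — which
makes a constant trace give exactly zero and suppresses the baseline bias
from slow drifts such as acquisition photobleaching. Each channel's lag is
reported at the geometric mean of the raw-lag span it averages over (the
exact lag on the finest level). The estimator is invariant under uniform
intensity scaling. Replicate curves are averaged pointwise (the per-cell
"average of 10 × 10 s runs" workflow); the per-lag standard deviation
across replicates is attached and can weight subsequent fits.

## Fitting

All fits use bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`) with tolerances 1e-12 and a deterministic
multistart (default 8 starts) over diffusion times log-spaced between 1 µs
and 1 s. ACF fits use the lag window τ ≥ 0.01 ms by default (shorter lags
are dominated by detector artefacts in measured curves) and unit weights
unless replicate SDs are supplied. Occupancy and diffusion times are fitted
in log space; the two-component model is parameterized as
`τd2 = τd1·(1 + exp(u))`, so the fast/slow ordering is structural and no
label swapping can occur. The two-component multistart additionally
includes the one-component solution at F1 = 1, so on data with no slow
component the fit collapses exactly onto the nested model. Non-convergence
(including curves with no positive amplitude, where N is unidentifiable) is
reported via a `converged` flag rather than an exception.

Model selection fits both models and compares AIC
(`n·ln(SSE/n) + 2k`); optionally it also requires a Wald–Wolfowitz runs
test to reject randomness of the one-component residuals at α = 0.05
(structured residuals being the signature of a missing component). The SSE
entering the AIC is floored at `n·(100·ε·max|g|)²` (ε machine epsilon): on
noiseless data both models fit to machine precision and the floor makes the
ranking fall to the parameter-count penalty instead of meaningless
epsilon-scale residual differences.

FRAP normalization computes `(Ib − Bg)/(Ic − Bg)` frame by frame — the
division by the whole-cell signal cancels acquisition photobleaching
exactly when bleaching acts multiplicatively on both ROIs — then divides by
the plateau maximum, taken as the maximum of a 3-frame moving average over
the last 20% of frames so a single noise spike cannot set the scale. A
consequence of plateau normalization is that the fitted `fi` lands near 1
regardless of the underlying recovery level, so mobile fractions computed
from plateau-normalized curves saturate near 100%; mobile fractions below
100% are meaningful when the curve keeps its pre-bleach scale. The first
acquired post-bleach frame defines t = one frame interval; F(0) = fd is
extrapolated by the fit.

### Identifiability of the FRAP half-time

With 1 s frames and a 2 s half-time, only one frame precedes t½ and the
(fd, m, α) parameters trade off: Monte-Carlo at 2% curve noise shows the
global least-squares optimum itself carries ~20% median error on m. This
is a property of the sampling, not of the optimizer — the test suite
verifies both that the fit reaches the global optimum at coarse sampling
and that the median error drops below 5% once the frame interval resolves
the half-time (≈ 0.1–0.2 s frames). Half-times estimated from 1 s-frame
acquisitions of fast-recovering proteins should be read with this
uncertainty in mind.

## Synthetic data

The synthetic layer generates every pipeline input with known truth:

* **Analytic ACFs** evaluate a model on a lag grid, optionally with i.i.d.
  multiplicative Gaussian noise (constant relative noise approximates real
  correlation-curve noise well enough for estimator exercises).
* **Brownian-dynamics traces**: point emitters in a periodic cubic box
  (≥ 10 beam waists wide, so boundary artefacts are negligible), a 3D pool
  stepping isotropically with per-axis SD √(2DΔt) and a 2D pool confined to
  a flat plane at configurable z; detection through a 3D Gaussian profile
  (not a diffraction-realistic PSF — deliberately matched to the model
  equations being tested); Poisson counts with a uniform background. The
  time step equals the bin width and a warning is raised when √(2DΔt)
  exceeds 0.3·wxy. Defaults (30 fast + 15 membrane particles, 145 nm
  waist, s = 5, 10 µs bins, 60 s) represent a membrane-proximal
  measurement and run in about a minute on one CPU; the test suite uses
  these defaults for the end-to-end recovery checks and shorter traces
  elsewhere.
* **FRAP series** build the three raw intensity vectors from a recovery
  curve, an exponential whole-cell acquisition-bleaching envelope,
  a constant background and additive Gaussian read noise; by construction
  the bleach-correction ratio inverts them exactly in the noiseless case.
* **Synthetic images**: a circular cell (cytosol disc + brighter membrane
  ring) with Gaussian endosomal puncta; channel 2 repeats a configurable
  fraction of channel 1's puncta positions. ROI masks (four membrane arcs,
  whole cell, background frame) are returned alongside.

What the generators do not emulate: fluorophore photophysics (triplet
blinking, photobleaching of diffusers during FCS), non-Gaussian detection
volumes, cell-shaped geometry, vesicular or active transport, and detector
afterpulsing. Passing round-trip tests therefore demonstrates correctness
of the estimators and fits under the stated model, not robustness to every
artefact of real acquisitions.

## Image quantification

The membrane/total ratio is `(⟨membrane⟩ − ⟨bg⟩)/(⟨total⟩ − ⟨bg⟩)` with
means over pooled membrane ROIs, the whole-cell ROI and an empty-area ROI.
Background is subtracted from the ROI means (linearity makes this identical
to per-pixel subtraction). Pearson colocalization is offered plain and with
a Costes-style automatic threshold: thresholds descend along the
least-squares regression line of channel 2 on channel 1 until the
sub-threshold pixels are uncorrelated (r ≤ 0), and the coefficient is then
computed over pixels above threshold in either channel. When the search
bottoms out (e.g. anticorrelated channels), every pixel is kept and the
result equals the plain coefficient.

## Known limitations

* `F1` mixes brightness and number when species brightnesses differ.
* The AIC criterion assumes i.i.d. residuals; correlation-curve noise is
  lag-correlated, so selection on heavily averaged curves is conservative
  rather than exact.
* The Brownian-dynamics simulator's membrane is a flat infinite plane; the
  real plasma membrane curves through the focal volume.
* No global (multi-curve) fitting, no Bayesian posteriors, no
  reaction–diffusion FRAP models, no triplet/anomalous-diffusion FCS
  models, no 3D image stacks.
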