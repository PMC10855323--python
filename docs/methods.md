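# Methods

This note documents the models, numerical choices and declared
assumptions behind `cellmech`, in the package's own words.

## Contact mechanics and rheology

Spherical (parabolic) indentation of an incompressible sample gives
`F = 4√R/(3(1−ν²)) · f_BEC(δ) · E · δ^{3/2}` with `ν = 0.5` fixed.  The
tip radius is configuration, not a constant: the live-cell probe family
this pipeline targets has a nominal apex radius near 70 nm, which is the
package default, but every dataset should carry its own value.

**Bottom-effect correction.** Living cells are thin layers bonded to
glass; the semi-infinite Hertz force underestimates the constraint of
the rigid support.  `cellmech` uses the bonded-spherical-indenter
polynomial family, `f_BEC = 1 + 1.133χ + 1.497χ² + 1.469χ³ + 0.755χ⁴`
with `χ = √(Rδ)/h` (incompressible, bonded case).  The factor is ≥ 1,
tends to 1 as `h → ∞`, and raises a domain error at `δ ≥ h`.  `kind=
"none"` disables it for semi-infinite analysis.  The series is accurate
for `χ ≲ 1`; deeper relative indentations are outside its validity.

**Power-law rheology.** `E(t) = E₁ t^{−α} + η δ_D(t)`; `E₁` (Pa) is the
relaxation modulus at 1 s, `α ∈ [0, 1]` the fluidity exponent, `η`
(Pa·s) an instantaneous Newtonian term.  Pointwise evaluation excludes
the Dirac part; the Ting solver applies it as `η · d(δ^{3/2})/dt` while
the tip is in contact (centred differences per phase, so the rate
discontinuity at the turnaround is not smeared).  The Dirac term is
excluded from the t₁ equation: its weight when the Dirac sits exactly at
the integration endpoint is ambiguous, and the power-law term dominates
t₁.

## Ting solver

The hereditary integral is discretised by treating `d(δ^{3/2})/dξ` (and
`dδ/dξ` in the t₁ equation) as piecewise constant on the sampling grid
and integrating the kernel `(t−ξ)^{−α}` analytically on every
subinterval.  This handles the weak endpoint singularity exactly; no
adaptive quadrature is needed.  For retract times, t₁ is found by
scanning the node values of the unloading integral (monotone in t₁) and
solving the final subinterval in closed form — exact to the
discretisation and deterministic.  Halving the time step changes the
predicted force by < 0.1% (regression-tested), and the solver matches an
independent dense midpoint-rule oracle to < 0.5% on random histories.

At `α = 1` the kernel is non-integrable against a non-vanishing rate;
the kernel exponent is clipped at 0.999 (pointwise `E(t)` is exact at
`α = 1`).

## Per-curve processing

Units are uniform: nm, nN, Pa, Pa·s, s.  Calibration: `force = k ·
sensitivity · deflection`.

**Contact detection** (the acquisition protocol does not prescribe an
algorithm): a linear baseline is fitted to the early approach; candidate
contact indices around the first sustained excursion above 5× the noise
RMS are scored by a piecewise model (baseline, then baseline +
A·(z−z₀)^{3/2}), and the residual minimiser wins.  The contact position
is then refined continuously between grid nodes, trying both a 3/2-power
and a linear contact shape; the latter is exact for rigid (substrate)
curves, whose kink the Hertzian shape biases by ~2 nm.  Known
limitation: on soft *viscoelastic* curves the onset is shallower than
the elastic shape and detection lands ~10–15 nm early; the model fits
absorb this through their own contact-offset refinement, and it cancels
to first order in cohort height folds, but absolute heights of soft
cells carry this bias.

**Indentation history**: `δ(t) = (z − z₀) − F_corr/k`, clipped at 0,
time origin at contact, turnaround `t_m` at the piezo reversal (not the
argmax of noisy δ).  On the retract the history ends where either δ or
the corrected force returns to zero — a viscoelastic sample can remain
geometrically overlapped after the contact force vanishes, and those
samples carry no contact information.

**Hertz fit**: linear least squares for E over the indentation window
[10%, 90%] of max δ (configurable; excludes contact-region noise and
deep-indentation correction dominance), with bounded continuous
refinement of the contact offset.

**Ting fit**: the force is linear in (E₁, η) at fixed α, so the fit is a
1-d profile over α (21-point grid plus bounded refinement) with a
non-negative linear solve inside, alternated twice with a bounded
contact-offset refinement.  Deterministic, no starting-point
sensitivity.  Standard errors: linear covariance for (E₁, η) at the
optimum; profile-curvature for α.

**η is held at 0 by default** (`FitConfig.fit_eta`).  On trigger-limited
ramps the η basis function is nearly collinear with the (E₁, α) family,
and when the viscous term truncates the retract there is almost no data
to separate them: fits with η free can wander to (low α, high E₁, η>0)
solutions that match the data within noise.  Whether the original
processing ever freed η is not documented; fixing it is standard
practice and is the package default, with `fit_eta=True` available.

**Long curves** are block-averaged to ≤ 600 samples before fitting
(approach and retract separately).  Averaging, not striding: it keeps
the noise-reduction benefit of fast sampling while bounding the O(n²)
hereditary-integral cost.

## Force-volume maps

Topography is the negated contact extension, referenced to the substrate
plane (masked substrate pixels, else a lowest-decile plane fit); global
tilt correction subtracts the best-fit substrate plane and is exact for
an added plane.  Cell masks are provided or derived by height
thresholding (substrate level + 3× substrate roughness, connected
components).  The central-part filter retains exactly ⌈n/2⌉
highest pixels of each cell (ties to the lower index); peripheral pixels
are discarded because the thin, F-actin-rich cell edge does not reflect
bulk mechanics.  Cell height is the apex (maximum tilt-corrected height;
mean available via configuration).  Per-pixel sample thickness from the
topography feeds the bottom-effect correction during map fitting.

Fold changes are reported activated/control for moduli and η
("fold increase") and control/activated for height and α ("fold
decrease"), matching how activation effects are conventionally quoted.
Significance testing is delegated to standard library routines
(Mann-Whitney U), not re-implemented.

## Synthetic data: the stated world

`simulate_curve` couples the Ting forward model to the cantilever by a
quasi-static force balance `k·d = F(δ = z − z₀ − d)` solved per sample
(fixed-point; a bracketed root for the elastic fast path).  Cantilever
dynamics are neglected — at 183 µm/s these ramps are quasi-static for
cells.  Acquisition defaults follow the stated protocol: 3 µm ramp,
183 µm/s piezo speed, 0.1 N/m spring constant, 1 nN trigger (upper end
of the stated 0.5–1 nN range).  The 100 kHz sampling rate (1.83 nm
z-steps) is a package choice within the realistic capture-rate range of
fast-force-volume instruments.  Baseline offset/tilt and seeded Gaussian
force noise are added after generation.  On thin pixels the indentation
is capped at 90% of the local thickness; beyond it the compressed layer
"bottoms out" and residual travel loads the cantilever as a hard wall.

Phantom cells are spherical caps on a rigid substrate (per-pixel
thickness drives the correction; substrate pixels are perfectly rigid).
Cohort presets (`presets.yaml`, provenance-tagged per value):

- M1 modulus distributions are log-normal with linear-space mean ± sd of
  2.8 ± 1.09 kPa (control) and 6.92 ± 2.87 kPa (activated) — printed
  values.  M2 moduli are declared assumptions (3.0 → 5.0 kPa) encoding
  only the printed direction.
- Absolute cell heights are not printed; the control apex anchors at
  4.0 µm and activated heights reproduce the printed folds (÷1.53 for
  M1, ÷1.69 for M2).  Apex height CV is 5% — a within-donor
  morphological-reproducibility scale chosen once; real cross-donor
  variability is larger, so green cohort tests establish pipeline
  recovery, not biological effect sizes.
- α presets 0.25 → 0.15 encode the printed direction of the exponent
  decrease (numeric values are figure-only); η defaults to 0.

Assay generators: log-normal-shaped ROS bursts with closed-form
(truncated) AUC ground truth; two-component log-normal cytometry
mixtures with the gate at the 99.5th percentile of a no-particle
control.  MFI is the median by convention (mean via configuration).

What the generators do **not** emulate: instrument drift and hysteresis,
adhesion, cantilever dynamics, cell-internal heterogeneity, optical
cross-talk.  A green recovery test therefore establishes correctness of
the computation chain, not robustness to every instrumental artefact.

## Degenerate inputs and tie-breaks

Curves whose maximum excursion stays below 3× the noise RMS are
classified NoContact and excluded with a logged reason.  Constant rows
in z-standardization yield NaN with a warning.  Groups with fewer than
2 cells are excluded from cohort summaries with a warning.  Tilt
correction with fewer than 3 non-collinear substrate pixels is skipped
with a warning.  All stochastic code takes explicit seeds; fitters are
deterministic given their inputs.
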