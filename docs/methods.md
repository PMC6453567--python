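# Methods

## Trilayer stability model

The colony is modelled as three bonded isotropic elastic layers: the
biofilm film (*G*_f, *h*_f), the residual matrix layer (*G*_r,
*h*_r = 0.3 *h*_f by default), and a thick agar substrate (*G*_s,
*h*_s ≥ 5 *h*_f).  For the stability analysis all layers may be taken
incompressible (ν = 0.5); only shear moduli enter.  With a sinusoidal
surface undulation of wavenumber *n*, the longitudinal film stress is

    S(n) = G_f h_f² n²/3 + K̃(n)/(h_f n²),
    K̃(n) = 4 G_s n / (n h_r (G_s/G_r − 1) + 2).

The bending term grows with *n* and the substrate term diverges as
*n* → 0, so *S* has an interior minimum; its minimiser is the critical
wavenumber.  `solve_wrinkling` minimises *S* on log *n* over
*n h*_f ∈ [10⁻³, 10³] (bounded scalar minimisation, robust to flat
minima) and then polishes the root of the analytic d*S*/d*n* with Brent's
method; the returned stationarity residual |d*S*/d*n|·*n*/*S* is verified
below 10⁻⁸.  K̃'s denominator can become non-positive for a *stiff*
interlayer (*G*_r > *G*_s) at large *n h*_r; that is outside the model's
assumptions and raises a validity error rather than being clipped.

Derived quantities follow the model's conventions: λ_cr = 2π/*n*_cr,
*S*_cr = *S*(*n*_cr), ε_cr = *S*_cr/3*G*_f.  Note that in the bilayer
limit this ε_cr is 4/3 of the classical onset strain
(1/4)(3*G*_s/*G*_f)^(2/3); both conventions are exposed
(`classical_bilayer_critical_strain`) so users can compare against either
convention in the literature.

The effective substrate modulus is *G*′_s = K̃(*n*_cr)·*h*′_s with *h*′_s
the depth of the strained substrate region.  No closed form for *h*′_s
exists in this model family; the default is 1/*n*_cr, the natural decay
depth of a sinusoidal surface load, with an explicit override.  The
normalised adhesion Γ* = Γ/(*h*_f *G*′_s) summarises the
wrinkle-vs-delaminate competition; Γ* ≪ 1 is delamination-prone.

Two stiffness-contrast bounds quoted from the bilayer phase-diagram
literature (flat-to-wrinkle transition requires *G*_f/*G*_s ≳ 1.3; the
bilayer branch needs log-strain coordinates > 4.75) are stored as
documented constants only — they are not derivable from the equations
implemented here.

### Residual-stiffness fit

*G*_r is experimentally inaccessible and is the model's only free
parameter.  `fit_residual_stiffness` minimises
Σ(λ_model/*h*_f − λ_data/*h*_f)² over *G*_r/*G*_f on a log bracket
(default (10⁻³, 1]: the residual layer is softer than the film by
construction) by bisection on the sign of the SSE derivative, falling
back to bounded golden-section search if the bracket endpoints do not
show a sign change (non-unimodal or boundary minimum; the latter is
flagged).  Relative tolerance 10⁻³, typically ~13 bisection steps.

## Growth simulation

A plane-strain domain [0, *L*] × [0, *h*_f+*h*_r+*h*_s] with *L* set from
the predicted wavelength (default 10 λ_cr to limit finite-size effects).
Growth enters through the multiplicative split **F** = **F**_e **F**_g,
with **F**_g = diag(1+*g*, 1) in film and residual layer and **F**_g = I
in the substrate; the induced mismatch strain is ε = *g*/(1+*g*).  Each
layer is compressible neo-Hookean,

    Ψ(F_e) = (μ_e/2)(I_C − 2 − 2 ln J) + (λ_e/2)(ln J)²,
    μ_e = G,  λ_e = 2Gν/(1−2ν),

with ν = 0.45 for all layers by default (a compromise between
incompressibility and numerical conditioning; configurable).  The total
energy Π = Σ_elements area·Ψ(**F**_e)·*J*_g is exact for the piecewise
affine displacement of first-order triangles.  Boundary conditions pin
*u*₁ on both side walls and *u*₂ on the bottom: the growing layers are
laterally confined by the fixed domain.

**Mesh.**  Structured crossed triangles (four per quad around a centre
node, which mitigates volumetric locking at ν = 0.45).  The film carries
`elements_per_hf` uniform rows (default 4), the residual layer at least
two, and substrate rows coarsen geometrically (ratio 2) with depth.
Horizontal spacing targets `elements_per_wavelength` (default 12) columns
per predicted wavelength.  Interfaces coincide exactly with element rows.

**Solver.**  Incremental loading with Δ*g* = 0.002 per step, each step
warm-started from the previous equilibrium.  The energy is minimised by
damped Newton iteration on the BC-reduced unknowns: the analytic sparse
tangent (material tangent
D = μ δδ + (μ − λ ln J) Q⊗Q′ + λ Q⊗Q with Q = **F**_e⁻ᵀ) is factorised
directly; Levenberg damping is added whenever the Newton step is not a
descent direction, and every step passes an Armijo backtracking line
search on Π.  A quasi-Newton (L-BFGS) formulation was tried first and
rejected: the problem's conditioning (stiffness contrast × slender
geometry) left it thousands of iterations from tolerance at each growth
step.  Convergence requires the projected gradient below
`gtol_scale`·*G*_f·*h*_f² (default 10⁻⁸).

**Bifurcation handling.**  Newton converges to stationary points, and the
flat compressed state remains an (unstable) equilibrium beyond onset.  Two
mechanisms move the solver onto the wrinkled branch: (i) before each
minimisation the film-surface nodes are perturbed vertically by a seeded
random-phase multi-sine of amplitude `perturbation_amplitude`·*h*_f
(default 10⁻⁴), and (ii) a converged iterate is accepted only if the
smallest eigenvalue of the reduced tangent (shift-invert Lanczos at zero)
is non-negative; at a saddle the unstable mode is followed downhill and
iteration continues.  Both mechanisms are disabled when
`perturbation_amplitude = 0`, in which case the flat branch persists for
all *g* — asserted in the tests, and the reason the perturbation exists.

**Onset and wavelength.**  The onset criterion is a surface deflection
exceeding 0.01 *h*_f, where deflection is the deviation of the top-surface
*u*₂ from its mean.  The mean is subtracted because the flat compressed
film thickens uniformly (Poisson effect) by far more than 0.01 *h*_f
before any instability; only the deviation measures the wrinkle.  The
wrinkle wavelength is the dominant nonzero FFT mode of the surface
profile, measured `steps_past_onset` (default 10) increments after onset.

**Accuracy expectations.**  At the default desk-scale resolution the
simulated onset strain sits ~15–20% below the ε_cr = *S*_cr/3*G*_f
convention (consistent with that convention exceeding the classical onset
by 4/3) and the wavelength within ~15% of λ_cr; onset *g* moves < 10%
when the film row count doubles.  These scales keep a full run around
20 s on one CPU.

## Image and contour analysis

**Normalisation and segmentation.**  Intensities are rescaled so the
image minimum maps to 0 and the background histogram mode to 0.9.  The
background peak is the *brightest* substantial histogram mode (≥ 5% of
the maximum bin count) — in transmission the background transmits the
most light; using the global mode instead fails when the colony covers
more than half the frame.  The 256-bin histogram is smoothed (Gaussian,
2 bins) before peak and valley detection so intensity noise inside a mode
cannot masquerade as the inter-mode valley.  The threshold is the first
local minimum below the background peak; the colony is the largest
below-threshold connected component after a 3×3 median filter, holes
filled.  The colony centre is taken from the frame at (or nearest) 12 h
and reused for all frames.

**Ring counting and wavelength.**  I(θ) is sampled by bilinear
interpolation at 1024 equal angles; the feature count *N* is the dominant
FFT harmonic, searched from harmonic 3 upward to exclude
centring/ellipticity artefacts, and cross-checked against the first
significant autocorrelation peak (multiples of the fundamental lag peak
equally high, so the *first* comparable peak is used).  Disagreement
beyond one harmonic flags the ring, and flagged rings are excluded from
the wavelength fit.  The intrinsic wavelength pools all (r, t, N) samples
and fits *N* = 2π*r*/λ through the origin (closed form
λ = 2πΣ*rN*/Σ*N*²).  *R*_p, where *N* falls to zero, is reported per
frame as the innermost patterned radius; for a disordered core this is the
inner edge of the outermost patterned annulus.

**Contours.**  The sub-pixel boundary (marching squares at level 0.5) is
resampled to ≥ 2 samples per pixel of arc length and smoothed with a
periodic Gaussian of σ = 1.5 px for perimeter/area/acircularity: wide
enough to suppress the staircase that otherwise inflates digitised
perimeters by ~5%, narrow enough that a square stays within 1% of
α = 4/π.  For curvature and velocity the contour is resampled to 512
uniform arc-length points (σ = 2 samples); each point gets
Gaussian-weighted quadratic fits of x(s), y(s) over a 9-point window, and
κ = (x′y″ − y′x″)/(x′²+y′²)^{3/2} with CCW orientation so κ > 0 means
bulging outward.  Velocities join each point to its nearest neighbour on
the next contour (KD-tree), V = |Δr|/Δt.  The 9-point window biases κ
where the osculating radius approaches the window's arc span; resolution
should be raised for strongly curved features.

**Expansion kinematics.**  ⟨R_f⟩(t) is fitted with a continuous
two-segment line (hinge basis, breakpoint grid-searched over interior
sample times).  A breakpoint at the boundary of the candidate set or a
negligible slope change reports "no break".

**Blisters.**  The baseline averages z over the outer 10% of samples on
each side; H is the peak height above baseline and W the distance between
the two half-height crossings (linear interpolation), making both
invariant to horizontal translation and baseline offset.

**Interfacial-energy hierarchy.**  The event sequence follows from which
interfaces are cheap to create and expensive to keep: delamination first
(immediately, skipping wrinkling, when adhesion is unmeasurably small);
blister-wall contact when film–liquid is dearer than film–air; lateral
merging/collapse of neighbouring blisters in the opposite regime.

## Synthetic data

The generators are pure functions of (parameters, seed) and ship a ground
truth record with every artifact; all round-trip tests compare analysis
output to that truth.  Defaults describe a day-old wrinkled colony:
6 mm radius, 1 mm intrinsic wavelength, 50 µm pixels, expansion slowing
from 0.12 to 0.05 mm/h at t_c = 40 h, six-fold petal modulation growing
to 15% afterwards.  Stripe counts follow N(r) = round(2πr/λ) — stripes
bifurcate where the count increments, keeping the local spacing within a
factor √2 of λ.  Image noise is additive Gaussian (σ = 0.05 for "noisy"
conditions); wavelength data carry multiplicative log-normal noise
(σ = 0.05), keeping wavelengths positive.  Blister stages interpolate
from a wide cosine bump to a flat-topped tanh-wall profile whose
half-height width is exactly 2 *h*_f.

What the generators do *not* emulate: uneven illumination, camera vignetting
and stitching seams, partial-colony fields of view, overlapping colonies,
sub-wavelength texture, or the disordered wrinkle cores of real colonies.
Passing round-trip tests therefore demonstrates the correctness of the
analysis chain under its stated assumptions, not robustness to every
real-microscopy artefact.

## Problem sizes and determinism

Default test and acceptance runs use: 15-point stability scans per decade
window, 8-ratio fit datasets, a growth simulation of ~6000 degrees of
freedom and ~90 increments (~20 s), 300×300 px synthetic images, and
100–200-replicate Monte-Carlo recovery studies for the noisy fits.  Every
random choice flows from an explicit integer seed; identical seeds give
bit-identical outputs, and the pipeline derives per-stage seeds from one
root seed by hashing.

## Known limitations

- The stability theory is small-strain; its ε_cr convention
  (= *S*_cr/3*G*_f) exceeds the classical bilayer onset by 4/3, and
  finite-strain simulations onset below it accordingly.
- First-order triangles at ν = 0.45 can lock volumetrically; the crossed
  mesh and moderate ν mitigate but do not eliminate this (a fidelity
  limit, accepted and documented).
- No contact mechanics: blister wall touching and post-contact evolution
  are represented only by the synthetic profile family, not simulated.
- No delamination/cohesive-zone mechanics: the simulation covers the
  wrinkling pathway; delamination enters only through Γ* and the
  interfacial-energy comparator.
- No viscoelasticity or plasticity, hence no hysteresis.
- Real-micrograph wrinkle-vs-blister classification is out of scope; the
  pattern metrics operate on segmentable transmission images and
  synthetic ground truth.
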