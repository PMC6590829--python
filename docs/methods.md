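# Methods

This note records the models implemented in `scatterfit`, the conventions
and defaults, the numerical choices, and what the synthetic data used in
the test suite do and do not probe.

## Units and conventions

Lengths are nm, momentum transfer q in nm⁻¹, scattering length densities
(SLD) in nm⁻², times in ns and frequencies in ns⁻¹ (any self-consistent
system works; nothing in the code pins the absolute scale). Contrast
always means particle minus solvent SLD. Form factors with a material
contrast report absolute intensity per particle with forward scattering
I₀ = (V_p ρ)²; models without a natural contrast (Gaussian chain,
Beaucage, Teubner–Strey) are normalized (I(0) = 1, Beaucage to its
Guinier prefactor G).

## Data container and ASCII dialect

A line is interpreted from its first words: two leading numbers → data
row; an identifier followed by a float → attribute (all trailing tokens
parsed as floats where possible: scalar, vector, else the raw string);
anything else → comment. Blocks split at blank lines, at
attribute/comment lines following data, or at a user keyword. Two
reserved comment-style lines extend the dialect so the writer is
lossless: `#@roles X 0 Y 1 eY 2` records the column roles, `#@s name
value…` carries attributes whose value does not start with a float.
Numbers are written with `%.17g`, so the float round trip is exact.
Role defaults are X=0, Y=1, and eY=2 when a third column exists.

`prune` averages rows in linear or logarithmic X intervals; the output
error is the standard error of the bin mean when the input has no error
column (0 for singleton bins), otherwise √(Σe²)/n. Equal-population bins
therefore conserve the global Y mean exactly.

## Fitting

`MultiDataModel(collection, func, fixed=…, bounds=…)` resolves every
model parameter to exactly one source with priority user-fixed > free
start > dataset attribute > model default. A scalar start makes a
parameter common, a list start (length = number of datasets) independent;
independent parameters occupy contiguous slices of the optimizer vector,
one slice per name. χ² uses eY as 1σ weights where present, unit weights
otherwise. Algorithms: `leastsquare` (scipy `least_squares`;
Levenberg–Marquardt unbounded, trust-region-reflective when bounds are
given — bounds by parameter transform were considered and rejected as
strictly less robust than scipy's native TRF), `neldermead`, `bfgs`, and
`diffev` (differential evolution; mandatory seed, default 12345, so runs
are reproducible bit for bit). Inequality constraints enter as one-sided
quadratic penalties with weight 10⁶ appended to the residual vector.

The covariance is (JᵀJ)⁻¹ scaled by the reduced χ², with J the central
finite-difference Jacobian at the optimum; errors are the square roots of
its diagonal (NaN with a warning when singular). Model functions may
return a plain vector or a `DataSet`; attributes computed inside the
model propagate into the result's curves.

## Form factors

* Sphere: I = (Vρ)²[3(sin qR − qR cos qR)/(qR)³]², with the q → 0 limit
  taken analytically (all q = 0 singularities in the package are handled
  by series, never by offsetting q).
* Multishell sphere: amplitude as a telescoping sum of sphere kernels
  over the shell radii, F_a = Σ_k ρ_k[V_kΦ(qr_k) − V_{k−1}Φ(qr_{k−1})];
  a single shell is exactly the sphere, splitting a shell at constant
  contrast changes nothing, and a staircase of shells approximates a
  radial SLD profile.
* Gaussian chain: Debye function 2(e^{−x} + x − 1)/x², x = q²R_g².
* Beaucage: unified Guinier + power law with exponent d ∈ [1, 4],
  I = G e^{−q²R_g²/3} + B(erf(qR_g/√6)³/q)^d with the matched prefactor
  B = G d/R_g^d (6d²/((2+d)(2+2d)))^{d/2} Γ(d/2). This is the variant
  without an extra low-q cutoff in the power-law branch; the matched B
  gives a clean q^{−d} tail (slope verified to 2 %).
* Teubner–Strey: I = (8π/ξ)/(a₂ + c₁q² + q⁴) with k = 2π/d,
  a₂ = (k² + ξ⁻²)², c₁ = −2(k² − ξ⁻²). The 8π/ξ prefactor is a fixed
  convention (literature normalizations differ); the peak sits at
  q* = √(−c₁/2) when kξ > 1.

`distributed_average` integrates any one-parameter family over
normal/lognorm/gamma/lorentz/uniform distributions by fixed
Gauss–Legendre quadrature (41 points default) on the support truncated at
±5 widths (lorentz ±20, uniform exactly ±width), weights renormalized to
unit mass on the window; poisson and discrete-uniform are exact sums.
`width` is the standard deviation for normal/lognorm/gamma, half-width
for uniform, HWHM for lorentz.

## Point-cloud scattering

For each |q| the amplitude A(qu) = Σᵢ bᵢ f_a(q) e^{iqu·rᵢ} is evaluated
on an orientation grid and averaged: I = ⟨|A|²⟩, β = |⟨A⟩|²/⟨|A|²⟩.
The Fibonacci grid uses the golden-angle spiral with exactly 2n+1 points;
the default grid size is n = max(100, q_max · cloud extent), a heuristic
that keeps the discretization error of smooth clouds below ~0.1 %.
Orientational averaging is direct summation (exact for the grid, no FFT
approximation), chunked over q so the (n_q × n_dir × N) phase tensor
never materializes.

Gaussian positional disorder with rms displacement σ uses the standard
coherent + diffuse decomposition I = DW·⟨|A|²⟩ + (1 − DW)·Σbᵢ²f_a²,
DW = e^{−q²σ²}: the Bragg-like coherent part is attenuated and the
complement appears as incoherent diffuse scattering, with the exact
limits I → Σbᵢ² as σ → ∞ and I(0) = (Σbᵢ)². The subparticle amplitude
f_a defaults to 1 (point scatterers); the normalized sphere amplitude is
available as `formfactor.sphere_amplitude`.

Lattice-cloud builders generate conventional sc/bcc/fcc cells clipped to
a cube (coordinates in [0, size], inclusive) or a sphere (|r| ≤ size).

## Structure factors

All fluid models are evaluated through the Baxter factor function q(r):
S(k) = |1 − 12η q̃(k)|⁻² with q̃(k) = ∫₀^∞ q(r)e^{ikr}dr in hard-core
diameter units (σ = 1, 12η = 2πρσ³). The Fourier integrals are closed
forms, with an 8-term series below |kσ| = 10⁻³.

* Percus–Yevick: q(r) = ½a(r²−1) + b(r−1), a = (1+2η)/(1−η)²,
  b = −3η/(2(1−η)²); identical to the Wertheim direct-correlation closed
  form (the test suite compares both routes to 10⁻¹²).
* Sticky hard spheres (Baxter): q(r) gains the constant λ/12 and the
  coefficient relations follow from the same boundary conditions —
  re-derived symbolically in this package rather than copied:
  (η/12)λ² − (τ + η/(1−η))λ + (1+η/2)/(1−η)² = 0 (smaller root physical,
  no real root ⇒ two-phase region, rejected with the critical τ named),
  μ = λη(1−η), α = (1+2η−μ)/(1−η)², β = (μ−3η)/(2(1−η)²). The `width`
  argument is bookkeeping for the finite-well picture the sticky limit
  idealizes; the limiting S(q) does not depend on it. A low-density
  check against the adhesive second virial coefficient
  (S(0) ≈ 1 − 8φ + 2φ/τ) pins the sign conventions.
* Screened Coulomb (RMSA): potential βu(x) = γe^{−z(x−1)}/x for x > 1
  with z = ak the dimensionless screening constant κσ and γ the contact
  potential in kT. The MSA closure (c = −βu outside, g = 0 inside) is
  solved with the factor-function ansatz
  q(x) = Ax²/2 + Bx + E + C_i e^{−zx} (inside), C_o e^{−zx} (outside).
  The Baxter relations give five conditions linear in
  (A, B, E, C_i, J) at fixed C_o — J = ∫₁^∞ u h(u)e^{−zu}du is the tail
  moment — and the Yukawa tail match closes the system. Eliminating the
  linear block turns the closing condition into a quartic in C_o.
  The coefficient expressions are generated symbolically once
  (`scripts/derive_msa.py`, verified to collapse exactly onto
  Percus–Yevick at γ = 0) into `_msa_generated.py`; at run time the
  closing polynomial is recovered exactly by sampling det·(tail residual)
  on a complex circle and reading the coefficients off an FFT, and all
  roots come from the companion matrix (`numpy.roots`).
  For every real root S(q) is built and g(r) obtained by sine transform;
  roots are scored by the mean |g| over r ∈ [0.4, 0.6]σ (away from both
  the r → 0 amplification and the contact discontinuity, where Gibbs
  ringing would contaminate the score) and the smallest score wins.
  Spurious roots of the determinant factor are rejected by the tail
  residual. If the analytic contact value g(σ⁺) of the selected solution
  is below −10⁻³, the Hansen–Hayter rescaling maps to an effective larger
  diameter (η′ = ηs³, z′ = zs, γ′ = γe^{−z(s−1)}/s), with s found by
  geometric bracketing plus bisection (≤ 50 iterations, η′ capped at
  0.72). Attributes report the selected root, number of real roots,
  rescaling flag, effective packing and contact value. γ < 10⁻¹⁴ is
  routed to the exact PY coefficients (the analytic γ → 0 limit).

`sq_to_gr` computes g(r) = 1 + [1/(2π²nr)]∫ q(S−1)sin(qr)dq by trapezoid
rule on the curve's own grid, warning (and attaching a truncation
attribute) when |S−1| at q_max exceeds 0.01. Hard-core violation
measurements use q_max σ ≈ 2000: the ringing from the contact
discontinuity decays like jump/(π q_max Δr), so this keeps the numerical
floor near 0.01 at Δr = 0.1σ from contact.

* Lattice powder patterns: reciprocal vectors of the conventional cell
  are enumerated to |h|,|k|,|l| ≤ ⌈q_max a/2π⌉+1 (error above 10⁵
  points), extinctions emerge from |F_hkl|², equal-|q| shells merge with
  their multiplicity. Z(q) = (c/q²)Σ m|F|²P(q−q_hkl) with unit-area
  Lorentzian (default) or Gaussian peaks of HWHM δ = 2π/L, and
  c = 2π²/(v_cell n_basis) — the unique normalization for which Z → 1 on
  shell average at large q, equivalently ∫Z q²dq/c across an isolated
  peak equals m|F|². Assembly: S = 1 + β(q)[Z e^{−q²u₂/3} − 1] with
  u₂ = ⟨u²⟩ the 3-D mean-square displacement, so the Debye–Waller
  attenuation is complemented by diffuse scattering, and β(q) is the
  particle asymmetry factor from `cloud_intensity`.

## Dynamic models

Time domain: exp(−q²Dt), exp(−(Γt)^β) (β ∈ (0,2]), and jump diffusion
exp(−Γ_j t) with Γ_j = Dq²/(1+Dq²τ). Frequency domain: unit-area
Lorentzians with those widths; diffusion in a reflecting sphere
(eigenvalues x_{l,n} of j_l′(x) = 0, computed by bracketed Brent root
finding on first use and cached — l, n cutoffs default 7/7 — with
amplitudes A_n^l(y) = (2l+1)·6x²/(x²−l(l+1))·[y j_l′(y)/(y²−x²)]², the
removable singularity at y = x handled by l'Hôpital, and EISF
[3j₁(qR)/qR]²; completeness Σ = 1 is tested); overdamped harmonic
confinement (EISF e^{−q²u₂}, Lorentzian ladder (q²u₂)ⁿ/n! at widths
n/τ); Sears rotational diffusion ((2l+1)j_l²(qR) at widths l(l+1)D_r).
All spectra are classical (symmetric); no detailed-balance factor.

Elastic lines are single-bin spikes of value EISF/Δω at ω = 0 — exact
under the discrete convolution (spike ⊗ f = f), conserved by binning and
removable in the HWHM extraction (`exclude_elastic`).

`time_to_frequency` multiplies I(t) by e^{−σ²t²/2} (the time-domain
image of a Gaussian ω-resolution of width σ, which doubles as the
transform window — the only windowing applied) and cosine-transforms by
trapezoid onto the requested symmetric grid. The time grid (2¹⁴ points)
extends until the windowed I(t) falls below 0.5 % of I(0) (doubling
search; a truncation-leak warning and attribute otherwise). Truncated
sum rules beyond 1 % attach warning attributes rather than failing.

`hwhm` interpolates the half-maximum crossing linearly on the ω > 0
side; first-order accurate in the grid step.

## Smearing and desmearing

Gaussian kernels take a scalar, per-point array or callable σ(q); rows
are normalized to unit mass on an oversampled quadrature grid (step
min(Δq/4, σ/6)). The slit kernel is the infinite-slit average
(1/L)∫₀^L I(√(q²+u²))du with 64-point midpoint quadrature. Beyond the
measured range the curve continues as a Porod A q⁻⁴ tail whose amplitude
is the mean of I q⁴ over the last decade of points — linear in I, so the
smearing operator is exactly linear; a constant curve is preserved in
the interior but sags within a kernel width of the upper edge, the price
of the Porod assumption there. Below the range the curve continues
flat.

The Lake iteration is multiplicative, I_{n+1} = I_n·[I_meas/smear(I_n)],
which preserves positivity. The moving-average smoothing (odd width,
default 5) is applied to the *update ratio*, not the iterate: the ratio
is 1 + noise, so smoothing it suppresses noise amplification without
flattening sharp minima — smoothing the iterate itself was found to
stall the χ² far above the degrees of freedom. Stopping: χ² between
smear(I_n) and the measurement (eY-weighted) reaches the number of
points, or improves by less than 0.1 %; three consecutive increases
abort with the best iterate attached. Because the smoothing acts on the
ratio, wider windows do not reduce the iteration count (convergence is
~10 iterations regardless); their stabilizing effect shows as smoother
output at a fixed iteration budget, which is what the stability test
asserts.

## Synthetic data and what the tests show

All test inputs are generated in-process: random containers for the I/O
round trip, exponential decays with 1 % Gaussian noise at fixed seeds
for fit recovery, analytic sphere curves (smeared, noised, desmeared)
for the resolution round trip, and lattice clouds for the
crystal cross-checks. These probe correctness of the mathematics and the
estimators under ideal, well-specified noise; they do not probe
instrument backgrounds, multiple scattering, non-Gaussian or correlated
noise, incoherent backgrounds in QENS, or calibration errors — real-data
features a user's model must supply. Problem sizes (e.g. 10⁵-point q
grids for g(r), 2¹⁴-point time grids, ~17 000-point clouds) were chosen
so each check runs in seconds while its numerical floor sits well below
the tested tolerance.

## Known limitations

* RMSA screening is validated for z = κσ ≤ ~60 and φ ≤ 0.5; far outside
  that range the closing-polynomial conditioning degrades.
* The hard-core violation measure is transform-limited near contact
  (Gibbs ringing ~0.01 at the default q_max); statements about g inside
  the core are to that tolerance.
* The slit smearing assumes an infinite slit of uniform weight; no
  wavelength-spread decomposition of σ(q) from instrument geometry.
* Lattice peaks use a single isotropic peak shape; no asymmetric
  (paracrystalline) broadening.
* 2-D detector patterns, oriented-cloud scattering and hydrodynamic
  corrections are out of scope.
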