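# Methods

This note documents the models behind `memkappa`, the numerical choices made
where the underlying publications leave details open, and what the synthetic
generators do and do not emulate.

## Unit system

Internally: lengths in Å, wave vectors in Å⁻¹, the bending modulus κ in units
of thermal energy kBT, the smectic compression modulus B in kBT/Å⁴, and the
surface moduli K_A and K_t in mN/m at the interface (kBT/Å² internally;
1 mN/m = 10⁻²³ J/Å²). The Boltzmann constant is the exact CODATA value. The
default temperature is 310.15 K (37 °C, the membrane measurement temperature);
the Stokes–Einstein sizing helper defaults to 298.15 K, the usual temperature
of dynamic light scattering. With these conventions every thermal-energy
prefactor in the Caillé, Zilman–Granek and Helfrich–Canham expressions becomes
unity or a plain unit conversion, and round-trip conversions are exact to
machine precision.

On K_A arithmetic: converting κ (kBT) to K_A (mN/m) through K_A = a·κ·kBT/ℓ²
gives 253.8 mN/m for the cholesterol model at κ = 4 kBT and 63.4 mN/m for the
uncoupled model — published summaries round such values to 250 and 62; the
package always reports the unrounded number, and its tests compare at the few
percent level that rounding implies.

## Caillé smectic analysis (module `xds`)

A multilamellar membrane stack is described by the smectic Hamiltonian with a
single-membrane bending modulus κ and an inter-membrane compression modulus B.
The diffuse intensity at fixed q_z is proportional to the structure factor

    S(q_z, q_∥) = Σ_n H_z(|n|d) cos(q_z n d)
                  ∫₀^∞ r dr H_r(r) J₀(q_∥ r) exp(−q_z² δu_n(r)/2),

with the pair correlation

    δu_n(r) = (2η_c/q₁²) ∫₀^∞ dx [1 − J₀((r/ξ)√(2x)) (√(1+x²) − x)^{2|n|}]
                                  / (x√(1+x²)),

η_c = kBT q₁²/(8π√(Bκ)), ξ = (κ/B)^{1/4}. The Bessel argument of the radial
transform is J₀(q_∥ r), the standard cylindrical average for an in-plane
powder.

**Finite-size factors.** The literature this analysis descends from does not
print closed forms for H_z and H_r; we use one shared, interpretable form for
both: the triangular self-overlap max(0, 1 − s/L) of a domain of extent L,
averaged over a normal distribution of domain sizes (mean L, spread σ,
truncated to positive sizes). Defaults σ_r = L_r/4, L_z = 10·d, σ_z = L_z/4;
all four are configurable. This reproduces the qualitative role of the factors
(damping the layer sum and radial integral on the domain scale) with two
parameters each.

**Numerics.** δu_n is evaluated in the substitution u = √(2x), which makes the
Bessel oscillation uniform. The production engine uses composite
Gauss–Legendre quadrature (6144 nodes to u = 60) with the exact analytic tail
asinh(2/u_max²); splitting the integrand as (1−g^{2n})K + g^{2n}K(1−J₀)
isolates the J₀(ru/ξ) matrix so that one Bessel evaluation serves every layer
index n. δu_n is tabulated on a 120-point logarithmic r grid (with δu(0) = 0
pinned exactly) and interpolated monotonically (PCHIP) onto the radial
quadrature nodes. The radial integral uses 1400 composite Gauss–Legendre nodes
up to the radius where H_r < 10⁻⁴; the layer sum is truncated where
H_z < 10⁻⁴ and folded to n ≥ 0 by symmetry. Under node doubling the structure
factor is stable to ~2×10⁻⁴ on the fitted q range, and it agrees with an
independent dense-Simpson brute-force oracle to better than 0.5% (tested).
A separate point-wise `delta_u` uses adaptive quadrature at ~10⁻⁶ relative
tolerance and serves as the reference for the fast engine.

**Fitting.** Slices at q_z = 2q₁ and 2.5q₁ (the orders visible in weakly
ordered stacks) are normalized to their intensity at q_∥ = 0.01 Å⁻¹ and fit
jointly by weighted least squares: shared (κ, B) optimized in log₁₀ space
within κ ∈ [0.1, 100] kBT, B ∈ [10⁻¹⁰, 10⁻³] kBT/Å⁴, one free multiplicative
scale per slice solved analytically each iteration (the electron-density
constant is per-q_z linear and of no further concern). Weights are 1/σ² from
counting statistics. Solutions within 10⁻³ log-units of a bound are flagged;
degenerate data (e.g. a flat slice) therefore never succeed silently. The
parameter covariance comes from the Gauss–Newton approximation at the optimum.

**Domain-size scan.** The primary fit is repeated over a grid of L_r and the
minimizing entry selected. The default criterion is χ²; selecting by smallest
fitted ξ² is also available, because the source literature's wording can be
read either way (the χ² reading is almost certainly the intended one).

**Tilt emulation.** Lipid tilt adds short-wavelength roughness that a
tilt-free Caillé fit misreads as a softer membrane. We model tilt as an
additive per-membrane Gaussian roughness field with 2-D spectrum kBT/(K_t Q²),
band-limited to Q ∈ [2π/L_r, 2π/10 Å]; fields on different membranes are
uncorrelated. Same-membrane pairs then acquire
Δ_t(r) = (kBT/πK_t)∫(1−J₀(Qr))/Q dQ and cross-membrane pairs the constant
2σ_w² with σ_w² = (kBT/2πK_t)·ln(Q_max/Q_min). Emulated slices are built with
δu_n + Δ_t and re-fit with the tilt-free model; scanning the emulated κ
locates the input modulus whose tilt-free fit matches a target. At the
red-blood-cell stack parameters (d = 74.8 Å, B = 2×10⁻⁷ kBT/Å⁴, K_t = 4 mN/m,
L_r = 500 Å, target fit 2 kBT) the scan selects κ_emu = 7.5 kBT. The exact
stack-tilt theory used in the source analysis is not published in formulas;
our band-limited uncorrelated model is a declared approximation, so the
emulation result carries a correspondingly generous uncertainty (a couple of
kBT) rather than the precision of the rest of the module.

## Zilman–Granek spin-echo analysis (module `nse`)

The intermediate scattering function of membrane undulations decays as
I(q,t)/I(q,0) = exp[−(Γt)^{2/3}]; the exponent 2/3 is definitional and never
a free parameter. Γ is fit per q by weighted least squares (lmfit), optionally
after dividing out a vesicle-diffusion factor exp(−Dq²t); D comes either from
an explicit value or by Stokes–Einstein from the vesicle radius (default
99.5 nm, half the light-scattering diameter). The rates are then fit to
Γ = c·q³ through the origin and inverted via

    Γ = 0.025 (kBT/κ̃)^{1/2} (kBT/η) q³  ⇒  κ̃ = (0.025·kBT/(η c))² in kBT,

with η the solvent viscosity (a small D₂O table ships: 8.52×10⁻⁴ Pa·s at
310.15 K, 1.095×10⁻³ at 298.15 K). The effective modulus κ̃ = κ + h²K_A
(Watson–Brown) is reduced to κ by eliminating K_A with one of three
monolayer-coupling models: K_A = a·κ/ℓ² with (a, ℓ) = (48, 2D_c) for
uncoupled uniform monolayers, (24, 2D_c) for the polymer-brush picture, and
(12, δ) for the stiff-layer model appropriate at high cholesterol content.
Thus κ = κ̃/(1 + a(h/ℓ)²); with h = D_c = 18 Å, 2D_c = 36 Å, δ = 9 Å the
amplification factors are 13, 7 and 49 respectively. Ignoring a real
diffusion contribution inflates Γ and therefore deflates κ — the direction of
the corrected/uncorrected pair of published values — and the package
reproduces this exactly in its tests. Γ fits are per-q and independent; a
global fit across q is deliberately not the default, matching how such data
are usually reduced.

## Undulation spectra (module `undulation`)

With h(r) = Σ_Q ĥ_Q e^{iQ·r} and ĥ_Q = FFT2(h)/N², the reported spectrum is
⟨|h(Q)|²⟩ = L²⟨|ĥ_Q|²⟩ (Å⁴), fixed by the discrete Parseval identity
Var(h) = Σ_Q ⟨|h(Q)|²⟩/L² (tested on a pure mode and on white noise). Modes
are averaged in radial shells of width ΔQ = 2π/L; the value is the mean over
frames, the error the standard error over frames. Equilibrium of an elastic
sheet with bending and tilt gives ⟨|h(Q)|²⟩ = kBT/(κQ⁴) + kBT/(K_tQ²), fit by
weighted linear least squares in (1/κ, 1/K_t) on shells below
Q_max = 0.2 Å⁻¹, above which molecular structure breaks the continuum
picture. A non-positive tilt coefficient is reported as K_t at its rigid
bound with a pure-Q⁻⁴ refit, never silently.

One estimator detail matters: a ΔQ shell mixes modes whose |Q| differ by up
to ~40%, and Q⁻⁴ is convex enough that evaluating the model at the shell
centre biases κ upward by tens of percent on a 340 Å box. The spectrum
therefore also records the per-shell means of Q⁻⁴ and Q⁻² over the actual
member modes, and the fit uses those as regressors — averaging the model
exactly as the data were averaged, which makes the recovery unbiased (tested
over independent generations).

## Lipid mapping (module `lipids`)

An experimental lipid with tails (carbons:double-bonds) is assigned the
coarse-grained library lipid minimizing E = E_sat + E_tail, the summed
per-tail absolute differences in double-bond and carbon counts, over the tail
pairing that minimizes the total (this reduces to the order-preserving
pairing in the published worked example, 18:2–14:1 vs 18:1–16:1 → 1 + 2 = 3).
E_sat is compared per tail, not on whole-lipid totals — both readings agree
on the only published example; per-tail is the stricter and is what we
implement. Ties are broken by library order and flagged. Leaflet asymmetry
splits each species' count at a given outer:inner ratio with
largest-remainder rounding (totals conserved exactly; half-integers round to
the upper leaflet, so 3:1 with 10 molecules gives 8/2).

## Synthetic data (module `simulate`)

The generators define the study conditions under which every fitter is
validated:

* **Diffuse maps** — smectic stack κ = 2 kBT, B = 2×10⁻⁷ kBT/Å⁴, d = 74.8 Å
  (q₁ = 0.084 Å⁻¹), domains L_r = 500 Å, rows at q_z = 2q₁ and 2.5q₁ over
  q_∥ ∈ [0.005, 0.105] Å⁻¹, Poisson counting noise with the brightest pixel
  at 10⁵ expected counts (intensity near a lamellar peak is orders of
  magnitude above the diffuse tail, so relative errors are far smaller
  there).
* **Spin-echo decays** — the four experimental q values (0.0523–0.0959 Å⁻¹),
  40 logarithmic Fourier times from 0.01 to 100 ns, κ = 4.1 kBT under the
  stiff-layer model, D₂O viscosity at 37 °C, Gaussian noise whose relative σ
  grows from 0.5% to 2% towards late echo times, and an optional diffusion
  factor.
* **Height fields** — L = 340 Å (the ~34 nm simulation patch), N = 64,
  200 frames, κ = 4.2 kBT, K_t = 3.63 mN/m; independent Gaussian Fourier
  amplitudes with the target spectrum, Hermitian-symmetrized by filtering a
  white real field, zero-mean by construction.

Every generator embeds its ground truth and seed in the output metadata and
is bit-reproducible for a fixed integer seed. What the generators do *not*
emulate: instrument resolution and wavelength spread, detector geometry
corrections (absorption, polarization, footprint), vesicle polydispersity,
background scattering beyond a flat term, correlated frames (every height
field is an independent equilibrium draw), and any protein or compositional
degrees of freedom. Passing recovery tests therefore demonstrates estimator
correctness under the stated statistical model, not robustness to every
systematic present in real measurements.

## Problem sizes and runtime

The shipped tests and the acceptance script run the tilt-emulation scan on a
21-point κ grid with 37 q_∥ points per slice, 20-seed recovery ensembles for
the X-ray and spin-echo tracks, and 200-frame spectrum fits — sizes chosen to
give sub-percent to few-percent statistical resolution while keeping a full
run in minutes on one core. All quadrature node counts are collected in
`XdsSettings` and can be raised for verification runs.

## Known limitations

* The finite-size factors and the tilt-stack roughness are declared
  approximations of unpublished forms; they reproduce roles and magnitudes,
  not exact line shapes, and the tilt-emulation output inherits a ±(1–2) kBT
  model uncertainty.
* Uncertainty propagation is first-order (fit standard errors through the
  conversion chain); no correlated or systematic error budget.
* The smectic fit assumes the structure factor alone carries the q_∥
  dependence (form-factor and detector corrections are out of scope).
* Real trajectories enter only as pre-extracted height grids; building the
  reference surface from molecular coordinates is out of scope.
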