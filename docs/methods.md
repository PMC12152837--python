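# Methods

Model definitions, numerical choices and known limitations for
`micellekit`. Units throughout: lengths in nm, scattering vector q in
nm⁻¹, absolute intensities in cm⁻¹, concentrations in g cm⁻³, molar
ellipticities in deg cm² dmol⁻¹.

## SAXS form factors (`micellekit.saxs.models`)

- **Homogeneous sphere.** P(q) = [3(sin x − x cos x)/x³]², x = qR. For
  x < 10⁻⁴ the closed form loses digits to cancellation, so a Taylor
  series in x² is used there; the two branches join to better than 10⁻⁶
  (measured ≈ 5×10⁻⁸ at the switch).
- **Core–shell sphere.** Amplitude A(q) = (ρ_c − ρ_sh)V_c f(qR_c) +
  (ρ_sh − ρ_0)V_o f(qR_o) with the same spherical kernel f; the form
  factor is normalized to 1 at q → 0. Verified against an independent
  radial quadrature of ∫(ρ(r) − ρ₀)·4πr²·sinc(qr) dr to < 10⁻⁸ relative.
- **Debye Gaussian chain.** I(q) = i0 · 2(e^−x + x − 1)/x², x = (qR_g)²,
  with a series branch at small x. I(x = 1)/i0 = 2/e exactly.
- **Power law.** I(q) = A·q^−α, for mass-fractal-like aggregates
  (α ≈ 2.6 in the fresh-solution preset).

## Structure factors

- **Percus–Yevick hard spheres** (analytic): the standard closed form
  from the PY direct correlation function. S(0) = (1−φ)⁴/(1+2φ)²
  (φ = 0.2 → 0.20898).
- **Charged spheres (Hayter–Penfold-style rescaled MSA)**
  (`micellekit.saxs.oz`): the MSA closure for a hard core of diameter d
  plus the DLVO screened-Coulomb tail
  βu(r) = z_eff²·λ_B·e^{−κ(r−d)} / [r·(1 + κd/2)²] is solved
  numerically: Ornstein–Zernike in k-space on a uniform radial
  grid (default dr = d/60, 8192 points) with type-I discrete sine
  transforms and Picard iteration on the indirect correlation γ = h − c.
  When the physical solution would give g(r) < 0 at contact
  (dilute/strongly coupled conditions), Hansen–Hayter rescaling inflates
  the hard core at fixed number density until g(d⁺) = 0 (Brent root
  find), then the structure factor is evaluated on the original q grid.
  A warm-start cache (`RescaledMSACache`) reuses the previous γ during
  fitting; the cached fixed point agrees with a cold solve to < 10⁻⁹.
- **Screening.** κ is computed from counterions only:
  κ² = 4π·λ_B·z_eff·n, with Bjerrum length λ_B ≈ 0.714 nm (water,
  ε = 78.5, 298 K). No added salt term is included.

The numerical solver was validated against (a) the analytic PY result
for z_eff = 0 (max |ΔS| < 10⁻³ at φ = 0.05 and 0.2) and (b) an
independent real-space OZ solver using bipolar-coordinate convolution
(kept in `tests/oracles.py`), agreeing to < 5×10⁻³ for the charged
study-condition parameter point.

## Fitting (`micellekit.saxs.fitting`)

`SAXSModelFitter` follows the scikit-learn estimator convention
(constructor takes configuration, `fit` ingests data, learned values get
trailing underscores). Residuals are σ-weighted (unit weights when σ is
absent) and minimized with `scipy.optimize.least_squares` (trust-region
reflective, bounded parameters). Multi-start uses Latin-hypercube draws
over the bounds, seeded for determinism; an explicit `init` dict adds an
informed start. Parameter combinations that violate model geometry
(e.g. core radius ≥ outer radius) or fail OZ convergence return a large
constant residual so the optimizer retreats rather than aborting.
Uncertainties come from the Jacobian-based covariance at the optimum,
scaled by the reduced χ².

Ancillary estimators: `GuinierForwardIntensity` (weighted ln I vs q²
regression restricted to qR_g ≲ 1.3, or a low-q plateau average),
`PowerLawExponentFitter` (weighted log–log regression),
`BreakpointFitter` (two-segment continuous least squares with an F-test
against a single line, for CMC determination), and
`detect_interference_peak` (smoothed prominence test with a
noise-aware threshold, flagging a concentration-dependent structure
peak).

## Absolute-intensity molar mass (`micellekit.mass`)

M_mic = I(0)·N_A / (c·K), K = [r₀·v_p·(ρ_l − ρ_0)·10²⁴]², with r₀ the
Thomson electron radius in cm, v_p the partial specific volume in
cm³ g⁻¹, and electron densities in e Å⁻³ (the 10²⁴ converts to e cm⁻³
per unit v_p). Association number p = M_mic/M_mol. Free-monomer
subtraction (c → c − cmc) is available but off by default. Tail volumes
use the Tanford formula V = 27.4 + 26.9·n_C ų; tail electron density is
electrons/V.

## CD (`micellekit.cd`)

Molar ellipticity [θ] = θ_mdeg/(10·c·l) with c the molar concentration
(per residue for per-residue values) and l the path length in cm. The
fully helical per-residue limit is chain-length corrected:
[θ]₂₂₂ = −37400·(1 − 2.5/N); N = 31 gives −34384 (nearest integer).
Helix fraction f_a = [θ]₂₂₂,obs/[θ]₂₂₂,theor (per residue), clipped at 1
with a flag. The 222/208 ratio classifies single helices vs coiled
coils. Smoothing is Savitzky–Golay.

## Coordinates (`micellekit.coords`)

- **Radial electron density**: electrons summed per spherical shell
  around the electron-weighted center, divided by shell volume (e Å⁻³);
  the profile conserves the total electron count exactly.
- **SASA**: Shrake–Rupley with a deterministic Fibonacci point set. The
  point set is expressed in a body frame built from the
  electron-weighted covariance eigenvectors (signs fixed by third
  moments, right-handed), so the result is exactly invariant under
  rigid rotations and translations rather than approximately so.
  Default probe 0.14 nm, 960 points/atom. Validated against a
  random-direction Monte-Carlo oracle and the analytic two-sphere
  formula.
- **Aggregation propensity**: AP = SASA(dispersed)/SASA(assembled);
  AP > 1 indicates burial of surface on assembly.

## Synthetic generators (`micellekit.synthetic`)

Presets mirror the study conditions: `aged_1wt` (core–shell micelles,
core 1.5 nm, outer = hard-sphere radius 2.45 nm, z_eff = 10.8,
φ = c·v_p = 0.0117, q ∈ [0.05, 5] nm⁻¹, absolute scale set by the
forward-scattering relation for p = 30 monomers), `aged_0.5wt` (same
family, z_eff = 9.81, R = 2.3 nm), `aged_0.1wt` (Gaussian coils,
R_g = 1.8 nm, I(0) = 2.5×10⁻³ cm⁻¹) and `fresh_0.1wt` (power law,
α = 2.6). Noise is multiplicative Gaussian, σ = relative_sd × ideal
(+ optional floor), with σ stored in the curve; all randomness is
seeded. Coordinate generators build micelles of p rigid 8-bead chains
(4 united-atom CH2 tail beads inside the core, head beads in the shell)
with minimum-distance rejection; the dispersed arrangement reuses the
same rigid chain template. Titrations are two-segment log-linear
responses around the CMC.

## Numerical tolerances

Key internal tolerances: OZ Picard convergence 10⁻¹⁰ on γ (max-norm,
structure-factor default), rescaling root tolerance 10⁻⁵ on the
diameter scale factor s = d'/d; fitter default `xtol/ftol`
from `least_squares` defaults. All test oracles are independent
implementations (radial quadrature, real-space OZ, Monte-Carlo SASA),
never re-calls of the code under test.

## Limitations

- The charged-sphere structure factor uses the one-component
  macroion/MSA picture: monovalent point counterions enter only through
  κ; no added-salt or explicit-ion effects.
- The decoupling of P(q) and S(q) assumes monodisperse spheres; no
  polydispersity smearing is implemented.
- Guinier extraction assumes the dilute curve is structure-factor free.
- The coordinate generators are geometric bead models, not molecular
  dynamics; they are intended for validating the analysis code, not for
  predicting conformations.
- The CD generator composes Gaussian basis bands and is designed to be
  exactly invertible by the analysis path, not to reproduce real
  spectrometer band shapes.
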