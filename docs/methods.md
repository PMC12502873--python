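# Methods

This note documents the models implemented in `memsas`, their assumptions,
the numerical choices behind every quadrature and simulation, and what the
synthetic-data tests do and do not demonstrate.

## Model overview

The scattering object is a laterally stationary membrane described through
its space- and time-dependent SLD `rho(x, t)`; per unit projected area, the
intermediate scattering function `I(q, tau)` is the Fourier transform of the
two-point correlation `C_rho(r, tau)` (elastic SAXS/SANS is `tau = 0`;
NSE reports `I(q, tau)/I(q, 0)`).  All intensities are per unit area and
carry an arbitrary scale relative to data; scale and flat background are
nuisance parameters of the fitting layer, never of the model functions.

### Membrane as a layer stack

A `LayerStack` is a piecewise-constant profile: boundaries
`a_0 < ... < a_N`, one SLD per slab, solvent outside.  The symmetric
bilayer convenience type expands `(l_C, l_H, l_S)` to the stack
solvent|S|H|C|C|H|S|solvent centred on the midplane (z = 0 convention;
empty layers are dropped, so the common `l_S = 0` case is a 4-layer stack).
"Bogus" layers with the solvent SLD may be appended to host protein parts
that protrude into the solvent.  The 1D amplitude

    rho(q_z) = sum_n (rho_n - rho_ref) [e^{i q_z a_{n+1}} - e^{i q_z a_n}] / (i q_z)

is closed-form; `rho_ref` distinguishes void contrast (0) from solvent
contrast (`rho_W`).  For a symmetric profile it is purely real.

### Protein cylinders and the composition rule

Proteins are cylinders normal to the membrane with per-layer SLD
`rho_p^(n)` (a scalar broadcasts; protruding solvated parts may carry their
own lower contrast).  The only assumption of the composition is statistical
independence between the protein positions and the membrane conformation;
expanding the two-point average of
`rho = rho_m (1 - chi_p) + rho_p chi_p` then gives exactly

    C_rho = C^(a) + C_p * C^(c),

with the average-SLD and contrast-SLD membrane correlations defined in the
README and `C_p = <chi_1 chi_2> - phi_p^2` the covariance of the cylinder
phase.  The identity is verified three independent ways in the test suite:
a real-space field-sampling oracle, a reciprocal-space FFT oracle, and the
exact algebraic degeneracies (`rho_p^(n) = rho^(n)` for all n, or
`phi_p in {0, 1}`, leave the bare membrane).

### In-plane statistics

*Hard discs* (elastic only): `I_p = theta_p A_p^2 P_p(q) S_HD(q)` with the
disc/ellipse orientation-averaged form factor and the low-density
structure-factor closure `S_HD = 1 / (1 + 4 phi_p * 2J1(2qR)/(2qR))` (the
direct correlation function truncated at the Mayer function of the
exclusion disc).  This closure is deliberately isolated behind one function
with the contract `S -> 1` as `phi_p -> 0` and `q -> inf`, `S(0) < 1`, so a
higher-order closure can be swapped in; a warning is logged above
`phi_p = 0.5`.  For elliptical cross-sections the exclusion radius is
identified with the semi-major axis.

*Boolean model*: discs overlap freely on a Poisson point process;
`phi_p = 1 - exp(-theta_p A_p)` and
`C_p = (1-phi_p)^2 [exp(theta_p K(r, tau)) - 1]`.  The covariogram `K` is
the lens area for discs and the affine-scaled, orientation-averaged lens
for ellipses; protein diffusion convolves `K` with an isotropic Gaussian of
per-axis variance `2 D_p tau` (2D MSD `4 D_p tau`), evaluated with a
numerically stable Rician kernel (`i0e`), cross-checked against the
spectral route `K(q) e^{-q^2 D_p tau}` to 1e-5.

A consequence worth knowing: the overlap prefactor `(1-phi_p)^2` makes the
dilute-limit convergence to `theta_p A_p^2 P_p(q)` first order in
`theta_p A_p` with coefficient ~1.77 (closed-form series), i.e. ~1.8%
residual at `theta A = 0.01` and <1% only below `theta A ~ 5.6e-3`.

### Gaussian fluctuating membrane

Bending fluctuations displace the rigid stack vertically by
`h = l_alpha W`, with W a unit-variance stationary Gaussian field with
space-time covariance `g_W` (README).  `g_W` is exactly the normalized
covariance of Gaussian wave packets of size `l_xy` diffusing with
coefficient D and superposed with random signs — verified against a direct
packet simulation.  Compression (thickness) fluctuations are excluded by
construction.  Because the displacement is rigid,

    FT_{r_z} C(r_z, r_xy, tau) = |rho(q_z)|^2 exp[-q_z^2 l_alpha^2 (1 - g_W(r_xy, tau))],

whose `g_W -> 0` limit is the average-structure (slab-like) term
`2 pi |rho(q)|^2 e^{-q^2 l_alpha^2} / q^2` and whose remainder is the
fluctuation term.  The same statistics expressed through layer-occupation
probabilities (one-point normal, two-point bivariate-normal rectangle
probabilities with correlation `g_W`) are implemented in
`layer_probabilities` / `membrane_correlation` and agree with the
transformed route to quadrature accuracy; intensities use the transformed
route because it is exact in `q_z` and needs no z grid.

The roughness factor (true/projected area) follows from the gradient
variance of `h`: `|grad h|^2` is exponential with mean
`m = l_alpha^2 / l_xy^2`, giving
`E sqrt(1+|grad h|^2) = 1 + (sqrt(pi m)/2) erfcx(1/sqrt(m))` — about 1.06
at `l_alpha = 23 A`, `l_xy = 63 A` under this `g_W` normalization.  (The
numeric value is convention-dependent: a `1/(2 l_xy^2)` Gaussian exponent
instead of `1/(4 l_xy^2)` would double `m`; reported values near 1.2 for
comparable membranes correspond to such alternative normalizations.  The
package treats `l_xy` consistently under its own convention, which rescales
fitted `l_xy` and D without changing model expressiveness.)

The correlation time is reported as `tau_c = l_xy^2 / (4 D)` with the
formula printed alongside (the factor 4 from the 2D mean-square
displacement `4 D tau`); it is never hard-coded as a number.

### NSE

NSE is computed from the average-SLD membrane term alone: with neutron
contrasts the protein addend is two orders of magnitude below the membrane
term, so proteins enter only through the averaged SLDs.  The normalized
surface is monotone non-increasing in tau with plateau
(average term)/(total at tau = 0).

## Numerical choices

* Rotational (mu) average: Gauss-Legendre, order 64 on mu in [0, 1] (the
  integrand is even); an order-doubling check with relative tolerance 1e-4
  raises with diagnostics on failure.
* Hankel transforms: trapezoid on r in [0, r_max] with 2048 nodes;
  `r_max = max(6 * 2R_p, 6 sqrt(2 D_p tau) + 2R_p)` for protein
  correlations (compact support) and `8 l_xy sqrt(1 + D tau / l_xy^2)` for
  membrane fluctuation kernels.  Fit evaluators freeze the radial grid from
  an upper bound on `l_xy` (150 A) so Bessel kernels are cached across
  optimizer iterations.
* Exponentials are always formed as `exp(-q_z^2 l_alpha^2 (1 - g))`
  (bounded by 1), never via `exp(+q_z^2 l_alpha^2 g)`.
* Bivariate-normal rectangle probabilities: Owen's-T decomposition
  (`scipy.special.owens_t`), ~1e-14 accurate, with explicit `|rho| -> 1`
  and zero/infinite-bound limits; validated against
  `scipy.stats.multivariate_normal`.
* z quadrature (probability route only): midpoint grid with spacing
  `min(layer thickness, l_alpha)/4` extending `5 l_alpha` beyond the stack
  (0.02 A spacing in the rigid limit, where the profile is discontinuous).
* Degenerate inputs: `l_alpha = 0` short-circuits to the slab everywhere;
  `q = 0` is excluded from intensity grids (per-area convention diverges);
  zero-thickness layers are dropped; the Boolean inverse requires
  `phi_p < 1`.

## Realization simulator and FFT oracle

Height fields are synthesized spectrally on a periodic n x n grid: mode
variances come from the analytic spectrum
`l_alpha^2 4 pi l_xy^2 e^{-k^2 l_xy^2} / dx^2` (the DFT of the wrapped
covariance is avoided — its wrap-seam kink leaks spurious high-k power),
and successive times evolve each mode as an AR(1) process with correlation
`e^{-k^2 D dt}`, the exact spectral transcription of `g_W`.  Boolean discs
are a Poisson number of uniform centres with Brownian motion, periodically
wrapped; coverage is sampled pointwise at voxel centres (pointwise sampling
preserves two-point statistics at lattice lags exactly).

Voxelization assigns each lateral column the membrane (or protein) contrast
profile shifted by the local height.  The profile is apodized with a
Gaussian of width `1.25 dz` before point sampling: the sampled field is
then analytic in the height (no staircase harmonics in the lateral
spectrum) and z-aliasing is suppressed below e^-30; the analytic
expectation carries the identical `e^{-q_z^2 sigma^2}` factor, so the
comparison is exact.  A `smear_z = 0` mode with exact voxel averages exists
for static fields.  Intensities are `|FFT|^2 / L^2` binned into isotropic
shells of width `2 pi / L_z` — chosen so the estimator is consistent for
the slab's transverse delta sheet (each shell captures one pair of axis
modes) — and `lattice_expected_intensity` bins the analytic per-mode
expectation over the same lattice, making the oracle comparison free of
binning bias.  Default boxes: L = 512 A laterally (n = 128 or 256, i.e.
4 or 2 A voxels), L_z = 256 A at 1 A; comparisons use 12 seeds with
seed-scatter standard errors, and lateral grids/q windows are chosen so
2D aliasing of the protein spectrum tail stays well below one standard
error.

## Fitting

`ElasticModel` performs joint weighted least squares across datasets with
shared geometry; per-dataset scale and background are profiled out
analytically at every iteration (linear subproblem), so the optimizer sees
only the geometric parameters, with positivity bounds and 5 seeded
multistarts.  Weights are `1/sigma` when uncertainties exist, else `1/I`.
Uncertainties come from the curvature at the optimum; `chi^2/dof` and the
derived total thickness `2(l_C + l_H)` are reported.  Joint
SAXS+SANS fitting (shared geometry, per-radiation SLD tables) is the
default; per-dataset fitting is a CLI switch.  `NSEModel` fixes all
structural parameters and fits D alone against every (q, tau) cell.

## Synthetic data: what it shows and what it does not

The fixture generator reproduces the statistical structure of reduced
data — instrument-like q windows (8e-3 to 0.5 1/A), the three NSE q values
0.036/0.071/0.109 1/A with spin-echo times to 500 ns, multiplicative
Gaussian noise (2% elastic, 5% NSE) with stored sigmas, reference truths
`l_C = 16.3`, `l_H = 5.0`, `l_alpha = 23`, `l_xy = 63 A`,
`D = 1.85 A^2/ns`, `phi_p = 0.23`, equivalent band 3 radius 21.4 A, and
the standard X-ray/neutron SLD tables.  It does not emulate instrument
resolution smearing, multilamellar Bragg contamination, incoherent
backgrounds with structure, correlated reduction errors, or concentration
effects; recovery results on these fixtures therefore demonstrate
identifiability and estimator correctness under the stated noise model,
not robustness to those real-data effects.  Resolution smearing and
Bayesian posterior exploration are out of scope.

## Known limitations

* The hard-disc structure factor is a low-density closure; no dynamic
  extension exists on that path (the Boolean path covers dynamics).
* Protein placement is independent of membrane conformation — no
  curvature coupling.
* Monodisperse cross-sections only; no inter-protein attraction.
* The Gaussian membrane includes bending only; compression fluctuations
  and a physical (bending-rigidity) interpretation of D are out of scope.
* Asymmetric bilayers are expressible via raw `LayerStack`s but have no
  convenience constructor.
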