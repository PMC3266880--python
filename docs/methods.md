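# Methods

## The quenched-oscillator route to Turing patterning

Classical diffusion-driven (Turing) instability is usually presented in
the activator–inhibitor frame: two diffusible species, one
self-enhancing, one long-range inhibitory. The architecture modelled
here is different. An intracellular *oscillator loop* — a three-stage
repression ring — is intrinsically unstable and would oscillate on its
own. A second, *quenching* feedback loop reads the oscillator's state
through a diffusible messenger and feeds back so as to suppress the
oscillation: the well-mixed system has a stable homogeneous steady
state. Because the quench signal is carried by the one diffusible
species, spatial modes of high wave number dilute the quench — the
messenger produced by a short-wavelength fluctuation diffuses away
before it can act locally — and the oscillator's instability re-emerges
mode by mode. The result is diffusion-driven instability with a single
diffuser, producing patterns that oscillate in both space and time.

Linearizing the reaction system about its homogeneous steady state
gives `du/dt = (A − μ_k D) u` per spatial cosine mode
`cos(kπx/L)`, where `A` is the reaction Jacobian, `D` the diagonal
diffusion matrix (one nonzero entry) and `μ_k = (kπ/L)²` the Laplacian
eigenvalue under zero-flux boundaries. Three conditions define the
patterning regime:

1. the oscillator block `A11` (the ring sub-Jacobian) has an eigenvalue
   pair with positive real part;
2. `A` itself is stable — the quench works when well mixed;
3. `A − μ_k D` is unstable for some integer `k ≥ 1`.

Because exactly one species diffuses, instability of `A − sE` (with `E`
the unit matrix at the diffuser's diagonal) depends on the product
`s = D·μ` alone. The package computes the critical `s*` by bisection on
the leading eigenvalue real part (relative tolerance 1e-8, geometric
bracketing capped at 1e8) and derives the minimum unstable integer wave
number from it. As `D·μ → ∞` the surviving eigenvalues approach those
of the reaction system with the diffuser removed, whose leading part is
the oscillator block's — which is why condition 3 follows from
condition 1 at large enough `D·μ` and why, empirically, condition 3
implies condition 1 on every parameter draw we test. All eigenvalue
work is numeric (`numpy.linalg.eigvals`); real parts within ±1e-12 of
zero are flagged marginal rather than silently classified. Symbolic
closed forms exist for the four-species model but do not scale to the
ten-species circuit, so the numeric path is primary.

## The two models

**Toy model** (dimensionless). Species X1–X3 form the repression ring
(X1 ⊣ X2 ⊣ X3 ⊣ X1); X4 closes the quench loop (X1 ⊣ X4, X4 → X1) and
is the only diffuser. All degradation rates are scaled to 1, the
domain to [0, 1]. Production terms are Hill functions with a common
exponent h. A three-stage ring with Hill exponent h has ring gain
product strictly below h³ (each stage's normalized gain is bounded by
h·u/(1+u) at its operating point), and the ring instability condition
requires the product to exceed 8; h = 2 therefore cannot oscillate and
the packaged fixture uses h = 4. The shipped parameters
(p = 10, 2, 10, 10, 8) give an instability threshold D·μ* ≈ 13.41, so
with D = 1 the k = 2 mode (D·μ₂ = 4π² ≈ 39.5) grows while k = 1 does
not; with D = 0.25 the k = 2 mode decays slowly (rate ≈ −0.03) and with
D = 0 quickly (≈ −0.18). Those three regimes are the package's
reference demonstration.

**Genetic circuit** (nM, hours, µm). The oscillator loop is the
repressilator — TetR, λ cI and LacI repressing each other's promoters
in a ring, with transcription and translation resolved (six states).
The quench loop couples in through TetR: TetR represses a second
promoter driving *luxI*; LuxI synthesizes the membrane-diffusible
signal AHL; AHL binds the constitutive LuxR pool; the LuxR–AHL complex
homodimerizes and activates a lux promoter driving a second copy of
*tetR*. The tetR mRNA is therefore split into an oscillator-derived and
a quench-derived pool sharing one protein. Ten states evolve
dynamically (five mRNAs, four proteins, AHL); the LuxR–AHL complex is a
derived quantity under the fast-binding (QSSA) assumption, solved from
the conservation-consistent quadratic
`(R_T − RA)(A − RA) = K_d·RA` in the numerically stable form
`RA = 2·A·R_T / (S + √(S² − 4AR_T))`, `S = A + R_T + K_d`. Promoter
responses are leaky Hill functions `l + (1−l)/(1+(x/K)^h)`
(repression) and the mirror image (activation); mRNA production is
copy-number × velocity × response, so rate vectors are invariant under
`(n, k) → (αn, k/α)`. Total LuxR is constant by construction.

The quench loop must have less phase lag than the oscillator loop, so
its stages (luxI mRNA, LuxI, AHL, quench tetR mRNA) degrade 2–5×
faster than the oscillator species in both parameter sets.

## Parameter fixtures

The packaged fixtures are reconstructions: kinetic values were chosen
once, from ranges typical of the underlying parts (plasmid copy number
4; transcription tens–hundreds nM/hr per copy; mRNA half-lives of
minutes; tagged-protein half-lives tens of minutes; repressor K_d tens
of nM; leakage 0.2%), subject to the structural requirements stated for
each set, and then frozen. They are labelled as reconstructions in the
YAML files.

* **Parameter Set 1** (deterministic regime): satisfies the three
  conditions with threshold ≈ 7.3/hr and minimum unstable wave number 2
  on the 100 µm domain; its smallest steady states sit near or below
  one molecule per cell (0.87 molecules), which is precisely why a
  discrete treatment of this set is dominated by noise and why a second
  set exists. Well-mixed damped-oscillation period ≈ 4.4 hr.
* **Parameter Set 2** (stochastic regime): the same topology with
  faster rates (period ≈ 2.2 hr), a stronger quench, and operating
  concentrations raised — velocities and dissociation constants
  co-scaled, which leaves the loop gains nearly unchanged — until every
  steady state clears 4 molecules per cell (minimum 4.1). The LuxR pool
  is pinned at 12 molecules per cell (19.9265 nM at C = 1.66054
  nM/molecule), so at most six promoters can ever be bound by complex
  homodimers; this hard bound is a genuinely discrete feature no
  concentration model reproduces. Threshold ≈ 13.4/hr, minimum unstable
  wave number 2.

Cells are 1 µm cubes (1 fL), giving the single-molecule concentration
C = 1e9/(N_A·1e-15) ≈ 1.66054 nM; C is stored in the fixtures and
cross-checked against the cell volume. The AHL diffusion coefficient is
an effective value for transport across a dense line of cells,
5·10³ µm²/hr — far below the free-solution value, reflecting
membrane-permeation-limited exchange — chosen once so that the unstable
band begins at small but nonzero wave number on the 100-cell domain.

## Deterministic simulation

Method of lines on an evenly spaced vertex grid (default 101 points for
the 100 µm line, i.e. one cell per grid interval), 3-point Laplacian
with mirror ghost points for zero flux. The single-cell geometry places
one reacting grid cell at the centre of a 50 µm empty volume; only AHL
diffuses, with Dirichlet zero ends ("the signal diffuses away"); with
diffusion off the centre cell is bit-identical to the well-mixed ODE.
Integration is BDF (`scipy.integrate.solve_ivp`) with the analytic
sparse Jacobian (per-point reaction blocks plus the constant diffusion
tridiagonal); tolerances rtol 1e-6, atol 1e-9 × per-species scale.
Values in (−atol, 0) produced by the solver are clipped to zero with a
logged count. The PDE system has no noise: a homogeneous initial state
stays homogeneous to solver tolerance, and perturbations are imprinted
explicitly as single cosine modes, default amplitude 10% of the
perturbed species' steady state peak-to-peak (the reference
harmonic-cascade run uses 50% so that saturation is reached inside its
30 hr window).

Mode growth is measured as the least-squares slope of log |DCT_k|
versus time. Quenched-oscillator Turing modes grow with an oscillating
phase, so when the mode amplitude itself oscillates (≥ 3 local maxima
in log scale, prominence 0.5 log-units) the slope is fitted on the
envelope maxima, which removes the bias from zero crossings. Measured
rates match the dispersion relation within ~1% for a 2% imprint over
the linear window; a 10% imprint leaves the linear regime within tens
of time units, which bounds the windows used in the checks.

## Stochastic simulation

The Hill responses of the deterministic model are expanded into
elementary mass action per cubic cell: repressors dimerize
(2P ⇌ P₂), dimers bind enumerated operator sites (P₂ + O ⇌ OP₂), AHL
binds LuxR (R + A ⇌ RA), the complex homodimerizes (2RA ⇌ RA₂) and
RA₂ binds the lux operator. Transcription fires from free operators at
the full velocity and from bound operators at the leak velocity
(mirrored for the activated promoter). Every protein-containing form
decays at its protein's rate (bound forms release the operator), so
total protein obeys exactly the deterministic balance; every
AHL-containing form decays at γ_A with LuxR recycled, so total AHL
obeys the PDE law and total LuxR is conserved to the molecule. Promoter
site totals are conserved per cell by construction and checked at build
time. Equilibrium constants are split as K_d² = K_dimer·K_operator with
K_dimer large (1e5 nM for repressors), placing the system in the
monomer-dominated regime where the deterministic Hill form is the exact
fast-equilibrium limit; with binding rates sent to that limit at
inflated volume the mean-field steady state of the generated reaction
set matches the deterministic model to < 1% per species. Forward rates
default to documented fast values (dimer dissociation 1000/hr, operator
association 2000/nM/hr, AHL–LuxR association 200/nM/hr); the
deterministic model constrains only the ratios.

AHL hops between adjacent compartments at D/h² per molecule per
direction (reflecting ends for the line; for the single cell, an
explicit 51-compartment empty volume with absorbing far ends).
Sampling is the exact next-reaction method: per-channel absolute
firing times in an indexed binary heap, a precomputed dependency graph,
exponential rescaling of non-fired dependents and fresh draws on
reactivation from zero propensity (valid by memorylessness), compiled
with numba. A (model digest, seed) pair fully determines the output;
recording at fixed intervals does not perturb the dynamics. Typical
throughput is a few million events per second; the 100-cell, 30 hr
reference run is ~4·10⁸ events.

Initial conditions round the deterministic steady state to whole
molecules (AHL split into free and complexed parts via the QSSA,
operators free). Reported totals use monomer equivalents: dimers count
2, promoter-bound dimers count 2, and AHL totals include
receptor-bound ligand.

## Pattern metrics

Zero-flux boundaries make cosines the Laplacian eigenfunctions, so
spectra use the DCT. Two pinned conventions: orthonormal type-II for
cell-centred (compartment) data, where Parseval holds exactly; type-I
with trapezoid endpoint weighting (end samples scaled by 1/√2 around
the orthonormal transform) for vertex-centred PDE grids, which makes
the sampled cosines exactly orthogonal so that `cos(kπx/L)` maps to
coefficient k alone. Both are invertible to 1e-12. Time-averaged
spectra take the mean of |DCT| over a window (absolute values prevent
sign cancellation of oscillating modes) and omit the k = 0 offset by
default, since non-negative concentrations always carry a dominant
offset. The low-pass measure divides the mean magnitude over the top
quartile of wave numbers by that over the bottom quartile (k ≥ 1);
diffusion attenuates high wave numbers, so the diffuser scores lowest.
Oscillation periods come from prominence-thresholded peaks
(prominence 10% of range, moving-average smoothing 1% of the sample
count) with the spread of inter-peak spacings as the uncertainty;
monotone series and series with fewer than three peaks are flagged
rather than estimated.

## What the reference simulations show — and what they do not

The deterministic phenomenology is reproduced in full: imprinted waves
above the threshold grow and below it decay (both models); the
quenched single cell decays to steady state without diffusion and locks
onto a regular limit cycle when AHL drains away, with a longer period;
the Set 2 line grows its imprint and then cascades energy into
harmonics of the imprinted wave number.

The stochastic reconstruction reproduces the qualitative discrete
effects: stochastic periods exceed the matched PDE periods, the
diffusing single cell oscillates slower and with larger amplitude than
the non-diffusing one, firing-like excursions appear in the quenched
cell, the line of cells develops large oscillations from a homogeneous
start, and the AHL spectrum is low-passed relative to every
non-diffusing species. Two quantitative stochastic benchmarks this architecture is expected
to reach are *not* reproduced at that magnitude by the reconstructed
parameters: the stochastic slowdown here is ~1.1× rather than ~5–10×,
and the line's amplitude saturates within a few hours rather than
around hour 20 (late/early excursion ratio ~2 rather than > 5). Both
trace to the same physics: with a 12-molecule LuxR pool and
weak-dimerization kinetics (required for the deterministic Hill limit
to be exact), the quench loop is noisy enough that cells leave the
steady state quickly. Slowing the elementary binding kinetics deepens
the slowdown but makes the homogeneous state noisier still; speeding
them quiets the cells but removes the slowdown. The acceptance script
reports the measured ratios; the corresponding tests assert the
published magnitudes and fail, documenting the gap rather than hiding
it.

## Problem sizes used in the checks

Stability oracle comparisons use 200 random log-normal parameter draws
per model (60 in the unit suite) against a brute-force eigenvalue scan
over k = 0..50. Linear-regime checks use 101-point grids and 2%
imprints. The stochastic period comparison averages 20 seeds per
condition in the test suite and 8 in the acceptance script; the
line-of-cells run is 100 cells for 30 hr (the long-horizon 50–80 hr
spectral window is accessible by raising `t_end` in the `fig8`
protocol). Exactness checks use ≥ 1e5 events for stationary moments,
1e4 events for waiting times, and a 100× volume inflation for the
law-of-large-numbers comparison.

## Known limitations

One spatial dimension only; no cell growth, division or dilution; no
tau-leaping or hybrid acceleration (the exact kernel is fast enough at
these molecule numbers); dimer accounting conventions are pinned but
other conventions exist; the elementary reaction set realizes Hill
coefficient 2 only (dimer binding) and rejects other exponents; the
parameter fixtures are reconstructions, not measured values, and the
stochastic magnitudes above should be read accordingly.
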