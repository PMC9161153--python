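# Methods

`mlcmd` implements machine-learning facilitated centroid molecular
dynamics (ML-CMD) on self-contained model systems: the quantum centroid
force is sampled exactly, its locality is quantified analytically, the
quantum force *correction* is learned by a localized atomic-environment
model, and dynamics with the learned correction run at classical cost.
This note records the models, the numerical choices, and what the
bundled tests do and do not demonstrate.

## Path-integral background and conventions

An atom at inverse temperature β = 1/kT is represented by a cyclic ring
polymer of P beads x₁…x_P with Boltzmann weight

    exp{ −β [ Σ_k ½ m ω_P² (x_{k+1} − x_k)² + U(x_k)/P ] },  ω_P = √P/βℏ,

whose P → ∞ limit reproduces the quantum Boltzmann distribution.  The
centroid x_c = (1/P) Σ_k x_k is the coarse-grained coordinate of
centroid MD; its potential of mean force U_c has the mean force

    F_c(x_c) = ⟨ (1/P) Σ_k F(x_k) ⟩ | centroid fixed at x_c,

an identity that holds exactly at finite P.  The learning target is the
quantum correction ΔF_c = F_c − F, with F the classical force at the
centroid geometry.

Internal units are Å, fs, amu, kJ/mol, K.  Path-integral formulas are
evaluated in the mechanically consistent energy unit amu Å²/fs²
(= 10⁴ kJ/mol up to the molar-mass constant), which removes all unit
juggling from ω_P, thermostat noise and width formulas; conversion
happens once, at module boundaries.

## PIMD sampler (`ringpolymer`)

Normal-mode representation with exact free-ring-polymer propagation and
per-mode Langevin friction (PILE): internal mode k of frequency
ω_k = 2ω_P sin(πk/P) is damped at γ_k = 2ω_k, the centroid at the
user's friction constant (default 1.0 ps⁻¹).  The integrator splitting
is O–B–A–B–O with one force evaluation per step; the default timestep
is 0.5 fs.  Fictitious mode masses equal the physical mass on every
mode — only the sampled configurational distribution matters here, not
mode dynamics fidelity.

Fixed-centroid sampling freezes the centroid mode (its momentum and
force are zeroed every substep), making the constraint exact in mode
space; observed centroid drift is at the 1e-10 Å level over 10⁵ steps.
Beads start collapsed on the target geometry; the first 10% of steps
are discarded as burn-in; the statistical error of the mean bead force
is estimated by block averaging over 20 blocks, and a record whose
maximum SEM exceeds a tolerance (default 0.2 kJ/(mol·Å)) is flagged
rather than discarded.  The bead-count policy is 32 beads at room
temperature and 64 at 100 K.

Classical MD (`dynamics.run_md`) is the exact P = 1 special case of the
same integrator, so ML-CMD and classical trajectories share one code
path, and a zero correction reproduces classical MD bitwise.

## Exact 1D fixed-centroid oracle (`oracle`)

For one-dimensional potentials the constrained centroid density is
computed without sampling.  The centroid constraint is written through
its Fourier representation, ρ_c(x_c) ∝ ∫dλ e^{−iλx_c} Tr[(T D_λ)^P],
with T the symmetric single-link transfer matrix on a dense position
grid and D_λ = diag(e^{iλx/P}).  The trace is evaluated by matrix
powering for every λ on the conjugate grid (the spectrum is truncated
once it falls below 1e-15 of its λ = 0 value), and ρ_c, its spectral
derivative and hence F_c = kT ∂ln ρ_c/∂x_c follow by band-limited
synthesis at arbitrary output points.  At matched P this is the exact
law the fixed-centroid sampler draws from, so sampler and oracle are
two independent routes to the same quantity — the basis of the
equivalence test.

Diagnostics: the centroid density must decay below 1e-6 of its maximum
at the quadrature-domain edges, and the constraint spectrum must decay
by the Nyquist frequency; violations raise a convergence error instead
of returning silently wrong tables.  Unconfined systems (free particle)
cannot satisfy the edge criterion on a finite box — `strict_edges=False`
reports the box interior only, which is how the F_c ≡ 0 free-particle
check is run.  A `check_P` option recomputes at 2P and fails if the
mean force moves by more than 1e-3 kJ/mol/Å.  The quartic high-T
consistency check asserts the 1/T decay of U_c − U rather than a fixed
small number: at 3000 K the residual quantum correction
(≈ (3/2)cσ²x², σ² = ℏ²β/12m) is still of order 0.01–0.1 kJ/mol over
the thermally accessible range — a physical effect, not a numerical
error.

## Locality theory (`locality`)

The bead-distribution second moment of an atom in a locally harmonic
potential is the Matsubara-mode sum

    ⟨x²⟩ = (βℏ²/2π²m) [ −1/2t² + (π/2t)coth(πt) ],  t = βℏω/2π,

bounded above by the free-particle/Feynman–Hibbs value ℏ²β/12m and by
the harmonic-oscillator ground-state variance ℏ/2mω.  ω is accepted in
cm⁻¹ (spectroscopy convention; the worst case for water-like systems is
the ≈670 cm⁻¹ hydrogen libration).  coth is evaluated through expm1 and
saturates to 1 beyond z = 350, and t < 1e-4 switches to the series
π²/6 − π⁴t²/90, so the formula is overflow-free over T ∈ [0.1, 10⁶] K.
An independent direct summation (10⁶ modes plus an integral tail) is
kept as the oracle for the closed form.

The relative quantum correction to a Coulombic pair force at separation
R is bounded by (3/R²)(⟨x_i²⟩+⟨x_j²⟩−2⟨x_i x_j⟩); dropping the
cross-correlation gives the ambient estimate, and Cauchy–Schwarz gives
the worst case 12⟨x²⟩/R².  At R = 4 Å these evaluate to ≈0.43% (300 K)
and ≈1.87% (maximized over 1–1000 K) for hydrogen — the quantitative
justification for a 4 Å learning cutoff.  The cross-correlation decays
with distance on its own; it is exposed as an argument rather than
modeled.  The "below 0.15 Å at all temperatures" width statement is
verified on the documented grid 100–500 K; the pure T → 0 asymptote
(0.158 Å) exceeds it, so the claim is range-dependent by nature.

## Feynman–Hibbs baseline (`fhc`)

The Gaussian-smearing effective potential K(x) = (U ∗ N(0, σ²))(x) with
σ² = ℏ²/12mkT, and the pairwise second-order correction
(βℏ²/24μ)[u″ + 2u′/r].  The 1D convolution uses trapezoid quadrature on
a uniform grid (spectrally accurate for smooth integrands) and returns
only the interior points where less than 1e-10 of the kernel mass falls
outside the tabulated domain; a kernel narrower than a quarter grid
spacing returns the identity.  The Coulomb pair correction vanishes
identically (the 1/r Laplacian), which doubles as a test landmark.

## Learned correction model (`mlcorrection`)

Embedded-atom-style descriptor: for each of 11 Gaussian radial centers
spanning [0, r_c] and each angular order l ≤ 2, the feature is the
multinomially weighted squared Cartesian-moment sum over neighbors
within r_c (default 4 Å), with per-element embedding coefficients and
the cutoff function ½(1+cos πr/r_c) making everything C¹ at r_c and
exactly zero for an isolated atom.  Features are invariant under
rotation, translation and same-element permutation by construction;
analytic position gradients are verified against finite differences at
1e-5 relative.  The Gaussian width parameter α defaults to
1/(2·spacing²).  Neighbor search is a brute-force distance matrix
(systems here are ≤ a few hundred atoms); periodic systems use the
minimum image.

Per-element tanh networks (default 2×20, configurable down to a pure
linear readout) map normalized features to atomic energies whose
negative gradient is the predicted ΔF_c — conservative, summing to zero
over atoms, and equivariant.  Only forces are ever fitted: fixed-
centroid sampling yields no energy labels, so the scalar is defined up
to a constant and the output bias is dropped.

Training = force matching in two stages.  Stage 1 (ELM): hidden weights
are drawn from a seeded stream; the predicted forces are then *linear*
in the output-layer weights, which are obtained by one ridge-regularized
least-squares solve.  Stage 2: Levenberg–Marquardt on all weights, with
a finite-difference Jacobian over a precomputed force-assembly structure
(forces are linear in the per-atom feature gradients, so only the small
network pass is repeated per parameter).  The loss is the RMS force
residual in kJ/mol/Å; the convergence threshold defaults to 0.1 and is
a parameter.  Training is bitwise reproducible for a fixed seed.

Model capacity is matched to data: for the 1D quartic closure (20
training geometries) the linear readout over the smooth GTO features is
used — a 40-output-weight network interpolates 20 constraints exactly
and oscillates between them, whereas the linear model generalizes to
≈1% of max|ΔF_c|.  The hidden-layer default is for many-atom datasets
(hundreds to thousands of atomic environments), where the teacher–
student closure recovers a known model to <1% in-domain and ≈0.6%
held-out force RMSE.

One-dimensional systems are represented for learning as anchored pairs:
a fictitious anchor atom at the origin gives the moving atom an
environment whose single distance encodes |x|, and the odd correction
force is exactly representable as the gradient of a scalar of that
distance.  The anchor carries the reaction force, preserving
translation invariance.

## ML-CMD propagation and observables (`dynamics`, `analysis`)

ML-CMD = velocity-Verlet/Langevin dynamics on classical forces plus the
predicted ΔF_c.  Structural observables (RDFs) are computed on centroid
variables.  Pressure uses the pair-virial form (N kB T + W/3)/V;
self-diffusion uses multiple-origin MSD with a log-log-slope diagnostic
that flags ballistic or arrested regimes.  NPT is out of scope;
pressure–density curves are produced by NVT scans.

For the distribution-recovery test, many statistically independent
copies of the anchored quartic system are batched into one
configuration (anchors 10 Å apart — beyond twice the descriptor cutoff,
so the walkers cannot interact through the model or the potential).
This gives ~10⁵ centroid samples from a few thousand integrator steps.
At 100 K, 64 beads, quartic stiffness c = 10 kJ/mol/Å⁴ and hydrogen
mass, the quantum centroid distribution is visibly narrower than the
classical one; ML-CMD reproduces exp(−βU_c) to a Kolmogorov–Smirnov
distance of ≈0.01 while classical MD sits at ≈0.04.

## Pipeline and synthetic systems (`pipeline`, `potentials`)

The toy water model is a flexible 3-site molecule: harmonic O–H bonds
(k = 4000 kJ/mol/Å², r₀ = 1 Å), harmonic H–O–H angle (300 kJ/mol/rad²,
109.47°), LJ on oxygen (ε = 0.65 kJ/mol, σ = 3.166 Å) and SPC-like
point charges (−0.82/+0.41 e) with bare 1/r Coulomb — deliberately
generic, not a fit to any published water force field.  Bulk boxes are
built at 0.997 g/ml by rejection insertion plus damped steepest-descent
relaxation and a short Langevin equilibration; periodic interactions
use the minimum image with a shifted cutoff (no Ewald — locality
arguments need only generic pair interactions, and bulk electrostatics
is out of scope).

Cluster extraction follows the first-solvation-shell recipe: a random
frame, a random central molecule, its 7 nearest molecules by
center-of-mass minimum-image distance, unwrapped to one contiguous
image and stripped of periodicity.  Defaults in configuration files are
2000 clusters and nanosecond sampling; the bundled tests run tens of
clusters and picosecond sampling, which keeps every statistical
tolerance expressed in units of the measured SEM.

For the toy box the pipeline tests use a 3 Å descriptor cutoff: at this
density the atoms that octamer extraction removes can sit well inside
4 Å of a cluster atom, so a 4 Å descriptor sees systematically
truncated environments, while at 3 Å the missing atoms fall where the
cutoff function is ≈0.02.

## What the tests show — and what they do not

The synthetic systems exercise every mechanism of the method — exact
constrained sampling, locality bounds, conservative localized learning,
classical-cost propagation — but they are not bulk water: there is no
Ewald electrostatics, no polarizability, and cluster/sampling counts
are orders of magnitude below production scale.  Consequently the
cluster-to-bulk transferability of the learned correction is
demonstrated here only in its mechanism (strict locality of the
prediction, teacher–student recovery, walker-lattice independence), not
at the statistical scale where the correction model trained on octamers
matches bulk reference forces within a factor two of its in-domain
residual; that regime needs training sets far larger than a test suite
can generate.  Bulk diffusion constants and experimental-force-field
RDF comparisons are likewise out of scope by design.
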