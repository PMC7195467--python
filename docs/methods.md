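# Methods

This note documents the models, conventions, and design choices behind the
toolkit: what each component computes, which parameters matter, what the
synthetic fixtures emulate, and where the genuinely open choices were made.

## Units and constants

Energies are Hartree, lengths Angstrom, forces Ha/Å, masses amu, time fs.
Conversions: 1 Ha = 627.5094740631 kcal/mol; k_B = 3.166811563×10⁻⁶ Ha/K;
the MD integrator converts Ha to amu·Å²/fs² via CODATA constants
(scipy.constants), so velocities are Å/fs.  The dataset layer stores units
as the format defines them (Ha, Å, Ha/Å, e·Å, a.u.) and performs no
conversion.

## Ensemble disagreement

`rho` is the population (ddof = 0) standard deviation of the ensemble's
per-member total energies, converted to kcal/mol and divided by √N_atoms.
The proportionality constant is fixed at 1, so `rho` carries units
kcal/mol·atom^(−1/2); selection thresholds are configuration values, not
constants of the method, and the shipped defaults (around 1) are arbitrary
placeholders scaled to the surrogate potentials.  Selection is strict
(`rho > threshold`), so a zero threshold still excludes exactly-agreeing
ensembles.

## Langevin MD sampler

The integrator is BAOAB splitting: half kick, half drift,
Ornstein–Uhlenbeck velocity update with `c1 = exp(−γ dt)` and noise
amplitude `sqrt((1−c1²) kT/m)`, half drift, half kick with forces
recomputed at the new positions.  With γ = 0 the map reduces exactly to
velocity Verlet, which is why `langevin_step` takes a force callback — a
stale-force final kick would break symplecticity and show secular energy
drift.  Defaults follow the sampling protocol the datasets were built
with: temperature drawn uniformly from 50–800 K per trajectory, dt 0.5 fs,
friction 0.02 fs⁻¹, disagreement checked every 5 steps, trajectory
terminated at the first trigger.  `max_steps` (default 10 000) caps
trajectories that never trigger; the protocol itself specifies no cap.
Velocities initialize from Maxwell–Boltzmann at the drawn temperature.
Instantaneous kinetic temperature uses all 3N degrees of freedom; on small
test systems the time average carries O(1/√(N_dof·N_eff)) statistical
noise, which is why the thermostat checks use a 5-atom system and 2×10⁵
steps against a 5 % band.

## Normal-mode sampling

Modes are stored as mass-orthonormal Cartesian vectors `u_i`
(`u_iᵀ M u_j = δ_ij`, M in amu) with force constants `k_i` equal to the
mass-weighted Hessian eigenvalues, so a displacement `q·u_i` has harmonic
energy `½ k_i q²`.  Each generated conformer displaces every mode by
`q_i = ± sqrt(2 c_i kT / k_i)` with independent `c_i ~ U[0,1)` and random
sign: the per-mode energy is bounded by kT and averages kT/2, which the
tests verify to 5 % over 10⁴ draws.  The displacement rule is this
package's concrete choice for "random displacement along each normal
mode"; the sampling temperature (default 300 K) and the number of
conformers per molecule are configuration.  Modes with non-positive force
constants (rigid-body remnants, saddle directions at halted scan points)
are skipped with a warning.  When no external modes are supplied, a
central finite-difference Hessian (step 0.005 Å) of the ensemble-mean
energy provides them; the 6 smallest-|λ| modes are dropped (5 would be the
choice for a linear molecule, exposed as `n_remove`).

## Dimer sampler

Box construction draws each cell edge uniformly from 20–30 Å, selects
molecules with probability ∝ n_heavy^(−exponent) (default exponent 1;
hydrogen-only molecules count as one heavy atom) until a target atom
density — drawn uniformly from 0.005–0.02 atoms/Å³ — is met, and places
each molecule with a uniform random rotation (normalized random
quaternion) and position, rejecting placements with any cross-molecule
minimum-image distance below 1.5 Å.  The density range is this package's
choice; the protocol states only that density is randomized.  Monomers are
kept whole (coordinates never wrapped); the rectangular cell defines only
the minimum-image metric, including for the pair forces used during the
100-step Langevin stage at 50–600 K.  Decomposition emits one dimer per
unordered molecule pair whose minimum-image contact distance is ≤ 6 Å,
translating the partner molecule by the lattice vector that realizes the
closest contact so the extracted dimer is a free-space structure.  Tests
audit both the placement constraint and the dimer set against a 27-image
brute-force oracle.

## Torsion sampler

A structure provider maps a SMILES string to a 3-D conformation plus
rotatable-bond torsions; the default uses RDKit (embedding seeded from the
run RNG), and a fixture provider serves tests.  The scan: optimize
(L-BFGS on the ensemble mean), then 36 constrained minimizations at +10°
increments from the optimized dihedral.  The constrained minimizer is
projected gradient descent with backtracking: steps move along the force
component tangent to the dihedral constraint (analytic dihedral gradient),
and the dihedral is re-enforced exactly after every step by rigid rotation
of the rotating side, so the returned angle is within 0.1° of target by
construction.  Convergence is max projected force ≤ `opt_tolerance`
(default 10⁻³ Ha/Å); exhausting `opt_max_iter` flags the result instead.
The scan halts at the first point with `rho` above threshold; the halted
structure itself is never selected — instead its harmonic modes (finite
differences of the ensemble mean) generate `n_perturbed = 4` small random
displacements, scaled by a 50 K-equivalent temperature (the "slightly
perturbed" magnitude is unquantified in the protocol; both values are
configuration).  Scan direction and start (+10° steps from the optimized
dihedral) are likewise this package's choice.

## CCSD(T)*/CBS composite

`E = Extrap(3/4, HF) + Extrap(3/4, MP2) − E(3, MP2) + E(3, NPNO) +
E(2, TPNO) − E(2, NPNO)`, with the exponential HF form (α = 5.46) and the
power-law correlation form (β = 3.05), cardinals 2/3/4 = cc-pVDZ/TZ/QZ.
The MP2 and CCSD(T) terms are interpreted as correlation energies — the
dataset keys are `*.corr_energy` and a total-energy reading would
double-count HF — so the composite is HF/CBS plus correlation pieces.
Both extrapolations are affine in their energy arguments and tend to the
quadruple-zeta value as their exponent grows; the public API is double
precision, and the test oracle evaluates the same formulas in extended
precision (sympy at 40 digits; long-double for the batch oracle),
agreeing to better than 10⁻¹² relative.

## Dataset layer

One HDF5 group per isomer, keyed `FORMULA_index`; one dataset per property
with the canonical key strings and dtypes (energies float64, geometric and
per-atom quantities float32, atomic numbers uint8).  Missing per-conformer
values are NaN-padded rather than ragged — the observable behavior of the
published loader — and the filtered iterator keeps exactly the conformers
for which every requested key is non-NaN, preserving order and silently
skipping emptied groups.  The quadrupole's six components are ordered
(xx, yy, zz, xy, xz, yz); the format specifies only the count.
`validate_schema` reports every dtype/shape deviation and unknown key
without raising.

## Surrogate potentials and fixtures

`SurrogateEnsemble` is a pairwise Morse potential
(`D (1 − e^{−a(r−r0)})²`, D = 0.12 Ha, a = 2 Å⁻¹, r0 from covalent radii,
minimum-image aware) with per-member perturbations
`amplitude · η_m · L(x)`, η_m fixed standard-normal draws.  The
localization L is the base energy itself ("global"), a short-range
bond-stretch functional, or a Gaussian window in one dihedral — the last
two give the spatially structured disagreement the sampler tests need.
Forces are analytic and verified against finite differences to 10⁻⁶.
Amplitude 0 makes members identical (rho ≡ 0 exactly).  Energy scales are
chosen so typical disagreements are 0.01–0.1 Ha, keeping kcal/mol
thresholds meaningful.  What the fixtures do *not* emulate: real
electronic-structure surfaces, reactive events, or realistic
conformational ensembles — passing tests demonstrate the correctness of
the sampling/selection machinery and bookkeeping, not the chemical quality
of any dataset produced with real labels.

## Shipped trainer and the toy-surface benchmark

The trainer contract (`fit(dataset) → ensemble`) is filled by an ensemble
of ridge regressors on member-specific random Fourier feature maps
(`φ(x) = sqrt(2/D) cos(Wx+b)`, W ~ N(0, 1/ls²), D = 200 features,
standardized inputs, target mean removed, ridge 10⁻⁶).  Independent random
feature maps per member emulate the initialization diversity of a
neural-network committee: members agree where data constrains them and
diverge away from it, which is the property that makes disagreement a
usable acquisition signal.  (A plain bootstrap committee over a single
interpolator was tried first and rejected: its disagreement correlated
poorly with error on held-out points and uncertainty-driven selection did
not beat random sampling.)  The default ensemble size is k = 8.

The toy benchmark surface is a shallow quadratic bowl with a
high-frequency corrugation confined to a Gaussian patch — a miniature of a
potential surface with an under-resolved hard region.  The benchmark runs
the real `al_iteration` loop on a fixed 400-point candidate pool (15
initial labels, 5 iterations × 10 labels) with selection either by top
disagreement or uniformly at random, and compares the final ensemble's
maximum absolute error on the never-labeled points.  The comparison uses
ten fixed campaign seeds (0–9) with both arms sharing each seed.

## Numerical choices and degenerate inputs

* Dihedral angles use the atan2 convention on (−180°, 180]; the analytic
  gradient follows the Blondel–Karplus construction and is FD-verified.
* `set_dihedral` resolves the rotation-sign ambiguity empirically (apply,
  measure, flip if needed), making the enforced angle exact to 10⁻⁶ °.
* Histograms align bin edges to multiples of the bin width (1 mHa for
  energies, 1 for atom counts); empty input yields empty arrays.
* The per-element energy baseline is OLS on element counts without a
  global intercept (exposed as a flag); a rank-deficient design — e.g.
  every conformer sharing one formula — raises rather than returning an
  unidentifiable fit.
* The 2-D embedding hook defaults to the top two principal axes;
  zero-variance input warns and returns zeros.  Heavier embedders (t-SNE,
  UMAP) plug in as callables.
* XYZ parsing reports the offending line number; coordinates are written
  at 10⁻⁸ Å precision, so round-trips are lossless at that scale.

## Problem sizes used in tests and the acceptance script

Tests run entirely on toy molecules (3–9 atoms), 20–50 random dimer boxes,
10⁴–2×10⁵-step MD trajectories, 10³ random CBS component sets, and
400-point AL pools — sizes chosen so the full suite completes in about a
minute while every statistical check retains comfortable resolution at its
stated tolerance.

## Known limitations

* The loader's NaN-padding convention is verified behaviorally on planted
  fixtures, not against the published multi-gigabyte file; the two
  published loader counts (≈5 M and ≈500 k conformers) are therefore not
  reproduced here.
* `rho` uses energies only; force-based or per-atom disagreement variants
  are out of scope.
* The shipped trainer is adequate for toy-surface recovery, not a
  production interatomic potential; descriptor-based fits on real data
  would need hyperparameter work that is deliberately not attempted.
* Dimer MD applies minimum-image pair forces; whether the original
  campaigns used periodic forces or free-space forces with the cell only
  constraining placement is not documented.
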