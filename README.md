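# alchemforge

Active-learning data generation for machine-learned interatomic potentials:
query-by-committee conformer sampling, a CCSD(T)*/CBS composite
extrapolation for high-accuracy labels, and the conformer-property HDF5
dataset format with its key-filtered loader.

## Who this is for

Building a general-purpose ML potential requires a training set that covers
both chemical space (which molecules) and conformational space (which
geometries).  Uniform or equilibrium-only sampling produces clustered,
redundant data; the remedy used for the large organic-molecule datasets in
this field is **active learning**: train an ensemble of models, look for
structures where the ensemble members disagree, label exactly those with
quantum chemistry, retrain, repeat.  This package implements that loop and
all four of its conformer samplers as a reusable, testable toolkit.  QM
labeling and model training are pluggable contracts, so the entire pipeline
runs against cheap analytic surrogate potentials — no electronic-structure
engine is needed to develop against it or to test it.

## The method

**Acquisition signal.**  For a structure with `N_a` atoms and ensemble
member energies `E_1..E_k` (Hartree), the disagreement is

    rho = sigma_pop(E_1..E_k) * 627.5094740631 / sqrt(N_a)    [kcal/mol/sqrt(atom)]

Structures with `rho` above a configured threshold are collected into
batches for reference labeling.  Four samplers feed the batch:

* **MD sampling** — Langevin dynamics (random T in 50–800 K, dt = 0.5 fs,
  friction 0.02 fs⁻¹); `rho` checked every 5 steps; the trajectory halts at
  the first trigger.
* **Normal-mode sampling** — random signed displacements along harmonic
  modes, each mode given energy `c·kT` with `c ~ U[0,1)`.
* **Dimer sampling** — random 20–30 Å periodic boxes of small molecules
  (≥ 1.5 Å intermolecular separation), 100 MD steps at 50–600 K, then
  decomposition into all molecule pairs in contact within 6 Å.
* **Torsion sampling** — relaxed dihedral scans in 10° steps (36 points);
  where the scan halts on high `rho`, four normal-mode-perturbed copies of
  the halted structure are harvested.

**High-accuracy labels.**  The composite CCSD(T)*/CBS energy is

    E = Extrap(3/4, HF) + Extrap(3/4, MP2) − E(3, MP2)
        + E(3, NPNO-CCSD(T)) + E(2, TPNO-CCSD(T)) − E(2, NPNO-CCSD(T))

with the HF extrapolation `(e^{−α√4}·E₃ − e^{−α√3}·E₄)/(e^{−α√4} − e^{−α√3})`
(α = 5.46) and the correlation extrapolation
`(4^β·E₄ − 3^β·E₃)/(4^β − 3^β)` (β = 3.05); cardinal numbers 2/3/4 denote
cc-pVDZ/TZ/QZ.

**Dataset format.**  One HDF5 group per isomer; one dataset per property
using the canonical key strings (`'wb97x_dz.energy'`, `'ccsd(t)_cbs.energy'`,
`'wb97x_tz.mbis_charges'`, ...); per-conformer values that are unavailable
are stored NaN, and `iter_data_buckets(path, keys)` yields only conformers
that carry *all* requested keys.

## Worked example

```python
import numpy as np
import alchemforge as af

# an ensemble of surrogate potentials whose disagreement grows with bond stretch
ens = af.make_surrogate_ensemble(k=4, amplitude=0.05, localization="stretch", seed=2)
water = af.make_toy_molecules("water")[0]

batch = af.md_sample(water, ens, af.MDConfig(rho_threshold=2.0, max_steps=1000),
                     np.random.default_rng(3))
e = batch.entries[0]
print(len(batch), round(e.rho, 2), e.provenance["step"])

comp = af.EnergyComponents(hf={3: -76.05, 4: -76.06},
                           mp2_corr={3: -0.30, 4: -0.32},
                           ccsdt_corr_npno={2: -0.25, 3: -0.29},
                           ccsdt_corr_tpno={2: -0.26})
print(round(af.ccsdt_star_cbs(comp), 6))
```

Output:

```
1 5.13 5
-76.397251
```

The MD sampler triggered at the very first disagreement check (step 5) with
`rho = 5.13 kcal/mol/sqrt(atom)` — above the 2.0 threshold — and returned
that single structure with its provenance.  The composite energy assembles
the six terms above: HF/CBS ≈ −76.0624 Ha plus the extrapolated MP2
correlation corrected by the coupled-cluster pieces.

A command-line interface mirrors the library
(`alchemforge validate|dump|cbs|sample-md|sample-nms|sample-dimer|
sample-torsion|al-run|ccx-select|stats|featurize|fixtures`); see
`alchemforge --help`.

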