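"""Langevin MD and normal-mode sampling."""

import numpy as np
import pytest

from alchemforge.dataset_io import Conformation
from alchemforge.samplers_local import (
    KB_HARTREE_PER_K,
    MDConfig,
    NormalModes,
    NumericalError,
    finite_difference_modes,
    kinetic_temperature,
    langevin_step,
    masses_of,
    maxwell_boltzmann_velocities,
    md_sample,
    nms_generate,
    nms_sample,
)
from alchemforge.samplers_torsion import _mean_force_fn
from alchemforge.synthetic_fixtures import HarmonicWell, make_surrogate_ensemble
from alchemforge.uncertainty import rho


@pytest.fixture
def tethered_atoms():
    """Five atoms in an isotropic harmonic tether (analytic test system)."""
    rng = np.random.default_rng(42)
    ref = Conformation([8, 8, 6, 6, 1], rng.normal(scale=2.0, size=(5, 3)))
    return ref, HarmonicWell(ref, 0.05)


class TestLangevinStep:
    def test_zero_friction_reduces_to_velocity_verlet(self, tethered_atoms):
        # symplectic limit: bounded energy drift over 1000 steps
        ref, well = tethered_atoms
        cfg = MDConfig(friction_per_fs=0.0, dt_fs=0.5)
        rng = np.random.default_rng(0)
        masses = masses_of(ref.atomic_numbers)
        conf = Conformation(ref.atomic_numbers, ref.coordinates + 0.3)
        vel = maxwell_boltzmann_velocities(masses, 300.0, rng)
        forces = well.forces(conf)

        def total_energy(c, v):
            from alchemforge.samplers_local import HARTREE_TO_AMU_A2_FS2
            ke = 0.5 * np.sum(masses[:, None] * v**2) / HARTREE_TO_AMU_A2_FS2
            return well.energy(c) + ke

        e0 = total_energy(conf, vel)
        for _ in range(1000):
            conf, vel, forces = langevin_step(
                conf, vel, forces, masses, 300.0, cfg, rng, well.forces
            )
        assert abs(total_energy(conf, vel) - e0) / abs(e0) < 5e-3

    def test_deterministic_given_rng_state(self, tethered_atoms):
        ref, well = tethered_atoms
        cfg = MDConfig()
        masses = masses_of(ref.atomic_numbers)
        results = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            conf = ref.copy()
            vel = maxwell_boltzmann_velocities(masses, 200.0, rng)
            forces = well.forces(conf)
            for _ in range(50):
                conf, vel, forces = langevin_step(
                    conf, vel, forces, masses, 200.0, cfg, rng, well.forces
                )
            results.append((conf.coordinates.copy(), vel.copy()))
        assert np.array_equal(results[0][0], results[1][0])
        assert np.array_equal(results[0][1], results[1][1])

    def test_thermostat_reaches_set_point(self, tethered_atoms):
        # time-averaged kinetic temperature within 5% of the 300 K set point
        ref, well = tethered_atoms
        cfg = MDConfig(dt_fs=0.5, friction_per_fs=0.02)
        rng = np.random.default_rng(11)
        masses = masses_of(ref.atomic_numbers)
        conf = ref.copy()
        vel = maxwell_boltzmann_velocities(masses, 300.0, rng)
        forces = well.forces(conf)
        acc, n = 0.0, 0
        for step in range(200_000):
            conf, vel, forces = langevin_step(
                conf, vel, forces, masses, 300.0, cfg, rng, well.forces
            )
            if step >= 2_000:
                acc += kinetic_temperature(vel, masses)
                n += 1
        assert acc / n == pytest.approx(300.0, rel=0.05)

    def test_nonfinite_force_raises(self, tethered_atoms):
        ref, _ = tethered_atoms
        cfg = MDConfig()
        masses = masses_of(ref.atomic_numbers)
        bad = np.full((5, 3), np.nan)
        with pytest.raises(NumericalError):
            langevin_step(ref, np.zeros((5, 3)), bad, masses, 300.0, cfg,
                          np.random.default_rng(0))


class TestMDSample:
    def test_zero_disagreement_returns_empty_after_max_steps(self, water, quiet_ensemble):
        cfg = MDConfig(rho_threshold=0.0, max_steps=50)
        batch = md_sample(water, quiet_ensemble, cfg, np.random.default_rng(1))
        assert len(batch) == 0

    def test_zero_threshold_halts_at_first_check(self, water, noisy_ensemble):
        cfg = MDConfig(rho_threshold=0.0, max_steps=1000)
        batch = md_sample(water, noisy_ensemble, cfg, np.random.default_rng(2))
        assert len(batch) == 1
        assert batch.entries[0].provenance["step"] == cfg.check_interval_steps

    def test_halt_is_minimal_by_trajectory_replay(self, water, noisy_ensemble):
        # replay the identical rng stream and re-check every 5th frame
        cfg = MDConfig(rho_threshold=2.0, max_steps=400)
        seed = 3
        batch = md_sample(water, noisy_ensemble, cfg, np.random.default_rng(seed))
        if len(batch) == 0:
            pytest.skip("no halt under these conditions; nothing to audit")
        halt_step = batch.entries[0].provenance["step"]
        rng = np.random.default_rng(seed)
        temp = rng.uniform(*cfg.temp_range_K)
        masses = masses_of(water.atomic_numbers)
        vel = maxwell_boltzmann_velocities(masses, temp, rng)
        force_fn = lambda c: noisy_ensemble.member_forces(c).mean(axis=0)
        conf = water.copy()
        forces = force_fn(conf)
        for step in range(1, halt_step + 1):
            conf, vel, forces = langevin_step(
                conf, vel, forces, masses, temp, cfg, rng, force_fn
            )
            r = rho(noisy_ensemble.predict(conf))
            if step % cfg.check_interval_steps == 0 and step < halt_step:
                assert r <= cfg.rho_threshold
        assert r > cfg.rho_threshold
        assert np.allclose(conf.coordinates, batch.entries[0].conformation.coordinates)

    def test_atoms_and_finiteness_preserved(self, water, noisy_ensemble):
        batch = md_sample(
            water, noisy_ensemble, MDConfig(rho_threshold=0.0), np.random.default_rng(4)
        )
        conf = batch.entries[0].conformation
        assert np.array_equal(conf.atomic_numbers, water.atomic_numbers)
        assert np.all(np.isfinite(conf.coordinates))


def _two_mode_toy():
    ref = Conformation([1, 1], [[0.0, 0.0, 0.0], [0.9, 0.0, 0.0]])
    m = masses_of(ref.atomic_numbers)
    v1 = np.zeros((2, 3)); v1[0, 1] = 1.0
    v2 = np.zeros((2, 3)); v2[1, 2] = 1.0
    v1 /= np.sqrt(m[0]); v2 /= np.sqrt(m[1])  # mass-normalize
    return NormalModes([0.5, 1.2], np.stack([v1, v2]), ref)


class TestNMS:
    def test_zero_temperature_reproduces_reference(self):
        modes = _two_mode_toy()
        confs = nms_generate(modes, 5, 0.0, np.random.default_rng(0))
        for c in confs:
            assert np.allclose(c.coordinates, modes.reference_geometry.coordinates)

    def test_per_mode_energy_bounded_by_kT(self):
        modes = _two_mode_toy()
        T = 500.0
        kT = KB_HARTREE_PER_K * T
        rng = np.random.default_rng(1)
        for c in nms_generate(modes, 200, T, rng):
            disp = c.coordinates - modes.reference_geometry.coordinates
            m = masses_of(modes.reference_geometry.atomic_numbers)
            for k, u in zip(modes.force_constants, modes.mode_vectors):
                q = float(np.sum(disp * u * m[:, None]))  # mass-weighted projection
                assert 0.5 * k * q * q <= kT * (1 + 1e-9)

    def test_mean_harmonic_energy_matches_equipartition(self):
        # each mode draws c*kT with c ~ U[0,1): mean total = n_modes * kT / 2
        modes = _two_mode_toy()
        T = 300.0
        kT = KB_HARTREE_PER_K * T
        rng = np.random.default_rng(2)
        m = masses_of(modes.reference_geometry.atomic_numbers)
        total = 0.0
        n = 10_000
        for c in nms_generate(modes, n, T, rng):
            disp = c.coordinates - modes.reference_geometry.coordinates
            for k, u in zip(modes.force_constants, modes.mode_vectors):
                q = float(np.sum(disp * u * m[:, None]))
                total += 0.5 * k * q * q
        assert total / n == pytest.approx(len(modes.force_constants) * kT / 2, rel=0.05)

    def test_nonpositive_force_constant_skipped_with_warning(self):
        bad = _two_mode_toy()
        bad = NormalModes([-0.5, 1.2], bad.mode_vectors, bad.reference_geometry)
        with pytest.warns(RuntimeWarning, match="non-positive"):
            confs = nms_generate(bad, 3, 300.0, np.random.default_rng(3))
        disp = confs[0].coordinates - bad.reference_geometry.coordinates
        assert np.allclose(disp[:, 1], 0.0)  # skipped mode direction untouched

    def test_nms_sample_equals_brute_force_filter(self, water, noisy_ensemble):
        modes = finite_difference_modes(water, _mean_force_fn(noisy_ensemble))
        threshold = 5.0
        batch = nms_sample(
            modes, noisy_ensemble, 50, 300.0, threshold, np.random.default_rng(5)
        )
        regen = nms_generate(modes, 50, 300.0, np.random.default_rng(5))
        brute = [c for c in regen if rho(noisy_ensemble.predict(c)) > threshold]
        assert len(batch) == len(brute)
        for e, c in zip(batch, brute):
            assert np.allclose(e.conformation.coordinates, c.coordinates)

    def test_identical_ensemble_yields_empty_selection(self, water, quiet_ensemble):
        modes = finite_difference_modes(water, _mean_force_fn(quiet_ensemble))
        batch = nms_sample(modes, quiet_ensemble, 20, 300.0, 0.0, np.random.default_rng(6))
        assert len(batch) == 0


class TestFiniteDifferenceModes:
    def test_harmonic_tether_eigenvalues_recovered(self):
        # isotropic tether k=0.1: mass-weighted Hessian eigenvalues are k/m
        ref = Conformation([8], [[0.0, 0.0, 0.0]])
        well = HarmonicWell(ref, 0.1)
        modes = finite_difference_modes(ref, well.forces, n_remove=0)
        m = masses_of(ref.atomic_numbers)[0]
        assert np.allclose(modes.force_constants, 0.1 / m, rtol=1e-6)

    def test_modes_are_mass_orthonormal(self, water, noisy_ensemble):
        modes = finite_difference_modes(water, _mean_force_fn(noisy_ensemble))
        assert modes.mass_orthonormality_error() < 1e-8
        assert modes.n_modes == 3 * water.n_atoms - 6

    def test_json_round_trip(self, water, quiet_ensemble):
        modes = finite_difference_modes(water, _mean_force_fn(quiet_ensemble))
        back = NormalModes.from_json(modes.to_json())
        assert np.allclose(back.force_constants, modes.force_constants)
        assert np.allclose(back.mode_vectors, modes.mode_vectors)
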