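"""Torsion sampling: constrained minimization, relaxed scans, perturbations."""

import numpy as np
import pytest
from scipy.optimize import NonlinearConstraint, minimize as scipy_minimize

from alchemforge.dataset_io import Conformation
from alchemforge.samplers_local import KB_HARTREE_PER_K, finite_difference_modes, masses_of
from alchemforge.samplers_torsion import (
    EnsembleMeanPotential,
    RDKitEmbedder,
    TorsionConfig,
    TorsionSpec,
    constrained_minimize,
    dihedral_deg,
    dihedral_gradient,
    perturb_along_modes,
    relaxed_scan,
    set_dihedral,
    torsion_sampling_iteration,
    _mean_force_fn,
)
from alchemforge.synthetic_fixtures import (
    FixtureEmbedder,
    HarmonicWell,
    make_surrogate_ensemble,
)


def _wrap(a):
    return (a + 180.0) % 360.0 - 180.0


class TestDihedralGeometry:
    def test_gradient_matches_finite_differences(self, rng):
        for _ in range(10):
            x = rng.normal(size=(6, 3)) * 2.0
            g = dihedral_gradient(x, 0, 2, 3, 5)
            h = 1e-6
            for a in (0, 2, 3, 5):
                for c in range(3):
                    xp, xm = x.copy(), x.copy()
                    xp[a, c] += h
                    xm[a, c] -= h
                    d = np.radians(
                        _wrap(dihedral_deg(xp, 0, 2, 3, 5) - dihedral_deg(xm, 0, 2, 3, 5))
                    )
                    assert g[a, c] == pytest.approx(d / (2 * h), abs=1e-5)

    def test_set_dihedral_hits_target_exactly(self, rng, fixture_embedder):
        conf = fixture_embedder.conf
        spec = fixture_embedder.torsion
        for target in (-170.0, -45.0, 0.0, 10.0, 155.0):
            new = set_dihedral(conf, spec, target)
            got = dihedral_deg(new.coordinates, spec.i, spec.j, spec.k, spec.l)
            assert abs(_wrap(got - target)) < 1e-8
            # non-rotating atoms untouched
            fixed = [a for a in range(conf.n_atoms) if a not in spec.rotating]
            assert np.allclose(new.coordinates[fixed], conf.coordinates[fixed])

    def test_torsion_spec_invariants(self):
        with pytest.raises(ValueError):
            TorsionSpec(0, 1, 2, 3, frozenset({0, 3}))  # rotating contains i
        with pytest.raises(ValueError):
            TorsionSpec(0, 1, 1, 3, frozenset({3}))  # repeated index


class TestConstrainedMinimize:
    def test_start_at_constrained_minimum_stays_put(self, fixture_embedder):
        conf = fixture_embedder.conf
        spec = fixture_embedder.torsion
        well = HarmonicWell(conf, 0.2)
        target = dihedral_deg(conf.coordinates, spec.i, spec.j, spec.k, spec.l)
        res = constrained_minimize(conf, well, spec, target, tol=1e-6, max_iter=100)
        assert res.converged
        assert np.allclose(res.conformation.coordinates, conf.coordinates, atol=1e-6)

    def test_matches_scipy_trust_constr_oracle(self, fixture_embedder):
        # quadratic tether with the dihedral driven 40 degrees away:
        # independent constrained optimizer must find the same minimum energy
        conf = fixture_embedder.conf
        spec = fixture_embedder.torsion
        well = HarmonicWell(conf, 0.2)
        phi0 = dihedral_deg(conf.coordinates, spec.i, spec.j, spec.k, spec.l)
        target = phi0 + 40.0
        res = constrained_minimize(conf, well, spec, target, tol=1e-7, max_iter=2000)

        na = conf.n_atoms
        def fun(x):
            c = Conformation(conf.atomic_numbers, x.reshape(na, 3))
            return well.energy(c)
        def con(x):
            return np.radians(
                _wrap(dihedral_deg(x.reshape(na, 3), spec.i, spec.j, spec.k, spec.l) - target)
            )
        oracle = scipy_minimize(
            fun,
            res.conformation.coordinates.ravel() + 0.01,
            method="trust-constr",
            constraints=[NonlinearConstraint(con, 0.0, 0.0)],
            options={"maxiter": 2000, "gtol": 1e-10},
        )
        assert well.energy(res.conformation) == pytest.approx(oracle.fun, abs=1e-6)

    def test_dihedral_within_tenth_degree_on_random_starts(self, rng, fixture_embedder):
        spec = fixture_embedder.torsion
        ens = make_surrogate_ensemble(k=2, amplitude=0.0, seed=0)
        pot = EnsembleMeanPotential(ens)
        for _ in range(5):
            start = Conformation(
                fixture_embedder.conf.atomic_numbers,
                fixture_embedder.conf.coordinates + rng.normal(scale=0.1, size=(6, 3)),
            )
            target = float(rng.uniform(-180, 180))
            res = constrained_minimize(start, pot, spec, target, tol=1e-3, max_iter=300)
            got = dihedral_deg(res.conformation.coordinates, spec.i, spec.j, spec.k, spec.l)
            assert abs(_wrap(got - target)) < 0.1


class TestRelaxedScan:
    def test_zero_disagreement_full_scan_36_points_10_degrees(self, fixture_embedder, quiet_ensemble):
        cfg = TorsionConfig(rho_threshold=1.0, opt_tolerance=5e-3, opt_max_iter=100)
        points, halt = relaxed_scan(
            fixture_embedder.conf, quiet_ensemble, fixture_embedder.torsion, cfg
        )
        assert halt is None
        assert len(points) == 36
        angles = [p.dihedral_deg for p in points]
        increments = _wrap(np.diff(angles))
        assert np.allclose(increments, 10.0, atol=0.1)

    def test_zero_threshold_halts_at_first_point(self, fixture_embedder, noisy_ensemble):
        cfg = TorsionConfig(rho_threshold=0.0, opt_tolerance=5e-3, opt_max_iter=100)
        points, halt = relaxed_scan(
            fixture_embedder.conf, noisy_ensemble, fixture_embedder.torsion, cfg
        )
        assert halt == 0
        assert len(points) == 1

    def test_halt_falls_inside_disagreement_window(self, fixture_embedder):
        spec = fixture_embedder.torsion
        ens = make_surrogate_ensemble(
            k=4, amplitude=0.5, localization="dihedral", seed=4,
            torsion=spec, window_center_deg=90.0, window_width_deg=15.0,
        )
        cfg = TorsionConfig(rho_threshold=5.0, opt_tolerance=5e-3, opt_max_iter=100)
        points, halt = relaxed_scan(fixture_embedder.conf, ens, spec, cfg)
        assert halt is not None
        assert abs(_wrap(points[halt].dihedral_deg - 90.0)) < 60.0
        # minimality audit: no earlier checked point exceeded the threshold
        from alchemforge.uncertainty import rho
        for p in points[:halt]:
            assert rho(ens.predict(p.conformation)) <= cfg.rho_threshold
        assert points[halt].rho > cfg.rho_threshold


class TestPerturbAlongModes:
    def _halted_structure(self, fixture_embedder, quiet_ensemble):
        conf = fixture_embedder.conf
        modes = finite_difference_modes(conf, _mean_force_fn(quiet_ensemble))
        return conf, modes

    def test_exactly_n_structures_returned(self, fixture_embedder, quiet_ensemble):
        conf, modes = self._halted_structure(fixture_embedder, quiet_ensemble)
        out = perturb_along_modes(conf, modes, 4, 50.0, np.random.default_rng(0))
        assert len(out) == 4
        for c in out:
            assert not np.allclose(c.coordinates, conf.coordinates)

    def test_zero_scale_gives_copies(self, fixture_embedder, quiet_ensemble):
        conf, modes = self._halted_structure(fixture_embedder, quiet_ensemble)
        out = perturb_along_modes(conf, modes, 3, 0.0, np.random.default_rng(1))
        for c in out:
            assert np.allclose(c.coordinates, conf.coordinates)

    def test_displacement_energy_bounded_per_mode(self, fixture_embedder, quiet_ensemble):
        conf, modes = self._halted_structure(fixture_embedder, quiet_ensemble)
        scale_K = 80.0
        kT = KB_HARTREE_PER_K * scale_K
        m = masses_of(conf.atomic_numbers)
        for c in perturb_along_modes(conf, modes, 20, scale_K, np.random.default_rng(2)):
            disp = c.coordinates - conf.coordinates
            for k, u in zip(modes.force_constants, modes.mode_vectors):
                if k <= 0:
                    continue
                q = float(np.sum(disp * u * m[:, None]))
                assert 0.5 * k * q * q <= kT * (1 + 1e-9)

    def test_modes_from_other_geometry_rejected(self, fixture_embedder, quiet_ensemble, water):
        _, modes = self._halted_structure(fixture_embedder, quiet_ensemble)
        with pytest.raises(ValueError):
            perturb_along_modes(water, modes, 4, 50.0, np.random.default_rng(3))


class TestTorsionSamplingIteration:
    def _window_ensemble(self, spec, amplitude=0.5):
        return make_surrogate_ensemble(
            k=4, amplitude=amplitude, localization="dihedral", seed=4,
            torsion=spec, window_center_deg=90.0, window_width_deg=15.0,
        )

    def test_no_halt_yields_empty_batch(self, fixture_embedder, quiet_ensemble):
        cfg = TorsionConfig(rho_threshold=1.0, opt_tolerance=5e-3, opt_max_iter=100)
        batch = torsion_sampling_iteration(
            "CCCC", fixture_embedder, quiet_ensemble, cfg, np.random.default_rng(0)
        )
        assert len(batch) == 0

    def test_halt_yields_n_perturbed_with_provenance(self, fixture_embedder):
        ens = self._window_ensemble(fixture_embedder.torsion)
        cfg = TorsionConfig(rho_threshold=5.0, opt_tolerance=5e-3, opt_max_iter=100)
        batch = torsion_sampling_iteration(
            "CCCC", fixture_embedder, ens, cfg, np.random.default_rng(1)
        )
        assert len(batch) == cfg.n_perturbed == 4
        for e in batch:
            assert e.provenance["sampler"] == "torsion"
            assert e.provenance["smiles"] == "CCCC"
            assert "halt_step" in e.provenance

    def test_halted_structure_itself_not_in_batch(self, fixture_embedder):
        ens = self._window_ensemble(fixture_embedder.torsion)
        cfg = TorsionConfig(rho_threshold=5.0, opt_tolerance=5e-3, opt_max_iter=100)
        rng = np.random.default_rng(2)
        batch = torsion_sampling_iteration("CCCC", fixture_embedder, ens, cfg, rng)
        points, halt = relaxed_scan(
            fixture_embedder.conf, ens, fixture_embedder.torsion, cfg
        )
        halted = points[halt].conformation
        for e in batch:
            assert not np.allclose(e.conformation.coordinates, halted.coordinates)

    def test_fixed_seed_reproducible(self, fixture_embedder):
        ens = self._window_ensemble(fixture_embedder.torsion)
        cfg = TorsionConfig(rho_threshold=5.0, opt_tolerance=5e-3, opt_max_iter=100)
        b1 = torsion_sampling_iteration("CCCC", fixture_embedder, ens, cfg, np.random.default_rng(5))
        b2 = torsion_sampling_iteration("CCCC", fixture_embedder, ens, cfg, np.random.default_rng(5))
        for e1, e2 in zip(b1, b2):
            assert np.array_equal(e1.conformation.coordinates, e2.conformation.coordinates)

    def test_unparseable_smiles_raises_with_smiles(self):
        cfg = TorsionConfig()
        with pytest.raises(ValueError, match="not-a-smiles"):
            torsion_sampling_iteration(
                "not-a-smiles", RDKitEmbedder(), None, cfg, np.random.default_rng(0)
            )


class TestRDKitEmbedder:
    def test_butane_embeds_with_rotatable_bond(self):
        conf, torsions = RDKitEmbedder().embed("CCCC", np.random.default_rng(0))
        assert conf.n_atoms == 14  # C4H10
        assert len(torsions) >= 1
        spec = torsions[0]
        assert spec.l in spec.rotating and spec.i not in spec.rotating
        phi = dihedral_deg(conf.coordinates, spec.i, spec.j, spec.k, spec.l)
        assert np.isfinite(phi)
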