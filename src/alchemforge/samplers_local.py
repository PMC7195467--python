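"""Single-molecule conformer samplers: Langevin MD and normal-mode sampling.

Both samplers are gated by the ensemble-disagreement metric rho.  The MD
sampler runs a Langevin trajectory at a random temperature drawn from
50-800 K and checks rho every 5 steps, halting at the first structure whose
rho exceeds the configured threshold.  The normal-mode sampler displaces an
optimized geometry along its harmonic modes, assigning each mode an energy
drawn uniformly from [0, kT), and keeps the high-rho conformers.

Internal units: energy in Hartree, length in Angstrom, mass in amu, time in
femtoseconds.  Forces are Ha/A.  The conversion 1 Ha = 0.02625... amu*A^2/fs^2
is derived from CODATA constants, so velocities are in A/fs.
"""

from __future__ import annotations

import warnings
import json
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy import constants as _const

from .dataset_io import Conformation
from .uncertainty import SelectionBatch, SelectionEntry, rho, select_high_rho

__all__ = [
    "KB_HARTREE_PER_K",
    "HARTREE_TO_AMU_A2_FS2",
    "ATOMIC_MASSES_AMU",
    "NumericalError",
    "MDConfig",
    "NormalModes",
    "masses_of",
    "maxwell_boltzmann_velocities",
    "kinetic_temperature",
    "langevin_step",
    "md_sample",
    "nms_generate",
    "nms_sample",
    "finite_difference_modes",
]

#: Boltzmann constant in Hartree/K.
KB_HARTREE_PER_K = 3.166811563e-6
#: 1 Hartree expressed in amu * Angstrom^2 / fs^2.
HARTREE_TO_AMU_A2_FS2 = _const.physical_constants["Hartree energy"][0] / (
    _const.atomic_mass * 1e10  # (1e-10 m)^2 / (1e-15 s)^2 = 1e10 m^2/s^2
)

ATOMIC_MASSES_AMU = {1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 9: 18.998, 16: 32.06}


class NumericalError(RuntimeError):
    """A potential returned a non-finite energy or force (surrogate blow-up)."""


def masses_of(atomic_numbers) -> np.ndarray:
    return np.array([ATOMIC_MASSES_AMU[int(z)] for z in np.ravel(atomic_numbers)])


@dataclass
class MDConfig:
    """Langevin MD sampling parameters.

    Defaults follow the published protocol: temperature drawn uniformly from
    50-800 K, 0.5 fs time step, 0.02 fs^-1 friction, disagreement check
    every 5 steps.  ``max_steps`` caps trajectories that never trigger.
    """

    temp_range_K: tuple[float, float] = (50.0, 800.0)
    dt_fs: float = 0.5
    friction_per_fs: float = 0.02
    check_interval_steps: int = 5
    rho_threshold: float = 1.0
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.temp_range_K
        if not (0 < lo <= hi):
            raise ValueError("temp_range_K must be positive and ordered")
        if self.dt_fs <= 0:
            raise ValueError("dt_fs must be positive")
        if self.friction_per_fs < 0:
            raise ValueError("friction must be >= 0")
        if self.check_interval_steps < 1:
            raise ValueError("check_interval_steps must be >= 1")


def maxwell_boltzmann_velocities(masses: np.ndarray, temp_K: float, rng: np.random.Generator) -> np.ndarray:
    """Velocities (A/fs) drawn from the Maxwell-Boltzmann distribution."""
    kT = KB_HARTREE_PER_K * temp_K * HARTREE_TO_AMU_A2_FS2
    sigma = np.sqrt(kT / masses)[:, None]
    return rng.standard_normal((len(masses), 3)) * sigma


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature (K) from velocities in A/fs."""
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))  # amu A^2/fs^2
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * KB_HARTREE_PER_K * HARTREE_TO_AMU_A2_FS2)


def langevin_step(
    conf: Conformation,
    velocities: np.ndarray,
    forces: np.ndarray,
    masses: np.ndarray,
    temp_K: float,
    cfg: MDConfig,
    rng: np.random.Generator,
    force_fn: Callable[[Conformation], np.ndarray] | None = None,
) -> tuple[Conformation, np.ndarray, np.ndarray]:
    """One BAOAB Langevin update; returns ``(conf', velocities', forces')``.

    The splitting is kick(dt/2) - drift(dt/2) - Ornstein-Uhlenbeck - drift(dt/2)
    - kick(dt/2), with the final kick using forces recomputed at the new
    positions via ``force_fn``.  With zero friction the noise vanishes and
    the map reduces exactly to velocity Verlet.  If ``force_fn`` is omitted
    the final kick reuses the stale forces (first-order accurate; fine for
    single exploratory steps, not for long trajectories).

    ``forces`` are Ha/A at the *current* positions; deterministic given the
    rng state.
    """
    if not np.all(np.isfinite(forces)):
        raise NumericalError("non-finite force entering Langevin step")
    dt = cfg.dt_fs
    gamma = cfg.friction_per_fs
    m = masses[:, None]
    x = conf.coordinates.copy()
    v = velocities.copy()

    a = forces * HARTREE_TO_AMU_A2_FS2 / m  # A/fs^2
    v += 0.5 * dt * a
    x += 0.5 * dt * v
    if gamma > 0:
        kT = KB_HARTREE_PER_K * temp_K * HARTREE_TO_AMU_A2_FS2
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT / m)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x += 0.5 * dt * v

    new_conf = Conformation(conf.atomic_numbers, x, conf.cell, conf.molecule_ids)
    new_forces = forces if force_fn is None else np.asarray(force_fn(new_conf))
    if not np.all(np.isfinite(new_forces)):
        raise NumericalError("non-finite force after Langevin step")
    v += 0.5 * dt * new_forces * HARTREE_TO_AMU_A2_FS2 / m
    return new_conf, v, new_forces


def _mean_force_fn(ensemble) -> Callable[[Conformation], np.ndarray]:
    return lambda c: np.asarray(ensemble.member_forces(c)).mean(axis=0)


def md_sample(
    mol: Conformation,
    ensemble,
    cfg: MDConfig,
    rng: np.random.Generator,
    parent_id: str | None = None,
) -> SelectionBatch:
    """Disagreement-gated Langevin MD on one molecule.

    Draws a temperature uniformly from ``cfg.temp_range_K``, initializes
    Maxwell-Boltzmann velocities, and integrates.  Every
    ``check_interval_steps`` steps rho is evaluated; at the first structure
    with ``rho > cfg.rho_threshold`` the trajectory terminates and that
    single structure is returned.  An empty batch means ``max_steps`` passed
    without a trigger.
    """
    seed_state = rng.bit_generator.state["state"]
    temp = rng.uniform(*cfg.temp_range_K)
    masses = masses_of(mol.atomic_numbers)
    vel = maxwell_boltzmann_velocities(masses, temp, rng)
    force_fn = _mean_force_fn(ensemble)
    conf = mol.copy()
    forces = force_fn(conf)
    for step in range(1, cfg.max_steps + 1):
        conf, vel, forces = langevin_step(
            conf, vel, forces, masses, temp, cfg, rng, force_fn
        )
        if step % cfg.check_interval_steps == 0:
            r = rho(ensemble.predict(conf))
            if r > cfg.rho_threshold:
                prov = {
                    "sampler": "md",
                    "parent": parent_id or mol.formula(),
                    "temperature_K": temp,
                    "step": step,
                    "rng_state": seed_state,
                }
                return SelectionBatch([SelectionEntry(conf, r, prov)])
    return SelectionBatch([])


# ---------------------------------------------------------------------------
# Normal modes
# ---------------------------------------------------------------------------

@dataclass
class NormalModes:
    """Harmonic modes of a reference geometry.

    ``mode_vectors[i]`` is an ``(Na, 3)`` Cartesian displacement direction,
    mass-orthonormal (``u_i^T M u_j = delta_ij`` with M in amu), so the
    harmonic energy of a displacement ``q * u_i`` is ``0.5 * k_i * q**2``
    with ``force_constants[i] = k_i`` in Ha/(amu A^2) — numerically the
    eigenvalue of the mass-weighted Hessian.
    """

    force_constants: np.ndarray
    mode_vectors: np.ndarray  # (n_modes, Na, 3)
    reference_geometry: Conformation

    def __post_init__(self) -> None:
        self.force_constants = np.asarray(self.force_constants, dtype=np.float64).ravel()
        self.mode_vectors = np.asarray(self.mode_vectors, dtype=np.float64)
        if self.mode_vectors.shape != (
            len(self.force_constants),
            self.reference_geometry.n_atoms,
            3,
        ):
            raise ValueError("mode_vectors shape inconsistent with modes/atoms")

    @property
    def n_modes(self) -> int:
        return len(self.force_constants)

    def mass_orthonormality_error(self) -> float:
        m = masses_of(self.reference_geometry.atomic_numbers)
        u = self.mode_vectors.reshape(self.n_modes, -1)
        w = np.repeat(m, 3)
        gram = (u * w) @ u.T
        return float(np.max(np.abs(gram - np.eye(self.n_modes))))

    def to_json(self) -> str:
        ref = self.reference_geometry
        return json.dumps(
            {
                "force_constants": self.force_constants.tolist(),
                "mode_vectors": self.mode_vectors.reshape(self.n_modes, -1).tolist(),
                "atomic_numbers": ref.atomic_numbers.tolist(),
                "coordinates": ref.coordinates.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalModes":
        d = json.loads(text)
        ref = Conformation(d["atomic_numbers"], d["coordinates"])
        vecs = np.asarray(d["mode_vectors"]).reshape(-1, ref.n_atoms, 3)
        return cls(np.asarray(d["force_constants"]), vecs, ref)


def finite_difference_modes(
    conf: Conformation,
    force_fn: Callable[[Conformation], np.ndarray],
    step_A: float = 0.005,
    n_remove: int = 6,
) -> NormalModes:
    """Harmonic modes from a central finite-difference Hessian of ``force_fn``.

    The Hessian is built column-wise from force differences, symmetrized,
    mass-weighted, and diagonalized; the ``n_remove`` modes of smallest
    absolute eigenvalue (rigid translations/rotations: 6, or 5 for linear
    molecules) are dropped.
    """
    na = conf.n_atoms
    n = 3 * na
    x0 = conf.coordinates.ravel().copy()
    hess = np.empty((n, n))
    for a in range(n):
        xp, xm = x0.copy(), x0.copy()
        xp[a] += step_A
        xm[a] -= step_A
        fp = np.asarray(force_fn(Conformation(conf.atomic_numbers, xp.reshape(na, 3)))).ravel()
        fm = np.asarray(force_fn(Conformation(conf.atomic_numbers, xm.reshape(na, 3)))).ravel()
        hess[:, a] = -(fp - fm) / (2.0 * step_A)
    hess = 0.5 * (hess + hess.T)
    m = np.repeat(masses_of(conf.atomic_numbers), 3)
    hess_mw = hess / np.sqrt(np.outer(m, m))
    evals, evecs = np.linalg.eigh(hess_mw)
    order = np.argsort(np.abs(evals))
    keep = np.sort(order[n_remove:])
    vecs = (evecs[:, keep].T / np.sqrt(m)).reshape(-1, na, 3)
    return NormalModes(evals[keep], vecs, conf.copy())


def nms_generate(
    modes: NormalModes,
    n_conf: int,
    temp_K: float,
    rng: np.random.Generator,
) -> list[Conformation]:
    """Random harmonic displacements of the reference geometry.

    Each conformer displaces every mode by an independent random signed
    amplitude ``q_i = +/- sqrt(2 c_i kT / k_i)`` with ``c_i`` uniform on
    [0, 1), so each mode carries harmonic energy ``c_i * kT`` (bounded by
    kT; expectation kT/2 per mode).  Modes with non-positive force constant
    are skipped with a warning.  T = 0 returns copies of the reference.
    """
    if n_conf < 1:
        raise ValueError("n_conf must be >= 1")
    if temp_K < 0:
        raise ValueError("temperature must be >= 0")
    ok = modes.force_constants > 0
    if not ok.all():
        warnings.warn(
            f"skipping {int((~ok).sum())} mode(s) with non-positive force constant",
            RuntimeWarning,
            stacklevel=2,
        )
    k = modes.force_constants[ok]
    vecs = modes.mode_vectors[ok]
    kT = KB_HARTREE_PER_K * temp_K
    out = []
    for _ in range(n_conf):
        c = rng.uniform(0.0, 1.0, size=len(k))
        sign = rng.choice([-1.0, 1.0], size=len(k))
        q = sign * np.sqrt(2.0 * c * kT / k)
        disp = np.tensordot(q, vecs, axes=(0, 0))
        out.append(
            Conformation(
                modes.reference_geometry.atomic_numbers,
                modes.reference_geometry.coordinates + disp,
            )
        )
    return out


def nms_sample(
    modes: NormalModes,
    ensemble,
    n_conf: int,
    temp_K: float,
    threshold: float,
    rng: np.random.Generator,
    parent_id: str | None = None,
) -> SelectionBatch:
    """Generate ``n_conf`` normal-mode conformers and keep the high-rho ones."""
    confs = nms_generate(modes, n_conf, temp_K, rng)
    candidates = [(c, ensemble.predict(c)) for c in confs]
    prov: dict[str, Any] = {
        "sampler": "nms",
        "parent": parent_id or modes.reference_geometry.formula(),
        "temperature_K": temp_K,
    }
    return select_high_rho(candidates, threshold, provenance=prov)
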