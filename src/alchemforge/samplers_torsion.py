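"""Torsion sampling: relaxed dihedral scans gated by ensemble disagreement.

A molecule is embedded in 3-D from its SMILES string (via a pluggable
structure provider; the default uses RDKit), one rotatable bond is chosen,
the geometry is optimized, and a relaxed scan steps the dihedral by 10
degrees over the full 360-degree profile (36 constrained minimizations).
The disagreement rho is measured at every scan point; at the first point
with rho above threshold the scan halts, harmonic modes are computed at the
halted structure from the ensemble-mean energy, and four small random
mode-space perturbations of it — not the structure itself — form the
selection batch.  Perturbing around the halted point samples the region
around the torsion valley rather than the scan path itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .dataset_io import Conformation
from .samplers_local import (
    NormalModes,
    NumericalError,
    finite_difference_modes,
    nms_generate,
    _mean_force_fn,
)
from .uncertainty import SelectionBatch, SelectionEntry, rho

__all__ = [
    "TorsionConfig",
    "TorsionSpec",
    "ScanPoint",
    "MinimizeResult",
    "EnsembleMeanPotential",
    "dihedral_deg",
    "dihedral_gradient",
    "set_dihedral",
    "optimize_geometry",
    "constrained_minimize",
    "relaxed_scan",
    "perturb_along_modes",
    "torsion_sampling_iteration",
    "RDKitEmbedder",
]


# ---------------------------------------------------------------------------
# Dihedral geometry
# ---------------------------------------------------------------------------

def _wrap_deg(a: float) -> float:
    """Wrap an angle difference to (-180, 180]."""
    return float(-((-a + 180.0) % 360.0 - 180.0))


def dihedral_deg(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral angle i-j-k-l in degrees, in (-180, 180]."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))


def dihedral_gradient(coords: np.ndarray, i: int, j: int, k: int, l: int) -> np.ndarray:
    """Analytic gradient of the dihedral angle (radians) w.r.t. coordinates.

    Returns an array of the same shape as ``coords``; only rows i, j, k, l
    are non-zero.  Uses the Blondel-Karplus expressions.
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    # dphi/db1, dphi/db2, dphi/db3 in the (n1, n2) basis
    da = -(b2n / (n1 @ n1)) * n1
    db = ((b1 @ b2) / (b2n * (n1 @ n1))) * n1 + ((b3 @ b2) / (b2n * (n2 @ n2))) * n2
    dc = -(b2n / (n2 @ n2)) * n2
    g = np.zeros_like(coords)
    g[i] = -da
    g[j] = da - db
    g[k] = db - dc
    g[l] = dc
    return g


@dataclass(frozen=True)
class TorsionSpec:
    """A rotatable dihedral: atom indices i-j-k-l plus the rotating side.

    ``rotating`` is the set of atoms rigidly rotated about the j-k axis when
    the dihedral is driven; it must contain ``l`` (and conventionally ``k``)
    and must not contain ``i`` or ``j``.
    """

    i: int
    j: int
    k: int
    l: int
    rotating: frozenset[int]

    def __post_init__(self) -> None:
        idx = (self.i, self.j, self.k, self.l)
        if len(set(idx)) != 4:
            raise ValueError("dihedral needs four distinct atoms")
        if self.l not in self.rotating or self.i in self.rotating or self.j in self.rotating:
            raise ValueError("rotating side must contain l and exclude i, j")


def set_dihedral(conf: Conformation, spec: TorsionSpec, target_deg: float) -> Conformation:
    """Rotate the rotating-side atoms about the j-k axis to the target angle."""
    x = conf.coordinates.copy()
    cur = dihedral_deg(x, spec.i, spec.j, spec.k, spec.l)
    delta = np.radians(_wrap_deg(target_deg - cur))
    axis = x[spec.k] - x[spec.j]
    axis /= np.linalg.norm(axis)
    origin = x[spec.j]
    rot_idx = sorted(a for a in spec.rotating if a not in (spec.j,))

    def _apply(angle: float) -> np.ndarray:
        c, s = np.cos(angle), np.sin(angle)
        xx = x.copy()
        v = xx[rot_idx] - origin
        # Rodrigues rotation about `axis`
        xx[rot_idx] = (
            origin
            + v * c
            + np.cross(axis, v) * s
            + np.outer(v @ axis, axis) * (1.0 - c)
        )
        return xx

    new = _apply(delta)
    if abs(_wrap_deg(dihedral_deg(new, spec.i, spec.j, spec.k, spec.l) - target_deg)) > 1e-6:
        new = _apply(-delta)
    return Conformation(conf.atomic_numbers, new, conf.cell, conf.molecule_ids)


# ---------------------------------------------------------------------------
# Config, potentials
# ---------------------------------------------------------------------------

@dataclass
class TorsionConfig:
    increment_deg: float = 10.0
    n_steps: int = 36
    n_perturbed: int = 4
    n_iterations: int = 20
    rho_threshold: float = 1.0
    opt_tolerance: float = 1e-3  # Ha/A, max force component
    opt_max_iter: int = 200
    perturb_scale_K: float = 50.0  # temperature equivalent of the mode perturbation

    def __post_init__(self) -> None:
        if abs(self.increment_deg * self.n_steps - 360.0) > 1e-9:
            raise ValueError("increment_deg * n_steps must equal 360")
        if self.n_perturbed < 1:
            raise ValueError("n_perturbed must be >= 1")


class EnsembleMeanPotential:
    """Adapter exposing the ensemble mean as a single potential."""

    def __init__(self, ensemble):
        self._ens = ensemble

    def energy(self, conf: Conformation) -> float:
        return float(np.mean(self._ens.member_energies(conf)))

    def forces(self, conf: Conformation) -> np.ndarray:
        return np.asarray(self._ens.member_forces(conf)).mean(axis=0)


@dataclass
class MinimizeResult:
    conformation: Conformation
    converged: bool
    n_iter: int
    max_force: float


@dataclass
class ScanPoint:
    conformation: Conformation
    dihedral_deg: float
    rho: float


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def optimize_geometry(
    conf: Conformation,
    potential,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> Conformation:
    """Unconstrained geometry optimization (L-BFGS on the potential energy)."""
    na = conf.n_atoms

    def fun(x):
        c = Conformation(conf.atomic_numbers, x.reshape(na, 3), conf.cell, conf.molecule_ids)
        e = potential.energy(c)
        g = -np.asarray(potential.forces(c)).ravel()
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            raise NumericalError("non-finite energy/force during optimization")
        return e, g

    res = _scipy_minimize(
        fun, conf.coordinates.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol},
    )
    return Conformation(conf.atomic_numbers, res.x.reshape(na, 3), conf.cell, conf.molecule_ids)


def constrained_minimize(
    conf: Conformation,
    potential,
    torsion: TorsionSpec,
    target_deg: float,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> MinimizeResult:
    """Minimize the energy with the dihedral held at ``target_deg``.

    Projected gradient descent with backtracking: each step moves along the
    force component tangent to the constraint manifold, then re-enforces
    the dihedral exactly by rigid rotation of the rotating side.
    Convergence means the largest projected force component is <= ``tol``
    (Ha/A); hitting ``max_iter`` first is flagged via ``converged=False``.
    The returned dihedral is within 0.1 degree of the target by
    construction.
    """
    x = set_dihedral(conf, torsion, target_deg)
    e = potential.energy(x)
    if not np.isfinite(e):
        raise NumericalError("non-finite energy at constrained start")
    alpha = 0.05  # step length in A per (Ha/A) of force
    it = 0
    max_f = np.inf
    for it in range(1, max_iter + 1):
        forces = np.asarray(potential.forces(x))
        if not np.all(np.isfinite(forces)):
            raise NumericalError("non-finite force in constrained minimization")
        n = dihedral_gradient(x.coordinates, torsion.i, torsion.j, torsion.k, torsion.l)
        nf = n.ravel()
        nf = nf / np.linalg.norm(nf)
        fp = forces.ravel() - (forces.ravel() @ nf) * nf
        max_f = float(np.abs(fp).max())
        if max_f <= tol:
            return MinimizeResult(x, True, it, max_f)
        stepped = False
        while alpha >= 1e-9:
            trial = set_dihedral(
                Conformation(
                    x.atomic_numbers,
                    x.coordinates + alpha * fp.reshape(-1, 3),
                    x.cell,
                    x.molecule_ids,
                ),
                torsion,
                target_deg,
            )
            et = potential.energy(trial)
            if np.isfinite(et) and et < e:
                x, e = trial, et
                alpha = min(alpha * 1.3, 0.5)
                stepped = True
                break
            alpha *= 0.5
        if not stepped:
            break  # no descent direction at machine step; treat as stationary
    converged = max_f <= tol
    return MinimizeResult(x, converged, it, max_f)


# ---------------------------------------------------------------------------
# Scan and sampling
# ---------------------------------------------------------------------------

def relaxed_scan(
    conf: Conformation,
    ensemble,
    torsion: TorsionSpec,
    cfg: TorsionConfig,
) -> tuple[list[ScanPoint], int | None]:
    """Relaxed dihedral scan with disagreement-gated halting.

    Optimizes the start geometry, then performs up to ``cfg.n_steps``
    constrained minimizations at ``cfg.increment_deg`` increments from the
    optimized geometry's dihedral.  rho is evaluated at every scan point;
    the scan halts at the first point with ``rho > cfg.rho_threshold`` and
    returns its index, otherwise all points are returned with halt ``None``.
    """
    pot = EnsembleMeanPotential(ensemble)
    x = optimize_geometry(conf, pot, tol=cfg.opt_tolerance, max_iter=cfg.opt_max_iter)
    phi0 = dihedral_deg(x.coordinates, torsion.i, torsion.j, torsion.k, torsion.l)
    points: list[ScanPoint] = []
    prev = x
    for s in range(cfg.n_steps):
        target = phi0 + s * cfg.increment_deg
        res = constrained_minimize(
            prev, pot, torsion, target, tol=cfg.opt_tolerance, max_iter=cfg.opt_max_iter
        )
        prev = res.conformation
        phi = dihedral_deg(prev.coordinates, torsion.i, torsion.j, torsion.k, torsion.l)
        r = rho(ensemble.predict(prev))
        points.append(ScanPoint(prev, phi, r))
        if r > cfg.rho_threshold:
            return points, s
    return points, None


def perturb_along_modes(
    x: Conformation,
    modes: NormalModes,
    n: int,
    scale_K: float,
    rng: np.random.Generator,
) -> list[Conformation]:
    """``n`` small random mode-space displacements of ``x`` (x not included).

    Uses the same bounded-energy rule as normal-mode sampling with
    temperature ``scale_K``; ``scale_K = 0`` yields ``n`` copies of ``x``.
    ``modes`` must have been computed at ``x``.
    """
    if not np.allclose(modes.reference_geometry.coordinates, x.coordinates, atol=1e-8):
        raise ValueError("modes were not computed at the supplied structure")
    return nms_generate(modes, n, scale_K, rng)


def torsion_sampling_iteration(
    smiles: str,
    embedder,
    ensemble,
    cfg: TorsionConfig,
    rng: np.random.Generator,
) -> SelectionBatch:
    """One torsion-sampling pass for one SMILES string.

    embed -> optimize -> relaxed scan -> on halt, perturb the halted
    structure along its ensemble-derived normal modes and return those
    ``cfg.n_perturbed`` structures.  An un-halted scan yields an empty
    batch.
    """
    try:
        conf, torsions = embedder.embed(smiles, rng)
    except Exception as exc:
        raise ValueError(f"embedding failed for SMILES {smiles!r}: {exc}") from exc
    if not torsions:
        raise ValueError(f"no rotatable bond found for SMILES {smiles!r}")
    torsion = torsions[int(rng.integers(len(torsions)))]
    points, halt = relaxed_scan(conf, ensemble, torsion, cfg)
    if halt is None:
        return SelectionBatch([])
    x = points[halt].conformation
    modes = finite_difference_modes(x, _mean_force_fn(ensemble))
    perturbed = perturb_along_modes(x, modes, cfg.n_perturbed, cfg.perturb_scale_K, rng)
    prov: dict[str, Any] = {
        "sampler": "torsion",
        "smiles": smiles,
        "torsion": (torsion.i, torsion.j, torsion.k, torsion.l),
        "halt_step": halt,
    }
    return SelectionBatch(
        [SelectionEntry(p, points[halt].rho, dict(prov)) for p in perturbed]
    )


# ---------------------------------------------------------------------------
# Structure provider
# ---------------------------------------------------------------------------

class RDKitEmbedder:
    """Default structure provider: RDKit 3-D embedding + rotatable bonds."""

    _ROTATABLE_SMARTS = "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"

    def embed(
        self, smiles: str, rng: np.random.Generator | None = None
    ) -> tuple[Conformation, list[TorsionSpec]]:
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError("RDKit could not parse the SMILES")
        mol = Chem.AddHs(mol)
        seed = 2025 if rng is None else int(rng.integers(2**31 - 1))
        if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
            raise ValueError("RDKit 3-D embedding failed")
        coords = mol.GetConformer().GetPositions()
        zs = [a.GetAtomicNum() for a in mol.GetAtoms()]
        conf = Conformation(zs, coords)

        patt = Chem.MolFromSmarts(self._ROTATABLE_SMARTS)
        torsions: list[TorsionSpec] = []
        seen_bonds = set()
        for j, k in mol.GetSubstructMatches(patt):
            if (min(j, k), max(j, k)) in seen_bonds:
                continue
            seen_bonds.add((min(j, k), max(j, k)))
            nj = [a.GetIdx() for a in mol.GetAtomWithIdx(j).GetNeighbors() if a.GetIdx() != k]
            nk = [a.GetIdx() for a in mol.GetAtomWithIdx(k).GetNeighbors() if a.GetIdx() != j]
            if not nj or not nk:
                continue
            i = max(nj, key=lambda a: mol.GetAtomWithIdx(a).GetAtomicNum())
            l = max(nk, key=lambda a: mol.GetAtomWithIdx(a).GetAtomicNum())
            rotating = self._side_of(mol, j, k)
            torsions.append(TorsionSpec(i, j, k, l, frozenset(rotating)))
        return conf, torsions

    @staticmethod
    def _side_of(mol, j: int, k: int) -> set[int]:
        """Atoms on the k side of the j-k bond (BFS with the bond cut)."""
        side = {k}
        queue = [k]
        while queue:
            a = queue.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                idx = nb.GetIdx()
                if idx == j or idx in side:
                    continue
                side.add(idx)
                queue.append(idx)
        return side
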