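"""Dimer sampling: random periodic boxes, short MD, contact-dimer extraction.

A rectangular cell with edges drawn uniformly from 20-30 A is filled with
molecules drawn from a pool, biased toward molecules with fewer heavy atoms,
until a randomly drawn target atom density is reached.  Each molecule is
rigidly rotated and translated, rejecting placements that bring atoms of
different molecules within 1.5 A (minimum image).  After a short Langevin
trajectory (100 steps, 50-600 K) the box is decomposed into all molecule
pairs with at least one cross pair within 6 A, and the high-disagreement
dimers are selected.

Monomer coordinates are kept whole (never wrapped); the cell only defines
the minimum-image metric, and extracted dimers are translated to their
minimum-image relative position and carry no cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset_io import Conformation
from .samplers_local import (
    MDConfig,
    langevin_step,
    masses_of,
    maxwell_boltzmann_velocities,
    _mean_force_fn,
)
from .uncertainty import SelectionBatch, select_high_rho

__all__ = [
    "DimerConfig",
    "PlacementError",
    "choose_molecules",
    "build_box",
    "decompose_to_dimers",
    "dimer_sampling_round",
    "min_image_displacements",
]


class PlacementError(RuntimeError):
    """Could not place all molecules at the requested density."""


@dataclass
class DimerConfig:
    cell_range_A: tuple[float, float] = (20.0, 30.0)
    min_intermolecular_dist_A: float = 1.5
    temp_range_K: tuple[float, float] = (50.0, 600.0)
    md_steps: int = 100
    contact_cutoff_A: float = 6.0
    rho_threshold: float = 1.0
    density_range: tuple[float, float] = (0.005, 0.02)  # atoms / A^3
    size_bias_exponent: float = 1.0
    dt_fs: float = 0.5
    friction_per_fs: float = 0.02
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        lo, hi = self.cell_range_A
        if not (0 < lo <= hi):
            raise ValueError("cell_range_A must be positive and ordered")
        if self.min_intermolecular_dist_A <= 0 or self.contact_cutoff_A <= 0:
            raise ValueError("cutoffs must be positive")
        if self.md_steps < 0:
            raise ValueError("md_steps must be >= 0")


def min_image_displacements(d: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if cell is None:
        return d
    return d - cell * np.round(d / cell)


def _cross_min_distance(xa: np.ndarray, xb: np.ndarray, cell: np.ndarray | None) -> float:
    d = xb[None, :, :] - xa[:, None, :]
    d = min_image_displacements(d, cell)
    return float(np.sqrt((d**2).sum(axis=-1)).min())


def choose_molecules(
    pool: Sequence[Conformation],
    cfg: DimerConfig,
    rng: np.random.Generator,
    volume_A3: float | None = None,
) -> list[Conformation]:
    """Draw molecules (with replacement) until the target atom count is met.

    Selection probability is proportional to ``n_heavy ** (-size_bias_exponent)``
    (hydrogen-only molecules count as one heavy atom), biasing toward small
    molecules.  The target atom count is a density drawn uniformly from
    ``cfg.density_range`` times the box volume; if no volume is given a
    provisional cell is drawn from ``cfg.cell_range_A``.
    """
    if len(pool) == 0:
        raise ValueError("molecule pool is empty")
    if volume_A3 is None:
        volume_A3 = float(np.prod(rng.uniform(*cfg.cell_range_A, size=3)))
    heavy = np.array(
        [max(1, int(np.sum(np.asarray(m.atomic_numbers) > 1))) for m in pool],
        dtype=float,
    )
    weights = heavy ** (-cfg.size_bias_exponent)
    weights /= weights.sum()
    target_atoms = rng.uniform(*cfg.density_range) * volume_A3
    chosen: list[Conformation] = []
    total = 0
    while total < target_atoms:
        m = pool[int(rng.choice(len(pool), p=weights))]
        chosen.append(m)
        total += m.n_atoms
    return chosen


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_box(
    molecules: Sequence[Conformation],
    cfg: DimerConfig,
    rng: np.random.Generator,
    cell: np.ndarray | None = None,
) -> Conformation:
    """Embed molecules in a rectangular periodic cell with random pose.

    Each molecule is rigidly rotated (uniform rotation) and translated to a
    uniform position in the cell; a placement is rejected if any atom comes
    within ``min_intermolecular_dist_A`` (minimum image) of an already
    placed molecule.  Raises :class:`PlacementError` when the per-molecule
    attempt cap is exhausted (box too dense).
    """
    if len(molecules) == 0:
        raise ValueError("no molecules to place")
    if cell is None:
        cell = rng.uniform(*cfg.cell_range_A, size=3)
    cell = np.asarray(cell, dtype=float)
    placed_coords: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    mol_ids: list[np.ndarray] = []
    for mi, mol in enumerate(molecules):
        centered = mol.coordinates - mol.coordinates.mean(axis=0)
        for attempt in range(cfg.max_place_attempts):
            rot = _random_rotation(rng)
            pos = centered @ rot.T + rng.uniform(0.0, 1.0, size=3) * cell
            ok = all(
                _cross_min_distance(prev, pos, cell) >= cfg.min_intermolecular_dist_A
                for prev in placed_coords
            )
            if ok:
                placed_coords.append(pos)
                zs.append(np.asarray(mol.atomic_numbers))
                mol_ids.append(np.full(mol.n_atoms, mi))
                break
        else:
            raise PlacementError(
                f"could not place molecule {mi} after {cfg.max_place_attempts} attempts"
            )
    return Conformation(
        np.concatenate(zs),
        np.vstack(placed_coords),
        cell=cell,
        molecule_ids=np.concatenate(mol_ids),
    )


def decompose_to_dimers(box: Conformation, cutoff_A: float = 6.0) -> list[Conformation]:
    """Extract all contact dimers from a multi-molecule box.

    One dimer per unordered molecule pair whose minimum-image cross-molecule
    minimum distance is <= ``cutoff_A``.  The second monomer is translated
    by the lattice vector realizing the closest contact, so the dimer is a
    free-space (cell-less) structure with ``molecule_ids`` 0 and 1.
    """
    if box.molecule_ids is None:
        raise ValueError("box has no molecule_ids")
    ids = np.unique(box.molecule_ids)
    dimers = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            sel_a = box.molecule_ids == ids[ai]
            sel_b = box.molecule_ids == ids[bi]
            xa = box.coordinates[sel_a]
            xb = box.coordinates[sel_b]
            d = xb[None, :, :] - xa[:, None, :]
            dmin = min_image_displacements(d, box.cell)
            dist = np.sqrt((dmin**2).sum(axis=-1))
            if dist.min() > cutoff_A:
                continue
            ia, ib = np.unravel_index(np.argmin(dist), dist.shape)
            # lattice shift that realizes the closest contact for pair (ia, ib)
            shift = dmin[ia, ib] - d[ia, ib]
            dimers.append(
                Conformation(
                    np.concatenate([box.atomic_numbers[sel_a], box.atomic_numbers[sel_b]]),
                    np.vstack([xa, xb + shift]),
                    molecule_ids=np.concatenate(
                        [np.zeros(sel_a.sum(), int), np.ones(sel_b.sum(), int)]
                    ),
                )
            )
    return dimers


def dimer_sampling_round(
    pool: Sequence[Conformation],
    ensemble,
    cfg: DimerConfig,
    rng: np.random.Generator,
) -> SelectionBatch:
    """One full dimer-sampling pipeline pass.

    choose -> build box -> ``cfg.md_steps`` Langevin steps at a random
    temperature from ``temp_range_K`` -> decompose into contact dimers ->
    rho per dimer -> select above threshold.
    """
    cell = rng.uniform(*cfg.cell_range_A, size=3)
    molecules = choose_molecules(pool, cfg, rng, volume_A3=float(np.prod(cell)))
    box = build_box(molecules, cfg, rng, cell=cell)
    if cfg.md_steps > 0:
        temp = rng.uniform(*cfg.temp_range_K)
        md_cfg = MDConfig(
            temp_range_K=cfg.temp_range_K,
            dt_fs=cfg.dt_fs,
            friction_per_fs=cfg.friction_per_fs,
            rho_threshold=np.inf,
            max_steps=cfg.md_steps,
        )
        masses = masses_of(box.atomic_numbers)
        vel = maxwell_boltzmann_velocities(masses, temp, rng)
        force_fn = _mean_force_fn(ensemble)
        forces = force_fn(box)
        for _ in range(cfg.md_steps):
            box, vel, forces = langevin_step(
                box, vel, forces, masses, temp, md_cfg, rng, force_fn
            )
    dimers = decompose_to_dimers(box, cfg.contact_cutoff_A)
    candidates = [(d, ensemble.predict(d)) for d in dimers]
    batch = select_high_rho(candidates, cfg.rho_threshold, provenance={"sampler": "dimer"})
    for entry in batch.entries:
        d = entry.conformation
        entry.provenance["monomer_atom_counts"] = (
            int((d.molecule_ids == 0).sum()),
            int((d.molecule_ids == 1).sum()),
        )
    return batch
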