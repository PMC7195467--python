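"""Dataset statistics and diversity featurization.

* Per-element linear energy baseline: ordinary least squares of total energy
  on element counts; subtracting it leaves the conformational/atomization
  part of the energy, which is what the 1-millihartree-bin energy histogram
  summarizes.
* Atom-count histograms (bin width one).
* Bonded-neighbor environment labels (e.g. the two carbons of ethanol are
  "HHHC" and "HHCO") from a covalent-radius bond rule.
* Atomic environment vectors (AEVs): rotation/translation/permutation
  invariant per-atom descriptors built from radial and angular symmetry
  functions; with the 4-species H/C/N/O configuration the descriptor has
  length 16*4 + 32*10 = 384.
* A pluggable 2-D embedding hook (default: top-2 principal axes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable, Sequence

import numpy as np

from .dataset_io import Conformation, ConformerGroup, element_symbol

__all__ = [
    "ElementFit",
    "DescriptorConfig",
    "COVALENT_RADII_A",
    "linear_element_fit",
    "energy_histogram",
    "size_histogram",
    "bonded_neighbors",
    "neighbor_environment_label",
    "atomic_descriptor",
    "descriptor_matrix",
    "embed_2d",
]

COVALENT_RADII_A = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "S": 1.05}
#: bond iff r_ij <= BOND_FACTOR * (r_cov_i + r_cov_j)
BOND_FACTOR = 1.3
#: canonical element sort order for environment labels
_LABEL_ORDER = {"H": 0, "C": 1, "N": 2, "O": 3, "F": 4, "S": 5}


# ---------------------------------------------------------------------------
# Linear element baseline and histograms
# ---------------------------------------------------------------------------

@dataclass
class ElementFit:
    coefficients: dict[str, float]
    intercept: float
    residuals: np.ndarray


def linear_element_fit(
    energies: Sequence[float],
    formulas: Sequence[dict[str, int]],
    with_intercept: bool = False,
) -> ElementFit:
    """Least-squares fit of energies (Ha) on per-element atom counts.

    The design matrix has one column per element present in ``formulas``
    (plus an optional global intercept, off by default).  Raises on a
    rank-deficient design, e.g. when every conformer has the same formula.
    """
    energies = np.asarray(energies, dtype=np.float64)
    if len(energies) != len(formulas):
        raise ValueError("energies and formulas length mismatch")
    elements = sorted({el for f in formulas for el in f})
    ncol = len(elements) + int(with_intercept)
    if len(energies) < ncol:
        raise ValueError(f"need at least {ncol} conformers for {ncol} coefficients")
    design = np.zeros((len(energies), ncol))
    for r, f in enumerate(formulas):
        for c, el in enumerate(elements):
            design[r, c] = f.get(el, 0)
    if with_intercept:
        design[:, -1] = 1.0
    rank = np.linalg.matrix_rank(design)
    if rank < ncol:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {ncol}); "
            "element counts do not vary independently across conformers"
        )
    coef, *_ = np.linalg.lstsq(design, energies, rcond=None)
    residuals = energies - design @ coef
    intercept = float(coef[-1]) if with_intercept else 0.0
    per_element = dict(zip(elements, map(float, coef)))
    return ElementFit(per_element, intercept, residuals)


def _unit_histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    if len(values) == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def energy_histogram(
    residuals: Sequence[float], bin_width_Ha: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of baseline-subtracted energies; default bin width 1 mHa."""
    residuals = np.asarray(residuals, dtype=np.float64)
    if residuals.size and not np.all(np.isfinite(residuals)):
        raise ValueError("non-finite residuals")
    return _unit_histogram(residuals, bin_width_Ha)


def size_histogram(groups: Sequence[ConformerGroup]) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of total atoms per conformer, bin width one."""
    sizes = np.concatenate(
        [np.full(g.n_conformers, g.n_atoms, dtype=np.float64) for g in groups]
    ) if groups else np.empty(0)
    return _unit_histogram(sizes, 1.0)


# ---------------------------------------------------------------------------
# Bond perception and environment labels
# ---------------------------------------------------------------------------

def bonded_neighbors(conf: Conformation, atom_index: int) -> list[int]:
    """Indices bonded to ``atom_index`` by the covalent-radius rule."""
    syms = [element_symbol(int(z)) for z in conf.atomic_numbers]
    ri = COVALENT_RADII_A[syms[atom_index]]
    d = np.linalg.norm(conf.coordinates - conf.coordinates[atom_index], axis=1)
    out = []
    for jdx, sym in enumerate(syms):
        if jdx == atom_index:
            continue
        if d[jdx] <= BOND_FACTOR * (ri + COVALENT_RADII_A[sym]):
            out.append(jdx)
    return out


def neighbor_environment_label(conf: Conformation, atom_index: int) -> str:
    """Element symbols of the bonded neighbors, sorted H < C < N < O."""
    syms = [element_symbol(int(conf.atomic_numbers[j])) for j in bonded_neighbors(conf, atom_index)]
    return "".join(sorted(syms, key=lambda s: _LABEL_ORDER.get(s, 99)))


# ---------------------------------------------------------------------------
# Atomic environment vectors
# ---------------------------------------------------------------------------

@dataclass
class DescriptorConfig:
    """Symmetry-function hyperparameters (ANI-style defaults).

    Descriptor length = n_radial * |species| +
    (n_ang_radial * n_ang_sections) * C(|species|+1, 2); the default
    H/C/N/O configuration gives 16*4 + 32*10 = 384.
    """

    species: tuple[str, ...] = ("H", "C", "N", "O")
    n_radial: int = 16
    radial_cutoff_A: float = 5.2
    radial_eta: float = 16.0
    angular_cutoff_A: float = 3.5
    n_ang_radial: int = 8
    n_ang_sections: int = 4
    angular_eta: float = 8.0
    angular_zeta: float = 32.0

    @property
    def length(self) -> int:
        pairs = len(self.species) * (len(self.species) + 1) // 2
        return self.n_radial * len(self.species) + (
            self.n_ang_radial * self.n_ang_sections
        ) * pairs

    @property
    def radial_shifts(self) -> np.ndarray:
        return np.linspace(0.9, self.radial_cutoff_A, self.n_radial, endpoint=False)

    @property
    def angular_shifts(self) -> np.ndarray:
        return np.linspace(0.9, self.angular_cutoff_A, self.n_ang_radial, endpoint=False)

    @property
    def angle_sections(self) -> np.ndarray:
        return (np.arange(self.n_ang_sections) + 0.5) * np.pi / self.n_ang_sections


def _fc(r: np.ndarray, rc: float) -> np.ndarray:
    """Smooth cosine cutoff, zero at and beyond rc."""
    return np.where(r < rc, 0.5 * np.cos(np.pi * r / rc) + 0.5, 0.0)


def atomic_descriptor(
    conf: Conformation, atom_index: int, cfg: DescriptorConfig | None = None
) -> np.ndarray:
    """AEV of one atom: radial blocks per species, angular per species pair.

    Invariant under rigid rotation/translation and permutation of
    same-species atoms; an isolated atom (no neighbors inside the cutoffs)
    maps to the zero vector.
    """
    cfg = cfg or DescriptorConfig()
    syms = [element_symbol(int(z)) for z in conf.atomic_numbers]
    xi = conf.coordinates[atom_index]
    rel = conf.coordinates - xi
    dist = np.linalg.norm(rel, axis=1)
    neighbors = [
        j for j in range(conf.n_atoms)
        if j != atom_index and dist[j] < cfg.radial_cutoff_A and syms[j] in cfg.species
    ]
    out = np.zeros(cfg.length)
    # radial block
    shifts = cfg.radial_shifts
    for j in neighbors:
        s = cfg.species.index(syms[j])
        g = np.exp(-cfg.radial_eta * (dist[j] - shifts) ** 2) * _fc(dist[j], cfg.radial_cutoff_A)
        out[s * cfg.n_radial : (s + 1) * cfg.n_radial] += g
    # angular block
    ang_neighbors = [j for j in neighbors if dist[j] < cfg.angular_cutoff_A]
    pair_index = {
        pair: p for p, pair in enumerate(combinations_with_replacement(cfg.species, 2))
    }
    block = cfg.n_ang_radial * cfg.n_ang_sections
    base = cfg.n_radial * len(cfg.species)
    ash = cfg.angular_shifts
    ts = cfg.angle_sections
    for a_i, j in enumerate(ang_neighbors):
        for k in ang_neighbors[a_i + 1 :]:
            cosang = np.clip(
                (rel[j] @ rel[k]) / (dist[j] * dist[k]), -1.0, 1.0
            )
            theta = np.arccos(cosang)
            ravg = 0.5 * (dist[j] + dist[k])
            radial_part = np.exp(-cfg.angular_eta * (ravg - ash) ** 2) * _fc(
                dist[j], cfg.angular_cutoff_A
            ) * _fc(dist[k], cfg.angular_cutoff_A)
            angular_part = (
                2.0 ** (1.0 - cfg.angular_zeta)
                * (1.0 + np.cos(theta - ts)) ** cfg.angular_zeta
            )
            feat = np.outer(angular_part, radial_part).ravel()
            pair = tuple(sorted((syms[j], syms[k]), key=cfg.species.index))
            p = pair_index[pair]
            out[base + p * block : base + (p + 1) * block] += feat
    return out


def descriptor_matrix(
    conformations: Sequence[Conformation], cfg: DescriptorConfig | None = None
) -> np.ndarray:
    """Stack of per-atom AEVs for every atom of every conformation."""
    cfg = cfg or DescriptorConfig()
    rows = [
        atomic_descriptor(conf, a, cfg)
        for conf in conformations
        for a in range(conf.n_atoms)
    ]
    return np.vstack(rows) if rows else np.empty((0, cfg.length))


# ---------------------------------------------------------------------------
# 2-D embedding hook
# ---------------------------------------------------------------------------

def embed_2d(
    descriptors: np.ndarray,
    embedder: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Project descriptor rows to 2-D.

    Delegates to ``embedder`` when given (any callable mapping an (N, D)
    matrix to (N, 2), e.g. a t-SNE or UMAP wrapper); the default projects
    onto the top two principal axes.  Zero-variance input yields zeros with
    a warning.
    """
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if not np.all(np.isfinite(descriptors)):
        raise ValueError("non-finite descriptor entries")
    if embedder is not None:
        out = np.asarray(embedder(descriptors))
        if out.shape != (len(descriptors), 2):
            raise ValueError("embedder must return an (N, 2) array")
        return out
    centered = descriptors - descriptors.mean(axis=0, keepdims=True)
    if len(descriptors) == 0:
        return np.empty((0, 2))
    if np.allclose(centered, 0.0):
        warnings.warn("zero-variance descriptors; returning zeros", RuntimeWarning, stacklevel=2)
        return np.zeros((len(descriptors), 2))
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    ncomp = min(2, vt.shape[0])
    proj = np.zeros((len(descriptors), 2))
    proj[:, :ncomp] = centered @ vt[:ncomp].T
    return proj
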