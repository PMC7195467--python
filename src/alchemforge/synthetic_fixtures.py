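"""Synthetic fixtures: everything needed to exercise the toolkit offline.

* Toy H/C/N/O molecules with sane geometries (water, methane, ethanol,
  ammonia, random heavy-atom chains).
* :class:`SurrogateEnsemble` — an ensemble of cheap analytic pairwise Morse
  potentials with controllable, optionally localized, member disagreement.
  It honors the potential-ensemble contract (energies in Ha, analytic
  forces in Ha/A, minimum-image aware) and stands in for a trained ML
  potential ensemble wherever one is required.
* Schema-valid HDF5 fixture files with *planted* per-key availability, so
  filtered-loader counts are predictable.
* Component-energy tables with ground-truth composite energies computed by
  an extended-precision oracle.

Every fixture is deterministic given its seed.  Surrogate energy scales are
chosen so that typical disagreements are in the 0.01-0.1 Ha range, keeping
kcal/mol thresholds meaningful; no physical realism beyond smoothness and
correct units is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import (
    Conformation,
    ConformerGroup,
    TABLE_SCHEMA,
    write_dataset,
)
from .samplers_dimer import min_image_displacements
from .samplers_torsion import TorsionSpec, dihedral_deg, dihedral_gradient
from .uncertainty import EnsemblePrediction

__all__ = [
    "SurrogateEnsemble",
    "HarmonicWell",
    "FixtureEmbedder",
    "make_toy_molecules",
    "make_surrogate_ensemble",
    "make_fixture_h5",
    "make_component_table",
    "FixtureManifest",
]

_COV_R = {1: 0.31, 6: 0.76, 7: 0.71, 8: 0.66}


# ---------------------------------------------------------------------------
# Toy molecules
# ---------------------------------------------------------------------------

def _water() -> Conformation:
    return Conformation(
        [8, 1, 1],
        [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]],
    )


def _methane() -> Conformation:
    d = 1.087 / np.sqrt(3.0)
    return Conformation(
        [6, 1, 1, 1, 1],
        [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]],
    )


def _ammonia() -> Conformation:
    return Conformation(
        [7, 1, 1, 1],
        [
            [0.0, 0.0, 0.1173],
            [0.0, 0.9377, -0.2737],
            [0.8121, -0.4689, -0.2737],
            [-0.8121, -0.4689, -0.2737],
        ],
    )


def _ethanol() -> Conformation:
    # CH3-CH2-OH; methyl carbon first, then the HHCO carbon.
    return Conformation(
        [6, 6, 8, 1, 1, 1, 1, 1, 1],
        [
            [1.2306, -0.2429, 0.0000],
            [0.0000, 0.5575, 0.0000],
            [-1.1677, -0.2354, 0.0000],
            [2.1102, 0.4078, 0.0000],
            [1.2631, -0.8806, 0.8863],
            [1.2631, -0.8806, -0.8863],
            [0.0292, 1.2115, 0.8819],
            [0.0292, 1.2115, -0.8819],
            [-1.9290, 0.3437, 0.0000],
        ],
    )


def _random_chain(n_heavy: int, rng: np.random.Generator) -> Conformation:
    """Zig-zag heavy-atom chain (C/N/O) with hydrogens filling valence-ish."""
    zs: list[int] = []
    coords: list[np.ndarray] = []
    pos = np.zeros(3)
    direction = np.array([1.0, 0.0, 0.0])
    for h in range(n_heavy):
        z = int(rng.choice([6, 6, 7, 8]))
        zs.append(z)
        coords.append(pos.copy())
        n_h = {6: 2, 7: 1, 8: 0}[z] if 0 < h < n_heavy - 1 else {6: 3, 7: 2, 8: 1}[z]
        for k in range(n_h):
            ang = 2.0 * np.pi * (k + 0.5) / max(n_h, 1)
            off = np.array([0.0, np.cos(ang), np.sin(ang)]) * 1.05
            off += direction * (0.35 if h == 0 else -0.35)
            zs.append(1)
            coords.append(pos + off)
        step = np.array([1.25, 0.55 * (-1.0) ** h, 0.0])
        step += rng.normal(scale=0.03, size=3)
        pos = pos + step
    return Conformation(zs, np.array(coords))


_BUILDERS = {
    "water": _water,
    "methane": _methane,
    "ammonia": _ammonia,
    "ethanol": _ethanol,
}


def make_toy_molecules(spec, rng: np.random.Generator | None = None) -> list[Conformation]:
    """Build toy molecules by name.

    ``spec`` is a name or list of names from ``water``, ``methane``,
    ``ammonia``, ``ethanol``, or ``chain_N`` for a random N-heavy-atom
    chain (requires ``rng``).
    """
    if isinstance(spec, str):
        spec = [spec]
    out = []
    for name in spec:
        if name in _BUILDERS:
            out.append(_BUILDERS[name]())
        elif name.startswith("chain_"):
            if rng is None:
                raise ValueError("random chains require an rng")
            out.append(_random_chain(int(name.split("_", 1)[1]), rng))
        else:
            raise ValueError(f"unknown toy molecule {name!r}; valid: "
                             f"{sorted(_BUILDERS)} or 'chain_N'")
    return out


# ---------------------------------------------------------------------------
# Surrogate potentials
# ---------------------------------------------------------------------------

class SurrogateEnsemble:
    """Ensemble of pairwise Morse potentials with controllable disagreement.

    The base energy is ``sum_{i<j} D (1 - exp(-a (r_ij - r0_ij)))**2`` with
    ``r0_ij`` the sum of covalent radii; member ``m`` predicts
    ``E_base + amplitude * eta_m * L(x)`` where ``eta_m`` are fixed
    per-member standard-normal draws and ``L`` is the localization
    functional:

    * ``None`` / ``"global"`` — ``L = E_base`` (members scale the whole
      surface);
    * ``"stretch"`` — ``L`` grows quadratically as short-range pairs
      stretch away from their equilibrium distance, so disagreement rises
      with bond elongation;
    * ``"dihedral"`` — a Gaussian window in one dihedral angle (requires
      ``torsion``, ``window_center_deg``, ``window_width_deg``), spiking
      disagreement inside the window.

    ``amplitude = 0`` makes all members identical (rho = 0 everywhere).
    Minimum-image distances are used when a conformation carries a cell.
    """

    def __init__(
        self,
        k: int = 4,
        amplitude: float = 0.0,
        localization: str | None = None,
        seed: int = 0,
        well_depth_Ha: float = 0.12,
        steepness_per_A: float = 2.0,
        torsion: TorsionSpec | None = None,
        window_center_deg: float = 90.0,
        window_width_deg: float = 20.0,
    ):
        if k < 2:
            raise ValueError("ensemble needs k >= 2 members")
        if localization not in (None, "global", "stretch", "dihedral"):
            raise ValueError(f"unknown localization {localization!r}")
        if localization == "dihedral" and torsion is None:
            raise ValueError("dihedral localization requires a torsion")
        self.k = k
        self.amplitude = float(amplitude)
        self.localization = localization or "global"
        self.well_depth = well_depth_Ha
        self.steepness = steepness_per_A
        self.torsion = torsion
        self.window_center = window_center_deg
        self.window_width = window_width_deg
        self.eta = np.random.default_rng(seed).standard_normal(k)

    @property
    def n_members(self) -> int:
        return self.k

    # -- base Morse surface -------------------------------------------------
    def _pair_geometry(self, conf: Conformation):
        x = conf.coordinates
        n = len(x)
        iu, ju = np.triu_indices(n, k=1)
        d = x[ju] - x[iu]
        d = min_image_displacements(d, conf.cell)
        r = np.linalg.norm(d, axis=1)
        rc = np.array([_COV_R.get(int(z), 0.75) for z in conf.atomic_numbers])
        r0 = rc[iu] + rc[ju]
        return iu, ju, d, r, r0

    def _base(self, conf: Conformation):
        iu, ju, d, r, r0 = self._pair_geometry(conf)
        ex = np.exp(-self.steepness * (r - r0))
        e = float(np.sum(self.well_depth * (1.0 - ex) ** 2))
        dv_dr = 2.0 * self.steepness * self.well_depth * (1.0 - ex) * ex
        forces = np.zeros_like(conf.coordinates)
        fpair = -(dv_dr / r)[:, None] * d  # force on j from i along +d
        np.add.at(forces, ju, fpair)
        np.subtract.at(forces, iu, fpair)
        return e, forces

    # -- localization functionals --------------------------------------------
    def _local(self, conf: Conformation):
        if self.localization == "global":
            return self._base(conf)
        if self.localization == "stretch":
            iu, ju, d, r, r0 = self._pair_geometry(conf)
            rc_out = 2.6  # only short-range (bond-like) pairs contribute
            mask = r < rc_out
            s = np.zeros_like(r)
            t = np.zeros_like(r)
            rr = r[mask]
            t[mask] = 0.5 * np.cos(np.pi * rr / rc_out) + 0.5
            s[mask] = (rr - r0[mask]) ** 2 * t[mask]
            e = float(np.sum(s))
            ds_dr = np.zeros_like(r)
            ds_dr[mask] = 2.0 * (rr - r0[mask]) * t[mask] + (rr - r0[mask]) ** 2 * (
                -0.5 * np.pi / rc_out * np.sin(np.pi * rr / rc_out)
            )
            forces = np.zeros_like(conf.coordinates)
            fpair = -(ds_dr / r)[:, None] * d
            np.add.at(forces, ju, fpair)
            np.subtract.at(forces, iu, fpair)
            return e, forces
        # dihedral window
        t = self.torsion
        phi = dihedral_deg(conf.coordinates, t.i, t.j, t.k, t.l)
        dphi = (phi - self.window_center + 180.0) % 360.0 - 180.0
        g = float(np.exp(-0.5 * (dphi / self.window_width) ** 2))
        # dL/dx = g'(phi) * dphi/dx, with phi in degrees
        dg_dphi = -dphi / self.window_width**2 * g  # per degree
        grad_phi = np.degrees(dihedral_gradient(conf.coordinates, t.i, t.j, t.k, t.l))
        return g, -dg_dphi * grad_phi

    # -- ensemble contract ----------------------------------------------------
    def member_energies(self, conf: Conformation) -> np.ndarray:
        e0, _ = self._base(conf)
        if self.amplitude == 0.0:
            return np.full(self.k, e0)
        el, _ = self._local(conf)
        return e0 + self.amplitude * self.eta * el

    def member_forces(self, conf: Conformation) -> np.ndarray:
        e0, f0 = self._base(conf)
        if self.amplitude == 0.0:
            return np.broadcast_to(f0, (self.k,) + f0.shape).copy()
        el, fl = self._local(conf)
        return f0[None] + self.amplitude * self.eta[:, None, None] * fl[None]

    def predict(self, conf: Conformation) -> EnsemblePrediction:
        return EnsemblePrediction(self.member_energies(conf), conf.n_atoms)

    def mean_energy(self, conf: Conformation) -> float:
        return float(self.member_energies(conf).mean())


def make_surrogate_ensemble(
    k: int = 4,
    amplitude: float = 0.0,
    localization: str | None = None,
    seed: int = 0,
    **kwargs,
) -> SurrogateEnsemble:
    """Factory for :class:`SurrogateEnsemble` (deterministic given seed)."""
    return SurrogateEnsemble(k=k, amplitude=amplitude, localization=localization,
                             seed=seed, **kwargs)


class HarmonicWell:
    """Isotropic harmonic tether to a reference geometry (test potential)."""

    def __init__(self, reference: Conformation, k_Ha_per_A2: float = 0.1):
        self.x0 = reference.coordinates.copy()
        self.k = k_Ha_per_A2

    def energy(self, conf: Conformation) -> float:
        return 0.5 * self.k * float(np.sum((conf.coordinates - self.x0) ** 2))

    def forces(self, conf: Conformation) -> np.ndarray:
        return -self.k * (conf.coordinates - self.x0)


class FixtureEmbedder:
    """Structure provider returning a fixed butane-like chain and torsion.

    Lets torsion-sampling tests run without any cheminformatics dependency;
    the "SMILES" argument is ignored beyond being recorded.
    """

    def __init__(self):
        # 4 heavy atoms + terminal Hs, staggered start
        coords = np.array(
            [
                [-1.95, 0.55, 0.0],
                [-0.65, -0.25, 0.0],
                [0.65, 0.55, 0.0],
                [1.95, -0.25, 0.3],
                [-2.85, -0.05, 0.3],
                [2.45, 0.35, 1.1],
            ]
        )
        self.conf = Conformation([6, 6, 6, 6, 1, 1], coords)
        self.torsion = TorsionSpec(0, 1, 2, 3, frozenset({2, 3, 5}))

    def embed(self, smiles: str, rng=None):
        return self.conf.copy(), [self.torsion]


# ---------------------------------------------------------------------------
# HDF5 fixture with planted availability
# ---------------------------------------------------------------------------

@dataclass
class FixtureManifest:
    """Bookkeeping of what was planted in a fixture file."""

    path: str
    availability: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def expected_count(self, keys: list[str]) -> int:
        """Conformers surviving the filtered loader for this key set."""
        total = 0
        for _, masks in self.availability.items():
            nc = len(next(iter(masks.values())))
            keep = np.ones(nc, dtype=bool)
            for k in keys:
                if k in ("coordinates", "atomic_numbers"):
                    continue
                if k not in masks:
                    keep[:] = False
                    break
                keep &= masks[k]
            total += int(keep.sum())
        return total


_FIXTURE_KEYS = [
    "wb97x_dz.energy",
    "wb97x_tz.energy",
    "ccsd(t)_cbs.energy",
    "wb97x_dz.forces",
    "wb97x_dz.dipole",
    "wb97x_tz.quadrupole",
    "wb97x_dz.cm5_charges",
]


def make_fixture_h5(
    path,
    n_groups: int = 5,
    nc_range: tuple[int, int] = (3, 12),
    missing_fraction: float = 0.3,
    seed: int = 0,
) -> FixtureManifest:
    """Write a schema-valid HDF5 fixture with known per-key availability.

    ``'wb97x_dz.energy'`` is always fully available; the other planted keys
    have each conformer missing (NaN) independently with probability
    ``missing_fraction``.  The returned manifest predicts filtered-loader
    counts exactly.
    """
    rng = np.random.default_rng(seed)
    base_names = ["water", "methane", "ammonia", "ethanol"]
    groups = []
    manifest = FixtureManifest(str(path))
    for gi in range(n_groups):
        name = base_names[gi % len(base_names)]
        mol = make_toy_molecules(name)[0]
        nc = int(rng.integers(nc_range[0], nc_range[1] + 1))
        na = mol.n_atoms
        coords = (
            mol.coordinates[None] + rng.normal(scale=0.05, size=(nc, na, 3))
        ).astype(np.float32)
        props: dict[str, np.ndarray] = {"coordinates": coords}
        masks: dict[str, np.ndarray] = {}
        for key in _FIXTURE_KEYS:
            dtype, trailing = TABLE_SCHEMA[key]
            tail = tuple(na if t == "Na" else t for t in trailing)
            arr = rng.normal(scale=1.0, size=(nc,) + tail).astype(dtype)
            if key.endswith(".energy"):
                arr = (arr * 0.01 - 40.0 * na / 3).astype(dtype)
            if key == "wb97x_dz.energy":
                mask = np.ones(nc, dtype=bool)
            else:
                mask = rng.uniform(size=nc) >= missing_fraction
                arr[~mask] = np.nan
            props[key] = arr
            masks[key] = mask
        gkey = f"{mol.formula()}_{gi:05d}"
        groups.append(ConformerGroup(gkey, mol.atomic_numbers, props))
        manifest.availability[gkey] = masks
    write_dataset(groups, path)
    return manifest


# ---------------------------------------------------------------------------
# Component-energy tables
# ---------------------------------------------------------------------------

def _composite_longdouble(row: dict[str, np.longdouble], alpha, beta) -> np.longdouble:
    """Extended-precision composite oracle (independent of the public API)."""
    a = np.longdouble(alpha)
    b = np.longdouble(beta)
    w4 = np.exp(-a * np.sqrt(np.longdouble(4.0)))
    w3 = np.exp(-a * np.sqrt(np.longdouble(3.0)))
    hf = (w4 * row["hf3"] - w3 * row["hf4"]) / (w4 - w3)
    p4 = np.longdouble(4.0) ** b
    p3 = np.longdouble(3.0) ** b
    corr = (p4 * row["mp2_4"] - p3 * row["mp2_3"]) / (p4 - p3)
    return hf + corr - row["mp2_3"] + row["npno3"] + row["tpno2"] - row["npno2"]


def make_component_table(path, n_records: int = 50, seed: int = 0,
                         alpha: float = 5.46, beta: float = 3.05):
    """Write a random component-energy CSV plus ground-truth composites.

    Returns ``(path, truth)`` with ``truth`` a dict id -> composite energy
    computed by the extended-precision oracle.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, float] = {}
    for n in range(n_records):
        rid = f"rec{n:04d}"
        hf3 = -40.0 - 60.0 * rng.uniform()
        vals = {
            "hf3": np.longdouble(hf3),
            "hf4": np.longdouble(hf3 - 0.01 * rng.uniform()),
            "mp2_3": np.longdouble(-0.2 - 0.4 * rng.uniform()),
            "npno2": np.longdouble(-0.2 - 0.3 * rng.uniform()),
            "tpno2": np.longdouble(-0.2 - 0.3 * rng.uniform()),
        }
        vals["mp2_4"] = vals["mp2_3"] - np.longdouble(0.05 * rng.uniform())
        vals["npno3"] = vals["npno2"] - np.longdouble(0.05 * rng.uniform())
        for method, card, key in [
            ("hf", 3, "hf3"),
            ("hf", 4, "hf4"),
            ("mp2_corr", 3, "mp2_3"),
            ("mp2_corr", 4, "mp2_4"),
            ("npno_ccsdt_corr", 2, "npno2"),
            ("npno_ccsdt_corr", 3, "npno3"),
            ("tpno_ccsdt_corr", 2, "tpno2"),
        ]:
            rows.append((rid, method, card, f"{float(vals[key]):.12f}"))
        vals_r = {k: np.longdouble(f"{float(v):.12f}") for k, v in vals.items()}
        truth[rid] = float(_composite_longdouble(vals_r, alpha, beta))
    with open(path, "w") as fh:
        fh.write("id,method,cardinal,energy_Ha\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")
    return str(path), truth


# ---------------------------------------------------------------------------
# Toy 2-D potential-surface benchmark for the active-learning loop
# ---------------------------------------------------------------------------

def toy_pes_2d(x, y):
    """Smooth 2-D test surface with a localized rough patch.

    A shallow quadratic bowl plus a high-frequency corrugation confined to a
    Gaussian patch near (1, 1): the kind of surface where uniform sampling
    wastes labels on the easy region while the hard region stays
    under-resolved.  Units are nominal Hartree.
    """
    patch = np.exp(-((x - 1.0) ** 2 + (y - 1.0) ** 2) / (2 * 0.7**2))
    return 0.025 * (x**2 + y**2) + 0.15 * np.sin(5.5 * x) * np.sin(5.5 * y) * patch


def al_benchmark(
    seed: int,
    strategy: str,
    n_pool: int = 400,
    n_init: int = 15,
    n_iterations: int = 5,
    budget: int = 10,
    k_members: int = 8,
) -> float:
    """Max held-out ensemble error after an active-learning campaign.

    Runs the real :func:`~alchemforge.active_learning.al_iteration` loop on
    a fixed candidate pool over :func:`toy_pes_2d`, with the label budget
    spent either on the highest-disagreement pool points
    (``strategy="al"``) or uniformly at random (``strategy="random"``).
    Returns the maximum absolute error of the final ensemble mean over the
    never-labeled pool points.  Deterministic given ``seed``.
    """
    from .active_learning import (
        ALState,
        EnsembleRegressorTrainer,
        al_iteration,
        groups_from_labeled,
    )
    from .uncertainty import SelectionBatch as _Batch, SelectionEntry as _Entry
    from .uncertainty import rho as _rho

    if strategy not in ("al", "random"):
        raise ValueError("strategy must be 'al' or 'random'")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-2.0, 2.0, size=(n_pool, 2))
    pool = [Conformation([6], [[x, y, 0.0]]) for x, y in xy]
    energies = toy_pes_2d(xy[:, 0], xy[:, 1])

    featurizer = lambda c: c.coordinates[0, :2]

    class _PESLabeler:
        def label(self, confs):
            return [
                {"wb97x_dz.energy": float(toy_pes_2d(*featurizer(c)))} for c in confs
            ]

    labeled_idx: set[int] = set(rng.choice(n_pool, n_init, replace=False).tolist())

    def sampler(ensemble, rng_):
        rest = [i for i in range(n_pool) if i not in labeled_idx]
        if strategy == "al":
            scored = [(i, _rho(ensemble.predict(pool[i]))) for i in rest]
            scored.sort(key=lambda t: -t[1])
            chosen = [i for i, _ in scored[:budget]]
        else:
            chosen = [rest[i] for i in rng_.choice(len(rest), budget, replace=False)]
        labeled_idx.update(chosen)
        return _Batch(
            [_Entry(pool[i], 0.0, {"sampler": strategy, "pool_index": i}) for i in chosen]
        )

    init = [(pool[i], {"wb97x_dz.energy": float(energies[i])}) for i in sorted(labeled_idx)]
    state = ALState(dataset=groups_from_labeled(init, "boot"))
    trainer = EnsembleRegressorTrainer(
        k=k_members, featurizer=featurizer, lengthscale=0.5, seed=seed
    )
    for _ in range(n_iterations):
        state = al_iteration(state, trainer, [sampler], _PESLabeler(), rng)
    ensemble = trainer.fit(state.dataset)
    rest = [i for i in range(n_pool) if i not in labeled_idx]
    errors = [
        abs(ensemble.mean_energy(pool[i]) - float(energies[i])) for i in rest
    ]
    return float(max(errors))
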