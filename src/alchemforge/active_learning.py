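"""Active-learning outer loops.

Two orchestrations:

* :func:`al_iteration` — one cycle of dataset growth: train an ensemble on
  the current dataset, run the configured samplers, label the union of the
  selected high-disagreement structures, and append the new records.
  Iterated, this grows a successively more diverse dataset.
* :func:`ccx_subset_selection` — disagreement-driven subset selection for
  re-labeling at a higher level of theory: seed with a uniform random
  subset, then for a fixed number of cycles train on the labeled subset,
  score the remaining source points by rho, and label the ones above
  threshold.  Four cycles is the published protocol.

Trainers and labelers are duck-typed contracts: a trainer has
``fit(dataset) -> ensemble`` (the ensemble honoring the potential-ensemble
contract: ``member_energies(conf)`` and ``predict(conf)``), a labeler has
``label(conformations) -> list[dict | None]`` with ``None`` marking a
per-structure failure.  The shipped :class:`EnsembleRegressorTrainer` is a
bootstrap ensemble of RBF kernel-ridge regressors on a configurable
featurization — adequate for toy potential-surface recovery, not a
production interatomic potential.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .dataset_io import Conformation, ConformerGroup, TABLE_SCHEMA
from .diversity_analysis import DescriptorConfig, atomic_descriptor
from .uncertainty import EnsemblePrediction, SelectionBatch, rho

__all__ = [
    "EventLog",
    "ALState",
    "al_iteration",
    "ccx_subset_selection",
    "EnsembleRegressorTrainer",
    "RegressorEnsemble",
    "make_pool_sampler",
    "groups_from_labeled",
    "conformation_id",
]


class EventLog:
    """JSON-lines event log making every selection auditable/replayable."""

    def __init__(self, path=None):
        self.events: list[dict] = []
        self.path = path

    def record(self, **event: Any) -> None:
        self.events.append(event)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(event, default=str) + "\n")


def conformation_id(conf: Conformation, provenance: dict | None = None) -> str:
    """Stable identity for dedup: provenance plus a coordinate digest."""
    h = hashlib.sha1()
    h.update(np.round(conf.coordinates, 8).tobytes())
    h.update(bytes(conf.atomic_numbers.astype(np.uint8)))
    if provenance:
        h.update(json.dumps(provenance, sort_keys=True, default=str).encode())
    return h.hexdigest()


def groups_from_labeled(
    labeled: Sequence[tuple[Conformation, dict[str, Any]]],
    key_prefix: str = "batch",
) -> list[ConformerGroup]:
    """Pack labeled conformations into schema-conformant conformer groups.

    Conformations are grouped by their atomic-number sequence; property
    values missing for some conformers of a group are NaN-padded.
    """
    by_z: dict[tuple, list[tuple[Conformation, dict]]] = {}
    for conf, props in labeled:
        by_z.setdefault(tuple(conf.atomic_numbers), []).append((conf, props))
    groups = []
    for gi, (z, items) in enumerate(sorted(by_z.items())):
        confs = [c for c, _ in items]
        na = len(z)
        props_union = sorted({k for _, p in items for k in p})
        arrays: dict[str, np.ndarray] = {
            "coordinates": np.stack([c.coordinates for c in confs]).astype(np.float32)
        }
        for key in props_union:
            if key not in TABLE_SCHEMA:
                raise KeyError(f"labeler produced unknown property key {key!r}")
            dtype, trailing = TABLE_SCHEMA[key]
            tail = tuple(na if t == "Na" else t for t in trailing)
            arr = np.full((len(items),) + tail, np.nan, dtype=dtype)
            for r, (_, p) in enumerate(items):
                if key in p:
                    arr[r] = p[key]
            arrays[key] = arr
        formula = confs[0].formula()
        groups.append(ConformerGroup(f"{formula}_{key_prefix}_{gi:05d}", np.asarray(z), arrays))
    return groups


@dataclass
class ALState:
    """State threaded through active-learning iterations."""

    iteration: int = 0
    dataset: list[ConformerGroup] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    labeled_ids: set[str] = field(default_factory=set)

    @property
    def n_conformers(self) -> int:
        return sum(g.n_conformers for g in self.dataset)


def al_iteration(
    state: ALState,
    trainer,
    samplers: Sequence[Callable[[Any, np.random.Generator], SelectionBatch]],
    labeler,
    rng: np.random.Generator,
    log: EventLog | None = None,
) -> ALState:
    """One dataset-growth cycle: train, sample, label, append.

    Each sampler is a callable ``(ensemble, rng) -> SelectionBatch``.
    Structures already labeled in a previous iteration (by provenance
    identity) are skipped; labeler failures (``None`` records) are dropped
    and logged, and the loop continues.
    """
    ensemble = trainer.fit(state.dataset)
    new_entries = []
    batch_sizes = []
    for sampler in samplers:
        batch = sampler(ensemble, rng)
        batch_sizes.append(len(batch))
        for entry in batch:
            cid = conformation_id(entry.conformation, entry.provenance)
            if cid not in state.labeled_ids and cid not in {c for c, _ in new_entries}:
                new_entries.append((cid, entry))
    labels = labeler.label([e.conformation for _, e in new_entries]) if new_entries else []
    labeled, failed = [], 0
    for (cid, entry), props in zip(new_entries, labels):
        if props is None:
            failed += 1
            continue
        labeled.append(((cid, entry.conformation), props))
    new_groups = groups_from_labeled(
        [(conf, props) for (_, conf), props in labeled],
        key_prefix=f"it{state.iteration:03d}",
    )
    new_state = ALState(
        iteration=state.iteration + 1,
        dataset=state.dataset + new_groups,
        history=state.history
        + [
            {
                "iteration": state.iteration,
                "batch_sizes": batch_sizes,
                "n_labeled": len(labeled),
                "n_failed": failed,
            }
        ],
        labeled_ids=state.labeled_ids | {cid for (cid, _), _ in labeled},
    )
    if log:
        log.record(event="al_iteration", **new_state.history[-1])
    return new_state


def ccx_subset_selection(
    source: Sequence[tuple[str, Conformation]],
    trainer,
    labeler_hi,
    threshold: float,
    rng: np.random.Generator,
    init_fraction: float = 0.05,
    n_cycles: int = 4,
    cap: int | None = None,
    log: EventLog | None = None,
) -> list[ConformerGroup]:
    """Select and re-label a high-value subset of an existing dataset.

    ``source`` is a sequence of ``(record_id, Conformation)``.  Cycle 0
    labels a uniform random ``init_fraction`` of the source with
    ``labeler_hi``; each of the ``n_cycles`` subsequent cycles trains the
    ensemble on everything labeled so far, computes rho for every remaining
    record, and labels those with ``rho > threshold`` (optionally the top
    ``cap`` of them).  Returns the labeled subset as conformer groups.
    """
    if not source:
        raise ValueError("source dataset is empty")
    if not (0.0 < init_fraction < 1.0):
        raise ValueError("init_fraction must be in (0, 1)")
    ids = [rid for rid, _ in source]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in source")
    n_init = max(1, int(round(init_fraction * len(source))))
    order = rng.permutation(len(source))
    selected = set(order[:n_init].tolist())
    labeled: list[tuple[Conformation, dict]] = []

    def _label(indices: list[int]) -> None:
        confs = [source[i][1] for i in indices]
        for i, props in zip(indices, labeler_hi.label(confs)):
            if props is not None:
                labeled.append((source[i][1], props))

    _label(sorted(selected))
    if log:
        log.record(event="ccx_init", n_selected=n_init)
    for cycle in range(1, n_cycles + 1):
        dataset = groups_from_labeled(labeled, key_prefix=f"ccx{cycle:02d}")
        ensemble = trainer.fit(dataset)
        remaining = [i for i in range(len(source)) if i not in selected]
        scored = [
            (i, rho(ensemble.predict(source[i][1]))) for i in remaining
        ]
        picked = [(i, r) for i, r in scored if r > threshold]
        picked.sort(key=lambda t: -t[1])
        if cap is not None:
            picked = picked[:cap]
        if log:
            log.record(
                event="ccx_cycle",
                cycle=cycle,
                threshold=threshold,
                selected=[(ids[i], r) for i, r in picked],
            )
        selected.update(i for i, _ in picked)
        _label(sorted(i for i, _ in picked))
    return groups_from_labeled(labeled, key_prefix="ccx_final")


# ---------------------------------------------------------------------------
# Shipped trainer: random-feature ridge ensemble
# ---------------------------------------------------------------------------

def _mean_aev_featurizer(conf: Conformation) -> np.ndarray:
    cfg = DescriptorConfig()
    return np.mean(
        [atomic_descriptor(conf, a, cfg) for a in range(conf.n_atoms)], axis=0
    )


class _RandomFeatureRidge:
    """Ridge regression on a member-specific random Fourier feature map.

    ``phi(x) = sqrt(2/D) cos(W x + b)`` with ``W ~ N(0, 1/ls^2)``
    approximates an RBF kernel machine; because each ensemble member draws
    its own ``(W, b)``, members agree where data pins them down and diverge
    where it does not — the same behavior that makes neural-network
    ensembles useful committees.
    """

    def __init__(self, dim: int, n_features: int, lengthscale: float, alpha: float, seed: int):
        r = np.random.default_rng(seed)
        self.W = r.normal(size=(dim, n_features)) / lengthscale
        self.b = r.uniform(0.0, 2.0 * np.pi, n_features)
        self.alpha = alpha
        self.w: np.ndarray | None = None

    def _phi(self, x: np.ndarray) -> np.ndarray:
        return np.sqrt(2.0 / self.W.shape[1]) * np.cos(x @ self.W + self.b)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_RandomFeatureRidge":
        p = self._phi(x)
        a = p.T @ p + self.alpha * np.eye(p.shape[1])
        self.w = np.linalg.solve(a, p.T @ y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._phi(x) @ self.w


class RegressorEnsemble:
    """Potential-ensemble contract over fitted per-member regressors."""

    def __init__(self, models, featurizer, mean: np.ndarray, scale: np.ndarray,
                 y_shift: float):
        self._models = models
        self._featurizer = featurizer
        self._mean = mean
        self._scale = scale
        self._y_shift = y_shift

    @property
    def n_members(self) -> int:
        return len(self._models)

    def _features(self, conf: Conformation) -> np.ndarray:
        x = np.asarray(self._featurizer(conf), dtype=np.float64).reshape(1, -1)
        return (x - self._mean) / self._scale

    def member_energies(self, conf: Conformation) -> np.ndarray:
        x = self._features(conf)
        return np.array([float(m.predict(x)[0]) for m in self._models]) + self._y_shift

    def predict(self, conf: Conformation) -> EnsemblePrediction:
        return EnsemblePrediction(self.member_energies(conf), conf.n_atoms)

    def mean_energy(self, conf: Conformation) -> float:
        return float(self.member_energies(conf).mean())


class EnsembleRegressorTrainer:
    """Ensemble of random-feature ridge regressors on conformer features.

    Each of the ``k`` members draws an independent random feature map (and
    optionally an independent subsample of the data), so member
    disagreement grows away from the training data — the query-by-committee
    acquisition signal.  Features are standardized and the target mean is
    removed before fitting.
    """

    def __init__(
        self,
        k: int = 8,
        energy_key: str = "wb97x_dz.energy",
        featurizer: Callable[[Conformation], np.ndarray] | None = None,
        n_features: int = 200,
        lengthscale: float = 0.5,
        ridge_alpha: float = 1e-6,
        subsample: float = 1.0,
        seed: int = 0,
    ):
        if k < 2:
            raise ValueError("ensemble needs k >= 2")
        self.k = k
        self.energy_key = energy_key
        self.featurizer = featurizer or _mean_aev_featurizer
        self.n_features = n_features
        self.lengthscale = lengthscale
        self.ridge_alpha = ridge_alpha
        self.subsample = subsample
        self.seed = seed

    def fit(self, dataset: Sequence[ConformerGroup]) -> RegressorEnsemble:
        feats, targets = [], []
        for g in dataset:
            energies = g.properties.get(self.energy_key)
            if energies is None:
                continue
            for c in range(g.n_conformers):
                if np.isnan(energies[c]):
                    continue
                feats.append(self.featurizer(g.conformation(c)))
                targets.append(float(energies[c]))
        if len(feats) < 2:
            raise ValueError("need at least 2 labeled conformers to train")
        x = np.asarray(feats, dtype=np.float64)
        y = np.asarray(targets, dtype=np.float64)
        mean = x.mean(axis=0, keepdims=True)
        scale = x.std(axis=0, keepdims=True)
        scale[scale < 1e-12] = 1.0
        xs = (x - mean) / scale
        y_shift = float(y.mean())
        n = len(y)
        models = []
        for member in range(self.k):
            mseed = self.seed + 7919 * member
            take = np.arange(n)
            if self.subsample < 1.0:
                mrng = np.random.default_rng(mseed)
                take = mrng.choice(n, size=max(2, int(round(self.subsample * n))), replace=False)
            model = _RandomFeatureRidge(
                xs.shape[1], self.n_features, self.lengthscale, self.ridge_alpha, mseed
            )
            model.fit(xs[take], y[take] - y_shift)
            models.append(model)
        return RegressorEnsemble(models, self.featurizer, mean, scale, y_shift)


def make_pool_sampler(
    candidate_provider: Callable[[np.random.Generator, int], list[Conformation]],
    budget: int,
    n_candidates: int = 200,
    name: str = "pool",
) -> Callable:
    """Pool-based acquisition: top-``budget`` candidates by disagreement.

    ``candidate_provider(rng, n)`` supplies candidate conformations; the
    sampler scores them all with the current ensemble and returns the
    ``budget`` highest-rho ones.
    """

    def sampler(ensemble, rng: np.random.Generator) -> SelectionBatch:
        from .uncertainty import SelectionEntry

        cands = candidate_provider(rng, n_candidates)
        scored = [(c, rho(ensemble.predict(c))) for c in cands]
        scored.sort(key=lambda t: -t[1])
        entries = [
            SelectionEntry(c, r, {"sampler": name, "rank": i})
            for i, (c, r) in enumerate(scored[:budget])
        ]
        return SelectionBatch(entries)

    return sampler
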