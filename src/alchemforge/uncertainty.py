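"""Ensemble-disagreement acquisition metric.

The active-learning signal is the query-by-committee disagreement rho: the
population standard deviation of the per-member energy predictions for one
structure, converted to kcal/mol and normalized by the square root of the
number of atoms.  Structures whose rho exceeds a configured threshold are
collected into selection batches for reference labeling.

The proportionality constant of rho is fixed at 1, so its units are
kcal/mol/sqrt(atom); thresholds are configuration values, not constants of
the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .dataset_io import Conformation

__all__ = [
    "HARTREE_TO_KCAL_PER_MOL",
    "EnsemblePrediction",
    "SelectionEntry",
    "SelectionBatch",
    "rho",
    "select_high_rho",
]

#: 1 Hartree in kcal/mol (CODATA).
HARTREE_TO_KCAL_PER_MOL = 627.5094740631


@dataclass
class EnsemblePrediction:
    """Per-member total energies (Hartree) of one structure."""

    member_energies: np.ndarray
    n_atoms: int

    def __post_init__(self) -> None:
        self.member_energies = np.asarray(self.member_energies, dtype=np.float64).ravel()
        if len(self.member_energies) < 2:
            raise ValueError("an ensemble prediction needs at least 2 members")
        if not np.all(np.isfinite(self.member_energies)):
            raise ValueError("non-finite member energy")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be positive")


@dataclass
class SelectionEntry:
    conformation: Conformation
    rho: float
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class SelectionBatch:
    """A set of high-disagreement structures with provenance."""

    entries: list[SelectionEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def conformations(self) -> list[Conformation]:
        return [e.conformation for e in self.entries]

    def extend(self, other: "SelectionBatch") -> None:
        self.entries.extend(other.entries)


def rho(pred: EnsemblePrediction) -> float:
    """Disagreement metric in kcal/mol/sqrt(atom).

    Population (ddof=0) standard deviation of the member energies, converted
    from Hartree to kcal/mol and divided by sqrt(n_atoms).  Zero iff all
    members agree exactly.
    """
    sigma = float(np.std(pred.member_energies, ddof=0))
    return sigma * HARTREE_TO_KCAL_PER_MOL / np.sqrt(pred.n_atoms)


def select_high_rho(
    candidates: Sequence[tuple[Conformation, EnsemblePrediction]],
    threshold: float,
    provenance: dict[str, Any] | None = None,
) -> SelectionBatch:
    """Keep exactly the candidates with ``rho > threshold`` (order preserved)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    batch = SelectionBatch()
    for idx, (conf, pred) in enumerate(candidates):
        r = rho(pred)
        if r > threshold:
            prov = dict(provenance or {})
            prov.setdefault("candidate_index", idx)
            batch.entries.append(SelectionEntry(conf, r, prov))
    return batch
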