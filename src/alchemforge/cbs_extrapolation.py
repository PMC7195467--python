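"""CCSD(T)*/CBS composite extrapolation.

Reconstructs an approximate CCSD(T) complete-basis-set total energy from
cheap components:

* a two-point exponential extrapolation of the Hartree-Fock energy from the
  cc-pVTZ/cc-pVQZ pair (cardinal numbers 3/4),
* a two-point power-law extrapolation of the MP2 correlation energy from the
  same pair,
* a DLPNO-CCSD(T) correlation correction at cc-pVTZ (NormalPNO), and
* a PNO-accuracy correction, the TightPNO minus NormalPNO difference at
  cc-pVDZ.

The composite is

    E = Extrap(3/4, HF) + Extrap(3/4, MP2) - E(3, MP2)
        + E(3, NPNO-CCSD(T)) + E(2, TPNO-CCSD(T)) - E(2, NPNO-CCSD(T))

where all MP2/CCSD(T) terms are *correlation* energies (the HF part is
carried entirely by its own extrapolation).  Cardinal numbers map
2 -> cc-pVDZ, 3 -> cc-pVTZ, 4 -> cc-pVQZ.  The default exponents
alpha = 5.46 (HF) and beta = 3.05 (correlation) are the values optimized for
cc-pV[TQ]Z extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .dataset_io import ParseError

__all__ = [
    "EnergyComponents",
    "CBSParams",
    "extrap_hf",
    "extrap_corr",
    "ccsdt_star_cbs",
    "read_components",
    "METHOD_TAGS",
]

#: method tags accepted in component tables -> EnergyComponents field.
METHOD_TAGS = {
    "hf": "hf",
    "mp2_corr": "mp2_corr",
    "npno_ccsdt_corr": "ccsdt_corr_npno",
    "tpno_ccsdt_corr": "ccsdt_corr_tpno",
}

_CARDINALS = (2, 3, 4)


@dataclass
class EnergyComponents:
    """Component energies keyed by basis-set cardinal number (Hartree).

    ``hf`` holds HF total energies; the other maps hold correlation
    energies.  Cardinals: 2 = cc-pVDZ, 3 = cc-pVTZ, 4 = cc-pVQZ.
    """

    hf: dict[int, float] = field(default_factory=dict)
    mp2_corr: dict[int, float] = field(default_factory=dict)
    ccsdt_corr_npno: dict[int, float] = field(default_factory=dict)
    ccsdt_corr_tpno: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hf", "mp2_corr", "ccsdt_corr_npno", "ccsdt_corr_tpno"):
            m = getattr(self, name)
            for card, e in m.items():
                if card not in _CARDINALS:
                    raise ValueError(f"{name}: cardinal {card} not in {_CARDINALS}")
                if not math.isfinite(e):
                    raise ValueError(f"{name}[{card}]: non-finite energy")

    def _require(self, name: str, card: int) -> float:
        m = getattr(self, name)
        if card not in m:
            raise ValueError(f"missing component {name} at cardinal {card}")
        return m[card]


@dataclass
class CBSParams:
    """Extrapolation exponents; defaults optimized for cc-pV[TQ]Z."""

    alpha: float = 5.46
    beta: float = 3.05

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def extrap_hf(e3: float, e4: float, alpha: float = 5.46) -> float:
    """Two-point exponential CBS extrapolation of the HF energy.

    ``(exp(-a*sqrt(4))*e3 - exp(-a*sqrt(3))*e4) / (exp(-a*sqrt(4)) - exp(-a*sqrt(3)))``
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    w4 = math.exp(-alpha * math.sqrt(4.0))
    w3 = math.exp(-alpha * math.sqrt(3.0))
    return (w4 * e3 - w3 * e4) / (w4 - w3)


def extrap_corr(e3: float, e4: float, beta: float = 3.05) -> float:
    """Two-point power-law CBS extrapolation of a correlation energy.

    ``(4**b*e4 - 3**b*e3) / (4**b - 3**b)``
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    p4 = 4.0 ** beta
    p3 = 3.0 ** beta
    return (p4 * e4 - p3 * e3) / (p4 - p3)


def ccsdt_star_cbs(c: EnergyComponents, p: CBSParams | None = None) -> float:
    """Assemble the six-term CCSD(T)*/CBS composite energy (Hartree)."""
    p = p or CBSParams()
    hf3 = c._require("hf", 3)
    hf4 = c._require("hf", 4)
    mp2_3 = c._require("mp2_corr", 3)
    mp2_4 = c._require("mp2_corr", 4)
    npno3 = c._require("ccsdt_corr_npno", 3)
    npno2 = c._require("ccsdt_corr_npno", 2)
    tpno2 = c._require("ccsdt_corr_tpno", 2)
    return (
        extrap_hf(hf3, hf4, p.alpha)
        + extrap_corr(mp2_3, mp2_4, p.beta)
        - mp2_3
        + npno3
        + tpno2
        - npno2
    )


def read_components(path) -> list[tuple[str, EnergyComponents]]:
    """Read a delimited component-energy table.

    Expected columns: ``id``, ``method`` (one of ``hf``, ``mp2_corr``,
    ``npno_ccsdt_corr``, ``tpno_ccsdt_corr``), ``cardinal`` (2/3/4) and
    ``energy_Ha``.  Rows are grouped per id, preserving first-appearance
    order.  Duplicate (id, method, cardinal) rows and malformed values raise
    :class:`~alchemforge.dataset_io.ParseError` with the offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"id", "method", "cardinal", "energy_Ha"}
    if not required.issubset(df.columns):
        raise ParseError(f"missing columns {sorted(required - set(df.columns))}")
    records: dict[str, EnergyComponents] = {}
    seen: set[tuple[str, str, int]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        method = str(row.method).strip()
        if method not in METHOD_TAGS:
            raise ParseError(
                f"row {row_no}: unknown method tag {method!r}; "
                f"valid: {sorted(METHOD_TAGS)}"
            )
        try:
            card = int(str(row.cardinal).strip())
            energy = float(str(row.energy_Ha).strip())
        except ValueError:
            raise ParseError(f"row {row_no}: non-numeric cardinal or energy") from None
        if card not in _CARDINALS:
            raise ParseError(f"row {row_no}: cardinal {card} not in {_CARDINALS}")
        if not math.isfinite(energy):
            raise ParseError(f"row {row_no}: non-finite energy")
        rid = str(row.id).strip()
        sig = (rid, method, card)
        if sig in seen:
            raise ParseError(f"row {row_no}: duplicate entry {sig}")
        seen.add(sig)
        comp = records.setdefault(rid, EnergyComponents())
        getattr(comp, METHOD_TAGS[method])[card] = energy
    return list(records.items())
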