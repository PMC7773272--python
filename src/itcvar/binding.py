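"""Noise-free forward model of an incremental ITC titration.

An isothermal titration calorimetry (ITC) experiment injects a titrant
solution (ligand L, syringe concentration ``C_syr``) in small increments into
a fixed-volume perfusion cell containing the titrand (macromolecule M,
concentration ``C_cell``).  After each injection the 1:1 independent-binding
equilibrium

    M + L  <=>  ML,      Ka = [ML] / ([M]_free [L]_free)

re-establishes and the heat released is proportional to the moles of complex
formed.  The cell overflows: each injection of volume ``v`` instantaneously
mixes into the cell and an equal volume of the *mixed* contents is expelled,
so total concentrations are diluted by ``V_cell / (V_cell + v)`` per
injection ("instantaneous injection" overflow model).

Unit conventions (fixed throughout the package):

=============  ======  =====================================================
quantity       unit    note
=============  ======  =====================================================
volumes        uL
concentrations mM      mM * uL = nmol
Ka             1/M     converted internally to 1/mM
enthalpy dH    kJ/mol  kJ/mol * nmol = uJ, so heats need no extra factor
heats Q        uJ
=============  ======  =====================================================

The shape of the isotherm is governed by the Wiseman c-value
``c = Ka * C_cell`` (dimensionless): high c gives a sharp sigmoidal
transition at mole ratio ~ n, low c a shallow curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "TitrationConfig",
    "ReactionParams",
    "CellState",
    "equilibrium_complex",
    "apply_injection",
    "injection_heat",
    "reaction_heats",
    "Isotherm",
    "simulate_isotherm",
    "titration_states",
]

#: conversion factor 1/M -> 1/mM
_PER_M_TO_PER_MM = 1e-3


@dataclass(frozen=True)
class TitrationConfig:
    """Geometry and injection schedule of one titration.

    Parameters
    ----------
    V_cell : float
        Effective sample-cell volume, uL.  Default 943 uL (NanoITC Standard
        Volume cell).
    C_syr : float
        Titrant (syringe) concentration, mM.
    C_cell : float
        Titrand (cell) concentration, mM.  The default 6:1 syringe:cell
        ratio gives a full isotherm within one syringe fill.
    injection_volumes : sequence of float
        Preset injection volumes ``V_0``, uL, in injection order.
    syringe_volume : float
        Total deliverable syringe volume, uL; the schedule must fit in one
        fill.
    drop_first : bool
        Exclude injection 1 from downstream analysis.  The first injection
        of a real experiment is systematically low (stepper-motor backlash,
        syringe-tip diffusion during equilibration) and is conventionally
        discarded.
    """

    V_cell: float = 943.0
    C_syr: float = 6.0
    C_cell: float = 1.0
    injection_volumes: tuple[float, ...] = (10.0,) * 25
    syringe_volume: float = 250.0
    drop_first: bool = True

    def __post_init__(self) -> None:
        vols = tuple(float(v) for v in self.injection_volumes)
        object.__setattr__(self, "injection_volumes", vols)
        if not self.V_cell > 0:
            raise ValueError(f"V_cell must be > 0, got {self.V_cell}")
        if len(vols) == 0:
            raise ValueError("injection schedule is empty")
        if any(v <= 0 for v in vols):
            raise ValueError("all injection volumes must be > 0")
        if self.C_syr < 0 or self.C_cell < 0:
            raise ValueError("concentrations must be >= 0")
        if sum(vols) > self.syringe_volume * (1 + 1e-12):
            raise ValueError(
                f"schedule needs {sum(vols):g} uL but the syringe holds "
                f"{self.syringe_volume:g} uL"
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @property
    def effective_slice(self) -> slice:
        """Index slice of the injections retained for analysis."""
        return slice(1, None) if self.drop_first else slice(0, None)



@dataclass(frozen=True)
class ReactionParams:
    """Thermodynamic parameters of the 1:1 binding reaction.

    Ka : association constant, 1/M; dH : molar enthalpy, kJ/mol (negative =
    exothermic); n : binding stoichiometry (sites per titrand molecule).
    """

    Ka: float = 1e5
    dH: float = -40.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.Ka > 0:
            raise ValueError(f"Ka must be > 0, got {self.Ka}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")

    def c_value(self, C_cell_mM: float) -> float:
        """Wiseman c-value ``Ka * C_cell`` (dimensionless)."""
        return self.Ka * C_cell_mM * 1e-3


@dataclass(frozen=True)
class CellState:
    """Total and complexed concentrations in the cell (mM), post-overflow."""

    M_tot: float
    L_tot: float
    ML: float

    def __post_init__(self) -> None:
        if self.M_tot < 0 or self.L_tot < 0 or self.ML < -1e-12:
            raise ValueError("concentrations must be >= 0")

    def bound_fraction(self, n: float = 1.0) -> float:
        """Fraction of titrand sites occupied, ML / (n * M_tot)."""
        cap = n * self.M_tot
        return self.ML / cap if cap > 0 else 0.0


def equilibrium_complex(
    M_tot: ArrayLike,
    L_tot: ArrayLike,
    Ka: ArrayLike,
    n: float = 1.0,
) -> NDArray[np.float64] | float:
    """Equilibrium complex concentration [ML] in mM.

    Solves the mass-action condition ``Ka' * (n*M_tot - x)(L_tot - x) = x``
    (``Ka'`` in 1/mM) for the physical (smaller) root of the quadratic,
    using the numerically stable form ``x = 2C / (B + sqrt(B^2 - 4AC))``.

    All arguments broadcast; returns a scalar for scalar input.
    """
    M = np.asarray(M_tot, dtype=float)
    L = np.asarray(L_tot, dtype=float)
    k = np.asarray(Ka, dtype=float)
    if np.any(M < 0) or np.any(L < 0):
        raise ValueError("total concentrations must be >= 0")
    if np.any(k <= 0):
        raise ValueError("Ka must be > 0")
    k = k * _PER_M_TO_PER_MM
    a = n * M  # site concentration, mM
    B = k * (a + L) + 1.0
    C = k * a * L
    disc = B * B - 4.0 * k * C
    # disc = (k(a-L))^2 + 2k(a+L) + 1 > 0 for all valid inputs
    assert np.all(disc >= 0.0)
    x = 2.0 * C / (B + np.sqrt(disc))
    x = np.clip(x, 0.0, np.minimum(a, L))
    return float(x) if x.ndim == 0 else x


def apply_injection(
    state: CellState,
    v: float,
    C_syr: float,
    V_cell: float,
    Ka: float,
    n: float = 1.0,
) -> CellState:
    """Advance the cell by one injection (mix-then-overflow, re-equilibrate).

    The injected plug of volume ``v`` mixes instantaneously into the cell;
    totals dilute by ``V_cell / (V_cell + v)`` while the injected titrant
    adds ``C_syr * v / (V_cell + v)``; the overflow plug then leaves with
    the mixed composition, returning the cell to ``V_cell``.
    """
    if not v > 0:
        raise ValueError(f"injection volume must be > 0, got {v}")
    Vtot = V_cell + v
    M_new = state.M_tot * V_cell / Vtot
    L_new = (state.L_tot * V_cell + C_syr * v) / Vtot
    ML_new = equilibrium_complex(M_new, L_new, Ka, n)
    return CellState(M_tot=M_new, L_tot=L_new, ML=float(ML_new))


def injection_heat(
    state_before: CellState,
    state_after: CellState,
    dH: float,
    V_cell: float,
    v: float,
) -> float:
    """Reaction heat of one injection, uJ (sign follows dH).

    ``Q = dH * dn_complex`` with the moles of complex formed counted in the
    momentarily enlarged cell before the overflow plug is expelled:
    ``dn = ML_after*(V_cell+v) - ML_before*V_cell``  (mM * uL = nmol, and
    kJ/mol * nmol = uJ).
    """
    dn = state_after.ML * (V_cell + v) - state_before.ML * V_cell
    return dH * dn


def reaction_heats(
    volumes: ArrayLike,
    C_syr: ArrayLike,
    C_cell: ArrayLike,
    V_cell: float,
    Ka: ArrayLike,
    dH: ArrayLike,
    n: float = 1.0,
) -> NDArray[np.float64]:
    """Per-injection reaction heats for one or many titrations, uJ.

    Vectorized core shared by the noise-free simulator and the Monte-Carlo
    sampler: ``volumes`` has shape ``(n_inj,)`` or ``(n_rep, n_inj)``;
    ``C_syr``, ``Ka``, ``dH`` may be scalars or per-replicate arrays of
    shape ``(n_rep,)``.  Returns heats of shape ``(n_rep, n_inj)``.
    """
    V = np.atleast_2d(np.asarray(volumes, dtype=float))
    n_rep, n_inj = V.shape
    C_syr = np.broadcast_to(np.asarray(C_syr, dtype=float), (n_rep,))
    Ka = np.broadcast_to(np.asarray(Ka, dtype=float), (n_rep,))
    dH = np.broadcast_to(np.asarray(dH, dtype=float), (n_rep,))
    M = np.full(n_rep, float(C_cell))
    L = np.zeros(n_rep)
    ML = np.zeros(n_rep)
    Q = np.empty((n_rep, n_inj))
    for i in range(n_inj):
        v = V[:, i]
        Vtot = V_cell + v
        M = M * V_cell / Vtot
        L = (L * V_cell + C_syr * v) / Vtot
        ML_new = equilibrium_complex(M, L, Ka, n)
        Q[:, i] = dH * (ML_new * Vtot - ML * V_cell)
        ML = ML_new
    return Q


@dataclass(frozen=True)
class Isotherm:
    """Noise-free binding isotherm: per-injection heats vs mole ratio."""

    injection_index: NDArray[np.int_]  # 1-based
    V0: NDArray[np.float64]  # preset volumes, uL
    mole_ratio: NDArray[np.float64]
    Q: NDArray[np.float64]  # uJ, signed
    config: TitrationConfig
    rxn: ReactionParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "injection_index": self.injection_index,
                "V_uL": self.V0,
                "mole_ratio": self.mole_ratio,
                "Q_uJ": self.Q,
            }
        )


def mole_ratios(config: TitrationConfig) -> NDArray[np.float64]:
    """Cumulative injected titrant moles over initial titrand moles.

    The conventional ITC abscissa; uncorrected for overflow losses.  NaN for
    a blank titration (no titrand in the cell).
    """
    V0 = np.asarray(config.injection_volumes)
    injected = np.cumsum(config.C_syr * V0)  # nmol
    initial = config.C_cell * config.V_cell
    if initial == 0:
        return np.full(V0.shape, np.nan)
    return injected / initial


def simulate_isotherm(config: TitrationConfig, rxn: ReactionParams) -> Isotherm:
    """Deterministic noise-free isotherm at the preset injection volumes."""
    V0 = np.asarray(config.injection_volumes)
    Q = reaction_heats(
        V0, config.C_syr, config.C_cell, config.V_cell, rxn.Ka, rxn.dH, rxn.n
    )[0]
    return Isotherm(
        injection_index=np.arange(1, config.n_injections + 1),
        V0=V0,
        mole_ratio=mole_ratios(config),
        Q=Q,
        config=config,
        rxn=rxn,
    )


def titration_states(
    config: TitrationConfig, rxn: ReactionParams
) -> list[CellState]:
    """Cell states after each injection (scalar path; initial state first)."""
    state = CellState(M_tot=config.C_cell, L_tot=0.0, ML=0.0)
    out = [state]
    for v in config.injection_volumes:
        state = apply_injection(state, v, config.C_syr, config.V_cell, rxn.Ka, rxn.n)
        out.append(state)
    return out
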