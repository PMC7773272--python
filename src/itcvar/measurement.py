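"""Stochastic measurement model: noisy realizations of a titration.

The measured (blank-subtracted) heat of injection ``i`` is modelled as

    Q_i = r(V_inj,i) * (1 + P_i) + Q_b,i

with three basic instrument error components, all Gaussian:

* injection-volume error  ``V_inj = V_0 + V_eps``, ``V_eps ~ N(0, sigma_v^2)``
  (independent of the preset volume ``V_0``);
* proportional error      ``P ~ N(0, sigma_p^2)``, applied to the realized
  reaction heat;
* background noise        ``Q_b ~ N(0, V_0 * sigma_b^2)`` — its variance
  scales with the *preset* volume, so ``sigma_b`` carries units
  uJ * uL^-0.5.

Dilution and friction heats are treated as blank-subtracted (identically
zero here); their residual randomness is absorbed into sigma_b / sigma_p by
construction.

Optional *additional* error components model solution-preparation and batch
effects: relative Gaussian perturbations of the titrant concentration and of
the reaction parameters (Ka, dH), drawn once per titration and held fixed
across its injections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .binding import ReactionParams, TitrationConfig, mole_ratios, reaction_heats

__all__ = [
    "ErrorParams",
    "AdditionalErrors",
    "IsothermRealization",
    "sample_injection_volume",
    "sample_background",
    "sample_heats",
    "realize_titration",
]


@dataclass(frozen=True)
class ErrorParams:
    """Basic instrument error parameters.

    Defaults are the NanoITC Standard Volume values estimated from saturated
    CaCl2/EDTA and water-blank titrations: sigma_b = 0.1771 uJ*uL^-0.5,
    sigma_p = 0.00309, sigma_v = 0.0214 uL.
    """

    sigma_b: float = 0.1771  # uJ * uL^-0.5
    sigma_p: float = 0.00309  # dimensionless
    sigma_v: float = 0.0214  # uL

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_p < 0 or self.sigma_v < 0:
            raise ValueError("error parameters must be >= 0")

    def as_array(self) -> NDArray[np.float64]:
        return np.array([self.sigma_b, self.sigma_p, self.sigma_v])


@dataclass(frozen=True)
class AdditionalErrors:
    """Relative SDs of per-titration fluctuations (all default 0)."""

    rel_sd_Csyr: float = 0.0
    rel_sd_Ka: float = 0.0
    rel_sd_dH: float = 0.0

    def __post_init__(self) -> None:
        if min(self.rel_sd_Csyr, self.rel_sd_Ka, self.rel_sd_dH) < 0:
            raise ValueError("relative SDs must be >= 0")

    @property
    def any_active(self) -> bool:
        return (self.rel_sd_Csyr or self.rel_sd_Ka or self.rel_sd_dH) != 0


#: convenience instance: basic errors only
NO_ADDITIONAL = AdditionalErrors()


def sample_injection_volume(V0, sigma_v, rng, size=None):
    """Realized injection volume(s) ``V0 + V_eps``, uL.

    Non-positive draws (probability ~0 at instrument scales) are rejected
    and resampled so volumes stay physical.
    """
    if sigma_v < 0:
        raise ValueError("sigma_v must be >= 0")
    if np.any(np.asarray(V0) <= 0):
        raise ValueError("V0 must be > 0")
    v = V0 + rng.normal(0.0, sigma_v, size=size)
    v = np.asarray(v, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    bad = v <= 0
    while np.any(bad):
        v[bad] = np.broadcast_to(V0, v.shape)[bad] + rng.normal(
            0.0, sigma_v, size=int(bad.sum())
        )
        bad = v <= 0
    return float(v[0]) if scalar and size is None else v.reshape(np.shape(V0) if size is None else size)


def sample_background(V0, sigma_b, rng, size=None):
    """Background-noise heat(s) drawn from N(0, V0 * sigma_b^2), uJ."""
    if sigma_b < 0:
        raise ValueError("sigma_b must be >= 0")
    if np.any(np.asarray(V0) <= 0):
        raise ValueError("V0 must be > 0")
    V0 = np.asarray(V0, dtype=float)
    sd = sigma_b * np.sqrt(V0)
    if size is None:
        size = V0.shape
    out = rng.normal(0.0, 1.0, size=size) * sd
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class IsothermRealization:
    """One noisy titration: preset/realized volumes and total heats."""

    injection_index: NDArray[np.int_]
    V0: NDArray[np.float64]
    V_inj: NDArray[np.float64]
    Q: NDArray[np.float64]  # uJ, signed
    mole_ratio: NDArray[np.float64]
    replicate_id: int = 0
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "injection_index": self.injection_index,
                "V_uL": self.V0,
                "V_inj_uL": self.V_inj,
                "mole_ratio": self.mole_ratio,
                "Q_uJ": self.Q,
                "replicate_id": self.replicate_id,
            }
        )


def sample_heats(
    config: TitrationConfig,
    rxn: ReactionParams,
    errs: ErrorParams,
    add: AdditionalErrors | None,
    n_rep: int,
    rng: np.random.Generator,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Vectorized sampler: ``n_rep`` independent noisy titrations.

    Returns ``(V_inj, Q)`` arrays of shape ``(n_rep, n_inj)``.  Draw order
    (fixed for reproducibility): per-titration deltas for C_syr, Ka, dH;
    the injection-volume matrix; the proportional-error matrix P; the
    background matrix Q_b.  The delta draws are consumed even when all
    additional SDs are zero, so the random stream does not depend on `add`.
    """
    if add is None:
        add = NO_ADDITIONAL
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    V0 = np.asarray(config.injection_volumes)
    n_inj = V0.size

    C_syr = config.C_syr * (1.0 + rng.normal(0.0, add.rel_sd_Csyr, n_rep))
    Ka = rxn.Ka * (1.0 + rng.normal(0.0, add.rel_sd_Ka, n_rep))
    dH = rxn.dH * (1.0 + rng.normal(0.0, add.rel_sd_dH, n_rep))
    if np.any(Ka <= 0) or np.any(C_syr < 0):
        raise ValueError("additional-error draw produced unphysical Ka/C_syr")

    V_inj = sample_injection_volume(
        np.broadcast_to(V0, (n_rep, n_inj)), errs.sigma_v, rng, size=(n_rep, n_inj)
    )
    r = reaction_heats(V_inj, C_syr, config.C_cell, config.V_cell, Ka, dH, rxn.n)
    P = rng.normal(0.0, errs.sigma_p, (n_rep, n_inj))
    Qb = rng.normal(0.0, 1.0, (n_rep, n_inj)) * (errs.sigma_b * np.sqrt(V0))
    Q = r * (1.0 + P) + Qb
    return V_inj, Q


def realize_titration(
    config: TitrationConfig,
    rxn: ReactionParams,
    errs: ErrorParams,
    add: AdditionalErrors | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    replicate_id: int = 0,
) -> IsothermRealization:
    """One noisy realization of the configured titration."""
    if rng is None:
        rng = np.random.default_rng(seed)
    V_inj, Q = sample_heats(config, rxn, errs, add, 1, rng)
    return IsothermRealization(
        injection_index=np.arange(1, config.n_injections + 1),
        V0=np.asarray(config.injection_volumes),
        V_inj=V_inj[0],
        Q=Q[0],
        mole_ratio=mole_ratios(config),
        replicate_id=replicate_id,
        seed=seed,
    )
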