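"""Closed-form heat variance functions and the Monte-Carlo comparison metric.

Three empirical variance-function forms from the ITC error-analysis
literature express the per-injection heat variance in terms of the heat
``Q_i`` and injection volume ``V_i``:

    form A:  sigma_i^2 = sigma_b^2 + sigma_p^2 Q_i^2 + (sigma_v/V_i)^2 Q_i^2
    form B:  sigma_i^2 = sigma_b^2 + (sigma_p Q_i)^2
    form C:  sigma_i^2 = sigma_b^2 V_i + sigma_p^2 Q_i^2 + sigma_v^2 (Q_i/V_i)^2

Form C (background variance proportional to the injection volume, volume
error acting through Q/V) is the baseline used throughout this package; it
is exact in the saturated constant-heat regime but, being monotone in |Q|,
cannot reproduce the SDR peak that the full measurement model produces in
the transition region of high-c isotherms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .binding import ReactionParams, TitrationConfig, simulate_isotherm
from .measurement import ErrorParams
from .montecarlo import DEFAULT_N_REP, PropagationResult, propagate

__all__ = [
    "VarianceFunctionSpec",
    "eval_variance",
    "vf_sd",
    "max_relative_deviation",
    "deviation_table",
    "compare_to_variance_function",
    "standard_comparison",
]


def standard_comparison(
    c_value: float,
    C_cell: float = 1.0,
    ratio: float = 6.0,
    injection_volume: float = 10.0,
    n_injections: int = 25,
    dH: float = -40.0,
) -> tuple[TitrationConfig, ReactionParams]:
    """Standard comparison conditions for a given Wiseman c-value.

    The cell concentration is held at 1 mM (6:1 syringe:cell ratio, so the
    heat scale is the same across the series) and the association constant
    is set to ``Ka = c / C_cell``; 25 x 10 uL injections into the 943 uL
    cell.  This is the configuration family used for the SDR-vs-variance-
    function comparisons across c-values.
    """
    Ka = c_value / (C_cell * 1e-3)  # 1/M
    config = TitrationConfig(
        C_cell=C_cell,
        C_syr=ratio * C_cell,
        injection_volumes=(injection_volume,) * n_injections,
    )
    return config, ReactionParams(Ka=Ka, dH=dH)


@dataclass(frozen=True)
class VarianceFunctionSpec:
    """A variance-function form with its parameters.

    Units are form-specific: form C takes sigma_b in uJ*uL^-0.5, forms A/B
    in uJ; sigma_v is in uL for forms A and C and is ignored by form B.
    """

    form: str = "C"
    sigma_b: float = 0.1771
    sigma_p: float = 0.00309
    sigma_v: float = 0.0214

    def __post_init__(self) -> None:
        if self.form not in ("A", "B", "C"):
            raise ValueError(f"unknown variance-function form {self.form!r}")
        if min(self.sigma_b, self.sigma_p, self.sigma_v) < 0:
            raise ValueError("variance-function parameters must be >= 0")

    @classmethod
    def from_error_params(cls, errs: ErrorParams, form: str = "C"):
        return cls(form, errs.sigma_b, errs.sigma_p, errs.sigma_v)


def eval_variance(spec: VarianceFunctionSpec, Q: ArrayLike, V: ArrayLike):
    """Variance sigma^2 (uJ^2) of the selected form at heat Q and volume V."""
    Q = np.asarray(Q, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("injection volume must be > 0")
    b, p, v = spec.sigma_b, spec.sigma_p, spec.sigma_v
    if spec.form == "A":
        out = b**2 + (p * Q) ** 2 + (v / V) ** 2 * Q**2
    elif spec.form == "B":
        out = b**2 + (p * Q) ** 2
    else:  # C
        out = b**2 * V + (p * Q) ** 2 + v**2 * (Q / V) ** 2
    return float(out) if out.ndim == 0 else out


def vf_sd(spec: VarianceFunctionSpec, Q: ArrayLike, V: ArrayLike):
    """Predicted SD (uJ) = sqrt(eval_variance)."""
    return np.sqrt(eval_variance(spec, Q, V))


def max_relative_deviation(
    sdr_mc: ArrayLike,
    spec: VarianceFunctionSpec,
    Q_theory: ArrayLike,
    V: ArrayLike,
) -> float:
    """Maximum relative deviation (percent) of MC SDR from the prediction.

    ``max_i |SDR_mc(i) - sigma_vf(i)| / sigma_vf(i) * 100`` with
    ``sigma_vf`` evaluated at the *noise-free* heats ``Q_theory``.  Series
    must be aligned and already restricted to the effective injections
    (first injection excluded upstream when dropped).
    """
    sdr_mc = np.asarray(sdr_mc, dtype=float)
    sigma_vf = vf_sd(spec, Q_theory, V)
    if sdr_mc.shape != sigma_vf.shape:
        raise ValueError("series are not aligned")
    if np.any(sigma_vf == 0):
        raise ValueError("variance function is zero (degenerate configuration)")
    return float(np.max(np.abs(sdr_mc - sigma_vf) / sigma_vf) * 100.0)


def deviation_table(
    result: PropagationResult,
    spec: VarianceFunctionSpec,
    Q_theory: NDArray[np.float64],
):
    """Per-injection comparison table over the effective injections.

    Columns: mole_ratio, SDR_mc (uJ), sigma_vf (uJ), rel_dev_percent
    (signed).  ``Q_theory`` is the full noise-free heat series aligned with
    ``result``.
    """
    import pandas as pd

    sl = slice(1, None) if result.drop_first else slice(0, None)
    sigma_vf = vf_sd(spec, Q_theory[sl], result.V0[sl])
    sdr = result.sdr[sl]
    return pd.DataFrame(
        {
            "injection_index": result.injection_index[sl],
            "mole_ratio": result.mole_ratio[sl],
            "SDR_mc_uJ": sdr,
            "sigma_vf_uJ": sigma_vf,
            "rel_dev_percent": (sdr - sigma_vf) / sigma_vf * 100.0,
        }
    )


def compare_to_variance_function(
    config: TitrationConfig,
    rxn: ReactionParams,
    errs: ErrorParams,
    n_rep: int = DEFAULT_N_REP,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    spec: VarianceFunctionSpec | None = None,
):
    """Run the full MC-vs-variance-function comparison for one isotherm.

    Returns ``(table, max_dev_percent)`` where the maximum is taken over
    the effective injections of the absolute relative deviation.
    """
    if spec is None:
        spec = VarianceFunctionSpec.from_error_params(errs, "C")
    result = propagate(
        config, rxn, errs, n_rep=n_rep, rng=rng, seed=seed, ci=False
    )
    Q_theory = simulate_isotherm(config, rxn).Q
    table = deviation_table(result, spec, Q_theory)
    max_dev = float(np.max(np.abs(table["rel_dev_percent"].to_numpy())))
    return table, max_dev
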