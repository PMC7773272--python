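"""Distribution propagation by Monte Carlo.

Repeats the stochastic titration many times and summarizes, per injection,
the mean heat, its variance, the SDR (standard deviation of the heat
residual) and an empirical 95% confidence interval.  Statistics are
accumulated chunk-wise (pairwise mean/M2 combination) so memory stays flat
at large replicate counts; the raw heat matrix is retained only when
percentile confidence intervals are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .binding import ReactionParams, TitrationConfig, mole_ratios
from .measurement import AdditionalErrors, ErrorParams, sample_heats

__all__ = ["PropagationResult", "propagate", "sdr_curve"]

DEFAULT_N_REP = 100_000


@dataclass(frozen=True)
class PropagationResult:
    """Per-injection summary statistics over ``n_rep`` noisy titrations."""

    injection_index: NDArray[np.int_]
    V0: NDArray[np.float64]
    mole_ratio: NDArray[np.float64]
    mean: NDArray[np.float64]  # uJ, signed
    variance: NDArray[np.float64]  # uJ^2
    sdr: NDArray[np.float64]  # uJ
    ci_low: NDArray[np.float64] | None
    ci_high: NDArray[np.float64] | None
    n_rep: int
    seed: int | None
    drop_first: bool

    def __post_init__(self) -> None:
        if np.any(self.variance < 0):
            raise ValueError("variance must be >= 0")
        if self.ci_low is not None and np.any(self.ci_low > self.ci_high):
            raise ValueError("CI bounds out of order")

    def to_frame(self):
        import pandas as pd

        d = {
            "injection_index": self.injection_index,
            "V_uL": self.V0,
            "mole_ratio": self.mole_ratio,
            "Q_mean_uJ": self.mean,
            "Q_var_uJ2": self.variance,
            "SDR_uJ": self.sdr,
        }
        if self.ci_low is not None:
            d["ci95_low_uJ"] = self.ci_low
            d["ci95_high_uJ"] = self.ci_high
        return pd.DataFrame(d)


def _combine(count, mean, M2, c_count, c_mean, c_M2):
    """Chan et al. pairwise combination of (count, mean, sum-of-squares)."""
    total = count + c_count
    delta = c_mean - mean
    mean = mean + delta * (c_count / total)
    M2 = M2 + c_M2 + delta * delta * (count * c_count / total)
    return total, mean, M2


def propagate(
    config: TitrationConfig,
    rxn: ReactionParams,
    errs: ErrorParams,
    add: AdditionalErrors | None = None,
    n_rep: int = DEFAULT_N_REP,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    ci: bool = True,
    ci_level: float = 0.95,
    chunk_size: int = 25_000,
) -> PropagationResult:
    """Monte-Carlo propagation of the error model through the isotherm.

    Parameters
    ----------
    n_rep : int
        Number of independent titration replicates (>= 2).
    ci : bool
        Also report the empirical ``ci_level`` interval (percentiles of the
        simulated heats, assumption-free); requires holding all replicates.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2 (variance undefined otherwise)")
    if rng is None:
        rng = np.random.default_rng(seed)

    n_inj = config.n_injections
    count = 0
    mean = np.zeros(n_inj)
    M2 = np.zeros(n_inj)
    kept: list[NDArray[np.float64]] = []
    remaining = n_rep
    while remaining > 0:
        m = min(chunk_size, remaining)
        _, Q = sample_heats(config, rxn, errs, add, m, rng)
        c_mean = Q.mean(axis=0)
        c_M2 = ((Q - c_mean) ** 2).sum(axis=0)
        count, mean, M2 = _combine(count, mean, M2, m, c_mean, c_M2)
        if ci:
            kept.append(Q)
        remaining -= m

    variance = M2 / (count - 1)
    if ci:
        allQ = np.vstack(kept)
        alpha = 100.0 * (1.0 - ci_level) / 2.0
        ci_low, ci_high = np.percentile(allQ, [alpha, 100.0 - alpha], axis=0)
    else:
        ci_low = ci_high = None

    return PropagationResult(
        injection_index=np.arange(1, n_inj + 1),
        V0=np.asarray(config.injection_volumes),
        mole_ratio=mole_ratios(config),
        mean=mean,
        variance=variance,
        sdr=np.sqrt(variance),
        ci_low=ci_low,
        ci_high=ci_high,
        n_rep=n_rep,
        seed=seed,
        drop_first=config.drop_first,
    )


def sdr_curve(result: PropagationResult):
    """Ordered (mole_ratio, SDR) series for plotting/CSV export.

    The first injection is excluded when the underlying configuration
    dropped it from analysis.
    """
    import pandas as pd

    sl = slice(1, None) if result.drop_first else slice(0, None)
    return pd.DataFrame(
        {
            "mole_ratio": result.mole_ratio[sl],
            "SDR_uJ": result.sdr[sl],
        }
    )
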