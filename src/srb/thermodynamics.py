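"""Finite-temperature behavior of SRB realizations.

The participation ratio

    Y(T) = sum_s exp(-2 u_s / T) / (sum_s exp(-u_s / T))**2

is the probability that two independent draws from the Boltzmann measure of a
complex occupy the same configuration; 1/Y counts the states that dominate
the measure.  All Boltzmann sums are evaluated in the log domain (energies
shifted by the spectrum minimum) because u/T reaches ~ -40 at low T.

Individual realizations founded on the same coupling statistics can have
drastically different Y(T) curves and apparent melting temperatures (the peak
of -dY/dT); only the disorder average recovers the smooth REM-like
condensation law 1 - T/Tc.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .analytics import critical_temperature, rem_participation_limit
from .energetics import Spectrum, heterodimer_level_samples
from .model_core import ModelParams

__all__ = [
    "participation_ratio",
    "ground_state_participation",
    "MeltingCurve",
    "melting_curve",
    "EnsembleParticipation",
    "ensemble_mean_participation",
]


def _energies(spectrum) -> np.ndarray:
    e = spectrum.energies if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if e.size == 0:
        raise ValueError("empty spectrum")
    return e


def participation_ratio(spectrum, T) -> float | np.ndarray:
    """Y(T) of a spectrum (Spectrum or plain energy array); T > 0, scalar or grid."""
    e = _energies(spectrum)
    T = np.asarray(T, dtype=float)
    if (T <= 0).any():
        raise ValueError("temperature must be positive (T=0 is the degeneracy limit)")
    x = -e[..., None] / T.reshape(-1)  # (n, nT)
    out = np.exp(logsumexp(2.0 * x, axis=0) - 2.0 * logsumexp(x, axis=0))
    return float(out[0]) if T.ndim == 0 else out.reshape(T.shape)


def ground_state_participation(spectrum, rel_tol: float = 1e-12) -> float:
    """The T -> 0 limit of Y: 1/k for a k-fold degenerate ground state."""
    e = _energies(spectrum)
    k = int(np.sum(e <= e.min() + rel_tol * max(1.0, abs(e.min()))))
    return 1.0 / k


@dataclasses.dataclass(frozen=True)
class MeltingCurve:
    """Y(T) on a temperature grid with its numerical derivative.

    ``melting_temperature`` is the grid point maximizing -dY/dT, or None for
    a flat curve (e.g. a single-level spectrum), where no peak is defined.
    """

    temperatures: np.ndarray
    Y: np.ndarray
    dY_dT: np.ndarray
    melting_temperature: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"T": self.temperatures, "Y": self.Y, "dY_dT": self.dY_dT})


def melting_curve(spectrum, temperatures) -> MeltingCurve:
    """Participation ratio and melting point of one realization on a T grid."""
    T = np.asarray(temperatures, dtype=float)
    if T.ndim != 1 or T.size < 3 or (np.diff(T) <= 0).any() or (T <= 0).any():
        raise ValueError("need >= 3 strictly increasing positive temperatures")
    Y = participation_ratio(spectrum, T)
    dY = np.gradient(Y, T)  # central differences, one-sided at the ends
    if np.max(np.abs(dY)) < 1e-12:
        Tm = None
    else:
        Tm = float(T[np.argmax(-dY)])
    return MeltingCurve(T, Y, dY, Tm)


@dataclasses.dataclass(frozen=True)
class EnsembleParticipation:
    """Disorder-averaged participation ratio on a T/Tc grid."""

    t_over_tc: np.ndarray
    mean_Y: np.ndarray
    se_Y: np.ndarray
    Tc: float
    n_levels: int
    n_realizations: int

    @property
    def rem_limit(self) -> np.ndarray:
        return rem_participation_limit(self.t_over_tc, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_over_Tc": self.t_over_tc,
                "T": self.t_over_tc * self.Tc,
                "mean_Y": self.mean_Y,
                "se_Y": self.se_Y,
                "rem_limit": self.rem_limit,
            }
        )


def ensemble_mean_participation(
    params: ModelParams,
    nP: int,
    nB: int,
    t_over_tc,
    n_realizations: int,
    seed: int,
) -> EnsembleParticipation:
    """<Y(T)> over independent (P, B, J) realizations on a T/Tc grid."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    t_over_tc = np.asarray(t_over_tc, dtype=float)
    n = 2 * nP * nB
    Tc = critical_temperature(n, params.l_prime, params.sigma_J)
    T = t_over_tc * Tc
    acc = np.zeros(T.size)
    acc2 = np.zeros(T.size)
    # chunked so realizations x levels x temperatures stays within a memory budget
    chunk = max(1, int(8e6 // (n * max(1, T.size))))
    done = 0
    while done < n_realizations:
        c = min(chunk, n_realizations - done)
        levels = heterodimer_level_samples(params, nP, nB, c, seed + done)
        x = -levels[:, :, None] / T  # (c, n, nT)
        y = np.exp(logsumexp(2.0 * x, axis=1) - 2.0 * logsumexp(x, axis=1))
        acc += y.sum(0)
        acc2 += (y * y).sum(0)
        done += c
    mean = acc / n_realizations
    var = np.maximum(acc2 / n_realizations - mean**2, 0.0)
    se = np.sqrt(var / n_realizations)
    return EnsembleParticipation(t_over_tc, mean, se, Tc, n, n_realizations)
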