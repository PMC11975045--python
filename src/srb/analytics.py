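"""Closed-form SRB statistics.

With Gaussian couplings, a peptide-peptide binding energy is the sum of ``l'``
iid N(0, sigma_J**2) terms, hence exactly N(0, l' sigma_J**2).  The binding
energy of a nonspecific complex of two random proteins is the minimum of
``n = 2 nP nB`` such levels; for large n this follows a min-type Gumbel law
whose location ``mu`` and scale are the Gaussian lower-tail quantiles at
probabilities 1/n and 1/(n e):

    mu   = sqrt(l') sigma_J  Phi^-1(1/n)                 (<= 0 for n >= 2)
    beta = sqrt(l') sigma_J [Phi^-1(1/n) - Phi^-1(1/(n e))]   (> 0)

The printed scale parameter ``phi`` of the law equals ``-beta``; the mean
nonspecific binding energy is ``mu - gamma beta`` with gamma the
Euler-Mascheroni constant.  These are n -> infinity limits: they are exposed
for every n >= 2 but carry O(1/log n) finite-n corrections (see the methods
note), which is why quantitative tests compare at n >= 800.

The module also provides the REM correspondence: critical temperature
``Tc = sigma_J sqrt(l' / (2 log n))``, the limiting participation ratio
``<Y> = max(0, 1 - T/Tc)``, and the fraction of motif sequences that are
images of primary sequences (the search space available to evolution).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "GumbelParams",
    "level_pdf",
    "density_of_states",
    "gumbel_params",
    "nonspecific_pdf",
    "nonspecific_cdf",
    "mean_nonspecific",
    "critical_temperature",
    "rem_participation_limit",
    "invertible_fraction",
]


@dataclasses.dataclass(frozen=True)
class GumbelParams:
    """Location/scale of the min-Gumbel law of nonspecific binding energies.

    ``beta`` is the positive scale; the literature convention ``phi = -beta``
    is exposed for reporting.
    """

    location: float  # mu
    scale: float     # beta > 0
    n: int
    l_prime: int
    sigma_J: float

    @property
    def phi(self) -> float:
        return -self.scale

    def distribution(self):
        """The scipy frozen min-Gumbel distribution with these parameters."""
        return stats.gumbel_l(loc=self.location, scale=self.scale)


def level_pdf(u, l_prime: int, sigma_J: float):
    """Density of one level: N(0, l' sigma_J**2), exact under Gaussian couplings."""
    if l_prime < 1:
        raise ValueError("l_prime must be >= 1")
    if sigma_J <= 0:
        raise ValueError("sigma_J must be positive")
    return stats.norm.pdf(u, scale=math.sqrt(l_prime) * sigma_J)


def density_of_states(u, n: int, l_prime: int, sigma_J: float):
    """Expected density of states of an n-level complex: n * level_pdf(u)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * level_pdf(u, l_prime, sigma_J)


def gumbel_params(n: int, l_prime: int, sigma_J: float = 1.0) -> GumbelParams:
    """Asymptotic min-Gumbel parameters for the minimum of n levels."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if l_prime < 1 or sigma_J <= 0:
        raise ValueError("invalid l_prime or sigma_J")
    s = math.sqrt(l_prime) * sigma_J
    mu = s * stats.norm.ppf(1.0 / n)
    beta = s * (stats.norm.ppf(1.0 / n) - stats.norm.ppf(1.0 / (n * math.e)))
    return GumbelParams(float(mu), float(beta), n, l_prime, sigma_J)


def nonspecific_pdf(U, gp: GumbelParams):
    """Min-Gumbel density of the nonspecific complex binding energy."""
    return gp.distribution().pdf(U)


def nonspecific_cdf(U, gp: GumbelParams):
    return gp.distribution().cdf(U)


def mean_nonspecific(gp: GumbelParams) -> float:
    """Disorder-averaged nonspecific binding energy, mu - gamma beta."""
    return gp.location - np.euler_gamma * gp.scale


def critical_temperature(n: int, l_prime: int, sigma_J: float = 1.0) -> float:
    """REM condensation temperature Tc = sigma_J sqrt(l' / (2 log n))."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return sigma_J * math.sqrt(l_prime / (2.0 * math.log(n)))


def rem_participation_limit(T, Tc: float):
    """n -> infinity mean participation ratio: 1 - T/Tc below Tc, else 0."""
    T = np.asarray(T, dtype=float)
    if (T < 0).any():
        raise ValueError("temperature must be non-negative")
    if Tc <= 0:
        raise ValueError("Tc must be positive")
    out = np.maximum(0.0, 1.0 - T / Tc)
    return float(out) if out.ndim == 0 else out


def invertible_fraction(alphabet_size: int, peptide_length: int, xi: int) -> float:
    """Fraction of motif sequences that invert to a primary sequence.

    Of the ``|M|**l'`` possible motif sequences only ``|A|**l`` are images of
    primary sequences, a fraction ``|A| ** (l - l' xi)`` (1 at xi = 1 or
    xi = l, astronomically small in between).
    """
    if not 1 <= xi <= peptide_length:
        raise ValueError("xi must satisfy 1 <= xi <= peptide_length")
    l_prime = peptide_length - xi + 1
    return float(alphabet_size) ** (peptide_length - l_prime * xi)
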