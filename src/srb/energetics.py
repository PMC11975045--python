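"""Oriented binding energies, complex spectra and interface classification.

Two epitopes interact full-length and in register, in one of two orientations:

* parallel:      ``u = sum_i J[f(p)_i, f(b)_i]``
* antiparallel:  ``u = sum_i J[f(p)_{l'-i+1}, f(b)_i]``

A heterodimer of proteins P (nP epitopes) and B (nB epitopes) is a spectrum of
``n = 2 nP nB`` such levels; the complex binding energy is the spectrum
minimum (the T -> 0 limit).  A homodimer PP has a smaller state space because
exchanging the two epitope roles gives the same energy: unordered distinct
pairs are counted once per orientation, plus two *isologous* states (parallel
and antiparallel self-binding) per epitope — ``nP (nP - 1) + 2 nP`` levels,
420 at nP = 20.  Antiparallel self-binding pairs contact i with contact
l'-i+1, so for even l' it is twice a sum of l'/2 couplings and carries twice
the variance of any other level; this is the statistical origin of the bias
toward antiparallel isologous homodimer interfaces.

The module also houses the batched disorder-average samplers (fresh proteins
and fresh couplings per realization) used by the analytics reproductions, and
the numba kernels shared with the evolution dynamics.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtri

from .model_core import (
    CouplingTable,
    residue_dtype,
    ModelParams,
    MotifMap,
    Protein,
    _counter_normal,
    _mix64,
    build_motif_map,
    counter_normals,
    stream,
)

__all__ = [
    "Orientation",
    "Category",
    "InterfaceConfig",
    "Spectrum",
    "binding_energy",
    "complex_spectrum",
    "homodimer_spectrum",
    "complex_binding_energy",
    "classify_interface",
    "CensusResult",
    "random_homodimer_census",
    "sample_nonspecific_minima",
    "sample_isologous_energies",
    "heterodimer_level_samples",
]


class Orientation(enum.IntEnum):
    PARALLEL = 0
    ANTIPARALLEL = 1


class Category(enum.IntEnum):
    HETEROLOGOUS = 0
    PARALLEL_ISOLOGOUS = 1
    ANTIPARALLEL_ISOLOGOUS = 2
    HETERODIMER = 3


@dataclasses.dataclass(frozen=True)
class InterfaceConfig:
    """One interface configuration: which epitopes bind, and how."""

    epitope_i: int
    epitope_j: int
    orientation: Orientation
    category: Category


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """All configuration energies of a complex, tagged with their interfaces.

    Levels are stored in lexicographic (epitope_i, epitope_j, orientation)
    order, which makes ``argmin`` ties resolve lexicographically for free.
    """

    energies: np.ndarray
    epitope_i: np.ndarray
    epitope_j: np.ndarray
    orientation: np.ndarray
    category: np.ndarray
    kind: str  # 'heterodimer' | 'homodimer'

    @property
    def n_levels(self) -> int:
        return self.energies.size

    def config(self, level: int) -> InterfaceConfig:
        return InterfaceConfig(
            int(self.epitope_i[level]),
            int(self.epitope_j[level]),
            Orientation(int(self.orientation[level])),
            Category(int(self.category[level])),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_index": np.arange(self.n_levels),
                "energy": self.energies,
                "epitope_i": self.epitope_i,
                "epitope_j": self.epitope_j,
                "orientation": [Orientation(o).name.lower() for o in self.orientation],
                "category": [Category(c).name.lower() for c in self.category],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Single-complex operations
# --------------------------------------------------------------------------

def binding_energy(
    peptide_p: np.ndarray,
    peptide_b: np.ndarray,
    orientation: Orientation,
    motif_map: MotifMap,
    table: CouplingTable,
) -> float:
    """Oriented peptide-peptide binding energy (sum of l' motif couplings)."""
    mp = motif_map.encode(np.asarray(peptide_p))
    mb = motif_map.encode(np.asarray(peptide_b))
    if Orientation(orientation) is Orientation.ANTIPARALLEL:
        mp = mp[::-1]
    return float(np.sum(table.coupling(mp, mb)))


def _pair_energies(ma: np.ndarray, mb: np.ndarray, table: CouplingTable):
    """(nA, nB) parallel and antiparallel energy matrices for two motif sets."""
    e_par = table.coupling(ma[:, None, :], mb[None, :, :]).sum(-1)
    e_anti = table.coupling(ma[:, None, ::-1], mb[None, :, :]).sum(-1)
    return e_par, e_anti


def complex_spectrum(
    protein_P: Protein,
    protein_B: Protein,
    motif_map: MotifMap,
    table: CouplingTable,
) -> Spectrum:
    """Heterodimer spectrum: every epitope pair in both orientations (n = 2 nP nB)."""
    mp = motif_map.encode(protein_P.epitopes)
    mb = motif_map.encode(protein_B.epitopes)
    e_par, e_anti = _pair_energies(mp, mb, table)
    nP, nB = e_par.shape
    energies = np.stack([e_par, e_anti], axis=-1).reshape(-1)
    i = np.repeat(np.arange(nP), nB * 2)
    j = np.tile(np.repeat(np.arange(nB), 2), nP)
    orient = np.tile(np.array([0, 1]), nP * nB)
    category = np.full(energies.size, int(Category.HETERODIMER))
    return Spectrum(energies, i, j, orient, category, "heterodimer")


def homodimer_spectrum(protein: Protein, motif_map: MotifMap, table: CouplingTable) -> Spectrum:
    """Homodimer spectrum: unordered distinct pairs x 2 orientations, plus the
    parallel and antiparallel isologous state of each epitope."""
    m = motif_map.encode(protein.epitopes)
    e_par, e_anti = _pair_energies(m, m, table)
    nP = e_par.shape[0]
    iu, ju = np.triu_indices(nP)  # row-major: lexicographic (i, j), i <= j
    energies = np.stack([e_par[iu, ju], e_anti[iu, ju]], axis=-1).reshape(-1)
    i = np.repeat(iu, 2)
    j = np.repeat(ju, 2)
    orient = np.tile(np.array([0, 1]), iu.size)
    category = np.where(
        i == j,
        np.where(orient == 0, int(Category.PARALLEL_ISOLOGOUS),
                 int(Category.ANTIPARALLEL_ISOLOGOUS)),
        int(Category.HETEROLOGOUS),
    )
    return Spectrum(energies, i, j, orient, category, "homodimer")


def complex_binding_energy(spectrum: Spectrum) -> tuple[float, InterfaceConfig]:
    """Minimum of the spectrum and its interface (first level on exact ties,
    i.e. lexicographic in (epitope_i, epitope_j, orientation))."""
    if spectrum.n_levels == 0:
        raise ValueError("empty spectrum")
    k = int(np.argmin(spectrum.energies))
    return float(spectrum.energies[k]), spectrum.config(k)


def classify_interface(spectrum: Spectrum) -> Category:
    """Category of the minimal-energy interface of a homodimer spectrum."""
    if spectrum.kind != "homodimer":
        raise ValueError("interface classification is defined for homodimer spectra")
    _, cfg = complex_binding_energy(spectrum)
    return cfg.category


# --------------------------------------------------------------------------
# Jitted kernels (shared with the evolution dynamics)
#
# Both kernels scan levels in lexicographic (i, j, orientation) order with a
# strict '<', so ties resolve exactly as complex_binding_energy does.
# --------------------------------------------------------------------------

@njit(cache=True)
def _best_homodimer(motifs: np.ndarray, J: np.ndarray):
    """Per member: minimal homodimer level and its (i, j, orientation)."""
    N, nP, lp = motifs.shape
    U = np.empty(N)
    bi = np.empty(N, np.int64)
    bj = np.empty(N, np.int64)
    bo = np.empty(N, np.int64)
    for n in range(N):
        best = np.inf
        pi = pj = po = 0
        for i in range(nP):
            for j in range(i, nP):
                ep = 0.0
                ea = 0.0
                for k in range(lp):
                    ep += J[motifs[n, i, k], motifs[n, j, k]]
                    ea += J[motifs[n, i, lp - 1 - k], motifs[n, j, k]]
                if ep < best:
                    best = ep; pi = i; pj = j; po = 0
                if ea < best:
                    best = ea; pi = i; pj = j; po = 1
        U[n] = best; bi[n] = pi; bj[n] = pj; bo[n] = po
    return U, bi, bj, bo


@njit(cache=True)
def _best_heterodimer(motifs_p: np.ndarray, motifs_b: np.ndarray, J: np.ndarray):
    N, nP, lp = motifs_p.shape
    nB = motifs_b.shape[1]
    U = np.empty(N)
    bi = np.empty(N, np.int64)
    bj = np.empty(N, np.int64)
    bo = np.empty(N, np.int64)
    for n in range(N):
        best = np.inf
        pi = pj = po = 0
        for i in range(nP):
            for j in range(nB):
                ep = 0.0
                ea = 0.0
                for k in range(lp):
                    ep += J[motifs_p[n, i, k], motifs_b[n, j, k]]
                    ea += J[motifs_p[n, i, lp - 1 - k], motifs_b[n, j, k]]
                if ep < best:
                    best = ep; pi = i; pj = j; po = 0
                if ea < best:
                    best = ea; pi = i; pj = j; po = 1
        U[n] = best; bi[n] = pi; bj[n] = pj; bo[n] = po
    return U, bi, bj, bo


@njit(cache=True)
def _update_homodimer(motifs, changed, E, J):
    """Refresh rows/columns of per-member pair-energy matrices for epitopes
    whose sequence changed.  E has shape (N, nP, nP, 2) with the last axis
    (parallel, antiparallel); both orientation matrices are symmetric."""
    N, nP, lp = motifs.shape
    for n in range(N):
        for e in range(nP):
            if changed[n, e]:
                for j in range(nP):
                    ep = 0.0
                    ea = 0.0
                    for k in range(lp):
                        ep += J[motifs[n, e, k], motifs[n, j, k]]
                        ea += J[motifs[n, e, lp - 1 - k], motifs[n, j, k]]
                    E[n, e, j, 0] = ep
                    E[n, j, e, 0] = ep
                    E[n, e, j, 1] = ea
                    E[n, j, e, 1] = ea


@njit(cache=True)
def _scan_homodimer(E):
    """Argmin over the homodimer state space (i <= j, both orientations),
    lexicographic on (i, j, orientation) as in complex_binding_energy."""
    N, nP = E.shape[0], E.shape[1]
    U = np.empty(N)
    bi = np.empty(N, np.int64)
    bj = np.empty(N, np.int64)
    bo = np.empty(N, np.int64)
    for n in range(N):
        best = np.inf
        pi = pj = po = 0
        for i in range(nP):
            for j in range(i, nP):
                if E[n, i, j, 0] < best:
                    best = E[n, i, j, 0]; pi = i; pj = j; po = 0
                if E[n, i, j, 1] < best:
                    best = E[n, i, j, 1]; pi = i; pj = j; po = 1
        U[n] = best; bi[n] = pi; bj[n] = pj; bo[n] = po
    return U, bi, bj, bo


@njit(cache=True)
def _update_heterodimer(motifs_p, motifs_b, changed_p, changed_b, E, J):
    """Heterodimer counterpart of _update_homodimer; E is (N, nP, nB, 2)."""
    N, nP, lp = motifs_p.shape
    nB = motifs_b.shape[1]
    for n in range(N):
        for e in range(nP):
            if changed_p[n, e]:
                for j in range(nB):
                    ep = 0.0
                    ea = 0.0
                    for k in range(lp):
                        ep += J[motifs_p[n, e, k], motifs_b[n, j, k]]
                        ea += J[motifs_p[n, e, lp - 1 - k], motifs_b[n, j, k]]
                    E[n, e, j, 0] = ep
                    E[n, e, j, 1] = ea
        for j in range(nB):
            if changed_b[n, j]:
                for e in range(nP):
                    ep = 0.0
                    ea = 0.0
                    for k in range(lp):
                        ep += J[motifs_p[n, e, k], motifs_b[n, j, k]]
                        ea += J[motifs_p[n, e, lp - 1 - k], motifs_b[n, j, k]]
                    E[n, e, j, 0] = ep
                    E[n, e, j, 1] = ea


@njit(cache=True)
def _scan_heterodimer(E):
    N, nP, nB = E.shape[0], E.shape[1], E.shape[2]
    U = np.empty(N)
    bi = np.empty(N, np.int64)
    bj = np.empty(N, np.int64)
    bo = np.empty(N, np.int64)
    for n in range(N):
        best = np.inf
        pi = pj = po = 0
        for i in range(nP):
            for j in range(nB):
                if E[n, i, j, 0] < best:
                    best = E[n, i, j, 0]; pi = i; pj = j; po = 0
                if E[n, i, j, 1] < best:
                    best = E[n, i, j, 1]; pi = i; pj = j; po = 1
        U[n] = best; bi[n] = pi; bj[n] = pj; bo[n] = po
    return U, bi, bj, bo


@njit(cache=True)
def _best_homodimer_lazy(motifs, mixed_seed, n_motifs, sigma_J):
    """As _best_homodimer but couplings hashed on the fly (huge motif alphabets)."""
    N, nP, lp = motifs.shape
    M = np.uint64(n_motifs)
    U = np.empty(N)
    bi = np.empty(N, np.int64)
    bj = np.empty(N, np.int64)
    bo = np.empty(N, np.int64)
    for n in range(N):
        best = np.inf
        pi = pj = po = 0
        for i in range(nP):
            for j in range(i, nP):
                ep = 0.0
                ea = 0.0
                for k in range(lp):
                    a = np.uint64(motifs[n, i, k]); b = np.uint64(motifs[n, j, k])
                    lo = a if a < b else b
                    hi = b if a < b else a
                    ep += _counter_normal(mixed_seed, lo * M + hi)
                    a = np.uint64(motifs[n, i, lp - 1 - k])
                    lo = a if a < b else b
                    hi = b if a < b else a
                    ea += _counter_normal(mixed_seed, lo * M + hi)
                ep *= sigma_J
                ea *= sigma_J
                if ep < best:
                    best = ep; pi = i; pj = j; po = 0
                if ea < best:
                    best = ea; pi = i; pj = j; po = 1
        U[n] = best; bi[n] = pi; bj[n] = pj; bo[n] = po
    return U, bi, bj, bo


@njit(cache=True)
def _best_heterodimer_lazy(motifs_p, motifs_b, mixed_seed, n_motifs, sigma_J):
    N, nP, lp = motifs_p.shape
    nB = motifs_b.shape[1]
    M = np.uint64(n_motifs)
    U = np.empty(N)
    bi = np.empty(N, np.int64)
    bj = np.empty(N, np.int64)
    bo = np.empty(N, np.int64)
    for n in range(N):
        best = np.inf
        pi = pj = po = 0
        for i in range(nP):
            for j in range(nB):
                ep = 0.0
                ea = 0.0
                for k in range(lp):
                    a = np.uint64(motifs_p[n, i, k]); b = np.uint64(motifs_b[n, j, k])
                    lo = a if a < b else b
                    hi = b if a < b else a
                    ep += _counter_normal(mixed_seed, lo * M + hi)
                    a = np.uint64(motifs_p[n, i, lp - 1 - k])
                    lo = a if a < b else b
                    hi = b if a < b else a
                    ea += _counter_normal(mixed_seed, lo * M + hi)
                ep *= sigma_J
                ea *= sigma_J
                if ep < best:
                    best = ep; pi = i; pj = j; po = 0
                if ea < best:
                    best = ea; pi = i; pj = j; po = 1
        U[n] = best; bi[n] = pi; bj[n] = pj; bo[n] = po
    return U, bi, bj, bo


# --------------------------------------------------------------------------
# Disorder-average samplers
#
# Each realization draws fresh random proteins *and* a fresh coupling seed
# (quenched-disorder average).  Couplings are evaluated through the same
# counter hash as CouplingTable, so these paths are exact re-parameterizations
# of the object API, just batched.
# --------------------------------------------------------------------------

def _batch_motifs(params: ModelParams, motif_map: MotifMap, shape, rng) -> np.ndarray:
    res = rng.integers(0, params.alphabet_size, size=shape + (params.peptide_length,),
                       dtype=residue_dtype(params.alphabet_size))
    return motif_map.encode(res)


def _mix64_array(z: np.ndarray) -> np.ndarray:
    z = z.copy()
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


def _batch_couplings(params, coupling_seeds, ma, mb):
    """Couplings for motif arrays with a per-realization leading axis.

    ``coupling_seeds`` broadcasts against the leading axes of ``ma``/``mb``.
    """
    M = np.uint64(params.n_motifs)
    lo = np.minimum(ma, mb).astype(np.uint64)
    hi = np.maximum(ma, mb).astype(np.uint64)
    keys = lo * M + hi
    mixed = _mix64_array(np.asarray(coupling_seeds, dtype=np.uint64))
    h = _mix64_array(mixed + (keys + np.uint64(1)) * np.uint64(0x9E3779B97F4A7C15))
    u = (h >> np.uint64(11)).astype(np.float64) * 2.0**-53 + 2.0**-54
    return params.sigma_J * ndtri(u)


def heterodimer_level_samples(
    params: ModelParams,
    nP: int,
    nB: int,
    n_realizations: int,
    seed: int,
    motif_map: MotifMap | None = None,
) -> np.ndarray:
    """(n_realizations, 2 nP nB) heterodimer level energies, fresh disorder per row."""
    motif_map = motif_map or build_motif_map(params)
    rng = stream(seed, "heterodimer_levels")
    out = np.empty((n_realizations, 2 * nP * nB))
    chunk = max(1, int(4e6 // (2 * nP * nB)))
    done = 0
    while done < n_realizations:
        c = min(chunk, n_realizations - done)
        seeds = rng.integers(0, 2**63, size=(c, 1, 1, 1), dtype=np.uint64)
        mp = _batch_motifs(params, motif_map, (c, nP), rng)
        mb = _batch_motifs(params, motif_map, (c, nB), rng)
        a = np.broadcast_to(mp[:, :, None, :], (c, nP, nB, params.l_prime))
        b = np.broadcast_to(mb[:, None, :, :], (c, nP, nB, params.l_prime))
        e_par = _batch_couplings(params, seeds, a, b).sum(-1)
        e_anti = _batch_couplings(params, seeds, a[..., ::-1], b).sum(-1)
        out[done:done + c] = np.concatenate(
            [e_par.reshape(c, -1), e_anti.reshape(c, -1)], axis=1)
        done += c
    return out


def sample_nonspecific_minima(
    params: ModelParams,
    nP: int,
    nB: int,
    n_realizations: int,
    seed: int,
) -> np.ndarray:
    """Minimum binding energy U(P, B) of independent random-complex realizations."""
    mins = np.empty(n_realizations)
    chunk = max(1, int(4e6 // (2 * nP * nB)))
    motif_map = build_motif_map(params)
    rng = stream(seed, "heterodimer_levels")
    done = 0
    while done < n_realizations:
        c = min(chunk, n_realizations - done)
        seeds = rng.integers(0, 2**63, size=(c, 1, 1, 1), dtype=np.uint64)
        mp = _batch_motifs(params, motif_map, (c, nP), rng)
        mb = _batch_motifs(params, motif_map, (c, nB), rng)
        a = np.broadcast_to(mp[:, :, None, :], (c, nP, nB, params.l_prime))
        b = np.broadcast_to(mb[:, None, :, :], (c, nP, nB, params.l_prime))
        e_par = _batch_couplings(params, seeds, a, b).sum(-1)
        e_anti = _batch_couplings(params, seeds, a[..., ::-1], b).sum(-1)
        mins[done:done + c] = np.minimum(
            e_par.reshape(c, -1).min(1), e_anti.reshape(c, -1).min(1))
        done += c
    return mins


@dataclasses.dataclass(frozen=True)
class CensusResult:
    """Counts of minimal-energy interface categories over realizations."""

    antiparallel_isologous: int
    parallel_isologous: int
    heterologous: int

    @property
    def n_realizations(self) -> int:
        return self.antiparallel_isologous + self.parallel_isologous + self.heterologous

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_realizations
        return {
            "antiparallel_isologous": self.antiparallel_isologous / n,
            "parallel_isologous": self.parallel_isologous / n,
            "heterologous": self.heterologous / n,
        }


def random_homodimer_census(
    params: ModelParams,
    nP: int,
    n_realizations: int,
    seed: int,
) -> CensusResult:
    """Classify the minimal-energy interface of independent random homodimers."""
    motif_map = build_motif_map(params)
    rng = stream(seed, "homodimer_census")
    counts = np.zeros(3, dtype=np.int64)  # anti-iso, par-iso, heterologous
    chunk = max(1, int(2e6 // (nP * nP)))
    lp = params.l_prime
    done = 0
    while done < n_realizations:
        c = min(chunk, n_realizations - done)
        seeds = rng.integers(0, 2**63, size=(c, 1, 1, 1), dtype=np.uint64)
        m = _batch_motifs(params, motif_map, (c, nP), rng)
        a = np.broadcast_to(m[:, :, None, :], (c, nP, nP, lp))
        b = np.broadcast_to(m[:, None, :, :], (c, nP, nP, lp))
        e_par = _batch_couplings(params, seeds, a, b).sum(-1)
        e_anti = _batch_couplings(params, seeds, a[..., ::-1], b).sum(-1)
        ar = np.arange(nP)
        iso_anti = e_anti[:, ar, ar].min(1)
        iso_par = e_par[:, ar, ar].min(1)
        iu, ju = np.triu_indices(nP, 1)
        het = np.minimum(e_par[:, iu, ju].min(1), e_anti[:, iu, ju].min(1))
        best = np.argmin(np.stack([iso_anti, iso_par, het]), axis=0)
        counts += np.bincount(best, minlength=3)
        done += c
    return CensusResult(int(counts[0]), int(counts[1]), int(counts[2]))


def sample_isologous_energies(
    params: ModelParams,
    n_samples: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-binding energies (u_parallel, u_antiparallel) of random peptides,
    fresh couplings per sample (disorder average over peptides and J)."""
    motif_map = build_motif_map(params)
    rng = stream(seed, "isologous")
    m = _batch_motifs(params, motif_map, (n_samples,), rng)
    seeds = rng.integers(0, 2**63, size=(n_samples, 1), dtype=np.uint64)
    u_par = _batch_couplings(params, seeds, m, m).sum(-1)
    u_anti = _batch_couplings(params, seeds, m[:, ::-1], m).sum(-1)
    return u_par, u_anti
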