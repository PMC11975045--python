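"""Core definitions of the Structured Random Binding (SRB) universe.

SRB abstracts a protein as a bag of surface-exposed peptide *epitopes*.  A
peptide is a string of length ``l`` over a primary alphabet of size ``|A|``
(the 20 proteinogenic amino acids, or a reduced alphabet for heavy numerics).
Sliding windows of ``xi`` consecutive residues — ``xi`` is the structural
correlation length along the backbone — are mapped bijectively onto structural
*motifs*, so every peptide carries a secondary structure of
``l' = l - xi + 1`` motifs.  All energetics are carried by a quenched random
symmetric motif-motif coupling table ``J`` with zero mean and variance
``sigma_J**2``; here ``J`` entries are Gaussian, which makes the peptide-level
energy distribution exactly normal at every ``l'``.

Everything random flows from named, reproducible streams derived from a master
seed.  Coupling entries are generated lazily by a counter-based hash of
``(coupling_seed, unordered motif pair)`` so that tables far too large to
materialize (``|M| = |A|**xi`` grows fast) still yield deterministic,
identically distributed values; a materialized table is simply the lazy
generator evaluated on every pair, so the two storage modes agree entry for
entry.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.special import ndtri
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numba import njit

__all__ = [
    "ModelParams",
    "MotifMap",
    "CouplingTable",
    "Protein",
    "build_motif_map",
    "encode_secondary",
    "coupling",
    "random_peptide",
    "random_protein",
    "stream",
    "seed_u64",
    "load_config",
    "save_config",
    "proteins_to_fasta",
    "proteins_from_fasta",
]

# Boltzmann constant is 1; energies and temperatures share the unit sigma_J.
DEFAULT_SIGMA_J = 1.0

# Largest motif alphabet for which a dense |M| x |M| table is materialized
# (8192**2 doubles ~ 537 MB); beyond that only lazy generation is offered.
DENSE_TABLE_MAX_MOTIFS = 8192


# --------------------------------------------------------------------------
# Parameters and seeding
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Global SRB parameters.

    Parameters
    ----------
    alphabet_size : int
        Size of the primary alphabet ``|A|`` (>= 2).
    peptide_length : int
        Epitope length ``l`` in residues.
    xi : int
        Structural correlation length (motif window width), ``1 <= xi <= l``.
    sigma_J : float
        Standard deviation of motif-motif couplings; sets the energy unit.
    master_seed : int
        Root of every named random stream used with these parameters.
    """

    alphabet_size: int
    peptide_length: int
    xi: int
    sigma_J: float = DEFAULT_SIGMA_J
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2 (a one-letter alphabet is trivial)")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if not 1 <= self.xi <= self.peptide_length:
            raise ValueError("xi must satisfy 1 <= xi <= peptide_length")
        if self.sigma_J <= 0:
            raise ValueError("sigma_J must be positive")

    @property
    def l_prime(self) -> int:
        """Number of motif-motif contacts per peptide pair, ``l - xi + 1``."""
        return self.peptide_length - self.xi + 1

    @property
    def n_motifs(self) -> int:
        """Motif alphabet size ``|M| = |A|**xi``."""
        return self.alphabet_size**self.xi


def stream(master_seed: int, *names: object) -> np.random.Generator:
    """Named random stream: a Generator reproducibly derived from the master seed.

    Each distinct ``names`` tuple yields an independent stream; strings are
    hashed (CRC32) so stream identity does not depend on interpreter hashing.
    """
    key = tuple(
        n if isinstance(n, (int, np.integer)) else zlib.crc32(str(n).encode())
        for n in names
    )
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def seed_u64(master_seed: int, *names: object) -> np.uint64:
    """A single 64-bit seed (e.g. for a coupling table) from a named stream."""
    return stream(master_seed, *names).integers(0, 2**63, dtype=np.uint64)


# --------------------------------------------------------------------------
# Counter-based deterministic normals (lazy couplings)
#
# splitmix64: output k of the stream seeded at s is mix13(mix13(s) + (k+1)*G).
# The uniform deviate is mapped to a standard normal with Wichura's AS241
# inverse-normal-CDF (double precision, ~1e-15 relative error), implemented
# here so that the same jitted code serves lazy lookups, materialized tables
# and the hot simulation kernels bit-identically.
# --------------------------------------------------------------------------

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True)
def _mix64(z: np.uint64) -> np.uint64:
    z = np.uint64(z)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


@njit(cache=True)
def _ndtri(p: float) -> float:
    """Inverse standard normal CDF (Wichura 1988, algorithm AS241, PPND16)."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    r = p if q < 0.0 else 1.0 - p
    r = np.sqrt(-np.log(r))
    if r <= 5.0:
        r -= 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r -= 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    x = num / den
    return -x if q < 0.0 else x


@njit(cache=True)
def _counter_normal(mixed_seed: np.uint64, counter: np.uint64) -> float:
    """Standard normal deviate at position ``counter`` of the hashed stream."""
    h = _mix64(mixed_seed + (counter + np.uint64(1)) * _GOLDEN)
    u = np.float64(h >> np.uint64(11)) * 1.1102230246251565e-16 + 5.551115123125783e-17
    return _ndtri(u)


def _mix64_py(z) -> np.uint64:
    """Python-side splitmix64 finalizer (numpy uint64, wrapping arithmetic)."""
    z = np.asarray(z, dtype=np.uint64).copy()
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z if z.ndim else np.uint64(z)


def counter_normals(seed: int | np.uint64, counters: np.ndarray) -> np.ndarray:
    """Vectorized deterministic standard normals keyed by (seed, counter).

    Uses scipy's vectorized inverse normal CDF; the jitted scalar path
    (:func:`_counter_normal`, used inside simulation kernels when the table
    is too large to materialize) evaluates the same hash through AS241 and
    agrees to ~1e-15.
    """
    counters = np.asarray(counters, dtype=np.uint64)
    h = _mix64_py(_mix64_py(seed) + (counters + np.uint64(1)) * _GOLDEN)
    u = (h >> np.uint64(11)).astype(np.float64) * 1.1102230246251565e-16 \
        + 5.551115123125783e-17
    return ndtri(u)


# --------------------------------------------------------------------------
# Motif map
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MotifMap:
    """Bijection f from xi-tuples of the primary alphabet to motif indices.

    Tuples are identified with their base-``|A|`` integer encoding; the map is
    ``permutation[code]``.  The identity permutation is the default — any
    bijection is statistically equivalent because J is random — but a seeded
    random permutation is available.
    """

    params: ModelParams
    permutation: np.ndarray

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=np.int64)
        object.__setattr__(self, "permutation", perm)
        n = self.params.n_motifs
        if perm.shape != (n,) or not np.array_equal(np.sort(perm), np.arange(n)):
            raise ValueError("permutation must be a bijection on range(n_motifs)")

    @property
    def inverse_permutation(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(self.permutation.size)
        return inv

    def encode_tuple(self, residues: Sequence[int]) -> int:
        """Motif index of one xi-tuple."""
        residues = np.asarray(residues)
        if residues.shape != (self.params.xi,):
            raise ValueError(f"expected a tuple of {self.params.xi} residues")
        code = 0
        for r in residues:
            code = code * self.params.alphabet_size + int(r)
        return int(self.permutation[code])

    def decode_motif(self, motif: int) -> np.ndarray:
        """Inverse map: the xi-tuple of residues encoding to ``motif``."""
        code = int(self.inverse_permutation[motif])
        out = np.empty(self.params.xi, dtype=np.int64)
        for k in range(self.params.xi - 1, -1, -1):
            out[k] = code % self.params.alphabet_size
            code //= self.params.alphabet_size
        return out

    def encode(self, residues: np.ndarray) -> np.ndarray:
        """Secondary structure: motif index per sliding xi-window.

        Accepts any array with residues on the last axis (length ``l``);
        returns an array with ``l'`` motif indices on the last axis.
        """
        residues = np.asarray(residues)
        p = self.params
        if residues.shape[-1] != p.peptide_length:
            raise ValueError(
                f"peptide length {residues.shape[-1]} != l = {p.peptide_length}")
        lp = p.l_prime
        code = np.zeros(residues.shape[:-1] + (lp,), dtype=np.int64)
        for k in range(p.xi):
            code = code * p.alphabet_size + residues[..., k:k + lp]
        return self.permutation[code]


def build_motif_map(params: ModelParams, permutation_seed: int | None = None) -> MotifMap:
    """Construct the motif map; identity encoding unless a seed asks for a shuffle."""
    n = params.n_motifs
    if permutation_seed is None:
        perm = np.arange(n, dtype=np.int64)
    else:
        perm = stream(params.master_seed, "motif_map", permutation_seed).permutation(n)
    return MotifMap(params, perm)


def encode_secondary(peptide: np.ndarray, motif_map: MotifMap) -> np.ndarray:
    """Functional alias for :meth:`MotifMap.encode` on a single peptide."""
    return motif_map.encode(peptide)


# --------------------------------------------------------------------------
# Coupling table
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CouplingTable:
    """Symmetric random motif-motif couplings J(m, m').

    Entries over distinct unordered pairs (diagonal included, same law) are
    iid Gaussian(0, sigma_J**2), generated deterministically from
    ``coupling_seed`` and the unordered pair index.  ``mode='materialized'``
    precomputes the dense table by evaluating the same generator on every
    pair, so both modes agree exactly.
    """

    params: ModelParams
    coupling_seed: int
    mode: str = "lazy"
    _table: np.ndarray | None = dataclasses.field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in ("lazy", "materialized"):
            raise ValueError("mode must be 'lazy' or 'materialized'")
        if self.mode == "materialized" and self._table is None:
            n = self.params.n_motifs
            if n > DENSE_TABLE_MAX_MOTIFS:
                raise ValueError(
                    f"refusing to materialize a {n}x{n} table; use mode='lazy'")
            object.__setattr__(self, "_table", self._dense())

    @property
    def mixed_seed(self) -> np.uint64:
        return _mix64_py(self.coupling_seed)

    def _values(self, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
        n = np.uint64(self.params.n_motifs)
        lo = np.minimum(m1, m2).astype(np.uint64)
        hi = np.maximum(m1, m2).astype(np.uint64)
        z = counter_normals(self.coupling_seed, lo * n + hi)
        return self.params.sigma_J * z

    def coupling(self, m1, m2) -> np.ndarray | float:
        """J(m1, m2); accepts scalars or broadcastable integer arrays."""
        m1 = np.asarray(m1)
        m2 = np.asarray(m2)
        n = self.params.n_motifs
        if (m1 < 0).any() or (m1 >= n).any() or (m2 < 0).any() or (m2 >= n).any():
            raise ValueError(f"motif index out of range [0, {n})")
        m1, m2 = np.broadcast_arrays(m1, m2)
        if self._table is not None:
            out = self._table[m1, m2]
        else:
            out = self._values(m1, m2)
        return float(out) if out.ndim == 0 else out

    def _dense(self) -> np.ndarray:
        """Evaluate the lazy generator on every pair, in row blocks to keep
        the hashing temporaries small."""
        n = self.params.n_motifs
        out = np.empty((n, n))
        step = max(1, int(8e6 // n))
        cols = np.arange(n)[None, :]
        for start in range(0, n, step):
            rows = np.arange(start, min(start + step, n))[:, None]
            out[start:start + len(rows)] = self._values(rows, cols)
        return out

    def dense(self) -> np.ndarray:
        """The full |M| x |M| table (materializing it on the fly if lazy)."""
        if self._table is not None:
            return self._table
        n = self.params.n_motifs
        if n > DENSE_TABLE_MAX_MOTIFS:
            raise ValueError(f"{n}x{n} table too large to densify")
        return self._dense()


def build_coupling_table(
    params: ModelParams,
    coupling_seed: int | None = None,
    mode: str | None = None,
) -> CouplingTable:
    """Coupling table with seed derived from the master seed unless given.

    ``mode=None`` picks materialized storage when the motif alphabet is small
    enough for the dense table to be cheap, lazy otherwise.
    """
    if coupling_seed is None:
        coupling_seed = int(seed_u64(params.master_seed, "couplings"))
    if mode is None:
        mode = "materialized" if params.n_motifs <= 256 else "lazy"
    return CouplingTable(params, coupling_seed, mode)


def coupling(table: CouplingTable, m1, m2):
    """Functional alias for :meth:`CouplingTable.coupling`."""
    return table.coupling(m1, m2)


# --------------------------------------------------------------------------
# Peptides and proteins
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Protein:
    """A bag of epitopes: integer residue array of shape (n_epitopes, l)."""

    epitopes: np.ndarray
    params: ModelParams

    def __post_init__(self) -> None:
        ep = np.asarray(self.epitopes, dtype=residue_dtype(self.params.alphabet_size))
        if ep.ndim != 2 or ep.shape[0] < 1:
            raise ValueError("epitopes must be a (n_epitopes >= 1, l) array")
        if ep.shape[1] != self.params.peptide_length:
            raise ValueError("epitope length differs from params.peptide_length")
        if (ep < 0).any() or (ep >= self.params.alphabet_size).any():
            raise ValueError("residue code out of alphabet range")
        object.__setattr__(self, "epitopes", ep)

    @property
    def n_epitopes(self) -> int:
        return self.epitopes.shape[0]


def residue_dtype(alphabet_size: int) -> type:
    """Smallest signed integer dtype that holds every letter code."""
    return np.int8 if alphabet_size <= 127 else np.int32


def random_peptide(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """One random peptide: iid uniform letters."""
    return rng.integers(0, params.alphabet_size, size=params.peptide_length,
                        dtype=residue_dtype(params.alphabet_size))


def random_protein(params: ModelParams, n_epitopes: int, rng: np.random.Generator) -> Protein:
    """A protein of ``n_epitopes`` iid-uniform random epitopes."""
    if n_epitopes < 1:
        raise ValueError("n_epitopes must be >= 1")
    ep = rng.integers(0, params.alphabet_size,
                      size=(n_epitopes, params.peptide_length),
                      dtype=residue_dtype(params.alphabet_size))
    return Protein(ep, params)


# --------------------------------------------------------------------------
# Config file and FASTA round trips
# --------------------------------------------------------------------------

def load_config(path) -> tuple[ModelParams, int]:
    """Read a YAML config; returns (ModelParams, n_epitopes)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    params = ModelParams(
        alphabet_size=int(cfg["alphabet_size"]),
        peptide_length=int(cfg["peptide_length"]),
        xi=int(cfg["xi"]),
        sigma_J=float(cfg.get("sigma_J", DEFAULT_SIGMA_J)),
        master_seed=int(cfg.get("master_seed", 0)),
    )
    return params, int(cfg.get("n_epitopes", 1))


def save_config(path, params: ModelParams, n_epitopes: int) -> None:
    cfg = {
        "alphabet_size": params.alphabet_size,
        "peptide_length": params.peptide_length,
        "xi": params.xi,
        "sigma_J": params.sigma_J,
        "n_epitopes": n_epitopes,
        "master_seed": params.master_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _letters(alphabet_size: int) -> str:
    if alphabet_size == 4:
        return "ACGT"
    if alphabet_size > 26:
        raise ValueError("FASTA export supports alphabets of at most 26 letters")
    return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:alphabet_size]


def proteins_to_fasta(proteins: Iterable[Protein], path) -> None:
    """Write proteins as FASTA, one record per epitope (>protein_<id>_epitope_<k>)."""
    records = []
    for pid, prot in enumerate(proteins):
        letters = _letters(prot.params.alphabet_size)
        for k, ep in enumerate(prot.epitopes):
            seq = "".join(letters[r] for r in ep)
            records.append(SeqRecord(Seq(seq), id=f"protein_{pid}_epitope_{k}", description=""))
    SeqIO.write(records, path, "fasta")


def proteins_from_fasta(path, params: ModelParams) -> list[Protein]:
    """Inverse of :func:`proteins_to_fasta` under the same parameters."""
    letters = _letters(params.alphabet_size)
    lut = {c: i for i, c in enumerate(letters)}
    groups: dict[int, list[np.ndarray]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("_")
        pid = int(parts[1])
        groups.setdefault(pid, []).append(
            np.array([lut[c] for c in str(rec.seq)], dtype=np.int8))
    return [Protein(np.stack(groups[pid]), params) for pid in sorted(groups)]
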