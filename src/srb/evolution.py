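"""Mutation-selection dynamics of an ensemble of binary complexes.

A population of N identical founder complexes (two random proteins in
heterodimer mode, one in homodimer mode) evolves in discrete generations:

1. every residue of every member mutates independently with probability
   ``epsilon`` (a substitution draws uniformly from the other letters);
2. each member's binding energy U is recomputed as the minimum of its
   complex spectrum;
3. the selection threshold U0 is set to the current (post-mutation,
   pre-selection) ensemble mean, so selection pressure tracks the ensemble;
4. each member survives with Fermi probability 1/(exp((U - U0)/w) + 1),
   with width w = sigma_J by default;
5. survivors are resampled uniformly with replacement back to size N
   (Wright-Fisher style; a zero-survivor generation keeps the pre-selection
   ensemble).

Affinity gain is strongest for short structural correlation length xi: a
single-residue mutation then perturbs few motifs, so binding energy remains
correlated with sequence and the population can descend the energy landscape.
The evolved-homodimer census classifies the minimal-energy interface of the
best final member of each independent realization; evolution drives it to
almost always antiparallel isologous.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.special import expit

from . import energetics
from .model_core import (
    ModelParams,
    MotifMap,
    Protein,
    DENSE_TABLE_MAX_MOTIFS,
    CouplingTable,
    build_motif_map,
    random_protein,
    seed_u64,
    stream,
)
from .energetics import (
    Category,
    CensusResult,
    InterfaceConfig,
    _best_heterodimer_lazy,
    _best_homodimer_lazy,
    _scan_heterodimer,
    _scan_homodimer,
    _update_heterodimer,
    _update_homodimer,
)

__all__ = [
    "EvolutionParams",
    "EvolutionTrajectory",
    "mutate",
    "survival_probability",
    "evolve_population",
    "specificity_assay",
    "evolved_homodimer_census",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the mutation-selection dynamics."""

    mode: str = "heterodimer"  # or "homodimer"
    n_epitopes: int = 20
    ensemble_size: int = 1000
    mutation_rate: float = 0.01
    generations: int = 1000
    selection_width: float | None = None  # defaults to sigma_J
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("heterodimer", "homodimer"):
            raise ValueError("mode must be 'heterodimer' or 'homodimer'")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.selection_width is not None and self.selection_width <= 0:
            raise ValueError("selection_width must be positive")


@dataclasses.dataclass(frozen=True)
class EvolutionTrajectory:
    """Per-generation records plus the final population.

    ``threshold[t]`` is U0 at generation t and equals ``mean_energy[t]`` (the
    post-mutation, pre-selection ensemble mean) by construction.
    """

    model_params: ModelParams
    evo_params: EvolutionParams
    coupling_seed: int
    threshold: np.ndarray
    mean_energy: np.ndarray
    min_energy: np.ndarray
    survivors: np.ndarray
    final_population_P: np.ndarray  # (N, n_epitopes, l)
    final_population_B: np.ndarray | None  # None in homodimer mode
    final_energies: np.ndarray

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.final_energies))

    def best_proteins(self) -> tuple[Protein, Protein | None]:
        b = self.best_index
        P = Protein(self.final_population_P[b], self.model_params)
        if self.final_population_B is None:
            return P, None
        return P, Protein(self.final_population_B[b], self.model_params)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(self.threshold.size),
                "U0": self.threshold,
                "mean_U": self.mean_energy,
                "min_U": self.min_energy,
                "survivors": self.survivors,
            }
        )


def mutate(protein: Protein, epsilon: float, rng: np.random.Generator) -> Protein:
    """Point-mutate a protein: each residue substituted with probability epsilon."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    ep = _mutate_batch(protein.epitopes[None], epsilon, protein.params.alphabet_size, rng)[0]
    return Protein(ep, protein.params)


def _mutate_batch(pop: np.ndarray, epsilon: float, alphabet_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    return _mutate_batch_flagged(pop, epsilon, alphabet_size, rng)[0]


def _mutate_batch_flagged(pop, epsilon, alphabet_size, rng):
    """Mutated population plus a per-epitope 'sequence changed' flag array."""
    if epsilon == 0.0:
        return pop, np.zeros(pop.shape[:-1], dtype=np.bool_)
    mask = rng.random(pop.shape) < epsilon
    # shifting by 1..A-1 modulo A guarantees a *different* letter, uniformly
    shift = rng.integers(1, alphabet_size, size=pop.shape, dtype=pop.dtype)
    return np.where(mask, (pop + shift) % alphabet_size, pop), mask.any(-1)


def survival_probability(U, U0, width: float):
    """Fermi survival rule: 1 / (exp((U - U0)/width) + 1)."""
    if width <= 0:
        raise ValueError("selection width must be positive")
    x = (np.asarray(U, dtype=float) - U0) / width
    out = expit(-x)  # logistic sigmoid; overflow-safe in both tails
    return float(out) if out.ndim == 0 else out


class _PopulationEnergies:
    """Per-member spectrum minima, maintained incrementally.

    With a dense coupling table each member carries its full pair-energy
    matrix; after a mutation only the rows/columns of changed epitopes are
    recomputed, and resampling just copies matrices.  For motif alphabets too
    large to tabulate the full spectrum is rehashed lazily every generation.
    """

    def __init__(self, table: CouplingTable, dense_J, n_members, nP, nB=None):
        self.table = table
        self.dense_J = dense_J
        self.heterodimer = nB is not None
        if dense_J is not None:
            shape = (n_members, nP, nB, 2) if self.heterodimer else (n_members, nP, nP, 2)
            self.E = np.empty(shape)

    def compute(self, motifs_P, motifs_B, changed_P, changed_B):
        t = self.table
        if self.dense_J is None:
            if self.heterodimer:
                return _best_heterodimer_lazy(
                    motifs_P, motifs_B, t.mixed_seed, t.params.n_motifs, t.params.sigma_J)
            return _best_homodimer_lazy(
                motifs_P, t.mixed_seed, t.params.n_motifs, t.params.sigma_J)
        if self.heterodimer:
            _update_heterodimer(motifs_P, motifs_B, changed_P, changed_B,
                                self.E, self.dense_J)
            return _scan_heterodimer(self.E)
        _update_homodimer(motifs_P, changed_P, self.E, self.dense_J)
        return _scan_homodimer(self.E)

    def resample(self, keep):
        if self.dense_J is not None:
            self.E = np.ascontiguousarray(self.E[keep])


def evolve_population(
    model_params: ModelParams,
    evo_params: EvolutionParams,
    motif_map: MotifMap | None = None,
    coupling_seed: int | None = None,
) -> EvolutionTrajectory:
    """Run the mutation-selection dynamics; see the module docstring."""
    p, e = model_params, evo_params
    motif_map = motif_map or build_motif_map(p)
    if coupling_seed is None:
        coupling_seed = int(seed_u64(p.master_seed, "evolution_couplings", e.seed))
    table = CouplingTable(p, coupling_seed, "lazy")
    dense_J = table.dense() if p.n_motifs <= DENSE_TABLE_MAX_MOTIFS else None
    width = e.selection_width if e.selection_width is not None else p.sigma_J
    rng = stream(p.master_seed, "evolution", e.seed)
    N = e.ensemble_size

    founder_P = random_protein(p, e.n_epitopes, rng).epitopes
    pop_P = np.repeat(founder_P[None], N, axis=0)
    if e.mode == "heterodimer":
        founder_B = random_protein(p, e.n_epitopes, rng).epitopes
        pop_B = np.repeat(founder_B[None], N, axis=0)
    else:
        pop_B = None

    threshold = np.empty(e.generations)
    mean_energy = np.empty(e.generations)
    min_energy = np.empty(e.generations)
    survivors = np.empty(e.generations, dtype=np.int64)

    def encode(pop):
        return np.ascontiguousarray(motif_map.encode(pop))

    energies = _PopulationEnergies(
        table, dense_J, N, e.n_epitopes,
        e.n_epitopes if e.mode == "heterodimer" else None)
    all_changed = np.ones((N, e.n_epitopes), dtype=np.bool_)
    fresh = True  # the energy matrices have never been filled

    def current_energies(changed_P, changed_B):
        return energies.compute(
            encode(pop_P), None if pop_B is None else encode(pop_B),
            changed_P, changed_B)

    for t in range(e.generations):
        pop_P, changed_P = _mutate_batch_flagged(pop_P, e.mutation_rate,
                                                 p.alphabet_size, rng)
        changed_B = None
        if pop_B is not None:
            pop_B, changed_B = _mutate_batch_flagged(pop_B, e.mutation_rate,
                                                     p.alphabet_size, rng)
        if fresh:
            changed_P, changed_B = all_changed, all_changed
            fresh = False
        U, _, _, _ = current_energies(changed_P, changed_B)
        U0 = float(U.mean())
        alive = rng.random(N) < survival_probability(U, U0, width)
        idx = np.flatnonzero(alive)
        threshold[t] = U0
        mean_energy[t] = U0
        min_energy[t] = float(U.min())
        survivors[t] = idx.size
        if idx.size:  # zero survivors: keep the pre-selection ensemble
            keep = rng.choice(idx, size=N, replace=True)
            pop_P = pop_P[keep]
            if pop_B is not None:
                pop_B = pop_B[keep]
            energies.resample(keep)

    no_change = np.zeros((N, e.n_epitopes), dtype=np.bool_)
    U, _, _, _ = current_energies(*((all_changed, all_changed) if fresh
                                    else (no_change, no_change)))
    return EvolutionTrajectory(
        p, e, coupling_seed, threshold, mean_energy, min_energy, survivors,
        pop_P, pop_B, U)


def _best_config(trajectory: EvolutionTrajectory) -> InterfaceConfig:
    """Argmin interface of the lowest-U final member."""
    p = trajectory.model_params
    table = CouplingTable(p, trajectory.coupling_seed, "lazy")
    motif_map = build_motif_map(p)
    P, B = trajectory.best_proteins()
    if B is None:
        spec = energetics.homodimer_spectrum(P, motif_map, table)
    else:
        spec = energetics.complex_spectrum(P, B, motif_map, table)
    _, cfg = energetics.complex_binding_energy(spec)
    return cfg


def specificity_assay(
    trajectories,
    n_random_partners: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolved-partner vs random-partner binding energies.

    Sample 1: U of the best final (P, B) pair of each heterodimer trajectory.
    Sample 2: U of each such evolved protein against fresh random proteins of
    the same shape, under the *same* couplings as its own evolution.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    evolved = []
    random_partner = []
    rng = stream(seed, "specificity")
    for traj in trajectories:
        p = traj.model_params
        motif_map = build_motif_map(p)
        table = CouplingTable(p, traj.coupling_seed, "lazy")
        P, B = traj.best_proteins()
        if B is None:
            raise ValueError("specificity assay is defined for heterodimer trajectories")
        evolved.append(energetics.complex_binding_energy(
            energetics.complex_spectrum(P, B, motif_map, table))[0])
        for prot in (P, B):
            for _ in range(n_random_partners):
                R = random_protein(p, traj.evo_params.n_epitopes, rng)
                random_partner.append(energetics.complex_binding_energy(
                    energetics.complex_spectrum(prot, R, motif_map, table))[0])
    return np.asarray(evolved), np.asarray(random_partner)


def evolved_homodimer_census(
    model_params: ModelParams,
    evo_params: EvolutionParams,
    n_realizations: int,
    seed: int,
) -> CensusResult:
    """Interface census of the best evolved homodimer across realizations.

    Each realization draws a fresh founder protein and fresh couplings,
    evolves for ``evo_params.generations`` generations, and contributes the
    category of its lowest-U final member.  ``generations=0`` reduces to the
    random-homodimer census (one label per founder).
    """
    if evo_params.mode != "homodimer":
        raise ValueError("census requires homodimer mode")
    counts = {Category.ANTIPARALLEL_ISOLOGOUS: 0,
              Category.PARALLEL_ISOLOGOUS: 0,
              Category.HETEROLOGOUS: 0}
    for r in range(n_realizations):
        mp = dataclasses.replace(model_params,
                                 master_seed=int(seed_u64(seed, "census", r)) % 2**31)
        traj = evolve_population(mp, dataclasses.replace(evo_params, seed=r))
        cfg = _best_config(traj)
        counts[cfg.category] += 1
        logger.info(
            "census realization %d/%d: U=%.3f category=%s",
            r + 1, n_realizations, traj.final_energies[traj.best_index],
            cfg.category.name.lower())
    return CensusResult(
        counts[Category.ANTIPARALLEL_ISOLOGOUS],
        counts[Category.PARALLEL_ISOLOGOUS],
        counts[Category.HETEROLOGOUS],
    )
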