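# srb — Structured Random Binding

A simulator and analytics package for **Structured Random Binding (SRB)**, a
minimal statistical-physics model of protein–protein interactions. SRB is
aimed at people who study protein interaction networks, nonspecific binding
("sticky" pulldown backgrounds), or homodimer interface statistics and want a
tractable null model grounded in the physics of disordered systems rather
than in structural detail.

## The model

A peptide `p = p₁p₂…pₗ` is a string over a primary alphabet `A` (the 20
amino acids). Sliding windows of `ξ` consecutive residues — `ξ` is the
*structural correlation length* along the backbone — map bijectively onto
structural motifs, giving `p` a secondary structure of `l′ = l − ξ + 1`
motifs. A protein is a bag of `n_P` such epitopes. All energetics are carried
by a quenched random symmetric coupling table `J(m, m′)` with mean 0 and
variance `σ_J²` (Gaussian here). Two epitopes bind in register, parallel or
antiparallel:

    u↑↑(p, b) = Σᵢ J[f(p)ᵢ, f(b)ᵢ]        u↑↓(p, b) = Σᵢ J[f(p)_{l′−i+1}, f(b)ᵢ]

and a complex's binding energy is the minimum over all `n = 2 n_P n_B`
oriented epitope pairs, `U(P, B) = min u(p, b)`.

From these ingredients follow, and the package computes:

* **Nonspecific binding.** Levels are exactly `N(0, l′σ_J²)`; minima follow a
  min-Gumbel law with quantile parameters
  `μ = √(l′)σ_J Φ⁻¹(1/n)`, `β = √(l′)σ_J [Φ⁻¹(1/n) − Φ⁻¹(1/(ne))]` and mean
  `⟨U⟩_NS = μ − γβ`. Any two random proteins with enough surface bind.
* **Condensation.** The complex is an n-level random-energy system: below
  `T_c = σ_J √(l′ / 2 ln n)` the Boltzmann measure freezes onto a few
  configurations and a definite interface appears; the mean participation
  ratio approaches `⟨Y(T)⟩ = 1 − T/T_c`.
* **Affinity evolution.** Mutation–selection dynamics with a Fermi survival
  rule `Θ(U; U₀) = 1/(e^{(U−U₀)/σ_J} + 1)` and a coevolving threshold `U₀`
  (the ensemble mean) turn weak nonspecific complexes into tightly-bound,
  highly specific ones — but only when `ξ` is short.
* **Homodimer bias.** Antiparallel self-binding pairs contact `i` with
  contact `l′−i+1`, so it is twice a sum of `l′/2` couplings and carries
  **twice the variance** of any other interface. Random homodimers are ~33%
  antiparallel isologous; evolved tightly-bound homodimers are ~98%, matching
  the predominance of antiparallel isologous interfaces in real homodimers.

## Worked example

```python
import srb

params = srb.ModelParams(alphabet_size=20, peptide_length=10, xi=3, master_seed=42)

# analytic nonspecific-binding statistics for nP = nB = 20 (n = 800 levels)
gp = srb.gumbel_params(n=800, l_prime=params.l_prime)
print(gp.location, gp.scale, srb.mean_nonspecific(gp))
# -8.551300935527404 0.8221207179518452 -9.025841892369304

# simulated minima agree (10^4-realization mean is ~0.5% above the n->inf formula)
mins = srb.sample_nonspecific_minima(params, 20, 20, 5000, seed=42)
print(round(mins.mean(), 3))          # -8.978

# variance doubling of antiparallel self-binding
u_par, u_anti = srb.sample_isologous_energies(params, 50_000, seed=42)
print(round(float(u_anti.var() / u_par.var()), 3))   # 1.993

# interface census of random homodimers
census = srb.random_homodimer_census(params, 20, 2000, seed=42)
print(census.fractions)
# {'antiparallel_isologous': 0.33, 'parallel_isologous': 0.031, 'heterologous': 0.639}
```

`gp.location` and `gp.scale` are the Gumbel location and (positive) scale in
units of `σ_J`; `mean_nonspecific` is the disorder-averaged binding energy of
a nonspecific complex, and the census fractions say which interface type the
ground state of a random homodimer adopts — antiparallel isologous is ten
times more common than its 1/21 share of states would suggest.

The same computations are scriptable from the shell:

```sh
srb analytics --n 800 --l-prime 8
srb homodimer --profile smoke --out runs/homodimer
srb condense --profile full --out runs/condensation
```

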