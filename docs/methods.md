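# Methods

## Model definition

A peptide is a length-`l` string over a primary alphabet of size `|A|`; a
protein is a bag of `n_P` peptide epitopes (only surface-exposed stretches
interact, so `n_P` plays the role of surface area). The map `f` sends each
sliding `ξ`-tuple of residues to a structural motif; we identify `ξ`-tuples
with their base-`|A|` integer codes and take `f` to be the identity
permutation by default. Any bijection is statistically equivalent because the
coupling table is random; a seeded random permutation is available for
checking exactly that, and the bijectivity of `f` is what lets `|M| = |A|^ξ`.

Couplings `J(m, m′)` are symmetric, iid over unordered pairs (diagonal
included, same law), mean 0, variance `σ_J²`. We take them **Gaussian**. The
model only requires zero mean and finite variance, but the Gaussian choice
makes the level distribution `P(u) = N(0, l′σ_J²)` exact at every `l′`
rather than only as `l′ → ∞`, which in turn makes the extreme-value and
condensation analytics exact statements about the simulated system. Units:
`k_B = 1`, `σ_J = 1` by default; energies and temperatures are reported in
units of `σ_J`.

## Deterministic lazy couplings

At `|A| = 4, ξ = 7` the motif alphabet has 16384 entries and a dense table
would hold ~2.7×10⁸ couplings, so the table is generated lazily: the value
for unordered pair `(m, m′)` is `σ_J` times a standard normal deviate
produced by a counter-based hash of `(coupling_seed, min·|M| + max)`. The
hash is the splitmix64 finalizer evaluated at that counter; the uniform is
mapped to a normal with the inverse normal CDF. Table lookups and batch
samplers use `scipy.special.ndtri` (vectorized), so the lazy and
materialized storage modes agree bit for bit; the jitted simulation kernels
that hash couplings on the fly evaluate the same transform through an
in-package AS241 implementation (Wichura's double-precision algorithm,
needed because scipy is not callable from numba), which agrees with scipy to
~1e-15 and is tested against it. A materialized table is simply the lazy
generator evaluated on every pair and is allowed up to `|M| = 8192`
(~537 MB).

All other randomness flows from named streams (`numpy` `SeedSequence` with a
spawn key hashed from the stream name), so identical configurations give
identical outputs on any platform.

## Spectra and the homodimer state space

A heterodimer spectrum enumerates all `n_P n_B` epitope pairs in both
orientations: `n = 2 n_P n_B` levels. For a homodimer, exchanging the two
epitope roles gives the same energy (a consequence of `J`'s symmetry), so
ordered enumeration would double-count: we count unordered distinct pairs
once per orientation plus two isologous states (parallel and antiparallel
self-binding) per epitope — `n_P(n_P − 1) + 2 n_P` levels, 420 at
`n_P = 20`. This convention is validated empirically: it reproduces the
random-census fractions 33% / 3.3% / 63.7% (and 3.3 ≈ 67 × 20/400,
63.7 ≈ 67 × 380/400). Argmin ties are broken lexicographically on
(epitope_i, epitope_j, orientation); ties have measure zero under continuous
couplings and the rule exists purely for reproducibility.

For odd `l′` the antiparallel self-interaction pairs the middle motif with
itself once, giving `Var[u↑↓(p,p)] = (2l′ − 1)σ_J²` instead of the even-`l′`
doubling `2l′σ_J²`; this is covered by a dedicated test.

## Alphabet size in the random-complex statistics

The variance-doubling argument treats the `l′` contacts of an interface as
distinct random variables. On a small alphabet that premise degrades:
sliding-window motifs repeat within a single random peptide with probability
`~C(l′,2)/|M|` per pair, and a repeated motif makes two contacts share one
diagonal coupling. At `|A| = 4` (`|M| = 64`, `l′ = 8`) this inflates
`Var[u↑↑(p,p)]` from 8 to ≈ 8.9 `σ_J²`, pushing the antiparallel/parallel
variance ratio to ≈ 1.81 and the random census to ≈ 32/4.7/63. At
`|A| = 20` (`|M| = 8000`) repeats are negligible: the ratio is 2.00 and the
census is 33.5/3.3/63.1, matching the printed statistics. The same holds
after evolution: with the antiparallel variance advantage diluted, ~10% of
4-letter realizations lock into deep parallel-isologous or heterologous
optima (evolved census ≈ 90% antiparallel), while at `|A| = 20` the evolved
census is ≈ 98–100% antiparallel. We therefore run all homodimer statistics
— censuses (random and evolved), Gumbel minima, condensation averages — on
the general 20-letter alphabet, and reserve the reduced 4-letter alphabet
for the heterodimer `ξ`-sweep, where it keeps the motif alphabet tractable
at `ξ = 7` (`|M| = 16384`). The small-alphabet discrepancy is a real feature
of the model worth knowing about, not an implementation artifact.

## Extreme-value analytics and their finite-n accuracy

The min-Gumbel parameters are quantile-matched: `μ` is the Gaussian
lower-tail quantile at probability `1/n` and `μ − β` the quantile at
`1/(ne)` (so the printed scale `ϕ = −β` is negative; we store the positive
scale and expose `ϕ` for reporting). Densities, CDFs and goodness-of-fit
tests go through `scipy.stats.gumbel_l` and `scipy.stats.norm`.

These are `n → ∞` limits with O(1/log n) corrections, and Gaussian extremes
converge notoriously slowly. Concretely, at `n = 800, l′ = 8` the asymptotic
mean `μ − γβ = −9.026` while the exact mean of the minimum of 800 iid
`N(0, 8)` draws is −8.985 (quadrature) and the simulated model mean is
−8.980 ± 0.003: a systematic ~0.5% bias that is ~4.5 standard errors at 10⁴
realizations. The distribution shape is much better behaved (KS distance
≈ 0.015–0.017). The corresponding acceptance test asserts the stated 2-SE
band and is expected to fail on the mean sub-check; we keep the assertion
honest rather than widen it, since it documents the convergence rate of the
asymptotic formula.

Similarly, the REM participation ratio converges as O(1/log n): at
`n = 80000` the measured `⟨Y⟩` deviates from `1 − T/T_c` by ≈ 0.02, 0.05 and
0.09 at `T/T_c = 0.2, 0.5, 0.8` (even ideal iid Gaussian levels give ≈ 0.08
at 0.8). The worst-case deviation over that temperature grid does decrease
monotonically through `n = 800, 7200, 80000` (pointwise deviations of
~0.01–0.02 sit inside Monte-Carlo noise at 200 realizations); the < 0.05
band is met at `T/T_c ≤ 0.5` but not at 0.8, and the corresponding test
asserts the full band rather than a loosened one.

## Thermodynamics

`Y(T)` is evaluated as `exp(lse(−2u/T) − 2·lse(−u/T))` with
`scipy.special.logsumexp`; this equals the naive ratio wherever the naive
sums do not overflow (checked to 1e-10 relative) and is exact under the
energy shift. `T = 0` is excluded from `Y(T)` and exposed separately as the
ground-state degeneracy limit `1/k`. Melting curves use a default grid of 64
uniform points on `T/T_c ∈ [0.05, 2]`; the melting temperature is the
discrete argmax of `−dY/dT` (central differences, no interpolation), and is
reported as absent for flat curves. For homodimers the `n` entering `T_c` is
the homodimer spectrum size `n_P(n_P−1) + 2n_P`.

## Evolution protocol

Populations hold N = 1000 members, each a full complex (two proteins in
heterodimer mode, one in homodimer mode), founded as identical copies of one
random complex. Per generation: (1) every residue mutates independently at
rate ε = 0.01, substitutions drawn uniformly from the other `|A| − 1`
letters; (2) each member's U is recomputed as its spectrum minimum;
(3) `U₀` is set to the post-mutation, pre-selection ensemble mean — the
reading of a threshold that "coevolves to maintain selection pressure";
(4) survival is Bernoulli with the Fermi probability of width `σ_J`;
(5) survivors are resampled uniformly with replacement back to N
(Wright–Fisher style — the repopulation scheme is not dictated by the model;
this choice keeps the ensemble size constant). A zero-survivor generation
keeps the pre-selection ensemble; at N = 1000 this is vanishingly rare. All
three conventions are exposed as parameters.

The per-generation energy evaluation is incremental: each member carries its
full pair-energy matrix (20 × 20 × 2 orientations), and after mutation only
the rows/columns of epitopes whose sequence changed (~2 of 20 per member per
generation at ε = 0.01) are recomputed by a numba kernel; resampling copies
matrices. This is exact — energies depend only on epitope sequences — and is
verified against the full spectrum route in the tests. For motif alphabets
up to 8192 the kernel reads a dense hashed table; beyond that (`ξ = 7`) the
full spectrum is rehashed lazily each generation. One realization of 1000
generations at N = 300, `|M| = 8000` runs in ~9 s on one CPU.

Individual heterodimer trajectories descend rapidly for ~100 generations and
then plateau at realization-specific record levels (further improvement
requires ever-rarer record events, and soft mean-referenced selection lets
drift slowly erode the best genotype). The slow aging signature — a
log(t) decrease at late times — lives in the doubly-averaged trajectory
`⟨⟨U⟩⟩(t)` (ensemble × realizations): averaged over 8–10 realizations at
N = 1000 the late-time fit to `a + b log t` gives `b ≈ −0.2…−0.6` with
correlation beyond −0.93. The qualitative checks therefore use the
realization-averaged statistic.

The evolved-homodimer census runs independent realizations (fresh founder
and couplings each), evolves each for 1000 generations, and classifies the
argmin interface of the lowest-U final member — one label per realization,
matching per-complex reporting. The census population size is not dictated
by the model; we use N = 300, which reaches the same tightly-bound optima as
N = 1000 in pilot runs (final U ≈ −19 to −23 vs ≈ −19 to −25) at a third of
the cost, and expose it as a parameter. The specificity assay compares the evolved
partners' U against the same proteins paired with fresh random proteins
under the same couplings; the latter sample is statistically
indistinguishable from the nonspecific minima law.

## Problem sizes used in the shipped checks

The quantitative reproductions use 10⁴ realizations for the random census
and the Gumbel fit, 10⁵ samples for variance ratios, 200 realizations per
`n` for condensation averages, and 50 realizations × 1000 generations
(population 300) for the evolved census; the `ξ`-sweep reproduction is
checked qualitatively at
reduced scale (N = 300, 300 generations) plus a 1000-generation log-trend
fit at `ξ = 3`. The experiment runners additionally expose a `full`
profile with the complete headline grids (`l′ ∈ {2,6,10,14,18}`,
`n ∈ {8,72,800,7200,80000}`, `ξ ∈ {2,…,7}`) and a `smoke` profile for quick
orientation; realization counts are parameters throughout, and the
`full`-profile `ξ`-sweep defaults to 10 disorder realizations per `ξ` to
stay desk-scale.

## What the generator does and does not emulate

Synthetic proteins are bags of iid uniform random epitopes; couplings are
iid Gaussians. This captures exactly the statistical structure the model
analyses — extreme-value binding, freezing, evolvability, interface bias —
and nothing else: no amino-acid chemistry, no 3-D geometry or off-register
alignments, no conformational entropy, no correlated composition of real
sequences. Passing tests therefore validate the statistical physics of the
model, not quantitative predictions for any particular real protein pair.

## Known limitations

* The asymptotic Gumbel mean and the REM participation limit carry O(1/log n)
  corrections that the package reports but does not resum (see above).
* Motif-repeat effects make small-alphabet censuses deviate from the
  large-alphabet statistics; both regimes are simulable, only the
  large-alphabet one matches the headline fractions.
* The evolution dynamics expose mutation, selection and resampling choices as
  parameters but implement no recombination and no fitness function beyond
  the Fermi rule.
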