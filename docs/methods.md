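# Methods

## The model

`biomeshift` models how species gain and lose *established* and *enabled*
affinities for a set of B discrete biomes along a time-calibrated
phylogeny.  Per biome, a species is coded 0 (non-affinity), 1 (enabled: the
biome lies within the species' fundamental niche but is unoccupied) or 2
(established: occupied and persisting, the realized-niche analogue).  A
valid affinity-set state is any length-B code vector containing at least
one 2 — an extant species must persist somewhere — giving `3^B − 2^B`
states (5 for two biomes, 19 for three).  Established affinities are
treated as a subset of enabled ones: code 2 implies suitability, so there
is no separate "established but not enabled" level.

### Anagenesis

Along a branch, single-biome events occur at five rates: enabled gain
`g01` (0→1), established gain `g12` (1→2), "lock-step" double gain `g02`
(0→2, the rapid adapt-while-colonizing path), established loss `l21`
(2→1) and enabled loss `l10` (1→0).  Double losses (2→0) are forbidden —
losing occupancy does not instantly erase suitability — and any event that
would remove the last established affinity has no destination state and
simply cannot occur.  These rules define a sparse generator Q over the
state space; finite-time transition probabilities are `expm(Q t)`.

Rates are in events per unit tree height.  Analyses rescale the input tree
to height 1 (`Phylogeny.rescaled`), matching the prior scale convention.

### Cladogenesis

At a speciation node the parental established set is inherited under one
of three scenarios with probabilities `pe + ps + pb = 1`:

* **equal** — both daughters copy the parent (1 outcome);
* **subset** — one daughter keeps the full established set, the other a
  proper non-empty subset (`2^(n+2) − 8` outcomes for n established
  biomes, counting daughter order and reduction mode);
* **split** — the established set is divided into two disjoint non-empty
  parts (`2^(n+1) − 4` outcomes).

Established biomes a daughter does not inherit all reduce together either
to enabled (code 1; divergence unrelated to suitability, e.g. geographic)
or to non-affinity (code 0; ecological divergence).  The reduction mode is
one choice per event, not per biome — only this reading reproduces the
closed-form outcome counts above, which the tests confirm by brute-force
enumeration.  Enabled-only biomes (code 1) pass unchanged to both
daughters in every scenario, consistent with the worked single-established
example, where the parent's state (including its enabled biomes) is copied
identically with probability 1.  Outcomes within a scenario are equally
likely, giving the sparse tensor P(i; j, k), normalized per parent and
symmetric under daughter exchange.

### Likelihood

Tip data enter as 0/1 masks over the state space (see *Tip coding*).
Pruning proceeds postorder: child partials pass through `expm(Q t)` along
branches and combine at nodes through P; the root partial is dotted with
the root state frequencies.  The root defaults to uniform over the valid
states — the least informative choice, recorded in run headers — with a
user-supplied vector as the alternative; no extra cladogenetic event is
imposed at the root beyond the standard combine.  Partials are rescaled at
every internal node with log-scale accumulation, so 500-tip trees do not
underflow (verified against unscaled computation on small trees, and
against full enumeration over all node/corner/tip states on 3- and 4-tip
trees).  Zero-length branches use the identity matrix.  The machinery is
generic over (space, Q, P), so the binary baseline reuses it.

`expm` is evaluated through a one-time eigendecomposition of Q reused
across all branches of the tree; the eigenbasis residual `|V V⁻¹ − I|` is
checked against 1e-9 and the code falls back to scipy's
scaling-and-squaring per branch if the basis is ill-conditioned.  Row-sum
and normalization checks use 1e-10..1e-12 absolute tolerances; tiny
negative entries from the reconstruction are clipped to 0.

### Tip coding and ambiguity

Established affinities are observable; unestablished biomes are ambiguous
between enabled and non-affinity.  The worst-case coding admits every
state matching the observed established pattern with unestablished biomes
free over {0, 1} (a species established in one of three biomes gets the
four states 211/210/201/200, all equally likely).  Constraints shrink the
set: *includes* force a biome to exactly code 1 at unestablished biomes —
evidence such as garden survival demonstrates suitability, not occupancy —
*excludes* force code 0 and may never touch an observed established biome,
and the *climatic adjacency* rule drops states in which two established
biomes flank a non-affinity along a declared environmental gradient.  By
default the rule triggers only on established flanks (the documented
empirical usage); a switch extends it to enabled flanks.  Adjacency
filters tip ambiguity sets only — it does not alter the state space or Q,
which would change the process itself.  Masks are hard 0/1 indicators;
all admitted states share one likelihood weight.

### Inference

The five rates carry a shared Exponential(β) prior (β in events per unit
tree height); `ps, pb ~ Uniform(0,1)` with `pe = 1 − ps − pb` and zero
density off the simplex.  Sampling is Metropolis–Hastings with a
univariate multiplier proposal `x′ = x e^{λu}`, `u ~ U(−0.5, 0.5)`
(Hastings correction `log x′/x`), swept deterministically over the seven
free parameters each iteration; off-simplex clado proposals die on the
zero prior.  Rates are initialized from the prior and `ps = pb = 1/3`;
burn-in defaults to 10% (reported, configurable).  Default tunings are
λ = 1.5 for rates and 0.2 for clado probabilities — the long-chain
configuration — but the bundled scaled-down experiments raise λ_clado to
1.0–2.0 so that short chains reach the ESS ≥ 200 retention bar; with
±10% multiplier steps the clado simplex takes hundreds of iterations to
traverse, which only half-million-iteration chains can afford.

HPD intervals are the shortest contiguous window of sorted samples holding
⌈mass·n⌉ draws (ties → lowest start).  ESS uses Geyer's
initial-positive-sequence truncation, `n / (1 + 2 Σ ρ_k)` with the sum cut
at the first non-positive adjacent-lag pair, capped at n so antithetic
chains never report super-efficiency.  Chains with any parameter below
ESS 200 are *flagged*, not silently dropped; experiment tables carry the
flag per replicate.

### Ancestral states

Joint histories (state at every node before cladogenesis, and at every
branch start — "corner" — after it) are drawn by backward filtering /
forward sampling at the current parameters: root ∝ π·D, corner pairs ∝
P(i; j,k)·F_left(j)·F_right(k), child node states ∝ expm(Q t)·D.  Draws
are taken every `history_every` iterations after burn-in (the cadence is
configurable; full-scale analyses use every 100 steps).  Sampled states
are marginalized per biome into affinity-type probabilities (p0, p1, p2
summing to 1 per location and biome).  Accuracy for a type is the mean
posterior probability assigned to the true type over all (location, biome)
cells where the truth has that type; the chance-level null baseline is the
pooled mean probability assigned to the type across all cells of all
replicate posteriors, which corrects for the baseline advantage a 2-level
model (1-in-2 guessing) holds over a 3-level one (1-in-3).

### The binary baseline

The comparison model is DEC-like: presence/absence per biome over the
`2^B − 1` non-empty subsets (the empty range is excluded, mirroring the
at-least-one-established convention), two anagenetic rates (gain, loss;
losing the last presence is forbidden), and the same three cladogenetic
scenarios acting on presence sets (subset: `2(2^n − 2)` outcomes; split:
`2^n − 2`).  The structure deliberately mirrors the full model so the
comparison isolates the value of the enabled tier rather than unrelated
modeling choices.  Input is the recoding 2 → presence, {0,1} → absence,
which collapses all worst-case ambiguity into singletons.

## Simulation and experiment design

Trees are pure-birth (Yule) with the required tip count, rescaled to unit
height; the tree process behind the published experiments is unreported,
so tree-dependent results are treated as properties, not numeric
reproductions.  Character histories are simulated by Gillespie's algorithm
along branches (competing exponentials over the current state's allowed
events) with tensor draws at nodes; single-branch marginals are verified
against `expm` rows and node-event frequencies against (pe, ps, pb).

Generating parameters are drawn from the same priors used in inference
(rates Exponential(β), clado uniform on the simplex), which is what makes
HPD coverage a calibration check: 95% HPDs must cover truth for ~95% of
replicates regardless of the observation process.  Ambiguity treatments
start from worst-case coding and remove `ceil(f × n_non_true)` non-true
states for a treated fraction of tips, f ∈ {0, 1/3, 2/3, 1} (on a 4-state
worst case, 1/3 removes one state and 2/3 removes two; f = 1 confirms the
single true state).  The truth is never removed.

The bundled experiment scales are desk-scale versions of the full designs
(which use 100 replicates, 500k iterations and up to 500 tips):

* coverage — 20 replicates, 50 tips, B = 2, β = 1.0, 14k iterations;
  the pass bound is the exact one-sided binomial(n_retained, 0.95) 0.001
  quantile, e.g. ≥ 15/20;
* ancestral accuracy — 20 replicates, 150 tips, B = 3, β = 1.0,
  entirely-confirmed tips, histories every 25 iterations;
* ambiguity sensitivity — 20 paired replicates (same data per treatment),
  100 tips, B = 3, treatments entirely-confirmed / 66% @ 75% / entirely
  ambiguous;
* baseline comparison — 20 replicates, 50 tips, B = 3, both models on the
  same simulated data (full model on masked states, baseline on recoded).

## What the simulations do and do not show

The generator emulates the model's own data-generating process on clean
ultrametric trees with exact established observations.  Passing tests
demonstrate internal consistency (correct likelihood, calibrated
uncertainty, recoverable ancestral states) — they do not certify
performance on real data with phylogenetic error, detection error in
established affinities, non-Yule trees, or misspecified biome
discretizations.  The climatic-adjacency rule is a tip-data filter whose
biological validity rests with the user.

A consequence of drawing cladogenetic probabilities from the flat simplex
prior is that roughly two thirds of speciation events carry subset- or
split-inheritance, each of which re-randomizes the affinity tier of
non-inherited established biomes.  Deep-node reconstruction of the
enabled and non-affinity tiers is therefore intrinsically less certain
than reconstruction of established affinities or of the collapsed
occupied-vs-unoccupied distinction, and the per-type accuracy tables the
experiments emit show exactly that ordering.

## Known limitations

* State count grows as `3^B − 2^B`; dense expm is comfortable to B ≈ 5,
  beyond which data-augmentation samplers would be needed.
* No diversification feedback (no state-dependent speciation/extinction),
  no time-varying biome availability, no geographic structure.
* Tip priors are hard 0/1 masks; no soft probabilistic tip weights.
* Single-chain MH with fixed tunings; no adaptation or tempering.
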