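# Methods

This note documents the models, numerical choices and design decisions
behind `mablwe`, and states what the toy-system validations do and do not
show about real molecular systems.

## The weighted-ensemble loop

One iteration is: propagate every walker by τ → (optionally recycle walkers
that reached the target state back to the source, recording their weight as
flux) → score → resample → conservation check. Total weight is asserted to
be 1 within 1e-12 after every propagation and every resampling step; a
violation aborts the run with the iteration index. A single seeded
`numpy.random.Generator` drives all stochastic choices in a fixed order
(propagation noise first, then merge-survivor draws), so a run is
bit-reproducible given (config, seed). Parallelism is represented by
vectorized propagation, not concurrency.

Weights are double-precision reals. Exact rational arithmetic would make
conservation literally exact but is far too slow for ensembles of hundreds
of walkers over hundreds of iterations; the 1e-12 tolerance is ~4 orders of
magnitude above accumulated rounding in practice (observed drift is at the
1e-16 level).

Splitting divides a walker's weight as `w/k` per child, with the last child
assigned `w − (k−1)(w/k)` so the children sum to the parent bit-exactly;
for the default k = 2 both children are identical halves. Merging draws the
survivor with probability proportional to weight; the survivor keeps its
own coordinates and payload and inherits the summed weight. Every resampler
in the package is built from these two primitives only, which is why the
unbiasedness tests hold for all of them.

## The progress score

`S = [Π_m C_m · progress_m] · balance(P) · Π(region factors)` with
`progress_m = 1 − |q_m − q_t| / |q_i − q_t|`, clamped to [0, 1] by default
(overshoot past the target or backtracking behind the start would otherwise
take the score outside its ranking scale; clamping also gives the clean
identity S = 0 exactly when some coordinate sits at, or behind, its initial
value). Since all C_m enter multiplicatively, they rescale every walker's
score identically and never change the rank order; they matter only if a
downstream consumer uses score magnitudes.

Two renderings of the weight-balance term circulate: the literal
`(1 − ln P)` and the reciprocal `1/(−ln P)`. They behave oppositely: the
literal form *grows* as weight shrinks, favoring low-weight walkers for
further splitting, while the reciprocal form shrinks — which is the
behavior a soft threshold must have (low-weight walkers less favored for
splitting, more favored for merging). The reciprocal is the default;
the literal form is kept as `balance: one_minus_log` for comparison, and
`none` disables the term. `1/(−ln P)` diverges at P = 1 — the state of
every walker ensemble at iteration 0 — so it is capped at
`balance_cap = 1e3`; any finite cap ≫ 1 gives identical rankings because
all P = 1 walkers tie anyway.

Region scalings are windows `(lo, hi, factor)` on a coordinate; while the
coordinate's value lies in the closed window the walker's *whole* score is
multiplied by the factor. Applying the factor to the whole score rather
than to one term is equivalent for a single window (the score is a product)
and composes predictably when windows on different coordinates overlap.

Score definitions may be changed mid-run (`update_spec`): the score only
ranks walkers and never touches weights, so re-targeting a coordinate or
adding a window alters future split/merge choices but cannot bias the
ensemble statistics. The run record logs the iteration of each change.

## Resamplers

**Binless (MABL).** Rank all walkers by score (descending; ties broken by
descending weight then ascending id, so reruns are deterministic), split
the top N in two, remove N by merging. The removal policy is `absorb_up`:
each bottom-N walker merges with the lowest-ranked not-yet-consumed walker
above the bottom-N cutoff, never a split walker; when that pool is empty
(count = 2N) the remaining bottom walkers chain onto the previous merge
group. This preserves the count for every valid (count, N), including the
5-walker / N = 2 teaching shape where only one above-cutoff partner exists.
`pairwise_bottom` (merge the bottom 2N pairwise) is available when
3N ≤ count.

**MAB.** Per dimension: find the lagging and leading edges of sampled
progress (direction-aware), space `nbins` equal-width bins between them,
give the edge walkers dedicated bins, and, when enabled, give a dedicated
bin to the *bottleneck* walker — the max-weight walker sitting just before
the steepest increase of −ln(weight) between adjacent occupied bins along
the progress direction. The layout is recomputed every iteration. With all
walkers at one point the layout degenerates to a single bin.

**Multi-MAB.** A user-defined outer grid (half-open cells `[lo, hi)`, ±inf
boundaries allowed) with an independent MAB scheme nested in each used
cell, registered by a placement key — a coordinate vector inside the cell.
A walker in a cell with no registered scheme is a configuration error: the
outer grid is part of the model of the system, and silently inventing a
scheme would hide a mis-specified grid.

**Fixed bins.** A static grid; every occupied bin is brought to a target
count by splitting largest-weight walkers first (halving the largest weight
reduces weight variance fastest) or merging the two smallest-weight walkers
repeatedly. Per-bin weight is conserved exactly, hence also globally.

**Rule-violating mode.** Identical to the binless resampler except the
merge survivor is the highest-score candidate instead of a
weight-proportional draw. This breaks the second statistical rule of WE
resampling and is included purely as a negative control; it refuses to run
without `allow_biased: true`. On the double-well toy it reproduces the
characteristic pathology: the entire weight of the ensemble arrives at the
product state with no weight decay across the barrier, whereas correct
resampling leaves the maximum walker weight near the target orders of
magnitude below the source-side weights.

## Toy systems and oracles

**Markov chain.** Payload is the state index; one iteration is one chain
step by default, so the exact ensemble distribution after n iterations is
`p0 · T^n` and mean first-passage times come from the fundamental matrix
`N = (I − Q)^{-1}`. The default 3-state chain (stay probability 0.9/0.8/0.9,
nearest-neighbor hopping 0.1) has MFPT(0→2) = 30 steps, solvable by hand.
Used to test unbiasedness of every resampler (200 replicates, 3 SE), the
failure of the violating mode (>5 SE), and rate recovery through recycling.

**1-D double well.** Overdamped Langevin dynamics in
`U(x) = h (x² − 1)² + tilt·x`, Euler–Maruyama with kT = 1, friction 1,
dt = 1e-3, 10 steps per τ. The barrierless limit is free diffusion
(MSD = 2Dt) and a long unresampled run at moderate temperature reproduces
the Boltzmann ratio of the tilted wells (checked against numerical
quadrature of e^{−U}). At h = 8 kT a single unresampled trajectory does
not cross in 1e4 steps while the WE run crosses in a few dozen iterations —
the premise of the whole strategy. dt = 1e-3 keeps the Euler–Maruyama
discretization error negligible against the 5 % test tolerances (the
stiffest force in these tests is ~32 at h = 8, giving per-step drift ≪ σ).

**Surrogate unbinding (2-D).** A desk-scale stand-in for charged-ligand
unbinding, built so the three lessons the score machinery embodies are
exercised without MD:

* coordinate `d` ("distance-like"): shallow bound well at d = 1.5
  (k = 0.05), Gaussian barrier of 6 kT at d = 5.2 (width 1.2), unbound at
  d ≥ 8;
* coordinate `r` ("rmsd-like"): a *bistable channel*, blended smoothly as a
  log-sum of two Gaussian valleys — the main track `r = 2.8 d` (k = 1.0)
  and a corridor at `r = 9.6` (k = 1.5) that exists only for d ≥ 3.8 and
  sits 1.5 kT above the track;
* an exit block of 12 kT that seals the barrier passage for r above 10
  (saturating in r so it exerts no force on states far above the onset).

Because the track has climbed to r ≈ 11–13 by the time it reaches the
barrier, walkers that follow apparent rmsd progress pile up in a crowd of
encounter-complex-like states pressed against the closed gate — inside the
score's 10–13 region-scaling window — and the only way over the barrier is
the corridor, reached by *backward* motion along r. The derived third
coordinate ("energy-like") is a smooth function of d running from +350 at
contact to −200 when unbound, with a +250 repulsive bump just before the
exit, so the weighted histogram over (energy, distance) shows mass at
positive energies immediately before unbinding. An earlier design realized
the trap as a Gaussian basin beside the channel, but walkers either crossed
before the basin engaged or escaped it by transient fluctuations; the
paper-like phenomenology (trapping at high rmsd, essential backward motion)
requires the off-pathway state to be metastable *and* the backward
excursion to lead into a second metastable valley, which the bistable
channel provides.

The recommended score for this system uses the ranges rmsd 0→25, energy
350→−200, distance 0→10 and the 0.8 window on rmsd ∈ [10, 13]. The energy
range is taken literally (initial +350, target −200) even though a strongly
positive bound-state interaction energy is physically unusual; here it is
simply a monotone observable of separation. States: bound (distance ≤ 2),
encounter (rmsd ∈ [10, 13] and distance ≤ 6), unbound (distance ≥ 8);
interval conditions are closed on the state side.

## Efficiency comparisons and their limits

The efficiency currency is the *first-event aggregate time*: Σ over
iterations up to and including the first arrival in the target state of
(walker count × τ). Every propagated walker-τ is counted from iteration 1,
whether or not it belongs to the successful lineage — this is the total
sampling cost of producing the first event. Runs that never produce an
event are scored at their full budget (a censored value), which makes
median comparisons conservative.

The shipped comparison (40 walkers, N = 5, τ = 1, 400 iterations, 20 paired
seeds) pits the binless resampler against (a) a fixed-bin baseline binning
all three score coordinates (rmsd at 2.5-unit resolution up to 13, energy
at 25-unit resolution, distance at 1-unit resolution, 4 walkers per
occupied bin) and (b) the identical binless run without the 0.8 window.
The fixed-bin comparison is robust: even, non-adaptive coverage of a
three-coordinate space costs hundreds of walkers per iteration, and the
binless run reaches the unbound state at roughly half the median aggregate
cost across every seed block we examined. The window comparison is
directional but *modest and high-variance*: the balance term is log-flat in
weight, so a 0.8 score de-emphasis is compensated by roughly one extra
weight-halving of split rotation, bounding the window's rank leverage at
~1.25× and its median effect at the tens-of-percent level on this system.
On desk-scale toys the soft weight threshold thus substitutes for much of
the window's role; the window's decisive effects belong to systems with
much larger score gaps between trapped and productive states than a smooth
2-D landscape can sustain.

These toys validate the *statistical machinery* — conservation, survivor
statistics, unbiasedness, rate recovery, count invariance — exactly. They
do not emulate high-dimensional metastability, force-field realism,
correlated coordinate noise, or the cost structure of real MD, so efficiency
magnitudes measured here say nothing quantitative about molecular systems.

## Rates and recycling

With recycling on, walkers arriving in the target state are reset to the
source configuration keeping their weight, and the recycled weight per
iteration is the flux into the target; at steady state flux = 1/MFPT (the
Hill relation). `flux_rate_estimate` reports the post-burn-in mean flux per
unit time with a block-bootstrap standard error (blocks of 10 iterations,
1000 resamples) to respect serial correlation. On the 3-state chain a
600-iteration run with 100 iterations of burn-in recovers 1/MFPT within
10 %; on the 2-state symmetric chain the closed-form rate lies within the
bootstrap error. Rate machinery is validated on chains only — the
surrogate-unbinding runs here are transient, far from the steady state a
flux estimate requires, so no rate is quoted for them.

## Archive format

HDF5, schema-versioned: `/meta` (seed, τ, coordinate names, config JSON,
logged score-spec changes), `/iterations/<k>/{ids, parents, weights,
coords, scores}` with resampling events as JSON attributes, `/flux`.
Parents refer to walker ids of the previous iteration, so any walker's
lineage traces back to iteration 0 through exactly one chain; the lineage
graph is a forest rooted at the initial walkers. Reads of newer schema
versions fail loudly; a truncated archive (killed mid-write) is recovered
up to the last complete iteration and flagged.

## Degenerate inputs and tie-breaks

All-identical positions give a MAB layout of one bin; values exactly on a
bin boundary go to the upper half-open cell; values exactly on a state
boundary are inside the state; equal scores rank by descending weight then
ascending id; merge groups of equal-weight walkers pick the survivor
uniformly (the weight-proportional rule's degenerate case). Log-probability
histogram output floors at 1e-300 before taking log10.
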