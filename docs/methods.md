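# Methods

## The penalized-likelihood model

A rooted phylogram supplies branch lengths `b_k` in expected
substitutions per site; multiplying by the alignment length `L` gives the
expected substitution count `x_k = b_k·L`, kept real-valued (no
rounding). Node ages `t` (Ma; extant tips fixed at 0) and per-branch
rates `r_k` are estimated by maximizing

    F(t, r) = Σ_k [ x_k·ln(r_k·t_k) − r_k·t_k ] − λ·Φ(r)

where `t_k` is the duration of branch `k` under the candidate ages, the
`ln x_k!` term of the Poisson log-likelihood is dropped (constant in the
parameters), and the additive penalty is

    Φ(r) = Σ_{k : parent edge j} (r_j − r_k)²  +  s²(rates of the root's
                                                   child edges)

with `s²` the sample variance (for a bifurcating root,
`(r_1 − r_2)²/2`). Branches with `t_k = 0` are handled with a duration
floor of 1e-6 Myr (configurable), which leaves a branch with `x_k = 0`
contributing essentially nothing and prevents log singularities.

**Rate scale.** Inside the objective, rates live on the substitution-count
scale (counts/Myr): the stationarity condition of the Poisson term is
`r_k = x_k/t_k`. This is the scale on which the conventional half-decade
smoothing grid `10⁻² … 10⁶` actually interpolates between free per-branch
rates and an enforced clock for kilobase-to-megabase alignments, and it
makes the fit exactly invariant under trading branch-length scale against
alignment length (`b → c·b`, `L → L/c` leaves every `x_k`, hence the fit,
unchanged). Rates annotated on the output chronogram are divided by `L`,
i.e. reported in substitutions/site/Myr.

## Constraints and parameterization

Calibrations are (taxon set, min age, max age) triples resolved to nodes
by MRCA. Minimum ages are propagated rootward (a node can never be
younger than the oldest minimum in its subtree), infeasibility is
rejected, and the root must carry a finite maximum — without one the age
scale is unbounded.

Ordered ages are enforced by construction: each internal node's age is
encoded as a proportion `p ∈ [0,1]` of its feasible window
`[floor, min(parent age, calibration max)]`, the root's over
`[floor, root max]`. Every constraint becomes a box constraint, and
L-BFGS-B (with analytic gradients back-propagated through the nested
windows, JIT-compiled with numba when available) solves the problem.
Rates are optimized as logs, bounded in `[e⁻³⁵, e⁸]` counts/Myr.

Initialization: the root at the midpoint of its window; other ages by
path-length interpolation down the phylogram; all rates at the tree-wide
clock value `Σx / Σt`. Five restarts by default: the deterministic start
plus seed-controlled perturbations. Perturbations of the rate block
shrink as `(1+λ)^(-1/4)`: at heavy smoothing the optimum rates differ by
`O(1/λ)`, and large random rate offsets would strand restarts on penalty
barriers they cannot descend within the iteration budget. Each restart is
finished by up to three "polish" re-runs from its endpoint (restarting
L-BFGS-B resets the Hessian approximation and tightens the attainable
precision). Convergence uses a relative objective tolerance of 1e-10 on
the objective normalized by `1 + Σx`.

Passing a warm start is supported and used heavily: sweeps and
cross-validation walk the λ grid by continuation, which reliably finds
basins that fresh starts miss at high smoothing.

## Gradient check

A fit passes when (a) the projected-gradient ∞-norm at the solution is
below `3·10⁻⁴·√(1+λ)` on the normalized scale — penalty curvature grows
with λ, which bounds the gradient precision attainable under a fixed
relative-objective stopping rule — and (b) no restart reaches a
near-best objective (relative 1e-6) while ending at a different age
vector (1% of the root age). The latter is the operational ridge
detector: at weak smoothing, rate/age trade-offs produce equal objectives
at ages tens of Myr apart, exactly what this catches. Restarts trapped in
clearly inferior local optima do not contradict a converged best solution
and are ignored; requiring two independent hits on the best basin instead
would fail routinely at high λ, where only continuation finds it.

## Cross-validation

For each λ and each terminal branch `j`: prune `j` (merging the resulting
unifurcation's edge lengths), refit, and predict
`x̂_j = r̂ · t̂_j · L`, where `r̂` is the refit rate on the edge at the
attachment point and `t̂_j` the attachment age. When the pruned tip's
parent node was suppressed into a merged edge, the attachment age is
interpolated along that edge in proportion to the two observed branch
lengths — without this, cherry tips are systematically over-predicted.
The score is `CV(λ) = Σ_j (x_j − x̂_j)²/x̂_j`; the optimum is the
minimum-score λ among those passing the gradient check. Pruned refits are
warm-started from the previous λ's solution (one restart each); full-tree
fits per λ use three restarts.

## Branch lengths on a fixed topology

`log_likelihood` implements Felsenstein pruning under GTR+G+I: GTR
exchangeabilities (GT fixed at 1), empirical base frequencies, four
equal-probability discrete gamma categories represented by their means,
and an invariant-site class whose contribution sums stationary
frequencies over the states compatible with every sequence. Site patterns
are compressed; ambiguity codes enter as indicator vectors over their
compatible states. `fit_branch_lengths` interleaves per-edge Brent
optimization (using inner/outer partial caching so each edge evaluation
is O(patterns)) with bounded quasi-Newton on (log exchangeabilities,
log α, logit p_inv), to a relative log-likelihood tolerance of 1e-6;
lengths are bounded in [0, 10]. Topology is never searched.

Under a reversible model only the *sum* of the two root-adjacent branch
lengths is identifiable (pulley principle), so after fitting, that sum is
re-apportioned in the input topology's proportions. This is
likelihood-neutral and keeps the root split stable across bootstrap
replicates; without it the arbitrary drift of the split corrupts the ages
of root-adjacent nodes.

## Bootstrap confidence intervals

`bootstrap_dates` draws column-resampled pseudo-replicates, re-estimates
branch lengths on the fixed topology, re-dates each replicate, and
reports the empirical 2.5/97.5 percentiles of the target node's age.
The smoothing policy is configurable: reuse a given λ (default — one
cross-validated optimum is computed once, matching the usual single
reported optimum) or re-cross-validate inside every replicate
(`lam="cv"`). Replicate-level failures are logged, excluded and counted.

## The synthetic generator

`template_chronogram` ships a fixed 32-taxon land-plant-shaped
ultrametric tree (fixture file, so clades keep stable identities): root
(land-plant crown) at 475 Ma, a lycophyte clade whose quillwort-like
6-tip ingroup crown sits at a configurable age (default 50 Ma) on a
350 Myr stem from the 400 Ma split with a 4-tip *Selaginella*-like
sister, plus moss, fern, gymnosperm and angiosperm outgroups.
Birth–death simulation (via dendropy) provides random chronograms for
recovery and coverage studies.

`apply_rates` assigns each edge `base_rate × lognormal(0, σ) ×` the
product of applicable clade multipliers (crown-group edges of a taxon
set's MRCA) and stem multipliers (the subtending edge); draws are
per-edge independent — an autocorrelated mode is out of scope.
`to_phylogram` converts to branch lengths either exactly
(`b = r·t`, the deterministic expectation mode) or with Poisson noise
(`b = Poisson(r·t·L)/L`). `simulate_alignment` generates sequences under
the same GTR+G+I model the estimator fits.

### The two presets

Both presets put the ingroup crown at 50 Ma with the calibrations used
throughout: the ingroup+sister crown bounded in [358, 485] Ma and the
root in [421, 485] Ma (the template's true ages, 400 and 475 Ma, satisfy
both).

The preset multipliers are derived from the observable geometry of the
real matrices rather than fixed by hand, because the observables pin them
tightly. A 4.5× path-length contrast measured from a common ancestor
400 Myr deep, combined with a crown/stem mean-branch-length ratio of
5.8, forces the stem to be nearly substitution-free — the contrast is
carried by the dead stem, not by a uniformly fast sister. And for heavy
smoothing to date the crown *young* (the direction the real chloroplast
matrix shows), the crown must run below the tree-wide average rate.

* **chloroplast-like** (`L = 55,000`): ingroup crown at 0.38× the
  background rate — chosen so the heavy-smoothing shrinkage factor
  matches the magnitude of the published chloroplast-vs-nuclear
  discrepancy (≈24 vs ≈59 Ma) — stem multiplier derived from the 5.8
  crown/stem ratio (≈0.004), sister multiplier from the 4.5 path ratio
  (≈0.23), and per-branch lognormal dispersion σ = 0.5, making rates on
  neighbouring branches poorly correlated. Larger dispersion (σ = 0.8)
  was rejected at design time: occasional crown-rate draws then exceed
  the tree average and invert the bias direction.
* **nuclear-like** (`L = 694,000`, scalable): stem at 0.9, sister from
  the 1.25 path ratio (≈1.14), σ = 0.05, plus mild clade-level background
  multipliers (0.7–1.3 on the outgroup clades) — block-structured
  variation that weak smoothing can track, so cross-validation selects a
  small λ, as for the real nuclear matrix.

What the presets do and do not show: they reproduce the *mechanism* —
weak smoothing inflates the crown age massively and fails gradient
checks, heavy smoothing compresses it below truth with stem ρ ≪ 1,
cross-validation picks a lower optimum for the nuclear-like regime than
the chloroplast-like one and recovers the nuclear crown age to within
10%. They do not reproduce the real chloroplast matrix's absolute CV
optimum (λ = 1000): the crown/sister rate blocks that create the bias
geometry are themselves learnable by mild smoothing in leave-one-out CV,
so the synthetic chloroplast optimum sits around λ ≈ 1–3. Real
chloroplast rate variation is evidently less block-like than any
few-multiplier scenario. Passing tests on these presets therefore
validates the estimator and the diagnostic machinery, not the claim that
the generator matches every statistical property of real organellar
data.

## Numerical choices

* Duration floor 1e-6 Myr; branch lengths snapped to 0 below 2e-9.
* λ grid: `10⁻², 10⁻¹·⁵, …, 10⁶` (17 values, endpoints inclusive).
* The crown-age decline across the top of the λ grid is real but of
  magnitude 1e-2–1e-4 Ma per half-decade step; tests that assert strict
  monotonicity there run the fits at `ftol = 1e-16` with extra polish
  cycles, below which solver resolution produces spurious ties.
* Site-class ambiguity conventions: `"missing"` (default; IUPAC
  ambiguity codes and N are treated like gaps) or `"state"` (each code
  counts as a state). Published matrix summaries rarely state their
  convention, so both are provided.
* `"?"` and `"-"` are equivalent missing symbols; completeness counts
  unambiguous A/C/G/T only.
* Column subsampling is without replacement (distinct sites, original
  order); the bootstrap is with replacement at full length.
* Crown branch averaging in `crown_to_stem_length_ratio` uses all crown
  edges by default, switchable to terminal edges only.
* QQ plotting positions are Blom's `(i − 3/8)/(n + 1/4)`; results are
  insensitive to this choice for n ≥ 30.
* Gene trees are consumed rooted; trees with a basal polytomy are
  midpoint-rooted with a log note. Length ties in monospecific-clade
  pruning break by lexicographic sequence id.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at desk scale: recovery over 20 (tests) or 8 (script) replicates at
`L = 50,000`; bias studies over 20/10 replicates at `L = 55,000`;
bootstrap coverage over 10 (tests) or 12 (script) clock datasets of
6 taxa at `L = 8,000` with 40 replicates each; the orthology oracle over hundreds of random
trees of ≤ 8 leaves. The reproduction tests against the published
matrices run at full scale when the supplementary files are provided
(see README).

## Known limitations

* The PL surface at weak smoothing is genuinely ridged; reported ages
  there depend on the optimizer path, which is why gradient checks exist
  and should be consulted before trusting any low-λ estimate.
* Cross-validation refits every pruned tree at every λ
  (`O(tips × grid)` optimizations); trees beyond a few hundred tips will
  be slow.
* The substitution engine fits exchangeabilities, α and p_inv but keeps
  base frequencies empirical; no partitioned models.
* Calibrations are hard bounds — PL has no machinery for soft priors, so
  a "uniform between 358 and 485" constraint is min/max truncation.
* Rate draws are independent across edges; autocorrelated rate evolution
  is not modelled.
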