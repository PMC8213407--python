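# Methods

## Model overview

`oriturn` couples a *within-S-phase* kinetic layer to a *between-species*
birth–death process.

The kinetic layer treats single-fork stalling as a Poisson process with
per-nucleotide rate π, so the probability that the two converging forks
replicating an inter-origin region of length *l* both stall (a lethal
double stall) is `P^DS(l) = 1 − (1+πl)e^(−πl)`, the closed form of the
double integral of the single-fork stall law `P_S(x) = π e^(−πx)` over
`x + y ≤ l`. Origin firing is exponential with the origin's normalized
rate λ′ (dimensionless; rates are normalized to unit mean within a
species). Passive replication of origin *i* by neighbor *j* at distance
*d* is the race probability `λ′ⱼ/(λ′ⱼ+λ′ᵢ)·exp(−λ′ᵢ d/v)`, and
efficiency is the pairwise product `effᵢ = (1−P_left)(1−P_right)`.

The evolutionary layer changes the origin complement at rates expressed
per unit of protein-sequence divergence *t*:

| parameter | meaning | default | unit |
|---|---|---|---|
| π (`pi_stall`) | per-nucleotide fork-stall rate | 5·10⁻⁸ | bp⁻¹ |
| v | fork speed relative to normalized-rate time | 45 000 | bp per unit time |
| b̄ (`b_bar`) | genome-wide birth rate density | 13.5627 | Mbp⁻¹ t⁻¹ |
| d̄ (`d_bar`) | mean per-origin death rate | 0.612287 | t⁻¹ |
| R (`reshuffle_rate`) | per-origin rate-resampling rate | 0.92 | t⁻¹ |
| γ (`gamma`) | birth bias strength on P^DS | 2.2 | – |
| β (`beta`) | death bias strength on efficiency | 1.9 | – |
| L (`length_bp`) | genome length | 10 700 000 | bp |

b̄, d̄, R and L are the values estimated from origin turnover across the
*Lachancea* clade (terminal-branch event counts divided by `L·T` and
`n·T` respectively, averaged over branches — the same estimator
implemented in `analysis.estimate_rates`); γ and β are the best-fit
bias strengths for the joint model. Birth rates are
`bᵢ = N·b̄·(Pᵢ^DS)^γ·lᵢ` with N fixed so the genome-wide total is always
`b̄·L`; joint-model death rates are `dᵢ = N·d̄·e^(−β·effᵢ)` with the mean
fixed to d̄. Because both totals are pinned, the origin count follows an
immigration–death process with stationary mean `b̄L/d̄ ≈ 237` at the
defaults, independent of the biases; the biases decide *where* events
fall, not how many occur. Newborns are placed at the floored midpoint
of their region and draw a rate from the same pool used for
reshuffling (the only rate distribution the model introduces).

The fork speed v deserves emphasis: only the combination `λ′·d/v`
enters the kinetics, and with rates normalized to unit mean there is no
way to recover the absolute scale from published quantities. The
default, 45 kbp per unit normalized-rate time, is of the order of the
mean inter-origin spacing, making typical exponents O(1). Every
quantity built on efficiencies — the efficiency histogram, the death
bias, the strength of the post-loss "interference release" of a lost
origin's neighbors — shifts with this choice.

## Numerical scheme

Time advances by a tau-leap sweep: per-region birth probabilities
`bᵢ·dt`, per-origin death probabilities `dᵢ·dt` and reshuffle
probabilities `R·dt` are all evaluated on the frozen start-of-step
configuration, sampled independently, and applied together at the step
end. Newborns cannot die or reshuffle in their birth step; ordering
artifacts vanish as dt → 0. The step size is chosen adaptively each
sweep as the largest value keeping every single-event probability at or
below a cap (0.05 by default), so dt shrinks automatically while the
rate landscape is rugged (e.g. during relaxation from a random initial
layout, when one long region can carry most of the birth weight) and
recovers afterwards. Halving the cap leaves the stationary count and
distance histogram within Monte-Carlo noise (tested).

Numerical details worth knowing:

* `1 − (1+x)e^(−x)` is evaluated by a series for `x < 10⁻⁴`; the naive
  expression loses ~10 significant digits at typical spacings.
* Midpoints are floored to integer bp; if a midpoint is occupied (only
  possible in toy genomes) the position shifts by +1 until free.
* Death is suppressed (one origin spared, with a logged warning) if a
  step would empty the genome; at the default rates this never fires.
* A configuration's identifier high-water mark travels with it, and the
  tree simulator serializes branch runs so identifiers are unique
  across the whole phylogeny — family membership is exact id matching.
* All randomness flows through a caller-supplied `numpy` Generator;
  identical seeds give bit-identical snapshots and event logs.

The pairwise-product efficiency is an approximation in two ways: it
ignores origins beyond the two nearest, and it treats the two neighbor
races as independent although both are resolved by the same firing time
of the focal origin. Against a full stochastic S-phase simulation it is
accurate when each origin has at most one serious competitor and can be
off by ~0.05–0.1 under symmetric crowding (both directions occur; see
the kinetics tests). The evolutionary model uses the closed form
throughout, as the model definition, not as an estimate.

## Synthetic firing-rate pool

The model resamples rates from "the empirical normalized-rate pool",
which cannot be shipped here. The stand-in
(`io.synthetic_rate_distribution`) is a unit-mean lognormal with log-sd
0.6 (a gamma family and empirical resampling from an origin table are
also available), giving a broad right-skewed distribution and, through
the kinetics, a broad efficiency distribution (median ≈ 0.63,
10–90 range ≈ 0.29–0.91 at stationarity). What the synthetic pool does
*not* emulate: possible heavy mass of near-zero rates, within-species
structure, and any rate–position correlation of the real data. Tests
passing under the stand-in validate the machinery and the qualitative
selection effects, not quantitative agreement with empirical rate data.

Two stationary features turn out to be sensitive to the pool and to v,
and are therefore reported by the code as computed rather than matched
to published values: the time-averaged origin count lands ~5% above the
published ≈225 (at the balance value b̄L/d̄ ≈ 237), and the stationary
inter-origin-distance histogram (5-kbp bins) peaks at 42.5 kbp for the
joint model at full genome length — above the ≈35 kbp peak of the
empirical and published-simulation histograms. The peak location is
insensitive to the tau-leap cap and to moderate changes of pool spread
or v, but moves with genome length (the heavy-tailed birth weights are
normalized globally, so allocation to a region of given length depends
on the whole-genome length spectrum) and with β. On the reduced 2-Mbp
test genome the same model peaks near 27–37 kbp.

## Tree protocol and event classification

A root genome is produced by a burned-in single-lineage run (default
burn-in 20/d̄ ≈ 33 t, i.e. twenty relaxation times of the count
process; convergence is also visible as agreement of first- and
second-half means). Each branch continues its parent-node genome for
the branch length; at nodes the genome is copied to both children. The
bundled nine-leaf Newick tree reproduces the *Lachancea* clade's
topology shape — three shallow sister pairs and a ladder of deeper
splits — with synthetic branch lengths (mean terminal branch 0.15 t);
the empirical lengths are not distributed with the package.

Per branch, origins are classified by comparing endpoint genomes:
conserved (alive at both ends), lost (alive at the start only; position
and rate taken from the parent genome), gained (born in-branch and
alive at the end). Origins born and dying within a branch are
unobservable in endpoint comparisons and belong to no class, matching
what comparative data can see. For neighbor statistics, the nearest
origin of a lost origin is found among the parent's origins; for
conserved and gained origins the search space is the branch's full
observable set — branch-end origins plus lost origins at their
ancestral positions — mirroring the projection of lost origins onto
extant genomes in the empirical procedure. Each origin's efficiency is
evaluated in the genome where its class is observed; a conserved
neighbor of a lost origin is therefore measured *after* the loss, so it
includes the interference-release boost. That convention makes even the
unbiased-death variant show a small positive lost-vs-neighbor gap
(≈0.05 at v = 45 000, versus ≈0.15 for the joint model); the contrast
between variants, not the raw gap, is the discriminating signal.

Consecutive snapshots of a single lineage (interval 0.15 t, the mean
terminal branch length) are classified with exactly the same machinery
and serve as cheap pseudo-branches for statistics that do not need tree
structure.

The null model for divergence comparisons applies prescribed per-branch
event counts uniformly: the prescribed deaths first (uniform over
origins), then the prescribed births (uniform positions, fresh ids).
Matching its per-branch counts to a paired model run isolates the
effect of *where* events fall from *how many* there are.

## Fitting and model comparison

The bias strengths are fitted by grid search against target histograms:
inter-origin distances (5-kbp bins on [0, 200 kbp]) select γ and
efficiencies (0.05 bins on [0, 1]) select β, each by minimizing the
mean-over-runs L1 distance (bounded by 0 and 2), ties breaking toward
the smaller parameter. Bin widths are recorded in the run config; they
are of the order of the resolution of the corresponding empirical
histograms. The default sweep is one round of coordinate descent (γ at
the central β, then β at the chosen γ), exploiting the distance
histogram's near-independence from the death bias; a full cartesian
sweep is available. A practical warning from the package's own
self-consistency experiments: with ~10 simulations per grid point the
efficiency histogram's sampling noise exceeds the β signal of a 0.2
grid step, so β recovery at that resolution needs run counts of the
order of 100 per point.

The simplified likelihood-ratio test scores four marginals — efficiency
and firing rate of lost origins and of their nearest neighbors —
against Laplace-smoothed histogram densities estimated from reference
simulations of each variant, treating the marginals as independent
("partial" likelihood). `Lr = 2(l_joint − l_DS)` is referred to a
chi-squared law with one degree of freedom (β is the single extra
parameter of the joint model). With β = 0 the joint model *is* the
reference, so `Lr` is centered at zero by construction when both
references come from the same variant (tested). No multiple-testing
correction is applied: one planned test, plus descriptive summaries.

## Design choices on genuinely open points

* **Stepping.** The dynamics is described as both a discrete-time chain
  and an event-driven algorithm in the source material; the
  implementation commits to the frozen-rate sweep with a per-event
  probability cap because it matches the "compute all probabilities,
  then sample every region/origin" structure and is convergence-testable
  by shrinking the cap.
* **Newborn rates** come from the reshuffling pool — the only
  distribution the model defines; no neighbor correlation is imposed.
* **"Lost in a pair"** for shared-loss divergence counts an MRCA origin
  absent from *at least one* of the two leaves.
* **Root size for the null model** defaults to 220 origins at full
  scale (the inferred root-species count); paired comparisons instead
  use the matched model run's root count.
* **Extinction guard** exists for robustness in toy settings only.

## Reduced problem sizes

The test suite exercises the full dynamics mostly on a 2-Mbp genome
(stationary count ≈ 44) with the per-origin and per-Mbp rates
unchanged, sampling windows of 25–60 t, and 10–30 replicate runs;
stationary-state checks run at the full 10.7-Mbp defaults with a 33-t
burn-in and 50-t averaging window. These sizes are the package's chosen
test conditions; per-origin dynamics are scale-free, but globally
normalized quantities (notably the spacing distribution, see above) do
depend on genome length, which is why headline stationary numbers are
quoted at full scale.

## Known limitations

* Firing-rate evolution is pure reshuffling; gradual (diffusive) rate
  change is out of scope, as are non-midpoint placement rules,
  rearrangements, speciation dynamics, and synteny-based orthology
  inference (lineage identity is exact by construction).
* Linear genomes are supported in the kinetics and distance machinery
  (chromosome ends contribute no passive replication and no birth
  regions), but the evolutionary defaults assume the circular genome.
* The absolute fork-speed scale v and the empirical rate pool are
  irreducible unknowns here; quantities downstream of efficiency are
  conditional on their defaults.
* The likelihood is "partial" (independent marginals, histogram
  densities); its absolute p-values should be read qualitatively.
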