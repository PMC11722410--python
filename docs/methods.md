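# Methods

## The group-structured model

A population consists of up to `Kg` groups, each holding `K` sites shared
between social individuals (A, "cooperators"), asocial individuals (B,
"cheaters") and unconsumed resources.  Time is discrete; within one step,
three things can happen, in this order:

1. **Within-group reproduction** (every group in parallel).  A group with
   `nA` cooperators and `nB` cheaters gains one A with probability
   `(nA/K)(1 − n/K)`, one B with probability `b (nB/K)(1 − n/K)`
   (`n = nA + nB`), or stays unchanged.  The scale factor `b ≥ 1` is the
   cheater's frequency-independent reproductive advantage.  The two birth
   probabilities sum to at most 1 for every state exactly when `b ≤ 4` (the
   sum peaks at `nA = 0, nB = K/2`), hence `b ∈ [1, 4]`.  There is no
   individual death.
2. **Splitting.**  If at least one group has filled its `K` sites and the
   population is below `Kg`, exactly one such group (uniformly chosen)
   splits.  Each daughter receives `mA ~ U{0..nA}` A's and, independently,
   `mB ~ U{0..nB}` B's (the complement goes to the other daughter).  An
   empty daughter is discarded immediately — an *abortive* split that leaves
   the parent intact and still eligible.  Under the independent-uniform
   draw the abortive probability of a mixed parent is
   `1/((nA+1)(nB+1))` per empty-daughter case (e.g. `2/(K+1)` for a
   single-type parent).
3. **Group death.**  At most one group dies per step, drawn from a single
   categorical distribution.  Three weighting modes over the cooperator
   fractions `f_j`:
   * `neutral` — `μ/Ng` each; total death probability exactly `μ`.
   * `relative` — weights `1 − a f_j` normalised across groups and scaled
     by `μ`; cooperators are protected only *relative to the others*, and
     the total stays exactly `μ` whatever the composition.  If every weight
     vanishes (all-cooperator population at `a = 1`) the weights are 0/0;
     we fall back to the uniform `μ/Ng` split, which preserves the
     conservation property.
   * `absolute` — `(μ/Ng)(1 − a f_j)` per group; cooperators lower the
     total death probability itself (sum ≤ μ).

   `a ∈ [0, 1]` is the social trait strength.

The default event order (reproduction → split → death) exposes a freshly
split pair to the death draw in the same step; the alternative
(death first, on the previous step's composition) is available as
`SimConfig.death_first` for sensitivity analysis.  Results in the package's
experiments are insensitive to this choice at the parameter scales used.

Initial conditions: `neutral_uniform` (single-type groups, sizes uniform on
{1..K−1} — size K would split at t = 0 and size 0 is not a group),
`homogeneous_mix` (pure-A and pure-B groups with the same size rule),
`heterogeneous` (`nA, nB ~ U{0..⌊K/2⌋}` independently, (0,0) resampled), and
`homogeneous_at_threshold` (pure groups of size exactly K — the rare-death
limit's initial condition).

## Analytical companion

A single group of size `n` with per-step survival probability `δ` performs a
pure-birth walk on `[0, K]`; the probability of reaching `K` before being
eliminated has the product form

    ψ_n = ∏_{l=n}^{K−1} δ b T_l / (1 − δ + δ b T_l),   T_l = (l/K)(1 − l/K).

The proliferation criterion for a population is `⟨ψ⟩ > 1/2` with
`⟨ψ⟩ = mean(ψ_1..ψ_{K−1})`: on average more than one of a split's two
daughters must itself reach the threshold.  Near `δ = 1`,

    ⟨ψ⟩ ≈ 1 − (1 − δ) H_{K−1} K² / (b (K−1)),

(`H` a harmonic number, computed by direct summation), which yields closed
forms for the critical death probability `μ* = Ng·b(K−1)/(2 H_{K−1} K²)`, the
critical group number, and the competition thresholds `a*`, `b*(a)` for both
fitness modes (via the homogeneous-population survival probabilities
`δ_A, δ_B`).

**The linearised thresholds are bounds, not 2%-approximations.**  The
`⟨ψ⟩ = 1/2` crossing sits at `(1−δ)H_{K−1}K²/(b(K−1)) = 1/2`, which is
outside the linear regime by construction; the exact root (found by
bracketed `brentq` on the product form, tolerance 1e−8) lies ≈30–40% higher
in `μ` for every K we checked.  The two curves *bracket* the simulated
transition — exactly how the package's survival maps (and the phase-diagram
acceptance checks) use them.  Within the linear window
(`1−δ ≲ 10⁻³(K−1)/(K²H_{K−1})`) the expansion is 1%-accurate, and
numerically inverting the linearised criterion reproduces the closed forms
to well under 2% — those are the two accuracy statements the test suite
asserts.  Out-of-range thresholds (`a* ∉ [0,1]`, `b* ∉ [1,4]`, `μ* > 1`) are
flagged or raised, never clipped.

In the rare-death limit (`μ ≪ 1`, population at `Kg`, all groups at the
threshold) the competition reduces to a birth–death chain over the number of
all-A groups whose down/up transition ratio is `1 − a` in both fitness
modes, giving the fixation probability
`φ = (1 − (1−a)^i) / (1 − (1−a)^{Kg})`.

## Engines, randomness, reproducibility

The reference `simulator.step` composes the operation-level functions with a
`numpy.random.Generator`.  Replicate campaigns use a numba kernel
(`_core.run_lattice`) implementing the identical draw scheme — one uniform
per below-threshold group, one split draw, one categorical death draw — with
numba's own RNG; the suite checks the two engines are statistically
indistinguishable (two-sample KS on terminal group counts).  Per-replicate
and per-sweep-cell seeds derive from the root seed via
`numpy.random.SeedSequence` spawn keys, so every experiment is bit-for-bit
reproducible from its manifest and kernel seeds stay below 2³¹.

Problem sizes in the shipped tests: the survival, competition and scenario
experiments use scaled grids (7×7 cells, M = 10–20 replicates, T = 3000–5000)
chosen to resolve the regime topology; the rare-death fixation check uses
μ = 0.001, Kg = 30, 500 replicates started at carrying capacity.

## Biofilm model

Cells live in continuous 3D above a square substrate of `grid_n²` anchor
points spaced `D` apart (400 anchors for the full 500-cell capacity).  The
pair pseudo-force is `H/d⁶ − Ḡ/d²` along the separation axis (`Ḡ` the mean
of the two cells' attraction constants); the baseline constant satisfies
zero net force for an asocial pair at spacing `D` (`G = H/D⁴`).
Extracellular-matrix producers (social) have `100 G` and divide 5-fold
slower — the social trait is a stronger glue paid for in growth rate.
Anchors attract with constant `G/2` (baseline `G` for all phenotypes; using
the cell's own constant is a config switch, off by default, since matrix
production is modelled as modifying cell–cell adhesion).  Per step each cell
moves a fixed distance `D` along `normalize((1−F)·u_force + F·u_rand)`
(`F = 0.5`; `u_rand` uniform on the sphere; pure force descent when
randomisation is off), with a reflective substrate boundary and a 1e−6·D
uniqueness jitter.  Division is Poisson per phenotype with mean
`n_ph · r_ph (1 − N/K_BF) dt` (`r_asocial = ln 2`, `dt = 0.01`; daughters
placed within ±0.05·D of the parent).  The predation interface is the
topmost cell of every occupied `D`-sized window; removal is Poisson with
mean `m·L·dt` (`L = 0.1`), uniform over the interface.

Free numerical choices: initial colony cells occupy a central square of 5%
of the substrate side with heights uniform in `[0, D/2]` (a thin random
pad that breaks the vertical symmetry of a perfectly planar start); division
jitter ±0.05·D is small enough that daughters are immediately pushed apart
by the `1/d⁶` core.  Reduced-capacity test colonies rescale the substrate by
the footprint rule (grid side ≈ twice the colony footprint): 16×16 anchors
at `K_BF = 150`, 12×12 at `K_BF = 60`.

Protocols: *steady state* (relaxation for 1000 steps with force descent
only, then full dynamics), *seeding* (single founder; success when the
population exceeds 300), *fixation* (one cell of an asocial steady-state
colony relabelled social; run to homogenisation).  The neutral-control
variant relabels without changing attraction or division rate, so fixation
must occur at the lineage-neutral rate ≈ 1/N.

### What the model reproduces, and a known limitation

At matched parameters, homogeneous producer and non-producer colonies reach
the same steady-state size; producers keep a significantly smaller fraction
of their cells in the predation interface (the group-level protection
mechanism); and seeding success is ≈4-fold higher for non-producers (slow
early division loses the race against founder predation).  A single producer
mutant buries itself inside the colony (its long-range attraction points
toward the local cluster), cutting its per-capita death far below average
while its birth rate is only 5-fold reduced — the ingredients of
high-probability fixation.

The strength of that protection scales with colony depth.  At the full
500-cell capacity the measured mutant interface exposure is ≈3% of the
population average and the mutant lineage reliably establishes, growing
from one cell to several dozen.  Its expansion is self-limiting, however:
as the social cluster grows it forms its own mound whose surface cells
enter the predation interface, and in recorded 1.5-million-step runs the
lineage plateaus near 10% of the colony instead of sweeping to fixation.
In 150-cell colonies (only ~4 cells deep, mutant exposure ≈12–19% of
average) the lineage is barely supercritical and dies out.  Whole-colony
producer fixation is therefore *not* a reliable outcome of this
implementation at the tested scales and step budgets; the corresponding
acceptance check documents this honestly rather than passing.  What the
tests do establish is the protection mechanism itself (exposure
asymmetry), establishment and persistence of the producer lineage at full
scale, the seeding disadvantage, and neutral-control calibration.

## What the synthetic data does and does not show

All inputs are generated internally from parameter configurations; there is
no external data.  Passing tests therefore demonstrate internal consistency
of the stochastic processes with their analytic descriptions (absorption
probabilities, conservation laws, fixation laws, phase-diagram topology),
not agreement with any empirical biofilm or population measurement.  The
biofilm component in particular is a caricature — logistic growth, pseudo-
forces, predation only from above — intended to show that the group-model
phenomena survive in a spatial, individual-based setting, not to model any
specific organism quantitatively.
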