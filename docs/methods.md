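# Methods

## Model

`worldviews` treats the space of ideas as a chemical reaction network.  A
network is a species set *M* and reactions
`r_i : c_i1 s_1 + … + c_in s_n → p_i1 s_1 + … + p_in s_n`
with non-negative integer coefficients; the stoichiometric matrix
`S[j,i] = p_ij − c_ij` records net production, and a non-negative process
vector **v** (how often each reaction fires along a pathway) yields the
pathway's net production `S·v`.

A species set *X* triggers the reactions whose reactant support lies in *X*
(`R_X`).  *X* is **closed** when triggered reactions produce nothing outside
*X*, and **self-maintaining** when some process vector, strictly positive on
all of `R_X`, gives `(S·v)_j ≥ 0` for every member *j*.  An **organization**
is a set that is both — a sub-network that creates nothing new and can keep
all of its members from decaying.  In the worldview reading, species are
belief attitudes and belief-change triggers, and organizations are the
candidate stable worldviews; dynamical attractors of the mass-action system
project onto them.

Dynamics follow mass action: `ds/dt = S·v(s)` with
`v_i = k_i · Π_j s_j^{c_ij}`.  Time is in model days; all bundled rate
constants are per-day.  A state is linked back to structure by its
ε-abstraction Ω(s): the species whose concentration exceeds a class-dependent
threshold (below).

### Single-theme model

Five species: zero-sum belief attitudes S, U, D (satisfaction,
uncomfortability, discontent; S+U+D is conserved) and free belief-change
triggers s ("this is a solution") and p ("this is a problem"), which decay
quadratically and are replenished by feedback or external input.  The ten
reactions, with defaults:

| family | reactions | rate |
|---|---|---|
| spontaneous relaxation | D→U, U→S | k0 = k1 = 0.1 |
| trigger reproduction | S+s→S+2s; D+p→D+2p | k2 = 0.2, k3 = 0.3 |
| induced attitude shift | S+p→U+p, U+p→D+p, D+s→U+s, U+s→S+s | k4..k7 = 0.3 |
| trigger decay (forgetting) | 2p→p, 2s→s | k8 = k9 = 0.15 |

k3 > k2 encodes the asymmetry that discontent reproduces problem perceptions
faster than satisfaction reproduces solution perceptions (violating it only
warns).  k8, k9 are the "memory" of triggers: smaller constants mean slower
forgetting.  The reactive organizations are the satisfaction pair {s,S}, the
discontent worldview {p,S,U,D} and their join {s,p,S,D,U}.

### Two-theme model

Forty species: 36 compound beliefs — one attitude bonded with one trigger per
theme, named theme-1 pair then theme-2 pair (`Sp1Us2` = satisfied about
theme 1 while perceiving a problem, uncomfortable about theme 2 with a
solution perception) — plus free triggers s1, p1, s2, p2.  Reaction families
apply the single-theme rules per theme slot (relaxation, catalysis by
matching (S,s_i)/(D,p_i) slots, trigger-induced attitude shifts, decay), with
the single-theme rates reused per theme, plus two bond-level families:

* **bond swap** — a free trigger induces replacement of the opposite bonded
  trigger of its theme and the displaced trigger is released,
  `X(A,s_i) + p_i → X(A,p_i) + p_i + s_i` (and conversely), at rate 0.3.
  The inducing trigger acts catalytically: triggers are informational and are
  not consumed by inducing change, exactly as in the attitude-shift family.
  Releasing the displaced trigger matters structurally: if it stays bound, a
  38/39-species closed self-maintaining set (everything except one free
  solution trigger) appears and the organization structure is wrong; if the
  inducing trigger is instead consumed, free problem triggers acquire a fast
  linear sink and external input can never destabilise satisfaction.
* **satisfied-bond relaxation** — `(S,p_i) → (S,s_i)` spontaneously at 0.1.
  Without it a theme-local discontent organization lacking the free solution
  trigger appears; with it, every organization keeps s1 or s2 active.

Both families are toggleable on the spec object but the defaults are frozen:
`validate_two_theme` checks the generated network's reactive organizations —
full member sets, reactive trigger sets and sizes — against the published
eight (sizes 2, 2, 3, 8, 8, 9, 9, 40).  Organization structure depends only
on stoichiometry, never on rates, so this validation pins down the reaction
set itself.  The builder skips validation by default (it costs a full
enumeration, ~0.5 s); the test suite and the acceptance script always run it.

## Self-maintenance and enumeration

Strict positivity `v_i > 0` is encoded as `v_i ≥ 1`; the feasible region is a
cone, so this loses no generality.  Feasibility is decided with HiGHS
(`scipy.optimize.linprog`); the non-negativity constraints allow a violation
of at most 1e−9, and witnesses are clamped to their lower bound (a ≤1e−9
shift) so certificates satisfy their stated invariants exactly.
Self-maintenance is only evaluated on closed sets (organizations pair the two
conditions); a closure-then-test convenience wrapper is provided.

Enumeration is exhaustive for networks of ≤20 species: the complete
closed-set lattice is generated breadth-first from closure(∅) by adding one
species at a time and re-closing (complete because closure is monotone), and
every closed set is LP-tested.  Larger networks use a constructive join
search: closures of all singletons are seeds; discovered self-maintaining
closed sets are joined pairwise with the seeds and each other, closing and
testing each join, until fixpoint.  The join search can in principle miss
organizations that are not joins of singleton closures; it reproduces the
exhaustive result on the single-theme network and the published table on the
two-theme network, which is the intended domain.  Organizations triggering no
reaction at all (the empty set, inert singletons such as {S}) are excluded by
default — matching the published organization lists — and exposed with
`reactive_only=False`.

## ε-abstraction thresholds

`EpsilonRule` computes per-class thresholds at every evaluated state:
trigger-tagged species use `trigger_fraction` (default 0.10) of the current
free-trigger total; all other species (attitudes, compounds) use
`attitude_fraction` (default 0.10) of their class total.  Since the attitude
total of the bundled models is conserved at 1, the default attitude threshold
is effectively the absolute 0.1; fixed absolute overrides are available for
both classes.

With `per_species=True` the fractions apply to the class *mean* rather than
the class total.  This is the appropriate scale for the two-theme model,
whose conserved unit of belief mass is spread over 36 compounds: under the
class-total rule at most ⌊1/0.1⌋ = 9 compounds can ever clear the threshold
simultaneously, so "all species salient" is unreachable by arithmetic alone,
while the per-species rule asks each compound to exceed 10% of the uniform
share (1/360).  The single-theme experiments use the class-total default;
the two-theme trace experiment uses `per_species=True`.

## Integration and events

`solve_ivp` with LSODA, rtol 1e−8 / atol 1e−10 (the dynamics mix fast
catalytic and slow decay terms; LSODA switches stiffness regimes as needed).
States are reported on a uniform grid of one point per day; reported
concentrations are clipped at zero, and the most negative pre-clip value is
retained on the trajectory (round-off scale, ≥ −1e−9, in a healthy run).
Perturbation events split the integration: the named species is incremented
by the event amount and the run continues; a grid point coinciding with an
event shows the post-event state.  Events with amount exactly zero are
dropped, so a zero-amplitude schedule is bit-identical to the unperturbed
run.

Perturbation schedules draw waiting times from Normal(mean, sd) truncated
below at 0.1 day (negative draws would otherwise occur at sd = 3.5), amounts
uniform on [0, amount_max], and one target species uniformly per event.  The
"discontent" stop rule (D > 2·S) is evaluated on the reporting grid, not
inside integrator micro-steps; once it first holds, all later events are
cancelled.  All draws come from one seeded `numpy` Generator, so every
protocol output is bit-reproducible under its seed.

## Experiment defaults and problem sizes

* Initial-condition survey: attitudes uniform on the 2-simplex, p0 uniform on
  [0,1], s0 = 1−p0; horizon 500 days with a convergence guard (abstraction
  constant over the final 50 days; failing runs are reported separately, not
  classified).  The survey and memory-sweep tests use n = 200 conditions per
  (k, seed) over k8 = k9 ∈ {0.15, 0.10, 0.05} and three seeds.
* Discontent-transition protocol: weekly problem input (mean 7 d, sd 1 d,
  amounts ≤ 0.25) from the satisfaction instance, 3000-day horizon, stop rule
  D > 2S, 20 seeds.  Transitions are rare threshold crossings; a few of the
  20 seeds cross.
* Two-theme trace: input on p1/p2 (mean 7 d, sd 3.5 d, amounts ≤ 0.3), 300
  events over 2500 days, starting from the level-1 instance of
  {Ss1Ss2, s1, s2}, per-species ε rule.

## Numerical and degenerate-input choices

* Species order is declaration/first-appearance order and fixes all vector
  and matrix layouts; organization reports order by size, then lexicographic
  member list; Hasse edges are the covering relations of inclusion, sorted.
* The empty reaction side is an empty coefficient map; reactant-free
  reactions are triggered by every set, including ∅.  ∅ is closed and
  vacuously self-maintaining; it is reported only with
  `reactive_only=False`.
* The set distance d(X1,X2) = |XΔY|/|X∪Y| is defined as 0 when both sets are
  empty.
* `classify_abstraction` assigns a state's abstraction to the nearest
  organization by d, ties broken toward the smaller organization.  End states
  in the discontent basin typically have abstraction {p,D,U} or {p,D} (S and
  U can sit below the 10% threshold at the fixed point); their *closure* is
  exactly the discontent organization, which is how survey tests identify the
  basin.

## What the generators emulate — and what they do not

The bundled networks are idealisations: belief mass is exactly conserved,
interactions are well-mixed mass action, rate constants are uniform across
themes, and the two themes do not interact (no cross-theme trigger
catalysis).  Real opinion data have none of these symmetries — heterogeneous
agents, network structure, non-stationary input.  Passing tests therefore
demonstrate the internal consistency of the framework (structure–dynamics
correspondence, irreversibility of induced transitions, memory dependence of
basin sizes), not fidelity to any empirical opinion dataset.

## Known limitations

* The constructive organization enumeration is not complete in general
  (documented above); distributed organizations and structurally changing
  networks are out of scope.
* Stochastic (Gillespie) kinetics are not implemented; perturbations are the
  only source of randomness.
* The stop rule's grid evaluation can lag the true first crossing by up to
  one reporting day.
* Figure-level quantities of the source studies (exact visited-abstraction
  counts, trace geometry) are seed-dependent; the package checks their orders
  of magnitude and qualitative structure only.
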